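"""Hard-filter expressions and ploidy-informed DP / AN / QD threshold sweeps.

The hard-filter set is the standard autosomal recommendation: a site is
labeled with each filter whose inequality it satisfies, exactly as written
(strict comparisons); missing annotations never fail a filter. The DP band
filter retains sites whose total depth lies within [lo, hi] x mean DP, where
the mean is derived either from diploid chromosomes (autosomes) or from the
haploid X/Y non-PARs of XY samples — the contrast whose stringency mismatch
costs true positives on haploid chromosomes. The AN filter retains sites with
at least ``k`` successfully genotyped allele copies; with n haploid-called
samples AN can never reach 2n, so a diploid-based threshold empties haploid
regions by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import pandas as pd

from .caller import SiteCall
from .genome_sim import GenomeArchitecture

#: (label, annotation, direction, threshold): fail iff value <dir> threshold
HardFilter = tuple[str, str, str, float]

DEFAULT_QD_SWEEP = (1.0, 1.5, 2.0, 12.0, 16.0, 20.0, 28.0)
DEFAULT_AN_SWEEP = (20, 15, 10, 5, 4, 3, 2, 1)


@dataclass(frozen=True)
class FilterConfig:
    qd_min: float = 2.0
    qual_min: float = 30.0
    sor_max: float = 3.0
    fs_max: float = 60.0
    mq_min: float = 40.0
    mq_rank_sum_min: float = -12.5
    read_pos_rank_sum_min: float = -8.0
    dp_band: tuple[float, float] = (0.5, 1.5)
    an_sweep: tuple[int, ...] = DEFAULT_AN_SWEEP
    qd_sweep: tuple[float, ...] = DEFAULT_QD_SWEEP

    def __post_init__(self) -> None:
        lo, hi = self.dp_band
        if not lo < hi:
            raise ValueError("DP band requires lo < hi")

    def hard_filters(self) -> list[HardFilter]:
        return [
            ("QD2", "QD", "<", self.qd_min),
            ("QUAL30", "QUAL", "<", self.qual_min),
            ("SOR3", "SOR", ">", self.sor_max),
            ("FS60", "FS", ">", self.fs_max),
            ("MQ40", "MQ", "<", self.mq_min),
            ("MQRankSum-12.5", "MQRankSum", "<", self.mq_rank_sum_min),
            ("ReadPosRankSum-8", "ReadPosRankSum", "<", self.read_pos_rank_sum_min),
        ]


def apply_hard_filters(
    sites: Sequence[SiteCall], cfg: FilterConfig = FilterConfig()
) -> list[SiteCall]:
    """Label each site PASS or with every hard filter it fails (in place).

    Comparisons are strict, so e.g. MQ exactly 40.0 passes the MQ filter.
    Filter composition is conjunctive and order-independent: all failed
    filter names are recorded.
    """
    for site in sites:
        failed = []
        for label, ann, direction, threshold in cfg.hard_filters():
            value = site.qual if ann == "QUAL" else site.info.get(ann)
            if value is None:
                continue  # missing annotation does not fail the filter
            if (direction == "<" and value < threshold) or (
                direction == ">" and value > threshold
            ):
                failed.append(label)
        site.filters = failed
    return list(sites)


def pass_sites(sites: Iterable[SiteCall]) -> list[SiteCall]:
    return [s for s in sites if s.is_pass]


def mean_dp(sites: Iterable[SiteCall], selector: Callable[[SiteCall], bool] | None = None) -> float:
    """Mean site DP over (a selection of) emitted variant sites."""
    vals = [s.info["DP"] for s in sites if "DP" in s.info and (selector is None or selector(s))]
    if not vals:
        raise ValueError("no sites with DP available for the requested mean")
    return float(sum(vals) / len(vals))


def diploid_mean_dp(sites: Iterable[SiteCall]) -> float:
    """'Diploid-based' mean DP source: emitted sites on the autosome."""
    return mean_dp(sites, lambda s: s.chrom == "A")


def haploid_mean_dp(sites: Iterable[SiteCall], arch: GenomeArchitecture) -> float:
    """'Haploid-based' mean DP source: X and Y non-PAR sites (XY samples)."""

    def sel(s: SiteCall) -> bool:
        if s.chrom not in ("X", "Y"):
            return False
        return arch.class_at(s.chrom, s.pos - 1) not in ("PAR1", "PAR2")

    return mean_dp(sites, sel)


def dp_band_filter(
    sites: Iterable[SiteCall], mean: float, lo: float = 0.5, hi: float = 1.5
) -> list[SiteCall]:
    """Retain sites whose DP falls between lo and hi times the mean (inclusive)."""
    if mean <= 0:
        raise ValueError("mean DP must be positive")
    return [s for s in sites if lo * mean <= s.info.get("DP", float("nan")) <= hi * mean]


def an_filter(sites: Iterable[SiteCall], k: int) -> list[SiteCall]:
    """Retain sites with at least ``k`` successfully genotyped allele copies."""
    return [s for s in sites if s.info.get("AN", 0) >= k]


def qd_filter(sites: Iterable[SiteCall], threshold: float) -> list[SiteCall]:
    """Retain sites with QD at or above the threshold (missing QD removed)."""
    return [s for s in sites if s.info.get("QD", float("-inf")) >= threshold]


def threshold_sweep(
    sites: Sequence[SiteCall],
    labels: pd.DataFrame,
    dimension: str,
    values: Sequence,
    arch: GenomeArchitecture,
) -> pd.DataFrame:
    """Retained TP/FP counts per threshold and region class.

    ``labels`` is the per-sample benchmark classification of the *unfiltered*
    call set (from :mod:`sexchrom_varbench.bench`); a TP/FP label is retained
    at a threshold iff its site survives the corresponding filter. For the
    DP dimension, values are (mean_dp, lo, hi) band specifications and the
    reported threshold is the mean.
    """
    from .bench import region_class_column

    if dimension not in ("QD", "AN", "DP"):
        raise ValueError(f"unknown sweep dimension {dimension!r}")
    lab = labels[labels["label"].isin(["TP", "FP"])].copy()
    lab["region"] = region_class_column(lab, arch)
    rows = []
    for value in values:
        if dimension == "QD":
            kept = qd_filter(sites, float(value))
            shown = value
        elif dimension == "AN":
            kept = an_filter(sites, int(value))
            shown = value
        else:
            mean, lo, hi = value
            kept = dp_band_filter(sites, mean, lo, hi)
            shown = mean
        kept_keys = {(s.chrom, s.pos) for s in kept}
        mask = [
            (c, p) in kept_keys for c, p in zip(lab["chrom"], lab["pos"])
        ]
        sub = lab[mask]
        for (chrom, region), grp in sub.groupby(["chrom", "region"], sort=True):
            counts = grp["label"].value_counts()
            rows.append(
                (dimension, shown, chrom, region, int(counts.get("TP", 0)), int(counts.get("FP", 0)))
            )
    return pd.DataFrame(
        rows, columns=["dimension", "threshold", "chrom", "region", "TP", "FP"]
    )
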