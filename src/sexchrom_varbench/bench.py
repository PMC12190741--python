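"""Golden-truth benchmarking and the factorial strategy experiment.

Scoring follows the study definitions exactly: a true positive (TP) is a SNP
both called and simulated with matching ref and alt alleles; a false
positive (FP) is called but not simulated; a false negative (FN) is
simulated but not called. A called site whose alt allele mismatches the
simulated one is scored as one FP plus one FN (a declared convention,
flagged in the labels so it can be audited). Genotype concordance is not
scored — the definitions are site/allele-level.

Counts are stratified per sample by region class (PARs, XTR, ampliconic,
non-PAR remainder) and by fixed windows (50 kb by default), with proportions
taken against the per-sample simulated totals. :func:`run_experiment`
executes the full strategy factorial — reference kind x ploidy mode — and
emits the per-cell tables plus headline summary metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import dna, filters, mapsim, read_sim, refprep
from .caller import CallerParams, PloidyMap, SiteCall, joint_genotype
from .filters import FilterConfig, an_filter, apply_hard_filters
from .genome_sim import (
    CohortConfig,
    GenomeArchitecture,
    ReferencePair,
    SampleTruth,
    default_architecture,
    simulate_cohort,
    simulate_reference_pair,
)
from .read_sim import CoveragePolicy, ReadParams, TrimConfig

#: region classes as reported (PAR1/PAR2 merged)
REPORT_CLASSES = ("PAR", "XTR", "AMP", "NONPAR")

LABEL_COLUMNS = ["sample", "chrom", "pos", "label", "ref", "alt", "note"]


def _report_class(arch: GenomeArchitecture, chrom: str, pos1: int) -> str:
    cls = arch.class_at(chrom, pos1 - 1)
    return "PAR" if cls in ("PAR1", "PAR2") else cls


def region_class_column(labels: pd.DataFrame, arch: GenomeArchitecture) -> pd.Series:
    return pd.Series(
        [_report_class(arch, c, p) for c, p in zip(labels["chrom"], labels["pos"])],
        index=labels.index,
        dtype="object",
    )


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def golden_sites_by_sample(
    samples: Sequence[SampleTruth], arch: GenomeArchitecture
) -> dict[str, dict[tuple[str, int], tuple[str, str]]]:
    """Per-sample golden site sets: (chrom, pos1) -> (ref, alt)."""
    out = {}
    for s in samples:
        out[s.sample_id] = {
            (chrom, pos + 1): (dna.BASES[ref], dna.BASES[alt])
            for (chrom, pos), (ref, alt, _, _) in s.site_truth(arch).items()
        }
    return out


def called_sites_by_sample(
    sites: Iterable[SiteCall], pass_only: bool = True
) -> dict[str, dict[tuple[str, int], tuple[str, str]]]:
    """Explode a joint call set per sample: a sample carries a site iff its
    genotype includes at least one alt allele."""
    out: dict[str, dict[tuple[str, int], tuple[str, str]]] = {}
    for site in sites:
        if pass_only and not site.is_pass:
            continue
        for sid, call in site.samples.items():
            if call.n_alt > 0:
                out.setdefault(sid, {})[(site.chrom, site.pos)] = (site.ref, site.alt)
    return out


def classify_calls(
    golden: Mapping[tuple[str, int], tuple[str, str]],
    called: Mapping[tuple[str, int], tuple[str, str]],
    sample: str,
) -> pd.DataFrame:
    """TP/FP/FN labels for one sample (the study's site/allele definitions)."""
    rows = []
    for key in golden.keys() | called.keys():
        chrom, pos = key
        g, c = golden.get(key), called.get(key)
        if g is not None and c is not None:
            if g == c:
                rows.append((sample, chrom, pos, "TP", c[0], c[1], ""))
            else:  # same position, mismatching alleles: one FP and one FN
                rows.append((sample, chrom, pos, "FP", c[0], c[1], "alt_mismatch"))
                rows.append((sample, chrom, pos, "FN", g[0], g[1], "alt_mismatch"))
        elif c is not None:
            rows.append((sample, chrom, pos, "FP", c[0], c[1], ""))
        else:
            rows.append((sample, chrom, pos, "FN", g[0], g[1], ""))
    df = pd.DataFrame(rows, columns=LABEL_COLUMNS)
    return df.sort_values(["chrom", "pos", "label"]).reset_index(drop=True)


def classify_cohort(
    golden_by_sample: Mapping[str, Mapping],
    called_by_sample: Mapping[str, Mapping],
) -> pd.DataFrame:
    frames = [
        classify_calls(golden_by_sample[sid], called_by_sample.get(sid, {}), sid)
        for sid in golden_by_sample
    ]
    if not frames:
        return pd.DataFrame(columns=LABEL_COLUMNS)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# stratification
# ---------------------------------------------------------------------------


def stratify_by_region(
    labels: pd.DataFrame,
    arch: GenomeArchitecture,
    golden_by_sample: Mapping[str, Mapping[tuple[str, int], tuple]],
) -> pd.DataFrame:
    """Per sample x chromosome x region class tallies with proportions.

    Denominators are the per-sample simulated totals of each class;
    proportions are left undefined (NaN) for empty classes. The conservation
    identity TP + FN = simulated count is asserted for every row.
    """
    samples = sorted(golden_by_sample)
    index = []
    for sid in samples:
        for chrom in arch.chrom_lengths:
            present = {_report_class(arch, chrom, r.start + 1) for r in arch.regions_of(chrom)}
            for cls in REPORT_CLASSES:
                if cls in present:
                    index.append((sid, chrom, cls))
    counts = {key: {"TP": 0, "FP": 0, "FN": 0} for key in index}
    if len(labels):
        cls_col = region_class_column(labels, arch)
        for (sid, chrom, cls, label), n in (
            labels.assign(region=cls_col)
            .groupby(["sample", "chrom", "region", "label"])
            .size()
            .items()
        ):
            counts[(sid, chrom, cls)][label] += int(n)
    n_sim = {key: 0 for key in index}
    for sid in samples:
        for (chrom, pos1) in golden_by_sample[sid]:
            n_sim[(sid, chrom, _report_class(arch, chrom, pos1))] += 1
    rows = []
    for key in index:
        sid, chrom, cls = key
        tp, fp, fn = counts[key]["TP"], counts[key]["FP"], counts[key]["FN"]
        sim = n_sim[key]
        if tp + fn != sim:
            raise AssertionError(
                f"conservation violated for {key}: TP {tp} + FN {fn} != simulated {sim}"
            )
        rows.append(
            (
                sid,
                chrom,
                cls,
                tp,
                fp,
                fn,
                sim,
                fp / sim if sim else np.nan,
                fn / sim if sim else np.nan,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["sample", "chrom", "region", "TP", "FP", "FN", "n_sim", "fp_prop", "fn_prop"],
    )


def window_counts(
    labels: pd.DataFrame, arch: GenomeArchitecture, window: int = 50_000
) -> pd.DataFrame:
    """Per sample x chromosome x fixed window TP/FP/FN tallies.

    Windows are anchored at coordinate 0; the final (truncated) window is
    included. All windows are reported, including empty ones.
    """
    rows = []
    samples = sorted(labels["sample"].unique()) if len(labels) else []
    grouped = {}
    if len(labels):
        win = ((labels["pos"] - 1) // window) * window
        grouped = (
            labels.assign(win=win)
            .groupby(["sample", "chrom", "win", "label"])
            .size()
            .to_dict()
        )
    for sid in samples:
        for chrom, length in arch.chrom_lengths.items():
            for start in range(0, length, window):
                rows.append(
                    (
                        sid,
                        chrom,
                        start,
                        min(start + window, length),
                        grouped.get((sid, chrom, start, "TP"), 0),
                        grouped.get((sid, chrom, start, "FP"), 0),
                        grouped.get((sid, chrom, start, "FN"), 0),
                    )
                )
    return pd.DataFrame(
        rows, columns=["sample", "chrom", "start", "end", "TP", "FP", "FN"]
    )


def mean_windows(windows: pd.DataFrame) -> pd.DataFrame:
    """Cross-sample mean per window (the per-window track the figures use)."""
    return (
        windows.groupby(["chrom", "start", "end"], as_index=False)[["TP", "FP", "FN"]]
        .mean()
        .sort_values(["chrom", "start"])
        .reset_index(drop=True)
    )


def difference_track(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Per-window mean difference a - b (e.g. SCC minus default TP tracks)."""
    ma, mb = mean_windows(a), mean_windows(b)
    merged = ma.merge(mb, on=["chrom", "start", "end"], suffixes=("_a", "_b"))
    for col in ("TP", "FP", "FN"):
        merged[col] = merged[f"{col}_a"] - merged[f"{col}_b"]
    return merged[["chrom", "start", "end", "TP", "FP", "FN"]]


# ---------------------------------------------------------------------------
# experiment orchestration
# ---------------------------------------------------------------------------

#: one factorial cell: (cohort karyotype, reference kind, ploidy mode)
Cell = tuple[str, str, str]

DEFAULT_CELLS: tuple[Cell, ...] = (
    ("XX", "default", "matched"),
    ("XX", "xx_scc", "matched"),
    ("XY", "default", "matched"),
    ("XY", "xy_scc", "matched"),
    ("XY", "xy_scc", "force-diploid"),
    ("XY", "xy_scc_yxtr_masked", "matched"),
)


@dataclass(frozen=True)
class ExperimentConfig:
    arch: GenomeArchitecture = field(default_factory=default_architecture)
    n_xx: int = 10
    n_xy: int = 10
    theta: float = 0.001
    policy: CoveragePolicy = CoveragePolicy()
    read_params: ReadParams = ReadParams()
    trim: TrimConfig = TrimConfig()
    caller_params: CallerParams = CallerParams()
    filter_config: FilterConfig = FilterConfig()
    window: int = 50_000
    cells: tuple[Cell, ...] = DEFAULT_CELLS

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in ("n_xx", "n_xy", "theta", "window"):
            if key in raw:
                kwargs[key] = raw[key]
        if "depth_per_copy" in raw:
            kwargs["policy"] = CoveragePolicy(raw["depth_per_copy"])
        if "cells" in raw:
            kwargs["cells"] = tuple(tuple(c) for c in raw["cells"])
        return cls(**kwargs)


@dataclass
class CellResult:
    cell: Cell
    sites: list[SiteCall]  # annotated, hard-filter labeled
    labels: pd.DataFrame  # PASS-site classification
    labels_unfiltered: pd.DataFrame  # pre-filter classification
    counts: pd.DataFrame
    windows: pd.DataFrame


@dataclass
class ExperimentReport:
    config: ExperimentConfig
    seed: int
    samples: dict[str, list[SampleTruth]]  # karyotype -> cohort
    cellresults: dict[Cell, CellResult]
    summary: dict[str, float]

    def counts_table(self) -> pd.DataFrame:
        frames = []
        for (kt, kind, mode), res in self.cellresults.items():
            df = res.counts.copy()
            df.insert(0, "ploidy_mode", mode)
            df.insert(0, "reference", kind)
            df.insert(0, "cohort", kt)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def _child_seed(root: int, *tags: str) -> int:
    """Stable, independent sub-seed derived from the root seed and tags."""
    import zlib

    ss = np.random.SeedSequence(
        [root, *(zlib.crc32(t.encode()) & 0x7FFFFFFF for t in tags)]
    )
    return int(ss.generate_state(1)[0] % (2**31))


def _simulate_trimmed(
    samples: Sequence[SampleTruth],
    refpair: ReferencePair,
    cfg: ExperimentConfig,
    seed: int,
) -> dict[str, list[read_sim.ReadPair]]:
    reads = {}
    for s in samples:
        pairs = read_sim.simulate_reads(
            s, refpair, cfg.arch, cfg.policy, cfg.read_params,
            seed=_child_seed(seed, "reads", s.sample_id),
        )
        trimmed, _ = read_sim.trim_reads(pairs, cfg.trim)
        reads[s.sample_id] = trimmed
    return reads


def call_cohort(
    samples: Sequence[SampleTruth],
    reads: Mapping[str, list[read_sim.ReadPair]],
    refpair: ReferencePair,
    arch: GenomeArchitecture,
    refkind: str,
    ploidy_mode: str,
    caller_params: CallerParams,
    seed: int,
) -> list[SiteCall]:
    """Align a cohort's reads to one reference kind and joint-genotype."""
    reference = refprep.build_reference(refkind, refpair, arch)
    index = mapsim.ReferenceIndex(reference)
    pileups = {}
    for s in samples:
        aligned = mapsim.align_pairs(
            reads[s.sample_id], index, seed=_child_seed(seed, "align", s.sample_id)
        )
        pileups[s.sample_id] = mapsim.build_pileups(aligned, reference)
    karyotypes = {s.sample_id: s.karyotype for s in samples}
    pm = PloidyMap(arch, mode=ploidy_mode)
    return joint_genotype(pileups, karyotypes, reference, pm, caller_params)


def _xtr_x_site_count(sites: Iterable[SiteCall], arch: GenomeArchitecture) -> int:
    ivls = arch.intervals("XTR", "X")
    return sum(
        1
        for s in sites
        if s.chrom == "X" and any(lo < s.pos <= hi for lo, hi in ivls)
    )


def run_experiment(config: ExperimentConfig, seed: int) -> ExperimentReport:
    """Execute the strategy factorial and assemble tables and summary metrics.

    Identical config + seed reproduce the report exactly. Summary metrics
    (each present only when its cells were run):

    ``default_par_tp_mean_xx``
        Mean per-XX-sample PAR true positives under the default reference
        with the standard hard filters — the empty-PAR observable.
    ``xtr_overcall_ratio``
        Joint-called X-XTR sites over the mean per-sample number of distinct
        simulated X-XTR sites when the Y XTR is masked (XY cohort); the
        cohort-union denominator variant is reported alongside.
    ``an20_nonpar_tp``
        True positives surviving AN >= 20 on X/Y non-PARs with haploid
        calling of the XY cohort (diploid-based allele-number wipeout).
    ``y_tp_diff_default_vs_scc``
        Summed per-sample difference in Y-chromosome true positives between
        default and complement-matched alignment of XY samples.
    """
    cfg = config
    refpair = simulate_reference_pair(cfg.arch, _child_seed(seed, "reference"))
    cohorts: dict[str, list[SampleTruth]] = {}
    cohort_cfg = {"XX": cfg.n_xx, "XY": cfg.n_xy}
    needed = {kt for kt, _, _ in cfg.cells}
    for kt in ("XX", "XY"):
        if kt in needed and cohort_cfg[kt] > 0:
            cc = CohortConfig(
                n_xx=cohort_cfg[kt] if kt == "XX" else 0,
                n_xy=cohort_cfg[kt] if kt == "XY" else 0,
                theta=cfg.theta,
            )
            cohorts[kt] = simulate_cohort(
                cfg.arch, refpair, cc, _child_seed(seed, "cohort", kt)
            )
    reads = {
        kt: _simulate_trimmed(cohorts[kt], refpair, cfg, _child_seed(seed, "simreads", kt))
        for kt in cohorts
    }
    golden = {kt: golden_sites_by_sample(cohorts[kt], cfg.arch) for kt in cohorts}

    cellresults: dict[Cell, CellResult] = {}
    for kt, refkind, mode in cfg.cells:
        if kt not in cohorts:
            continue
        sites = call_cohort(
            cohorts[kt], reads[kt], refpair, cfg.arch, refkind, mode, cfg.caller_params, seed
        )
        apply_hard_filters(sites, cfg.filter_config)
        labels_raw = classify_cohort(
            golden[kt], called_sites_by_sample(sites, pass_only=False)
        )
        labels = classify_cohort(golden[kt], called_sites_by_sample(sites, pass_only=True))
        counts = stratify_by_region(labels, cfg.arch, golden[kt])
        windows = window_counts(labels, cfg.arch, cfg.window)
        cellresults[(kt, refkind, mode)] = CellResult(
            (kt, refkind, mode), sites, labels, labels_raw, counts, windows
        )

    summary = _summarize(cfg, cohorts, golden, cellresults)
    return ExperimentReport(cfg, seed, cohorts, cellresults, summary)


def _summarize(cfg, cohorts, golden, cellresults) -> dict[str, float]:
    summary: dict[str, float] = {}
    arch = cfg.arch

    res = cellresults.get(("XX", "default", "matched"))
    if res is not None:
        par = res.counts[(res.counts["chrom"] == "X") & (res.counts["region"] == "PAR")]
        if len(par):
            summary["default_par_tp_mean_xx"] = float(par["TP"].mean())

    res = cellresults.get(("XY", "xy_scc_yxtr_masked", "matched"))
    if res is not None:
        called = _xtr_x_site_count(res.sites, arch)
        ivls = arch.intervals("XTR", "X")
        per_sample = [
            sum(1 for (c, p) in g if c == "X" and any(lo < p <= hi for lo, hi in ivls))
            for g in golden["XY"].values()
        ]
        union = len(
            {
                (c, p)
                for g in golden["XY"].values()
                for (c, p) in g
                if c == "X" and any(lo < p <= hi for lo, hi in ivls)
            }
        )
        mean_sim = float(np.mean(per_sample)) if per_sample else 0.0
        summary["xtr_called_sites"] = float(called)
        summary["xtr_simulated_per_sample"] = mean_sim
        if mean_sim > 0:
            summary["xtr_overcall_ratio"] = called / mean_sim
        if union > 0:
            summary["xtr_overcall_ratio_union"] = called / union

    res = cellresults.get(("XY", "xy_scc", "matched"))
    if res is not None:
        kept = an_filter(res.sites, 20)
        called = called_sites_by_sample(kept, pass_only=False)
        labels = classify_cohort(golden["XY"], called)
        cls = region_class_column(labels, arch) if len(labels) else pd.Series(dtype=object)
        nonpar = labels[
            (labels["label"] == "TP")
            & (labels["chrom"].isin(["X", "Y"]))
            & (cls != "PAR")
        ]
        summary["an20_nonpar_tp"] = float(len(nonpar))

    res_def = cellresults.get(("XY", "default", "matched"))
    res_scc = cellresults.get(("XY", "xy_scc", "matched"))
    if res_def is not None and res_scc is not None:
        tp_def = res_def.counts[res_def.counts["chrom"] == "Y"].groupby("sample")["TP"].sum()
        tp_scc = res_scc.counts[res_scc.counts["chrom"] == "Y"].groupby("sample")["TP"].sum()
        summary["y_tp_diff_default_vs_scc"] = float((tp_def - tp_scc).abs().sum())
    return summary


# ---------------------------------------------------------------------------
# VCF-file entry points (external interface)
# ---------------------------------------------------------------------------


def load_golden_vcf(path) -> dict[tuple[str, int], tuple[str, str]]:
    """Golden VCF file -> (chrom, pos1) -> (ref, alt)."""
    from .genome_sim import read_golden_vcf

    return {key: (ref, alt) for key, (ref, alt, _) in read_golden_vcf(path).items()}


def load_called_vcf(path, pass_only: bool = True) -> dict[str, dict[tuple[str, int], tuple[str, str]]]:
    """Multi-sample called VCF -> per-sample site sets (>=1 alt allele)."""
    import pysam

    out: dict[str, dict[tuple[str, int], tuple[str, str]]] = {}
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            if pass_only and "PASS" not in rec.filter and len(rec.filter) > 0:
                continue
            for sid in rec.samples:
                gt = rec.samples[sid]["GT"]
                if gt is None:
                    continue
                alleles = [a for a in (gt if isinstance(gt, tuple) else (gt,)) if a is not None]
                if any(a == 1 for a in alleles):
                    out.setdefault(sid, {})[(rec.chrom, rec.pos)] = (rec.ref, rec.alts[0])
    return out
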