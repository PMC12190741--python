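"""Biallelic SNP calling with explicit haploid/diploid genotype likelihoods.

The model is the standard per-read substitution likelihood: a read base ``b``
with error probability ``e`` (from its quality, floored at ``eps_floor``)
supports allele ``a`` with ``P(b|a) = 1 - e`` if ``b == a`` else ``e / 3``.
Haploid likelihoods multiply ``P(b|a)`` over reads; diploid likelihoods use
the allele mixture ``(P(b|a1) + P(b|a2)) / 2``. Joint genotyping across a
cohort supports mixed ploidy at one site (e.g. X non-PAR haploid in XY,
diploid in XX) and emits sites with at least one called alt allele.

Reads with MAPQ below the floor (default 20) never enter likelihoods, and
MAPQ 0 reads are always excluded; a site covered only by multi-mapping reads
has no calling-usable data. This is the mechanism behind the empty PARs under
an unmasked default reference. Site annotations follow GATK conventions
(QD, MQ, FS, SOR, MQRankSum, ReadPosRankSum), with MQ computed over the raw
pileup (multi-mappers included) so that ambiguously mapped regions carry low
RMS mapping quality.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from . import dna
from .genome_sim import GenomeArchitecture, ploidy_of
from .mapsim import Pileup

PLOIDY_MODES = ("matched", "force-diploid")


@dataclass(frozen=True)
class CallerParams:
    mapq_floor: int = 20  # reads below this (and all MAPQ 0) are excluded
    eps_floor: float = 1e-4  # error-probability floor (avoids zero likelihoods)
    het_prior: float = 1e-3  # prior mass on each heterozygous genotype
    min_alt_reads: int = 2  # candidate-site trigger per sample


@dataclass(frozen=True)
class PloidyMap:
    """(karyotype, chrom, pos) -> ploidy, with a force-diploid override mode."""

    arch: GenomeArchitecture
    mode: str = "matched"

    def __post_init__(self) -> None:
        if self.mode not in PLOIDY_MODES:
            raise ValueError(f"unknown ploidy mode {self.mode!r}")

    def ploidy(self, karyotype: str, chrom: str, pos: int) -> int:
        p = ploidy_of(self.arch, karyotype, chrom, pos)
        if self.mode == "force-diploid" and p > 0:
            return 2
        return p


@dataclass
class SampleCall:
    gt: tuple[int, ...] | None  # allele indices (0 ref, 1 alt); None = no call
    gq: int
    dp: int  # calling-usable depth (MAPQ-floor passing)

    @property
    def n_alt(self) -> int:
        return sum(a == 1 for a in self.gt) if self.gt else 0

    def gt_string(self) -> str:
        if self.gt is None:
            return "."
        return "/".join(str(a) for a in self.gt)


@dataclass
class SiteCall:
    """A joint-genotyped biallelic SNP with per-sample calls and annotations."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    samples: dict[str, SampleCall]
    qual: float
    info: dict[str, float] = field(default_factory=dict)
    filters: list[str] = field(default_factory=list)

    @property
    def is_pass(self) -> bool:
        return not self.filters


def genotype_likelihoods(
    bases: np.ndarray,
    quals: np.ndarray,
    ref: int,
    alt: int,
    ploidy: int,
    eps_floor: float = 1e-4,
) -> dict[tuple[int, ...], float]:
    """log10 likelihood per genotype over the {ref, alt} allele pair.

    Genotypes are tuples of allele indices: haploid ``(0,)``/``(1,)``;
    diploid ``(0,0)``, ``(0,1)``, ``(1,1)``. An empty column yields uniform
    (zero) log-likelihoods, flagging "no data" to the caller.
    """
    if ploidy not in (1, 2):
        raise ValueError(f"ploidy must be 1 or 2, got {ploidy}")
    gts = [(0,), (1,)] if ploidy == 1 else [(0, 0), (0, 1), (1, 1)]
    if len(bases) == 0:
        return {g: 0.0 for g in gts}
    e = dna.phred_to_error(quals, floor=eps_floor)
    p_allele = {}  # allele index -> per-read P(base | allele)
    for ai, a in enumerate((ref, alt)):
        p_allele[ai] = np.where(bases == a, 1.0 - e, e / 3.0)
    out = {}
    for g in gts:
        per_read = np.mean([p_allele[a] for a in g], axis=0)
        out[g] = float(np.log10(np.clip(per_read, 1e-300, None)).sum())
    return out


def genotype_posteriors(
    gls: Mapping[tuple[int, ...], float], het_prior: float
) -> dict[tuple[int, ...], float]:
    """Normalized posteriors under the heterozygosity prior.

    Variant genotypes get prior ``het_prior`` (homozygous/hemizygous alt gets
    ``het_prior / 2``); the reference genotype takes the remaining mass.
    """
    priors = {}
    for g in gls:
        if all(a == 0 for a in g):
            priors[g] = None  # fill below
        elif any(a == 0 for a in g):
            priors[g] = het_prior
        else:
            priors[g] = het_prior / 2.0
    rest = 1.0 - sum(v for v in priors.values() if v is not None)
    log_post = {}
    for g, gl in gls.items():
        prior = rest if priors[g] is None else priors[g]
        log_post[g] = gl + np.log10(max(prior, 1e-300))
    m = max(log_post.values())
    unnorm = {g: 10.0 ** (lp - m) for g, lp in log_post.items()}
    z = sum(unnorm.values())
    return {g: p / z for g, p in unnorm.items()}


def _candidate_sites(
    pileups: Mapping[str, Pileup],
    chrom: str,
    ref: np.ndarray,
    params: CallerParams,
) -> np.ndarray:
    """Positions where any sample shows >= min_alt_reads of one non-ref base."""
    cand: list[np.ndarray] = []
    for pu in pileups.values():
        cols = pu.arrays(chrom)
        pos = cols["pos"]
        if len(pos) == 0:
            continue
        usable = (cols["mapq"] >= params.mapq_floor) & (cols["mapq"] > 0)
        base = cols["base"]
        ok = usable & (base < 4) & (ref[pos] < 4) & (base != ref[pos])
        if not ok.any():
            continue
        keyed = pos[ok] * 4 + base[ok]
        uniq, counts = np.unique(keyed, return_counts=True)
        hits = uniq[counts >= params.min_alt_reads] // 4
        if hits.size:
            cand.append(hits)
    if not cand:
        return np.empty(0, dtype=np.int64)
    return np.unique(np.concatenate(cand))


def joint_genotype(
    pileups: Mapping[str, Pileup],
    karyotypes: Mapping[str, str],
    reference: Mapping[str, np.ndarray],
    ploidy_map: PloidyMap,
    params: CallerParams = CallerParams(),
    annotate: bool = True,
) -> list[SiteCall]:
    """Joint-genotype a cohort of per-sample pileups over a shared reference.

    Per candidate site the alt allele is the most frequent non-reference base
    across the cohort (highest-count alt kept at multi-allelic columns, with
    a warning); each sample gets its MAP genotype at its own ploidy; site
    QUAL is the phred-scaled posterior probability that every sample is
    homozygous/hemizygous reference. Sites with ``QUAL > 0`` and ``AC >= 1``
    are emitted, sorted by (chrom, pos).
    """
    sites: list[SiteCall] = []
    chroms = [c for c in reference if any(c in pu.chroms() for pu in pileups.values())]
    for chrom in chroms:
        ref_arr = np.asarray(reference[chrom], dtype=np.uint8)
        for pos0 in _candidate_sites(pileups, chrom, ref_arr, params):
            site = _call_site(
                pileups, karyotypes, chrom, int(pos0), ref_arr, ploidy_map, params, annotate
            )
            if site is not None:
                sites.append(site)
    sites.sort(key=lambda s: (s.chrom, s.pos))
    return sites


def _call_site(
    pileups: Mapping[str, Pileup],
    karyotypes: Mapping[str, str],
    chrom: str,
    pos0: int,
    ref_arr: np.ndarray,
    ploidy_map: PloidyMap,
    params: CallerParams,
    annotate: bool,
) -> SiteCall | None:
    ref = int(ref_arr[pos0])
    slices = {sid: pu.slice_at(chrom, pos0) for sid, pu in pileups.items()}
    usable = {}
    alt_counts = np.zeros(4, dtype=np.int64)
    for sid, sl in slices.items():
        ok = (sl["mapq"] >= params.mapq_floor) & (sl["mapq"] > 0) & (sl["base"] < 4)
        u = {k: v[ok] for k, v in sl.items()}
        usable[sid] = u
        for b in range(4):
            if b != ref:
                alt_counts[b] += int((u["base"] == b).sum())
    if alt_counts.sum() == 0:
        return None
    alt = int(alt_counts.argmax())
    if (alt_counts > 0).sum() > 1:
        warnings.warn(
            f"multi-allelic column at {chrom}:{pos0 + 1}; keeping highest-count alt"
        )
    calls: dict[str, SampleCall] = {}
    log10_p_ref_all = 0.0
    for sid, u in usable.items():
        ploidy = ploidy_map.ploidy(karyotypes[sid], chrom, pos0)
        dp = len(u["base"])
        if ploidy == 0 or dp == 0:
            calls[sid] = SampleCall(None, 0, dp)
            continue
        gls = genotype_likelihoods(u["base"], u["qual"], ref, alt, ploidy, params.eps_floor)
        post = genotype_posteriors(gls, params.het_prior)
        best_gt = max(post, key=post.get)
        gq = int(min(99, round(-10.0 * np.log10(max(1.0 - post[best_gt], 1e-10)))))
        calls[sid] = SampleCall(best_gt, gq, dp)
        ref_gt = tuple([0] * ploidy)
        log10_p_ref_all += np.log10(max(post[ref_gt], 1e-300))
    ac = sum(c.n_alt for c in calls.values())
    an = sum(len(c.gt) for c in calls.values() if c.gt is not None)
    qual = -10.0 * log10_p_ref_all
    if ac < 1 or qual <= 0.0:
        return None
    site = SiteCall(
        chrom,
        pos0 + 1,
        dna.BASES[ref],
        dna.BASES[alt],
        calls,
        round(qual, 2),
        info={"AC": float(ac), "AN": float(an)},
    )
    if annotate:
        annotate_site(site, pileups, params)
    return site


def annotate_site(
    site: SiteCall, pileups: Mapping[str, Pileup], params: CallerParams = CallerParams()
) -> SiteCall:
    """Attach GATK-convention site annotations computed from cohort pileups.

    DP: calling-usable depth summed over samples. MQ: root-mean-square MAPQ
    of all covering reads (multi-mappers included). QD: QUAL over the depth
    of samples carrying an alt allele. FS: phred-scaled two-sided Fisher
    exact p of the ref/alt x forward/reverse table. SOR: symmetric strand
    odds ratio. MQRankSum / ReadPosRankSum: rank-sum z-scores of alt-vs-ref
    read MAPQs and distances from the read end (omitted when either allele
    has no reads).
    """
    pos0 = site.pos - 1
    ref_code = dna.BASES.index(site.ref)
    alt_code = dna.BASES.index(site.alt)
    all_mapqs, dp_used = [], 0
    ref_fwd = ref_rev = alt_fwd = alt_rev = 0
    alt_mapq, ref_mapq, alt_end, ref_end = [], [], [], []
    variant_dp = 0
    for sid, pu in pileups.items():
        sl = pu.slice_at(site.chrom, pos0)
        all_mapqs.append(sl["mapq"])
        ok = (sl["mapq"] >= params.mapq_floor) & (sl["mapq"] > 0) & (sl["base"] < 4)
        base, strand = sl["base"][ok], sl["strand"][ok]
        mapq, endd = sl["mapq"][ok], sl["enddist"][ok]
        dp_used += int(ok.sum())
        is_ref, is_alt = base == ref_code, base == alt_code
        ref_fwd += int((is_ref & (strand == 1)).sum())
        ref_rev += int((is_ref & (strand == 0)).sum())
        alt_fwd += int((is_alt & (strand == 1)).sum())
        alt_rev += int((is_alt & (strand == 0)).sum())
        ref_mapq.append(mapq[is_ref])
        alt_mapq.append(mapq[is_alt])
        ref_end.append(endd[is_ref])
        alt_end.append(endd[is_alt])
        call = site.samples.get(sid)
        if call is not None and call.n_alt > 0:
            variant_dp += call.dp
    info = site.info
    info["DP"] = float(dp_used)
    mq_all = np.concatenate(all_mapqs) if all_mapqs else np.empty(0)
    if mq_all.size:
        info["MQ"] = round(float(np.sqrt(np.mean(mq_all.astype(float) ** 2))), 2)
    if variant_dp > 0:
        info["QD"] = round(site.qual / variant_dp, 2)
    table = np.array([[ref_fwd, ref_rev], [alt_fwd, alt_rev]])
    if table.sum() > 0 and (alt_fwd + alt_rev) > 0:
        p = stats.fisher_exact(table, alternative="two-sided")[1]
        info["FS"] = round(-10.0 * np.log10(max(p, 1e-300)), 3)
        info["SOR"] = round(_strand_odds_ratio(ref_fwd, ref_rev, alt_fwd, alt_rev), 3)
    ref_mq = np.concatenate(ref_mapq)
    alt_mq = np.concatenate(alt_mapq)
    if ref_mq.size and alt_mq.size:
        info["MQRankSum"] = round(float(stats.ranksums(alt_mq, ref_mq).statistic), 3)
        info["ReadPosRankSum"] = round(
            float(stats.ranksums(np.concatenate(alt_end), np.concatenate(ref_end)).statistic), 3
        )
    return site


def _strand_odds_ratio(rf: int, rr: int, af: int, ar: int) -> float:
    """GATK's StrandOddsRatio: symmetric odds ratio with +1 pseudocounts."""
    r = ((rf + 1) * (ar + 1)) / ((rr + 1) * (af + 1))
    sym = r + 1.0 / r
    ref_ratio = (min(rf, rr) + 1) / (max(rf, rr) + 1)
    alt_ratio = (min(af, ar) + 1) / (max(af, ar) + 1)
    return float(np.log(sym) + np.log(ref_ratio) - np.log(alt_ratio))


# ---------------------------------------------------------------------------
# VCF output
# ---------------------------------------------------------------------------

_INFO_FIELDS = (
    ("AC", "A", "Integer", "Called alternate allele count"),
    ("AN", "1", "Integer", "Number of called allele copies (ploidy-weighted)"),
    ("DP", "1", "Integer", "Calling-usable read depth across samples"),
    ("QD", "1", "Float", "Site quality over variant-sample depth"),
    ("MQ", "1", "Float", "RMS mapping quality of covering reads"),
    ("FS", "1", "Float", "Phred-scaled Fisher strand bias"),
    ("SOR", "1", "Float", "Symmetric strand odds ratio"),
    ("MQRankSum", "1", "Float", "Alt-vs-ref mapping-quality rank-sum z"),
    ("ReadPosRankSum", "1", "Float", "Alt-vs-ref read-position rank-sum z"),
)

_FILTER_DESCRIPTIONS = {
    "QD2": "QD < 2.0",
    "QUAL30": "QUAL < 30.0",
    "SOR3": "SOR > 3.0",
    "FS60": "FS > 60.0",
    "MQ40": "MQ < 40.0",
    "MQRankSum-12.5": "MQRankSum < -12.5",
    "ReadPosRankSum-8": "ReadPosRankSum < -8.0",
}


def write_vcf(
    sites: Sequence[SiteCall],
    sample_ids: Sequence[str],
    chrom_lengths: Mapping[str, int],
    path: str | os.PathLike,
) -> None:
    """Write joint-genotyped sites as VCF 4.2 with INFO/FORMAT annotations."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sexchrom_varbench caller\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        for fid, num, typ, desc in _INFO_FIELDS:
            fh.write(f'##INFO=<ID={fid},Number={num},Type={typ},Description="{desc}">\n')
        for fid, desc in _FILTER_DESCRIPTIONS.items():
            fh.write(f'##FILTER=<ID={fid},Description="{desc}">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(sample_ids) + "\n")
        for s in sites:
            parts = []
            for key in ("AC", "AN", "DP"):
                if key in s.info:
                    parts.append(f"{key}={int(s.info[key])}")
            for key in ("QD", "MQ", "FS", "SOR", "MQRankSum", "ReadPosRankSum"):
                if key in s.info:
                    parts.append(f"{key}={s.info[key]}")
            filt = ";".join(s.filters) if s.filters else "PASS"
            cols = [
                s.chrom,
                str(s.pos),
                ".",
                s.ref,
                s.alt,
                f"{s.qual:.2f}",
                filt,
                ";".join(parts) or ".",
                "GT:DP:GQ",
            ]
            for sid in sample_ids:
                call = s.samples.get(sid)
                if call is None:
                    cols.append("./.")
                else:
                    cols.append(f"{call.gt_string()}:{call.dp}:{call.gq}")
            fh.write("\t".join(cols) + "\n")
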