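"""Genotype-likelihood model, joint genotyping, annotations, VCF output."""

from fractions import Fraction

import numpy as np
import pytest

from sexchrom_varbench import bench, mapsim
from sexchrom_varbench import genome_sim as gs
from sexchrom_varbench.caller import (
    CallerParams,
    PloidyMap,
    annotate_site,
    genotype_likelihoods,
    genotype_posteriors,
    joint_genotype,
    write_vcf,
)

from conftest import make_mini_arch, run_cohort_pipeline

REF, ALT = 0, 1  # A and C


def column(n_ref, n_alt, q=20):
    bases = np.array([REF] * n_ref + [ALT] * n_alt, dtype=np.uint8)
    quals = np.full(len(bases), q, dtype=np.uint8)
    return bases, quals


class TestGenotypeLikelihoods:
    def test_haploid_log_ratio_closed_form(self):
        """10 clean alt reads at Q20: log10 LR = 10*log10(0.99/(0.01/3))."""
        bases, quals = column(0, 10, q=20)
        gls = genotype_likelihoods(bases, quals, REF, ALT, ploidy=1)
        expected = 10 * np.log10(0.99 / (0.01 / 3))
        assert gls[(1,)] - gls[(0,)] == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(24.7, abs=0.05)

    def test_diploid_balanced_column_prefers_het(self):
        bases, quals = column(5, 5, q=20)
        gls = genotype_likelihoods(bases, quals, REF, ALT, ploidy=2)
        assert max(gls, key=gls.get) == (0, 1)

    def test_empty_column_is_uniform_no_data(self):
        gls = genotype_likelihoods(
            np.empty(0, dtype=np.uint8), np.empty(0, dtype=np.uint8), REF, ALT, 2
        )
        assert set(gls.values()) == {0.0}

    def test_invalid_ploidy_rejected(self):
        bases, quals = column(1, 1)
        with pytest.raises(ValueError, match="ploidy"):
            genotype_likelihoods(bases, quals, REF, ALT, ploidy=3)

    @pytest.mark.parametrize("ploidy", [1, 2])
    @pytest.mark.parametrize("depth_seed", [(4, 0), (8, 1), (12, 2), (11, 3)])
    def test_posteriors_match_rational_enumeration(self, ploidy, depth_seed):
        """Float posteriors equal exhaustive rational-arithmetic enumeration
        over all genotypes on columns of depth <= 12."""
        depth, seed = depth_seed
        rng = np.random.default_rng(seed)
        bases = rng.choice([REF, ALT, 2], size=depth, p=[0.5, 0.4, 0.1]).astype(np.uint8)
        quals = rng.integers(5, 41, size=depth).astype(np.uint8)
        params = CallerParams()
        gls = genotype_likelihoods(bases, quals, REF, ALT, ploidy, params.eps_floor)
        post = genotype_posteriors(gls, params.het_prior)

        # independent oracle: exact Fractions, no logs
        errs = [
            Fraction(float(np.clip(10.0 ** (-float(q) / 10.0), params.eps_floor, 0.75)))
            for q in quals
        ]
        gts = [(0,), (1,)] if ploidy == 1 else [(0, 0), (0, 1), (1, 1)]
        prior = {}
        for g in gts:
            if all(a == 0 for a in g):
                prior[g] = None
            elif any(a == 0 for a in g):
                prior[g] = Fraction(1, 1000)
            else:
                prior[g] = Fraction(1, 2000)
        rest = 1 - sum(v for v in prior.values() if v is not None)
        weights = {}
        for g in gts:
            lik = Fraction(1)
            for b, e in zip(bases, errs):
                per_allele = [
                    (1 - e) if b == a_base else e / 3
                    for a_base in [(REF, ALT)[a] for a in g]
                ]
                lik *= sum(per_allele) / len(per_allele)
            weights[g] = lik * (rest if prior[g] is None else prior[g])
        z = sum(weights.values())
        for g in gts:
            assert post[g] == pytest.approx(float(weights[g] / z), abs=1e-9)


def _clean_aligned(chrom, pos0, base, n, ref, q=30, mapq=60, strand_split=True):
    """n single-base reads stacked at one position (synthetic pileup input)."""
    out = []
    for i in range(n):
        strand = "+" if (i % 2 == 0 or not strand_split) else "-"
        out.append(
            mapsim.AlignedRead(
                mapsim.Alignment(f"r{pos0}.{base}.{i}", chrom, pos0, strand, 0, mapq, 1),
                np.array([base], dtype=np.uint8),
                np.array([q], dtype=np.uint8),
            )
        )
    return out


@pytest.fixture(scope="module")
def flat_arch():
    # X entirely non-PAR: ploidy 2 for XX, 1 for XY
    return gs.build_architecture([("NONPAR", 1000)])


def _reference(flat_arch):
    return {"X": np.zeros(1000, dtype=np.uint8)}  # all 'A'


class TestJointGenotyping:
    def test_all_reference_cohort_emits_nothing(self, flat_arch):
        ref = _reference(flat_arch)
        pus = {
            sid: mapsim.build_pileups(_clean_aligned("X", 10, REF, 10, ref), ref)
            for sid in ("s1", "s2")
        }
        sites = joint_genotype(pus, {"s1": "XX", "s2": "XX"}, ref, PloidyMap(flat_arch))
        assert sites == []

    def test_single_haploid_carrier_ac1_an10(self, flat_arch):
        ref = _reference(flat_arch)
        pus = {}
        for i in range(10):
            base = ALT if i == 0 else REF
            pus[f"s{i}"] = mapsim.build_pileups(_clean_aligned("X", 50, base, 10, ref), ref)
        karyos = {f"s{i}": "XY" for i in range(10)}
        sites = joint_genotype(pus, karyos, ref, PloidyMap(flat_arch))
        assert len(sites) == 1
        site = sites[0]
        assert (site.info["AC"], site.info["AN"]) == (1, 10)
        assert site.samples["s0"].gt == (1,)

    def test_mixed_ploidy_allele_number(self, flat_arch):
        """4 diploid + 2 haploid genotyped samples: AN = 4*2 + 2*1 = 10."""
        ref = _reference(flat_arch)
        pus, karyos = {}, {}
        for i in range(4):
            pus[f"xx{i}"] = mapsim.build_pileups(_clean_aligned("X", 70, ALT, 6, ref), ref)
            karyos[f"xx{i}"] = "XX"
        for i in range(2):
            pus[f"xy{i}"] = mapsim.build_pileups(_clean_aligned("X", 70, ALT, 6, ref), ref)
            karyos[f"xy{i}"] = "XY"
        sites = joint_genotype(pus, karyos, ref, PloidyMap(flat_arch))
        assert len(sites) == 1
        assert sites[0].info["AN"] == 10
        assert sites[0].samples["xx0"].gt == (1, 1)
        assert sites[0].samples["xy0"].gt == (1,)

    def test_force_diploid_override(self):
        arch = make_mini_arch()
        pm = PloidyMap(arch, mode="force-diploid")
        assert pm.ploidy("XY", "X", 20_000) == 2  # haploid region forced diploid
        assert pm.ploidy("XY", "Y", 10_000) == 2
        assert pm.ploidy("XX", "Y", 10_000) == 0  # absent chromosome stays absent
        matched = PloidyMap(arch, mode="matched")
        assert matched.ploidy("XY", "X", 20_000) == 1
        assert matched.ploidy("XY", "X", 1000) == 2  # PAR1 diploid

    def test_mapq0_only_coverage_yields_no_calls(self, flat_arch):
        """Sites covered only by multi-mapping reads have no usable data."""
        ref = _reference(flat_arch)
        reads = _clean_aligned("X", 90, ALT, 8, ref, mapq=0)
        pus = {"s": mapsim.build_pileups(reads, ref)}
        sites = joint_genotype(pus, {"s": "XX"}, ref, PloidyMap(flat_arch))
        assert sites == []


class TestAnnotations:
    @pytest.fixture(scope="class")
    def het_site(self, flat_arch):
        ref = _reference(flat_arch)
        reads = _clean_aligned("X", 100, REF, 6, ref) + _clean_aligned("X", 100, ALT, 6, ref)
        pus = {"s": mapsim.build_pileups(reads, ref)}
        sites = joint_genotype(pus, {"s": "XX"}, ref, PloidyMap(flat_arch))
        assert len(sites) == 1
        return sites[0], pus

    def test_mq_is_rms_of_constant(self, het_site):
        site, _ = het_site
        assert site.info["MQ"] == 60.0

    def test_qd_is_qual_over_variant_depth(self, het_site):
        site, _ = het_site
        assert site.info["QD"] == pytest.approx(site.qual / 12, abs=0.01)

    def test_balanced_strands_give_fs_zero(self, het_site):
        site, _ = het_site
        assert site.info["FS"] == 0.0  # Fisher p = 1 on a balanced table
        assert site.info["SOR"] == pytest.approx(np.log(2.0), abs=5e-4)  # stored rounded

    def test_rank_sums_near_zero_for_exchangeable_reads(self, het_site):
        site, _ = het_site
        assert abs(site.info["MQRankSum"]) < 1e-9  # identical MAPQs
        assert abs(site.info["ReadPosRankSum"]) < 1e-9  # identical end distances

    def test_dp_counts_usable_reads(self, het_site):
        site, _ = het_site
        assert site.info["DP"] == 12


class TestPloidyContracts:
    @pytest.fixture(scope="class")
    def clean_run(self, mini_arch, refpair):
        """Error-free reads, complement-matched reference: text-book calls."""
        from sexchrom_varbench.read_sim import ReadParams, simulate_reads, trim_reads

        cohort = gs.simulate_cohort(
            mini_arch, refpair, gs.CohortConfig(0, 2, theta=0.002), seed=70
        )
        reads = {}
        for i, s in enumerate(cohort):
            pairs = simulate_reads(
                s, refpair, mini_arch, params=ReadParams(epsilon=0.0), seed=71 + i
            )
            reads[s.sample_id], _ = trim_reads(pairs)
        out = {}
        for mode in ("matched", "force-diploid"):
            sites, _ = run_cohort_pipeline(
                mini_arch, cohort, refpair, "xy_scc", mode, reads, seed=73
            )
            out[mode] = sites
        return cohort, out

    def test_haploid_calling_never_emits_heterozygotes(self, clean_run):
        cohort, out = clean_run
        arch = make_mini_arch()
        for site in out["matched"]:
            for sid, call in site.samples.items():
                if call.gt is None:
                    continue
                ploidy = gs.ploidy_of(arch, "XY", site.chrom, site.pos - 1)
                if ploidy == 1:
                    assert call.gt in ((0,), (1,))

    def test_error_free_diploid_and_haploid_calls_agree(self, clean_run):
        """With no sequencing errors and unique mapping, the override changes
        genotype encoding but not which samples carry which sites."""
        _, out = clean_run
        a = bench.called_sites_by_sample(out["matched"], pass_only=False)
        b = bench.called_sites_by_sample(out["force-diploid"], pass_only=False)
        assert set(a) == set(b)
        for sid in a:
            assert a[sid] == b[sid]


class TestVcfOutput:
    def test_roundtrip_through_pysam(self, tmp_path, flat_arch):
        import pysam

        ref = _reference(flat_arch)
        pus, karyos = {}, {}
        for i in range(3):
            base = ALT if i < 2 else REF
            pus[f"s{i}"] = mapsim.build_pileups(_clean_aligned("X", 200, base, 8, ref), ref)
            karyos[f"s{i}"] = "XY" if i == 0 else "XX"
        sites = joint_genotype(pus, karyos, ref, PloidyMap(flat_arch))
        path = tmp_path / "calls.vcf"
        write_vcf(sites, list(karyos), {"X": 1000}, path)
        with pysam.VariantFile(str(path)) as vf:
            recs = list(vf)
        assert len(recs) == len(sites) == 1
        rec = recs[0]
        assert (rec.chrom, rec.pos, rec.ref, rec.alts[0]) == ("X", 201, "A", "C")
        assert rec.info["AN"] == int(sites[0].info["AN"])
        assert rec.samples["s0"]["GT"] == (1,)  # haploid GT survives the roundtrip
        assert rec.samples["s1"]["GT"] == (1, 1)
        assert rec.samples["s2"]["GT"] == (0, 0)
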