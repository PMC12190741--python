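"""Architecture validation, reference similarity structure, cohort truth sets."""

import numpy as np
import pytest

from sexchrom_varbench import dna
from sexchrom_varbench import genome_sim as gs



class TestArchitecture:
    def test_tiling_matches_per_base_oracle(self):
        """Segment spec -> per-base class assignment agrees with a brute scan."""
        spec = [
            ("PAR1", 10_000),
            ("NONPAR", 70_000),
            ("XTR", 30_000),
            ("AMP", 10_000),
            ("NONPAR", 75_000),
            ("PAR2", 5_000),
        ]
        arch = gs.build_architecture(spec, spec)
        # independent per-base assignment straight from the ordered spec
        oracle = np.concatenate(
            [np.full(length, gs.REGION_CLASSES.index(cls), dtype=np.int8) for cls, length in spec]
        )
        assert len(oracle) == arch.chrom_lengths["X"] == 200_000
        assert np.array_equal(arch.class_array("X"), oracle)
        # every base belongs to exactly one region (tiling, no overlap)
        covered = np.zeros(200_000, dtype=int)
        for r in arch.regions_of("X"):
            covered[r.start : r.end] += 1
        assert (covered == 1).all()

    def test_overlapping_regions_rejected_with_interval_named(self):
        regions = (
            gs.Region("X", 0, 1000, "PAR1"),
            gs.Region("X", 500, 2000, "XTR"),  # overlaps PAR1
            gs.Region("X", 2000, 3000, "PAR2"),
        )
        with pytest.raises(gs.ArchitectureError, match="XTR"):
            gs.GenomeArchitecture({"X": 3000}, regions)

    def test_par_must_anchor_chromosome_ends(self):
        with pytest.raises(gs.ArchitectureError, match="PAR1"):
            gs.build_architecture(
                [("NONPAR", 1000), ("PAR1", 1000), ("PAR2", 1000)],
            )

    def test_homolog_length_mismatch_rejected(self):
        with pytest.raises(gs.ArchitectureError, match="XTR"):
            gs.build_architecture(
                [("PAR1", 1000), ("XTR", 2000), ("NONPAR", 1000), ("PAR2", 1000)],
                [("PAR1", 1000), ("XTR", 1000), ("NONPAR", 1000), ("PAR2", 1000)],
            )

    def test_zero_length_xtr_is_valid_and_empty_downstream(self):
        arch = gs.build_architecture(
            [("PAR1", 1000), ("XTR", 0), ("NONPAR", 3000), ("PAR2", 1000)],
            [("PAR1", 1000), ("XTR", 0), ("NONPAR", 2000), ("PAR2", 1000)],
        )
        assert arch.intervals("XTR", "X") == []
        assert arch.intervals("XTR", "Y") == []

    def test_region_beds_cover_every_class(self, tmp_path, mini_arch):
        paths = gs.write_region_beds(mini_arch, tmp_path)
        combined = dna.read_bed(paths["combined"])
        total = sum(e - s for _, s, e, _ in combined)
        assert total == sum(mini_arch.chrom_lengths.values())
        par_rows = dna.read_bed(paths["PAR1"])
        assert par_rows == [("X", 0, 4000), ("Y", 0, 4000)]


class TestReferencePair:
    def test_xtr_divergence_is_exact_hamming_count(self):
        arch = gs.build_architecture(
            [("PAR1", 2000), ("XTR", 30_000), ("NONPAR", 5000), ("PAR2", 2000)],
            [("PAR1", 2000), ("XTR", 30_000), ("NONPAR", 3000), ("PAR2", 2000)],
        )
        pair = gs.simulate_reference_pair(arch, seed=3)
        (xs, xe), (ys, ye) = arch.homolog_pair("XTR")[0]
        ham = int((pair.seqs["X"][xs:xe] != pair.seqs["Y"][ys:ye]).sum())
        assert ham == 366  # floor(0.0122 * 30000), direct Hamming count

    def test_identity_cases(self, mini_arch):
        arch_ident = gs.GenomeArchitecture(
            mini_arch.chrom_lengths, mini_arch.regions, s_par=1.0, s_xtr=1.0
        )
        pair = gs.simulate_reference_pair(arch_ident, seed=4)
        (xs, xe), (ys, ye) = arch_ident.homolog_pair("XTR")[0]
        assert np.array_equal(pair.seqs["X"][xs:xe], pair.seqs["Y"][ys:ye])
        for (ps, pe), (qs, qe) in arch_ident.homolog_pair("PAR1"):
            assert np.array_equal(pair.seqs["X"][ps:pe], pair.seqs["Y"][qs:qe])

    def test_nonpar_sequence_is_unrelated(self, mini_arch, refpair):
        (xs, xe) = mini_arch.intervals("NONPAR", "X")[0]
        (ys, ye) = mini_arch.intervals("NONPAR", "Y")[0]
        L = min(xe - xs, ye - ys)
        frac = (refpair.seqs["X"][xs : xs + L] != refpair.seqs["Y"][ys : ys + L]).mean()
        assert 0.70 < frac < 0.80  # ~3/4 for independent uniform sequence

    def test_seed_reproducibility(self, mini_arch):
        a = gs.simulate_reference_pair(mini_arch, seed=9)
        b = gs.simulate_reference_pair(mini_arch, seed=9)
        for chrom in mini_arch.chrom_lengths:
            assert np.array_equal(a.seqs[chrom], b.seqs[chrom])


class TestCohort:
    def test_theta_zero_gives_empty_truth(self, mini_arch, refpair):
        cohort = gs.simulate_cohort(
            mini_arch, refpair, gs.CohortConfig(1, 1, theta=0.0), seed=5
        )
        for s in cohort:
            assert all(len(v) == 0 for v in s.snps.values())

    def test_karyotype_consistency(self, mini_arch, refpair):
        cohort = gs.simulate_cohort(
            mini_arch, refpair, gs.CohortConfig(2, 2, theta=0.002), seed=6
        )
        for s in cohort:
            chroms = {c for snps in s.snps.values() for c, *_ in snps}
            if s.karyotype == "XX":
                assert "Y" not in chroms
            else:
                # PAR variation is X-anchored: no Y-PAR golden records
                for snps in s.snps.values():
                    for chrom, pos, _, _ in snps:
                        if chrom == "Y":
                            assert mini_arch.class_at("Y", pos) not in ("PAR1", "PAR2")

    def test_snp_counts_in_poisson_interval(self):
        """theta=0.001 on a 100 kb diploid chromosome: ~Poisson(200) per sample."""
        arch = gs.build_architecture([("NONPAR", 1000)], autosome_length=100_000)
        pair = gs.simulate_reference_pair(arch, seed=7)
        lam = 2 * 0.001 * 100_000  # two haplotypes
        lo, hi = 200 - 2.576 * np.sqrt(lam), 200 + 2.576 * np.sqrt(lam)
        counts = []
        for seed in range(60):
            (s,) = gs.simulate_cohort(arch, pair, gs.CohortConfig(1, 0, 0.001), seed=seed)
            counts.append(len(s.snps["A.0"]) + len(s.snps["A.1"]))
        counts = np.array(counts)
        assert lo < counts.mean() < hi
        # individual draws stay within a generous 4-sigma envelope
        assert ((counts > 200 - 4 * np.sqrt(lam)) & (counts < 200 + 4 * np.sqrt(lam))).all()

    def test_no_duplicate_positions_per_haplotype(self, mini_arch, refpair):
        cohort = gs.simulate_cohort(
            mini_arch, refpair, gs.CohortConfig(1, 1, theta=0.02), seed=8
        )
        for s in cohort:
            for snps in s.snps.values():
                keys = [(c, p) for c, p, _, _ in snps]
                assert len(keys) == len(set(keys))


class TestGoldenVcf:
    def test_roundtrip_reproduces_truth(self, tmp_path, mini_arch, refpair):
        cohort = gs.simulate_cohort(
            mini_arch, refpair, gs.CohortConfig(1, 1, theta=0.002), seed=12
        )
        for s in cohort:
            path = tmp_path / f"{s.sample_id}.vcf"
            gs.write_golden_vcf(s, mini_arch, path)
            back = gs.read_golden_vcf(path)
            expected = {
                (c, p): (r, a, g) for c, p, r, a, g in gs.golden_records(s, mini_arch)
            }
            assert back == expected

    def test_haploid_gt_on_male_x_nonpar(self, mini_arch, refpair):
        cohort = gs.simulate_cohort(
            mini_arch, refpair, gs.CohortConfig(0, 1, theta=0.005), seed=13
        )
        recs = gs.golden_records(cohort[0], mini_arch)
        saw_haploid = saw_diploid_par = False
        for chrom, pos1, ref, alt, gt in recs:
            cls = mini_arch.class_at(chrom, pos1 - 1)
            if chrom == "X" and cls not in ("PAR1", "PAR2"):
                assert gt == "1"
                saw_haploid = True
            if chrom == "X" and cls in ("PAR1", "PAR2"):
                assert gt in ("0/1", "1/1")
                saw_diploid_par = True
            if chrom == "Y":
                assert gt == "1"
        assert saw_haploid and saw_diploid_par

    def test_empty_truth_writes_valid_header_only_vcf(self, tmp_path, mini_arch, refpair):
        (s,) = gs.simulate_cohort(
            mini_arch, refpair, gs.CohortConfig(1, 0, theta=0.0), seed=14
        )
        path = tmp_path / "empty.vcf"
        gs.write_golden_vcf(s, mini_arch, path)
        assert gs.read_golden_vcf(path) == {}

    def test_outputs_byte_identical_across_runs(self, tmp_path, mini_arch):
        out = []
        for run in range(2):
            pair = gs.simulate_reference_pair(mini_arch, seed=15)
            (s,) = gs.simulate_cohort(mini_arch, pair, gs.CohortConfig(0, 1, 0.001), seed=16)
            fa, vcf = tmp_path / f"r{run}.fa", tmp_path / f"r{run}.vcf"
            dna.write_fasta(pair.seqs, fa)
            gs.write_golden_vcf(s, mini_arch, vcf)
            out.append((fa.read_bytes(), vcf.read_bytes()))
        assert out[0] == out[1]
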