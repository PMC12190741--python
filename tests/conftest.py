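"""Shared fixtures: desk-scale architectures and cached pipeline runs.

The heavy fixtures (full simulate-align-call runs) are session-scoped and
shared across test modules; every random draw is seeded so the suite is
deterministic.
"""

from __future__ import annotations

import warnings

import pytest

from sexchrom_varbench import bench, genome_sim as gs, read_sim as rs
from sexchrom_varbench import mapsim, refprep
from sexchrom_varbench.caller import CallerParams, PloidyMap, joint_genotype
from sexchrom_varbench.filters import FilterConfig, apply_hard_filters


def make_mini_arch(autosome_length: int = 20_000) -> gs.GenomeArchitecture:
    """40 kb X / 30 kb Y with all region classes; boundaries on 1 kb grid."""
    return gs.build_architecture(
        x_segments=[
            ("PAR1", 4_000),
            ("NONPAR", 12_000),
            ("XTR", 8_000),
            ("AMP", 2_000),
            ("NONPAR", 10_000),
            ("PAR2", 4_000),
        ],
        y_segments=[
            ("PAR1", 4_000),
            ("NONPAR", 5_000),
            ("XTR", 8_000),
            ("AMP", 2_000),
            ("NONPAR", 7_000),
            ("PAR2", 4_000),
        ],
        autosome_length=autosome_length,
    )


def make_micro_arch() -> gs.GenomeArchitecture:
    """Smaller layout for replicate-heavy property tests."""
    return gs.build_architecture(
        x_segments=[
            ("PAR1", 3_000),
            ("NONPAR", 6_000),
            ("XTR", 5_000),
            ("AMP", 2_000),
            ("NONPAR", 5_000),
            ("PAR2", 3_000),
        ],
        y_segments=[
            ("PAR1", 3_000),
            ("NONPAR", 3_000),
            ("XTR", 5_000),
            ("AMP", 2_000),
            ("NONPAR", 3_000),
            ("PAR2", 3_000),
        ],
        autosome_length=10_000,
    )


def run_cohort_pipeline(
    arch,
    samples,
    refpair,
    refkind,
    ploidy_mode,
    reads,
    seed,
    caller_params=CallerParams(),
):
    """Align pre-simulated reads to one reference kind and joint-genotype."""
    reference = refprep.build_reference(refkind, refpair, arch)
    index = mapsim.ReferenceIndex(reference)
    pileups = {}
    for i, s in enumerate(samples):
        aligned = mapsim.align_pairs(reads[s.sample_id], index, seed=seed + i)
        pileups[s.sample_id] = mapsim.build_pileups(aligned, reference)
    karyotypes = {s.sample_id: s.karyotype for s in samples}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sites = joint_genotype(
            pileups, karyotypes, reference, PloidyMap(arch, ploidy_mode), caller_params
        )
    apply_hard_filters(sites, FilterConfig())
    return sites, pileups


def simulate_trimmed_cohort(arch, refpair, n_xx, n_xy, theta, seed):
    cohort = gs.simulate_cohort(
        arch, refpair, gs.CohortConfig(n_xx=n_xx, n_xy=n_xy, theta=theta), seed=seed
    )
    reads = {}
    for i, s in enumerate(cohort):
        pairs = rs.simulate_reads(s, refpair, arch, seed=seed + 100 + i)
        reads[s.sample_id], _ = rs.trim_reads(pairs)
    return cohort, reads


@pytest.fixture(scope="session")
def mini_arch():
    return make_mini_arch()


@pytest.fixture(scope="session")
def refpair(mini_arch):
    return gs.simulate_reference_pair(mini_arch, seed=11)


@pytest.fixture(scope="session")
def xy_bundle(mini_arch, refpair):
    """Ten XY samples aligned to default / SCC / SCC+Y-XTR-masked references."""
    cohort, reads = simulate_trimmed_cohort(
        mini_arch, refpair, n_xx=0, n_xy=10, theta=0.001, seed=21
    )
    golden = bench.golden_sites_by_sample(cohort, mini_arch)
    sites = {}
    for kind in ("default", "xy_scc", "xy_scc_yxtr_masked"):
        sites[kind], _ = run_cohort_pipeline(
            mini_arch, cohort, refpair, kind, "matched", reads, seed=31
        )
    return {
        "arch": mini_arch,
        "samples": cohort,
        "reads": reads,
        "golden": golden,
        "sites": sites,
    }


@pytest.fixture(scope="session")
def xx_bundle(mini_arch, refpair):
    """Ten XX samples aligned to default and XX-SCC references."""
    cohort, reads = simulate_trimmed_cohort(
        mini_arch, refpair, n_xx=10, n_xy=0, theta=0.001, seed=41
    )
    golden = bench.golden_sites_by_sample(cohort, mini_arch)
    sites = {}
    for kind in ("default", "xx_scc"):
        sites[kind], _ = run_cohort_pipeline(
            mini_arch, cohort, refpair, kind, "matched", reads, seed=51
        )
    return {
        "arch": mini_arch,
        "samples": cohort,
        "reads": reads,
        "golden": golden,
        "sites": sites,
    }


def labels_and_counts(bundle, kind, pass_only=True):
    arch, golden = bundle["arch"], bundle["golden"]
    called = bench.called_sites_by_sample(bundle["sites"][kind], pass_only=pass_only)
    labels = bench.classify_cohort(golden, called)
    counts = bench.stratify_by_region(labels, arch, golden)
    return labels, counts
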