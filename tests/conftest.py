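"""Shared fixtures: a desk-scale design and a noise-free simulated run.

The desk scale (2 groups x 12 samples x 4 amplicons, fixed depth 25) stands
in for the full 16 x 36 x 20 design; heavier whole-pipeline fixtures are
session-scoped so the aligner compiles and runs once.
"""

import pytest

from amplisnp import (
    CoverageModel,
    ErrorModel,
    build_pileup,
    demux_reads,
    make_design,
    run_cascade,
    simulate_haplotypes,
    simulate_reads,
)


@pytest.fixture(scope="session")
def desk_design():
    reference, panel, design = make_design(
        n_groups=2, samples_per_group=12, n_amplicons=4
    )
    return reference, panel, design


@pytest.fixture(scope="session")
def noise_free_run(desk_design):
    """Simulate -> demux -> align -> pileup -> cascade with all error rates
    zero: 40 planted variants (2-5 carriers each, 10% indels), depth 25."""
    reference, panel, design = desk_design
    variants = simulate_haplotypes(
        design,
        reference,
        n_variants=40,
        carrier_count_distribution=lambda rng: int(rng.integers(2, 6)),
        indel_fraction=0.1,
        seed=11,
    )
    reads, truth = simulate_reads(
        design,
        reference,
        variants,
        CoverageModel(mean_depth=25, sd_depth=0.0),
        ErrorModel(),
        seed=12,
    )
    assigned, unassigned = demux_reads(
        [(r.read_id, r.sequence, r.group_id) for r in reads], design
    )
    pileup = build_pileup(assigned, panel, reference)
    validated, trace = run_cascade(pileup, reference, panel)
    return {
        "reference": reference,
        "panel": panel,
        "design": design,
        "variants": variants,
        "reads": reads,
        "truth": truth,
        "assigned": assigned,
        "unassigned": unassigned,
        "pileup": pileup,
        "validated": validated,
        "trace": trace,
    }
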