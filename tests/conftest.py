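"""Shared fixtures: one moderately sized ground-truthed simulation that the
caller / recovery tests reuse, plus small helpers."""

from __future__ import annotations

import pytest

from amplimhc import (
    assign_genotypes,
    generate_allele_pool,
    simulate_amplicon_reads,
)
from amplimhc.calling import call_genotypes
from amplimhc.qc import QualityRead, run_qc
from amplimhc.simulate import FWD_PRIMER, REV_PRIMER, ReadSimConfig


def to_quality_reads(reads):
    return [
        QualityRead(rid, seq, [ord(c) - 33 for c in qual]) for rid, seq, qual in reads
    ]


def run_pipeline(pool, truth, readcfg, min_coverage=110):
    reads, truth_reads, mid_table = simulate_amplicon_reads(truth, pool, readcfg)
    qreads = to_quality_reads(reads)
    amplicons, rejects = run_qc(qreads, mid_table, (FWD_PRIMER, REV_PRIMER))
    catalog, matrix, audit = call_genotypes(amplicons, min_coverage=min_coverage)
    return {
        "reads": reads,
        "qreads": qreads,
        "truth_reads": truth_reads,
        "mid_table": mid_table,
        "amplicons": amplicons,
        "rejects": rejects,
        "catalog": catalog,
        "matrix": matrix,
        "audit": audit,
    }


@pytest.fixture(scope="session")
def study_pool():
    """The default 7x10 allele pool (70 nt / 60 aa alleles, indel alleles)."""
    return generate_allele_pool(seed=1)


@pytest.fixture(scope="session")
def study_truth(study_pool):
    return assign_genotypes(study_pool, seed=2)


@pytest.fixture(scope="session")
def noisy_run(study_pool, study_truth):
    """Full pipeline on a 454-style error simulation: 65 individuals,
    2x300 coverage, substitutions 2e-3/base, homopolymer indels, 3% chimeras."""
    cfg = ReadSimConfig(coverage=(300, 300, "uniform"), seed=3)
    return run_pipeline(study_pool, study_truth, cfg)


@pytest.fixture(scope="session")
def clean_run(study_pool, study_truth):
    """Same design with every error process switched off."""
    cfg = ReadSimConfig(
        substitution_rate=0.0,
        homopolymer_indel_rate=0.0,
        chimera_rate=0.0,
        low_quality_read_fraction=0.0,
        coverage=(300, 300, "uniform"),
        seed=4,
    )
    return run_pipeline(study_pool, study_truth, cfg)
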