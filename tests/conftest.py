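"""Shared fixtures: a small fast simulation and the full-scale study run.

Everything is generated programmatically; the only persistent state is the
in-memory pipeline result shared across tests of one session.
"""

from __future__ import annotations

import pytest

from sorgvar.pipeline import PipelineResult, run_full
from sorgvar.simdata import SimConfig


def small_config(seed: int = 1) -> SimConfig:
    """200-kb single-chromosome design used for fast integration tests."""
    return SimConfig(
        genome_length=200_000,
        n_chromosomes=1,
        n_genes=30,
        seed=seed,
        snps_per_line=60,
        coding_nonsyn_per_line=4,
        coding_syn_per_line=3,
        indels_per_line=12,
        coding_indels_per_line=2,
        intergenic_pavs_per_line=1,
        genic_pavs_per_line=0,
        cnv_ratios=(3.0,),
        sweet_snp_genes=2,
        sweet_indel_genes=1,
        sweet_pav_genes=1,
    )


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return small_config()


@pytest.fixture(scope="session")
def small_result(small_cfg) -> PipelineResult:
    return run_full(small_cfg)


@pytest.fixture(scope="session")
def study_cfg() -> SimConfig:
    """The full study design: 1 Mb, three lines, 12×, 44-bp pairs."""
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def study_result(study_cfg) -> PipelineResult:
    return run_full(study_cfg)
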