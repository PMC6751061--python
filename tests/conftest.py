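from __future__ import annotations

import time

import pytest

from rendscope import synthetic as syn
from rendscope.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def small_genome():
    """10 kb reference, two plus/minus TUs, one mask locus."""
    return syn.make_genome(
        n_refs=1,
        ref_lengths=10_000,
        n_tus=2,
        tu_spec=[
            {"length": 1500, "strand": "+", "abundance": {"c": 1.0, "i": 1.0}},
            {"length": 1200, "strand": "-", "abundance": {"c": 1.0, "i": 1.0}},
        ],
        seed=42,
    )


@pytest.fixture(scope="session")
def std_run(tmp_path_factory):
    """One full standard-fixture pipeline run (60 kb, 12 TUs, 8 induced
    100-fold, 50,000 reads per condition, seed 7), shared across tests."""
    out = tmp_path_factory.mktemp("std_run")
    cfg = PipelineConfig(output_dir=str(out), seed=7)
    t0 = time.monotonic()
    result = run_pipeline(cfg)
    elapsed = time.monotonic() - t0
    return result, elapsed


@pytest.fixture(scope="session")
def induced_truth(std_run):
    """Planted TSSs of the induced TUs of the standard run."""
    result, _ = std_run
    fc = {
        tu.name: tu.abundance["induced"] / max(tu.abundance["WT"], 1e-12)
        for tu in result.genome.planted_tus
    }
    return {
        tu.name: (tu.tss, tu.strand)
        for tu in result.genome.planted_tus
        if fc[tu.name] >= 10
    }
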