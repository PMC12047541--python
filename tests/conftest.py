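"""Shared fixtures: tiny genomes, panels, and a cached null-pipeline run."""

from __future__ import annotations

import numpy as np
import pytest

from aschip.variants import PhasedGenotypePanel, Variant


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def tiny_genome(rng):
    """A 6 kb random single-chromosome genome."""
    seq = "".join(rng.choice(list("ACGT"), size=6000))
    return {"chr1": seq}


def make_panel(variants: list[Variant], gts: list[list[tuple[int, int]]],
               samples: list[str] | None = None) -> PhasedGenotypePanel:
    if samples is None:
        samples = [f"S{j}" for j in range(len(gts[0]))]
    gt = np.array(gts, dtype=np.int8)
    return PhasedGenotypePanel(variants, samples, gt)


@pytest.fixture(scope="session")
def null_pipeline_run(tmp_path_factory):
    """Full read-level pipeline on the study-scale null simulation.

    Expensive (simulate, map, allele-swap filter, count for 8 lines x 20
    regions at 1,000 fragments/region), so computed once per session and
    shared between the calibration checks.
    """
    from aschip.synth import (SimulationConfig, mean_allelic_ratio,
                              run_read_pipeline, simulate_panel)

    workdir = tmp_path_factory.mktemp("nullrun")
    cfg = SimulationConfig(seed=42)
    sim = simulate_panel(cfg)
    bams, stats = run_read_pipeline(sim, str(workdir))
    ratio = mean_allelic_ratio(sim, bams)
    return {"sim": sim, "bams": bams, "stats": stats, "ratio": ratio}
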