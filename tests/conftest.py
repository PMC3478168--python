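"""Shared fixtures: a small synthetic bundle for unit tests and one full
default-size pipeline run reused by the acceptance tests."""

from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracles helpers

from orthodiv.pipeline import PipelineConfig, run_all, simulate_inputs


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A 60-gene synthetic input bundle with its ground truth."""
    cfg = PipelineConfig(seed=11, quiet=True)
    cfg.evol.n_genes = 60
    cfg.evol.seed = cfg.seed
    outdir = tmp_path_factory.mktemp("bundle60")
    paths, truth = simulate_inputs(cfg, outdir)
    return cfg, paths, truth


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """A complete 60-gene pipeline run (reports + truth)."""
    cfg = PipelineConfig(seed=11, quiet=True)
    cfg.evol.n_genes = 60
    workdir = tmp_path_factory.mktemp("run60")
    summary = run_all(cfg, workdir, simulate=True)
    return cfg, workdir, summary


@pytest.fixture(scope="session")
def full_run(tmp_path_factory):
    """One default-size (500-gene) end-to-end run at seed 7, with truth.

    Regenerates the truth objects in memory alongside the file-based run so
    tests can score outputs against ground truth.
    """
    from orthodiv import simulate as sim

    cfg = PipelineConfig(seed=7, quiet=True)
    workdir = tmp_path_factory.mktemp("run500")
    summary = run_all(cfg, workdir, simulate=True)
    # rebuild the same truth in memory (same seed, same order of draws)
    params = sim.EvolParams(seed=7)
    ancestors, truth = sim.simulate_ancestors(params)
    species_sets = sim.evolve_triple(ancestors, params, truth)
    species_sets = sim.plant_paralogs(species_sets, params, truth)
    sim.simulate_reads(species_sets["A"], params, truth)
    return cfg, workdir, summary, truth, species_sets
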