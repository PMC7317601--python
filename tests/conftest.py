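"""Shared fixtures: planted-truth simulations and a full demo run.

The 20-seed co-expression benchmark and the end-to-end demo are expensive, so
they are computed once per session and shared by the recovery, screening and
pipeline tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

from mirhub import pipeline, synthdata, wgcna

BENCH_SEEDS = range(20)
BENCH_MODULES = [60, 50, 40, 30]


@dataclass
class PlantedRun:
    """One planted-module simulation and its full co-expression analysis."""

    expr: pd.DataFrame
    truth: synthdata.PlantedTruth
    result: wgcna.WGCNAResult

    @property
    def planted_trait_genes(self) -> set[str]:
        return set(self.truth.trait_module_genes(list(self.expr.index), trait_module=0))

    @property
    def noise_genes(self) -> set[str]:
        return {g for g, lab in zip(self.expr.index, self.truth.module_label) if lab == 0}

    def high_loading_genes(self, floor: float = 0.8) -> set[str]:
        """Planted trait-module genes whose realized factor correlation exceeds the floor."""
        f = self.truth.latent_factors[0]
        fz = (f - f.mean()) / f.std(ddof=1)
        vals = self.expr.to_numpy()
        zs = (vals - vals.mean(1, keepdims=True)) / vals.std(1, ddof=1, keepdims=True)
        loading = zs @ fz / (len(f) - 1)
        return {
            g
            for g, lab, lo in zip(self.expr.index, self.truth.module_label, loading)
            if lab == 1 and abs(lo) > floor
        }


@pytest.fixture(scope="session")
def planted_runs() -> list[PlantedRun]:
    """Twenty seeded planted-module simulations with their analyses."""
    runs = []
    for seed in BENCH_SEEDS:
        cfg = synthdata.SimulationConfig(
            n_genes=500, n_samples=100, module_sizes=BENCH_MODULES,
            within_module_cor=0.64, trait_module=0, trait_cor=0.5, seed=seed,
        )
        expr, truth = synthdata.generate_modular_expression(cfg)
        traits = pd.DataFrame({"grade": truth.trait}, index=expr.columns)
        runs.append(PlantedRun(expr=expr, truth=truth, result=wgcna.run_wgcna(expr, traits)))
    return runs


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One fixed-seed end-to-end demo run (report + planted truth + inputs)."""
    import time

    outdir = tmp_path_factory.mktemp("demo")
    t0 = time.time()
    config, truth, expr = pipeline.generate_demo_inputs(outdir, seed=7)
    report = pipeline.run_all(config, force=True)
    elapsed = time.time() - t0
    return {
        "report": report, "truth": truth, "expr": expr,
        "outdir": outdir, "config": config, "elapsed": elapsed,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
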