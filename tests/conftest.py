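"""Shared fixtures: small deterministic replica sets and the default benchmark campaign."""

from __future__ import annotations

import numpy as np
import pytest

from dfekit.deposition_io import FESProfile, GaussianKernel, KernelSequence
from dfekit.fes_reconstruction import average_fes, primitive_fes
from dfekit.pipeline_cli import CampaignConfig, run_campaign
from dfekit.toy_metadynamics import benchmark_config, benchmark_potential, simulate_run

BENCHMARK_SEED_START = 2007
BENCHMARK_N = 50
BENCHMARK_DURATION = 3.0  # ns


def make_constant_profile(value: float, lo: float = 0.0, hi: float = 10.0, n: int = 101,
                          kind: str = "averaged") -> FESProfile:
    grid = np.linspace(lo, hi, n)
    return FESProfile(grid=grid, energies=np.full(n, float(value)), kind=kind)


def make_kernel_sequence(centers, width=0.05, height=0.01, wall=40.0, run_id="synthetic",
                         seed=0, dt=0.09) -> KernelSequence:
    kernels = [
        GaussianKernel(time=(i + 1) * dt, center=float(c), width=width, height=height)
        for i, c in enumerate(centers)
    ]
    duration = max(len(kernels) * dt / 1000.0, 1e-6)
    return KernelSequence(run_id=run_id, seed=seed, kernels=kernels,
                          wall_position=wall, duration=duration)


@pytest.fixture(scope="session")
def benchmark_replicas():
    """50 replicas of the default campaign (12 kcal/mol well), seed order 2007..2056."""
    pot = benchmark_potential()
    out = []
    for i in range(BENCHMARK_N):
        cfg = benchmark_config(seed=BENCHMARK_SEED_START + i, duration=BENCHMARK_DURATION)
        seq, traj = simulate_run(pot, cfg)
        out.append((seq, traj))
    return out


@pytest.fixture(scope="session")
def benchmark_primitives(benchmark_replicas):
    return [primitive_fes(seq) for seq, _ in benchmark_replicas]


@pytest.fixture(scope="session")
def benchmark_ensemble(benchmark_primitives, benchmark_replicas):
    return average_fes(benchmark_primitives, [seq.run_id for seq, _ in benchmark_replicas])


@pytest.fixture(scope="session")
def benchmark_manifest():
    """The full default campaign, as the pipeline runs it."""
    cfg = CampaignConfig(
        potential=benchmark_potential(),
        n_replicas=BENCHMARK_N,
        seed_start=BENCHMARK_SEED_START,
        duration=BENCHMARK_DURATION,
        campaign_id="default-benchmark",
    )
    return run_campaign(cfg, log=lambda msg: None)
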