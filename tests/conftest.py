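"""Shared fixtures: generated schemes and one full study run.

The study fixture runs the whole phantom -> fit -> track -> connectome
grid once per session at a reduced but representative scale (64^3
phantom, angular subsets {12, 45, 60, 120}, spatial factors {1, 4});
all trend and acceptance tests read from it so the expensive fits are
computed exactly once.
"""

from __future__ import annotations

import numpy as np
import pytest

from protocol_lab.gradients import (
    GradientScheme,
    generate_uniform_directions,
    interleave_b0s,
    subset_by_dot_product,
)
from protocol_lab.pipeline import ExperimentConfig, run_experiment

MASTER_SEED = 0


@pytest.fixture(scope="session")
def scheme120() -> GradientScheme:
    return generate_uniform_directions(120)


@pytest.fixture(scope="session")
def snapped(scheme120):
    """Snapped subsets of the 120-direction table, keyed by size."""
    out = {120: scheme120}
    for n in (12, 45, 60):
        target = generate_uniform_directions(n)
        out[n] = scheme120.subset(subset_by_dot_product(scheme120, target), name=f"snapped-{n}")
    return out


@pytest.fixture(scope="session")
def acq120(scheme120):
    """120-direction acquisition with interleaved b0 volumes."""
    return interleave_b0s(scheme120)


@pytest.fixture(scope="session")
def study(tmp_path_factory):
    """One full experiment run with intermediates retained."""
    config = ExperimentConfig(
        angles_imaging=(12, 45, 60, 120),
        factors=(1, 4),
        n_rotations=5000,
        n_bootstrap=25,
        samples_per_voxel=16,
        max_steps=260,
        master_seed=MASTER_SEED,
        keep_intermediates=True,
        outdir=str(tmp_path_factory.mktemp("study")),
    )
    return run_experiment(config)


def spearman_of(report, combo_a, combo_b) -> float:
    sp = report.spearman
    m = sp[
        ((sp.angles_a == combo_a[0]) & (sp.factor_a == combo_a[1])
         & (sp.angles_b == combo_b[0]) & (sp.factor_b == combo_b[1]))
        | ((sp.angles_a == combo_b[0]) & (sp.factor_a == combo_b[1])
           & (sp.angles_b == combo_a[0]) & (sp.factor_b == combo_a[1]))
    ]
    assert len(m) == 1
    return float(m.rho.iloc[0])
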