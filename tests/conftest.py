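"""Shared fixtures: small synthetic recordings and derived feature tables.

Everything is generated programmatically with fixed seeds; the heavier
session-scoped fixtures are shared across test modules to keep the suite
fast.
"""

from __future__ import annotations

import numpy as np
import pytest

from eegharx import (
    ActivityProfile,
    SimulationConfig,
    build_feature_table,
    generate_recording,
)
from eegharx.preprocess import segment_epochs
from eegharx.simulate import ACTIVITIES, artifact_free, default_profiles

FS = 250.0


@pytest.fixture(scope="session")
def clean_small_recording():
    """Artifact-free recording, 10 epochs per activity."""
    cfg = artifact_free(
        SimulationConfig(
            epochs_per_activity={a: 10 for a in ACTIVITIES}, seed=11
        )
    )
    return cfg, generate_recording(cfg)


@pytest.fixture(scope="session")
def clean_recovery_recording():
    """Artifact-free recording, 40 epochs per activity (for mean-recovery checks)."""
    cfg = artifact_free(
        SimulationConfig(
            epochs_per_activity={a: 40 for a in ACTIVITIES}, seed=2
        )
    )
    return cfg, generate_recording(cfg)


@pytest.fixture(scope="session")
def clean_feature_table(clean_recovery_recording):
    _, rec = clean_recovery_recording
    return build_feature_table(segment_epochs(rec))


def central_gamma_profiles() -> list[ActivityProfile]:
    """Profiles where the working activity is defined by elevated central
    gamma: every non-working class keeps central gamma low, and working's
    non-central regions copy reading's."""
    profs = {
        p.activity: {r: dict(b) for r, b in p.target_rp.items()}
        for p in default_profiles()
    }
    profs["working"] = {r: dict(profs["reading"][r]) for r in "FCTO"}
    profs["working"]["C"] = {
        "delta": 0.15, "theta": 0.15, "alpha": 0.15, "beta": 0.15, "gamma": 0.40,
    }
    profs["walking"]["C"] = {
        "delta": 0.15, "theta": 0.20, "alpha": 0.15, "beta": 0.42, "gamma": 0.08,
    }
    return [ActivityProfile(activity=a, target_rp=profs[a]) for a in ACTIVITIES]


@pytest.fixture(scope="session")
def labelled_feature_table(clean_small_recording):
    """Feature table from the small clean recording (40 rows)."""
    _, rec = clean_small_recording
    return build_feature_table(segment_epochs(rec))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
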