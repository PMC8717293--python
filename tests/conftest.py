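"""Shared fixtures: small virtual climates and the two expensive study
set-ups (oracle scenario suite, virtual-species recovery run) are built once
per session and reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from nichesdm.ensemble import (
    build_ensemble,
    fit_all_members,
    make_training_set,
    sample_pseudo_absences,
    split_train_eval,
)
from nichesdm.occurrences import background_env, extract_env
from nichesdm.synthetic import (
    SyntheticClimateSpec,
    VirtualNicheSpec,
    default_climate_spec,
    generate_climate_stack,
    sample_occurrences,
    true_suitability,
)

RECOVERY_VARIABLES = ["bio4", "bio5", "bio12"]


@pytest.fixture(scope="session")
def small_climate():
    """50 x 50 cells, two layers, moderate spatial autocorrelation."""
    spec = SyntheticClimateSpec(
        extent=(0.0, 40.0, 12.5, 52.5),
        resolution=15.0,
        layer_names=("bio5", "bio12"),
        value_ranges={"bio5": (5.0, 42.0), "bio12": (0.0, 3000.0)},
        autocorrelation_length=3.0,
        seed=11,
    )
    return generate_climate_stack(spec)


@pytest.fixture(scope="session")
def recovery_run():
    """Noiseless Gaussian virtual species, 500 presences + 10,000
    pseudo-absences on a 120 x 120 raster, full six-member ensemble."""
    spec = default_climate_spec(
        layer_names=tuple(RECOVERY_VARIABLES), seed=1, extent=(-10.0, 35.0, 10.0, 55.0)
    )
    climate = generate_climate_stack(spec)
    niche = VirtualNicheSpec(
        tuple(RECOVERY_VARIABLES),
        optimum=(600.0, 25.0, 1500.0),
        breadth=(90.0, 3.0, 280.0),
    )
    truth = true_suitability(climate, niche)
    occ = sample_occurrences(truth, 500, seed=2, status="native")
    pa = sample_pseudo_absences(occ, climate, n=10000, seed=3)
    ts = make_training_set(
        extract_env(occ, climate, RECOVERY_VARIABLES, "presence"),
        extract_env(pa, climate, RECOVERY_VARIABLES, "absence"),
    )
    train, evaluation = split_train_eval(ts, 0.8, seed=4)
    members = fit_all_members(train, evaluation, seed=5)
    ensemble = build_ensemble(members, cutoff=0.95)
    ensemble.evaluate(evaluation)
    return {
        "climate": climate,
        "niche": niche,
        "truth": truth,
        "occurrences": occ,
        "pseudo_absences": pa,
        "train": train,
        "evaluation": evaluation,
        "members": members,
        "ensemble": ensemble,
    }


@pytest.fixture(scope="session")
def uniform_wide_climate():
    """One very wide uniform-marginal layer pair; room for 10-breadth
    niche separations."""
    spec = SyntheticClimateSpec(
        extent=(-20.0, 30.0, 20.0, 60.0),
        layer_names=("bio5", "bio12"),
        value_ranges={"bio5": (0.0, 60.0), "bio12": (500.0, 1500.0)},
        marginal="uniform",
        seed=21,
    )
    return generate_climate_stack(spec)


@pytest.fixture(scope="session")
def background_scores(small_climate):
    rng = np.random.default_rng(0)
    bg = background_env(small_climate, ["bio5", "bio12"])
    return bg
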