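import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nichesdm.ensemble import (
    ALGORITHMS,
    EmptyEnsembleError,
    FittedMember,
    ModelSpec,
    PseudoAbsenceExhaustionError,
    StratificationError,
    UndefinedAUCError,
    build_ensemble,
    compute_auc,
    equal_sens_spec_threshold,
    fit_member,
    make_training_set,
    sample_pseudo_absences,
    split_train_eval,
    tss_from_rates,
)
from nichesdm.occurrences import EnvTable, make_occurrence_frame
from nichesdm.raster import ClimateStack, GridTransform


def _toy_training(n=200, seed=0, rule=lambda x: x[:, 1] > 30, noise=0.0):
    """Two-variable toy set; presence decided by `rule` on the env matrix,
    optionally with a small label-flip rate (perfectly separated labels make
    unpenalized logistic fits degenerate)."""
    rng = np.random.default_rng(seed)
    X = np.column_stack(
        [rng.uniform(0, 1000, 2 * n), rng.uniform(10, 50, 2 * n)]
    )
    y = rule(X).astype(int)
    if noise > 0:
        flip = rng.random(len(y)) < noise
        y = np.where(flip, 1 - y, y)
    pres = EnvTable(pd.DataFrame(X[y == 1], columns=["bio12", "bio5"]), "presence")
    abse = EnvTable(pd.DataFrame(X[y == 0], columns=["bio12", "bio5"]), "absence")
    return make_training_set(pres, abse)


class TestPseudoAbsences:
    def _stack(self, n=30):
        rng = np.random.default_rng(0)
        return ClimateStack(
            layers={"bio5": rng.uniform(5, 42, size=(n, n))},
            transform=GridTransform(0.0, float(n) / 4, 0.25),
        )

    def test_zero_radius_excludes_only_presence_cells(self):
        stack = self._stack(10)
        lon, lat = stack.transform.cell_center([0, 1], [0, 1])
        occ = make_occurrence_frame(lon, lat)
        pa = sample_pseudo_absences(occ, stack, n=98, exclusion_radius_km=0.0, seed=1)
        assert len(pa) == 98
        rows, cols = stack.transform.cell_of(pa["lon"].to_numpy(), pa["lat"].to_numpy())
        assert not set(zip(rows.tolist(), cols.tolist())) & {(0, 0), (1, 1)}

    def test_all_points_respect_radius(self):
        stack = self._stack(30)
        lon, lat = stack.transform.cell_center([15], [15])
        occ = make_occurrence_frame(lon, lat)
        radius = 80.0
        pa = sample_pseudo_absences(occ, stack, n=200, exclusion_radius_km=radius, seed=2)

        def gc_km(lon1, lat1, lon2, lat2):
            p1 = np.radians(lat1)
            p2 = np.radians(lat2)
            dlat = p2 - p1
            dlon = np.radians(lon2 - lon1)
            a = np.sin(dlat / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlon / 2) ** 2
            return 2 * 6371.0088 * np.arcsin(np.sqrt(a))

        d = gc_km(lon[0], lat[0], pa["lon"].to_numpy(), pa["lat"].to_numpy())
        assert (d >= radius).all()

    def test_exact_exhaustive_case(self):
        stack = self._stack(5)
        lon, lat = stack.transform.cell_center([0], [0])
        occ = make_occurrence_frame(lon, lat)
        pa = sample_pseudo_absences(occ, stack, n=24, exclusion_radius_km=0.0, seed=3)
        assert len(pa) == 24

    def test_exhaustion_reports_shortfall(self):
        stack = self._stack(5)
        lon, lat = stack.transform.cell_center([0], [0])
        occ = make_occurrence_frame(lon, lat)
        with pytest.raises(PseudoAbsenceExhaustionError, match="shortfall 1"):
            sample_pseudo_absences(occ, stack, n=25, exclusion_radius_km=0.0, seed=3)

    def test_reproducible(self):
        stack = self._stack(20)
        lon, lat = stack.transform.cell_center([5], [5])
        occ = make_occurrence_frame(lon, lat)
        a = sample_pseudo_absences(occ, stack, n=50, seed=7)
        b = sample_pseudo_absences(occ, stack, n=50, seed=7)
        assert a.equals(b)


class TestSplit:
    def test_stratified_80_20(self):
        ts = _toy_training(n=100, rule=lambda x: np.arange(len(x)) < len(x) // 2)
        train, ev = split_train_eval(ts, 0.8, seed=0)
        assert (train.labels == 1).sum() == 80 and (train.labels == 0).sum() == 80
        assert (ev.labels == 1).sum() == 20 and (ev.labels == 0).sum() == 20

    def test_same_seed_identical(self):
        ts = _toy_training(n=50)
        a_train, a_ev = split_train_eval(ts, 0.8, seed=4)
        b_train, b_ev = split_train_eval(ts, 0.8, seed=4)
        assert a_train.env.equals(b_train.env) and a_ev.env.equals(b_ev.env)

    def test_half_split_of_ten_and_ten(self):
        ts = _toy_training(n=10, rule=lambda x: np.arange(len(x)) < 10)
        train, ev = split_train_eval(ts, 0.5, seed=1)
        for part in (train, ev):
            assert (part.labels == 1).sum() == 5 and (part.labels == 0).sum() == 5

    def test_degenerate_split_raises(self):
        ts = _toy_training(n=2, rule=lambda x: np.arange(len(x)) < 2)
        with pytest.raises((StratificationError, ValueError)):
            split_train_eval(ts, 0.95, seed=0)


class TestAuc:
    def test_perfect_and_reversed(self):
        assert compute_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
        assert compute_auc([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0]) == 0.0

    def test_hand_example(self):
        assert compute_auc([0.9, 0.8, 0.4, 0.2], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_one_class_rejected(self):
        with pytest.raises(UndefinedAUCError):
            compute_auc([0.1, 0.2], [1, 1])

    def test_matches_pairwise_brute_force_on_random_data(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            scores = rng.choice([0.1, 0.3, 0.3, 0.7, 0.9], size=12)
            labels = rng.integers(0, 2, size=12)
            if labels.min() == labels.max():
                continue
            pos, neg = scores[labels == 1], scores[labels == 0]
            brute = np.mean(
                [(p > n) + 0.5 * (p == n) for p in pos for n in neg]
            )
            assert compute_auc(scores, labels) == pytest.approx(brute)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.random(30)
        labels = rng.integers(0, 2, 30)
        if labels.min() == labels.max():
            return
        a = compute_auc(scores, labels)
        b = compute_auc(np.exp(3 * scores) - 1, labels)
        assert a == pytest.approx(b)


class TestEqualSensSpec:
    def test_worked_consensus_rates(self):
        assert tss_from_rates(91.341, 89.940) == pytest.approx(0.813, abs=5e-4)

    def test_perfect_separation(self):
        t, sens, spec, tss = equal_sens_spec_threshold(
            [0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]
        )
        assert sens == 100.0 and spec == 100.0 and tss == pytest.approx(1.0)

    def test_coin_flip_scores(self):
        t, sens, spec, tss = equal_sens_spec_threshold(
            [0.6, 0.4, 0.6, 0.4], [1, 1, 0, 0]
        )
        assert sens == pytest.approx(50.0)
        assert spec == pytest.approx(50.0)
        assert tss == pytest.approx(0.0, abs=1e-12)

    def test_threshold_balances_rates(self):
        rng = np.random.default_rng(1)
        scores = np.concatenate([rng.normal(0.7, 0.15, 300), rng.normal(0.3, 0.15, 300)])
        labels = np.concatenate([np.ones(300, int), np.zeros(300, int)])
        t, sens, spec, tss = equal_sens_spec_threshold(scores, labels)
        assert abs(sens - spec) < 2.0
        assert tss == pytest.approx(sens / 100 + spec / 100 - 1)


class TestMembers:
    def test_every_algorithm_separates_toy_data(self):
        ts = _toy_training(n=150, seed=1, noise=0.02)
        train, ev = split_train_eval(ts, 0.8, seed=2)
        for alg in ALGORITHMS:
            m = fit_member(ModelSpec(alg, seed=3), train, ev)
            assert m.converged, f"{alg}: {m.diagnostics}"
            assert m.auc > 0.95, f"{alg} AUC {m.auc}"
            p = m.predict(ev.X)
            assert p.min() >= 0 and p.max() <= 1

    def test_glm_recovers_quadratic_term(self):
        hits = 0
        n_seeds = 25
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            X = rng.uniform(-2, 2, size=(600, 2))
            # presence probability peaks mid-range of x0: pure quadratic signal
            logit = 1.5 - 3.0 * X[:, 0] ** 2
            y = rng.random(600) < 1 / (1 + np.exp(-logit))
            if y.sum() < 10 or (~y).sum() < 10:
                continue
            pres = EnvTable(pd.DataFrame(X[y], columns=["a", "b"]), "presence")
            abse = EnvTable(pd.DataFrame(X[~y], columns=["a", "b"]), "absence")
            ts = make_training_set(pres, abse)
            m = fit_member(ModelSpec("GLM", seed=seed), ts)
            if "x0^2" in m.spec.hyperparameters["terms"]:
                hits += 1
        assert hits >= int(0.9 * n_seeds)

    def test_failed_member_is_flagged_not_fatal(self):
        ts = _toy_training(n=30)
        bad = ModelSpec("GAM", hyperparameters={"df": 5000}, seed=0)
        m = fit_member(bad, ts)
        assert not m.converged
        assert m.diagnostics


class _Const:
    def __init__(self, value):
        self.value = value

    def predict(self, X):
        return np.full(len(X), self.value)


def _member(auc, value):
    m = FittedMember(spec=ModelSpec("RF"), predictor=_Const(value))
    m.auc = auc
    return m


class TestEnsemble:
    def test_hand_weighted_mean(self):
        ens = build_ensemble([_member(0.96, 0.0), _member(0.98, 1.0)], cutoff=0.95)
        pred = ens.predict(np.zeros((1, 2)))
        assert pred[0] == pytest.approx(0.98 / 1.94, abs=1e-9)

    def test_single_qualifying_member(self):
        ens = build_ensemble([_member(0.99, 0.7), _member(0.90, 0.1)], cutoff=0.95)
        assert len(ens.members) == 1
        assert ens.predict(np.zeros((3, 2))) == pytest.approx([0.7] * 3)

    def test_member_at_cutoff_excluded(self):
        with pytest.raises(EmptyEnsembleError):
            build_ensemble([_member(0.94, 0.5)], cutoff=0.95)

    def test_prediction_within_member_range(self):
        members = [_member(0.96, 0.2), _member(0.97, 0.5), _member(0.99, 0.9)]
        ens = build_ensemble(members, cutoff=0.95)
        pred = ens.predict(np.zeros((5, 2)))
        assert (pred >= 0.2).all() and (pred <= 0.9).all()

    def test_weights_sum_to_one(self):
        ens = build_ensemble([_member(0.96, 0.0), _member(0.98, 1.0)], cutoff=0.95)
        assert ens.weights.sum() == pytest.approx(1.0)
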