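"""Presence/pseudo-absence ensemble habitat-suitability modelling.

Six presence-absence algorithms — artificial neural network (ANN),
generalized additive model (GAM), gradient-boosted trees (GBM), logistic
regression with stepwise quadratic selection (GLM), flexible discriminant
analysis (FDA) and random forest (RF) — are fitted to presences plus
pseudo-absences drawn by a disk strategy (random background cells outside a
buffer around every presence).  Members are evaluated on a held-out split by
ROC AUC and the true skill statistic (TSS = sensitivity + specificity - 1)
at the equal-sensitivity/specificity threshold; members with AUC above a
cutoff (default 0.95) are combined into a consensus whose prediction is the
AUC-weighted mean of member suitabilities.

Hyperparameters follow the ensemble-modelling conventions for these
algorithms: ANN tunes hidden size and weight decay by 5-fold
cross-validation with at most 200 iterations; GBM uses up to 2500 trees,
learning rate 0.01, interaction depth 7 and at least 10 observations per
terminal node (tree count picked by internal validation); GLM does
bidirectional stepwise AIC over linear + quadratic terms; RF grows 500
trees with node size 5; FDA uses an adaptive piecewise-linear (hinge)
regression basis with at most 21 functions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .occurrences import EnvTable
from .raster import ClimateStack

__all__ = [
    "ALGORITHMS",
    "TrainingSet",
    "ModelSpec",
    "FittedMember",
    "Ensemble",
    "sample_pseudo_absences",
    "make_training_set",
    "split_train_eval",
    "fit_member",
    "fit_all_members",
    "compute_auc",
    "tss_from_rates",
    "equal_sens_spec_threshold",
    "build_ensemble",
]

ALGORITHMS = ("ANN", "GAM", "GBM", "GLM", "FDA", "RF")

_EARTH_RADIUS_KM = 6371.0088


class PseudoAbsenceExhaustionError(RuntimeError):
    """Fewer eligible background cells than pseudo-absences requested."""


class StratificationError(ValueError):
    pass


class UndefinedAUCError(ValueError):
    pass


class EmptyEnsembleError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Training data
# ---------------------------------------------------------------------------


@dataclass
class TrainingSet:
    """Presence (1) / pseudo-absence (0) rows with class-balancing weights."""

    env: pd.DataFrame  # chosen climate variables, fixed column order
    labels: np.ndarray  # 0/1
    weights: np.ndarray  # per-row; presence and absence classes sum equal

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.env.isna().any().any():
            raise ValueError("training environment contains missing values")
        if set(np.unique(self.labels)) != {0, 1}:
            raise ValueError("training set must contain both classes")

    @property
    def X(self) -> np.ndarray:
        return self.env.to_numpy(dtype=float)

    @property
    def variables(self) -> list[str]:
        return list(self.env.columns)


def make_training_set(presence_env: EnvTable, absence_env: EnvTable) -> TrainingSet:
    """Stack presence and pseudo-absence environments; weight the classes to
    equal total weight (prevalence 0.5) so 10,000 absences cannot swamp a
    few hundred presences."""
    if list(presence_env.data.columns) != list(absence_env.data.columns):
        raise ValueError("presence and absence tables have different variables")
    env = pd.concat([presence_env.data, absence_env.data], ignore_index=True)
    n1, n0 = len(presence_env.data), len(absence_env.data)
    labels = np.concatenate([np.ones(n1, int), np.zeros(n0, int)])
    weights = np.concatenate([np.full(n1, 0.5 / n1), np.full(n0, 0.5 / n0)])
    weights = weights / weights.mean()  # mean-1 scaling keeps likelihoods sane
    return TrainingSet(env=env, labels=labels, weights=weights)


def sample_pseudo_absences(
    presences: pd.DataFrame,
    stack: ClimateStack,
    n: int = 10000,
    exclusion_radius_km: float | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Disk-strategy pseudo-absences: n distinct non-nodata cells, all at
    least ``exclusion_radius_km`` (great-circle, cell centre to cell centre)
    from every presence, drawn uniformly over the eligible cells.

    The default radius is two grid cells.  Presence cells themselves are
    always ineligible, even with radius 0.
    """
    from sklearn.neighbors import BallTree

    if exclusion_radius_km is None:
        exclusion_radius_km = 2.0 * stack.transform.cell_size * 111.19
    rows, cols = stack.valid_cells()
    lon, lat = stack.transform.cell_center(rows, cols)

    prow, pcol = stack.transform.cell_of(
        presences["lon"].to_numpy(), presences["lat"].to_numpy()
    )
    nrow, ncol = stack.shape
    inside = (prow >= 0) & (prow < nrow) & (pcol >= 0) & (pcol < ncol)
    prow, pcol = prow[inside], pcol[inside]
    plon, plat = stack.transform.cell_center(prow, pcol)

    eligible = np.ones(len(rows), dtype=bool)
    # presence cells are out regardless of the radius
    presence_ids = set(zip(prow.tolist(), pcol.tolist()))
    cell_ids = list(zip(rows.tolist(), cols.tolist()))
    eligible &= np.array([cid not in presence_ids for cid in cell_ids])
    if exclusion_radius_km > 0 and len(plon):
        tree = BallTree(np.radians(np.column_stack([plat, plon])), metric="haversine")
        dist, _ = tree.query(np.radians(np.column_stack([lat, lon])), k=1)
        eligible &= dist[:, 0] * _EARTH_RADIUS_KM >= exclusion_radius_km

    idx = np.nonzero(eligible)[0]
    if len(idx) < n:
        raise PseudoAbsenceExhaustionError(
            f"requested {n} pseudo-absences but only {len(idx)} eligible cells "
            f"(shortfall {n - len(idx)})"
        )
    rng = np.random.default_rng(seed)
    pick = idx if len(idx) == n else rng.choice(idx, size=n, replace=False)
    from .occurrences import make_occurrence_frame

    return make_occurrence_frame(
        lon[pick], lat[pick], species="pseudo-absence", status="absence"
    )


def split_train_eval(
    ts: TrainingSet, fraction: float = 0.8, seed: int = 0
) -> tuple[TrainingSet, TrainingSet]:
    """Stratified train/evaluation split (single split by default)."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    idx = np.arange(len(ts.labels))
    try:
        train_idx, eval_idx = train_test_split(
            idx,
            train_size=fraction,
            stratify=ts.labels,
            random_state=seed,
            shuffle=True,
        )
    except ValueError as exc:
        raise StratificationError(str(exc))
    out = []
    for sel in (train_idx, eval_idx):
        labels = ts.labels[sel]
        if len(np.unique(labels)) < 2:
            raise StratificationError("a split lost one of the classes")
        out.append(
            TrainingSet(
                env=ts.env.iloc[sel].reset_index(drop=True),
                labels=labels,
                weights=ts.weights[sel],
            )
        )
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Scores and thresholds
# ---------------------------------------------------------------------------


def compute_auc(scores, labels) -> float:
    """Rank-based AUC (Mann-Whitney), ties counted half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise UndefinedAUCError("AUC needs both classes")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def tss_from_rates(sensitivity_pct: float, specificity_pct: float) -> float:
    """True skill statistic from percentage rates: sens + spec - 1."""
    return sensitivity_pct / 100.0 + specificity_pct / 100.0 - 1.0


def equal_sens_spec_threshold(scores, labels) -> tuple[float, float, float, float]:
    """Binarization threshold where sensitivity and specificity are closest.

    Candidate thresholds are the midpoints between consecutive distinct
    scores; ties on |sens - spec| break toward higher TSS, then lower
    threshold.  Returns (threshold, sensitivity %, specificity %, TSS).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise UndefinedAUCError("threshold needs both classes")
    uniq = np.unique(scores)
    if len(uniq) == 1:
        cands = uniq
    else:
        cands = (uniq[:-1] + uniq[1:]) / 2.0
    best = None
    for t in cands:
        sens = float((pos >= t).mean())
        spec = float((neg < t).mean())
        key = (abs(sens - spec), -(sens + spec - 1.0), t)
        if best is None or key < best[0]:
            best = (key, t, sens, spec)
    _, t, sens, spec = best
    return float(t), sens * 100.0, spec * 100.0, sens + spec - 1.0


# ---------------------------------------------------------------------------
# Member models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    algorithm: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; expected one of {ALGORITHMS}"
            )


@dataclass
class FittedMember:
    spec: ModelSpec
    predictor: object  # has .predict(X: ndarray) -> suitability in [0, 1]
    converged: bool = True
    diagnostics: str = ""
    auc: float | None = None
    tss: float | None = None
    threshold: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None

    def predict(self, X) -> np.ndarray:
        p = np.asarray(self.predictor.predict(np.asarray(X, dtype=float)))
        return np.clip(p, 0.0, 1.0)

    def evaluate(self, eval_ts: TrainingSet) -> None:
        scores = self.predict(eval_ts.X)
        self.auc = compute_auc(scores, eval_ts.labels)
        t, sens, spec, tss = equal_sens_spec_threshold(scores, eval_ts.labels)
        self.threshold, self.sensitivity, self.specificity, self.tss = (
            t, sens, spec, tss,
        )

    def card(self) -> dict:
        return {
            "algorithm": self.spec.algorithm,
            "hyperparameters": self.spec.hyperparameters,
            "seed": self.spec.seed,
            "converged": self.converged,
            "auc": self.auc,
            "tss": self.tss,
            "threshold": self.threshold,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


class _SklearnProbPredictor:
    def __init__(self, model):
        self.model = model

    def predict(self, X):
        return self.model.predict_proba(X)[:, 1]


def _replicate_for_balance(X, y, weights):
    """Integer-replicate rows so per-class totals match the weights
    (for estimators that accept no sample weights)."""
    w = weights / weights.min()
    reps = np.maximum(np.round(w).astype(int), 1)
    idx = np.repeat(np.arange(len(y)), reps)
    return X[idx], y[idx]


def _fit_ann(train: TrainingSet, seed: int, hp: dict):
    sizes = hp.get("hidden_sizes", (2, 4, 6, 8))
    decays = hp.get("decays", (0.001, 0.01, 0.1))
    max_iter = hp.get("max_iter", 200)
    pipe = Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "mlp",
                MLPClassifier(max_iter=max_iter, random_state=seed, solver="lbfgs"),
            ),
        ]
    )
    grid = {
        "mlp__hidden_layer_sizes": [(s,) for s in sizes],
        "mlp__alpha": list(decays),
    }
    cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    search = GridSearchCV(pipe, grid, scoring="roc_auc", cv=cv, n_jobs=1)
    Xb, yb = _replicate_for_balance(train.X, train.labels, train.weights)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        search.fit(Xb, yb)
    return _SklearnProbPredictor(search.best_estimator_), {
        "hidden_size": search.best_params_["mlp__hidden_layer_sizes"][0],
        "decay": search.best_params_["mlp__alpha"],
    }


def _fit_gbm(train: TrainingSet, seed: int, hp: dict):
    model = GradientBoostingClassifier(
        n_estimators=hp.get("max_trees", 2500),
        learning_rate=hp.get("learning_rate", 0.01),
        max_depth=hp.get("interaction_depth", 7),
        min_samples_leaf=hp.get("min_obs_in_node", 10),
        validation_fraction=0.2,
        n_iter_no_change=hp.get("patience", 25),
        random_state=seed,
    )
    model.fit(train.X, train.labels, sample_weight=train.weights)
    return _SklearnProbPredictor(model), {"n_trees_used": int(model.n_estimators_)}


def _fit_rf(train: TrainingSet, seed: int, hp: dict):
    model = RandomForestClassifier(
        n_estimators=hp.get("n_trees", 500),
        min_samples_leaf=hp.get("node_size", 5),
        random_state=seed,
        n_jobs=1,
    )
    model.fit(train.X, train.labels, sample_weight=train.weights)
    return _SklearnProbPredictor(model), {}


class _GlmPredictor:
    def __init__(self, result, terms, mean, scale):
        self.result, self.terms, self.mean, self.scale = result, terms, mean, scale

    def design(self, X):
        Xs = (X - self.mean) / self.scale
        cols = [np.ones(len(Xs))]
        for j, p in self.terms:
            cols.append(Xs[:, j] ** p)
        return np.column_stack(cols)

    def predict(self, X):
        return np.asarray(self.result.predict(self.design(X)))


def _fit_glm(train: TrainingSet, seed: int, hp: dict):
    """Logistic regression with bidirectional stepwise AIC over linear and
    quadratic terms (quadratic allowed only alongside its linear term)."""
    X = train.X
    mean, scale = X.mean(axis=0), X.std(axis=0)
    scale[scale == 0] = 1.0
    Xs = (X - mean) / scale
    y = train.labels
    w = train.weights
    k = X.shape[1]
    all_terms = [(j, 1) for j in range(k)] + [(j, 2) for j in range(k)]

    def aic_of(terms):
        cols = [np.ones(len(y))] + [Xs[:, j] ** p for j, p in terms]
        design = np.column_stack(cols)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, design, family=sm.families.Binomial(), var_weights=w).fit()
        return res.aic, res

    current = list(all_terms)  # start from the full model, step both ways
    best_aic, best_res = aic_of(current)
    improved = True
    while improved:
        improved = False
        moves = []
        for t in all_terms:
            if t in current:
                j, p = t
                if p == 1 and (j, 2) in current:
                    continue  # keep hierarchy: drop quadratic first
                moves.append([x for x in current if x != t])
            else:
                j, p = t
                if p == 2 and (j, 1) not in current:
                    continue
                moves.append(current + [t])
        for cand in moves:
            aic, res = aic_of(cand)
            if aic < best_aic - 1e-9:
                best_aic, best_res, current, improved = aic, res, cand, True
        # greedy: accept the single best move per sweep
    sel = sorted(current)
    best_aic, best_res = aic_of(sel)  # refit so coefficients match column order
    return _GlmPredictor(best_res, sel, mean, scale), {
        "terms": [f"x{j}^{p}" for j, p in sel],
        "aic": float(best_aic),
    }


class _GamPredictor:
    def __init__(self, result, smoother, train_min, train_max):
        self.result = result
        self.smoother = smoother
        self.train_min, self.train_max = train_min, train_max

    def predict(self, X):
        Xc = np.clip(X, self.train_min, self.train_max)
        return np.asarray(
            self.result.predict(np.ones((len(Xc), 1)), exog_smooth=Xc)
        )


def _fit_gam(train: TrainingSet, seed: int, hp: dict):
    from statsmodels.gam.api import BSplines, GLMGam

    X = train.X
    k = X.shape[1]
    df = hp.get("df", 6)
    smoother = BSplines(X, df=[df] * k, degree=[3] * k)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = GLMGam(
            train.labels,
            exog=np.ones((len(X), 1)),
            smoother=smoother,
            family=sm.families.Binomial(),
        )
        res = model.fit()
    return _GamPredictor(res, smoother, X.min(axis=0), X.max(axis=0)), {"df": df}


class _FdaPredictor:
    """Optimal-scoring discriminant on a hinge basis, with a logistic map
    from discriminant score to probability."""

    def __init__(self, basis, coef, calibrator):
        self.basis, self.coef, self.calibrator = basis, coef, calibrator

    def design(self, X):
        cols = [np.ones(len(X))]
        for j, knot, sign in self.basis:
            h = np.maximum(sign * (X[:, j] - knot), 0.0)
            cols.append(h)
        return np.column_stack(cols)

    def predict(self, X):
        score = self.design(X) @ self.coef
        return self.calibrator.predict_proba(score[:, None])[:, 1]


def _fit_fda(train: TrainingSet, seed: int, hp: dict):
    """Forward-selected piecewise-linear (hinge) basis, weighted least
    squares on optimal scores, then logistic calibration of the score."""
    X = train.X
    y = train.labels.astype(float)
    w = train.weights
    max_basis = hp.get("max_basis", 21)
    n, k = X.shape
    # optimal scores for two classes reduce to the centred class indicator
    target = np.where(y == 1, 1.0, -1.0)
    knots = [
        (j, q)
        for j in range(k)
        for q in np.quantile(X[:, j], np.linspace(0.1, 0.9, 9))
    ]
    sw = np.sqrt(w)

    def wrss(design):
        a = design * sw[:, None]
        b = target * sw
        coef, *_ = np.linalg.lstsq(a, b, rcond=None)
        resid = b - a @ coef
        return float(resid @ resid), coef

    basis: list[tuple[int, float, float]] = []
    design = np.ones((n, 1))
    best_rss, coef = wrss(design)
    while len(basis) + 1 < max_basis - 1:
        best_gain, best_add = 0.0, None
        for j, knot in knots:
            if any(bj == j and bk == knot for bj, bk, _ in basis):
                continue
            hplus = np.maximum(X[:, j] - knot, 0.0)
            hminus = np.maximum(knot - X[:, j], 0.0)
            cand = np.column_stack([design, hplus, hminus])
            rss, c = wrss(cand)
            gain = best_rss - rss
            if gain > best_gain:
                best_gain, best_add = gain, (j, knot, cand, c, rss)
        if best_add is None or best_gain < 1e-6 * best_rss:
            break
        j, knot, design, coef, best_rss = best_add
        basis.append((j, knot, 1.0))
        basis.append((j, knot, -1.0))
    score = design @ coef
    calibrator = LogisticRegression(C=1e6, max_iter=1000)
    calibrator.fit(score[:, None], train.labels, sample_weight=w)
    return _FdaPredictor(basis, coef, calibrator), {"n_basis": len(basis) + 1}


_FITTERS = {
    "ANN": _fit_ann,
    "GAM": _fit_gam,
    "GBM": _fit_gbm,
    "GLM": _fit_glm,
    "FDA": _fit_fda,
    "RF": _fit_rf,
}


def fit_member(
    spec: ModelSpec, train: TrainingSet, evaluation: TrainingSet | None = None
) -> FittedMember:
    """Fit one algorithm; optionally evaluate on a held-out set.

    A member that fails to fit is returned flagged (``converged=False``)
    with the error message in ``diagnostics`` so the caller can exclude it
    from the ensemble rather than abort the run.
    """
    fitter = _FITTERS[spec.algorithm]
    try:
        predictor, info = fitter(train, spec.seed, dict(spec.hyperparameters))
    except Exception as exc:  # noqa: BLE001 - member failure is data, not fatal
        return FittedMember(
            spec=spec, predictor=None, converged=False, diagnostics=str(exc)
        )
    member = FittedMember(
        spec=ModelSpec(spec.algorithm, {**spec.hyperparameters, **info}, spec.seed),
        predictor=predictor,
    )
    if evaluation is not None:
        member.evaluate(evaluation)
    return member


def fit_all_members(
    train: TrainingSet,
    evaluation: TrainingSet,
    seed: int = 0,
    algorithms=ALGORITHMS,
) -> list[FittedMember]:
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=len(algorithms))
    return [
        fit_member(ModelSpec(a, seed=int(s)), train, evaluation)
        for a, s in zip(algorithms, seeds)
    ]


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------


@dataclass
class Ensemble:
    members: list[FittedMember]
    weights: np.ndarray
    cutoff: float
    threshold: float | None = None  # equal-sens/spec cut of the consensus
    auc: float | None = None
    tss: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        preds = np.stack([m.predict(X) for m in self.members])
        return np.einsum("m,mn->n", self.weights, preds)

    def evaluate(self, eval_ts: TrainingSet) -> None:
        scores = self.predict(eval_ts.X)
        self.auc = compute_auc(scores, eval_ts.labels)
        t, sens, spec, tss = equal_sens_spec_threshold(scores, eval_ts.labels)
        self.threshold, self.sensitivity, self.specificity, self.tss = (
            t, sens, spec, tss,
        )

    def manifest(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "weights": {
                m.spec.algorithm: float(w) for m, w in zip(self.members, self.weights)
            },
            "auc": self.auc,
            "tss": self.tss,
            "threshold": self.threshold,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "members": [m.card() for m in self.members],
        }


def build_ensemble(members: list[FittedMember], cutoff: float = 0.95) -> Ensemble:
    """AUC-weighted consensus of members with evaluation AUC above cutoff."""
    scored = [m for m in members if m.converged and m.auc is not None]
    kept = [m for m in scored if m.auc > cutoff]
    if not kept:
        aucs = {m.spec.algorithm: round(m.auc, 3) for m in scored}
        raise EmptyEnsembleError(
            f"no member has AUC > {cutoff}; member AUCs: {aucs} — "
            "consider reviewing the cutoff"
        )
    aucs = np.array([m.auc for m in kept])
    return Ensemble(members=kept, weights=aucs / aucs.sum(), cutoff=cutoff)
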