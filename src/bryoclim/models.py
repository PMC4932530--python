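"""The three modelling techniques, their evaluation, and the AUC-weighted
consensus.

Techniques
----------
* ``envelope`` -- a climatic-envelope (BIOCLIM-style) score: for each
  variable the presence empirical CDF ``F`` gives a symmetric percentile
  score ``s(v) = 1 - 2|F(v) - 0.5|``; a site scores the minimum over
  variables, and 0 outside the presence min-max on any variable.
* ``maxent_like`` -- a penalized presence-background discriminative model
  on standardized linear + quadratic features with an L1 penalty (convex,
  deterministic, sparse); the logistic output is the suitability.
* ``random_forest`` -- class-probability output of a seeded random forest
  (delegated to scikit-learn).

Calibration weights presences and pseudo-absences to neutral (0.5)
prevalence.  Performance is assessed by repeated 70/30 stratified splits
scored with AUC and TSS; techniques failing mean AUC >= 0.8 or mean
TSS >= 0.7 are eliminated, and the survivors form a consensus whose
weights are proportional to mean AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression


class ModelError(RuntimeError):
    pass


class NoPassingModelError(ModelError):
    """All candidate techniques failed the AUC/TSS quality filter."""


# ---------------------------------------------------------------------------
# evaluation statistics


def auc(scores_presence: Sequence[float], scores_absence: Sequence[float]) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic.

    Equals P(presence score > absence score) + 0.5 P(tie).
    """
    sp = np.asarray(scores_presence, dtype=float)
    sa = np.asarray(scores_absence, dtype=float)
    if sp.size == 0 or sa.size == 0:
        raise ValueError("both score lists must be non-empty")
    ranks = rankdata(np.concatenate([sp, sa]))
    r_p = ranks[: sp.size].sum()
    return float((r_p - sp.size * (sp.size + 1) / 2) / (sp.size * sa.size))


def tss(scores_presence: Sequence[float], scores_absence: Sequence[float]) -> float:
    """True skill statistic: max over observed thresholds of sens + spec - 1.

    A site is classified present when its score is >= the threshold; every
    distinct observed score is tried as a threshold.
    """
    sp = np.asarray(scores_presence, dtype=float)
    sa = np.asarray(scores_absence, dtype=float)
    if sp.size == 0 or sa.size == 0:
        raise ValueError("both score lists must be non-empty")
    best = -1.0
    for t in np.unique(np.concatenate([sp, sa])):
        sens = np.mean(sp >= t)
        spec = np.mean(sa < t)
        best = max(best, float(sens + spec - 1))
    return best


def prevalence_weights(n_presence: int, n_absence: int) -> tuple[float, float]:
    """Per-record weights giving neutral (0.5) prevalence; w_presence = 1."""
    if n_presence < 1 or n_absence < 1:
        raise ValueError("both classes need at least one record")
    return 1.0, n_presence / n_absence


# ---------------------------------------------------------------------------
# technique: climatic envelope


@dataclass
class EnvelopeModel:
    technique: str = field(default="envelope", init=False)
    variables: list[str] = field(default_factory=list)
    presence_values: list[np.ndarray] = field(default_factory=list)  # sorted per variable

    def predict(self, env: np.ndarray) -> np.ndarray:
        env = np.atleast_2d(np.asarray(env, dtype=float))
        n = env.shape[0]
        suit = np.ones(n)
        for j, vals in enumerate(self.presence_values):
            v = env[:, j]
            lo, hi = vals[0], vals[-1]
            if lo == hi:  # degenerate envelope: spike at the constant value
                s = np.where(v == lo, 1.0, 0.0)
            else:
                # mid-rank empirical CDF of the presence sample
                below = np.searchsorted(vals, v, side="left")
                at = np.searchsorted(vals, v, side="right") - below
                f = (below + 0.5 * at) / vals.size
                s = 1.0 - 2.0 * np.abs(f - 0.5)
                s = np.where((v < lo) | (v > hi), 0.0, s)
            suit = np.minimum(suit, s)
        return suit


def fit_envelope(presence_env: np.ndarray, variables: Sequence[str]) -> EnvelopeModel:
    """Fit the per-variable percentile envelope on presence environments."""
    x = np.asarray(presence_env, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3:
        raise ModelError("envelope needs >= 3 presences")
    if not np.isfinite(x).all():
        raise ModelError("envelope input contains missing values")
    cols = []
    import logging

    for j, name in enumerate(variables):
        vals = np.sort(x[:, j])
        if vals[0] == vals[-1]:
            logging.getLogger(__name__).info(
                "envelope: variable %s constant across presences (degenerate)", name
            )
        cols.append(vals)
    return EnvelopeModel(variables=list(variables), presence_values=cols)


# ---------------------------------------------------------------------------
# technique: penalized presence-background model


@dataclass
class MaxentLikeModel:
    technique: str = field(default="maxent_like", init=False)
    variables: list[str] = field(default_factory=list)
    feature_means: np.ndarray | None = None
    feature_sds: np.ndarray | None = None
    coef: np.ndarray | None = None
    intercept: float = 0.0
    features: str = "lq"

    def _design(self, env: np.ndarray) -> np.ndarray:
        env = np.atleast_2d(np.asarray(env, dtype=float))
        if self.features == "lq":
            raw = np.hstack([env, env**2])
        else:
            raw = env
        return (raw - self.feature_means) / self.feature_sds

    def predict(self, env: np.ndarray) -> np.ndarray:
        z = self._design(env) @ self.coef + self.intercept
        return 1.0 / (1.0 + np.exp(-z))

    @property
    def linear_coef_(self) -> dict[str, float]:
        """Linear-term coefficients on the original variable scale."""
        k = len(self.variables)
        return {
            v: float(self.coef[j] / self.feature_sds[j]) for j, v in enumerate(self.variables)
        }


def fit_maxent_like(
    presence_env: np.ndarray,
    background_env: np.ndarray,
    variables: Sequence[str],
    regularization: float = 1.0,
    features: str = "lq",
    max_iter: int = 2000,
) -> MaxentLikeModel:
    """Fit the penalized presence-background discriminative model.

    ``regularization`` scales the L1 penalty (larger = sparser).  Records
    are weighted to neutral prevalence.  Raises :class:`ModelError` on
    non-convergence.
    """
    xp = np.asarray(presence_env, dtype=float)
    xb = np.asarray(background_env, dtype=float)
    if xp.shape[0] < 5:
        raise ModelError("maxent_like needs >= 5 presences")
    if xb.shape[0] < xp.shape[0]:
        raise ModelError("background must be at least as large as the presence set")
    if features not in ("l", "lq"):
        raise ValueError(f"unknown feature set '{features}'")

    x = np.vstack([xp, xb])
    raw = np.hstack([x, x**2]) if features == "lq" else x
    means = raw.mean(axis=0)
    sds = raw.std(axis=0)
    sds = np.where(sds == 0, 1.0, sds)
    design = (raw - means) / sds

    y = np.concatenate([np.ones(xp.shape[0]), np.zeros(xb.shape[0])])
    w_p, w_a = prevalence_weights(xp.shape[0], xb.shape[0])
    w = np.where(y == 1, w_p, w_a)

    clf = LogisticRegression(
        l1_ratio=1.0,
        C=1.0 / regularization,
        solver="liblinear",
        max_iter=max_iter,
        random_state=0,
        tol=1e-8,
    )
    clf.fit(design, y, sample_weight=w)
    if clf.n_iter_[0] >= max_iter:
        raise ModelError(
            f"maxent_like did not converge within {max_iter} iterations "
            f"(n={x.shape[0]}, regularization={regularization})"
        )
    return MaxentLikeModel(
        variables=list(variables),
        feature_means=means,
        feature_sds=sds,
        coef=clf.coef_.ravel(),
        intercept=float(clf.intercept_[0]),
        features=features,
    )


# ---------------------------------------------------------------------------
# technique: random forest


@dataclass
class RandomForestModel:
    technique: str = field(default="random_forest", init=False)
    variables: list[str] = field(default_factory=list)
    forest: RandomForestClassifier | None = None

    def predict(self, env: np.ndarray) -> np.ndarray:
        env = np.atleast_2d(np.asarray(env, dtype=float))
        return self.forest.predict_proba(env)[:, 1]


def fit_random_forest(
    presence_env: np.ndarray,
    background_env: np.ndarray,
    variables: Sequence[str],
    n_trees: int = 100,
    seed: int = 0,
) -> RandomForestModel:
    """Fit a seeded random forest on neutral-prevalence weighted data."""
    xp = np.asarray(presence_env, dtype=float)
    xb = np.asarray(background_env, dtype=float)
    if xp.shape[0] == 0 or xb.shape[0] == 0:
        raise ModelError("random forest needs both classes present")
    x = np.vstack([xp, xb])
    y = np.concatenate([np.ones(xp.shape[0]), np.zeros(xb.shape[0])])
    w_p, w_a = prevalence_weights(xp.shape[0], xb.shape[0])
    w = np.where(y == 1, w_p, w_a)
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    forest.fit(x, y, sample_weight=w)
    return RandomForestModel(variables=list(variables), forest=forest)


# ---------------------------------------------------------------------------
# evaluation by repeated splitting


@dataclass
class EvaluationResult:
    technique: str
    aucs: list[float]
    tsses: list[float]
    auc_min: float = 0.8
    tss_min: float = 0.7

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.aucs))

    @property
    def mean_tss(self) -> float:
        return float(np.mean(self.tsses))

    @property
    def passed(self) -> bool:
        return self.mean_auc >= self.auc_min and self.mean_tss >= self.tss_min


def evaluate(
    fitter: Callable[[np.ndarray, np.ndarray], "object"],
    presence_env: np.ndarray,
    background_env: np.ndarray,
    split: float = 0.7,
    reps: int = 10,
    seed: int = 0,
    auc_min: float = 0.8,
    tss_min: float = 0.7,
    technique: str = "model",
) -> EvaluationResult:
    """Repeated stratified-split evaluation of one technique.

    Each of ``reps`` splits keeps ``split`` of each class for calibration
    and scores the rest with AUC and TSS; the pass flag applies the quality
    thresholds to the means across splits.
    """
    xp = np.asarray(presence_env, dtype=float)
    xb = np.asarray(background_env, dtype=float)
    n_p_train = int(round(split * xp.shape[0]))
    n_b_train = int(round(split * xb.shape[0]))
    if min(n_p_train, xp.shape[0] - n_p_train) < 2 or min(n_b_train, xb.shape[0] - n_b_train) < 2:
        raise ModelError(
            f"split {split} infeasible: classes of size {xp.shape[0]}/{xb.shape[0]} "
            f"leave fewer than 2 records in a partition"
        )
    aucs, tsses = [], []
    for rep in range(reps):
        rng = np.random.default_rng([seed, rep])
        pi = rng.permutation(xp.shape[0])
        bi = rng.permutation(xb.shape[0])
        model = fitter(xp[pi[:n_p_train]], xb[bi[:n_b_train]])
        sp = model.predict(xp[pi[n_p_train:]])
        sa = model.predict(xb[bi[n_b_train:]])
        aucs.append(auc(sp, sa))
        tsses.append(tss(sp, sa))
    return EvaluationResult(
        technique=technique, aucs=aucs, tsses=tsses, auc_min=auc_min, tss_min=tss_min
    )


# ---------------------------------------------------------------------------
# consensus


@dataclass
class EnsembleModel:
    """Surviving techniques with normalized AUC-proportional weights."""

    members: list
    weights: np.ndarray
    variables: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.members) < 1:
            raise ModelError("ensemble needs at least one member")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ModelError(f"weights sum to {self.weights.sum()!r}, not 1")

    def predict(self, env: np.ndarray) -> np.ndarray:
        env = np.atleast_2d(np.asarray(env, dtype=float))
        out = np.zeros(env.shape[0])
        for w, m in zip(self.weights, self.members):
            out += w * m.predict(env)
        return out


def build_consensus(evaluated: list[tuple[object, EvaluationResult]]) -> EnsembleModel:
    """Combine passing techniques, weighting each by its mean AUC.

    Weights use the raw mean AUC (not AUC - 0.5 rescaling), normalized to
    sum to 1.  Raises :class:`NoPassingModelError` when every technique was
    eliminated; callers exclude the species and log the reason.
    """
    passing = [(m, e) for m, e in evaluated if e.passed]
    if not passing:
        detail = ", ".join(
            f"{e.technique}: AUC={e.mean_auc:.3f} TSS={e.mean_tss:.3f}" for _, e in evaluated
        )
        raise NoPassingModelError(f"no technique passed the quality filter ({detail})")
    aucs = np.array([e.mean_auc for _, e in passing])
    weights = aucs / aucs.sum()
    members = [m for m, _ in passing]
    return EnsembleModel(
        members=members, weights=weights, variables=list(members[0].variables)
    )
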