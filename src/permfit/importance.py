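"""Permutation feature importance test with cross-fitting.

The importance of feature j is measured as the drop in per-observation
Bernoulli log-likelihood caused by replacing the validation column j with a
random permutation of itself:

    M_ij = Y_i log(pihat(x_i) / pihat(x_i^(j)))
         + (1 - Y_i) log((1 - pihat(x_i)) / (1 - pihat(x_i^(j))))

Scores are averaged over ``n_perm`` independent permutations per
observation, then over the n_V validation observations; the test statistic
is the one-sample z

    delta = mean / se,      p = 1 - Phi(delta),

where se estimates the sampling SD of the mean score (observation
component plus a permutation Monte-Carlo component; see
:func:`_score_stats`).  The estimator is always fitted on data disjoint from the
validation set (cross-fitting) so that overfitting does not masquerade as
importance.  Multi-column encodings of one clinical feature are permuted
jointly as a block and tested as a single feature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cohort import CohortTable, split_data
from .learners import RiskEstimator, fit_learner

logger = logging.getLogger(__name__)

__all__ = [
    "PermutationPlan",
    "ImportanceResult",
    "permute_feature",
    "per_obs_importance",
    "importance_test",
    "run_permfit",
    "select_important",
]

P_FLOOR = 1e-16


@dataclass(frozen=True)
class PermutationPlan:
    """Number of permutations and per-permutation seeds for one feature test."""

    n_perm: int = 100
    seed: int = 0
    seeds: tuple = field(default=None)

    def __post_init__(self):
        if self.seeds is None:
            ss = np.random.SeedSequence(self.seed).spawn(self.n_perm)
            object.__setattr__(
                self, "seeds", tuple(int(s.generate_state(1)[0] % 2**31) for s in ss)
            )
        if len(self.seeds) != self.n_perm:
            raise ValueError("need one seed per permutation")


@dataclass(frozen=True)
class ImportanceResult:
    """Permutation importance of one clinical feature on the validation set."""

    feature: str
    score: float        # mean permutation-averaged per-observation score
    se: float           # standard error of that mean
    z: float            # delta = score / se
    p_value: float      # one-sided upper-tail normal probability
    n_validation: int
    n_perm: int = 0

    @property
    def display_p(self) -> str:
        return "<0.001" if self.p_value < 0.001 else f"{self.p_value:.3f}"


def permute_feature(
    X: np.ndarray, j: int | list[int], seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Return a copy of ``X`` with column(s) ``j`` jointly row-permuted.

    ``j`` may be a single column index or the list of encoded columns of one
    categorical feature; the same row rearrangement is applied to all of
    them so the feature's level pattern stays intact.  A single-row matrix
    is returned unchanged.
    """
    X = np.asarray(X)
    out = X.copy()
    if X.shape[0] < 2:
        return out
    cols = [j] if np.isscalar(j) else list(j)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    order = rng.permutation(X.shape[0])
    out[:, cols] = X[np.ix_(order, cols)]
    return out


def per_obs_importance(
    pi_orig: np.ndarray, pi_perm: np.ndarray, Y: np.ndarray
) -> np.ndarray:
    """Per-observation log-likelihood drop between original and permuted fits."""
    pi_orig, pi_perm, Y = map(np.asarray, (pi_orig, pi_perm, Y))
    if not (pi_orig.shape == pi_perm.shape == Y.shape):
        raise ValueError(
            f"length mismatch: {pi_orig.shape}, {pi_perm.shape}, {Y.shape}"
        )
    return Y * np.log(pi_orig / pi_perm) + (1 - Y) * np.log((1 - pi_orig) / (1 - pi_perm))


def _score_stats(
    scores: np.ndarray, orders: np.ndarray | None, variance_mode: str
) -> tuple[float, float, float, float]:
    """mean, se, z, p from an (n_perm, n_V) matrix of per-observation scores.

    ``scores[k, i]`` is the score of observation i under permutation k,
    i.e. the pair kernel h(i, j) evaluated at j = orders[k, i] (the row
    whose feature value observation i received).  The mean score is an
    incomplete U-statistic over ordered pairs, so the default SE uses the
    Hajek projection: g_i = (row mean_i + column mean_i)/2, where the row
    mean averages scores in which i is the observation and the column mean
    averages scores in which i donated the permuted value.  Then

        se^2 = 4 Var(g)/n_V + Var(per-permutation means)/n_perm,

    the second term being the Monte-Carlo noise of sampling only n_perm of
    the n_V! permutations.  The column component captures the positive
    cross-observation covariance that makes the naive s/sqrt(n_V)
    anti-conservative, most visibly for low-prevalence binary features.
    ``variance_mode="simple"`` is that naive form; ``"unscaled"`` uses the
    per-observation SD itself (a z that does not shrink with n_V), kept
    for comparison with implementations that report that convention.
    """
    n_perm, n_v = scores.shape
    per_obs = scores.mean(axis=0)
    mean = float(scores.mean())
    if variance_mode == "unscaled":
        # per-observation SD, not the SD of the mean
        se = float(per_obs.std(ddof=0))
    elif variance_mode == "simple":
        se = float(per_obs.std(ddof=1)) / np.sqrt(n_v)
    elif variance_mode == "mean":
        if orders is None:
            raise ValueError("variance_mode='mean' needs the permutation orders")
        col = np.zeros(n_v)
        for k in range(n_perm):
            np.add.at(col, orders[k], scores[k])
        g = (per_obs + col / n_perm) / 2.0
        perm_var = (scores.mean(axis=1).var(ddof=1) / n_perm) if n_perm > 1 else 0.0
        se = float(np.sqrt(4.0 * g.var(ddof=1) / n_v + perm_var))
    else:
        raise ValueError(f"unknown variance_mode {variance_mode!r}")
    if se == 0.0:
        return mean, 0.0, 0.0, 1.0
    z = mean / se
    p = float(stats.norm.sf(z))
    return mean, se, z, max(p, P_FLOOR)


def importance_test(
    estimator: RiskEstimator,
    validation: CohortTable,
    j: int | str,
    plan: PermutationPlan | None = None,
    variance_mode: str = "mean",
) -> ImportanceResult:
    """Test one clinical feature's importance on a held-out validation table.

    ``j`` is a feature name or its position in ``validation.meta``.  All
    ``plan.n_perm`` permutations are scored; per-observation scores are
    averaged across permutations before the mean/SD over observations.
    """
    plan = plan or PermutationPlan()
    name = validation.feature_names[j] if isinstance(j, (int, np.integer)) else j
    cols = validation.column_map[name]
    n_v = validation.n
    if n_v < 2:
        raise ValueError("validation set needs >= 2 rows")
    Xv, Yv = validation.X, validation.Y

    pi_orig = estimator.predict_prob(Xv)
    # stack all permuted copies into one matrix: one predict call per feature
    orders = np.empty((plan.n_perm, n_v), dtype=int)
    stacked = np.tile(Xv, (plan.n_perm, 1))
    for k, s in enumerate(plan.seeds):
        orders[k] = np.random.default_rng(s).permutation(n_v)
        block = slice(k * n_v, (k + 1) * n_v)
        stacked[block, :][:, cols] = Xv[np.ix_(orders[k], cols)]
    pi_perm = estimator.predict_prob(stacked).reshape(plan.n_perm, n_v)

    scores = per_obs_importance(
        np.broadcast_to(pi_orig, (plan.n_perm, n_v)), pi_perm,
        np.broadcast_to(Yv, (plan.n_perm, n_v)),
    )
    mean, se, z, p = _score_stats(scores, orders, variance_mode)
    return ImportanceResult(
        feature=name, score=mean, se=se, z=z, p_value=p,
        n_validation=n_v, n_perm=plan.n_perm,
    )


def _combine_folds(parts: list[ImportanceResult], feature: str) -> ImportanceResult:
    """Pool per-fold importance estimates; folds have disjoint validation
    rows, so their estimates are combined as independent weighted means."""
    n = sum(p.n_validation for p in parts)
    w = np.array([p.n_validation / n for p in parts])
    mean = float(np.sum(w * [p.score for p in parts]))
    se = float(np.sqrt(np.sum(w**2 * np.array([p.se for p in parts]) ** 2)))
    if se == 0.0:
        z, p = 0.0, 1.0
    else:
        z = mean / se
        p = max(float(stats.norm.sf(z)), P_FLOOR)
    return ImportanceResult(feature=feature, score=mean, se=se, z=z, p_value=p,
                            n_validation=n, n_perm=parts[0].n_perm)


def _stratified_folds(Y: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    folds = np.zeros(Y.size, dtype=int)
    for cls in np.unique(Y):
        rows = rng.permutation(np.flatnonzero(Y == cls))
        folds[rows] = np.arange(rows.size) % k
    return folds


def run_permfit(
    cohort: CohortTable,
    learner_kind: str = "dnn_ensemble",
    configs: dict | None = None,
    val_fraction: float = 0.2,
    alpha: float = 0.05,
    n_perm: int = 100,
    seed: int = 0,
    variance_mode: str = "mean",
    k_folds: int | None = None,
) -> list[ImportanceResult]:
    """End-to-end feature-identification procedure.

    By default the cohort is split once into a fitting portion and a
    stratified ``val_fraction`` validation portion; the learner is fitted
    on the former and every clinical feature is tested on the latter.  With
    ``k_folds`` set, K-fold cross-fitting is used instead: each fold is
    scored by a learner fitted on the other folds, so every observation
    contributes a validation score and per-fold estimates are pooled.
    Results are returned in the cohort's feature order.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if not cohort.has_both_classes():
        raise ValueError("cohort outcome must contain both classes")
    names = cohort.feature_names
    plan_seeds = [
        int(ss.generate_state(1)[0] % 2**31)
        for ss in np.random.SeedSequence(seed).spawn(len(names))
    ]

    def _test_all(estimator, val_part, seed_offset=0) -> list[ImportanceResult]:
        out = []
        for name, ps in zip(names, plan_seeds):
            plan = PermutationPlan(n_perm=n_perm, seed=ps + seed_offset)
            try:
                out.append(importance_test(estimator, val_part, name, plan, variance_mode))
            except Exception as exc:
                raise RuntimeError(f"importance test failed for feature {name!r}") from exc
        return out

    if k_folds is not None:
        if k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        folds = _stratified_folds(cohort.Y, k_folds, np.random.default_rng(seed))
        per_fold = []
        for f in range(k_folds):
            fit_part = cohort.subset_rows(np.flatnonzero(folds != f))
            val_part = cohort.subset_rows(np.flatnonzero(folds == f))
            estimator = fit_learner(fit_part, learner_kind, configs, seed=seed)
            per_fold.append(_test_all(estimator, val_part, seed_offset=f + 1))
        logger.info("permfit: learner=%s %d-fold cross-fit n=%d n_perm=%d seed=%d",
                    learner_kind, k_folds, cohort.n, n_perm, seed)
        return [
            _combine_folds([per_fold[f][j] for f in range(k_folds)], name)
            for j, name in enumerate(names)
        ]

    split = split_data(
        cohort, test_n=max(2, int(round(val_fraction * cohort.n))),
        seed=seed, stratified=True,
    )
    fit_part = cohort.subset_rows(split.train_idx)
    val_part = cohort.subset_rows(split.test_idx)
    estimator = fit_learner(fit_part, learner_kind, configs, seed=seed)
    logger.info(
        "permfit: learner=%s n_fit=%d n_val=%d n_perm=%d seed=%d",
        learner_kind, fit_part.n, val_part.n, n_perm, seed,
    )
    return _test_all(estimator, val_part)


def select_important(
    results: list[ImportanceResult], alpha: float = 0.05, adjust: str | None = None
) -> list[str]:
    """Features with p < alpha, sorted by p ascending.

    No multiplicity adjustment by default; ``adjust`` may name any method
    accepted by ``statsmodels.stats.multitest.multipletests`` (e.g.
    ``"fdr_bh"``, ``"bonferroni"``).
    """
    if not results:
        raise ValueError("empty results")
    p = np.array([r.p_value for r in results])
    if adjust is not None:
        from statsmodels.stats.multitest import multipletests
        p = multipletests(p, alpha=alpha, method=adjust)[1]
    order = np.argsort(p, kind="stable")
    return [results[i].feature for i in order if p[i] < alpha]
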