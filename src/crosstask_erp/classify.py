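"""Shrinkage-regularized LDA and the transfer-evaluation schemes.

With ~800 epochs and 930 spatio-temporal features the empirical covariance
is poorly conditioned, so the discriminant uses an analytically shrunk
estimate: Sigma_hat = (1-gamma) S + gamma nu I, where S is the pooled
(class-wise centered) empirical covariance, nu = trace(S)/D its mean
eigenvalue, and gamma the closed-form optimal shrinkage intensity (ratio of
the summed sampling variances of the entries of S to the squared Frobenius
distance between S and nu I, clipped to [0, 1]).

Evaluation follows the study design: the rank-based AUC, 10-fold
cross-validation within a condition, full-train/full-test transfer between
conditions (3 x 3 matrices per participant), leave-one-participant-out
transfer, a learning curve over the number of training subjects (conditions
merged), and one-sided Wilcoxon signed-rank population tests against
chance (AUC 0.5) with Bonferroni correction over the nine train/test
combinations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .containers import FeatureMatrix

logger = logging.getLogger(__name__)


class FittingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# shrinkage covariance and LDA

def analytic_shrinkage_covariance(X_centered: np.ndarray) -> tuple[np.ndarray, float]:
    """Shrunk covariance (1-gamma) S + gamma nu I with the closed-form
    optimal gamma.

    ``X_centered`` must hold already-centered rows; S is computed with the
    1/n convention.  For degenerate input with zero dispersion around the
    shrinkage target, gamma is forced to 1 with a warning.
    """
    X = np.asarray(X_centered, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise FittingError("need at least two centered observations")
    n, d = X.shape
    S = (X.T @ X) / n
    nu = np.trace(S) / d
    target_dist2 = np.sum((S - nu * np.eye(d)) ** 2)
    if target_dist2 <= 0:
        logger.warning("covariance equals the shrinkage target; gamma forced to 1")
        return nu * np.eye(d), 1.0
    # sum over entries of the estimated Var(S_ij):
    #   (1/n^2) sum_k ||x_k x_k' - S||_F^2 = (1/n^2) sum_k ||x_k||^4 - (1/n)||S||_F^2
    sq_norms = np.einsum("ij,ij->i", X, X)
    var_sum = np.sum(sq_norms**2) / n**2 - np.sum(S**2) / n
    gamma = float(np.clip(var_sum / target_dist2, 0.0, 1.0))
    sigma = (1.0 - gamma) * S + gamma * nu * np.eye(d)
    return sigma, gamma


@dataclass
class LdaModel:
    """Fitted linear discriminant: score(x) = w . x + b."""

    w: np.ndarray
    b: float
    gamma: float
    mean_target: np.ndarray
    mean_distractor: np.ndarray
    nu: float = 0.0

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.w + self.b


def fit_lda(X: np.ndarray, y: np.ndarray, gamma: float | None = None) -> LdaModel:
    """Fit shrinkage LDA for targets (y=1) versus distractors (y=0).

    The pooled covariance is estimated from class-wise centered epochs with
    the analytic shrinkage intensity (or a fixed ``gamma`` if given);
    w = Sigma_hat^{-1} (mu1 - mu0), and the bias places the decision
    threshold midway between the projected class means (irrelevant to AUC,
    which is rank-based).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if set(np.unique(y)) != {0, 1}:
        raise FittingError("both classes (0 and 1) must be present")
    mu0 = X[y == 0].mean(axis=0)
    mu1 = X[y == 1].mean(axis=0)
    Xc = X - np.where(y[:, None] == 1, mu1[None, :], mu0[None, :])

    n, d = X.shape
    nu = float(np.einsum("ij,ij->", Xc, Xc) / (n * d))  # trace(S)/d
    if gamma is None:
        gamma = _analytic_gamma(Xc, nu)
    elif not (0.0 <= gamma <= 1.0):
        raise FittingError("gamma must lie in [0, 1]")
    diff = mu1 - mu0
    if nu <= 0:
        logger.warning("zero-variance features; falling back to the class-mean "
                       "difference direction")
        w = diff.copy()
    else:
        w = _solve_shrunk(Xc, diff, gamma, nu)
    b = float(-w @ (mu1 + mu0) / 2.0)
    return LdaModel(w=w, b=b, gamma=float(gamma), mean_target=mu1,
                    mean_distractor=mu0, nu=float(nu))


def _analytic_gamma(Xc: np.ndarray, nu: float) -> float:
    """Closed-form shrinkage intensity without materializing S when the
    problem is undersampled (n < d): uses ||S||_F^2 = ||G||_F^2 / n^2 with
    the n x n Gram matrix G = Xc Xc'."""
    n, d = Xc.shape
    if d <= n:
        _, gamma = analytic_shrinkage_covariance(Xc)
        return gamma
    G = Xc @ Xc.T
    s_frob2 = float(np.einsum("ij,ij->", G, G)) / n**2
    target_dist2 = s_frob2 - nu**2 * d  # ||S - nu I||_F^2, since trace(S) = nu d
    if target_dist2 <= 0:
        logger.warning("covariance equals the shrinkage target; gamma forced to 1")
        return 1.0
    sq_norms = np.diag(G)
    var_sum = float(np.sum(sq_norms**2)) / n**2 - s_frob2 / n
    return float(np.clip(var_sum / target_dist2, 0.0, 1.0))


def _solve_shrunk(Xc: np.ndarray, rhs: np.ndarray, gamma: float, nu: float
                  ) -> np.ndarray:
    """Solve ((1-gamma) Xc'Xc/n + gamma nu I) w = rhs.

    Undersampled problems (n < d, gamma > 0) are solved in the dual n x n
    space via the Woodbury identity; otherwise directly in feature space.
    """
    n, d = Xc.shape
    alpha = gamma * nu
    beta = (1.0 - gamma) / n
    if n < d and alpha > 0:
        G = Xc @ Xc.T
        inner = G / alpha + (1.0 / beta) * np.eye(n) if beta > 0 else None
        if inner is None:  # gamma == 1: pure identity target
            return rhs / alpha
        c = cho_factor(inner)
        return rhs / alpha - (Xc.T @ cho_solve(c, Xc @ rhs)) / alpha**2
    S = (Xc.T @ Xc) / n
    sigma = (1.0 - gamma) * S + alpha * np.eye(d)
    try:
        c = cho_factor(sigma)
        return cho_solve(c, rhs)
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(sigma, rhs, rcond=None)[0]


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve with midrank tie
    handling; invariant under strictly increasing score transforms."""
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: only one class present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


# ---------------------------------------------------------------------------
# evaluation schemes

def crossvalidate_within(X: np.ndarray, y: np.ndarray, k: int = 10,
                         seed: int = 0) -> float:
    """Mean AUC over stratified k-fold cross-validation."""
    y = np.asarray(y).astype(int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise FittingError(
            f"smallest class has {counts.min()} epochs; cannot build {k} stratified folds"
        )
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    aucs = []
    for train, test in cv.split(X, y):
        model = fit_lda(X[train], y[train])
        aucs.append(auc(model.decision_scores(X[test]), y[test]))
    return float(np.mean(aucs))


@dataclass
class TransferResult:
    """3x3 AUC matrix over (train condition, test condition)."""

    auc: np.ndarray
    conditions: list[str]
    participant: str = ""
    scheme: str = "within"  # within | across

    def cell(self, train: str, test: str) -> float:
        return float(self.auc[self.conditions.index(train),
                              self.conditions.index(test)])


FeaturesByCondition = dict[str, FeatureMatrix]


def transfer_within_participant(features: FeaturesByCondition, k: int = 10,
                                seed: int = 0) -> TransferResult:
    """All pairwise train/test condition combinations for one participant.

    Off-diagonal cells train on all epochs of one condition and test on all
    epochs of another; diagonal cells come from stratified k-fold
    cross-validation (the two are not directly comparable).
    """
    conds = sorted(features)
    n = len(conds)
    out = np.full((n, n), np.nan)
    participant = next(iter(features.values())).participant
    for i, ctr in enumerate(conds):
        ftr = features[ctr]
        model = fit_lda(ftr.X, ftr.y)
        for j, cte in enumerate(conds):
            if i == j:
                out[i, j] = crossvalidate_within(ftr.X, ftr.y, k=k, seed=seed)
            else:
                fte = features[cte]
                out[i, j] = auc(model.decision_scores(fte.X), fte.y)
    return TransferResult(auc=out, conditions=conds, participant=participant,
                          scheme="within")


Cohort = dict[str, FeaturesByCondition]  # participant -> condition -> features


def _pooled(features_list: list[FeatureMatrix]) -> tuple[np.ndarray, np.ndarray]:
    X = np.concatenate([f.X for f in features_list], axis=0)
    y = np.concatenate([f.y for f in features_list], axis=0)
    return X, y


def transfer_across_participants(cohort: Cohort) -> list[TransferResult]:
    """Leave-one-participant-out transfer for every train/test condition
    combination; each participant is tested once."""
    participants = sorted(cohort)
    if len(participants) < 2:
        raise FittingError("need at least two participants")
    conds = sorted(next(iter(cohort.values())))
    results = []
    for held_out in participants:
        train_parts = [p for p in participants if p != held_out]
        mat = np.full((len(conds), len(conds)), np.nan)
        for i, ctr in enumerate(conds):
            Xtr, ytr = _pooled([cohort[p][ctr] for p in train_parts])
            model = fit_lda(Xtr, ytr)
            for j, cte in enumerate(conds):
                fte = cohort[held_out][cte]
                mat[i, j] = auc(model.decision_scores(fte.X), fte.y)
        results.append(TransferResult(auc=mat, conditions=conds,
                                      participant=held_out, scheme="across"))
    return results


@dataclass
class LearningCurve:
    """Across-participant AUC versus number of training subjects
    (conditions merged)."""

    n_train_subjects: np.ndarray
    #: participants x n-values mean AUC over redraws
    auc: np.ndarray
    participants: list[str]
    n_draws: int
    #: bootstrap 68% CI of the across-participant mean per n, shape (2, n)
    ci68: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def mean_auc(self) -> np.ndarray:
        return self.auc.mean(axis=0)


def learning_curve(cohort: Cohort, n_range: range | list[int] | None = None,
                   n_draws: int = 20, seed: int = 0,
                   n_boot: int = 1000) -> LearningCurve:
    """Across-participant AUC as a function of the number of training
    subjects, with conditions merged.

    For each held-out participant and each n, ``n_draws`` random subsets of
    n training subjects are drawn from the remainder; the per-(participant,
    n) AUC is the mean over draws.  The 68% bootstrap CI of the mean across
    participants is attached.
    """
    from .discriminability import bootstrap_ci

    participants = sorted(cohort)
    n_max = len(participants) - 1
    if n_max < 1:
        raise FittingError("need at least two participants")
    ns = list(n_range) if n_range is not None else list(range(1, n_max + 1))
    if any(n < 1 or n > n_max for n in ns):
        raise FittingError(f"n_range must lie within 1..{n_max}")
    rng = np.random.default_rng(seed)

    merged = {p: _pooled(list(cohort[p].values())) for p in participants}
    aucs = np.zeros((len(participants), len(ns)))
    for pi, held_out in enumerate(participants):
        rest = [p for p in participants if p != held_out]
        Xte, yte = merged[held_out]
        for ni, n in enumerate(ns):
            draws = []
            seen: set[tuple[str, ...]] = set()
            max_distinct = _n_choose_k(len(rest), n)
            for _ in range(min(n_draws, max_distinct)):
                for _attempt in range(1000):
                    pick = tuple(sorted(rng.choice(rest, size=n, replace=False)))
                    if pick not in seen or len(seen) >= max_distinct:
                        break
                seen.add(pick)
                Xtr = np.concatenate([merged[p][0] for p in pick], axis=0)
                ytr = np.concatenate([merged[p][1] for p in pick], axis=0)
                model = fit_lda(Xtr, ytr)
                draws.append(auc(model.decision_scores(Xte), yte))
            aucs[pi, ni] = float(np.mean(draws))
    ci = np.array([
        bootstrap_ci(aucs[:, ni], n_boot=n_boot, level=0.68, seed=rng)
        for ni in range(len(ns))
    ]).T
    return LearningCurve(n_train_subjects=np.array(ns), auc=aucs,
                         participants=participants, n_draws=n_draws, ci68=ci)


def _n_choose_k(n: int, k: int) -> int:
    from math import comb

    return comb(n, k)


# ---------------------------------------------------------------------------
# population statistics

def population_test(per_participant_aucs: np.ndarray, chance: float = 0.5,
                    n_comparisons: int = 9) -> dict[str, np.ndarray | float]:
    """One-sided Wilcoxon signed-rank test (above chance) per transfer cell.

    ``per_participant_aucs`` has shape (participants, ...); the test is run
    along the first axis for every trailing cell.  Bonferroni correction
    multiplies p by ``n_comparisons`` (capped at 1).
    """
    arr = np.asarray(per_participant_aucs, dtype=float)
    cells = arr.reshape(arr.shape[0], -1)
    p_raw = np.empty(cells.shape[1])
    for j in range(cells.shape[1]):
        diffs = cells[:, j] - chance
        if np.allclose(diffs, 0.0):
            p_raw[j] = 1.0
            continue
        res = stats.wilcoxon(diffs, alternative="greater")
        p_raw[j] = res.pvalue
    p_corr = np.minimum(p_raw * n_comparisons, 1.0)
    shape = arr.shape[1:] if arr.ndim > 1 else ()
    return {
        "p_uncorrected": p_raw.reshape(shape) if shape else float(p_raw[0]),
        "p_corrected": p_corr.reshape(shape) if shape else float(p_corr[0]),
        "n_comparisons": n_comparisons,
    }


def stack_transfer(results: list[TransferResult]) -> np.ndarray:
    """Stack per-participant 3x3 AUC matrices into participants x 3 x 3."""
    conds = results[0].conditions
    for r in results:
        if r.conditions != conds:
            raise ValueError("condition sets differ between results")
    return np.stack([r.auc for r in results])
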