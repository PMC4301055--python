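"""Linear discriminant classification of calls to individuals.

This is the statistical core of the individuality analysis: Fisher linear
classification functions from group means and the pooled within-group
covariance, resubstitution (or leave-one-out) classification matrices,
per-variable partial Wilks' lambda contributions, and the label-permutation
null distribution of classification accuracy that replaces the naive 1/k
chance level.

Resubstitution accuracy (classifying the training calls themselves) is the
primary accuracy measure: its overfitting inflation is exactly what the
permutation null quantifies, which is why chance levels far above 1/k are
meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_GROUP_COL = "individual_id"


class SingularCovarianceError(np.linalg.LinAlgError):
    """Pooled within-group covariance is singular; names suspect variables."""


@dataclass
class DFAModel:
    """Linear classification functions: score_g(x) = x' C_g + c_g + ln p_g."""

    groups: np.ndarray          # group labels, in fitting order
    means: np.ndarray           # (k, p) group means
    pooled_cov: np.ndarray      # (p, p) pooled within-group covariance
    coef: np.ndarray            # (k, p) classification-function coefficients
    intercept: np.ndarray       # (k,) classification-function constants
    priors: np.ndarray          # (k,)
    variables: tuple[str, ...]

    def scores(self, X: np.ndarray) -> np.ndarray:
        return X @ self.coef.T + self.intercept


@dataclass
class ClassificationResult:
    """Confusion matrix and percent-correct summaries of one classification."""

    groups: np.ndarray
    confusion: np.ndarray       # (k, k) true x assigned counts
    n_calls: int

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def n_correct(self) -> int:
        return int(np.trace(self.confusion))

    @property
    def average_pct_correct(self) -> float:
        return 100.0 * self.n_correct / self.n_calls

    @property
    def per_group_pct_correct(self) -> np.ndarray:
        sizes = self.confusion.sum(axis=1)
        return 100.0 * np.diag(self.confusion) / np.maximum(sizes, 1)

    def to_dict(self) -> dict:
        return {
            "groups": list(map(str, self.groups)),
            "confusion": self.confusion.tolist(),
            "n_calls": self.n_calls,
            "average_pct_correct": self.average_pct_correct,
            "per_group_pct_correct": self.per_group_pct_correct.tolist(),
        }


@dataclass
class VariableContribution:
    variable: str
    partial_lambda: float       # in (0, 1]; smaller = more discriminative
    f_to_remove: float


@dataclass
class PermutationNull:
    """Distribution of chance accuracies under label permutation."""

    samples: np.ndarray         # (n_permutations,) average % correct
    seed: int

    @property
    def n_permutations(self) -> int:
        return len(self.samples)

    @property
    def mean(self) -> float:
        return float(self.samples.mean())

    @property
    def sd(self) -> float:
        return float(self.samples.std(ddof=1))

    def percentile(self, q: float) -> float:
        return float(np.percentile(self.samples, q))

    def to_dict(self) -> dict:
        return {
            "n_permutations": self.n_permutations,
            "mean": self.mean, "sd": self.sd,
            "p95": self.percentile(95), "p99": self.percentile(99),
            "p999": self.percentile(99.9), "seed": self.seed,
        }


def _design(t: pd.DataFrame, variables: Sequence[str], group_col: str
            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    missing = [v for v in variables if v not in t.columns]
    if missing:
        raise KeyError(f"feature table lacks variables: {missing}")
    X = t[list(variables)].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing values among selected variables")
    labels, idx = np.unique(t[group_col].to_numpy(), return_inverse=True)
    return X, idx, labels


def _pooled_scatter(X: np.ndarray, idx: np.ndarray, k: int
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Group means, group sizes, and within-group scatter (sum of squares).

    The scatter is computed on globally centred data (which leaves it
    unchanged) to avoid cancellation when the variables carry large
    offsets.
    """
    onehot = np.zeros((k, len(idx)))
    onehot[idx, np.arange(len(idx))] = 1.0
    sizes = onehot.sum(axis=1)
    means = (onehot @ X) / sizes[:, None]
    Xc = X - X.mean(axis=0)
    mc = (onehot @ Xc) / sizes[:, None]
    W = Xc.T @ Xc - (mc * sizes[:, None]).T @ mc
    return means, sizes, W


def _fit_arrays(X: np.ndarray, idx: np.ndarray, k: int,
                priors: np.ndarray, variables: Sequence[str],
                labels: np.ndarray, ridge: float = 0.0) -> DFAModel:
    n, p = X.shape
    if k < 2:
        raise ValueError("need at least 2 groups")
    sizes = np.bincount(idx, minlength=k)
    if sizes.min() < 2:
        raise ValueError("every group needs at least 2 calls")
    if n <= p + k:
        raise ValueError(
            f"n calls ({n}) must exceed n variables + n groups ({p + k})")
    means, _, W = _pooled_scatter(X, idx, k)
    S = W / (n - k)
    if ridge > 0:
        S = S + ridge * np.trace(S) / p * np.eye(p)
    # solve in per-variable standardized space: exactly equivalent algebra,
    # but conditioning no longer depends on the variables' units
    scale = np.sqrt(np.maximum(np.diag(S), np.finfo(float).tiny))
    Ss = S / np.outer(scale, scale)
    if not np.all(np.isfinite(Ss)) or np.linalg.cond(Ss) > 1e12:
        raise SingularCovarianceError(
            "pooled within-group covariance is singular; suspect collinear "
            f"variables: {_collinear_variables(S, variables)}")
    try:
        L = np.linalg.cholesky(Ss)
        Ssinv = np.linalg.inv(L.T) @ np.linalg.inv(L)
    except np.linalg.LinAlgError:
        raise SingularCovarianceError(
            "pooled within-group covariance is singular; suspect collinear "
            f"variables: {_collinear_variables(S, variables)}") from None
    Sinv = Ssinv / np.outer(scale, scale)
    coef = means @ Sinv
    intercept = -0.5 * np.einsum("ij,ij->i", coef, means) + np.log(priors)
    return DFAModel(groups=labels, means=means, pooled_cov=S, coef=coef,
                    intercept=intercept, priors=priors,
                    variables=tuple(variables))


def _collinear_variables(S: np.ndarray, variables: Sequence[str]) -> list[str]:
    d = np.sqrt(np.maximum(np.diag(S), np.finfo(float).tiny))
    corr = S / np.outer(d, d)
    _, vecs = np.linalg.eigh(corr)
    weight = np.abs(vecs[:, 0])
    return [v for v, w in zip(variables, weight) if w > 1.0 / len(variables)]


def fit_dfa(
    t: pd.DataFrame,
    variables: Sequence[str],
    group_col: str = DEFAULT_GROUP_COL,
    priors: str = "equal",
    ridge: float = 0.0,
) -> DFAModel:
    """Fit linear classification functions on a feature table.

    ``priors`` is "equal" (default, appropriate for the near-balanced call
    designs) or "proportional".  Singular pooled covariance raises
    :class:`SingularCovarianceError` unless a ridge (fraction of the mean
    diagonal) is explicitly requested.
    """
    X, idx, labels = _design(t, variables, group_col)
    k = len(labels)
    if priors == "equal":
        pri = np.full(k, 1.0 / k)
    elif priors == "proportional":
        pri = np.bincount(idx, minlength=k) / len(idx)
    else:
        raise ValueError("priors must be 'equal' or 'proportional'")
    return _fit_arrays(X, idx, k, pri, variables, labels, ridge=ridge)


def classify(
    m: DFAModel, t: pd.DataFrame, group_col: str = DEFAULT_GROUP_COL
) -> ClassificationResult:
    """Assign each call to the group with the highest classification score.

    When ``t`` is the training table this is resubstitution accuracy.
    Ties break toward the lowest group index (with continuous features
    they are astronomically rare).
    """
    X, _, _ = _design(t, m.variables, group_col)
    true_labels = t[group_col].to_numpy()
    unknown = set(true_labels) - set(map(str, m.groups)) - set(m.groups)
    if unknown:
        raise ValueError(f"table contains groups unseen by the model: "
                         f"{sorted(map(str, unknown))}")
    assigned = np.argmax(m.scores(X), axis=1)
    lookup = {g: i for i, g in enumerate(m.groups)}
    true_idx = np.array([lookup[g] for g in true_labels])
    k = len(m.groups)
    confusion = np.zeros((k, k), dtype=int)
    np.add.at(confusion, (true_idx, assigned), 1)
    return ClassificationResult(groups=m.groups, confusion=confusion,
                                n_calls=len(X))


def classify_loo(
    t: pd.DataFrame,
    variables: Sequence[str],
    group_col: str = DEFAULT_GROUP_COL,
    priors: str = "equal",
) -> ClassificationResult:
    """Leave-one-out classification: each call scored by a model fitted
    without it.  Not the default accuracy measure (see module docstring)."""
    X, idx, labels = _design(t, variables, group_col)
    k = len(labels)
    n = len(X)
    confusion = np.zeros((k, k), dtype=int)
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        sub_idx = idx[keep]
        if np.bincount(sub_idx, minlength=k).min() < 2:
            raise ValueError("leave-one-out needs >= 3 calls per group")
        pri = (np.full(k, 1.0 / k) if priors == "equal"
               else np.bincount(sub_idx, minlength=k) / (n - 1))
        m = _fit_arrays(X[keep], sub_idx, k, pri, variables, labels)
        assigned = int(np.argmax(m.scores(X[i:i + 1]), axis=1)[0])
        confusion[idx[i], assigned] += 1
    return ClassificationResult(groups=labels, confusion=confusion, n_calls=n)


def wilks_contributions(
    t: pd.DataFrame,
    variables: Sequence[str],
    group_col: str = DEFAULT_GROUP_COL,
) -> list[VariableContribution]:
    """Partial Wilks' lambda and F-to-remove for each variable.

    Partial lambda is Wilks' lambda of the full model divided by that of
    the model without the variable; smaller values mark the variables
    contributing most to group separation.
    """
    X, idx, labels = _design(t, variables, group_col)
    n, p = X.shape
    k = len(labels)
    if n <= p + k:
        raise ValueError("too few calls for a Wilks decomposition")

    def wilks(cols: np.ndarray) -> float:
        Xc = X[:, cols]
        _, _, W = _pooled_scatter(Xc, idx, k)
        centred = Xc - Xc.mean(axis=0)
        T = centred.T @ centred
        sign_w, logdet_w = np.linalg.slogdet(W)
        sign_t, logdet_t = np.linalg.slogdet(T)
        if (sign_w <= 0 or sign_t <= 0
                or not np.isfinite(logdet_w) or not np.isfinite(logdet_t)
                or np.linalg.cond(W) > 1e12):
            raise SingularCovarianceError(
                "singular scatter matrix; suspect collinear variables: "
                f"{_collinear_variables(W, [variables[c] for c in cols])}")
        return float(np.exp(logdet_w - logdet_t))

    all_cols = np.arange(p)
    lam_full = wilks(all_cols)
    out = []
    for j in range(p):
        lam_wo = wilks(np.delete(all_cols, j))
        partial = lam_full / lam_wo
        partial = min(partial, 1.0)
        f_stat = ((1 - partial) / max(partial, np.finfo(float).tiny)
                  * (n - k - p + 1) / (k - 1))
        out.append(VariableContribution(
            variable=variables[j], partial_lambda=partial, f_to_remove=f_stat))
    return out


def permutation_null(
    t: pd.DataFrame,
    variables: Sequence[str],
    group_col: str = DEFAULT_GROUP_COL,
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationNull:
    """Chance-level distribution of resubstitution accuracy.

    For each permutation the rows are randomly reassigned to groups
    (preserving the original group sizes), the model is refitted with
    equal priors, and the average percent correct on the permuted labels
    is recorded.  Deterministic under ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X, idx, labels = _design(t, variables, group_col)
    k = len(labels)
    n, p = X.shape
    if n <= p + k:
        raise ValueError(
            f"n calls ({n}) must exceed n variables + n groups ({p + k})")
    rng = np.random.default_rng(seed)
    XtX = X.T @ X
    accs = np.empty(n_perm)
    for b in range(n_perm):
        perm_idx = rng.permutation(idx)
        onehot = np.zeros((k, n))
        onehot[perm_idx, np.arange(n)] = 1.0
        sizes = onehot.sum(axis=1)
        means = (onehot @ X) / sizes[:, None]
        W = XtX - (means * sizes[:, None]).T @ means
        S = W / (n - k)
        Sinv = np.linalg.inv(S)
        coef = means @ Sinv
        intercept = -0.5 * np.einsum("ij,ij->i", coef, means)
        assigned = np.argmax(X @ coef.T + intercept, axis=1)
        accs[b] = 100.0 * np.mean(assigned == perm_idx)
    return PermutationNull(samples=accs, seed=seed)


def significance(observed_pct: float, null: PermutationNull) -> str:
    """One-sided percentile category of an observed accuracy vs its null.

    Returns "p < 0.001", "p < 0.01", "p < 0.05" or "n.s." according to
    whether the observed value exceeds 99.9%, 99% or 95% of the null
    samples.
    """
    for q, label in ((99.9, "p < 0.001"), (99.0, "p < 0.01"),
                     (95.0, "p < 0.05")):
        if observed_pct > null.percentile(q):
            return label
    return "n.s."
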