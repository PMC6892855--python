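"""Regularized Ising network estimation (eLasso).

Each node is regressed on all others with an L1-penalized logistic
regression along a decreasing lambda path; the penalty is selected per
node by the Extended Bayesian Information Criterion

    EBIC = -2*loglik + k*ln(n) + 2*gamma*k*ln(P)

with k the number of nonzero coefficients and P = p - 1 candidate
predictors.  Directed coefficients are symmetrized by the AND rule (edge
present iff both directions survive; weight = mean of the two) or the OR
rule (either direction).  gamma = 0.25 and the AND rule follow the
standard eLasso convention; both are configurable and recorded on the
fitted network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._solver import cd_logistic_path, fit_nodewise
from .binarize import BinaryMatrix


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class LassoPath:
    """Solution path of one nodewise regression."""

    lambdas: np.ndarray      # decreasing
    coefs: np.ndarray        # (n_lambda, p)
    intercepts: np.ndarray   # (n_lambda,)
    logliks: np.ndarray      # (n_lambda,)
    nnz: np.ndarray          # (n_lambda,)


@dataclass(frozen=True)
class IsingNetwork:
    """Estimated symmetric Ising network for one group."""

    weights: np.ndarray      # (p, p) symmetric, zero diagonal
    intercepts: np.ndarray   # (p,) selected nodewise intercepts
    nodes: list[str]
    n_fit: int
    gamma: float
    rule: str
    dropped: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0.0):
            raise ValueError("weights must have a zero diagonal")
        object.__setattr__(self, "weights", w)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def edge_set(self) -> set[tuple[int, int]]:
        i, j = np.nonzero(np.triu(self.weights, 1))
        return set(zip(i.tolist(), j.tolist()))


def ebic(loglik: float, k_nonzero: int, n: int, n_candidates: int, gamma: float) -> float:
    """Extended BIC; gamma = 0 reduces to the ordinary BIC."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if k_nonzero < 0:
        raise ValueError("k_nonzero must be >= 0")
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    return (
        -2.0 * loglik
        + k_nonzero * np.log(n)
        + 2.0 * gamma * k_nonzero * np.log(max(n_candidates, 1))
    )


def lambda_sequence(
    y: np.ndarray,
    X: np.ndarray,
    n_lambda: int = 100,
    lambda_ratio: float = 0.01,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Log-spaced penalty grid from the data-derived lambda_max down to
    ``lambda_ratio * lambda_max``.

    lambda_max is the smallest penalty zeroing every coefficient: by the
    KKT conditions it equals the largest absolute score-component
    |sum_i w_i x_ij (y_i - ybar)| at the intercept-only fit.
    """
    if n_lambda < 2:
        raise ValueError("n_lambda must be >= 2")
    if not 0.0 < lambda_ratio < 1.0:
        raise ValueError("lambda_ratio must lie in (0, 1)")
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    w = np.ones(y.size) if weights is None else np.asarray(weights, dtype=float)
    ybar = (w * y).sum() / w.sum()
    lam_max = np.max(np.abs(X.T @ (w * (y - ybar))))
    lam_max = max(lam_max, 1e-10)
    # small margin so the first path point is exactly the null model even
    # under floating-point reassociation in the solver
    lam_max *= 1.0 + 1e-8
    return np.geomspace(lam_max, lambda_ratio * lam_max, n_lambda)


def logistic_lasso_path(
    y: np.ndarray,
    X: np.ndarray,
    lambdas: np.ndarray,
    weights: np.ndarray | None = None,
    tol: float = 1e-7,
    max_iter: int = 200,
) -> LassoPath:
    """Fit the L1 path; objective is -loglik + lambda*sum(|coef|) with the
    intercept unpenalized.  ``tol`` is the objective-scaled convergence
    threshold (relative to the null deviance; see ``sevnet._solver``).
    Errors on a constant response or predictor (degenerate node: the
    caller must have filtered) and on non-convergence at any lambda.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if y.ndim != 1 or X.shape[0] != y.size:
        raise ValueError("y must be a vector matching X rows")
    if np.isnan(y).any() or np.isnan(X).any():
        raise ValueError("missing values are not allowed")
    w = np.ones(y.size) if weights is None else np.asarray(weights, dtype=float)
    wy = w @ y
    if wy == 0 or wy == w.sum():
        raise ValueError("response is constant; node cannot be regressed")
    for j in range(X.shape[1]):
        col = X[:, j]
        if np.all(col == col[0]):
            raise ValueError(f"predictor column {j} is constant")
    lambdas = np.asarray(lambdas, dtype=float)
    coefs, icpt, ll, nnz, fail = cd_logistic_path(
        np.ascontiguousarray(X), y, w, lambdas, tol, max_iter
    )
    if fail >= 0:
        raise ConvergenceError(
            f"coordinate descent did not converge at lambda index {fail} "
            f"(lambda = {lambdas[fail]:.4g})"
        )
    return LassoPath(lambdas, coefs, icpt, ll, nnz)


def _collapse_rows(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unique binary rows with counts; exact reweighting of the likelihood."""
    n, p = values.shape
    if p <= 62:
        codes = values.astype(np.int64) @ (np.int64(1) << np.arange(p, dtype=np.int64))
        uniq_codes, counts = np.unique(codes, return_counts=True)
        uniq = ((uniq_codes[:, None] >> np.arange(p)) & 1).astype(float)
    else:
        uniq, counts = np.unique(values, axis=0, return_counts=True)
        uniq = uniq.astype(float)
    return uniq, counts.astype(float)


def fit_ising(
    data: BinaryMatrix | np.ndarray,
    gamma: float = 0.25,
    rule: str = "AND",
    n_lambda: int = 100,
    lambda_ratio: float = 0.01,
    nodes: list[str] | None = None,
    tol: float = 1e-7,
) -> IsingNetwork:
    """Estimate one group's Ising network by nodewise eLasso.

    ``data`` is the group's 0/1 matrix (or a single-group
    :class:`~sevnet.binarize.BinaryMatrix`).  Constant nodes are an error
    listing the nodes to drop; fitting with fewer observations than nodes
    only warns.
    """
    if isinstance(data, BinaryMatrix):
        if len(np.unique(data.group_labels)) != 1:
            raise ValueError("fit_ising expects a single group; subset first")
        values = data.values
        nodes = list(data.domains)
    else:
        values = np.asarray(data)
    n, p = values.shape
    if p < 2:
        raise ValueError("need at least two nodes")
    if nodes is None:
        nodes = [f"V{i + 1}" for i in range(p)]
    if rule not in ("AND", "OR"):
        raise ValueError("rule must be 'AND' or 'OR'")
    const = [nodes[j] for j in range(p) if np.all(values[:, j] == values[0, j])]
    if const:
        raise ValueError(f"constant nodes must be dropped before fitting: {const}")
    if n < p:
        warnings.warn(f"fewer observations ({n}) than nodes ({p})", stacklevel=2)

    urows, counts = _collapse_rows(values)
    coef_paths, icpt_paths, ll_paths, nnz_paths, _, fail = fit_nodewise(
        urows, counts, n_lambda, lambda_ratio, tol, 200
    )
    if fail >= 0:
        raise ConvergenceError(f"nodewise regression for {nodes[fail]!r} did not converge")
    directed = np.zeros((p, p))
    intercepts = np.zeros(p)
    others_idx = np.arange(p)
    # EBIC per lambda: -2*loglik + k*ln(n) + 2*gamma*k*ln(p-1)
    penalty = np.log(n) + 2.0 * gamma * np.log(max(p - 1, 1))
    crit = -2.0 * ll_paths + nnz_paths * penalty
    best = np.argmin(crit, axis=1)  # tie -> largest lambda (sparsest)
    for j in range(p):
        cols = others_idx[others_idx != j]
        directed[j, cols] = coef_paths[j, best[j]]
        intercepts[j] = icpt_paths[j, best[j]]

    present = (directed != 0) & (directed.T != 0) if rule == "AND" else (
        (directed != 0) | (directed.T != 0)
    )
    weights_mat = np.where(present, (directed + directed.T) / 2.0, 0.0)
    np.fill_diagonal(weights_mat, 0.0)
    return IsingNetwork(
        weights=weights_mat,
        intercepts=intercepts,
        nodes=nodes,
        n_fit=n,
        gamma=gamma,
        rule=rule,
    )


def fit_ising_drop_constant(values: np.ndarray, nodes: list[str] | None = None, **kw):
    """Fit after dropping constant nodes; dropped nodes come back isolated.

    Used inside permutation and bootstrap loops, where a resample can
    easily make a node constant.  Returns (network, n_dropped).
    """
    values = np.asarray(values)
    n, p = values.shape
    if nodes is None:
        nodes = [f"V{i + 1}" for i in range(p)]
    keep = np.flatnonzero(values.min(axis=0) != values.max(axis=0))
    dropped = [nodes[j] for j in range(p) if j not in set(keep.tolist())]
    if keep.size < 2:
        net = IsingNetwork(
            weights=np.zeros((p, p)),
            intercepts=np.zeros(p),
            nodes=list(nodes),
            n_fit=n,
            gamma=kw.get("gamma", 0.25),
            rule=kw.get("rule", "AND"),
            dropped=dropped,
        )
        return net, len(dropped)
    sub = fit_ising(values[:, keep], nodes=[nodes[j] for j in keep], **kw)
    weights_mat = np.zeros((p, p))
    weights_mat[np.ix_(keep, keep)] = sub.weights
    intercepts = np.zeros(p)
    intercepts[keep] = sub.intercepts
    net = IsingNetwork(
        weights=weights_mat,
        intercepts=intercepts,
        nodes=list(nodes),
        n_fit=n,
        gamma=sub.gamma,
        rule=sub.rule,
        dropped=dropped,
    )
    return net, len(dropped)


def global_strength(net: IsingNetwork | np.ndarray) -> float:
    """Absolute sum of all edge weights over unique node pairs i < j."""
    w = net.weights if isinstance(net, IsingNetwork) else np.asarray(net)
    return float(np.abs(np.triu(w, 1)).sum())


def binarize_network(net: IsingNetwork) -> IsingNetwork:
    """Unweighted version: 1 where an edge is present, else 0."""
    return IsingNetwork(
        weights=(net.weights != 0).astype(float),
        intercepts=net.intercepts,
        nodes=list(net.nodes),
        n_fit=net.n_fit,
        gamma=net.gamma,
        rule=net.rule,
        dropped=list(net.dropped),
    )
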