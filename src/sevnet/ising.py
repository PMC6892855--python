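"""Ising ground-truth networks: exact enumeration and sampling.

The pairwise Markov random field over binary symptom-endorsement states
x ∈ {0,1}^p is

    P(x) ∝ exp( Σ_i τ_i x_i + Σ_{i<j} β_ij x_i x_j )

with node thresholds τ (propensity to endorse) and symmetric couplings β
(pairwise dependence).  States are coded {0,1}, not {−1,+1}: coupling
values are encoding-dependent and this package uses the {0,1} convention
throughout, matching the nodewise-logistic parameterization in which the
conditional of node i given the rest is logistic(τ_i + Σ_j β_ij x_j).

For p ≤ 16 the distribution is enumerated exactly (2^p states), which
provides both an exact i.i.d. sampler and an oracle for every downstream
estimator.  A Gibbs sampler is provided for larger p.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_ENUM_MAX_P = 16


@dataclass(frozen=True)
class GroundTruthNetwork:
    """Known Ising parameters used to generate synthetic cohorts.

    Parameters
    ----------
    couplings : (p, p) ndarray
        Symmetric pairwise couplings β with an exactly zero diagonal.
    thresholds : (p,) ndarray
        Node thresholds τ.
    nodes : list of str, optional
        Node (symptom-domain) names; defaults to ``V1..Vp``.
    """

    couplings: np.ndarray
    thresholds: np.ndarray
    nodes: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        couplings = np.asarray(self.couplings, dtype=float)
        thresholds = np.asarray(self.thresholds, dtype=float)
        if couplings.ndim != 2 or couplings.shape[0] != couplings.shape[1]:
            raise ValueError("couplings must be a square matrix")
        p = couplings.shape[0]
        if p < 1:
            raise ValueError("need at least one node (p >= 1)")
        if thresholds.shape != (p,):
            raise ValueError(f"thresholds must have length {p}")
        if not np.allclose(couplings, couplings.T, atol=1e-12):
            raise ValueError("couplings must be symmetric")
        if np.any(np.diag(couplings) != 0.0):
            raise ValueError("couplings must have an exactly zero diagonal")
        object.__setattr__(self, "couplings", couplings)
        object.__setattr__(self, "thresholds", thresholds)
        nodes = self.nodes
        if nodes is None:
            nodes = [f"V{i + 1}" for i in range(p)]
        if len(nodes) != p:
            raise ValueError("nodes must match the number of rows in couplings")
        object.__setattr__(self, "nodes", list(nodes))

    @property
    def n_nodes(self) -> int:
        return self.couplings.shape[0]


def _check_enumerable(p: int) -> None:
    if p > _ENUM_MAX_P:
        raise ValueError(
            f"exact enumeration is limited to p <= {_ENUM_MAX_P} nodes "
            f"(got p = {p}); use the Gibbs sampler instead"
        )


def all_states(p: int) -> np.ndarray:
    """All 2^p binary states as an (2^p, p) 0/1 integer array.

    State ``s`` has bit ``i`` of ``s`` in column ``i`` (node ``i``), so row
    order is the natural binary counting order.
    """
    _check_enumerable(p)
    codes = np.arange(2**p, dtype=np.int64)
    return ((codes[:, None] >> np.arange(p)) & 1).astype(np.int8)


def enumerate_ising_distribution(net: GroundTruthNetwork) -> np.ndarray:
    """Exact state probabilities over all 2^p binary states.

    Returns
    -------
    (2^p,) ndarray
        ``probs[s]`` is P(x = bits(s)); rows match :func:`all_states`.
        Probabilities sum to 1 within 1e-12.
    """
    p = net.n_nodes
    _check_enumerable(p)
    states = all_states(p).astype(float)
    # Σ_{i<j} β_ij x_i x_j == 0.5 x' β x because β is symmetric, zero diag
    energy = states @ net.thresholds + 0.5 * np.einsum(
        "si,ij,sj->s", states, net.couplings, states
    )
    energy -= energy.max()  # guard against overflow; cancels in the ratio
    weights = np.exp(energy)
    return weights / weights.sum()


def sample_ising_exact(
    net: GroundTruthNetwork, n: int, seed: int | np.random.SeedSequence | None = None
) -> np.ndarray:
    """Draw ``n`` i.i.d. states from the exactly enumerated distribution.

    Identical seeds give bit-identical output.  Requires p ≤ 16.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    probs = enumerate_ising_distribution(net)
    rng = np.random.default_rng(seed)
    codes = rng.choice(probs.size, size=n, p=probs)
    return all_states(net.n_nodes)[codes]


def sample_ising_gibbs(
    net: GroundTruthNetwork,
    n: int,
    burn_in: int = 500,
    thinning: int = 10,
    seed: int | np.random.SeedSequence | None = None,
) -> np.ndarray:
    """Gibbs-sample ``n`` states via single-site conditional updates.

    The conditional of node i given the rest is
    P(x_i = 1 | x_-i) = logistic(τ_i + Σ_j β_ij x_j).  One "iteration" is a
    full sweep over nodes in index order; ``burn_in`` sweeps are discarded
    and one state is retained every ``thinning`` sweeps.  This is the
    fallback sampler for p > 16; for enumerable p it agrees with the exact
    sampler in all first and second moments.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if burn_in < 0:
        raise ValueError("burn_in must be >= 0")
    if thinning < 1:
        raise ValueError("thinning must be >= 1")
    p = net.n_nodes
    rng = np.random.default_rng(seed)
    x = (rng.random(p) < 0.5).astype(np.int8)
    out = np.empty((n, p), dtype=np.int8)
    beta = net.couplings
    tau = net.thresholds
    n_sweeps = burn_in + n * thinning
    # draw all uniforms up front; keeps the loop tight and reproducible
    u = rng.random((n_sweeps, p))
    kept = 0
    for t in range(n_sweeps):
        for i in range(p):
            eta = tau[i] + beta[i] @ x
            x[i] = u[t, i] < 1.0 / (1.0 + np.exp(-eta))
        if t >= burn_in and (t - burn_in + 1) % thinning == 0:
            out[kept] = x
            kept += 1
            if kept == n:
                break
    return out
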