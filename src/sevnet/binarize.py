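"""Severity-threshold binarization of domain scores.

Groups at different points on the severity continuum differ in symptom
means, hence variances, hence covariances — the raw unit of network
analysis.  To remove severity as a confound, each group gets its own
integer cutoff per domain, chosen so that the endorsement prevalence
(score >= cutoff) is as close as the discrete score grid allows to a
common per-domain target.  For binary data variance is p(1-p), so
equalized prevalences equalize variances; the Brown-Forsythe test
verifies this held after thresholding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class BinaryMatrix:
    """Individuals x domains 0/1 endorsement matrix with group labels."""

    values: np.ndarray           # (n, p) ints in {0,1}
    domains: list[str]
    group_labels: np.ndarray     # (n,) 0-based group index

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if not np.isin(values, (0, 1)).all():
            raise ValueError("binary matrix entries must be 0 or 1")
        if values.shape[1] != len(self.domains):
            raise ValueError("domains must match value columns")
        if values.shape[0] != len(self.group_labels):
            raise ValueError("group_labels must match value rows")
        object.__setattr__(self, "values", values.astype(np.int8))

    @property
    def n_groups(self) -> int:
        return int(np.max(self.group_labels)) + 1

    def group_values(self, g: int) -> np.ndarray:
        return self.values[self.group_labels == g]

    def constant_columns(self, g: int) -> list[str]:
        """Domains constant (all 0 or all 1) within group ``g``; these
        cannot enter Ising estimation and are flagged to the caller."""
        vals = self.group_values(g)
        const = (vals.min(axis=0) == vals.max(axis=0))
        return [d for d, c in zip(self.domains, const) if c]


@dataclass(frozen=True)
class ThresholdScheme:
    """Per-group, per-domain integer cutoffs (score >= cutoff => endorsed).

    ``cutoffs``/``achieved`` are (K, p) arrays in group order;
    ``target_prevalences`` is the per-domain target each group was matched
    to.  ``warnings`` collects domains whose target was unreachable.
    """

    cutoffs: np.ndarray
    achieved: np.ndarray
    target_prevalences: np.ndarray
    domains: list[str]
    warnings: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        k, p = self.cutoffs.shape
        for g in range(k):
            for j in range(p):
                rows.append(
                    {
                        "group": g + 1,
                        "domain": self.domains[j],
                        "cutoff": int(self.cutoffs[g, j]),
                        "achieved_prevalence": self.achieved[g, j],
                        "target_prevalence": self.target_prevalences[j],
                    }
                )
        return pd.DataFrame(rows)


def _achievable(scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Candidate integer cutoffs 1..max+1 and their prevalences."""
    cmax = int(scores.max())
    cuts = np.arange(1, cmax + 2)
    prev = np.array([(scores >= c).mean() for c in cuts])
    return cuts, prev


def default_targets(
    domain_scores: np.ndarray, group_labels: np.ndarray
) -> np.ndarray:
    """Default per-domain target prevalences.

    For each domain, take the most-severe group's cutoff at its median
    crossing (smallest c with group-K prevalence <= 0.5) and return the
    pooled-sample prevalence at that cutoff.  This anchors targets where
    the most severe group's endorsement is meaningful while keeping them
    reachable for milder groups.
    """
    g_max = int(np.max(group_labels))
    severe = domain_scores[group_labels == g_max]
    p = domain_scores.shape[1]
    targets = np.empty(p)
    for j in range(p):
        cuts, prev = _achievable(severe[:, j])
        ok = np.flatnonzero(prev <= 0.5)
        c = cuts[ok[0]] if ok.size else cuts[-1]
        targets[j] = (domain_scores[:, j] >= c).mean()
    return np.clip(targets, 1e-9, 1 - 1e-9)


def fit_thresholds(
    domain_scores: np.ndarray,
    group_labels: np.ndarray,
    domains: list[str],
    target_prevalences: np.ndarray | float | None = None,
) -> ThresholdScheme:
    """Choose per-group integer cutoffs matching a per-domain prevalence target.

    The cutoff minimizes |achieved prevalence - target| over all integer
    candidates; ties break to the lower cutoff (higher prevalence).  A
    domain constant within a group is an error; a target no candidate
    comes within 0.5 of is recorded as a warning on the scheme.
    """
    domain_scores = np.asarray(domain_scores)
    group_labels = np.asarray(group_labels)
    n_groups = int(group_labels.max()) + 1
    p = domain_scores.shape[1]
    if target_prevalences is None:
        targets = default_targets(domain_scores, group_labels)
    else:
        targets = np.broadcast_to(np.asarray(target_prevalences, dtype=float), (p,)).copy()
    if np.any((targets <= 0) | (targets >= 1)):
        raise ValueError("target prevalences must lie strictly in (0, 1)")

    cutoffs = np.zeros((n_groups, p), dtype=np.int64)
    achieved = np.zeros((n_groups, p))
    notes: list[str] = []
    for g in range(n_groups):
        scores_g = domain_scores[group_labels == g]
        for j in range(p):
            col = scores_g[:, j]
            if np.unique(col).size < 2:
                raise ValueError(
                    f"domain {domains[j]!r} is constant within group {g + 1}; "
                    "cannot fit a severity threshold"
                )
            cuts, prev = _achievable(col)
            dev = np.abs(prev - targets[j])
            best = int(np.argmin(dev))  # argmin takes the first == lower cutoff
            cutoffs[g, j] = cuts[best]
            achieved[g, j] = prev[best]
            if dev[best] > 0.5:
                notes.append(
                    f"group {g + 1}, domain {domains[j]!r}: no cutoff within 0.5 "
                    f"of target {targets[j]:.3f} (closest {prev[best]:.3f})"
                )
    return ThresholdScheme(cutoffs, achieved, targets, list(domains), notes)


def apply_thresholds(
    domain_scores: np.ndarray,
    group_labels: np.ndarray,
    scheme: ThresholdScheme,
) -> BinaryMatrix:
    """Binarize: endorsed iff score >= the individual's group cutoff.

    Missing scores are an error — individuals with partially missing
    domains must be excluded upstream, not silently imputed.
    """
    domain_scores = np.asarray(domain_scores, dtype=float)
    if np.isnan(domain_scores).any():
        raise ValueError("missing domain scores; exclude incomplete individuals first")
    group_labels = np.asarray(group_labels)
    if int(group_labels.max()) + 1 > scheme.cutoffs.shape[0]:
        raise ValueError("threshold scheme does not cover all groups present")
    if domain_scores.shape[1] != len(scheme.domains):
        raise ValueError("threshold scheme does not cover all domains present")
    row_cuts = scheme.cutoffs[group_labels]
    values = (domain_scores >= row_cuts).astype(np.int8)
    binary = BinaryMatrix(values, list(scheme.domains), group_labels)
    for g in range(binary.n_groups):
        const = binary.constant_columns(g)
        if const:
            warnings.warn(
                f"group {g + 1}: domains constant after thresholding: {const}",
                stacklevel=2,
            )
    return binary


def prevalence_table(binary: BinaryMatrix) -> pd.DataFrame:
    """Group x domain endorsement prevalences, plus the cross-group range.

    The final row ``range`` is max - min over groups per domain — after a
    successful severity correction it should not exceed the discreteness
    of the achievable-prevalence grid.
    """
    if binary.values.size == 0:
        raise ValueError("empty binary matrix")
    rows = {
        f"group{g + 1}": binary.group_values(g).mean(axis=0)
        for g in range(binary.n_groups)
    }
    table = pd.DataFrame(rows, index=binary.domains).T
    table.loc["range"] = table.max(axis=0) - table.min(axis=0)
    return table


def variance_equality_test(binary: BinaryMatrix) -> pd.DataFrame:
    """Brown-Forsythe (median-centered Levene) test per domain across groups.

    Robust to the extreme non-normality of 0/1 data; with prevalences
    equalized by thresholding the tests should come out non-significant.
    """
    if binary.n_groups < 2:
        raise ValueError("need at least two groups to compare variances")
    for g in range(binary.n_groups):
        if binary.group_values(g).shape[0] < 2:
            raise ValueError(f"group {g + 1} has fewer than 2 observations")
    out = []
    for j, dom in enumerate(binary.domains):
        samples = [binary.group_values(g)[:, j] for g in range(binary.n_groups)]
        stat, pval = stats.levene(*samples, center="median")
        out.append({"domain": dom, "statistic": stat, "p_value": pval})
    return pd.DataFrame(out).set_index("domain")
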