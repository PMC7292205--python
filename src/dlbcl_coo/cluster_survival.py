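"""Unsupervised structure and outcome stratification around the calls.

Hierarchical clustering uses one minus Pearson's correlation between 32-gene
expression profiles as the distance and complete linkage (cluster distance =
maximum pairwise member distance) for agglomeration. Overall survival is
summarized by Kaplan–Meier product-limit curves and compared across call
groups with the k-sample log-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .io import ExpressionMatrix


def pearson_distance(X: ExpressionMatrix, axis: str = "samples") -> pd.DataFrame:
    """Pairwise distance d = 1 − r (Pearson) between profiles.

    ``axis="samples"`` correlates the per-sample gene profiles (the usual
    sample dendrogram); ``axis="genes"`` correlates genes across samples.
    Distances lie in [0, 2]; a constant profile has no defined correlation and
    is rejected by name.
    """
    if axis == "samples":
        profiles = X.data  # columns are the profiles
    elif axis == "genes":
        profiles = X.data.T
    else:
        raise ValueError("axis must be 'samples' or 'genes'")
    if profiles.shape[0] < 2:
        raise ValueError("profiles need at least two observations")
    sd = profiles.std(axis=0, ddof=0)
    if (sd == 0).any():
        flat = list(sd.index[sd == 0])
        raise ValueError(f"constant profiles have no correlation: {flat}")
    r = np.corrcoef(profiles.to_numpy().T)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 2.0)
    return pd.DataFrame(d, index=profiles.columns, columns=profiles.columns)


@dataclass
class Merge:
    members_a: tuple[str, ...]
    members_b: tuple[str, ...]
    height: float

    @property
    def members(self) -> tuple[str, ...]:
        return tuple(sorted(self.members_a + self.members_b))


@dataclass
class Dendrogram:
    """Agglomeration record: n − 1 merges with non-decreasing heights."""

    leaves: list[str]
    merges: list[Merge] = field(default_factory=list)

    def cut(self, k: int) -> pd.Series:
        """Cluster labels obtained by undoing the last k − 1 merges."""
        if not 1 <= k <= len(self.leaves):
            raise ValueError("k must lie in [1, n_leaves]")
        clusters: list[set[str]] = [{l} for l in self.leaves]
        for m in self.merges[: len(self.leaves) - k]:
            a = next(c for c in clusters if set(m.members_a) <= c)
            clusters.remove(a)
            b = next(c for c in clusters if set(m.members_b) <= c)
            clusters.remove(b)
            clusters.append(a | b)
        labels = {}
        for i, c in enumerate(sorted(clusters, key=lambda c: sorted(c)[0])):
            for leaf in c:
                labels[leaf] = i
        return pd.Series(labels).reindex(self.leaves).rename("cluster")


def complete_linkage(d: pd.DataFrame) -> Dendrogram:
    """Agglomerative clustering with complete (maximum) linkage.

    At every step the two clusters with the smallest maximum pairwise member
    distance merge; ties merge the pair whose sorted member-id lists compare
    lexicographically smallest, which makes the dendrogram deterministic.
    """
    arr = d.to_numpy(dtype=float)
    if arr.shape[0] != arr.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(arr, arr.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(arr), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    leaves = [str(c) for c in d.columns]
    clusters: list[tuple[str, ...]] = [(l,) for l in leaves]
    idx = {l: i for i, l in enumerate(leaves)}
    dendro = Dendrogram(leaves=list(leaves))

    def linkage_dist(a: tuple[str, ...], b: tuple[str, ...]) -> float:
        rows = [idx[x] for x in a]
        cols = [idx[x] for x in b]
        return float(arr[np.ix_(rows, cols)].max())

    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                h = linkage_dist(clusters[i], clusters[j])
                key = (h, tuple(sorted(clusters[i] + clusters[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        (h, _), i, j = best
        a, b = clusters[i], clusters[j]
        dendro.merges.append(
            Merge(members_a=tuple(sorted(a)), members_b=tuple(sorted(b)), height=h)
        )
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(tuple(sorted(a + b)))
    return dendro


@dataclass
class SurvivalCurve:
    """Kaplan–Meier step function with at-risk counts."""

    times: np.ndarray  # event-time grid (months), starting at 0
    survival: np.ndarray  # S(t), starts at 1, non-increasing
    at_risk: np.ndarray

    def survival_at(self, t: float) -> float:
        i = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[max(i, 0)])

    @property
    def median(self) -> float:
        """Smallest time with S(t) ≤ 0.5 (inf if never reached)."""
        below = self.survival <= 0.5
        return float(self.times[below][0]) if below.any() else float("inf")


def km_curve(times: Sequence[float], events: Sequence[bool]) -> SurvivalCurve:
    """Product-limit survival estimate under right-censoring."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("no observations")
    if (times < 0).any():
        raise ValueError("survival times must be non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    grid = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).to_numpy(dtype=float)
    return SurvivalCurve(times=grid, survival=surv, at_risk=at_risk)


@dataclass
class LogrankResult:
    statistic: float
    df: int
    p_value: float


def logrank_test(
    times: Sequence[float], events: Sequence[bool], groups: Sequence[str]
) -> LogrankResult:
    """k-sample log-rank test of equal survival across groups."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    if not (times.size == events.size == groups.size):
        raise ValueError("times, events and groups must have equal length")
    labels, counts = np.unique(groups, return_counts=True)
    if labels.size < 2:
        raise ValueError("need at least two non-empty groups")
    res = multivariate_logrank_test(times, groups, events)
    return LogrankResult(
        statistic=float(res.test_statistic),
        df=int(labels.size - 1),
        p_value=float(res.p_value),
    )
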