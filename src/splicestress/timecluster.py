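"""Fuzzy c-means soft clustering of z-scored expression time courses.

Each gene's trajectory across timepoints is z-scored and clustered with
the classic fuzzy c-means (FCM) alternating scheme minimizing

    J = sum_i sum_c u_ic^m * ||x_i - v_c||^2,    sum_c u_ic = 1,

where m > 1 is the fuzzifier.  Soft memberships let a gene contribute
to several response shapes, which suits gradual stress responses better
than hard k-means.  Helpers provide hard assignment (for enrichment of
cluster members against pathway sets) and a monotonicity label for each
cluster trend (e.g. "gradually downregulated").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .expr_io import zscore_rows


@dataclass
class TimeSeriesMatrix:
    """Row z-scored gene-by-timepoint matrix (>= 4 timepoints)."""

    genes: list[str]
    timepoints: list[float]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.timepoints) < 4:
            raise ValueError("need at least four time points")
        if list(self.timepoints) != sorted(self.timepoints):
            raise ValueError("timepoints must be ordered")
        if any(t < 0 for t in self.timepoints):
            raise ValueError("timepoints must be non-negative")
        if self.values.shape != (len(self.genes), len(self.timepoints)):
            raise ValueError("matrix shape mismatch")

    @classmethod
    def from_raw(cls, genes, timepoints, values) -> "TimeSeriesMatrix":
        """Build from unscaled trajectories, applying row z-scoring."""
        return cls(list(genes), list(timepoints), zscore_rows(np.asarray(values)))


@dataclass
class FuzzyClustering:
    """FCM result: centers, soft memberships and the objective trace."""

    c: int
    m: float
    centers: np.ndarray
    membership: np.ndarray
    objective: float
    n_iter: int
    objective_trace: list[float]


def _memberships(data: np.ndarray, centers: np.ndarray, m: float) -> np.ndarray:
    """Membership update u_ic = 1 / sum_j (d_ic/d_jc)^(2/(m-1)).

    A point coincident with a center gets membership 1 there (standard
    singularity rule).
    """
    d2 = ((data[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    zero = d2 <= 0
    u = np.empty_like(d2)
    power = 1.0 / (m - 1.0)
    with np.errstate(divide="ignore"):
        inv = d2 ** (-power)
    regular = ~zero.any(axis=1)
    u[regular] = inv[regular] / inv[regular].sum(axis=1, keepdims=True)
    for i in np.nonzero(zero.any(axis=1))[0]:
        row = np.zeros(centers.shape[0])
        hits = np.nonzero(zero[i])[0]
        row[hits] = 1.0 / len(hits)
        u[i] = row
    return u


def _objective(data: np.ndarray, centers: np.ndarray, u: np.ndarray, m: float) -> float:
    d2 = ((data[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return float(((u ** m) * d2).sum())


def fuzzy_cmeans(
    data: TimeSeriesMatrix | np.ndarray,
    c: int,
    m: float = 2.0,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> FuzzyClustering:
    """Run fuzzy c-means on row-profiles.

    Centers are initialized as ``c`` distinct data rows drawn with a
    seeded generator (reproducible, and fast to converge on z-scored
    profiles); the alternation stops when the objective changes by less
    than ``tol``.  The objective trace is recorded and is non-increasing.
    """
    x = data.values if isinstance(data, TimeSeriesMatrix) else np.asarray(data, dtype=float)
    n = x.shape[0]
    if c < 2:
        raise ValueError("need at least two clusters")
    if c >= n:
        raise ValueError(f"c={c} must be smaller than the number of genes ({n})")
    if m <= 1:
        raise ValueError("fuzzifier m must exceed 1")

    rng = np.random.default_rng(seed)
    # prefer distinct rows so no two initial centers coincide
    unique_rows = np.unique(x, axis=0)
    if unique_rows.shape[0] >= c:
        pick = rng.choice(unique_rows.shape[0], size=c, replace=False)
        centers = unique_rows[pick].copy()
    else:
        pick = rng.choice(n, size=c, replace=False)
        centers = x[pick].copy()

    u = _memberships(x, centers, m)
    trace = [_objective(x, centers, u, m)]
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        um = u ** m
        centers = (um.T @ x) / um.sum(axis=0)[:, None]
        u = _memberships(x, centers, m)
        obj = _objective(x, centers, u, m)
        trace.append(obj)
        if abs(trace[-2] - obj) < tol:
            break
    return FuzzyClustering(
        c=c, m=m, centers=centers, membership=u,
        objective=trace[-1], n_iter=n_iter, objective_trace=trace,
    )


def choose_n_clusters(
    data: TimeSeriesMatrix | np.ndarray,
    candidates: Sequence[int] = tuple(range(4, 13)),
    m: float = 2.0,
    seed: int = 0,
) -> int:
    """Pick c by the minimum-centroid-distance elbow over candidate counts.

    The minimum pairwise distance between converged centers shrinks as c
    grows; the chosen c is the one just before the largest relative drop
    (the elbow), i.e. the largest c that still yields well-separated
    centers.
    """
    x = data.values if isinstance(data, TimeSeriesMatrix) else np.asarray(data, dtype=float)
    cands = [c for c in candidates if 2 <= c < x.shape[0]]
    if not cands:
        raise ValueError("no feasible cluster counts")
    if len(cands) == 1:
        return cands[0]
    min_dists = []
    for c in cands:
        fit = fuzzy_cmeans(x, c=c, m=m, seed=seed)
        d = np.sqrt(((fit.centers[:, None, :] - fit.centers[None, :, :]) ** 2).sum(axis=2))
        np.fill_diagonal(d, np.inf)
        min_dists.append(float(d.min()))
    drops = [
        (min_dists[i] - min_dists[i + 1]) / max(min_dists[i], 1e-12)
        for i in range(len(cands) - 1)
    ]
    return cands[int(np.argmax(drops))]


def cluster_gene_assignment(
    clustering: FuzzyClustering,
    genes: Sequence[str],
    min_membership: float = 0.5,
) -> dict[str, int | None]:
    """Hard-assign each gene to its argmax cluster if membership suffices.

    Genes whose maximum membership falls below ``min_membership`` map to
    ``None`` (unassigned).
    """
    if not (0.0 <= min_membership <= 1.0):
        raise ValueError("min_membership must lie in [0,1]")
    u = clustering.membership
    if len(genes) != u.shape[0]:
        raise ValueError("gene list does not match membership matrix")
    best = u.argmax(axis=1)
    out: dict[str, int | None] = {}
    for i, g in enumerate(genes):
        out[g] = int(best[i]) if u[i, best[i]] >= min_membership else None
    return out


def cluster_trend(
    clustering: FuzzyClustering,
    cluster: int,
    data: np.ndarray | None = None,
) -> tuple[np.ndarray, str]:
    """Mean trajectory of a cluster plus a monotonicity label.

    The trajectory is the membership^m-weighted mean of member profiles
    (equal to the converged center).  Monotonicity is judged on the
    center: strictly decreasing across all timepoints -> ``decreasing``,
    strictly increasing -> ``increasing``, otherwise ``non-monotone``.
    """
    if not (0 <= cluster < clustering.c):
        raise ValueError(f"cluster index {cluster} out of range")
    if data is not None:
        um = clustering.membership[:, cluster] ** clustering.m
        trajectory = (um[:, None] * np.asarray(data, float)).sum(axis=0) / um.sum()
    else:
        trajectory = clustering.centers[cluster]
    center = clustering.centers[cluster]
    diffs = np.diff(center)
    if (diffs < 0).all():
        label = "decreasing"
    elif (diffs > 0).all():
        label = "increasing"
    else:
        label = "non-monotone"
    return trajectory, label


def write_membership(
    clustering: FuzzyClustering, genes: Sequence[str], path,
    min_membership: float = 0.5,
) -> None:
    """Write ``gene<TAB>cluster<TAB>membership_0..membership_{c-1}``."""
    assign = cluster_gene_assignment(clustering, genes, min_membership)
    with open(path, "w") as fh:
        cols = "\t".join(f"membership_{c}" for c in range(clustering.c))
        fh.write(f"gene\tcluster\t{cols}\n")
        for i, g in enumerate(genes):
            cl = assign[g]
            mvals = "\t".join(f"{v:.6g}" for v in clustering.membership[i])
            fh.write(f"{g}\t{'' if cl is None else cl}\t{mvals}\n")
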