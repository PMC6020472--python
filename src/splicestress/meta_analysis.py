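"""Cross-study meta-analysis of differential-expression evidence.

Per-dataset p-values for a gene are combined with Wilkinson's
order-statistic method: under the null the r-th smallest of k
independent uniform p-values follows a Beta(r, k-r+1) distribution, so
the combined p-value is that Beta CDF evaluated at the observed r-th
smallest p.  r=1 recovers Tippett's minimum-p test, r=k the maximum-p
test.  Combined p-values are corrected with Benjamini-Hochberg FDR, and
a direction-consistency filter keeps only genes moving the same way
(exclusively up, or exclusively down) in every contributing study —
heterogeneity across platforms is deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .diffexpr import DEResult, DIRECTION_DOWN, DIRECTION_UP

CONSISTENT_UP = "up"
CONSISTENT_DOWN = "down"
CONSISTENT_NONE = "none"


@dataclass(frozen=True)
class MetaGeneRecord:
    """Combined evidence for one gene across k datasets."""

    gene: str
    k: int
    p_values: tuple[float, ...]
    directions: tuple[str, ...]
    p_combined: float
    q_value: float
    consistent: str

    @property
    def significant_consistent(self) -> bool:
        return self.consistent in (CONSISTENT_UP, CONSISTENT_DOWN)


def wilkinson_combine(p_values: Sequence[float], r: int = 1) -> float:
    """Combine p-values via the r-th order statistic (Wilkinson's method).

    Returns ``Pr(Beta(r, k-r+1) <= p_(r))`` where ``p_(r)`` is the r-th
    smallest of the k inputs.  With a single p-value the input is
    returned unchanged.
    """
    p = np.asarray(list(p_values), dtype=float)
    k = p.size
    if k == 0:
        raise ValueError("no p-values to combine")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if not (1 <= r <= k):
        raise ValueError(f"order statistic r={r} out of range for k={k}")
    if k == 1:
        return float(p[0])
    p_r = float(np.sort(p)[r - 1])
    return float(stats.beta.cdf(p_r, r, k - r + 1))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.array([], dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _consistency(directions: Sequence[str]) -> str:
    if all(d == DIRECTION_UP for d in directions):
        return CONSISTENT_UP
    if all(d == DIRECTION_DOWN for d in directions):
        return CONSISTENT_DOWN
    return CONSISTENT_NONE


def aggregate_datasets(
    results_per_dataset: Sequence[tuple[str, Sequence[DEResult]]],
    r: int = 1,
    alpha: float = 0.05,
    min_datasets: int | None = None,
    per_dataset_alpha: float | None = None,
) -> list[MetaGeneRecord]:
    """Combine per-dataset DE results into per-gene meta records.

    Genes are matched across datasets by (already harmonized) ID.  Only
    genes present in at least ``min_datasets`` studies (default: all of
    them) are aggregated; each gets a Wilkinson-combined p-value (order
    statistic ``min(r, k)`` for a gene found in k studies), a BH q-value
    computed over the aggregated gene family, and a consistency call.
    ``per_dataset_alpha``, when set, additionally requires every
    per-dataset p-value to pass that cutoff for the gene to be
    aggregated at all.
    """
    if not results_per_dataset:
        raise ValueError("need at least one dataset")
    n_datasets = len(results_per_dataset)
    if min_datasets is None:
        min_datasets = n_datasets
    if not (1 <= min_datasets <= n_datasets):
        raise ValueError(
            f"min_datasets={min_datasets} out of range for {n_datasets} datasets"
        )
    if not (1 <= r <= n_datasets):
        raise ValueError(f"wilkinson r={r} exceeds the number of datasets")

    per_gene: dict[str, list[DEResult]] = {}
    order: list[str] = []
    for _ds_id, results in results_per_dataset:
        seen: set[str] = set()
        for res in results:
            if res.gene in seen:
                raise ValueError(f"duplicate gene {res.gene} within one dataset")
            seen.add(res.gene)
            if res.gene not in per_gene:
                per_gene[res.gene] = []
                order.append(res.gene)
            per_gene[res.gene].append(res)

    records: list[tuple[str, tuple[float, ...], tuple[str, ...], float, str]] = []
    for gene in order:
        entries = per_gene[gene]
        if len(entries) < min_datasets:
            continue
        pvals = tuple(e.p_value for e in entries)
        if per_dataset_alpha is not None and any(p >= per_dataset_alpha for p in pvals):
            continue
        dirs = tuple(e.direction for e in entries)
        k = len(pvals)
        p_comb = wilkinson_combine(pvals, min(r, k))
        records.append((gene, pvals, dirs, p_comb, _consistency(dirs)))

    if not records:
        raise ValueError(
            f"no gene shared by >= {min_datasets} of the {n_datasets} datasets"
        )
    qvals = bh_fdr([rec[3] for rec in records])
    return [
        MetaGeneRecord(
            gene=gene,
            k=len(pvals),
            p_values=pvals,
            directions=dirs,
            p_combined=p_comb,
            q_value=float(q),
            consistent=cons,
        )
        for (gene, pvals, dirs, p_comb, cons), q in zip(records, qvals)
    ]


def significant_consistent_sets(
    records: Iterable[MetaGeneRecord], alpha: float = 0.05
) -> tuple[set[str], set[str]]:
    """Split significant (q < alpha) direction-consistent genes into up/down."""
    up: set[str] = set()
    down: set[str] = set()
    for rec in records:
        if rec.q_value < alpha:
            if rec.consistent == CONSISTENT_UP:
                up.add(rec.gene)
            elif rec.consistent == CONSISTENT_DOWN:
                down.add(rec.gene)
    return up, down


def write_meta_records(records: Iterable[MetaGeneRecord], path) -> None:
    """Write records as ``gene<TAB>k<TAB>p_combined<TAB>q<TAB>consistent<TAB>directions``."""
    with open(path, "w") as fh:
        fh.write("gene\tk\tp_combined\tq\tconsistent\tper_dataset_directions\n")
        for rec in records:
            fh.write(
                f"{rec.gene}\t{rec.k}\t{rec.p_combined:.6g}\t{rec.q_value:.6g}\t"
                f"{rec.consistent}\t{','.join(rec.directions)}\n"
            )
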