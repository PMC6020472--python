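"""Co-regulation network: correlated gene pairs and shared TF binding.

Splicing-related and mitosis-related genes that respond to therapy in a
correlated way may share upstream regulators.  Per dataset, all
cross-set gene pairs are scored by Spearman correlation across samples
(BH-FDR within the dataset's tested-pair family); retained pairs are
then linked to transcription factors whose binding intervals fall in
the promoter windows of *both* genes, and the TF sets are intersected
across datasets to find regulators common to every study.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .expr_io import ExpressionDataset
from .meta_analysis import bh_fdr

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenePair:
    """A retained co-expressed pair (splicing-set, mitotic-set member)."""

    gene_a: str
    gene_b: str
    rho: float
    p_value: float
    q_value: float


@dataclass(frozen=True)
class TFBindingMap:
    """TF name -> set of genes whose promoter window it binds."""

    targets: dict[str, frozenset[str]]
    window: int

    def binds(self, tf: str, gene: str) -> bool:
        return gene in self.targets.get(tf, frozenset())


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman correlation with t-approximation p-value.

    rho is the Pearson correlation of average-ranked values (ties share
    the mean rank); the p-value uses t = rho*sqrt((n-2)/(1-rho^2)) on
    n-2 df, with p = 0 at rho = +/-1.  Constant input is an error
    because ranks are then undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: Spearman rho undefined")
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0 - 1e-12:  # perfectly monotone up to float error
        return float(np.sign(rho)), 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return rho, p


def spearman_exact_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Exact permutation p-value for |rho| (two-sided), n <= 8 only."""
    from itertools import permutations

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n > 8:
        raise ValueError("exact permutation p limited to n <= 8")
    obs, _ = spearman_rho(x, y)
    count = total = 0
    for perm in permutations(range(n)):
        r, _ = spearman_rho(x, y[list(perm)])
        total += 1
        if abs(r) >= abs(obs) - 1e-12:
            count += 1
    return count / total


def correlated_pairs(
    dataset: ExpressionDataset,
    splicing_genes: Iterable[str],
    mitotic_genes: Iterable[str],
    rho_min: float = 0.7,
    alpha: float = 0.05,
) -> list[GenePair]:
    """Retain cross-set pairs with rho > rho_min and BH q < alpha.

    Every (splicing gene, mitotic gene) pair present in the dataset is
    tested; BH-FDR is computed over that whole tested family within the
    dataset.  Both thresholds are strict.
    """
    genes_in = set(dataset.genes)
    sset = sorted(set(splicing_genes) & genes_in)
    mset = sorted(set(mitotic_genes) & genes_in)
    if not sset:
        raise ValueError(f"{dataset.dataset_id}: no splicing-set genes in dataset")
    if not mset:
        raise ValueError(f"{dataset.dataset_id}: no mitotic-set genes in dataset")

    tested: list[tuple[str, str, float, float]] = []
    for a in sset:
        xa = dataset.data.loc[a].to_numpy()
        for b in mset:
            if a == b:
                continue
            rho, p = spearman_rho(xa, dataset.data.loc[b].to_numpy())
            tested.append((a, b, rho, p))
    if not tested:
        return []
    qvals = bh_fdr([t[3] for t in tested])
    return [
        GenePair(gene_a=a, gene_b=b, rho=rho, p_value=p, q_value=float(q))
        for (a, b, rho, p), q in zip(tested, qvals)
        if rho > rho_min and q < alpha
    ]


def read_tss_table(path: str | Path) -> dict[str, tuple[str, str, int]]:
    """Read ``gene<TAB>chrom<TAB>strand<TAB>tss`` (0-based TSS positions)."""
    out: dict[str, tuple[str, str, int]] = {}
    with open(path) as fh:
        first = fh.readline()
        if not first.lower().startswith("gene"):
            fh.seek(0)
        for line in fh:
            if not line.strip():
                continue
            gene, chrom, strand, tss = line.rstrip("\n").split("\t")[:4]
            out[gene] = (chrom, strand, int(tss))
    return out


def read_tf_peaks(path: str | Path, tf_name: str | None = None):
    """Read BED3+ peaks; TF name taken from column 4 unless given.

    Yields ``(tf, chrom, start, end)`` tuples.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if end <= start:
                raise ValueError(f"{path}:{lineno}: interval end <= start")
            tf = tf_name if tf_name is not None else fields[3]
            yield tf, chrom, start, end


def build_tf_map(
    peaks: Iterable[tuple[str, str, int, int]],
    tss: Mapping[str, tuple[str, str, int]],
    window: int = 2000,
) -> TFBindingMap:
    """Call TF->gene binding from peak/promoter-window overlap.

    A TF binds a gene iff any of its intervals overlaps the
    strand-agnostic window ``[tss-window, tss+window)`` by >= 1 bp.
    TFs with no bound gene are absent from the map.
    """
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for gene, (chrom, _strand, pos) in tss.items():
        by_chrom.setdefault(chrom, []).append((pos - window, pos + window, gene))
    targets: dict[str, set[str]] = {}
    for tf, chrom, start, end in peaks:
        if end <= start:
            raise ValueError(f"interval end <= start for {tf} on {chrom}")
        for win_start, win_end, gene in by_chrom.get(chrom, ()):
            if start < win_end and end > win_start:
                targets.setdefault(tf, set()).add(gene)
    return TFBindingMap(
        targets={tf: frozenset(g) for tf, g in targets.items()},
        window=window,
    )


def common_tfs(
    pairs_per_dataset: Sequence[tuple[str, Sequence[GenePair]]],
    tf_map: TFBindingMap,
) -> tuple[set[str], list[tuple[str, str, str, str]]]:
    """Intersect, across datasets, the TFs binding both genes of a pair.

    Per dataset the TF set is every TF with at least one retained pair
    whose two members it both binds; the common set is the intersection
    over all datasets.  Also returns annotated edges
    ``(tf, gene_a, gene_b, dataset_id)`` for TFs in the common set.
    """
    if not pairs_per_dataset:
        raise ValueError("need at least one dataset")
    per_dataset_tfs: list[set[str]] = []
    edges_all: list[tuple[str, str, str, str]] = []
    for ds_id, pairs in pairs_per_dataset:
        tf_set: set[str] = set()
        for tf, bound in tf_map.targets.items():
            for pair in pairs:
                if pair.gene_a in bound and pair.gene_b in bound:
                    tf_set.add(tf)
                    edges_all.append((tf, pair.gene_a, pair.gene_b, ds_id))
        per_dataset_tfs.append(tf_set)
    common = set.intersection(*per_dataset_tfs) if per_dataset_tfs else set()
    if not common:
        logger.info("no transcription factor common to all datasets")
    edges = [e for e in edges_all if e[0] in common]
    return common, edges


def write_edges(
    edges: Iterable[tuple[str, str, str, str]],
    pairs_by_dataset: Mapping[str, Sequence[GenePair]],
    path,
) -> None:
    """Write ``tf<TAB>gene_a<TAB>gene_b<TAB>dataset<TAB>rho`` edges."""
    rho_of = {
        (ds, p.gene_a, p.gene_b): p.rho
        for ds, pairs in pairs_by_dataset.items()
        for p in pairs
    }
    with open(path, "w") as fh:
        fh.write("tf\tgene_a\tgene_b\tdataset\trho\n")
        for tf, a, b, ds in edges:
            rho = rho_of.get((ds, a, b), float("nan"))
            fh.write(f"{tf}\t{a}\t{b}\t{ds}\t{rho:.6g}\n")
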