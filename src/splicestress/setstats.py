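"""Gene-set statistics: over-representation, overlap tests, Venn summaries.

Over-representation of a query gene list in named sets (GMT format) is
tested with the hypergeometric upper tail against an explicit,
mandatory universe — defaulting to "all genes" silently inflates
significance, so the background must be stated (measured genes for
expression results, detected proteins for proteome results).  Pairwise
set overlap uses Fisher's exact test on the 2x2 table over the same
universe; the one-sided "greater" p-value is mathematically identical
to the hypergeometric tail.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .meta_analysis import bh_fdr


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read gene sets from GMT: ``name<TAB>description<TAB>gene1<TAB>...``."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >=3 fields")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name}")
            genes = {g for g in fields[2:] if g}
            if not genes:
                raise ValueError(f"{path}:{lineno}: empty gene set {name}")
            sets[name] = genes
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write(name + "\t" + name + "\t" + "\t".join(sorted(genes)) + "\n")


@dataclass(frozen=True)
class EnrichmentRow:
    set_name: str
    k_overlap: int
    set_size: int
    query_size: int
    universe_size: int
    p_value: float
    q_value: float


@dataclass(frozen=True)
class OverlapTest:
    """Fisher 2x2 overlap result over a declared universe."""

    both: int
    a_only: int
    b_only: int
    neither: int
    odds_ratio: float
    p_value: float


def hypergeometric_enrichment(
    query: Iterable[str],
    sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> list[EnrichmentRow]:
    """Hypergeometric over-representation of ``query`` in each named set.

    Each set is intersected with the universe before testing; p is the
    upper tail Pr(X >= k) of Hypergeom(N=|universe|, K=|set|,
    n=|query|), computed in log space by scipy; q is BH over the
    collection.  Output is sorted by q then p.
    """
    universe = set(universe)
    query = set(query)
    if not universe:
        raise ValueError("empty universe")
    if not query:
        raise ValueError("empty query")
    extra = query - universe
    if extra:
        raise ValueError(f"query genes outside the universe: {sorted(extra)[:5]}")
    n = len(query)
    N = len(universe)
    rows: list[tuple[str, int, int, float]] = []
    for name, members in sets.items():
        in_universe = set(members) & universe
        if not in_universe:
            continue
        K = len(in_universe)
        k = len(query & in_universe)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((name, k, K, min(p, 1.0)))
    qvals = bh_fdr([r[3] for r in rows])
    out = [
        EnrichmentRow(
            set_name=name, k_overlap=k, set_size=K, query_size=n,
            universe_size=N, p_value=p, q_value=float(q),
        )
        for (name, k, K, p), q in zip(rows, qvals)
    ]
    out.sort(key=lambda r: (r.q_value, r.p_value, r.set_name))
    return out


def fisher_overlap(
    set_a: Iterable[str],
    set_b: Iterable[str],
    universe: Iterable[str],
    alternative: str = "greater",
) -> OverlapTest:
    """Fisher's exact test of the overlap between two sets.

    ``greater`` gives the hypergeometric upper tail at the observed
    overlap; ``two-sided`` sums all tables with probability no larger
    than the observed one.  The odds ratio is the sample odds ratio
    (both*neither)/(a_only*b_only), infinite when the denominator is 0.
    """
    if alternative not in ("greater", "two-sided"):
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    universe = set(universe)
    a = set(set_a)
    b = set(set_b)
    bad = (a | b) - universe
    if bad:
        raise ValueError(f"genes outside the universe: {sorted(bad)[:5]}")
    both = len(a & b)
    a_only = len(a - b)
    b_only = len(b - a)
    neither = len(universe) - both - a_only - b_only
    table = [[both, a_only], [b_only, neither]]
    alt = "greater" if alternative == "greater" else "two-sided"
    _, p = stats.fisher_exact(table, alternative=alt)
    if a_only * b_only == 0:
        odds = float("inf") if both * neither > 0 else float("nan")
    else:
        odds = (both * neither) / (a_only * b_only)
    return OverlapTest(
        both=both, a_only=a_only, b_only=b_only, neither=neither,
        odds_ratio=odds, p_value=float(min(p, 1.0)),
    )


def venn_counts(
    named_sets: Mapping[str, Iterable[str]],
    annotation: Iterable[str] = (),
) -> dict[tuple[str, ...], tuple[int, int]]:
    """Disjoint-region counts for 2 or 3 sets, with annotated subcounts.

    Keys are tuples of the set names a region belongs to (exclusively);
    values are ``(n_members, n_annotated_members)``.  Regions partition
    the union of the sets.
    """
    names = list(named_sets)
    if len(names) not in (2, 3):
        raise ValueError("venn_counts handles 2 or 3 sets")
    sets = {name: set(genes) for name, genes in named_sets.items()}
    ann = set(annotation)
    union = set().union(*sets.values())
    regions: dict[tuple[str, ...], tuple[int, int]] = {}
    from itertools import combinations

    for r in range(1, len(names) + 1):
        for inside in combinations(names, r):
            members = set(union)
            for name in inside:
                members &= sets[name]
            for name in names:
                if name not in inside:
                    members -= sets[name]
            regions[inside] = (len(members), len(members & ann))
    return regions


def write_enrichment(rows: Sequence[EnrichmentRow], path) -> None:
    """Write enrichment sorted by q with k/K/n/N columns."""
    with open(path, "w") as fh:
        fh.write("set\tk\tK\tn\tN\tp\tq\n")
        for r in rows:
            fh.write(
                f"{r.set_name}\t{r.k_overlap}\t{r.set_size}\t{r.query_size}\t"
                f"{r.universe_size}\t{r.p_value:.6g}\t{r.q_value:.6g}\n"
            )
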