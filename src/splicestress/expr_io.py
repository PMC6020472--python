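"""Expression-matrix I/O, normalization and transforms.

The downstream statistics assume a log2-scale, quantile-normalized
gene-by-sample matrix with every sample labelled ``control`` or
``treated``.  This module reads tab-separated expression tables and
group specifications, collapses platform probes to gene identifiers,
and provides quantile normalization, the log2 transform and row-wise
z-scoring used throughout the pipeline.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUP_CONTROL = "control"
GROUP_TREATED = "treated"
VALID_GROUPS = frozenset({GROUP_CONTROL, GROUP_TREATED})


@dataclass
class ExpressionDataset:
    """One study's expression matrix with sample group labels.

    Parameters
    ----------
    dataset_id:
        Short text label for the study.
    data:
        Gene-by-sample matrix (rows indexed by gene/probe ID, columns by
        sample ID).  Expected to be on the log2 scale after normalization.
    group_of:
        Mapping of every sample ID to ``"control"`` or ``"treated"``.
    time_of:
        Optional mapping of sample ID to hours after treatment start.
    """

    dataset_id: str
    data: pd.DataFrame
    group_of: dict[str, str]
    time_of: dict[str, float] | None = None

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample IDs: {dups}")
        missing = [s for s in self.data.columns if s not in self.group_of]
        if missing:
            raise ValueError(
                f"samples without a group label: {missing}"
            )
        bad = {s: g for s, g in self.group_of.items()
               if s in self.data.columns and g not in VALID_GROUPS}
        if bad:
            raise ValueError(
                f"group labels must be 'control'/'treated', got {bad}"
            )
        if not np.isfinite(self.data.to_numpy()).all():
            raise ValueError("expression matrix contains non-finite values")
        if self.time_of is not None:
            neg = {s: t for s, t in self.time_of.items() if t < 0}
            if neg:
                raise ValueError(f"negative time points: {neg}")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.data.columns if self.group_of[s] == group]

    def with_data(self, data: pd.DataFrame) -> "ExpressionDataset":
        """Return a copy of this dataset carrying a new matrix."""
        return ExpressionDataset(
            dataset_id=self.dataset_id,
            data=data,
            group_of=dict(self.group_of),
            time_of=None if self.time_of is None else dict(self.time_of),
        )


def read_group_spec(path: str | Path) -> tuple[dict[str, str], dict[str, float] | None]:
    """Read a two- or three-column ``sample<TAB>group[<TAB>time_h]`` table.

    Returns the sample->group mapping and, when a ``time_h`` column is
    present, the sample->hours mapping (otherwise ``None``).
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"group spec {path} must have >=2 columns")
    # tolerate a header line
    if str(df.iloc[0, 0]).lower() in {"sample", "sample_id"}:
        df = df.iloc[1:]
    group_of = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    bad = {s: g for s, g in group_of.items() if g not in VALID_GROUPS}
    if bad:
        raise ValueError(f"invalid group labels in {path}: {bad}")
    time_of = None
    if df.shape[1] >= 3 and df.iloc[:, 2].notna().any():
        time_of = {s: float(t) for s, t in zip(df.iloc[:, 0], df.iloc[:, 2])
                   if pd.notna(t)}
    return group_of, time_of


def read_expression(
    path: str | Path,
    group_spec: Mapping[str, str],
    *,
    dataset_id: str | None = None,
    scale: Literal["log2", "linear"] = "log2",
    time_of: Mapping[str, float] | None = None,
) -> ExpressionDataset:
    """Read an expression TSV (``gene_id`` header column then sample columns).

    ``scale`` declares whether the file is already log2-transformed; a
    ``linear`` matrix should subsequently go through
    :func:`quantile_normalize` and :func:`log2_transform`.

    Raises
    ------
    ValueError
        If a sample column is missing from ``group_spec``, if sample IDs
        are duplicated, or if any cell is non-numeric (the error names
        the offending row and column).
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.columns.duplicated().any():
        raise ValueError(
            f"duplicate sample IDs in {path}: "
            f"{raw.columns[raw.columns.duplicated()].tolist()}"
        )
    missing = [s for s in raw.columns if s not in group_spec]
    if missing:
        raise ValueError(
            f"sample(s) {missing} in {path} absent from the group spec"
        )
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any() or raw.isna().to_numpy().any():
        nas = (numeric.isna()).to_numpy().nonzero()
        i, j = nas[0][0], nas[1][0]
        raise ValueError(
            f"non-numeric cell in {path} at row '{raw.index[i]}', "
            f"column '{raw.columns[j]}'"
        )
    ds_id = dataset_id if dataset_id is not None else Path(path).stem
    return ExpressionDataset(
        dataset_id=ds_id,
        data=numeric,
        group_of={s: group_spec[s] for s in raw.columns},
        time_of=None if time_of is None else dict(time_of),
    )


def write_expression(dataset: ExpressionDataset, path: str | Path) -> None:
    """Write the matrix as a ``gene_id``-headed TSV (round-trips with reader)."""
    out = dataset.data.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_gene_id_map(path: str | Path) -> dict[str, str]:
    """Read a two-column ``probe<TAB>refseq`` mapping table."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"gene ID map {path} must have 2 columns")
    if (df.iloc[:, 1].isna() | (df.iloc[:, 1].str.len() == 0)).any():
        raise ValueError(f"empty target gene IDs in {path}")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def detection_filter(
    values: pd.DataFrame, detection_p: pd.DataFrame, threshold: float = 0.05
) -> pd.DataFrame:
    """Drop rows whose detection p-value exceeds ``threshold`` in all samples.

    Stand-in for the bead-array detection filter applied upstream of
    normalization; rows detected (p <= threshold) in at least one sample
    are retained.
    """
    det = detection_p.reindex(index=values.index, columns=values.columns)
    keep = (det <= threshold).any(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("detection filter dropped %d rows", dropped)
    return values.loc[keep]


def quantile_normalize(values):
    """Quantile-normalize columns of a gene-by-sample matrix.

    Every column is forced onto the common reference distribution: the
    across-column mean of sorted values.  Ties within a column receive
    the mean of the reference values over the tied rank span, which keeps
    the procedure deterministic and rank-preserving.

    Accepts and returns either an ``ndarray`` or a ``DataFrame``.  A
    single-column matrix is returned unchanged with a warning.
    """
    is_frame = isinstance(values, pd.DataFrame)
    arr = values.to_numpy(dtype=float) if is_frame else np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D gene-by-sample matrix")
    if not np.isfinite(arr).all():
        raise ValueError("matrix contains non-finite values")
    n_genes, n_samples = arr.shape
    if n_samples < 2:
        warnings.warn("quantile_normalize: single column, returned unchanged")
        return values.copy() if is_frame else arr.copy()

    order = np.argsort(arr, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(arr, order, axis=0)
    reference = sorted_vals.mean(axis=1)

    out = np.empty_like(arr)
    for j in range(n_samples):
        col_sorted = sorted_vals[:, j]
        ref = reference.copy()
        # average the reference over each run of tied input values
        start = 0
        for i in range(1, n_genes + 1):
            if i == n_genes or col_sorted[i] != col_sorted[start]:
                if i - start > 1:
                    ref[start:i] = ref[start:i].mean()
                start = i
        out[order[:, j], j] = ref

    if is_frame:
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    return out


def log2_transform(values, offset: float = 0.0):
    """Elementwise ``log2(value + offset)`` (variance stabilization).

    Raises ``ValueError`` if any ``value + offset`` is not positive.
    """
    if offset < 0:
        raise ValueError("offset must be non-negative")
    is_frame = isinstance(values, pd.DataFrame)
    arr = values.to_numpy(dtype=float) if is_frame else np.asarray(values, dtype=float)
    shifted = arr + offset
    if (shifted <= 0).any():
        raise ValueError("log2_transform: value + offset <= 0 encountered")
    out = np.log2(shifted)
    if is_frame:
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    return out


def collapse_probes(
    dataset: ExpressionDataset,
    idmap: Mapping[str, str],
    method: Literal["max-mean-probe", "mean"] = "max-mean-probe",
) -> ExpressionDataset:
    """Collapse platform probes to one row per gene ID.

    ``max-mean-probe`` keeps, for each gene, the probe with the highest
    mean signal (common microarray practice); ``mean`` averages all of
    the gene's probes elementwise.  Probes absent from ``idmap`` are
    dropped and counted in the log.
    """
    if method not in ("max-mean-probe", "mean"):
        raise ValueError(f"unknown collapse method: {method}")
    mapped = dataset.data.index.map(lambda p: idmap.get(p))
    keep = mapped.notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "collapse_probes: dropped %d unmapped probe(s) in %s",
            n_dropped, dataset.dataset_id,
        )
    data = dataset.data.loc[keep].copy()
    genes = pd.Index(mapped[keep], name="gene_id")
    if data.empty:
        raise ValueError("no probes left after ID mapping")
    if method == "mean":
        collapsed = data.groupby(genes, sort=True).mean()
    else:
        means = data.mean(axis=1).to_numpy()
        df = data.copy()
        df["_gene"] = genes
        df["_mean"] = means
        # stable: first probe wins ties on mean signal
        idx = (
            df.sort_values("_mean", ascending=False, kind="stable")
            .groupby("_gene", sort=True)
            .head(1)
            .sort_values("_gene")
        )
        collapsed = idx.drop(columns=["_gene", "_mean"])
        collapsed.index = pd.Index(sorted(set(genes)), name="gene_id")
    return dataset.with_data(collapsed)


def zscore_rows(values):
    """Z-score each row (mean 0, sample sd 1 with the n-1 denominator).

    Constant rows become rows of zeros with a warning, never NaN, so
    downstream clustering only ever sees finite values.
    """
    is_frame = isinstance(values, pd.DataFrame)
    arr = values.to_numpy(dtype=float) if is_frame else np.asarray(values, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("zscore_rows needs a matrix with >=2 columns")
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    constant = (sd == 0).ravel()
    if constant.any():
        warnings.warn(
            f"zscore_rows: {int(constant.sum())} constant row(s) set to zeros"
        )
    safe_sd = np.where(sd == 0, 1.0, sd)
    out = (arr - mean) / safe_sd
    out[constant, :] = 0.0
    if is_frame:
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    return out
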