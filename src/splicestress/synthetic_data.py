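"""Synthetic inputs with known ground truth for every pipeline stage.

The study conditions emulated here are: several independent two-group
expression datasets on different "platforms" sharing one concertedly
shifted pathway; multi-sample differential-splicing tables sharing
planted recurrent events (retained introns biased toward increased
inclusion after treatment); time courses with a gradually decreasing
cluster; transcripts whose retained introns carry known numbers of
in-frame stop codons; and a TF-binding fixture in which some factors
bind both members of co-expressed pairs in every dataset and others in
only a subset.  All generators are deterministic given the seed, and
every written file round-trips through the corresponding reader.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expr_io import ExpressionDataset, zscore_rows
from .splicing import COORD_COLUMNS, EventKey
from .timecluster import TimeSeriesMatrix

_NON_STOP_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
)
_STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class PlantedSpliceEvent:
    """One event planted into a chosen fraction of splicing samples."""

    event_type: str
    sign: int
    fraction: float


def _default_planted_events() -> tuple[PlantedSpliceEvent, ...]:
    # composition echoes the dominant pattern in therapy-treated lines:
    # retained introns mostly gaining inclusion, plus skipped exons
    evs = []
    evs += [PlantedSpliceEvent("RI", +1, 0.75)] * 6
    evs += [PlantedSpliceEvent("RI", -1, 0.75)] * 2
    evs += [PlantedSpliceEvent("SE", -1, 0.75)] * 4
    evs += [PlantedSpliceEvent("SE", +1, 0.75)] * 2
    evs += [PlantedSpliceEvent("A5SS", +1, 0.75)] * 2
    evs += [PlantedSpliceEvent("A3SS", -1, 0.75)] * 2
    evs += [PlantedSpliceEvent("MXE", +1, 0.75)] * 2
    return tuple(evs)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study (defaults ARE the study conditions).

    Expression meta-analysis: ``n_datasets`` two-group studies of
    ``genes_total`` genes, ``samples_per_group`` samples per arm,
    unit-variance log2-scale noise, and the planted pathway(s) shifted
    by ``planted_effect`` log2 units in every treated arm.
    """

    seed: int = 0
    # --- expression multiset ---
    n_datasets: int = 3
    genes_total: int = 2000
    pathway_sets: dict[str, int] = field(
        default_factory=lambda: {"spliceosome": 100}
    )
    planted_effect: dict[str, float] = field(
        default_factory=lambda: {"spliceosome": -1.0}
    )
    samples_per_group: int = 3
    noise_sd: float = 1.0
    platform_shift_sd: float = 0.5
    platform_scale_sd: float = 0.1
    # --- time course ---
    timepoints: tuple[float, ...] = (0.0, 6.0, 12.0, 24.0)
    genes_per_cluster: int = 60
    timecourse_noise_sd: float = 0.3
    cluster_templates: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "decreasing": (1.0, 0.4, -0.3, -1.0),
            "increasing": (-1.0, -0.3, 0.4, 1.0),
            "transient": (-0.8, 1.0, 0.2, -0.8),
        }
    )
    # --- splicing tables ---
    n_samples_splicing: int = 12
    planted_events: tuple[PlantedSpliceEvent, ...] = field(
        default_factory=_default_planted_events
    )
    background_events_per_sample: int = 40
    background_significant_rate: float = 0.5
    # --- transcripts ---
    transcript_stop_counts: tuple[int, ...] = (0, 1, 2, 3, 3, 4, 5, 2, 1, 3)
    # --- TF fixture ---
    n_tf_samples: int = 24
    n_planted_pairs: int = 4
    n_null_genes_per_set: int = 6
    pair_noise_sd: float = 0.1
    tf_plants: dict[str, tuple[int, ...]] = field(
        default_factory=lambda: {
            "SOX2": (0, 1, 2),
            "GFI1B": (0, 1, 2),
            "TARDBP": (0, 1, 2),
            "MYC": (0, 1),
            "NANOG": (0,),
        }
    )
    promoter_window: int = 2000

    def __post_init__(self) -> None:
        if self.genes_total <= 0 or self.n_datasets <= 0:
            raise ValueError("sizes must be positive")
        if sum(self.pathway_sets.values()) > self.genes_total:
            raise ValueError("planted sets larger than genes_total")
        unknown = set(self.planted_effect) - set(self.pathway_sets)
        if unknown:
            raise ValueError(f"planted_effect for unknown sets: {unknown}")
        for ev in self.planted_events:
            if not (0.0 <= ev.fraction <= 1.0):
                raise ValueError("planted event fraction outside [0,1]")

    def rng(self, *tag: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, *tag])


@dataclass
class ExpressionTruth:
    """Ground truth for the expression multiset."""

    pathway_members: dict[str, list[str]]
    direction_of: dict[str, str]  # planted gene -> true direction (all datasets)

    @property
    def planted_genes(self) -> set[str]:
        return set(self.direction_of)


def gen_expression_multiset(
    config: SimulationConfig,
) -> tuple[list[ExpressionDataset], ExpressionTruth]:
    """Simulate the multi-dataset two-group expression experiment.

    Per dataset: gene baselines ~ Normal(platform_shift, 1) scaled by a
    platform factor; i.i.d. Gaussian noise of ``noise_sd`` on the log2
    scale; every treated sample of a planted gene shifted by that
    pathway's delta.  Ground truth records the planted direction.
    """
    rng = config.rng(1)
    genes = [f"G{i:05d}" for i in range(config.genes_total)]

    members: dict[str, list[str]] = {}
    cursor = 0
    for name, size in config.pathway_sets.items():
        members[name] = genes[cursor:cursor + size]
        cursor += size
    direction_of = {
        g: ("down" if config.planted_effect.get(name, 0.0) < 0 else "up")
        for name, glist in members.items()
        if config.planted_effect.get(name, 0.0) != 0.0
        for g in glist
    }

    n = config.samples_per_group
    datasets: list[ExpressionDataset] = []
    for d in range(config.n_datasets):
        shift = rng.normal(0.0, config.platform_shift_sd)
        scale = float(np.exp(rng.normal(0.0, config.platform_scale_sd)))
        baseline = scale * rng.normal(shift + 8.0, 1.0, size=config.genes_total)
        noise = rng.normal(0.0, config.noise_sd, size=(config.genes_total, 2 * n))
        values = baseline[:, None] + noise
        for name, glist in members.items():
            delta = config.planted_effect.get(name, 0.0)
            if delta:
                idx = [genes.index(g) for g in glist]
                values[np.array(idx)[:, None], np.arange(n, 2 * n)] += delta
        samples = [f"D{d}_ctrl{j}" for j in range(n)] + [
            f"D{d}_trt{j}" for j in range(n)
        ]
        group_of = {s: ("control" if j < n else "treated")
                    for j, s in enumerate(samples)}
        datasets.append(ExpressionDataset(
            dataset_id=f"synthetic_ds{d}",
            data=pd.DataFrame(values, index=genes, columns=samples),
            group_of=group_of,
        ))
    return datasets, ExpressionTruth(pathway_members=members,
                                     direction_of=direction_of)


def gen_timecourse(
    config: SimulationConfig,
) -> tuple[TimeSeriesMatrix, list[str]]:
    """Simulate a z-scored time course with planted trajectory clusters.

    Each cluster template (over ``timepoints``) is replicated
    ``genes_per_cluster`` times with Gaussian noise, then row z-scored.
    Returns the matrix and the per-gene true cluster labels.
    """
    rng = config.rng(2)
    tps = list(config.timepoints)
    genes: list[str] = []
    labels: list[str] = []
    rows: list[np.ndarray] = []
    for name, template in config.cluster_templates.items():
        if len(template) != len(tps):
            raise ValueError(
                f"template {name} length != number of timepoints"
            )
        base = np.asarray(template, dtype=float)
        for j in range(config.genes_per_cluster):
            rows.append(base + rng.normal(0, config.timecourse_noise_sd,
                                          size=len(tps)))
            genes.append(f"T_{name}_{j:03d}")
            labels.append(name)
    values = zscore_rows(np.vstack(rows))
    return TimeSeriesMatrix(genes=genes, timepoints=tps, values=values), labels


def _random_coords(rng: np.random.Generator, event_type: str) -> tuple[int, ...]:
    """Draw a strictly ordered coordinate tuple for the given event type."""
    n_pairs = len(COORD_COLUMNS[event_type]) // 2
    start = int(rng.integers(1_000, 50_000_000))
    coords: list[int] = []
    pos = start
    for _ in range(n_pairs):
        lo = pos + int(rng.integers(100, 5_000))
        hi = lo + int(rng.integers(80, 3_000))
        coords.extend([lo, hi])
        pos = hi
    return tuple(coords)


def _inc_levels(rng: np.random.Generator, sign: int) -> tuple[float, float]:
    """Control/treated inclusion levels with |diff| in (0.1, 0.5), given sign."""
    diff = sign * rng.uniform(0.1, 0.5)
    lo = max(0.0, -diff) + 0.02
    hi = min(1.0, 1.0 - diff) - 0.02
    ctrl = rng.uniform(lo, hi)
    return float(ctrl), float(ctrl + diff)


def gen_splice_tables(
    config: SimulationConfig, out_dir: str | Path
) -> tuple[list[str], list[EventKey]]:
    """Write per-sample splicing tables; return sample IDs + planted keys.

    Each planted event appears, with its fixed coordinates and sign, in
    exactly ``ceil(fraction * n_samples)`` samples with FDR < 0.05 and
    |inclusion difference| > 0.05; background events get per-sample
    random coordinates (a fraction of them deliberately failing the
    significance filter).  Files use the junction-count dialect, with
    "sample 1" holding the treated condition.
    """
    out_dir = Path(out_dir)
    rng = config.rng(3)
    n = config.n_samples_splicing
    samples = [f"cellline_{i:02d}" for i in range(n)]

    planted: list[dict] = []
    for i, pev in enumerate(config.planted_events):
        coords = _random_coords(rng, pev.event_type)
        n_carriers = math.ceil(pev.fraction * n)
        carriers = sorted(rng.choice(n, size=n_carriers, replace=False))
        planted.append({
            "event_type": pev.event_type,
            "chrom": f"chr{1 + i % 22}",
            "strand": "+" if rng.random() < 0.5 else "-",
            "coords": coords,
            "sign": pev.sign,
            "gene": f"PL{i:03d}",
            "carriers": set(int(c) for c in carriers),
        })

    truth_keys = [
        EventKey(p["event_type"], p["chrom"], p["strand"], p["coords"], p["sign"])
        for p in planted
    ]

    for s_idx, sample in enumerate(samples):
        sdir = out_dir / sample
        sdir.mkdir(parents=True, exist_ok=True)
        rows_by_type: dict[str, list[dict]] = {t: [] for t in COORD_COLUMNS}
        for p in planted:
            if s_idx not in p["carriers"]:
                continue
            ctrl, trt = _inc_levels(rng, p["sign"])
            rows_by_type[p["event_type"]].append({
                "gene": p["gene"], "chrom": p["chrom"], "strand": p["strand"],
                "coords": p["coords"], "inc_ctrl": ctrl, "inc_trt": trt,
                "fdr": float(rng.uniform(0.0, 0.04)),
            })
        for _ in range(config.background_events_per_sample):
            etype = str(rng.choice(list(COORD_COLUMNS)))
            sign = 1 if rng.random() < 0.5 else -1
            if rng.random() < config.background_significant_rate:
                ctrl, trt = _inc_levels(rng, sign)
                fdr = float(rng.uniform(0.0, 0.04))
            else:
                # deliberately insignificant: tiny diff or large FDR
                ctrl = float(rng.uniform(0.3, 0.7))
                trt = ctrl + sign * float(rng.uniform(0.0, 0.04))
                fdr = float(rng.uniform(0.05, 1.0))
            rows_by_type[etype].append({
                "gene": f"BG{int(rng.integers(0, 10**6)):06d}",
                "chrom": f"chr{int(rng.integers(1, 23))}",
                "strand": "+" if rng.random() < 0.5 else "-",
                "coords": _random_coords(rng, etype),
                "inc_ctrl": ctrl, "inc_trt": float(np.clip(trt, 0, 1)),
                "fdr": fdr,
            })
        for etype, rows in rows_by_type.items():
            _write_mats_file(sdir / f"{etype}.MATS.JC.txt", etype, rows)
    return samples, truth_keys


def _write_mats_file(path: Path, event_type: str, rows: list[dict]) -> None:
    coord_cols = COORD_COLUMNS[event_type]
    header = ["ID", "GeneID", "geneSymbol", "chr", "strand", *coord_cols,
              "IncLevel1", "IncLevel2", "IncLevelDifference", "FDR"]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for i, r in enumerate(rows):
            # sample 1 = treated; write duplicate replicate values so the
            # per-condition mean equals the intended level exactly
            inc1 = f"{r['inc_trt']:.4f},{r['inc_trt']:.4f}"
            inc2 = f"{r['inc_ctrl']:.4f},{r['inc_ctrl']:.4f}"
            diff = round(r["inc_trt"], 4) - round(r["inc_ctrl"], 4)
            fields = [str(i), f'"{r["gene"]}"', r["gene"], r["chrom"],
                      r["strand"], *[str(c) for c in r["coords"]],
                      inc1, inc2, f"{diff:.4f}", f"{r['fdr']:.6g}"]
            fh.write("\t".join(fields) + "\n")


def gen_transcripts(
    config: SimulationConfig, out_dir: str | Path
) -> tuple[Path, Path, dict[str, int]]:
    """Write retained-intron transcripts with planted in-frame stop counts.

    Every transcript is built from non-stop codons in the annotated
    frame, so the only in-frame stops overlapping the intron are the
    planted ones.  Returns (fasta_path, annotation_path, truth counts).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = config.rng(4)
    fasta = out_dir / "retained_transcripts.fa"
    anno = out_dir / "retained_transcripts.tsv"
    truth: dict[str, int] = {}
    with open(fasta, "w") as fa, open(anno, "w") as an:
        an.write("transcript_id\tcds_start\tintron_start\tintron_end\n")
        for i, n_stops in enumerate(config.transcript_stop_counts):
            tid = f"TX{i:03d}"
            cds_start = int(rng.integers(0, 12))
            utr = "".join(rng.choice(list("ACGT"), size=cds_start))
            n_codons = int(rng.integers(40, 80))
            codons = ["ATG"] + [
                str(rng.choice(_NON_STOP_CODONS)) for _ in range(n_codons - 1)
            ]
            body = "".join(codons)
            # intron boundaries at arbitrary (not necessarily in-frame)
            # offsets inside the body, wide enough to hold the stops
            min_len = 3 * (n_stops + 4)
            i_start = cds_start + 3 + int(rng.integers(0, 30))
            i_end = i_start + min_len + int(rng.integers(0, 30))
            seq = utr + body
            if i_end > len(seq) - 6:
                i_end = len(seq) - 6
            # plant stops at in-frame offsets fully inside the intron
            frame_offsets = [
                off for off in range(cds_start, len(seq) - 2, 3)
                if off >= i_start and off + 3 <= i_end
            ]
            chosen = sorted(rng.choice(len(frame_offsets), size=n_stops,
                                       replace=False))
            seq_list = list(seq)
            for c in chosen:
                off = frame_offsets[c]
                stop = str(rng.choice(_STOP_CODONS))
                seq_list[off:off + 3] = stop
            seq = "".join(seq_list)
            fa.write(f">{tid}\n{seq}\n")
            an.write(f"{tid}\t{cds_start}\t{i_start}\t{i_end}\n")
            truth[tid] = int(n_stops)
    return fasta, anno, truth


@dataclass
class TFFixture:
    """Expression datasets + binding intervals with planted common TFs."""

    datasets: list[ExpressionDataset]
    splicing_genes: list[str]
    mitotic_genes: list[str]
    planted_pairs: dict[str, list[tuple[str, str]]]  # dataset_id -> pairs
    peaks: list[tuple[str, str, int, int]]  # (tf, chrom, start, end)
    tss: dict[str, tuple[str, str, int]]
    truth_common_tfs: set[str]


def gen_tf_fixture(config: SimulationConfig) -> TFFixture:
    """Simulate the co-regulation inputs.

    Per dataset, ``n_planted_pairs`` (splicing gene, mitotic gene) pairs
    share a latent per-sample factor (plus small noise), making them
    strongly rank-correlated; null genes are independent noise.  Each
    planted TF receives promoter peaks on both members of the planted
    pairs of exactly the datasets in its coverage list, so the TFs
    covering every dataset are the true common set.
    """
    rng = config.rng(5)
    n_ds = config.n_datasets
    n_pairs = config.n_planted_pairs
    n_null = config.n_null_genes_per_set
    n_samp = config.n_tf_samples

    datasets: list[ExpressionDataset] = []
    planted_pairs: dict[str, list[tuple[str, str]]] = {}
    all_genes: list[str] = []
    for d in range(n_ds):
        pairs = [(f"SPL_d{d}_{i}", f"MIT_d{d}_{i}") for i in range(n_pairs)]
        null_spl = [f"SPLN_d{d}_{i}" for i in range(n_null)]
        null_mit = [f"MITN_d{d}_{i}" for i in range(n_null)]
        genes = [g for p in pairs for g in p] + null_spl + null_mit
        all_genes.extend(genes)
        values = rng.normal(0.0, 1.0, size=(len(genes), n_samp))
        for i, (a, b) in enumerate(pairs):
            latent = rng.normal(0.0, 1.0, size=n_samp)
            ia, ib = genes.index(a), genes.index(b)
            values[ia] = latent + rng.normal(0, config.pair_noise_sd, n_samp)
            values[ib] = latent + rng.normal(0, config.pair_noise_sd, n_samp)
        samples = [f"TF{d}_s{j}" for j in range(n_samp)]
        group_of = {s: ("control" if j < n_samp // 2 else "treated")
                    for j, s in enumerate(samples)}
        ds_id = f"platinum_ds{d}"
        datasets.append(ExpressionDataset(
            dataset_id=ds_id,
            data=pd.DataFrame(values, index=genes, columns=samples),
            group_of=group_of,
        ))
        planted_pairs[ds_id] = pairs

    splicing_genes = sorted(g for g in all_genes if g.startswith(("SPL_", "SPLN_")))
    mitotic_genes = sorted(g for g in all_genes if g.startswith(("MIT_", "MITN_")))

    tss: dict[str, tuple[str, str, int]] = {}
    for i, g in enumerate(sorted(set(all_genes))):
        tss[g] = ("chr1", "+", 10_000 + 20_000 * i)

    peaks: list[tuple[str, str, int, int]] = []
    for tf, coverage in config.tf_plants.items():
        for d in coverage:
            if d >= n_ds:
                continue
            for a, b in planted_pairs[f"platinum_ds{d}"]:
                for gene in (a, b):
                    chrom, _, pos = tss[gene]
                    peaks.append((tf, chrom, max(0, pos - 100), pos + 100))
    truth_common = {
        tf for tf, coverage in config.tf_plants.items()
        if set(range(n_ds)) <= set(coverage)
    }
    return TFFixture(
        datasets=datasets,
        splicing_genes=splicing_genes,
        mitotic_genes=mitotic_genes,
        planted_pairs=planted_pairs,
        peaks=peaks,
        tss=tss,
        truth_common_tfs=truth_common,
    )


def write_tf_fixture(fixture: TFFixture, out_dir: str | Path) -> None:
    """Write the TF fixture as BED peaks + TSS table (round-trippable)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "tf_peaks.bed", "w") as fh:
        for tf, chrom, start, end in fixture.peaks:
            fh.write(f"{chrom}\t{start}\t{end}\t{tf}\n")
    with open(out_dir / "tss.tsv", "w") as fh:
        fh.write("gene\tchrom\tstrand\ttss\n")
        for gene, (chrom, strand, pos) in sorted(fixture.tss.items()):
            fh.write(f"{gene}\t{chrom}\t{strand}\t{pos}\n")
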