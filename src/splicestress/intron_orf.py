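"""Stop-codon scans of transcripts carrying a retained intron.

A retained intron usually disrupts the reading frame or introduces
premature termination codons (PTCs), flagging the transcript for decay
rather than translation.  Given the retained-form mRNA sequence, the
CDS start and the intron interval, this module walks the annotated
reading frame and counts in-frame stop codons that overlap the intron
— the signature that the retained transcript cannot encode the
functional protein.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_VALID = frozenset("ACGT")


@dataclass(frozen=True)
class TranscriptModel:
    """Retained-form transcript with CDS start and intron interval.

    ``spliced_seq`` is the mRNA *with* the intron retained, uppercase
    ACGT only.  ``intron_interval`` is 0-based half-open within that
    sequence and must start downstream of ``cds_start``.
    """

    transcript_id: str
    spliced_seq: str
    cds_start: int
    intron_interval: tuple[int, int]

    def __post_init__(self) -> None:
        seq = self.spliced_seq
        bad = set(seq) - _VALID
        if bad:
            raise ValueError(
                f"{self.transcript_id}: invalid characters {sorted(bad)} "
                "(uppercase ACGT only)"
            )
        start, end = self.intron_interval
        if not (0 <= start < end <= len(seq)):
            raise ValueError(
                f"{self.transcript_id}: intron interval [{start},{end}) "
                f"outside sequence of length {len(seq)}"
            )
        if not (0 <= self.cds_start < start):
            raise ValueError(
                f"{self.transcript_id}: intron must begin downstream of "
                f"cds_start ({self.cds_start} vs intron start {start})"
            )


@dataclass(frozen=True)
class StopScanResult:
    transcript_id: str
    n_inframe_stops_in_intron: int
    first_stop_offset: int | None
    ptc_flag: bool

    def __post_init__(self) -> None:
        if self.ptc_flag != (self.n_inframe_stops_in_intron >= 1):
            raise ValueError("ptc_flag inconsistent with stop count")


def scan_retained_intron(model: TranscriptModel) -> StopScanResult:
    """Count in-frame stop codons overlapping the retained intron.

    The reading frame is fixed by ``cds_start``; codons at offsets
    ``cds_start + 3j`` are scanned left to right.  A codon counts iff it
    is a stop triplet AND overlaps the intron interval by at least one
    base — a stop straddling the exon/intron boundary exists only
    because of the retention, so it is attributed to the intron.
    Scanning continues through the whole intron (all overlapping stops
    are tallied); ``first_stop_offset`` is the leftmost one.
    """
    seq = model.spliced_seq
    i_start, i_end = model.intron_interval
    n_stops = 0
    first: int | None = None
    for off in range(model.cds_start, len(seq) - 2, 3):
        if off >= i_end:
            break  # codons past the intron cannot overlap it
        codon = seq[off:off + 3]
        if codon in STOP_CODONS and off + 3 > i_start:
            n_stops += 1
            if first is None:
                first = off
    return StopScanResult(
        transcript_id=model.transcript_id,
        n_inframe_stops_in_intron=n_stops,
        first_stop_offset=first,
        ptc_flag=n_stops >= 1,
    )


def scan_all_frames(model: TranscriptModel) -> dict[int, StopScanResult]:
    """Optional report: the intron-overlap stop scan in all three frames.

    Keys are frame offsets 0/1/2 relative to ``cds_start``.
    """
    out = {}
    for frame in range(3):
        shifted = TranscriptModel(
            transcript_id=model.transcript_id,
            spliced_seq=model.spliced_seq,
            cds_start=model.cds_start + frame,
            intron_interval=model.intron_interval,
        )
        out[frame] = scan_retained_intron(shifted)
    return out


def batch_scan(
    models: Sequence[TranscriptModel],
) -> tuple[list[StopScanResult], float | None]:
    """Scan many transcripts; return per-transcript results + PTC fraction.

    The summary fraction is the share of transcripts with at least one
    in-frame stop in the intron, or ``None`` for empty input.
    """
    seen: set[str] = set()
    for m in models:
        if m.transcript_id in seen:
            raise ValueError(f"duplicate transcript_id {m.transcript_id}")
        seen.add(m.transcript_id)
    results = [scan_retained_intron(m) for m in models]
    if not results:
        return [], None
    frac = sum(r.ptc_flag for r in results) / len(results)
    return results, frac


def read_transcript_models(
    fasta_path: str | Path, annotation_path: str | Path
) -> list[TranscriptModel]:
    """Load retained-form transcripts from FASTA + companion annotation TSV.

    The annotation has columns
    ``transcript_id<TAB>cds_start<TAB>intron_start<TAB>intron_end``
    (0-based, half-open).  Every annotated transcript must appear in the
    FASTA.
    """
    seqs = {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(fasta_path), "fasta")}
    models: list[TranscriptModel] = []
    with open(annotation_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:1] != ["transcript_id"]:
            raise ValueError(
                f"{annotation_path}: expected header starting with transcript_id"
            )
        for line in fh:
            if not line.strip():
                continue
            tid, cds_start, i_start, i_end = line.rstrip("\n").split("\t")[:4]
            if tid not in seqs:
                raise ValueError(f"transcript {tid} missing from FASTA")
            models.append(TranscriptModel(
                transcript_id=tid,
                spliced_seq=seqs[tid],
                cds_start=int(cds_start),
                intron_interval=(int(i_start), int(i_end)),
            ))
    return models


def write_scan_results(
    results: Iterable[StopScanResult], path, summary_fraction: float | None = None
) -> None:
    """Write ``transcript_id<TAB>n_stops<TAB>first_stop_offset<TAB>ptc``."""
    with open(path, "w") as fh:
        fh.write("transcript_id\tn_stops\tfirst_stop_offset\tptc\n")
        for r in results:
            first = "" if r.first_stop_offset is None else str(r.first_stop_offset)
            fh.write(
                f"{r.transcript_id}\t{r.n_inframe_stops_in_intron}\t{first}\t"
                f"{'true' if r.ptc_flag else 'false'}\n"
            )
        if summary_fraction is not None:
            fh.write(f"# ptc_fraction\t{summary_fraction:.6g}\n")
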