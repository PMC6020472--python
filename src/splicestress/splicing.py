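"""Differential alternative-splicing tables: parsing, filtering, recurrence.

Consumes per-event-type tab-separated tables in the dialect of the
standard junction-count splicing caller (one file per event type: SE,
A5SS, A3SS, RI, MXE; coordinates 0-based half-open).  Events are
filtered on FDR and inclusion-level difference, keyed by their full
coordinate tuple plus the sign of the inclusion change, and counted
across samples to find events recurring in at least a given fraction of
samples — the signature of a shared, therapy-induced splicing response.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

EVENT_TYPES = ("SE", "A5SS", "A3SS", "RI", "MXE")

#: coordinate columns defining each event type, in key order
COORD_COLUMNS: dict[str, tuple[str, ...]] = {
    "SE": ("exonStart_0base", "exonEnd", "upstreamES", "upstreamEE",
           "downstreamES", "downstreamEE"),
    "RI": ("riExonStart_0base", "riExonEnd", "upstreamES", "upstreamEE",
           "downstreamES", "downstreamEE"),
    "MXE": ("1stExonStart_0base", "1stExonEnd", "2ndExonStart_0base",
            "2ndExonEnd", "upstreamES", "upstreamEE",
            "downstreamES", "downstreamEE"),
    "A5SS": ("longExonStart_0base", "longExonEnd", "shortES", "shortEE",
             "flankingES", "flankingEE"),
    "A3SS": ("longExonStart_0base", "longExonEnd", "shortES", "shortEE",
             "flankingES", "flankingEE"),
}


@dataclass(frozen=True)
class SpliceEvent:
    """One differential-splicing record from one sample's comparison.

    ``inc_diff`` is treated minus control inclusion level, on the [0,1]
    proportion scale, regardless of the orientation of the source file.
    """

    event_type: str
    gene: str
    chrom: str
    strand: str
    coords: tuple[int, ...]
    inc_level_control: float
    inc_level_treated: float
    inc_diff: float
    fdr: float
    sample_id: str

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        for lo, hi in zip(self.coords[::2], self.coords[1::2]):
            if hi <= lo:
                raise ValueError(
                    f"coordinates not strictly ordered: {self.coords}"
                )
        for v in (self.inc_level_control, self.inc_level_treated):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"inclusion level {v} outside [0,1]")
        if abs(self.inc_diff) > 1.0 + 1e-12:
            raise ValueError(f"inc_diff {self.inc_diff} outside [-1,1]")

    @property
    def key(self):
        """Identity key: type, position and direction of change.

        Events with ``inc_diff == 0`` carry no direction and have no key.
        """
        if self.inc_diff == 0:
            return None
        sign = 1 if self.inc_diff > 0 else -1
        return EventKey(self.event_type, self.chrom, self.strand,
                        self.coords, sign)


@dataclass(frozen=True)
class EventKey:
    event_type: str
    chrom: str
    strand: str
    coords: tuple[int, ...]
    sign: int


@dataclass(frozen=True)
class RecurrentEvent:
    """A splice-event key observed in multiple samples."""

    key: EventKey
    n_samples: int
    sample_ids: frozenset[str]
    mean_inc_diff: float

    def __post_init__(self) -> None:
        if self.n_samples != len(self.sample_ids):
            raise ValueError("n_samples inconsistent with sample_ids")


def _mean_inc(field: str, path: Path, lineno: int) -> float:
    vals = [float(v) for v in field.split(",") if v not in ("", "NA")]
    if not vals:
        raise ValueError(f"{path}:{lineno}: empty inclusion-level field")
    return sum(vals) / len(vals)


def read_rmats_table(
    path: str | Path,
    event_type: str,
    sample_id: str,
    sample1_is: str = "treated",
) -> list[SpliceEvent]:
    """Parse one per-type differential-splicing TSV.

    ``sample1_is`` declares which condition the file's "sample 1"
    (IncLevel1) holds; ``inc_diff`` is re-signed so that positive always
    means higher inclusion in treated cells.  In the source dialect
    ``IncLevelDifference`` is IncLevel1 minus IncLevel2.
    """
    if sample1_is not in ("treated", "control"):
        raise ValueError("sample1_is must be 'treated' or 'control'")
    path = Path(path)
    coord_cols = COORD_COLUMNS[event_type]
    events: list[SpliceEvent] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        col = {name: i for i, name in enumerate(header)}
        required = set(coord_cols) | {"chr", "strand", "IncLevel1",
                                      "IncLevel2", "IncLevelDifference", "FDR"}
        missing = required - set(col)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            try:
                coords = tuple(int(fields[col[c]]) for c in coord_cols)
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: malformed coordinate ({exc})"
                ) from None
            inc1 = _mean_inc(fields[col["IncLevel1"]], path, lineno)
            inc2 = _mean_inc(fields[col["IncLevel2"]], path, lineno)
            if sample1_is == "treated":
                inc_trt, inc_ctrl = inc1, inc2
            else:
                inc_trt, inc_ctrl = inc2, inc1
            events.append(SpliceEvent(
                event_type=event_type,
                gene=fields[col["geneSymbol"]] if "geneSymbol" in col else "",
                chrom=fields[col["chr"]],
                strand=fields[col["strand"]],
                coords=coords,
                inc_level_control=inc_ctrl,
                inc_level_treated=inc_trt,
                inc_diff=inc_trt - inc_ctrl,
                fdr=float(fields[col["FDR"]]),
                sample_id=sample_id,
            ))
    return events


def read_rmats_tables(
    directory: str | Path,
    sample_id: str,
    sample1_is: str = "treated",
    glob: str = "*.MATS.JC.txt",
) -> list[SpliceEvent]:
    """Read every per-type table in a directory for one sample.

    Files are matched by ``glob`` and assigned an event type from the
    filename prefix (``SE.MATS.JC.txt`` etc.); files whose prefix is not
    a known event type are skipped with a warning.
    """
    directory = Path(directory)
    events: list[SpliceEvent] = []
    for path in sorted(directory.glob(glob)):
        etype = path.name.split(".")[0]
        if etype not in EVENT_TYPES:
            logger.warning("skipping unknown event-type file %s", path.name)
            continue
        events.extend(read_rmats_table(path, etype, sample_id, sample1_is))
    return events


def filter_significant(
    events: Iterable[SpliceEvent],
    fdr_max: float = 0.05,
    min_abs_diff: float = 0.05,
) -> list[SpliceEvent]:
    """Keep events with ``fdr < fdr_max`` and ``|inc_diff| > min_abs_diff``.

    Both inequalities are strict; the defaults drop minor differences
    (FDR >= 5% or inclusion change of 5 percentage points or less).
    """
    return [e for e in events
            if e.fdr < fdr_max and abs(e.inc_diff) > min_abs_diff]


def find_recurrent(
    events_by_sample: Mapping[str, Sequence[SpliceEvent]],
    min_fraction: float = 0.5,
) -> list[RecurrentEvent]:
    """Find event keys recurring in at least ``min_fraction`` of samples.

    An event key (coordinates plus sign of the inclusion change) counts
    at most once per sample; the threshold is ``ceil(min_fraction * n)``
    samples, so "at least half" of 17 samples means 9.  Zero-difference
    events carry no key and never recur.
    """
    if not events_by_sample:
        raise ValueError("no samples")
    if not (0.0 <= min_fraction <= 1.0):
        raise ValueError("min_fraction must lie in [0, 1]")
    n_total = len(events_by_sample)
    threshold = max(1, math.ceil(min_fraction * n_total))

    by_key: dict[EventKey, dict[str, float]] = defaultdict(dict)
    for sample, events in events_by_sample.items():
        for ev in events:
            key = ev.key
            if key is None:
                continue
            # one contribution per sample; keep the first occurrence
            by_key[key].setdefault(sample, ev.inc_diff)

    out = [
        RecurrentEvent(
            key=key,
            n_samples=len(per_sample),
            sample_ids=frozenset(per_sample),
            mean_inc_diff=sum(per_sample.values()) / len(per_sample),
        )
        for key, per_sample in by_key.items()
        if len(per_sample) >= threshold
    ]
    out.sort(key=lambda r: (r.key.event_type, r.key.chrom, r.key.coords,
                            r.key.sign))
    return out


def type_summary(events: Sequence) -> dict:
    """Tally events per type, with directionality counts for RI.

    Accepts either :class:`SpliceEvent` or :class:`RecurrentEvent`
    items.  Returns ``{"counts": {type: n}, "ri_directionality":
    (n_positive, n_negative, fraction_positive)}``; the fraction is
    ``None`` when no signed RI events are present.
    """
    counts: dict[str, int] = {t: 0 for t in EVENT_TYPES}
    ri_pos = ri_neg = 0
    for ev in events:
        if isinstance(ev, RecurrentEvent):
            etype, diff = ev.key.event_type, float(ev.key.sign)
        else:
            etype, diff = ev.event_type, ev.inc_diff
        counts[etype] += 1
        if etype == "RI":
            if diff > 0:
                ri_pos += 1
            elif diff < 0:
                ri_neg += 1
    total_ri = ri_pos + ri_neg
    frac = ri_pos / total_ri if total_ri else None
    return {
        "counts": {t: n for t, n in counts.items() if n > 0} or {},
        "ri_directionality": (ri_pos, ri_neg, frac),
    }


def write_recurrent_events(events: Iterable[RecurrentEvent], path) -> None:
    """Write ``event_type<TAB>chrom<TAB>strand<TAB>coords<TAB>sign<TAB>n_samples<TAB>mean_inc_diff``."""
    with open(path, "w") as fh:
        fh.write("event_type\tchrom\tstrand\tcoords\tsign\tn_samples\tmean_inc_diff\n")
        for ev in events:
            coords = ",".join(str(c) for c in ev.key.coords)
            fh.write(
                f"{ev.key.event_type}\t{ev.key.chrom}\t{ev.key.strand}\t"
                f"{coords}\t{ev.key.sign:+d}\t{ev.n_samples}\t"
                f"{ev.mean_inc_diff:.6g}\n"
            )
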