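"""Splicing-table parsing, significance filtering and recurrence counting."""

import itertools
import logging

import numpy as np
import pytest

from splicestress.splicing import (
    EventKey,
    SpliceEvent,
    filter_significant,
    find_recurrent,
    read_rmats_table,
    read_rmats_tables,
    type_summary,
)

RI_HEADER = (
    "ID\tGeneID\tgeneSymbol\tchr\tstrand\triExonStart_0base\triExonEnd\t"
    "upstreamES\tupstreamEE\tdownstreamES\tdownstreamEE\t"
    "IncLevel1\tIncLevel2\tIncLevelDifference\tFDR\n"
)


def make_event(etype="RI", chrom="chr1", strand="+", coords=(100, 200, 10, 50, 250, 300),
               inc_diff=0.3, fdr=0.01, sample="s1", gene="GENE"):
    base = 0.4
    ctrl = base
    trt = min(1.0, max(0.0, base + inc_diff))
    return SpliceEvent(
        event_type=etype, gene=gene, chrom=chrom, strand=strand,
        coords=tuple(coords), inc_level_control=ctrl, inc_level_treated=trt,
        inc_diff=inc_diff, fdr=fdr, sample_id=sample,
    )


def recurrence_oracle(events_by_sample, min_fraction):
    """Nested-loop matcher: count per-key sample sets by direct comparison."""
    import math
    samples = list(events_by_sample)
    threshold = max(1, math.ceil(min_fraction * len(samples)))
    keys = []
    for s in samples:
        for ev in events_by_sample[s]:
            if ev.inc_diff == 0:
                continue
            k = (ev.event_type, ev.chrom, ev.strand, ev.coords,
                 1 if ev.inc_diff > 0 else -1)
            if k not in keys:
                keys.append(k)
    out = {}
    for k in keys:
        carriers = set()
        for s in samples:
            for ev in events_by_sample[s]:
                if ev.inc_diff == 0:
                    continue
                sign = 1 if ev.inc_diff > 0 else -1
                if (ev.event_type, ev.chrom, ev.strand, ev.coords, sign) == k:
                    carriers.add(s)
        if len(carriers) >= threshold:
            out[k] = carriers
    return out


class TestParsing:
    def _write_ri(self, tmp_path, inc1="0.5,0.7", inc2="0.2,0.2"):
        path = tmp_path / "RI.MATS.JC.txt"
        row = ("1\t\"G1\"\tG1\tchr2\t+\t1000\t1100\t900\t950\t1200\t1300\t"
               f"{inc1}\t{inc2}\t0.4\t0.001\n")
        path.write_text(RI_HEADER + row)
        return path

    def test_orientation_sample1_treated(self, tmp_path):
        path = self._write_ri(tmp_path)
        [ev] = read_rmats_table(path, "RI", "sampleA", sample1_is="treated")
        assert ev.inc_level_treated == pytest.approx(0.6)
        assert ev.inc_level_control == pytest.approx(0.2)
        assert ev.inc_diff == pytest.approx(0.4)
        assert ev.coords == (1000, 1100, 900, 950, 1200, 1300)

    def test_orientation_sample1_control_flips_sign(self, tmp_path):
        path = self._write_ri(tmp_path)
        [ev] = read_rmats_table(path, "RI", "sampleA", sample1_is="control")
        assert ev.inc_diff == pytest.approx(-0.4)

    def test_unknown_event_type_file_skipped_with_warning(self, tmp_path, caplog):
        (tmp_path / "XYZ.MATS.JC.txt").write_text(RI_HEADER)
        with caplog.at_level(logging.WARNING, logger="splicestress.splicing"):
            events = read_rmats_tables(tmp_path, "s1")
        assert events == []
        assert "XYZ" in caplog.text

    def test_malformed_coordinate_reports_line(self, tmp_path):
        path = tmp_path / "RI.MATS.JC.txt"
        row = ("1\t\"G1\"\tG1\tchr2\t+\toops\t1100\t900\t950\t1200\t1300\t"
               "0.5\t0.2\t0.3\t0.001\n")
        path.write_text(RI_HEADER + row)
        with pytest.raises(ValueError, match=":2"):
            read_rmats_table(path, "RI", "s")

    def test_resign_invariance_under_global_flip(self, tmp_path):
        path = self._write_ri(tmp_path)
        [fwd] = read_rmats_table(path, "RI", "s", sample1_is="treated")
        [rev] = read_rmats_table(path, "RI", "s", sample1_is="control")
        assert fwd.inc_diff == pytest.approx(-rev.inc_diff)
        assert fwd.key.sign == -rev.key.sign
        assert (fwd.key.coords, fwd.key.event_type) == (rev.key.coords,
                                                        rev.key.event_type)


class TestFilterSignificant:
    @pytest.mark.parametrize(
        "fdr,diff,kept",
        [
            (0.04, 0.06, True),
            (0.05, 0.5, False),   # FDR boundary is strict
            (0.001, -0.05, False),  # |diff| boundary is strict
            (0.001, -0.051, True),
        ],
    )
    def test_strict_thresholds(self, fdr, diff, kept):
        events = [make_event(inc_diff=diff, fdr=fdr)]
        assert (len(filter_significant(events)) == 1) is kept

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        events = [make_event(inc_diff=float(rng.uniform(-0.5, 0.5)),
                             fdr=float(rng.uniform(0, 0.2)))
                  for _ in range(50)]
        once = filter_significant(events)
        assert filter_significant(once) == once


class TestFindRecurrent:
    def test_at_least_half_uses_ceiling(self):
        # 9 of 18 kept (ceil(9)=9); 5 of 12 dropped (ceil(6)=6)
        ev = make_event()
        by_sample = {f"s{i}": ([ev] if i < 9 else []) for i in range(18)}
        assert len(find_recurrent(by_sample, 0.5)) == 1
        by_sample = {f"s{i}": ([ev] if i < 5 else []) for i in range(12)}
        assert find_recurrent(by_sample, 0.5) == []

    def test_opposite_signs_are_distinct_keys(self):
        a = make_event(inc_diff=0.1)
        b = make_event(inc_diff=-0.1)
        recurrent = find_recurrent({"s1": [a], "s2": [b]}, min_fraction=0.0)
        assert len(recurrent) == 2
        assert {r.key.sign for r in recurrent} == {1, -1}

    def test_zero_diff_events_have_no_key(self):
        ev = make_event(inc_diff=0.0)
        assert ev.key is None
        assert find_recurrent({"s1": [ev], "s2": [ev]}, 0.0) == []

    def test_extreme_fractions(self):
        a, b = make_event(), make_event(coords=(5, 9, 1, 3, 11, 15))
        by_sample = {"s1": [a, b], "s2": [a]}
        all_keys = find_recurrent(by_sample, min_fraction=0.0)
        assert len(all_keys) == 2
        universal = find_recurrent(by_sample, min_fraction=1.0)
        assert len(universal) == 1
        assert universal[0].n_samples == 2

    def test_event_counted_once_per_sample(self):
        ev = make_event(inc_diff=0.3)
        dup = make_event(inc_diff=0.2)  # same key (same sign/coords)
        rec = find_recurrent({"s1": [ev, dup]}, min_fraction=1.0)
        assert rec[0].n_samples == 1
        assert rec[0].mean_inc_diff == pytest.approx(0.3)  # first occurrence

    def test_agrees_with_nested_loop_oracle(self):
        rng = np.random.default_rng(99)
        for trial in range(10):
            n_samples = int(rng.integers(2, 8))
            coord_pool = [tuple(sorted(rng.choice(10_000, 6, replace=False)))
                          for _ in range(12)]
            by_sample = {}
            for s in range(n_samples):
                events = []
                for _ in range(int(rng.integers(0, 30))):
                    coords = coord_pool[int(rng.integers(len(coord_pool)))]
                    events.append(make_event(
                        etype=str(rng.choice(["SE", "RI"])),
                        coords=coords,
                        inc_diff=float(rng.choice([-0.3, 0.0, 0.3])),
                        sample=f"s{s}",
                    ))
                by_sample[f"s{s}"] = events
            frac = float(rng.choice([0.0, 0.3, 0.5, 1.0]))
            got = {
                (r.key.event_type, r.key.chrom, r.key.strand, r.key.coords,
                 r.key.sign): set(r.sample_ids)
                for r in find_recurrent(by_sample, frac)
            }
            assert got == recurrence_oracle(by_sample, frac)


class TestTypeSummary:
    def test_counting_with_ri_directionality(self):
        events = (
            [make_event(etype="SE", coords=(1, 2, 3, 4, 5, 6), inc_diff=0.2)] * 3
            + [make_event(etype="RI", inc_diff=0.2)] * 2
            + [make_event(etype="RI", inc_diff=-0.2)]
        )
        summary = type_summary(events)
        assert summary["counts"] == {"SE": 3, "RI": 3}
        n_pos, n_neg, frac = summary["ri_directionality"]
        assert (n_pos, n_neg) == (2, 1)
        assert frac == pytest.approx(2 / 3)

    def test_empty(self):
        summary = type_summary([])
        assert summary["counts"] == {}
        assert summary["ri_directionality"] == (0, 0, None)

    def test_recurrent_events_summarized_by_sign(self):
        ev = make_event(inc_diff=0.4)
        rec = find_recurrent({"s1": [ev]}, 0.0)
        summary = type_summary(rec)
        assert summary["counts"] == {"RI": 1}
        assert summary["ri_directionality"][0] == 1
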