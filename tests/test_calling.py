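"""Signal normalization, group aggregation, the calling rule, LoD."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from melchip.calling import (Call, GroupSignal, LodUndefinedError, QCError,
                             SampleReport, aggregate_groups, call_group,
                             call_sample, estimate_lod, normalize_signal)
from melchip.imaging import QuantTable, SpotQuant


def make_quant(layout, j_by_probe, i0=100.0, b_m=200.0, jitter=None):
    """Build a QuantTable realizing given per-probe J values (both duplicates
    equal unless jitter maps probe -> (j1, j2))."""
    spots = []
    for pid, (a, b) in layout.duplicate_pairs().items():
        j = j_by_probe.get(pid, 0.0)
        j1, j2 = jitter.get(pid, (j, j)) if jitter else (j, j)
        spots.append(SpotQuant(a, i0 + j1 * (b_m - i0), b_m, i0))
        spots.append(SpotQuant(b, i0 + j2 * (b_m - i0), b_m, i0))
    for m in layout.marker_spots:
        spots.append(SpotQuant(m, 30000.0, b_m, i0))
    return QuantTable("synthetic", tuple(spots))


class TestNormalizeSignal:
    def test_worked_example(self):
        assert normalize_signal(1000, 200, 100) == pytest.approx(9.0)

    def test_intensity_at_dark_current_gives_zero(self):
        assert normalize_signal(100, 950, 100) == 0.0

    def test_background_at_dark_current_fails_qc(self):
        with pytest.raises(QCError):
            normalize_signal(500, 100, 100)

    @settings(max_examples=200, derandomize=True)
    @given(i_m=st.floats(0, 1e5), b_m=st.floats(1, 1e5), i0=st.floats(0, 1e5))
    def test_matches_independent_formula(self, i_m, b_m, i0):
        if b_m <= i0:
            return
        expected = (i_m - i0) / (b_m - i0)  # independently coded
        assert normalize_signal(i_m, b_m, i0) == pytest.approx(expected, rel=1e-12)


class TestAggregateGroups:
    def test_duplicates_averaged(self, panel, layout):
        quant = make_quant(layout, {"WT:BRAF-600": 1.0},
                           jitter={"BRAF:c.1799T>A": (4.0, 6.0)})
        groups = {g.group_id: g for g in aggregate_groups(quant, layout, panel)}
        assert groups["BRAF-600"].j["BRAF:c.1799T>A"] == pytest.approx(5.0)

    def test_group_max_normalization(self, panel, layout):
        quant = make_quant(layout, {"WT:BRAF-600": 2.0, "BRAF:c.1799T>A": 8.0,
                                    "BRAF:c.1798G>A": 1.0})
        g = next(x for x in aggregate_groups(quant, layout, panel)
                 if x.group_id == "BRAF-600")
        jn = g.j_norm
        assert jn["BRAF:c.1799T>A"] == 1.0
        assert jn["WT:BRAF-600"] == pytest.approx(0.25)
        assert jn["BRAF:c.1798G>A"] == pytest.approx(0.125)

    def test_failed_duplicate_dropped(self, panel, layout):
        quant = make_quant(layout, {"BRAF:c.1799T>A": 6.0})
        a, _ = layout.duplicate_pairs()["BRAF:c.1799T>A"]
        spots = tuple(
            SpotQuant(s.spot_index, s.i_m, 50.0, s.i0)  # b_m below dark current
            if s.spot_index == a else s
            for s in quant.spots
        )
        g = next(x for x in aggregate_groups(QuantTable("q", spots), layout, panel)
                 if x.group_id == "BRAF-600")
        assert g.j["BRAF:c.1799T>A"] == pytest.approx(6.0)

    def test_both_duplicates_failed_probe_excluded(self, panel, layout):
        quant = make_quant(layout, {})
        bad = set(layout.duplicate_pairs()["BRAF:c.1799T>A"])
        spots = tuple(
            SpotQuant(s.spot_index, s.i_m, 50.0, s.i0) if s.spot_index in bad else s
            for s in quant.spots
        )
        g = next(x for x in aggregate_groups(QuantTable("q", spots), layout, panel)
                 if x.group_id == "BRAF-600")
        assert "BRAF:c.1799T>A" in g.excluded


def brute_force_rule(j_wt, mutants, min_sbr=2.0):
    """Independent restatement of the decision rule for the oracle check."""
    best, best_j = None, None
    tie = False
    for pid, j in mutants.items():
        if j > j_wt and j >= min_sbr:
            if best_j is None or j > best_j:
                best, best_j, tie = pid, j, False
            elif j == best_j:
                tie = True
    if tie:
        return "no-call"
    return best if best else "WT"


class TestCallGroup:
    def test_v600k_example(self, panel):
        """The V600K probe dominates its group and passes the criterion."""
        g = GroupSignal("BRAF-600",
                        {"WT:BRAF-600": 3.0, "BRAF:c.1798_1799delGTinsAA": 10.0,
                         "BRAF:c.1799T>A": 1.0},
                        wt_probe_id="WT:BRAF-600")
        call = call_group(g, panel)
        assert call.verdict == "BRAF:c.1798_1799delGTinsAA"
        assert call.entry.protein_change == "V600K"
        assert call.margin == pytest.approx(7.0)

    def test_all_mutants_below_wt_is_wild_type(self, panel):
        g = GroupSignal("BRAF-600", {"WT:BRAF-600": 5.0, "BRAF:c.1799T>A": 4.0},
                        wt_probe_id="WT:BRAF-600")
        assert call_group(g, panel).verdict == "WT"

    def test_sbr_below_threshold_is_wild_type(self, panel):
        # J_mut exceeds J_wt but fails the signal-to-background requirement
        g = GroupSignal("BRAF-600", {"WT:BRAF-600": 0.5, "BRAF:c.1799T>A": 1.5},
                        wt_probe_id="WT:BRAF-600")
        assert call_group(g, panel).verdict == "WT"

    def test_missing_wt_probe_is_no_call(self, panel):
        g = GroupSignal("BRAF-600", {"BRAF:c.1799T>A": 9.0},
                        excluded=frozenset({"WT:BRAF-600"}),
                        wt_probe_id="WT:BRAF-600")
        call = call_group(g, panel)
        assert call.verdict == "no-call"
        assert "wt-probe-failed" in call.qc_flags

    def test_exact_tie_is_no_call_with_flag(self, panel):
        g = GroupSignal("BRAF-600",
                        {"WT:BRAF-600": 1.0, "BRAF:c.1799T>A": 5.0,
                         "BRAF:c.1798G>A": 5.0},
                        wt_probe_id="WT:BRAF-600")
        call = call_group(g, panel)
        assert call.verdict == "no-call"
        assert "ambiguous-tie" in call.qc_flags

    def test_exhaustive_grid_matches_brute_force(self, panel):
        """Oracle equivalence over all small two-mutant groups on a J grid."""
        grid = [0.0, 0.5, 1.0, 1.9, 2.0, 2.1, 3.0, 5.0]
        probes = ("BRAF:c.1799T>A", "BRAF:c.1798G>A")
        n = 0
        for j_wt, j1, j2 in itertools.product(grid, repeat=3):
            g = GroupSignal("BRAF-600",
                            {"WT:BRAF-600": j_wt, probes[0]: j1, probes[1]: j2},
                            wt_probe_id="WT:BRAF-600")
            want = brute_force_rule(j_wt, {probes[0]: j1, probes[1]: j2})
            assert call_group(g, panel).verdict == want
            n += 1
        assert n == len(grid) ** 3


class TestCallSample:
    def _groups(self, panel, hot):
        out = []
        for grp in panel.groups:
            j = {grp.wt_probe_id: 1.0}
            j.update({e.probe_id: 0.2 for e in grp.entries})
            for pid, val in hot.items():
                if pid in j:
                    j[pid] = val
            out.append(GroupSignal(grp.group_id, j, wt_probe_id=grp.wt_probe_id))
        return out

    def test_braf_with_map2k1_not_warned(self, panel):
        groups = self._groups(panel, {"BRAF:c.1799T>A": 8.0, "MAP2K1:c.370C>T": 7.0})
        rep = call_sample(groups, panel)
        assert {e.gene for e in rep.called_entries()} == {"BRAF", "MAP2K1"}
        assert rep.warnings == ()

    def test_braf_with_nras_warns_exclusivity(self, panel):
        groups = self._groups(panel, {"BRAF:c.1799T>A": 8.0, "NRAS:c.181C>A": 7.0})
        rep = call_sample(groups, panel)
        assert len(rep.warnings) == 1
        assert "BRAF" in rep.warnings[0] and "NRAS" in rep.warnings[0]

    def test_all_wild_type_has_one_call_per_group(self, panel):
        rep = call_sample(self._groups(panel, {}), panel)
        assert len(rep.calls) == 11
        assert all(c.verdict == "WT" for c in rep.calls)


def fake_report(panel, sample_id, called=()):
    calls = []
    for grp in panel.groups:
        hit = next((e for e in grp.entries if e.probe_id in called), None)
        if hit:
            calls.append(Call(grp.group_id, hit.probe_id, entry=hit, margin=1.0))
        else:
            calls.append(Call(grp.group_id, "WT"))
    return SampleReport(sample_id, tuple(calls))


class TestEstimateLod:
    def test_published_detection_pattern(self, panel):
        target = panel.by_probe_id("BRAF:c.1799T>A")
        pattern = {0.0: 0, 0.0025: 1, 0.005: 3, 0.01: 3, 0.05: 3}
        reports = []
        for f, hits in pattern.items():
            for i in range(3):
                called = (target.probe_id,) if i < hits else ()
                reports.append((f, fake_report(panel, f"f{f}r{i}", called)))
        res = estimate_lod(reports, target, policy="all")
        assert res.lod_fraction == 0.005
        assert res.label == "0.5%"
        assert res.detection[0.0025] == (1, 3)

    def test_majority_policy(self, panel):
        target = panel.by_probe_id("BRAF:c.1799T>A")
        reports = []
        for f, hits in {0.0: 0, 0.0025: 2, 0.005: 3}.items():
            for i in range(3):
                called = (target.probe_id,) if i < hits else ()
                reports.append((f, fake_report(panel, f"f{f}r{i}", called)))
        assert estimate_lod(reports, target, policy="majority").lod_fraction == 0.0025
        assert estimate_lod(reports, target, policy="all").lod_fraction == 0.005

    def test_all_detected_lod_is_lowest_nonzero(self, panel):
        target = panel.by_probe_id("BRAF:c.1799T>A")
        reports = []
        for f in (0.0, 0.0025, 0.005):
            for i in range(3):
                called = (target.probe_id,) if f > 0 else ()
                reports.append((f, fake_report(panel, f"f{f}r{i}", called)))
        assert estimate_lod(reports, target).lod_fraction == 0.0025

    def test_false_calls_at_zero_undefined(self, panel):
        target = panel.by_probe_id("BRAF:c.1799T>A")
        reports = [(0.0, fake_report(panel, "bad", (target.probe_id,))),
                   (0.005, fake_report(panel, "ok", (target.probe_id,)))]
        with pytest.raises(LodUndefinedError):
            estimate_lod(reports, target)

    def test_nothing_detected_reports_above_range(self, panel):
        target = panel.by_probe_id("BRAF:c.1799T>A")
        reports = [(f, fake_report(panel, f"f{f}r{i}"))
                   for f in (0.0, 0.005, 0.01) for i in range(3)]
        with pytest.warns(UserWarning):
            res = estimate_lod(reports, target)
        assert res.lod_fraction is None
        assert res.label == "> 1%"
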