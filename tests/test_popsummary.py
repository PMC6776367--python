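"""Population summaries: cross-line merging, SFS, feature proximity, arm
site counting with the block ANOVA, hotspots, and the popgen-window join."""

import numpy as np
import pandas as pd
import pytest

import breakscan as bs

from conftest import make_pair


def _call(cid, line, a, b, support=5):
    return bs.RearrangementCall(
        call_id=cid, line=line, side_a=bs.Interval(*a), side_b=bs.Interval(*b),
        support=support, within_arm=a[0] == b[0], parallel_orientation=False)


class TestMerge:
    def test_same_event_in_three_lines_one_variant(self):
        per_line = {ln: [_call(f"{ln}_c0", ln, ("2L", 1000 + i, 1300 + i),
                               ("3R", 5000 + i, 5300 + i))]
                    for i, ln in enumerate(("A", "B", "C"))}
        (v,) = bs.merge_variants_across_lines(per_line)
        assert v.frequency == 3 and v.lines_present == {"A", "B", "C"}

    def test_events_ten_kb_apart_stay_separate(self):
        per_line = {"A": [_call("A_c0", "A", ("2L", 1000, 1300), ("3R", 5000, 5300))],
                    "B": [_call("B_c0", "B", ("2L", 11_000, 11_300),
                                ("3R", 5000, 5300))]}
        assert len(bs.merge_variants_across_lines(per_line)) == 2

    def test_symmetric_under_input_order(self):
        calls = [_call(f"c{i}", f"L{i % 3}",
                       ("2L", 1000 + 200 * i, 1100 + 200 * i),
                       ("3R", 5000 + 150 * i, 5100 + 150 * i))
                 for i in range(9)]
        fwd = bs.merge_variants_across_lines({"all": calls})
        rev = bs.merge_variants_across_lines({"all": calls[::-1]})
        key = lambda vs: sorted(
            (v.side_a, v.side_b, frozenset(c.call_id for c in v.calls))
            for v in vs)
        assert key(fwd) == key(rev)

    def test_matches_brute_force_transitive_closure(self):
        import networkx as nx
        rng = np.random.default_rng(11)
        calls = []
        for i in range(60):
            a = int(rng.integers(1, 4000))
            b = int(rng.integers(1, 4000))
            calls.append(_call(f"c{i}", f"L{i % 5}", ("2L", a, a + 100),
                               ("3R", b, b + 100)))
        got = bs.merge_variants_across_lines({"all": calls}, tol=325)
        g = nx.Graph()
        g.add_nodes_from(range(len(calls)))
        from breakscan.popsummary import _sides_close
        for i in range(len(calls)):
            for j in range(i + 1, len(calls)):
                if _sides_close(calls[i], calls[j], 325):
                    g.add_edge(i, j)
        oracle = {frozenset(calls[i].call_id for i in comp)
                  for comp in nx.connected_components(g)}
        assert {frozenset(c.call_id for c in v.calls) for v in got} == oracle


class TestSfs:
    def _variants(self, freqs, polarization=None):
        out = []
        for i, f in enumerate(freqs):
            v = bs.PopulationVariant(
                variant_id=f"v{i}", side_a=bs.Interval("2L", 1, 100),
                side_b=bs.Interval("3R", 1, 100),
                lines_present={f"L{k}" for k in range(f)})
            if polarization:
                v.polarization = polarization[i]
            out.append(v)
        return out

    def test_all_singletons(self):
        sfs = bs.compute_sfs(self._variants([1] * 10), n_lines=14)
        assert sfs[0] == 10 and sfs[1:].sum() == 0

    def test_sum_equals_included_variants(self):
        sfs = bs.compute_sfs(self._variants([1, 3, 3, 14, 7]), n_lines=14)
        assert sfs.sum() == 5
        assert sfs[2] == 2 and sfs[13] == 1

    def test_unpolarizable_excluded(self):
        variants = self._variants(
            [1, 2, 3], polarization=["ancestral", "unpolarizable",
                                     "derived_in_sample"])
        sfs = bs.compute_sfs(variants, n_lines=14)
        assert sfs.sum() == 2 and sfs[1] == 0


class TestProximity:
    FEATURES = pd.DataFrame({"arm": ["2L"], "start": [2000], "end": [3000],
                             "name": ["roo"]})

    def _variant(self, a, b):
        return bs.PopulationVariant(variant_id="v0", side_a=bs.Interval(*a),
                                    side_b=bs.Interval(*b),
                                    lines_present={"A"})

    def test_side_within_radius_flagged(self):
        v = self._variant(("2L", 3500, 3800), ("3R", 100, 200))  # 500 bp gap
        frame, summary = bs.annotate_proximity([v], self.FEATURES, radius=1000)
        assert frame.side_a_near.iloc[0] and not frame.side_b_near.iloc[0]
        assert summary == {"one_side": 1, "both_sides": 0,
                           "direct_overlap": 0, "sides_within_radius": 1}

    def test_direct_overlap(self):
        v = self._variant(("2L", 2500, 2600), ("3R", 100, 200))
        frame, summary = bs.annotate_proximity([v], self.FEATURES, radius=1000)
        assert frame.side_a_overlap.iloc[0]
        assert summary["direct_overlap"] == 1

    def test_radius_zero_only_overlaps(self):
        near = self._variant(("2L", 3100, 3200), ("3R", 100, 200))
        frame, summary = bs.annotate_proximity([near], self.FEATURES, radius=0)
        assert not frame.side_a_near.iloc[0]
        assert summary["one_side"] == 0

    def test_both_sides(self):
        v = self._variant(("2L", 1500, 1600), ("2L", 3200, 3300))
        _, summary = bs.annotate_proximity([v], self.FEATURES, radius=1000)
        assert summary["both_sides"] == 1 and summary["sides_within_radius"] == 2

    def test_malformed_features_rejected(self):
        bad = pd.DataFrame({"arm": ["2L"], "start": [3000], "end": [2000]})
        with pytest.raises(ValueError):
            bs.annotate_proximity([], bad)


class TestArmCounts:
    LENGTHS = {"X": 1000, "2L": 1000, "3R": 1000}

    def test_within_arm_counts_two_sites(self):
        calls = {"A": [_call("c0", "A", ("2L", 1, 100), ("2L", 500, 600))]}
        table = bs.arm_breakpoint_counts(calls, self.LENGTHS)
        t = table.set_index(["line", "arm"])
        assert t.loc[("A", "2L"), "sites"] == 2

    def test_between_arm_counts_one_each(self):
        calls = {"A": [_call("c0", "A", ("2L", 1, 100), ("3R", 500, 600))]}
        t = bs.arm_breakpoint_counts(calls, self.LENGTHS).set_index(["line", "arm"])
        assert t.loc[("A", "2L"), "sites"] == 1
        assert t.loc[("A", "3R"), "sites"] == 1

    def test_sites_equal_twice_calls_per_line(self):
        rng = np.random.default_rng(5)
        calls = {}
        for ln in ("A", "B"):
            cs = []
            for i in range(20):
                arms = rng.choice(["X", "2L", "3R"], size=2)
                cs.append(_call(f"{ln}_c{i}", ln,
                                (arms[0], 1, 100), (arms[1], 700, 800)))
            calls[ln] = cs
        table = bs.arm_breakpoint_counts(calls, self.LENGTHS)
        per_line = table.groupby("line")["sites"].sum()
        assert (per_line == 40).all()

    def test_rate_standardised_by_length(self):
        calls = {"A": [_call("c0", "A", ("2L", 1, 100), ("2L", 500, 600))]}
        table = bs.arm_breakpoint_counts(calls, {"2L": 2000, "X": 1000})
        t = table.set_index("arm")
        assert t.loc["2L", "rate"] == pytest.approx(2 / 2000)


class TestBlockAnova:
    def test_f_statistic_matches_textbook_formula(self):
        # 3 arms x 3 lines, hand-computable randomized complete block
        table = pd.DataFrame({
            "line": ["L1", "L1", "L1", "L2", "L2", "L2", "L3", "L3", "L3"],
            "arm": ["X", "2L", "3R"] * 3,
            "rate": [10.0, 7.0, 6.0, 12.0, 8.0, 7.0, 11.0, 9.0, 5.0]})
        y = table.pivot(index="line", columns="arm", values="rate").to_numpy()
        grand = y.mean()
        ss_treat = 3 * ((y.mean(axis=0) - grand) ** 2).sum()
        ss_block = 3 * ((y.mean(axis=1) - grand) ** 2).sum()
        ss_total = ((y - grand) ** 2).sum()
        ss_err = ss_total - ss_treat - ss_block
        f_expected = (ss_treat / 2) / (ss_err / 4)
        result = bs.block_anova_tukey(table)
        assert result["f_stat"] == pytest.approx(f_expected)
        assert result["df_treatment"] == 2 and result["df_error"] == 4

    def test_null_case_no_significant_pairs(self):
        rng = np.random.default_rng(0)
        rows = [(f"L{j}", arm, 5.0 + 0.5 * j + rng.normal(0, 0.01))
                for j in range(4) for arm in ("X", "2L", "3R")]
        result = bs.block_anova_tukey(
            pd.DataFrame(rows, columns=["line", "arm", "rate"]))
        assert result["p_value"] > 0.05
        assert not result["tukey"]["significant"].any()

    def test_inflated_arm_detected(self):
        rng = np.random.default_rng(1)
        rows = []
        for j in range(6):
            for arm in ("X", "2L", "2R", "3L", "3R"):
                rate = (25.0 if arm == "X" else 5.0) + rng.normal(0, 0.5)
                rows.append((f"L{j}", arm, rate))
        result = bs.block_anova_tukey(
            pd.DataFrame(rows, columns=["line", "arm", "rate"]))
        assert result["p_value"] < 1e-6
        tuk = result["tukey"]
        x_rows = tuk[(tuk.arm_1 == "X") | (tuk.arm_2 == "X")]
        other = tuk[(tuk.arm_1 != "X") & (tuk.arm_2 != "X")]
        assert x_rows["significant"].all()
        assert not other["significant"].any()

    def test_degenerate_table_rejected(self):
        table = pd.DataFrame({"line": ["L1", "L1"], "arm": ["X", "2L"],
                              "rate": [1.0, 2.0]})
        with pytest.raises(ValueError):
            bs.block_anova_tukey(table)


class TestHotspots:
    def _calls_at(self, positions, line="A"):
        return [_call(f"{line}_c{i}", line, ("2R", p, p + 10),
                      ("2R", p + 2_000_000, p + 2_000_010))
                for i, p in enumerate(positions)]

    def test_31_breakpoints_in_2kb_is_a_hotspot(self):
        # 31 side-a breakpoints inside 2 kb; side-b mates land 2 Mb away
        # spread over >5 kb so they do not themselves form a hotspot
        calls = {"A": self._calls_at([7_003_000 + 64 * i for i in range(31)])}
        spots = bs.detect_hotspots(calls, min_breakpoints=30)
        assert any(h.arm == "2R" and h.start <= 7_003_000 <= h.end
                   for h in spots)

    def test_30_breakpoints_is_not_over_threshold(self):
        calls = {"A": self._calls_at([7_003_000 + 64 * i for i in range(30)])}
        spots = bs.detect_hotspots(calls, min_breakpoints=30)
        assert not any(h.start <= 7_003_000 <= h.end for h in spots)

    def test_recurrent_locus_across_14_lines(self):
        # five calls per line at one locus in 14 lines -> >= 70 breakpoints
        calls = {f"L{j}": self._calls_at(
            [7_003_000 + 300 * i + 7 * j for i in range(5)], line=f"L{j}")
            for j in range(14)}
        spots = bs.detect_hotspots(calls, min_breakpoints=30)
        hit = [h for h in spots if h.start <= 7_003_000 <= h.end]
        assert hit and hit[0].breakpoint_count >= 70

    def test_invariant_to_sub_step_shifts(self):
        base = [7_003_000 + 64 * i for i in range(31)]
        a = bs.detect_hotspots({"A": self._calls_at(base)})
        b = bs.detect_hotspots({"A": self._calls_at([p + 1 for p in base])})
        assert len(a) == len(b)
        assert [x.breakpoint_count for x in a] == [y.breakpoint_count for y in b]

    def test_te_families_annotated(self):
        calls = {"A": self._calls_at([7_003_000 + 64 * i for i in range(31)])}
        tes = [bs.TE("roo", "2R", 7_002_500, 7_003_500)]
        spots = bs.detect_hotspots(calls, min_breakpoints=30, tes=tes)
        hit = [h for h in spots if h.start <= 7_003_000 <= h.end]
        assert hit[0].te_families_present == ("roo",)


class TestPopgenJoin:
    def _windows(self, ds):
        return pd.DataFrame({
            "arm": ["2R"] * len(ds),
            "start": [7_000_001 + 5000 * i for i in range(len(ds))],
            "end": [7_005_000 + 5000 * i for i in range(len(ds))],
            "theta_pi": 0.01, "theta_w": 0.012, "tajimas_d": ds})

    def _variant_at(self, pos):
        return bs.PopulationVariant(
            variant_id="v0", side_a=bs.Interval("2R", pos, pos + 100),
            side_b=bs.Interval("2R", pos + 2_000_000, pos + 2_000_100),
            lines_present={"A"})

    def test_bottom_five_percent_window_flagged(self):
        ds = [0.5] * 19 + [-2.1364] + [0.4] * 20  # 40 windows, 2 flagged
        windows = self._windows(ds)
        joined = bs.join_popgen_windows([self._variant_at(7_095_100)], windows)
        side_a = joined[joined.side == "a"].iloc[0]
        assert side_a.tajimas_d == pytest.approx(-2.1364)
        assert bool(side_a.bottom5_tajimas_d)

    def test_flat_distribution_flags_floor_fraction(self):
        windows = self._windows([0.3] * 40)
        joined = bs.join_popgen_windows([self._variant_at(7_000_200)], windows)
        flagged_starts = {7_000_001, 7_005_001}  # rank ties broken by position
        side_a = joined[joined.side == "a"].iloc[0]
        assert bool(side_a.bottom5_tajimas_d) == (
            side_a.window_start in flagged_starts)

    def test_empty_window_table(self):
        joined = bs.join_popgen_windows([self._variant_at(7_000_200)],
                                        pd.DataFrame(columns=[
                                            "arm", "start", "end", "theta_pi",
                                            "theta_w", "tajimas_d"]))
        assert joined.empty

    def test_side_outside_windows_unflagged(self):
        windows = self._windows([0.5, -1.0])
        v = self._variant_at(7_000_200)  # side_b at ~9 Mb: outside windows
        joined = bs.join_popgen_windows([v], windows)
        assert set(joined["side"]) == {"a"}
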