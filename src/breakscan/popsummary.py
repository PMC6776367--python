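"""Population summaries of rearrangements merged across lines.

Per-line calls are merged into population variants (single-linkage with a
both-sides tolerance equal to the library insert), frequencies corrected
for false negatives, and summarised as: a site frequency spectrum (SFS),
proximity to transposable elements and genes, chromosome-arm breakpoint
distribution with a randomized-complete-block ANOVA and Tukey HSD,
breakpoint hotspots in 5 kb windows, and a join to precomputed
population-genetic window statistics (theta_pi, theta_W, Tajima's D) with a
bottom-5% Tajima's D sweep flag.

Site counting follows the two/one rule: a within-arm rearrangement
contributes 2 sites to its arm, a between-arm rearrangement 1 site to each
arm involved, so per line the site total is exactly twice the call count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from intervaltree import IntervalTree
from scipy.stats import studentized_range

from .pairscan import Interval, RearrangementCall
from .errormodel import PresenceMatrix

logger = logging.getLogger(__name__)


@dataclass
class PopulationVariant:
    """A rearrangement merged across lines."""

    variant_id: str
    side_a: Interval
    side_b: Interval
    lines_present: set = field(default_factory=set)  # called (+ rescued)
    calls: list = field(default_factory=list)
    polarization: str | None = None

    @property
    def frequency(self) -> int:
        return len(self.lines_present)


class _UF:
    def __init__(self, n: int):
        self.p = list(range(n))

    def find(self, i):
        while self.p[i] != i:
            self.p[i] = self.p[self.p[i]]
            i = self.p[i]
        return i

    def union(self, i, j):
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.p[rj] = ri


def _interval_gap(x: Interval, y: Interval) -> int | None:
    if x.arm != y.arm:
        return None
    if x.end < y.start:
        return y.start - x.end
    if y.end < x.start:
        return x.start - y.end
    return 0


def _sides_close(c1: RearrangementCall, c2: RearrangementCall, tol: int) -> bool:
    ga = _interval_gap(c1.side_a, c2.side_a)
    gb = _interval_gap(c1.side_b, c2.side_b)
    return ga is not None and gb is not None and ga <= tol and gb <= tol


def merge_variants_across_lines(per_line_calls: Mapping[str, Sequence[RearrangementCall]],
                                tol: int = 325) -> list[PopulationVariant]:
    """Merge per-line calls into population variants.

    Calls merge when both side intervals lie within ``tol`` of each other
    (single linkage across lines: connected components, so the result is
    symmetric under input order). Variant side intervals are the min-max
    span over member calls; ``lines_present`` holds the calling lines
    (false-negative rescue widens it afterwards).
    """
    calls = [c for line in sorted(per_line_calls)
             for c in per_line_calls[line]]
    calls.sort(key=lambda c: (c.side_a.arm, c.side_a.start,
                              c.side_b.arm, c.side_b.start, c.call_id))
    uf = _UF(len(calls))
    by_arms: dict[tuple[str, str], list[int]] = {}
    for i, c in enumerate(calls):
        by_arms.setdefault((c.side_a.arm, c.side_b.arm), []).append(i)
    for idxs in by_arms.values():
        for k, i in enumerate(idxs):
            for j in idxs[k + 1:]:
                # sorted by side_a.start; beyond tol on side a no link possible
                if calls[j].side_a.start - calls[i].side_a.end > tol:
                    break
                if _sides_close(calls[i], calls[j], tol):
                    uf.union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(len(calls)):
        groups.setdefault(uf.find(i), []).append(i)
    variants = []
    for members in sorted(groups.values(), key=lambda m: m[0]):
        ms = [calls[i] for i in members]
        side_a = Interval(ms[0].side_a.arm,
                          min(c.side_a.start for c in ms),
                          max(c.side_a.end for c in ms))
        side_b = Interval(ms[0].side_b.arm,
                          min(c.side_b.start for c in ms),
                          max(c.side_b.end for c in ms))
        variants.append(PopulationVariant(
            variant_id=f"v{len(variants):04d}", side_a=side_a, side_b=side_b,
            lines_present={c.line for c in ms}, calls=ms))
    return variants


def apply_rescue(variants: Sequence[PopulationVariant],
                 presence: PresenceMatrix) -> None:
    """Widen each variant's ``lines_present`` with rescued lines."""
    for v in variants:
        if v.variant_id in presence.states.index:
            v.lines_present |= presence.lines_present(v.variant_id)


def compute_sfs(variants: Sequence[PopulationVariant],
                n_lines: int = 14) -> np.ndarray:
    """Site frequency spectrum over frequency classes 1..n_lines.

    Frequencies are post-rescue line counts; variants whose polarization is
    "unpolarizable" are excluded. Returns counts indexed 0..n_lines-1 for
    classes 1..n_lines; the sum equals the number of included variants.
    """
    sfs = np.zeros(n_lines, dtype=int)
    for v in variants:
        if v.polarization == "unpolarizable":
            continue
        f = v.frequency
        if not 1 <= f <= n_lines:
            raise ValueError(f"{v.variant_id}: frequency {f} outside 1..{n_lines}")
        sfs[f - 1] += 1
    return sfs


VARIANT_COLUMNS = ["variant_id", "arm_a", "start_a", "end_a",
                   "arm_b", "start_b", "end_b", "lines_present",
                   "frequency", "polarization"]


def variants_to_frame(variants: Sequence[PopulationVariant]) -> pd.DataFrame:
    rows = [(v.variant_id,
             v.side_a.arm, v.side_a.start, v.side_a.end,
             v.side_b.arm, v.side_b.start, v.side_b.end,
             ",".join(sorted(v.lines_present)), v.frequency,
             v.polarization or "") for v in variants]
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


def frame_to_variants(df: pd.DataFrame) -> list[PopulationVariant]:
    out = []
    for row in df.itertuples(index=False):
        lines = set(str(row.lines_present).split(",")) if row.lines_present else set()
        pol = str(row.polarization) if isinstance(row.polarization, str) and row.polarization else None
        out.append(PopulationVariant(
            variant_id=str(row.variant_id),
            side_a=Interval(row.arm_a, int(row.start_a), int(row.end_a)),
            side_b=Interval(row.arm_b, int(row.start_b), int(row.end_b)),
            lines_present=lines, polarization=pol))
    return out


# ---------------------------------------------------------------------------
# feature proximity

def annotate_proximity(variants: Sequence[PopulationVariant],
                       features: pd.DataFrame,
                       radius: int = 1000) -> tuple[pd.DataFrame, dict]:
    """Flag variant sides near annotated features (TEs, genes, DE genes).

    ``features`` columns: arm, start, end (1-based inclusive), name. Per
    variant, each side is tested for overlap with, or proximity within
    ``radius`` of, a feature. Returns a per-variant frame (side_a_near,
    side_b_near, side_a_overlap, side_b_overlap, features joined) and a
    summary dict: one_side, both_sides, direct_overlap,
    sides_within_radius. At radius 0 only direct overlaps are flagged.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    for col in ("arm", "start", "end"):
        if col not in features.columns:
            raise ValueError(f"feature table missing column {col!r}")
    if len(features) and (features["end"] < features["start"]).any():
        raise ValueError("malformed feature intervals (end < start)")
    names = (features["name"].astype(str) if "name" in features.columns
             else pd.Series("", index=features.index))
    trees: dict[str, IntervalTree] = {}
    for (_, row), name in zip(features.iterrows(), names):
        # intervaltree is half-open; widen end by 1 to keep 1-based inclusive
        trees.setdefault(row["arm"], IntervalTree()).addi(
            int(row["start"]), int(row["end"]) + 1, name)

    def probe(side: Interval, pad: int):
        tree = trees.get(side.arm)
        if tree is None:
            return set()
        return tree.overlap(side.start - pad, side.end + 1 + pad)

    rows = []
    for v in variants:
        near_a, near_b = probe(v.side_a, radius), probe(v.side_b, radius)
        ov_a, ov_b = probe(v.side_a, 0), probe(v.side_b, 0)
        rows.append((v.variant_id,
                     bool(near_a), bool(near_b), bool(ov_a), bool(ov_b),
                     ",".join(sorted({iv.data for iv in near_a | near_b}))))
    frame = pd.DataFrame(rows, columns=[
        "variant_id", "side_a_near", "side_b_near",
        "side_a_overlap", "side_b_overlap", "features"])
    summary = {
        "one_side": int(((frame.side_a_near | frame.side_b_near)).sum()),
        "both_sides": int((frame.side_a_near & frame.side_b_near).sum()),
        "direct_overlap": int((frame.side_a_overlap | frame.side_b_overlap).sum()),
        "sides_within_radius": int(frame.side_a_near.sum() + frame.side_b_near.sum()),
    }
    return frame, summary


# ---------------------------------------------------------------------------
# chromosome-arm distribution

def arm_breakpoint_counts(calls_by_line: Mapping[str, Sequence[RearrangementCall]],
                          arm_lengths: Mapping[str, int]) -> pd.DataFrame:
    """Breakpoint-site counts per (line, arm) under the two/one rule,
    with per-bp rates standardised by arm length.

    Within-arm calls add 2 sites to their arm; between-arm calls add 1 site
    to each arm involved. Per line the site total is 2x the call count.
    """
    arms = sorted(arm_lengths)
    rows = []
    for line in sorted(calls_by_line):
        sites = {a: 0 for a in arms}
        for c in calls_by_line[line]:
            if c.within_arm:
                sites[c.side_a.arm] += 2
            else:
                sites[c.side_a.arm] += 1
                sites[c.side_b.arm] += 1
        for a in arms:
            rows.append((line, a, sites[a], sites[a] / arm_lengths[a]))
    return pd.DataFrame(rows, columns=["line", "arm", "sites", "rate"])


def block_anova_tukey(table: pd.DataFrame, response: str = "rate"
                      ) -> dict:
    """Randomized-complete-block ANOVA with arm as treatment, line as block,
    plus Tukey HSD over arm means.

    The Tukey comparisons use the block model's error mean square (the
    one-way MSE would ignore the line blocking). Returns a dict with the
    arm F statistic, its p-value, degrees of freedom, the fitted arm means,
    and a pairwise Tukey table (diff, q, p, significant at 0.05).
    """
    arms = sorted(table["arm"].unique())
    lines = sorted(table["line"].unique())
    if len(arms) < 2 or len(lines) < 2:
        raise ValueError("block ANOVA needs >= 2 arms and >= 2 lines")
    model = smf.ols(f"{response} ~ C(arm) + C(line)", data=table).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    f_stat = float(aov.loc["C(arm)", "F"])
    p_value = float(aov.loc["C(arm)", "PR(>F)"])
    if np.isnan(f_stat) and aov.loc["C(arm)", "sum_sq"] < 1e-12:
        # no arm effect and a saturated block fit: report the null outcome
        f_stat, p_value = 0.0, 1.0
    df_treat = int(aov.loc["C(arm)", "df"])
    df_error = int(aov.loc["Residual", "df"])
    mse = float(aov.loc["Residual", "sum_sq"] / aov.loc["Residual", "df"])
    means = table.groupby("arm")[response].mean()
    b = len(lines)
    se = np.sqrt(mse / b) if mse > 0 else 0.0
    rows = []
    for i, a1 in enumerate(arms):
        for a2 in arms[i + 1:]:
            diff = float(means[a2] - means[a1])
            if se > 0:
                q = abs(diff) / se
                p = float(studentized_range.sf(q, len(arms), df_error))
            else:
                q, p = (np.inf, 0.0) if diff != 0 else (0.0, 1.0)
            rows.append((a1, a2, diff, q, p, p < 0.05))
    tukey = pd.DataFrame(rows, columns=["arm_1", "arm_2", "diff", "q",
                                        "p_value", "significant"])
    return {"f_stat": f_stat, "p_value": p_value,
            "df_treatment": df_treat, "df_error": df_error, "mse": mse,
            "arm_means": means, "tukey": tukey}


# ---------------------------------------------------------------------------
# hotspots

@dataclass
class HotspotWindow:
    arm: str
    start: int
    end: int
    breakpoint_count: int
    te_families_present: tuple = ()


def detect_hotspots(calls_by_line: Mapping[str, Sequence[RearrangementCall]],
                    window: int = 5000, min_breakpoints: int = 30,
                    step: int = 1000,
                    tes: Sequence | None = None) -> list[HotspotWindow]:
    """Sliding-window scan for recurrent breakpoint hotspots.

    Breakpoints are the midpoints of every side of every per-line call
    (pre-merge), pooled across lines. Windows of ``window`` bp advance by
    ``step``; windows with strictly more than ``min_breakpoints``
    breakpoints are kept and overlapping survivors are merged into maximal
    spans (counts re-tallied over the merged span). TE families overlapping
    a hotspot are listed when ``tes`` annotations are supplied.
    """
    points: dict[str, list[int]] = {}
    for line_calls in calls_by_line.values():
        for c in line_calls:
            for side in (c.side_a, c.side_b):
                points.setdefault(side.arm, []).append(
                    (side.start + side.end) // 2)
    hotspots = []
    for arm in sorted(points):
        pos = np.sort(np.array(points[arm]))
        lo, hi = int(pos[0]), int(pos[-1])
        starts = np.arange(max(lo - window + 1, 1), hi + 1, step)
        counts = (np.searchsorted(pos, starts + window, side="left")
                  - np.searchsorted(pos, starts, side="left"))
        keep = counts > min_breakpoints
        spans = []
        for s in starts[keep]:
            s, e = int(s), int(s) + window - 1
            if spans and s <= spans[-1][1] + 1:
                spans[-1][1] = e
            else:
                spans.append([s, e])
        for s, e in spans:
            n = int(np.searchsorted(pos, e, side="right")
                    - np.searchsorted(pos, s, side="left"))
            fams: tuple = ()
            if tes is not None:
                fams = tuple(sorted({t.family for t in tes
                                     if t.arm == arm and t.start <= e
                                     and s <= t.end}))
            hotspots.append(HotspotWindow(arm, s, e, n, fams))
    return hotspots


# ---------------------------------------------------------------------------
# population-genetic window join

def join_popgen_windows(variants: Sequence[PopulationVariant],
                        windows: pd.DataFrame,
                        bottom_fraction: float = 0.05) -> pd.DataFrame:
    """Attach per-window statistics and a bottom-5% Tajima's D flag.

    ``windows`` columns: arm, start, end, theta_pi, theta_w, tajimas_d.
    The sweep flag marks windows whose Tajima's D is among the empirical
    bottom ``floor(bottom_fraction * n_windows)`` by rank (ties broken by
    arm then start, so a flat distribution still flags exactly that many
    windows). A variant is flagged when any side falls in a flagged
    window; sides outside every window are logged and left unflagged.
    """
    if len(windows) == 0:
        logger.warning("empty popgen window table: no sweep flags assigned")
        return pd.DataFrame(columns=["variant_id", "side", "arm", "window_start",
                                     "window_end", "theta_pi", "theta_w",
                                     "tajimas_d", "bottom5_tajimas_d"])
    win = windows.sort_values(["tajimas_d", "arm", "start"],
                              kind="mergesort").reset_index(drop=True)
    n_flag = int(np.floor(bottom_fraction * len(win)))
    flagged = set(zip(win["arm"][:n_flag], win["start"][:n_flag]))
    trees: dict[str, IntervalTree] = {}
    for row in windows.itertuples(index=False):
        trees.setdefault(row.arm, IntervalTree()).addi(
            int(row.start), int(row.end) + 1, row)
    rows = []
    for v in variants:
        for side_name, side in (("a", v.side_a), ("b", v.side_b)):
            mid = (side.start + side.end) // 2
            tree = trees.get(side.arm)
            found = tree.at(mid) if tree is not None else set()
            if not found:
                logger.warning("variant %s side %s at %s:%d outside all windows",
                               v.variant_id, side_name, side.arm, mid)
                continue
            w = sorted(found, key=lambda iv: iv.begin)[0].data
            rows.append((v.variant_id, side_name, side.arm,
                         int(w.start), int(w.end), float(w.theta_pi),
                         float(w.theta_w), float(w.tajimas_d),
                         (w.arm, w.start) in flagged))
    return pd.DataFrame(rows, columns=["variant_id", "side", "arm",
                                       "window_start", "window_end",
                                       "theta_pi", "theta_w", "tajimas_d",
                                       "bottom5_tajimas_d"])
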