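"""False-negative rescue, coverage regression, and long-read confirmation.

Requiring four supporting pairs makes calling conservative, and sequencing
depth varies several-fold between lines, so a variant called in one line is
often invisibly present in another. Three error estimates address this:

* rescue: for every (variant, line) cell without a call, count supporting
  pairs at the variant's coordinates; 1-3 pairs mark a false negative
  ("rescued"), zero marks genuine absence;
* a linear regression of call count on depth of coverage, with per-line
  predictions standardised to a common target depth (93.7x, the deepest
  line) by a residual-preserving adjustment observed + slope*(target - depth);
* a long-read confirmation rate: a call is confirmed when a single long
  read hits within 2 kb of both of its sides; 1 - rate estimates the false
  positive rate per line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .pairscan import AlignmentRecord, RearrangementCall

logger = logging.getLogger(__name__)

CALLED = "called"
RESCUED = "rescued"
ABSENT = "absent"


@dataclass
class PresenceMatrix:
    """Variant x line grid of {called, rescued, absent} with the pair
    counts backing each rescued/absent cell."""

    states: pd.DataFrame  # index: variant_id, columns: lines, values: state
    pair_counts: pd.DataFrame  # same shape; supporting pairs per cell

    def lines_present(self, variant_id: str) -> set[str]:
        row = self.states.loc[variant_id]
        return set(row.index[(row == CALLED) | (row == RESCUED)])


def _pair_matches_variant(rec: AlignmentRecord, side_a, side_b,
                          window: int) -> bool:
    (a, b) = rec.canonical_sides()
    for (p, q) in ((a, b), (b, a)):
        if (p[0] == side_a.arm and side_a.distance_to(p[1]) <= window
                and q[0] == side_b.arm and side_b.distance_to(q[1]) <= window):
            return True
    return False


def rescue_false_negatives(variants: Sequence,
                           per_line_pairs: Mapping[str, Sequence[AlignmentRecord]],
                           window: int = 325) -> PresenceMatrix:
    """Survey every merged variant in every line lacking a call.

    ``variants`` are population variants (``variant_id``, ``side_a``,
    ``side_b``, ``lines_present`` of *called* lines); ``per_line_pairs``
    maps line -> duplicate-free abnormal pairs. A cell without a call is
    rescued when 1-3 pairs place both ends within ``window`` of the
    variant's sides, absent at zero. Four or more pairs without a call
    violate the calling contract and are logged, then treated as rescued.
    """
    lines = sorted(per_line_pairs)
    states = pd.DataFrame(ABSENT, index=[v.variant_id for v in variants],
                          columns=lines)
    counts = pd.DataFrame(0, index=states.index, columns=lines)
    for v in variants:
        for line in lines:
            if line in v.lines_present:
                states.loc[v.variant_id, line] = CALLED
                continue
            n = sum(1 for rec in per_line_pairs[line]
                    if _pair_matches_variant(rec, v.side_a, v.side_b, window))
            counts.loc[v.variant_id, line] = n
            if n == 0:
                continue
            if n > 3:
                logger.warning(
                    "variant %s line %s: %d supporting pairs without a call",
                    v.variant_id, line, n)
            states.loc[v.variant_id, line] = RESCUED
    return PresenceMatrix(states=states, pair_counts=counts)


@dataclass
class CoverageFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    target_depth: float
    predictions: pd.DataFrame  # line, depth, observed, predicted


def fit_coverage_regression(per_line: Sequence[tuple], target_depth: float = 93.7
                            ) -> CoverageFit:
    """OLS of call count on depth, with residual-preserving predictions.

    ``per_line`` holds (line, depth, count) triples (or (depth, count), in
    which case lines are numbered). Each line's prediction at
    ``target_depth`` is observed + slope*(target_depth - depth), so a
    line's prediction at its own depth equals its observed count.
    """
    rows = []
    for i, item in enumerate(per_line):
        if len(item) == 3:
            rows.append((str(item[0]), float(item[1]), float(item[2])))
        else:
            rows.append((f"line{i}", float(item[0]), float(item[1])))
    if len(rows) < 3:
        raise ValueError("coverage regression needs at least 3 lines")
    depth = np.array([r[1] for r in rows])
    count = np.array([r[2] for r in rows])
    if np.allclose(depth, depth[0]):
        raise ValueError("all depths equal: slope undefined")
    model = sm.OLS(count, sm.add_constant(depth)).fit()
    slope = float(model.params[1])
    intercept = float(model.params[0])
    pred = count + slope * (target_depth - depth)
    frame = pd.DataFrame({
        "line": [r[0] for r in rows], "depth": depth,
        "observed": count, "predicted": pred})
    return CoverageFit(slope=slope, intercept=intercept,
                       r_squared=float(model.rsquared),
                       p_value=float(model.f_pvalue),
                       target_depth=target_depth, predictions=frame)


def confirm_with_long_reads(calls: Sequence[RearrangementCall],
                            long_hits: pd.DataFrame,
                            proximity: int = 2000) -> pd.DataFrame:
    """Per-line long-read confirmation rates.

    A call is confirmed when one long read (grouped by ``read_id``) has
    hits within ``proximity`` of both call sides; hits are assumed
    pre-filtered at E <= 1e-10. Lines with zero calls are omitted. Returns
    one row per line: confirmed, total, rate, unconfirmed_ids.
    """
    hits_by_read: dict[str, list] = {}
    if len(long_hits):
        for row in long_hits.itertuples(index=False):
            hits_by_read.setdefault(str(row.read_id), []).append(
                (str(row.arm), int(row.start), int(row.end)))

    def near(side, hit) -> bool:
        arm, start, end = hit
        if arm != side.arm:
            return False
        if end < side.start:
            return side.start - end <= proximity
        if start > side.end:
            return start - side.end <= proximity
        return True

    rows = []
    by_line: dict[str, list[RearrangementCall]] = {}
    for c in calls:
        by_line.setdefault(c.line, []).append(c)
    for line in sorted(by_line):
        confirmed, unconfirmed = 0, []
        for call in by_line[line]:
            ok = any(
                any(near(call.side_a, h) for h in hs)
                and any(near(call.side_b, h) for h in hs)
                for hs in hits_by_read.values())
            if ok:
                confirmed += 1
            else:
                unconfirmed.append(call.call_id)
        total = len(by_line[line])
        rows.append((line, confirmed, total, confirmed / total,
                     ",".join(unconfirmed)))
    return pd.DataFrame(rows, columns=["line", "confirmed", "total", "rate",
                                       "unconfirmed_ids"])
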