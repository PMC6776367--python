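"""Rearrangement calling from abnormally mapping paired-end alignments.

A chromosomal rearrangement joins two distant genomic loci. In paired-end
DNA sequencing of a sample that carries one, fragments straddling the novel
junction produce *abnormal* (discordant) pairs: the two mates map to
different chromosome arms, or at least 1 Mb apart on the same arm. The
caller collapses PCR duplicates, extracts abnormal pairs on the major arms,
clusters pairs whose ends co-locate within the library insert size on both
sides (single linkage), and emits a call for every cluster with at least
four independent supporting pairs.

Each :class:`AlignmentRecord` here represents one read *pair* (the record
plus its mate coordinates); :func:`load_alignments` reduces a SAM/BAM file
to one record per pair.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import pandas as pd
import pysam

logger = logging.getLogger(__name__)

#: Euchromatic major chromosome arms (Muller elements A-E); the dot
#: chromosome (Muller F) and heterochromatic/unplaced scaffolds are excluded.
MAJOR_ARMS = ("X", "2L", "2R", "3L", "3R")


class Interval(NamedTuple):
    """1-based inclusive genomic interval on a single arm."""

    arm: str
    start: int
    end: int

    def distance_to(self, pos: int) -> int:
        """Gap between ``pos`` and this interval; 0 if inside."""
        if pos < self.start:
            return self.start - pos
        if pos > self.end:
            return pos - self.end
        return 0


@dataclass(slots=True)
class AlignmentRecord:
    """One aligned read pair with mate coordinates (leftmost, 1-based)."""

    read_id: str
    arm: str
    pos: int
    strand: str
    mate_arm: str
    mate_pos: int
    mate_strand: str
    line: str
    read_len: int = 75

    def dedup_key(self) -> tuple:
        return (self.arm, self.pos, self.strand,
                self.mate_arm, self.mate_pos, self.mate_strand)

    def canonical_sides(self) -> tuple[tuple[str, int, str], tuple[str, int, str]]:
        """Return ((arm, pos, strand), ...) with the lexicographically
        smaller (arm, pos) side first."""
        a = (self.arm, self.pos, self.strand)
        b = (self.mate_arm, self.mate_pos, self.mate_strand)
        return (a, b) if (a[0], a[1]) <= (b[0], b[1]) else (b, a)


@dataclass(frozen=True)
class CallerConfig:
    """Tunable thresholds of the caller.

    min_distance
        Minimum same-arm mate separation for a pair to count as abnormal
        (default 1 Mb; shorter separations are confounded with inversions
        and mid-size duplications and are deliberately excluded).
    cluster_window
        Maximum end-to-end distance, on both sides, for two pairs to be
        clustered together (default 325 bp, the library insert size).
    min_support
        Independent pairs required for a call (default 4).
    major_arms
        Arms retained for analysis; pairs touching any other sequence are
        dropped.
    """

    min_distance: int = 1_000_000
    cluster_window: int = 325
    min_support: int = 4
    major_arms: tuple[str, ...] = MAJOR_ARMS

    def __post_init__(self) -> None:
        if self.min_distance <= 0 or self.cluster_window <= 0 or self.min_support <= 0:
            raise ValueError("CallerConfig thresholds must be positive")
        if not self.major_arms:
            raise ValueError("major_arms must be non-empty")


@dataclass
class PairCluster:
    """A set of concordantly clustered abnormal pairs.

    ``side_a``/``side_b`` are the min-max spans of the clustered read
    extents (leftmost base to rightmost covered base) on each side, with
    side_a the lexicographically smaller (arm, start).
    """

    pairs: list[AlignmentRecord]
    side_a: Interval
    side_b: Interval
    orientation_summary: Counter = field(default_factory=Counter)

    @property
    def support(self) -> int:
        return len(self.pairs)


@dataclass
class RearrangementCall:
    call_id: str
    line: str
    side_a: Interval
    side_b: Interval
    support: int
    within_arm: bool
    parallel_orientation: bool
    orientation_summary: Counter = field(default_factory=Counter)


class SamFormatError(ValueError):
    """Raised for SAM/BAM input that cannot be interpreted."""


def load_alignments(path: str, line: str) -> list[AlignmentRecord]:
    """Read a SAM/BAM file into one :class:`AlignmentRecord` per pair.

    Unmapped reads, reads with unmapped mates, and secondary/supplementary
    alignments are dropped. Of each primary pair only the first-in-pair read
    is kept, so every pair yields exactly one record. Records without mate
    coordinates are skipped and counted.
    """
    try:
        af = pysam.AlignmentFile(path, require_index=False)
    except (OSError, ValueError) as exc:
        raise SamFormatError(f"cannot open {path}: {exc}") from exc
    if not af.header.get("SQ"):
        raise SamFormatError(f"{path}: missing @SQ header lines (arm lengths unknown)")
    records: list[AlignmentRecord] = []
    n_skipped = 0
    try:
        for aln in af:
            if aln.is_unmapped or aln.mate_is_unmapped:
                continue
            if aln.is_secondary or aln.is_supplementary:
                continue
            if not aln.is_read1:
                continue
            if aln.next_reference_name is None or aln.next_reference_start < 0:
                n_skipped += 1
                continue
            records.append(AlignmentRecord(
                read_id=aln.query_name,
                arm=aln.reference_name,
                pos=aln.reference_start + 1,
                strand="-" if aln.is_reverse else "+",
                mate_arm=aln.next_reference_name,
                mate_pos=aln.next_reference_start + 1,
                mate_strand="-" if aln.mate_is_reverse else "+",
                line=line,
                read_len=aln.query_length or aln.infer_query_length() or 75,
            ))
    except (OSError, ValueError) as exc:
        raise SamFormatError(f"{path}: truncated or corrupt alignment data: {exc}") from exc
    finally:
        af.close()
    if n_skipped:
        logger.warning("%s: skipped %d records lacking mate coordinates", path, n_skipped)
    return records


def remove_duplicates(records: Iterable[AlignmentRecord]) -> list[AlignmentRecord]:
    """Collapse PCR duplicates: pairs identical in both mates' (arm, pos,
    strand) are reduced to the first seen. Idempotent."""
    seen: set[tuple] = set()
    out: list[AlignmentRecord] = []
    for rec in records:
        key = rec.dedup_key()
        if key in seen:
            continue
        seen.add(key)
        out.append(rec)
    return out


def extract_abnormal_pairs(records: Iterable[AlignmentRecord],
                           cfg: CallerConfig) -> list[AlignmentRecord]:
    """Keep pairs with mates on different major arms or >= min_distance
    apart on the same arm; drop pairs touching non-major sequences."""
    major = set(cfg.major_arms)
    out = []
    for rec in records:
        if rec.arm not in major or rec.mate_arm not in major:
            continue
        if rec.arm != rec.mate_arm:
            out.append(rec)
        elif abs(rec.mate_pos - rec.pos) >= cfg.min_distance:
            out.append(rec)
    return out


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        p = self.parent
        while p[i] != i:
            p[i] = p[p[i]]
            i = p[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def cluster_pairs(pairs: Sequence[AlignmentRecord],
                  cfg: CallerConfig) -> list[PairCluster]:
    """Single-linkage clustering of abnormal pairs.

    Two pairs are linked when both of their canonically ordered ends lie on
    the same arms within ``cluster_window`` of each other; clusters are the
    connected components of that graph, so the result is independent of
    input order. Pairs are canonically oriented (lexicographically smaller
    (arm, pos) side first) before comparison.
    """
    w = cfg.cluster_window
    canon = []
    for rec in pairs:
        (a, b) = rec.canonical_sides()
        canon.append((a, b, rec))
    order = sorted(range(len(canon)),
                   key=lambda i: (canon[i][0][0], canon[i][0][1],
                                  canon[i][1][0], canon[i][1][1],
                                  canon[i][2].read_id))
    uf = _UnionFind(len(canon))
    # group by arm pair; within a group sort by side-a position and only
    # compare pairs whose side-a positions are within the window
    by_arms: dict[tuple[str, str], list[int]] = {}
    for i in order:
        a, b, _ = canon[i]
        by_arms.setdefault((a[0], b[0]), []).append(i)
    for idxs in by_arms.values():
        for k, i in enumerate(idxs):
            ai, bi, _ = canon[i]
            for j in idxs[k + 1:]:
                aj, bj, _ = canon[j]
                if aj[1] - ai[1] > w:
                    break
                if abs(bj[1] - bi[1]) <= w:
                    uf.union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(len(canon)):
        groups.setdefault(uf.find(i), []).append(i)
    clusters = []
    for members in groups.values():
        recs = [canon[i][2] for i in members]
        a_pos = [canon[i][0][1] for i in members]
        b_pos = [canon[i][1][1] for i in members]
        a_arm = canon[members[0]][0][0]
        b_arm = canon[members[0]][1][0]
        rlen = [r.read_len for r in recs]
        side_a = Interval(a_arm, min(a_pos),
                          max(p + l - 1 for p, l in zip(a_pos, rlen)))
        side_b = Interval(b_arm, min(b_pos),
                          max(p + l - 1 for p, l in zip(b_pos, rlen)))
        orient = Counter((canon[i][0][2], canon[i][1][2]) for i in members)
        clusters.append(PairCluster(pairs=recs, side_a=side_a, side_b=side_b,
                                    orientation_summary=orient))
    clusters.sort(key=lambda c: (c.side_a.arm, c.side_a.start,
                                 c.side_b.arm, c.side_b.start))
    return clusters


def call_rearrangements(clusters: Sequence[PairCluster],
                        cfg: CallerConfig,
                        line: str) -> list[RearrangementCall]:
    """Promote clusters with support >= min_support to calls.

    Clusters below threshold are not calls but remain available upstream for
    false-negative rescue (1-3 supporting pairs).
    """
    calls = []
    for clu in clusters:
        if clu.support < cfg.min_support:
            continue
        dominant, _ = clu.orientation_summary.most_common(1)[0]
        calls.append(RearrangementCall(
            call_id=f"{line}_c{len(calls):04d}",
            line=line,
            side_a=clu.side_a,
            side_b=clu.side_b,
            support=clu.support,
            within_arm=clu.side_a.arm == clu.side_b.arm,
            parallel_orientation=dominant[0] == dominant[1],
            orientation_summary=clu.orientation_summary,
        ))
    return calls


def call_pipeline(records: Iterable[AlignmentRecord], cfg: CallerConfig,
                  line: str) -> list[RearrangementCall]:
    """Duplicate removal -> abnormal-pair extraction -> clustering -> calls."""
    deduped = remove_duplicates(records)
    abnormal = extract_abnormal_pairs(deduped, cfg)
    return call_rearrangements(cluster_pairs(abnormal, cfg), cfg, line)


# ---------------------------------------------------------------------------
# tabular export / import

CALL_COLUMNS = ["call_id", "line", "arm_a", "start_a", "end_a",
                "arm_b", "start_b", "end_b", "support",
                "within_arm", "parallel_orientation"]


def calls_to_frame(calls: Sequence[RearrangementCall]) -> pd.DataFrame:
    rows = [(c.call_id, c.line,
             c.side_a.arm, c.side_a.start, c.side_a.end,
             c.side_b.arm, c.side_b.start, c.side_b.end,
             c.support, c.within_arm, c.parallel_orientation)
            for c in calls]
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def frame_to_calls(df: pd.DataFrame) -> list[RearrangementCall]:
    calls = []
    for row in df.itertuples(index=False):
        calls.append(RearrangementCall(
            call_id=str(row.call_id), line=str(row.line),
            side_a=Interval(row.arm_a, int(row.start_a), int(row.end_a)),
            side_b=Interval(row.arm_b, int(row.start_b), int(row.end_b)),
            support=int(row.support), within_arm=bool(row.within_arm),
            parallel_orientation=bool(row.parallel_orientation)))
    return calls


def calls_to_bedpe(calls: Sequence[RearrangementCall]) -> pd.DataFrame:
    """BEDPE export (0-based half-open on both sides)."""
    rows = [(c.side_a.arm, c.side_a.start - 1, c.side_a.end,
             c.side_b.arm, c.side_b.start - 1, c.side_b.end,
             c.call_id, c.support, "+", "+")
            for c in calls]
    return pd.DataFrame(rows, columns=["chrom1", "start1", "end1",
                                       "chrom2", "start2", "end2",
                                       "name", "score", "strand1", "strand2"])
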