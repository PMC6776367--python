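"""Fusion-transcript matching and de novo exon / chimera classification.

A rearrangement that moves untranscribed DNA next to the 5' end of an
expressed gene can create a chimeric transcript with a de novo exon: the
new transcript inherits the host gene's promoter and start codon and reads
through into sequence that was never transcribed before. In RNA-seq data
such transcripts leave split reads and (in paired-end libraries) spanning
read pairs whose two parts map to the two sides of the genomic junction.

This module matches genomic rearrangement calls against that RNA evidence
(>= 3 reads within 1 kb of both call sides), confirms candidates against
assembled-transcript alignments, and classifies each candidate by whether
the breakpoint falls downstream of an annotated start codon (chimera with
an inherited translation start) or not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .pairscan import Interval, RearrangementCall

TISSUES = ("testes", "male_carcass", "ovaries", "female_carcass")
#: germline tissue -> somatic counterpart of the same sex
_SOMA_OF = {"testes": "male_carcass", "ovaries": "female_carcass"}


class JunctionPoint(NamedTuple):
    arm: str
    pos: int


@dataclass(slots=True)
class FusionEvidence:
    """One RNA read (split read or spanning pair) supporting a fusion
    junction between two genomic loci."""

    line: str
    tissue: str
    junction_a: JunctionPoint
    junction_b: JunctionPoint
    read_kind: str  # "split" | "spanning-pair"
    read_id: str


@dataclass
class NewGeneCall:
    """A candidate de novo transcript anchored to one rearrangement call."""

    call_id: str
    line: str
    side_a: Interval
    side_b: Interval
    tissues_expressed: set = field(default_factory=set)
    supporting_reads: dict = field(default_factory=dict)  # tissue -> count
    start_codon_before_breakpoint: bool = False
    parent_gene: str | None = None
    confirmed_by_transcript: bool = False


def _near(side: Interval, point: JunctionPoint, slack: int) -> bool:
    return side.arm == point.arm and side.distance_to(point.pos) <= slack


def match_fusion_evidence(calls: Sequence[RearrangementCall],
                          evidence: Iterable[FusionEvidence],
                          slack: int = 1000,
                          min_reads: int = 3) -> list[NewGeneCall]:
    """Match rearrangement calls to RNA fusion evidence.

    An evidence read supports a call when one of its junction ends is within
    ``slack`` of one call side and the other end within ``slack`` of the
    other side (both side assignments are tried). A call becomes a
    :class:`NewGeneCall` when at least ``min_reads`` reads (split and
    spanning combined) support it in at least one tissue.
    """
    ev = list(evidence)
    out = []
    for call in calls:
        counts: dict[str, int] = {}
        for e in ev:
            hit = ((_near(call.side_a, e.junction_a, slack)
                    and _near(call.side_b, e.junction_b, slack))
                   or (_near(call.side_a, e.junction_b, slack)
                       and _near(call.side_b, e.junction_a, slack)))
            if hit:
                counts[e.tissue] = counts.get(e.tissue, 0) + 1
        expressed = {t for t, n in counts.items() if n >= min_reads}
        if expressed:
            out.append(NewGeneCall(call_id=call.call_id, line=call.line,
                                   side_a=call.side_a, side_b=call.side_b,
                                   tissues_expressed=expressed,
                                   supporting_reads=counts))
    return out


def relative_coverage(depth_track, total_mapped: int) -> np.ndarray:
    """Per-base depth divided by the library's total mapped read count.

    This normalisation makes coverage comparable between libraries of
    different sizes (analogous to an FPKM correction), so a sample track can
    be contrasted with reference tracks over a candidate region.
    """
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    return np.asarray(depth_track, dtype=float) / float(total_mapped)


def confirm_with_transcripts(candidate: NewGeneCall,
                             transcript_hits: pd.DataFrame,
                             slack: int = 1000) -> bool:
    """True when a single assembled transcript has alignment segments within
    ``slack`` of both sides of the candidate's rearrangement.

    ``transcript_hits`` columns: transcript_id, arm, start, end (1-based
    inclusive), identity, evalue; rows are assumed pre-filtered at
    E <= 1e-10 by the producer. Sets ``candidate.confirmed_by_transcript``.
    """
    confirmed = False
    if len(transcript_hits):
        for _, grp in transcript_hits.groupby("transcript_id"):
            hits = [Interval(r.arm, int(r.start), int(r.end))
                    for r in grp.itertuples(index=False)]
            if (any(_segments_close(h, candidate.side_a, slack) for h in hits)
                    and any(_segments_close(h, candidate.side_b, slack) for h in hits)):
                confirmed = True
                break
    candidate.confirmed_by_transcript = confirmed
    return confirmed


def _segments_close(a: Interval, b: Interval, slack: int) -> bool:
    if a.arm != b.arm:
        return False
    if a.end < b.start:
        return b.start - a.end <= slack
    if b.end < a.start:
        return a.start - b.end <= slack
    return True  # overlap


def classify_chimera(candidate: NewGeneCall, genes) -> NewGeneCall:
    """Set ``start_codon_before_breakpoint`` from annotation geometry.

    A candidate is chimeric (inherits a translation start) when one call
    side lies inside an annotated gene downstream, in the direction of
    transcription, of that gene's start codon. Side position is taken as
    the interval midpoint; side a is tried first.

    ``genes`` is an iterable with attributes gene_id, arm, start, end,
    strand, start_codon_pos (as produced by the synthetic genome builder or
    parsed from GFF3).
    """
    candidate.start_codon_before_breakpoint = False
    candidate.parent_gene = None
    for side in (candidate.side_a, candidate.side_b):
        mid = (side.start + side.end) // 2
        for g in genes:
            if g.arm != side.arm or not (g.start <= mid <= g.end):
                continue
            downstream = (mid >= g.start_codon_pos if g.strand == "+"
                          else mid <= g.start_codon_pos)
            if downstream:
                candidate.start_codon_before_breakpoint = True
                candidate.parent_gene = g.gene_id
                return candidate
    return candidate


def tissue_sharing(candidates: Sequence[NewGeneCall]) -> pd.DataFrame:
    """Per-tissue expression summary of candidate new genes.

    Returns one row per tissue with: total (candidates expressed there),
    shared (also expressed in the same-sex counterpart tissue, i.e.
    germline/soma sharing), exclusive (expressed in that tissue only).
    """
    rows = []
    for t in TISSUES:
        counterpart = _SOMA_OF.get(t) or next(
            g for g, s in _SOMA_OF.items() if s == t)
        total = shared = exclusive = 0
        for c in candidates:
            if t not in c.tissues_expressed:
                continue
            total += 1
            if counterpart in c.tissues_expressed:
                shared += 1
            if c.tissues_expressed == {t}:
                exclusive += 1
        rows.append((t, total, shared, exclusive))
    return pd.DataFrame(rows, columns=["tissue", "total", "shared", "exclusive"])
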