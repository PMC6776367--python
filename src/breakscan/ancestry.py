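"""Polarization of rearrangements against an outgroup genome.

Every rearrangement is called relative to the reference strain, so a call
can mean either a new mutation in the sampled line or the ancestral
configuration that the *reference* subsequently rearranged. Polarization
asks an outgroup: take 1 kb flanks from both sides of the call and locate
them in the outgroup assembly. If the two flanks co-locate (nearest edges
within 2 kb on the same outgroup arm) the sampled arrangement is ancestral
and the reference carries the derived allele; if they map far apart the
call is derived in the sample. Hits need >= 85% identity and must span the
breakpoint segment; flank pairs co-locating in more than 10 places (the
signature of repetitive sequence) make the call unpolarizable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .pairscan import Interval, RearrangementCall
from .synth import GenomeModel

DERIVED_IN_SAMPLE = "derived_in_sample"
ANCESTRAL = "ancestral"
UNPOLARIZABLE = "unpolarizable"


@dataclass(frozen=True)
class FlankRecord:
    call_id: str
    side: str  # "a" | "b"
    arm: str
    start: int
    end: int
    clipped: bool
    sequence: str | None = None

    @property
    def flank_id(self) -> str:
        return f"{self.call_id}|{self.side}"


@dataclass(frozen=True)
class OutgroupHit:
    flank_id: str
    outgroup_arm: str
    start: int
    end: int
    percent_identity: float
    spans_breakpoint: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.percent_identity <= 100:
            raise ValueError("percent_identity must be in [0, 100]")


@dataclass(frozen=True)
class PolarizedCall:
    call_id: str
    state: str  # DERIVED_IN_SAMPLE | ANCESTRAL | UNPOLARIZABLE


def extract_flanks(call: RearrangementCall, genome: GenomeModel,
                   flank: int = 1000) -> tuple[FlankRecord, FlankRecord]:
    """Flank coordinates (and sequence, when available) around each call side.

    Each side contributes one flank covering ``flank`` bp on either side of
    its interval, clipped at arm ends (clipped flanks are flagged).
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    lengths = genome.arm_lengths()
    out = []
    for side_name, side in (("a", call.side_a), ("b", call.side_b)):
        arm_len = lengths[side.arm]
        start = side.start - flank
        end = side.end + flank
        clipped = start < 1 or end > arm_len
        start, end = max(start, 1), min(end, arm_len)
        seq = None
        if genome.sequences is not None:
            seq = genome.sequences[side.arm][start - 1:end]
        out.append(FlankRecord(call.call_id, side_name, side.arm,
                               start, end, clipped, seq))
    return out[0], out[1]


def _edge_gap(h1: OutgroupHit, h2: OutgroupHit) -> int:
    if h1.end < h2.start:
        return h2.start - h1.end
    if h2.end < h1.start:
        return h1.start - h2.end
    return 0


def polarize(call: RearrangementCall, hits: Sequence[OutgroupHit],
             proximity: int = 2000, min_identity: float = 85.0,
             max_locations: int = 10) -> PolarizedCall:
    """Assign one of three ancestral states to a call.

    Hits are first filtered to ``percent_identity >= min_identity`` and
    ``spans_breakpoint``. The call is *ancestral* when some pair of hits
    (one per flank) lies on the same outgroup arm with nearest edges within
    ``proximity``; *unpolarizable* when either flank has no qualifying hit
    or when the flanks co-locate in more than ``max_locations`` places;
    otherwise *derived in the sample*. When proximal and distal hit pairs
    coexist, the proximal evidence wins (the criterion is existential).
    """
    usable = [h for h in hits
              if h.percent_identity >= min_identity and h.spans_breakpoint]
    a_hits = [h for h in usable if h.flank_id.endswith("|a")]
    b_hits = [h for h in usable if h.flank_id.endswith("|b")]
    if not a_hits or not b_hits:
        return PolarizedCall(call.call_id, UNPOLARIZABLE)
    n_colocated = sum(
        1 for ha in a_hits for hb in b_hits
        if ha.outgroup_arm == hb.outgroup_arm
        and _edge_gap(ha, hb) <= proximity)
    if n_colocated > max_locations:
        return PolarizedCall(call.call_id, UNPOLARIZABLE)
    if n_colocated >= 1:
        return PolarizedCall(call.call_id, ANCESTRAL)
    return PolarizedCall(call.call_id, DERIVED_IN_SAMPLE)


def hits_from_frame(df: pd.DataFrame) -> list[OutgroupHit]:
    """Parse a BLAST tabular (outfmt 6) hit table keyed by flank id.

    Expects columns qseqid, sseqid, pident, sstart, send (extra outfmt-6
    columns are ignored). An optional boolean ``spans_breakpoint`` column is
    honoured; plain outfmt-6 tables default it to True.
    """
    spans = (df["spans_breakpoint"].astype(bool)
             if "spans_breakpoint" in df.columns
             else pd.Series(True, index=df.index))
    hits = []
    for (_, row), sp in zip(df.iterrows(), spans):
        start, end = int(row["sstart"]), int(row["send"])
        if end < start:
            start, end = end, start
        hits.append(OutgroupHit(
            flank_id=str(row["qseqid"]), outgroup_arm=str(row["sseqid"]),
            start=start, end=end, percent_identity=float(row["pident"]),
            spans_breakpoint=bool(sp)))
    return hits


def polarization_to_frame(polarized: Sequence[PolarizedCall]) -> pd.DataFrame:
    return pd.DataFrame([(p.call_id, p.state) for p in polarized],
                        columns=["call_id", "state"])
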