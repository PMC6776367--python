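"""SAM export of simulated read pairs (coordinate-sorted, valid @SQ/@CO)."""

from __future__ import annotations

from typing import Mapping, Sequence

import pysam

from .pairscan import AlignmentRecord

_PAIRED = 0x1
_REV = 0x10
_MREV = 0x20
_READ1 = 0x40
_READ2 = 0x80


def write_pairs_sam(records: Sequence[AlignmentRecord],
                    arm_lengths: Mapping[str, int],
                    path: str,
                    comments: Sequence[str] = ()) -> None:
    """Write one SAM file with two records (read1/read2) per pair.

    The header declares every arm (@SQ) and echoes simulation parameters as
    @CO comment lines; records are coordinate-sorted. Sequences and
    qualities are omitted ("*"), which SAM permits.
    """
    arms = list(arm_lengths)
    tid = {a: i for i, a in enumerate(arms)}
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": a, "LN": int(arm_lengths[a])} for a in arms],
        "CO": list(comments),
    }
    reads = []
    for rec in records:
        f1 = _PAIRED | _READ1
        f2 = _PAIRED | _READ2
        if rec.strand == "-":
            f1 |= _REV
            f2 |= _MREV
        if rec.mate_strand == "-":
            f1 |= _MREV
            f2 |= _REV
        reads.append((tid[rec.arm], rec.pos - 1, rec.read_id, f1,
                      tid[rec.mate_arm], rec.mate_pos - 1, rec.read_len))
        reads.append((tid[rec.mate_arm], rec.mate_pos - 1, rec.read_id, f2,
                      tid[rec.arm], rec.pos - 1, rec.read_len))
    reads.sort(key=lambda r: (r[0], r[1], r[2], r[3]))
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for rtid, pos, name, flag, mtid, mpos, rlen in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = name
            a.flag = flag
            a.reference_id = rtid
            a.reference_start = pos
            a.mapping_quality = 60
            a.cigarstring = f"{rlen}M"
            a.next_reference_id = mtid
            a.next_reference_start = mpos
            a.template_length = 0
            out.write(a)
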