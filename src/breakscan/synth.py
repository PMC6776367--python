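"""Synthetic genomes, planted rearrangements, and simulated evidence.

Every downstream stage of the pipeline is testable against known truth by
generating a toy multi-arm genome, planting insertions/translocations with
two junctions each, and emitting the evidence those events would leave:

* DNA paired-end alignment records (reference coordinates, bypassing an
  aligner) with PCR duplicates and per-line coverage variation;
* RNA split reads / spanning pairs over fusion junctions plus a depth
  track showing new transcription over the inserted segment;
* an outgroup hit table in which ancestral events co-locate their flanks
  and derived events do not;
* a long-read hit table spanning a chosen fraction of breakpoints.

Fragment model
--------------
Fragments have length ~ Normal(insert_size, insert_sd) with reads of
``read_len`` at each end. A fragment spanning a junction yields a usable
discordant pair only when the junction falls in the inner gap between the
two reads (a junction inside a read would break its alignment). The number
of fragments covering a point at depth *d* is d*F/(2R), of which a fraction
(F-2R)/F have the junction in the gap, so the expected number of spanning
pairs per junction is ``d*(F-2R)/(2R)`` — see
:func:`expected_spanning_pairs`. At the default F=325, R=75 that is
~1.17*d: about 47 pairs at 40x, comfortably clearing the 4-pair calling
threshold, and ~23 at 20x where P(>= 4) > 0.99 under the Poisson count.

Concordant background pairs carry no rearrangement signal (the caller
discards them), so they are sampled at a thinned, fixed effective depth
(``background_depth``) decoupled from the line's nominal depth; junction
spanning pairs always use the line's true depth.

Coordinates are 1-based inclusive internally; BED output is 0-based
half-open and GFF3 1-based, matching each format's convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .fusion import FusionEvidence, JunctionPoint, TISSUES
from .pairscan import MAJOR_ARMS, AlignmentRecord

DEFAULT_INSERT = 325
DEFAULT_READ_LEN = 75
#: tissues whose RNA libraries are paired-end; ovaries and female carcass
#: emulate single-end libraries (split reads only)
PAIRED_TISSUES = ("testes", "male_carcass")


class SizingError(ValueError):
    """Requested features do not fit on the requested arms."""


class ConflictError(ValueError):
    """Planted events collide within one line."""


@dataclass(frozen=True)
class Arm:
    name: str
    length: int


@dataclass(frozen=True)
class Gene:
    gene_id: str
    arm: str
    start: int
    end: int
    strand: str
    start_codon_pos: int


@dataclass(frozen=True)
class TE:
    family: str
    arm: str
    start: int
    end: int


@dataclass
class GenomeModel:
    """A toy multi-arm genome with gene and TE annotations.

    ``sequences`` (per-arm nucleotide strings) is optional; all callers work
    from coordinates alone, sequence is only needed for FASTA demos.
    """

    arms: list[Arm]
    genes: list[Gene] = field(default_factory=list)
    tes: list[TE] = field(default_factory=list)
    sequences: dict[str, str] | None = None

    def __post_init__(self) -> None:
        names = [a.name for a in self.arms]
        if len(set(names)) != len(names):
            raise ValueError("arm names must be unique")
        lengths = self.arm_lengths()
        for g in self.genes:
            if not (1 <= g.start <= g.end <= lengths[g.arm]):
                raise ValueError(f"gene {g.gene_id} outside arm {g.arm}")
            if not (g.start <= g.start_codon_pos <= g.end):
                raise ValueError(f"start codon of {g.gene_id} outside gene span")
        for t in self.tes:
            if not (1 <= t.start <= t.end <= lengths[t.arm]):
                raise ValueError(f"TE {t.family} outside arm {t.arm}")

    def arm_lengths(self) -> dict[str, int]:
        return {a.name: a.length for a in self.arms}

    @property
    def arm_names(self) -> list[str]:
        return [a.name for a in self.arms]


@dataclass(frozen=True)
class PlantedRearrangement:
    """Ground truth for one planted event.

    ``source`` is the segment (arm, start, end) moved/copied; ``destination``
    is (arm, position) where it lands. Same-arm events must separate source
    and destination by at least 1 Mb so they fall inside the caller's
    definition of a rearrangement.
    """

    event_id: str
    kind: str  # "insertion" | "reciprocal-translocation"
    source: tuple[str, int, int]
    destination: tuple[str, int]
    lines_carrying: frozenset
    te_mediated: bool = False
    creates_fusion: bool = False
    fusion_gene: str | None = None
    expressed_in: frozenset = frozenset(PAIRED_TISSUES)

    def __post_init__(self) -> None:
        s_arm, s_start, s_end = self.source
        if s_end < s_start:
            raise ValueError(f"{self.event_id}: empty source segment")
        d_arm, d_pos = self.destination
        if s_arm == d_arm and min(abs(d_pos - s_start), abs(d_pos - s_end)) < 1_000_000:
            raise ValueError(
                f"{self.event_id}: same-arm source and destination closer than 1 Mb")
        if self.creates_fusion and self.fusion_gene is None:
            raise ValueError(f"{self.event_id}: creates_fusion requires fusion_gene")


@dataclass(frozen=True)
class Junction:
    """One novel adjacency created by an event: destination locus joined to
    one edge of the source segment."""

    event_id: str
    label: str  # "left" | "right"
    arm_a: str
    pos_a: int  # destination side
    arm_b: str
    pos_b: int  # source edge


@dataclass
class TruthTable:
    events: list[PlantedRearrangement]
    junctions: list[Junction]

    def events_for_line(self, line: str) -> list[PlantedRearrangement]:
        return [e for e in self.events if line in e.lines_carrying]

    def junctions_for_event(self, event_id: str) -> list[Junction]:
        return [j for j in self.junctions if j.event_id == event_id]

    @property
    def lines(self) -> list[str]:
        return sorted({ln for e in self.events for ln in e.lines_carrying})

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.events:
            for j in self.junctions_for_event(e.event_id):
                rows.append((e.event_id, e.kind, j.label,
                             j.arm_a, j.pos_a, j.arm_b, j.pos_b,
                             ",".join(sorted(e.lines_carrying)),
                             e.te_mediated, e.creates_fusion,
                             e.fusion_gene or ""))
        return pd.DataFrame(rows, columns=[
            "event_id", "kind", "junction", "arm_dest", "pos_dest",
            "arm_src", "pos_src", "lines", "te_mediated", "creates_fusion",
            "fusion_gene"])


# ---------------------------------------------------------------------------
# genome construction

def build_genome(n_arms: int = 5, arm_length: int = 15_000_000,
                 n_genes: int = 100, n_tes: int = 50, seed: int = 1,
                 with_sequence: bool = False) -> GenomeModel:
    """Build a deterministic toy genome.

    Arm names mirror the five Drosophila major arms (X, 2L, 2R, 3L, 3R);
    extra arms beyond five are numbered. Genes are non-overlapping with a
    strand and a start codon near the 5' end; TEs may overlap each other.
    """
    if arm_length < 10_000:
        raise SizingError("arm_length must be at least 10 kb")
    rng = np.random.default_rng(seed)
    names = list(MAJOR_ARMS[:n_arms]) + [f"arm{i}" for i in range(6, n_arms + 1)]
    arms = [Arm(n, arm_length) for n in names]

    genes: list[Gene] = []
    occupied: dict[str, list[tuple[int, int]]] = {n: [] for n in names}
    attempts = 0
    while len(genes) < n_genes:
        attempts += 1
        if attempts > 50 * max(n_genes, 1):
            raise SizingError("arms too short to host the requested genes")
        arm = names[int(rng.integers(len(names)))]
        length = int(rng.integers(500, 3000))
        if arm_length <= length + 2:
            raise SizingError("arm too short to host a gene")
        start = int(rng.integers(1, arm_length - length))
        end = start + length
        if any(s <= end and start <= e for s, e in occupied[arm]):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        offset = int(rng.integers(0, min(100, length)))
        codon = start + offset if strand == "+" else end - offset
        occupied[arm].append((start, end))
        genes.append(Gene(f"g{len(genes):04d}", arm, start, end, strand, codon))

    tes: list[TE] = []
    families = ["roo", "jockey", "copia", "DNAREP1", "gypsy"]
    for i in range(n_tes):
        arm = names[int(rng.integers(len(names)))]
        length = int(rng.integers(300, 7000))
        if arm_length <= length + 2:
            raise SizingError("arm too short to host a TE")
        start = int(rng.integers(1, arm_length - length))
        tes.append(TE(families[i % len(families)], arm, start, start + length))

    sequences = None
    if with_sequence:
        alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
        sequences = {
            n: rng.choice(alphabet, size=arm_length).tobytes().decode("ascii")
            for n in names}
    return GenomeModel(arms=arms, genes=genes, tes=tes, sequences=sequences)


def plant_rearrangements(genome: GenomeModel,
                         specs: Sequence[PlantedRearrangement]
                         ) -> tuple[dict[str, list[PlantedRearrangement]], TruthTable]:
    """Record planted events per line and derive their truth junctions.

    Each insertion creates two junctions, both anchored at the destination
    position: left = dest <-> source start, right = dest <-> source end.
    Reciprocal translocations are modelled with the same two junction pairs
    (segment exchange marked at the same adjacencies). Destinations closer
    than 1 kb within one line conflict (their pair clusters would collide).
    """
    lengths = genome.arm_lengths()
    per_line: dict[str, list[PlantedRearrangement]] = {}
    junctions: list[Junction] = []
    for spec in specs:
        s_arm, s_start, s_end = spec.source
        d_arm, d_pos = spec.destination
        for arm, lo, hi in ((s_arm, s_start, s_end), (d_arm, d_pos, d_pos)):
            if arm not in lengths or not (1 <= lo <= hi <= lengths[arm]):
                raise ValueError(f"{spec.event_id}: coordinates outside genome")
        for line in spec.lines_carrying:
            for other in per_line.get(line, []):
                o_arm, o_pos = other.destination
                if o_arm == d_arm and abs(o_pos - d_pos) < 1000:
                    raise ConflictError(
                        f"{spec.event_id} and {other.event_id} destinations "
                        f"collide in line {line}")
            per_line.setdefault(line, []).append(spec)
        junctions.append(Junction(spec.event_id, "left", d_arm, d_pos, s_arm, s_start))
        junctions.append(Junction(spec.event_id, "right", d_arm, d_pos, s_arm, s_end))
    return per_line, TruthTable(events=list(specs), junctions=junctions)


# ---------------------------------------------------------------------------
# DNA paired-end simulation

def expected_spanning_pairs(depth: float, insert_size: int = DEFAULT_INSERT,
                            read_len: int = DEFAULT_READ_LEN) -> float:
    """Expected usable discordant pairs per junction under the fragment
    model: depth * (insert - 2*read_len) / (2*read_len)."""
    gap = insert_size - 2 * read_len
    if gap <= 0:
        return 0.0
    return depth * gap / (2.0 * read_len)


def simulate_dna_pairs(genome: GenomeModel, truth: TruthTable, line: str,
                       mean_depth: float,
                       insert_size: int = DEFAULT_INSERT,
                       insert_sd: float = 30.0,
                       read_len: int = DEFAULT_READ_LEN,
                       dup_rate: float = 0.0,
                       seed: int = 1,
                       background_depth: float = 2.0,
                       n_noise_pairs: int = 0) -> list[AlignmentRecord]:
    """Emit reference-coordinate alignment records for one line.

    Junction-spanning pairs are drawn per junction of the line's events at
    Poisson(:func:`expected_spanning_pairs`) using the line's ``mean_depth``
    (floored at one fragment when depth is positive but tiny). Concordant
    background pairs are sampled at ``background_depth``. ``n_noise_pairs``
    adds scattered random discordant pairs (mapping noise). PCR duplicates
    are exact coordinate copies injected so that a fraction ``dup_rate`` of
    emitted records are duplicates.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if not 0 <= dup_rate < 1:
        raise ValueError("dup_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    lengths = genome.arm_lengths()
    records: list[AlignmentRecord] = []
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"{line}:p{counter:07d}"

    # junction-spanning pairs
    gap_max = max(insert_size - 2 * read_len, 1)
    for event in truth.events_for_line(line):
        for j in truth.junctions_for_event(event.event_id):
            lam = expected_spanning_pairs(mean_depth, insert_size, read_len)
            n_span = int(rng.poisson(lam)) if lam > 0 else 0
            for _ in range(n_span):
                frag = max(int(rng.normal(insert_size, insert_sd)), 2 * read_len + 2)
                gap = frag - 2 * read_len
                u = int(rng.integers(0, min(gap, gap_max) + 1))
                # destination-side read sits left of the junction point,
                # source-side read right of the source edge
                pos_a = max(j.pos_a - u - read_len, 1)
                pos_b = min(j.pos_b + (gap - u), lengths[j.arm_b] - read_len)
                pos_b = max(pos_b, 1)
                records.append(AlignmentRecord(
                    read_id=new_id(), arm=j.arm_a, pos=pos_a, strand="+",
                    mate_arm=j.arm_b, mate_pos=pos_b, mate_strand="-",
                    line=line, read_len=read_len))

    # concordant background
    if background_depth > 0:
        total_len = sum(lengths.values())
        n_bg = int(round(background_depth * total_len / (2 * read_len)))
        arm_names = genome.arm_names
        probs = np.array([lengths[a] for a in arm_names], dtype=float)
        probs /= probs.sum()
        arm_idx = rng.choice(len(arm_names), size=n_bg, p=probs)
        frags = np.clip(rng.normal(insert_size, insert_sd, size=n_bg).astype(int),
                        2 * read_len + 2, None)
        for ai, frag in zip(arm_idx, frags):
            arm = arm_names[int(ai)]
            hi = lengths[arm] - int(frag)
            if hi < 1:
                continue
            pos = int(rng.integers(1, hi + 1))
            records.append(AlignmentRecord(
                read_id=new_id(), arm=arm, pos=pos, strand="+",
                mate_arm=arm, mate_pos=pos + int(frag) - read_len,
                mate_strand="-", line=line, read_len=read_len))

    # scattered mapping noise (random discordant singletons)
    arm_names = genome.arm_names
    for _ in range(n_noise_pairs):
        a1, a2 = rng.choice(len(arm_names), size=2, replace=True)
        arm1, arm2 = arm_names[int(a1)], arm_names[int(a2)]
        p1 = int(rng.integers(1, lengths[arm1] - read_len))
        p2 = int(rng.integers(1, lengths[arm2] - read_len))
        if arm1 == arm2 and abs(p2 - p1) < 1_000_000:
            continue
        records.append(AlignmentRecord(
            read_id=new_id(), arm=arm1, pos=p1, strand="+",
            mate_arm=arm2, mate_pos=p2, mate_strand="-",
            line=line, read_len=read_len))

    # PCR duplicates: exact coordinate copies with fresh read ids
    if dup_rate > 0 and records:
        n_dup = int(round(dup_rate / (1.0 - dup_rate) * len(records)))
        picks = rng.integers(0, len(records), size=n_dup)
        for i in picks:
            records.append(replace(records[int(i)], read_id=new_id()))
        order = rng.permutation(len(records))
        records = [records[int(i)] for i in order]
    return records


# ---------------------------------------------------------------------------
# RNA evidence simulation

def simulate_rna_evidence(truth: TruthTable, line: str, tissue: str,
                          reads_per_junction: int = 3, paired: bool = True,
                          seed: int = 1,
                          ) -> tuple[list[FusionEvidence], dict[str, np.ndarray]]:
    """Emit fusion-supporting RNA reads and a depth track per fusion event.

    For every ``creates_fusion`` event carried by ``line`` and expressed in
    ``tissue``, exactly ``reads_per_junction`` evidence reads are emitted at
    each of its two junctions: split reads, alternating with spanning pairs
    when ``paired`` (single-end mode, emulating the ovary / female-carcass
    libraries, emits split reads only). The depth track (one array per
    event, spanning the inserted source segment +- 500 bp) shows new
    transcription over previously untranscribed sequence.
    """
    if tissue not in TISSUES:
        raise ValueError(f"unknown tissue {tissue!r}; expected one of {TISSUES}")
    if reads_per_junction < 0:
        raise ValueError("reads_per_junction must be >= 0")
    rng = np.random.default_rng(seed)
    evidence: list[FusionEvidence] = []
    tracks: dict[str, np.ndarray] = {}
    counter = 0
    for event in truth.events_for_line(line):
        if not event.creates_fusion or tissue not in event.expressed_in:
            continue
        for j in truth.junctions_for_event(event.event_id):
            for k in range(reads_per_junction):
                counter += 1
                kind = ("spanning-pair" if paired and k % 2 == 1 else "split")
                jit_a = int(rng.integers(-150, 151))
                jit_b = int(rng.integers(-150, 151))
                evidence.append(FusionEvidence(
                    line=line, tissue=tissue,
                    junction_a=JunctionPoint(j.arm_a, max(j.pos_a + jit_a, 1)),
                    junction_b=JunctionPoint(j.arm_b, max(j.pos_b + jit_b, 1)),
                    read_kind=kind,
                    read_id=f"{line}:{tissue}:r{counter:05d}"))
        if reads_per_junction > 0:
            _, s_start, s_end = event.source
            size = (s_end - s_start + 1) + 1000
            track = np.zeros(size, dtype=float)
            track[500:size - 500] = rng.poisson(
                max(reads_per_junction, 1), size - 1000)
            tracks[event.event_id] = track
    return evidence, tracks


# ---------------------------------------------------------------------------
# outgroup and long-read evidence

OUTGROUP_HIT_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch",
                        "gapopen", "qstart", "qend", "sstart", "send",
                        "evalue", "bitscore"]


def derive_outgroup_hits(genome: GenomeModel, truth: TruthTable,
                         ancestral_events: set[str],
                         identity: float = 95.0,
                         seed: int = 1) -> pd.DataFrame:
    """Outgroup flank-hit table (BLAST outfmt-6 columns) for polarization.

    Every event contributes one hit per flank (query ids ``<event>|a`` for
    the destination flank, ``<event>|b`` for the source flank). For events
    in ``ancestral_events`` the outgroup carries the rearranged
    configuration: both flanks land on the same outgroup arm with a
    nearest-edge gap of ~500 bp (< 2 kb). Otherwise the outgroup mirrors
    the reference: the destination flank maps near the destination and the
    source flank near the source, >= 1 Mb apart or on different arms.
    """
    if not 0 <= identity <= 100:
        raise ValueError("identity must be in [0, 100]")
    rng = np.random.default_rng(seed)
    rows = []
    flank = 1000
    for event in truth.events:
        d_arm, d_pos = event.destination
        s_arm, s_start, s_end = event.source
        if event.event_id in ancestral_events:
            base = int(rng.integers(10_000, 1_000_000))
            hits = {"a": (d_arm, base, base + flank),
                    "b": (d_arm, base + flank + 500, base + 2 * flank + 500)}
        else:
            hits = {"a": (d_arm, max(d_pos - flank, 1), d_pos),
                    "b": (s_arm, s_start, s_start + flank)}
        for side, (arm, start, end) in hits.items():
            rows.append((f"{event.event_id}|{side}", arm, float(identity),
                         end - start + 1, 0, 0, 1, flank, start, end,
                         1e-50, 1800.0))
    return pd.DataFrame(rows, columns=OUTGROUP_HIT_COLUMNS)


LONG_READ_COLUMNS = ["read_id", "line", "arm", "start", "end", "evalue"]


def simulate_long_read_hits(truth: TruthTable, line: str,
                            span_fraction: float = 1.0,
                            seed: int = 1) -> pd.DataFrame:
    """Long-read hit table: for ``span_fraction`` of the line's events a
    single read hits within 2 kb of both breakpoint sides."""
    if not 0 <= span_fraction <= 1:
        raise ValueError("span_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    events = truth.events_for_line(line)
    n_span = int(round(span_fraction * len(events)))
    chosen = set(rng.choice(len(events), size=n_span, replace=False)) if n_span else set()
    rows = []
    for i, event in enumerate(events):
        if i not in chosen:
            continue
        d_arm, d_pos = event.destination
        s_arm, s_start, _ = event.source
        rid = f"{line}:lr{i:04d}"
        rows.append((rid, line, d_arm, max(d_pos - 500, 1), d_pos + 500, 1e-80))
        rows.append((rid, line, s_arm, max(s_start - 500, 1), s_start + 500, 1e-80))
    return pd.DataFrame(rows, columns=LONG_READ_COLUMNS)


def cy17c_example_pairs(line: str = "CY17C") -> list[AlignmentRecord]:
    """Read pairs at the published CY17C worked-example coordinates.

    The insertion of 2L:12260976-12261178 between 3R:902154 and 3R:902563
    leaves two discordant-pair clusters: 2L:12260976-12261229 joined to
    3R:901825-902154 (five pairs) and to 3R:902563-902607 (four pairs).
    Clustering these nine pairs must yield exactly two calls.
    """
    red = [(12_260_976, 901_825), (12_261_020, 901_910), (12_261_061, 901_990),
           (12_261_100, 902_060), (12_261_154, 902_079)]
    blue = [(12_261_000, 902_563), (12_261_050, 902_570),
            (12_261_100, 902_580), (12_261_150, 902_533)]
    pairs = [AlignmentRecord(read_id=f"red{i}", arm="2L", pos=p2l, strand="+",
                             mate_arm="3R", mate_pos=p3r, mate_strand="-",
                             line=line)
             for i, (p2l, p3r) in enumerate(red)]
    pairs += [AlignmentRecord(read_id=f"blue{i}", arm="3R", pos=p3r,
                              strand="+", mate_arm="2L", mate_pos=p2l,
                              mate_strand="-", line=line)
              for i, (p2l, p3r) in enumerate(blue)]
    return pairs


# ---------------------------------------------------------------------------
# text-format export

def genes_to_gff3(genome: GenomeModel) -> str:
    """GFF3 (1-based inclusive) with gene and start_codon features."""
    lines = ["##gff-version 3"]
    for a in genome.arms:
        lines.append(f"##sequence-region {a.name} 1 {a.length}")
    for g in genome.genes:
        lines.append("\t".join([
            g.arm, "breakscan", "gene", str(g.start), str(g.end), ".",
            g.strand, ".", f"ID={g.gene_id}"]))
        lines.append("\t".join([
            g.arm, "breakscan", "start_codon", str(g.start_codon_pos),
            str(min(g.start_codon_pos + 2, g.end)), ".", g.strand, ".",
            f"Parent={g.gene_id}"]))
    return "\n".join(lines) + "\n"


def tes_to_bed(genome: GenomeModel) -> str:
    """BED (0-based half-open) of TE annotations."""
    lines = [f"{t.arm}\t{t.start - 1}\t{t.end}\t{t.family}"
             for t in genome.tes]
    return "\n".join(lines) + ("\n" if lines else "")


def genome_to_fasta(genome: GenomeModel, width: int = 70) -> str:
    if genome.sequences is None:
        raise ValueError("genome has no sequence (build with with_sequence=True)")
    chunks = []
    for arm in genome.arm_names:
        seq = genome.sequences[arm]
        chunks.append(f">{arm}")
        chunks.extend(seq[i:i + width] for i in range(0, len(seq), width))
    return "\n".join(chunks) + "\n"
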