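import pytest

import breakscan as bs


def make_pair(arm, pos, mate_arm, mate_pos, read_id="r", line="L1",
              strand="+", mate_strand="-", read_len=75):
    return bs.AlignmentRecord(read_id=read_id, arm=arm, pos=pos,
                              strand=strand, mate_arm=mate_arm,
                              mate_pos=mate_pos, mate_strand=mate_strand,
                              line=line, read_len=read_len)


@pytest.fixture(scope="session")
def tiny_genome():
    """Five 3 Mb arms, 30 genes, 20 TEs; large enough for 1 Mb same-arm
    events, small enough to simulate quickly."""
    return bs.build_genome(n_arms=5, arm_length=3_000_000, n_genes=30,
                           n_tes=20, seed=7)


@pytest.fixture(scope="session")
def planted_cohort(tiny_genome):
    """Three lines carrying two insertions with known junctions."""
    specs = [
        bs.PlantedRearrangement(
            "ev0", "insertion", ("2L", 1_200_000, 1_202_000),
            ("3R", 902_154), frozenset({"A", "B"})),
        bs.PlantedRearrangement(
            "ev1", "insertion", ("X", 400_000, 402_500),
            ("X", 2_500_000), frozenset({"C"})),
    ]
    per_line, truth = bs.plant_rearrangements(tiny_genome, specs)
    return tiny_genome, per_line, truth


def fig3_pairs(line="CY17C"):
    """Read pairs at the published CY17C worked-example coordinates
    (two clusters: 2L:12260976-12261229 joined to 3R:901825-902154 and to
    3R:902563-902607)."""
    return bs.cy17c_example_pairs(line)
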