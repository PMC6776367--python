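"""Population summaries: SFS, TE proximity, arm distribution, hotspots,
and the sweep-window join.

A 14-line cohort with planted frequencies is merged into population
variants; the site frequency spectrum should reproduce the planted
histogram, the X-biased planting should surface in the block ANOVA, a
recurrent locus should appear as a hotspot, and variants falling in
windows with bottom-5% Tajima's D get a sweep flag.
"""

import numpy as np
import pandas as pd

import breakscan as bs

lines = [f"L{i:02d}" for i in range(14)]
genome = bs.build_genome(5, 3_000_000, n_genes=40, n_tes=30, seed=7)

specs = []
for i in range(12):  # mostly singletons, destinations biased to the X
    freq = 1 if i < 8 else (2 if i < 10 else 11)
    dest_arm = "X" if i % 3 else ["2L", "2R", "3L"][i % 3 - 1]
    specs.append(bs.PlantedRearrangement(
        f"ev{i}", "insertion",
        ("3R", 150_000 + 40_000 * i, 152_000 + 40_000 * i),
        (dest_arm, 1_500_000 + 20_000 * i),
        frozenset(lines[(i + k) % 14] for k in range(freq))))
for k in range(4):  # a recurrent hotspot locus on 2R
    specs.append(bs.PlantedRearrangement(
        f"hs{k}", "insertion",
        ("3L", 150_000 + 50_000 * k, 152_000 + 50_000 * k),
        ("2R", 2_600_000 + 1_100 * k),
        frozenset(lines[(3 * k + m) % 14] for m in range(4))))
_, truth = bs.plant_rearrangements(genome, specs)

cfg = bs.CallerConfig()
calls = {}
for k, line in enumerate(lines):
    recs = bs.simulate_dna_pairs(genome, truth, line, 40, seed=100 + k,
                                 background_depth=0.2)
    calls[line] = bs.call_pipeline(recs, cfg, line)
print(f"total calls across 14 lines: {sum(map(len, calls.values()))}")

variants = bs.merge_variants_across_lines(calls)
sfs = bs.compute_sfs(variants, n_lines=14)
print(f"\nSFS over frequency classes 1..14: {sfs.tolist()}")
print("each planted insertion contributes its two junction variants at the"
      " planted line frequency; most variants are singletons")

# TE calls for these lines: the random background plus one roo element
# sitting at the hotspot locus (TE-mediated rearrangements cluster there)
tes = pd.DataFrame(
    [(t.arm, t.start, t.end, t.family) for t in genome.tes]
    + [("2R", 2_599_800, 2_604_500, "roo")],
    columns=["arm", "start", "end", "name"])
_, summary = bs.annotate_proximity(variants, tes, radius=1000)
print(f"\nTE association within 1 kb: {summary}")

table = bs.arm_breakpoint_counts(calls, genome.arm_lengths())
anova = bs.block_anova_tukey(table)
print(f"\narm block-ANOVA (arm = treatment, line = block): "
      f"F = {anova['f_stat']:.2f}, p = {anova['p_value']:.2e}")
sig = anova["tukey"][anova["tukey"].significant]
print(f"significant Tukey pairs: "
      f"{[f'{r.arm_1}-{r.arm_2}' for r in sig.itertuples()]}")
print("the X excess planted above shows up as X vs autosome contrasts")

spots = bs.detect_hotspots(calls, window=5000, min_breakpoints=30)
for h in spots:
    print(f"\nhotspot {h.arm}:{h.start}-{h.end} with "
          f"{h.breakpoint_count} breakpoints pooled across lines")

windows = pd.DataFrame({
    "arm": "2R", "start": 1 + 5000 * np.arange(600),
    "end": 5000 * (1 + np.arange(600)),
    "theta_pi": 0.01, "theta_w": 0.012,
    "tajimas_d": np.where(np.arange(600) == 520, -2.1364, 0.3)})
joined = bs.join_popgen_windows(variants, windows)
flagged = joined[joined.bottom5_tajimas_d]
print(f"\nvariant sides in bottom-5% Tajima's D windows: {len(flagged)}"
      f" (sweep-like signal at the hotspot locus)" if len(flagged) else
      "\nno variant sides fall in bottom-5% Tajima's D windows")
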