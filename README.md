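# nupvar

Consensus pathogenicity prioritization, sequence-hotspot detection, protein
subdomain enrichment and PPI network topology analysis for rare missense
variants — built around the nucleoporin gene *NUP155*, whose variants
(R391H, L503F) are clinically linked with atrial fibrillation.

## The problem

Population databases (gnomAD, NHLBI-EVS, dbNSFP) report thousands of
*NUP155* single-nucleotide variants, almost all of uncertain significance.
This package implements a prognostic scoring pipeline that narrows them to
a small prioritized set and asks where those variants sit:

1. **Consensus prioritization.** Each missense variant carries six
   predictor annotations — PolyPhen-2 (class + score 0–1), Grantham
   distance (5–215), PROVEAN (deleterious < −2.5), SIFT (deleterious
   < 0.05), PhastCons (0–1) and GERP (−12.3–6.17). Per-metric deleterious
   flags combine under a configurable consensus rule (`class_only`,
   `all_metrics`, or `k_of_n`).
2. **MAF benchmarking.** Candidates are kept only if rarer (strict <) than
   confirmed pathogenic *SCN5A* alleles: S216L (MAF 6.5×10⁻⁴) and F2004L
   (1.9×10⁻³).
3. **Hotspot detection.** For the m prioritized residue positions on a
   protein of length L (1,391 for NUP155), every pair of observed positions
   defines a candidate cluster. A bootstrap null (B = 1,000) redraws m
   positions uniformly; a cluster of n variants with span s gets
   p = (1 + #{replicates whose tightest n-variant window ≤ s}) / (B + 1),
   followed by Benjamini–Hochberg correction. Significant clusters are
   summed into a per-residue hotspot track.
4. **Domain enrichment.** Variants are assigned to named subdomain
   intervals (β-propeller, crescent α-helical region, C-terminal stack) and
   enrichment is tested with an exact one-sided binomial against uniform
   placement: p = P(X ≥ obs), X ~ Binomial(m, span/L).
5. **Network topology.** Undirected PPI edge lists (SIF/TSV) are merged;
   per-node degree, neighborhood connectivity, normalized betweenness and
   Wasserman–Faust closeness identify hubs, and the sign of the log–log
   slope of mean neighborhood connectivity vs degree classifies mixing
   (negative slope = disassortative = hub architecture).

A synthetic-data module generates annotated variant tables (realistic score
distributions, allele frequencies 4×10⁻⁶–7×10⁻⁴, configurable planted
hotspots) and hub-containing preferential-attachment PPI graphs, so every
stage is testable without database downloads. The one real-data fixture is
the transcribed table of the 24 prioritized rare NUP155 missense variants
with their published annotation scores (`nupvar.synthetic_data.nup155_variants`).

## Worked example

```python
from nupvar import consensus_prioritize, maf_filter, rank_variants, nup155_variants
from nupvar.prioritize import ThresholdConfig
from nupvar.hotspot import call_hotspots

variants = nup155_variants()                      # 24 annotated records
config = ThresholdConfig(consensus_mode="class_only", polyphen2_score_min=0.97)
ranked = rank_variants(consensus_prioritize(variants, config))
print(sum(r.prioritized for r in ranked))         # 24
print(len(maf_filter(variants, 6.5e-4)))          # 23  (V402M, MAF 7.0e-4, excluded)
print(str(ranked[0].variant.protein_change))      # R672G  (rank 1, 6/6 metrics)

calls, track = call_hotspots([v.position for v in variants], L=1391, B=1000, seed=1)
print(len(calls), sum(c.significant for c in calls))   # 300 0
```

All 24 variants pass the reproduction-default consensus rule; 23 are rarer
than the stricter SCN5A benchmark; R672G (rs373376199) ranks most
pathogenic. On these 24 real positions the bootstrap caller enumerates 300
candidate clusters and — under this null statistic — finds none significant
after BH correction; planted-hotspot simulations (see `analysis/` and the
test suite) show the caller recovers genuine clustering with high power.

The same numbers come from the command line:

```sh
nupvar reproduce-nup155 --out runs/repro --seed 1
# input 24; prioritized 24; below MAF benchmark 23
```

The numbered scripts in `analysis/` run the full narrative (source
filtering → prioritization → hotspot scan → domain enrichment → network
topology) and write their tables under `results/`.

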