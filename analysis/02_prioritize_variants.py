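"""Stage 2 — consensus prioritization, MAF benchmarking and ranking of the
24 rare NUP155 missense variants shipped with the package.

Expected headline numbers: all 24 variants carry a PolyPhen-2
probably-damaging call with score >= 0.97; 23 of 24 fall below the rarer
SCN5A benchmark frequency (6.5e-4) with V402M the exception (7.0e-4, still
below the second benchmark 1.9e-3); R672G ranks first; the strict
all-metric rule keeps only R672G, G754R and D429V.

Writes results/prioritized_variants.tsv.
"""

from pathlib import Path

from nupvar.pipeline import REPRODUCTION_THRESHOLDS, _write_prioritization
from nupvar.prioritize import ThresholdConfig, consensus_prioritize, maf_filter, rank_variants
from nupvar.synthetic_data import nup155_variants

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    variants = nup155_variants()

    ranked = rank_variants(consensus_prioritize(variants, REPRODUCTION_THRESHOLDS))
    _write_prioritization(ranked, RESULTS / "prioritized_variants.tsv")
    n_prioritized = sum(r.prioritized for r in ranked)
    print(f"{len(variants)} variants; {n_prioritized} prioritized "
          f"(PolyPhen-2 probably-damaging, score >= 0.97)")

    rare = maf_filter(variants, 6.5e-4)
    dropped = {str(v.protein_change) for v in variants} - {
        str(v.protein_change) for v in rare
    }
    print(f"{len(rare)} of {len(variants)} below the rarer SCN5A benchmark "
          f"(6.5e-4); above it: {', '.join(sorted(dropped))}")
    print(f"{len(maf_filter(variants, 1.9e-3))} of {len(variants)} below the "
          f"second benchmark (1.9e-3)")

    top = ranked[0]
    print(f"top-ranked variant: {top.variant.protein_change} "
          f"({top.variant.rsid}), {top.flags.n_pass}/6 metrics deleterious")

    strict = consensus_prioritize(variants, ThresholdConfig(consensus_mode="all_metrics"))
    kept = sorted(str(r.variant.protein_change) for r in strict if r.prioritized)
    print(f"strict all-metric consensus keeps: {', '.join(kept)}")


if __name__ == "__main__":
    main()
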