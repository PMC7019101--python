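"""Consensus deleteriousness prioritization and allele-frequency benchmarking.

Six predictor metrics are thresholded independently (PolyPhen-2 class+score,
Grantham distance, PROVEAN, SIFT, PhastCons, GERP) and combined under one of
three consensus modes:

``class_only``
    Prioritized iff the PolyPhen-2 flag passes (probably-damaging class and
    score at or above ``polyphen2_score_min``).
``all_metrics``
    All six metric flags must pass.
``k_of_n``
    At least ``k`` of the six flags pass.

Threshold conventions: Grantham and the two conservation scores pass at or
above their cutoffs (>= 125, >= 0.95, >= 2.0 by default); PROVEAN and SIFT
pass strictly below theirs (< -2.5, < 0.05); a missing score never passes.
Allele-frequency benchmarking compares each variant's frequency (strict <)
against reference frequencies of confirmed pathogenic alleles — the defaults
are the two SCN5A benchmarks S216L (6.5e-4) and F2004L (1.9e-3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .variant_io import AnnotatedVariant, SCORE_RANGES

__all__ = [
    "MafBenchmark",
    "ThresholdConfig",
    "MetricFlags",
    "PrioritizationResult",
    "ConfigError",
    "METRICS",
    "score_flags",
    "consensus_prioritize",
    "maf_filter",
    "maf_tier",
    "rank_variants",
]

METRICS = ("polyphen2", "grantham", "provean", "sift", "phastcons", "gerp")

CONSENSUS_MODES = ("class_only", "all_metrics", "k_of_n")
MAF_MODES = ("strict_rare", "two_tier")


class ConfigError(ValueError):
    """Invalid threshold or mode configuration."""


@dataclass(frozen=True)
class MafBenchmark:
    label: str
    allele_frequency: float


#: SCN5A pathogenic-variant frequency benchmarks used for the default
#: two-tier rarity filter.
DEFAULT_MAF_BENCHMARKS = (
    MafBenchmark("S216L", 6.5e-4),
    MafBenchmark("F2004L", 1.9e-3),
)


@dataclass(frozen=True)
class ThresholdConfig:
    """Per-metric cutoffs and the consensus/MAF policy."""

    polyphen2_required_class: str = "probably-damaging"
    polyphen2_score_min: float = 0.85
    grantham_min: float = 125.0
    provean_max: float = -2.5
    sift_max: float = 0.05
    phastcons_min: float = 0.95
    gerp_min: float = 2.0
    consensus_mode: str = "class_only"
    k: int | None = None
    maf_benchmarks: tuple[MafBenchmark, ...] = DEFAULT_MAF_BENCHMARKS
    maf_mode: str = "strict_rare"

    def __post_init__(self) -> None:
        if self.consensus_mode not in CONSENSUS_MODES:
            raise ConfigError(f"unknown consensus_mode {self.consensus_mode!r}")
        if self.maf_mode not in MAF_MODES:
            raise ConfigError(f"unknown maf_mode {self.maf_mode!r}")
        if self.consensus_mode == "k_of_n":
            if self.k is None:
                raise ConfigError("consensus_mode 'k_of_n' requires k")
            if not 1 <= self.k <= len(METRICS):
                raise ConfigError(f"k={self.k} outside 1..{len(METRICS)}")
        for name, cutoff in (
            ("polyphen2_score", self.polyphen2_score_min),
            ("grantham", self.grantham_min),
            ("sift", self.sift_max),
            ("phastcons", self.phastcons_min),
            ("gerp", self.gerp_min),
        ):
            lo, hi = SCORE_RANGES[name if name in SCORE_RANGES else "sift"]
            if not lo <= cutoff <= hi:
                raise ConfigError(
                    f"cutoff for {name} ({cutoff}) outside metric range [{lo}, {hi}]"
                )


@dataclass(frozen=True)
class MetricFlags:
    """Per-metric pass/fail/missing flags; ``n_pass`` counts the passes."""

    flags: dict[str, str]

    def __post_init__(self) -> None:
        unknown = set(self.flags) - set(METRICS)
        if unknown:
            raise ConfigError(f"unknown metric flag(s) {sorted(unknown)}")

    @property
    def n_pass(self) -> int:
        return sum(1 for f in self.flags.values() if f == "pass")

    def __getitem__(self, metric: str) -> str:
        return self.flags[metric]


@dataclass(frozen=True)
class PrioritizationResult:
    variant: AnnotatedVariant
    flags: MetricFlags
    prioritized: bool
    maf_tier: str = "fail"
    rank: int | None = None


def _flag(value: float | None, passes: bool) -> str:
    if value is None:
        return "missing"
    return "pass" if passes else "fail"


def score_flags(variant: AnnotatedVariant, config: ThresholdConfig) -> MetricFlags:
    """Evaluate all six metric thresholds on one variant.

    Missing scores flag as ``"missing"`` and never count as a pass.
    """
    s = variant.scores
    pp2_known = s.polyphen2_class != "missing" and s.polyphen2_score is not None
    flags = {
        "polyphen2": (
            "missing"
            if not pp2_known
            else (
                "pass"
                if s.polyphen2_class == config.polyphen2_required_class
                and s.polyphen2_score >= config.polyphen2_score_min
                else "fail"
            )
        ),
        "grantham": _flag(s.grantham, s.grantham is not None and s.grantham >= config.grantham_min),
        "provean": _flag(s.provean, s.provean is not None and s.provean < config.provean_max),
        "sift": _flag(s.sift, s.sift is not None and s.sift < config.sift_max),
        "phastcons": _flag(
            s.phastcons, s.phastcons is not None and s.phastcons >= config.phastcons_min
        ),
        "gerp": _flag(s.gerp, s.gerp is not None and s.gerp >= config.gerp_min),
    }
    return MetricFlags(flags)


def consensus_prioritize(
    variants: Sequence[AnnotatedVariant], config: ThresholdConfig
) -> list[PrioritizationResult]:
    """Apply the configured consensus rule to every variant, preserving order."""
    results = []
    for v in variants:
        flags = score_flags(v, config)
        if config.consensus_mode == "class_only":
            prioritized = flags["polyphen2"] == "pass"
        elif config.consensus_mode == "all_metrics":
            prioritized = all(flags[m] == "pass" for m in METRICS)
        else:  # k_of_n, k validated at construction
            prioritized = flags.n_pass >= config.k
        results.append(
            PrioritizationResult(
                variant=v,
                flags=flags,
                prioritized=prioritized,
                maf_tier=maf_tier(v, config),
            )
        )
    return results


def maf_tier(variant: AnnotatedVariant, config: ThresholdConfig) -> str:
    """Tier a variant against the benchmark frequencies, rarest first:
    below the first benchmark → ``rare_pass``; below a later one →
    ``tier2_pass``; otherwise (or frequency missing) → ``fail``."""
    af = variant.allele_frequency
    if af is None or not config.maf_benchmarks:
        return "fail"
    benchmarks = sorted(config.maf_benchmarks, key=lambda b: b.allele_frequency)
    if af < benchmarks[0].allele_frequency:
        return "rare_pass"
    if any(af < b.allele_frequency for b in benchmarks[1:]):
        return "tier2_pass"
    return "fail"


def maf_filter(
    variants: Sequence[AnnotatedVariant], threshold: float
) -> list[AnnotatedVariant]:
    """Retain variants with allele frequency strictly below ``threshold``.

    Variants without a recorded frequency are dropped (they cannot be shown
    to be rarer than the benchmark).
    """
    if not 0.0 < threshold <= 1.0:
        raise ConfigError(f"MAF threshold {threshold} outside (0, 1]")
    return [
        v
        for v in variants
        if v.allele_frequency is not None and v.allele_frequency < threshold
    ]


def _rank_key(result: PrioritizationResult) -> tuple:
    s = result.variant.scores
    return (
        -result.flags.n_pass,
        -(s.polyphen2_score if s.polyphen2_score is not None else -math.inf),
        s.sift if s.sift is not None else math.inf,
        s.provean if s.provean is not None else math.inf,
        result.variant.rsid or "",
    )


def rank_variants(
    results: Sequence[PrioritizationResult],
) -> list[PrioritizationResult]:
    """Order results from most to least pathogenic and attach 1-based ranks.

    The sort key is descending lexicographic on (number of passing metrics,
    PolyPhen-2 score, -SIFT, -PROVEAN); full ties break by rsID ascending.
    Missing scores sort as least pathogenic for their key component.
    """
    ordered = sorted(results, key=_rank_key)
    return [
        PrioritizationResult(
            variant=r.variant,
            flags=r.flags,
            prioritized=r.prioritized,
            maf_tier=r.maf_tier,
            rank=i,
        )
        for i, r in enumerate(ordered, start=1)
    ]
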