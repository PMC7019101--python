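"""Synthetic inputs with the statistical structure the analysis assumes.

The real study inputs are database exports (gnomAD / EVS / dbNSFP annotation
tables) and tool-exported PPI edge lists, none of which are redistributable
here.  This module generates stand-ins for every stage:

* annotated missense variant tables whose score distributions, allele
  frequencies (log-uniform over roughly 4e-6..7e-4) and positional
  clustering mirror the published 24-variant NUP155 table, with sidecar
  truth labels (class, in-hotspot status) for power/recovery checks;
* gnomAD-like protein-coding tables with controlled numbers of
  indel/start-stop-loss, duplicate and rsID-less rows for filter
  arithmetic;
* hub-containing undirected PPI graphs grown by preferential attachment
  with an attachment boost on planted hub nodes.

It also ships the transcribed table of the 24 prioritized rare NUP155
missense variants with their published annotation scores
(:func:`nup155_variants`), the one real-data fixture in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .variant_io import (
    AnnotatedVariant,
    ProteinChange,
    ScoreProfile,
    read_variant_table,
)

__all__ = [
    "SyntheticVariantSpec",
    "SyntheticGraphSpec",
    "SpecError",
    "gen_variant_table",
    "gen_coding_table",
    "gen_ppi_graph",
    "nup155_variants",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Per-metric (range, beta shape toward the deleterious extreme).  The
#: damaging class samples Beta(a, b) oriented so its mass sits at the
#: deleterious end; the benign class uses the mirrored Beta(b, a).  Shapes
#: are chosen so the default thresholds separate the classes imperfectly
#: (roughly 10% overlap), as real predictor scores do.
_METRIC_MODELS: dict[str, tuple[float, float, float, float, bool]] = {
    # name: (lo, hi, a, b, high_is_deleterious)
    "polyphen2_score": (0.0, 1.0, 8.0, 1.5, True),
    "grantham": (5.0, 215.0, 6.0, 2.0, True),
    "provean": (-13.0, 5.0, 6.0, 2.0, False),
    "sift": (0.0, 1.0, 8.0, 1.5, False),
    "phastcons": (0.0, 1.0, 8.0, 1.5, True),
    "gerp": (-12.3, 6.17, 8.0, 2.0, True),
}


class SpecError(ValueError):
    """Invalid synthetic-data specification."""


@dataclass(frozen=True)
class SyntheticVariantSpec:
    """Recipe for an annotated missense variant table.

    ``hotspot_intervals`` are (start, end, weight) with weights read as
    mixture probabilities: each position lands in interval i with
    probability ``weight_i`` (then uniform within it) and falls back to the
    uniform background over 1..L with the remaining probability, so zero
    weights give a fully uniform table.
    """

    n_variants: int
    L: int = 1391
    hotspot_intervals: tuple[tuple[int, int, float], ...] = ()
    class_mix: float = 0.5
    af_log10_range: tuple[float, float] = (-5.4, -3.15)
    score_overrides: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise SpecError("n_variants must be >= 1")
        if self.L < 1:
            raise SpecError("L must be >= 1")
        if not 0.0 <= self.class_mix <= 1.0:
            raise SpecError("class_mix must lie in [0, 1]")
        total = 0.0
        for start, end, weight in self.hotspot_intervals:
            if not 1 <= start <= end <= self.L:
                raise SpecError(f"interval {start}..{end} outside 1..{self.L}")
            if weight < 0:
                raise SpecError("interval weights must be >= 0")
            total += weight
        if total > 1.0:
            raise SpecError(f"interval weights sum to {total} > 1")
        if self.af_log10_range[0] > self.af_log10_range[1]:
            raise SpecError("af_log10_range must be (lo, hi) with lo <= hi")
        for cls in self.score_overrides:
            if cls not in ("damaging", "benign"):
                raise SpecError(f"score_overrides class must be damaging/benign, got {cls!r}")


@dataclass(frozen=True)
class SyntheticGraphSpec:
    """Recipe for one preferential-attachment PPI subnetwork."""

    n_nodes: int = 35
    attachment: int = 2
    hub_boost: float = 8.0
    planted_hubs: tuple[str, ...] = ("HUB1",)
    label_prefix: str = "G"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise SpecError("n_nodes must be >= 2")
        if self.attachment < 1:
            raise SpecError("attachment must be >= 1")
        if self.hub_boost < 1:
            raise SpecError("hub_boost must be >= 1")


def _draw_positions(spec: SyntheticVariantSpec, rng: np.random.Generator) -> np.ndarray:
    weights = [w for _, _, w in spec.hotspot_intervals]
    background = 1.0 - sum(weights)
    component = rng.choice(
        len(weights) + 1, size=spec.n_variants, p=weights + [background]
    )
    positions = np.empty(spec.n_variants, dtype=int)
    for i, comp in enumerate(component):
        if comp < len(weights):
            start, end, _ = spec.hotspot_intervals[comp]
            positions[i] = rng.integers(start, end + 1)
        else:
            positions[i] = rng.integers(1, spec.L + 1)
    return positions


def _draw_score(
    metric: str, damaging: bool, rng: np.random.Generator
) -> float:
    lo, hi, a, b, high_bad = _METRIC_MODELS[metric]
    toward_deleterious = damaging == high_bad
    shape = (a, b) if toward_deleterious else (b, a)
    return float(lo + (hi - lo) * rng.beta(*shape))


def gen_variant_table(
    spec: SyntheticVariantSpec,
) -> tuple[list[AnnotatedVariant], pd.DataFrame]:
    """Generate annotated missense variants plus per-variant truth labels.

    Deterministic per seed.  The truth frame records each variant's class
    (damaging/benign), residue position and whether it was drawn from a
    hotspot interval.
    """
    rng = np.random.default_rng(spec.seed)
    positions = _draw_positions(spec, rng)
    in_hotspot = np.array(
        [
            any(s <= p <= e for s, e, _ in spec.hotspot_intervals)
            for p in positions
        ]
    )
    damaging = rng.random(spec.n_variants) < spec.class_mix

    variants: list[AnnotatedVariant] = []
    truth_rows = []
    for i in range(spec.n_variants):
        cls = "damaging" if damaging[i] else "benign"
        overrides = spec.score_overrides.get(cls, {})

        def metric(name: str) -> float:
            if name in overrides:
                return float(overrides[name])
            return _draw_score(name, bool(damaging[i]), rng)

        pp2_score = metric("polyphen2_score")
        if "polyphen2_class" in overrides:
            pp2_class = str(overrides["polyphen2_class"])
        elif damaging[i]:
            pp2_class = "probably-damaging" if rng.random() < 0.9 else "possibly-damaging"
        else:
            pp2_class = "benign" if rng.random() < 0.8 else "possibly-damaging"

        ref = AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))]
        alt = AMINO_ACIDS[rng.integers(len(AMINO_ACIDS) - 1)]
        if alt >= ref:  # skip over ref so alt != ref, uniform over the rest
            alt = AMINO_ACIDS[(AMINO_ACIDS.index(alt) + 1) % len(AMINO_ACIDS)]
        af = float(10.0 ** rng.uniform(*spec.af_log10_range))
        rsid = f"rs9{spec.seed % 1000:03d}{i:05d}"
        variants.append(
            AnnotatedVariant(
                rsid=rsid,
                gene="NUP155",
                protein_change=ProteinChange(ref, int(positions[i]), alt),
                consequence="missense",
                variant_class="snv",
                allele_frequency=af,
                hom_count=0,
                scores=ScoreProfile(
                    polyphen2_class=pp2_class,
                    polyphen2_score=pp2_score,
                    grantham=metric("grantham"),
                    provean=metric("provean"),
                    sift=metric("sift"),
                    phastcons=metric("phastcons"),
                    gerp=metric("gerp"),
                ),
            )
        )
        truth_rows.append(
            {
                "rsid": rsid,
                "class": cls,
                "position": int(positions[i]),
                "in_hotspot": bool(in_hotspot[i]),
            }
        )
    return variants, pd.DataFrame(truth_rows)


def gen_coding_table(
    n_records: int,
    n_indel: int = 0,
    n_duplicate: int = 0,
    n_missing_rsid: int = 0,
    L: int = 1391,
    seed: int = 0,
) -> list[AnnotatedVariant]:
    """A protein-coding table with controlled filter-fodder composition.

    Of ``n_records`` rows, ``n_indel`` are indel/start-stop-loss records,
    ``n_duplicate`` repeat an earlier rsID, and ``n_missing_rsid`` lack an
    rsID; the remainder are clean unique missense SNVs.  Row categories are
    shuffled deterministically per seed.
    """
    n_special = n_indel + n_duplicate + n_missing_rsid
    if n_special > n_records:
        raise SpecError("special rows exceed n_records")
    n_clean = n_records - n_special
    if n_duplicate > 0 and n_clean < 1:
        raise SpecError("duplicates need at least one clean record to repeat")
    rng = np.random.default_rng(seed)

    base, _ = gen_variant_table(
        SyntheticVariantSpec(n_variants=max(n_clean, 1), L=L, seed=seed)
    )
    records: list[AnnotatedVariant] = list(base[:n_clean])
    from dataclasses import replace

    for i in range(n_indel):
        donor = base[i % len(base)]
        cls = "indel" if i % 2 == 0 else "startstop_loss"
        records.append(
            replace(
                donor,
                rsid=f"rs8{seed % 1000:03d}{i:05d}",
                consequence="other",
                variant_class=cls,
                protein_change=None,
            )
        )
    for i in range(n_duplicate):
        records.append(records[i % n_clean])
    for i in range(n_missing_rsid):
        donor = base[i % len(base)]
        records.append(replace(donor, rsid=None))
    order = rng.permutation(len(records))
    return [records[i] for i in order]


def gen_ppi_graph(spec: SyntheticGraphSpec) -> tuple[nx.Graph, list[str]]:
    """Grow a simple undirected graph by preferential attachment with an
    attachment-probability boost on the planted hub nodes.

    Returns the graph and the planted hub labels.  Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    hubs = list(spec.planted_hubs)
    n_regular = spec.n_nodes - len(hubs)
    if n_regular < 0:
        raise SpecError("more planted hubs than nodes")
    labels = hubs + [f"{spec.label_prefix}{i:04d}" for i in range(n_regular)]

    graph = nx.Graph()
    m0 = min(spec.n_nodes, spec.attachment + 1)
    seed_nodes = labels[:m0]
    graph.add_nodes_from(labels[:m0])
    for i in range(m0):
        for j in range(i + 1, m0):
            graph.add_edge(seed_nodes[i], seed_nodes[j])

    for new in labels[m0:]:
        existing = list(graph.nodes)
        weights = np.array(
            [
                graph.degree(n) * (spec.hub_boost if n in spec.planted_hubs else 1.0)
                for n in existing
            ],
            dtype=float,
        )
        weights /= weights.sum()
        n_links = min(spec.attachment, len(existing))
        targets = rng.choice(len(existing), size=n_links, replace=False, p=weights)
        graph.add_node(new)
        for t in targets:
            graph.add_edge(new, existing[t])
    return graph, hubs


def nup155_variants() -> list[AnnotatedVariant]:
    """The 24 prioritized rare NUP155 missense variants with their published
    PolyPhen-2, Grantham, PROVEAN, SIFT, PhastCons and GERP annotations and
    gnomAD allele frequencies, shipped as package data."""
    with resources.as_file(
        resources.files("nupvar.data").joinpath("nup155_prioritized.tsv")
    ) as path:
        return read_variant_table(path, dialect="generic")
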