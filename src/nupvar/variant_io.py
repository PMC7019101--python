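"""Reading, classifying, filtering and intersecting variant annotation tables.

The input tables are flat exports in the style of gnomAD / dbNSFP annotation
downloads: one row per variant with an rsID, a protein change such as
``R672G``, a consequence annotation, allele frequency/count fields,
per-population and per-sex carrier counts, and the six deleteriousness
predictor scores consumed downstream (PolyPhen-2 class+score, Grantham,
PROVEAN, SIFT, PhastCons, GERP).

Three dialects are supported:

``generic``
    The package's own TSV schema (also what :func:`write_variant_table`
    emits): columns ``rsid gene protein_change consequence variant_class
    allele_frequency allele_count hom_count pop_<label>... male female
    polyphen2_class polyphen2_score grantham provean sift phastcons gerp``.
    Empty cell = missing. UTF-8, no quoting.
``gnomad`` / ``dbnsfp``
    The same record model behind a column-name remapping table
    (:data:`DIALECT_COLUMN_MAPS`), overridable by the caller.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ProteinChange",
    "ScoreProfile",
    "AnnotatedVariant",
    "SourceSet",
    "VariantTableError",
    "read_variant_table",
    "write_variant_table",
    "classify_consequence",
    "filter_coding",
    "intersect_sources",
    "summarize_population",
]

#: Closed predictor score ranges enforced at load time.
SCORE_RANGES: dict[str, tuple[float, float]] = {
    "polyphen2_score": (0.0, 1.0),
    "grantham": (5.0, 215.0),
    "sift": (0.0, 1.0),
    "phastcons": (0.0, 1.0),
    "gerp": (-12.3, 6.17),
}

POLYPHEN2_CLASSES = frozenset({"benign", "possibly-damaging", "probably-damaging"})
CONSEQUENCES = ("missense", "lof", "synonymous", "other")
VARIANT_CLASSES = ("snv", "indel", "startstop_loss")

_PROTEIN_CHANGE_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


class VariantTableError(ValueError):
    """Raised for malformed variant tables; names the offending row/column."""


@dataclass(frozen=True)
class ProteinChange:
    """A single amino-acid substitution in 1-letter notation, e.g. R672G."""

    ref_aa: str
    position: int
    alt_aa: str

    def __str__(self) -> str:
        return f"{self.ref_aa}{self.position}{self.alt_aa}"

    @classmethod
    def parse(cls, text: str) -> "ProteinChange":
        m = _PROTEIN_CHANGE_RE.match(text)
        if m is None:
            raise VariantTableError(
                f"malformed protein change {text!r}: expected e.g. 'R672G'"
            )
        return cls(m.group(1), int(m.group(2)), m.group(3))


@dataclass(frozen=True)
class ScoreProfile:
    """Six-metric deleteriousness profile; ``None`` marks a missing score.

    ``extra_scores`` is an open map reserved for additional predictors
    (REVEL, MetaLR, ...); the core prioritization logic ignores it.
    """

    polyphen2_class: str = "missing"
    polyphen2_score: float | None = None
    grantham: float | None = None
    provean: float | None = None
    sift: float | None = None
    phastcons: float | None = None
    gerp: float | None = None
    extra_scores: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.polyphen2_class not in POLYPHEN2_CLASSES | {"missing"}:
            raise VariantTableError(
                f"unknown PolyPhen-2 class {self.polyphen2_class!r}"
            )
        for name, (lo, hi) in SCORE_RANGES.items():
            value = getattr(self, name)
            if value is not None and not (lo <= value <= hi):
                raise VariantTableError(
                    f"score {name}={value} outside declared range [{lo}, {hi}]"
                )


@dataclass(frozen=True)
class AnnotatedVariant:
    """One annotated variant record as exported from a population database."""

    rsid: str | None
    gene: str
    protein_change: ProteinChange | None
    consequence: str
    variant_class: str
    allele_frequency: float | None
    allele_count: int | None = None
    hom_count: int | None = None
    population_counts: Mapping[str, int] = field(default_factory=dict)
    sex_counts: Mapping[str, int] = field(default_factory=dict)
    scores: ScoreProfile = field(default_factory=ScoreProfile)

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCES:
            raise VariantTableError(f"unknown consequence {self.consequence!r}")
        if self.variant_class not in VARIANT_CLASSES:
            raise VariantTableError(f"unknown variant_class {self.variant_class!r}")
        if self.allele_frequency is not None and not (
            0.0 <= self.allele_frequency <= 1.0
        ):
            raise VariantTableError(
                f"allele_frequency {self.allele_frequency} outside [0, 1]"
            )
        if (
            self.hom_count is not None
            and self.allele_count is not None
            and self.hom_count > self.allele_count
        ):
            raise VariantTableError("hom_count exceeds allele_count")
        if self.consequence == "missense":
            if self.protein_change is None:
                raise VariantTableError("missense variant lacks a protein change")
            if self.protein_change.ref_aa == self.protein_change.alt_aa:
                raise VariantTableError(
                    f"missense change {self.protein_change} does not alter the residue"
                )

    @property
    def position(self) -> int | None:
        return self.protein_change.position if self.protein_change else None


@dataclass(frozen=True)
class SourceSet:
    """The rsID membership of one source database (e.g. gnomAD)."""

    label: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if any(not m for m in self.members):
            raise VariantTableError(f"source {self.label!r} contains empty rsIDs")


# ---------------------------------------------------------------------------
# consequence vocabulary
# ---------------------------------------------------------------------------

# Sequence-Ontology-style synonyms folded into the four working categories.
# Loss of function covers stop gained, splice donor and frameshift
# annotations; UTR/splice-region/intronic and any unrecognized term land in
# "other" (with a warning for genuinely unknown vocabulary).
_LOF_TERMS = {
    "stop gained",
    "stop_gained",
    "splice donor",
    "splice_donor_variant",
    "frameshift",
    "frameshift_variant",
}
_MISSENSE_TERMS = {"missense", "missense_variant"}
_SYNONYMOUS_TERMS = {"synonymous", "synonymous_variant", "stop_retained_variant"}
_OTHER_TERMS = {
    "5_prime_utr_variant",
    "3_prime_utr_variant",
    "5' utr",
    "3' utr",
    "utr",
    "splice_region_variant",
    "splice region",
    "intron_variant",
    "intronic",
    "intergenic_variant",
    "upstream_gene_variant",
    "downstream_gene_variant",
    "non_coding_transcript_exon_variant",
    "start_lost",
    "stop_lost",
    "inframe_insertion",
    "inframe_deletion",
}


def classify_consequence(raw_annotation: str) -> str:
    """Map a raw consequence annotation onto {missense, lof, synonymous, other}.

    Unrecognized vocabulary degrades to ``"other"`` with a logged warning
    rather than failing the load, since source vocabularies drift.
    """
    if not raw_annotation:
        raise VariantTableError("empty consequence annotation")
    term = raw_annotation.strip().lower().replace("-", "_")
    if term in _LOF_TERMS or term.replace(" ", "_") in _LOF_TERMS:
        return "lof"
    if term in _MISSENSE_TERMS:
        return "missense"
    if term in _SYNONYMOUS_TERMS:
        return "synonymous"
    if term not in _OTHER_TERMS and term.replace(" ", "_") not in _OTHER_TERMS:
        logger.warning("unrecognized consequence annotation %r -> 'other'", raw_annotation)
    return "other"


# ---------------------------------------------------------------------------
# table reading / writing
# ---------------------------------------------------------------------------

GENERIC_FIXED_COLUMNS = [
    "rsid",
    "gene",
    "protein_change",
    "consequence",
    "variant_class",
    "allele_frequency",
    "allele_count",
    "hom_count",
]
GENERIC_SCORE_COLUMNS = [
    "polyphen2_class",
    "polyphen2_score",
    "grantham",
    "provean",
    "sift",
    "phastcons",
    "gerp",
]

#: Source-column → generic-column remaps for foreign dialects.  These cover
#: the common export headers; callers may pass their own map to
#: :func:`read_variant_table` when a download uses different names.
DIALECT_COLUMN_MAPS: dict[str, dict[str, str]] = {
    "generic": {},
    "gnomad": {
        "rsIDs": "rsid",
        "rsID": "rsid",
        "Gene": "gene",
        "Protein Consequence": "protein_change",
        "VEP Annotation": "consequence",
        "Variant Class": "variant_class",
        "Allele Frequency": "allele_frequency",
        "Allele Count": "allele_count",
        "Number of Homozygotes": "hom_count",
    },
    "dbnsfp": {
        "rs_dbSNP": "rsid",
        "genename": "gene",
        "aachange": "protein_change",
        "effect": "consequence",
        "variant_type": "variant_class",
        "AF": "allele_frequency",
        "AC": "allele_count",
        "nhomalt": "hom_count",
        "Polyphen2_HDIV_pred": "polyphen2_class",
        "Polyphen2_HDIV_score": "polyphen2_score",
        "Grantham": "grantham",
        "PROVEAN_score": "provean",
        "SIFT_score": "sift",
        "phastCons17way_primate": "phastcons",
        "GERP_RS": "gerp",
    },
}

_PP2_CLASS_ALIASES = {
    "benign": "benign",
    "possibly-damaging": "possibly-damaging",
    "possibly_damaging": "possibly-damaging",
    "probably-damaging": "probably-damaging",
    "probably_damaging": "probably-damaging",
    "b": "benign",
    "p": "possibly-damaging",
    "d": "probably-damaging",
}


def _cell(row: Mapping[str, object], column: str) -> str | None:
    value = row.get(column)
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    text = str(value).strip()
    return text or None


def _parse_float(text: str | None, *, row: int, column: str) -> float | None:
    if text is None:
        return None
    try:
        return float(text)
    except ValueError:
        raise VariantTableError(
            f"row {row}: column {column!r}: cannot parse {text!r} as a number"
        ) from None


def _parse_int(text: str | None, *, row: int, column: str) -> int | None:
    value = _parse_float(text, row=row, column=column)
    return None if value is None else int(value)


def _parse_polyphen2(
    class_cell: str | None, score_cell: str | None, *, row: int
) -> tuple[str, float | None]:
    """Accept either split class/score cells or the fused ``Class:score`` form."""
    if class_cell is not None and ":" in class_cell and score_cell is None:
        class_cell, score_cell = class_cell.split(":", 1)
    pp2_class = "missing"
    if class_cell is not None:
        key = class_cell.strip().lower()
        if key not in _PP2_CLASS_ALIASES:
            raise VariantTableError(
                f"row {row}: column 'polyphen2_class': unknown class {class_cell!r}"
            )
        pp2_class = _PP2_CLASS_ALIASES[key]
    return pp2_class, _parse_float(score_cell, row=row, column="polyphen2_score")


def read_variant_table(
    path: str | Path,
    dialect: str = "generic",
    *,
    column_map: Mapping[str, str] | None = None,
) -> list[AnnotatedVariant]:
    """Parse a variant annotation TSV into :class:`AnnotatedVariant` records.

    Row order is preserved; empty cells become missing values.  Score cells
    outside their declared range, malformed protein changes and unparsable
    numbers raise :class:`VariantTableError` naming the row and column.
    """
    if dialect not in DIALECT_COLUMN_MAPS:
        raise VariantTableError(
            f"unknown dialect {dialect!r}; expected one of {sorted(DIALECT_COLUMN_MAPS)}"
        )
    remap = dict(DIALECT_COLUMN_MAPS[dialect])
    if column_map:
        remap.update(column_map)

    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    frame = frame.replace("", None)
    if remap:
        frame = frame.rename(columns=remap)
    missing = [c for c in ("rsid", "consequence") if c not in frame.columns]
    if missing:
        raise VariantTableError(
            f"table {path} lacks required column(s) {missing} after dialect remap"
        )

    pop_columns = [c for c in frame.columns if c.startswith("pop_")]
    variants: list[AnnotatedVariant] = []
    for i, row in enumerate(frame.to_dict(orient="records"), start=1):
        consequence_raw = _cell(row, "consequence")
        if consequence_raw is None:
            raise VariantTableError(f"row {i}: missing consequence annotation")
        consequence = (
            consequence_raw
            if consequence_raw in CONSEQUENCES
            else classify_consequence(consequence_raw)
        )

        change_cell = _cell(row, "protein_change")
        protein_change = None
        if change_cell is not None:
            # dbNSFP-style "p.R672G" prefixes are tolerated
            cleaned = change_cell.removeprefix("p.")
            try:
                protein_change = ProteinChange.parse(cleaned)
            except VariantTableError as err:
                raise VariantTableError(f"row {i}: {err}") from None

        pp2_class, pp2_score = _parse_polyphen2(
            _cell(row, "polyphen2_class"), _cell(row, "polyphen2_score"), row=i
        )
        try:
            scores = ScoreProfile(
                polyphen2_class=pp2_class,
                polyphen2_score=pp2_score,
                grantham=_parse_float(_cell(row, "grantham"), row=i, column="grantham"),
                provean=_parse_float(_cell(row, "provean"), row=i, column="provean"),
                sift=_parse_float(_cell(row, "sift"), row=i, column="sift"),
                phastcons=_parse_float(
                    _cell(row, "phastcons"), row=i, column="phastcons"
                ),
                gerp=_parse_float(_cell(row, "gerp"), row=i, column="gerp"),
            )
            variant = AnnotatedVariant(
                rsid=_cell(row, "rsid"),
                gene=_cell(row, "gene") or "",
                protein_change=protein_change,
                consequence=consequence,
                variant_class=_cell(row, "variant_class") or "snv",
                allele_frequency=_parse_float(
                    _cell(row, "allele_frequency"), row=i, column="allele_frequency"
                ),
                allele_count=_parse_int(
                    _cell(row, "allele_count"), row=i, column="allele_count"
                ),
                hom_count=_parse_int(_cell(row, "hom_count"), row=i, column="hom_count"),
                population_counts={
                    c.removeprefix("pop_"): _parse_int(_cell(row, c), row=i, column=c)
                    for c in pop_columns
                    if _cell(row, c) is not None
                },
                sex_counts={
                    s: _parse_int(_cell(row, s), row=i, column=s)
                    for s in ("male", "female")
                    if _cell(row, s) is not None
                },
                scores=scores,
            )
        except VariantTableError as err:
            msg = str(err)
            raise VariantTableError(
                msg if msg.startswith(f"row {i}") else f"row {i}: {err}"
            ) from None
        variants.append(variant)
    return variants


def _format(value: object | None) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_variant_table(
    variants: Sequence[AnnotatedVariant], path: str | Path
) -> None:
    """Write records in the generic dialect; floats use repr so that a
    read → write → read cycle reproduces every parsed field exactly."""
    pop_labels = sorted({p for v in variants for p in v.population_counts})
    columns = (
        GENERIC_FIXED_COLUMNS
        + [f"pop_{p}" for p in pop_labels]
        + ["male", "female"]
        + GENERIC_SCORE_COLUMNS
    )
    lines = ["\t".join(columns)]
    for v in variants:
        cells = [
            _format(v.rsid),
            _format(v.gene),
            _format(str(v.protein_change) if v.protein_change else None),
            v.consequence,
            v.variant_class,
            _format(v.allele_frequency),
            _format(v.allele_count),
            _format(v.hom_count),
        ]
        cells += [_format(v.population_counts.get(p)) for p in pop_labels]
        cells += [_format(v.sex_counts.get(s)) for s in ("male", "female")]
        s = v.scores
        cells += [
            s.polyphen2_class if s.polyphen2_class != "missing" else "",
            _format(s.polyphen2_score),
            _format(s.grantham),
            _format(s.provean),
            _format(s.sift),
            _format(s.phastcons),
            _format(s.gerp),
        ]
        lines.append("\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# filtering and intersection
# ---------------------------------------------------------------------------

def filter_coding(
    variants: Sequence[AnnotatedVariant],
) -> tuple[list[AnnotatedVariant], dict[str, int]]:
    """Drop indel/start-stop-loss records, rsID-less records, and duplicate
    rsIDs (first occurrence kept), in that order.

    Returns the retained list and a removal report mapping reason → count;
    ``len(retained) == len(variants) - sum(report.values())``.  Idempotent.
    """
    report = {"indel_startstop_loss": 0, "missing_rsid": 0, "duplicate_rsid": 0}
    retained: list[AnnotatedVariant] = []
    seen: set[str] = set()
    for v in variants:
        if v.variant_class in ("indel", "startstop_loss"):
            report["indel_startstop_loss"] += 1
        elif v.rsid is None:
            report["missing_rsid"] += 1
        elif v.rsid in seen:
            report["duplicate_rsid"] += 1
        else:
            seen.add(v.rsid)
            retained.append(v)
    return retained, {k: n for k, n in report.items() if n}


def intersect_sources(
    sources: Sequence[SourceSet],
) -> tuple[dict[str, int], frozenset[str]]:
    """Venn-region counts across ≥ 2 sources, plus the common-to-all rsID set.

    Region labels join the member source labels with ``&`` (e.g.
    ``"dbNSFP&gnomAD"`` for ids present in exactly those two).  Every id in
    the union lands in exactly one region, so counts sum to ``|union|``.
    """
    if len(sources) < 2:
        raise VariantTableError("intersection requires at least two sources")
    labels = [s.label for s in sources]
    if len(set(labels)) != len(labels):
        raise VariantTableError(f"duplicate source labels in {labels}")

    union = frozenset().union(*(s.members for s in sources))
    regions: dict[str, int] = {}
    for rsid in union:
        region = "&".join(sorted(s.label for s in sources if rsid in s.members))
        regions[region] = regions.get(region, 0) + 1
    common = frozenset.intersection(*(s.members for s in sources))
    return regions, common


def summarize_population(variants: Iterable[AnnotatedVariant]) -> pd.DataFrame:
    """Per-variant population summary: dominant population (argmax of the
    per-population carrier counts; ties resolve to the lexicographically
    smallest label and are flagged), per-sex counts and homozygote count."""
    rows = []
    for v in variants:
        counts = dict(v.population_counts)
        if counts:
            top = max(counts.values())
            leaders = sorted(label for label, n in counts.items() if n == top)
            dominant, tie = leaders[0], len(leaders) > 1
        else:
            dominant, tie = "unknown", False
        rows.append(
            {
                "rsid": v.rsid,
                "protein_change": str(v.protein_change) if v.protein_change else None,
                "dominant_population": dominant,
                "tie": tie,
                "male": v.sex_counts.get("male"),
                "female": v.sex_counts.get("female"),
                "hom_count": v.hom_count,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "rsid",
            "protein_change",
            "dominant_population",
            "tie",
            "male",
            "female",
            "hom_count",
        ],
    )
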