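"""End-to-end orchestration: prioritize → MAF filter → rank → hotspot →
domain enrichment → network topology, with a reproducible JSON manifest.

Each stage is individually skippable and writes plain-text outputs (TSV /
bedGraph / SIF) into the run directory.  The manifest records the package
version, the seed, SHA-256 digests of file inputs and per-stage record
counts — and deliberately no wall-clock information, so identical configs
produce bit-identical runs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import __version__
from .domain_map import DomainInterval, assign_domains, domain_enrichment, read_domain_table
from .hotspot import (
    DEFAULT_ALPHA,
    DEFAULT_BOOTSTRAP,
    DEFAULT_PROTEIN_LENGTH,
    call_hotspots,
    write_clusters,
    write_track_bedgraph,
)
from .network import (
    assortativity_fit,
    merge_networks,
    node_metrics,
    read_edge_list,
    top_hubs,
    write_node_metrics,
    write_sif,
)
from .prioritize import ThresholdConfig, consensus_prioritize, maf_filter, rank_variants
from .synthetic_data import (
    SyntheticGraphSpec,
    SyntheticVariantSpec,
    gen_ppi_graph,
    gen_variant_table,
    nup155_variants,
)
from .variant_io import AnnotatedVariant, read_variant_table, write_variant_table

__all__ = ["RunConfig", "run_pipeline", "REPRODUCTION_THRESHOLDS"]

ALL_STAGES = ("prioritize", "hotspot", "domains", "network")

#: The reproduction default: PolyPhen-2 probably-damaging class with score
#: >= 0.97 as the consensus rule (the reading consistent with the published
#: 24-variant outcome), plus the SCN5A MAF benchmarks.
REPRODUCTION_THRESHOLDS = ThresholdConfig(
    consensus_mode="class_only", polyphen2_score_min=0.97
)


@dataclass(frozen=True)
class RunConfig:
    out_dir: Path
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    # variant source: exactly one of a table path, a synthetic spec, or the
    # packaged NUP155 fixture (the fallback)
    variant_table: Path | None = None
    variant_dialect: str = "generic"
    synthetic_variants: SyntheticVariantSpec | None = None
    thresholds: ThresholdConfig = REPRODUCTION_THRESHOLDS
    maf_threshold: float | None = None  # None → rarest configured benchmark
    protein_length: int = DEFAULT_PROTEIN_LENGTH
    bootstrap: int = DEFAULT_BOOTSTRAP
    alpha: float = DEFAULT_ALPHA
    domains_path: Path | None = None
    edge_lists: tuple[Path, ...] = ()
    edge_format: str = "sif"
    synthetic_graphs: tuple[SyntheticGraphSpec, ...] = ()
    n_hubs: int = 4

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s) {sorted(unknown)}")
        if self.variant_table is not None and self.synthetic_variants is not None:
            raise ValueError("give either variant_table or synthetic_variants, not both")
        if self.edge_lists and self.synthetic_graphs:
            raise ValueError("give either edge_lists or synthetic_graphs, not both")


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _load_variants(config: RunConfig, manifest: dict) -> list[AnnotatedVariant]:
    if config.variant_table is not None:
        manifest["inputs"][str(config.variant_table)] = _sha256(config.variant_table)
        return read_variant_table(config.variant_table, dialect=config.variant_dialect)
    if config.synthetic_variants is not None:
        variants, _ = gen_variant_table(config.synthetic_variants)
        return variants
    return nup155_variants()


def _write_prioritization(results, out: Path) -> None:
    from .prioritize import METRICS

    header = (
        ["rsid", "protein_change", "position", "allele_frequency"]
        + list(METRICS)
        + ["n_pass", "prioritized", "maf_tier", "rank"]
    )
    lines = ["\t".join(header)]
    for r in results:
        v = r.variant
        cells = [
            v.rsid or "",
            str(v.protein_change) if v.protein_change else "",
            str(v.position) if v.position is not None else "",
            repr(v.allele_frequency) if v.allele_frequency is not None else "",
        ]
        cells += [r.flags[m] for m in METRICS]
        cells += [
            str(r.flags.n_pass),
            str(int(r.prioritized)),
            r.maf_tier,
            str(r.rank) if r.rank is not None else "",
        ]
        lines.append("\t".join(cells))
    out.write_text("\n".join(lines) + "\n", encoding="utf-8")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the manifest (also written
    to ``<out_dir>/manifest.json``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "nupvar",
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "inputs": {},
        "params": {
            "consensus_mode": config.thresholds.consensus_mode,
            "polyphen2_score_min": config.thresholds.polyphen2_score_min,
            "protein_length": config.protein_length,
            "bootstrap": config.bootstrap,
            "alpha": config.alpha,
        },
    }

    variants: list[AnnotatedVariant] = []
    retained: list[AnnotatedVariant] = []
    if "prioritize" in config.stages:
        variants = _load_variants(config, manifest)
        write_variant_table(variants, out / "input_variants.tsv")
        results = consensus_prioritize(variants, config.thresholds)
        ranked = rank_variants(results)
        _write_prioritization(ranked, out / "prioritized.tsv")
        prioritized = [r.variant for r in results if r.prioritized]
        threshold = config.maf_threshold
        if threshold is None and config.thresholds.maf_benchmarks:
            threshold = min(b.allele_frequency for b in config.thresholds.maf_benchmarks)
        retained = maf_filter(prioritized, threshold) if threshold else prioritized
        manifest["stages"]["prioritize"] = {
            "input": len(variants),
            "prioritized": len(prioritized),
            "maf_retained": len(retained),
        }

    positions = [v.position for v in retained if v.position is not None]
    if "hotspot" in config.stages and positions:
        calls, track = call_hotspots(
            positions,
            L=config.protein_length,
            B=config.bootstrap,
            alpha=config.alpha,
            seed=config.seed,
        )
        write_clusters(calls, out / "clusters.tsv")
        write_track_bedgraph(track, out / "hotspot_track.bedgraph")
        n_sig = sum(1 for c in calls if c.significant)
        manifest["stages"]["hotspot"] = {
            "candidates": len(calls),
            "significant": n_sig,
            "max_track_count": int(track.counts.max()),
        }

    if "domains" in config.stages and config.domains_path and positions:
        manifest["inputs"][str(config.domains_path)] = _sha256(config.domains_path)
        domains = read_domain_table(config.domains_path, L=config.protein_length)
        labels = assign_domains(positions, domains, L=config.protein_length)
        lines = ["position\tdomain"]
        lines += [f"{p}\t{lab}" for p, lab in zip(positions, labels)]
        enr_lines = ["domain\tobserved\texpected\tp_value"]
        for d in domains:
            e = domain_enrichment(positions, d, L=config.protein_length)
            enr_lines.append(f"{e.domain}\t{e.observed}\t{e.expected!r}\t{e.p_value!r}")
        (out / "domain_assignment.tsv").write_text("\n".join(lines) + "\n")
        (out / "domain_enrichment.tsv").write_text("\n".join(enr_lines) + "\n")
        manifest["stages"]["domains"] = {"positions": len(positions), "domains": len(domains)}

    if "network" in config.stages and (config.edge_lists or config.synthetic_graphs):
        graphs = []
        for path in config.edge_lists:
            manifest["inputs"][str(path)] = _sha256(path)
            graphs.append(read_edge_list(path, format=config.edge_format))
        for spec in config.synthetic_graphs:
            graph, _ = gen_ppi_graph(spec)
            graphs.append(graph)
        merged = merge_networks(graphs)
        write_sif(merged, out / "merged_network.sif")
        metrics = node_metrics(merged)
        write_node_metrics(metrics, out / "network_metrics.tsv")
        fit = assortativity_fit(merged)
        hubs = top_hubs(metrics, k=min(config.n_hubs, len(metrics)), key="betweenness")
        manifest["stages"]["network"] = {
            "subnetworks": len(graphs),
            "nodes": merged.number_of_nodes(),
            "edges": merged.number_of_edges(),
            "mixing": fit.mixing,
            "slope": fit.slope,
            "top_hubs_betweenness": hubs,
        }

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest
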