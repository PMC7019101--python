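"""Bootstrap detection of positional variant clusters ("hotspots").

The question: do the residue positions of prioritized variants cluster along
the protein more tightly than uniform placement would produce?  The caller
supplies the m variant positions and the protein length L (1,391 residues
for NUP155 by default).  The procedure:

1. Every ordered pair of distinct observed positions defines a candidate
   cluster (start, end, number of member variants) — no cluster size or
   length is pre-specified.
2. A bootstrap null (B = 1,000 replicates by default) redraws m positions
   i.i.d. uniformly over 1..L.  For each replicate and each count c, the
   minimal window span containing c of the redrawn positions is recorded
   (an order-statistic minimum over sliding windows).
3. A candidate with n members and span s gets
   ``p = (1 + #{replicates: min_span(n) <= s}) / (B + 1)`` — the chance the
   null produces an equally tight cluster of n variants anywhere, with a
   pseudocount so finite resampling never yields p = 0.
4. Benjamini–Hochberg step-up correction across all candidates at level
   alpha (0.05 default).
5. The per-residue hotspot track counts how many significant clusters cover
   each residue.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "Candidate",
    "ClusterCall",
    "NullModel",
    "HotspotTrack",
    "enumerate_candidate_clusters",
    "build_null",
    "cluster_pvalue",
    "bh_adjust",
    "call_hotspots",
    "write_clusters",
    "write_track_bedgraph",
]

DEFAULT_PROTEIN_LENGTH = 1391  # residues in human NUP155
DEFAULT_BOOTSTRAP = 1000
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class Candidate:
    """A candidate cluster spanning two observed variant positions."""

    start: int
    end: int
    n_variants: int

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ClusterCall:
    start: int
    end: int
    n_variants: int
    p_raw: float
    q_bh: float
    significant: bool

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class NullModel:
    """Bootstrap null: per replicate, the minimal span containing c of m
    uniformly redrawn positions, for every c in 1..m."""

    m: int
    L: int
    B: int
    seed: int
    min_width_table: np.ndarray  # shape (B, m); column c-1 holds min span for c

    def __post_init__(self) -> None:
        assert self.min_width_table.shape == (self.B, self.m)


@dataclass(frozen=True)
class HotspotTrack:
    L: int
    counts: np.ndarray  # length L, counts[i] covers residue i+1

    def __post_init__(self) -> None:
        assert len(self.counts) == self.L


def enumerate_candidate_clusters(positions: Sequence[int]) -> list[Candidate]:
    """All intervals bounded by a pair of distinct observed position values.

    Duplicated positions contribute multiplicity to member counts but do not
    create duplicate candidates; d distinct values yield d(d+1)/2 candidates.
    """
    if len(positions) == 0:
        return []
    pos = np.sort(np.asarray(positions, dtype=int))
    distinct, counts = np.unique(pos, return_counts=True)
    cum = np.concatenate([[0], np.cumsum(counts)])
    out = []
    for i in range(len(distinct)):
        for j in range(i, len(distinct)):
            out.append(
                Candidate(
                    start=int(distinct[i]),
                    end=int(distinct[j]),
                    n_variants=int(cum[j + 1] - cum[i]),
                )
            )
    return out


def build_null(m: int, L: int, B: int = DEFAULT_BOOTSTRAP, seed: int = 0) -> NullModel:
    """Resample m positions uniformly over 1..L, B times, and tabulate the
    minimal window span containing each count c of resampled positions."""
    if m < 1 or L < 1 or B < 1:
        raise ValueError(f"need m, L, B >= 1 (got m={m}, L={L}, B={B})")
    rng = np.random.default_rng(seed)
    draws = np.sort(rng.integers(1, L + 1, size=(B, m)), axis=1)
    table = np.empty((B, m), dtype=np.int64)
    for c in range(1, m + 1):
        # sliding windows of c order statistics: span = p[j+c-1] - p[j] + 1
        spans = draws[:, c - 1 :] - draws[:, : m - c + 1] + 1
        table[:, c - 1] = spans.min(axis=1)
    return NullModel(m=m, L=L, B=B, seed=seed, min_width_table=table)


def cluster_pvalue(candidate: Candidate, null: NullModel) -> float:
    """Pseudocounted bootstrap tail probability that the null packs
    ``candidate.n_variants`` positions into a window no wider than the
    candidate's span."""
    if candidate.n_variants > null.m:
        raise ValueError(
            f"candidate has {candidate.n_variants} members but null resamples {null.m}"
        )
    hits = int(
        np.count_nonzero(
            null.min_width_table[:, candidate.n_variants - 1] <= candidate.span
        )
    )
    return (1 + hits) / (null.B + 1)


def bh_adjust(
    p_values: Sequence[float], alpha: float = DEFAULT_ALPHA
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up adjustment.

    Returns (q_values, significant) in the input order, with
    ``q_(i) = min_{j >= i} p_(j) * n / j`` capped at 1 and significance
    declared at ``q <= alpha``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q, q <= alpha


def call_hotspots(
    positions: Sequence[int],
    L: int = DEFAULT_PROTEIN_LENGTH,
    B: int = DEFAULT_BOOTSTRAP,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
) -> tuple[list[ClusterCall], HotspotTrack]:
    """Full pipeline: enumerate candidates, build the bootstrap null, score
    each candidate, BH-correct, and accumulate the per-residue track.

    Deterministic for a given (positions, L, B, alpha, seed).
    """
    positions = list(positions)
    if not positions:
        raise ValueError("no variant positions supplied")
    if max(positions) > L or min(positions) < 1:
        raise ValueError(
            f"positions must lie in 1..{L} (got range "
            f"{min(positions)}..{max(positions)})"
        )
    candidates = enumerate_candidate_clusters(positions)
    null = build_null(m=len(positions), L=L, B=B, seed=seed)

    # vectorized p-values: per member count c, rank each span against the
    # sorted null column
    spans = np.array([c.span for c in candidates])
    sizes = np.array([c.n_variants for c in candidates])
    p_raw = np.empty(len(candidates))
    for c in np.unique(sizes):
        null_col = np.sort(null.min_width_table[:, c - 1])
        mask = sizes == c
        hits = np.searchsorted(null_col, spans[mask], side="right")
        p_raw[mask] = (1 + hits) / (null.B + 1)

    q, significant = bh_adjust(p_raw, alpha=alpha)
    calls = [
        ClusterCall(
            start=cand.start,
            end=cand.end,
            n_variants=cand.n_variants,
            p_raw=float(p),
            q_bh=float(qv),
            significant=bool(sig),
        )
        for cand, p, qv, sig in zip(candidates, p_raw, q, significant)
    ]

    counts = np.zeros(L, dtype=np.int64)
    for call in calls:
        if call.significant:
            counts[call.start - 1 : call.end] += 1
    return calls, HotspotTrack(L=L, counts=counts)


def write_clusters(calls: Sequence[ClusterCall], path) -> None:
    """Write cluster calls as TSV (start, end, n, span, p, q, significant)."""
    lines = ["start\tend\tn_variants\tspan\tp_raw\tq_bh\tsignificant"]
    for c in calls:
        lines.append(
            f"{c.start}\t{c.end}\t{c.n_variants}\t{c.span}\t"
            f"{c.p_raw!r}\t{c.q_bh!r}\t{int(c.significant)}"
        )
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_track_bedgraph(
    track: HotspotTrack, path, name: str = "NUP155"
) -> None:
    """Write the track as bedGraph-like text: 0-based half-open intervals of
    constant count (converted from the 1-based inclusive residue convention)."""
    lines = []
    counts = track.counts
    start = 0
    for i in range(1, track.L + 1):
        if i == track.L or counts[i] != counts[start]:
            lines.append(f"{name}\t{start}\t{i}\t{int(counts[start])}")
            start = i
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
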