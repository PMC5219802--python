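"""Duplication-mechanism labelling from gene order.

Candidate pairs become anchors in gene-rank coordinates.  Collinear chains
are extracted per chromosome pair by highest-scoring-chain dynamic
programming (forward and reverse passes, greedy best-first extraction);
pairs in a chain are WGD-derived, pairs on one chromosome separated by at
most ``max_intervening`` genes are tandem-derived, and everything else is
undefined.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

from .homology import CandidatePair

logger = logging.getLogger(__name__)

__all__ = [
    "Anchor",
    "SyntenyChain",
    "ChainParams",
    "MechanismLabel",
    "GeneCoordinate",
    "build_anchors",
    "chain_anchors",
    "classify_mechanism",
]

WGD = "WGD"
TANDEM = "tandem"
UNDEFINED = "undefined"


@dataclass(frozen=True)
class GeneCoordinate:
    gene: str
    chromosome: str
    ordinal_index: int  # 1-based rank along the chromosome
    start_bp: int = 0
    strand: str = "+"


@dataclass(frozen=True)
class Anchor:
    gene_a: str
    gene_b: str
    chrom_a: str
    chrom_b: str
    idx_a: int
    idx_b: int
    score: float


@dataclass(frozen=True)
class SyntenyChain:
    anchors: tuple[Anchor, ...]
    orientation: str  # "forward" | "reverse"
    total_score: float


@dataclass(frozen=True)
class ChainParams:
    """Chain-DP parameters in gene-index space (reconstruction of common
    collinearity-chainer defaults; all configurable)."""

    score_cap: float = 50.0
    gap_penalty: float = 1.0  # per skipped gene per axis
    max_gap: int = 20  # max index advance per axis between linked anchors
    min_anchors: int = 5
    tandem_window: int = 10  # self-comparison diagonal exclusion


@dataclass(frozen=True)
class MechanismLabel:
    gene_a: str
    gene_b: str
    label: str  # WGD | tandem | undefined
    chain_id: int | None = None


def anchor_score(evalue: float, cap: float = 50.0) -> float:
    """min(cap, -log10(evalue)) with a floor of 1."""
    if evalue <= 0:
        return cap
    return max(1.0, min(cap, -math.log10(evalue)))


def build_anchors(
    pairs: Iterable[CandidatePair],
    coords: Mapping[str, GeneCoordinate],
    score_cap: float = 50.0,
) -> tuple[list[Anchor], list[CandidatePair]]:
    """Place candidate pairs in gene-rank coordinates.  Returns (anchors,
    pairs lacking coordinates).  The (chrom_a, chrom_b) combination is
    canonicalized so chrom_a <= chrom_b, with idx_a <= idx_b within a
    chromosome."""
    anchors = []
    missing = []
    for p in pairs:
        ca = coords.get(p.gene_a)
        cb = coords.get(p.gene_b)
        if ca is None or cb is None:
            missing.append(p)
            continue
        ga, gb = p.gene_a, p.gene_b
        if (ca.chromosome, ca.ordinal_index) > (cb.chromosome, cb.ordinal_index):
            ca, cb = cb, ca
            ga, gb = gb, ga
        anchors.append(
            Anchor(
                gene_a=ga,
                gene_b=gb,
                chrom_a=ca.chromosome,
                chrom_b=cb.chromosome,
                idx_a=ca.ordinal_index,
                idx_b=cb.ordinal_index,
                score=anchor_score(p.source_hit.evalue, score_cap),
            )
        )
    if missing:
        logger.warning("%d pairs lack coordinates; labelled undefined", len(missing))
    return anchors, missing


def _best_chain(
    anchors: list[Anchor], params: ChainParams, reverse: bool
) -> tuple[float, list[int]]:
    """Single highest-scoring chain over the given anchors (DP).

    Forward pass requires both indices strictly increasing; the reverse
    pass mirrors idx_b.  Returns (total score, anchor positions in input
    list); an empty list when no anchor exists.
    """
    if not anchors:
        return -math.inf, []
    sign = -1 if reverse else 1
    order = sorted(
        range(len(anchors)), key=lambda i: (anchors[i].idx_a, sign * anchors[i].idx_b)
    )
    n = len(order)
    best = [anchors[order[i]].score for i in range(n)]
    prev = [-1] * n
    for i in range(n):
        ai = anchors[order[i]]
        bi = sign * ai.idx_b
        for j in range(i):
            aj = anchors[order[j]]
            bj = sign * aj.idx_b
            da = ai.idx_a - aj.idx_a
            db = bi - bj
            if da <= 0 or db <= 0:
                continue
            if da > params.max_gap or db > params.max_gap:
                continue
            cand = best[j] + ai.score - params.gap_penalty * (da + db - 2)
            if cand > best[i] + 1e-12:
                best[i] = cand
                prev[i] = j
    end = max(range(n), key=lambda i: best[i])
    path = []
    i = end
    while i >= 0:
        path.append(order[i])
        i = prev[i]
    path.reverse()
    return best[end], path


def chain_anchors(
    anchors: Iterable[Anchor], params: ChainParams | None = None
) -> list[SyntenyChain]:
    """Greedy best-first extraction of collinear chains on one chromosome
    pair.  Within-chromosome self-comparisons exclude near-diagonal anchors
    (|idx_a - idx_b| <= tandem_window) and duplicate mirror anchors.
    """
    params = params or ChainParams()
    pool = list(anchors)
    if pool:
        chroms = {(a.chrom_a, a.chrom_b) for a in pool}
        if len(chroms) > 1:
            raise ValueError("chain_anchors expects anchors from one chromosome pair")
        ca, cb = next(iter(chroms))
        if ca == cb:
            pool = [a for a in pool if abs(a.idx_a - a.idx_b) > params.tandem_window]
    chains: list[SyntenyChain] = []
    while pool:
        f_score, f_path = _best_chain(pool, params, reverse=False)
        r_score, r_path = _best_chain(pool, params, reverse=True)
        candidates = []
        if len(f_path) >= params.min_anchors:
            candidates.append((f_score, f_path, "forward"))
        if len(r_path) >= params.min_anchors:
            candidates.append((r_score, r_path, "reverse"))
        if not candidates:
            break
        # determinism: higher score, then longer, then smallest first index
        candidates.sort(
            key=lambda t: (-t[0], -len(t[1]), pool[t[1][0]].idx_a, t[2])
        )
        score, path, orientation = candidates[0]
        # a gene may not appear twice within one chain (possible only in
        # self-comparisons where a gene sits on both axes); drop offenders
        kept: list[Anchor] = []
        seen_genes: set[str] = set()
        for i in path:
            a = pool[i]
            if a.gene_a in seen_genes or a.gene_b in seen_genes:
                continue
            seen_genes.update((a.gene_a, a.gene_b))
            kept.append(a)
        taken = set(path)
        pool = [a for i, a in enumerate(pool) if i not in taken]
        if len(kept) < params.min_anchors:
            continue
        if len(kept) < len(path):
            score = _rescore(kept, params)
        chains.append(SyntenyChain(tuple(kept), orientation, score))
    return chains


def _rescore(chain: list[Anchor], params: ChainParams) -> float:
    total = sum(a.score for a in chain)
    for prev_a, a in zip(chain, chain[1:]):
        da = abs(a.idx_a - prev_a.idx_a)
        db = abs(a.idx_b - prev_a.idx_b)
        total -= params.gap_penalty * (da + db - 2)
    return total


def find_chains(
    anchors: Iterable[Anchor], params: ChainParams | None = None
) -> list[SyntenyChain]:
    """Run chain extraction on every (chrom_a, chrom_b) combination."""
    params = params or ChainParams()
    groups: dict[tuple[str, str], list[Anchor]] = {}
    for a in anchors:
        groups.setdefault((a.chrom_a, a.chrom_b), []).append(a)
    chains: list[SyntenyChain] = []
    for key in sorted(groups):
        chains.extend(chain_anchors(groups[key], params))
    return chains


def classify_mechanism(
    pairs: Iterable[CandidatePair],
    chains: Iterable[SyntenyChain],
    coords: Mapping[str, GeneCoordinate],
    max_intervening: int = 10,
) -> list[MechanismLabel]:
    """Partition candidate pairs into WGD / tandem / undefined.

    Chain membership is tested first, so a pair that is both a chain
    member and within the tandem window is WGD.
    """
    in_chain: dict[frozenset, int] = {}
    for cid, chain in enumerate(chains):
        for a in chain.anchors:
            in_chain.setdefault(frozenset((a.gene_a, a.gene_b)), cid)
    labels = []
    for p in pairs:
        key = frozenset((p.gene_a, p.gene_b))
        if key in in_chain:
            labels.append(MechanismLabel(p.gene_a, p.gene_b, WGD, in_chain[key]))
            continue
        ca = coords.get(p.gene_a)
        cb = coords.get(p.gene_b)
        if ca is None or cb is None:
            logger.warning(
                "missing coordinates for pair (%s, %s); labelled undefined",
                p.gene_a,
                p.gene_b,
            )
            labels.append(MechanismLabel(p.gene_a, p.gene_b, UNDEFINED))
            continue
        if (
            ca.chromosome == cb.chromosome
            and abs(ca.ordinal_index - cb.ordinal_index) - 1 <= max_intervening
        ):
            labels.append(MechanismLabel(p.gene_a, p.gene_b, TANDEM))
        else:
            labels.append(MechanismLabel(p.gene_a, p.gene_b, UNDEFINED))
    return labels
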