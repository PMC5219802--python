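"""Pairwise Ks/Ka estimation from protein-guided codon alignments.

Two counting estimators are provided:

* ``NG86`` — equal-weight pathway counting with Jukes–Cantor correction.
* ``YN00`` — transition/transversion-aware counting: kappa is estimated
  from fourfold-degenerate and nondegenerate sites, and the synonymous
  distance comes from degeneracy-class-stratified two-parameter (K80-type)
  corrections evaluated at positions whose class is conserved between the
  two rows.  Stratifying by class keeps the transition-only twofold
  channel separate from the fourfold channel, which removes the large
  upward bias a pooled correction shows beyond Ks ~ 1.

Both report a delta-method standard error of Ks, the quantity the
downstream retention filter (Ks <= 2, SE < 0.5) binds on.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from ._codon import (
    AA,
    CODON_INDEX,
    DEGENERACY,
    N_SENSE,
    SENSE_CODONS,
    SINGLE_STEP,
    cds_to_codon_indices,
    is_transition,
)

__all__ = [
    "CodonAlignment",
    "KsEstimate",
    "codon_align",
    "estimate_ks",
    "filter_estimates",
]


@dataclass(frozen=True)
class CodonAlignment:
    """Gap-free pairwise codon columns retained for substitution counting."""

    gene_a: str
    gene_b: str
    codons_a: np.ndarray  # sense codon indices, one per retained column
    codons_b: np.ndarray

    @property
    def n_codons_used(self) -> int:
        return len(self.codons_a)


@dataclass(frozen=True)
class KsEstimate:
    gene_a: str
    gene_b: str
    ks: float
    ka: float
    se: float
    kappa_hat: float
    n_codons: int
    method: str
    saturated: bool = False
    flags: tuple[str, ...] = field(default_factory=tuple)


def _protein_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def codon_align(cds_a: str, cds_b: str, name_a: str = "a", name_b: str = "b") -> CodonAlignment:
    """Globally align the two translations (BLOSUM62, affine gaps) and
    back-translate onto codons; columns gapped in either row are dropped."""
    idx_a = cds_to_codon_indices(cds_a, name_a)
    idx_b = cds_to_codon_indices(cds_b, name_b)
    prot_a = "".join(AA[i] for i in idx_a)
    prot_b = "".join(AA[i] for i in idx_b)
    aln = _protein_aligner().align(prot_a, prot_b)[0]
    cols_a: list[int] = []
    cols_b: list[int] = []
    for (sa, ea), (sb, eb) in zip(*aln.aligned):
        cols_a.extend(range(sa, ea))
        cols_b.extend(range(sb, eb))
    return CodonAlignment(name_a, name_b, idx_a[np.array(cols_a, dtype=int)], idx_b[np.array(cols_b, dtype=int)])


# ---------------------------------------------------------------------------
# site counting

def _site_counts_ng(idx: np.ndarray) -> float:
    """NG86 synonymous sites: equal-weight fraction per position, stop-codon
    targets excluded from the denominator."""
    s_per_codon = np.zeros(N_SENSE)
    for i in range(N_SENSE):
        for p in range(3):
            alts = [(j, syn) for j, _, syn in SINGLE_STEP[i][p] if j >= 0]
            if alts:
                s_per_codon[i] += sum(syn for _, syn in alts) / len(alts)
    return float(s_per_codon[idx].sum())


# ---------------------------------------------------------------------------
# pathway-weighted difference counting

def _pathways(ca: str, cb: str) -> list[list[tuple[str, str]]]:
    """All minimal substitution pathways from codon ca to cb, as lists of
    (from_codon, to_codon) single-nucleotide steps."""
    diff = [p for p in range(3) if ca[p] != cb[p]]
    paths = []
    for order in itertools.permutations(diff):
        cur = ca
        steps = []
        for p in order:
            nxt = cur[:p] + cb[p] + cur[p + 1 :]
            steps.append((cur, nxt))
            cur = nxt
        paths.append(steps)
    return paths


def _step_class(cu: str, cv: str) -> tuple[bool, bool]:
    """(is_transition, is_synonymous) for a single-nt codon step; steps
    into stops are classed nonsynonymous."""
    p = next(k for k in range(3) if cu[k] != cv[k])
    ts = is_transition(cu[p], cv[p])
    if cv in CODON_INDEX and cu in CODON_INDEX:
        syn = AA[CODON_INDEX[cu]] == AA[CODON_INDEX[cv]]
    else:
        syn = False
    return ts, syn


def _count_pair_differences(
    ia: int, ib: int, kappa: float | None, pi: np.ndarray | None
) -> np.ndarray:
    """Expected (syn_ts, syn_tv, nonsyn_ts, nonsyn_tv) differences for one
    aligned codon pair, averaging over minimal pathways.

    With kappa/pi given, pathways are weighted by the product of
    symmetrized step weights kappa^(ts) * sqrt(pi_u * pi_v) (symmetric in
    the two rows); pathways crossing a stop codon get zero weight.  With
    kappa=None, pathways are weighted equally (NG86), still excluding
    stop-crossing pathways when an alternative exists.
    """
    ca, cb = SENSE_CODONS[ia], SENSE_CODONS[ib]
    if ca == cb:
        return np.zeros(4)
    paths = _pathways(ca, cb)
    weights = []
    per_path = []
    for steps in paths:
        if any(s[1] not in CODON_INDEX for s in steps[:-1]):
            # intermediate stop codon
            weights.append(0.0)
            per_path.append(np.zeros(4))
            continue
        counts = np.zeros(4)
        w = 1.0
        for cu, cv in steps:
            ts, syn = _step_class(cu, cv)
            counts[(0 if syn else 2) + (0 if ts else 1)] += 1
            if kappa is not None:
                w *= (kappa if ts else 1.0) * math.sqrt(
                    pi[CODON_INDEX[cu]] * pi[CODON_INDEX[cv]]
                )
        weights.append(w)
        per_path.append(counts)
    wsum = sum(weights)
    if wsum <= 0:  # every pathway blocked by stops: fall back to equal weights
        weights = [1.0] * len(paths)
        per_path = []
        for steps in paths:
            counts = np.zeros(4)
            for cu, cv in steps:
                ts, syn = _step_class(cu, cv)
                counts[(0 if syn else 2) + (0 if ts else 1)] += 1
            per_path.append(counts)
        wsum = float(len(paths))
    out = np.zeros(4)
    for w, c in zip(weights, per_path):
        out += (w / wsum) * c
    return out


def _class_of(i: int, p: int) -> int:
    """Degeneracy class of codon i at position p: 0 = nondegenerate,
    1 = twofold-ish (1-2 synonymous changes), 2 = fourfold."""
    d = DEGENERACY[i, p]
    return 2 if d == 3 else (0 if d == 0 else 1)


# Per ordered codon pair (i, j) and degeneracy class c: number of positions
# whose class is c in BOTH codons, and the observed transition/transversion
# differences at those positions.  Restricting the counts to class-stable
# positions keeps each substitution channel homogeneous, which is what the
# per-class distance corrections assume.
_STABLE_TABLES: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None


def _stable_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    global _STABLE_TABLES
    if _STABLE_TABLES is None:
        L = np.zeros((N_SENSE, N_SENSE, 3))
        ts = np.zeros((N_SENSE, N_SENSE, 3))
        tv = np.zeros((N_SENSE, N_SENSE, 3))
        for i in range(N_SENSE):
            for j in range(N_SENSE):
                ca, cb = SENSE_CODONS[i], SENSE_CODONS[j]
                for p in range(3):
                    c = _class_of(i, p)
                    if c != _class_of(j, p):
                        continue
                    L[i, j, c] += 1
                    if ca[p] != cb[p]:
                        if is_transition(ca[p], cb[p]):
                            ts[i, j, c] += 1
                        else:
                            tv[i, j, c] += 1
        _STABLE_TABLES = (L, ts, tv)
    return _STABLE_TABLES


# ---------------------------------------------------------------------------
# distance corrections

def _jc(p: float, n_sites: float) -> tuple[float, float, bool]:
    w = 1.0 - 4.0 * p / 3.0
    if w <= 0:
        return math.nan, math.nan, True
    d = -0.75 * math.log(w)
    var = p * (1.0 - p) / (w * w * max(n_sites, 1.0))
    return d, math.sqrt(max(var, 0.0)), False


def _k80_parts(p: float, q: float) -> tuple[float, float, bool]:
    """Transition distance A and per-direction transversion distance B for
    one degeneracy class (K80 / two-state channel decomposition)."""
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0 or w2 <= 0:
        return math.nan, math.nan, True
    a = -0.5 * math.log(w1) + 0.25 * math.log(w2)
    b = -0.5 * math.log(w2)
    return a, b, False


def _stratified_ds(L: np.ndarray, ts_c: np.ndarray, tv_c: np.ndarray) -> tuple[float, bool]:
    """Synonymous distance from the twofold and fourfold classes:
    averaged transition distance plus the fourfold transversion distance."""
    l24 = L[1] + L[2]
    if l24 <= 0:
        return math.nan, True
    a_sum = 0.0
    for c in (1, 2):
        if L[c] <= 0:
            continue
        a, _, sat = _k80_parts(ts_c[c] / L[c], tv_c[c] / L[c])
        if sat:
            return math.nan, True
        a_sum += L[c] * a
    if L[2] > 0:
        _, b4, sat = _k80_parts(ts_c[2] / L[2], tv_c[2] / L[2])
        if sat:
            return math.nan, True
    else:
        b4 = 0.0
    return a_sum / l24 + b4, False


def _stratified_dn(L: np.ndarray, ts_c: np.ndarray, tv_c: np.ndarray) -> tuple[float, bool]:
    """Nonsynonymous distance: nondegenerate transition distance plus the
    averaged transversion distance over nondegenerate and twofold classes."""
    l02 = L[0] + L[1]
    if l02 <= 0:
        return math.nan, True
    a0 = 0.0
    if L[0] > 0:
        a0, _, sat = _k80_parts(ts_c[0] / L[0], tv_c[0] / L[0])
        if sat:
            return math.nan, True
    b_sum = 0.0
    for c in (0, 1):
        if L[c] <= 0:
            continue
        _, b, sat = _k80_parts(ts_c[c] / L[c], tv_c[c] / L[c])
        if sat:
            return math.nan, True
        b_sum += L[c] * b
    return a0 + b_sum / l02, False


def _stratified_ds_se(L: np.ndarray, ts_c: np.ndarray, tv_c: np.ndarray) -> float:
    """Delta-method SE of the stratified synonymous distance: per-class
    (P, Q) are multinomial proportions over L_c sites, classes independent;
    gradient taken numerically."""
    base, sat = _stratified_ds(L, ts_c, tv_c)
    if sat or math.isnan(base):
        return math.nan
    h = 1e-6
    var = 0.0
    for c in (1, 2):
        if L[c] <= 0:
            continue
        p, q = ts_c[c] / L[c], tv_c[c] / L[c]
        dts = np.array(ts_c)
        dts[c] += h * L[c]
        gp = (_stratified_ds(L, dts, tv_c)[0] - base) / h
        dtv = np.array(tv_c)
        dtv[c] += h * L[c]
        gq = (_stratified_ds(L, ts_c, dtv)[0] - base) / h
        vp = p * (1.0 - p) / L[c]
        vq = q * (1.0 - q) / L[c]
        cpq = -p * q / L[c]
        var += gp * gp * vp + gq * gq * vq + 2.0 * gp * gq * cpq
    return math.sqrt(max(var, 0.0))


def _estimate_kappa(idx_a: np.ndarray, idx_b: np.ndarray) -> tuple[float, bool]:
    """Kappa from fourfold-degenerate and nondegenerate sites, pooled K80
    transition/transversion branch lengths.  Returns (kappa, ok)."""
    l_sites = np.zeros(2)  # [fourfold, nondegenerate]
    ts_cnt = np.zeros(2)
    tv_cnt = np.zeros(2)
    for ia, ib in zip(idx_a, idx_b):
        ca, cb = SENSE_CODONS[ia], SENSE_CODONS[ib]
        for p in range(3):
            da, db = DEGENERACY[ia, p], DEGENERACY[ib, p]
            if da == 3 and db == 3:
                cls = 0
            elif da == 0 and db == 0:
                cls = 1
            else:
                continue
            l_sites[cls] += 1
            if ca[p] != cb[p]:
                if is_transition(ca[p], cb[p]):
                    ts_cnt[cls] += 1
                else:
                    tv_cnt[cls] += 1
    total = l_sites.sum()
    if total < 10:
        return 1.0, False
    a_pool = b_pool = 0.0
    weight = 0.0
    for cls in range(2):
        if l_sites[cls] == 0:
            continue
        p = ts_cnt[cls] / l_sites[cls]
        q = tv_cnt[cls] / l_sites[cls]
        w1 = 1.0 - 2.0 * p - q
        w2 = 1.0 - 2.0 * q
        if w1 <= 0 or w2 <= 0:
            continue
        a_branch = -0.5 * math.log(w1) + 0.25 * math.log(w2)  # transition distance
        b_branch = -0.25 * math.log(w2)  # per-type transversion distance
        a_pool += l_sites[cls] * a_branch
        b_pool += l_sites[cls] * b_branch
        weight += l_sites[cls]
    if weight == 0 or b_pool <= 0:
        if weight > 0 and a_pool > 0:
            return 20.0, False
        return 1.0, False
    kappa = a_pool / b_pool
    return float(min(max(kappa, 0.01), 99.0)), True


def estimate_ks(
    alignment: CodonAlignment,
    method: str = "YN00",
    min_codons: int = 30,
) -> KsEstimate:
    """Estimate Ks, Ka and the Ks standard error from gap-free codon columns."""
    method = method.upper()
    if method not in {"YN00", "NG86"}:
        raise ValueError(f"unknown method {method!r}")
    n = alignment.n_codons_used
    if n < min_codons:
        raise ValueError(f"alignment has {n} codons, need at least {min_codons}")
    ia, ib = alignment.codons_a, alignment.codons_b

    flags: list[str] = []
    # unique aligned codon pairs, symmetric in the two rows
    key = np.minimum(ia, ib) * N_SENSE + np.maximum(ia, ib)
    uniq, counts = np.unique(key, return_counts=True)

    if method == "YN00":
        kappa, kappa_ok = _estimate_kappa(ia, ib)
        if not kappa_ok:
            flags.append("kappa_default")
        tab_l, tab_ts, tab_tv = _stable_tables()
        i_arr = (uniq // N_SENSE).astype(int)
        j_arr = (uniq % N_SENSE).astype(int)
        l_cls = (counts[:, None] * tab_l[i_arr, j_arr]).sum(axis=0)
        ts_cls = (counts[:, None] * tab_ts[i_arr, j_arr]).sum(axis=0)
        tv_cls = (counts[:, None] * tab_tv[i_arr, j_arr]).sum(axis=0)
        ks, sat_s = _stratified_ds(l_cls, ts_cls, tv_cls)
        ka, sat_n = _stratified_dn(l_cls, ts_cls, tv_cls)
        se_s = _stratified_ds_se(l_cls, ts_cls, tv_cls)
    else:
        kappa = 1.0
        s_sites = 0.5 * (_site_counts_ng(ia) + _site_counts_ng(ib))
        n_sites = 3.0 * n - s_sites
        diff = np.zeros(4)  # syn_ts, syn_tv, nonsyn_ts, nonsyn_tv
        for k, c in zip(uniq, counts):
            i, j = int(k) // N_SENSE, int(k) % N_SENSE
            if i == j:
                continue
            diff += c * _count_pair_differences(i, j, None, None)
        sd_ts, sd_tv, nd_ts, nd_tv = diff
        ks, se_s, sat_s = _jc((sd_ts + sd_tv) / s_sites, s_sites)
        ka, _, sat_n = _jc((nd_ts + nd_tv) / n_sites, n_sites)
    saturated = bool(sat_s)
    if sat_n and not math.isnan(ks):
        ka = math.nan
        flags.append("ka_saturated")
    if saturated:
        flags.append("saturated")
    return KsEstimate(
        gene_a=alignment.gene_a,
        gene_b=alignment.gene_b,
        ks=ks,
        ka=ka,
        se=se_s,
        kappa_hat=kappa,
        n_codons=n,
        method=method,
        saturated=saturated,
        flags=tuple(flags),
    )


def filter_estimates(
    estimates: list[KsEstimate],
    max_ks: float = 2.0,
    max_se: float = 0.5,
) -> tuple[list[KsEstimate], dict[str, int]]:
    """Retention filter: keep Ks <= max_ks (inclusive) and SE < max_se
    (strict).  Returns (kept, counts of exclusions by reason)."""
    kept = []
    dropped = {"saturated": 0, "ks_gt_max": 0, "se_ge_max": 0}
    for e in estimates:
        if e.saturated or math.isnan(e.ks):
            dropped["saturated"] += 1
        elif e.ks > max_ks:
            dropped["ks_gt_max"] += 1
        elif not (e.se < max_se):
            dropped["se_ge_max"] += 1
        else:
            kept.append(e)
    return kept, dropped
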