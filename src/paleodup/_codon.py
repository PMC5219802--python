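"""Codon-level machinery shared by the simulator and the Ks estimators.

Standard genetic code only.  Sense codons are indexed 0..60 in
lexicographic order; stop codons are excluded from every table and all
substitution processes assign them zero rate.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]

NUCS = "ACGT"
STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c in ("".join(p) for p in itertools.product(NUCS, repeat=3)) if c not in STOP_CODONS)
)
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
N_SENSE = len(SENSE_CODONS)  # 61
AA = tuple(_TABLE.forward_table[c] for c in SENSE_CODONS)

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def is_transition(a: str, b: str) -> bool:
    return (a, b) in _TRANSITIONS


# For each sense codon i and position p: list of (target sense index or -1
# for stop, transition?, synonymous?).  -1 targets only occur with syn=False.
SINGLE_STEP: list[list[list[tuple[int, bool, bool]]]] = []
for _i, _c in enumerate(SENSE_CODONS):
    per_pos = []
    for _p in range(3):
        alts = []
        for _n in NUCS:
            if _n == _c[_p]:
                continue
            t = _c[:_p] + _n + _c[_p + 1 :]
            ts = is_transition(_c[_p], _n)
            if t in STOP_CODONS:
                alts.append((-1, ts, False))
            else:
                j = CODON_INDEX[t]
                alts.append((j, ts, AA[_i] == AA[j]))
        per_pos.append(alts)
    SINGLE_STEP.append(per_pos)

# Degeneracy per codon/position: number of the 3 single-nt changes that are
# synonymous (changes to stops count as nonsynonymous).
DEGENERACY = np.array(
    [[sum(1 for (j, _, syn) in SINGLE_STEP[i][p] if syn) for p in range(3)] for i in range(N_SENSE)],
    dtype=int,
)


def translate_codon(codon: str) -> str:
    if codon in STOP_CODONS:
        return "*"
    return _TABLE.forward_table[codon]


def cds_to_codon_indices(cds: str, name: str = "sequence") -> np.ndarray:
    """Split a CDS into sense-codon indices; reject internal stops and non-codon length.

    A single terminal stop codon is silently dropped.
    """
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3 != 0:
        raise ValueError(f"{name}: CDS length {len(cds)} is not a multiple of 3")
    codons = [cds[k : k + 3] for k in range(0, len(cds), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    idx = np.empty(len(codons), dtype=np.int64)
    for k, c in enumerate(codons):
        if c in STOP_CODONS:
            raise ValueError(f"{name}: internal stop codon {c} at codon index {k}")
        if c not in CODON_INDEX:
            raise ValueError(f"{name}: unrecognized codon {c!r} at codon index {k}")
        idx[k] = CODON_INDEX[c]
    return idx


def indices_to_cds(idx: np.ndarray) -> str:
    return "".join(SENSE_CODONS[i] for i in idx)


def translate_indices(idx: np.ndarray) -> str:
    return "".join(AA[i] for i in idx)


def rate_matrix(kappa: float, omega: float) -> np.ndarray:
    """GY-style 61x61 codon rate matrix with uniform codon frequencies.

    Symmetric off-diagonal (uniform stationary distribution); zero rate to
    and from stop codons by construction; multi-nucleotide changes have
    zero rate.
    """
    q = np.zeros((N_SENSE, N_SENSE))
    for i in range(N_SENSE):
        for p in range(3):
            for j, ts, syn in SINGLE_STEP[i][p]:
                if j < 0:
                    continue
                r = kappa if ts else 1.0
                if not syn:
                    r *= omega
                q[i, j] = r
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def synonymous_flux(kappa: float, omega: float) -> tuple[float, float]:
    """Mean (synonymous, nonsynonymous) substitution rate per codon under
    the uniform-frequency model, per unit of raw matrix time."""
    syn = nonsyn = 0.0
    for i in range(N_SENSE):
        for p in range(3):
            for j, ts, s in SINGLE_STEP[i][p]:
                if j < 0:
                    continue
                r = kappa if ts else 1.0
                if s:
                    syn += r
                else:
                    nonsyn += r * omega
    return syn / N_SENSE, nonsyn / N_SENSE


def synonymous_sites_per_codon(kappa: float) -> float:
    """Mutational-opportunity synonymous sites per codon (omega = 1),
    kappa-weighted, averaged over the uniform codon distribution."""
    syn, nonsyn = synonymous_flux(kappa, 1.0)
    return 3.0 * syn / (syn + nonsyn)


class CodonEvolver:
    """Endpoint sampler for the codon substitution process.

    Branch lengths are given in Ks units (expected synonymous substitutions
    per kappa-weighted synonymous site).  Descendant states are drawn from
    the exact transition matrix P(t) = exp(Qt); because the generator gives
    stop codons zero rate this is equivalent to per-site event sampling
    with stop-codon rejection.
    """

    def __init__(self, kappa: float = 2.0, omega: float = 0.2):
        if kappa <= 0 or omega <= 0:
            raise ValueError("kappa and omega must be > 0")
        self.kappa = float(kappa)
        self.omega = float(omega)
        q = rate_matrix(kappa, omega)
        # symmetric => real orthogonal eigendecomposition
        self._eigval, self._eigvec = np.linalg.eigh(q)
        syn_rate, _ = synonymous_flux(kappa, omega)
        self._ks_per_time = syn_rate / synonymous_sites_per_codon(kappa)

    def transition_matrix(self, ks_branch: float) -> np.ndarray:
        t = ks_branch / self._ks_per_time
        p = (self._eigvec * np.exp(self._eigval * t)) @ self._eigvec.T
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=1, keepdims=True)
        return p

    def evolve(self, codon_idx: np.ndarray, ks_branch: float, rng: np.random.Generator) -> np.ndarray:
        """Evolve a codon-index array along one branch of the given Ks length."""
        if ks_branch < 0:
            raise ValueError("branch length must be >= 0")
        if ks_branch == 0:
            return codon_idx.copy()
        p = self.transition_matrix(ks_branch)
        cum = np.cumsum(p, axis=1)
        u = rng.random(len(codon_idx))
        rows = cum[codon_idx]
        return (rows > u[:, None]).argmax(axis=1).astype(np.int64)


def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """Uniform random sense codons (no stops anywhere)."""
    idx = rng.integers(0, N_SENSE, size=n_codons)
    return indices_to_cds(idx)
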