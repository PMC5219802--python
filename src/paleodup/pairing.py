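"""Representative-pair selection.

Each gene keeps one pair by precedence: its lowest-Ks WGD pair if it has
any (rule I), else its lowest-Ks tandem pair (rule II), else its lowest-Ks
undefined pair (rule III).  A partner being claimed under a different rule
never blocks a pairing; pairs selected from both endpoints are emitted
once.  Only pairs that survived the Ks/SE filter are visible here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .mechanism import TANDEM, UNDEFINED, WGD

__all__ = ["LabelledPair", "RepresentativePair", "select_pairs"]

_RULE_FOR_LABEL = {WGD: "I", TANDEM: "II", UNDEFINED: "III"}
_PRECEDENCE = (WGD, TANDEM, UNDEFINED)


@dataclass(frozen=True)
class LabelledPair:
    gene_a: str
    gene_b: str
    label: str  # WGD | tandem | undefined
    ks: float


@dataclass(frozen=True)
class RepresentativePair:
    gene_a: str
    gene_b: str
    label: str
    ks: float
    selected_by_rule: str  # I | II | III


def select_pairs(pairs: Iterable[LabelledPair]) -> list[RepresentativePair]:
    """Apply the per-gene precedence rules and deduplicate the result.

    Ks ties are broken by the lexicographically smaller partner id, so the
    output is invariant to input ordering.
    """
    by_gene: dict[str, list[LabelledPair]] = {}
    for p in pairs:
        if p.label not in _RULE_FOR_LABEL:
            raise ValueError(f"unknown mechanism label {p.label!r}")
        by_gene.setdefault(p.gene_a, []).append(p)
        by_gene.setdefault(p.gene_b, []).append(p)

    chosen: dict[tuple[str, str], RepresentativePair] = {}
    for gene in sorted(by_gene):
        mine = by_gene[gene]
        pick = None
        for label in _PRECEDENCE:
            with_label = [p for p in mine if p.label == label]
            if with_label:
                pick = min(
                    with_label,
                    key=lambda p: (p.ks, p.gene_b if p.gene_a == gene else p.gene_a),
                )
                break
        if pick is None:
            continue
        key = tuple(sorted((pick.gene_a, pick.gene_b)))
        chosen.setdefault(
            key,
            RepresentativePair(
                gene_a=key[0],
                gene_b=key[1],
                label=pick.label,
                ks=pick.ks,
                selected_by_rule=_RULE_FOR_LABEL[pick.label],
            ),
        )
    return [chosen[k] for k in sorted(chosen)]
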