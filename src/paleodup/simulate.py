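"""Synthetic genomes with a known duplication history.

The generator lays ancestral genes on chromosomes, applies one or more
whole-genome duplications (duplicated chromosome segments preserve
ancestral gene order, retention is Bernoulli and may be biased toward a
chosen GO term), sprinkles tandem duplications near their source genes,
and evolves codon sequences so each surviving pair's realized synonymous
divergence sits around its nominal age.  Ground truth (pair, mechanism,
age, event index) is emitted alongside the standard input files the
pipeline consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._codon import CodonEvolver, indices_to_cds, translate_indices, N_SENSE

__all__ = ["SimConfig", "WgdEvent", "TruthRecord", "GenomeBundle", "simulate_genome", "evolve_codon_pair"]

MIN_CHAIN_LENGTH = 5  # minimum detectable collinear run; used for config sanity


@dataclass(frozen=True)
class WgdEvent:
    target_ks: float
    retention_prob_baseline: float
    retention_prob_biased: float
    biased_go_term: str | None = None


@dataclass(frozen=True)
class SimConfig:
    n_chromosomes: int = 5
    n_ancestral_genes: int = 1000
    codon_length_range: tuple[int, int] = (120, 200)
    wgd_events: tuple[WgdEvent, ...] = (WgdEvent(1.0, 0.3, 0.3),)
    tandem_rate: float = 0.1
    tandem_target_ks_max: float = 0.5
    tandem_rate_biased: float | None = None  # optional loss bias for the GO term
    kappa: float = 2.0
    omega: float = 0.2
    go_terms: tuple[tuple[str, float], ...] = (("GO:0003700", 0.1), ("GO:0008150", 0.3))
    ks_jitter_sd: float = 0.1  # lognormal sigma on each pair's realized age
    seed: int = 0

    def __post_init__(self):
        if self.n_chromosomes < 1 or self.n_ancestral_genes < 1:
            raise ValueError("need at least one chromosome and one gene")
        lo, hi = self.codon_length_range
        if lo < 100 or hi < lo:
            raise ValueError("codon_length_range minimum must be >= 100 codons")
        seen = set()
        for ev in self.wgd_events:
            if ev.target_ks <= 0 or ev.target_ks in seen:
                raise ValueError("WGD target Ks values must be distinct and > 0")
            seen.add(ev.target_ks)
            for p in (ev.retention_prob_baseline, ev.retention_prob_biased):
                if not 0.0 <= p <= 1.0:
                    raise ValueError("retention probabilities must be in [0, 1]")
        if self.tandem_rate < 0 or self.tandem_target_ks_max < 0:
            raise ValueError("tandem parameters must be nonnegative")
        if self.kappa <= 0 or self.omega <= 0:
            raise ValueError("kappa and omega must be > 0")
        for _, frac in self.go_terms:
            if not 0.0 <= frac <= 1.0:
                raise ValueError("GO annotation fractions must be in [0, 1]")
        for ev in self.wgd_events:
            expected = self.n_ancestral_genes * max(
                ev.retention_prob_baseline, ev.retention_prob_biased
            )
            if expected < 2 * MIN_CHAIN_LENGTH:
                raise ValueError(
                    f"expected retained gene count {expected:.1f} after WGD at "
                    f"Ks={ev.target_ks} is below 2 x minimum chain length "
                    f"({2 * MIN_CHAIN_LENGTH}); chains would be undetectable"
                )


@dataclass(frozen=True)
class TruthRecord:
    gene_a: str
    gene_b: str
    true_mechanism: str  # "WGD" | "tandem"
    true_ks: float
    wgd_index: int | None = None


@dataclass
class GeneRecord:
    gene: str
    chromosome: str
    ordinal_index: int
    start_bp: int
    strand: str
    family: str


@dataclass
class GenomeBundle:
    """In-memory genome artifact set; ``write`` emits the on-disk formats."""

    genes: list[GeneRecord]
    cds: dict[str, str]
    proteins: dict[str, str]
    families: dict[str, str]
    go_annotations: dict[str, tuple[str, ...]]
    truth: list[TruthRecord] = field(default_factory=list)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "cds": outdir / "genome.cds.fna",
            "proteins": outdir / "genome.proteins.faa",
            "coords_tsv": outdir / "genome.coords.tsv",
            "gff3": outdir / "genome.genes.gff3",
            "families": outdir / "genome.families.tsv",
            "go": outdir / "genome.go.tsv",
            "truth": outdir / "truth.tsv",
        }
        order = [g.gene for g in self.genes]
        with open(paths["cds"], "w") as fh:
            for g in order:
                if g in self.cds:
                    fh.write(f">{g}\n{self.cds[g]}\n")
        with open(paths["proteins"], "w") as fh:
            for g in order:
                if g in self.proteins:
                    fh.write(f">{g}\n{self.proteins[g]}\n")
        with open(paths["coords_tsv"], "w") as fh:
            fh.write("gene\tchromosome\tordinal_index\tstart_bp\tstrand\n")
            for rec in self.genes:
                fh.write(
                    f"{rec.gene}\t{rec.chromosome}\t{rec.ordinal_index}\t{rec.start_bp}\t{rec.strand}\n"
                )
        with open(paths["gff3"], "w") as fh:
            fh.write("##gff-version 3\n")
            for rec in self.genes:
                length = len(self.cds.get(rec.gene, "")) or 300
                end = rec.start_bp + max(length, 1) - 1
                fh.write(
                    f"{rec.chromosome}\tpaleodup\tgene\t{rec.start_bp}\t{end}\t.\t{rec.strand}\t.\tID={rec.gene}\n"
                )
        with open(paths["families"], "w") as fh:
            for rec in self.genes:
                fh.write(f"{rec.gene}\t{rec.family}\n")
        with open(paths["go"], "w") as fh:
            for rec in self.genes:
                for term in self.go_annotations.get(rec.gene, ()):
                    fh.write(f"{rec.gene}\t{term}\n")
        with open(paths["truth"], "w") as fh:
            fh.write("gene_a\tgene_b\ttrue_mechanism\ttrue_Ks\twgd_index\n")
            for t in self.truth:
                w = "" if t.wgd_index is None else str(t.wgd_index)
                fh.write(f"{t.gene_a}\t{t.gene_b}\t{t.true_mechanism}\t{t.true_ks:.6f}\t{w}\n")
        return paths


def evolve_codon_pair(
    ancestor_cds: str,
    target_ks: float,
    kappa: float,
    omega: float,
    rng: np.random.Generator,
    evolver: CodonEvolver | None = None,
) -> tuple[str, str]:
    """Evolve an ancestral CDS down two branches whose summed expected
    synonymous divergence equals ``target_ks``; returns the two descendants.
    """
    from ._codon import cds_to_codon_indices

    if target_ks < 0:
        raise ValueError("target_ks must be >= 0")
    idx = cds_to_codon_indices(ancestor_cds, "ancestor")
    if target_ks == 0:
        return ancestor_cds, ancestor_cds
    if evolver is None or evolver.kappa != kappa or evolver.omega != omega:
        evolver = CodonEvolver(kappa, omega)
    half = target_ks / 2.0
    a = evolver.evolve(idx, half, rng)
    b = evolver.evolve(idx, half, rng)
    return indices_to_cds(a), indices_to_cds(b)


# ---------------------------------------------------------------------------

def _jitter(rng: np.random.Generator, sd: float) -> float:
    if sd <= 0:
        return 1.0
    return float(np.exp(rng.normal(-0.5 * sd * sd, sd)))


def simulate_genome(
    config: SimConfig, with_sequences: bool = True
) -> tuple[GenomeBundle, list[TruthRecord]]:
    """Generate a genome bundle plus its truth table.

    ``with_sequences=False`` skips codon evolution (empty CDS/protein maps)
    for structure-only experiments; everything else is identical.
    """
    rng = np.random.default_rng(config.seed)

    # --- ancestral layout ------------------------------------------------
    n = config.n_ancestral_genes
    per_chrom = np.full(config.n_chromosomes, n // config.n_chromosomes)
    per_chrom[: n % config.n_chromosomes] += 1
    chromosomes: list[list[str]] = []
    gene_meta: dict[str, dict] = {}
    gid = 0
    for ci, count in enumerate(per_chrom):
        chrom = []
        for _ in range(count):
            gid += 1
            name = f"g{gid:05d}"
            chrom.append(name)
            gene_meta[name] = {
                "family": f"fam{gid:05d}",
                "strand": "+" if rng.random() < 0.5 else "-",
                "go": tuple(
                    term for term, frac in config.go_terms if rng.random() < frac
                ),
            }
        chromosomes.append(chrom)

    # --- WGD events (oldest first) ---------------------------------------
    # parent_info[copy] = (source, realized split age, mechanism, wgd index,
    # nominal age); realized ages drive sequence divergence, nominal ages
    # are what the truth table reports.
    parent_info: dict[str, tuple[str, float, str, int | None, float]] = {}
    events = sorted(enumerate(config.wgd_events), key=lambda kv: -kv[1].target_ks)
    copy_counter = 0
    for event_idx, ev in events:
        new_chromosomes = []
        for ci, chrom in enumerate(list(chromosomes)):
            retained = []
            for gene in chrom:
                meta = gene_meta[gene]
                biased = ev.biased_go_term is not None and ev.biased_go_term in meta["go"]
                p = ev.retention_prob_biased if biased else ev.retention_prob_baseline
                if rng.random() >= p:
                    continue
                copy_counter += 1
                copy = f"{gene}w{copy_counter}"
                gene_meta[copy] = {
                    "family": meta["family"],
                    "strand": meta["strand"],
                    "go": meta["go"],
                }
                retained.append(copy)
                age = ev.target_ks * _jitter(rng, config.ks_jitter_sd)
                parent_info[copy] = (gene, age, "WGD", event_idx, ev.target_ks)
            if retained:
                new_chromosomes.append(retained)
        chromosomes.extend(new_chromosomes)

    # --- tandem duplications ---------------------------------------------
    tandem_events: list[tuple[str, str, float]] = []
    for chrom in chromosomes:
        for gene in list(chrom):
            meta = gene_meta[gene]
            rate = config.tandem_rate
            if (
                config.tandem_rate_biased is not None
                and config.wgd_events
                and config.wgd_events[0].biased_go_term in meta["go"]
            ):
                rate = config.tandem_rate_biased
            n_dup = rng.poisson(rate)
            for _ in range(min(n_dup, 3)):
                copy_counter += 1
                copy = f"{gene}t{copy_counter}"
                gene_meta[copy] = {
                    "family": meta["family"],
                    "strand": meta["strand"],
                    "go": meta["go"],
                }
                age = float(rng.uniform(0.0, config.tandem_target_ks_max))
                age = max(age, 1e-3)
                tandem_events.append((gene, copy, age))
    # insert copies 0-2 genes away from their source
    for source, copy, age in tandem_events:
        for chrom in chromosomes:
            if source in chrom:
                pos = chrom.index(source)
                offset = int(rng.integers(0, 3))
                chrom.insert(min(pos + 1 + offset, len(chrom)), copy)
                break
        parent_info[copy] = (source, age, "tandem", None, age)

    # --- coordinates ------------------------------------------------------
    genes: list[GeneRecord] = []
    for ci, chrom in enumerate(chromosomes):
        cname = f"chr{ci + 1}"
        for rank, gene in enumerate(chrom, start=1):
            genes.append(
                GeneRecord(
                    gene=gene,
                    chromosome=cname,
                    ordinal_index=rank,
                    start_bp=1 + (rank - 1) * 2000,
                    strand=gene_meta[gene]["strand"],
                    family=gene_meta[gene]["family"],
                )
            )

    families = {g.gene: g.family for g in genes}
    go_annotations = {g.gene: gene_meta[g.gene]["go"] for g in genes}

    # --- sequences --------------------------------------------------------
    cds: dict[str, str] = {}
    proteins: dict[str, str] = {}
    if with_sequences:
        evolver = CodonEvolver(config.kappa, config.omega)
        lo, hi = config.codon_length_range
        children: dict[str, list[tuple[str, float]]] = {}
        for child, (src, age, _, _, _) in parent_info.items():
            children.setdefault(src, []).append((child, age))
        for src in children:  # oldest split first along the lineage
            children[src].sort(key=lambda t: (-t[1], t[0]))
        final: dict[str, np.ndarray] = {}

        def develop(gene: str, seq: np.ndarray, remaining: float) -> None:
            # seq = this lineage's state `remaining` half-Ks units before present;
            # each split at pair-age a leaves a/2 on both sides.
            for child, age in children.get(gene, ()):  # noqa: B023
                r_child = age / 2.0
                step = max(remaining - r_child, 0.0)
                if step > 0:
                    seq = evolver.evolve(seq, step, rng)
                remaining = min(remaining, r_child)
                develop(child, seq, r_child)
            if remaining > 0:
                seq = evolver.evolve(seq, remaining, rng)
            final[gene] = seq

        roots = [g.gene for g in genes if g.gene not in parent_info]
        for root in roots:
            length = int(rng.integers(lo, hi + 1))
            seq0 = rng.integers(0, N_SENSE, size=length)
            first = children.get(root)
            develop(root, seq0, first[0][1] / 2.0 if first else 0.0)
        for g in genes:
            cds[g.gene] = indices_to_cds(final[g.gene])
            proteins[g.gene] = translate_indices(final[g.gene])

    # truth = one record per duplication event (copy vs its source lineage);
    # pairs related only through deeper shared history (e.g. a tandem copy
    # vs its source's WGD partner) are intentionally absent
    truth = [
        TruthRecord(*sorted((child, src)), mech, nominal, widx)
        for child, (src, _, mech, widx, nominal) in parent_info.items()
    ]
    truth_sorted = sorted(truth, key=lambda t: (t.gene_a, t.gene_b))
    bundle = GenomeBundle(
        genes=genes,
        cds=cds,
        proteins=proteins,
        families=families,
        go_annotations=go_annotations,
        truth=truth_sorted,
    )
    return bundle, truth_sorted
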