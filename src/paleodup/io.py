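"""Readers and writers for the plain-text formats passed between stages."""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

from .divergence import KsEstimate
from .homology import CandidatePair, HomologyHit
from .mechanism import GeneCoordinate, MechanismLabel, SyntenyChain
from .pairing import LabelledPair, RepresentativePair


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_two_column_tsv(path: str | Path) -> dict[str, str]:
    """gene -> value map (family table); later rows win on duplicates."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            out[row[0]] = row[1]
    return out


def read_go_tsv(path: str | Path) -> dict[str, tuple[str, ...]]:
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            out.setdefault(row[0], []).append(row[1])
    return {g: tuple(ts) for g, ts in out.items()}


def read_coordinates(path: str | Path) -> dict[str, GeneCoordinate]:
    """Gene coordinates from the 5-column TSV or from GFF3 (type=gene,
    ordinal index assigned by start position per chromosome)."""
    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3"}:
        return _read_gff3(path)
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "chromosome", "ordinal_index", "start_bp", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing coordinate columns {sorted(missing)}")
    return {
        r.gene: GeneCoordinate(
            gene=r.gene,
            chromosome=str(r.chromosome),
            ordinal_index=int(r.ordinal_index),
            start_bp=int(r.start_bp),
            strand=str(r.strand),
        )
        for r in df.itertuples()
    }


def _read_gff3(path: Path) -> dict[str, GeneCoordinate]:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            gene = attrs.get("ID") or attrs.get("Name")
            if gene is None:
                continue
            rows.append((f[0], int(f[3]), gene, f[6]))
    coords: dict[str, GeneCoordinate] = {}
    by_chrom: dict[str, list] = {}
    for chrom, start, gene, strand in rows:
        by_chrom.setdefault(chrom, []).append((start, gene, strand))
    for chrom, lst in by_chrom.items():
        for rank, (start, gene, strand) in enumerate(sorted(lst), start=1):
            coords[gene] = GeneCoordinate(gene, chrom, rank, start, strand)
    return coords


# --- stage tables ----------------------------------------------------------

def write_pairs_tsv(pairs: Iterable[CandidatePair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "gene_a\tgene_b\tfamily\tpident\tlength\tmismatch\tgapopen\tevalue\tbitscore\n"
        )
        for p in pairs:
            h = p.source_hit
            fh.write(
                f"{p.gene_a}\t{p.gene_b}\t{p.family}\t{h.percent_identity}\t"
                f"{h.alignment_length}\t{h.mismatches}\t{h.gap_opens}\t{h.evalue:.3g}\t{h.bitscore}\n"
            )


def read_pairs_tsv(path: str | Path) -> list[CandidatePair]:
    df = pd.read_csv(path, sep="\t")
    return [
        CandidatePair(
            gene_a=r.gene_a,
            gene_b=r.gene_b,
            family=r.family,
            source_hit=HomologyHit(
                query=r.gene_a,
                subject=r.gene_b,
                percent_identity=float(r.pident),
                alignment_length=int(r.length),
                mismatches=int(r.mismatch),
                gap_opens=int(r.gapopen),
                evalue=float(r.evalue),
                bitscore=float(r.bitscore),
            ),
        )
        for r in df.itertuples()
    ]


def write_labels_tsv(labels: Iterable[MechanismLabel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tlabel\tchain_id\n")
        for m in labels:
            cid = "NA" if m.chain_id is None else str(m.chain_id)
            fh.write(f"{m.gene_a}\t{m.gene_b}\t{m.label}\t{cid}\n")


def read_labels_tsv(path: str | Path) -> list[MechanismLabel]:
    df = pd.read_csv(path, sep="\t", dtype={"chain_id": str}, keep_default_na=False)
    return [
        MechanismLabel(
            r.gene_a,
            r.gene_b,
            r.label,
            None if r.chain_id in ("NA", "") else int(r.chain_id),
        )
        for r in df.itertuples()
    ]


def write_chains_tsv(chains: Iterable[SyntenyChain], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "chain_id\torientation\ttotal_score\tgene_a\tgene_b\tchrom_a\tchrom_b\tidx_a\tidx_b\n"
        )
        for cid, c in enumerate(chains):
            for a in c.anchors:
                fh.write(
                    f"{cid}\t{c.orientation}\t{c.total_score:.2f}\t{a.gene_a}\t{a.gene_b}\t"
                    f"{a.chrom_a}\t{a.chrom_b}\t{a.idx_a}\t{a.idx_b}\n"
                )


def write_ks_tsv(estimates: Iterable[KsEstimate], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tKs\tKa\tSE\tkappa_hat\tn_codons\tmethod\tflags\n")
        for e in estimates:
            flags = ",".join(e.flags) if e.flags else "."
            fh.write(
                f"{e.gene_a}\t{e.gene_b}\t{e.ks:.6f}\t{e.ka:.6f}\t{e.se:.6f}\t"
                f"{e.kappa_hat:.4f}\t{e.n_codons}\t{e.method}\t{flags}\n"
            )


def read_ks_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_representative_tsv(pairs: Iterable[RepresentativePair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tlabel\tKs\trule\n")
        for p in pairs:
            fh.write(f"{p.gene_a}\t{p.gene_b}\t{p.label}\t{p.ks:.6f}\t{p.selected_by_rule}\n")


def read_representative_tsv(path: str | Path) -> list[RepresentativePair]:
    df = pd.read_csv(path, sep="\t")
    return [
        RepresentativePair(r.gene_a, r.gene_b, r.label, float(r.Ks), r.rule)
        for r in df.itertuples()
    ]


def read_labelled_with_ks(labels_path: str | Path, ks_path: str | Path) -> list[LabelledPair]:
    """Join the mechanism labels with the filtered Ks table."""
    labels = {(m.gene_a, m.gene_b): m.label for m in read_labels_tsv(labels_path)}
    out = []
    for r in read_ks_tsv(ks_path).itertuples():
        label = labels.get((r.gene_a, r.gene_b))
        if label is None:
            continue
        out.append(LabelledPair(r.gene_a, r.gene_b, label, float(r.Ks)))
    return out
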