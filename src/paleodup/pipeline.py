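"""End-to-end orchestration with plain-file handoffs between stages.

Stages run in order homology -> mechanism -> divergence -> pairing ->
age statistics -> enrichment; each stage reads and writes files under the
output directory so a run can resume from any completed stage.  A summary
row (gene count, pair counts by mechanism and by Ks range) and a manifest
of the effective configuration are emitted per run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from . import age_stats, enrichment, io
from .divergence import codon_align, estimate_ks, filter_estimates
from .homology import FilterThresholds, align_all_vs_all, build_candidate_pairs, filter_hits, parse_hits
from .mechanism import ChainParams, TANDEM, UNDEFINED, WGD, build_anchors, classify_mechanism, find_chains
from .pairing import select_pairs

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "GenomeSummary", "run_pipeline", "default_obo_path"]


def default_obo_path() -> Path:
    """Packaged minimal ontology fixture."""
    return Path(resources.files("paleodup") / "data" / "minimal_go.obo")


@dataclass
class RunConfig:
    proteins: str
    cds: str
    coords: str
    families: str
    go: str | None = None
    obo: str | None = None
    hits: str | None = None  # precomputed 12-column tabular hits
    out_dir: str = "paleodup_out"
    # homology thresholds (printed defaults)
    max_evalue: float = 1e-20
    min_identity: float = 50.0
    min_aln_bp: int = 300
    max_mismatches: int = 550
    max_gap_opens: int = 30
    aln_units: str = "aa"
    # mechanism
    max_intervening: int = 10
    min_anchors: int = 5
    chain_gap_penalty: float = 1.0
    chain_max_gap: int = 20
    # divergence
    ks_method: str = "YN00"
    max_ks: float = 2.0
    max_se: float = 0.5
    min_codons: int = 30
    # age stats
    bin_width: float = 0.05
    h_range: tuple[float, float] = (0.05, 5.0)
    gof_bootstraps: int = 200
    # enrichment
    min_set: int = 10
    # misc
    seed: int = 0
    resume: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "h_range" in raw:
            raw["h_range"] = tuple(raw["h_range"])
        return cls(**raw)

    def to_manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["h_range"] = list(d["h_range"])
        return d


@dataclass
class GenomeSummary:
    initial_gene_count: int
    duplicate_pair_count: int
    mechanism_counts: dict = field(default_factory=dict)
    ks_range_counts: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage_done(path: Path, resume: bool) -> bool:
    return resume and path.exists()


def run_pipeline(config: RunConfig) -> GenomeSummary:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "manifest.json", "w") as fh:
        json.dump(config.to_manifest(), fh, indent=2, sort_keys=True)

    proteins = io.read_fasta(config.proteins)
    families = io.read_two_column_tsv(config.families)
    coords = io.read_coordinates(config.coords)

    # --- homology ---------------------------------------------------------
    pairs_path = out / "pairs.tsv"
    if not _stage_done(pairs_path, config.resume):
        try:
            if config.hits:
                with open(config.hits) as fh:
                    hits = parse_hits(fh)
            else:
                hits = align_all_vs_all(proteins, families=families)
            thresholds = FilterThresholds(
                max_evalue=config.max_evalue,
                min_identity=config.min_identity,
                min_aln_bp=config.min_aln_bp,
                max_mismatches=config.max_mismatches,
                max_gap_opens=config.max_gap_opens,
                aln_units=config.aln_units,
            )
            kept = filter_hits(hits, thresholds)
            pairs = build_candidate_pairs(kept, families)
            io.write_pairs_tsv(pairs, pairs_path)
            logger.info("homology: %d hits -> %d filtered -> %d pairs", len(hits), len(kept), len(pairs))
        except Exception as exc:
            raise RuntimeError(f"stage homology failed: {exc}") from exc
    pairs = io.read_pairs_tsv(pairs_path)

    # --- mechanism --------------------------------------------------------
    labels_path = out / "labels.tsv"
    if not _stage_done(labels_path, config.resume):
        try:
            params = ChainParams(
                gap_penalty=config.chain_gap_penalty,
                max_gap=config.chain_max_gap,
                min_anchors=config.min_anchors,
                tandem_window=config.max_intervening,
            )
            anchors, _ = build_anchors(pairs, coords)
            chains = find_chains(anchors, params)
            labels = classify_mechanism(pairs, chains, coords, config.max_intervening)
            io.write_chains_tsv(chains, out / "chains.tsv")
            io.write_labels_tsv(labels, labels_path)
        except Exception as exc:
            raise RuntimeError(f"stage mechanism failed: {exc}") from exc

    # --- divergence -------------------------------------------------------
    ks_all_path = out / "ks_all.tsv"
    ks_path = out / "ks.tsv"
    if not _stage_done(ks_path, config.resume):
        try:
            cds = io.read_fasta(config.cds)
            estimates = []
            for p in pairs:
                if p.gene_a not in cds or p.gene_b not in cds:
                    logger.warning("missing CDS for pair (%s, %s)", p.gene_a, p.gene_b)
                    continue
                aln = codon_align(cds[p.gene_a], cds[p.gene_b], p.gene_a, p.gene_b)
                if aln.n_codons_used < config.min_codons:
                    continue
                estimates.append(estimate_ks(aln, config.ks_method, config.min_codons))
            io.write_ks_tsv(estimates, ks_all_path)
            kept, dropped = filter_estimates(estimates, config.max_ks, config.max_se)
            io.write_ks_tsv(kept, ks_path)
            logger.info("divergence: %d estimates, dropped %s", len(estimates), dropped)
        except Exception as exc:
            raise RuntimeError(f"stage divergence failed: {exc}") from exc

    # --- pairing ----------------------------------------------------------
    rep_path = out / "representative.tsv"
    if not _stage_done(rep_path, config.resume):
        try:
            labelled = io.read_labelled_with_ks(labels_path, ks_path)
            reps = select_pairs(labelled)
            io.write_representative_tsv(reps, rep_path)
        except Exception as exc:
            raise RuntimeError(f"stage pairing failed: {exc}") from exc
    reps = io.read_representative_tsv(rep_path)

    # --- age statistics ---------------------------------------------------
    try:
        rng = np.random.default_rng(config.seed)
        gof_out = {}
        for subset in ("all", "WGD", "tandem"):
            if subset == "all":
                vals = [p.ks for p in reps if 0 < p.ks <= config.max_ks]
            else:
                vals = [p.ks for p in reps if p.label == subset and 0 < p.ks <= config.max_ks]
            if not vals:
                continue
            hist = age_stats.build_histogram(vals, config.bin_width, subset, config.max_ks)
            _write_histogram(hist, out / f"hist_{subset}.tsv")
            if len(vals) >= 50:
                smap = age_stats.sizer_map(vals, h_range=config.h_range, bin_width=config.bin_width)
                _write_sizer(smap, out / f"sizer_{subset}.tsv")
            if len(vals) >= 30 and min(vals) < max(vals):
                res = age_stats.ks_gof_test(vals, config.gof_bootstraps, rng)
                gof_out[subset] = {
                    "D": res.d, "p_value": res.p_value, "rate": res.rate, "n": res.n,
                }
        with open(out / "gof.json", "w") as fh:
            json.dump(gof_out, fh, indent=2)
    except Exception as exc:
        raise RuntimeError(f"stage age_stats failed: {exc}") from exc

    # --- enrichment -------------------------------------------------------
    if config.go:
        try:
            annotations = io.read_go_tsv(config.go)
            obo = config.obo or default_obo_path()
            with open(obo) as fh:
                ontology = enrichment.parse_obo(fh)
            annotations = enrichment.propagate_annotations(annotations, ontology)
            groups = enrichment.build_groups(reps)
            background = frozenset(g for p in reps for g in (p.gene_a, p.gene_b))
            all_results = []
            for grp in groups:
                res = enrichment.ora_test(
                    grp,
                    background,
                    annotations,
                    min_set=config.min_set,
                    exclude_terms=ontology.roots(),
                )
                all_results.extend(res)
            _write_enrichment(all_results, out / "enrichment.tsv")
            _write_heatmap_table(all_results, out / "enrichment_matrix.tsv")
        except Exception as exc:
            raise RuntimeError(f"stage enrichment failed: {exc}") from exc

    # --- summary ----------------------------------------------------------
    mech_counts = {WGD: 0, TANDEM: 0, UNDEFINED: 0}
    for m in io.read_labels_tsv(labels_path):
        mech_counts[m.label] += 1
    ks_ranges = {"(0,0.5]": 0, "(0.5,1]": 0, "(1,1.5]": 0, "(1.5,2]": 0, ">2": 0}
    for r in io.read_ks_tsv(ks_all_path).itertuples():
        ks = float(r.Ks)
        if math.isnan(ks) or ks > 2:
            ks_ranges[">2"] += 1
        elif ks <= 0.5:
            ks_ranges["(0,0.5]"] += 1
        elif ks <= 1.0:
            ks_ranges["(0.5,1]"] += 1
        elif ks <= 1.5:
            ks_ranges["(1,1.5]"] += 1
        else:
            ks_ranges["(1.5,2]"] += 1
    summary = GenomeSummary(
        initial_gene_count=len(proteins),
        duplicate_pair_count=len(pairs),
        mechanism_counts=mech_counts,
        ks_range_counts=ks_ranges,
    )
    with open(out / "summary.json", "w") as fh:
        json.dump(summary.to_dict(), fh, indent=2, sort_keys=True)
    return summary


def _write_histogram(hist: age_stats.KsHistogram, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("bin_low\tbin_high\tcount\n")
        for lo, hi, c in zip(hist.bin_edges[:-1], hist.bin_edges[1:], hist.counts):
            fh.write(f"{lo:.4f}\t{hi:.4f}\t{c}\n")


def _write_sizer(smap: age_stats.SiZerMap, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("h\\x\t" + "\t".join(f"{x:.4f}" for x in smap.x) + "\n")
        for h, row in zip(smap.h, smap.states):
            fh.write(f"{h:.4f}\t" + "\t".join(row) + "\n")


def _write_enrichment(results, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("group\tterm\tk\tn\tK\tN\traw_p\tcorrected_p\tdirection\n")
        for r in results:
            fh.write(
                f"{r.group}\t{r.term}\t{r.k}\t{r.n}\t{r.K}\t{r.N}\t"
                f"{r.raw_p:.4g}\t{r.corrected_p:.4g}\t{r.direction}\n"
            )


def _write_heatmap_table(results, path: Path) -> None:
    """term x group corrected-p matrix (tabular twin of the heat maps)."""
    groups = sorted({r.group for r in results})
    terms = sorted({r.term for r in results})
    lookup = {(r.term, r.group): r.corrected_p for r in results}
    with open(path, "w") as fh:
        fh.write("term\t" + "\t".join(groups) + "\n")
        for t in terms:
            cells = [
                f"{lookup[(t, g)]:.4g}" if (t, g) in lookup else "NA" for g in groups
            ]
            fh.write(t + "\t" + "\t".join(cells) + "\n")
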