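# paleodup

Analysis pipeline for duplicate-gene retention in plant genomes: detect
paralog pairs from all-vs-all protein similarity, classify each pair's
duplication mechanism (whole-genome duplication vs tandem vs undefined)
from gene order, date pairs by synonymous divergence (Ks), and test for
biased functional retention by mechanism and by age — plus a
synthetic-genome simulator with known duplication history that makes
every stage verifiable without external data.

## Stages

| stage       | what it does |
|-------------|--------------|
| `simulate`  | synthetic multi-chromosome genomes: WGDs at chosen Ks depths with (optionally GO-biased) Bernoulli retention, tandem arrays, codon sequences evolved to target divergence, ground-truth pair table |
| `homology`  | all-vs-all protein hits (internal BLOSUM62 aligner or BLAST outfmt-6 input), the five printed filters (e-value ≤ 1e-20, identity ≥ 50%, alignment > 300 bp, mismatches < 550, gap opens < 30), self-hit removal, same-family constraint |
| `mechanism` | collinear-chain dynamic programming in gene-rank space → WGD labels; ≤ 10 intervening genes on one chromosome → tandem; the rest undefined |
| `ks`        | protein-guided codon alignment; Ks/Ka with SE by a transition/transversion-aware counting estimator (`yn00` flavour) or NG86; retention filter Ks ≤ 2, SE < 0.5 |
| `pair`      | per-gene representative-pair selection with precedence WGD > tandem > undefined, lowest Ks within the winning class |
| `agestats`  | Ks histograms, goodness of fit against a constant birth–death null (truncated exponential, parametric bootstrap), slope-significance (SiZer-style) maps over a bandwidth grid |
| `enrich`    | GO over-representation of the eight paralog groups (WGD, tandem, Ks ranges A–F) with ontology propagation, min set size 10, BH correction |

## CLI

Each stage is a subcommand; `run` chains everything from a YAML config.

```sh
paleodup simulate --config sim.yaml --out bundle/
paleodup homology --proteins bundle/genome.proteins.faa \
    --families bundle/genome.families.tsv --out pairs.tsv
paleodup mechanism --pairs pairs.tsv --coords bundle/genome.genes.gff3 \
    --out labels.tsv --max-intervening 10 --min-anchors 5
paleodup ks --cds bundle/genome.cds.fna --pairs pairs.tsv --out ks.tsv
paleodup pair --labels labels.tsv --ks ks.tsv --out rep.tsv
paleodup agestats --pairs rep.tsv --subset wgd
paleodup enrich --pairs rep.tsv --go bundle/genome.go.tsv --out enrich.tsv
paleodup run --config run.yaml          # end-to-end, resumable with --resume
```

A `run.yaml` needs `proteins`, `cds`, `coords`, `families` paths (plus
optional `go`, `obo`, `hits`, and any threshold overrides); every
threshold defaults to the values above. Precomputed BLAST tabular hits
(outfmt 6) are accepted via `hits:` / `--hits` so real-data runs can use
real BLAST; the internal aligner exists so the test suite needs no
external binaries.

## Layout

```
src/paleodup/
  simulate.py    synthetic genomes + ground truth
  homology.py    hit parsing, filtering, candidate pairs, internal aligner
  mechanism.py   anchor chaining DP and mechanism labels
  divergence.py  codon alignment, Ks/Ka estimators, retention filter
  pairing.py     representative-pair rules
  age_stats.py   histograms, birth–death GoF, slope-significance maps
  enrichment.py  OBO parsing, annotation propagation, ORA, paralog groups
  pipeline.py    end-to-end orchestration, summary, manifest
  cli.py         click CLI
  data/          minimal GO ontology fixture
```
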