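# spongescan

Infer condition-specific circRNA–miRNA–mRNA sponge mechanisms from
multi-level transcript expression data. Given log-transformed expression
matrices (circRNA, mRNA, optionally miRNA), a two-condition sample
annotation, per-binding-site predicted miRNA–target interaction tables and
circRNA spliced lengths, spongescan ranks every candidate (miRNA, circRNA)
pair by a multi-criteria sponge score and exports interpretable
circRNA–miRNA–mRNA subnetworks.

## Method outline

1. **miRNA sufficiency filter** — keep miRNAs with nonzero total expression
   that exceed the pooled first-quartile cutoff in strictly more than 90% of
   samples (skipped when a pre-filtered miRNA signature replaces the matrix).
2. **Interaction reliability** — per (miRNA, target) pair: collapse binding
   sites keeping the strongest context score (lower = stronger, TargetScan
   convention); calibrate an affinity cutoff as the 95th percentile of scores
   restricted to validated pairs with ≥2 CLIP-seq and ≥2 degradome-seq
   supports; min–max rescale affinities to [0, 1]; normalize circRNA site
   counts by spliced length; test per-miRNA site enrichment on each circRNA
   with an upper-tail binomial model, BH-adjusted, keeping adjusted p < 0.05.
3. **Expression criteria** — log2 fold change (condition_2 − condition_1),
   per-miRNA median expression, and the larger per-condition mean per target.
4. **Prerequisites** — a candidate pair needs a kept miRNA, a differentially
   directed circRNA, and ≥1 mRNA target co-directional with the circRNA.
5. **Scoring** — TOPSIS over all eligible miRNA–mRNA pairs gives SG; a
   preranked weighted-KS enrichment test (permutation p, exact enumeration at
   small sizes) asks whether each miRNA's pairs concentrate at the top of the
   SG ranking; TOPSIS over all eligible miRNA–circRNA pairs (five benefit
   criteria, two adjusted enrichment p-values as cost) gives the sponge score
   SS, ranked globally and within each condition into a 16-column matrix.
6. **Networks & enrichment** — star subnetworks around a selected
   interaction (top 10% of SG-ranked mRNA targets, minimum 1), exported as
   GraphML/JSON; local hypergeometric over-representation analysis against
   user-supplied GMT gene-set files.

A seeded synthetic-fixture generator with planted sponge mechanisms makes the
whole pipeline testable without external downloads.

## CLI

```bash
# generate a synthetic bundle with one planted mechanism
spongescan simulate --out fixture/ --seed 1

# run the pipeline (YAML config holds paths and parameters)
spongescan run --config cfg.yaml --out matrix.csv --sg-out sg.csv

# export the subnetwork around the top-ranked pair
spongescan network --matrix matrix.csv --sg sg.csv \
    --select "hsa-miR-100-5p,hsa_circ_0000001" --format json --out net.json

# gene-set over-representation for a list of symbols
spongescan enrich --genes GENE0001,GENE0002 --gmt sets.gmt --out enrich.csv
```

Minimal `cfg.yaml`:

```yaml
paths:
  circ_expr: fixture/circ_expression.csv
  mrna_expr: fixture/mrna_expression.csv
  mirna_expr: fixture/mirna_expression.csv   # or mirna_signature: sig.csv
  annotation: fixture/annotation.csv
  circ_sites: fixture/circ_sites.csv
  mrna_sites: fixture/mrna_sites.csv
  circ_lengths: fixture/circ_lengths.csv
  validated: fixture/validated.csv           # optional, enables the cutoff
seed: 1
nperm: 10000
```

Exit codes: 0 success, 2 validation error, 3 empty result (the error names
the stage that emptied the candidate set).

## Input formats

All CSV, UTF-8, header row required. Expression files: first column =
feature id, remaining columns = samples. Annotation: columns `samples`,
`conditions` with values `condition_1` (control) / `condition_2`, ≥3 samples
each. Site tables: columns `mirna_id`, `target_id`, `target_type`,
`raw_score`, `site_index` (one row per predicted binding site; more negative
scores = stronger). Lengths: `circ_id`, `length`. Validated interactions:
`mirna_id`, `circ_id`, `n_clipseq`, `n_degradome`. Identifiers are checked:
circRNAs `hsa_circ_` + 7 digits (the common `has_circ_` typo is
auto-corrected with a warning), miRNAs `hsa-miR-*`/`hsa-let-*`, mRNAs
non-empty official gene symbols. Gene sets: standard GMT.

## Tests

```bash
python -m pytest tests/ -q
```

The suite includes unit tests per module, property tests (hypothesis), and
`tests/test_acceptance.py` which checks the implementation against
independent oracles (step-by-step TOPSIS reference, exact binomial pmf
summation, exhaustive GSEA permutation enumeration, hypergeometric tail
counting), plus a 20-seed planted-mechanism recovery experiment and a
bit-for-bit determinism snapshot.

`scripts/acceptance.py --seed 1 --out results/acceptance.json` runs a seeded
end-to-end sanity check; there are no numeric acceptance targets (the
published case-study figures require external cohort data), so the JSON is
an empty map.
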