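# cernaforge

Circular RNAs (circRNAs) sequester shared microRNAs — the "sponge" effect —
and thereby de-repress those microRNAs' mRNA targets. In plasma case/control
transcriptomics this competing-endogenous-RNA (ceRNA) logic turns three
expression matrices and two circRNA caller outputs into a candidate
regulatory network: which down-regulated circRNAs stopped absorbing which
up-regulated miRNAs, releasing them onto which down-regulated mRNAs.

`cernaforge` is a tested, reusable implementation of that analysis for small
two-group RNA-seq studies (the motivating design is 10 cases vs 8 controls):

* **Consensus circRNA calling** — intersect two back-spliced-junction (BSJ)
  callers (find_circ and CIRCexplorer2 table layouts supported), keep
  junctions with ≥ 2 BSJ reads in a strict majority of samples, classify
  against gene models (protein_coding / sense_intronic / lncRNA /
  intergenic).
* **Quantification** — BSJ reads per million mapped reads ("BSJ-TPM"),
  global group-shift test, per-feature log₂ fold changes, and group-exclusive
  expression calls.
* **Differential expression** — a self-contained negative-binomial Wald test
  per feature: median-of-ratios size factors, Cox–Reid adjusted
  profile-likelihood dispersion, Wald statistic on the group coefficient
  referred to a t distribution; significant iff fold change > 1.5 and
  p < 0.05 (BH-adjusted p reported alongside).
* **Target prediction** — miRNA seed (positions 2–8) complementarity scan
  with G:U wobble, banded duplex extension, and nearest-neighbor free energy
  (Turner 2004 parameters) gated at ≤ −20 kcal/mol.
* **Network assembly** — edges between differentially expressed features
  filtered to inverse expression (one Up, one Down), assembled into
  circRNA–miRNA–mRNA triples through shared miRNAs, exported as edge-list
  TSV or GraphML.
* **Downstream** — hypergeometric gene-set enrichment (significant iff
  FDR < 0.05 and p < 0.01) and per-group circRNA–mRNA correlation-pattern
  comparison.
* **Synthetic studies** — `cernaforge simulate` generates a complete
  in-silico study with planted differential expression, exclusive circRNAs,
  caller dropout and miRNA response elements, with full ground truth, so the
  whole pipeline is testable offline.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

The repository packages the transcription of a published miRNA–circRNA pair
table (24 predicted pairs with duplex energies and site positions,
`src/cernaforge/data/table3.tsv`). Reproducing its network summary:

```python
from cernaforge.io_formats import load_table3
from cernaforge.cerna import edges_from_pair_table, inverse_filter, network_summary

edges = edges_from_pair_table(load_table3())
s = network_summary(edges)
print(f"pairs={s['n_pairs']}  miRNAs={s['n_distinct_mirna']}  "
      f"circRNAs={s['n_distinct_circ']}  opposite={s['pct_opposite']}%")

inv = network_summary(inverse_filter(edges))
print(f"inverse subset: {inv['n_pairs']} pairs, {inv['n_mirna_up']} Up miRNAs "
      f"-> {inv['n_partner_down']} Down circRNAs")
print("hsa-miR-16-5p degree:", inv['mirna_degree']['hsa-miR-16-5p'])
```

prints

```
pairs=24  miRNAs=10  circRNAs=16  opposite=58.3%
inverse subset: 14 pairs, 6 Up miRNAs -> 10 Down circRNAs
hsa-miR-16-5p degree: 4
```

i.e. 24 predicted circRNA–miRNA pairs over 10 miRNAs and 16 circRNAs, of
which 58.3% join one up- and one down-regulated feature; the
inverse-expression constraint leaves 6 up-regulated miRNAs targeting 10
down-regulated circRNAs, with hsa-miR-16-5p the most connected miRNA
(4 circRNAs).

## Command line

```bash
cernaforge simulate --seed 1 --out study/          # synthetic study bundle
cernaforge run --config study.yaml                 # full pipeline
# or stage by stage:
cernaforge circ --calls-a study/calls/find_circ --calls-b study/calls/circexplorer2 \
    --annotation study/gene_models.tsv --out consensus_counts.tsv
cernaforge de --counts study/mirna_counts.tsv --rna-class mirna \
    --groups study/groups.tsv --out de_mirna.tsv
cernaforge targets --mirnas mirna.fa --targets targets.fa \
    --energy-threshold -20 --out hits.tsv
```

`cernaforge run` writes every intermediate with a SHA-256 manifest; rerunning
on the same inputs reproduces identical checksums.

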