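# sigscreen

Signature-based screening for nuclear-receptor modulation in gene expression
compendia. The package implements, end to end:

1. **Differential expression** (`sigscreen.deg`) — per-gene two-group
   one-way ANOVA (pooled-variance t-test), Benjamini–Hochberg FDR control,
   and filtering into a *bioset* (a statistically filtered gene list with
   signed linear fold-changes).
2. **Knockout-anchored signature construction**
   (`sigscreen.signature_builder`) — from paired wild-type/receptor-null
   experiments over several chemicals, genes are kept only if they respond
   in wild-type but not (in the same direction) in null animals, differ
   between treated wild-type and treated null, agree in direction across
   chemicals, are supported by at least two chemicals, clear a 1.5-fold
   average magnitude floor, and are not claimed by an exclusion signature.
3. **Rank-based directional similarity** (`sigscreen.running_fisher`) — a
   fold-change rank-based scan that computes one-sided Fisher exact
   (hypergeometric) overlap p-values at successive cut depths of the
   bioset's up/down halves, corrects the best cut for the scan count,
   weighs concordant against discordant evidence, and combines the winning
   pairs by Fisher's method into a signed −log10 score.
4. **Compendium screening** (`sigscreen.screening`) — applies a signature
   across annotated biosets, calls activation/suppression at p ≤ 1e-4
   (a BH-derived cutoff is computed alongside), and tabulates calls by
   factor category and by target-gene concordance.
5. **Accuracy accounting** (`sigscreen.evaluation`) — confusion-matrix
   sensitivity/specificity/balanced accuracy on labeled bioset sets.
6. **Synthetic data** (`sigscreen.synthetic_data`) — fully seeded
   generators for knockout experiments with a planted receptor-dependent
   program (plus genotype-independent decoys) and for annotated
   activator/suppressor/null compendia with tunable signature overlap.

## CLI

```sh
# simulate paired wild-type/null experiments with known ground truth
sigscreen simulate ko --seed 1 --out ko/

# call DEGs for one contrast of a grouped matrix
sigscreen degs --matrix ko/chem1_matrix.tsv --groups ko/chem1_groups.tsv \
    --group-a wt_treated --group-b wt_ctrl --fdr 0.01 --out bioset.tsv

# derive a receptor-dependent signature from per-chemical stats tables
sigscreen build-signature --experiments experiments.yaml \
    --min-support 2 --min-fc 1.5 --out sig.gmt --out-fc sig_fc.tsv

# compare the signature to one bioset / screen a directory of biosets
sigscreen compare --signature sig.gmt --signature-fc sig_fc.tsv \
    --bioset bioset.tsv --json result.json
sigscreen simulate compendium --truth ko/truth.json --seed 2 --out comp/
sigscreen screen --signature sig.gmt --signature-fc sig_fc.tsv \
    --compendium comp/ --threshold 1e-4 --out table.tsv

# score the screen against truth labels
sigscreen evaluate --table table.tsv --truth truth_labels.tsv --out report.json
```

File formats are plain text throughout: GMT for signatures (with an
optional 2-column fold-change table), 3-column TSV or RNK for biosets
(`# universe=N` and metadata directives in the header), GCT 1.2 or TSV for
matrices, TSV for screen tables.

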