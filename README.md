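# fixcurate

Fixation-aware curation of plant single-cell RNA-seq, and detection of
tissue-specific and dual drought responses on the curated atlas.

Protoplast isolation — the enzymatic cell-wall digestion every plant
scRNA-seq experiment starts with — induces a strong stress transcriptome
that can mask the biology under study. Fixing the transcriptome with
actinomycin D during digestion suppresses the artifact, but some cells
escape fixation and still mount the digestion program. `fixcurate`
implements the full analysis around that problem, for researchers running
factorial bulk + single-cell designs on stressed plant tissue:

* **bulk_de** — median-of-ratios normalization, a minimal negative-binomial
  Wald test, a digestion × condition interaction likelihood-ratio test,
  Benjamini–Hochberg FDR, Z-scoring, and clustering of gene response
  profiles on Kendall-correlation distance;
* **signature** — the digestion-response gene signature (top 250 genes of
  the digestion-induced cluster after removing drought-responsive and
  interacting genes) plus the audit statistics: directional DEG counts,
  opposite-direction percentages across isolation methods, overlap
  enrichment, UpSet set decompositions;
* **cell_score** — single-cell QC, log-normalization, the per-cell module
  score with expression-matched binned control genes
  (score = mean signature expression − mean control expression), a
  Gaussian-mixture escape threshold, and atlas curation;
* **sc_response** — per-tissue Wilcoxon drought DE (p < 0.05, |log2FC| >
  0.75, ≥ 5% detection in the induced side), pseudobulk aggregation and DE,
  classification of mesophyll cells into the mutually exclusive
  canonical-ABA vs iron-starvation drought programs, coexpression
  exclusivity, and the marker filter for regulon-inference input;
* **simdata** — a negative-binomial simulator that plants all of the above
  structure (digestion/drought/interaction programs, escape cells, the dual
  programs on a latent drought gradient) with ground-truth labels, so every
  stage is testable without the original data.

The model-shaped pieces are scikit-learn-style estimators
(`KendallProfileClusterer`, `EscapeScorer`, `DualProgramClassifier`-style
`dual_program_detection`) with `fit`/`predict` and `get_params`; the
module-level functions are thin wrappers.

## Worked example

```python
from fixcurate import run_pipeline

report = run_pipeline(seed=1)
print(report["bulk"]["drought_degs_undigested"])   # {'up': 123, 'down': 69, 'total': 192}
print(report["bulk"]["opposite_in_digested"])      # {'n_opposite': 61, 'pct_opposite': 32}
print(report["bulk"]["opposite_in_fixed_digested"])# {'n_opposite': 17, 'pct_opposite': 9}
print(report["cells"]["pct_flagged"])              # 25
print(report["response"]["dual_program_counts"])   # {'canonical': 32, 'iron': 72, 'shared': 0, 'none': 77}
```

Reading the numbers: in the undigested bulk samples 192 genes respond to
mild drought (123 up, 69 down). Of those, 32% flip sign in digested
protoplasts but only 9% in fixed-digested ones — fixation preserves the
drought response that digestion scrambles. In the single-cell data 25% of
fixed-digested cells are flagged as having escaped fixation (24% were
planted) and removed; among the curated mild-drought mesophyll cells two
non-overlapping drought populations emerge, 32 cells expressing the
canonical ABA program and 72 the iron-starvation program.

The same pipeline is available from the shell:

```bash
fixcurate simulate --outdir data --seed 1
fixcurate bulk-de --counts data/bulk/bulk_counts.tsv --design data/bulk/bulk_design.tsv \
    --contrast MD:WW --within U --out de_drought_U.tsv
fixcurate score --cells data/cells --signature sig.txt --seed 1 --out flags.tsv
fixcurate curate --cells data/cells --flags flags.tsv --outdir curated
fixcurate run --seed 1 --outdir results/run1   # everything end to end
```

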