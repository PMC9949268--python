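# Methods

## The enhancement problem

A GWAS summary-statistics table gives each variant an effect size and a
p-value; loci are declared at genome-wide significance (p < 5×10⁻⁸).
Many true loci sit just under that line, and whether a borderline variant
is real correlates with things the single-variant test ignores: its LD
with already-significant variants, its minor allele frequency, and whether
it falls in regulatory sequence. The package learns that correlation
structure from a pair of studies of the same trait — the smaller supplies
the 33 input features, the larger supplies binary labels (significant /
not) — and then scores any study's variants with the trained network.

## Features

Order and composition are configuration (`deepgwas.schema.DEFAULT_SCHEMA`);
the default 33 columns are:

| group | features | notes |
|---|---|---|
| GWAS statistics | −log₁₀ p, OR | −log₁₀ p capped at 320 so underflowed p = 0 stays finite |
| population genetics | MAF, overall LD score, LD score with known variants | LD window 1 Mb; r² on genotype allele counts, pairwise-complete individuals |
| eQTL | 1 binary flag | union over sources, nominal p < 10⁻⁶ strictly |
| pathogenicity | phyloP, FATHMM-XF, CADD-PHRED | missing scores filled with 0 (or track median, configurable) |
| intervals | 2 open chromatin, 4 FIRE/super-FIRE, 1 selective sweep, 5 cCRE | 0-based half-open BED; 1-based position p overlaps [start, end) iff start < p ≤ end |
| meta-annotations | 11 | average-linkage clustering of epigenomic tracks on 1 − Jaccard, cut at 11 clusters, base-pair union within clusters |
| user slot | 1 | zeros unless supplied |

The **overall LD score** includes a self term (minimum 1, the standard
LD-score convention); the **known-variant LD score** counts the self term
iff the target itself is significant, so that setting "known = all panel
variants" reproduces the overall score exactly — a subset-consistency
identity the tests exploit as an oracle. The self term is a flag
(`include_self`, default on) because conventions differ.

Clustering sorts tracks by name before computing distances, making the
meta-annotations deterministic and invariant to input order.

## Network and training

*F* is a fully connected net: 33 inputs, hidden widths
256-256-128-128-128-64-64-64-32-32-16-8 (ReLU, dropout 0.1), one logistic
output — 14 layers counting input and output. The published description
fixes only the depth and the loss; widths, activation, optimizer and
schedule here are this package's choices, all exposed in `NetworkConfig` /
`TrainingHyper`. Training is minibatch Adam (lr 10⁻³, batch 128) on binary
cross entropy with probabilities clipped at ε = 10⁻¹²; a label-stratified
10 % split is held out, training stops after 20 epochs without validation
improvement, and the best-validation weights are restored. Batch size 128
(rather than a more conventional 512) is deliberate: after 10 : 1
under-sampling a genome's training set is only a few thousand rows, and
larger batches give the optimizer too few steps per epoch before early
stopping triggers, selecting an under-fit model.

Everything is NumPy: the backward pass is hand-derived and verified
against central finite differences (relative error ≤ 10⁻⁴) in the test
suite. Dropout is inverted (scaling at train time) and inactive at
inference, so prediction is deterministic. Checkpoints (`save_model`) are
a zip of weight arrays plus a JSON header carrying the architecture, the
feature schema, and the standardization parameters — predictions reload
bit-identically.

Under-sampling keeps every positive and draws ⌈ratio × #positives⌉
negatives uniformly without replacement (ratio 10 by default; the
published value is not stated). Negatives are not matched on MAF or LD.
Standardization is fit on the under-sampled training subset only and
applied unchanged to every other matrix, so no application- or test-set
statistics leak into training; constant columns pass through unscaled.

## Loci, enhancement, and metrics

A **locus** is a single-linkage merge of significant variants: consecutive
variants ≤ 250 kb apart (boundary joins) form one locus, whose index
variant is the top scorer (−log₁₀ p for input loci, P̂ for predicted
loci). The merge distance and the locus-matching slack (also 250 kb,
spans extended both ways) are package choices; the source material never
defines its locus algorithm.

An **enhanced variant** has P̂ ≥ threshold (default 0.5, compared with ≥)
and input p ≥ 5×10⁻⁸. An **enhanced locus** is a predicted-significant
locus in a *novel region*: no input-significant variant within 250 kb of
its span. Requiring mere absence of significant members is not enough — a
locus bordering a known signal would be counted as "new", and its status
would flicker with the threshold. **Anti-enhanced** loci (input-significant,
all members below threshold) flag potential false positives of the input
study.

The **threshold sweep** (0.50 to 0.95 in steps of 0.05) calls enhanced
loci once at the loosest threshold and counts, at each stricter one, the
loci whose index P̂ survives. Counting survivors of a fixed base set —
rather than re-calling loci per threshold — is both how a sweep from
hundreds of loci down to dozens is naturally reported and the only
version that is monotone by construction: independent re-calling lets
loci split or flip to novel as variants drop out.

Variant metrics report TP/FP/FN/TN at the threshold, TPR, precision, and
F1 = TP/(TP + ½(FP + FN)); ROC and PRC curves come from scikit-learn, and
trapezoid AUROC agrees with the concordance-pair (Mann-Whitney) statistic
to 10⁻¹², which the tests assert against a brute-force pair count. Locus
metrics match loci by slack-extended span overlap: matched truth loci are
TPs, unmatched predicted loci FPs. Validation binning groups enhanced loci
by index P̂ in 0.05-wide bins and reports the proportion matched in ≥ 1
independent study — true positives should be validated more often, and by
more studies.

One reported quantity in the source is named "CPR" without definition;
precision (PPV) is reported in its place.

## Synthetic benchmark

`deepgwas.simulate` generates the full three-study design with known
ground truth, no downloads:

* **Panel** — 20,000 variants in 40 LD blocks (two per chromosome, 10 Mb
  apart, variants every 5 kb), 200 individuals. Within a block, two latent
  Gaussian haplotypes per individual share an exchangeable correlation
  ρ = 0.6 and are thresholded at each variant's MAF quantile
  (MAF ~ U(0.05, 0.5)), giving Hardy-Weinberg genotypes; blocks are
  independent.
* **Truth** — 24 causal variants clustered into 12 true loci (one block
  each, ≥ 1 causal per chosen block); standardized effects
  a ~ N(0, 0.04²).
* **Studies** — summary statistics via the standard multivariate-normal
  model: per block z ~ N(√n · R a, R) with R the block's panel
  correlation (eigenvalues clipped at 10⁻⁶ when the finite-panel estimate
  is not PSD), p = 2Φ(−|z|), OR = exp(z/√n). Three studies share the
  truth at n = 20k / 60k / 120k. The OR scale is a standardized-liability
  convenience: the features use its magnitude, not its epidemiological
  meaning.
* **Annotations** — each binary track covers causal variants at rate
  e·q = 0.25 and others at q = 0.05, as short intervals (half-width 400 bp
  < spacing, so membership is exact); 15 epigenomic tracks share 11 core
  patterns with noise, giving the Jaccard clustering real structure; score
  tracks are N(0, 1) plus a +1 shift at causal variants; the eQTL table
  contains sub-10⁻⁶ associations for 60 % of causal vs 5 % of other
  variants, plus above-threshold chaff so the p-filter matters.

`effect_sd = 0.04` is calibrated to the regime the method targets: the
feature study alone detects roughly half the true loci and the larger
studies most but not all (per-causal-variant detection probabilities
≈ 0.33 / 0.58 / 0.69 at the three sample sizes), mirroring study triples
whose detected-locus counts step 108 → 145 → 287. Much weaker effects put
the feature study near zero detections — a regime where no method with
these inputs could work.

For transfer experiments a second trait's causal variants are drawn with
probability ∝ 1 + (e − 1) × (annotation hit count), so the annotations
enriched for trait 1 are informative for trait 2 without sharing causal
variants.

The whole benchmark is deterministic given one master seed (children
spawned via `SeedSequence`). Problem sizes were chosen so the full
five-seed benchmark, null control, and transfer runs complete in a few
minutes on one CPU core.

**What the simulator does not model:** coalescent realism, population
structure, case-control ascertainment, imputation error, strand issues,
and tissue specificity of annotations. Passing tests show the pipeline
recovers planted signal under its own generative assumptions — they say
nothing about annotation quality or confounding in real data.

## Numerical and degenerate-input choices

* r² is undefined for monomorphic variants; LD sums treat such pairs as 0
  with a note, and per-variant calls raise.
* Vectorised LD scoring mean-imputes missing genotypes; per-variant calls
  use pairwise-complete individuals (identical on complete panels, which
  the tests verify). Panel variants with > 10 % missingness are dropped at
  load.
* p-values are clipped to ≥ 10⁻³²⁰ before logs; −log₁₀ p capped at 320.
* Probabilities are clipped to [10⁻¹², 1 − 10⁻¹²] inside the loss; the
  forward pass returns values in the open unit interval.
* Logistic-regression separation falls back to a ridge-stabilised
  (λ = 10⁻⁶) Newton fit with a warning rather than failing, so the
  comparison harness always completes.
* A null benchmark (effect_sd = 0) typically yields zero significant
  label-study variants; the network is then untrainable by contract
  (under-sampling requires ≥ 1 positive), and the pipeline reports an
  empty enhancement instead of raising.
* Harmonization flips OR → 1/OR when the study's effect allele is the
  panel's reference allele; A/T and C/G variants are matched by position
  and allele pair without strand inference, counted and reported, not
  resolved. All inputs must share a genome build; only chromosome-name
  compatibility is checked.

## Known limitations

* The published architecture internals (widths, activation, optimizer)
  are not public; this implementation fixes them by choice, so numerical
  outputs will not match the original released model.
* Desk-scale LD only: windowed dense correlation, no banded/streaming
  computation for biobank-scale panels.
* The exact composition of the 28 annotation features follows the
  documented grouping; a different schema can be supplied as a name list
  provided the model input width agrees.
* No liftover, imputation, meta-analysis, or derivation of annotation
  resources from raw data — annotation files are consumed as given.
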