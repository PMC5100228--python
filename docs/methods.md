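# Methods

This note records the statistical models implemented by `tagdge`, the
choices made where the underlying protocol leaves details open, and what
the synthetic experiments do and do not demonstrate.

## Tag-count model and the exact pairwise test

A DGE library assigns each transcript a tag; the count x of a gene in a
library of N total tags is modelled as Poisson, since any one gene
occupies a tiny fraction of the library. For two libraries (x, N₁) and
(y, N₂), conditioning on the total x + y removes the unknown expression
level and leaves

p(y|x) = (N₂/N₁)^y · (x+y)! / (x!·y!·(1+N₂/N₁)^{x+y+1}),

a negative-binomial law in y with x+1 "successes" and success probability
N₁/(N₁+N₂). The two-sided p-value doubles the smaller tail of
S = Σ_{i=0..y} p(i|x) — 2S when S ≤ 0.5, otherwise 2(1−S) — clamped to
[0, 1]. As printed, the upper branch excludes the observed point from the
tail; we implement the rule exactly as stated.

**Numerics.** The pmf is evaluated in log space with log-gamma. The
partial sum S uses the regularized incomplete beta identity
S = I_p(x+1, y+1), p = N₁/(N₁+N₂); the upper branch is evaluated directly
as I_{1−p}(y+1, x+1) rather than 1−S, and the two tails are renormalized
by their sum (which is 1 up to rounding). This keeps agreement with exact
rational arithmetic at ~10⁻¹⁵ relative error and makes symmetric cases
(x = y with equal totals) return exactly 1.0. The test suite checks the
implementation against an independent `fractions.Fraction` oracle for all
x, y ≤ 12 at library ratios ½, 1, 2.

Because the test is discrete it is conservative: on simulated truly-null
Poisson pairs the fraction of raw p < 0.05 sits near 0.04–0.05, and
Benjamini–Hochberg at q ≤ 0.001 calls essentially nothing. DEG calls
additionally require |log₂FC| ≥ 1 on RPKM; both thresholds are
configurable (the protocol this follows states no explicit cutoffs, so the
conventional q ≤ 0.001 and 2-fold defaults are used). Zero RPKM values are
substituted with 0.001 before ratios so every log₂FC is finite — the same
substitution rule the group screen defines.

## RPKM

RPKM = 10⁶·C/(N·L/10³). Zero-depth libraries are rejected rather than
pseudocounted (the quantity is undefined and the generator never produces
them). Values are kept at float64 precision internally; tables are written
at 6 significant digits.

## Group screen (noise-distribution dominance)

With replicated conditions, every within-condition replicate pair
contributes, for every gene, a noise point (M, D) with M = log₂(x₁/x₂)
(zeros replaced by 0.001 so the log is defined; D keeps the original
values since |x₁−x₂| is well-defined at zero). Pooling across genes and
conditions yields an empirical picture of how large fold changes and
absolute differences get *between biological replicates*. A gene's
between-condition signal, computed the same way from condition means
(arithmetic means of RPKM), is scored by the fraction of noise points it
strictly dominates in both coordinates; genes above probability 0.8 (the
published convention for this family of methods) are called. The source
protocol describes only the noise-distribution construction, so this
simplest dominance statistic is adopted deliberately; it is monotone in
|M| and D by construction. Noise pooling defaults to every condition in
the analysis scope and can be restricted to the contrasted pair
(`noise_scope`), since whether pooling crossed cultivars is not specified.

A known property of the dominance statistic: a gene whose baseline
expression is near the detection floor has a small absolute difference D
no matter how large its fold change, so it cannot dominate the noise of
well-expressed genes. This is shared with the method family, not an
artifact of this implementation.

## Term enrichment

P(X ≥ m) for the hypergeometric distribution with background N (the
annotated universe of the loaded map — genes without annotation drop out
of both N and n, and are logged), DEG count n, term size M, overlap m;
evaluated with `scipy.stats.hypergeom` and verified against exhaustive
rational enumeration for every feasible configuration with N ≤ 30.
Bonferroni multiplies by the number of terms in the namespace. The
significance rule is corrected p ≤ 0.05: the source text prints "≥ 0.05",
which contradicts its own description of *significantly enriched* terms
and is treated as a typo. The rich factor m/M is attached to every record.
KEGG maps reuse the identical machinery with the universe re-scoped to
pathway-annotated genes. GO terms are counted exactly as mapped, with no
ancestor propagation (annotation maps are taken as given, as the upstream
annotation tool would have emitted them).

## Co-expression network

All gene pairs are scored by sample Pearson correlation of expression
profiles; p-values come from the exact-under-normality t transform
t = r·√((n−2)/(1−r²)) with n−2 degrees of freedom (the protocol names only
"Pearson" and "FDR", so the standard test is used). FDR is
Benjamini–Hochberg across *all* tested pairs. Edges require |R| > 0.99 and
FDR < 0.05 (both exposed). Zero-variance genes are excluded up front and
logged. Note that at these thresholds a set of strongly differentially
expressed genes forms dense near-cliques — their profiles are all
dominated by the same condition effect — so the pipeline's network stage
over DEG nodes is expected to be dense; module detection against an
otherwise-null background is the discriminating test.

## qPCR validation

ΔΔCt = (Ct_target − Ct_reference)_treatment − (Ct_target −
Ct_reference)_control, fold change 2^−ΔΔCt; replicate Ct values are
averaged (arithmetic mean of cycles) before the contrast, since no
replicate-handling rule is stated. Validation is scored as sign
concordance with the RNA-Seq log₂ ratio — the claim being validated is
directional, not a stated correlation. Amplification-efficiency correction
is out of scope.

## Synthetic experiments

The generator emulates the study design: two cultivars × three treatments
(control Ck, chromium Cr, Cr + glutathione), with duplicate libraries per
condition — two being the minimum the group screen needs, and the DGE
libraries of the emulated protocol were essentially unreplicated. Defaults
are desk-scale stand-ins for production libraries: 5,000 genes, 10⁶ tags
per library (vs ~1.2×10⁷ in real tag libraries); gene lengths uniform on
200–3,000 bp, matching assembled-unigene length scales.

* **Abundance**: baseline expected proportions are log-normal (σ = 1),
  the canonical skewed-abundance shape.
* **Counts**: Poisson around proportion × library size by default — the
  model the exact test assumes; a negative-binomial option
  (variance = μ + φμ²) exists for robustness experiments. The Fano factor
  of replicate counts is ≈ 1 at default settings (tested).
* **Planted DE**: 200 genes get their expected proportion multiplied by
  2^(±log₂FC) (signs random, log₂FC = 2 by default) in the chromium
  conditions. DE is planted only in genes above the 25th percentile of
  baseline abundance: a fold change at an undetectable baseline is
  biologically meaningless, and no counting-based screen could recover it.
* **Planted term**: one annotation term collects 50 of the planted DE
  genes; ~100 further terms are random draws, across three GO namespaces
  and a KEGG map with level-1/level-2 labels.
* **Planted module**: five genes share a per-library latent log₂ profile
  (sd 2.0 — roughly ±4-fold swings, as for a tightly co-regulated stress
  module) plus small per-gene noise (sd 0.05). Module genes sit at the
  75th percentile of baseline abundance: high enough that counting noise
  is small next to the latent signal, low enough that the module's share
  of the library stays negligible — a large share would couple every other
  gene through the RPKM denominator and manufacture spurious correlations.
* All randomness flows from one integer seed through a single
  `numpy.random.Generator`; no global state.

What passing tests on this generator do **not** show about real data:
biological replicate variance beyond Poisson/NB, assembly artifacts and
multi-mapping, annotation incompleteness or bias, batch effects, and
compositional effects of a few extremely abundant genes. The generator's
planted structures are deliberately clean so that failures indicate
implementation errors rather than modelling mismatch.

## Problem sizes used by tests and the acceptance script

Chosen as the smallest sizes at which the statistical properties are
stable: 10,000 genes × 10⁶ tags for null calibration; 5,000 genes for
pairwise recovery; 2,000 genes × (2 conditions × 3 replicates) for the
group screen; 1,000 genes × 12 libraries for module recovery (fewer
libraries leave the correlation FDR under-powered across ~500k pairs; a
smaller catalog makes the module a non-negligible library share); 50 genes
for the independent-noise network floor; the full 12-library default
design for the end-to-end pipeline, run twice to confirm byte-identical
output.

## Known limitations

* The dominance-based group screen has no smoothing; with few replicates
  its probabilities are coarse multiples of 1/|noise|.
* BH q-values, not raw p, drive pairwise calls; with very few genes the
  FDR step is conservative.
* The network stage is O(G²) in nodes; the pipeline restricts nodes to
  called DEGs (plus the known module in synthetic runs) and caps them.
* Venn partitioning supports 2–3 sets, matching the figure style it
  reproduces.
* The quality/error conversion is the log-odds variant, not standard
  Phred; the two differ materially only at low quality.
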