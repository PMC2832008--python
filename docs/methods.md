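# Methods

This note documents the models, numerical choices and known limits of the
package. It is written for users deciding whether the implemented procedures
fit their data, and for maintainers wondering why a particular rule looks
the way it does.

## Two-channel normalization model

Each array is a Cy5-labelled sample hybridized against a common Cy3
reference (an equimolar probe mix), so the quantity of interest per gene is
the sample/reference intensity ratio. Replicate spots of a gene collapse to
the **median** ratio over spots with both channels positive — robust to a
single bad spot, which is the typical failure mode of spotted arrays. Genes
whose spots are all non-positive are excluded with a warning and appear as
missing values downstream.

Because the probe set derives from a nodule cDNA library, total sample
intensity differs systematically between root and nodule samples, so global
(total-intensity) normalization would be biased. Instead, a set of
expression-invariant genes is found by anchoring to a constitutive control
spotted 12 times across the slide: the invariance score of a gene is the
standard deviation across arrays of log2(gene ratio / anchor ratio), and the
*n* lowest-scoring genes are taken (default *n* = 1500; ties broken by
gene id so selection is order-independent; the anchor itself is excluded —
it is the scoring reference). Each array is then divided by the **median of
the linear ratios** of the invariant genes. Medianising in the linear rather
than log domain is a convention choice (the median commutes with monotone
transforms for odd counts and differs negligibly for even ones); the linear
domain was chosen and is asserted by the post-condition
`median_{g∈inv}(normalized ratio) = 1 ± 1e-9` per array. Normalization is
idempotent and equivariant under per-array intensity rescaling.

## Stage model and differential selection

The time course (0, 2, 4, 6, 7, 8, 10, 13, 20, 29 dpi) maps onto three
developmental stages by dpi cutpoints: roots 0–6, incipient nodules 7–10,
mature nodules ≥ 13. Days 11–12 were never sampled and deliberately raise
rather than guess.

Differential expression uses Welch's (unequal-variance) two-sided *t*-test
on log2 ratios for each of the three stage pairs; a gene is selected when
any of the three raw p-values is below α = 0.01. No multiple-testing
correction is applied — that is the analysis convention this package
reproduces, and users should expect ≈ 2–3 % of null genes in the selection
(the union of three correlated 1 %-level tests). Degenerate zero-variance
comparisons use the convention p = 1 for equal means and p = 0 for unequal
means; "zero" is assessed at a relative tolerance of 1e-9 of the value
scale, because bit-identical pipelines (zero planted noise) still produce
~1e-16 float jitter that must not masquerade as biological variance.

The **digital transform** maps each gene's three stage means to integer
tiers 1–3: order the stages by mean (ties broken by the fixed order
roots < incipient < nodules), give the lowest tier 1, and walking upward
increment the tier only when the pairwise p-value against the current
tier's representative stage is below α, otherwise the stage joins the
current tier. The original tool's exact algorithm is not published; this
merge rule is the package's defined reading, frozen by tests (e.g.
low / high / high with an insignificant upper pair yields 1, 2, 2).

## Temporal profiles and waves

Each selected gene is summarised by its standardized (z-scored) triple of
stage means. In that representation squared Euclidean distance is
proportional to 1 − Pearson correlation of the profiles, i.e. clustering
sees only profile *shape*. The tree is built with **Ward linkage** and cut
into exactly *k* = 8 clusters. Ward rather than average linkage is a
deliberate robustness choice: the raw-p selection feeding this step always
contains a few percent of flat false-positive genes whose standardized
shapes are random directions; under average linkage those survive the k = 8
cut as small spurious clusters (forcing two genuine profiles to merge),
while Ward's variance criterion absorbs them into their nearest real
profile. Cluster ids are renumbered to a stable semantic order (1–3
repressed variants, 4 incipient-transient, 5–6 first wave, 7–8 second wave)
by a correlation-maximising assignment against the reference shapes; with
k ≠ 8 a repressed-to-activated ordering key is used instead. *k* is a
parameter, not an inference — the package does not claim to discover the
number of profiles.

Sample structure uses PCA (genes mean-centred) and hierarchical clustering
of samples with 1 − Pearson distance and average linkage, cut at *k* = 3;
sample vectors are long (thousands of genes), so the contamination issue
above does not arise there and the conventional linkage is kept.

**Wave scores**: for a query sample, wave 1 is the median over profile-5∪6
genes of (log2 value − root baseline), wave 2 likewise over profiles 7∪8; a
wave is active at ≥ 1.0 log2 (2-fold). The threshold is a package default —
the original assessment was visual — and is configurable; scores are
translation-consistent by construction.

## Secretome categories and enrichment

Annotation flags (signal peptide, transmembrane-domain count, curated
secretory-system membership, protein length) are inputs, not predictions
made here. The category precedence is: secretory-system component >
membrane protein (≥1 TM domain; signal-anchor ambiguity resolves to
membrane) > secretory protein (signal peptide, 0 TM), with a peptide
subclass at length < 220 aa (strict, signal peptide included) > non-
secretory. Enrichment of a gene set against the probe-set background uses a
two-sided Fisher's exact test whose hypergeometric tail is summed in log
space (logsumexp over log-pmf values at most the observed one, with a 1e-7
relative tie tolerance matching common practice); this keeps log10(p)
meaningful down to the 1e-50-scale enrichments typical of nodule secretome
sets. Odds ratios apply the Haldane–Anscombe ½ correction when a cell is
zero. The combined "protein secretion" super-category (everything except
non-secretory) is tested alongside the four base categories.

## Ploidy, endoreduplication index, bacteroids

DAPI histograms carry peaks at geometric positions anchor×2ʲ for 2C–64C.
Each bin's mass is assigned to the nearest expected peak in **log2
fluorescence** (peaks are geometrically spaced, so log-space nearest-centre
is the natural gate); percentages are computed per replicate and then
averaged (default 3 replicates per sample). The instrument anchor (2C
position) is supplied as calibration; an optional estimator takes the
lowest local maximum carrying ≥ 2 % of total mass in a half-octave window.
No debris or doublet modelling is attempted — the generator produces clean
histograms and the assignment rule is frozen by tests; real cytometry data
should be gated upstream.

EI = %16C·3 + %32C·4 + %64C·5, linear in the profile and independent of
nucleus count. Decision bounds: EI < 2 → no symbiotic-cell differentiation,
EI > 15 → differentiated; the gap returns "indeterminate" rather than a
guess (archetypal samples never fall there, and classification refuses to
proceed on indeterminate evidence). Ploidy profiles cluster with Euclidean
distance and average linkage on the 6-dimensional percentage vectors; the
k = 2 cut separates root-like from nodule-like profiles.

Bacteroid differentiation: fold ratio of mean cell length, nodule-derived
over cultured. Cultured rods sit at 1–2 µm and fully differentiated
bacteroids 4–5× longer, so the decision threshold 2.5× is the midpoint
between the two regimes; the boundary is inclusive (fold = threshold →
differentiated).

## Mutant classification

Markers decide, the transcriptome corroborates. The rule table:
uninfected ∧ undifferentiated cells → category 4 (empty nodules);
infected ∧ infection-thread network ∧ undifferentiated cells → category 3;
differentiated cells ∧ undifferentiated bacteroids → category 2;
differentiated cells ∧ differentiated bacteroids → category 1, or
wild-type-like when nitrogen fixation is effective. Two marker combinations
are biologically unreachable (differentiated cells without infection;
infected and undifferentiated without an infection-thread network) and
raise validation errors instead of guessing. Expected wave patterns
(cat 1: both, cat 2: wave 1 only, cat 3/4: neither) set a consistency flag;
a mismatch warns but does not reclassify, since differentiation markers are
the stronger evidence. Genes induced in all queried mutants are the
intersection of one-sided (greater) Welch tests vs roots at α = 0.01 —
one-sided because the question is induction.

## qPCR (Pfaffl)

ratio = E_t^(CP_t,cal − CP_t,s) / E_r^(CP_r,cal − CP_r,s), with per-primer
efficiencies E ∈ (1, 2] (2 = perfect doubling; percent efficiencies are
converted at I/O). Technical replicates average at the CP level; ratios are
computed per biological replicate and averaged per sample; the calibrator is
the sample with the lowest mean ratio and the minimum mean fold is scaled
to exactly 1. With E_t = E_r = 2 the method reduces to the classical
2^(−ΔΔCP). Input-amount shifts that move target and reference CPs together
cancel exactly when efficiencies are equal.

## Synthetic-data generator

The generator is the package's benchmark instrument; its defaults encode
the study conditions: 2366 genes, 520 differential (65 per profile), 1500
invariant, anchor spotted 12×, time points 0–29 dpi with 3 arrays per time
point (array replication is not documented in the original design and is
exposed as a parameter), a 15-genotype mutant panel at 3 arrays per
genotype, ploidy mixtures per archetype (root-like: 60/30/10 over 2C/4C/8C;
nodule-like spanning 2C–64C so that EI > 15 by construction), bacteroid
lengths uniform on 1–2 µm (cultured) vs normal with mean 6.75 µm
(differentiated, 4.5× the cultured mean of 1.5 µm), and qPCR crossing
points derived from planted folds under the Pfaffl model.

Profile templates are stage-tier triples on the log2 scale (tier step =
3.0 log2, i.e. 8-fold): 1 = (1,0,0), 2 = (1,0,1), 3 = (1,1,0),
4 = (0,1,0), 5 = (0,1,½), 6 = (0,1,1), 7 = (0,½,1), 8 = (0,0,1). The three
repressed templates are placed so the eight standardized shapes spread as
evenly as the wave structure allows, making the planted truth maximally
distinguishable. Channel noise is multiplicative log-normal per spot
(default sd 0.25 log2); invariant genes get gene-specific constant
baselines centred so the linear-median of the invariant set is exactly 1;
background genes additionally wobble per array (sd 0.6 log2) with no stage
structure — they are what makes invariant-gene selection a real task.
Mutant archetypes express DE genes at the stage column matching their
block: wild-type-like at nodule levels throughout, bacA-like with profiles
5–6 at nodule and everything else at root levels, root-like archetypes at
root levels plus a 20-gene "common" set induced 2.0 log2 (4-fold — chosen
so the planted induction is reliably detectable at p < 0.01 with 3
replicates, which is the property that defines this gene set, while staying
clearly below the nodule-specific 8-fold steps).

Gene roles and baselines are a function of the seed alone, so a time course
and a mutant panel generated from the same seed describe the same probe set
(only the noise streams differ) — required for applying time-course profile
assignments to panel samples, as the pipeline does.

**What the generator does not emulate**: spatial slide artefacts, dye bias,
print-tip effects, missing spots, background fluorescence, S-phase nuclei
and cytometry debris, length-dependent qPCR efficiency drift, and any
sequence-level structure. Recovery results on synthetic data therefore
demonstrate correctness of the inference chain under its stated noise
model, not robustness to every artefact of real arrays.

## Problem sizes and determinism

All simulations and tests run at the study's native scale (2366 genes, 30
time-course arrays, 17 panel samples, 10⁴ nuclei per cytometry replicate)
or a documented down-scale (300 genes for unit tests); a full pipeline run
takes a few seconds. Every stochastic component takes an explicit seed and
all generators are pure functions of (config, seed); the pipeline report is
reproducible bit-for-bit under a fixed seed.

## Known limitations

- The digital-genes merge rule and the wave-activation threshold are
  package-defined conventions where the original procedure was visual or
  unpublished; both are configurable and frozen by tests.
- Raw-p selection admits false positives by design; downstream profile
  clustering is robust to them (Ward), but selected-set sizes exceed the
  planted count by the expected ~2–3 %.
- The Fisher test's tie tolerance (1e-7 relative) can, on knife-edge
  tables, include or exclude a table differently from exact rational
  arithmetic; the property suite bounds the effect below 1e-10 in log10(p)
  on tables up to N = 200.
- Mutant classification requires complete marker evidence; it refuses
  indeterminate endoreduplication rather than imputing.
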