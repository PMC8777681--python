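# Methods

## Problem setting

A single patient fibroblast line (measured in triplicate) is compared
against several unrelated control lines (one run each) on a whole-cell DIA
proteome of a few thousand proteins. The design is tiny and unbalanced by
construction — rare-disease diagnostics rarely affords more — so the
pipeline's statistics are deliberately simple and transparent: plain
t-tests per protein, aggregation over complex subunits for power at the
complex level, and exact set-overlap tests for enrichment.

## Differential abundance

Linear MS2-style quantities are log2-transformed once (the container
records the scale; a second transform is refused). A protein enters the
test only with ≥ 2 valid values in each group; below that it is *filtered*,
not imputed — with n = 3 vs 5 any imputation would dominate the statistic.
The default t-test is the pooled-variance (Student) form, matching the
default of the quantification software this pipeline sits downstream of;
Welch is available and recorded in the output metadata. Volcano classes use
inclusive comparisons (|log2 diff| ≥ 1 and p ≤ 0.05): the rule is stated as
an equality threshold, and inclusivity is the reading that keeps boundary
proteins significant. Two-sided p-values; no per-protein multiple-testing
correction (deliberate and prominent: the volcano classifies on raw p; FDR
appears only at the enrichment stage). Degenerate zero-variance proteins
are resolved explicitly: identical groups give t = 0, p = 1; disjoint
constant groups give p = 0.

## Relative complex abundance

The sampling unit is the *subunit*: the per-subunit differences d_i are
treated as the sample, so the 95% CI is mean(d_i) ± t(0.975, n−1)·sd/√n and
the significance test is the one-sample t-test of {d_i} against zero —
algebraically the paired t-test pairing each subunit's patient and control
means. The percent ratio is 2^mean(d_i) × 100, i.e. the geometric mean of
subunit ratios — consistent with a log2 pipeline; the arithmetic mean of
linear ratios would be dominated by single subunits. Subunit inclusion
reuses the differential filter (class ≠ filtered) rather than inventing a
second validity rule. A complex with < 2 usable subunits reports its point
ratio only; sd = 0 collapses the CI to the point and clamps p to 0 with a
`degenerate_sd` flag. Complex membership (OXPHOS CI–CV, mitoribosome
LSU/SSU) ships as an editable TSV — gene content is configuration, not
code; the bundled set uses human gene symbols (44 CI subunits, 48 LSU,
34 SSU).

An alternative reading of the paired test — pairing *samples* rather than
subunits — is possible; the subunit pairing is implemented because it is
the one consistent with per-subunit difference whiskers and with an
unbalanced 3 vs 5 design, where sample pairing is undefined.

## Structure painting

Per-protein log2 differences are written into the per-atom B-factor
(isotropic displacement) column of a user-supplied mmCIF/PDB file through a
user-supplied chain → accession table, clipped to a palette range (default
±2 log2 units). The B-factor column is chosen because every structure
viewer can colour by it; PDB output quantizes to two decimals, mmCIF keeps
more. Chains without a mapping, or mapped to unquantified/filtered
proteins, carry the sentinel 0 and are listed in a sidecar report. No
bundled chain map is shipped: the published chain → gene correspondence of
any given mitoribosome structure is a curation question, so the table is a
required input.

## Enrichment

One-sided Fisher exact p, computed as the hypergeometric upper tail
P(X ≥ k) — the exact identity, tested exhaustively against
integer-arithmetic tail sums. The background is the set of proteins passing
the valid-value filter (the analysed proteins, not the whole search
database). The ≥ 5-protein minimum term size is applied to the term's
*effective* size after restriction to the background — the statistically
coherent reading, since the test conditions on the background. FDR is
Benjamini–Hochberg (step-up with monotone enforcement); term hierarchies
are not modelled — terms are flat sets supplied as files, because the
enrichment semantics reduce to set overlap and ontology propagation would
add a heavy dependency without a testable anchor here. The discovery query
used in the planted-signal checks is the *nominally decreased* set
(p ≤ 0.05 and log2 diff < 0): a 70% complex depletion is a 0.51-log2
effect, below the two-fold volcano line by design, so the strict volcano
"down" class cannot contain it — the nominal query is the set a
complex-level discovery question actually needs.

## Phenotype assays

Growth: blanked RFU is normalized to the day-0 **mean over replicate
wells** of the same line and condition (per-well normalization is a flag);
the blank subtraction makes the index exactly invariant to any plate-wide
additive offset. The curve comparison is a two-way fixed-effects ANOVA
(line, day, interaction) with per-day contrasts: Welch t with Šidák
correction over days for a pairwise comparison, Dunnett many-to-one when
several comparator lines are given at once.

Imaging: background correction subtracts the image's 0.10 quantile (the
upstream tool's correction is unparameterized, so it is configuration
here), masks are whole-cell (global Otsu on the corrected image), and
components < 50 px are discarded to suppress speckle. All three knobs are
exposed. Intensity comparison is a one-way ANOVA with Šidák-corrected
pairwise Welch contrasts.

## Synthetic data: what it emulates and what it does not

The generator draws per-protein baseline log2 means Normal(20, 2) — a
dynamic-range stand-in; only relative quantities matter downstream — and
applies the disease as multiplicative factors on the patient group's linear
means: the default profile is CI → 0.70, LSU → 0.60, SSU → 0.75, plus 200
extra down and 60 extra up non-complex proteins at 1.5 log2 units
(emulating the scale of a real whole-proteome response), 5% missingness,
15% replicate CV. Noise is multiplicative log-normal with E[factor] = 1 (DIA
intensity CVs behave multiplicatively). Missingness is uniform (MAR) by
default; an MNAR option triples the dropout probability below the 0.25
abundance quantile at the same overall rate, since low-abundance dropout is
the realistic mechanism — MAR keeps test arithmetic simple. The patient
triplicate is modelled as three independent draws around the patient mean;
the within-group CV is a free knob, not an estimate from real fibroblast
data. Growth plates follow blank + capacity·logistic(rate·day); images are
non-overlapping constant-intensity discs on a constant background with
Gaussian noise.

Consequences: passing tests demonstrate the *inference machinery* —
filtering, test statistics, aggregation, calibration, discovery — under a
clean generative model. They do not demonstrate robustness to batch
effects, peptide-level noise, shared-peptide protein inference, isoform
ambiguity, correlated subunit noise, or non-disc cell morphology, none of
which the generator produces.

## Problem sizes and seeds

The reference fixture is 2000 proteins (the bundled complexes occupy 173),
3 patient vs 5 control samples, seed 42 — large enough that the complex-I
mean over ~43 usable subunits has a standard error near 2% of control, so
its recovery is stable across seeds. Calibration checks use 200 replicates.
Every generator takes an explicit integer seed and is bit-reproducible;
the pipeline derives per-stage seeds from the config seed by fixed offsets
and writes SHA-256 digests of every output into the run manifest, so
digest equality is the determinism contract.

## Known limitations

- No normalization between samples: the input matrix is taken as already
  normalized upstream; no imputation of missing values.
- The t-based RCA confidence interval treats subunit differences as
  independent; biological co-regulation within a complex makes it
  anti-conservative in principle.
- Enrichment terms are flat sets; no ontology hierarchy or term pruning.
- The CLI's `image` grouping convention (filename stem up to the last
  underscore) is a convenience, not a schema.
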