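# Methods

## Scope and model

`popband` analyses two independent data layers. The *band layer* is an
individuals × loci presence/absence matrix from a dominant marker system:
each locus is treated as biallelic (band allele vs null allele) under
Hardy–Weinberg equilibrium, with the heterozygote indistinguishable from
the dominant homozygote. The *barcode layer* is a pre-aligned two-species
nuclear marker (ITS-style) matrix used solely to support the species
boundary; no within-species population inference is drawn from it.

All band-layer indices are band-based comparative summaries, not
allele-resolved estimates of heterozygosity or gene flow — comparisons are
meaningful within one matrix scored under one protocol, not across studies.

## Band-layer estimators

* Null-allele frequency: the pure square-root estimator q = sqrt(1 − f),
  with no Lynch–Milligan small-sample correction. This matches the
  convention of the widely used spreadsheet tools for dominant data and
  keeps the index ceilings exact: He = 2pq ≤ 0.5, I ≤ ln 2, Ne ∈ [1, 2].
* Shannon's I is computed on the two estimated allele frequencies, not on
  band-phenotype frequencies; PIC is taken equal to He for a biallelic
  dominant locus.
* Polymorphism is the strict criterion 0 < f < 1 (no 95% rule), judged
  within the analysis unit: a locus fixed inside one population but
  variable overall is monomorphic for that population's summary and
  polymorphic for the pooled summary. Consequently
  mean Na · L = 2P + (L − P) holds exactly for every reported unit.
* Reported rounding: indices to 3 d.p., PPB to 1 d.p.

## AMOVA / Phi_PT

Squared Euclidean distance on 0/1 phenotypes (= mismatch count) feeds the
standard two-level decomposition; the unequal-sample-size coefficient
n0 = (N − Σ n_g²/N)/(k − 1) converts the among-group mean square into Va.
Negative Va is truncated to 0 *before* forming Phi_PT, so Phi_PT ∈ [0, 1]
and pct_among = 100·Phi_PT exactly. Zero total variance returns a
degenerate flag with Phi_PT = 0 rather than an error.

Permutation inference reassigns whole individuals among units with unit
sizes fixed (loci are never permuted), uses the ≥ convention for ties with
a small numerical guard (1e−12), and the +1/+1 p-value convention, making
1/(n_perm+1) the attainable floor. Pairwise Phi_PT runs the same machinery
on each pair of populations; each pair derives its own RNG substream from
(seed, sorted pair labels) via SHA-256, so neither population order nor row
order affects any pair's p-value.

The grouped ("mainland/island") scenario pools populations into two units
and reruns the two-level AMOVA — a deliberate two-unit reading rather than
a three-level hierarchical AMOVA, because the target output is a single
Phi_PT with one among/within split. A hierarchical decomposition is out of
scope.

## Ordination

Sokal–Michener dissimilarity (simple matching on 0/1 profiles) ties the
ordination to the AMOVA metric: d_SM = d²/L identically. PCoA is classical
Torgerson scaling of the *squared* dissimilarities: double-center
B = −½ J D² J, eigendecompose, scale eigenvectors by sqrt(eigenvalue).
Negative eigenvalues (possible for non-Euclidean inputs) are reported but
excluded from the percentage-of-variance denominator; no Lingoes/Cailliez
correction is applied. Axis signs are arbitrary, so tests and consumers
should compare distances or absolute loadings only. The implementation is
cross-checked in the test suite against scikit-bio's independent PCoA.

## Subsampling sensitivity

Populations larger than the target n are redrawn without replacement
(default n = 20, 1000 iterations), recomputing all indices per draw;
summaries are means with 2.5/97.5 percentiles (numpy's linear
interpolation between order statistics). A population already at the
target is reported with its observed values and flagged "observed, not
resampled". One user-facing seed (default 20260510) feeds per-population
substreams hashed from (seed, population label), making results independent
of processing order and bit-reproducible.

## Barcode layer

The shared gap-free core drops every column containing a gap in *any*
sequence (rather than stripping gaps per sequence), so all distances are
computed on a common coordinate system; removed column indices are recorded
as provenance and the operation is idempotent. p-distances use pairwise
deletion of N sites; diagnostic sites require fixation within each species,
different states between species, and no N anywhere in the column — the
most conservative reading. Internally coordinates are 0-based half-open;
reports print 1-based positions. A single-sequence species yields a
degenerate (0, 0) within-species range, flagged rather than fatal. Input
characters outside {A, C, G, T, N, -} are rejected; IUPAC ambiguity codes
are not expanded. Tree inference is deliberately absent: species support is
carried entirely by the barcode-gap statistics.

## Synthetic data generator

The generator defines the default study conditions: four populations
(CG/DN/PQ/CD) of 30/30/30/20 individuals, 81 loci over a 12-primer panel
with loci-per-primer counts (8, 9, 8, 8, 7, 5, 3, 6, 6, 9, 11, 1),
optionally plus 5 off-target reference rows. Loci follow the
Balding–Nichols construction: ancestral q0 ~ Beta(2, 2) — chosen so the
pooled expected gene diversity sits near 0.4, a realistic level for an
81-locus ISSR panel in a fragmented tree species — and per-population
q_g ~ Beta(q0(1−F)/F, (1−q0)(1−F)/F) with the single differentiation knob
F = 0.25 by default, the Phi_PT magnitude reported for such systems. Bands
appear with probability 1 − q_g² (HWE dominant phenotype). The true q_g
matrix is returned for estimator-recovery tests.

What the generator does *not* emulate: linkage between loci, scoring error
and band homoplasy (co-migrating non-homologous bands), null-allele
deviations from HWE, isolation-by-distance spatial structure, and any
mutation-model realism in the barcode layer beyond fixed differences and
optional private substitutions. Passing tests therefore demonstrate
correctness of the estimators and inference machinery under the stated
model, not robustness of ISSR scoring itself. Note that the band-level
Phi_PT estimated from a Balding–Nichols matrix is systematically somewhat
above the allele-level F used to simulate it (dominance compresses
within-population variance), which is why the monotonicity of Phi_PT in F —
not numerical equality — is the tested contract.

## Numerical and design choices

* p-values can never be 0 (the +1 convention); ties count as exceedances.
* Permutation loops reuse the precomputed pairwise distance matrix; only
  within-group sums are recomputed per draw, so 999 permutations over 110
  individuals run in well under a second.
* The long CSV dialect (`sample_id,population,<locus>…`) is the native
  band-matrix format; a GenAlEx-like export (two extra header lines) is
  tolerated on read, and `dialect="auto"` tries both in order. Missing or
  non-binary cells are a hard validation error naming the offending cell —
  no imputation pathway exists.
* Problem sizes in the test suite and acceptance script (e.g. 99-permutation
  type-I-error replicates, 50 replicates per differentiation grid point,
  30–81 loci) are chosen to give stable Monte-Carlo tolerances at a few
  seconds per check; the headline analyses use the full study-shaped
  dataset with 999 permutations and 1000 resampling iterations.

## Known limitations

* Dominant-marker He/I are biased for small samples without the
  Lynch–Milligan correction; the package intentionally reproduces the
  uncorrected convention and should not be used for absolute
  cross-study comparisons of He.
* The two-unit grouped AMOVA does not estimate a separate
  among-population-within-group component.
* PCoA percentage-of-variance values are sensitive to the treatment of
  negative eigenvalues; other tools' variants can differ by a few points.
* Bit-exact reproduction of third-party resampling runs is impossible when
  the original RNG and draw order are unknown; agreement is in
  distribution (means and percentile intervals).
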