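# Methods

This note documents the models, conventions and design choices behind
`pfascreen`, in the spirit of a statistical-software methods appendix.
It states no empirical result that the test suite or the acceptance
script does not itself compute.

## Mass conventions

Monoisotopic element masses (Da) are fixed in `pfascreen.chem`:
H 1.0078250319, C 12 (exact), N 14.0030740052, O 15.9949146221,
F 18.9984032, P 30.97376151, S 31.97207069, Cl 34.96885271; proton
1.00727646. The supported alphabet is deliberately restricted to the
elements that occur in PFAS suspect lists so that formula typos fail
loudly.

The deprotonated ion is computed as [M−H]⁻ = M − m(proton), i.e. the
electron stays with the ion. This is the convention that reproduces the
curated table's printed mass errors for the standard-confirmed
compounds; adding or ignoring the electron mass (±0.00055 Da, ≈1–2 ppm
at m/z 300–500) does not. Formulas without hydrogen (perfluorinated
esters and sulfonyl fluorides appear in negative-mode data regardless)
are computed the same way but emit a warning, since a genuine
deprotonation site is absent.

## Kendrick rescaling

KM = m/z × 50 / 49.9968064 and KMD = KM − round(KM) ∈ (−0.5, +0.5].
49.9968064 is the exact monoisotopic CF₂ mass (12 + 2 × 18.9984032).
Some vendor documentation quotes a CF₂ referent of 50.0080, which is
neither the exact nor the nominal CF₂ mass and does not make homologues
share a defect; both the nominal and exact base are configurable, and
the chemically correct pair (50, 49.9968064) is the default. With this
sign convention fluorine-rich ions have small negative defects, which is
why the screening window is the asymmetric [−0.25, +0.15].

## Prioritization cascade

Stage order: exclusion list → blank ratio → intensity → KMD window →
MS² availability. The order is not canonical in the field; blank-based
background removal is applied first because it is the cheapest and the
most universally agreed-on step, and the funnel report makes order
effects auditable (every stage records the removed feature ids, and
in/out counts telescope by construction). Duplicate injections are
collapsed (mean by default, max configurable) before filtering.

Rule details that were genuinely open and are fixed here:

* **Blank ratio.** A feature is *removed* when its maximum area over
  tissue samples is below 10× its maximum area over procedural blanks,
  evaluated globally rather than per tissue group. Features absent from
  every blank are always kept (no division).
* **Intensity.** Strictly greater than 10⁶ arbitrary units, on the
  maximum over non-blank samples.
* **KMD window.** Inclusive bounds, with a 1e-12 guard against
  floating-point round-off of the rescaling. Default mode
  `or_with_suspect`: an out-of-window feature with a suspect-list hit is
  retained and tagged, because several curated hydrogen-rich
  polyfluorinated compounds (e.g. C22H37F9) fall outside the window
  under this convention and a literal hard window would discard them.
  `hard` mode mirrors the literal window.
* **Exclusion list.** Built from blank-only runs by merging entries
  within ±5 ppm and ±0.2 min to their mean m/z and RT. When no
  blank-run list is supplied the stage passes features through
  unchanged (the blank-ratio stage still uses the in-table blanks);
  running the blank-ratio stage without blank samples raises rather
  than silently keeping everything.

## Annotation and confidence levels

Suspect matching is at ±5 ppm on the theoretical [M−H]⁻ of each library
formula. When several suspects fall inside the tolerance (isomers share
a formula exactly), the hit with the best evidence wins: standard-RT
match first, then spectral score, then diagnostic-fragment count, then
|Δppm|, then name. This is what lets fragment evidence disambiguate a
branched from a linear isomer at identical mass.

Series detection treats features as nodes of a DAG ordered by m/z with
an edge where the gap is n × 49.9968064 (n ≤ 3) within ±5 ppm of the
heavier member and, by default, RT strictly increases. Chains are
extracted greedily, longest first, ties to the lower-m/z start, each
feature in at most one series. An independent O(n²) dynamic-programming
longest-chain finder backs the tests.

Spectral similarity is a greedy-pairing cosine: peaks are paired
closest-m/z-first within max(10 ppm, 0.01 Th) — the floor matches the
2–3 decimal precision at which diagnostic ions are typically printed —
and the score is the intensity dot product over pairs divided by the
full L2 norms, scaled to 0–100. It is symmetric, 100 for identical and
0 for disjoint spectra, and agrees with matchms's greedy cosine in the
tests. It stands in for an online library score, which is not available
offline; the scoring function is pluggable.

The confidence decision list (first clause wins):

1. standard-RT match (±0.2 min) **and** (spectral ≥ 60 **or** ≥1
   diagnostic fragment) → CL1;
2. spectral score **strictly** > 60 → CL2 (a "higher than 60" criterion
   is read as strict; at CL1 the standard is primary evidence and a
   score of exactly 60 suffices);
3. mass-list hit **and** (≥1 diagnostic fragment **or** series
   membership) → CL3;
4. unambiguous formula (or bare mass-list hit) → CL4;
5. otherwise CL5.

Adding evidence can only improve (never worsen) the level; this
monotonicity is property-tested.

## Differential analysis

Per-sample median normalization (each sample's median over detected
compounds scaled to the global median of detected entries; zeros
preserved), log2 transform with per-compound half-minimum imputation of
zeros, then a two-sided Welch t-test per compound on the log2 values.
The test is not canonical for this kind of data — vendor pipelines do
not document theirs — so it is the explicit, pluggable default;
Benjamini–Hochberg adjustment is available but off by default because
the reference volcano thresholds (p = 0.05, |log2FC| = 1) are on raw
p-values. Fold change is oriented liver/muscle (positive = up in
liver).

Compounds detected in only one tissue carry no testable contrast: they
bypass the test (p = NaN), are classed as up in the tissue where they
occur, and are flagged in `exclusive_to`. Compounds with fewer than two
detected values in a group are likewise routed through the exclusivity
rule rather than producing an unstable t-statistic.

PCA is column-centered over samples via scikit-learn; zero-variance
compounds are dropped with a warning, and the all-constant degenerate
case returns zero scores rather than failing. Hierarchical clustering
uses Euclidean distance on row-standardized log2 data with Ward
linkage; leaf order is scipy's deterministic distance-then-index order;
dendrograms export as Newick with branch lengths.

## Synthetic scenarios

The generator emulates the tissue study the curated table derives from:
18 animals per tissue (a config knob; the source reporting is ambiguous
between 18 and 20), duplicate injections, one procedural blank injected
twice, pooled QC injections. Feature populations:

* **True PFAS** (60): placed at the theoretical [M−H]⁻ of the curated
  formulas with Normal(0, 1.5 ppm) mass error and Normal(0, 0.05 min)
  RT jitter around the curated retention times; per-compound base
  abundance is the curated maximum area divided by 3, per-sample
  biological variation lognormal with CV 30%, technical replicate noise
  CV 10%, per-injection loading factors lognormal(0, 0.2). MS² spectra
  contain the curated diagnostic ions with lognormal(0, 0.2) intensity
  perturbation around the library intensities plus Poisson(3) low
  random noise peaks.
* **Blank contaminants** (50): present in blanks; the maximum tissue
  area is pinned at ratio × blank level with ratio ~ U(0.5, 8), i.e.
  strictly below the removal threshold of 10.
* **Background** (2000): hydrogen-rich by construction — KMD drawn from
  U(+0.15, +0.45) — with 5% carrying random MS², so the KMD window is a
  meaningful discriminator.

Planted effects: 20 compounds up in liver and 12 up in muscle at folds
U(2, 8) (chosen so recovery at n = 18/group is high but not saturated —
a fold of 2 sits exactly on the |log2FC| = 1 boundary), plus 4
muscle-only and 3 liver-only exclusives fixed to the compounds the
source study reported as tissue-exclusive. The ground-truth manifest
covers every feature exactly once. Homologous-series ground truth is
computed on the noise-free masses with the generated retention times
(adjacent curated homologues can elute within 0.01 min of each other,
so the realized RT order — not the idealized one — defines the planted
chains).

What the generator does **not** emulate: chromatographic peak shapes,
matrix effects and ion suppression, isotope patterns, co-eluting
isobars beyond the curated isomer pairs, or missingness mechanisms
other than tissue exclusivity. Passing planted-truth tests therefore
demonstrates correctness of the decision rules and statistics under the
stated noise model, not robustness to every artifact of real data.

## Problem sizes and determinism

Default scenarios (2110 features × 76 injections) generate in well under
a second, so the test suite runs the full design rather than a reduced
one; the multi-seed recovery checks use 20 seeds. All randomness flows
from a single integer seed through `numpy.random.default_rng`; two runs
with the same seed produce byte-identical exports, which the CLI tests
verify by checksum.

## Known limitations

* Only the [M−H]⁻ adduct and charge 1 are supported; adduct-rich
  ionization would need an extension of `chem.adduct_mz`.
* Three rows of the packaged curated table (codes 1, 36, 39) do not
  recompute from their printed formula/m/z under any standard
  convention tried (36 is off by ~36 Da, consistent with a
  transcription slip); `validate-table1` flags them and the validation
  summary counts them as discrepant rather than forcing agreement.
* The spectral score is a local cosine, not a cloud-library match
  score; absolute values are comparable only within a library.
* The pipeline starts from aligned feature tables; peak picking and RT
  alignment are out of scope.
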