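# Methods

This note documents the models implemented in `cysfoot`, the parameter
choices that matter, and what the synthetic-data-based validation does and
does not demonstrate.

## Spectral-count labeling quantification

The unit of quantification is the peptide-spectrum match (PSM): one
identified MS/MS spectrum, counted once, with no intensity weighting. For a
cysteine at protein residue *i*, every PSM whose peptide spans *i*
contributes one total count; PSMs whose localized modification sits at *i*
contribute one modified count. The labeling ratio is r = SC_mod/SC_total,
a fraction in [0, 1] interpretable as the site's probe-accessibility during
the labeling window.

**Replicate aggregation.** Replicate k contributes its ratio r_k with
weight w_k = n_k/N proportional to its total count n_k (N = Σ n_k). The
weighted mean Σ w_k r_k is algebraically identical to pooling all counts —
this exact equivalence is enforced by a property test and is the pipeline's
main internal oracle. Three error terms are reported per site/condition:

- **weighted standard error** SE = √(Σ w_k (r_k − r̄)² / (m − 1)), m = number
  of replicates with data; defined as 0 for m = 1. This is the simplest
  weighted dispersion consistent with a count-weighted mean; other
  conventions exist (e.g. effective-sample-size corrections) and would give
  slightly different values at strongly unbalanced depths.
- **measurement error** ME = √N/N = 1/√N, the counting (signal-to-noise)
  error of N pooled spectral counts. It equals 1 at N = 1 and decreases
  monotonically.
- **total error** = √(SE² + ME²) (quadrature). An RMS variant
  √((SE² + ME²)/2) is available via `rms=True`; quadrature is the default
  because the two error sources are independent and additive in variance.

**Multi-cysteine peptides.** When a peptide holds k > 1 cysteines and the
search engine cannot localize the modification, two policies are offered:
`localized_only` (default) excludes such PSMs from all their sites and
reports them in `ambiguous_fraction`; `fractional` credits 1/k modified
count to each contained site. The default is conservative: unlocalized PSMs
are necessarily modified ones, so exclusion biases ratios slightly downward
at affected sites (by roughly a factor (1 − f) on the modified counts at
failure rate f) — a bias well inside the counting error at realistic
depths, but worth remembering when multi-cysteine peptides dominate a site.
Both policies coincide exactly when every PSM is localized.

**Digestion and mapping.** Trypsin/LysC specificity: cleavage C-terminal to
K/R, suppressed before proline (LysC adds no sites under this rule).
Defaults: ≤ 2 missed cleavages, peptide length 5–50 — a typical LC-MS
detectability window, chosen here as an explicit package default. Peptides
are mapped to the protein by exact, unique substring match; I/L are not
conflated; ambiguous peptides raise rather than guess.

## Differential statistics

Welch's unequal-variance t-test runs on replicate-level ratios (one number
per replicate per condition) — the granularity at which independent
observations exist. Technical replicates and independent preparations are
treated alike as observations. Degrees of freedom follow
Welch–Satterthwaite; p-values are two-sided. Degenerate inputs (both
variances zero) return p = 1 for equal means and p = 0 otherwise; fewer
than two replicates on a side yields a reported row without a p-value
rather than an error. Significance stars use inclusive thresholds
(p ≤ 0.05/0.01/0.001). Raw per-site p-values are reported by default,
matching common practice for small fixed site panels; Benjamini–Hochberg
q-values are optional. Sites detected in only one condition are emitted as
presence/absence rows.

## Shear-force model

The cone-plate rheometer applies uniform shear γ̇ to a Newtonian fluid of
viscosity η, so the wall stress is τ = η·γ̇ (120 Pa at the modeled
conditions η = 0.02 Pa·s, γ̇ = 6000 s⁻¹). A filament of length L and width
d lying flat presents a rectangle A = L·d (0.0392 μm² at L = 4.9 μm,
d = 8 nm), and a complex tethering it feels F = τ·A (≈ 4.7 pN at mean
length). The flat-lying assumption is justified by the Weissenberg number
Wi = γ̇/D_r with the dilute-suspension rigid-rod coefficient

    D_r = 3 k_B T (ln(L/d) − γ_end) / (π η L³),  γ_end = 0.8.

At the defaults (T = 289.15 K, i.e. the 16 °C labeling experiment) this
gives D_r ≈ 9.1×10⁻³ s⁻¹ and Wi ≈ 6.6×10⁵; tethered-polymer experiments
show sub-degree tilt at Wi orders of magnitude smaller, so no tilt
correction is applied. The end-correction constant is a modeling choice;
published variants (0.66–1.57 depending on aspect-ratio treatment) move Wi
by well under a factor of 1.3 at aspect ratio ~600.

**Force distribution.** Polymerized filaments are modeled with an
exponential length distribution truncated at `max_length` (default 20 μm),
with rate λ solved (Brent) so the truncated mean equals `mean_length`
(4.9 μm). Since the truncated mean is bounded by max_length/2, a requested
mean at or above that bound raises an explanatory error; `max_length=inf`
selects the untruncated model. Force being linear in length, the mean force
and exceedance fractions are closed-form in the length CDF; a seeded
inverse-CDF Monte Carlo cross-checks the mean. Whether the quoted 4.9 μm
mean refers to the truncated or untruncated distribution is ambiguous in
the source data; the truncated reading is the default and the difference is
a few percent in the tail fractions.

## SASA and salt bridges

Shrake–Rupley with a 1.4 Å probe and 960 test points per atom by default;
points come from a Fibonacci (golden-spiral) lattice, which keeps the
isolated-sphere error under 1% at 960 points. Van der Waals radii are a
Bondi-type set (C 1.70, N 1.55, O 1.52, S 1.80, H 1.20, P 1.80 Å; unknown
elements get 1.70 Å with a warning). Neighbor pruning uses a k-d tree with
search radius 2×(max inflated radius). The implementation is validated
against the closed-form isolated sphere and against a 10⁵-point
random-direction brute-force reference on overlapping pairs (2%
tolerance), plus rigid-motion invariance.

Cysteine "side-chain SASA" sums CB and SG (and attached hydrogens when
present); backbone atoms are excluded. Multi-model PDB files are treated as
trajectory frames sharing one atom list. Salt-bridge distances are the
per-frame minimum over the charged-group heavy atoms (ASP OD1/OD2,
GLU OE1/OE2, ARG NH1/NH2/NE, LYS NZ, HIS ND1/NE2); a rupture is flagged
when the distance stays above a cutoff (default 4.5 Å — a conventional
choice, not a measured one) for a configurable dwell. Absolute SASA values
depend on the radius set and algorithm; comparisons across structures
computed with the same settings are meaningful, direct comparison to
figures produced with unknown settings is not.

## Binding thermodynamics

ΔG = R·T·ln(K_D) with R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹ and T = 298.15 K by
default (ITC at 25 °C); TΔS = ΔH − ΔG. Reported values round to one
decimal; consistency checks against measured tables use a 0.2 kcal/mol
tolerance to absorb rounding of the published columns. The package reports
computed affinity ratios directly (e.g. the full-length wild-type vs R551A
vinculin-D1 ratio 1.8×10⁻⁶/4.1×10⁻⁹ ≈ 440) rather than any pre-stated fold
number. ITC curve fitting is out of scope; inputs are fitted K_D/ΔH.

## Synthetic-data generator

The generator emulates a targeted single-protein footprinting experiment:
a toy protein with cysteines at the 12 αE-catenin positions (K/R placed
~every 12 residues so each cysteine falls in a detectable tryptic peptide),
and per condition/replicate a spectral depth per peptide drawn
Poisson(mean_depth) — MS sampling depth varies between injections — with
each cysteine of the peptide independently labeled with its ground-truth
probability. Marginally each site's modified count is Binomial(n, p_site);
simulating per peptide (rather than per site) keeps PSMs of shared
multi-cysteine peptides jointly consistent with spectral-count tallying.
Modified multi-cysteine PSMs are flagged unlocalized at a configurable
failure rate (default 0.2). Defaults: 5 replicates per condition and a mean
depth of 50 PSMs/site/replicate, reflecting a replicate structure and
spectral depth typical of targeted single-protein analyses.

Optional replicate heterogeneity (logit-normal perturbation of p_site,
default off) exercises the weighted-SE path. The generator does **not**
emulate: peptide-specific detectability/ionization efficiency, dynamic
labeling kinetics (time-dependence of r), lysine side-reactions, FDR/decoy
machinery, or intensity information. Passing recovery tests therefore show
that the quantification arithmetic and error model are correct under the
stated sampling model — not that real instrument-dependent biases are
absent.

## Validation scale and numerical choices

The test suite validates: exact pooled-count equivalence over random
replicate splits; ground-truth recovery (p = 0.4, mean depth 200,
4 replicates, 200 seeded experiments; ≥ 99% of site estimates within 3×
their reported total error); Welch type-I calibration on 4000 null sites at
depth ~200 and 5 replicates per side (tolerance ±0.012 around 0.05, ~3.5
binomial standard errors — at 5 replicates the t reference is itself
approximate for binomial ratios); and the SASA tolerances above. These
sizes keep the full suite under half a minute while leaving the Monte-Carlo
tolerances comfortably non-trivial.

Tie-breaks and degenerate inputs: simulated PSMs use the shortest digest
peptide containing a site (leftmost on ties); zero-coverage sites are
flagged absent rather than given a ratio; λ in the truncated-exponential
solver switches to series/asymptotic forms below λ·max_length ≈ 10⁻⁸ and
above 700 to avoid overflow; all random draws flow from a single
`numpy.random.default_rng` seed per run, making outputs byte-reproducible.
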