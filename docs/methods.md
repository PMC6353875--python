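# Methods

## Scope and model

`cspfit` analyzes protein-observed NMR titrations: a ¹⁵N-labelled
protein at fixed concentration is followed by ¹H-¹⁵N HSQC while an
unlabelled ligand (here, histone-tail peptides) is added stepwise. Each
assigned backbone amide reports a 2-D peak position (δH, δN); binding in
fast exchange moves peaks continuously toward their bound-state
position, and the displacement amplitude per residue follows the
single-site binding isotherm.

### Normalized CSP

The 2-D displacement relative to the apo spectrum is collapsed to

    Δδ = sqrt(ΔδH² + (w·ΔδN)²),   w = 0.20,

with w compensating the wider ppm dispersion of the ¹⁵N dimension. The
weight is uniform across residue types (some labs down-weight glycine
nitrogens; we keep a single configurable factor). The endpoint Δδ (apo
vs final titration point) is the quantity used for significance
classification; the full per-point trajectory feeds the fits. For
residues that broaden beyond detection mid-titration the trajectory is
truncated at the first absent point and the endpoint is the last
defined value; such residues are excluded from both the significance
population and the fits but reported with a `broadened` flag.

### Significance rule

The per-titration population is the endpoint Δδ of all assigned,
non-broadened residues (n ≥ 5 required). The ceil(10%) largest values
are removed, the mean and sample (n−1) SD are computed on the
remainder, and a residue is significant when its Δδ strictly exceeds
mean + 1.0·SD (a second tier at mean + 1.5·SD is also reported).
Trimming exists so that genuinely shifted binding-site residues do not
inflate their own threshold; trimmed residues are still classified
against the thresholds. Ties at the trim boundary break toward the
lower residue number so output is deterministic. ceil() rounding and
sample SD are our choices where the rule's prose leaves rounding and
the SD convention open.

### Binding isotherm and fitting

At 0.05–0.1 mM protein the bound ligand is a non-negligible fraction of
total ligand, so the hyperbola is replaced by the ligand-depletion
(quadratic) isotherm

    Δδ(L) = Δδmax · ((L+P+Kd) − sqrt((L+P+Kd)² − 4PL)) / (2P).

The implementation evaluates the algebraically identical rationalized
form `2·L·Δδmax / (s + sqrt(s² − 4PL))`, `s = L+P+Kd`, which avoids
catastrophic cancellation as P → 0 (the naive form loses ~7 digits at
P = 1e-9·Kd; the rationalized form agrees with the hyperbolic limit to
better than 1e-6 relative, and with a numerical quadratic-root solver
to 1e-10).

Per residue, (Kd, Δδmax) are estimated by trust-region least squares
(scipy's `trf` via lmfit) with positivity bounds and scale-aware starts:
Kd₀ = median non-zero ligand concentration, Δδmax₀ = 1.2× the largest
observed Δδ. Convergence tolerances are 1e-12 so noiseless round trips
recover truth to ~1e-7. Each fit records the fraction of protein bound
at the last fitted point; a fit is "saturated" when that fraction
reaches `saturation_cutoff` (default 0.8 — the underlying rule invokes
"lack of saturation" without a number, so the cutoff is exposed in
config).

### Global Kd aggregation

Candidates are the converged fits of significant residues (≥ 2
required). One pass: mean and sample SD over all candidate Kd values;
residues with |Kd − mean| ≥ 2·SD are excluded and mean/SD are
recomputed over the retained set. When SD = 0 the exclusion criterion
is skipped (it would otherwise vacuously exclude everything). The
result degrades to a lower-limit form "> min(Kd)" when either (a) the
excluded fraction reaches 50% or (b) more than half of the candidate
fits are unsaturated. The literal ≥2-SD trigger in (a) is nearly
impossible to trip for half of a sample (Chebyshev); trigger (b) is the
practical route to a lower limit and both are implemented because the
underlying wording supports both readings.

### The NB ("no binding") call

The relative threshold alone cannot produce "no significant residues"
on real (noisy) data: any continuous noise distribution has an upper
tail, and after trimming, roughly a fifth of noise-only residues exceed
mean + 1 SD. The pipeline therefore reports binding only when at least
one residue passes the tier **and** an absolute floor
`min_csp` (default 0.02 ppm, a conventional minimum detectable amide
shift, ~4× a typical 0.005 ppm peak-position uncertainty). A titration
in which no residue clears both is reported as NB and no fits are
attempted. The floor gates only the binding decision — significance
tables always report the pure relative classification.

## Synthetic data

The generator is the forward model the analysis assumes. Binder
residues share one true Kd; each gets a random fixed 2-D direction
(linear trajectories — fast exchange) and a saturation amplitude Δδmax
drawn from `ddmax_range`; the displacement magnitude at each point is
the isotherm value, resolved along the direction such that the
*weighted* CSP norm of the noiseless displacement equals the isotherm
exactly. Non-binders stay at their apo position. Independent Gaussian
noise (σ = `noise_sd` per dimension) is added to every non-apo point;
the apo spectrum is generated noise-free because it is the reference.
Optional broadening removes binder peaks on points whose fraction bound
falls inside a window (default 0.3–0.7 when enabled), mimicking
intermediate-exchange disappearance near half-saturation.

Defaults (chosen once as a realistic desk-scale titration):
[P] = 0.1 mM, molar ratios 0, 1, 2, 4, 8, 16, 32; 60 residues with a
25% binder fraction (~15 binders, the order of the significant-CSP
count on a ~110-residue construct); Δδmax ∈ [0.05, 0.25] ppm;
σ = 0.005 ppm. Two seeds separate structure (`direction_seed`: binder
identity, directions, amplitudes, apo positions) from measurement noise
(`noise_seed`), so noise replicates share one "protein".

What the generator does **not** emulate: peak overlap and assignment
ambiguity, residue-specific exchange regimes, protein dilution during
the titration, temperature/pH drift, and lineshapes of any kind.
Passing tests therefore demonstrate correctness of the analysis rules
and estimator behaviour under the stated noise model, not robustness to
spectral artefacts.

## Region mapping, restraints, genomic overlap

The default construct annotation covers EZH2 SRM-SANT1 residues
141–251 with helices α1 168–178, α2 221–230, α3 237–247; the SRM
C-terminal boundary (158) is an approximation and the annotation is
fully overridable by file. Significant residues (at a configurable
tier) become chain-A active residues of ambiguous interaction
restraints, each paired with the disjunction of the user-supplied
partner (chain B) residues; distance bounds default to 0–2.0 Å
effective distance per common docking practice and are configurable. No
passive residues are emitted by default.

Genomic co-occurrence uses the rule: same chromosome, compatible
strand, gap ≤ 150 bp on 0-based half-open intervals
(gap = max(0, max(starts) − min(ends)); touching intervals gap 0).
"." matches any strand by default (ChIP-seq peaks are usually
unstranded); `strict` mode requires equality. The implementation is a
per-chromosome sort + binary-search sweep, tested for exact agreement
with an O(n²) oracle. Counts are peak-wise (not merged-region-wise).

## Problem sizes used in tests

Unit and property suites run on populations of 5–200 residues, peak
sets ≤ 200 intervals, and titrations of 60 residues × 7 points; the
noisy-recovery study uses 200 replicates at σ = 0.005 ppm. These sizes
were chosen as the smallest that exercise every rule and keep the
estimator statistics stable.

## Known limitations

* Fast-exchange linear trajectories only; no two-site or cooperative
  models, and no global shared-Kd simultaneous fit (the per-residue
  fits are averaged instead, by design).
* Per-residue Kd standard errors are reported from the fit covariance
  but do not enter the aggregation.
* The NB floor is a fixed ppm value, not estimated from replicate
  spectra; with much noisier data it should be raised by config.
* Peak identity is by assigned residue number; there is no
  nearest-neighbour peak tracking for unassigned spectra.
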