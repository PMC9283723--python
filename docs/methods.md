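# Methods

This note records the models, defaults and design decisions behind
`cypselect`, in the order the pipeline runs.

## Signal model and the synthetic study

The generator emulates an inhibition-format luminescence screen. A compound
well's mean read is

    V = μ_DMSO + (a/100)·(μ_DMSO − μ_pos)

where `a` is the noise-free % activity from the compound's latent Hill
curve at that well's concentration, `μ_DMSO` the negative-control level and
`μ_pos` the positive-control (fully inhibited) level. Defaults
μ_DMSO = 3000, μ_pos = 100 give a ~30× signal-to-background ratio, the
magnitude typical of a well-behaved P450-Glo run. Noise is multiplicative
Gaussian with CV 10 % (luminescence noise scales with intensity); 10 % is
the level at which the per-plate CV quality bound (≤ 10 %) is attainable
but not guaranteed, matching the observation that real runs can exceed it,
and the QC stage therefore *flags* failing plates rather than aborting.
Activators are generated through the same map with positive efficacy
(signal above DMSO).

Latent activity: the default plan makes ~60 % of the library interact with
CYP3A7; 74 % of those also interact with CYP3A4 and 29 % of the remainder
interact with CYP3A4 alone, reproducing the published screen's common/
selective hit proportions at scale. 10 % of actives are activators. AC50 is
log-uniform on 0.01–30 µM, the Hill slope uniform on 0.8–2.5, absolute
efficacy uniform on 40–110 % (capped at 120 so super-maximal responses stay
plausible). Substrate status is drawn jointly (P(both) = 0.157,
P(3A7 only) = 0.063, P(3A4 only) = 0.293, matching the published 22 %/45 %
rates with 71 % overlap); substrate half-lives are **log-uniform** on their
range because first-order rate constants span orders of magnitude.
Descriptor tables are drawn per selectivity group from published group
profiles (diagonal-covariance normals; binary indicators as Bernoulli).

The plate artifact model is a separable row×column linear gradient whose
amplitude may drift linearly across the stack — deliberately the simplest
pattern the correction stage must remove. What the generator does **not**
emulate: luciferin-substrate chemistry, enzyme kinetics beyond the
Hill-response abstraction, dispensing errors, well-level outliers, or
correlated (non-separable) spatial artifacts. Passing round-trip tests
therefore demonstrates correctness of the estimators under the stated
noise model, not robustness to every failure mode of real plate data.

## Plate processing

Controls are aggregated by **median** for normalization and by **mean with
population SD (ddof = 0)** for the QC statistics (Z′, CV, S/B are
conventionally moment-based; medians are the robust choice for anchoring
% activity). CV is computed on the DMSO wells. S/B is mean DMSO over mean
positive signal (inhibition format: background = fully inhibited signal).

The stack correction is a documented substitute for proprietary in-house
algorithms: each all-DMSO plate yields a per-well profile (reads divided by
the plate median, hence scale-free), profiles are linearly interpolated
across stack position, and compound plates are divided well-wise by the
interpolated profile. It removes exactly the class of artifacts the
generator plants (separable gradients, linear drift) and is not a
reimplementation of any unpublished method.

## Concentration–response

The four-parameter Hill model is fit by bounded least squares in log10
concentration with multi-start initialization over a 7-point log-spaced
AC50 grid; AC50 is bounded to [min conc/10, max conc×10], the slope to
[0.3, 8], asymptotes to ±150 %. An analytic Jacobian keeps 1,000-series
runs fast. A best fit with AC50 above the top tested concentration is
retained but flagged beyond-range (and triaged as inactive: the data show
only a lower limb).

Curve classes follow the qHTS convention; since only the hit-calling
mapping is normative, the class definitions are config-exposed:

* class 4 — fit failed, |efficacy| below the noise band (default 20 %, or
  3× the DMSO-well SD when available), or beyond-range;
* class 3 — response above the noise band at the single highest
  concentration only (checked against the *data* before any completeness
  test, because a steep Hill curve can fit single-point activity
  arbitrarily well), or a residual fit supported by neither rule below;
* classes 1.1/1.2 — both asymptotes supported by at least one point within
  5 % of the fitted span; split at 80 % absolute efficacy;
* classes 2.1/2.2 — exactly one asymptote supported (the baseline for
  ordinary potencies, the response plateau for compounds saturating from
  the lowest tested concentration) and r² ≥ 0.9; same 80 % split.

Hit calls: 1.1/1.2/2.1 active; 2.2 active iff |efficacy| > 50 (strict, as
printed); 4 inactive; else inconclusive. Thresholds compare |efficacy|
because measured inhibition efficacies are negative while the criteria are
stated unsigned. The baseline is the low-concentration asymptote; data are
never re-zeroed.

## Selectivity

Selective = potency ≤ 1 µM, |efficacy| ≥ 65 %, ≥ 10-fold IC50 separation.
An inactive counterpart enters the fold ratio at the 100 µM sentinel rather
than excluding the pair, consistent with treating one-enzyme inhibition as
enzyme-specific. Inconclusive calls propagate to `not_classified`. The
scatter encoding uses pIC50 arithmetic with inactives pinned at exactly 4.0
(= 100 µM); the source material is internally inconsistent on whether the
sentinel means "above 50 µM" or "100 µM", and the 100 µM pIC50 reading is
used. Quadrants are taken relative to the sentinel with CYP3A7 on the
x-axis; points on exactly one sentinel axis get an enzyme-specific
boundary-box flag.

## Substrate depletion

Ordinary least squares of ln(% remaining) on time; k = −slope clipped at 0;
t½ = ln2/k; CLint = k·V/E with V = 110 µl and E = 3 pmol. Points below the
1 % limit of quantification are excluded; fewer than three usable points
(including t = 0) is a quantification failure. A fit is censored —
reported as the literal ">120" — when the fitted t½ exceeds 120 min **or**
the one-sided p-value for a negative slope exceeds 0.05; the two criteria
are OR-ed because reported ">120" values may come from either extrapolation
or slope insignificance. The censor horizon is 120 min although incubation
stops at 60 min, mirroring the extrapolated reporting convention. The
boundary t½ = 30 min counts as fast (`boundary_inclusive` flips to the
strict reading). Minus-NADPH control correction is intentionally not
modeled.

## Chemical space

The SOM is the plain online Kohonen algorithm (hand-written; no
pre-installed library provides one): Gaussian neighborhood on hex (default)
or rect grids, radius decaying linearly from half the larger grid dimension
to 0.5, learning rate from 0.5 to 0.01, Euclidean distance on raw bits,
codebook initialized from sampled data rows, deterministic under a fixed
seed. The default grid is auto-sized to ~10 compounds per node (the
published 5,000-compound/508-cluster ratio); any fixed grid, including
exactly 508 nodes, is config. Best-matching-unit ties break to the lowest
node index.

Enrichment uses two one-sided hypergeometric tests per occupied node
(enrichment and depletion are colored separately), heat =
−log10(min p) signed positive for enrichment. No multiple-testing
correction is applied to the heat coloring; a Benjamini–Hochberg column is
emitted for users. Descriptor comparisons are one-way ANOVA + Tukey HSD on
raw (untransformed) values; a descriptor constant across groups is
reported as p = 1 with a degenerate flag. Structure mode computes 1024-bit
hashed path fingerprints from SMILES via RDKit; no attempt is made to
bit-reproduce any particular fingerprint dialect.

## Validation experiments and problem sizes

The seeded experiments in `cypselect.validation` (shared by the test suite
and `scripts/acceptance.py`) use: 500 11-point curves at 10 % multiplicative
response noise for AC50 recovery and hit recall; 1,000 six-point time
courses at 10 % noise with true t½ log-uniform on 5–60 min for half-life
recovery; 100 seeds of a 500-compound, 10-cluster library with one cluster
planted at 90 % active fraction against a 10 % background, a 4×3 SOM and
5 epochs, for enrichment recovery; and exhaustive rational-arithmetic
enumeration of all 2×2 tables with N ≤ 12 for the Fisher tails. The
end-to-end demo default is 500 compounds on 384-well plate geometry; all
sizes are configuration, chosen to make the demo comfortably interactive.

## Known limitations

* The curve-class taxonomy is a reconstruction of the qHTS convention; only
  the hit-calling mapping is fixed.
* The stack correction removes separable multiplicative artifacts only.
* No bell-shaped (mixed-direction) curve modeling and no cytotoxicity
  counter-screen logic.
* Substrate/inhibitor disambiguation relies entirely on the depletion arm;
  the inhibition assay cannot distinguish the two.
* Screen-scale absolute hit counts depend on the latent activity plan and
  are not validation targets; the validated quantities are the recovery
  rates and the reference-panel classifications.
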