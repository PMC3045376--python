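# Methods

This note documents the models, defaults, and numerical choices behind
`effconn`, and states what the synthetic-data generator does and does not
emulate — hence what passing tests do and do not establish about real
acquisitions.

## Generative model

**Paradigm.** Stimuli are contiguous 15 s segments in five categories
(care, justice, neutral, strategic, tactical), presented as adjacent
same-category pairs with a neutral segment between consecutive pairs; the
default design is 6/6/17/6/6 segments (41 segments, 615 s). Surplus neutral
segments beyond the mandatory separators are placed at the start or end of
the sequence, reproducibly under the seed. The scan grid appends 16 s after
the last segment so that delayed-window block extraction and the HRF tail
remain on-grid. The repetition time is a free parameter; the default is
`tr = 2.0 s`, a common value for whole-brain 3 T echo-planar imaging.

**Neural model.** At each scan the active stimulus category selects a
path-coefficient matrix `B_c` and innovation variances `ψ_c`; neural
activity is the instantaneous structural equilibrium
`x = (I − B_c)⁻¹ e`, `e ~ N(0, diag(ψ_c))`. Outside any segment the
neutral variances apply with `B = 0`. Innovations are temporally white —
the simplest generative story consistent with downstream covariance-based
fitting; no physiological (cardiac/respiratory) or motion structure is
simulated. Condition switching happens at segment boundaries in the
innovations; the HRF convolution is applied afterwards.

**BOLD model.** Each node's neural series is convolved with the canonical
double-gamma HRF (response peak delay 6 s, undershoot delay 16 s, both
dispersions 1 s, undershoot ratio 1/6, kernel length 32 s, unit peak) and
receives white measurement noise of standard deviation `noise_sd`
(default 1.0, roughly 1/5 of the neural signal scale under the default
networks).

**Default networks.** The three modelled conditions use the published
group path-coefficient matrices of the four-node network (FP, pSTS, PCC,
rACC) as generating truth. Reciprocal path pairs in those matrices imply
loop gains at or above 1 (the care pSTS↔FP loop is 1.09 × 0.918 ≈ 1.0006),
which would make `I − B` numerically singular, so both members of every
reciprocal pair are rescaled by 0.7; after stabilisation
`det(I − B)` is 0.29 (neutral), 0.51 (care), and 0.51 (justice). The
strategic and tactical categories, for which no network is published,
reuse the neutral matrix. All innovation variances default to 1.

**Subjects and behaviour.** A cohort draws per-subject path coefficients
by adding `N(0, subject_sd²)` jitter (default 0.2) to every nonzero path,
independently per condition. The behaviour score is
`base + Σ slope·(subject's path value) + N(0, score_sd²)` with
`score_sd = 20`. The default link puts a negative slope on the
justice-condition pSTS→PCC path, sized as `slope = −√1.5·score_sd/subject_sd`
so that the linked path accounts for 60% of the score variance at the
generating level; the base is offset so the cohort mean sits at 350,
keeping scores in the instrument's 300–400 band (higher = more developed
justice reasoning; the score decreases as the linked path strengthens).

**What the generator does not emulate.** Voxel geometry and spatial
preprocessing; event-related responses to button presses (condition
regressors are block-level); autocorrelated or non-Gaussian innovations;
scanner drift (the GLM includes drift regressors, but the generator does
not inject drift); condition-dependent mean shifts — conditions differ in
*covariance structure*, not in mean BOLD amplitude, so contrast–behaviour
correlations carry no signal under this generator and brain–behaviour
coupling flows exclusively through path strengths. One important emergent
property: convolving variance-switching white innovations produces strong
common low-frequency envelopes, so BOLD-level covariances are inflated and
highly cross-correlated relative to the neural-level `Σ = (I−B)⁻¹Ψ(I−B)⁻ᵀ`.
Recovery results at the neural level do not transfer quantitatively to the
BOLD level.

## GLM

Condition boxcars (sampled at the scan grid) are convolved with the HRF;
drift is a discrete-cosine basis with a 128 s high-pass cutoff (the count
of drift columns is `⌊2·T/128⌋`), plus a constant. All five categories are
modelled; contrasts are named weight vectors over condition labels
(e.g. `care_gt_neutral: {care: 1, neutral: −1}`). Estimation is ordinary
least squares with `t = c'β̂ / √(σ̂² c'(X'X)⁻¹c)`. The rank and condition
number of the design are checked; a rank-deficient design raises an error
naming the collinear columns. The contrast–behaviour association is the
Pearson correlation with its F-test p; the median split assigns subjects
strictly above the median score to "high", with ties at the median going
to "low" (a deterministic rule), and compares groups with Welch's t.

## PPI

The seed's physiological series is taken as given (for multi-member
regions, `first_eigenvariate` returns the first left singular vector of
the column-centered member matrix, scaled to the standard deviation of the
mean member series and signed to correlate positively with it). The
psychological vector codes the two contrasted conditions +1/−1, 0
elsewhere, and is mean-centered over the coded scans. Two interaction
constructions are provided: `multiply` (default; the centered seed times
the psychological vector — the construction contemporaneous with the
block-design literature this pipeline reflects) and `deconvolve` (ridge
deconvolution of the seed against the HRF convolution operator with the
penalty chosen by generalized cross-validation, product at the neural
scale, reconvolution). The interaction slope is tested by OLS of the
target on [physiological, psychological, interaction, drift confounds,
constant]. Group inference is a paired t-test on per-subject interaction
slopes.

## SEM engine

**Block extraction.** For each block of a condition, the window
`[onset + shift, onset + duration + shift)` is taken (default shift 6 s,
absorbing the hemodynamic delay), its first two and last one scans are
dropped, and surviving scans are concatenated; the sample covariance uses
denominator `n − 1`. At `tr = 2 s` a 15 s block contributes 4–5 scans, so
a default-design subject yields ~27 justice-condition samples and a
17-subject pooled covariance ~460.

**Fitting.** Free parameters are one coefficient per directed edge plus
one log-residual-variance per node (positivity by construction). Because
`Σ = (I−B)⁻¹ diag(ψ) (I−B)⁻ᵀ` is positive definite whenever `ψ > 0` and
`I − B` is invertible, the objective needs no factorization:
`Σ⁻¹ = (I−B)' diag(1/ψ) (I−B)` and `ln|Σ| = Σ ln ψ − 2 ln|det(I−B)|`.
The analytic gradient is
`∂F/∂B = 2 (I−B)⁻ᵀ G Σ` and `∂F/∂ln ψ_k = ψ_k [(I−B)⁻ᵀ G (I−B)⁻¹]_kk`
with `G = Σ⁻¹(Σ − S)Σ⁻¹` (verified against finite differences in the
tests). Optimisation is multi-start L-BFGS-B (default 10 seeded restarts;
first start `B = 0`, `ψ = diag(S)`) followed by Newton polishing on a
central-difference Hessian toward a gradient tolerance of 1e−8. Standard
errors come from the observed information of the fit function:
`acov = 2/(n−1) · H⁻¹`, with ψ's SEs delta-transformed from the log scale.

**Convergence semantics.** A fit that misses the gradient tolerance or
whose observed information is not positive definite is returned with
`converged = False` and a reason — never an exception. This is how
under-identification surfaces: a model with more free parameters than the
`p(p+1)/2` covariance moments is rejected outright, and a structurally
non-identified topology (e.g. many reciprocal pairs at `df = 0`) shows up
as a singular information matrix. Every fit also reports the spectral
radius of `B̂` (a stability diagnostic) and whether the topology is
recursive (acyclic).

**Fit indices.** `χ² = (n−1)F_ML`; `RMSEA = √(max(χ²−df, 0)/(df(n−1)))`;
model AIC `= χ² + 2q` (the convention of the covariance-structure program
the pipeline mirrors; other AIC conventions differ by data-dependent
constants and would not change rankings); `GFI = 1 −
tr[(Σ̂⁻¹S − I)²]/tr[(Σ̂⁻¹S)²]`; `AGFI = 1 − [p(p+1)/(2df)](1 − GFI)`;
`PGFI = [2df/(p(p+1))]·GFI`; SRMR is the root mean square of the
standardized residuals of `S − Σ̂` over unique elements; `min_t` is the
smallest |t| among free path coefficients. At `df = 0`, RMSEA, AGFI, and
PGFI are reported as NaN (not applicable) rather than divided by zero.

**Search.** Enumeration yields every subset of the `p(p−1)` directed
edges, edge-count ascending then lexicographic, optionally capped by
`max_edges` and by the `df ≥ 0` identifiability rule (for 4 nodes: 2510
models). Non-converged fits are excluded from the ranking and retained
with reasons. Ranking sorts by the chosen index; criterion values are
quantized (1e−4 on AIC, 1e−6 on RMSEA) before sorting so that
covariance-equivalent topologies — whose optima differ only by optimizer
round-off — fall through to the deterministic tie-breaks: RMSEA, then
fewer edges, then enumeration order. Searches use fewer restarts per model
(default 3) than single fits; the full 4-node space takes ~35 s on one CPU.

**Identifiability caveats (important).** With 4 nodes there are only 10
covariance moments. Any just-identified topology (`df = 0`, e.g. any
6-edge model) reproduces *any* positive-definite covariance exactly, so a
fit criterion cannot distinguish among them — ranking within that set is
tie-breaking, not evidence. Published 7-path 4-node models have `q = 11 >
10` and are structurally under-identified; this engine surfaces that as a
precondition error rather than guessing at hidden constraints. Cyclic
just-identified models can also admit multiple exact parameter roots, so
per-subject confirmatory fits should use recursive (acyclic) topologies;
the end-to-end tests use the recursive reduction
pSTS→{FP, PCC, rACC}, rACC→PCC of the justice network for this reason.

## Group inference

Pathwise condition comparisons are paired t-tests across subjects on
per-subject confirmatory coefficients, with per-comparison threshold
`α/n_comparisons` (Bonferroni); a path absent from either condition's
model is reported as not-comparable, never dropped silently. (Group-level
summary tables with per-path standard deviations do not determine any
single comparison statistic; the paired per-subject test is the only
subject-resolved, self-consistent reading, and the package commits to it.)
Within-condition path significance is `|t| ≥ t_crit(α = 0.05, df = n−1)`.

Stepwise regression follows the classic forward–backward convention:
enter the predictor with the largest partial correlation if its increment
F-test (df 1, n−k−1) has `p < p_in = 0.05`; after each entry remove any
predictor whose partial F p rises above `p_out = 0.10`; iterate to a fixed
point. An empty selection is a legitimate outcome. A numerically perfect
fit stops entry (partial F on round-off noise is meaningless).

## Problem sizes in the test suite

Simulation-based tests are sized to single-CPU budgets: Monte-Carlo
covariance oracles use 10⁶ draws; null calibrations 500–1000 simulations;
power checks 200 runs; search-recovery 25–50 replicates; the end-to-end
stepwise recovery 100 cohort replicates. The long-paradigm recovery test
uses 240 justice blocks (~1080 extracted scans/subject) — far beyond a
realistic session — precisely to isolate per-subject estimation noise:
with the default 41-segment design (~27 scans/subject/condition) the
estimation error in per-subject coefficients attenuates the
coefficient–behaviour correlation to ~0.42, below what a 17-subject
sample can reliably detect at p < 0.05, so first-selection rates settle
near 50% rather than the ≥ 80% seen at large per-subject n. Analogously,
AIC-ranked search cannot single out a just-identified (df = 0) generating
topology at any sample size (see the identifiability caveats), and for a
correctly specified over-identified DAG the rank-first rate is capped near
`P(χ²₁ < 2) ≈ 0.84` — the chance that no superset's likelihood-ratio gain
exceeds AIC's 2-point penalty.

## Known limitations

- SEM treats extracted scans as independent samples; HRF-induced
  autocorrelation makes the effective n smaller than the nominal one, so
  χ²-based indices are anti-conservative at the BOLD level.
- The deconvolution PPI mode uses a single GCV-chosen ridge penalty per
  seed series; no uncertainty is propagated from the deconvolution step.
- The exhaustive search is exponential in edges; it is practical for the
  4-node network it was designed around, not for large networks.
- Between-subject jitter is independent across paths and conditions; real
  cohorts likely have correlated individual differences.
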