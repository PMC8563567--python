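# Methods

This note documents the models, conventions and numerical choices behind
`dynconn`, in the order the pipeline applies them.

## Input model

The unit of analysis is a per-subject matrix of T timepoints × N network
(or region) time courses at a fixed repetition time (TR), assumed to be
extracted, nuisance-regressed and band-pass filtered (0.01–0.1 Hz)
upstream. Defaults throughout mirror a resting-state acquisition of
290 volumes at TR = 2.072 s over ~21 networks. The package never touches
images; adapters from images to time courses are out of scope.

## Synthetic cohorts

The generator plants recoverable ground truth rather than mimicking BOLD
physiology:

- **State dynamics.** A first-order Markov chain over K states, switching
  at TR resolution, initial state drawn from the stationary distribution.
  Per-volume switching keeps dwell-time ground truth exact: with stay
  probability p, planted dwell times are geometric with mean 1/(1−p).
- **Emissions.** At each volume an N-vector is drawn from a zero-mean
  multivariate Gaussian with the active state's covariance; i.i.d.
  Gaussian observation noise is added afterwards, so planted covariances
  remain analytically recoverable.
- **Phase-coupled variant.** For the LEiDA pathway, networks are
  sinusoids at a common base frequency (default inside the 0.01–0.1 Hz
  band); each network carries a state-dependent phase offset scaled by
  (1 − its mean coupling to the other networks), drawn uniform on
  (−π, π]. Full coupling gives identical phases, zero coupling gives
  independent offsets; a K×N `phase_offsets` override allows exact
  constructions (e.g. quadrature pairs).
- **Cohorts.** Groups differ only through explicit overrides of the
  transition matrix or covariances. Ages are uniform on [65, 85] and
  sexes Bernoulli(0.5) — the covariates are real regressors but carry no
  planted effect. All generation is bit-reproducible from a single seed
  via spawned child seeds per subject.

What this does **not** emulate: haemodynamic convolution, scanner drift
and motion artefacts, spatially correlated noise, non-Gaussian BOLD
amplitude distributions, or autocorrelation within states (emissions are
temporally white given the state). Passing recovery tests on these
cohorts therefore demonstrates correctness of the estimators under the
stated model, not robustness to fMRI physiology.

## Time-course preparation

- **Detrending** removes a least-squares polynomial up to cubic order
  (including the mean) per column, computed on a Legendre basis for
  conditioning; the result is an exact linear projection.
- **Despiking** flags samples deviating from an 11-sample running median
  by more than 5 robust SDs and replaces them by a cubic spline fitted to
  the clean samples. The robust SD is estimated from first differences,
  σ̂ = 1.4826·MAD(Δx)/√2, because it is insensitive both to smooth
  deterministic structure (a running-median residual is zero in monotone
  segments and concentrated at extrema, which defeats residual-based MAD
  scales) and to the isolated spikes being detected. The exact despiking
  algorithm used by the toolchains this mirrors is unspecified, so this
  MAD-based rule is this package's own definition; window and threshold
  are configurable.

## Tapered sliding-window connectivity

- **Taper.** A length-L rectangle of ones is convolved with a discretised
  Gaussian (σ in TR units, support ±4σ), cropped symmetrically about the
  convolution peak to length L and normalised to sum 1. Normalisation and
  crop are conventions of this package; they make the windowed covariance
  scale-free. With L = 22 and step 1 over 290 volumes there are exactly
  269 windows; alternative lengths (18, 20, 24, 26) support sensitivity
  analyses.
- **Windowed covariance.** Taper weights act as observation weights:
  columns are centred by the weighted mean and cross-products weighted,
  normalised by the weight sum (a uniform taper reduces to the ordinary
  biased sample covariance). Multiplying the signal by the taper instead
  would be an alternative convention; observation weighting was chosen
  because it keeps single-state windowed correlations unbiased.
- **Graphical LASSO.** The precision maximises
  log det Θ − tr(SΘ) − λ‖Θ‖₁ over off-diagonal entries (diagonal
  unpenalised, the standard convention preserving positive-definiteness).
  The solver is scikit-learn's coordinate descent; because short tapered
  windows yield near-singular covariances on which coordinate descent can
  stall or cycle, failures fall back in order to LARS mode, a 1e-8
  relative diagonal jitter, and finally a self-contained proximal-gradient
  solver with backtracking (stopping when the successive-iterate
  max-change < 1e-6). λ = 0 uses the direct inverse and requires a
  well-conditioned S.
- **λ selection.** 20-fold cross-validation over windows with
  *contiguous* folds: overlapping windows are strongly dependent, so
  random folds would leak training information into the held-out score.
  Θ is fitted on the mean training-window covariance and scored by the
  mean held-out Gaussian log-likelihood log det Θ − tr(S_test Θ). Ties
  break toward larger λ (more regularisation). The default grid is 20
  log-spaced values on [1e-3, 1], a package choice. CV fits use a looser
  dual-gap tolerance (1e-4) than final fits since model selection does
  not need fully converged solutions.
- **Fisher z.** Window precisions are inverted to covariances,
  standardised to correlations and atanh-transformed. Diagonals are
  stored as 0 (self-connections are undefined on the z scale) and all
  edge summaries use the strict upper triangle in row-major order.
- **Residualisation** regresses each edge (or summary) on
  [intercept, centred age, centred sex] across subjects by OLS and
  returns residual + intercept, keeping values on the z scale. Group
  membership is deliberately excluded from this model. A constant
  covariate column is dropped with a warning.
- **Variability.** Per-edge sample SD across windows (denominator W−1);
  per-network values average the network's row excluding the diagonal;
  the global value averages the strict upper triangle.

## Brain-state clustering

- **L1 k-means.** Assignment minimises Manhattan distance; the centroid
  update is the coordinate-wise median, the exact minimiser of the
  within-cluster L1 objective (the objective is asserted non-increasing
  every iteration). Each restart initialises centroids at k distinct data
  rows; the study setting uses 500 restarts, and the lowest-objective
  solution is kept. Empty clusters are repaired by reseeding with the
  point farthest from its centroid. Returned states are relabelled in
  descending frequency order.
- **Validity index and elbow.** Index = (Σ distances to own centroid) /
  (Σ distances to all other centroids); k is the interior value
  maximising the discrete second difference of the index over consecutive
  k (greatest curvature), ties toward smaller k. k is scanned over 2..6.
- **State metrics.** Frequency; mean dwell time over maximal runs
  (boundary-censored first/last runs are *included* by default — with
  ~269 windows per subject, excluding them discards substantial data;
  a flag switches to exclusion); number of transitions = runs − 1; mean
  intertransition time = mean gap between 1-based positions of the first
  window of each new run, reported as missing with fewer than two
  transitions. Times are in window units; multiply by TR × step for
  seconds.
- Cohort fits pool all subjects' pattern vectors, then split labels back
  per subject in temporal order.

## LEiDA

- Columns are mean-centred before the Hilbert transform (the analytic
  phase of a non-centred signal is distorted); one volume is dropped at
  each end by default to blunt transform edge effects (configurable).
- dFC(n,p,t) = cos(θ_n − θ_p): 1 for aligned, 0 for orthogonal, −1 for
  antiphase; symmetric, unit diagonal, trace N.
- The leading eigenvector is the unit eigenvector of the algebraically
  largest eigenvalue. Eigenvectors are sign-ambiguous, and k-means
  results depend on the choice, so the sign is fixed with the common
  LEiDA convention: the majority of components negative; with exactly
  balanced counts, the first nonzero component negative. A near-degenerate
  top eigenvalue (gap < 1e-10 relative) is logged; the returned vector is
  still deterministic (LAPACK ordering plus the sign rule).
- The FCD matrix is the pairwise dot product of the unit eigenvectors
  (cosine similarity), clipped to [−1, 1] against rounding; its strict
  upper-triangle mean is the per-subject recurrence summary compared
  between groups.

## Static netmats and permutation inference

- Full correlations are Pearson over the whole series; partial
  correlations come from the (optionally ridge-regularised) precision,
  r_ij = −P_ij/√(P_ii P_jj). The default ridge is 0.1 × mean diagonal of
  S when T < 5N and 0 otherwise — a package rule, since common practice
  varies. Both are Fisher-z transformed with zero diagonal.
- The group test fits, per edge and correlation type, a linear model with
  one-hot group columns plus centred age and sex; the statistic is the
  contrast t-value for each signed pairwise group difference (six
  contrasts for three groups, equivalent to two-sided tests of the three
  comparisons). The null follows the Freedman–Lane scheme: data are
  residualised against the nuisance-only model, residual rows permuted,
  fitted nuisance added back, and the full model refitted. Family-wise
  error is controlled by the permutation distribution of the maximum
  statistic across the entire family (edges × types × contrasts). The
  unpermuted labelling is one of the n permutations, so the smallest
  attainable corrected p is 1/n; corrected p-values can never fall below
  uncorrected ones.

## Group statistics

- Kruskal–Wallis (tie-corrected, χ² reference) and Mann–Whitney U. The
  U test computes a two-sided exact p by full enumeration of group
  assignments with average-rank tie handling whenever n_a·n_b ≤ 400 (and
  the enumeration is small enough); otherwise the tie-corrected normal
  approximation with continuity correction. All-identical inputs return
  the degenerate (0, 1) result rather than an error.
- The nonparametric MANOVA rank-transforms each response column, computes
  the Pillai trace of the one-way between/within decomposition on ranks,
  and permutes group labels for the null; the observed labelling is
  counted, so p ≥ 1/(n_permutations+1). This is this package's own
  rank-permutation construction — a substitute for unspecified
  nonparametric MANOVA procedures in the literature, not a reproduction
  of any particular one. Default 5000 permutations.
- The medication-subgroup comparison runs the U test per scalar measure
  between flagged and unflagged subjects, skipping measures with an empty
  subgroup.

## Problem sizes used in the test suite

Simulation-based checks run at sizes chosen to exercise the estimators
while keeping the suite practical on a single CPU: planted-state recovery
uses cohorts of 10 subjects × 290 volumes × 10 networks with three
block-correlation covariance regimes (within-block r = 0.6, observation
noise SD 0.2, stay probability 0.95), a fixed λ = 0.1 for the per-window
fits and 10 k-means restarts; dwell-time group detection uses planted
label sequences at n = 30 per group; family-wise error calibration uses
200 null cohorts of 6 networks × 30 subjects with 200 permutations; rank
test calibration uses 2000 null replicates. The full cross-validated λ
path is exercised separately at smaller sizes.

## Known limitations

- The despiking rule and the rank-permutation MANOVA are this package's
  own constructions (documented above), chosen for testability; they are
  not bit-compatible with any external toolbox.
- Graphical-LASSO estimates on 22-sample windows are strongly
  regularisation-dependent; interpretation should rest on contrasts
  between groups processed identically, not on absolute edge values.
- The synthetic generator's scope (see above) limits what green tests
  imply about real fMRI data.
- k-means with forced k ≥ 2 always partitions the data; on cohorts with a
  single connectivity pattern the validity index is non-informative and
  coincident centroids raise an error rather than reporting spurious
  states.
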