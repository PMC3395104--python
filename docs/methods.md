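# Methods

This note records the models implemented in `somkit`, the choices made
where the classical self-organising-map (SOM) literature leaves the
design open, and what the synthetic data generators do and do not
emulate.

## The map and its geometry

A map is a rectangle of `n_rows x n_cols` hexagonal cells in odd-r
offset layout (odd rows shifted half a cell to the right).  Cells are
indexed row-major from 0.  Map distance between cells is the hexagonal
lattice distance: offset coordinates are converted to cube coordinates
and the distance is the maximum absolute cube-axis difference, which is
identical to the hop count over the neighbour graph.  Distances are
therefore integers (ring counts), not Euclidean centre-to-centre
distances; neighbourhood radii are interpreted in the same ring units.
Every interior cell has six immediate neighbours; edge cells have three
to five.

The default map size follows the common rule of thumb of roughly three
cells per training sample, searching rows x cols factorisations for the
cell count closest to `3 n` with an aspect ratio near 1.5, floored at
2 x 2.  The rule exists only to give samples room to spread; crowded or
very sparse maps are legitimate, and size should be overridden freely
(a 600-cell map for 72 samples is a perfectly reasonable choice when
well-separated BMU displays are wanted).

## Training

Training is the classical online algorithm.  Each of `T` iterations
draws one sample uniformly **with replacement** (this is what makes the
never-drawn probability `((N-1)/N)^T` exact), finds its best matching
unit (BMU) by Euclidean distance (ties to the lowest cell index), and
updates every cell `c` by

    W_c <- W_c + alpha(t) * h(d(c, b), sigma(t)) * (x - W_c)

with a truncated Gaussian kernel `h(d, sigma) = exp(-d^2 / 2 sigma^2)`,
zeroed beyond `d > ceil(3 sigma)`.  At `sigma = 0` only the BMU moves.
The learning rate `alpha` and width `sigma` are interpolated from start
to end values, linearly by default (exponential decay is available).
Defaults: `alpha` from 0.5 to 0.01, `sigma` from a quarter of the longer
map side down to 0.5, and `T = max(10000, 100 n)` so each sample is
drawn many times.  The kernel shape, decay law and endpoint values are
design choices of this toolkit — the classical algorithm only requires
that both quantities shrink.

All stochastic steps run off a single seeded generator, so a given
(data, grid, schedule, seed) produces a bit-identical codebook.  The
training log records the quantization error (mean sample-to-BMU
distance) at ten evenly spaced checkpoints rather than every pass, which
keeps logging cost negligible on large maps.

Initialisation is per-variable uniform over the observed data range by
default.  PCA initialisation lays the codebook on the plane of the first
two principal axes (`mean + u s1 p1 + v s2 p2` for fractional cell
position `(u, v)` in `[-1, 1]^2`, with `s` the singular values scaled to
standard deviations); it reduces the iterations needed but removes the
run-to-run variability that the significance machinery exploits, so
random starts remain the default.

## Map views

* **BMUs / hit histogram** — per-sample best cells and per-cell hit
  counts; counts always sum to the number of samples.
* **Class map** — each cell takes the class mixture of its nearest BMU
  cell(s) in map distance.  When several BMU cells tie for nearest, the
  fractions are proportional to the number of *samples* each tying cell
  hosts (a cell equally close to two single-sample class-A BMUs and one
  class-B BMU is 2/3 A, 1/3 B).  Weighting by hosted samples rather than
  by tying cells keeps the rule sensible when one cell hosts many
  samples.
* **U-matrix** — per-cell Euclidean dissimilarity to the ring-1
  neighbours; ridges mark cluster borders.  The default is the *mean*
  over neighbours so that edge cells (fewer neighbours) are comparable
  to interior ones; the plain sum is available as an option.
* **Component plane** — a codebook column min-max scaled so the most
  positive weight is 1 and the least positive 0.  A constant column has
  no contrast and maps to all zeros by convention.

## Supervised SOMs

Supervision appends one class-membership plane per class.  Training
samples carry crisp one-hot membership rows (fuzzy memberships in
[0, 1] are accepted); cell class planes start uniform on [0, 1].  The
joint BMU distance is

    d^2 = (1 - w) d_X^2 / nu_X  +  w d_C^2 / nu_C

where each block normaliser `nu` is the mean squared pairwise sample
distance of that block, fixed before training.  The normalisers give the
class weight `w` an interpretable scale: `w = 0.5` means the two blocks
carry equal importance regardless of dimensionality or units.  Updates
apply the same kernel to both blocks; class planes are clipped back to
[0, 1] after each update (range maintenance is a toolkit choice).

`w = 0` reproduces the unsupervised map **bitwise** for the same seed.
Internally the `w = 0` path uses a block scale of exactly 1 rather than
`1 / nu_X`, because rescaling squared distances by a constant can flip
float-rounded near-ties in the BMU argmin even though the exact argmin
is unchanged.

Prediction uses the variable block only (class membership is unknown
for a test sample): the test BMU's class fractions are read from the
class map of the training BMUs, so a test BMU equidistant between a
class-A and a class-B training BMU is assigned 50% to each.  %CC is the
mean fraction placed on the true class, times 100 — boundary samples
contribute fractionally.  One supervised map is trained per factor of
interest; maps for different factors are not comparable.

High class weights force class structure onto the map whether or not the
data support it, so training-set %CC is not evidence of a real effect —
always compare against a held-out test set.  The dummy-factor check in
the acceptance suite demonstrates the failure mode: near-total
training-set separation on a factor with no effect, with test-set %CC at
the random-model level.

## SOMDI and marker significance

The class component plane of class `k` is the class-map column for `k`
(1 where all nearest BMUs belong to `k`, 0 where none do, tie fractions
between).  The SOMDI index of variable `j` for class `k` is the sum over
cells of the scaled component plane times the class plane.  The
discrimination score subtracts the index of the merged complement
("everything except `k`" treated as one class): positive scores mark the
variable for `k`, negative for the rest; with two classes the score is
antisymmetric.  Indices are not normalised by class-region size by
default (an `index / sum(q)` variant is exposed for maps with very
uneven regions).  On unsupervised maps the scores are only meaningful
when the class of interest dominates the layout; the toolkit warns when
the strict-dominance class regions fragment into more than three regions
per class.

A single map is a stochastic object, so significance comes from
reformation: train `R` independent maps from fresh random starts (seeds
`base_seed + i`), score every variable, and count reforms with a
strictly positive score.  A variable positive in all `R` reforms is a
*stable* marker at confidence `1 - 1/R` (99% at the recommended
`R = 100`); a variable that flips sign is not significant, and a null
variable's positive count scatters binomially around `R/2`.  Reforms are
pure functions of their seeds, so results are independent of execution
order and worker count (`n_jobs` uses joblib).

## One-class process monitoring

A map trained only on the Normal Operating Conditions (NOC) window
describes the in-control process.  Every sample has a BMU — the map
cannot refuse a sample — so the decision statistic is how *well* the
sample fits: its grid of distances to all cells, summarised by default
as the minimum (a mean-of-k-smallest variant is available).  The control
limit is a percentile (default 95) of the NOC samples' own statistics.

Two calibration details matter and both default to the careful option:

* **Leave-one-out calibration.**  Scoring each NOC sample against the
  map it helped train is badly optimistic — with three cells per sample
  the map effectively memorises the window, resubstitution statistics
  collapse, and genuine in-control samples are flagged constantly.  The
  default therefore scores each NOC sample against a map trained with
  that sample left out, which mimics how unseen samples are scored.
  Resubstitution is kept as a cheap option.
* **Weibull plotting position.**  With a 30-sample calibration set, the
  usual linear percentile interpolation lands between the 2nd and 3rd
  largest order statistics, giving roughly an 8% expected exceedance
  instead of 5%.  The `(n + 1)`-convention (Weibull) percentile makes
  the expected false-alarm rate of a fresh in-control sample match the
  nominal level.

Even so, a limit estimated from 30 values is noisy: individual
monitoring runs show false-alarm rates scattered well around the nominal
5%, and calibration checks should compare the *average* rate over
repeated runs against the nominal level using the run-to-run spread.
Any preprocessing (centring parameters and the like) is fitted on NOC
data only and frozen for monitoring.

## Synthetic study designs

The generators reproduce published-style *designs* exactly and put
simple additive-Gaussian signal on top, returning the generating truth
so recovery can be verified.

* **Oils (NIR-like):** 72 samples in classes of 18/30/16/8 over 100
  variables.  Class means are mixtures of 3–5 Gaussian bumps rescaled so
  the smallest between-class centroid distance is 4x the expected
  within-class sample distance — tightly clustered, clearly separated
  groups.
* **Polymers:** 293 samples, nine groups of 35/47/10/56/45/30/20/10/40
  nested in two types (92 amorphous, 201 semi-crystalline); group means
  sit around type means with the between-type gap (8x within-group
  spread) larger than the within-type gaps (3x).
* **Saliva (NMR-like):** the 2 x 16 x 3 crossed design — 2 treatments x
  16 donors x 3 days, 96 samples, 6 per donor with 3 treated.  Treatment
  adds 2 noise-SDs to 5 planted marker variables of treated samples;
  each donor adds 2 SDs to 3 donor-specific variables; day has no effect
  (the dummy factor).  All marker sets are disjoint.  Effect sizes are
  standardised and were fixed once as "strong but not trivial" marker
  effects typical of a clearly detectable metabolomic response.
* **Process (HPLC-like):** 309 time-stamped samples of 12 peak areas
  over 105.11 h.  Composition is stationary (5% multiplicative
  log-normal noise) through sample 200, covering the NOC window at
  samples 63–92; from sample 201 four peak areas shift by ±30%
  (relative), ramped in over 10 samples and sustained.  Raw areas are
  emitted; square-root scaling and closure to a constant row total are
  applied by the preprocessing pipeline, as is standard for relative
  peak-area data.

What the generators do **not** emulate: realistic NIR/NMR lineshapes,
baseline and scatter artefacts, bucketing, peak integration,
heteroscedastic or correlated noise, and non-additive effects.  Passing
tests therefore demonstrate that the algorithms recover the structure
they are designed to recover under clean conditions; they say nothing
about robustness to instrument artefacts, which real studies handle in
preprocessing before data reach this toolkit.

## Numerical and testing notes

* BMU ties break to the lowest cell index everywhere; ranking ties keep
  input order (stable sort).
* The never-drawn probability is evaluated in log space
  (`exp(T log1p(-1/N))`), exact to double precision down to ~1e-300.
  For 500 samples and 1,000 iterations the exact value is 0.13506 —
  commonly quoted truncated as "0.13 or 13%".
* Quantization error uses direct (not expanded-quadratic) distance
  computation so identical codebook/data rows give exactly zero.
* Degenerate inputs have documented conventions: constant variables stay
  constant under random initialisation; constant component planes map to
  zeros; a single-class supervision or an `R = 1` stability run warn.
* The full-scale acceptance checks run 600-cell maps at 10,000
  iterations and 25-reform stability loops; module-level unit tests
  exercise the same code paths on smaller maps (≤200 cells, ≤3,000
  iterations) to keep the default suite fast.  Problem sizes are stated
  in each test.
* Model files are JSON containers written with sorted keys, so
  save → load → save is byte-identical and files are diffable.
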