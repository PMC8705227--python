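# Methods

This note records the modelling assumptions, parameter conventions and
numerical choices behind `dynmesh`, and what the synthetic benchmarks do and
do not establish.

## The estimation model

Each region's preprocessed series `r_i` is modelled, within a window of z+1
columns centred on a measured task volume, as a linear combination of its
functional neighbors: `r_i ≈ Σ_{j∈η_p[i]} w_{j,i} r_j`. All meshes are
trained jointly as a single-layer linear network by full-batch gradient
descent on

    Loss_i = mean_t (r_i,t − Σ_j w_{j,i} r_j,t)² + λ ‖w_i‖² .

Conventions and choices:

- **Objective scale.** The data term is the *mean* over the window's columns
  (an empirical expectation). The closed-form per-mesh ridge baseline solves
  the *same* objective, i.e. `w_i = (XᵀX + KλI)⁻¹ Xᵀ y` with K the window
  size. Writing ridge with an unscaled `λI` would make "ridge" and "trained
  network with weight decay" minimize different objectives and their
  agreement contingent on K; tying them to one objective makes the
  convergence oracle exact (they agree to ~1e-12 in practice).
- **L2 gradient.** The weight-decay term contributes `2λw` to the gradient by
  default (`include_l2_gradient=True`); a flag drops it to reproduce a
  data-term-only update.
- **Initialization** is zeros (deterministic; gradient descent from zero on a
  rank-deficient least-squares problem converges toward the minimum-norm
  solution, which matches the ridge baseline's `lstsq` fallback at λ=0).
  Seeded Gaussian init is available.
- **Learning rate.** The documented protocol default is 1e-8 with 10 epochs,
  which is tuned to raw scanner-unit BOLD magnitudes. On unit-scale synthetic
  data that rate barely moves the weights, so the package also offers
  `learning_rate="auto"`: 1/L with `L = 2·s/K + 2λ`, `s` the top eigenvalue
  of the window Gram matrix — the largest per-mesh Lipschitz constant, which
  guarantees monotone loss descent. Convergence-sensitive analyses (oracle
  comparisons, recovery) use auto rate with an early-stop tolerance on the
  gradient norm.
- **Neighborhoods.** `p` defaults to the full neighborhood M−1 (self-
  connections are forbidden, so requests of p ≥ active regions clamp to
  active−1 with a warning). Constant-in-window regions correlate 0 with
  everything; inactive regions are never neighbors.
- **Windows** are truncated at puzzle boundaries rather than dropped
  (minimum 3 columns, else the instant is logged and skipped): dropping
  boundary instants would discard the first volume of every puzzle — the
  start of planning. Windows are trained independently per instant, with no
  warm start, matching the per-window definition of the network.

## Preprocessing conventions

- ANOVA groups are exactly {planning, execution}; rest/fixation volumes never
  enter the F computation. Constant voxels (MSW = 0) are scored +inf,
  flagged, and excluded from selection by default — a constant series carries
  no dynamics worth averaging into a region.
- Voxel selection is per run; ties in F break by voxel index, which makes
  top-k selection monotone in k. The elbow cut maximizes perpendicular
  distance between the sorted-score curve and its endpoint chord.
- Splines are confined to within-puzzle segments: interpolating across a rest
  period would manufacture task–rest transitions that were never sampled.
  Two-knot segments degenerate to the straight line (a cubic through two
  points is underdetermined); single-volume segments pass through with a
  warning.
- Noise moments `μ(r_j)`, `σ²(r_j)` are estimated over the run's task
  columns. Noise is *added in place* (`r̃ = r + τ`), not appended as extra
  samples: the study's instance counts show no augmentation.
- Labels of interpolated columns come from the nearest measured volume; with
  even z there are no ties (offsets 1..z/2 inherit left, the rest right).

## Graph measures

Estimated weights are signed; before graph analysis each network is shifted
by |most negative weight|, scaled by the resulting maximum into [0, 1], and
pruned of inactive nodes. Shift and scale are computed **per network** so
every instant's graph independently spans [0, 1]. Distances use the length
matrix `L = 1/W` (∞ off-support); unreachable pairs contribute 0 to
efficiency and betweenness sums.

Two weighted-clustering conventions are implemented: the default sums
`(w_ij · w_ih · w_jh)^{1/3}` over ordered neighbor pairs; the `fagiolo`
mode uses the direction-split form
`[(W^{1/3} + (Wᵀ)^{1/3})³]_ii / (2·triplets_i)`. Both are verified against
brute-force enumeration; the latter also against networkx. A node's local
efficiency is the global efficiency of the subgraph induced by the union of
its in- and out-neighbors. Betweenness uses Brandes' algorithm with the
directed normalization 1/((M−1)(M−2)).

Per-phase aggregation averages each per-node metric across a run's instants
of that phase (pruned regions excluded via NaN); this instant→run reduction
is a package choice — any monotone summary would support the same
ranking-style analyses.

## Decoding

- Default folding is puzzle-grouped: a measured instant and its own
  interpolated neighbors share ~8/9 of their generating spline, so
  instance-level folds leak. The instance scheme is provided for protocol
  fidelity.
- The 2-means cluster→label mapping is chosen on *training* rows (majority
  label per cluster — equivalently the better of the two assignments on the
  training set) and applied to held-out rows. Choosing the mapping on test
  rows inflates chance-level accuracy by ≈0.4/√n_fold, which would bias any
  permutation-null assessment.
- Chance-level checks are only calibrated against 0.5 when the evaluated rows
  are class-balanced; `decoding.balance_classes` subsamples the majority
  class for exactly this purpose. With the study's unequal phase lengths a
  majority-class learner scores the majority fraction under any label
  permutation — a property of the data, not of the decoder.

## The synthetic generator

The generator emulates: multi-subject, multi-run recordings at TR = 1 s;
18 puzzles per run, each a planning block then an execution block (lengths
1 + Poisson(mean−1), means 5.91/5.63) separated by 12-volume rests with a
28-volume closing fixation; region-structured voxels (each voxel = its
region's latent signal + i.i.d. noise, a configurable fraction additionally
carrying a condition shift of `effect_size` voxel-noise SDs during
planning); and latent inter-region dependencies from a known stable coupling
matrix, either lagged (`x_t = Wᵀx_{t−1} + ε`, default) or contemporaneous
(`x = (I − Wᵀ)⁻¹ε`). Every draw flows from one root seed.

It does **not** simulate hemodynamic convolution (the pipeline operates on
raw series and has no HRF model), physiological/scanner noise spectra, or
spatial autocorrelation beyond region membership. Passing benchmarks on this
substrate establish algorithmic correctness — that the estimator recovers
the generating coupling, that the measures match their definitions, that the
decoders find planted effects and nothing else — not that the pipeline's
accuracies on real recordings will match any particular value.

**Recovery fixture.** A simultaneous linear system `x = Wᵀx + ε` is
identifiable by least squares only up to reciprocal-pair mixing (regressing
`x_i` on all other regions estimates approximately `W + Wᵀ` minus
second-order terms), so an asymmetric ground truth bounds attainable
element-wise correlation near 1/√2 regardless of estimator quality. The
recovery fixture therefore defaults to a random *symmetric* stable coupling
in contemporaneous mode — the well-posed case — where converged estimates
correlate ≈0.99 with the truth. The latent condition offset in the general
generator has its own amplitude (`latent_effect_size`, default 0) so a zero
`effect_size` yields an exact null for score calibration.

## Problem sizes

The shipped benchmarks run on scaled-down studies chosen to exercise every
code path: graph-measure oracles on ≤8-node digraphs (1,000 draws),
estimator–oracle agreement on 100 random 9-column windows, recovery at
M = 5 × 1,000 volumes, decoding on 16-puzzle runs with 20 regions × 20
voxels, and null calibration at 90 regions × 112 voxels (~10,000 voxel
scores, the scale at which the selection threshold operates). The full
90-region, 18-subject configuration is the generator default and runs the
same code.

## Known limitations

- With z = 0 there are no interpolated columns and windows degenerate to
  single measured volumes; estimation requires ≥3 columns and refuses.
- λ for the ridge/weight-decay term has no published value; the default (1.0)
  is exposed as configuration and analyses that need exact least squares set
  it to 0.
- The per-network shift/normalization makes absolute weight magnitudes
  incomparable across instants; all shipped analyses use within-network
  structure or cross-phase comparisons, which are invariant to it.
- TSV export of networks is lossy (formatted floats); HDF5 is the canonical
  store and round-trips bit-exactly.
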