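# Methods

## Overview

`topovar` compares two conformational ensembles of the same molecule — a
control protein and a case protein with the same residue numbering — and
flags cycles (loops and voids of the CA backbone) whose geometry differs
intrinsically between the two, beyond what thermal fluctuation explains.
The pipeline is: per-frame persistent homology → cycle tracking and
control/case matching → conjugate Bayesian inference per cycle per
protein → Jeffreys-divergence scoring with a detection threshold.

## Persistent homology

**Filtration.** The physical picture is balls of common radius r grown
on the CA points; a loop (1-cycle) or void (2-cycle) is born when the
union of balls first encloses it and dies when the balls fill it in.
The default backend is the **alpha complex**: faces of the Delaunay
triangulation, each entering at the radius of its smallest empty
circumscribing ball (Gabriel faces at their own circumradius, other
faces inheriting the smallest coface value, with a final monotonicity
clamp against floating-point round-off in circumradii). In 3-D this
reproduces the growing-balls (Čech) persistence exactly while keeping
the complex linear in the number of points. A **Vietoris–Rips** backend
(simplex value = longest edge) is available for cross-checking; both
report on a common **ball-radius scale** in ångströms (Rips diameters
halved), with a `scale="diameter"` option for edge-length units.
Degenerate clouds are handled by triangulating in the points' affine
hull (coplanar) or connecting consecutive points (collinear), which
gives the same growing-balls persistence as the ambient construction.

**Reduction and representatives.** Persistence pairs come from the
standard R = D·V column reduction of the Z/2 boundary matrix, columns
stored as integer bitsets, simplices ordered by (filtration value,
dimension, lexicographic vertex tuple) — deterministic by construction.
Each finite interval carries the **birth representative**: the cycle
recorded in the V column of its creator simplex. We use the birth-time
rather than the death-time representative deliberately: at birth only
the feature's own simplices exist, so the representative's vertex set is
reproducible across noisy re-samplings of the same geometry, whereas
near death an avalanche of nearly tied simplices makes the death
column's support unstable. Representatives are not minimal in general;
determinism and stability were preferred over minimality. Intervals
with lifespan ≤ 1e-9 Å are dropped: exact ties in filtration values
(zero-persistence pairs) acquire machine-epsilon lifespans under
floating point, far below any physical feature.

Infinite (essential) classes and dimension-0 components are not
reported; only finite loops and voids are modelled downstream.

## Cycle identity, tracking, filters

A cycle's identity is the pair (homology dimension, representative
residue set), compared by exact set equality — a loop is "the same"
across frames and across proteins when the same residues span it. Both
chains of a multi-chain molecule enter one joint point cloud, so a cycle
may span chains. Within one frame, duplicate identities keep the
largest-lifespan interval, giving at most one observation x_t per frame
per cycle, as the i.i.d. model assumes. Frames are numbered from 1.

A matched control/case pair of tracks is scored only if, in *both*
proteins, the cycle is observed at least `min_obs` = 5 times (this also
guarantees a proper posterior; see below) and first appears within the
first `first_steps` = 5 frames. "Steps" are the saved frames the
analysis sees.

Exact-set identity is conservative: a representative that gains or
loses one residue starts a new track. The observation-count filter then
discards such fragments, which costs sensitivity for marginal cycles
but never invents matches. (The birth-representative choice above is
what keeps the main features' sets stable in practice.)

## Bayesian model and SV score

Per cycle and protein p, observations x_t = (b_t, l_t) with lifespan
l_t = d_t − b_t (lifespans decorrelate the otherwise nearly equal birth
and death times). Model: x_t ~ N(μ⁽ᵖ⁾, Σ⁽ᵖ⁾) with conjugate prior
Σ ~ W⁻¹(Ψ₀, ν₀), μ|Σ ~ N(m₀, Σ/κ₀); defaults Ψ₀ = I, ν₀ = 2 (the
dimension), κ₀ = +0. The κ₀ → +0 limit is implemented exactly: the
posterior mean equals the sample mean and m₀ drops out. (Formally the
limiting prior factor on μ is ∝ |Σ|^(−1/2); with that factor the
textbook updates Ψ = Ψ₀ + S, ν = ν₀ + N, m = x̄, κ = N hold verbatim,
which the conjugacy test verifies against grid-evaluated Bayes' rule.)
N ≥ 5 observations make the posterior proper; `fit_posterior` refuses
fewer. Identical observations (zero scatter) are allowed — Ψ = Ψ₀ keeps
the posterior proper without extra regularisation.

**Scoring.** From each posterior, 1,000 (μ, Σ) pairs are drawn on
independent seeded streams (Σ ~ W⁻¹(Ψ, ν), then μ ~ N(m, Σ/κ)); draw i
of control is paired with draw i of case, giving 1,000 Jeffreys
divergences between N(μ⁽¹⁾, Σ⁽¹⁾) and N(μ⁽²⁾, Σ⁽²⁾) via the closed
form for normals. The SV score is the 5th percentile (linear
interpolation between order statistics) of those draws; detection is
the strict comparison SV > D\* with D\* = 4. The number of draws is a
Monte-Carlo accuracy knob: 1,000 keeps the 5th-percentile error small
while remaining fast; the draw pairing (rather than a cross product)
changes the percentile only at O(1/n_draws).

**Interpretation of D\* = 4.** When Σ⁽¹⁾ = Σ⁽²⁾ = Σ and both sample
sizes grow, the posteriors concentrate and every divergence draw tends
to the squared Mahalanobis distance (μ₂−μ₁)ᵀΣ⁻¹(μ₂−μ₁); the threshold
therefore reads "cycle means more than 2 SD apart". The score measures
magnitude of difference, not statistical significance, and no
multiple-testing correction is applied across cycles.

## Geometry module

Cartesian corroboration of topological detections: Kabsch least-squares
superposition (SVD with a determinant correction; proper rotations
only), an average structure obtained by iteratively superposing all
conformations onto the running mean until it moves < 1e-6 Å RMS (≤ 50
iterations), and per-frame RMSD profiles of each protein against a
reference average, with per-protein mean and SD. Superposition is
per-frame; the average is defined up to a global rigid motion.

## Synthetic data

The generator emulates what the pipeline needs from an MD trajectory:
labelled CA-like points with persistent features and frame-to-frame
noise.

* **ring** (loop): n evenly spaced points on a circle. Default 8 points
  at radius 5 Å gives 3.8 Å spacing — the CA–CA distance of a real
  backbone. On the radius scale the loop is born at half the largest
  gap (≈ 1.9 Å) and dies at the circumradius (≈ 5 Å).
* **shell** (void): n Fibonacci-lattice points on a sphere (default 12
  at 6 Å); the void dies at the sphere radius. A shell also carries
  short-lived incidental loops of its triangulation — realistic
  nuisance structure that exercises the filters.
* **background**: a straight strand with 3.8 Å spacing placed at least
  3× the largest feature size away, standing in for the rest of the
  chain; a `clutter` option scatters it uniformly instead, for stress
  tests.

Thermal vibration is i.i.d. isotropic Gaussian jitter per frame,
default σ = 0.3 Å (a typical backbone fluctuation scale in structured
regions), matching the i.i.d. assumption of the Bayesian model. The
default frame count is 500, the sampling depth the pipeline expects
from an MD run; tests and the examples use 12–100 frames, which already
saturate the observation-count filter. A control/case pair shares
residue labels and *identical background coordinates* (placed from the
control geometry — otherwise a shifted feature would drag the
background and plant spurious differences); the case shifts one
feature's radius and/or center; the two ensembles get independent noise
streams, like separately sampled trajectories.

What the generator does **not** emulate: autocorrelated dynamics,
anisotropic or residue-dependent fluctuations, bonded geometry along
the chain, and conformational substates (multimodal x_t). Passing tests
on synthetic data therefore validate the machinery — exact persistence,
correct conjugate inference, calibrated null behaviour, power against
planted shifts — not robustness to violations of the i.i.d. normal
assumption in real trajectories.

## Numerical choices and edge cases

* Simplex order ties broken by dimension then lexicographic vertex
  tuple; point clouds are canonically sorted by (chain, residue index,
  insertion code), so results are independent of input point order.
* Alpha filtration values are clamped to be monotone over faces
  (round-off guard); rigid-motion invariance of intervals holds to
  ≈ 1e-9 Å on generic clouds.
* PDB parsing keeps altloc 'A' or blank, folds insertion codes into the
  residue key, ignores HETATM and non-CA atoms, and rejects frames
  whose residue lists differ (no imputation — cycle identity needs a
  stable residue universe).
* Masking below 3 points, or persistence on < 3 (loops) / < 4 (voids)
  points, is a degenerate-input error.
* Per-cycle scoring seeds are spawned deterministically from the run
  seed in the sorted cycle order, so a run is reproducible
  byte-for-byte from its manifest.

## Problem sizes

The test-suite and acceptance computations use desk-scale inputs chosen
to make each property unambiguous: clouds of ≤ 40 points per frame,
ensembles of 12–100 frames (60 frames × 20 seeds for the ground-truth
recovery study), 10,000 observations per group for the Mahalanobis
limit, and 1,000 posterior draws per score. Real MD-derived ensembles
(hundreds of residues, 500 frames) run through the same code paths; the
alpha backend keeps per-frame cost near-linear in residue count.

## Known limitations

* Exact residue-set identity can fragment tracks of marginal features;
  a Jaccard-threshold matcher would be more permissive but risks
  chaining distinct cycles, and is not currently implemented.
* The Rips backend enumerates all simplices up to dimension 3 and is
  practical only for small clouds (tens of points).
* Scores of overlapping cycles are correlated (shared residues), and
  no multiplicity control is applied — consistent with reading SV
  scores as effect magnitudes.
* Disorder exclusion is the user's responsibility via the residue
  mask; no secondary-structure assignment is performed.
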