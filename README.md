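# topovar

Detecting **intrinsic structural variation** between two conformational
ensembles of a protein — a control form and a case (e.g. mutant) form —
while discriminating it from ordinary thermal fluctuation.

A single pair of static structures cannot tell whether a geometric
difference is meaningful: both molecules vibrate. `topovar` consumes an
*ensemble* per protein (e.g. frames of a molecular-dynamics trajectory,
as a multi-model PDB or a plain coordinate table), extracts the loops and
voids of the alpha-carbon backbone with persistent homology, and scores
each matched cycle with a Bayesian measure of how far the case's cycle
geometry lies from the control's, relative to each protein's own thermal
spread. Typical users are structural bioinformaticians comparing mutant
forms of the same protein (polymorphic immune receptors, viral spike
variants) from sampled conformations.

## Method

1. **Topology per frame.** For each frame, the CA coordinates (optionally
   after removing user-masked disordered residues) form a point cloud.
   Growing balls of common radius r on the points creates and destroys
   loops (H₁) and voids (H₂); each cycle contributes a birth–death pair
   (b, d) in ångströms. The filtration is computed exactly with an alpha
   complex (Vietoris–Rips available as an option), and every interval
   carries a representative cycle's residue set.
2. **Tracking and filtering.** A cycle's identity is (dimension,
   representative residue set). Identities link observations across
   frames and match cycles between control and case. Only cycles observed
   ≥ 5 times in *both* proteins, and first appearing within the first 5
   frames in *both*, are scored.
3. **Bayesian model.** For protein p ∈ {1, 2}, the per-frame observations
   x_t = (b_t, l_t), with lifespan l_t = d_t − b_t, are modelled as
   x_t ~ N(μ⁽ᵖ⁾, Σ⁽ᵖ⁾) under a conjugate Normal–Inverse-Wishart prior
   Σ ~ W⁻¹(Ψ₀, ν₀), μ|Σ ~ N(m₀, Σ/κ₀) with the non-informative choice
   Ψ₀ = I, ν₀ = 2, κ₀ = +0. The posterior is closed-form:
   Ψ = Ψ₀ + S, ν = ν₀ + N, m = x̄, κ = N.
4. **SV score.** Parameter pairs are sampled from both posteriors and
   compared with the Jeffreys divergence
   D_J = D_KL(p‖q) + D_KL(q‖p) (closed form for normals). The
   **structural variation score** is the 5th percentile of 1,000 paired
   divergence draws — a lower credible bound on the dissimilarity — and a
   cycle is flagged when it exceeds the threshold D\* = 4. When the two
   covariances agree, the SV score tends to the squared Mahalanobis
   distance (μ₂−μ₁)ᵀΣ⁻¹(μ₂−μ₁), so D\* = 4 means "means more than 2 SD
   apart".

See `docs/methods.md` for assumptions, parameter choices and limitations.

## Worked example

Plant two 8-residue rings (radius 5 Å, CA-like 3.8 Å spacing, 0.3 Å
thermal jitter) plus background residues; widen the first ring by 0.9 Å
(3 noise SD) in the case ensemble only. With `example_spec.json`:

```json
{
  "n_frames": 100,
  "noise_sd": 0.3,
  "features": [
    {"kind": "ring", "n_points": 8, "size": 5.0, "center": [0.0, 0.0, 0.0]},
    {"kind": "ring", "n_points": 8, "size": 5.0, "center": [25.0, 0.0, 0.0]}
  ],
  "background_points": 5,
  "seed": 7,
  "clutter": false
}
```

```sh
topovar simulate --spec example_spec.json --pair --radius-delta 0.9 --out fixtures
topovar run --control fixtures/control.pdb --case fixtures/case.pdb \
            --seed 11 --out run1
```

Output:

```
matched cycles: 6
detected variations: 1
results written to run1
```

`run1/results.csv` (abridged):

```
cycle_id                             n_control  n_case  sv_score   detected
H1[A:1;A:2;A:3;A:4;A:5;A:6;A:7;A:8]        100     100  15.650102  True
H1[A:1;B:5;Z:1;Z:2;Z:3]                     27      22   0.145229  False
H1[B:1;B:2;B:3;B:4;B:5;B:6;B:7;B:8]        100     100   0.031511  False
H1[B:5;Z:2;Z:3;Z:4]                          6       7   0.383436  False
```

The widened ring (chain A) is the only detection: its SV score 15.65 says
the posterior cycle geometries of control and case are far apart even at
the credible lower bound, while the untouched ring (chain B, SV 0.03) and
incidental short-lived cycles stay well under D\* = 4. The full run
directory also contains per-frame persistence tables, Jeffreys-divergence
samples per cycle, summary statistics tables and a JSON manifest that
reproduces the run byte-for-byte.

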