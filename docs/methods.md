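# Methods

This note records the models and conventions behind `cyclokit`, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical choices that matter when interpreting output.

## Units and frames

All quantities are in the MD engine's native units: nm, ps, kJ/mol,
elementary charge, kelvin (`kB = 0.0083145 kJ/mol/K`, default temperature
300 K). Coordinate frames travel as concatenated fixed-column text GRO
blocks (3-decimal nm) or multi-MODEL PDB (read-only, Å converted to nm).
Only rectangular periodic boxes are supported; every distance-like operation
applies the minimum-image convention when a frame carries a box and plain
Euclidean arithmetic otherwise. When GRO titles carry no `t=` stamp, frames
are numbered 0, 1, 2, …; all kinetics operations accept an explicit `dt` to
override. Analyses that summarize a trajectory default to the trailing 10 %
window (`window_fraction = 0.10`), the convention used for equilibrated
production averages; the window is a parameter everywhere because which
frames enter an average is an analysis decision, not a property of the data.

## Host geometry model

The cyclodextrin is described by three stacked atom rims: the primary
hydroxyl rim (PHR, all O6 — the narrow side), the middle glycosidic ring
(MID, all O1) and the secondary hydroxyl rim (SHR, all O3 — the wide side).
A `CDTopology` maps per-glucose roles (O1…O6, C1…C6, CM2/CM3/CM6 methyl
pseudo-atoms) to atom indices in azimuthal ring order.

* **Rim area** uses centroid-fan triangulation in 3-D: the sum of triangle
  areas (centroid, vᵢ, vᵢ₊₁) over consecutive ring members. This is well
  defined for puckered (non-planar) rings and reduces exactly to the
  shoelace area for planar convex rings (tested to 1e-12).
* **Circularity** Ω defaults to the *radial* mode, min/max member distance
  to the rim centroid, which is 1 for a regular polygon. The literal
  "smallest to largest distance between any pair" reading is available as
  `mode="pairwise"`, but note it gives sin(π/7)/sin(3π/7) ≈ 0.445 for a
  *perfect* heptagon — irreconcilable with near-unity printed circularities,
  which is why radial is the default.
* **Heights** h12 and h16 are distances between rim centers of mass
  (O1-ring ↔ O2-ring, O1-ring ↔ O6-ring); for all-oxygen rims center of
  mass and center of geometry coincide.
* **Cavity volume** treats the cavity as two conical frusta sharing the
  middle ring: `Vc = (h12/3)(A_SHR + A_MID + √(A_SHR·A_MID)) +
  (h16/3)(A_PHR + A_MID + √(A_PHR·A_MID))`. This reconstruction reproduces
  the published descriptor table it was validated against: exact 2-decimal
  agreement on 12 of 14 host rows and ≤ 0.006 nm³ absolute error everywhere,
  with the residual attributable to the 2-decimal rounding of the printed
  inputs. The window mean of Vc averages per-frame volumes by default;
  `vc_from_means=True` evaluates the formula on window-averaged descriptors
  instead (both are reported choices, not equivalent for fluctuating hosts).

Distance/entry analyses use the center of geometry (unweighted); rim heights
use centers of mass. COG unwrapping is minimum-image relative to the first
selection member, so compact groups straddling a box wall are handled
correctly; selections wider than half the box are the caller's
responsibility.

## Shape, fluctuation

The gyration tensor is mass-weighted about the group's center of mass;
eigenvalues are sorted descending, `Rg² = Σλ`, and
`RSA = 1 − 3(λ₁λ₂+λ₂λ₃+λ₁λ₃)/(Σλ)²`, which is exactly 0 for isotropic and
1 for collinear configurations. RMSF superposes every window frame onto the
window-average structure — computed as the mean of frames first fitted to
the initial frame, then one refinement pass — using the Kabsch algorithm
with reflection correction; `RMSF_i = √⟨|rᵢ − ⟨rᵢ⟩|²⟩`. A rigid body with
isotropic per-coordinate jitter σ has RMSF σ√3; superposition absorbs six
rigid-body degrees of freedom, biasing the recovery low by roughly
`1 − 6/(3N)` in mean square (≈ 1 % for the 84-atom host), well inside the
5 % validation band.

## Entry kinetics

`detect_entry_time` reports the first time the host–guest COG distance
drops below a threshold and stays below it for `persistence` consecutive
frames; single-frame dips (collision artifacts) are thereby rejected.
The threshold defaults to the midpoint of the far and bound distances.
Because the criterion is a strict `<`, a noise-free trace whose midpoint
falls exactly on a frame triggers one frame later — irrelevant at any
realistic noise level. Orientation at entry: the guest end whose COG is
nearer the host COG leads; the rim whose center of mass is nearer the guest
is the approach rim; exact ties break toward the secondary rim (the
conventional initial-placement side) with a warning.

## Solvation

The RDF is referenced to the host center of geometry (a point), matching
the concentric-sphere picture used for cavity hydration:
`g(r) = ⟨n(r)⟩/(ρ·4πr²Δr)` with bulk density ρ = N_water/V_box — exact for
uniform water, which is the null model the generator provides. Cumulative
`N(r)` counts raw molecules within r. Shell counts use half-open [a, b)
intervals and default to the 0–0.5 and 0.5–1.0 nm layers (the first RDF
minimum sits near 0.5 nm). SASA is Shrake–Rupley with a deterministic
golden-spiral point set (960 points/atom, probe 0.14 nm); the point set is
fixed in the lab frame, so rotational invariance holds to the point-set
resolution (≈ 0.5 % at defaults, exact in the limit). The default radius
table (C 0.17, O 0.152, H 0.12, CH3 0.20 nm) is a minimal element map,
overridable everywhere; absolute SASA values depend on it, ratios and
trends barely do. "Molecular volume" for SA/V is a grid fill of the bare
van der Waals spheres (0.02 nm spacing); the frustum cavity volume can be
substituted via `cavity_volume=` and the choice is recorded in every
report.

## Hydrogen bonds

A donor–hydrogen–acceptor triple is bonded when the D–A minimum-image
distance is below 0.35 nm and the H–D–A angle at the donor is below 30° —
the de-facto standard geometric criterion; both are parameters because
criteria conventions differ between analysis tools. Water–water bonds are
excluded from summaries by default. Lifetimes: *continuous* mode is the
mean length of maximal presence runs × dt; runs censored by the window
edges are included (with a warning) because excluding them biases
long-lived bonds, and `exclude_censored=True` is available. *Intermittent*
mode fits `exp(−τ/τ₀)` to the normalized presence autocorrelation
`C(τ) = ⟨b(t)b(t+τ)⟩/⟨b⟩` down to its 1/e crossing. Two discretization
effects matter at coarse sampling (dt = 2 ps against ~11 ps dwells): runs
sampled on a grid are biased long by about `dt/(1−e^(−dt/τ))/τ`, and breaks
shorter than dt are invisible, merging adjacent runs. At the validation
scenario (τ_on = 11 ps, τ_off = 44 ps, i.e. occupancy 0.2) the combined
bias is ~11 %, inside the 15 % recovery band; at occupancy ≥ 0.5 run
merging would push it past 20 % — a property of this class of estimator,
not of the implementation.

## Free energies

`ti_integrate` applies trapezoidal quadrature to window means of ∂H/∂λ —
exact for linear integrands, with the textbook `(b−a)h²|f″|/12` error bound
for smooth ones; the standard error propagates per-window standard errors
through the trapezoid weights. Trapezoid (not spline) is the default
because its error analysis is transparent. `bar_estimate` solves the
self-consistent Bennett equation by bracketed root finding (tolerance 1e-8
kJ/mol) with `C = kT·ln(n_F/n_R)`; the reverse samples carry the work of
the reverse process, so a noiseless pair (+x, −x) yields exactly x. Errors
are Bennett's asymptotic variance or, optionally, a seeded bootstrap.
Non-overlapping work distributions raise a convergence error advising more
intermediate windows rather than returning a garbage number.
`binding_cycle` composes two decoupling legs,
`ΔG_bind = ΔG_decouple(complex) − ΔG_decouple(water)`, errors in
quadrature; negative means favorable binding.

Group interaction energies use a plain cutoff (default 1.2 nm) for both
Coulomb (`f = 138.935458 kJ·mol⁻¹·nm·e⁻²`) and Lennard-Jones terms with
Lorentz–Berthelot combination. This is a deliberate divergence from
mesh-Ewald electrostatics: the report is a descriptive per-pair statistic,
not a force-field energy, and should be read comparatively. The soft-core
λ-Hamiltonian that produces ∂H/∂λ data inside an engine is out of scope;
this package consumes such data.

## Synthetic generators

The generators exist to give every analysis a known ground truth:

* `build_cd_frame` places O6/O1/O3 (and O2) on exact circles whose radii
  invert the regular-polygon area formula `A = (n/2)r²sin(2π/n)` and whose
  plane offsets are the heights, so with zero noise every descriptor the
  geometry layer computes equals its construction parameter to 1e-12. The
  defaults realize the aqueous β-CD descriptor row (A = 1.10/0.83/1.32 nm²,
  h12/h16 = 0.22/0.33 nm, Vc = 0.55 nm³). Remaining atoms fill a plausible
  glucose wedge; they carry no ground-truth claims.
* `build_complex_trajectory` moves a rigid 4-site guest (distinct
  hydroxyl-end and ketone-end sites) along a logistic distance schedule
  `d(t) = d_bound + (d_far−d_bound)/(1+e^{k(t−t_entry)})`, chosen because
  capture traces are sigmoidal; steepness defaults to `10/(t_span/100)`.
  `d_far` defaults to 1.5 nm off the secondary rim, the conventional
  initial placement. Waters are uniform with solute exclusion (0.15 nm) and
  an optional cavity-exclusion sphere; each water has a random rigid
  orientation and optional per-frame whole-molecule jitter so hydrogen
  bonds flicker.
* `make_work_samples` draws the unique equal-variance Gaussian pair
  satisfying the Crooks relation for the requested ΔG (forward mean
  ΔG + σ²/2kT, reverse mean −ΔG + σ²/2kT).
* `make_telegraph_bonds` simulates the continuous-time two-state process
  exactly and samples it, so stationary occupancy is exactly
  τ_on/(τ_on+τ_off); infinite dwells are allowed.
* All generators are bit-reproducible given a seed.

What the synthetic data does *not* emulate: force-field energetics,
water structure (no pair correlations), guest flexibility or chemistry,
and rim puckering dynamics beyond isotropic jitter. Passing tests therefore
demonstrate the correctness of the estimators and descriptors, not the
behavior of real methylated cyclodextrins. Test scenarios run at 1/1000 of
production timescales (ns → ps) and at reduced water counts; all kinetics
operations are scale-free, so this only affects statistics, and the
problem sizes used in the validation battery (e.g. 2000 frames × 3000
waters for the RDF null model, 10⁴ work samples per direction for BAR,
300 × 3000-frame telegraph matrices) were sized to make the stated
tolerance bands statistically meaningful.

## Known limitations

* Rectangular boxes only; no triclinic support.
* Per-atom proximal RDFs, water orientational order, pucker/tilt angles,
  and energetic H-bond scoring are out of scope.
* SASA ignores periodic images (hosts are assumed compact relative to the
  box).
* The intermittent lifetime is a single-exponential fit; multi-timescale
  kinetics will be summarized by an effective constant.
* Plain-cutoff Coulomb means absolute interaction energies are not
  comparable to Ewald-based numbers; comparisons between groups within one
  system are.
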