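# cyclokit

Trajectory analysis for cyclodextrin host–guest inclusion complexes.

Cyclodextrins (CDs) are cyclic glucose oligomers whose truncated-cone cavity
can encapsulate small drug molecules such as hydrocortisone; methylating the
R2/R3/R6 hydroxyl positions changes the cavity shape, hydration, and binding
thermodynamics. `cyclokit` implements the complete analysis layer such a
molecular-dynamics study needs — without an MD engine in the loop:

* **Conformational descriptors** of the CD torus: areas of the primary
  hydroxyl rim (O6 atoms, `A_PHR`), middle glycosidic ring (O1, `A_MID`) and
  secondary hydroxyl rim (O3, `A_SHR`) by centroid-fan triangulation, rim
  circularity Ω, inter-rim heights `h12`/`h16` from rim centers of mass, and
  the cavity volume as two stacked conical frusta
  `Vc = (h12/3)(A_SHR + A_MID + √(A_SHR·A_MID)) + (h16/3)(A_PHR + A_MID + √(A_PHR·A_MID))`.
* **Shape anisotropy**: gyration-tensor eigenvalues λ₁ ≥ λ₂ ≥ λ₃,
  `Rg² = λ₁+λ₂+λ₃`, and the relative shape anisotropy
  `RSA = 1 − 3(λ₁λ₂+λ₂λ₃+λ₁λ₃)/(λ₁+λ₂+λ₃)²` (0 = isotropic, 1 = linear).
* **Fluctuations**: Kabsch superposition and per-atom RMSF.
* **Loading kinetics**: host–guest center-of-geometry distance traces,
  persistence-filtered entry-time detection, and entry orientation (which
  guest end leads, through which rim).
* **Solvation structure**: radial distribution function of water around the
  host center, hydration-shell counts (0–0.5 / 0.5–1.0 nm layers),
  Shrake–Rupley SASA, grid-based van der Waals volume, and SA/V.
* **Hydrogen bonds**: geometric detection (0.35 nm / 30° H–D–A criterion by
  default) and lifetimes from presence runs or autocorrelation.
* **Energetics**: group–group Coulomb + Lennard-Jones energies from a
  parameter table, thermodynamic integration
  `ΔG = ∫₀¹ ⟨∂H/∂λ⟩ dλ` (trapezoid), the Bennett acceptance ratio (BAR)
  estimator with asymptotic or bootstrap errors, and the two-leg
  decoupling thermodynamic cycle for binding free energies.
* **Synthetic data with analytic ground truth**: an idealized 7-unit
  toroidal host whose rim radii and plane offsets *are* the descriptors, a
  rigid two-ended guest on a logistic capture schedule, uniform water with
  cavity exclusion, telegraph hydrogen-bond processes, and Crooks-consistent
  Gaussian work samples — so every estimator can be validated end to end.

## Worked example

```python
import cyclokit as ck

# idealized aqueous beta-CD host
frame, topo = ck.build_cd_frame(ck.CDBuildParams())
_, mean = ck.conformational_report(ck.Trajectory([frame]), topo,
                                   window_fraction=1.0)
print(f"A_PHR={mean.a_phr:.2f} A_MID={mean.a_mid:.2f} A_SHR={mean.a_shr:.2f} "
      f"Omega={mean.omega_o1:.2f} h12={mean.h12:.2f} h16={mean.h16:.2f} "
      f"Vc={mean.vc:.2f}")

shape = ck.gyration_shape(frame, topo.all_atoms())
print(f"Rg={shape.rg:.3f} nm  RSA={shape.rsa:.3f}")

kt = ck.KB * 300
w = ck.make_work_samples(ck.WorkGenParams(dG_true=3 * kt, sigma_w=kt,
                                          n_forward=10_000, n_reverse=10_000,
                                          seed=42))
est = ck.bar_estimate(w)
print(f"BAR: dG = {est.dG:.3f} +/- {est.stderr:.3f} kJ/mol")
```

prints

```
A_PHR=1.10 A_MID=0.83 A_SHR=1.32 Omega=1.00 h12=0.22 h16=0.33 Vc=0.55
Rg=0.642 nm  RSA=0.133
BAR: dG = 7.447 +/- 0.018 kJ/mol
```

The first line is the builder's round trip: the default host realizes the
aqueous β-CD descriptor set (areas in nm², heights in nm, cavity volume
0.55 nm³), and the geometry layer recovers each value from coordinates
alone. The RSA of 0.13 reflects the mild oblate anisotropy of the torus.
The BAR estimate recovers the known 3 kT ≈ 7.48 kJ/mol free-energy
difference from 10⁴ noisy work samples per direction to within its reported
standard error's order.

## Command line

```sh
cyclokit simulate --what complex --out traj.gro --n-frames 100 --n-water 200 --seed 1
cyclokit conformation --traj traj.gro --topology traj.topology.tsv --out conf.tsv
cyclokit entry --traj traj.gro --topology traj.topology.tsv --out entry.tsv
cyclokit report --out bundle --seed 1   # all analyses + manifest.json
```

`cyclokit report` runs the entire pipeline on a seeded synthetic complex and
is byte-reproducible for a fixed seed. Exit code 2 marks input validation
failures, 1 computation failures.

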