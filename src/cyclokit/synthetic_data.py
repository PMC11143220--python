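"""Synthetic inputs with analytic ground truth.

Everything the analysis layer consumes can be generated here without an MD
engine: an idealized 7-unit toroidal cyclodextrin whose rim radii and plane
offsets ARE the conformational descriptors the geometry layer measures, a
rigid two-ended guest approaching the cavity on a logistic schedule, uniform
water with solute exclusion, telegraph (two-state Markov) hydrogen-bond
presence, and Gaussian work / dH-dlambda samples consistent with a chosen
free-energy difference through the Crooks relation.

The default host dimensions realize the aqueous beta-cyclodextrin descriptor
set (A_PHR = 1.10, A_MID = 0.83, A_SHR = 1.32 nm^2; h12 = 0.22,
h16 = 0.33 nm): radii follow from inverting the regular-polygon area
A = (n/2) r^2 sin(2 pi / n).  Kinetics generators are scale-free; test
scenarios run at 1/1000 of the production timescale (ns -> ps) so suites
finish in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .energetics import DEFAULT_TEMPERATURE, LambdaSeries, WorkSamples
from .exceptions import CapacityError, ValidationError
from .geometry import CDTopology
from .io_formats import Frame, Selection, Trajectory

__all__ = [
    "CDBuildParams",
    "GuestSchedule",
    "WorkGenParams",
    "make_param_table",
    "radius_for_area",
    "polygon_area",
    "build_cd_frame",
    "build_complex_trajectory",
    "build_water_box",
    "make_dhdl_series",
    "make_work_samples",
    "make_telegraph_bonds",
]


def polygon_area(r: float, n: int) -> float:
    """Area of a regular n-gon with circumradius r."""
    return 0.5 * n * r * r * np.sin(2.0 * np.pi / n)


def radius_for_area(area: float, n: int) -> float:
    """Circumradius of the regular n-gon with the given area."""
    return float(np.sqrt(2.0 * area / (n * np.sin(2.0 * np.pi / n))))


# Default rim geometry: the aqueous beta-CD descriptor row.
_N_UNITS = 7
_A_PHR, _A_MID, _A_SHR = 1.10, 0.83, 1.32  # nm^2
_H12, _H16 = 0.22, 0.33  # nm


@dataclass
class CDBuildParams:
    """Geometry of the idealized toroidal host.

    Rim circumradii (nm) and rim plane z-offsets (nm, middle ring at z = 0;
    the primary rim sits at -h16, the secondary at +h12).  ``noise_sigma``
    adds isotropic Gaussian jitter per atom per frame.
    """

    n_units: int = _N_UNITS
    r_phr: float = radius_for_area(_A_PHR, _N_UNITS)
    r_mid: float = radius_for_area(_A_MID, _N_UNITS)
    r_shr: float = radius_for_area(_A_SHR, _N_UNITS)
    z_phr: float = -_H16
    z_shr: float = +_H12
    noise_sigma: float = 0.0
    methylation: frozenset = frozenset()
    seed: int = 0

    def __post_init__(self):
        if self.n_units < 3:
            raise ValidationError("need at least 3 glucose units")
        if min(self.r_phr, self.r_mid, self.r_shr) <= 0:
            raise ValidationError("rim radii must be positive")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be non-negative")
        bad = set(self.methylation) - {"R2", "R3", "R6"}
        if bad:
            raise ValidationError(f"unknown methylation sites {bad}")


@dataclass
class GuestSchedule:
    """Logistic approach schedule of the rigid guest toward the cavity.

    The host-guest COG distance follows
    d(t) = d_bound + (d_far - d_bound) / (1 + exp(steepness (t - t_entry))).
    ``orientation`` selects which guest end leads; ``approach_rim`` selects
    the side of the torus the guest comes from.  The default ``d_far`` of
    1.5 nm mirrors the study's initial placement off the secondary rim.
    """

    d_far: float = 1.5
    d_bound: float = 0.0
    t_entry: float = 50.0
    steepness: float | None = None  # 1/ps; default 10 / (t_span / 100)
    orientation: str = "hydroxyl_first"
    approach_rim: str = "SHR"

    def __post_init__(self):
        if not self.d_far > self.d_bound >= 0:
            raise ValidationError("require d_far > d_bound >= 0")
        if self.orientation not in ("hydroxyl_first", "ketone_first"):
            raise ValidationError(f"unknown orientation {self.orientation!r}")
        if self.approach_rim not in ("PHR", "SHR"):
            raise ValidationError(f"unknown approach rim {self.approach_rim!r}")

    def distance(self, t: np.ndarray, t_span: float) -> np.ndarray:
        k = self.steepness if self.steepness is not None else 10.0 / (t_span / 100.0)
        return self.d_bound + (self.d_far - self.d_bound) / (
            1.0 + np.exp(k * (np.asarray(t, float) - self.t_entry)))


@dataclass
class WorkGenParams:
    """Gaussian work-sample generator settings (Crooks-consistent)."""

    dG_true: float
    sigma_w: float = 1.0
    n_forward: int = 1000
    n_reverse: int = 1000
    temperature: float = DEFAULT_TEMPERATURE
    seed: int = 0

    def __post_init__(self):
        if self.sigma_w <= 0:
            raise ValidationError("sigma_w must be positive")
        if self.n_forward < 1 or self.n_reverse < 1:
            raise ValidationError("sample counts must be >= 1")


# ---------------------------------------------------------------------------
# Host builder
# ---------------------------------------------------------------------------

# Per-unit roles: (role, radius key, z key, azimuthal offset in units of the
# inter-unit angle).  Oxygens O6/O1/O3 define the three rims exactly; O2
# shares the secondary rim plane so the h12 height is realized by
# construction; the remaining sites fill out a plausible glucose wedge.
_UNIT_LAYOUT = [
    ("O1", "mid", 0.00, 0.00),
    ("O2", "shr", 1.00, 0.25),
    ("O3", "shr", 1.00, 0.00),
    ("O4", "mid", 0.00, 0.50),
    ("O5", "p5", 0.50, 0.10),
    ("O6", "phr", 1.00, 0.00),
    ("C1", "c1", 0.10, 0.10),
    ("C2", "c2", 0.85, 0.20),
    ("C3", "c2", 0.95, -0.15),
    ("C4", "c1", 0.05, 0.45),
    ("C5", "p5", 0.60, 0.05),
    ("C6", "c6", 0.95, 0.05),
]
_METHYL_LAYOUT = {
    "R2": ("CM2", "shr", 1.15, 0.25, 0.12),
    "R3": ("CM3", "shr", 1.15, -0.05, 0.12),
    "R6": ("CM6", "phr", 1.15, 0.05, -0.12),
}


def _radius_map(p: CDBuildParams) -> dict[str, float]:
    return {
        "mid": p.r_mid,
        "shr": p.r_shr,
        "phr": p.r_phr,
        "p5": 0.5 * (p.r_mid + p.r_phr),
        "c1": 0.97 * p.r_mid,
        "c2": 0.95 * p.r_shr,
        "c6": 0.97 * p.r_phr,
    }


def build_cd_frame(params: CDBuildParams,
                   rng: np.random.Generator | None = None,
                   ) -> tuple[Frame, CDTopology]:
    """One idealized host frame plus its role topology.

    With zero noise, every conformational descriptor computed downstream
    equals its construction value: rim areas via the regular-polygon formula,
    heights via the plane offsets, circularity exactly 1.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    radii = _radius_map(params)
    names, resnames, resids, pos = [], [], [], []
    units: list[dict[str, int]] = []
    dtheta = 2.0 * np.pi / params.n_units

    for k in range(params.n_units):
        theta0 = k * dtheta
        unit: dict[str, int] = {}
        layout = list(_UNIT_LAYOUT)
        for site in sorted(params.methylation):
            role, rkey, zfrac, aoff, zext = _METHYL_LAYOUT[site]
            layout.append((role, rkey, zfrac, aoff, zext))
        for entry in layout:
            role, rkey, zfrac, aoff = entry[0], entry[1], entry[2], entry[3]
            zext = entry[4] if len(entry) > 4 else 0.0
            r = radii[rkey]
            # zfrac interpolates between the mid plane (0) and the rim plane
            # this site is associated with: positive fractions follow the
            # secondary side for shr-keyed radii, the primary side otherwise.
            plane = params.z_shr if rkey in ("shr", "c2") else params.z_phr
            if rkey in ("mid", "c1"):
                z = zfrac * 0.1  # slight pucker off the mid plane
            else:
                z = zfrac * plane + zext
            theta = theta0 + aoff * dtheta
            p = np.array([r * np.cos(theta), r * np.sin(theta), z])
            if params.noise_sigma > 0:
                p = p + rng.normal(0.0, params.noise_sigma, 3)
            unit[role] = len(names)
            names.append(role)
            resnames.append("GLC")
            resids.append(k + 1)
            pos.append(p)
        units.append(unit)
    frame = Frame(names, resnames, resids, np.array(pos))
    return frame, CDTopology(units)


# ---------------------------------------------------------------------------
# Complex trajectory builder
# ---------------------------------------------------------------------------

_GUEST_SITES = [
    ("OHG", -0.30),  # hydroxyl-rich end
    ("CG1", -0.10),
    ("CG2", +0.10),
    ("OKG", +0.30),  # ketone end
]


def _place_waters(rng: np.random.Generator, n_water: int, box: np.ndarray,
                  solute: np.ndarray, min_dist: float,
                  cavity_center: np.ndarray | None,
                  cavity_exclusion: float, max_tries: int = 200_000,
                  ) -> np.ndarray:
    placed = np.empty((n_water, 3))
    count = 0
    for _ in range(max_tries):
        if count == n_water:
            break
        p = rng.uniform(0.0, 1.0, 3) * box
        if len(solute):
            if np.min(np.linalg.norm(solute - p, axis=1)) < min_dist:
                continue
        if cavity_center is not None and cavity_exclusion > 0:
            if np.linalg.norm(p - cavity_center) < cavity_exclusion:
                continue
        placed[count] = p
        count += 1
    if count < n_water:
        raise CapacityError(
            f"placed only {count}/{n_water} waters after {max_tries} tries; "
            "enlarge the box or reduce n_water")
    return placed


def build_complex_trajectory(
    cd: CDBuildParams,
    guest: GuestSchedule,
    n_frames: int = 100,
    dt: float = 1.0,
    n_water: int = 0,
    box: float | np.ndarray = 5.0,
    seed: int = 0,
    guest_noise: float = 0.0,
    cavity_exclusion: float = 0.0,
    water_min_dist: float = 0.15,
    water_noise: float = 0.0,
    water_max_tries: int = 200_000,
) -> tuple[Trajectory, CDTopology, Selection, Selection]:
    """Host + approaching guest + water, on a logistic capture schedule.

    The guest is a rigid 4-site rod with distinguishable hydroxyl
    (``OHG``) and ketone (``OKG``) end sites; its COG tracks the schedule's
    logistic distance curve along the approach axis (plus ``guest_noise``
    Gaussian jitter on the distance).  Waters (``SOL``: OW with two HW sites
    at 0.1 nm) are placed uniformly once, rejecting positions within
    ``water_min_dist`` of any solute atom and inside the optional
    ``cavity_exclusion`` sphere around the host center.  Each water gets a
    random rigid orientation; ``water_noise`` adds an independent Gaussian
    whole-molecule translation per frame so hydrogen bonds flicker.

    Returns (trajectory, topology, guest selection, water-oxygen selection).
    """
    if n_frames < 1:
        raise ValidationError("n_frames must be >= 1")
    box = np.asarray(box, float) * np.ones(3)
    rng = np.random.default_rng(seed)
    t_span = n_frames * dt
    if not 0.0 <= guest.t_entry <= t_span:
        raise ValidationError("t_entry must lie within the trajectory span")
    if guest.d_far > float(np.min(box)) / 2.0:
        raise ValidationError("box too small to hold the far guest distance")

    base_cd, topo = build_cd_frame(
        CDBuildParams(**{**cd.__dict__, "noise_sigma": 0.0}))
    center = box / 2.0
    cd_pos0 = base_cd.positions - base_cd.positions.mean(axis=0) + center
    n_cd = len(cd_pos0)

    # approach axis: +z points toward the secondary rim (z_shr > 0)
    axis = np.array([0.0, 0.0, 1.0 if guest.approach_rim == "SHR" else -1.0])
    guest_names = [s[0] for s in _GUEST_SITES]
    offsets = np.array([s[1] for s in _GUEST_SITES])
    if guest.orientation == "ketone_first":
        offsets = -offsets  # ketone end becomes the leading (-0.3) site

    guest_idx = np.arange(n_cd, n_cd + len(_GUEST_SITES))

    # place waters against the far-guest configuration of the solute
    d0 = guest.distance(np.array([0.0]), t_span)[0]
    guest_pos0 = center[None, :] + axis * d0 + np.outer(offsets, axis)
    solute0 = np.vstack([cd_pos0, guest_pos0])
    water_o = np.empty((0, 3))
    if n_water > 0:
        water_o = _place_waters(rng, n_water, box, solute0, water_min_dist,
                                center, cavity_exclusion, water_max_tries)
    # two hydrogens per water at 0.1 nm, 104.5-degree H-O-H angle, random
    # rigid orientation per molecule
    def _water_h_dirs(n: int) -> np.ndarray:
        u = rng.normal(size=(n, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        v = rng.normal(size=(n, 3))
        v -= (np.sum(u * v, axis=1, keepdims=True)) * u
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        ang = np.deg2rad(104.5)
        h2 = np.cos(ang)[None] * u + np.sin(ang)[None] * v
        return np.stack([u, h2], axis=1)  # (n, 2, 3)

    h_dirs = _water_h_dirs(n_water) if n_water else np.empty((0, 2, 3))

    names = (list(base_cd.names) + guest_names
             + [nm for _ in range(n_water) for nm in ("OW", "HW1", "HW2")])
    resnames = (list(base_cd.residue_names) + ["HC"] * len(_GUEST_SITES)
                + [rn for _ in range(n_water) for rn in ("SOL",) * 3])
    max_res = int(base_cd.residue_ids.max()) if n_cd else 0
    resids = (list(base_cd.residue_ids) + [max_res + 1] * len(_GUEST_SITES)
              + [max_res + 2 + w for w in range(n_water) for _ in range(3)])
    water_block = np.empty((3 * n_water, 3))
    for w in range(n_water):
        water_block[3 * w] = water_o[w]
        water_block[3 * w + 1] = water_o[w] + 0.1 * h_dirs[w, 0]
        water_block[3 * w + 2] = water_o[w] + 0.1 * h_dirs[w, 1]

    times = np.arange(n_frames) * dt
    dists = guest.distance(times, t_span)
    if guest_noise > 0:
        dists = dists + rng.normal(0.0, guest_noise, n_frames)

    frames = []
    for k in range(n_frames):
        cd_pos = cd_pos0.copy()
        if cd.noise_sigma > 0:
            cd_pos = cd_pos + rng.normal(0.0, cd.noise_sigma, cd_pos.shape)
        guest_center = center + axis * max(dists[k], 0.0)
        # rod aligned with the approach axis; the "leading" offset site sits
        # closest to the host along -axis
        guest_pos = guest_center[None, :] + np.outer(offsets, axis)
        waters_k = water_block
        if water_noise > 0 and n_water:
            shift = np.repeat(rng.normal(0.0, water_noise, (n_water, 3)),
                              3, axis=0)
            waters_k = water_block + shift
        pos = np.vstack([cd_pos, guest_pos, waters_k])
        frames.append(Frame(names, resnames, resids, pos, box=box.copy(),
                            time=float(times[k])))

    guest_sel = Selection(guest_idx, label="guest")
    water_o_idx = n_cd + len(_GUEST_SITES) + 3 * np.arange(n_water)
    water_sel = Selection(water_o_idx, label="water-O")
    return Trajectory(frames), topo, guest_sel, water_sel


def build_water_box(n_frames: int, n_water: int, box: float | np.ndarray,
                    seed: int = 0) -> tuple[Trajectory, Selection]:
    """Ideal-gas water: oxygens re-drawn uniformly each frame.

    A null model for the radial distribution function (g(r) = 1 everywhere).
    """
    box = np.asarray(box, float) * np.ones(3)
    rng = np.random.default_rng(seed)
    names = ["OW"] * n_water
    resnames = ["SOL"] * n_water
    resids = list(range(1, n_water + 1))
    frames = [Frame(names, resnames, resids,
                    rng.uniform(0.0, 1.0, (n_water, 3)) * box,
                    box=box.copy(), time=float(k))
              for k in range(n_frames)]
    return Trajectory(frames), Selection(np.arange(n_water), label="water-O")


# ---------------------------------------------------------------------------
# Free-energy sample generators
# ---------------------------------------------------------------------------

def make_dhdl_series(dG_true: float, n_lambda: int = 25,
                     samples_per_window: int = 100, noise: float = 0.0,
                     shape: str = "linear", seed: int = 0,
                     temperature: float = DEFAULT_TEMPERATURE) -> LambdaSeries:
    """dH/dlambda windows whose exact lambda-integral equals ``dG_true``.

    ``linear``: constant integrand dG_true.  ``quadratic``: integrand
    3 dG_true lambda^2 (same exact integral, nonzero curvature so trapezoid
    error is exercised).
    """
    if n_lambda < 2:
        raise ValidationError("need at least 2 lambda windows")
    rng = np.random.default_rng(seed)
    lambdas = np.linspace(0.0, 1.0, n_lambda)
    if shape == "linear":
        means = np.full(n_lambda, dG_true)
    elif shape == "quadratic":
        means = 3.0 * dG_true * lambdas**2
    else:
        raise ValidationError(f"unknown integrand shape {shape!r}")
    samples = [m + (rng.normal(0.0, noise, samples_per_window) if noise > 0
                    else np.zeros(samples_per_window))
               for m in means]
    return LambdaSeries(lambdas, samples, temperature)


def make_work_samples(params: WorkGenParams) -> WorkSamples:
    """Crooks-consistent Gaussian work samples for a known dG_true.

    Forward work ~ N(dG + sigma^2 / 2kT, sigma^2) and reverse work
    ~ N(-dG + sigma^2 / 2kT, sigma^2): the unique equal-variance Gaussian
    pair satisfying P_F(W) / P_R(-W) = exp((W - dG)/kT).
    """
    rng = np.random.default_rng(params.seed)
    kt = 0.0083145 * params.temperature
    dissipation = params.sigma_w**2 / (2.0 * kt)
    fwd = rng.normal(params.dG_true + dissipation, params.sigma_w,
                     params.n_forward)
    rev = rng.normal(-params.dG_true + dissipation, params.sigma_w,
                     params.n_reverse)
    return WorkSamples(fwd, rev, params.temperature)


# ---------------------------------------------------------------------------
# Nonbonded parameters
# ---------------------------------------------------------------------------

# Generic per-site nonbonded parameters (charge e, sigma nm, epsilon kJ/mol)
# for the synthetic frames.  Water is a neutral 3-site model; host/guest
# sites carry modest partial charges so Coulomb terms are exercised.
_PARAM_RULES = {
    "OW": (-0.8476, 0.3166, 0.6502),
    "HW": (+0.4238, 0.0000, 0.0000),
    "O": (-0.50, 0.300, 0.650),
    "C": (+0.25, 0.350, 0.300),
    "CH3": (0.00, 0.374, 0.867),
    "H": (+0.30, 0.100, 0.065),
}


def make_param_table(frame: Frame):
    """A plausible ParamTable for any synthetic frame, keyed on atom names."""
    from .io_formats import ParamTable, infer_element

    q = np.empty(frame.n_atoms)
    s = np.empty(frame.n_atoms)
    e = np.empty(frame.n_atoms)
    for i, name in enumerate(frame.names):
        name = str(name)
        if name == "OW":
            row = _PARAM_RULES["OW"]
        elif name.startswith("HW"):
            row = _PARAM_RULES["HW"]
        else:
            row = _PARAM_RULES.get(infer_element(name), (0.0, 0.3, 0.3))
        q[i], s[i], e[i] = row
    return ParamTable(q, s, e)


# ---------------------------------------------------------------------------
# Telegraph hydrogen bonds
# ---------------------------------------------------------------------------

def make_telegraph_bonds(n_pairs: int, tau_on: float, tau_off: float,
                         n_frames: int, dt: float, seed: int = 0) -> np.ndarray:
    """Boolean presence matrix of two-state Markov (telegraph) bonds.

    Each pair alternates exponential on-dwells (mean ``tau_on``) and
    off-dwells (mean ``tau_off``), sampled every ``dt`` ps; the continuous
    process is simulated exactly, so the stationary occupancy is
    tau_on / (tau_on + tau_off).  Infinite dwell times are allowed.
    """
    if tau_on <= 0 or tau_off <= 0:
        raise ValidationError("dwell time constants must be positive")
    rng = np.random.default_rng(seed)
    out = np.zeros((n_pairs, n_frames), dtype=bool)
    t_end = n_frames * dt
    for p in range(n_pairs):
        if np.isinf(tau_on) and np.isinf(tau_off):
            state = bool(rng.random() < 0.5)
        elif np.isinf(tau_on):
            state = True
        elif np.isinf(tau_off):
            state = False
        else:
            state = bool(rng.random() < tau_on / (tau_on + tau_off))
        t = 0.0
        frame = 0
        while t < t_end and frame < n_frames:
            tau = tau_on if state else tau_off
            dwell = np.inf if np.isinf(tau) else rng.exponential(tau)
            t_next = t + dwell
            # frames sampled at k*dt falling inside [t, t_next)
            last = n_frames if np.isinf(t_next) else min(
                n_frames, int(np.ceil(t_next / dt)))
            if state:
                out[p, frame:last] = True
            frame = last
            t = t_next
            state = not state
    return out
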