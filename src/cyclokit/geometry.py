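"""Conformational and shape descriptors of the cyclodextrin torus.

The host is described by three stacked atom rims: the primary hydroxyl rim
(PHR, the narrow O6 side), the middle glycosidic-oxygen ring (MID, O1), and
the secondary hydroxyl rim (SHR, the wide O2/O3 side).  Per-frame descriptors
are rim areas (centroid-fan triangulation, robust to rim puckering), rim
circularity, inter-rim heights from rim centers of mass, and a cavity volume
modelled as two conical frusta stacked at the middle rim:

    Vc = (h12/3)(A_SHR + A_MID + sqrt(A_SHR * A_MID))
       + (h16/3)(A_PHR + A_MID + sqrt(A_PHR * A_MID))

Shape anisotropy comes from the gyration tensor: with eigenvalues
l1 >= l2 >= l3, Rg^2 = l1 + l2 + l3 and

    RSA = 1 - 3 (l1 l2 + l2 l3 + l1 l3) / (l1 + l2 + l3)^2,

0 for an isotropic mass distribution and 1 for an ideal linear chain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .exceptions import ValidationError
from .io_formats import Frame, Selection, Trajectory, infer_element
from .util import minimum_image

__all__ = [
    "CDTopology",
    "ConformationalRecord",
    "ShapeDescriptor",
    "FluctuationProfile",
    "EntryEvent",
    "DEFAULT_MASSES",
    "masses_for",
    "center_of_geometry",
    "center_of_mass",
    "rim_area",
    "circularity",
    "rim_height",
    "cavity_volume",
    "conformational_report",
    "kabsch_superpose",
    "rmsf",
    "gyration_shape",
    "rsa_from_eigenvalues",
    "distance_timeseries",
    "detect_entry_time",
    "leading_end",
]

DEFAULT_MASSES = {"O": 15.999, "C": 12.011, "H": 1.008, "CH3": 15.035, "X": 1.0}

OXYGEN_ROLES = ("O1", "O2", "O3", "O4", "O5", "O6")
CARBON_ROLES = ("C1", "C2", "C3", "C4", "C5", "C6")
METHYL_ROLES = ("CM2", "CM3", "CM6")


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------

@dataclass
class CDTopology:
    """Role map of a cyclodextrin: per-glucose-unit atom indices.

    ``units[k]`` maps role names (O1..O6, C1..C6, CM2/CM3/CM6 for methyl
    pseudo-atoms) to 0-based atom indices; units are listed in azimuthal ring
    order, so the rim index arrays returned here are ordered around the ring.
    Rims: PHR = all O6, MID = all O1, SHR = all O3.
    """

    units: list[dict[str, int]]

    def __post_init__(self):
        for k, unit in enumerate(self.units):
            if len(set(unit.values())) != len(unit):
                raise ValidationError(f"unit {k} maps two roles to one atom")

    @property
    def n_units(self) -> int:
        return len(self.units)

    def rim_indices(self, role: str) -> np.ndarray:
        """Atom indices of one role per unit, in ring order."""
        try:
            return np.array([u[role] for u in self.units], dtype=int)
        except KeyError:
            raise ValidationError(f"role {role!r} missing from topology")

    @property
    def phr(self) -> Selection:
        return Selection(self.rim_indices("O6"), label="PHR")

    @property
    def mid(self) -> Selection:
        return Selection(self.rim_indices("O1"), label="MID")

    @property
    def shr(self) -> Selection:
        return Selection(self.rim_indices("O3"), label="SHR")

    def all_atoms(self) -> Selection:
        idx = [i for u in self.units for i in u.values()]
        return Selection(np.array(idx), label="CD")

    def heavy_atoms(self) -> Selection:
        idx = [i for u in self.units for r, i in u.items() if not r.startswith("H")]
        return Selection(np.array(idx), label="CD-heavy")

    # -- text round trip ----------------------------------------------------

    def to_tsv(self, path: str | Path) -> Path:
        p = Path(path)
        lines = ["unit\trole\tindex"]
        for k, unit in enumerate(self.units):
            for role, idx in sorted(unit.items()):
                lines.append(f"{k}\t{role}\t{idx}")
        p.write_text("\n".join(lines) + "\n")
        return p

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CDTopology":
        units: dict[int, dict[str, int]] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("unit"):
                continue
            k, role, idx = line.split("\t")
            units.setdefault(int(k), {})[role] = int(idx)
        return cls([units[k] for k in sorted(units)])

    @classmethod
    def detect(cls, frame: Frame, residue_name: str = "GLC") -> "CDTopology":
        """Guess a topology from atom-name conventions (O1..O6 per residue)."""
        per_res: dict[int, dict[str, int]] = {}
        roles = set(OXYGEN_ROLES) | set(CARBON_ROLES) | set(METHYL_ROLES)
        for i in range(frame.n_atoms):
            if frame.residue_names[i] != residue_name:
                continue
            name = str(frame.names[i])
            if name in roles:
                per_res.setdefault(int(frame.residue_ids[i]), {})[name] = i
        units = [per_res[r] for r in sorted(per_res)]
        if not units:
            raise ValidationError(
                f"no {residue_name} residues with recognized role names found")
        return cls(units)


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------

@dataclass
class ConformationalRecord:
    """One row of conformational descriptors (areas nm^2, heights nm, Vc nm^3)."""

    a_phr: float
    a_mid: float
    a_shr: float
    omega_o1: float
    h12: float
    h16: float
    vc: float
    time: float = 0.0

    @property
    def h(self) -> float:
        return self.h12 + self.h16


@dataclass(frozen=True)
class ShapeDescriptor:
    """Gyration-tensor eigenvalues (nm^2, descending), Rg (nm) and RSA."""

    eigenvalues: np.ndarray
    rg: float
    rsa: float


@dataclass(frozen=True)
class FluctuationProfile:
    """Per-atom RMSF (nm) for a selection, index-aligned with it."""

    indices: np.ndarray
    rmsf: np.ndarray


@dataclass(frozen=True)
class EntryEvent:
    """Result of entry-time detection on a host-guest distance trace."""

    entry_time: float | None
    entry_index: int | None = None
    leading_end: str | None = None
    approach_rim: str | None = None

    @property
    def entered(self) -> bool:
        return self.entry_time is not None


# ---------------------------------------------------------------------------
# Centers
# ---------------------------------------------------------------------------

def _unwrapped(frame: Frame, indices: np.ndarray) -> np.ndarray:
    """Member positions unwrapped by minimum image around the first member."""
    pos = frame.positions[np.asarray(indices)]
    if frame.box is None or len(pos) == 0:
        return pos
    return pos[0] + minimum_image(pos - pos[0], frame.box)


def masses_for(frame: Frame, sel: Selection,
               table: Mapping[str, float] = DEFAULT_MASSES) -> np.ndarray:
    return np.array([table.get(infer_element(str(frame.names[i])), 1.0)
                     for i in sel.indices])


def center_of_geometry(frame: Frame, sel: Selection) -> np.ndarray:
    """Unweighted mean position, minimum-image unwrapped around the first member."""
    if len(sel) == 0:
        raise ValidationError("selection is empty")
    return _unwrapped(frame, sel.indices).mean(axis=0)


def center_of_mass(frame: Frame, sel: Selection,
                   masses: np.ndarray | None = None) -> np.ndarray:
    """Mass-weighted mean position; equals the COG for equal masses."""
    if len(sel) == 0:
        raise ValidationError("selection is empty")
    if masses is None:
        masses = masses_for(frame, sel)
    masses = np.asarray(masses, dtype=float)
    if np.any(masses <= 0):
        raise ValidationError("masses must be positive")
    pos = _unwrapped(frame, sel.indices)
    return (masses[:, None] * pos).sum(axis=0) / masses.sum()


# ---------------------------------------------------------------------------
# Rim descriptors
# ---------------------------------------------------------------------------

def rim_area(frame: Frame, rim: Selection | Sequence[int]) -> float:
    """Area of a (possibly non-planar) atom ring, nm^2.

    Centroid-fan triangulation: the sum over consecutive member pairs of the
    3-D triangle (centroid, v_i, v_{i+1}).  Members must be ordered around
    the ring (topology order); for planar convex rings this equals the
    shoelace area of the plane projection.
    """
    indices = rim.indices if isinstance(rim, Selection) else np.asarray(rim, int)
    if len(indices) < 3:
        raise ValidationError("a rim needs at least 3 atoms")
    v = _unwrapped(frame, indices)
    c = v.mean(axis=0)
    a = v - c
    b = np.roll(v, -1, axis=0) - c
    return float(0.5 * np.linalg.norm(np.cross(a, b), axis=1).sum())


def circularity(frame: Frame, rim: Selection | Sequence[int],
                mode: str = "radial") -> float:
    """Rim circularity in (0, 1]; 1 for a regular polygon (radial mode).

    ``radial`` (default): min/max member distance to the rim centroid.
    ``pairwise``: min/max over all member-pair distances — note a perfect
    heptagon then scores sin(pi/7)/sin(3pi/7) ~ 0.445, not 1.
    """
    indices = rim.indices if isinstance(rim, Selection) else np.asarray(rim, int)
    if len(indices) < 3:
        raise ValidationError("a rim needs at least 3 atoms")
    v = _unwrapped(frame, indices)
    if mode == "radial":
        r = np.linalg.norm(v - v.mean(axis=0), axis=1)
        return float(r.min() / r.max()) if r.max() > 0 else 1.0
    if mode == "pairwise":
        d = np.linalg.norm(v[:, None, :] - v[None, :, :], axis=-1)
        iu = np.triu_indices(len(v), k=1)
        pd = d[iu]
        return float(pd.min() / pd.max()) if pd.max() > 0 else 1.0
    raise ValidationError(f"unknown circularity mode {mode!r}")


def rim_height(frame: Frame, rim_a: Selection, rim_b: Selection,
               masses_a: np.ndarray | None = None,
               masses_b: np.ndarray | None = None) -> float:
    """Distance between the centers of mass of two rims, nm."""
    ca = center_of_mass(frame, rim_a, masses_a)
    cb = center_of_mass(frame, rim_b, masses_b)
    d = minimum_image(cb - ca, frame.box)
    return float(np.linalg.norm(d))


def cavity_volume(a_phr: float, a_mid: float, a_shr: float,
                  h12: float, h16: float) -> float:
    """Cavity volume of the torus as two stacked conical frusta, nm^3.

    The wide frustum spans the secondary rim and the middle ring over height
    h12; the narrow frustum spans the middle ring and the primary rim over
    h16.  Each contributes (h/3)(A1 + A2 + sqrt(A1 A2)).
    """
    for v in (a_phr, a_mid, a_shr, h12, h16):
        if v < 0:
            raise ValidationError("areas and heights must be non-negative")
    return (h12 / 3.0) * (a_shr + a_mid + np.sqrt(a_shr * a_mid)) \
         + (h16 / 3.0) * (a_phr + a_mid + np.sqrt(a_phr * a_mid))


def _frame_record(frame: Frame, topo: CDTopology,
                  circ_mode: str = "radial") -> ConformationalRecord:
    o1 = topo.rim_indices("O1")
    o2 = topo.rim_indices("O2")
    o3 = topo.rim_indices("O3")
    o6 = topo.rim_indices("O6")
    a_phr = rim_area(frame, o6)
    a_mid = rim_area(frame, o1)
    a_shr = rim_area(frame, o3)
    omega = circularity(frame, o1, mode=circ_mode)
    h12 = rim_height(frame, Selection(o1), Selection(o2))
    h16 = rim_height(frame, Selection(o1), Selection(o6))
    vc = cavity_volume(a_phr, a_mid, a_shr, h12, h16)
    return ConformationalRecord(a_phr, a_mid, a_shr, omega, h12, h16, vc,
                                time=frame.time)


def conformational_report(traj: Trajectory, topo: CDTopology,
                          window_fraction: float = 0.10,
                          circ_mode: str = "radial",
                          vc_from_means: bool = False,
                          ) -> tuple[list[ConformationalRecord], ConformationalRecord]:
    """Per-frame descriptor records plus the trailing-window mean.

    By default the window mean of Vc averages per-frame volumes;
    ``vc_from_means=True`` instead evaluates the frustum formula on the
    window-averaged areas and heights.
    """
    if len(traj) == 0:
        raise ValidationError("empty trajectory")
    records = [_frame_record(f, topo, circ_mode) for f in traj]
    n = len(records)
    k = max(1, int(round(window_fraction * n)))
    win = records[n - k:]

    def mean(attr):
        return float(np.mean([getattr(r, attr) for r in win]))

    mean_rec = ConformationalRecord(
        mean("a_phr"), mean("a_mid"), mean("a_shr"), mean("omega_o1"),
        mean("h12"), mean("h16"), mean("vc"), time=win[-1].time)
    if vc_from_means:
        mean_rec.vc = cavity_volume(mean_rec.a_phr, mean_rec.a_mid,
                                    mean_rec.a_shr, mean_rec.h12, mean_rec.h16)
    return records, mean_rec


# ---------------------------------------------------------------------------
# Superposition and fluctuation
# ---------------------------------------------------------------------------

def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     weights: np.ndarray | None = None,
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper rotation R and translation t with weighted RMSD.

    Minimizes the weighted RMSD of ``mobile @ R.T + t`` against
    ``reference``; a reflection correction guarantees det(R) = +1.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape or len(mobile) < 3:
        raise ValidationError("need matching coordinate sets of >= 3 points")
    n = len(mobile)
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValidationError("weights must be non-negative with positive sum")
    w = w / w.sum()
    mc = mobile - (w[:, None] * mobile).sum(axis=0)
    rc = reference - (w[:, None] * reference).sum(axis=0)
    h = (w[:, None] * mc).T @ rc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = (w[:, None] * reference).sum(axis=0) - rot @ (w[:, None] * mobile).sum(axis=0)
    fitted = mobile @ rot.T + t
    rmsd = float(np.sqrt((w * np.sum((fitted - reference) ** 2, axis=1)).sum()))
    return rot, t, rmsd


def superpose_trajectory(coords: np.ndarray, reference: np.ndarray,
                         weights: np.ndarray | None = None) -> np.ndarray:
    """Fit every (n_atoms, 3) slab of ``coords`` onto ``reference``."""
    out = np.empty_like(coords)
    for k in range(len(coords)):
        rot, t, _ = kabsch_superpose(coords[k], reference, weights)
        out[k] = coords[k] @ rot.T + t
    return out


def rmsf(traj: Trajectory, sel: Selection,
         window_fraction: float = 1.0) -> FluctuationProfile:
    """Per-atom root mean square fluctuation after rigid-body superposition.

    Each window frame is fitted to the window-average structure (the average
    of frames first fitted to the initial frame, one refinement pass), then
    RMSF_i = sqrt(<|r_i - <r_i>|^2>).
    """
    win = traj.window(window_fraction)
    if len(win) < 2:
        raise ValidationError("RMSF needs at least 2 frames in the window")
    coords = np.stack([f.positions[sel.indices] for f in win])
    fitted = superpose_trajectory(coords, coords[0])
    mean_structure = fitted.mean(axis=0)
    fitted = superpose_trajectory(coords, mean_structure)
    mean_structure = fitted.mean(axis=0)
    msd = np.mean(np.sum((fitted - mean_structure) ** 2, axis=2), axis=0)
    return FluctuationProfile(sel.indices.copy(), np.sqrt(msd))


# ---------------------------------------------------------------------------
# Gyration shape
# ---------------------------------------------------------------------------

def rsa_from_eigenvalues(eigenvalues: Sequence[float]) -> float:
    """Relative shape anisotropy from gyration-tensor eigenvalues."""
    l1, l2, l3 = sorted(np.asarray(eigenvalues, float), reverse=True)
    tr = l1 + l2 + l3
    if tr <= 0:
        raise ValidationError("gyration tensor has non-positive trace")
    return float(1.0 - 3.0 * (l1 * l2 + l2 * l3 + l1 * l3) / tr**2)


def gyration_shape(frame: Frame, sel: Selection,
                   masses: np.ndarray | None = None) -> ShapeDescriptor:
    """Mass-weighted gyration tensor, its eigenvalues, Rg and RSA."""
    if len(sel) < 2:
        raise ValidationError("gyration shape needs >= 2 points")
    pos = _unwrapped(frame, sel.indices)
    if np.allclose(pos, pos[0]):
        raise ValidationError("all points coincide; gyration tensor is zero")
    w = np.ones(len(pos)) if masses is None else np.asarray(masses, float)
    w = w / w.sum()
    com = (w[:, None] * pos).sum(axis=0)
    d = pos - com
    tensor = (w[:, None, None] * d[:, :, None] * d[:, None, :]).sum(axis=0)
    eig = np.sort(np.linalg.eigvalsh(tensor))[::-1]
    eig = np.clip(eig, 0.0, None)
    rg = float(np.sqrt(eig.sum()))
    return ShapeDescriptor(eig, rg, rsa_from_eigenvalues(eig))


# ---------------------------------------------------------------------------
# Distances and entry kinetics
# ---------------------------------------------------------------------------

def distance_timeseries(traj: Trajectory, sel_a: Selection, sel_b: Selection,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame minimum-image |COG_A - COG_B| in nm."""
    if len(sel_a) == 0 or len(sel_b) == 0:
        raise ValidationError("both selections must be non-empty")
    times = traj.times
    dist = np.empty(len(traj))
    for k, frame in enumerate(traj):
        d = minimum_image(center_of_geometry(frame, sel_a)
                          - center_of_geometry(frame, sel_b), frame.box)
        dist[k] = np.linalg.norm(d)
    return times, dist


def detect_entry_time(times: np.ndarray, distances: np.ndarray,
                      threshold: float, persistence: int = 1) -> EntryEvent:
    """First time the distance drops below threshold and stays there.

    ``persistence`` is the number of consecutive frames (including the first)
    the trace must remain below threshold; brief spurious dips shorter than
    that are rejected.
    """
    times = np.asarray(times, float)
    distances = np.asarray(distances, float)
    if len(times) == 0 or len(times) != len(distances):
        raise ValidationError("times and distances must be equal-length, non-empty")
    if len(times) > 1 and not np.all(np.diff(times) > 0):
        raise ValidationError("times must be strictly increasing")
    if persistence < 1:
        raise ValidationError("persistence must be >= 1")
    below = distances < threshold
    run = 0
    for i, b in enumerate(below):
        run = run + 1 if b else 0
        if run >= persistence:
            start = i - persistence + 1
            return EntryEvent(entry_time=float(times[start]), entry_index=start)
    return EntryEvent(entry_time=None)


def leading_end(traj: Trajectory, topo: CDTopology,
                guest_end_selections: Mapping[str, Selection],
                at_entry: EntryEvent) -> tuple[str, str]:
    """Orientation at the entry frame: (leading end label, approach rim).

    The guest end whose COG is nearer the host COG leads; the rim whose
    center of mass is nearer the guest COG is the approach rim.  Exact ties
    break toward SHR (with a warning).
    """
    if not at_entry.entered or at_entry.entry_index is None:
        raise ValidationError("no entry event detected")
    frame = traj[at_entry.entry_index]
    cd_cog = center_of_geometry(frame, topo.all_atoms())

    def dist_to(point, sel):
        return float(np.linalg.norm(minimum_image(
            center_of_geometry(frame, sel) - point, frame.box)))

    end_d = {name: dist_to(cd_cog, sel)
             for name, sel in guest_end_selections.items()}
    lead = min(end_d, key=end_d.get)

    guest_all = Selection(np.concatenate(
        [s.indices for s in guest_end_selections.values()]))
    guest_cog = center_of_geometry(frame, guest_all)
    d_phr = float(np.linalg.norm(minimum_image(
        center_of_mass(frame, topo.phr) - guest_cog, frame.box)))
    d_shr = float(np.linalg.norm(minimum_image(
        center_of_mass(frame, topo.shr) - guest_cog, frame.box)))
    if np.isclose(d_phr, d_shr):
        warnings.warn("guest equidistant from both rims; tie broken toward SHR")
        rim = "SHR"
    else:
        rim = "PHR" if d_phr < d_shr else "SHR"
    return lead, rim
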