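"""Water structure around the host: RDF, shell counts, SASA, volume, SA/V.

The radial distribution function is referenced to the host center of
geometry (a point), matching the concentric "hypothetical sphere" shell
picture used for cavity hydration: g(r) = <n(r)> / (rho 4 pi r^2 dr) with
the bulk density rho = N_water / V_box, and the cumulative N(r) counts the
water oxygens within r.  Shell counting defaults to the 0-0.5 and
0.5-1.0 nm layers (the first RDF minimum sits near 0.5 nm).

SASA is Shrake-Rupley with a deterministic golden-spiral point set; the
molecular volume is a van der Waals grid fill, and SA/V divides the
window-averaged surface by the window-averaged volume.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .exceptions import ValidationError
from .geometry import center_of_geometry
from .io_formats import Frame, Selection, Trajectory, infer_element
from .util import minimum_image

__all__ = [
    "RDFProfile",
    "ShellCountRecord",
    "SurfaceReport",
    "DEFAULT_RADII",
    "radii_for",
    "rdf",
    "count_in_shells",
    "sasa",
    "molecular_volume",
    "sa_to_v",
]

# Minimal van der Waals radius table (nm); the methyl pseudo-atom is a
# united site.  Overridable everywhere radii are accepted.
DEFAULT_RADII = {"C": 0.17, "O": 0.152, "H": 0.12, "CH3": 0.20, "X": 0.15}


def radii_for(frame: Frame, sel: Selection,
              table: Mapping[str, float] = DEFAULT_RADII) -> np.ndarray:
    return np.array([table.get(infer_element(str(frame.names[i])), 0.15)
                     for i in sel.indices])


@dataclass(frozen=True)
class RDFProfile:
    """g(r) and cumulative count N(r) on a uniform radial grid."""

    r: np.ndarray            # bin centers, nm
    g: np.ndarray            # dimensionless
    n_cumulative: np.ndarray  # mean molecules within the bin's right edge
    bin_width: float
    bulk_density: float      # nm^-3


@dataclass(frozen=True)
class ShellCountRecord:
    """Mean water count per concentric shell around the host center."""

    bounds: tuple            # ((a0, b0), (a1, b1), ...) nm, half-open [a, b)
    counts: np.ndarray
    n_frames: int


@dataclass(frozen=True)
class SurfaceReport:
    """Window-averaged SASA (nm^2), volume (nm^3) and their ratio (nm^-1)."""

    sasa: float
    volume: float
    sa_to_v: float
    probe: float
    n_points: int
    n_frames: int
    volume_kind: str = "vdw-grid"


# ---------------------------------------------------------------------------
# RDF and shells
# ---------------------------------------------------------------------------

def _center_distances(frame: Frame, center_sel: Selection,
                      water_sel: Selection) -> np.ndarray:
    cog = center_of_geometry(frame, center_sel)
    d = minimum_image(frame.positions[water_sel.indices] - cog, frame.box)
    return np.linalg.norm(d, axis=1)


def rdf(traj: Trajectory, center_sel: Selection, water_o_sel: Selection,
        bin_width: float = 0.002, r_max: float | None = None,
        window_fraction: float = 1.0) -> RDFProfile:
    """Radial distribution of water oxygens around the host center.

    Bulk density is taken from the whole box, N_water / V_box, which makes
    g(r) -> 1 exactly for uniformly distributed water.
    """
    win = traj.window(window_fraction)
    box = win[0].box
    if box is None:
        raise ValidationError("RDF requires frames with a box")
    if r_max is None:
        r_max = float(np.min(box)) / 2.0
    if r_max > float(np.min(box)) / 2.0 + 1e-12:
        raise ValidationError("r_max exceeds half the smallest box edge")
    edges = np.arange(0.0, r_max + bin_width * 0.5, bin_width)
    counts = np.zeros(len(edges) - 1)
    n_frames = len(win)
    for frame in win:
        if len(water_o_sel) == 0:
            continue
        d = _center_distances(frame, center_sel, water_o_sel)
        counts += np.histogram(d, bins=edges)[0]
    mean_counts = counts / n_frames
    centers = 0.5 * (edges[:-1] + edges[1:])
    rho = len(water_o_sel) / float(np.prod(box))
    shell_vol = 4.0 * np.pi * centers**2 * bin_width
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(shell_vol > 0, mean_counts / (rho * shell_vol), 0.0) \
            if rho > 0 else np.zeros_like(mean_counts)
    return RDFProfile(centers, g, np.cumsum(mean_counts), bin_width, rho)


def count_in_shells(traj: Trajectory, center_sel: Selection,
                    water_o_sel: Selection,
                    shell_bounds: Sequence[tuple[float, float]] = ((0.0, 0.5),
                                                                   (0.5, 1.0)),
                    window_fraction: float = 1.0) -> ShellCountRecord:
    """Mean number of water oxygens per half-open [a, b) shell."""
    for a, b in shell_bounds:
        if a > b:
            raise ValidationError(f"shell bound {a}:{b} is reversed")
    win = traj.window(window_fraction)
    totals = np.zeros(len(shell_bounds))
    for frame in win:
        if len(water_o_sel) == 0:
            continue
        d = _center_distances(frame, center_sel, water_o_sel)
        for j, (a, b) in enumerate(shell_bounds):
            totals[j] += np.count_nonzero((d >= a) & (d < b))
    return ShellCountRecord(tuple(tuple(b) for b in shell_bounds),
                            totals / len(win), len(win))


# ---------------------------------------------------------------------------
# Shrake-Rupley SASA and grid volume
# ---------------------------------------------------------------------------

def _golden_spiral(n: int) -> np.ndarray:
    """Deterministic, nearly uniform n-point set on the unit sphere."""
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def sasa(frame: Frame, sel: Selection, radii: np.ndarray | None = None,
         probe: float = 0.14, n_points: int = 960) -> float:
    """Shrake-Rupley solvent-accessible surface area, nm^2.

    Each atom is sampled on a golden-spiral shell at radius r_i + probe; a
    point is exposed when it lies outside every other atom's expanded
    sphere.  The point set is fixed in the lab frame, so rotational
    invariance holds to the point-set resolution (about 0.5 % at the
    default 960 points).
    """
    if len(sel) == 0:
        raise ValidationError("SASA selection is empty")
    if radii is None:
        radii = radii_for(frame, sel)
    radii = np.asarray(radii, float)
    if np.any(radii <= 0):
        raise ValidationError("radii must be positive")
    pos = frame.positions[sel.indices]
    expanded = radii + probe
    sphere = _golden_spiral(n_points)
    total = 0.0
    for i in range(len(pos)):
        sep = pos - pos[i]
        dist = np.linalg.norm(sep, axis=1)
        neighbors = np.nonzero((dist < expanded + expanded[i]) &
                               (np.arange(len(pos)) != i))[0]
        pts = pos[i] + expanded[i] * sphere
        exposed = np.ones(n_points, dtype=bool)
        for j in neighbors:
            exposed &= (np.linalg.norm(pts - pos[j], axis=1) >= expanded[j])
            if not exposed.any():
                break
        total += exposed.mean() * 4.0 * np.pi * expanded[i] ** 2
    return float(total)


def molecular_volume(frame: Frame, sel: Selection,
                     radii: np.ndarray | None = None,
                     spacing: float = 0.02) -> float:
    """Grid-fill van der Waals volume, nm^3.

    Counts grid cells whose centers fall inside any atom's bare van der
    Waals sphere, times the cell volume.
    """
    if spacing <= 0:
        raise ValidationError("grid spacing must be positive")
    if len(sel) == 0:
        return 0.0
    if radii is None:
        radii = radii_for(frame, sel)
    radii = np.asarray(radii, float)
    pos = frame.positions[sel.indices]
    lo = (pos - radii[:, None]).min(axis=0) - spacing
    hi = (pos + radii[:, None]).max(axis=0) + spacing
    shape = np.ceil((hi - lo) / spacing).astype(int)
    inside = np.zeros(shape, dtype=bool)
    for p, r in zip(pos, radii):
        i0 = np.floor((p - r - lo) / spacing).astype(int)
        i1 = np.ceil((p + r - lo) / spacing).astype(int) + 1
        i0 = np.clip(i0, 0, shape)
        i1 = np.clip(i1, 0, shape)
        ax = [lo[d] + (np.arange(i0[d], i1[d]) + 0.5) * spacing for d in range(3)]
        dx2 = (ax[0] - p[0])[:, None, None] ** 2 \
            + (ax[1] - p[1])[None, :, None] ** 2 \
            + (ax[2] - p[2])[None, None, :] ** 2
        inside[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]] |= dx2 <= r * r
    return float(inside.sum()) * spacing**3


def sa_to_v(traj: Trajectory, sel: Selection, radii: np.ndarray | None = None,
            window_fraction: float = 0.10, probe: float = 0.14,
            n_points: int = 960, spacing: float = 0.02,
            cavity_volume: float | None = None) -> SurfaceReport:
    """Window-averaged SASA over window-averaged volume.

    Passing ``cavity_volume`` substitutes the frustum cavity volume for the
    grid van der Waals volume in the denominator.
    """
    win = traj.window(window_fraction)
    areas = np.empty(len(win))
    vols = np.empty(len(win))
    for k, frame in enumerate(win):
        areas[k] = sasa(frame, sel, radii, probe, n_points)
        vols[k] = (cavity_volume if cavity_volume is not None
                   else molecular_volume(frame, sel, radii, spacing))
    mean_a, mean_v = float(areas.mean()), float(vols.mean())
    if mean_v <= 0:
        raise ValidationError("volume is non-positive; cannot form SA/V")
    return SurfaceReport(mean_a, mean_v, mean_a / mean_v, probe, n_points,
                         len(win),
                         "cavity" if cavity_volume is not None else "vdw-grid")
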