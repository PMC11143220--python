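"""Text-format I/O and atom selection.

Coordinate frames travel as concatenated fixed-column GRO blocks (the MD
engine's native text format) or multi-MODEL PDB (read-only).  Free-energy
inputs travel as ``#``-commented whitespace tables.  Units are fixed
package-wide: nm, ps, kJ/mol, elementary charge, kelvin.

Only rectangular boxes are supported; the minimum-image convention is applied
in downstream distance computations whenever a frame carries a box.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .energetics import LambdaSeries, WorkSamples
from .exceptions import (
    FormatOverflowError,
    ParseError,
    StructureError,
    ValidationError,
)

__all__ = [
    "Atom",
    "Frame",
    "Trajectory",
    "Selection",
    "ParamTable",
    "read_gro",
    "write_gro",
    "read_pdb",
    "read_energy_table",
    "write_energy_table",
    "read_param_table",
    "select",
    "infer_element",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

def infer_element(name: str) -> str:
    """Guess the element label from an atom name.

    Methyl pseudo-atoms (names starting with ``CM``) are treated as a united
    ``CH3`` site; otherwise the first alphabetic character wins (``OW`` -> O,
    ``HW1`` -> H, ``C6`` -> C).
    """
    if name.upper().startswith("CM"):
        return "CH3"
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "X"


@dataclass(frozen=True)
class Atom:
    """A single labelled atom (a read-only view into a Frame)."""

    index: int
    name: str
    residue_name: str
    residue_id: int
    position: np.ndarray  # (3,) nm

    @property
    def element(self) -> str:
        return infer_element(self.name)


class Frame:
    """One timestamped coordinate set.

    Parameters
    ----------
    names, residue_names : sequences of atom / residue labels
    residue_ids : positive integers, one per atom
    positions : (n, 3) array, nm
    box : optional 3 positive rectangular edge lengths, nm
    time : ps
    """

    def __init__(
        self,
        names: Sequence[str],
        residue_names: Sequence[str],
        residue_ids: Sequence[int],
        positions: np.ndarray,
        box: np.ndarray | None = None,
        time: float = 0.0,
    ):
        self.names = np.asarray(names, dtype=object)
        self.residue_names = np.asarray(residue_names, dtype=object)
        self.residue_ids = np.asarray(residue_ids, dtype=int)
        self.positions = np.asarray(positions, dtype=float).reshape(-1, 3)
        self.box = None if box is None else np.asarray(box, dtype=float).reshape(3)
        self.time = float(time)
        n = len(self.positions)
        if not (len(self.names) == len(self.residue_names) == len(self.residue_ids) == n):
            raise ValidationError("per-atom arrays have mismatched lengths")
        if not np.all(np.isfinite(self.positions)):
            raise ValidationError("non-finite atom position")
        if any(not str(nm) for nm in self.names):
            raise ValidationError("empty atom name")
        if self.box is not None and not np.all(self.box > 0):
            raise ValidationError("box edges must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    def atom(self, i: int) -> Atom:
        return Atom(i, str(self.names[i]), str(self.residue_names[i]),
                    int(self.residue_ids[i]), self.positions[i])

    @property
    def atoms(self) -> Iterator[Atom]:
        return (self.atom(i) for i in range(self.n_atoms))

    @property
    def elements(self) -> np.ndarray:
        return np.array([infer_element(str(nm)) for nm in self.names], dtype=object)

    def copy(self) -> "Frame":
        return Frame(self.names.copy(), self.residue_names.copy(),
                     self.residue_ids.copy(), self.positions.copy(),
                     None if self.box is None else self.box.copy(), self.time)


class Trajectory:
    """Time-ordered sequence of frames with a constant atom roster."""

    def __init__(self, frames: Sequence[Frame]):
        frames = list(frames)
        if frames:
            n0 = frames[0].n_atoms
            for k, f in enumerate(frames):
                if f.n_atoms != n0:
                    raise StructureError(
                        f"frame {k} has {f.n_atoms} atoms, expected {n0}")
            times = np.array([f.time for f in frames])
            if len(times) > 1 and not np.all(np.diff(times) > 0):
                raise ValidationError("frame times must be strictly increasing")
        self.frames = frames

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return Trajectory(self.frames[i])
        return self.frames[i]

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    @property
    def dt(self) -> float | None:
        """Median frame spacing in ps (None for < 2 frames)."""
        if len(self.frames) < 2:
            return None
        return float(np.median(np.diff(self.times)))

    @property
    def n_atoms(self) -> int:
        return self.frames[0].n_atoms if self.frames else 0

    def window(self, window_fraction: float = 1.0) -> "Trajectory":
        """Trailing fraction of the trajectory (e.g. 0.10 = last 10 %)."""
        if not 0.0 < window_fraction <= 1.0:
            raise ValidationError("window_fraction must be in (0, 1]")
        n = len(self.frames)
        k = max(1, int(round(window_fraction * n)))
        return Trajectory(self.frames[n - k:])


@dataclass(frozen=True)
class Selection:
    """Sorted unique 0-based atom ordinals with a free-text label."""

    indices: np.ndarray
    label: str = ""

    def __post_init__(self):
        idx = np.unique(np.asarray(self.indices, dtype=int))
        object.__setattr__(self, "indices", idx)
        if len(idx) and idx[0] < 0:
            raise ValidationError("negative atom index in selection")

    def __len__(self) -> int:
        return len(self.indices)

    def __iter__(self):
        return iter(self.indices)

    def union(self, other: "Selection", label: str = "") -> "Selection":
        return Selection(np.union1d(self.indices, other.indices), label or self.label)


@dataclass
class ParamTable:
    """Per-atom nonbonded parameters: charge (e), LJ sigma (nm), epsilon (kJ/mol)."""

    charge: np.ndarray
    sigma: np.ndarray
    epsilon: np.ndarray

    def __post_init__(self):
        self.charge = np.asarray(self.charge, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        if not (len(self.charge) == len(self.sigma) == len(self.epsilon)):
            raise ValidationError("parameter columns have mismatched lengths")
        if np.any(self.sigma < 0) or np.any(self.epsilon < 0):
            raise ValidationError("sigma and epsilon must be non-negative")

    def __len__(self) -> int:
        return len(self.charge)


# ---------------------------------------------------------------------------
# GRO
# ---------------------------------------------------------------------------

_TIME_RE = re.compile(r"t\s*=\s*([-+0-9.eE]+)")


def _parse_gro_block(lines: list[str], start: int, lineno0: int) -> tuple[Frame | None, int]:
    """Parse one GRO block starting at ``lines[start]``; returns (frame, next)."""
    i = start
    while i < len(lines) and not lines[i].strip():
        i += 1
    if i >= len(lines):
        return None, i
    title = lines[i]
    m = _TIME_RE.search(title)
    time = float(m.group(1)) if m else None
    try:
        n_atoms = int(lines[i + 1].strip())
    except (IndexError, ValueError):
        raise ParseError("expected atom-count line", lineno0 + i + 2)
    names, resnames, resids = [], [], []
    pos = np.empty((n_atoms, 3))
    for k in range(n_atoms):
        ln = i + 2 + k
        try:
            line = lines[ln]
        except IndexError:
            raise ParseError("unexpected end of file inside atom block", lineno0 + ln + 1)
        if len(line.rstrip("\n")) < 44:
            raise ParseError("atom line shorter than fixed 44-column minimum",
                             lineno0 + ln + 1)
        try:
            resids.append(int(line[0:5]))
            resnames.append(line[5:10].strip())
            names.append(line[10:15].strip())
            pos[k, 0] = float(line[20:28])
            pos[k, 1] = float(line[28:36])
            pos[k, 2] = float(line[36:44])
        except ValueError as exc:
            raise ParseError(f"malformed atom columns ({exc})", lineno0 + ln + 1)
    ln = i + 2 + n_atoms
    try:
        box_fields = lines[ln].split()
        box = np.array([float(x) for x in box_fields[:3]])
    except (IndexError, ValueError):
        raise ParseError("missing or malformed box line", lineno0 + ln + 1)
    frame = Frame(names, resnames, resids, pos,
                  box=box if np.all(box > 0) else None,
                  time=0.0 if time is None else time)
    frame._had_time = time is not None  # type: ignore[attr-defined]
    return frame, ln + 1


def read_gro(path: str | Path) -> Trajectory:
    """Read a (possibly multi-frame, concatenated) GRO file.

    Titles carrying ``t= X`` set frame times in ps; otherwise frames are
    numbered 0, 1, 2, ... in index units.
    """
    lines = Path(path).read_text().splitlines()
    frames: list[Frame] = []
    i = 0
    while True:
        frame, i = _parse_gro_block(lines, i, 0)
        if frame is None:
            break
        frames.append(frame)
    if not frames:
        raise ParseError("no frames found in GRO file")
    if not all(getattr(f, "_had_time", False) for f in frames):
        for k, f in enumerate(frames):
            f.time = float(k)
    return Trajectory(frames)


def write_gro(traj: Trajectory | Frame, path: str | Path, title: str = "cyclokit") -> Path:
    """Write frames as concatenated fixed-column GRO (3-decimal nm)."""
    if isinstance(traj, Frame):
        traj = Trajectory([traj])
    if len(traj) == 0:
        raise ValidationError("cannot write an empty trajectory")
    buf = io.StringIO()
    for frame in traj:
        if np.any(np.abs(frame.positions) >= 10000.0):
            raise FormatOverflowError(
                "coordinate magnitude >= 10000 nm does not fit 8.3f columns")
        buf.write(f"{title} t= {frame.time:.4f}\n")
        buf.write(f"{frame.n_atoms:5d}\n")
        for i in range(frame.n_atoms):
            x, y, z = frame.positions[i]
            buf.write(
                f"{int(frame.residue_ids[i]) % 100000:5d}"
                f"{str(frame.residue_names[i])[:5]:<5s}"
                f"{str(frame.names[i])[:5]:>5s}"
                f"{(i + 1) % 100000:5d}"
                f"{x:8.3f}{y:8.3f}{z:8.3f}\n")
        box = frame.box if frame.box is not None else np.zeros(3)
        buf.write(f"{box[0]:10.5f}{box[1]:10.5f}{box[2]:10.5f}\n")
    p = Path(path)
    p.write_text(buf.getvalue())
    return p


# ---------------------------------------------------------------------------
# PDB (read-only)
# ---------------------------------------------------------------------------

def read_pdb(path: str | Path) -> Trajectory:
    """Read a PDB file (MODEL/ENDMDL frames); angstroms are converted to nm."""
    frames: list[Frame] = []
    names, resnames, resids, pos = [], [], [], []
    box = None
    in_model = False
    any_model = False

    def flush(time: float):
        nonlocal names, resnames, resids, pos
        if pos:
            frames.append(Frame(names, resnames, resids, np.array(pos), box, time))
        names, resnames, resids, pos = [], [], [], []

    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        rec = line[:6]
        if rec == "CRYST1":
            try:
                box = np.array([float(line[6:15]), float(line[15:24]),
                                float(line[24:33])]) / 10.0
            except ValueError:
                raise ParseError("malformed CRYST1 record", lineno)
        elif rec == "MODEL ":
            in_model = any_model = True
        elif rec == "ENDMDL":
            flush(float(len(frames)))
            in_model = False
        elif rec in ("ATOM  ", "HETATM"):
            try:
                names.append(line[12:16].strip())
                resnames.append(line[17:20].strip() or "UNK")
                resids.append(int(line[22:26]))
                pos.append([float(line[30:38]) / 10.0,
                            float(line[38:46]) / 10.0,
                            float(line[46:54]) / 10.0])
            except ValueError:
                raise ParseError("malformed ATOM/HETATM record", lineno)
    if in_model or not any_model:
        flush(float(len(frames)))
    if not frames:
        raise ParseError("no coordinates found in PDB file")
    return Trajectory(frames)


# ---------------------------------------------------------------------------
# Lambda-energy / work tables
# ---------------------------------------------------------------------------

def read_energy_table(path: str | Path) -> LambdaSeries | WorkSamples:
    """Read a ``#``-commented whitespace table of dH/dlambda or work samples.

    A ``# mode= dhdl`` table has columns ``time lambda dhdl`` (kJ/mol); a
    ``# mode= work`` table has columns ``direction work`` with direction F or
    R.  Temperature comes from a ``# T= <kelvin>`` comment, default 300 K.
    """
    mode = None
    temperature = 300.0
    rows: list[list[str]] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            m = re.match(r"mode\s*=\s*(\w+)", body)
            if m:
                mode = m.group(1).lower()
            m = re.match(r"T\s*=\s*([-+0-9.eE]+)", body)
            if m:
                temperature = float(m.group(1))
            continue
        rows.append(line.split())
    if mode not in ("dhdl", "work"):
        raise ParseError(f"unknown or missing table mode {mode!r}; "
                         "expected '# mode= dhdl' or '# mode= work'")
    if mode == "dhdl":
        lam_to_samples: dict[float, list[float]] = {}
        for r in rows:
            if len(r) < 3:
                raise ParseError("dhdl rows need columns: time lambda dhdl")
            lam_to_samples.setdefault(float(r[1]), []).append(float(r[2]))
        if not lam_to_samples:
            raise ValidationError("dhdl table contains no samples")
        lambdas = sorted(lam_to_samples)
        return LambdaSeries(
            lambdas=np.array(lambdas),
            samples=[np.array(lam_to_samples[l]) for l in lambdas],
            temperature=temperature)
    forward, reverse = [], []
    for r in rows:
        if len(r) < 2 or r[0].upper() not in ("F", "R"):
            raise ParseError("work rows need columns: direction(F|R) work")
        (forward if r[0].upper() == "F" else reverse).append(float(r[1]))
    if not forward or not reverse:
        raise ValidationError("work table needs samples in both directions")
    return WorkSamples(forward=np.array(forward), reverse=np.array(reverse),
                       temperature=temperature)


def write_energy_table(data: LambdaSeries | WorkSamples, path: str | Path) -> Path:
    """Write a dhdl or work table in the format read_energy_table accepts."""
    buf = io.StringIO()
    buf.write(f"# T= {data.temperature:.6g}\n")
    if isinstance(data, LambdaSeries):
        buf.write("# mode= dhdl\n# time lambda dhdl\n")
        for lam, samples in zip(data.lambdas, data.samples):
            for t, v in enumerate(samples):
                buf.write(f"{float(t):.1f} {lam:.10g} {v:.10g}\n")
    elif isinstance(data, WorkSamples):
        buf.write("# mode= work\n# direction work\n")
        for w in data.forward:
            buf.write(f"F {w:.10g}\n")
        for w in data.reverse:
            buf.write(f"R {w:.10g}\n")
    else:
        raise ValidationError(f"cannot serialize {type(data).__name__}")
    p = Path(path)
    p.write_text(buf.getvalue())
    return p


def read_param_table(path: str | Path, n_atoms: int | None = None) -> ParamTable:
    """Read a TSV/whitespace table with columns: index charge sigma epsilon."""
    idx, q, s, e = [], [], [], []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#") or line.lower().startswith("index"):
            continue
        f = line.split()
        if len(f) < 4:
            raise ParseError("param rows need columns: index charge sigma epsilon",
                             lineno)
        idx.append(int(f[0])); q.append(float(f[1]))
        s.append(float(f[2])); e.append(float(f[3]))
    n = n_atoms if n_atoms is not None else (max(idx) + 1 if idx else 0)
    charge = np.zeros(n); sigma = np.zeros(n); eps = np.zeros(n)
    for i, qi, si, ei in zip(idx, q, s, e):
        charge[i], sigma[i], eps[i] = qi, si, ei
    return ParamTable(charge, sigma, eps)


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

def select(frame: Frame, residue_name: str | None = None,
           atom_names: set[str] | Sequence[str] | None = None,
           label: str = "") -> Selection:
    """Atoms matching all provided criteria, in index order."""
    if frame.n_atoms == 0:
        raise ValidationError("cannot select from an empty frame")
    mask = np.ones(frame.n_atoms, dtype=bool)
    if residue_name is not None:
        mask &= np.array([rn == residue_name for rn in frame.residue_names])
    if atom_names is not None:
        wanted = set(atom_names)
        mask &= np.array([nm in wanted for nm in frame.names])
    return Selection(np.nonzero(mask)[0], label=label)
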