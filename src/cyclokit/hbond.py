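"""Geometric hydrogen-bond detection and lifetime estimation.

A donor-hydrogen-acceptor triple counts as bonded when the donor-acceptor
minimum-image distance is below ``r_cut`` and the hydrogen-donor-acceptor
angle (at the donor) is below ``angle_cut``.  The 0.35 nm / 30 degree
defaults are the de-facto standard geometric criterion; both are tunable.

Lifetimes come from the 0/1 presence matrix of triples over time:
``continuous`` mode reports the mean length of maximal unbroken runs times
the frame spacing (runs censored by the window edges are included, with a
warning); ``intermittent`` mode fits exp(-tau/tau0) to the normalized
presence autocorrelation down to its 1/e crossing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import ValidationError
from .io_formats import Frame, Selection, Trajectory
from .util import minimum_image

__all__ = [
    "HBondCriteria",
    "HBondSummary",
    "detect_hbonds",
    "hbond_count",
    "hbond_presence",
    "hbond_lifetime",
    "hbond_lifetime_from_matrix",
    "water_donor_pairs",
]


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric criterion: distance cut (nm) and H-D-A angle cut (degrees)."""

    r_cut: float = 0.35
    angle_cut: float = 30.0

    def __post_init__(self):
        if self.r_cut <= 0:
            raise ValidationError("r_cut must be positive")
        if not 0.0 < self.angle_cut < 90.0:
            raise ValidationError("angle_cut must be in (0, 90) degrees")


@dataclass(frozen=True)
class HBondSummary:
    """Mean bond count per frame and characteristic lifetime for a group pair."""

    mean_count: float
    lifetime: float  # ps
    n_frames: int
    label: str = ""


def water_donor_pairs(frame: Frame, residue_name: str = "SOL",
                      ) -> list[tuple[int, int]]:
    """(O, H) donor pairs of every 3-site water residue in the frame."""
    pairs = []
    by_res: dict[int, dict[str, int]] = {}
    for i in range(frame.n_atoms):
        if frame.residue_names[i] == residue_name:
            by_res.setdefault(int(frame.residue_ids[i]), {})[str(frame.names[i])] = i
    for atoms in by_res.values():
        if "OW" in atoms:
            for h in ("HW1", "HW2"):
                if h in atoms:
                    pairs.append((atoms["OW"], atoms[h]))
    return pairs


def detect_hbonds(frame: Frame, donors: Sequence[tuple[int, int]],
                  acceptors: Selection,
                  criteria: HBondCriteria = HBondCriteria(),
                  exclude_same_residue: bool = False,
                  ) -> set[tuple[int, int, int]]:
    """All (donor, hydrogen, acceptor) triples meeting the criterion."""
    acc = np.asarray(acceptors.indices)
    if len(acc) == 0 or len(donors) == 0:
        return set()
    cos_cut = np.cos(np.deg2rad(criteria.angle_cut))
    found: set[tuple[int, int, int]] = set()
    acc_pos = frame.positions[acc]
    for d, h in donors:
        da = minimum_image(acc_pos - frame.positions[d], frame.box)
        r = np.linalg.norm(da, axis=1)
        close = (r < criteria.r_cut) & (acc != d)
        if exclude_same_residue:
            close &= frame.residue_ids[acc] != frame.residue_ids[d]
        if not close.any():
            continue
        dh = minimum_image(frame.positions[h] - frame.positions[d], frame.box)
        dh_norm = np.linalg.norm(dh)
        if dh_norm == 0:
            raise ValidationError(f"hydrogen {h} coincides with donor {d}")
        cosang = (da[close] @ dh) / (r[close] * dh_norm)
        for a, ok in zip(acc[close], cosang > cos_cut):
            if ok:
                found.add((d, h, int(a)))
    return found


def hbond_count(traj: Trajectory, donors: Sequence[tuple[int, int]],
                acceptors: Selection,
                criteria: HBondCriteria = HBondCriteria(),
                window_fraction: float = 0.10,
                exclude_same_residue: bool = False) -> float:
    """Mean number of bonded triples per frame over the trailing window."""
    win = traj.window(window_fraction)
    counts = [len(detect_hbonds(f, donors, acceptors, criteria,
                                exclude_same_residue)) for f in win]
    return float(np.mean(counts))


def hbond_presence(traj: Trajectory, donors: Sequence[tuple[int, int]],
                   acceptors: Selection,
                   criteria: HBondCriteria = HBondCriteria(),
                   window_fraction: float = 1.0,
                   exclude_same_residue: bool = False,
                   ) -> tuple[np.ndarray, list[tuple[int, int, int]]]:
    """Presence matrix b(triple, frame) over every triple ever observed."""
    win = traj.window(window_fraction)
    per_frame = [detect_hbonds(f, donors, acceptors, criteria,
                               exclude_same_residue) for f in win]
    triples = sorted(set().union(*per_frame)) if per_frame else []
    mat = np.zeros((len(triples), len(win)), dtype=bool)
    index = {t: i for i, t in enumerate(triples)}
    for k, frame_set in enumerate(per_frame):
        for t in frame_set:
            mat[index[t], k] = True
    return mat, triples


def _run_lengths(row: np.ndarray) -> tuple[list[int], bool]:
    """Maximal runs of True; second value flags an edge-censored run."""
    runs, censored = [], False
    n = len(row)
    i = 0
    while i < n:
        if row[i]:
            j = i
            while j < n and row[j]:
                j += 1
            runs.append(j - i)
            if i == 0 or j == n:
                censored = True
            i = j
        else:
            i += 1
    return runs, censored


def hbond_lifetime_from_matrix(matrix: np.ndarray, dt: float,
                               mode: str = "continuous",
                               exclude_censored: bool = False) -> float:
    """Characteristic bond lifetime (ps) from a 0/1 presence matrix."""
    matrix = np.atleast_2d(np.asarray(matrix, dtype=bool))
    if dt <= 0:
        raise ValidationError("dt must be positive")
    if matrix.size == 0 or not matrix.any():
        warnings.warn("no bonds ever present; lifetime reported as 0")
        return 0.0
    if mode == "continuous":
        all_runs: list[int] = []
        any_censored = False
        n = matrix.shape[1]
        for row in matrix:
            runs, censored = _run_lengths(row)
            if censored and exclude_censored:
                if row[0] and runs:
                    runs = runs[1:]
                if row[-1] and runs:
                    runs = runs[:-1]
            any_censored |= censored
            all_runs.extend(runs)
        if any_censored and not exclude_censored:
            warnings.warn("window-censored bond runs included in lifetime")
        if not all_runs:
            warnings.warn("all runs censored and excluded; lifetime 0")
            return 0.0
        return float(np.mean(all_runs) * dt)
    if mode == "intermittent":
        b = matrix.astype(float)
        n = b.shape[1]
        mean_b = b.mean()
        max_lag = n - 1
        taus, corr = [0.0], [1.0]
        for lag in range(1, max_lag):
            c = float(np.mean(b[:, :-lag] * b[:, lag:])) / mean_b
            taus.append(lag * dt)
            corr.append(c)
            if c < np.exp(-1.0):
                break
        taus = np.asarray(taus)
        corr = np.asarray(corr)
        keep = corr > 0
        if keep.sum() < 2:
            return float(taus[-1])
        slope = np.polyfit(taus[keep], np.log(corr[keep]), 1)[0]
        if slope >= 0:
            warnings.warn("non-decaying autocorrelation; lifetime unresolved, "
                          "returning the window span")
            return float(matrix.shape[1] * dt)
        return float(-1.0 / slope)
    raise ValidationError(f"unknown lifetime mode {mode!r}")


def hbond_lifetime(traj: Trajectory, donors: Sequence[tuple[int, int]],
                   acceptors: Selection,
                   criteria: HBondCriteria = HBondCriteria(),
                   mode: str = "continuous",
                   window_fraction: float = 1.0,
                   exclude_same_residue: bool = False,
                   dt: float | None = None) -> float:
    """Bond lifetime (ps) from trajectory presence; dt defaults to the frame spacing."""
    if len(traj) < 2:
        raise ValidationError("lifetime estimation needs >= 2 frames")
    mat, _ = hbond_presence(traj, donors, acceptors, criteria,
                            window_fraction, exclude_same_residue)
    if dt is None:
        dt = traj.window(window_fraction).dt or 1.0
    return hbond_lifetime_from_matrix(mat, dt, mode=mode)
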