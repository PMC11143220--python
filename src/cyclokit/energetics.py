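"""Group interaction energies, thermodynamic integration, and BAR.

The free-energy layer consumes per-window ``dH/dlambda`` samples (TI) or
forward/reverse work samples (BAR) produced elsewhere; the soft-core
lambda-Hamiltonian that generates such data in an MD engine is out of scope
here.  Group-group energies use a plain cutoff for both Coulomb and
Lennard-Jones terms: they are descriptive per-pair statistics, not a
force-field reimplementation.

Conventions
-----------
* kB = 0.0083145 kJ/mol/K, default temperature 300 K.
* Coulomb prefactor f = 138.935458 kJ mol^-1 nm e^-2.
* Lorentz-Berthelot combination: sigma arithmetic mean, epsilon geometric.
* Binding cycle sign: negative ``dG_bind`` means favorable binding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .exceptions import ConvergenceError, ValidationError

KB = 0.0083145  # kJ/mol/K
COULOMB_CONST = 138.935458  # kJ mol^-1 nm e^-2
DEFAULT_TEMPERATURE = 300.0  # K

__all__ = [
    "KB",
    "COULOMB_CONST",
    "LambdaSeries",
    "WorkSamples",
    "FreeEnergyEstimate",
    "InteractionEnergyRecord",
    "group_interaction_energy",
    "ti_integrate",
    "bar_estimate",
    "binding_cycle",
    "interaction_report",
]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class LambdaSeries:
    """Per-window dH/dlambda samples along an alchemical path.

    ``lambdas`` is strictly increasing in [0, 1]; ``samples[i]`` holds the
    kJ/mol samples of window i.
    """

    lambdas: np.ndarray
    samples: list[np.ndarray]
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self):
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        self.samples = [np.atleast_1d(np.asarray(s, dtype=float)) for s in self.samples]
        if len(self.lambdas) != len(self.samples):
            raise ValidationError("lambdas and samples lengths differ")
        if len(self.lambdas) and not np.all(np.diff(self.lambdas) > 0):
            raise ValidationError("lambda values must be strictly increasing")
        if any(len(s) == 0 for s in self.samples):
            raise ValidationError("every lambda window needs at least one sample")

    @property
    def means(self) -> np.ndarray:
        return np.array([s.mean() for s in self.samples])

    @property
    def sems(self) -> np.ndarray:
        return np.array([s.std(ddof=1) / np.sqrt(len(s)) if len(s) > 1 else 0.0
                         for s in self.samples])


@dataclass
class WorkSamples:
    """Forward and reverse nonequilibrium work samples (kJ/mol)."""

    forward: np.ndarray
    reverse: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self):
        self.forward = np.atleast_1d(np.asarray(self.forward, dtype=float))
        self.reverse = np.atleast_1d(np.asarray(self.reverse, dtype=float))
        if len(self.forward) == 0 or len(self.reverse) == 0:
            raise ValidationError("both work directions must be non-empty")


@dataclass(frozen=True)
class FreeEnergyEstimate:
    """A free-energy difference with its standard error (kJ/mol)."""

    dG: float
    stderr: float
    method: str
    temperature: float = DEFAULT_TEMPERATURE
    n_bootstrap: int = 0

    def __post_init__(self):
        if self.stderr < 0:
            raise ValidationError("stderr must be non-negative")


@dataclass(frozen=True)
class InteractionEnergyRecord:
    """Pairwise nonbonded energy between two atom groups (kJ/mol)."""

    e_coulomb: float
    e_lj: float
    cutoff: float
    label_a: str = ""
    label_b: str = ""

    @property
    def e_total(self) -> float:
        return self.e_coulomb + self.e_lj


# ---------------------------------------------------------------------------
# Group-group nonbonded energy
# ---------------------------------------------------------------------------

def group_interaction_energy(frame, sel_a, sel_b, params, cutoff: float = 1.2,
                             label_a: str = "A", label_b: str = "B",
                             ) -> InteractionEnergyRecord:
    """Cutoff Coulomb + Lennard-Jones energy between two disjoint groups.

    Pairs beyond the minimum-image ``cutoff`` (nm) contribute nothing.
    """
    ia = np.asarray(sel_a.indices)
    ib = np.asarray(sel_b.indices)
    if len(np.intersect1d(ia, ib)):
        raise ValidationError("selections overlap; groups must be disjoint")
    n_params = len(params)
    if (len(ia) and ia.max() >= n_params) or (len(ib) and ib.max() >= n_params):
        raise ValidationError("parameter table does not cover both groups")

    from .util import pairwise_min_image_distances

    r = pairwise_min_image_distances(frame.positions[ia], frame.positions[ib],
                                     frame.box)
    if np.any(r == 0.0):
        i, j = np.argwhere(r == 0.0)[0]
        raise ValidationError(
            f"singular pair at zero distance: atoms {ia[i]} and {ib[j]}")
    within = r <= cutoff

    qq = np.outer(params.charge[ia], params.charge[ib])
    e_coul = float(np.sum(np.where(within, COULOMB_CONST * qq / r, 0.0)))

    sig = 0.5 * (params.sigma[ia][:, None] + params.sigma[ib][None, :])
    eps = np.sqrt(np.outer(params.epsilon[ia], params.epsilon[ib]))
    with np.errstate(divide="ignore", over="ignore"):
        sr6 = (sig / r) ** 6
        e_lj_mat = 4.0 * eps * (sr6 * sr6 - sr6)
    e_lj = float(np.sum(np.where(within, e_lj_mat, 0.0)))

    return InteractionEnergyRecord(e_coul, e_lj, cutoff, label_a, label_b)


def interaction_report(traj, group_pairs, params, cutoff: float = 1.2,
                       window_fraction: float = 0.10):
    """Window-averaged Coulomb/LJ/total energies for labelled group pairs.

    ``group_pairs`` maps ``(label_a, label_b)`` to ``(Selection, Selection)``.
    Returns a pandas DataFrame with one row per pair.
    """
    import pandas as pd

    win = traj.window(window_fraction)
    rows = []
    for (la, lb), (sa, sb) in group_pairs.items():
        coul = np.empty(len(win))
        lj = np.empty(len(win))
        for k, frame in enumerate(win):
            rec = group_interaction_energy(frame, sa, sb, params, cutoff, la, lb)
            coul[k], lj[k] = rec.e_coulomb, rec.e_lj
        rows.append({"pair": f"{la}-{lb}",
                     "E_coulomb": coul.mean(),
                     "E_lj": lj.mean(),
                     "E_total": coul.mean() + lj.mean(),
                     "n_frames": len(win)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Thermodynamic integration
# ---------------------------------------------------------------------------

def ti_integrate(series: LambdaSeries) -> FreeEnergyEstimate:
    """Trapezoidal quadrature of window-mean dH/dlambda over lambda.

    dG = integral of <dH/dlambda> d(lambda); the standard error propagates
    each window's standard error of the mean through the trapezoid weights.
    """
    lam = series.lambdas
    if len(lam) < 2:
        raise ValidationError("thermodynamic integration needs >= 2 windows")
    means = series.means
    sems = series.sems
    # trapezoid weights: w_0 = d0/2, w_i = (d_{i-1}+d_i)/2, w_last = d_last/2
    d = np.diff(lam)
    w = np.zeros_like(lam)
    w[0] = d[0] / 2.0
    w[-1] = d[-1] / 2.0
    w[1:-1] = (d[:-1] + d[1:]) / 2.0
    dg = float(np.dot(w, means))
    stderr = float(np.sqrt(np.dot(w**2, sems**2)))
    return FreeEnergyEstimate(dg, stderr, method="TI",
                              temperature=series.temperature)


# ---------------------------------------------------------------------------
# Bennett acceptance ratio
# ---------------------------------------------------------------------------

def _bar_residual(dg: float, wf: np.ndarray, wr: np.ndarray, beta: float,
                  m: float) -> float:
    # sum_F 1/(1+exp(M + beta(W_F - dG))) - sum_R 1/(1+exp(-M + beta(W_R + dG)))
    term_f = expit(-(m + beta * (wf - dg))).sum()
    term_r = expit(-(-m + beta * (wr + dg))).sum()
    return term_f - term_r


def bar_estimate(work: WorkSamples, tol: float = 1e-8, max_iter: int = 200,
                 n_bootstrap: int = 0, seed: int | None = None,
                 ) -> FreeEnergyEstimate:
    """Bennett acceptance ratio estimate from two-sided work samples.

    Solves the self-consistent BAR equation by bracketed root finding; the
    reverse samples carry the work of the reverse process, so a noiseless
    pair (W_F, W_R) = (+x, -x) yields dG = x exactly.  The standard error is
    Bennett's asymptotic variance; ``n_bootstrap > 0`` replaces it with a
    resampling estimate.
    """
    wf, wr = work.forward, work.reverse
    beta = 1.0 / (KB * work.temperature)
    m = np.log(len(wf) / len(wr))

    lo = min(wf.min(), -wr.max()) - 1.0
    hi = max(wf.max(), -wr.min()) + 1.0
    f_lo = _bar_residual(lo, wf, wr, beta, m)
    f_hi = _bar_residual(hi, wf, wr, beta, m)
    for _ in range(60):
        if f_lo * f_hi <= 0:
            break
        span = hi - lo
        lo -= span
        hi += span
        f_lo = _bar_residual(lo, wf, wr, beta, m)
        f_hi = _bar_residual(hi, wf, wr, beta, m)
    else:
        raise ConvergenceError(
            "BAR equation has no bracketable root: the forward and reverse "
            "work distributions do not overlap; add intermediate windows")
    dg = float(brentq(_bar_residual, lo, hi, args=(wf, wr, beta, m),
                      xtol=tol, maxiter=max_iter))

    ff = expit(-(m + beta * (wf - dg)))
    fr = expit(-(-m + beta * (wr + dg)))
    mean_ff, mean_fr = ff.mean(), fr.mean()
    if mean_ff <= 0 or mean_fr <= 0:
        raise ConvergenceError(
            "all BAR Fermi terms saturated; work distributions do not overlap")
    var = (1.0 / beta**2) * (
        (np.mean(ff**2) / mean_ff**2 - 1.0) / len(wf)
        + (np.mean(fr**2) / mean_fr**2 - 1.0) / len(wr))
    stderr = float(np.sqrt(max(var, 0.0)))

    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        boots = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            rs = WorkSamples(rng.choice(wf, size=len(wf), replace=True),
                             rng.choice(wr, size=len(wr), replace=True),
                             work.temperature)
            boots[b] = bar_estimate(rs, tol=tol, max_iter=max_iter).dG
        stderr = float(boots.std(ddof=1))

    return FreeEnergyEstimate(dg, stderr, method="BAR",
                              temperature=work.temperature,
                              n_bootstrap=n_bootstrap)


# ---------------------------------------------------------------------------
# Thermodynamic cycle
# ---------------------------------------------------------------------------

def binding_cycle(dg_decouple_in_water: FreeEnergyEstimate,
                  dg_decouple_in_complex: FreeEnergyEstimate,
                  ) -> FreeEnergyEstimate:
    """Binding free energy from the two decoupling legs of the cycle.

    dG_bind = dG_decouple(complex) - dG_decouple(water); errors add in
    quadrature.  Negative values mean spontaneous binding.
    """
    a, b = dg_decouple_in_water, dg_decouple_in_complex
    if not np.isclose(a.temperature, b.temperature):
        raise ValidationError("cycle legs must share a temperature")
    return FreeEnergyEstimate(
        b.dG - a.dG,
        float(np.hypot(a.stderr, b.stderr)),
        method="cycle",
        temperature=a.temperature)
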