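"""Thermodynamic (statistical-mechanical) models of simple repression and induction.

All energies are in units of kBT (β ≡ 1). The occupancy model treats the
promoter as competing for RNAP and repressor against N_NS nonspecific genomic
sites; expression is assumed proportional to the probability that RNAP
occupies the promoter,

    p_bound = (P/N_NS) e^(−Δε_P) / [1 + (P/N_NS) e^(−Δε_P) + (2R/N_NS) e^(−Δε_R)],

and for a weak promoter the fold-change in expression reduces to

    fold-change = 1 / [1 + (2R/N_NS) e^(−Δε_R)].

The factor 2 counts the two DNA-binding heads of a LacI tetramer and is a
parameter (``heads``) so dimeric repressors reuse the model. Induction by an
allosteric effector follows the two-state MWC picture with dissociation
constants K_A (active) and K_I (inactive), n effector sites per dimer, and an
active/inactive free-energy difference Δε_AI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

N_NS_ECOLI = 4.6e6  # nonspecific binding sites in the E. coli genome

# MWC parameters for LacI with IPTG
KA_LACI_UM = 139.0
KI_LACI_UM = 0.53
EPS_AI_LACI = 4.5
N_SITES_LACI = 2

BOLTZMANN_KCAL_PER_MOL_K = 1.987204259e-3  # kcal/(mol·K)


def kbt_to_kcal_per_mol(n_kbt: float = 1.0, temperature_c: float = 37.0) -> float:
    """Thermal energy n·kBT expressed in kcal/mol at the given temperature.

    At 37 °C one kBT is ≈ 0.62 kcal/mol.
    """
    return n_kbt * BOLTZMANN_KCAL_PER_MOL_K * (temperature_c + 273.15)


@dataclass
class ThermoParams:
    """Copy numbers and binding energies entering the occupancy model."""

    P: float = 1000.0          # RNAP copy number
    eps_P: float = -5.0        # RNAP binding energy, kBT (effective weak-promoter value)
    R: float = 130.0           # repressor copy number (tetramers for LacI)
    N_NS: float = N_NS_ECOLI   # nonspecific genomic sites
    eps_R: float = -15.3       # repressor binding energy, kBT
    heads_per_repressor: int = 2

    def __post_init__(self) -> None:
        if self.N_NS <= 0:
            raise ValueError("N_NS must be positive")
        if self.R < 0 or self.P < 0:
            raise ValueError("copy numbers must be nonnegative")


@dataclass
class AllosteryParams:
    """MWC allostery parameters (concentrations in μM, energies in kBT)."""

    K_A: float = KA_LACI_UM
    K_I: float = KI_LACI_UM
    eps_AI: float = EPS_AI_LACI
    n: int = N_SITES_LACI

    def __post_init__(self) -> None:
        if self.K_A <= 0 or self.K_I <= 0:
            raise ValueError("dissociation constants must be positive")
        if self.n < 1:
            raise ValueError("n must be >= 1")

    def active_fraction(self, c) -> np.ndarray:
        """Probability that the repressor is in its DNA-binding (active) state."""
        c = np.asarray(c, dtype=float)
        a = (1.0 + c / self.K_A) ** self.n
        i = (1.0 + c / self.K_I) ** self.n
        return a / (a + math.exp(-self.eps_AI) * i)


def p_bound(tp: ThermoParams, eps_R: Optional[float] = None):
    """Equilibrium probability that RNAP occupies the promoter.

    ``eps_R`` may be a scalar or array overriding ``tp.eps_R`` (used when a
    matrix supplies per-sequence binding energies).
    """
    e = tp.eps_R if eps_R is None else np.asarray(eps_R, dtype=float)
    pol = (tp.P / tp.N_NS) * math.exp(-tp.eps_P)
    rep = (tp.heads_per_repressor * tp.R / tp.N_NS) * np.exp(-e)
    out = pol / (1.0 + pol + rep)
    return float(out) if np.isscalar(e) or np.ndim(e) == 0 else out


def fold_change_simple(R, eps_R, N_NS: float = N_NS_ECOLI, heads: int = 2):
    """Weak-promoter fold-change of a simple-repression architecture."""
    R = np.asarray(R, dtype=float)
    if np.any(R < 0):
        raise ValueError("R must be nonnegative")
    out = 1.0 / (1.0 + (heads * R / N_NS) * np.exp(-np.asarray(eps_R, dtype=float)))
    return float(out) if out.ndim == 0 else out


def fold_change_induction(ap: AllosteryParams, c, R, eps_R, N_NS: float = N_NS_ECOLI,
                          heads: int = 2):
    """Fold-change of an inducible simple-repression circuit at inducer concentration c (μM)."""
    out = 1.0 / (1.0 + ap.active_fraction(c) * (heads * np.asarray(R, float) / N_NS)
                 * np.exp(-np.asarray(eps_R, float)))
    return float(out) if out.ndim == 0 else out


@dataclass
class InductionPhenotypes:
    """Phenotypic summary of an induction curve (fold-change units; ec50 in μM)."""

    leakiness: float
    saturation: float
    dynamic_range: float
    ec50: float


def phenotypes(ap: AllosteryParams, R, eps_R, N_NS: float = N_NS_ECOLI,
               heads: int = 2) -> InductionPhenotypes:
    """Leakiness, saturation, dynamic range, and EC50 of the induction response.

    Leakiness and saturation are the analytic c→0 and c→∞ limits of the
    induction fold-change (the MWC bracket tends to 1/(1+e^(−Δε_AI)) and
    1/(1+e^(−Δε_AI)(K_A/K_I)^n) respectively); the EC50 is found numerically
    as the concentration where fold-change equals the midpoint.
    """
    rep = heads * float(R) / N_NS * math.exp(-float(eps_R))
    act0 = 1.0 / (1.0 + math.exp(-ap.eps_AI))
    actinf = 1.0 / (1.0 + math.exp(-ap.eps_AI) * (ap.K_A / ap.K_I) ** ap.n)
    leak = 1.0 / (1.0 + act0 * rep)
    sat = 1.0 / (1.0 + actinf * rep)
    mid = 0.5 * (leak + sat)
    if ap.K_A == ap.K_I:
        raise ValueError("K_A == K_I: the response is flat in c and EC50 is undefined")
    if R == 0 or abs(sat - leak) < 1e-15:
        ec50 = float("nan")
    else:
        f = lambda logc: fold_change_induction(ap, math.exp(logc), R, eps_R, N_NS, heads) - mid
        lo, hi = math.log(1e-9), math.log(1e12)
        ec50 = math.exp(optimize.brentq(f, lo, hi, xtol=1e-12, rtol=1e-10))
    return InductionPhenotypes(leak, sat, sat - leak, ec50)


def fold_change_from_fluorescence(I_R, I_R0, I_auto):
    """Fold-change from mean fluorescence intensities, correcting autofluorescence."""
    denom = I_R0 - I_auto
    if denom <= 0:
        raise ValueError(
            f"unrepressed signal ({I_R0}) must exceed autofluorescence ({I_auto})"
        )
    return (I_R - I_auto) / denom


# -- binding-energy fit from titration data --------------------------------


@dataclass
class FitResult:
    """Point estimate with linearized asymptotic 95% confidence bounds."""

    estimate: float
    ci_low: float
    ci_high: float
    rss: float
    n_points: int


class RepressorTitrationFit:
    """Single-parameter nonlinear fit of the simple-repression fold-change curve.

    Estimates the repressor binding energy Δε_R (kBT) from (R, fold-change)
    titration data by least squares. Follows the scikit-learn estimator
    protocol: ``fit(R, fold_change)`` then ``predict(R)``; the fitted energy
    is ``eps_R_`` and the full summary ``result_``.
    """

    def __init__(self, N_NS: float = N_NS_ECOLI, heads: int = 2):
        self.N_NS = N_NS
        self.heads = heads

    def get_params(self, deep: bool = True) -> dict:
        return {"N_NS": self.N_NS, "heads": self.heads}

    def set_params(self, **params) -> "RepressorTitrationFit":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, R, fold_change, sample_weight=None) -> "RepressorTitrationFit":
        R = np.asarray(R, dtype=float).ravel()
        fc = np.asarray(fold_change, dtype=float).ravel()
        if R.shape != fc.shape:
            raise ValueError("R and fold_change must have the same length")
        keep = R > 0
        if not np.any(keep):
            raise ValueError("all R are 0: the binding energy is unidentifiable")
        R, fc = R[keep], fc[keep]
        w = None if sample_weight is None else np.asarray(sample_weight, float)[keep]

        if R.size == 1:
            # exact algebraic inversion of the fold-change formula
            eps = -math.log((1.0 / fc[0] - 1.0) * self.N_NS / (self.heads * R[0]))
            self.eps_R_ = float(eps)
            self.result_ = FitResult(self.eps_R_, self.eps_R_, self.eps_R_, 0.0, 1)
            return self

        model = lambda r, eps: fold_change_simple(r, eps, self.N_NS, self.heads)
        # crude initial guess from the median point's algebraic inversion
        mid = np.argsort(fc)[fc.size // 2]
        fc0 = min(max(fc[mid], 1e-9), 1 - 1e-9)
        eps0 = -math.log((1.0 / fc0 - 1.0) * self.N_NS / (self.heads * R[mid]))
        sigma = None if w is None else 1.0 / np.sqrt(w)
        popt, pcov = optimize.curve_fit(
            model, R, fc, p0=[eps0], sigma=sigma, absolute_sigma=False, maxfev=10000
        )
        resid = fc - model(R, popt[0])
        rss = float(resid @ resid)
        dof = R.size - 1
        se = math.sqrt(max(pcov[0, 0], 0.0))
        tcrit = stats.t.ppf(0.975, dof) if dof > 0 else float("nan")
        half = tcrit * se if dof > 0 else 0.0
        self.eps_R_ = float(popt[0])
        self.result_ = FitResult(self.eps_R_, self.eps_R_ - half, self.eps_R_ + half,
                                 rss, int(R.size))
        return self

    def predict(self, R) -> np.ndarray:
        if not hasattr(self, "eps_R_"):
            raise RuntimeError("fit() has not been called")
        return fold_change_simple(np.asarray(R, float), self.eps_R_, self.N_NS, self.heads)


def fit_eps_R(titration: Sequence, N_NS: float = N_NS_ECOLI, heads: int = 2) -> FitResult:
    """Fit Δε_R from (R, fold_change[, weight]) tuples; see RepressorTitrationFit."""
    rows = [tuple(t) for t in titration]
    R = [t[0] for t in rows]
    fc = [t[1] for t in rows]
    w = [t[2] for t in rows] if rows and len(rows[0]) > 2 else None
    est = RepressorTitrationFit(N_NS=N_NS, heads=heads).fit(R, fc, sample_weight=w)
    return est.result_
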