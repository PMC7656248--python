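"""One-site isothermal titration calorimetry: forward model, blank
subtraction, nonlinear fitting, and the G/H/-TS decomposition.

The forward model is the standard single-set-of-sites (Wiseman) isotherm
with the half-volume displacement correction used by instrument analysis
software: each injection displaces part of the cell content, so cell
concentrations are diluted and the measured heat of injection i includes a
correction for the displaced volume.

Sigmoidality of a thermogram is governed by the Wiseman c value
``c = N K [M]0``; at low c the isotherm carries almost no information on N,
and the conventional remedy — also used here — is refitting with the
stoichiometry fixed at 1.0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import lmfit

from .constants import R_KCAL

__all__ = [
    "ITCProtocol",
    "ITCExperiment",
    "ITCFitResult",
    "NonSigmoidalWarning",
    "ITCFitError",
    "one_site_heats",
    "subtract_blank",
    "fit_one_site",
    "derive_thermo",
]

KCAL_TO_UCAL = 1.0e9


class NonSigmoidalWarning(UserWarning):
    """Raised when the Wiseman c value indicates a non-sigmoidal isotherm."""


class ITCFitError(RuntimeError):
    """Nonlinear fit failed to converge from every start point."""


@dataclass(frozen=True)
class ITCProtocol:
    """Injection protocol and cell conditions.

    Defaults follow a VP-ITC style titration at 10 degC: 15 uM macromolecule
    in a 1.4 mL cell, 300 uM ligand in the syringe, 20 injections with an
    initial 2 uL pre-injection followed by 19 x 10 uL.
    """

    T: float = 283.15                      # K
    V0: float = 1.4                        # mL
    M0: float = 15.0                       # uM, cell macromolecule
    X0: float = 300.0                      # uM, syringe ligand
    injection_volumes: tuple[float, ...] = (2.0,) + (10.0,) * 19  # uL

    def __post_init__(self) -> None:
        if self.T <= 0 or self.V0 <= 0 or self.M0 <= 0 or self.X0 <= 0:
            raise ValueError("temperature, volumes and concentrations must be positive")
        if any(v <= 0 for v in self.injection_volumes):
            raise ValueError("injection volumes must be positive")

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes)


@dataclass
class ITCExperiment:
    """Per-injection heats (ucal) plus protocol metadata."""

    protocol: ITCProtocol
    heats: np.ndarray
    blank_heats: np.ndarray | None = None
    true_params: tuple[float, float, float] | None = None  # (N, K, dH)

    def __post_init__(self) -> None:
        self.heats = np.asarray(self.heats, dtype=float)
        if self.heats.shape != (self.protocol.n_injections,):
            raise ValueError("heats length must equal number of injections")
        if self.blank_heats is not None:
            self.blank_heats = np.asarray(self.blank_heats, dtype=float)


@dataclass
class ITCFitResult:
    N: float
    K: float          # 1/M
    dH: float         # kcal/mol
    dG: float         # kcal/mol
    mTdS: float       # -T dS, kcal/mol
    T: float          # K
    N_fixed: bool
    rss: float        # ucal^2
    c_value: float

    def __post_init__(self) -> None:
        assert self.K > 0
        assert abs(self.dG - self.dH - self.mTdS) < 1e-9


def _bound_fraction(N: float, K: float, Mt: np.ndarray, Xt: np.ndarray) -> np.ndarray:
    """Root in [0, min(1, Xt/(N Mt))] of the one-site quadratic in Theta."""
    r = Xt / (N * Mt)
    b = 1.0 + r + 1.0 / (N * K * Mt)
    disc = b * b - 4.0 * r
    if np.any(disc < 0):
        raise FloatingPointError("negative discriminant in one-site isotherm")
    return 0.5 * (b - np.sqrt(disc))


def one_site_heats(
    N: float,
    K: float,
    dH: float,
    protocol: ITCProtocol,
    displacement_correction: bool = True,
) -> np.ndarray:
    """Per-injection heats (ucal) of a one-site titration.

    Cumulative injected volume dV_i dilutes the cell by the half-volume
    displacement rule: M_i = M0 (1 - dV_i/2V0)/(1 + dV_i/2V0),
    X_i = X0 (dV_i/V0)/(1 + dV_i/2V0).  Total heat after injection i is
    Q_i = N Theta_i M_i dH V0, and the measured injection heat is
    q_i = Q_i - Q_{i-1} + (v_i/V0)(Q_i + Q_{i-1})/2.

    With ``displacement_correction=False`` the cell is treated as
    non-displacing (constant M, X accumulating as dV/V0, q_i = Q_i -
    Q_{i-1}); in that mode the injection heats sum exactly to the total
    binding heat, which is convenient for conservation checks.
    """
    if K <= 0:
        raise ValueError("K must be positive (1/M)")
    v = np.asarray(protocol.injection_volumes, dtype=float) * 1e-3  # uL -> mL
    dV = np.cumsum(v)
    V0 = protocol.V0
    if displacement_correction:
        M = protocol.M0 * 1e-6 * (1 - dV / (2 * V0)) / (1 + dV / (2 * V0))  # M
        X = protocol.X0 * 1e-6 * (dV / V0) / (1 + dV / (2 * V0))            # M
    else:
        M = np.full_like(dV, protocol.M0 * 1e-6)
        X = protocol.X0 * 1e-6 * (dV / V0)
    theta = _bound_fraction(N, K, M, X)
    Q = N * theta * M * dH * (V0 * 1e-3)  # kcal (V0 mL -> L, conc M -> mol/L)
    Qprev = np.concatenate([[0.0], Q[:-1]])
    if displacement_correction:
        q = Q - Qprev + (v / V0) * (Q + Qprev) / 2.0
    else:
        q = Q - Qprev
    return q * KCAL_TO_UCAL


def subtract_blank(exp: ITCExperiment) -> ITCExperiment:
    """Element-wise subtraction of ligand-dilution blank heats."""
    if exp.blank_heats is None:
        raise ValueError("experiment has no blank heats")
    if exp.blank_heats.shape != exp.heats.shape:
        raise ValueError("blank length does not match injection count")
    return ITCExperiment(
        protocol=exp.protocol,
        heats=exp.heats - exp.blank_heats,
        blank_heats=None,
        true_params=exp.true_params,
    )


def derive_thermo(K: float, dH: float, T: float) -> tuple[float, float]:
    """Free energy and entropic term from an association constant.

    Returns ``(dG, -T dS)`` in kcal/mol, with dG = -RT ln K and
    -T dS = dG - dH.
    """
    if K <= 0 or T <= 0:
        raise ValueError("K and T must be positive")
    dG = -R_KCAL * T * np.log(K)
    return dG, dG - dH


_LOGK_STARTS = (3.0, 4.0, 5.0, 6.0, 7.0, 8.0)


def fit_one_site(
    exp: ITCExperiment,
    fix_N: float | None = None,
    first_injection_excluded: bool = True,
) -> ITCFitResult:
    """Least-squares fit of (N, K, dH) — or (K, dH) with N fixed — to heats.

    Blank heats, if present, are subtracted first.  The initial small
    pre-injection is excluded from the residuals by default (it still enters
    the cumulative-volume bookkeeping of the forward model).  Initialisation
    is multistart over a log10 K grid; a ``NonSigmoidalWarning`` is emitted
    when the fitted c value drops below 1.
    """
    if exp.blank_heats is not None:
        exp = subtract_blank(exp)
    heats = exp.heats
    n_used = len(heats) - (1 if first_injection_excluded else 0)
    if n_used < 3:
        raise ValueError("need at least 3 usable injections")
    use = np.ones(len(heats), dtype=bool)
    if first_injection_excluded:
        use[0] = False

    def residuals(params: lmfit.Parameters) -> np.ndarray:
        model = one_site_heats(
            params["N"].value, 10.0 ** params["logK"].value, params["dH"].value,
            exp.protocol,
        )
        return model[use] - heats[use]

    # crude dH start: total observed heat / total macromolecule heat capacity
    dh0 = np.sum(heats[use]) / KCAL_TO_UCAL / (
        exp.protocol.M0 * 1e-6 * exp.protocol.V0 * 1e-3
    )
    dh_starts = [dh0, dh0 / 2 if dh0 != 0 else 1.0]

    best = None
    for logk0 in _LOGK_STARTS:
        for dh_start in dh_starts:
            params = lmfit.Parameters()
            if fix_N is None:
                params.add("N", value=1.0, min=0.05, max=20.0)
            else:
                params.add("N", value=float(fix_N), vary=False)
            params.add("logK", value=logk0, min=0.0, max=12.0)
            params.add("dH", value=dh_start if dh_start != 0 else 1.0)
            try:
                res = lmfit.minimize(
                    residuals, params, method="leastsq", xtol=1e-14, ftol=1e-14
                )
            except Exception:
                continue
            rss = float(np.sum(np.asarray(res.residual) ** 2))
            if best is None or rss < best[0]:
                best = (rss, res)
    if best is None:
        raise ITCFitError("one-site fit failed from every start point")
    rss, res = best
    N = float(res.params["N"].value)
    K = float(10.0 ** res.params["logK"].value)
    dH = float(res.params["dH"].value)
    dG, mTdS = derive_thermo(K, dH, exp.protocol.T)
    c = N * K * exp.protocol.M0 * 1e-6
    if c < 1.0:
        warnings.warn(
            f"c = {c:.3g} < 1: non-sigmoidal isotherm; consider fix_N=1.0",
            NonSigmoidalWarning,
        )
    return ITCFitResult(
        N=N, K=K, dH=dH, dG=dG, mTdS=mTdS, T=exp.protocol.T,
        N_fixed=fix_N is not None, rss=rss, c_value=c,
    )
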