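"""Lanthanide-series thermodynamic decomposition.

Works on a La..Lu table of per-ion binding thermodynamics (dG, dH, -TdS in
kcal/mol, optional KD in nM, ionic radius in angstrom): pairwise
difference (Delta-Delta) quantities between named ions, detection of
branch points where a trend along the series reverses direction, and the
three-regime classification of the series

    I   : La .. first branch ion (weaker, water-infiltrated complexes)
    II  : first branch .. Yb, split at Tb into IIa and IIb
    III : Lu alone

with boundary ions (Sm, Tb) belonging to two adjacent regimes, as the
inclusive class boundaries require.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
import numpy as np

from .constants import LN_SERIES

__all__ = [
    "validate_series_table",
    "delta_delta",
    "delta_delta_components",
    "fold_affinity_ratio",
    "detect_branch_points",
    "classify_regimes",
    "RegimeAssignment",
]

_IDENTITY_TOL = 0.02   # kcal/mol, printed-value rounding
_RADIUS_SPREAD_MAX = 0.26  # A


@dataclass
class RegimeAssignment:
    """Regime membership per ion; boundary ions may carry two regimes."""

    regimes: dict[str, tuple[str, ...]]   # ion -> regimes, series order
    branch_ions: tuple[str, ...]
    dual_membership: tuple[str, ...]

    def ions_in(self, regime: str) -> tuple[str, ...]:
        return tuple(i for i, r in self.regimes.items() if regime in r)


def validate_series_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the row-wise dG = dH + (-TdS) identity and radius ordering."""
    t = table.set_index("ion") if "ion" in table.columns else table
    resid = (t["dG"] - t["dH"] - t["mTdS"]).abs()
    if (resid > _IDENTITY_TOL).any():
        bad = resid.idxmax()
        raise ValueError(
            f"dG != dH + (-TdS) beyond {_IDENTITY_TOL} kcal/mol at {bad}"
        )
    if "ionic_radius_A" in t.columns:
        r = t["ionic_radius_A"].to_numpy(dtype=float)
        if not np.all(np.diff(r) < 0):
            raise ValueError("ionic radius must decrease strictly La->Lu")
        if r[0] - r[-1] >= _RADIUS_SPREAD_MAX:
            raise ValueError(f"radius spread must be < {_RADIUS_SPREAD_MAX} A")
    return t


def delta_delta(
    table: pd.DataFrame, ion_a: str, ion_b: str
) -> tuple[float, float, float]:
    """(ddG, ddH, -Tdds) of ion_b relative to ion_a, kcal/mol."""
    t = table.set_index("ion") if "ion" in table.columns else table
    for ion in (ion_a, ion_b):
        if ion not in t.index:
            raise KeyError(f"ion {ion!r} not in table")
    ddG = float(t.loc[ion_b, "dG"] - t.loc[ion_a, "dG"])
    ddH = float(t.loc[ion_b, "dH"] - t.loc[ion_a, "dH"])
    mTddS = float(t.loc[ion_b, "mTdS"] - t.loc[ion_a, "mTdS"])
    return ddG, ddH, mTddS


def delta_delta_components(ddH: float, mTddS: float) -> float:
    """ddG from its enthalpic and entropic components: ddG = ddH + (-TddS)."""
    return ddH + mTddS


def fold_affinity_ratio(kd_a: float, kd_b: float) -> float:
    """Affinity fold difference as the dissociation-constant ratio kd_a/kd_b."""
    if kd_a <= 0 or kd_b <= 0:
        raise ValueError("KD values must be positive")
    return kd_a / kd_b


def detect_branch_points(
    values, ions=LN_SERIES, tol: float = 0.05
) -> list[str]:
    """Ions at which the series trend reverses direction.

    Successive differences with magnitude <= ``tol`` (kcal/mol) continue
    the prior direction; a sign flip between consecutive effective
    directions marks the intervening ion as a branch point.  A series whose
    differences all sit within tol has no branches.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 3:
        raise ValueError("need at least 3 values")
    if len(ions) != len(v):
        raise ValueError("ions and values must align")
    diffs = np.diff(v)
    branches: list[str] = []
    direction = 0
    for k, d in enumerate(diffs):
        if abs(d) <= tol:
            continue
        step = 1 if d > 0 else -1
        if direction != 0 and step != direction:
            branches.append(ions[k])
        direction = step
    return branches


def classify_regimes(
    table: pd.DataFrame,
    branch_ions: list[str] | tuple[str, ...],
    split_ion: str = "Tb",
) -> RegimeAssignment:
    """Three-regime classification of the series.

    Regime I runs La through the first branch ion inclusive; regime II
    from the first branch through the second (Yb-like) branch, split at
    ``split_ion`` into IIa/IIb; regime III is everything after the second
    branch (Lu).  Boundary ions are members of both adjacent regimes and
    are reported under ``dual_membership``.  With no branches the whole
    series is regime I (with a warning).
    """
    t = table.set_index("ion") if "ion" in table.columns else table
    ions = [i for i in LN_SERIES if i in t.index]
    for b in branch_ions:
        if b not in ions:
            raise KeyError(f"branch ion {b!r} not in table")
    if not branch_ions:
        warnings.warn("no branch points: whole series assigned regime I")
        return RegimeAssignment({i: ("I",) for i in ions}, (), ())
    order = {ion: k for k, ion in enumerate(ions)}
    b1 = order[branch_ions[0]]
    b2 = order[branch_ions[1]] if len(branch_ions) > 1 else len(ions) - 1
    split = order.get(split_ion, b2)
    regimes: dict[str, tuple[str, ...]] = {}
    for ion in ions:
        k = order[ion]
        mine: list[str] = []
        if k <= b1:
            mine.append("I")
        if b1 <= k <= split:
            mine.append("IIa")
        if split <= k <= b2:
            mine.append("IIb")
        if k > b2:
            mine.append("III")
        regimes[ion] = tuple(mine)
    dual = tuple(i for i in ions if len(regimes[i]) > 1)
    return RegimeAssignment(regimes, tuple(branch_ions), dual)
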