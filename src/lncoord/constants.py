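"""Physical constants and the lanthanide series table.

Ionic radii are Shannon effective radii for 8-coordinate Ln3+ in angstrom.
Only the strict La->Lu contraction and the <0.26 A total spread are relied
upon downstream, not the individual values.
"""

from __future__ import annotations

# Gas constant in kcal/(mol K)
R_KCAL: float = 1.987204e-3

#: Lanthanide series in atomic-number order.
LN_SERIES: tuple[str, ...] = (
    "La", "Ce", "Pr", "Nd", "Pm", "Sm", "Eu", "Gd",
    "Tb", "Dy", "Ho", "Er", "Tm", "Yb", "Lu",
)

#: Shannon 8-coordinate Ln3+ ionic radii, angstrom.
IONIC_RADIUS_A = {
    "La": 1.160, "Ce": 1.143, "Pr": 1.126, "Nd": 1.109, "Pm": 1.093,
    "Sm": 1.079, "Eu": 1.066, "Gd": 1.053, "Tb": 1.040, "Dy": 1.027,
    "Ho": 1.015, "Er": 1.004, "Tm": 0.994, "Yb": 0.985, "Lu": 0.977,
}

ATOMIC_NUMBER = {ion: 57 + i for i, ion in enumerate(LN_SERIES)}

#: Oxygen contact radius used to tie bound donor-ion distance to ion size (A).
OXYGEN_CONTACT_RADIUS_A: float = 1.40

#: Residue names recognised as water in topologies.
WATER_RESNAMES = frozenset({"HOH", "WAT", "SOL"})


def ionic_radius_nm(ion: str) -> float:
    """Shannon 8-coordinate radius of ``ion`` in nm."""
    try:
        return IONIC_RADIUS_A[ion] / 10.0
    except KeyError:
        raise KeyError(f"unknown lanthanide symbol: {ion!r}") from None
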