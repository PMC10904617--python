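"""Deterministic derived-ADME formulas.

These close the gap between what property models predict (plasma protein
binding, Vss, half-life, Caco-2 permeability) and what the PBPK model
consumes (fup, clapp, gi_ka).
"""

from __future__ import annotations

__all__ = ["fup_from_ppbr", "clapp_from_vss_halflife", "gika_from_papp"]


def fup_from_ppbr(ppbr: float) -> float:
    """Fraction unbound in plasma from the plasma protein binding ratio."""
    if not 0 <= ppbr < 1:
        raise ValueError(f"ppbr must lie in [0, 1): {ppbr}")
    return 1.0 - ppbr


def clapp_from_vss_halflife(vss_L: float, half_life_h: float) -> float:
    """Apparent clearance (L/h) from Vss (L) and elimination half-life (h).

    Uses the one-compartment relation CL = Vss * 0.693 / t_half with the
    conventional rounded ln(2).
    """
    if vss_L <= 0 or half_life_h <= 0:
        raise ValueError("vss and half-life must be positive")
    return vss_L * 0.693 / half_life_h


def gika_from_papp(papp_cm_h: float, radius_cm: float = 1.25) -> float:
    """First-order gut absorption rate (1/h) from Caco-2 permeability.

    For a cylindrical small intestine of the given radius (default
    1.25 cm, i.e. a 2.5 cm diameter), ka = 2 * Papp / radius.
    """
    if papp_cm_h <= 0 or radius_cm <= 0:
        raise ValueError("permeability and radius must be positive")
    return 2.0 * papp_cm_h / radius_cm
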