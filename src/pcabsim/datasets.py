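"""Bundled worked-example fixtures: the vonoprazan ADME/partition table
and the potency table for seven acid pump blockers.

Derived potency columns (kd, k) are stored at printed precision alongside
the primaries; :func:`pcab_potency` recomputes them at full precision, so
consumers always work with exact derivations while tests can compare
against the printed values.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from .compound import CompoundParameterSet, load_compound
from .pdmodel import PotencyParameters
from .physiology import PhysiologyModel, reference_adult

__all__ = [
    "vonoprazan_parameters",
    "pcab_potency_table",
    "pcab_potency",
    "vonoprazan_potency",
]


def _data(name: str):
    return resources.files("pcabsim.data") / name


def vonoprazan_parameters(
    phys: PhysiologyModel | None = None, solve_scaler: bool = True
) -> CompoundParameterSet:
    """The vonoprazan ADME + partition fixture.

    With ``solve_scaler`` (default) the Kp scaler is solved against the
    given physiology (bundled reference adult if omitted) so that the
    model Vss reproduces the fixture's vss_per_kg.
    """
    data = json.loads(_data("vonoprazan_adme.json").read_text())
    phys = phys or reference_adult()
    return load_compound(data, phys if solve_scaler else None)


def pcab_potency_table() -> pd.DataFrame:
    """The raw potency fixture (printed precision) as a DataFrame."""
    with resources.as_file(_data("pcab_potency.csv")) as path:
        return pd.read_csv(path)


def pcab_potency(intersys: float = 1.0e3) -> dict[str, PotencyParameters]:
    """Potency parameters per compound, derived columns at full precision."""
    table = pcab_potency_table()
    out = {}
    for _, row in table.iterrows():
        out[row["name"]] = PotencyParameters(
            name=row["name"],
            ic50_uM=float(row["ic50_uM"]),
            dissociation_half_life_h=float(row["dissoc_half_life_h"]),
            intersys=intersys,
        )
    return out


def vonoprazan_potency(intersys: float = 1.0e3) -> PotencyParameters:
    return pcab_potency(intersys)["vonoprazan"]
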