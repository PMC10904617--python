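"""Compound parameter sets and dosing regimens.

A :class:`CompoundParameterSet` carries everything the whole-body PK model
needs for one molecule: fraction unbound in plasma (fup), blood-to-plasma
ratio (bpr), first-order gastrointestinal absorption rate (gi_ka, 1/h),
apparent plasma clearance (clapp, L/h), steady-state volume of
distribution (vss_per_kg, L/kg), fraction absorbed (fa) and the tissue
partition block.  The SMILES string is carried as metadata only.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .physiology import (
    TISSUES,
    PhysiologyModel,
    TissuePartition,
    solve_kp_scaler,
)

__all__ = ["CompoundParameterSet", "DoseRegimen", "CompoundError", "load_compound"]


class CompoundError(ValueError):
    """Raised when a compound parameter set is invalid or incomplete."""


def molecular_weight_from_smiles(smiles: str) -> float:
    """Molecular weight (g/mol) via the optional cheminformatics backend."""
    try:
        from rdkit import Chem
        from rdkit.Chem import Descriptors
    except ImportError as exc:  # pragma: no cover
        raise CompoundError(
            "molecular weight not supplied and rdkit is not installed"
        ) from exc
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise CompoundError(f"could not parse SMILES: {smiles!r}")
    return float(Descriptors.MolWt(mol))


@dataclass(frozen=True)
class CompoundParameterSet:
    name: str
    fup: float
    bpr: float
    gi_ka: float  # 1/h
    clapp: float  # L/h
    vss_per_kg: float  # L/kg
    fa: float
    partition: TissuePartition | None = None
    smiles: str | None = None
    molecular_weight: float | None = None  # g/mol
    calibration: object | None = None  # provenance of applied factors

    def __post_init__(self) -> None:
        if not 0 < self.fup <= 1:
            raise CompoundError(f"fup must be in (0, 1]: {self.fup}")
        if not 0 < self.fa <= 1:
            raise CompoundError(f"fa must be in (0, 1]: {self.fa}")
        for attr in ("gi_ka", "clapp", "vss_per_kg", "bpr"):
            if getattr(self, attr) <= 0:
                raise CompoundError(f"{attr} must be positive: {getattr(self, attr)}")

    def mw(self) -> float:
        """Molecular weight, from the explicit field or from the SMILES."""
        if self.molecular_weight is not None:
            return self.molecular_weight
        if self.smiles:
            return molecular_weight_from_smiles(self.smiles)
        raise CompoundError(f"{self.name}: no molecular weight and no SMILES")

    def with_solved_scaler(self, phys: PhysiologyModel) -> "CompoundParameterSet":
        """Return a copy whose Kp scaler reproduces ``vss_per_kg`` exactly."""
        if self.partition is None:
            raise CompoundError(f"{self.name}: no tissue partition block")
        s = solve_kp_scaler(self.vss_per_kg, self.partition.kp, phys, self.bpr, self.fup)
        return dataclasses.replace(self, partition=self.partition.with_scaler(s))

    def replace(self, **changes) -> "CompoundParameterSet":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "smiles": self.smiles,
            "fup": self.fup,
            "bpr": self.bpr,
            "gi_ka_1_h": self.gi_ka,
            "clapp_L_h": self.clapp,
            "vss_L_kg": self.vss_per_kg,
            "fa": self.fa,
            "molecular_weight": self.molecular_weight,
        }
        if self.partition is not None:
            d.update({f"kp.{t}": self.partition.kp[t] for t in TISSUES})
            d["kp_scaler"] = self.partition.kp_scaler
        return d


# Kp defaults for tissues that parameter tables commonly omit: the stomach
# behaves like its splanchnic neighbour (gut), the pancreas like the spleen,
# and the lumped remainder is taken as unity.
_KP_FALLBACKS = {"stomach": "gut", "pancreas": "spleen"}


def _partition_from_mapping(kp_map: Mapping[str, float], scaler) -> TissuePartition:
    kp = dict(kp_map)
    for tissue, donor in _KP_FALLBACKS.items():
        if tissue not in kp and donor in kp:
            kp[tissue] = kp[donor]
    kp.setdefault("rest_of_body", 1.0)
    return TissuePartition(kp=kp, kp_scaler=float(scaler) if scaler else 1.0)


def load_compound(source, phys: PhysiologyModel | None = None) -> CompoundParameterSet:
    """Load a compound from a JSON file or mapping.

    Schema keys: ``name, smiles, fup, bpr, gi_ka_1_h, clapp_L_h, vss_L_kg,
    fa, molecular_weight, kp.<tissue>, kp_scaler``.  A blank/absent
    ``kp_scaler`` is solved from ``vss_L_kg`` when a physiology is given.
    """
    if isinstance(source, (str, Path)):
        data = json.loads(Path(source).read_text())
    else:
        data = dict(source)
    kp_map = {
        k.split(".", 1)[1]: float(v) for k, v in data.items() if k.startswith("kp.")
    }
    if "kp" in data and isinstance(data["kp"], Mapping):
        kp_map.update({k: float(v) for k, v in data["kp"].items()})
    partition = _partition_from_mapping(kp_map, data.get("kp_scaler")) if kp_map else None
    compound = CompoundParameterSet(
        name=data["name"],
        smiles=data.get("smiles"),
        fup=float(data["fup"]),
        bpr=float(data["bpr"]),
        gi_ka=float(data.get("gi_ka_1_h", data.get("gi_ka"))),
        clapp=float(data.get("clapp_L_h", data.get("clapp"))),
        vss_per_kg=float(data.get("vss_L_kg", data.get("vss_per_kg"))),
        fa=float(data["fa"]),
        molecular_weight=(
            float(data["molecular_weight"]) if data.get("molecular_weight") else None
        ),
        partition=partition,
    )
    if phys is not None and partition is not None and not data.get("kp_scaler"):
        compound = compound.with_solved_scaler(phys)
    return compound


@dataclass(frozen=True)
class DoseRegimen:
    """Oral dosing schedule: dose (mg) given at each time (h)."""

    dose_mg: float
    times_h: Sequence[float] = (0.0,)
    duration_h: float = 48.0
    route: str = "oral"

    def __post_init__(self) -> None:
        if self.dose_mg < 0:
            raise CompoundError(f"dose must be non-negative: {self.dose_mg}")
        times = tuple(self.times_h)
        if any(t < 0 for t in times):
            raise CompoundError("administration times must be non-negative")
        if list(times) != sorted(times):
            raise CompoundError("administration times must be sorted")
        if times and self.duration_h <= max(times):
            raise CompoundError("duration must exceed the last administration time")
        if self.route != "oral":
            raise CompoundError(f"unsupported route: {self.route!r}")
        object.__setattr__(self, "times_h", times)
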