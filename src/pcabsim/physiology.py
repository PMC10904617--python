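"""Reference virtual subject and tissue partitioning.

The whole-body model uses a fixed circulatory topology: 14 well-stirred
tissue compartments (lung, heart, brain, muscle, adipose, skin, spleen,
pancreas, liver, stomach, gut, bone, kidney and a lumped rest-of-body)
plus venous and arterial blood pools.  Lungs sit in series between the
venous and arterial pools; the splanchnic organs (gut, spleen, pancreas,
stomach) drain through the portal vein into the liver.

Tissue partitioning is described by tissue:plasma partition coefficients
(Kp).  A single multiplicative *Kp scaler* rescales every Kp in equal
proportion so that the model's steady-state volume of distribution
matches a compound's predicted Vss (L/kg).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "TISSUES",
    "PORTAL_TISSUES",
    "PhysiologyModel",
    "TissuePartition",
    "PhysiologyError",
    "load_physiology",
    "reference_adult",
    "solve_kp_scaler",
    "distribution_volume",
]

#: Canonical tissue ordering used throughout the package (and the ODE state).
TISSUES: tuple[str, ...] = (
    "lung",
    "heart",
    "brain",
    "muscle",
    "adipose",
    "skin",
    "spleen",
    "pancreas",
    "liver",
    "stomach",
    "gut",
    "bone",
    "kidney",
    "rest_of_body",
)

#: Tissues whose venous outflow drains into the liver via the portal vein.
PORTAL_TISSUES: tuple[str, ...] = ("gut", "spleen", "pancreas", "stomach")


class PhysiologyError(ValueError):
    """Raised when a physiology configuration is inconsistent."""


@dataclass(frozen=True)
class PhysiologyModel:
    """A single virtual subject: volumes (L), blood flows (L/h), weight (kg).

    ``blood_flows`` holds the arterial supply of each tissue.  The lung
    entry equals the cardiac output (the lung is perfused in series by the
    entire venous return); the liver entry is the hepatic-artery flow only,
    with total liver perfusion being hepatic artery plus portal drainage.
    """

    body_weight_kg: float
    tissue_volumes: Mapping[str, float]
    blood_volumes: Mapping[str, float]  # keys: "venous", "arterial"
    plasma_volume_L: float
    blood_flows: Mapping[str, float]
    cardiac_output_L_h: float
    gut_lumen_radius_cm: float = 1.25

    def __post_init__(self) -> None:
        missing = set(TISSUES) - set(self.tissue_volumes)
        if missing:
            raise PhysiologyError(f"missing tissue volumes: {sorted(missing)}")
        extra = set(self.tissue_volumes) - set(TISSUES)
        if extra:
            raise PhysiologyError(f"unknown tissues: {sorted(extra)}")
        missing_f = set(TISSUES) - set(self.blood_flows)
        if missing_f:
            raise PhysiologyError(f"missing tissue flows: {sorted(missing_f)}")
        for name, v in self.tissue_volumes.items():
            if v <= 0:
                raise PhysiologyError(f"tissue volume must be positive: {name}={v}")
        for name, q in self.blood_flows.items():
            if q <= 0:
                raise PhysiologyError(f"blood flow must be positive: {name}={q}")
        for pool in ("venous", "arterial"):
            if self.blood_volumes.get(pool, 0) <= 0:
                raise PhysiologyError(f"blood volume must be positive: {pool}")
        if self.plasma_volume_L <= 0:
            raise PhysiologyError("plasma_volume_L must be positive")
        if self.body_weight_kg <= 0:
            raise PhysiologyError("body_weight_kg must be positive")
        if self.cardiac_output_L_h <= 0:
            raise PhysiologyError("cardiac_output_L_h must be positive")
        if self.gut_lumen_radius_cm <= 0:
            raise PhysiologyError("gut_lumen_radius_cm must be positive")
        # The lung receives the whole cardiac output (series topology).
        q_lung = self.blood_flows["lung"]
        if abs(q_lung - self.cardiac_output_L_h) > 1e-6 * self.cardiac_output_L_h:
            raise PhysiologyError(
                "lung flow must equal cardiac output "
                f"(got {q_lung}, cardiac output {self.cardiac_output_L_h})"
            )
        # Systemic flows (everything except the lung) must balance the
        # cardiac output within 1%; rest_of_body is the closure term.
        systemic = sum(q for t, q in self.blood_flows.items() if t != "lung")
        if abs(systemic - self.cardiac_output_L_h) > 0.01 * self.cardiac_output_L_h:
            raise PhysiologyError(
                f"sum of tissue flows {systemic:.3f} L/h differs from cardiac "
                f"output {self.cardiac_output_L_h:.3f} L/h by more than 1%"
            )

    @property
    def total_blood_volume_L(self) -> float:
        return self.blood_volumes["venous"] + self.blood_volumes["arterial"]

    def systemic_flow(self) -> float:
        """Total arterial outflow to tissues (excludes the in-series lung)."""
        return sum(q for t, q in self.blood_flows.items() if t != "lung")

    def to_dict(self) -> dict:
        return {
            "body_weight_kg": self.body_weight_kg,
            "cardiac_output_L_h": self.cardiac_output_L_h,
            "plasma_volume_L": self.plasma_volume_L,
            "gut_lumen_radius_cm": self.gut_lumen_radius_cm,
            "blood_volumes": dict(self.blood_volumes),
            "tissues": {
                t: {
                    "volume_L": self.tissue_volumes[t],
                    "flow_L_h": self.blood_flows[t],
                }
                for t in TISSUES
            },
        }


@dataclass(frozen=True)
class TissuePartition:
    """Tissue:plasma partition coefficients plus the uniform Kp scaler.

    The effective partition coefficient of tissue ``t`` is
    ``kp[t] * kp_scaler``.
    """

    kp: Mapping[str, float]
    kp_scaler: float = 1.0

    def __post_init__(self) -> None:
        missing = set(TISSUES) - set(self.kp)
        if missing:
            raise PhysiologyError(f"missing Kp entries: {sorted(missing)}")
        for name, v in self.kp.items():
            if v <= 0:
                raise PhysiologyError(f"Kp must be positive: {name}={v}")
        if self.kp_scaler <= 0:
            raise PhysiologyError(f"kp_scaler must be positive: {self.kp_scaler}")

    def effective(self, tissue: str) -> float:
        return self.kp[tissue] * self.kp_scaler

    def with_scaler(self, scaler: float) -> "TissuePartition":
        return replace(self, kp_scaler=scaler)


def _closure(config: dict) -> dict:
    """Fill a missing rest_of_body volume/flow by mass/flow balance."""
    cfg = {k: v for k, v in config.items()}
    tissues = {name: dict(entry) for name, entry in cfg.get("tissues", {}).items()}
    bw = cfg.get("body_weight_kg")
    co = cfg.get("cardiac_output_L_h")
    blood = cfg.get("blood_volumes", {})
    rob = tissues.setdefault("rest_of_body", {})
    if "volume_L" not in rob:
        if bw is None:
            raise PhysiologyError("cannot close rest_of_body volume without body_weight_kg")
        others = sum(
            entry["volume_L"] for name, entry in tissues.items() if name != "rest_of_body"
        )
        blood_vol = blood.get("venous", 0.0) + blood.get("arterial", 0.0)
        # 1 kg of body mass is taken as 1 L for the closure.
        rob["volume_L"] = bw - others - blood_vol
    if "flow_L_h" not in rob:
        if co is None:
            raise PhysiologyError("cannot close rest_of_body flow without cardiac_output_L_h")
        others = sum(
            entry["flow_L_h"]
            for name, entry in tissues.items()
            if name not in ("rest_of_body", "lung")
            and "flow_L_h" in entry
        )
        rob["flow_L_h"] = co - others
    tissues.setdefault("lung", {}).setdefault("flow_L_h", co)
    cfg["tissues"] = tissues
    return cfg


def load_physiology(source) -> PhysiologyModel:
    """Build a validated :class:`PhysiologyModel` from a config document.

    ``source`` may be a mapping, a path to a YAML/JSON file, or the name of
    a bundled physiology (currently ``"reference_adult"``).  A missing
    rest-of-body volume or flow is computed by closure against body weight
    (1 kg = 1 L) and cardiac output.
    """
    if isinstance(source, str) and not source.endswith((".yaml", ".yml", ".json")):
        ref = resources.files("pcabsim.data") / f"{source}_physiology.yaml"
        if not ref.is_file():
            raise PhysiologyError(f"unknown bundled physiology: {source!r}")
        config = yaml.safe_load(ref.read_text())
    elif isinstance(source, (str, Path)):
        text = Path(source).read_text()
        config = (
            json.loads(text) if str(source).endswith(".json") else yaml.safe_load(text)
        )
    elif isinstance(source, Mapping):
        config = dict(source)
    else:
        raise TypeError(f"cannot load physiology from {type(source)!r}")

    config = _closure(config)
    tissues = config["tissues"]
    try:
        volumes = {name: float(entry["volume_L"]) for name, entry in tissues.items()}
        flows = {name: float(entry["flow_L_h"]) for name, entry in tissues.items()}
    except KeyError as exc:  # pragma: no cover - message carries the field
        raise PhysiologyError(f"tissue entry missing field: {exc}") from exc
    return PhysiologyModel(
        body_weight_kg=float(config["body_weight_kg"]),
        tissue_volumes=volumes,
        blood_volumes={k: float(v) for k, v in config["blood_volumes"].items()},
        plasma_volume_L=float(config["plasma_volume_L"]),
        blood_flows=flows,
        cardiac_output_L_h=float(config["cardiac_output_L_h"]),
        gut_lumen_radius_cm=float(config.get("gut_lumen_radius_cm", 1.25)),
    )


def reference_adult() -> PhysiologyModel:
    """The bundled 70 kg reference adult used by all worked examples.

    Volumes and flows are the implementer's compilation from standard
    reference-human tables; they are a configuration artifact, not measured
    ground truth, and every toleranced comparison involving them says so.
    """
    return load_physiology("reference_adult")


def distribution_volume(
    partition: TissuePartition, phys: PhysiologyModel
) -> float:
    """Plasma-referenced steady-state distribution volume (L).

    Vss = V_plasma + sum_t V_t * Kp_t * scaler.
    """
    total = phys.plasma_volume_L
    for t in TISSUES:
        total += phys.tissue_volumes[t] * partition.effective(t)
    return total


def solve_kp_scaler(
    vss_per_kg: float,
    kp: Mapping[str, float],
    phys: PhysiologyModel,
    bpr: float | None = None,
    fup: float | None = None,
) -> float:
    """Solve for the uniform Kp scaler that reproduces a target Vss.

    The plasma-referenced distribution volume is linear in the scaler, so
    the solution is closed-form::

        s = (vss_per_kg * BW - V_plasma) / sum_t V_t * Kp_t

    ``bpr``/``fup`` are accepted for forward compatibility with partition
    conventions that reference blood rather than plasma; the default
    formula does not use them.

    Raises
    ------
    PhysiologyError
        If the target volume does not exceed the plasma volume (no
        positive scaler can reach it).
    """
    target = vss_per_kg * phys.body_weight_kg
    if target <= phys.plasma_volume_L:
        raise PhysiologyError(
            f"target Vss {target:.3f} L does not exceed plasma volume "
            f"{phys.plasma_volume_L:.3f} L; no feasible Kp scaler"
        )
    denom = 0.0
    for t in TISSUES:
        kpt = kp[t]
        if kpt <= 0:
            raise PhysiologyError(f"Kp must be positive: {t}={kpt}")
        denom += phys.tissue_volumes[t] * kpt
    return (target - phys.plasma_volume_L) / denom
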