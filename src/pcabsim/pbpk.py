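"""Whole-body PBPK core: the linear ODE system and its integrator.

State layout (amounts in micrograms):

    [gut_lumen, <14 tissues in TISSUES order>, venous, arterial, eliminated]

Every tissue obeys the well-stirred rate equation

    dA_t/dt = Q_t * C_in - Q_t * A_t / (V_t * Kp_eff_t)

with arterial inflow for systemic tissues, mixed-venous inflow for the
lung, and hepatic-artery plus portal inflow for the liver.  Oral dosing
places ``fa * dose`` into the gut lumen, which empties into the gut
tissue at the first-order rate ``gi_ka``.  Elimination occurs only in the
liver; the hepatic extraction coefficient is chosen as ``clapp / bpr`` so
that the emergent whole-body *plasma* clearance equals the apparent
clearance ``clapp`` (and hence AUC(0-inf) = fa * dose / clapp exactly in
this linear system).

Units are centralised here: amounts ug, volumes L, flows L/h, time h,
concentrations ng/mL (= ug/L).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .compound import CompoundParameterSet, DoseRegimen
from .physiology import PORTAL_TISSUES, TISSUES, PhysiologyModel, TissuePartition

__all__ = [
    "SolverOptions",
    "PKProfile",
    "PBPKError",
    "state_index",
    "build_system_matrix",
    "pbpk_rhs",
    "simulate_pk",
    "stomach_free_concentration",
]

MG_TO_UG = 1000.0

#: index of each named compartment in the state vector
IDX_LUMEN = 0
IDX_TISSUE = {t: 1 + i for i, t in enumerate(TISSUES)}
IDX_VEN = 1 + len(TISSUES)
IDX_ART = IDX_VEN + 1
IDX_ELIM = IDX_ART + 1
N_STATE = IDX_ELIM + 1

STATE_NAMES = ("gut_lumen", *TISSUES, "venous", "arterial", "eliminated")


class PBPKError(RuntimeError):
    """Raised on integration failure or inconsistent simulation inputs."""


def state_index(name: str) -> int:
    """Index of a named compartment in the state vector."""
    return STATE_NAMES.index(name)


@dataclass(frozen=True)
class SolverOptions:
    """Stiff-capable integrator settings (LSODA with an exact Jacobian)."""

    method: str = "LSODA"
    rtol: float = 1e-8
    atol: float = 1e-10  # ug
    output_step_h: float = 0.01
    negative_tolerance: float = 1e-6  # ug, beyond which negativity is an error

    def __post_init__(self) -> None:
        if self.rtol <= 0 or self.atol <= 0 or self.output_step_h <= 0:
            raise PBPKError("solver tolerances and output step must be positive")


def build_system_matrix(
    compound: CompoundParameterSet,
    phys: PhysiologyModel,
    partition: TissuePartition | None = None,
) -> np.ndarray:
    """Constant coefficient matrix A with dx/dt = A @ x.

    Columns sum to zero, so total drug (amounts + eliminated) is conserved
    exactly at the level of the vector field.
    """
    partition = partition if partition is not None else compound.partition
    if partition is None:
        raise PBPKError(f"{compound.name}: no tissue partition block")
    A = np.zeros((N_STATE, N_STATE))
    v_ven = phys.blood_volumes["venous"]
    v_art = phys.blood_volumes["arterial"]
    co = phys.cardiac_output_L_h
    cl_hepatic_blood = compound.clapp / compound.bpr  # L/h, blood-referenced

    A[IDX_LUMEN, IDX_LUMEN] = -compound.gi_ka
    A[IDX_TISSUE["gut"], IDX_LUMEN] = compound.gi_ka

    portal_q = sum(phys.blood_flows[t] for t in PORTAL_TISSUES)
    for t in TISSUES:
        i = IDX_TISSUE[t]
        v = phys.tissue_volumes[t]
        q = phys.blood_flows[t]
        k_out = 1.0 / (v * partition.effective(t))  # outflow conc per unit amount
        if t == "lung":
            A[i, IDX_VEN] += co / v_ven
            A[i, i] -= co * k_out
            A[IDX_ART, i] += co * k_out
        elif t == "liver":
            q_total = q + portal_q
            A[i, IDX_ART] += q / v_art
            for p in PORTAL_TISSUES:
                j = IDX_TISSUE[p]
                kp_out = 1.0 / (
                    phys.tissue_volumes[p] * partition.effective(p)
                )
                A[i, j] += phys.blood_flows[p] * kp_out
            A[i, i] -= (q_total + cl_hepatic_blood) * k_out
            A[IDX_VEN, i] += q_total * k_out
            A[IDX_ELIM, i] += cl_hepatic_blood * k_out
        elif t in PORTAL_TISSUES:
            A[i, IDX_ART] += q / v_art
            A[i, i] -= q * k_out  # outflow credited to the liver row above
        else:
            A[i, IDX_ART] += q / v_art
            A[i, i] -= q * k_out
            A[IDX_VEN, i] += q * k_out
    A[IDX_ART, IDX_ART] -= phys.systemic_flow() / v_art
    A[IDX_VEN, IDX_VEN] -= co / v_ven
    return A


def pbpk_rhs(
    state: np.ndarray,
    compound: CompoundParameterSet,
    phys: PhysiologyModel,
    partition: TissuePartition | None = None,
) -> np.ndarray:
    """Time derivative of the state vector (pure function of the state)."""
    state = np.asarray(state, dtype=float)
    if state.shape != (N_STATE,):
        raise PBPKError(f"state must have shape ({N_STATE},), got {state.shape}")
    return build_system_matrix(compound, phys, partition) @ state


def stomach_free_concentration(
    gut_amount_ug,
    compound: CompoundParameterSet,
    phys: PhysiologyModel,
    enrichment: float = 1.0,
    partition: TissuePartition | None = None,
):
    """Free drug concentration at the stomach acid pump site (ng/mL).

    Computed from the gut-tissue amount as

        Ce = enrichment * A_gut * bpr / (Kp_gut * kp_scaler * V_gut * fup)

    The unbound fraction divides: the product ``Kp_gut * scaler * V_gut *
    fup`` plays the role of an effective free-drug distribution volume.
    ``enrichment`` is the local accumulation factor at the pump
    (``intersys``); the default 1 gives the plain tissue observer.
    """
    partition = partition if partition is not None else compound.partition
    v_gut = phys.tissue_volumes["gut"]
    if v_gut <= 0:
        raise PBPKError("gut volume must be positive")
    denom = partition.effective("gut") * v_gut * compound.fup
    # base observer first, then the enrichment factor, so that scaling the
    # enrichment is bitwise-exactly linear
    return (np.asarray(gut_amount_ug) * compound.bpr / denom) * enrichment


@dataclass(frozen=True)
class PKProfile:
    """Time-resolved simulation output.

    ``amounts`` is a (n_times, n_state) array in the canonical state
    layout; ``plasma`` and ``stomach_free`` are ng/mL (stomach observer at
    enrichment 1).
    """

    time_h: np.ndarray
    plasma_ng_mL: np.ndarray
    stomach_free_ng_mL: np.ndarray
    amounts_ug: np.ndarray
    compound: CompoundParameterSet
    regimen: DoseRegimen
    physiology: PhysiologyModel

    def amount(self, name: str) -> np.ndarray:
        return self.amounts_ug[:, state_index(name)]

    @property
    def eliminated_ug(self) -> np.ndarray:
        return self.amounts_ug[:, IDX_ELIM]

    def absorbed_dose_ug(self, t: float | None = None) -> float:
        """Total fa-gated dose administered up to time ``t`` (default: all)."""
        horizon = self.time_h[-1] if t is None else t
        n = sum(1 for tt in self.regimen.times_h if tt <= horizon)
        return self.compound.fa * self.regimen.dose_mg * MG_TO_UG * n

    def mass_balance_error(self) -> np.ndarray:
        """Relative mass-balance defect at each output time."""
        dosed = np.array(
            [self.absorbed_dose_ug(t) for t in self.time_h]
        )
        total = self.amounts_ug.sum(axis=1)
        scale = max(dosed.max(), 1.0)
        return (total - dosed) / scale

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "time_h": self.time_h,
                "plasma_ng_mL": self.plasma_ng_mL,
                "stomach_free_ng_mL": self.stomach_free_ng_mL,
            }
        )
        for i, name in enumerate(STATE_NAMES):
            df[f"amount_{name}_ug"] = self.amounts_ug[:, i]
        return df


def simulate_pk(
    compound: CompoundParameterSet,
    regimen: DoseRegimen,
    phys: PhysiologyModel,
    solver: SolverOptions | None = None,
) -> PKProfile:
    """Integrate the whole-body model over the regimen horizon.

    Each administration inserts ``fa * dose`` into the gut lumen.  The
    plasma observable is the venous blood concentration divided by the
    blood-to-plasma ratio.
    """
    solver = solver or SolverOptions()
    if compound.partition is None:
        raise PBPKError(f"{compound.name}: no tissue partition block")
    A = build_system_matrix(compound, phys)

    # Segment boundaries: dose times plus the horizon.
    times = [t for t in regimen.times_h if t < regimen.duration_h]
    boundaries = sorted(set([0.0, *times, regimen.duration_h]))
    grid = np.round(
        np.arange(0.0, regimen.duration_h + 0.5 * solver.output_step_h, solver.output_step_h),
        10,
    )
    out_t: list[np.ndarray] = []
    out_x: list[np.ndarray] = []

    x = np.zeros(N_STATE)
    segments = list(zip(boundaries[:-1], boundaries[1:]))
    for i, (a, b) in enumerate(segments):
        if a in times:
            x = x.copy()
            x[IDX_LUMEN] += compound.fa * regimen.dose_mg * MG_TO_UG
        seg_eval = grid[(grid >= a - 1e-12) & (grid <= b + 1e-12)]
        if len(seg_eval) == 0 or seg_eval[0] > a:
            seg_eval = np.concatenate([[a], seg_eval])
        if seg_eval[-1] < b:
            seg_eval = np.concatenate([seg_eval, [b]])
        sol = solve_ivp(
            lambda t, y: A @ y,
            (a, b),
            x,
            method=solver.method,
            t_eval=seg_eval,
            jac=lambda t, y: A,
            rtol=solver.rtol,
            atol=solver.atol,
        )
        if not sol.success:
            raise PBPKError(
                f"integration failed on [{a}, {b}] h: {sol.message}; "
                f"compound={compound.to_dict()}"
            )
        # Boundary samples belong to the *following* segment so that a dose
        # time reports the post-dose state (consistent with mass balance).
        last = len(sol.t) if i == len(segments) - 1 else len(sol.t) - 1
        out_t.append(sol.t[:last])
        out_x.append(sol.y.T[:last])
        x = sol.y[:, -1]

    time = np.concatenate(out_t)
    amounts = np.concatenate(out_x, axis=0)

    worst = amounts.min()
    if worst < -solver.negative_tolerance * max(1.0, abs(amounts).max()):
        raise PBPKError(f"negative amounts beyond tolerance: min={worst}")
    amounts = np.clip(amounts, 0.0, None)

    v_ven = phys.blood_volumes["venous"]
    plasma = amounts[:, IDX_VEN] / v_ven / compound.bpr  # ug/L == ng/mL
    stomach = stomach_free_concentration(
        amounts[:, IDX_TISSUE["gut"]], compound, phys, enrichment=1.0
    )
    return PKProfile(
        time_h=time,
        plasma_ng_mL=plasma,
        stomach_free_ng_mL=np.asarray(stomach),
        amounts_ug=amounts,
        compound=compound,
        regimen=regimen,
        physiology=phys,
    )
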