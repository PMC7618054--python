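"""Mass-action ODE model of the AtoSC two-component system (TCS).

The model tracks the AtoS histidine kinase (HK), the AtoC response
regulator (RR), their phosphorylated forms and complexes, occupancy of the
RR-activated Pato promoter, and a downstream GFP reporter cascade
(mRNA -> immature GFP -> mature GFP).  The HK autophosphorylation rate
``k_ap`` stands in for the acetoacetate input: sweeping it produces the
biosensor's dose-response curve.

Species (12):
    S    free unphosphorylated HK
    Sp   free phospho-HK
    C    free RR
    Cp   free phospho-RR
    SpC  phospho-HK . RR complex (phosphotransfer intermediate)
    SCp  HK . phospho-RR complex (phosphatase intermediate)
    SC   HK . RR dead-end complex
    P    free Pato promoter
    PCp  Pato . phospho-RR complex (transcriptionally active)
    M    reporter mRNA
    Gi   immature (dark) GFP
    Gm   mature (fluorescent) GFP

Three quantities are conserved by construction: total HK
(S + Sp + SpC + SCp + SC), total RR (C + Cp + SpC + SCp + SC + PCp) and
total promoter (P + PCp).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import yaml
from scipy.integrate import solve_ivp

__all__ = [
    "SPECIES",
    "TCSParameters",
    "TCSState",
    "Reaction",
    "ParameterError",
    "IntegrationError",
    "build_reaction_network",
    "derivatives",
    "simulate_to_steady_state",
    "SteadyStateResult",
]

SPECIES = ("S", "Sp", "C", "Cp", "SpC", "SCp", "SC", "P", "PCp", "M", "Gi", "Gm")
_IDX = {name: i for i, name in enumerate(SPECIES)}

# File keys use the field-standard names: 'S', 'C', 'pato' for the totals
# and a 'rep_' prefix for the reporter-cascade constants.
PARAM_FILE_KEYS = {
    "k_ap": "k_ap",
    "k_ad": "k_ad",
    "k_b1": "k_b1",
    "k_b2": "k_b2",
    "k_b3": "k_b3",
    "k_bnd": "k_bnd",
    "k_d1": "k_d1",
    "k_d2": "k_d2",
    "k_d3": "k_d3",
    "k_lgexp": "k_lgexp",
    "k_ph": "k_ph",
    "k_pmgexp": "k_pmgexp",
    "k_pt": "k_pt",
    "k_unbnd": "k_unbnd",
    "S": "S_tot",
    "C": "C_tot",
    "pato": "P_tot",
    "rep_k_trl": "k_trl",
    "rep_k_mat": "k_mat",
    "rep_d_m": "d_m",
    "rep_d_g": "d_g",
}
PARAM_FIELD_TO_KEY = {v: k for k, v in PARAM_FILE_KEYS.items()}


class ParameterError(ValueError):
    """A parameter value violates the model's validity constraints."""


class IntegrationError(RuntimeError):
    """ODE integration failed; carries the last valid state and time."""

    def __init__(self, message: str, last_state: np.ndarray, last_time: float):
        super().__init__(message)
        self.last_state = last_state
        self.last_time = last_time


@dataclass(frozen=True)
class TCSParameters:
    """Rate constants and conserved totals of the AtoSC model.

    All rates are first- or second-order mass-action constants; S_tot,
    C_tot and P_tot are the conserved total HK, RR and promoter
    concentrations (the paper-style 'S', 'C' and 'pato' dials).  The
    reporter cascade (k_trl, k_mat, d_m, d_g) only scales the GFP output
    and is held fixed during sensitivity screening.
    """

    k_ap: float = 0.1       # HK autophosphorylation, 1/time (acetoacetate proxy)
    k_ad: float = 0.1       # HK autodephosphorylation, 1/time
    k_b1: float = 10.0      # Sp + C association, 1/(conc.time)
    k_d1: float = 0.1       # SpC dissociation, 1/time
    k_pt: float = 1.0       # phosphotransfer SpC -> S + Cp, 1/time
    k_b2: float = 10.0      # S + Cp association, 1/(conc.time)
    k_d2: float = 0.1       # SCp dissociation, 1/time
    k_ph: float = 1.0       # phosphatase SCp -> S + C, 1/time
    k_b3: float = 1.0       # S + C association, 1/(conc.time)
    k_d3: float = 1.0       # SC dissociation, 1/time
    k_bnd: float = 10.0     # Cp + P association, 1/(conc.time)
    k_unbnd: float = 0.1    # PCp dissociation, 1/time
    k_lgexp: float = 0.01   # leaky transcription from free P, 1/time
    k_pmgexp: float = 1.0   # induced transcription from PCp, 1/time
    S_tot: float = 1.0      # total HK, conc
    C_tot: float = 2.0      # total RR, conc
    P_tot: float = 0.1      # total Pato promoter, conc
    k_trl: float = 1.0      # translation, 1/time
    k_mat: float = 1.0      # GFP maturation, 1/time
    d_m: float = 1.0        # mRNA degradation, 1/time
    d_g: float = 0.1        # GFP degradation/dilution, 1/time

    def __post_init__(self):
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ParameterError(f"parameter {f.name} is not finite: {v!r}")
            if v < 0:
                raise ParameterError(f"parameter {f.name} is negative: {v!r}")
        for total in ("S_tot", "C_tot", "P_tot"):
            if getattr(self, total) <= 0:
                raise ParameterError(f"total {total} must be > 0 for a runnable model")

    def replace(self, **changes) -> "TCSParameters":
        return dataclasses.replace(self, **changes)

    # --- flat-file round trip -------------------------------------------
    def to_dict(self) -> dict:
        return {key: getattr(self, field) for key, field in PARAM_FILE_KEYS.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "TCSParameters":
        unknown = set(d) - set(PARAM_FILE_KEYS)
        if unknown:
            raise ParameterError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{PARAM_FILE_KEYS[k]: float(v) for k, v in d.items()})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_file(cls, path) -> "TCSParameters":
        """Load from flat YAML or JSON keyed by the standard names."""
        text = open(path).read()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(data)


@dataclass(frozen=True)
class TCSState:
    """Concentrations of the 12 molecular species."""

    S: float = 0.0
    Sp: float = 0.0
    C: float = 0.0
    Cp: float = 0.0
    SpC: float = 0.0
    SCp: float = 0.0
    SC: float = 0.0
    P: float = 0.0
    PCp: float = 0.0
    M: float = 0.0
    Gi: float = 0.0
    Gm: float = 0.0

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, s) for s in SPECIES], dtype=float)

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "TCSState":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (len(SPECIES),):
            raise ValueError(f"state must have {len(SPECIES)} entries")
        return cls(**{s: float(arr[i]) for i, s in enumerate(SPECIES)})

    @classmethod
    def initial(cls, params: TCSParameters) -> "TCSState":
        """Default initial condition: all protein/promoter free and unmodified."""
        return cls(S=params.S_tot, C=params.C_tot, P=params.P_tot)

    def conservation_sums(self) -> tuple[float, float, float]:
        """(total HK, total RR, total promoter) implied by this state."""
        hk = self.S + self.Sp + self.SpC + self.SCp + self.SC
        rr = self.C + self.Cp + self.SpC + self.SCp + self.SC + self.PCp
        prom = self.P + self.PCp
        return hk, rr, prom


@dataclass(frozen=True)
class Reaction:
    """One elementary mass-action rate law with its stoichiometry."""

    name: str
    rate_constant: str          # field name on TCSParameters
    reactant_indices: tuple     # species whose concentrations multiply the rate
    stoichiometry: np.ndarray   # length-12 change vector

    def rate(self, state: np.ndarray, params: TCSParameters) -> float:
        v = getattr(params, self.rate_constant)
        for i in self.reactant_indices:
            v *= state[i]
        return v


# (rate constant field, mass-action reactant species, net stoichiometry)
_REACTION_SPECS = [
    ("autophosphorylation",     "k_ap",     ("S",),        {"S": -1, "Sp": +1}),
    ("autodephosphorylation",   "k_ad",     ("Sp",),       {"Sp": -1, "S": +1}),
    ("Sp_C_binding",            "k_b1",     ("Sp", "C"),   {"Sp": -1, "C": -1, "SpC": +1}),
    ("Sp_C_unbinding",          "k_d1",     ("SpC",),      {"SpC": -1, "Sp": +1, "C": +1}),
    ("phosphotransfer",         "k_pt",     ("SpC",),      {"SpC": -1, "S": +1, "Cp": +1}),
    ("S_Cp_binding",            "k_b2",     ("S", "Cp"),   {"S": -1, "Cp": -1, "SCp": +1}),
    ("S_Cp_unbinding",          "k_d2",     ("SCp",),      {"SCp": -1, "S": +1, "Cp": +1}),
    ("phosphatase",             "k_ph",     ("SCp",),      {"SCp": -1, "S": +1, "C": +1}),
    ("S_C_binding",             "k_b3",     ("S", "C"),    {"S": -1, "C": -1, "SC": +1}),
    ("S_C_unbinding",           "k_d3",     ("SC",),       {"SC": -1, "S": +1, "C": +1}),
    ("promoter_binding",        "k_bnd",    ("Cp", "P"),   {"Cp": -1, "P": -1, "PCp": +1}),
    ("promoter_unbinding",      "k_unbnd",  ("PCp",),      {"PCp": -1, "Cp": +1, "P": +1}),
    ("leaky_transcription",     "k_lgexp",  ("P",),        {"M": +1}),
    ("induced_transcription",   "k_pmgexp", ("PCp",),      {"M": +1}),
    ("translation",             "k_trl",    ("M",),        {"Gi": +1}),
    ("maturation",              "k_mat",    ("Gi",),       {"Gi": -1, "Gm": +1}),
    ("mrna_degradation",        "d_m",      ("M",),        {"M": -1}),
    ("immature_gfp_degradation", "d_g",     ("Gi",),       {"Gi": -1}),
    ("mature_gfp_degradation",  "d_g",      ("Gm",),       {"Gm": -1}),
]


def build_reaction_network(params: TCSParameters) -> list[Reaction]:
    """Explicit reaction set of the model, one rate law per entry.

    Reversible binding steps appear as separate forward/backward rate laws,
    giving 19 rate laws in total.  Raises :class:`ParameterError` (naming
    the field) if any parameter is invalid; the dataclass enforces the same
    check at construction, so this re-validates defensively for mutated or
    duck-typed inputs.
    """
    for field_name in {spec[1] for spec in _REACTION_SPECS}:
        v = getattr(params, field_name)
        if not np.isfinite(v) or v < 0:
            raise ParameterError(f"parameter {field_name} is invalid: {v!r}")
    network = []
    for name, k, reactants, stoich in _REACTION_SPECS:
        vec = np.zeros(len(SPECIES))
        for sp, change in stoich.items():
            vec[_IDX[sp]] = change
        network.append(
            Reaction(name, k, tuple(_IDX[s] for s in reactants), vec)
        )
    return network


# Precompiled structure shared by all parameter sets: the stoichiometry
# matrix and the reactant index pairs (second index -1 for unimolecular).
_N = np.zeros((len(SPECIES), len(_REACTION_SPECS)))
_REACT_A = np.empty(len(_REACTION_SPECS), dtype=int)
_REACT_B = np.empty(len(_REACTION_SPECS), dtype=int)
_K_FIELDS = []
for _j, (_nm, _k, _reacts, _st) in enumerate(_REACTION_SPECS):
    for _sp, _c in _st.items():
        _N[_IDX[_sp], _j] = _c
    _REACT_A[_j] = _IDX[_reacts[0]]
    _REACT_B[_j] = _IDX[_reacts[1]] if len(_reacts) == 2 else -1
    _K_FIELDS.append(_k)
_BIMOL = _REACT_B >= 0


def _k_vector(params: TCSParameters) -> np.ndarray:
    return np.array([getattr(params, f) for f in _K_FIELDS])


def _rates(y: np.ndarray, k: np.ndarray) -> np.ndarray:
    v = k * y[_REACT_A]
    v[_BIMOL] *= y[_REACT_B[_BIMOL]]
    return v


def derivatives(state, params: TCSParameters) -> np.ndarray:
    """Time derivatives of all 12 species (stoichiometry x rate laws)."""
    y = state.to_array() if isinstance(state, TCSState) else np.asarray(state, float)
    return _N @ _rates(y, _k_vector(params))


def _jacobian(y: np.ndarray, k: np.ndarray) -> np.ndarray:
    """Analytic Jacobian d(dy/dt)/dy for the stiff integrator."""
    nr = len(_K_FIELDS)
    R = np.zeros((nr, len(SPECIES)))
    rows = np.arange(nr)
    # unimolecular: d(k*y_a)/dy_a = k
    uni = ~_BIMOL
    R[rows[uni], _REACT_A[uni]] = k[uni]
    # bimolecular: d(k*y_a*y_b)/dy_a = k*y_b and vice versa
    bi = rows[_BIMOL]
    R[bi, _REACT_A[_BIMOL]] += k[_BIMOL] * y[_REACT_B[_BIMOL]]
    R[bi, _REACT_B[_BIMOL]] += k[_BIMOL] * y[_REACT_A[_BIMOL]]
    return _N @ R


class SteadyStateResult(NamedTuple):
    state: TCSState
    converged: bool
    t_final: float


# conservation-law membership, used to replace redundant ODE rows in the
# Newton polish (S/C/P rows are linear combinations of the others)
_HK_MEMBERS = np.array([_IDX[s] for s in ("S", "Sp", "SpC", "SCp", "SC")])
_RR_MEMBERS = np.array([_IDX[s] for s in ("C", "Cp", "SpC", "SCp", "SC", "PCp")])
_PROM_MEMBERS = np.array([_IDX[s] for s in ("P", "PCp")])


def _newton_steady(y0: np.ndarray, k: np.ndarray, totals, scale: float) -> np.ndarray | None:
    """Newton solve of the steady-state equations from a warm start.

    The three redundant ODE rows (S, C, P) are replaced by the conservation
    constraints, making the Jacobian generically nonsingular.  Returns None
    when Newton fails to converge or lands on a negative/invalid root.
    """
    y = y0.copy()
    s_tot, c_tot, p_tot = totals
    for _ in range(50):
        F = _N @ _rates(y, k)
        J = _jacobian(y, k)
        F[_IDX["S"]] = y[_HK_MEMBERS].sum() - s_tot
        F[_IDX["C"]] = y[_RR_MEMBERS].sum() - c_tot
        F[_IDX["P"]] = y[_PROM_MEMBERS].sum() - p_tot
        for row, members in ((_IDX["S"], _HK_MEMBERS), (_IDX["C"], _RR_MEMBERS),
                             (_IDX["P"], _PROM_MEMBERS)):
            J[row] = 0.0
            J[row, members] = 1.0
        try:
            dy = np.linalg.solve(J, -F)
        except np.linalg.LinAlgError:
            return None
        if not np.all(np.isfinite(dy)):
            return None
        y = y + dy
        if np.max(np.abs(dy)) < 1e-13 * max(scale, np.max(np.abs(y)), 1.0):
            break
    else:
        return None
    if np.any(y < -1e-9 * max(scale, 1.0)):
        return None
    return np.clip(y, 0.0, None)


def simulate_to_steady_state(
    params: TCSParameters,
    init: TCSState | None = None,
    rel_tol: float = 1e-6,
    t_max: float = 1e6,
    check_conservation: bool = True,
    newton_polish: bool = True,
) -> SteadyStateResult:
    """Integrate the ODEs until every species has stopped changing.

    The system is integrated over geometrically growing horizons; after
    each horizon ``t`` a probe window of ``0.1 t`` is integrated and the
    state is declared stationary when the maximum relative change of every
    species across the window is below ``rel_tol``.  If ``t_max`` is
    reached first the flag is False.

    With ``newton_polish`` (default) each integrated checkpoint is first
    handed to a Newton solve of the algebraic steady-state system; a
    successful root is still certified by integrating the probe window and
    applying the same relative-change criterion, so the returned state
    always satisfies the windowed stationarity test (this guards against
    Newton landing on an unstable root).

    Uses the stiff-capable LSODA integrator with an analytic Jacobian:
    binding rates and expression rates can differ by orders of magnitude.
    """
    if init is None:
        init = TCSState.initial(params)
    totals = (params.S_tot, params.C_tot, params.P_tot)
    if check_conservation:
        for got, want, label in zip(init.conservation_sums(), totals, ("HK", "RR", "promoter")):
            if abs(got - want) > 1e-9 * max(want, 1.0):
                raise ValueError(
                    f"initial state violates {label} conservation: {got} != {want}"
                )
    k = _k_vector(params)
    scale = max(totals)
    atol = 1e-12 * scale
    floor = 1e-9 * scale  # relative-change denominator floor for near-zero species

    def rhs(t, y):
        return _N @ _rates(y, k)

    def jac(t, y):
        return _jacobian(y, k)

    def integrate(y, t0, t1, t_eval):
        sol = solve_ivp(rhs, (t0, t1), y, method="LSODA", jac=jac,
                        t_eval=t_eval, rtol=1e-8, atol=atol)
        if not sol.success:
            raise IntegrationError(
                f"integrator failed: {sol.message}", last_state=y, last_time=t0
            )
        return sol

    def window_stationary(y_start, t0, window):
        """Probe-window relative-change criterion from state y_start."""
        sol = integrate(y_start, t0, t0 + window, t_eval=[t0 + window])
        y_end = sol.y[:, -1]
        denom = np.maximum(np.abs(y_start), floor)
        ok = np.max(np.abs(y_end - y_start) / denom) < rel_tol
        return ok, y_end

    y = init.to_array()
    t_now = 0.0
    horizon = 100.0
    converged = False
    while True:
        t_checkpoint = min(horizon, t_max)
        sol = integrate(y, t_now, t_checkpoint, t_eval=[t_checkpoint])
        y, t_now = sol.y[:, -1], t_checkpoint
        window = 0.1 * t_now
        if newton_polish:
            y_root = _newton_steady(y, k, totals, scale)
            if y_root is not None:
                ok, y_end = window_stationary(y_root, t_now, window)
                if ok:
                    y, t_now, converged = y_end, t_now + window, True
                    break
        ok, y_end = window_stationary(y, t_now, window)
        if ok:
            y, t_now, converged = y_end, t_now + window, True
            break
        y, t_now = y_end, t_now + window
        if t_checkpoint >= t_max:
            break
        horizon *= 4.0
    # clip integrator noise: tolerate excursions below zero only to 1e-9
    y = np.where((y < 0) & (y > -1e-9 * max(scale, 1.0)), 0.0, y)
    return SteadyStateResult(TCSState.from_array(y), converged, t_now)


def trajectory_frame(params: TCSParameters, t_grid: Sequence[float], init: TCSState | None = None):
    """Integrate over an explicit time grid; tidy DataFrame (time, species, value)."""
    import pandas as pd

    if init is None:
        init = TCSState.initial(params)
    k = _k_vector(params)
    t_grid = np.asarray(t_grid, dtype=float)
    sol = solve_ivp(
        lambda t, y: _N @ _rates(y, k),
        (t_grid[0], t_grid[-1]),
        init.to_array(),
        method="LSODA",
        jac=lambda t, y: _jacobian(y, k),
        t_eval=t_grid,
        rtol=1e-8,
        atol=1e-12 * max(params.S_tot, params.C_tot, params.P_tot),
    )
    if not sol.success:
        raise IntegrationError(f"integrator failed: {sol.message}", sol.y[:, -1], sol.t[-1])
    records = []
    for j, t in enumerate(sol.t):
        for i, sp in enumerate(SPECIES):
            records.append({"time": t, "species": sp, "value": sol.y[i, j]})
    return pd.DataFrame.from_records(records)
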