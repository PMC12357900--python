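"""Deterministic ODE model of canonical / non-canonical NF-κB crosstalk.

The network tracks three Rel dimers — RelA:p50 (``A``), cRel:p50 (``C``) and
RelB:p52 (``B``) — three IκB activities (IκBα, IκBε and the IκBδ activity of
p100 multimers), and the kinase inputs IKK (canonical, parameterised by the
basal activation fraction ``b``) and NIK (non-canonical, stabilised by CD40
ligation).  The crosstalk mechanism is IκBδ: p100 is induced by nuclear RelA,
binds cRel:p50 with higher affinity than RelA:p50, and is processed in a
NIK-dependent manner — so CD40 stimulation releases sequestered cRel only in
cells with elevated basal canonical activity.

Species (concentrations in arbitrary units, time in minutes):

====================  ====================================================
``A_cyt``/``A_nuc``   free cytoplasmic / nuclear RelA:p50
``C_cyt``/``C_nuc``   free cytoplasmic / nuclear cRel:p50
``IkBa`` ``IkBe``     free IκBα, IκBε
``P100``              free p100 (carries the IκBδ inhibitory activity)
``IkBa_A`` …          inhibitor-bound dimer complexes (six of them)
``RelB_p100``         RelB sequestered by p100 (inactive)
``B_nuc``             active nuclear RelB:p52
``NIK``               NF-κB-inducing kinase level
====================  ====================================================

p50/p52 monomers are treated as non-limiting; p100 processing removes IκBδ
activity from the inhibitor pool (the p52 product is only visible as the
``RelB_p100 → B_nuc`` conversion).
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field, fields, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

logger = logging.getLogger("nfkb_crosstalk")

__all__ = [
    "SPECIES",
    "ModelParameters",
    "Trajectory",
    "CompositionBreakdown",
    "ConfigError",
    "ValidationError",
    "IntegrationError",
    "SteadyStateError",
    "build_parameters",
    "canonical_parameters",
    "derivatives",
    "simulate",
    "steady_state",
    "inhibitor_composition",
    "closed_test_parameters",
    "rk4_simulate",
    "zero_state",
    "state_array",
    "REL_POOLS",
]

SPECIES: tuple[str, ...] = (
    "A_cyt", "A_nuc", "C_cyt", "C_nuc",
    "IkBa", "IkBe", "P100",
    "IkBa_A", "IkBe_A", "Id_A",
    "IkBa_C", "IkBe_C", "Id_C",
    "RelB_p100", "B_nuc", "NIK",
)
_IDX = {name: i for i, name in enumerate(SPECIES)}

#: species making up the total pool of each Rel monomer (conservation checks)
REL_POOLS: dict[str, tuple[str, ...]] = {
    "RelA": ("A_cyt", "A_nuc", "IkBa_A", "IkBe_A", "Id_A"),
    "cRel": ("C_cyt", "C_nuc", "IkBa_C", "IkBe_C", "Id_C"),
    "RelB": ("RelB_p100", "B_nuc"),
}

MAX_BASAL_FRACTION = 0.005  # upper end of the 0–0.5% basal-activation sweep


class ConfigError(ValueError):
    """Unknown or malformed configuration key."""


class ValidationError(ValueError):
    """Parameter value violates a model invariant."""


class IntegrationError(RuntimeError):
    """ODE solver failed; carries the final time reached."""

    def __init__(self, message: str, t_reached: float):
        super().__init__(message)
        self.t_reached = t_reached


class SteadyStateError(RuntimeError):
    """Steady-state search did not converge; carries the residual norm."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelParameters:
    """Rate constants for one virtual cell.

    Units: first-order rates per minute, bimolecular rates per
    (concentration·minute), concentrations in arbitrary units.  ``b`` is the
    basal canonical activation fraction (IKK activity at rest), swept over
    0–0.5% of maximal.
    """

    # Rel dimer synthesis (into the cytoplasm / the RelB:p100 pool)
    k_syn_A: float = 0.05
    k_syn_C: float = 0.05
    k_syn_RelB: float = 0.05
    # Rel dimer turnover (applies to every complex containing the dimer)
    k_deg_A: float = 5e-4
    k_deg_C: float = 5e-4
    k_deg_RelB: float = 5e-3
    k_deg_Bnuc: float = 5e-3
    # IκB synthesis: basal + RelA-driven Hill term on nuclear RelA
    k0_Ia: float = 0.15
    k0_Ie: float = 0.08
    k0_p100: float = 2e-4
    g_Ia: float = 0.05
    g_Ie: float = 0.01
    g_p100: float = 0.18
    h: float = 4.0
    K_tx: float = 6.0
    # inhibitor–dimer binding (kb) and unbinding (ku)
    kb_Ia_A: float = 0.10
    kb_Ia_C: float = 0.01
    kb_Ie_A: float = 0.03
    kb_Ie_C: float = 0.30
    kb_Id_A: float = 0.01
    kb_Id_C: float = 0.30
    ku_Ia_A: float = 1e-3
    ku_Ia_C: float = 1e-3
    ku_Ie_A: float = 1e-3
    ku_Ie_C: float = 1e-3
    ku_Id_A: float = 1e-3
    ku_Id_C: float = 1e-4
    # IκB degradation: basal d0 plus IKK-driven gain (IκBα/ε only)
    d0_Ia: float = 1e-4
    d0_Ie: float = 1e-4
    d0_Id: float = 1e-3
    d_ikk_Ia: float = 2.0
    d_ikk_Ie: float = 2.0
    # NIK-dependent p100 processing (acts on P100, Id_A, Id_C, RelB_p100)
    k_proc: float = 4e-4
    k_syn_NIK: float = 0.01
    k_deg_NIK: float = 0.01
    # nuclear shuttling of free dimers
    k_in_A: float = 0.01
    k_out_A: float = 0.05
    k_in_C: float = 0.01
    k_out_C: float = 0.05
    # basal canonical activation fraction, 0–0.5 % of maximal IKK
    b: float = 0.0005

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(
                    f"parameter {f.name!r} must be finite and >= 0, got {v!r}"
                )
        if not self.kb_Id_C > self.kb_Id_A:
            raise ValidationError(
                "IκBδ must bind cRel:p50 more tightly than RelA:p50 "
                f"(kb.IkBd.C={self.kb_Id_C} <= kb.IkBd.A={self.kb_Id_A})"
            )
        if not self.kb_Ia_A > self.kb_Ia_C:
            raise ValidationError(
                "IκBα must bind RelA:p50 more tightly than cRel:p50 "
                f"(kb.IkBa.A={self.kb_Ia_A} <= kb.IkBa.C={self.kb_Ia_C})"
            )
        if self.b > MAX_BASAL_FRACTION:
            logger.warning(
                "basal activation fraction b=%g exceeds the calibrated "
                "0-0.005 range; proceeding (sensitivity analysis)", self.b,
            )


# namespaced config key -> dataclass field
_NAMESPACED = {
    "kb.IkBa.A": "kb_Ia_A", "kb.IkBa.C": "kb_Ia_C",
    "kb.IkBe.A": "kb_Ie_A", "kb.IkBe.C": "kb_Ie_C",
    "kb.IkBd.A": "kb_Id_A", "kb.IkBd.C": "kb_Id_C",
    "ku.IkBa.A": "ku_Ia_A", "ku.IkBa.C": "ku_Ia_C",
    "ku.IkBe.A": "ku_Ie_A", "ku.IkBe.C": "ku_Ie_C",
    "ku.IkBd.A": "ku_Id_A", "ku.IkBd.C": "ku_Id_C",
}
_FIELD_NAMES = {f.name for f in fields(ModelParameters)}


def _flatten(config: Mapping, prefix: str = "") -> dict[str, float]:
    out: dict[str, float] = {}
    for key, value in config.items():
        name = f"{prefix}{key}"
        if isinstance(value, Mapping):
            out.update(_flatten(value, prefix=f"{name}."))
        else:
            out[name] = value
    return out


def build_parameters(config: Mapping | None = None) -> ModelParameters:
    """Build a :class:`ModelParameters` from a (possibly nested) config mapping.

    Keys may be flat field names (``k_syn_A``) or namespaced binding keys
    (``kb.IkBd.C``, also acceptable as nested mappings).  Unspecified keys
    take the shipped canonical defaults.  Unknown keys raise
    :class:`ConfigError`; values violating invariants raise
    :class:`ValidationError`.
    """
    overrides: dict[str, float] = {}
    for key, value in _flatten(config or {}).items():
        if key in _NAMESPACED:
            overrides[_NAMESPACED[key]] = float(value)
        elif key in _FIELD_NAMES:
            overrides[key] = float(value)
        else:
            raise ConfigError(f"unknown parameter key {key!r}")
    return ModelParameters(**overrides)


def canonical_parameters() -> ModelParameters:
    """The shipped canonical parameter set (defaults; b = 0.0005)."""
    return ModelParameters()


# ---------------------------------------------------------------------------
# right-hand side
# ---------------------------------------------------------------------------

def _hill(x: float, K: float, h: float) -> float:
    if x <= 0.0:
        return 0.0
    xh = x ** h
    return xh / (K ** h + xh)


def derivatives(state, params: ModelParameters, stimulus=None, t: float = 0.0):
    """Time derivative of every species (pure mass-action function).

    ``state`` is a length-16 array ordered as :data:`SPECIES` (or a mapping
    from species name to value).  ``stimulus`` is a
    :class:`~nfkb_crosstalk.scenarios.StimulusSpec` or ``None`` (unstimulated).
    """
    from .scenarios import StimulusSpec, cd40_multiplier  # cycle-free at call time

    if isinstance(state, Mapping):
        y = np.array([state.get(s, 0.0) for s in SPECIES], dtype=float)
    else:
        y = np.asarray(state, dtype=float)
    if stimulus is None:
        stimulus = StimulusSpec()
    p = params

    (A_cyt, A_nuc, C_cyt, C_nuc, IkBa, IkBe, P100,
     IkBa_A, IkBe_A, Id_A, IkBa_C, IkBe_C, Id_C,
     RelB_p100, B_nuc, NIK) = y

    # canonical input: basal fraction (+ optional BCR pulse), BTK-scalable
    ikk = (p.b + stimulus.bcr_pulse) * stimulus.btk_inhibitor_factor
    deg_Ia = p.d0_Ia + p.d_ikk_Ia * ikk
    deg_Ie = p.d0_Ie + p.d_ikk_Ie * ikk

    # non-canonical input: NIK-dependent processing, NIK-inhibitor-scalable
    proc = p.k_proc * stimulus.nik_inhibitor_factor * NIK
    nik_deg_mult = 1.0
    if stimulus.cd40_on and t >= stimulus.cd40_start:
        nik_deg_mult = cd40_multiplier(t - stimulus.cd40_start)

    tx = _hill(A_nuc, p.K_tx, p.h)

    # binding fluxes
    b_Ia_A = p.kb_Ia_A * IkBa * A_cyt
    b_Ie_A = p.kb_Ie_A * IkBe * A_cyt
    b_Id_A = p.kb_Id_A * P100 * A_cyt
    b_Ia_C = p.kb_Ia_C * IkBa * C_cyt
    b_Ie_C = p.kb_Ie_C * IkBe * C_cyt
    b_Id_C = p.kb_Id_C * P100 * C_cyt

    d = np.empty_like(y)

    d[_IDX["A_cyt"]] = (
        p.k_syn_A - p.k_deg_A * A_cyt
        - p.k_in_A * A_cyt + p.k_out_A * A_nuc
        - b_Ia_A - b_Ie_A - b_Id_A
        + p.ku_Ia_A * IkBa_A + p.ku_Ie_A * IkBe_A + p.ku_Id_A * Id_A
        + deg_Ia * IkBa_A + deg_Ie * IkBe_A + p.d0_Id * Id_A
        + proc * Id_A
    )
    d[_IDX["A_nuc"]] = p.k_in_A * A_cyt - p.k_out_A * A_nuc - p.k_deg_A * A_nuc
    d[_IDX["C_cyt"]] = (
        p.k_syn_C - p.k_deg_C * C_cyt
        - p.k_in_C * C_cyt + p.k_out_C * C_nuc
        - b_Ia_C - b_Ie_C - b_Id_C
        + p.ku_Ia_C * IkBa_C + p.ku_Ie_C * IkBe_C + p.ku_Id_C * Id_C
        + deg_Ia * IkBa_C + deg_Ie * IkBe_C + p.d0_Id * Id_C
        + proc * Id_C
    )
    d[_IDX["C_nuc"]] = p.k_in_C * C_cyt - p.k_out_C * C_nuc - p.k_deg_C * C_nuc

    d[_IDX["IkBa"]] = (
        p.k0_Ia + p.g_Ia * tx - deg_Ia * IkBa
        - b_Ia_A - b_Ia_C + p.ku_Ia_A * IkBa_A + p.ku_Ia_C * IkBa_C
    )
    d[_IDX["IkBe"]] = (
        p.k0_Ie + p.g_Ie * tx - deg_Ie * IkBe
        - b_Ie_A - b_Ie_C + p.ku_Ie_A * IkBe_A + p.ku_Ie_C * IkBe_C
    )
    d[_IDX["P100"]] = (
        p.k0_p100 + p.g_p100 * tx - p.d0_Id * P100 - proc * P100
        - b_Id_A - b_Id_C + p.ku_Id_A * Id_A + p.ku_Id_C * Id_C
    )

    d[_IDX["IkBa_A"]] = b_Ia_A - (p.ku_Ia_A + deg_Ia + p.k_deg_A) * IkBa_A
    d[_IDX["IkBe_A"]] = b_Ie_A - (p.ku_Ie_A + deg_Ie + p.k_deg_A) * IkBe_A
    d[_IDX["Id_A"]] = b_Id_A - (p.ku_Id_A + p.d0_Id + proc + p.k_deg_A) * Id_A
    d[_IDX["IkBa_C"]] = b_Ia_C - (p.ku_Ia_C + deg_Ia + p.k_deg_C) * IkBa_C
    d[_IDX["IkBe_C"]] = b_Ie_C - (p.ku_Ie_C + deg_Ie + p.k_deg_C) * IkBe_C
    d[_IDX["Id_C"]] = b_Id_C - (p.ku_Id_C + p.d0_Id + proc + p.k_deg_C) * Id_C

    d[_IDX["RelB_p100"]] = p.k_syn_RelB - (p.k_deg_RelB + proc) * RelB_p100
    d[_IDX["B_nuc"]] = proc * RelB_p100 - p.k_deg_Bnuc * B_nuc
    d[_IDX["NIK"]] = p.k_syn_NIK - p.k_deg_NIK * nik_deg_mult * NIK
    return d


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Sampled solution of the model: ``states[i]`` at ``times[i]``.

    ``states`` is an (n_times, 16) array ordered as :data:`SPECIES`.
    """

    times: np.ndarray
    states: np.ndarray
    scenario: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)

    def __getitem__(self, species: str) -> np.ndarray:
        """Time series of one species by name."""
        return self.states[:, _IDX[species]]

    def initial(self) -> np.ndarray:
        return self.states[0]

    def final(self) -> np.ndarray:
        return self.states[-1]

    def to_frame(self, cell_id: str | None = None):
        """Tidy long-format DataFrame (time, species, value[, scenario, cell_id])."""
        import pandas as pd

        n_t = len(self.times)
        df = pd.DataFrame({
            "time": np.repeat(self.times, len(SPECIES)),
            "species": np.tile(SPECIES, n_t),
            "value": self.states.ravel(),
        })
        df["scenario"] = self.scenario
        if cell_id is not None:
            df["cell_id"] = cell_id
        return df


def zero_state() -> np.ndarray:
    return np.zeros(len(SPECIES))


def state_array(state) -> np.ndarray:
    if isinstance(state, Mapping):
        return np.array([state.get(s, 0.0) for s in SPECIES], dtype=float)
    arr = np.asarray(state, dtype=float)
    if arr.shape != (len(SPECIES),):
        raise ValidationError(f"state must have {len(SPECIES)} entries")
    return arr


DEFAULT_DURATION = 1440.0  # 24 h, the co-culture window
_N_OUT = 97  # output grid points (>= spec minimum)


def simulate(params: ModelParameters, initial, duration: float = DEFAULT_DURATION,
             stimulus=None, n_out: int = _N_OUT, rtol: float = 1e-8,
             atol: float = 1e-8, scenario: str = "") -> Trajectory:
    """Integrate the model over ``[0, duration]`` minutes.

    Uses an adaptive stiff solver (LSODA) at rel/abs tolerance 1e-8 and
    samples the solution on ``n_out`` evenly spaced points.  Non-negative
    clamping is applied on output only (transient solver undershoot below
    -1e-9 is not expected at these tolerances).
    """
    if duration <= 0:
        raise ValidationError("duration must be > 0")
    y0 = state_array(initial)
    t_eval = np.linspace(0.0, float(duration), max(int(n_out), 2))

    def rhs(t, y):
        return derivatives(y, params, stimulus, t)

    sol = solve_ivp(rhs, (0.0, float(duration)), y0, method="LSODA",
                    t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        t_reached = float(sol.t[-1]) if sol.t.size else 0.0
        raise IntegrationError(
            f"integration failed at t={t_reached:g} min: {sol.message}", t_reached)
    states = np.clip(sol.y.T, 0.0, None)
    states[0] = y0  # exact initial state, untouched by interpolation
    return Trajectory(times=sol.t, states=states, scenario=scenario)


def steady_state(params: ModelParameters, t_max: float = 20000.0,
                 initial=None) -> np.ndarray:
    """Unstimulated steady state of the model.

    Long-time integration (default 20 000 min) followed by a Newton polish of
    the algebraic system; convergence requires
    ``max|dy/dt| < 1e-10 * max(y)``.  Raises :class:`SteadyStateError`
    (carrying the residual norm) if that fails.
    """
    y0 = zero_state() if initial is None else state_array(initial)
    traj = simulate(params, y0, duration=t_max, n_out=25)
    y = traj.final()

    def f(yv):
        return derivatives(yv, params, None, 0.0)

    sol = root(f, y, method="hybr", tol=1e-13)
    if sol.success and np.all(sol.x >= -1e-9):
        y = np.clip(sol.x, 0.0, None)
    resid = float(np.max(np.abs(f(y))))
    scale = float(max(np.max(y), 1.0))
    if resid >= 1e-10 * scale:
        raise SteadyStateError(
            f"steady state not converged: residual {resid:g} "
            f"(tolerance {1e-10 * scale:g})", resid)
    return y


# ---------------------------------------------------------------------------
# composition readout
# ---------------------------------------------------------------------------

@dataclass
class CompositionBreakdown:
    """Allocation of one dimer pool among IκB complexes, free and nuclear forms.

    Fractions are over the inhibitor-bound pool only and sum to 1; for an
    empty bound pool they are reported as zeros with ``defined=False``.
    """

    dimer: str
    f_IkBa: float
    f_IkBe: float
    f_IkBd: float
    bound_total: float
    free_cyt: float
    nuclear: float
    defined: bool = True


def inhibitor_composition(state, dimer: str) -> CompositionBreakdown:
    """Fractional IκB composition of the bound pool of dimer ``A`` or ``C``."""
    if dimer not in ("A", "C"):
        raise ValidationError(f"unknown dimer {dimer!r}; expected 'A' or 'C'")
    y = state_array(state)
    ia = y[_IDX[f"IkBa_{dimer}"]]
    ie = y[_IDX[f"IkBe_{dimer}"]]
    idd = y[_IDX[f"Id_{dimer}"]]
    bound = ia + ie + idd
    if bound > 0:
        fr = (ia / bound, ie / bound, idd / bound)
        defined = True
    else:
        fr = (0.0, 0.0, 0.0)
        defined = False
    return CompositionBreakdown(
        dimer=dimer, f_IkBa=fr[0], f_IkBe=fr[1], f_IkBd=fr[2],
        bound_total=bound,
        free_cyt=y[_IDX[f"{dimer}_cyt"]],
        nuclear=y[_IDX[f"{dimer}_nuc"]],
        defined=defined,
    )


def closed_test_parameters(params: ModelParameters) -> ModelParameters:
    """Copy of ``params`` with all synthesis and degradation rates zeroed.

    In this closed mode each Rel-monomer total is conserved exactly, which
    the numerical-integrity tests exploit.
    """
    return replace(
        params,
        k_syn_A=0.0, k_syn_C=0.0, k_syn_RelB=0.0, k_syn_NIK=0.0,
        k_deg_A=0.0, k_deg_C=0.0, k_deg_RelB=0.0, k_deg_Bnuc=0.0,
        k_deg_NIK=0.0,
        k0_Ia=0.0, k0_Ie=0.0, k0_p100=0.0,
        g_Ia=0.0, g_Ie=0.0, g_p100=0.0,
        d0_Ia=0.0, d0_Ie=0.0, d0_Id=0.0,
        d_ikk_Ia=0.0, d_ikk_Ie=0.0,
    )


def rk4_simulate(params: ModelParameters, initial, duration: float,
                 stimulus=None, dt: float = 0.01, n_out: int = _N_OUT,
                 scenario: str = "") -> Trajectory:
    """Fixed-step classical RK4 integration (brute-force oracle).

    Slow by construction; used only to cross-check the adaptive solver.
    """
    y = state_array(initial).copy()
    t_eval = np.linspace(0.0, float(duration), max(int(n_out), 2))
    out = np.empty((len(t_eval), len(SPECIES)))
    out[0] = y
    next_i = 1
    t = 0.0
    n_steps = int(round(duration / dt))
    for k in range(n_steps):
        k1 = derivatives(y, params, stimulus, t)
        k2 = derivatives(y + 0.5 * dt * k1, params, stimulus, t + 0.5 * dt)
        k3 = derivatives(y + 0.5 * dt * k2, params, stimulus, t + 0.5 * dt)
        k4 = derivatives(y + dt * k3, params, stimulus, t + dt)
        y = y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        t = (k + 1) * dt
        while next_i < len(t_eval) and t >= t_eval[next_i] - 1e-9:
            out[next_i] = y
            next_i += 1
    while next_i < len(t_eval):
        out[next_i] = y
        next_i += 1
    return Trajectory(times=t_eval, states=np.clip(out, 0.0, None),
                      scenario=scenario)
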