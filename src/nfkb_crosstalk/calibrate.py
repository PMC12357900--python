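"""Calibration constraints for the canonical parameter set.

The shipped parameters are not fitted to rate measurements (none are
published for this reduced network); they are calibrated against the
qualitative claims the model must reproduce, expressed here as six
machine-checkable constraints C1–C6.  ``validate_calibration`` evaluates
all of them with margins and is exposed on the CLI.
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml

from .model import (ModelParameters, build_parameters, inhibitor_composition,
                    simulate, steady_state)
from .scenarios import (BASAL_HIGH, BASAL_LOW, StimulusSpec,
                        apply_basal_activation)

__all__ = ["ConstraintResult", "validate_calibration", "load_parameter_file"]


@dataclass
class ConstraintResult:
    name: str
    description: str
    passed: bool
    margin: float  # signed distance to the constraint boundary (>0 = pass)
    detail: str


def load_parameter_file(path) -> ModelParameters:
    """Load a YAML/JSON parameter file (namespaced keys supported)."""
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if config is None:
        raise ValueError(f"parameter file {path} is empty")
    if not isinstance(config, dict):
        raise ValueError(f"parameter file {path} must be a mapping")
    return build_parameters(config)


def validate_calibration(params: ModelParameters | str | None = None,
                         duration: float = 1440.0) -> list[ConstraintResult]:
    """Evaluate the six calibration constraints on a parameter set.

    C1  nuclear RelA higher at high than at low basal activation
    C2  CD40 induces nuclear RelB:p52 > 2-fold at both basal levels
    C3  nuclear RelA change under CD40 within ±20% at both levels
    C4  CD40 induces nuclear cRel ≥ 1.5-fold at high basal only
        (< 1.1-fold at low basal)
    C5  IκBα+IκBε hold ≤ 14% of the inhibitor-bound cRel pool at the
        high-basal steady state
    C6  binding-affinity orderings (IκBδ: cRel > RelA; IκBα: RelA > cRel)
    """
    if params is None:
        params = ModelParameters()
    elif isinstance(params, str):
        params = load_parameter_file(params)

    lo = apply_basal_activation(params, BASAL_LOW)
    hi = apply_basal_activation(params, BASAL_HIGH)
    ss = {"lo": steady_state(lo), "hi": steady_state(hi)}
    cd40 = StimulusSpec(cd40_on=True)
    tr = {k: simulate(p, ss[k], duration=duration, stimulus=cd40)
          for k, p in (("lo", lo), ("hi", hi))}

    def fold(key, sp):
        series = tr[key][sp]
        return float(series[-1] / series[0])

    i_anuc = 1  # SPECIES index of A_nuc
    a_lo, a_hi = float(ss["lo"][i_anuc]), float(ss["hi"][i_anuc])
    results = [
        ConstraintResult(
            "C1", "nuclear RelA elevated at high basal activation",
            a_hi > a_lo, a_hi - a_lo,
            f"A_nuc: high {a_hi:.3g} vs low {a_lo:.3g}"),
    ]

    b_folds = {k: fold(k, "B_nuc") for k in ("lo", "hi")}
    results.append(ConstraintResult(
        "C2", "CD40 induces RelB:p52 > 2-fold at both basal levels",
        all(v > 2.0 for v in b_folds.values()),
        min(b_folds.values()) - 2.0,
        f"B_nuc folds: {b_folds['lo']:.3g} (low), {b_folds['hi']:.3g} (high)"))

    a_folds = {k: fold(k, "A_nuc") for k in ("lo", "hi")}
    results.append(ConstraintResult(
        "C3", "nuclear RelA within ±20% under CD40",
        all(0.8 <= v <= 1.2 for v in a_folds.values()),
        0.2 - max(abs(v - 1.0) for v in a_folds.values()),
        f"A_nuc folds: {a_folds['lo']:.3g} (low), {a_folds['hi']:.3g} (high)"))

    c_folds = {k: fold(k, "C_nuc") for k in ("lo", "hi")}
    results.append(ConstraintResult(
        "C4", "CD40 induces nuclear cRel >= 1.5-fold only at high basal",
        c_folds["hi"] >= 1.5 and c_folds["lo"] < 1.1,
        min(c_folds["hi"] - 1.5, 1.1 - c_folds["lo"]),
        f"C_nuc folds: {c_folds['lo']:.3g} (low), {c_folds['hi']:.3g} (high)"))

    comp = inhibitor_composition(ss["hi"], "C")
    frac = comp.f_IkBa + comp.f_IkBe
    results.append(ConstraintResult(
        "C5", "IκBα+IκBε hold <= 14% of bound cRel at high-basal steady state",
        frac <= 0.14, 0.14 - frac,
        f"f_IkBa + f_IkBe = {100 * frac:.2f}%"))

    c6 = params.kb_Id_C > params.kb_Id_A and params.kb_Ia_A > params.kb_Ia_C
    results.append(ConstraintResult(
        "C6", "binding-affinity orderings hold",
        c6, min(params.kb_Id_C - params.kb_Id_A,
                params.kb_Ia_A - params.kb_Ia_C),
        f"kb_Id: C {params.kb_Id_C} vs A {params.kb_Id_A}; "
        f"kb_Ia: A {params.kb_Ia_A} vs C {params.kb_Ia_C}"))
    return results
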