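"""Perturbations of the NF-κB model: CD40 ligation, basal activity, genotypes,
and pharmacological inhibitors.

All ``apply_*`` helpers are pure — they return modified copies and commute
with each other (they only multiply independent rates).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

from .model import (MAX_BASAL_FRACTION, ModelParameters, ValidationError,
                    canonical_parameters, logger)

__all__ = [
    "StimulusSpec", "Genotype", "cd40_multiplier",
    "apply_basal_activation", "apply_genotype", "apply_inhibitor",
    "GENOTYPES", "BASAL_LOW", "BASAL_HIGH", "preset_scenario", "PRESETS",
]

#: basal-activation endpoints anchoring the low (RIVA-like) and high
#: (SUDHL8-like) canonical states of the 0–0.5 % sweep
BASAL_LOW = 0.0005
BASAL_HIGH = 0.005

CD40_TAU = 600.0  # min; timescale of NIK stabilisation after CD40 ligation


@dataclass(frozen=True)
class StimulusSpec:
    """Time-dependent inputs for one simulation.

    ``cd40_on`` slows NIK degradation by the factor ``1/(1 + t/600)`` from
    ``cd40_start`` onward.  The inhibitor factors scale NIK-dependent
    processing (NIK inhibitor) and IKK activity (BTK inhibitor); both are in
    (0, 1], 1 meaning no drug.  ``bcr_pulse`` is an optional additive IKK
    term on top of the basal fraction.
    """

    cd40_on: bool = False
    cd40_start: float = 0.0
    btk_inhibitor_factor: float = 1.0
    nik_inhibitor_factor: float = 1.0
    bcr_pulse: float = 0.0

    def __post_init__(self):
        for name in ("btk_inhibitor_factor", "nik_inhibitor_factor"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValidationError(f"{name} must be in (0, 1], got {v!r}")
        if self.cd40_start < 0:
            raise ValidationError("cd40_start must be >= 0")
        if self.bcr_pulse < 0:
            raise ValidationError("bcr_pulse must be >= 0")


def cd40_multiplier(t_since_onset: float) -> float:
    """NIK degradation multiplier ``1/(1 + t/600)`` under CD40 ligation.

    Equals 1 at onset, 0.5 at 600 min, and decays toward 0: NIK is
    progressively stabilised, driving non-canonical processing.
    """
    if t_since_onset < 0:
        raise ValidationError("time since CD40 onset must be >= 0")
    return 1.0 / (1.0 + t_since_onset / CD40_TAU)


@dataclass(frozen=True)
class Genotype:
    """IκB genotype as synthesis multipliers.

    ``IkBe_KO`` removes IκBε synthesis entirely; ``IkBa_kBkB`` (κB-site
    promoter mutant) reduces IκBα synthesis by a configurable factor
    (default 0.5); ``WT`` is the identity.
    """

    name: str
    ikba_mult: float = 1.0
    ikbe_mult: float = 1.0


GENOTYPES: dict[str, Genotype] = {
    "WT": Genotype("WT"),
    "IkBe_KO": Genotype("IkBe_KO", ikbe_mult=0.0),
    "IkBa_kBkB": Genotype("IkBa_kBkB", ikba_mult=0.5),
}


def apply_basal_activation(params: ModelParameters,
                           fraction: float) -> ModelParameters:
    """Copy of ``params`` with basal canonical activation set to ``fraction``.

    Values above the calibrated 0–0.5 % range are accepted with a logged
    warning (sensitivity analysis); negative values are rejected.
    """
    if fraction < 0:
        raise ValidationError(f"basal fraction must be >= 0, got {fraction}")
    if fraction > MAX_BASAL_FRACTION:
        logger.warning("basal fraction %g above calibrated range [0, %g]",
                       fraction, MAX_BASAL_FRACTION)
    return replace(params, b=float(fraction))


def apply_genotype(params: ModelParameters,
                   genotype: Genotype | str) -> ModelParameters:
    """Scale IκB synthesis rates (basal and RelA-driven) per the genotype."""
    if isinstance(genotype, str):
        try:
            genotype = GENOTYPES[genotype]
        except KeyError:
            raise ValidationError(
                f"unknown genotype {genotype!r}; expected one of "
                f"{sorted(GENOTYPES)}") from None
    # IkBa_kBkB is a κB-site promoter mutant: it removes NF-κB-inducible
    # IκBα synthesis but leaves the constitutive rate intact, so the
    # multiplier applies to the RelA-driven gain only.  The IκBε knock-out
    # removes the gene, hence both terms.
    return replace(
        params,
        g_Ia=params.g_Ia * genotype.ikba_mult,
        k0_Ie=params.k0_Ie * genotype.ikbe_mult,
        g_Ie=params.g_Ie * genotype.ikbe_mult,
    )


def apply_inhibitor(stimulus: StimulusSpec, drug: str, dose: float,
                    Ki: float) -> StimulusSpec:
    """Apply a kinase inhibitor at ``dose`` with inhibition constant ``Ki``.

    A simple occupancy factor ``1/(1 + dose/Ki)`` scales NIK-dependent
    processing (``NIK_inh``, e.g. Amgen16) or IKK activity (``BTK_inh``,
    e.g. ibrutinib).  Factors compose multiplicatively with any already in
    the stimulus.
    """
    if dose <= 0 or Ki <= 0:
        raise ValidationError("dose and Ki must be > 0")
    factor = 1.0 / (1.0 + dose / Ki)
    if drug == "NIK_inh":
        return replace(stimulus,
                       nik_inhibitor_factor=stimulus.nik_inhibitor_factor * factor)
    if drug == "BTK_inh":
        return replace(stimulus,
                       btk_inhibitor_factor=stimulus.btk_inhibitor_factor * factor)
    raise ValidationError(
        f"unknown drug {drug!r}; expected 'NIK_inh' or 'BTK_inh'")


# ---------------------------------------------------------------------------
# named presets
# ---------------------------------------------------------------------------

def preset_scenario(name: str) -> tuple[ModelParameters, StimulusSpec]:
    """Named (parameters, stimulus) presets for the cell-line scenarios.

    Basal mapping: RIVA- and U2932-like = 0.05 % basal canonical activation,
    SUDHL8-like = 0.5 % (the printed sweep endpoints).  Inhibitor presets use
    the documented default doses (ibrutinib 0.1 µM, Amgen16 50 µM) with
    Ki = dose/9 so the occupancy factor is 0.1.
    """
    base = canonical_parameters()
    low = apply_basal_activation(base, BASAL_LOW)
    high = apply_basal_activation(base, BASAL_HIGH)
    off = StimulusSpec()
    on = StimulusSpec(cd40_on=True)
    presets = {
        "RIVA_mono": (low, off),
        "RIVA_CD40": (low, on),
        "U2932_mono": (low, off),
        "U2932_CD40": (low, on),
        "SUDHL8_mono": (high, off),
        "SUDHL8_CD40": (high, on),
        "SUDHL8_CD40_ibrutinib": (high, apply_inhibitor(on, "BTK_inh", 0.1, 0.1 / 9)),
        "RIVA_CD40_amgen16": (low, apply_inhibitor(on, "NIK_inh", 50.0, 50.0 / 9)),
        "WT": (apply_genotype(low, "WT"), off),
        "IkBe_KO": (apply_genotype(low, "IkBe_KO"), off),
        "IkBa_kBkB": (apply_genotype(low, "IkBa_kBkB"), off),
    }
    try:
        return presets[name]
    except KeyError:
        raise ValidationError(
            f"unknown scenario {name!r}; available: {sorted(presets)}") from None


PRESETS = (
    "RIVA_mono", "RIVA_CD40", "U2932_mono", "U2932_CD40",
    "SUDHL8_mono", "SUDHL8_CD40", "SUDHL8_CD40_ibrutinib",
    "RIVA_CD40_amgen16", "WT", "IkBe_KO", "IkBa_kBkB",
)
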