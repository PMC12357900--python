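"""BCL2-family induction, BH3-mimetic viability surrogate, and 4PL fitting.

Nuclear NF-κB dimer activity drives anti-apoptotic gene expression:
RelB:p52 is the dominant input to BCLXL, nuclear cRel:p50 the dominant input
to MCL1, and BCL2 is essentially constitutive (no definitive NF-κB binding
at its TSS).  Protein levels follow Hill-activated synthesis with
first-order turnover, integrated along a model trajectory.

The viability model is a deliberate minimal surrogate for the BCL2
interactome: a cell survives while its remaining anti-apoptotic
sequestration capacity exceeds its pro-apoptotic load, with the load
threshold log-normally distributed across the population.  A BH3 mimetic at
dose ``d`` reduces the capacity contributed by its target protein by the
occupancy factor ``1/(1 + d/Ki)``.  Only LC50 *orderings* between
conditions are meaningful; absolute doses are not calibrated to any assay.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import curve_fit
from scipy.stats import norm

from .model import Trajectory, ValidationError, simulate, steady_state

__all__ = [
    "GENES", "TranscriptionWeights", "Bcl2Profile", "DrugSpec", "DRUGS",
    "FourPLFit", "CellLineProfile", "CELL_LINES",
    "induce_bcl2_family", "viability_curve", "fit_4pl", "four_pl",
    "resensitization_experiment",
]

GENES = ("BCL2", "BCLXL", "MCL1")
_DIMERS = ("A", "C", "B")  # nuclear RelA:p50, cRel:p50, RelB:p52


@dataclass(frozen=True)
class TranscriptionWeights:
    """Per-gene basal synthesis, per-dimer Hill weights, and turnover.

    ``w[gene][dimer]`` is the maximal dimer-driven synthesis rate (a.u./min);
    the Hill half-max ``K`` and coefficient ``h`` are shared.  ``half_life``
    is the protein half-life in minutes.  Defaults encode the regulatory
    logic above: w[BCLXL][B] dominant, w[MCL1][C] dominant, w[BCL2][·] ≈ 0,
    with small promiscuous weights on BCLXL (all dimers bind its TSS).
    """

    basal: dict = field(default_factory=lambda: {
        "BCL2": 2e-3, "BCLXL": 1e-3, "MCL1": 1e-3})
    w: dict = field(default_factory=lambda: {
        "BCL2": {"A": 0.0, "C": 0.0, "B": 0.0},
        "BCLXL": {"A": 2e-4, "C": 2e-4, "B": 8e-3},
        "MCL1": {"A": 3e-3, "C": 8e-3, "B": 0.0},
    })
    K: dict = field(default_factory=lambda: {"A": 8.0, "C": 4.0, "B": 1.0})
    h: float = 2.0
    half_life: dict = field(default_factory=lambda: {
        "BCL2": 600.0, "BCLXL": 600.0, "MCL1": 240.0})


@dataclass
class Bcl2Profile:
    """Endpoint abundances and fold-changes-vs-basal of the three proteins."""

    abundance: dict
    fold_change: dict
    label: str = ""

    def scaled(self, basal_abundance: dict, label: str = "") -> "Bcl2Profile":
        """Re-express the fold changes on a cell line's basal profile."""
        abund = {g: basal_abundance[g] * self.fold_change[g] for g in GENES}
        return Bcl2Profile(abundance=abund, fold_change=dict(self.fold_change),
                           label=label or self.label)


def _hill(x, K, h):
    x = np.maximum(x, 0.0)
    return x ** h / (K ** h + x ** h)


def induce_bcl2_family(trajectory: Trajectory,
                       weights: TranscriptionWeights | None = None) -> Bcl2Profile:
    """Integrate BCL2-family protein dynamics along an NF-κB trajectory.

    Each protein obeys ``dX/dt = basal + Σ_d w·Hill(dimer_nuc(t)) − X·ln2/t½``
    with the pre-stimulus steady level as initial condition, so a flat
    trajectory returns fold changes of exactly 1.
    """
    wts = weights or TranscriptionWeights()
    nuc = {
        "A": trajectory["A_nuc"], "C": trajectory["C_nuc"],
        "B": trajectory["B_nuc"],
    }
    times = trajectory.times
    prof_abund: dict[str, float] = {}
    prof_fold: dict[str, float] = {}
    for gene in GENES:
        kdeg = np.log(2.0) / wts.half_life[gene]
        syn = wts.basal[gene] + sum(
            wts.w[gene][d] * _hill(nuc[d], wts.K[d], wts.h) for d in _DIMERS)
        x0 = syn[0] / kdeg  # steady level at the t=0 baseline
        # exact exponential-integrator step per grid interval (syn piecewise
        # linear in t would need quadrature; trapezoid on syn is ample at
        # this grid density)
        x = x0
        for i in range(1, len(times)):
            dt = times[i] - times[i - 1]
            s = 0.5 * (syn[i - 1] + syn[i])
            x = s / kdeg + (x - s / kdeg) * np.exp(-kdeg * dt)
        prof_abund[gene] = float(x)
        prof_fold[gene] = float(x / x0)
    return Bcl2Profile(abundance=prof_abund, fold_change=prof_fold,
                       label=trajectory.scenario)


# ---------------------------------------------------------------------------
# BH3-mimetic viability surrogate
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DrugSpec:
    """A BH3 mimetic: one anti-apoptotic target and an inhibition constant."""

    name: str
    target: str
    Ki: float = 0.01  # µM-like dose units

    def __post_init__(self):
        if self.target not in GENES:
            raise ValidationError(f"unknown target {self.target!r}")
        if self.Ki <= 0:
            raise ValidationError("Ki must be > 0")


DRUGS: dict[str, DrugSpec] = {
    "ABT199": DrugSpec("ABT199", "BCL2"),      # venetoclax
    "A1331852": DrugSpec("A1331852", "BCLXL"),
    "AZD5991": DrugSpec("AZD5991", "MCL1"),
}

#: default per-protein pro-apoptotic load weights (how much of the BH3-only
#: load each protein sequesters per abundance unit)
DEFAULT_DEPENDENCE = {"BCL2": 1.0, "BCLXL": 1.0, "MCL1": 1.0}


def viability_curve(profile: Bcl2Profile, drug: DrugSpec, doses,
                    dependence: dict | None = None,
                    threshold_median: float = 1.0,
                    threshold_spread: float = 0.35,
                    background: list[tuple[DrugSpec, float]] | None = None):
    """Fraction of cells surviving each dose of a BH3 mimetic.

    Effective anti-apoptotic capacity at dose ``d`` is
    ``E(d) = Σ_X dep_X · abundance_X / (1 + d_X/Ki_X)`` where ``d_X`` is the
    dose hitting protein X (the titrated drug on its target, plus any fixed
    ``background`` co-treatments).  Viability is the fraction of a
    log-normal threshold distribution below ``E``:
    ``Φ((ln E − ln T_med)/σ)`` — monotone non-increasing in dose.

    Returns an array of viabilities in [0, 1] aligned with ``doses``.
    """
    doses = np.asarray(doses, dtype=float)
    if doses.size == 0:
        raise ValidationError("dose list must be non-empty")
    if np.any(doses < 0) or np.any(np.diff(doses) < 0):
        raise ValidationError("doses must be >= 0 and ascending")
    dep = dependence or DEFAULT_DEPENDENCE
    fixed = {g: 0.0 for g in GENES}
    for bg_drug, bg_dose in background or []:
        fixed[bg_drug.target] += bg_dose / bg_drug.Ki
    E = np.zeros_like(doses)
    for gene in GENES:
        occ = fixed[gene] + (doses / drug.Ki if gene == drug.target else 0.0)
        E += dep.get(gene, 0.0) * profile.abundance[gene] / (1.0 + occ)
    if threshold_spread <= 0:
        raise ValidationError("threshold_spread must be > 0")
    with np.errstate(divide="ignore"):
        z = (np.log(np.maximum(E, 1e-300)) - np.log(threshold_median))
    return norm.cdf(z / threshold_spread)


# ---------------------------------------------------------------------------
# four-parameter logistic fitting
# ---------------------------------------------------------------------------

def four_pl(dose, bottom, top, hill, lc50):
    """4PL response on dose: top at dose → 0, bottom at dose → ∞ (hill > 0)."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (dose / lc50) ** hill)


@dataclass
class FourPLFit:
    """Fitted four-parameter logistic dose-response curve.

    ``lc50`` is the inflection dose (the concentration at the midpoint
    between ``top`` and ``bottom``).  ``extrapolated`` flags an LC50 outside
    the fitted dose span; ``degenerate`` flags a flat response where no LC50
    is defined.
    """

    bottom: float
    top: float
    hill: float
    lc50: float
    residual_norm: float
    converged: bool
    extrapolated: bool = False
    degenerate: bool = False

    def predict(self, dose):
        return four_pl(dose, self.bottom, self.top, self.hill, self.lc50)


def fit_4pl(doses, viability) -> FourPLFit:
    """Least-squares 4PL fit on log-dose with multi-start initialisation.

    Requires >= 4 distinct positive doses.  A flat response (range < 1e-3)
    is returned with ``degenerate=True`` and undefined (NaN) LC50 rather
    than an arbitrary fit.
    """
    doses = np.asarray(doses, dtype=float)
    viab = np.asarray(viability, dtype=float)
    if doses.shape != viab.shape:
        raise ValidationError("doses and viability must align")
    if not np.all(np.isfinite(viab)):
        raise ValidationError("viability values must be finite")
    pos = doses > 0
    if len(np.unique(doses[pos])) < 4:
        raise ValidationError("need >= 4 distinct positive doses")
    d, v = doses[pos], viab[pos]

    top0, bot0 = float(np.max(v)), float(np.min(v))
    if top0 - bot0 < 1e-3:
        return FourPLFit(bottom=bot0, top=top0, hill=np.nan, lc50=np.nan,
                         residual_norm=0.0, converged=True, degenerate=True)

    # mid-response dose from linear interpolation as one of the starts
    mid = 0.5 * (top0 + bot0)
    order = np.argsort(d)
    below = v[order] <= mid
    guess_mid = d[order][np.argmax(below)] if below.any() else float(np.median(d))

    best = None
    logd = np.log10(d)
    span = (10 ** logd.min(), 10 ** logd.max())
    for lc0 in (guess_mid, float(np.median(d)),
                float(np.sqrt(span[0] * span[1]))):
        for hill0 in (0.5, 1.0, 2.0):
            try:
                popt, _ = curve_fit(
                    lambda ld, bottom, top, hill, llc50:
                        four_pl(10 ** ld, bottom, top, hill, 10 ** llc50),
                    logd, v,
                    p0=(bot0, top0, hill0, np.log10(max(lc0, 1e-12))),
                    bounds=([-0.5, -0.5, 0.05, logd.min() - 2.0],
                            [1.6, 1.6, 10.0, logd.max() + 2.0]),
                    maxfev=20000)
            except (RuntimeError, ValueError):
                continue
            resid = float(np.linalg.norm(
                four_pl(d, popt[0], popt[1], popt[2], 10 ** popt[3]) - v))
            if best is None or resid < best[1]:
                best = (popt, resid)
    if best is None:
        raise ValidationError("4PL fit did not converge from any start")
    (bottom, top, hill, llc50), resid = best
    if bottom > top:  # reparameterise to bottom <= top with positive hill
        bottom, top, hill = top, bottom, -hill
    lc50 = float(10 ** llc50)
    return FourPLFit(
        bottom=float(bottom), top=float(top), hill=float(hill), lc50=lc50,
        residual_norm=resid, converged=True,
        extrapolated=not (span[0] <= lc50 <= span[1]))


# ---------------------------------------------------------------------------
# end-to-end resensitization experiments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellLineProfile:
    """Basal anti-apoptotic profile of a cell line (a.u.).

    RIVA and U2932 are BCL2-dependent (venetoclax-sensitive); SUDHL8 is
    BCLXL-dependent.  Values are chosen so the monoculture LC50 of the
    on-target drug falls inside the standard 1e-4–100 dose range.
    """

    name: str
    basal: dict


CELL_LINES: dict[str, CellLineProfile] = {
    "RIVA": CellLineProfile("RIVA", {"BCL2": 1.6, "BCLXL": 0.25, "MCL1": 0.25}),
    "U2932": CellLineProfile("U2932", {"BCL2": 1.4, "BCLXL": 0.3, "MCL1": 0.35}),
    "SUDHL8": CellLineProfile("SUDHL8", {"BCL2": 0.25, "BCLXL": 1.6, "MCL1": 0.3}),
}

DEFAULT_DOSES = np.logspace(-4, 2, 25)  # 1e-4 .. 100, the assay dose range


def resensitization_experiment(cell_line: str, drug: DrugSpec | str,
                               modulator: tuple | None = None,
                               doses=None, weights=None,
                               n_out: int = 97) -> dict[str, FourPLFit]:
    """LC50 triple (mono, CD40 co-culture, co-culture + modulator).

    Runs the NF-κB model for the cell line's basal state with and without
    CD40, maps each trajectory to a BCL2-family profile, titrates ``drug``
    through the viability surrogate and fits 4PL curves.  ``modulator`` is
    either ``("NIK_inh"|"BTK_inh", dose, Ki)`` applied to the CD40
    simulation, or ``(DrugSpec, dose)`` added as a fixed co-treatment to the
    viability assay (sub-lethal BH3-mimetic combination).
    """
    from .scenarios import StimulusSpec, apply_inhibitor, preset_scenario

    if isinstance(drug, str):
        drug = DRUGS[drug]
    if cell_line not in CELL_LINES:
        raise ValidationError(f"unknown cell line {cell_line!r}")
    doses = DEFAULT_DOSES if doses is None else np.asarray(doses, float)
    params, _ = preset_scenario(f"{cell_line}_mono")
    ss = steady_state(params)
    basal = CELL_LINES[cell_line].basal

    conditions: dict[str, tuple[StimulusSpec, list]] = {
        "mono": (StimulusSpec(), []),
        "cd40": (StimulusSpec(cd40_on=True), []),
    }
    background: list = []
    stim_mod = StimulusSpec(cd40_on=True)
    if modulator is not None:
        if isinstance(modulator[0], DrugSpec):
            background = [(modulator[0], modulator[1])]
        else:
            kind, dose, Ki = modulator
            stim_mod = apply_inhibitor(stim_mod, kind, dose, Ki)
    conditions["cd40_mod"] = (stim_mod, background)

    fits: dict[str, FourPLFit] = {}
    for label, (stim, bg) in conditions.items():
        traj = simulate(params, ss, duration=1440.0, stimulus=stim,
                        scenario=f"{cell_line}_{label}", n_out=n_out)
        profile = induce_bcl2_family(traj, weights).scaled(basal, label)
        viab = viability_curve(profile, drug, doses, background=bg)
        fits[label] = fit_4pl(doses, viab)
    return fits
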