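"""Parameter-sampled virtual-cell ensembles and fold-change summaries.

Cell-to-cell heterogeneity is modelled as multiplicative log-normal jitter on
protein synthesis and degradation rates (expression-level variability), not
on binding affinities, which are treated as biophysical constants shared by
all cells.  The default ensemble size of 25 matches the simulation protocol
the scenarios were designed for.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .model import (IntegrationError, ModelParameters, Trajectory,
                    ValidationError, simulate, steady_state)

__all__ = [
    "SAMPLED_RATES", "EnsembleResult", "FoldChangeSummary", "READOUTS",
    "sample_cells", "run_ensemble", "fold_change", "ensemble_summary",
]

#: rates jittered between virtual cells: all synthesis and degradation,
#: never binding constants or transport
SAMPLED_RATES: tuple[str, ...] = (
    "k_syn_A", "k_syn_C", "k_syn_RelB", "k_syn_NIK",
    "k0_Ia", "k0_Ie", "k0_p100", "g_Ia", "g_Ie", "g_p100",
    "k_deg_A", "k_deg_C", "k_deg_RelB", "k_deg_Bnuc", "k_deg_NIK",
    "d0_Ia", "d0_Ie", "d0_Id", "d_ikk_Ia", "d_ikk_Ie",
)

DEFAULT_N_CELLS = 25
DEFAULT_CV = 0.15


def sample_cells(base: ModelParameters, n: int = DEFAULT_N_CELLS,
                 cv: float = DEFAULT_CV, seed: int = 0) -> list[ModelParameters]:
    """Draw ``n`` virtual cells around ``base``.

    Each sampled rate is multiplied by an independent log-normal factor with
    median 1 and log-sd ``cv``; ``cv=0`` returns identical copies.
    Deterministic for a given ``seed``.
    """
    if n < 1:
        raise ValidationError("ensemble size must be >= 1")
    if cv < 0:
        raise ValidationError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    cells = []
    for _ in range(n):
        factors = np.exp(rng.normal(0.0, cv, size=len(SAMPLED_RATES)))
        cells.append(replace(base, **{
            name: getattr(base, name) * f
            for name, f in zip(SAMPLED_RATES, factors)
        }))
    return cells


@dataclass
class EnsembleResult:
    """Per-cell parameters and trajectories for one scenario run."""

    cells: list[ModelParameters]
    trajectories: list[Trajectory]
    scenario: str = ""
    seed: int | None = None
    errors: dict[int, str] | None = None

    @property
    def n(self) -> int:
        return len(self.cells)

    @property
    def times(self) -> np.ndarray:
        return self.trajectories[0].times

    def stack(self, species: str) -> np.ndarray:
        """(n_cells, n_times) array of one species across the ensemble."""
        return np.stack([tr[species] for tr in self.trajectories])

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-cell export (cell_id, time, species, value, scenario)."""
        return pd.concat(
            [tr.to_frame(cell_id=f"cell{str(i).zfill(3)}")
             for i, tr in enumerate(self.trajectories)],
            ignore_index=True,
        )


def run_ensemble(cells: list[ModelParameters], stimulus=None,
                 duration: float = 1440.0, scenario: str = "",
                 from_steady_state: bool = True, seed: int | None = None,
                 n_out: int = 97) -> EnsembleResult:
    """Simulate every cell on a common time grid.

    Each cell starts from its own unstimulated steady state (so t = 0 is the
    monoculture baseline) unless ``from_steady_state`` is False, in which
    case the zero state is used.  Integration failures are collected per
    cell and reported together, never silently dropped.
    """
    if not cells:
        raise ValidationError("ensemble needs at least one cell")
    trajectories: list[Trajectory] = []
    errors: dict[int, str] = {}
    for i, cell in enumerate(cells):
        try:
            y0 = steady_state(cell) if from_steady_state else None
            traj = simulate(cell, y0 if y0 is not None else
                            np.zeros(16), duration=duration,
                            stimulus=stimulus, scenario=scenario, n_out=n_out)
            trajectories.append(traj)
        except Exception as exc:  # collected, never silently dropped
            errors[i] = str(exc)
    if errors:
        raise IntegrationError(
            f"{len(errors)}/{len(cells)} cells failed: {errors}", float("nan"))
    return EnsembleResult(cells=list(cells), trajectories=trajectories,
                          scenario=scenario, seed=seed, errors=None)


def ensemble_summary(result: EnsembleResult) -> pd.DataFrame:
    """Mean and standard deviation over cells per (time, species)."""
    from .model import SPECIES

    rows = []
    for sp in SPECIES:
        mat = result.stack(sp)
        rows.append(pd.DataFrame({
            "time": result.times, "species": sp,
            "mean": mat.mean(axis=0), "sd": mat.std(axis=0, ddof=1) if
            result.n > 1 else np.zeros(mat.shape[1]),
        }))
    df = pd.concat(rows, ignore_index=True)
    df["scenario"] = result.scenario
    return df


# ---------------------------------------------------------------------------
# fold changes
# ---------------------------------------------------------------------------

#: supported readouts: (species to sum, time point) — "ss" = t=0 baseline,
#: "end" = final time point
READOUTS: dict[str, tuple[tuple[str, ...], str]] = {
    "nuclear_RelA": (("A_nuc",), "ss"),
    "nuclear_cRel": (("C_nuc",), "ss"),
    "nuclear_RelB": (("B_nuc",), "ss"),
    "total_RelA": (("A_cyt", "A_nuc", "IkBa_A", "IkBe_A", "Id_A"), "ss"),
    "total_cRel": (("C_cyt", "C_nuc", "IkBa_C", "IkBe_C", "Id_C"), "ss"),
    "nuclear_RelA_end": (("A_nuc",), "end"),
    "nuclear_cRel_end": (("C_nuc",), "end"),
    "nuclear_RelB_end": (("B_nuc",), "end"),
}


def _readout_values(result: EnsembleResult, readout: str) -> np.ndarray:
    try:
        species, when = READOUTS[readout]
    except KeyError:
        raise ValidationError(
            f"unknown readout {readout!r}; available: {sorted(READOUTS)}"
        ) from None
    i = 0 if when == "ss" else -1
    vals = np.zeros(result.n)
    for sp in species:
        vals += result.stack(sp)[:, i]
    return vals


@dataclass
class FoldChangeSummary:
    """Per-cell fold changes of one readout against a reference ensemble mean."""

    readout: str
    folds: np.ndarray
    mean: float
    sd: float
    n: int


def fold_change(perturbed: EnsembleResult, reference: EnsembleResult,
                readout: str) -> FoldChangeSummary:
    """Fold change of ``readout`` per perturbed cell vs the reference mean.

    The denominator is the reference-ensemble mean (populations are
    unpaired); applying an ensemble to itself therefore gives folds whose
    mean is exactly 1.
    """
    if perturbed.n != reference.n:
        raise ValidationError("ensembles must have the same number of cells")
    if not np.allclose(perturbed.times, reference.times):
        raise ValidationError("ensembles must share the time grid")
    ref_mean = float(np.mean(_readout_values(reference, readout)))
    if ref_mean == 0:
        raise ValidationError(f"reference mean of {readout!r} is zero")
    folds = _readout_values(perturbed, readout) / ref_mean
    sd = float(np.std(folds, ddof=1)) if len(folds) > 1 else 0.0
    return FoldChangeSummary(readout=readout, folds=folds,
                             mean=float(np.mean(folds)), sd=sd, n=len(folds))
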