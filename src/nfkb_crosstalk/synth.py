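"""Synthetic data generators with planted ground truth.

Every generator is deterministic given its seed and returns a ground-truth
sidecar (a plain dict, JSON-serialisable) alongside the data, so estimator
tests read truth only from sidecars, never from the estimators themselves.
Intensity-like quantities (fluorescence, N:C ratios) are log-normal, the
standard distributional shape for cytometry and immunofluorescence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bcl2 import four_pl
from .model import ValidationError
from .quantify import FlowSample, PeakRecord, TssRecord

__all__ = [
    "FlowSpec", "DoseResponseSpec",
    "gen_flow_sample", "gen_dose_response", "gen_nc_ratios", "gen_chip_peaks",
]


@dataclass(frozen=True)
class FlowSpec:
    """One marker's synthetic flow sample: log-normal mixture + autofluorescence.

    ``log10_medians``/``log10_sds`` give one entry per population (clone);
    ``weights`` are the mixture proportions.  The matched unstained control
    draws from the autofluorescence floor alone.
    """

    marker: str
    log10_medians: tuple = (3.0,)
    log10_sds: tuple = (0.25,)
    weights: tuple = (1.0,)
    n: int = 5000
    autofluor_log10_median: float = 2.0
    autofluor_log10_sd: float = 0.15
    seed: int = 0
    sample_id: str = "synthetic"

    def __post_init__(self):
        if self.n < 1:
            raise ValidationError("n must be >= 1")
        if len(self.log10_medians) != len(self.weights) or \
                len(self.log10_sds) != len(self.weights):
            raise ValidationError("per-population fields must align")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValidationError("mixture weights must sum to 1")
        if any(s <= 0 for s in self.log10_sds):
            raise ValidationError("log10 sds must be > 0")


def gen_flow_sample(spec: FlowSpec) -> tuple[FlowSample, FlowSample, dict]:
    """Draw (stained, unstained, truth) for one marker.

    Stained values are a weighted log-normal mixture on top of (added to)
    the autofluorescence floor; the truth sidecar records the planted
    per-population medians and assignments summary.
    """
    rng = np.random.default_rng(spec.seed)
    pops = rng.choice(len(spec.weights), size=spec.n, p=np.asarray(spec.weights))
    log_mu = np.asarray(spec.log10_medians)[pops]
    log_sd = np.asarray(spec.log10_sds)[pops]
    signal = 10 ** rng.normal(log_mu, log_sd)
    autofluor = 10 ** rng.normal(spec.autofluor_log10_median,
                                 spec.autofluor_log10_sd, size=spec.n)
    stained = FlowSample(sample_id=spec.sample_id, marker=spec.marker,
                         values=signal + autofluor)
    unstained_vals = 10 ** rng.normal(spec.autofluor_log10_median,
                                      spec.autofluor_log10_sd, size=spec.n)
    unstained = FlowSample(sample_id=f"{spec.sample_id}_unstained",
                           marker=spec.marker, values=unstained_vals)
    truth = {
        "marker": spec.marker,
        "population_medians": [10 ** m for m in spec.log10_medians],
        "weights": list(spec.weights),
        "autofluor_median": 10 ** spec.autofluor_log10_median,
        "population_counts": np.bincount(
            pops, minlength=len(spec.weights)).tolist(),
        "seed": spec.seed,
    }
    return stained, unstained, truth


@dataclass(frozen=True)
class DoseResponseSpec:
    """Synthetic viability assay: a true 4PL plus Gaussian replicate noise."""

    bottom: float = 0.05
    top: float = 1.0
    hill: float = 2.0
    lc50: float = 0.5
    doses: tuple = tuple(float(d) for d in np.logspace(-4, 2, 9))
    replicates: int = 3
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        d = np.asarray(self.doses)
        if np.any(d <= 0) or np.any(np.diff(d) <= 0):
            raise ValidationError("doses must be positive and ascending")
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        if self.lc50 <= 0:
            raise ValidationError("lc50 must be > 0")


def gen_dose_response(spec: DoseResponseSpec) -> tuple[pd.DataFrame, dict]:
    """Viability table (dose, replicate, viability) plus truth sidecar.

    Viability is the true 4PL response plus N(0, noise_sd), clipped to
    [0, 1.05] to mimic assay readings slightly above the untreated control.
    """
    rng = np.random.default_rng(spec.seed)
    doses = np.repeat(spec.doses, spec.replicates)
    reps = np.tile(np.arange(spec.replicates), len(spec.doses))
    clean = four_pl(doses, spec.bottom, spec.top, spec.hill, spec.lc50)
    noisy = clean + rng.normal(0.0, spec.noise_sd, size=doses.size) \
        if spec.noise_sd > 0 else clean
    table = pd.DataFrame({
        "dose": doses, "replicate": reps,
        "viability": np.clip(noisy, 0.0, 1.05),
    })
    truth = {"bottom": spec.bottom, "top": spec.top, "hill": spec.hill,
             "lc50": spec.lc50, "noise_sd": spec.noise_sd, "seed": spec.seed}
    return table, truth


def gen_nc_ratios(populations: dict, n: int = 2000,
                  seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Per-cell nuclear:cytoplasmic ratio table for named populations.

    ``populations`` maps sample name to ``(median, log10_sd)`` or
    ``(median, log10_sd, shift)``; the planted co-culture shift multiplies
    the median (shift 1.0 = identity).  Returns a tidy table
    (sample, cell_id, nc_ratio) and the truth sidecar of effective medians.
    """
    rng = np.random.default_rng(seed)
    frames = []
    truth_medians: dict[str, float] = {}
    for name, spec in populations.items():
        median, log_sd = spec[0], spec[1]
        shift = spec[2] if len(spec) > 2 else 1.0
        if median <= 0 or shift <= 0:
            raise ValidationError("medians and shifts must be > 0")
        eff = median * shift
        vals = 10 ** rng.normal(np.log10(eff), log_sd, size=n)
        frames.append(pd.DataFrame({
            "sample": name,
            "cell_id": [f"{name}_{i}" for i in range(n)],
            "nc_ratio": vals,
        }))
        truth_medians[name] = eff
    table = pd.concat(frames, ignore_index=True)
    return table, {"medians": truth_medians, "n_per_sample": n, "seed": seed}


def gen_chip_peaks(n_in_window: int, n_out: int, tss_position: int = 100_000,
                   half_window: int = 1000, score_mean: float = 100.0,
                   score_sd: float = 20.0, n_outlier_scores: int = 0,
                   outlier_sd_multiple: float = 8.0, subunit: str = "cRel",
                   chrom: str = "chr1", peak_width: int = 200,
                   seed: int = 0) -> tuple[list[PeakRecord], TssRecord, dict]:
    """ChIP peak set with a known number of peaks inside a TSS window.

    In-window peaks start uniformly inside ±``half_window`` of the TSS
    (width-clipped so the whole peak overlaps); out-of-window peaks are
    placed strictly beyond the window on either side.  The last
    ``n_outlier_scores`` in-window peaks carry scores displaced by
    ``outlier_sd_multiple``·sd — planted outliers for ROUT tests.
    """
    if n_in_window < 0 or n_out < 0:
        raise ValidationError("counts must be >= 0")
    if n_outlier_scores > n_in_window:
        raise ValidationError("cannot plant more outliers than in-window peaks")
    rng = np.random.default_rng(seed)
    tss = TssRecord(gene="MCL1", chrom=chrom, position=tss_position)
    peaks: list[PeakRecord] = []
    win_lo = tss_position - half_window
    win_hi = tss_position + half_window  # inclusive last in-window base

    def score(i):
        base = abs(rng.normal(score_mean, score_sd)) + 1e-6
        if i >= n_in_window - n_outlier_scores:
            base = score_mean + outlier_sd_multiple * score_sd
        return base

    for i in range(n_in_window):
        start = int(rng.integers(win_lo, win_hi + 1))
        peaks.append(PeakRecord(chrom, start, start + peak_width,
                                score(i), subunit=subunit, dataset=f"in{i}"))
    for j in range(n_out):
        if rng.random() < 0.5:
            end = int(rng.integers(max(win_lo - 50_000, 0), win_lo))
            start = max(end - peak_width, 0)
        else:
            start = int(rng.integers(win_hi + 1, win_hi + 50_000))
            end = start + peak_width
        if start >= end:
            start, end = end, end + peak_width
        peaks.append(PeakRecord(chrom, start, end, abs(rng.normal(
            score_mean, score_sd)) + 1e-6, subunit=subunit, dataset=f"out{j}"))
    truth = {"n_in_window": n_in_window, "n_out": n_out,
             "n_outlier_scores": n_outlier_scores, "seed": seed,
             "tss_position": tss_position, "half_window": half_window}
    return peaks, tss, truth
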