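"""Joint normalization of fold changes across experiments.

Systematic differences between the four (condition, replicate) experiments —
pipetting, loading, ionisation drift — distort the comparison of melting
profiles.  Normalization selects a set of well-behaved "melter" proteins
quantified everywhere, computes each experiment's median fold-change curve
over that set, fits the melting model to each median curve, and rescales
every experiment onto the best-fitting (reference) curve.  After
normalization the median curves of all experiments coincide with the
reference fitted curve, rescaled to equal 1 at the reference temperature so
FC(T_min) = 1 is preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curves import MeltingCurveFit, fit_melting_curve, model_value
from .design import ExperimentDesign

logger = logging.getLogger(__name__)

#: Per-temperature fold-change windows a protein must satisfy in every
#: experiment to enter the normalization set.  Positions mirror the published
#: 10-temperature defaults (mid-curve, late, last) transposed onto the
#: 7-point gradient; override via configuration.
DEFAULT_WINDOWS: dict[float, tuple[float, float]] = {
    52.0: (0.4, 0.6),
    62.0: (0.0, 0.3),
    67.0: (0.0, 0.2),
}


class EmptyNormalizationSetError(ValueError):
    """No protein satisfied the selection windows in every experiment."""


@dataclass(frozen=True)
class NormalizationFactors:
    """Multiplicative corrections, one per (experiment, temperature).

    ``factors`` is experiments x temperatures (experiment labels like
    ``vehicle_1``); the factor at T_min is 1.  ``reference`` names the
    experiment whose fitted median curve all others are scaled onto, and
    ``reference_curve`` holds that fitted curve (rescaled to 1 at T_min)
    evaluated at the gradient temperatures.
    """

    factors: pd.DataFrame
    reference: str
    reference_curve: np.ndarray
    median_fits: dict[str, MeltingCurveFit]


def _experiment_label(condition: str, replicate: int) -> str:
    return f"{condition}_{replicate}"


def select_normalization_set(
    fc: pd.DataFrame,
    design: ExperimentDesign,
    windows: dict[float, tuple[float, float]] | None = None,
) -> set[str]:
    """Proteins quantified in every experiment with in-window fold changes.

    A protein qualifies when it has a complete (no missing) profile in every
    experiment and its fold change lies inside the configured window at each
    window temperature, in every experiment.
    """
    windows = DEFAULT_WINDOWS if windows is None else windows
    temps = set(design.gradient.temps)
    unknown = [t for t in windows if t not in temps]
    if unknown:
        raise ValueError(f"window temperatures {unknown} not in the gradient")

    keep = pd.Series(True, index=fc.index)
    for cond, rep in design.experiments():
        labels = design.experiment_labels(cond, rep)
        block = fc[labels]
        keep &= block.notna().all(axis=1)
        for t, (lo, hi) in windows.items():
            col = fc[design.sample_label(cond, rep, t)]
            keep &= (col >= lo) & (col <= hi)
    selected = set(fc.index[keep.fillna(False)])
    logger.info(
        "normalization set: %d of %d proteins selected", len(selected), len(fc)
    )
    if not selected:
        raise EmptyNormalizationSetError(
            "no protein passed the normalization windows in all experiments; "
            "relax the per-temperature windows"
        )
    return selected


def compute_correction_factors(
    fc: pd.DataFrame,
    design: ExperimentDesign,
    norm_set: set[str],
) -> NormalizationFactors:
    """Fit each experiment's median curve; scale all onto the best fit.

    The experiment with the highest median-curve R² is the reference (ties
    broken by lexicographic experiment label; non-converged fits fall back to
    the next-best R²).  With g(T) the reference fitted curve divided by its
    own value at T_min, the factor is g(T) / median(e, T), which is exactly 1
    at T_min because every median fold change there is 1.
    """
    if not norm_set:
        raise EmptyNormalizationSetError("normalization set is empty")
    temps = design.gradient.as_array()
    sub = fc.loc[sorted(norm_set)]

    medians: dict[str, np.ndarray] = {}
    fits: dict[str, MeltingCurveFit] = {}
    for cond, rep in design.experiments():
        label = _experiment_label(cond, rep)
        med = sub[design.experiment_labels(cond, rep)].median(axis=0).to_numpy()
        medians[label] = med
        fits[label] = fit_melting_curve(med, design.gradient)

    ranked = sorted(
        fits.items(),
        key=lambda kv: (-(kv[1].r_squared if kv[1].converged else -np.inf), kv[0]),
    )
    reference = None
    for label, fit in ranked:
        if fit.converged:
            reference = label
            break
    if reference is None:
        raise RuntimeError("median melting-curve fit failed for every experiment")

    ref_fit = fits[reference]
    curve = model_value(temps, ref_fit.a, ref_fit.b, ref_fit.plateau)
    curve = curve / curve[0]  # pin the reference curve to 1 at T_min

    rows = {}
    for label, med in medians.items():
        with np.errstate(divide="ignore", invalid="ignore"):
            factors = curve / med
        factors[0] = 1.0
        if np.any(~np.isfinite(factors)) or np.any(factors <= 0):
            raise RuntimeError(
                f"non-positive or undefined correction factor for {label}; "
                "normalization set medians must be positive"
            )
        rows[label] = factors
    table = pd.DataFrame.from_dict(rows, orient="index", columns=list(temps))
    table.index.name = "experiment"
    return NormalizationFactors(
        factors=table,
        reference=reference,
        reference_curve=curve,
        median_fits=fits,
    )


def apply_normalization(
    fc: pd.DataFrame,
    factors: NormalizationFactors,
    design: ExperimentDesign,
) -> pd.DataFrame:
    """Multiply each experiment's fold changes by its per-temperature factors.

    Missing values stay missing; FC(T_min) is preserved (factor there is 1).
    """
    out = fc.copy()
    for cond, rep in design.experiments():
        label = _experiment_label(cond, rep)
        row = factors.factors.loc[label].to_numpy()
        cols = design.experiment_labels(cond, rep)
        out[cols] = fc[cols].to_numpy() * row[None, :]
    return out


def write_factors_table(factors: NormalizationFactors, path) -> None:
    factors.factors.to_csv(path, sep="\t", float_format="%.10g")
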