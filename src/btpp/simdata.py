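"""Synthetic thermal-profiling experiments with known ground truth.

The generator emulates the data a label-free thermal proteome profiling (TPP)
run produces: per-protein soluble abundance across a temperature ladder, two
conditions (vehicle vs compound), replicated, with multiplicative measurement
noise and missing values.  Two modes are supported:

* ``bTPP`` — the microsomal fraction was removed before the thermal shift
  assay: every protein follows a clean sigmoid, and compound-treated target
  proteins melt at Tm + dTm.
* ``TPP`` — the soluble fraction still contains microsomal vesicles.  A
  per-protein ``vesicle_fraction`` of the signal sits in vesicles whose
  co-sedimentation *decreases* with temperature (smaller vesicles at higher
  temperature escape the 20-minute spin), so the observed signal is the
  convex mixture ``(1 - vf) * f(T) + vf * carryover(T)`` with carryover(T)
  increasing in T.  In addition the membrane pool sequesters part of the
  compound, attenuating the effective thermal shift of targets by a factor
  ``(1 - sequestration)``.

Ground-truth melting curves are parameterised by melting point, lower plateau
and the curve's slope at Tm; the model constants (a, b) are solved from
those, which keeps every simulated curve steep enough to pass the
steepest-slope quality criterion by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .curves import model_value
from .design import ExperimentDesign, TemperatureGradient

MODE_BTPP = "bTPP"
MODE_TPP = "TPP"

GROUND_TRUTH_COLUMNS = [
    "accession",
    "a_true",
    "b_true",
    "plateau_true",
    "tm_true",
    "dtm_true",
    "vesicle_fraction",
    "is_target",
    "baseline",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic thermal-profiling study.

    Defaults mirror the replicated 7-temperature, two-condition design:
    2 biological replicates, 10% of proteins are compound targets with a
    stabilising shift of 2-6 °C, 5% multiplicative noise (typical label-free
    MS1 precision), 5% missing measurements.
    """

    n_proteins: int = 1000
    n_replicates: int = 2
    target_fraction: float = 0.1
    dtm_range: tuple[float, float] = (2.0, 6.0)
    noise_cv: float = 0.05
    missing_rate: float = 0.05
    mode: str = MODE_BTPP
    sediment_t50: float = 70.0
    sediment_width: float = 5.0
    sequestration: float = 0.5
    vesicle_fraction_range: tuple[float, float] = (0.2, 0.8)
    steepness_range: tuple[float, float] = (0.065, 0.13)
    tm_mean: float = 50.0
    tm_sd: float = 4.0
    plateau_max: float = 0.25
    baseline_log10_mean: float = 6.0
    baseline_log10_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not 0.0 <= self.target_fraction <= 1.0:
            raise ValueError("target_fraction must lie in [0, 1]")
        if self.dtm_range[0] <= 0 or self.dtm_range[1] < self.dtm_range[0]:
            raise ValueError("dtm_range must be 0 < low <= high")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.mode not in (MODE_BTPP, MODE_TPP):
            raise ValueError(f"mode must be {MODE_BTPP!r} or {MODE_TPP!r}")
        if not 0.0 <= self.sequestration < 1.0:
            raise ValueError("sequestration must lie in [0, 1)")
        lo, hi = self.vesicle_fraction_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("vesicle_fraction_range must lie in [0, 1]")
        if not (0.0 < self.plateau_max < 0.5):
            raise ValueError("plateau_max must lie in (0, 0.5) so Tm is defined")
        if self.steepness_range[0] <= 0:
            raise ValueError("steepness_range must be positive")


def carryover(T, sediment_t50: float, width: float):
    """Fraction of vesicular material escaping sedimentation at temperature T.

    Monotone increasing logistic 1 - 1/(1 + exp((T - T50)/w)): at high
    temperature vesicles are smaller and stay in the supernatant.
    """
    T = np.asarray(T, dtype=float)
    out = 1.0 - 1.0 / (1.0 + np.exp((T - sediment_t50) / width))
    return out if out.ndim else float(out)


def _offset_for(plateau: np.ndarray | float) -> np.ndarray | float:
    # b = a/Tm + offset makes f cross 0.5 exactly at Tm
    return np.log(0.5 / (0.5 - plateau))


def _solve_b(a, tm, plateau):
    return a / tm + _offset_for(plateau)


def draw_ground_truth(
    config: SimulationConfig,
    gradient: TemperatureGradient | None = None,
) -> pd.DataFrame:
    """Draw the true melting proteome for one simulated study.

    Returns one row per protein with columns ``GROUND_TRUTH_COLUMNS``.
    Melting points are drawn Normal(tm_mean, tm_sd) and resampled until they
    fall inside the gradient span; plateaus Uniform(0, plateau_max).  The
    steepness constant ``a`` is solved from a drawn at-Tm slope magnitude
    (Uniform over ``steepness_range``), so every true curve clears the -0.06
    steepest-slope criterion.  Exactly round(n_proteins * target_fraction)
    proteins are targets with dTm drawn Uniform over ``dtm_range``.
    """
    gradient = gradient or TemperatureGradient()
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_proteins

    tm = rng.normal(config.tm_mean, config.tm_sd, n)
    lo, hi = gradient.span
    bad = (tm < lo) | (tm > hi)
    while bad.any():
        tm[bad] = rng.normal(config.tm_mean, config.tm_sd, int(bad.sum()))
        bad = (tm < lo) | (tm > hi)

    plateau = rng.uniform(0.0, config.plateau_max, n)
    slope_at_tm = rng.uniform(*config.steepness_range, n)
    # |df/dT| at Tm = (a / Tm^2) * 0.5 * (0.5 - p) / (1 - p), solved for a
    a = 2.0 * slope_at_tm * tm**2 * (1.0 - plateau) / (0.5 - plateau)
    b = _solve_b(a, tm, plateau)

    n_targets = round(n * config.target_fraction)
    is_target = np.zeros(n, dtype=bool)
    if n_targets:
        is_target[rng.choice(n, size=n_targets, replace=False)] = True
    dtm = np.zeros(n)
    dtm[is_target] = rng.uniform(*config.dtm_range, n_targets)

    # Always consume the draw so bTPP/TPP runs of the same seed share every
    # other ground-truth column; bTPP removes the vesicles (vf = 0).
    vf = rng.uniform(*config.vesicle_fraction_range, n)
    if config.mode == MODE_BTPP:
        vf = np.zeros(n)

    baseline = 10.0 ** rng.normal(
        config.baseline_log10_mean, config.baseline_log10_sd, n
    )

    return pd.DataFrame(
        {
            "accession": [f"SIM{i:05d}" for i in range(n)],
            "a_true": a,
            "b_true": b,
            "plateau_true": plateau,
            "tm_true": tm,
            "dtm_true": dtm,
            "vesicle_fraction": vf,
            "is_target": is_target,
            "baseline": baseline,
        }
    )


def effective_dtm(truth: pd.DataFrame, config: SimulationConfig) -> np.ndarray:
    """Thermal shift actually expressed under the compound condition.

    In TPP mode membrane sequestration lowers the free compound concentration
    and attenuates the shift by (1 - sequestration); bTPP expresses the full
    shift.
    """
    dtm = truth["dtm_true"].to_numpy(dtype=float)
    if config.mode == MODE_TPP:
        return dtm * (1.0 - config.sequestration)
    return dtm


def expected_profile_matrix(
    truth: pd.DataFrame,
    gradient: TemperatureGradient,
    config: SimulationConfig,
    condition: str = "vehicle",
) -> np.ndarray:
    """Noise-free expected signal, proteins x temperatures, for one condition.

    This is the generator's own mean formula — usable as an analytic oracle
    for qualitative properties such as the non-monotone aggregate signal of
    the TPP confound.
    """
    temps = gradient.as_array()
    a = truth["a_true"].to_numpy(dtype=float)[:, None]
    plateau = truth["plateau_true"].to_numpy(dtype=float)[:, None]
    tm = truth["tm_true"].to_numpy(dtype=float)[:, None]
    baseline = truth["baseline"].to_numpy(dtype=float)[:, None]
    vf = truth["vesicle_fraction"].to_numpy(dtype=float)[:, None]

    if condition == "vehicle":
        tm_eff = tm
    else:
        tm_eff = tm + effective_dtm(truth, config)[:, None]
    b = _solve_b(a, tm_eff, plateau)
    f = model_value(temps[None, :], a, b, plateau)
    co = carryover(temps, config.sediment_t50, config.sediment_width)[None, :]
    return baseline * ((1.0 - vf) * f + vf * co)


def simulate_experiment(
    truth: pd.DataFrame,
    gradient: TemperatureGradient,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, ExperimentDesign]:
    """Generate the raw abundance matrix for a full two-condition study.

    Returns ``(abundance, design)``: a proteins x samples table of raw
    soluble signals (NaN where the measurement dropped out) and the design
    describing its columns.  Signals are the expected mixture profile times
    mean-one log-normal noise with coefficient of variation ``noise_cv``.
    Identical truth/config/seed give byte-identical output.
    """
    if config.mode == MODE_BTPP and (truth["vesicle_fraction"] != 0).any():
        raise ValueError("bTPP-mode simulation requires vesicle_fraction == 0")
    design = ExperimentDesign(
        gradient=gradient, replicates=tuple(range(1, config.n_replicates + 1))
    )
    rng = np.random.default_rng([config.seed, 1])
    n = len(truth)
    n_t = len(gradient)
    sigma = math.sqrt(math.log(1.0 + config.noise_cv**2))

    expected = {
        cond: expected_profile_matrix(truth, gradient, config, condition=role)
        for cond, role in ((design.vehicle, "vehicle"), (design.treatment, "compound"))
    }

    columns: dict[str, np.ndarray] = {}
    for cond, rep in design.experiments():
        signal = expected[cond].copy()
        if sigma > 0:
            noise = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=(n, n_t)))
            signal = signal * noise
        if config.missing_rate > 0:
            drop = rng.random(size=(n, n_t)) < config.missing_rate
            signal = np.where(drop, np.nan, signal)
        for j, t in enumerate(gradient):
            columns[design.sample_label(cond, rep, t)] = signal[:, j]

    abundance = pd.DataFrame(columns, index=pd.Index(truth["accession"], name="accession"))
    return abundance, design


def simulate_study(
    config: SimulationConfig,
    gradient: TemperatureGradient | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, ExperimentDesign]:
    """Convenience wrapper: draw truth, simulate, return (truth, abundance, design)."""
    gradient = gradient or TemperatureGradient()
    truth = draw_ground_truth(config, gradient)
    abundance, design = simulate_experiment(truth, gradient, config)
    return truth, abundance, design


def paired_mode_configs(config: SimulationConfig) -> tuple[SimulationConfig, SimulationConfig]:
    """The same study in bTPP and TPP mode (identical seed and truth draws
    apart from the vesicle fractions, which bTPP forces to zero)."""
    return (
        replace(config, mode=MODE_BTPP),
        replace(config, mode=MODE_TPP),
    )


def write_ground_truth(truth: pd.DataFrame, path) -> None:
    """Tab-delimited ground-truth sidecar for recovery tests."""
    truth.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_ground_truth(path) -> pd.DataFrame:
    truth = pd.read_csv(path, sep="\t")
    missing = set(GROUND_TRUTH_COLUMNS).difference(truth.columns)
    if missing:
        raise ValueError(f"ground-truth table missing columns {sorted(missing)}")
    truth["is_target"] = truth["is_target"].astype(bool)
    for col in GROUND_TRUTH_COLUMNS:
        if col not in ("accession", "is_target"):
            truth[col] = truth[col].astype(float)
    return truth
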