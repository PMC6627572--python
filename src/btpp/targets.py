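"""Target calling: quality criteria and NPARC significance testing.

A protein is a candidate target when its four fitted melting curves (2
conditions x 2 biological replicates) satisfy all quality criteria:

(i)   both conditions' curves fit with R² > 0.8 in each replicate;
(ii)  the vehicle curve's plateau is < 0.3 in each replicate;
(iii) the treatment-minus-vehicle Tm shift of each replicate shares a sign
      and exceeds, in magnitude, the Tm difference between the two vehicle
      runs (the shift must beat the vehicle-vehicle reproducibility);
(iv)  in each replicate at least one curve of the vehicle/treatment pair has
      a steepest slope below -0.06 per °C.

All comparisons are strict.  NPARC (nonparametric analysis of response
curves) compares a single shared melting curve fitted to both conditions
(null) against one curve per condition (alternative), replicates pooled
within condition, via the residual sums of squares.  The p-value comes
either from the theoretical F distribution or — the default, since the F
approximation is rough for nested nonlinear fits — from a permutation null
in which condition labels are shuffled within each temperature.

``is_target`` reflects the quality criteria alone (the published tables list
every criteria-passing protein); ``passes_significance`` additionally
requires NPARC p < alpha (the starred subset).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .curves import (
    DEFAULT_EXTRAPOLATION,
    DEFAULT_MIN_POINTS,
    MeltingCurveFit,
    batch_fit_melting_curves,
    fit_melting_curve,
)
from .design import ExperimentDesign

N_MODEL_PARAMS = 3  # (a, b, plateau)


@dataclass(frozen=True)
class AnalysisThresholds:
    """Quality-criteria and significance thresholds (all strict)."""

    r2_min: float = 0.8
    vehicle_plateau_max: float = 0.3
    slope_max: float = -0.06
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.r2_min < 1.0:
            raise ValueError("r2_min must lie in (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class NparcResult:
    """Shared-vs-separate melting-curve comparison for one protein."""

    rss_null: float
    rss_alt: float
    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    method: str
    converged: bool = True


@dataclass(frozen=True)
class TargetRecord:
    """Per-protein verdict mirroring one row of the published target tables."""

    accession: str
    protein_name: str
    tm_vehicle_1: float
    tm_treatment_1: float
    tm_vehicle_2: float
    tm_treatment_2: float
    dtm_1: float
    dtm_2: float
    pass_fit_quality: bool
    pass_vehicle_plateau: bool
    pass_shift_consistency: bool
    pass_slope: bool
    nparc: NparcResult
    is_target: bool
    passes_significance: bool
    first_failed: str | None = None
    fits: tuple[MeltingCurveFit, ...] = field(default=(), repr=False)

    @property
    def p_value(self) -> float:
        return self.nparc.p_value


# ---------------------------------------------------------------------------
# Quality criteria
# ---------------------------------------------------------------------------

def criterion_fit_quality(
    fits: Sequence[MeltingCurveFit], thresholds: AnalysisThresholds
) -> bool:
    """(i) every curve converged with R² strictly above the threshold."""
    return all(f.converged and f.r_squared > thresholds.r2_min for f in fits)


def criterion_vehicle_plateau(
    vehicle_fits: Sequence[MeltingCurveFit], thresholds: AnalysisThresholds
) -> bool:
    """(ii) both vehicle plateaus strictly below the threshold."""
    return all(
        f.converged and f.plateau < thresholds.vehicle_plateau_max
        for f in vehicle_fits
    )


def criterion_shift_consistency(
    tm_vehicle_1: float | None,
    tm_treatment_1: float | None,
    tm_vehicle_2: float | None,
    tm_treatment_2: float | None,
) -> bool:
    """(iii) replicate shifts share a sign and each beats the vehicle spread.

    With dTm_r = Tm(treatment, r) - Tm(vehicle, r), require sign(dTm_1) ==
    sign(dTm_2) != 0 and min(|dTm_1|, |dTm_2|) > |Tm(vehicle,1) -
    Tm(vehicle,2)|.  Any undefined melting point fails.
    """
    tms = (tm_vehicle_1, tm_treatment_1, tm_vehicle_2, tm_treatment_2)
    if any(t is None or not math.isfinite(t) for t in tms):
        return False
    d1 = tm_treatment_1 - tm_vehicle_1
    d2 = tm_treatment_2 - tm_vehicle_2
    if d1 == 0 or d2 == 0 or (d1 > 0) != (d2 > 0):
        return False
    vehicle_diff = abs(tm_vehicle_1 - tm_vehicle_2)
    return min(abs(d1), abs(d2)) > vehicle_diff


def criterion_slope(
    replicate_pairs: Sequence[tuple[MeltingCurveFit, MeltingCurveFit]],
    thresholds: AnalysisThresholds,
) -> bool:
    """(iv) each vehicle/treatment pair has a curve steeper than the cutoff."""
    for veh, trt in replicate_pairs:
        slopes = [f.steepest_slope for f in (veh, trt) if f.converged]
        if not slopes or min(slopes) >= thresholds.slope_max:
            return False
    return True


# ---------------------------------------------------------------------------
# NPARC
# ---------------------------------------------------------------------------

def _pooled_layout(design: ExperimentDesign) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Slot layout for pooled fits: temperatures, vehicle mask, column order."""
    temps = []
    is_vehicle = []
    columns = []
    for cond, rep in design.experiments():
        for t in design.gradient:
            temps.append(t)
            is_vehicle.append(cond == design.vehicle)
            columns.append(design.sample_label(cond, rep, t))
    return np.asarray(temps, float), np.asarray(is_vehicle, bool), columns


def _permutation_masks(
    base_vehicle: np.ndarray,
    temps: np.ndarray,
    n_proteins: int,
    n_permutations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Condition labels shuffled within each temperature.

    Returns a boolean array (proteins, permutations, slots) marking which
    slots are labelled vehicle in each permutation; the label multiset at
    every temperature is preserved.
    """
    m = base_vehicle.size
    out = np.empty((n_proteins, n_permutations, m), dtype=bool)
    for t in np.unique(temps):
        idx = np.nonzero(temps == t)[0]
        block = np.broadcast_to(
            base_vehicle[idx], (n_proteins, n_permutations, idx.size)
        ).copy()
        out[:, :, idx] = rng.permuted(block, axis=2)
    return out


def _amplitude_corrected(
    Y: np.ndarray, temps: np.ndarray, n_experiments: int, n_iter: int = 4
) -> np.ndarray:
    """Divide out each experiment's shared multiplicative scale factor.

    Ratio-based fold changes inherit the reference measurement's noise: every
    FC of one experiment shares the factor 1/eps(T_min), so points within an
    experiment are correlated.  Left uncorrected this correlation makes any
    point-level resampling of condition labels anti-conservative, because the
    observed condition grouping aligns with it.  The scale of each experiment
    is estimated against a shared curve fitted to all points — a
    label-independent preprocessing step applied once per protein — and
    divided out of the non-reference points, leaving residual noise
    approximately independent across points.  The reference points (exactly 1
    by construction, noise-free) are left untouched.
    """
    P, m = Y.shape
    n_t = m // n_experiments
    Y3 = Y.reshape(P, n_experiments, n_t)
    finite3 = np.isfinite(Y3)
    informative = finite3.copy()
    informative[:, :, 0] = False  # reference points carry no information
    scales = np.ones((P, n_experiments))
    out3 = Y3.copy()
    for _ in range(n_iter):
        flat = out3.reshape(P, m)
        params, _, ok = batch_fit_melting_curves(temps, flat)
        u = params[:, 0:1] / temps[:n_t][None, :] - params[:, 1:2]
        ghat = (1.0 - params[:, 2:3]) / (1.0 + np.exp(-u)) + params[:, 2:3]
        g3 = ghat[:, None, :]  # (P, 1, n_t) shared curve per protein
        num = np.where(informative, np.where(finite3, Y3, 0.0) * g3, 0.0).sum(axis=2)
        den = np.where(informative, g3 * g3 * 1.0, 0.0).sum(axis=2)
        ratio = np.divide(num, den, out=np.ones_like(num), where=den > 0)
        new_scales = np.where((den > 0) & ok[:, None], ratio, 1.0)
        new_scales = np.clip(new_scales, 0.2, 5.0)
        scales = new_scales
        out3 = Y3.copy()
        nonref = np.ones(n_t, dtype=bool)
        nonref[0] = False
        out3[:, :, nonref] = Y3[:, :, nonref] / scales[:, :, None]
    return out3.reshape(P, m)


def _f_and_p_theoretical(rss_null, rss_alt, n_points):
    df_num = N_MODEL_PARAMS
    df_den = n_points - 2 * N_MODEL_PARAMS
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = ((rss_null - rss_alt) / df_num) / (rss_alt / np.maximum(df_den, 1))
    f_stat = np.where((rss_alt == 0) & (rss_null == 0), 0.0, f_stat)
    f_stat = np.maximum(np.nan_to_num(f_stat, nan=0.0, posinf=np.inf), 0.0)
    p = np.where(
        df_den >= 1,
        stats.f.sf(f_stat, df_num, np.maximum(df_den, 1)),
        1.0,
    )
    p = np.where(f_stat == 0.0, 1.0, p)
    return f_stat, df_den, p


def nparc_batch(
    fc: pd.DataFrame,
    design: ExperimentDesign,
    method: str = "permutation",
    n_permutations: int = 1000,
    seed: int = 0,
    chunk_size: int = 48,
    amplitude_correction: bool = True,
) -> list[NparcResult]:
    """NPARC for every protein in a fold-change matrix at once.

    Null model: one melting curve over all points of both conditions
    (replicates pooled).  Alternative: one curve per condition.  All fits use
    the batched solver; alternative fits (observed and permuted alike)
    warm-start from the null fit's parameters, which guarantees
    rss_alt <= rss_null and keeps the permutation test symmetric.

    ``amplitude_correction`` removes each experiment's shared reference-ratio
    scale before testing (see :func:`_amplitude_corrected`); without it the
    test is anti-conservative on ratio-normalised fold changes.
    """
    if method not in ("permutation", "theoretical_f"):
        raise ValueError("method must be 'permutation' or 'theoretical_f'")
    temps, base_vehicle, columns = _pooled_layout(design)
    Y = fc[columns].to_numpy(dtype=float)
    P, m = Y.shape
    if amplitude_correction and P:
        Y = _amplitude_corrected(Y, temps, len(design.experiments()))
    finite = np.isfinite(Y)
    n_points = finite.sum(axis=1)

    # one shared curve per protein over all observed points
    null_params, rss_null, null_ok = batch_fit_melting_curves(temps, Y)

    def fit_conditions(
        vehicle_mask_3d: np.ndarray, base: int = 0
    ) -> tuple[np.ndarray, np.ndarray]:
        """Fit (vehicle, treatment) curves for each (protein, permutation).

        ``vehicle_mask_3d``: (Pn, Q, m) boolean for proteins
        ``base .. base+Pn``.  Returns rss_alt (Pn, Q) and per-problem
        convergence (Pn, Q).
        """
        Pn, Q, _ = vehicle_mask_3d.shape
        rss_alt = np.empty((Pn, Q))
        ok = np.empty((Pn, Q), dtype=bool)
        rows_per_chunk = max(1, chunk_size * 1000 // max(Q, 1))
        for start in range(0, Pn, rows_per_chunk):
            stop = min(start + rows_per_chunk, Pn)
            gsl = slice(base + start, base + stop)  # global protein indices
            pc = stop - start
            masks = vehicle_mask_3d[start:stop]  # (pc, Q, m)
            W = np.empty((pc, Q, 2, m))
            W[:, :, 0, :] = masks
            W[:, :, 1, :] = ~masks
            W *= finite[gsl, None, None, :]
            K = pc * Q * 2
            Yk = np.broadcast_to(Y[gsl][:, None, None, :], (pc, Q, 2, m)).reshape(K, m)
            x0 = np.broadcast_to(
                null_params[gsl][:, None, None, :], (pc, Q, 2, 3)
            ).reshape(K, 3)
            _, rss_k, ok_k = batch_fit_melting_curves(
                temps, Yk, weights=W.reshape(K, m), x0=x0
            )
            rss_pair = rss_k.reshape(pc, Q, 2)
            ok_pair = ok_k.reshape(pc, Q, 2)
            rss_alt[start:stop] = rss_pair.sum(axis=2)
            ok[start:stop] = ok_pair.all(axis=2)
        return rss_alt, ok

    observed_mask = np.broadcast_to(base_vehicle, (P, 1, m))
    rss_alt_obs, alt_ok = fit_conditions(observed_mask)
    rss_alt_obs = rss_alt_obs[:, 0]
    alt_ok = alt_ok[:, 0] & null_ok
    rss_alt_obs = np.minimum(rss_alt_obs, rss_null)  # nesting, guard rounding

    f_stat, df_den, p_theory = _f_and_p_theoretical(rss_null, rss_alt_obs, n_points)

    if method == "permutation":
        rng = np.random.default_rng([seed, 2])
        p_perm = np.ones(P)
        block = max(1, min(P, chunk_size))
        for start in range(0, P, block):
            stop = min(start + block, P)
            masks = _permutation_masks(
                base_vehicle, temps, stop - start, n_permutations, rng
            )
            rss_alt_perm, _ = fit_conditions(masks, base=start)
            # smaller alternative RSS <=> larger F at fixed null RSS
            count = (rss_alt_perm <= rss_alt_obs[start:stop, None]).sum(axis=1)
            p_perm[start:stop] = (1.0 + count) / (1.0 + n_permutations)
        p_used = p_perm
    else:
        p_used = p_theory

    results = []
    for i in range(P):
        ok = bool(alt_ok[i]) and df_den[i] >= 1
        results.append(
            NparcResult(
                rss_null=float(rss_null[i]),
                rss_alt=float(rss_alt_obs[i]),
                f_statistic=float(f_stat[i]),
                df_num=N_MODEL_PARAMS,
                df_den=int(df_den[i]),
                p_value=float(p_used[i]) if ok else 1.0,
                method=method,
                converged=ok,
            )
        )
    return results


def nparc_test(
    fc_profiles: pd.DataFrame | pd.Series,
    design: ExperimentDesign,
    method: str = "permutation",
    n_permutations: int = 1000,
    seed: int = 0,
) -> NparcResult:
    """NPARC for a single protein's normalized fold changes.

    ``fc_profiles`` is one row (Series or single-row DataFrame) indexed by
    sample label.
    """
    if isinstance(fc_profiles, pd.Series):
        fc_profiles = fc_profiles.to_frame().T
    return nparc_batch(
        fc_profiles,
        design,
        method=method,
        n_permutations=n_permutations,
        seed=seed,
    )[0]


# ---------------------------------------------------------------------------
# Target calling
# ---------------------------------------------------------------------------

def _tm_or_nan(fit: MeltingCurveFit) -> float:
    return fit.tm if (fit.converged and fit.tm is not None) else math.nan


def call_targets(
    fc: pd.DataFrame,
    design: ExperimentDesign,
    thresholds: AnalysisThresholds | None = None,
    protein_names: dict[str, str] | None = None,
    nparc_method: str = "permutation",
    n_permutations: int = 1000,
    seed: int = 0,
    min_points: int = DEFAULT_MIN_POINTS,
    extrapolation: float = DEFAULT_EXTRAPOLATION,
) -> list[TargetRecord]:
    """Fit four curves per protein, apply criteria (i)-(iv), run NPARC.

    Returns one record per protein, sorted by accession.  ``is_target``
    requires all four criteria; ``passes_significance`` additionally requires
    NPARC p < alpha.  Records carry the first failed criterion for the
    exclusion report.
    """
    thresholds = thresholds or AnalysisThresholds()
    if len(design.replicates) != 2:
        raise ValueError("target calling expects exactly two biological replicates")
    protein_names = protein_names or {}

    fc = fc.sort_index()
    nparc_results = nparc_batch(
        fc,
        design,
        method=nparc_method,
        n_permutations=n_permutations,
        seed=seed,
    )

    r1, r2 = design.replicates
    records: list[TargetRecord] = []
    for i, acc in enumerate(fc.index):
        row = fc.loc[acc]
        fits: dict[tuple[str, int], MeltingCurveFit] = {}
        for cond, rep in design.experiments():
            profile = row[design.experiment_labels(cond, rep)].to_numpy(dtype=float)
            fits[(cond, rep)] = fit_melting_curve(
                profile,
                design.gradient,
                min_points=min_points,
                extrapolation=extrapolation,
            )
        veh1 = fits[(design.vehicle, r1)]
        veh2 = fits[(design.vehicle, r2)]
        trt1 = fits[(design.treatment, r1)]
        trt2 = fits[(design.treatment, r2)]
        all_fits = (veh1, trt1, veh2, trt2)

        tm_v1, tm_t1 = _tm_or_nan(veh1), _tm_or_nan(trt1)
        tm_v2, tm_t2 = _tm_or_nan(veh2), _tm_or_nan(trt2)

        c1 = criterion_fit_quality(all_fits, thresholds)
        c2 = criterion_vehicle_plateau((veh1, veh2), thresholds)
        c3 = criterion_shift_consistency(tm_v1, tm_t1, tm_v2, tm_t2)
        c4 = criterion_slope(((veh1, trt1), (veh2, trt2)), thresholds)
        flags = {
            "fit_quality": c1,
            "vehicle_plateau": c2,
            "shift_consistency": c3,
            "slope": c4,
        }
        first_failed = next((k for k, v in flags.items() if not v), None)

        nparc = nparc_results[i]
        is_target = c1 and c2 and c3 and c4
        records.append(
            TargetRecord(
                accession=str(acc),
                protein_name=protein_names.get(acc, ""),
                tm_vehicle_1=tm_v1,
                tm_treatment_1=tm_t1,
                tm_vehicle_2=tm_v2,
                tm_treatment_2=tm_t2,
                dtm_1=tm_t1 - tm_v1,
                dtm_2=tm_t2 - tm_v2,
                pass_fit_quality=c1,
                pass_vehicle_plateau=c2,
                pass_shift_consistency=c3,
                pass_slope=c4,
                nparc=nparc,
                is_target=is_target,
                passes_significance=is_target and nparc.p_value < thresholds.alpha,
                first_failed=first_failed,
                fits=all_fits,
            )
        )
    records.sort(key=lambda r: r.accession)
    return records


def records_to_frame(records: Sequence[TargetRecord]) -> pd.DataFrame:
    """Flatten target records into the results-table layout.

    Includes a Benjamini-Hochberg adjusted p-value column for reporting;
    target calling itself uses the raw p-value threshold.
    """
    rows = []
    for r in records:
        rows.append(
            {
                "accession": r.accession,
                "protein_name": r.protein_name,
                "tm_control_1": r.tm_vehicle_1,
                "tm_treatment_1": r.tm_treatment_1,
                "tm_control_2": r.tm_vehicle_2,
                "tm_treatment_2": r.tm_treatment_2,
                "p_value": r.p_value,
                "pass_fit_quality": r.pass_fit_quality,
                "pass_vehicle_plateau": r.pass_vehicle_plateau,
                "pass_shift_consistency": r.pass_shift_consistency,
                "pass_slope": r.pass_slope,
                "is_target": r.is_target,
                "passes_significance": r.passes_significance,
                "first_failed": r.first_failed or "",
            }
        )
    frame = pd.DataFrame(rows)
    if len(frame):
        frame.insert(
            frame.columns.get_loc("p_value") + 1,
            "p_value_bh",
            benjamini_hochberg(frame["p_value"].to_numpy()),
        )
    return frame


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH-FDR adjusted p-values (reported alongside, never used for calling)."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out
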