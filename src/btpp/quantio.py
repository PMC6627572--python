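"""Tabular input/output and label-free quantification steps.

All files are UTF-8 tab-delimited with a single header line.  Sample columns
are named ``condition_replicate_temperature`` (e.g. ``vehicle_1_37``).
Protein abundances are the mean of the top three peptide MS1 areas per
(protein, sample); fold changes are relative to the lowest temperature of the
same (condition, replicate) experiment.
"""

from __future__ import annotations

from importlib import resources
from typing import Iterable

import numpy as np
import pandas as pd

from .design import ExperimentDesign, design_from_columns

RESULT_COLUMNS = [
    "accession",
    "protein_name",
    "tm_control_1",
    "tm_treatment_1",
    "tm_control_2",
    "tm_treatment_2",
    "p_value",
]


class TableFormatError(ValueError):
    """Raised for malformed input tables (bad header, duplicates, negatives)."""


def aggregate_top3(
    peptides: pd.DataFrame, return_counts: bool = False
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Protein abundance = mean of the three largest peptide MS1 areas.

    ``peptides`` needs columns ``peptide``, ``accession``, ``sample`` and
    ``area``.  With fewer than three quantified peptides the mean of those
    available is used; a protein with no quantified peptide in a sample is
    missing there.  ``return_counts=True`` additionally returns the number of
    peptides that contributed to each (protein, sample) mean so downstream
    steps can filter on it.
    """
    required = {"peptide", "accession", "sample", "area"}
    missing = required.difference(peptides.columns)
    if missing:
        raise TableFormatError(f"peptide table missing columns {sorted(missing)}")
    if peptides.empty:
        raise TableFormatError("peptide table is empty")
    areas = peptides["area"]
    neg = areas.dropna() < 0
    if neg.any():
        row = int(neg[neg].index[0])
        raise TableFormatError(f"negative MS1 area at row {row}")

    quantified = peptides.dropna(subset=["area"])

    def top3_mean(s: pd.Series) -> float:
        return float(s.nlargest(3).mean())

    grouped = quantified.groupby(["accession", "sample"])["area"]
    abundance = grouped.apply(top3_mean).unstack("sample")
    abundance.index.name = "accession"
    if not return_counts:
        return abundance
    counts = grouped.apply(lambda s: int(min(len(s), 3))).unstack("sample")
    return abundance, counts


def compute_fold_changes(
    abundance: pd.DataFrame, design: ExperimentDesign
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fold changes relative to T_min, per (condition, replicate) experiment.

    Returns ``(fc, exclusions)``.  ``fc`` has the same shape as ``abundance``
    with FC(T_min) = 1 exactly wherever defined.  A (protein, experiment)
    whose reference abundance is missing or zero is unusable: its fold
    changes are all NaN and one row is appended to ``exclusions``
    (accession, condition, replicate, reason).
    """
    fc = pd.DataFrame(
        np.nan, index=abundance.index, columns=abundance.columns, dtype=float
    )
    excluded: list[tuple[str, str, int, str]] = []
    t_min = design.gradient.t_min
    for cond, rep in design.experiments():
        labels = design.experiment_labels(cond, rep)
        ref_label = design.sample_label(cond, rep, t_min)
        block = abundance[labels].to_numpy(dtype=float)
        ref = abundance[ref_label].to_numpy(dtype=float)
        usable = np.isfinite(ref) & (ref > 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = block / ref[:, None]
        vals[~usable, :] = np.nan
        # the reference measurement defines itself: exactly 1
        ref_col = labels.index(ref_label)
        vals[usable, ref_col] = 1.0
        fc[labels] = vals
        for acc in abundance.index[~usable]:
            ref_val = abundance.at[acc, ref_label]
            reason = "reference_zero" if np.isfinite(ref_val) else "reference_missing"
            excluded.append((acc, cond, rep, reason))
    exclusions = pd.DataFrame(
        excluded, columns=["accession", "condition", "replicate", "reason"]
    )
    return fc, exclusions


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _check_sample_frame(df: pd.DataFrame, path, kind: str) -> None:
    dup = df.index.duplicated()
    if dup.any():
        # +2: header line plus 1-based numbering
        row = int(np.nonzero(dup)[0][0]) + 2
        raise TableFormatError(
            f"{path}: duplicate accession {df.index[dup][0]!r} at row {row}"
        )
    values = df.to_numpy(dtype=float)
    bad = np.nonzero(np.nan_to_num(values, nan=0.0) < 0)
    if bad[0].size:
        raise TableFormatError(
            f"{path}: negative {kind} value at row {int(bad[0][0]) + 2}"
        )


def read_abundance_table(path) -> tuple[pd.DataFrame, ExperimentDesign]:
    """Read a proteins x samples abundance (or fold-change) table.

    The first column must be ``accession``; every other column must be a
    well-formed sample label covering a complete two-condition design.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "accession":
        raise TableFormatError(
            f"{path}: first column must be 'accession', found {df.columns[0]!r}"
        )
    df = df.set_index("accession")
    try:
        design = design_from_columns(list(df.columns))
    except ValueError as exc:
        raise TableFormatError(f"{path}: {exc}") from exc
    df = df[design.sample_labels()].astype(float)
    _check_sample_frame(df, path, "abundance")
    return df, design


def write_abundance_table(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.index.name = "accession"
    out.to_csv(path, sep="\t", float_format="%.10g")


# fold-change tables share the abundance dialect
read_fold_change_table = read_abundance_table
write_fold_change_table = write_abundance_table


def read_peptide_table(path) -> pd.DataFrame:
    """Read a long-format peptide quant table (peptide, accession, sample, area)."""
    df = pd.read_csv(path, sep="\t")
    required = ["peptide", "accession", "sample", "area"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: peptide table missing columns {missing}")
    neg = df["area"].dropna() < 0
    if neg.any():
        raise TableFormatError(
            f"{path}: negative MS1 area at row {int(neg[neg].index[0]) + 2}"
        )
    return df


def write_results_table(records: Iterable | pd.DataFrame, path) -> None:
    """Write the per-protein results file in the published table layout.

    Accepts a DataFrame already in that layout, or an iterable of objects
    exposing the attributes produced by the targets module (accession,
    protein_name, per-experiment tm, NPARC p-value, criteria flags).
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        rows = []
        for rec in records:
            row = {
                "accession": rec.accession,
                "protein_name": rec.protein_name,
                "tm_control_1": rec.tm_vehicle_1,
                "tm_treatment_1": rec.tm_treatment_1,
                "tm_control_2": rec.tm_vehicle_2,
                "tm_treatment_2": rec.tm_treatment_2,
                "p_value": rec.p_value,
                "pass_fit_quality": rec.pass_fit_quality,
                "pass_vehicle_plateau": rec.pass_vehicle_plateau,
                "pass_shift_consistency": rec.pass_shift_consistency,
                "pass_slope": rec.pass_slope,
                "is_target": rec.is_target,
                "passes_significance": rec.passes_significance,
            }
            rows.append(row)
        df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_results_table(path) -> pd.DataFrame:
    """Read a results (or published-target) table; checks the Tm/p columns."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: results table missing columns {missing}")
    dup = df["accession"].duplicated()
    if dup.any():
        raise TableFormatError(
            f"{path}: duplicate accession at row {int(dup[dup].index[0]) + 2}"
        )
    for col in RESULT_COLUMNS[2:]:
        df[col] = df[col].astype(float)
    return df


def load_published_targets(method: str) -> pd.DataFrame:
    """Published target tables (printed Tm and NPARC p-values) shipped as data.

    ``method`` is ``"bTPP"`` (9 proteins) or ``"TPP"`` (19 proteins).
    """
    names = {"bTPP": "btpp_targets.tsv", "TPP": "tpp_targets.tsv"}
    if method not in names:
        raise ValueError(f"method must be one of {sorted(names)}")
    ref = resources.files("btpp.data").joinpath(names[method])
    with resources.as_file(ref) as p:
        return read_results_table(p)
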