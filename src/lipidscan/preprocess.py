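"""Batch alignment, transformation, standardisation and analysis-set selection.

The preprocessing contract mirrors standard practice for targeted
lipidomics run in large analytical batches: each batch embeds pooled
plasma QC samples; per-lipid batch drift is removed by rescaling every
batch so its QC median matches the panel-wide QC median; concentrations
are then log10-transformed (plasma lipid species are positively skewed)
and z-scored within cohort over the rows actually entering each analysis.

Two analysis sets are produced per cohort:

* *prevalent* — AD vs CN at the participant's last acquired sample, MCI
  excluded, timepoint entering as categorical indicator covariates;
* *incident* — baseline samples only, prevalent-AD participants excluded,
  MCI retained (with an optional indicator), outcome given as
  (entry age, exit age, converted) for age-as-timescale Cox models.

Class totals are computed after batch alignment on the raw concentration
scale (sums are only meaningful on the concentration scale), then
log10-standardised exactly like the species.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from lipidscan.nomenclature import PanelRegistry, class_totals

__all__ = [
    "AnalysisSet",
    "align_batches",
    "log10_standardize",
    "select_prevalent",
    "select_incident",
    "build_covariate_design",
    "BASE_COVARIATES",
]

logger = logging.getLogger(__name__)

#: covariates common to both cohorts' association models
BASE_COVARIATES = [
    "age",
    "sex",
    "bmi",
    "total_cholesterol",
    "hdl_c",
    "triglycerides",
    "apoe4_count",
    "statin",
    "omega3",
]


@dataclass
class AnalysisSet:
    """One cohort's ready-to-model data for a prevalent or incident analysis."""

    role: str  # "prevalent" | "incident"
    cohort_id: str
    species: pd.DataFrame  # standardized log10 species matrix
    classes: pd.DataFrame  # standardized log10 class-total matrix
    covariates: pd.DataFrame  # numeric design columns (no intercept)
    outcome: pd.DataFrame  # prevalent: [ad]; incident: [entry_age, exit_age, event, mci]
    n_dropped_missing: int = 0

    @property
    def n(self) -> int:
        return len(self.outcome)


def align_batches(
    concentrations: pd.DataFrame,
    batch_ids: pd.Series,
    qc_flags: pd.Series,
) -> pd.DataFrame:
    """Align analytical batches on the pooled-QC median, per lipid.

    Each lipid in each batch is multiplied by
    (panel-wide QC median) / (batch QC median), so that after alignment
    the per-batch QC medians agree across batches for every lipid.
    Multiplicative correction on raw concentrations is equivalent to an
    additive shift in log space and preserves scale.
    """
    batch_ids = batch_ids.reindex(concentrations.index)
    qc_flags = qc_flags.reindex(concentrations.index).astype(bool)

    qc = concentrations.loc[qc_flags]
    for batch in pd.unique(batch_ids):
        if not qc_flags[batch_ids == batch].any():
            raise ValueError(f"batch {batch!r} contains no QC samples")

    global_median = qc.median(axis=0)
    batch_medians = qc.groupby(batch_ids.loc[qc.index]).median()
    zero = batch_medians.le(0)
    if zero.any().any():
        b, lip = next(
            (b, lip)
            for b in batch_medians.index
            for lip in batch_medians.columns
            if zero.loc[b, lip]
        )
        raise ValueError(f"non-positive QC median for lipid {lip!r} in batch {b!r}")

    factors = global_median / batch_medians  # batch x lipid
    aligned = concentrations * factors.reindex(batch_ids).to_numpy()
    return aligned


def log10_standardize(
    concentrations: pd.DataFrame, include: pd.Index | None = None, tol: float = 1e-12
) -> pd.DataFrame:
    """log10-transform then z-score each column over the included rows only.

    Returns the standardized matrix restricted to ``include`` (all rows if
    ``None``).  The mean/SD are computed exclusively on the included rows,
    so excluded rows can never leak into the scaling.
    """
    sub = concentrations if include is None else concentrations.loc[include]
    bad = sub.le(0)
    if bad.any().any():
        row = bad.any(axis=1).idxmax()
        col = bad.loc[row].idxmax()
        raise ValueError(f"non-positive concentration for lipid {col!r} in sample {row!r}")
    logged = np.log10(sub)
    sd = logged.std(axis=0, ddof=1)
    if (sd <= tol).any() or sd.isna().any():
        col = sd.index[(sd.isna() | (sd <= tol)).argmax()]
        raise ValueError(f"zero standard deviation for column {col!r}")
    return (logged - logged.mean(axis=0)) / sd


def _complete_case(meta: pd.DataFrame, columns: list[str], role: str) -> pd.DataFrame:
    present = [c for c in columns if c in meta.columns]
    keep = meta.dropna(subset=present)
    dropped = len(meta) - len(keep)
    if dropped:
        logger.warning("%s analysis: dropped %d rows with missing covariates", role, dropped)
    return keep


def _cohort_extra_covariates(meta: pd.DataFrame, *, timepoints: bool) -> list[str]:
    extra = []
    if "site" in meta.columns and meta["site"].notna().any():
        extra.append("site")
    if "fasting" in meta.columns and meta["fasting"].notna().any():
        extra.append("fasting")
    if timepoints and meta["timepoint"].nunique() > 1:
        extra.append("timepoint")
    return extra


def build_covariate_design(
    meta: pd.DataFrame, *, timepoints: bool = False, include_age: bool = True
) -> pd.DataFrame:
    """Numeric covariate design (no intercept) from a metadata subset.

    Continuous covariates pass through; sex/statin/omega-3/fasting become
    0/1; site and timepoint become categorical indicator columns (first
    level as reference).  Age is omitted when it serves as the Cox
    timescale.
    """
    cols = {}
    if include_age:
        cols["age"] = meta["age"].astype(float)
    cols["sex"] = (meta["sex"] == "F").astype(float)
    for c in ("bmi", "total_cholesterol", "hdl_c", "triglycerides"):
        cols[c] = meta[c].astype(float)
    cols["apoe4_count"] = meta["apoe4_count"].astype(float)
    for c in ("statin", "omega3"):
        cols[c] = meta[c].astype(bool).astype(float)
    design = pd.DataFrame(cols, index=meta.index)

    for cat in _cohort_extra_covariates(meta, timepoints=timepoints):
        if cat == "fasting":
            design["fasting"] = meta["fasting"].astype(bool).astype(float)
            continue
        series = meta[cat].astype(str) if cat == "site" else meta[cat].astype(int)
        dummies = pd.get_dummies(series, prefix=cat, drop_first=True, dtype=float)
        design = pd.concat([design, dummies], axis=1)
    return design


def _latest_rows(meta: pd.DataFrame) -> pd.DataFrame:
    """One row per participant at the maximum available timepoint.

    Duplicate aliquots at the same timepoint keep the first-read row with
    a warning.
    """
    ordered = meta.sort_values("timepoint", kind="stable")
    dup = ordered.duplicated(subset=["participant_id", "timepoint"])
    if dup.any():
        warnings.warn(
            f"{int(dup.sum())} duplicate participant-timepoint rows; keeping first-read",
            stacklevel=2,
        )
        ordered = ordered[~dup]
    return ordered.groupby("participant_id", sort=False).tail(1)


def select_prevalent(
    aligned: pd.DataFrame,
    meta: pd.DataFrame,
    registry: PanelRegistry,
) -> AnalysisSet:
    """Prevalent (AD vs CN) analysis set: last acquired sample, MCI excluded."""
    meta = meta.loc[~meta.get("is_qc", pd.Series(False, index=meta.index)).astype(bool)]
    species_cols = [sp.raw_name for sp in registry.species if sp.raw_name in aligned.columns]
    meta = meta.loc[meta.index.intersection(aligned.index)]

    last = _latest_rows(meta)
    last = last[last["diagnosis"].isin(["CN", "AD"])]
    n0 = len(last)
    last = _complete_case(last, BASE_COVARIATES, "prevalent")

    rows = last.index
    conc = aligned.loc[rows, species_cols]
    species_std = log10_standardize(conc)
    classes_std = log10_standardize(class_totals(conc, registry))
    design = build_covariate_design(last, timepoints=True, include_age=True)
    outcome = pd.DataFrame({"ad": (last["diagnosis"] == "AD").astype(int)}, index=rows)

    cohort = str(last["cohort_id"].iloc[0]) if len(last) else ""
    return AnalysisSet(
        role="prevalent",
        cohort_id=cohort,
        species=species_std,
        classes=classes_std,
        covariates=design,
        outcome=outcome,
        n_dropped_missing=n0 - len(last),
    )


def select_incident(
    aligned: pd.DataFrame,
    meta: pd.DataFrame,
    registry: PanelRegistry,
) -> AnalysisSet:
    """Incident (conversion) analysis set: baseline samples, baseline AD excluded.

    MCI participants are retained; an ``mci`` indicator is carried in the
    outcome frame for the optional sensitivity adjustment.  The outcome is
    (entry age, exit age, event) for age-as-timescale Cox models with left
    truncation at the baseline age.
    """
    meta = meta.loc[~meta.get("is_qc", pd.Series(False, index=meta.index)).astype(bool)]
    meta = meta.loc[meta.index.intersection(aligned.index)]
    base = meta[meta["timepoint"] == meta["timepoint"].min()]
    base = base[base["diagnosis"].isin(["CN", "MCI"])]

    bad = base["converted"].astype(bool) & (base["followup_years"] <= 0)
    if bad.any():
        raise ValueError(
            f"converters with non-positive follow-up: {list(base.index[bad])}"
        )
    n0 = len(base)
    base = _complete_case(base, BASE_COVARIATES + ["followup_years"], "incident")

    rows = base.index
    species_cols = [sp.raw_name for sp in registry.species if sp.raw_name in aligned.columns]
    conc = aligned.loc[rows, species_cols]
    species_std = log10_standardize(conc)
    classes_std = log10_standardize(class_totals(conc, registry))
    design = build_covariate_design(base, timepoints=False, include_age=False)
    outcome = pd.DataFrame(
        {
            "entry_age": base["age"].astype(float),
            "exit_age": base["age"].astype(float) + base["followup_years"].astype(float),
            "event": base["converted"].astype(bool).astype(int),
            "mci": (base["diagnosis"] == "MCI").astype(int),
        },
        index=rows,
    )

    cohort = str(base["cohort_id"].iloc[0]) if len(base) else ""
    return AnalysisSet(
        role="incident",
        cohort_id=cohort,
        species=species_std,
        classes=classes_std,
        covariates=design,
        outcome=outcome,
        n_dropped_missing=n0 - len(base),
    )
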