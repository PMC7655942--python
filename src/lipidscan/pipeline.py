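"""End-to-end orchestration: raw tables -> analysis sets -> scans -> meta.

Thin glue over the stage modules so scripts, the CLI and the test suite run
the same path: QC-median batch alignment, prevalent/incident analysis-set
selection, per-lipid scans with family-wise BH FDR, and the two-cohort
fixed-effects meta-analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from lipidscan.meta import meta_scan
from lipidscan.nomenclature import PanelRegistry
from lipidscan.preprocess import (
    AnalysisSet,
    align_batches,
    select_incident,
    select_prevalent,
)
from lipidscan.stats import scan_panel

__all__ = ["CohortData", "prepare_cohort", "scan_cohorts"]

_ANNOTATION_COLS = ("batch_id", "is_qc")


@dataclass
class CohortData:
    """One cohort after preprocessing."""

    cohort_id: str
    aligned: pd.DataFrame  # batch-aligned raw concentrations, species columns only
    metadata: pd.DataFrame
    registry: PanelRegistry
    prevalent: AnalysisSet
    incident: AnalysisSet


def prepare_cohort(
    concentrations: pd.DataFrame,
    metadata: pd.DataFrame,
    registry: PanelRegistry | None = None,
) -> CohortData:
    """Align batches and build both analysis sets for one cohort.

    ``concentrations`` carries the species columns plus ``batch_id`` and
    ``is_qc`` row annotations (the format the synthetic generator and the
    file readers produce).
    """
    species_cols = [c for c in concentrations.columns if c not in _ANNOTATION_COLS]
    if registry is None:
        registry = PanelRegistry.from_names(species_cols)
    aligned = align_batches(
        concentrations[species_cols],
        concentrations["batch_id"],
        concentrations["is_qc"],
    )
    aligned = aligned.loc[~concentrations["is_qc"].astype(bool)]
    prevalent = select_prevalent(aligned, metadata, registry)
    incident = select_incident(aligned, metadata, registry)
    cohort_id = prevalent.cohort_id or incident.cohort_id
    return CohortData(cohort_id, aligned, metadata, registry, prevalent, incident)


def scan_cohorts(
    cohorts: list[CohortData],
    role: str,
    *,
    species_family_size: int | None = None,
    class_family_size: int | None = None,
    adjust_mci: bool = False,
) -> tuple[list[pd.DataFrame], pd.DataFrame]:
    """Per-cohort association scans plus their fixed-effects meta-analysis."""
    tables = []
    for c in cohorts:
        aset = c.prevalent if role == "prevalent" else c.incident
        tables.append(
            scan_panel(
                aset,
                species_family_size=species_family_size,
                class_family_size=class_family_size,
                adjust_mci=adjust_mci,
            )
        )
    meta = meta_scan(
        tables,
        species_family_size=species_family_size,
        class_family_size=class_family_size,
    )
    return tables, meta
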