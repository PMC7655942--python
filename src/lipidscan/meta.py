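"""Inverse-variance fixed-effects meta-analysis across cohorts.

Per-lipid cohort estimates (beta, SE) are pooled with weights w_i = 1/se_i^2:
beta_meta = sum(w_i beta_i) / sum(w_i), se_meta = (sum w_i)^(-1/2),
z = beta_meta / se_meta, p = 2 Phi(-|z|).  Flagged cohort fits are dropped
before pooling; a lipid present in a single usable cohort passes through
with a ``single_study`` flag.  No heterogeneity statistics are computed
(fixed effects only).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from lipidscan.stats import AssociationResult, bh_fdr

__all__ = ["MetaResult", "fixed_effect_meta", "meta_scan"]


@dataclass
class MetaResult:
    """Pooled effect of one lipid across cohorts."""

    lipid: str
    beta_meta: float
    se_meta: float
    z: float
    p: float
    q: float | None = None
    studies: list[tuple[float, float, float]] = field(default_factory=list)  # (beta, se, weight)
    n_studies: int = 0
    flag: str | None = None


def fixed_effect_meta(results: list[AssociationResult]) -> MetaResult:
    """Pool one lipid's per-study estimates under a common-effect model."""
    usable = [r for r in results if r.ok and r.se > 0]
    if not usable:
        raise ValueError("no usable studies to pool")
    lipid = usable[0].lipid
    betas = np.array([r.beta for r in usable])
    ses = np.array([r.se for r in usable])
    w = 1.0 / ses**2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    z = beta / se
    p = float(2.0 * sps.norm.sf(abs(z)))
    return MetaResult(
        lipid=lipid,
        beta_meta=beta,
        se_meta=se,
        z=float(z),
        p=p,
        studies=[(float(b), float(s), float(wi)) for b, s, wi in zip(betas, ses, w)],
        n_studies=len(usable),
        flag="single_study" if len(usable) == 1 else None,
    )


def meta_scan(
    cohort_tables: list[pd.DataFrame],
    *,
    species_family_size: int | None = None,
    class_family_size: int | None = None,
) -> pd.DataFrame:
    """Meta-analyse per-cohort scan tables; BH-FDR within each lipid family.

    ``cohort_tables`` are outputs of :func:`lipidscan.stats.scan_panel`.
    Lipids are matched by (lipid, level); flagged cohort rows are dropped
    before pooling.
    """
    stacked = pd.concat(cohort_tables, ignore_index=True)
    rows = []
    for level in ("species", "class"):
        sub = stacked[stacked["level"] == level]
        for lipid, grp in sub.groupby("lipid", sort=False):
            usable = grp[grp["flag"].isna() & grp["p"].notna() & (grp["se"] > 0)]
            if usable.empty:
                rows.append(
                    {"lipid": lipid, "level": level, "beta_meta": np.nan,
                     "se_meta": np.nan, "z": np.nan, "p": np.nan,
                     "n_studies": 0, "flag": "no_usable_study"}
                )
                continue
            res = fixed_effect_meta(
                [
                    AssociationResult(
                        lipid=str(lipid), model=str(r.model), beta=r.beta, se=r.se, p=r.p
                    )
                    for r in usable.itertuples()
                ]
            )
            rows.append(
                {"lipid": lipid, "level": level, "beta_meta": res.beta_meta,
                 "se_meta": res.se_meta, "z": res.z, "p": res.p,
                 "n_studies": res.n_studies, "flag": res.flag}
            )
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    for level, fam in (("species", species_family_size), ("class", class_family_size)):
        mask = (out["level"] == level) & out["p"].notna()
        k = int(mask.sum())
        if k:
            m = max(fam if fam is not None else k, k)
            out.loc[mask, "q"] = bh_fdr(out.loc[mask, "p"].to_numpy(), m)
    return out
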