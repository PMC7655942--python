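"""Per-lipid association models, FDR control, and group-comparison tests.

Each lipid (species or class total) enters its own model as a standardized
log10 concentration, so ``exp(beta)`` is the odds ratio (logistic,
prevalent AD vs CN) or hazard ratio (Cox, incident conversion with age as
the timescale and left truncation at baseline age) per SD.  Two-sided Wald
p-values are corrected by Benjamini-Hochberg within the species family and
the class family separately; the family size can exceed the number of
testable lipids when some fits are flagged (separation / non-convergence)
and excluded.

Also provided are the two summary-statistic tests used for cohort
characteristics tables: a two-group one-way ANOVA reconstructed from
(n, mean, SD) pairs and a Pearson chi-square test of independence on
contingency tables of counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats as sps

from lipidscan.preprocess import AnalysisSet

__all__ = [
    "AssociationResult",
    "fit_logistic",
    "fit_cox",
    "bh_fdr",
    "two_group_anova_summary",
    "chisq_independence",
    "scan_panel",
]

logger = logging.getLogger(__name__)

# |beta| or SE beyond this marks quasi-complete separation / non-convergence
_SEPARATION_BETA = 15.0
_SEPARATION_SE = 50.0


@dataclass
class AssociationResult:
    """Effect of one lipid from one cohort's model."""

    lipid: str
    model: str  # "logistic" | "cox"
    beta: float  # per SD of log10 concentration
    se: float
    p: float
    q: float | None = None
    n_cases: int = 0
    n_total: int = 0
    covariate_set: str = ""
    flag: str | None = None  # "separation" | "non_converged" | "single_study"

    @property
    def ok(self) -> bool:
        return self.flag is None and np.isfinite(self.beta) and np.isfinite(self.p)


def _check_full_rank(design: pd.DataFrame) -> None:
    X = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        from scipy.linalg import qr

        _, _, piv = qr(X, mode="economic", pivoting=True)
        collinear = [str(design.columns[j]) for j in piv[rank:]]
        raise ValueError(
            f"design is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear columns: {collinear}"
        )


def fit_logistic(
    outcome: pd.Series,
    lipid: pd.Series,
    covariates: pd.DataFrame | None = None,
    *,
    lipid_name: str | None = None,
    covariate_set: str = "",
) -> AssociationResult:
    """Maximum-likelihood logistic fit of a binary outcome on one lipid.

    Returns the lipid coefficient with Wald SE and two-sided p.  Complete
    or quasi-complete separation is flagged (infinite-beta marker, p = NaN)
    rather than raised, so panel scans can proceed.
    """
    y = np.asarray(outcome, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    name = lipid_name or (lipid.name if lipid.name else "lipid")
    parts = {"lipid": np.asarray(lipid, dtype=float)}
    if covariates is not None and covariates.shape[1]:
        for c in covariates.columns:
            parts[str(c)] = covariates[c].to_numpy(dtype=float)
    design = pd.DataFrame(parts, index=outcome.index)
    _check_full_rank(design)
    X = sm.add_constant(design, prepend=True)

    flag = None
    beta = se = np.nan
    p = np.nan
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=False, maxiter=100)
        beta = float(fit.params["lipid"])
        se = float(fit.bse["lipid"])
        p = float(fit.pvalues["lipid"])
        if not fit.mle_retvals.get("converged", True):
            flag = "non_converged"
        elif abs(beta) > _SEPARATION_BETA or se > _SEPARATION_SE:
            flag = "separation"
    except Exception as exc:  # PerfectSeparationError and friends
        logger.warning("logistic fit failed for %s: %s", name, exc)
        flag = "separation"
        beta = np.inf

    if flag is not None:
        logger.warning("flagged logistic fit for %s: %s", name, flag)
        p = np.nan
    return AssociationResult(
        lipid=str(name),
        model="logistic",
        beta=beta,
        se=se,
        p=p,
        n_cases=int(y.sum()),
        n_total=int(len(y)),
        covariate_set=covariate_set,
        flag=flag,
    )


def fit_cox(
    entry_age: pd.Series,
    exit_age: pd.Series,
    event: pd.Series,
    lipid: pd.Series,
    covariates: pd.DataFrame | None = None,
    *,
    lipid_name: str | None = None,
    covariate_set: str = "",
) -> AssociationResult:
    """Cox partial-likelihood fit with age as timescale (left truncation).

    Entry at baseline age, exit at conversion or censoring age; Efron tie
    handling; Wald SE and two-sided p for the lipid coefficient.
    """
    entry = np.asarray(entry_age, dtype=float)
    exit_ = np.asarray(exit_age, dtype=float)
    ev = np.asarray(event, dtype=int)
    if np.any(exit_ <= entry):
        raise ValueError("exit age must exceed entry age for every row")
    if ev.sum() < 2:
        raise ValueError("need at least 2 events")
    x = np.asarray(lipid, dtype=float)
    if np.std(x) == 0:
        raise ValueError("lipid column has zero variance")

    name = lipid_name or (lipid.name if lipid.name else "lipid")
    df = pd.DataFrame({"entry": entry, "exit": exit_, "event": ev, "lipid": x})
    if covariates is not None and covariates.shape[1]:
        for c in covariates.columns:
            df[str(c)] = covariates[c].to_numpy(dtype=float)
    _check_full_rank(df.drop(columns=["entry", "exit", "event"]))

    flag = None
    beta = se = p = np.nan
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph = CoxPHFitter()
            cph.fit(df, duration_col="exit", event_col="event", entry_col="entry")
        beta = float(cph.params_["lipid"])
        se = float(cph.standard_errors_["lipid"])
        z = beta / se
        p = float(2.0 * sps.norm.sf(abs(z)))
        if abs(beta) > _SEPARATION_BETA or se > _SEPARATION_SE:
            flag = "non_converged"
    except ConvergenceError as exc:
        logger.warning("cox fit failed for %s: %s", name, exc)
        flag = "non_converged"

    if flag is not None:
        p = np.nan
    return AssociationResult(
        lipid=str(name),
        model="cox",
        beta=beta,
        se=se,
        p=p,
        n_cases=int(ev.sum()),
        n_total=int(len(ev)),
        covariate_set=covariate_set,
        flag=flag,
    )


def bh_fdr(p_values: np.ndarray | pd.Series, family_size: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment with an explicit family size.

    ``family_size`` may exceed ``len(p_values)`` when flagged fits were
    excluded from the testable set but still count toward the declared
    family (e.g. 569 species, 32 classes).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = int(family_size) if family_size is not None else p.size
    if m < p.size:
        raise ValueError(f"family_size {m} smaller than number of p-values {p.size}")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty_like(adj)
    out[order] = adj
    return out


def two_group_anova_summary(
    n1: int, mean1: float, sd1: float, n2: int, mean2: float, sd2: float
) -> tuple[float, float]:
    """One-way two-group ANOVA reconstructed from summary statistics.

    Pooled variance sp2 = ((n1-1)s1^2 + (n2-1)s2^2)/(n1+n2-2);
    F = (mean1-mean2)^2 / (sp2 (1/n1 + 1/n2)); p from F(1, n1+n2-2).
    Equivalent to the squared pooled two-sample t statistic.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 in each group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    df2 = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df2
    if sp2 == 0:
        if mean1 == mean2:
            return 0.0, 1.0
        logger.warning("degenerate ANOVA: zero pooled variance with unequal means")
        return np.inf, 0.0
    F = (mean1 - mean2) ** 2 / (sp2 * (1.0 / n1 + 1.0 / n2))
    p = float(sps.f.sf(F, 1, df2))
    return float(F), p


def chisq_independence(counts) -> tuple[float, int, float]:
    """Pearson chi-square test of independence, no continuity correction."""
    tab = np.asarray(counts, dtype=float)
    if tab.ndim != 2 or tab.shape[0] < 2 or tab.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if np.any(tab < 0):
        raise ValueError("counts must be non-negative")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise ValueError("table has a zero row or column margin")
    chi2, p, df, _ = sps.chi2_contingency(tab, correction=False)
    return float(chi2), int(df), float(p)


def _scan_matrix(
    matrix: pd.DataFrame,
    aset: AnalysisSet,
    *,
    adjust_mci: bool,
    covariate_set: str,
) -> list[AssociationResult]:
    results = []
    covs = aset.covariates
    if aset.role == "prevalent":
        y = aset.outcome["ad"]
        for col in matrix.columns:
            results.append(
                fit_logistic(y, matrix[col], covs, lipid_name=col, covariate_set=covariate_set)
            )
    else:
        covs_used = covs
        if adjust_mci:
            covs_used = covs.assign(mci=aset.outcome["mci"].astype(float))
        o = aset.outcome
        for col in matrix.columns:
            results.append(
                fit_cox(
                    o["entry_age"],
                    o["exit_age"],
                    o["event"],
                    matrix[col],
                    covs_used,
                    lipid_name=col,
                    covariate_set=covariate_set,
                )
            )
    return results


def scan_panel(
    aset: AnalysisSet,
    *,
    species_family_size: int | None = None,
    class_family_size: int | None = None,
    adjust_mci: bool = False,
) -> pd.DataFrame:
    """Fit every species and class total; BH-adjust within each family.

    Flagged fits (separation / non-convergence) are reported with p = NaN
    and excluded from the FDR family.  Returns a tidy results table with
    one row per lipid, ``level`` marking species vs class.
    """
    covset = "+".join(aset.covariates.columns)
    rows: list[dict] = []
    for level, matrix, fam in (
        ("species", aset.species, species_family_size),
        ("class", aset.classes, class_family_size),
    ):
        res = _scan_matrix(matrix, aset, adjust_mci=adjust_mci, covariate_set=covset)
        ok = [r for r in res if r.ok]
        fam_m = fam if fam is not None else len(ok)
        fam_m = max(fam_m, len(ok))
        q = bh_fdr(np.array([r.p for r in ok]), fam_m) if ok else np.array([])
        qmap = {r.lipid: qi for r, qi in zip(ok, q)}
        for r in res:
            rows.append(
                {
                    "lipid": r.lipid,
                    "level": level,
                    "model": r.model,
                    "beta": r.beta,
                    "se": r.se,
                    "p": r.p,
                    "q": qmap.get(r.lipid, np.nan),
                    "n_cases": r.n_cases,
                    "n_total": r.n_total,
                    "flag": r.flag,
                    "cohort": aset.cohort_id,
                }
            )
    return pd.DataFrame(rows)
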