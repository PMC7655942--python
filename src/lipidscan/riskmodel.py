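"""Cluster-aware cross-validated stepwise risk models with cross-cohort replication.

Discovery: within a stratified 10-fold cross-validation (optionally
repeated), forward stepwise selection adds lipid species to the clinical
base model (age, sex, BMI, APOE e4 count) while the Akaike Information
Criterion decreases, to a cap of 10 lipids for logistic (prevalent
diagnosis) and 5 for Cox (incident conversion, age as timescale).  The
number of training fits that incorporate each lipid is its *frequency*.
Because highly correlated species substitute for each other across folds
and dilute their individual frequencies, frequencies are summed within
correlation clusters, clusters are ranked by that sum, and each
contributing cluster is represented by its most-incorporated member; the
top-ranked representatives (up to the cap) form the final feature list.

Replication: the selected features are retrained from scratch on the
replication cohort inside a fresh 10-fold cross-validation; out-of-fold
risk scores pooled per repeat give the C-statistic (AUC for diagnosis,
Harrell's C under left truncation for incidence) and the category-free Net
Reclassification Index against the base model.  Point estimates are means
over 200 repeats with 2.5/97.5-percentile confidence intervals.

For low-incidence discovery cohorts with a large age gap between
converters and non-converters, a 2:1 age-sex-matched subset is drawn
before selection (:func:`match_discovery_subset`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from lipidscan._fastfit import cox_fit, cox_prep, logistic_fit
from lipidscan.clusters import ClusterAssignment, representative_ranking
from lipidscan.preprocess import AnalysisSet

__all__ = [
    "SelectionResult",
    "ModelEvaluation",
    "match_discovery_subset",
    "cv_stepwise_select",
    "finalize_features",
    "c_statistic",
    "nri_continuous",
    "replicate_evaluate",
    "BASE_MODEL_COVARIATES",
]

logger = logging.getLogger(__name__)

#: Clinical base model: age, sex, BMI, APOE e4 count.  For Cox models age
#: is the timescale, not a regressor.
BASE_MODEL_COVARIATES = ["age", "sex", "bmi", "apoe4_count"]

_MAX_LIPIDS = {"logistic": 10, "cox": 5}


@dataclass
class SelectionResult:
    """Outcome of discovery-cohort feature selection."""

    analysis: str  # "diagnosis" | "incidence"
    family: str  # "logistic" | "cox"
    base_covariates: list[str]
    frequencies: pd.Series  # per-lipid incorporation count over CV training fits
    cluster_ranking: pd.DataFrame  # from representative_ranking
    features: list[str]  # final representatives, <= cap
    max_k: int
    n_folds: int
    n_repeats: int
    n_fits: int
    seed: int


@dataclass
class ModelEvaluation:
    """Cross-validated replication performance of base vs base+lipids."""

    c_statistic: float
    c_ci: tuple[float, float]
    base_c_statistic: float
    base_c_ci: tuple[float, float]
    nri_total: float
    nri_total_ci: tuple[float, float]
    nri_event: float
    nri_event_ci: tuple[float, float]
    nri_nonevent: float
    nri_nonevent_ci: tuple[float, float]
    n_repeats: int
    per_repeat: pd.DataFrame = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# matching


def match_discovery_subset(
    meta: pd.DataFrame,
    ratio: int = 2,
    *,
    case_col: str = "converted",
) -> pd.DataFrame:
    """Greedy ratio:1 age-sex matching of non-cases to cases.

    Cases are processed in descending age (the hardest to match in ageing
    cohorts); each receives its ``ratio`` nearest-age same-sex non-cases,
    drawn without replacement.  Returns the matched rows (cases +
    controls).
    """
    cases = meta[meta[case_col].astype(bool)]
    controls = meta[~meta[case_col].astype(bool)]
    for sex, grp in cases.groupby("sex"):
        avail = (controls["sex"] == sex).sum()
        if avail < ratio * len(grp):
            raise ValueError(
                f"insufficient same-sex controls for sex={sex!r}: need "
                f"{ratio * len(grp)}, have {avail} (shortfall {ratio * len(grp) - avail})"
            )
    taken: list = []
    remaining = {
        sex: grp.sort_values("age") for sex, grp in controls.groupby("sex")
    }
    for idx in cases.sort_values("age", ascending=False).index:
        sex, age = meta.at[idx, "sex"], float(meta.at[idx, "age"])
        pool = remaining[sex]
        picks = (pool["age"] - age).abs().nsmallest(ratio, keep="first").index
        taken.extend(picks)
        remaining[sex] = pool.drop(index=picks)
    matched = pd.concat([cases, controls.loc[taken]])
    return matched.loc[meta.index.intersection(matched.index)]


# ---------------------------------------------------------------------------
# discovery selection


def _design(covariates: pd.DataFrame, lipids: pd.DataFrame, cols: list[str]) -> np.ndarray:
    parts = [covariates.to_numpy(float)]
    if cols:
        parts.append(lipids[cols].to_numpy(float))
    return np.hstack(parts)


def _stratified_folds(strata: np.ndarray, n_folds: int, rng_seed: int):
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rng_seed)
    return skf.split(np.zeros(len(strata)), strata)


def cv_stepwise_select(
    lipids: pd.DataFrame,
    covariates: pd.DataFrame,
    outcome: pd.DataFrame,
    family: str,
    max_k: int | None = None,
    n_folds: int = 10,
    n_repeats: int = 10,
    seed: int = 0,
) -> pd.Series:
    """Per-lipid incorporation frequencies from repeated CV forward stepwise AIC.

    ``lipids`` are standardized species columns, ``covariates`` the base
    design (no intercept; the intercept is added internally for logistic),
    ``outcome`` either a one-column binary frame (logistic) or
    [entry_age, exit_age, event] (Cox).  Within each fold's training
    portion, forward steps add the candidate lipid with the largest AIC
    decrease (AIC = 2k - 2 loglik; partial likelihood for Cox), stopping at
    ``max_k`` lipids or when no addition lowers AIC.  Returns the count of
    training fits (out of n_folds * n_repeats) that incorporated each
    lipid.
    """
    if family not in _MAX_LIPIDS:
        raise ValueError(f"unknown model family {family!r}")
    if max_k is None:
        max_k = _MAX_LIPIDS[family]
    freq = pd.Series(0, index=lipids.columns, dtype=int)
    if max_k == 0 or n_folds < 2:
        return freq

    L = lipids.to_numpy(float)
    C = covariates.to_numpy(float)
    names = list(lipids.columns)

    if family == "logistic":
        y_all = outcome.iloc[:, 0].to_numpy(float)
        strata = y_all.astype(int)
    else:
        entry = outcome["entry_age"].to_numpy(float)
        exit_ = outcome["exit_age"].to_numpy(float)
        ev = outcome["event"].to_numpy(int)
        strata = ev

    ss = np.random.SeedSequence(seed)
    fold_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_repeats)]

    for rep in range(n_repeats):
        for train_idx, _ in _stratified_folds(strata, n_folds, fold_seeds[rep]):
            Ltr, Ctr = L[train_idx], C[train_idx]
            if family == "logistic":
                ytr = y_all[train_idx]
                base = np.hstack([np.ones((len(train_idx), 1)), Ctr])
                prep = None

                def fit(Xtr, b0):
                    return logistic_fit(Xtr, ytr, b0)

            else:
                etr, xtr_t, evtr = entry[train_idx], exit_[train_idx], ev[train_idx]
                base = Ctr
                prep = cox_prep(etr, xtr_t, evtr)

                def fit(Xtr, b0):
                    return cox_fit(etr, xtr_t, evtr, Xtr, b0, prep=prep)

            selected: list[int] = []
            X_cur = base
            beta_cur, ll, ok = fit(X_cur, None)
            aic_cur = 2 * X_cur.shape[1] - 2 * ll
            for _ in range(max_k):
                best = (None, aic_cur, None)
                warm = np.append(beta_cur, 0.0)
                k_cols = X_cur.shape[1] + 1
                for j in range(L.shape[1]):
                    if j in selected:
                        continue
                    Xj = np.hstack([X_cur, Ltr[:, j : j + 1]])
                    bj, llj, okj = fit(Xj, warm)
                    if not okj:
                        logger.debug("skipping non-converged candidate %s", names[j])
                        continue
                    aic_j = 2 * k_cols - 2 * llj
                    if aic_j < best[1]:
                        best = (j, aic_j, bj)
                if best[0] is None:
                    break
                j, aic_cur, beta_cur = best
                selected.append(j)
                X_cur = np.hstack([X_cur, Ltr[:, j : j + 1]])
            for j in selected:
                freq.iloc[j] += 1
    return freq


def finalize_features(
    frequencies: pd.Series,
    assignment: ClusterAssignment,
    max_k: int,
    *,
    analysis: str = "diagnosis",
    family: str = "logistic",
    n_folds: int = 10,
    n_repeats: int = 10,
    seed: int = 0,
    tiebreak: pd.Series | None = None,
) -> SelectionResult:
    """Aggregate frequencies over clusters; keep the top representatives.

    Clusters are ranked by summed member frequency; only clusters with a
    positive sum contribute, each through its most-incorporated member, up
    to ``max_k`` features.
    """
    ranking = representative_ranking(frequencies, assignment, tiebreak=tiebreak)
    nonzero = ranking[ranking["frequency"] > 0]
    features = list(nonzero["representative"].head(max_k))
    if len(features) < max_k:
        logger.info(
            "only %d clusters with nonzero frequency (cap %d)", len(features), max_k
        )
    return SelectionResult(
        analysis=analysis,
        family=family,
        base_covariates=list(BASE_MODEL_COVARIATES),
        frequencies=frequencies,
        cluster_ranking=ranking,
        features=features,
        max_k=max_k,
        n_folds=n_folds,
        n_repeats=n_repeats,
        n_fits=int(n_folds * n_repeats),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# discrimination and reclassification


def c_statistic(
    scores,
    outcome=None,
    *,
    entry=None,
    exit=None,
    event=None,
) -> float:
    """Concordance of risk scores with the outcome; ties count 1/2.

    Binary outcome: the probability that a random case outscores a random
    control (the AUC).  Survival outcome (``entry``/``exit``/``event``):
    Harrell's C over comparable pairs under left truncation — a pair is
    comparable when the earlier event time falls inside the other subject's
    at-risk interval (entry, exit].
    """
    s = np.asarray(scores, dtype=float)
    if outcome is not None:
        y = np.asarray(outcome).astype(bool)
        if y.all() or not y.any():
            raise ValueError("need at least one case and one control")
        pos, neg = s[y], s[~y]
        greater = (pos[:, None] > neg[None, :]).sum()
        ties = (pos[:, None] == neg[None, :]).sum()
        return float((greater + 0.5 * ties) / (len(pos) * len(neg)))

    en = np.asarray(entry, dtype=float)
    ex = np.asarray(exit, dtype=float)
    ev = np.asarray(event).astype(bool)
    # pair (i, j) comparable when i fails at ex_i while j is at risk
    comp = ev[:, None] & (ex[:, None] < ex[None, :]) & (ex[:, None] > en[None, :])
    n_comp = comp.sum()
    if n_comp == 0:
        raise ValueError("no comparable pairs")
    conc = comp & (s[:, None] > s[None, :])
    tie = comp & (s[:, None] == s[None, :])
    return float((conc.sum() + 0.5 * tie.sum()) / n_comp)


def nri_continuous(base_scores, new_scores, outcome) -> tuple[float, float, float]:
    """Category-free (continuous) Net Reclassification Index.

    event component = P(new > base | event) - P(new < base | event);
    nonevent component = P(new < base | nonevent) - P(new > base | nonevent);
    total = event + nonevent.  Exact ties contribute zero.
    """
    b = np.asarray(base_scores, dtype=float)
    nw = np.asarray(new_scores, dtype=float)
    y = np.asarray(outcome).astype(bool)
    if not y.any() or y.all():
        raise ValueError("need at least one event and one nonevent")
    up, down = nw > b, nw < b
    ev = float(up[y].mean() - down[y].mean())
    ne = float(down[~y].mean() - up[~y].mean())
    return ev + ne, ev, ne


# ---------------------------------------------------------------------------
# replication


def replicate_evaluate(
    replication: AnalysisSet,
    selection: SelectionResult,
    n_folds: int = 10,
    n_repeats: int = 200,
    seed: int = 0,
) -> ModelEvaluation:
    """Retrain base and base+lipids on the replication cohort under CV.

    Per repeat: freshly randomised outcome-stratified folds; both models
    retrained on each training portion (the discovery cohort supplies only
    the feature list, never coefficients); out-of-fold linear-predictor
    scores pooled; C-statistic and continuous NRI computed on the pooled
    scores.  Point estimates are means over repeats, CIs the 2.5/97.5
    percentiles.
    """
    missing = [f for f in selection.features if f not in replication.species.columns]
    if missing:
        raise KeyError(f"features missing from replication panel: {missing}")

    lipids = replication.species[selection.features]
    if selection.family == "logistic":
        base_cols = ["age", "sex", "bmi", "apoe4_count"]
        y = replication.outcome["ad"].to_numpy(int)
        strata = y
    else:
        base_cols = ["sex", "bmi", "apoe4_count"]  # age is the timescale
        en = replication.outcome["entry_age"].to_numpy(float)
        ex = replication.outcome["exit_age"].to_numpy(float)
        evt = replication.outcome["event"].to_numpy(int)
        strata = evt
    covs = replication.covariates[base_cols]

    C = covs.to_numpy(float)
    Lip = lipids.to_numpy(float) if selection.features else np.empty((len(covs), 0))
    n = len(C)

    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_repeats)]

    rows = []
    for rep in range(n_repeats):
        score_base = np.empty(n)
        score_full = np.empty(n)
        for train_idx, test_idx in _stratified_folds(strata, n_folds, rep_seeds[rep]):
            if selection.family == "logistic":
                Xb_tr = np.hstack([np.ones((len(train_idx), 1)), C[train_idx]])
                Xf_tr = np.hstack([Xb_tr, Lip[train_idx]])
                bb, _, _ = logistic_fit(Xb_tr, y[train_idx])
                bf, _, _ = logistic_fit(Xf_tr, y[train_idx])
                Xb_te = np.hstack([np.ones((len(test_idx), 1)), C[test_idx]])
                Xf_te = np.hstack([Xb_te, Lip[test_idx]])
            else:
                prep = cox_prep(en[train_idx], ex[train_idx], evt[train_idx])
                bb, _, _ = cox_fit(
                    en[train_idx], ex[train_idx], evt[train_idx], C[train_idx], prep=prep
                )
                Xf = np.hstack([C, Lip])
                bf, _, _ = cox_fit(
                    en[train_idx], ex[train_idx], evt[train_idx], Xf[train_idx], prep=prep
                )
                Xb_te = C[test_idx]
                Xf_te = Xf[test_idx]
            score_base[test_idx] = Xb_te @ bb
            score_full[test_idx] = Xf_te @ bf

        if selection.family == "logistic":
            c_full = c_statistic(score_full, y)
            c_base = c_statistic(score_base, y)
            nri_t, nri_e, nri_ne = nri_continuous(score_base, score_full, y)
        else:
            c_full = c_statistic(score_full, entry=en, exit=ex, event=evt)
            c_base = c_statistic(score_base, entry=en, exit=ex, event=evt)
            nri_t, nri_e, nri_ne = nri_continuous(score_base, score_full, evt)
        rows.append(
            {"c": c_full, "c_base": c_base, "nri_total": nri_t,
             "nri_event": nri_e, "nri_nonevent": nri_ne}
        )

    per = pd.DataFrame(rows)

    def ci(col: str) -> tuple[float, float]:
        return (
            float(np.percentile(per[col], 2.5)),
            float(np.percentile(per[col], 97.5)),
        )

    return ModelEvaluation(
        c_statistic=float(per["c"].mean()),
        c_ci=ci("c"),
        base_c_statistic=float(per["c_base"].mean()),
        base_c_ci=ci("c_base"),
        nri_total=float(per["nri_total"].mean()),
        nri_total_ci=ci("nri_total"),
        nri_event=float(per["nri_event"].mean()),
        nri_event_ci=ci("nri_event"),
        nri_nonevent=float(per["nri_nonevent"].mean()),
        nri_nonevent_ci=ci("nri_nonevent"),
        n_repeats=n_repeats,
        per_repeat=per,
    )
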