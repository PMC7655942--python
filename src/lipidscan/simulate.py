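"""Synthetic two-cohort lipidomics generator with planted ground truth.

Emulates the structure of large ageing-cohort lipidomic studies (an
AIBL-like longitudinal plasma cohort and an ADNI-like baseline serum
cohort): a block-correlated log-normal species panel organised by lipid
class, analytical batches with embedded pooled-plasma QC samples and
multiplicative per-lipid batch drift, the usual clinical covariates,
prevalent diagnosis (CN/MCI/AD) generated from a logistic model with
planted per-SD lipid effects, and incident conversion generated from a
proportional-hazards model on the age scale (exponential baseline hazard,
left truncation at baseline age, administrative censoring).

Everything downstream of the generator can therefore be tested against a
known truth: planted effect sizes, correlation-block memberships and batch
factors are returned alongside the tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from lipidscan.nomenclature import PanelRegistry

__all__ = ["SimulationConfig", "SyntheticTruth", "generate_cohort", "default_panel"]

# (class, sphingoid base or None) for the desk-scale default panel
_DEFAULT_CLASSES: tuple[tuple[str, str | None], ...] = (
    ("PC", None),
    ("PE", None),
    ("TG", None),
    ("CE", None),
    ("LPC", None),
    ("SM", "d18:1"),
    ("Cer", "d18:1"),
    ("GM3", "d18:1"),
)


def default_panel(classes: int = 8, species_per_class: int = 25) -> list[str]:
    """Generate a valid shorthand species list: ``classes`` x ``species_per_class``.

    Glycerolipid/glycerophospholipid classes get sum-composition names
    (``PC(34:2)``); sphingolipid classes get base/acyl names
    (``SM(d18:1/24:1)``).  Names are unique and parse under the default
    grammar.
    """
    if classes > len(_DEFAULT_CLASSES):
        raise ValueError(
            f"default panel supports at most {len(_DEFAULT_CLASSES)} classes, got {classes}"
        )
    names: list[str] = []
    for cls, base in _DEFAULT_CLASSES[:classes]:
        made = 0
        if base is not None:
            for carbons in range(16, 27):
                for dbs in range(3):
                    if made >= species_per_class:
                        break
                    names.append(f"{cls}({base}/{carbons}:{dbs})")
                    made += 1
        else:
            start = 48 if cls == "TG" else (14 if cls in ("CE", "LPC", "AC") else 30)
            for carbons in range(start, start + 12):
                for dbs in range(4):
                    if made >= species_per_class:
                        break
                    names.append(f"{cls}({carbons}:{dbs})")
                    made += 1
        if made < species_per_class:
            raise ValueError(f"cannot make {species_per_class} species for class {cls}")
    return names


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults are a desk-scale cohort shaped like the ageing studies the
    pipeline targets: ~75 y mean age, ~57% female, APOE e4 allele counts
    (0/1/2) at (62%, 31%, 7%), CN/MCI/AD prevalence weights near 7:1:2.5,
    an exponential conversion hazard giving roughly 10% conversion over a
    4-9 year administrative follow-up, 8 lipid classes x 25 species with
    within-class correlation 0.5 over a 0.1 cohort-wide background, and
    batches of 120 samples carrying 4 pooled QC samples each with
    log-normal per-lipid scale drift (SD 0.1 on the log10 scale).
    """

    n_participants: int = 500
    n_timepoints: int = 1
    cohort_id: str = "COHORT_A"
    # AIBL-like cohorts carry a collection-site covariate; ADNI-like a
    # fasting-status covariate.
    has_site: bool = True
    has_fasting: bool = False
    prevalence_weights: tuple[float, float, float] = (0.67, 0.095, 0.235)  # CN, MCI, AD

    n_classes: int = 8
    species_per_class: int = 25
    rho_in: float = 0.5
    rho_out: float = 0.1

    samples_per_batch: int = 120
    qc_per_batch: int = 4
    batch_scale_sd: float = 0.1  # SD of log10 multiplicative batch factor
    qc_noise_sd: float = 0.02  # technical replicate noise of pooled QC, log10

    age_mean: float = 75.0
    age_sd: float = 6.9
    female_frac: float = 0.57
    bmi_mean: float = 26.3
    bmi_sd: float = 4.2
    chol_mean: float = 5.3
    chol_sd: float = 1.1
    hdl_mean: float = 1.55
    hdl_sd: float = 0.44
    trig_log_mean: float = 0.2  # natural-log scale
    trig_log_sd: float = 0.45
    apoe4_probs: tuple[float, float, float] = (0.62, 0.31, 0.07)
    statin_prob: float = 0.35
    omega3_prob: float = 0.2
    site_prob: float = 0.57  # P(site == "Melbourne") when has_site
    fasting_prob: float = 0.91  # P(fasted) when has_fasting

    # planted per-SD effects on the log-odds of prevalent AD and on the
    # log hazard of conversion, keyed by species name
    planted_prevalent: dict[str, float] = field(default_factory=dict)
    planted_incident: dict[str, float] = field(default_factory=dict)
    # covariate effects (log-odds / log-hazard per unit, age per year)
    prevalent_age_effect: float = 0.08
    prevalent_apoe_effect: float = 0.9
    prevalent_sex_effect: float = 0.0
    incident_apoe_effect: float = 0.7
    incident_sex_effect: float = 0.1
    incident_bmi_effect: float = -0.02

    baseline_hazard: float = 0.02  # per year, exponential on the age scale
    followup_min: float = 4.0
    followup_max: float = 9.0

    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.rho_out <= self.rho_in < 1.0):
            raise ValueError(
                "block correlation matrix not positive semi-definite: require "
                f"0 <= rho_out <= rho_in < 1, got rho_in={self.rho_in}, "
                f"rho_out={self.rho_out}"
            )
        w = self.prevalence_weights
        if abs(sum(w) - 1.0) > 1e-8 or min(w) < 0:
            raise ValueError(f"prevalence weights must be >= 0 and sum to 1, got {w}")


@dataclass
class SyntheticTruth:
    """Ground truth behind one generated cohort."""

    planted_prevalent: dict[str, float]
    planted_incident: dict[str, float]
    block_of: dict[str, str]  # species -> correlation block (class)
    batch_factors: pd.DataFrame  # batch x species multiplicative factors
    prevalent_linear_predictor: pd.Series  # per participant
    incident_linear_predictor: pd.Series
    prevalent_intercept: float


def _draw_block_normals(
    rng: np.random.Generator, n: int, blocks: np.ndarray, rho_in: float, rho_out: float
) -> np.ndarray:
    """n x p standard normals with corr rho_in within blocks, rho_out across."""
    p = blocks.size
    g_global = rng.standard_normal((n, 1))
    uniq = np.unique(blocks)
    g_block = rng.standard_normal((n, uniq.size))
    block_idx = np.searchsorted(uniq, blocks)
    eps = rng.standard_normal((n, p))
    z = (
        np.sqrt(rho_out) * g_global
        + np.sqrt(rho_in - rho_out) * g_block[:, block_idx]
        + np.sqrt(1.0 - rho_in) * eps
    )
    return z


def generate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate one cohort: concentration table, sample metadata, ground truth.

    Returns
    -------
    concentrations
        one row per acquired sample (participant-visits then per-batch QC
        rows), columns = species panel plus ``batch_id`` and ``is_qc``.
        Values are raw concentrations (positive) after multiplicative
        batch drift.
    metadata
        one row per participant-visit with the clinical covariates,
        diagnosis, follow-up and conversion status.
    truth
        planted effects, block memberships, batch factors and per-participant
        linear predictors.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    panel = default_panel(config.n_classes, config.species_per_class)
    registry = PanelRegistry.from_names(panel)
    block_of = registry.class_of
    blocks = np.array([block_of[s] for s in panel])
    p = len(panel)

    missing = [s for s in {**config.planted_prevalent, **config.planted_incident} if s not in panel]
    if missing:
        raise ValueError(f"planted species not in panel: {missing}")

    # per-species abundance scale on the log10 concentration scale
    mu = rng.uniform(0.5, 2.5, size=p)
    sd = rng.uniform(0.15, 0.3, size=p)

    n = config.n_participants
    T = config.n_timepoints

    # ---- covariates -------------------------------------------------------
    age = rng.normal(config.age_mean, config.age_sd, size=n)
    female = (rng.random(n) < config.female_frac).astype(int)
    bmi = rng.normal(config.bmi_mean, config.bmi_sd, size=n)
    chol = rng.normal(config.chol_mean, config.chol_sd, size=n)
    hdl = rng.normal(config.hdl_mean, config.hdl_sd, size=n).clip(min=0.4)
    trig = np.exp(rng.normal(config.trig_log_mean, config.trig_log_sd, size=n))
    apoe4 = rng.choice(3, size=n, p=config.apoe4_probs)
    statin = (rng.random(n) < config.statin_prob).astype(int)
    omega3 = (rng.random(n) < config.omega3_prob).astype(int)
    site = np.where(rng.random(n) < config.site_prob, "Melbourne", "Perth")
    fasting = (rng.random(n) < config.fasting_prob).astype(int)

    # ---- lipid latent structure ------------------------------------------
    # one standardized draw per participant-visit; outcomes are driven by
    # the visit actually used downstream (last visit for prevalent
    # diagnosis, baseline for incident conversion)
    z = _draw_block_normals(rng, n * T, blocks, config.rho_in, config.rho_out)
    z = z.reshape(n, T, p)
    z_baseline = z[:, 0, :]
    z_last = z[:, T - 1, :]

    beta_prev = np.array([config.planted_prevalent.get(s, 0.0) for s in panel])
    beta_inc = np.array([config.planted_incident.get(s, 0.0) for s in panel])

    eta_prev = (
        z_last @ beta_prev
        + config.prevalent_age_effect * (age - config.age_mean)
        + config.prevalent_apoe_effect * apoe4
        + config.prevalent_sex_effect * female
    )
    w_cn, w_mci, w_ad = config.prevalence_weights

    def mean_prev(alpha: float) -> float:
        return float(np.mean(expit(alpha + eta_prev))) - w_ad

    lo = float(logit(max(w_ad, 1e-6))) - abs(eta_prev).max() - 1.0
    hi = float(logit(min(max(w_ad, 1e-6), 1 - 1e-6))) + abs(eta_prev).max() + 1.0
    alpha = brentq(mean_prev, lo, hi)
    is_ad = rng.random(n) < expit(alpha + eta_prev)

    eta_inc = (
        z_baseline @ beta_inc
        + config.incident_apoe_effect * apoe4
        + config.incident_sex_effect * female
        + config.incident_bmi_effect * (bmi - config.bmi_mean)
    )

    # conversion: exponential hazard on the age scale, entry at baseline age;
    # memorylessness makes left truncation exact
    rate = config.baseline_hazard * np.exp(eta_inc)
    time_to_event = rng.exponential(1.0 / rate)
    horizon = rng.uniform(config.followup_min, config.followup_max, size=n)
    converted = (~is_ad) & (time_to_event < horizon)
    followup = np.where(is_ad, 0.0, np.minimum(time_to_event, horizon))

    # MCI: an intermediate latent-risk stratum among the non-AD — the
    # probability of an MCI label rises with the incident linear predictor
    # (so MCI enriches among future converters, as in the real cohorts)
    # without deterministically absorbing every high-risk participant
    diagnosis = np.where(is_ad, "AD", "CN").astype(object)
    non_ad_idx = np.flatnonzero(~is_ad)
    mci_frac = w_mci / max(w_cn + w_mci, 1e-12)
    if non_ad_idx.size and 0 < mci_frac < 1:
        eta_na = eta_inc[non_ad_idx]
        eta_std = (eta_na - eta_na.mean()) / max(eta_na.std(), 1e-12)

        def mean_mci(a: float) -> float:
            return float(np.mean(expit(a + eta_std))) - mci_frac

        a_mci = brentq(mean_mci, -30.0, 30.0)
        is_mci = rng.random(non_ad_idx.size) < expit(a_mci + eta_std)
        diagnosis[non_ad_idx[is_mci]] = "MCI"

    # ---- assemble visit rows ---------------------------------------------
    pid = [f"{config.cohort_id}_P{i:05d}" for i in range(n)]
    visit_rows = []
    log_conc_rows = []
    for t in range(T):
        for i in range(n):
            visit_rows.append(
                {
                    "sample_id": f"{pid[i]}_t{t}",
                    "participant_id": pid[i],
                    "cohort_id": config.cohort_id,
                    "timepoint": t,
                    "age": age[i] + 1.5 * t,
                    "sex": "F" if female[i] else "M",
                    "bmi": bmi[i],
                    "total_cholesterol": chol[i],
                    "hdl_c": hdl[i],
                    "triglycerides": trig[i],
                    "apoe4_count": int(apoe4[i]),
                    "statin": bool(statin[i]),
                    "omega3": bool(omega3[i]),
                    "site": site[i] if config.has_site else None,
                    "fasting": bool(fasting[i]) if config.has_fasting else None,
                    "diagnosis": diagnosis[i],
                    "followup_years": float(followup[i]),
                    "converted": bool(converted[i]),
                }
            )
            log_conc_rows.append(mu + sd * z[i, t, :])
    metadata = pd.DataFrame(visit_rows).set_index("sample_id")
    log_conc = np.vstack(log_conc_rows)
    sample_ids = list(metadata.index)

    # ---- batches and QC ---------------------------------------------------
    n_samples = len(sample_ids)
    n_batches = int(np.ceil(n_samples / config.samples_per_batch))
    batch_ids = np.repeat(
        [f"B{b + 1:02d}" for b in range(n_batches)], config.samples_per_batch
    )[:n_samples]
    log_factors = rng.normal(0.0, config.batch_scale_sd, size=(n_batches, p))
    batch_factors = pd.DataFrame(
        10.0 ** log_factors,
        index=[f"B{b + 1:02d}" for b in range(n_batches)],
        columns=panel,
    )

    qc_ids, qc_log, qc_batches = [], [], []
    for b in range(n_batches):
        for k in range(config.qc_per_batch):
            qc_ids.append(f"QC_B{b + 1:02d}_{k + 1}")
            qc_log.append(mu + rng.normal(0.0, config.qc_noise_sd, size=p))
            qc_batches.append(f"B{b + 1:02d}")

    all_ids = sample_ids + qc_ids
    all_log = np.vstack([log_conc, np.vstack(qc_log)])
    all_batches = np.concatenate([batch_ids, np.array(qc_batches)])
    batch_pos = {b: i for i, b in enumerate(batch_factors.index)}
    all_log = all_log + log_factors[[batch_pos[b] for b in all_batches], :]

    concentrations = pd.DataFrame(10.0 ** all_log, index=pd.Index(all_ids, name="sample_id"), columns=panel)
    concentrations["batch_id"] = all_batches
    concentrations["is_qc"] = [False] * len(sample_ids) + [True] * len(qc_ids)

    truth = SyntheticTruth(
        planted_prevalent=dict(config.planted_prevalent),
        planted_incident=dict(config.planted_incident),
        block_of=dict(block_of),
        batch_factors=batch_factors,
        prevalent_linear_predictor=pd.Series(alpha + eta_prev, index=pid),
        incident_linear_predictor=pd.Series(eta_inc, index=pid),
        prevalent_intercept=float(alpha),
    )
    return concentrations, metadata, truth


def two_cohort_configs(
    seed: int,
    n_participants: int = 500,
    planted_prevalent: dict[str, float] | None = None,
    planted_incident: dict[str, float] | None = None,
    **overrides,
) -> tuple[SimulationConfig, SimulationConfig]:
    """Paired AIBL-like / ADNI-like configs sharing one panel and planted truth.

    The two cohorts differ in design the way the real studies do: the
    first is a plasma cohort with a site covariate, slower conversion and
    long follow-up; the second a serum baseline cohort with a fasting
    covariate, faster conversion, shorter follow-up and an MCI-heavy case
    mix.
    """
    ss = np.random.SeedSequence(seed)
    s_a, s_b = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2))
    common = dict(
        n_participants=n_participants,
        planted_prevalent=planted_prevalent or {},
        planted_incident=planted_incident or {},
    )
    common.update(overrides)
    a_kw = dict(cohort_id="AIBL_SIM", has_site=True, has_fasting=False, seed=s_a)
    a_kw.update(common)
    b_kw = dict(
        cohort_id="ADNI_SIM",
        has_site=False,
        has_fasting=True,
        prevalence_weights=(0.30, 0.45, 0.25),
        baseline_hazard=0.10,
        followup_min=1.5,
        followup_max=3.5,
        seed=s_b,
    )
    b_kw.update(common)
    return SimulationConfig(**a_kw), SimulationConfig(**b_kw)
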