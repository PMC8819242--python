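"""Patient-level synthetic RCTs with the risk structure the analysis assumes.

The generator emulates a two-arm trial whose patients carry stable-state
type-2 biomarkers: each patient draws a stratum (low / high / very-high),
biomarkers uniformly within stratum-consistent bands (so classification
round-trips exactly), and an annual severe-attack count from a negative
binomial whose mean is

    mu = base_rate_low * m(stratum) * treatment_rr(stratum if active) * exposure

with ``m`` the risk-scale multiplier.  Counts are gamma-mixed Poisson
(negative binomial) because exacerbation counts in asthma trials are
overdispersed; the dispersion parameter ``k`` (variance = mu + mu^2/k)
defaults to 0.7, a conventional exacerbation-trial value, with the Poisson
limit available as ``dispersion=inf``.  The default treatment effect is the
counterfactual rule: active treatment collapses each stratum's rate to the
biomarker-low rate (rate ratio 1/m; no effect in the low stratum).

Aggregating simulated patients to stratum-arm records and pushing them
through the comparison pipeline recovers the generating multipliers and
treatment effects — the parameter-recovery check used by the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .risk_model import (
    STRATA,
    RiskScale,
    Thresholds,
    Type2Stratum,
    classify_stratum_arrays,
)
from .trial_ingest import StratumArmRecord, TrialTable, annualise_from_incidence

__all__ = [
    "SimConfig",
    "DEFAULT_STRATUM_PROBS",
    "DEFAULT_BIOMARKER_BANDS",
    "simulate_trial",
    "aggregate_to_table",
    "binary_endpoint_incidence",
    "recover_scale",
    "ScaleRecovery",
    "recovery_study",
]

#: Default stratum mix: the pooled composition of the four reference trials
#: (814 low / 3925 high / 243 very-high of 4982 stratified patients).
DEFAULT_STRATUM_PROBS = {
    "low": 814 / 4982,
    "high": 3925 / 4982,
    "very_high": 243 / 4982,
}

#: Uniform biomarker sampling bands per stratum, (eos_lo, eos_hi) x10^9/L and
#: (feno_lo, feno_hi) ppb.  Chosen inside the default thresholds so every
#: sampled profile classifies back into its generating stratum.
DEFAULT_BIOMARKER_BANDS = {
    "low": ((0.0, 0.15), (0.0, 25.0)),
    "high": ((0.15, 0.30), (25.0, 50.0)),
    "very_high": ((0.30, 1.50), (50.0, 150.0)),
}

PATIENT_COLUMNS = (
    "patient_id",
    "arm",
    "eosinophils",
    "feno",
    "stratum",
    "attacks",
    "exposure",
)


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for one synthetic two-arm trial.

    Parameters
    ----------
    n_per_arm
        Patients randomised to each arm.
    stratum_probs
        Sampling probabilities over {low, high, very_high}; must sum to 1.
        Default: the pooled stratum mix of the four reference trials.
    biomarker_bands
        Per-stratum uniform ranges ((eos_lo, eos_hi), (feno_lo, feno_hi));
        must be consistent with `thresholds` (checked at simulation time by
        reclassifying every sampled profile).
    base_rate_low
        Control-arm attack rate in the low stratum, attacks per
        patient-year.  Default 0.5 (mid-range of the reference trials'
        low-stratum control rates, 0.05-1.98).
    scale
        Risk-scale multipliers applied to `base_rate_low` per stratum.
    treatment_rr_by_stratum
        Multiplicative active-arm effect per stratum.  ``None`` (default)
        means the counterfactual rule, 1/m per stratum — i.e. 1.0 in low.
    dispersion
        Negative-binomial dispersion k > 0 (variance = mu + mu^2/k);
        ``math.inf`` gives Poisson counts.  Default 0.7.
    followup_years
        Exposure per patient (annualised rates ⇒ default 1.0).
    exposure_jitter
        Half-width of a uniform perturbation of exposure (robustness tests
        only; default 0 = fixed exposure).
    seed
        Seed for the single `numpy` generator driving all sampling.
    """

    n_per_arm: int = 50_000
    stratum_probs: dict = field(default_factory=lambda: dict(DEFAULT_STRATUM_PROBS))
    biomarker_bands: dict = field(default_factory=lambda: dict(DEFAULT_BIOMARKER_BANDS))
    base_rate_low: float = 0.5
    scale: RiskScale = field(default_factory=RiskScale)
    thresholds: Thresholds = field(default_factory=Thresholds)
    treatment_rr_by_stratum: Optional[dict] = None
    dispersion: float = 0.7
    followup_years: float = 1.0
    exposure_jitter: float = 0.0
    seed: int = 0

    def treatment_rr(self) -> dict[str, float]:
        """Per-stratum active-arm rate ratio; counterfactual rule by default."""
        if self.treatment_rr_by_stratum is None:
            return {s.value: 1.0 / self.scale.multiplier(s) for s in STRATA}
        return {Type2Stratum(k).value: float(v) for k, v in self.treatment_rr_by_stratum.items()}

    def validate(self) -> None:
        if self.n_per_arm <= 0:
            raise ValueError("n_per_arm must be > 0")
        probs = {Type2Stratum(k).value: float(v) for k, v in self.stratum_probs.items()}
        if any(not 0.0 <= p <= 1.0 for p in probs.values()):
            raise ValueError("stratum probabilities must lie in [0, 1]")
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ValueError(f"stratum probabilities must sum to 1, got {sum(probs.values())!r}")
        for s, ((e0, e1), (f0, f1)) in self.biomarker_bands.items():
            Type2Stratum(s)
            if not (0 <= e0 < e1 and 0 <= f0 < f1):
                raise ValueError(f"invalid biomarker band for stratum {s!r}")
        if not self.base_rate_low > 0:
            raise ValueError("base_rate_low must be > 0")
        if not self.dispersion > 0:
            raise ValueError("dispersion must be > 0 (inf for Poisson)")
        if not self.followup_years > 0:
            raise ValueError("followup_years must be > 0")
        if not 0 <= self.exposure_jitter < self.followup_years:
            raise ValueError("exposure_jitter must lie in [0, followup_years)")
        for s, rr in self.treatment_rr().items():
            if not (rr > 0 and math.isfinite(rr)):
                raise ValueError(f"treatment rate ratio for {s!r} must be in (0, inf)")


def _sample_counts(rng: np.random.Generator, mu: np.ndarray, k: float) -> np.ndarray:
    if math.isinf(k):
        return rng.poisson(mu)
    # NB with mean mu, variance mu + mu^2/k: n = k, p = k/(k+mu)
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    out[pos] = rng.negative_binomial(k, k / (k + mu[pos]))
    return out


def simulate_trial(config: SimConfig) -> pd.DataFrame:
    """Simulate one two-arm trial; returns one row per patient.

    Columns: patient_id, arm (control/active), eosinophils, feno, stratum,
    attacks (integer count), exposure (patient-years).  Fully reproducible
    from ``config.seed``; identical configs yield identical frames.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    probs = {Type2Stratum(k).value: float(v) for k, v in config.stratum_probs.items()}
    labels = [s.value for s in STRATA]
    p = np.array([probs.get(s, 0.0) for s in labels])
    rr = config.treatment_rr()

    frames = []
    for arm in ("control", "active"):
        n = config.n_per_arm
        strata = rng.choice(labels, size=n, p=p)
        eos = np.empty(n)
        feno = np.empty(n)
        for s in labels:
            mask = strata == s
            if not mask.any():
                continue
            (e0, e1), (f0, f1) = config.biomarker_bands[s]
            eos[mask] = rng.uniform(e0, e1, size=mask.sum())
            feno[mask] = rng.uniform(f0, f1, size=mask.sum())
        exposure = np.full(n, config.followup_years)
        if config.exposure_jitter > 0:
            exposure += rng.uniform(-config.exposure_jitter, config.exposure_jitter, size=n)
        m_map = {s: config.scale.multiplier(Type2Stratum(s)) for s in labels}
        mu = config.base_rate_low * np.array([m_map[s] for s in strata]) * exposure
        if arm == "active":
            mu = mu * np.array([rr[s] for s in strata])
        attacks = _sample_counts(rng, mu, config.dispersion)
        frames.append(
            pd.DataFrame(
                {
                    "arm": arm,
                    "eosinophils": eos,
                    "feno": feno,
                    "stratum": strata,
                    "attacks": attacks,
                    "exposure": exposure,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    df.insert(0, "patient_id", np.arange(len(df)))

    # biomarker bands must be consistent with the thresholds: round-trip check
    reclassified = classify_stratum_arrays(
        df["eosinophils"].to_numpy(), df["feno"].to_numpy(), config.thresholds
    )
    mismatch = reclassified != df["stratum"].to_numpy()
    if mismatch.any():
        bad = df.loc[mismatch, "stratum"].unique().tolist()
        raise ValueError(
            f"biomarker_bands inconsistent with thresholds: sampled strata {bad} "
            "do not classify back into their generating stratum"
        )
    return df[list(PATIENT_COLUMNS)]


def aggregate_to_table(
    records: pd.DataFrame,
    thresholds: Thresholds = Thresholds(),
    trial_id: str = "SIM",
) -> TrialTable:
    """Aggregate patient rows to stratum-arm records.

    Per (stratum, arm): n = patient count, rate = total attacks / total
    exposure (attacks per patient-year).  Strata with no patients are simply
    absent from the table; cells with zero total exposure are excluded.
    Classification is recomputed from the biomarkers with `thresholds`, so
    the aggregation does not trust the generator's stratum labels.
    """
    if len(records) == 0:
        raise ValueError("no patient records to aggregate")
    df = records.copy()
    df["stratum"] = classify_stratum_arrays(
        df["eosinophils"].to_numpy(), df["feno"].to_numpy(), thresholds
    )
    out = []
    for (stratum, arm), grp in df.groupby(["stratum", "arm"], sort=False):
        exposure = float(grp["exposure"].sum())
        if exposure <= 0:
            import warnings

            warnings.warn(f"cell ({stratum}, {arm}) has zero exposure; excluded")
            continue
        out.append(
            StratumArmRecord(
                trial_id=trial_id,
                stratum=Type2Stratum(stratum),
                arm=arm,
                n=int(len(grp)),
                rate=float(grp["attacks"].sum()) / exposure,
                source="observed",
            )
        )
    order = {s.value: i for i, s in enumerate(STRATA)}
    out.sort(key=lambda r: (order[r.stratum.value], r.arm != "control"))
    return TrialTable.from_records(out, provenance=f"aggregated from {len(records)} simulated patients")


def binary_endpoint_incidence(records: pd.DataFrame) -> pd.DataFrame:
    """Derive the 52-week binary endpoint per (stratum, arm).

    Returns columns stratum, arm, n, incidence (fraction of patients with
    >=1 attack) and rate_imputed (= -log10(1 - incidence)), mirroring how a
    trial reporting only percentage incidence is annualised on ingest.
    """
    rows = []
    for (stratum, arm), grp in records.groupby(["stratum", "arm"], sort=False):
        incidence = float((grp["attacks"] >= 1).mean())
        rows.append(
            {
                "stratum": stratum,
                "arm": arm,
                "n": int(len(grp)),
                "incidence": incidence,
                "rate_imputed": annualise_from_incidence(incidence)
                if incidence < 1.0
                else math.inf,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ScaleRecovery:
    """Scale multipliers and treatment effects estimated from one table."""

    m_high: float
    m_very_high: Optional[float]
    treatment_rr: dict  # stratum label -> active/control rate ratio


def recover_scale(table: TrialTable) -> ScaleRecovery:
    """Invert the aggregation: estimate multipliers and treatment effects.

    m_hat for a stratum is its control rate over the low control rate; the
    treatment rate ratio is active/control within the stratum.  Requires
    low and high strata with both arms; very-high is optional (None when
    absent).  On a noiseless table built directly from the risk-scale
    predictions the recovery is exact.
    """
    trials = table.trials()
    if len(trials) != 1:
        raise ValueError(f"recovery expects a single-trial table, got {trials}")
    trial = trials[0]

    def _rate(stratum, arm):
        return table.rate(trial, stratum, arm)

    low_c = _rate(Type2Stratum.LOW, "control")
    high_c = _rate(Type2Stratum.HIGH, "control")
    if low_c is None or high_c is None or _rate(Type2Stratum.LOW, "active") is None or _rate(Type2Stratum.HIGH, "active") is None:
        raise ValueError("recovery requires low and high strata with both arms")
    if low_c == 0:
        raise ValueError("low-stratum control rate is 0; multipliers undefined")
    very_c = _rate(Type2Stratum.VERY_HIGH, "control")
    rr = {}
    for s in STRATA:
        c, a = _rate(s, "control"), _rate(s, "active")
        if c is not None and a is not None and c > 0:
            rr[s.value] = a / c
    return ScaleRecovery(
        m_high=high_c / low_c,
        m_very_high=None if very_c is None else very_c / low_c,
        treatment_rr=rr,
    )


def recovery_study(
    config: SimConfig, n_replicates: int = 20, seed: int = 0
) -> pd.DataFrame:
    """Replicate simulation -> aggregation -> recovery for MC uncertainty.

    Each replicate re-runs :func:`simulate_trial` with a child seed drawn
    from `seed`; returns one row per replicate with the recovered m_high,
    m_very_high and per-stratum treatment rate ratios.  Summarise with
    ``df.mean()`` / ``df.std()``.
    """
    if n_replicates <= 0:
        raise ValueError("n_replicates must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        child = int(rng.integers(0, 2**31 - 1))
        patients = simulate_trial(replace(config, seed=child))
        rec = recover_scale(aggregate_to_table(patients, config.thresholds))
        rows.append(
            {
                "replicate": rep,
                "seed": child,
                "m_high": rec.m_high,
                "m_very_high": rec.m_very_high,
                "rr_low": rec.treatment_rr.get("low"),
                "rr_high": rec.treatment_rr.get("high"),
                "rr_very_high": rec.treatment_rr.get("very_high"),
            }
        )
    return pd.DataFrame(rows)
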