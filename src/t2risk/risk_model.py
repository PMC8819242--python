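"""Type-2 biomarker strata and the multiplicative attack-risk scale.

Asthma attack risk tracks type-2 airway inflammation, which is measured
non-invasively by two complementary biomarkers: the blood eosinophil count
(systemic compartment, x10^9 cells per L) and the exhaled nitric oxide
fraction FENO (airway compartment, ppb).  Patients are classified into three
mutually exclusive strata:

* ``low``        — eosinophils < 0.15 and FENO < 25 (both low)
* ``high``       — eosinophils >= 0.15 *or* FENO >= 25 (any biomarker high)
* ``very_high``  — eosinophils >= 0.30 *and* FENO >= 50 (both very high)

All cut-offs are inclusive (>=).  The risk scale models the annualised
severe-attack rate of a stratum as the biomarker-low rate times a
stratum-specific multiplier ``m`` (m = 1 for low).  The counterfactual
treatment hypothesis is that type-2 anti-inflammatory treatment removes
exactly the biomarker-conferred excess risk: the active-arm predicted rate of
every stratum collapses to the biomarker-low rate, so the predicted rate
ratio in a stratum is 1/m and the predicted percentage reduction is
1 - 1/m (0% in the low stratum by construction).

Default multipliers correspond to predicted reductions of 42% (high) and
72% (very high): m_high = 1/0.58, m_very_high = 1/0.28.  They are
configuration, not derived here, and can be overridden from a YAML/JSON file
(see :func:`load_scale_config`).
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import yaml

__all__ = [
    "Type2Stratum",
    "BiomarkerProfile",
    "Thresholds",
    "RiskScale",
    "classify_stratum",
    "classify_stratum_arrays",
    "predict_control_rate",
    "predict_active_rate",
    "predicted_reduction",
    "load_scale_config",
]


class Type2Stratum(str, enum.Enum):
    """Biomarker-defined risk stratum, ordered low < high < very_high."""

    LOW = "low"
    HIGH = "high"
    VERY_HIGH = "very_high"

    @property
    def rank(self) -> int:
        return _STRATUM_RANK[self]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


_STRATUM_RANK = {Type2Stratum.LOW: 0, Type2Stratum.HIGH: 1, Type2Stratum.VERY_HIGH: 2}

STRATA = (Type2Stratum.LOW, Type2Stratum.HIGH, Type2Stratum.VERY_HIGH)


def _require_finite_nonneg(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or value < 0:
        raise ValueError(f"{name} must be finite and >= 0, got {value!r}")
    return value


@dataclass(frozen=True)
class BiomarkerProfile:
    """One patient's stable-state biomarkers.

    Parameters
    ----------
    eosinophils
        Blood eosinophil count, x10^9 cells per L.
    feno
        Exhaled nitric oxide fraction, ppb.
    """

    eosinophils: float
    feno: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "eosinophils", _require_finite_nonneg("eosinophils", self.eosinophils)
        )
        object.__setattr__(self, "feno", _require_finite_nonneg("feno", self.feno))


@dataclass(frozen=True)
class Thresholds:
    """Biomarker cut-offs defining the strata (all inclusive, >=).

    Defaults: eosinophils 0.15 / 0.30 x10^9 per L, FENO 25 / 50 ppb for the
    high / very-high boundaries.
    """

    eos_high: float = 0.15
    eos_very_high: float = 0.30
    feno_high: float = 25.0
    feno_very_high: float = 50.0

    def __post_init__(self) -> None:
        if not (self.eos_very_high >= self.eos_high > 0):
            raise ValueError("require eos_very_high >= eos_high > 0")
        if not (self.feno_very_high >= self.feno_high > 0):
            raise ValueError("require feno_very_high >= feno_high > 0")


@dataclass(frozen=True)
class RiskScale:
    """Stratum rate multipliers relative to the biomarker-low stratum.

    ``m_high`` and ``m_very_high`` scale the low-stratum attack rate to the
    high and very-high strata.  Defaults are derived from predicted
    reductions of 42% and 72%: 1/(1-0.42) and 1/(1-0.72).
    """

    m_high: float = 1.0 / 0.58
    m_very_high: float = 1.0 / 0.28

    def __post_init__(self) -> None:
        if not (self.m_very_high >= self.m_high >= 1.0):
            raise ValueError("require m_very_high >= m_high >= 1")
        if not (math.isfinite(self.m_high) and math.isfinite(self.m_very_high)):
            raise ValueError("multipliers must be finite")

    def multiplier(self, stratum: Type2Stratum) -> float:
        """Rate multiplier of `stratum` relative to low."""
        stratum = Type2Stratum(stratum)
        if stratum is Type2Stratum.LOW:
            return 1.0
        if stratum is Type2Stratum.HIGH:
            return self.m_high
        return self.m_very_high

    @classmethod
    def from_reductions(cls, reduction_high: float, reduction_very_high: float) -> "RiskScale":
        """Build a scale from predicted proportional reductions (e.g. 0.42, 0.72)."""
        for name, r in (("reduction_high", reduction_high), ("reduction_very_high", reduction_very_high)):
            if not 0 <= r < 1:
                raise ValueError(f"{name} must lie in [0, 1), got {r!r}")
        return cls(m_high=1.0 / (1.0 - reduction_high), m_very_high=1.0 / (1.0 - reduction_very_high))


def classify_stratum(
    profile: BiomarkerProfile, thresholds: Thresholds = Thresholds()
) -> Type2Stratum:
    """Classify a biomarker profile into its type-2 stratum.

    very_high requires BOTH biomarkers at or above their very-high cut-offs;
    high requires EITHER biomarker at or above its high cut-off; otherwise
    low.  The predicates are evaluated in that order, so the labels are
    mutually exclusive and exhaustive.
    """
    eos, feno = profile.eosinophils, profile.feno
    if eos >= thresholds.eos_very_high and feno >= thresholds.feno_very_high:
        return Type2Stratum.VERY_HIGH
    if eos >= thresholds.eos_high or feno >= thresholds.feno_high:
        return Type2Stratum.HIGH
    return Type2Stratum.LOW


def classify_stratum_arrays(
    eosinophils: np.ndarray,
    feno: np.ndarray,
    thresholds: Thresholds = Thresholds(),
) -> np.ndarray:
    """Vectorised :func:`classify_stratum` over parallel biomarker arrays.

    Returns an object array of stratum label strings ("low"/"high"/"very_high").
    """
    eos = np.asarray(eosinophils, dtype=float)
    fen = np.asarray(feno, dtype=float)
    if not (np.all(np.isfinite(eos)) and np.all(np.isfinite(fen))):
        raise ValueError("biomarker arrays must be finite")
    if np.any(eos < 0) or np.any(fen < 0):
        raise ValueError("biomarker arrays must be non-negative")
    out = np.full(eos.shape, Type2Stratum.LOW.value, dtype=object)
    high = (eos >= thresholds.eos_high) | (fen >= thresholds.feno_high)
    very = (eos >= thresholds.eos_very_high) & (fen >= thresholds.feno_very_high)
    out[high] = Type2Stratum.HIGH.value
    out[very] = Type2Stratum.VERY_HIGH.value
    return out


def predict_control_rate(
    low_rate: float, stratum: Type2Stratum, scale: RiskScale = RiskScale()
) -> float:
    """Predicted control-arm annualised attack rate for a stratum.

    `low_rate` is the biomarker-low control rate (attacks per patient-year);
    the stratum rate is ``low_rate * m`` with m the stratum multiplier.
    """
    low_rate = _require_finite_nonneg("low_rate", low_rate)
    return low_rate * scale.multiplier(stratum)


def predict_active_rate(low_rate: float, stratum: Type2Stratum) -> float:
    """Predicted active-arm rate under the counterfactual treatment rule.

    Anti-inflammatory treatment is assumed to remove exactly the
    biomarker-conferred excess: every stratum's active-arm rate equals the
    biomarker-low rate (and the low stratum is unchanged — no effect when
    biomarkers are low).
    """
    low_rate = _require_finite_nonneg("low_rate", low_rate)
    Type2Stratum(stratum)  # validate label
    return low_rate


def predicted_reduction(stratum: Type2Stratum, scale: RiskScale = RiskScale()) -> float:
    """Predicted proportional attack-rate reduction, 1 - 1/m for the stratum.

    Independent of the low-stratum rate; 0.0 in the low stratum.
    """
    return 1.0 - 1.0 / scale.multiplier(stratum)


def load_scale_config(path: Union[str, Path]) -> tuple[Thresholds, RiskScale]:
    """Read thresholds and scale multipliers from a YAML or JSON file.

    Schema (all keys optional; defaults fill in the rest)::

        thresholds:
          eos_high: 0.15        # x10^9 per L
          eos_very_high: 0.30
          feno_high: 25         # ppb
          feno_very_high: 50
        scale:
          m_high: 1.724         # rate multiplier vs low stratum
          m_very_high: 3.571

    Unknown keys raise ``ValueError``.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"scale config must be a mapping, got {type(data).__name__}")
    unknown = set(data) - {"thresholds", "scale"}
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")

    def _build(cls, section_name, allowed):
        section = data.get(section_name) or {}
        if not isinstance(section, dict):
            raise ValueError(f"config section {section_name!r} must be a mapping")
        bad = set(section) - allowed
        if bad:
            raise ValueError(f"unknown keys in {section_name!r}: {sorted(bad)}")
        return cls(**{k: float(v) for k, v in section.items()})

    thresholds = _build(
        Thresholds, "thresholds", {"eos_high", "eos_very_high", "feno_high", "feno_very_high"}
    )
    scale = _build(RiskScale, "scale", {"m_high", "m_very_high"})
    return thresholds, scale
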