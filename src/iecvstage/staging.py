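"""Control-anchored fibrosis staging.

The upper limit of normal for iECV is derived from healthy volunteers as
mean + 2 SD (sample SD, n-1 denominator).  AS patients are then
classified hierarchically:

1. infarct-pattern LGE anywhere          -> ``excluded_infarct``
2. metrics unavailable (incomplete T1)   -> ``unclassified``
3. mid-wall LGE present                  -> ``replacement`` (overrides iECV)
4. iECV >= threshold                     -> ``expansion``
5. otherwise                             -> ``normal``

A value exactly at the threshold is expansion (the rule is ">=").
Controls are never staged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .metrics import LGE_INFARCT, LGE_MIDWALL, LGE_NONE
from .utils import round_half_up

__all__ = [
    "STAGE_NORMAL",
    "STAGE_EXPANSION",
    "STAGE_REPLACEMENT",
    "STAGE_EXCLUDED_INFARCT",
    "STAGE_UNCLASSIFIED",
    "CLASSIFIABLE_STAGES",
    "ThresholdSpec",
    "FibrosisStager",
    "StageSummary",
    "derive_threshold",
    "classify_subject",
    "stage_cohort",
]

STAGE_NORMAL = "normal"
STAGE_EXPANSION = "expansion"
STAGE_REPLACEMENT = "replacement"
STAGE_EXCLUDED_INFARCT = "excluded_infarct"
STAGE_UNCLASSIFIED = "unclassified"
CLASSIFIABLE_STAGES = (STAGE_NORMAL, STAGE_EXPANSION, STAGE_REPLACEMENT)


@dataclass(frozen=True)
class ThresholdSpec:
    """iECV upper limit of normal derived from a control sample."""

    control_mean: float
    control_sd: float
    threshold: float
    n_controls: int

    @classmethod
    def from_stats(
        cls, control_mean: float, control_sd: float, n_controls: int = 2,
        sd_multiplier: float = 2.0,
    ) -> "ThresholdSpec":
        """Build the mean + k*SD threshold directly from summary statistics."""
        if control_sd < 0:
            raise ValueError("control SD must be >= 0")
        if n_controls < 2:
            raise ValueError("need at least 2 controls")
        return cls(
            control_mean=float(control_mean),
            control_sd=float(control_sd),
            threshold=float(control_mean) + sd_multiplier * float(control_sd),
            n_controls=int(n_controls),
        )


class FibrosisStager(BaseEstimator):
    """Reference-range classifier for myocardial fibrosis stage.

    Parameters
    ----------
    sd_multiplier : float, default 2.0
        ``threshold = control mean + sd_multiplier * control SD``.
    fixed_threshold : float or None
        Bypass derivation and use a fixed iECV cut (ml/m^2); ``fit`` may
        then be called with ``X=None``.

    Attributes (after ``fit``)
    --------------------------
    control_mean_, control_sd_, threshold_, n_controls_, threshold_spec_
    """

    def __init__(self, sd_multiplier: float = 2.0, fixed_threshold: float | None = None):
        self.sd_multiplier = sd_multiplier
        self.fixed_threshold = fixed_threshold

    def fit(self, X=None, y=None) -> "FibrosisStager":
        """Fit on control iECV values (1-D array-like, ml/m^2)."""
        if self.fixed_threshold is not None:
            if not np.isfinite(self.fixed_threshold):
                raise ValueError("fixed_threshold must be finite")
            self.control_mean_ = np.nan
            self.control_sd_ = np.nan
            self.n_controls_ = 0
            self.threshold_ = float(self.fixed_threshold)
            self.threshold_spec_ = ThresholdSpec(
                np.nan, np.nan, self.threshold_, 0
            )
            return self
        x = np.asarray(X, dtype=float).ravel()
        x = x[np.isfinite(x)]
        if x.size < 2:
            raise ValueError("need >= 2 finite control iECV values")
        self.control_mean_ = float(np.mean(x))
        self.control_sd_ = float(np.std(x, ddof=1))
        self.n_controls_ = int(x.size)
        self.threshold_ = self.control_mean_ + self.sd_multiplier * self.control_sd_
        self.threshold_spec_ = ThresholdSpec(
            self.control_mean_, self.control_sd_, self.threshold_, self.n_controls_
        )
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "threshold_"):
            raise AttributeError("FibrosisStager is not fitted; call fit() first")

    def predict(self, X) -> np.ndarray:
        """Stage subjects given ``(iecv, lge_status)`` pairs.

        ``X`` may be a DataFrame with columns ``iecv``/``iecv_ml_m2`` and
        ``lge``/``lge_status``, or a 2-column array of (iecv, lge flag).
        NaN iECV means metrics unavailable.
        """
        self._check_fitted()
        if isinstance(X, pd.DataFrame):
            icol = "iecv" if "iecv" in X.columns else "iecv_ml_m2"
            lcol = "lge" if "lge" in X.columns else "lge_status"
            iecv = X[icol].to_numpy(float)
            lge = X[lcol].to_numpy(str)
        else:
            arr = np.asarray(X, dtype=object)
            if arr.ndim != 2 or arr.shape[1] != 2:
                raise ValueError("X must be (n, 2): iecv, lge flag")
            iecv = arr[:, 0].astype(float)
            lge = arr[:, 1].astype(str)
        bad = ~np.isin(lge, (LGE_NONE, LGE_MIDWALL, LGE_INFARCT))
        if bad.any():
            raise ValueError(f"unknown LGE flags: {sorted(set(lge[bad]))}")
        out = np.empty(len(iecv), dtype=object)
        missing = ~np.isfinite(iecv)
        out[:] = np.where(iecv >= self.threshold_, STAGE_EXPANSION, STAGE_NORMAL)
        out[missing] = STAGE_UNCLASSIFIED
        out[(lge == LGE_MIDWALL) & ~missing] = STAGE_REPLACEMENT
        out[lge == LGE_INFARCT] = STAGE_EXCLUDED_INFARCT
        return out


def derive_threshold(control_iecvs) -> ThresholdSpec:
    """Mean + 2 SD threshold from raw control iECV values."""
    return FibrosisStager().fit(control_iecvs).threshold_spec_


def classify_subject(iecv: float | None, lge_status: str, threshold: ThresholdSpec) -> str:
    """Stage one subject; ``iecv=None``/NaN marks metrics unavailable."""
    stager = FibrosisStager(fixed_threshold=threshold.threshold).fit()
    x = np.nan if iecv is None else float(iecv)
    return stager.predict(pd.DataFrame({"iecv": [x], "lge": [lge_status]}))[0]


@dataclass
class StageSummary:
    """Stage counts with exclusion bookkeeping."""

    counts: dict
    n_classifiable: int
    n_excluded_infarct: int
    n_unclassified: int
    proportions: dict          # fractions of classifiable subjects
    proportions_pct: dict      # integer percentages, half-up

    @classmethod
    def from_counts(cls, counts: dict) -> "StageSummary":
        n_class = sum(counts.get(s, 0) for s in CLASSIFIABLE_STAGES)
        if n_class == 0:
            warnings.warn(
                "no classifiable subjects; stage proportions undefined",
                stacklevel=2,
            )
            props = {s: np.nan for s in CLASSIFIABLE_STAGES}
            pcts = {s: np.nan for s in CLASSIFIABLE_STAGES}
        else:
            props = {s: counts.get(s, 0) / n_class for s in CLASSIFIABLE_STAGES}
            pcts = {s: int(round_half_up(100 * p)) for s, p in props.items()}
        return cls(
            counts=dict(counts),
            n_classifiable=n_class,
            n_excluded_infarct=counts.get(STAGE_EXCLUDED_INFARCT, 0),
            n_unclassified=counts.get(STAGE_UNCLASSIFIED, 0),
            proportions=props,
            proportions_pct=pcts,
        )


def stage_cohort(
    subjects: pd.DataFrame,
    threshold: ThresholdSpec | FibrosisStager,
) -> tuple[pd.DataFrame, StageSummary]:
    """Stage every AS subject in a metrics table.

    ``subjects`` needs ``iecv``/``iecv_ml_m2`` and ``lge``/``lge_status``
    columns (controls should already be excluded).  Returns the table
    with a ``stage`` column plus a :class:`StageSummary`.
    """
    if isinstance(threshold, FibrosisStager):
        stager = threshold
        stager._check_fitted()
    else:
        stager = FibrosisStager(fixed_threshold=threshold.threshold).fit()
    staged = subjects.copy()
    staged["stage"] = stager.predict(subjects)
    staged["threshold_ml_m2"] = stager.threshold_
    counts = staged["stage"].value_counts().to_dict()
    return staged, StageSummary.from_counts(counts)
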