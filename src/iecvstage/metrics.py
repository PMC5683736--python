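"""T1-mapping derived extracellular-volume metrics.

Per-subject inputs are ROI-level T1 values: six mid-cavity myocardial
segments (native and 20-min post-contrast), a blood-pool T1 pair, and a
hematocrit.  From these the module derives the partition coefficient

    lambda = dR1_myo / dR1_blood,    dR1 = 1/T1_post - 1/T1_native,

the extracellular volume fraction ECV = lambda * (1 - Hct), and the
indexed extracellular volume

    iECV = ECV * (LV mass / myocardial density) / BSA   [ml/m^2],

a measure of the *total* extracellular compartment of the left ventricle.
Segment inclusion follows the staging convention: segments with mid-wall
LGE are analysed, segments with infarct-pattern (subendocardial) LGE are
excluded.  Segment T1s are averaged before conversion to R1.

BSA uses the Du Bois formula; LV mass converts to end-diastolic
myocardial volume with a density of 1.05 g/ml (standard CMR convention,
overridable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MYOCARDIAL_DENSITY_G_PER_ML",
    "LGE_NONE",
    "LGE_MIDWALL",
    "LGE_INFARCT",
    "Segment",
    "SegmentalT1Panel",
    "EcvMetrics",
    "MetricsUnavailableError",
    "bsa_du_bois",
    "select_usable_segments",
    "partition_coefficient",
    "ecv_fraction",
    "indexed_volume",
    "compute_ecv_metrics",
    "compute_cohort_metrics",
]

MYOCARDIAL_DENSITY_G_PER_ML = 1.05

LGE_NONE = "none"
LGE_MIDWALL = "midwall"
LGE_INFARCT = "infarct"
_LGE_LEVELS = (LGE_NONE, LGE_MIDWALL, LGE_INFARCT)


class MetricsUnavailableError(ValueError):
    """ECV metrics cannot be computed (no usable segments / missing T1).

    Consumers treat this as the "incomplete T1 mapping" state: staging
    maps it to UNCLASSIFIED rather than failing the whole cohort.
    """


@dataclass(frozen=True)
class Segment:
    native_t1: float
    post_t1: float
    lge: str = LGE_NONE


@dataclass(frozen=True)
class SegmentalT1Panel:
    """Six mid-cavity segment T1 pairs plus blood pool and hematocrit."""

    segments: tuple[Segment, ...]
    blood_native_t1: float
    blood_post_t1: float
    hematocrit: float

    def __post_init__(self) -> None:
        if len(self.segments) != 6:
            raise ValueError(f"expected 6 segments, got {len(self.segments)}")
        for seg in self.segments:
            if seg.lge not in _LGE_LEVELS:
                raise ValueError(f"unknown LGE flag {seg.lge!r}")
        if not (0.0 < self.hematocrit < 1.0):
            raise ValueError(f"hematocrit must be in (0, 1), got {self.hematocrit}")
        for v in (self.blood_native_t1, self.blood_post_t1):
            if not (math.isfinite(v) and v > 0):
                raise ValueError("blood T1 values must be positive and finite")
        if not self.blood_post_t1 < self.blood_native_t1:
            raise ValueError("blood post-contrast T1 must be below native T1")


@dataclass(frozen=True)
class EcvMetrics:
    """Derived per-subject extracellular-volume metrics."""

    native_t1_mean: float
    post_t1_mean: float
    partition_coefficient: float
    ecv_fraction: float
    myocardial_volume_ml: float
    fibrosis_volume_ml: float
    iecv_ml_m2: float
    n_segments_used: int


def bsa_du_bois(height_cm: float, weight_kg: float) -> float:
    """Body surface area (m^2), Du Bois: 0.007184 * W^0.425 * H^0.725."""
    height_cm = float(height_cm)
    weight_kg = float(weight_kg)
    if not (height_cm > 0 and weight_kg > 0):
        raise ValueError("height and weight must be positive")
    return 0.007184 * weight_kg**0.425 * height_cm**0.725


def select_usable_segments(panel: SegmentalT1Panel) -> tuple[Segment, ...]:
    """Segments entering the T1 analysis: mid-wall LGE kept, infarct dropped."""
    usable = tuple(
        s for s in panel.segments
        if s.lge != LGE_INFARCT
        and math.isfinite(s.native_t1)
        and math.isfinite(s.post_t1)
    )
    if not usable:
        raise MetricsUnavailableError("no usable segments after exclusions")
    return usable


def partition_coefficient(
    native_myo: float, post_myo: float, blood_native: float, blood_post: float
) -> float:
    """lambda = (1/post_myo - 1/native_myo) / (1/blood_post - 1/blood_native)."""
    for v in (native_myo, post_myo, blood_native, blood_post):
        if not (math.isfinite(v) and v > 0):
            raise ValueError("T1 values must be positive and finite")
    if not post_myo < native_myo:
        raise ValueError("post-contrast myocardial T1 must be below native T1")
    dr1_blood = 1.0 / blood_post - 1.0 / blood_native
    if dr1_blood <= 0:
        raise ValueError("non-physiologic contrast kinetics: blood dR1 <= 0")
    dr1_myo = 1.0 / post_myo - 1.0 / native_myo
    return dr1_myo / dr1_blood


def ecv_fraction(partition_coeff: float, hematocrit: float) -> float:
    """ECV = lambda * (1 - Hct)."""
    if not (0.0 <= hematocrit < 1.0):
        raise ValueError(f"hematocrit must be in [0, 1), got {hematocrit}")
    if not (math.isfinite(partition_coeff) and partition_coeff > 0):
        raise ValueError("partition coefficient must be positive and finite")
    return partition_coeff * (1.0 - hematocrit)


def indexed_volume(volume_ml: float, bsa_m2: float) -> float:
    """Index a volume to body surface area (ml -> ml/m^2)."""
    if not bsa_m2 > 0:
        raise ValueError("BSA must be positive")
    return volume_ml / bsa_m2


def compute_ecv_metrics(
    panel: SegmentalT1Panel,
    lv_mass_g: float,
    bsa_m2: float,
    density_g_per_ml: float = MYOCARDIAL_DENSITY_G_PER_ML,
) -> EcvMetrics:
    """Full per-subject metric chain from a segmental panel.

    Raises :class:`MetricsUnavailableError` when no segment survives the
    LGE exclusion rule, and ``ValueError`` for non-physiologic inputs.
    """
    if not (lv_mass_g > 0 and bsa_m2 > 0 and density_g_per_ml > 0):
        raise ValueError("lv_mass, bsa and density must be positive")
    usable = select_usable_segments(panel)
    native_mean = float(np.mean([s.native_t1 for s in usable]))
    post_mean = float(np.mean([s.post_t1 for s in usable]))
    lam = partition_coefficient(
        native_mean, post_mean, panel.blood_native_t1, panel.blood_post_t1
    )
    ecv = ecv_fraction(lam, panel.hematocrit)
    myo_vol = lv_mass_g / density_g_per_ml
    fib_vol = ecv * myo_vol
    return EcvMetrics(
        native_t1_mean=native_mean,
        post_t1_mean=post_mean,
        partition_coefficient=lam,
        ecv_fraction=ecv,
        myocardial_volume_ml=myo_vol,
        fibrosis_volume_ml=fib_vol,
        iecv_ml_m2=indexed_volume(fib_vol, bsa_m2),
        n_segments_used=len(usable),
    )


# --------------------------------------------------------------------- #
# cohort-table interface


def _seg_cols(stub: str) -> list[str]:
    return [f"seg{i}_{stub}" for i in range(1, 7)]


def compute_cohort_metrics(
    cohort: pd.DataFrame,
    density_g_per_ml: float = MYOCARDIAL_DENSITY_G_PER_ML,
) -> pd.DataFrame:
    """Vectorised metric computation over a cohort table.

    Expects the cohort CSV schema (``seg{1..6}_native_t1_ms``,
    ``seg{1..6}_post_t1_ms``, ``seg{1..6}_lge``, ``blood_native_t1_ms``,
    ``blood_post_t1_ms``, ``hematocrit``, ``lv_mass_g``, ``height_cm``,
    ``weight_kg``).  Subjects whose panel is unusable (all segments
    infarct-flagged or T1 missing) get NaN metrics and a non-``ok``
    ``metrics_status`` instead of an exception, mirroring how an imaging
    core lab would carry incomplete studies forward for exclusion
    bookkeeping.
    """
    n = len(cohort)
    native = cohort[_seg_cols("native_t1_ms")].to_numpy(float)
    post = cohort[_seg_cols("post_t1_ms")].to_numpy(float)
    lge = cohort[_seg_cols("lge")].to_numpy(str)

    usable = (lge != LGE_INFARCT) & np.isfinite(native) & np.isfinite(post)
    n_used = usable.sum(axis=1)
    with np.errstate(invalid="ignore"):
        native_mean = np.where(
            n_used > 0, np.nansum(np.where(usable, native, 0.0), axis=1) / np.maximum(n_used, 1), np.nan
        )
        post_mean = np.where(
            n_used > 0, np.nansum(np.where(usable, post, 0.0), axis=1) / np.maximum(n_used, 1), np.nan
        )

    blood_nat = cohort["blood_native_t1_ms"].to_numpy(float)
    blood_post = cohort["blood_post_t1_ms"].to_numpy(float)
    hct = cohort["hematocrit"].to_numpy(float)
    bsa = np.array(
        [bsa_du_bois(h, w) for h, w in zip(cohort["height_cm"], cohort["weight_kg"])]
    )
    lv_mass = cohort["lv_mass_g"].to_numpy(float)

    with np.errstate(invalid="ignore", divide="ignore"):
        dr1_blood = 1.0 / blood_post - 1.0 / blood_nat
        dr1_myo = 1.0 / post_mean - 1.0 / native_mean
        lam = dr1_myo / dr1_blood
        ecv = lam * (1.0 - hct)
        myo_vol = lv_mass / density_g_per_ml
        fib_vol = ecv * myo_vol
        iecv = fib_vol / bsa

    status = np.where(n_used > 0, "ok", "no_usable_segments")
    bad = (n_used > 0) & ~((post_mean < native_mean) & (dr1_blood > 0) & (ecv > 0) & (ecv < 1))
    status = np.where(bad, "invalid_t1", status)
    ok = status == "ok"
    for arr in (native_mean, post_mean, lam, ecv, fib_vol, iecv):
        arr[~ok] = np.nan

    out = pd.DataFrame(
        {
            "subject_id": cohort["subject_id"].to_numpy(),
            "bsa_m2": bsa,
            "native_t1_mean_ms": native_mean,
            "post_t1_mean_ms": post_mean,
            "partition_coefficient": lam,
            "ecv_fraction": ecv,
            "myocardial_volume_ml": myo_vol,
            "fibrosis_volume_ml": fib_vol,
            "iecv_ml_m2": iecv,
            "n_segments_used": n_used.astype(int),
            "metrics_status": status,
        },
        index=cohort.index,
    )
    assert len(out) == n
    return out


def patient_lge_status(cohort: pd.DataFrame) -> pd.Series:
    """Patient-level LGE category: infarct dominates mid-wall dominates none."""
    lge = cohort[_seg_cols("lge")].to_numpy(str)
    has_inf = (lge == LGE_INFARCT).any(axis=1)
    has_mid = (lge == LGE_MIDWALL).any(axis=1)
    out = np.where(has_inf, LGE_INFARCT, np.where(has_mid, LGE_MIDWALL, LGE_NONE))
    return pd.Series(out, index=cohort.index, name="lge_status")
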