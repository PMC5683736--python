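"""Synthetic two-arm cohort generator.

The generator inverts the observational study design: each AS patient is
first assigned a latent fibrosis stage (normal myocardium, extracellular
expansion, replacement fibrosis), then an imaging panel consistent with
that stage is synthesised, so downstream staging can be validated against
ground truth.  Controls are drawn from the healthy-volunteer
distributions and carry no LGE.

Consistency construction
------------------------
For every subject a target iECV and ECV fraction are drawn from the
stage profile; LV mass index is then *derived* as
``LVMi = iECV * density / ECV`` and the segmental T1 values are
back-solved so that the metrics module exactly recovers the target
(segment noise is centred to zero over the usable segments).  This keeps
the generated table physiologically coherent and makes the
generator/metrics round trip exact to machine precision.

Survival is exponential with per-stage hazards plus uniform
administrative censoring; deaths occurring before the censor time are
flagged, with a configurable per-stage probability of being AS-related.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .config import GROUPS, STAGES, CohortConfig, ConfigError
from .metrics import LGE_INFARCT, LGE_MIDWALL, LGE_NONE, bsa_du_bois

__all__ = ["generate_cohort", "generate_biopsy_subset", "COHORT_COLUMNS"]

COHORT_COLUMNS = (
    ["subject_id", "group", "severity", "age", "sex", "height_cm", "weight_kg",
     "hematocrit", "lv_mass_g", "edv_ml", "blood_native_t1_ms", "blood_post_t1_ms"]
    + [f"seg{i}_native_t1_ms" for i in range(1, 7)]
    + [f"seg{i}_post_t1_ms" for i in range(1, 7)]
    + [f"seg{i}_lge" for i in range(1, 7)]
    + ["peak_velocity_m_s", "log_tni", "log_bnp", "walk_distance_m", "ee_ratio",
       "followup_years", "died", "as_related_death",
       "true_stage", "true_iecv", "true_ecv_fraction", "excluded_infarct", "missing_t1"]
)


def _assign_by_group(rng, group_labels: np.ndarray, dists: dict) -> np.ndarray:
    """Fill one value per subject, drawing group-wise in a fixed order."""
    out = np.empty(len(group_labels))
    for g in GROUPS:  # fixed iteration order keeps the rng stream stable
        mask = group_labels == g
        if mask.any():
            out[mask] = dists[g].draw(rng, int(mask.sum()))
    return out


def generate_cohort(config: CohortConfig, seed: int | None = None) -> pd.DataFrame:
    """Generate a seeded cohort table (one row per subject).

    Identical ``(config, seed)`` pairs produce identical tables.  The
    returned frame follows :data:`COHORT_COLUMNS`; ``true_*`` columns are
    simulation ground truth that real data would not carry.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_c, n_a = config.n_controls, config.n_as
    n = n_c + n_a
    if n == 0:
        return pd.DataFrame(columns=COHORT_COLUMNS)

    is_control = np.zeros(n, dtype=bool)
    is_control[:n_c] = True

    # --- arm structure ------------------------------------------------ #
    severity = np.full(n, "none", dtype=object)
    if n_a:
        cuts = np.cumsum(config.severity_mix)
        severity[n_c:] = np.array(["mild", "moderate", "severe"], dtype=object)[
            np.searchsorted(cuts[:-1], rng.random(n_a), side="right")
        ]
    prev = dict(zip(("mild", "moderate", "severe"), config.lge_prevalence_by_severity))
    midwall = np.zeros(n, dtype=bool)
    midwall[n_c:] = rng.random(n_a) < np.array([prev[s] for s in severity[n_c:]])

    u_excl = rng.random(n)
    missing_t1 = (~is_control) & (u_excl < config.missing_t1_rate)
    infarct = (~is_control) & ~missing_t1 & (
        u_excl < config.missing_t1_rate + config.infarct_lge_rate
    )

    stage = np.full(n, "control", dtype=object)
    u_stage = rng.random(n)
    stage[n_c:] = np.where(
        midwall[n_c:],
        "replacement",
        np.where(u_stage[n_c:] < config.expansion_given_no_lge, "expansion", "normal"),
    )

    # group used for drawing iECV etc.: infarct overlay has its own profile
    draw_group = stage.copy()
    draw_group[infarct] = "infarct"

    # --- demographics ------------------------------------------------- #
    male_p = np.where(is_control, config.male_fraction_controls, config.male_fraction_as)
    male = rng.random(n) < male_p
    age = config.age.draw(rng, n)
    height = np.where(
        male, config.height_male.draw(rng, n), config.height_female.draw(rng, n)
    )
    weight = np.where(
        male, config.weight_male.draw(rng, n), config.weight_female.draw(rng, n)
    )
    bsa = np.array([bsa_du_bois(h, w) for h, w in zip(height, weight)])
    hct = config.hematocrit.draw(rng, n)
    edvi = config.edvi.draw(rng, n)

    # --- stage-consistent imaging panel -------------------------------- #
    profs = config.groups
    iecv = _assign_by_group(rng, draw_group, {g: profs[g].iecv for g in GROUPS})
    # keep classifiable draws strictly on their side of the staging boundary
    b = config.stage_boundary_iecv
    m = config.boundary_margin
    iecv[(stage == "normal") & ~infarct] = np.minimum(
        iecv[(stage == "normal") & ~infarct], b - m
    )
    iecv[(stage == "expansion") & ~infarct] = np.maximum(
        iecv[(stage == "expansion") & ~infarct], b + m
    )
    ecv = _assign_by_group(rng, draw_group, {g: profs[g].ecv for g in GROUPS})
    native_t1 = _assign_by_group(rng, draw_group, {g: profs[g].native_t1 for g in GROUPS})

    lvmi = iecv * config.myocardial_density / ecv
    lv_mass = lvmi * bsa
    edv = edvi * bsa

    blood_nat = config.blood_native_t1.draw(rng, n)
    blood_post = config.blood_post_t1.draw(rng, n)
    lam = ecv / (1.0 - hct)
    dr1_blood = 1.0 / blood_post - 1.0 / blood_nat
    post_t1 = 1.0 / (1.0 / native_t1 + lam * dr1_blood)

    # --- per-segment LGE flags ----------------------------------------- #
    seg_lge = np.full((n, 6), LGE_NONE, dtype=object)
    perm = np.argsort(rng.random((n, 6)), axis=1)
    k_mid = np.where(midwall, 1 + (rng.random(n) < 0.4).astype(int), 0)
    k_inf = np.where(infarct, rng.integers(1, 4, size=n), 0)
    rows = np.arange(n)
    for j in range(6):
        sel_mid = k_mid > j
        seg_lge[rows[sel_mid], perm[sel_mid, j]] = LGE_MIDWALL
    for j in range(6):
        sel_inf = k_inf > j
        seg_lge[rows[sel_inf], perm[sel_inf, (k_mid[sel_inf] + j) % 6]] = LGE_INFARCT

    # --- segmental T1 values ------------------------------------------- #
    usable = seg_lge != LGE_INFARCT  # all rows keep >= 3 usable segments
    e_nat = rng.normal(0.0, config.segment_native_noise_sd, (n, 6))
    e_post = rng.normal(0.0, config.segment_post_noise_sd, (n, 6))
    # centre noise over usable segments so panel means recover targets exactly
    for e in (e_nat, e_post):
        row_mean = np.where(usable, e, 0.0).sum(axis=1) / usable.sum(axis=1)
        e -= np.where(usable, row_mean[:, None], 0.0)
    seg_native = native_t1[:, None] + e_nat
    seg_post = post_t1[:, None] + e_post
    seg_post[missing_t1, :] = np.nan

    # --- clinical markers ---------------------------------------------- #
    log_tni = _assign_by_group(rng, draw_group, {g: profs[g].log_tni for g in GROUPS})
    log_bnp = _assign_by_group(rng, draw_group, {g: profs[g].log_bnp for g in GROUPS})
    walk = _assign_by_group(rng, draw_group, {g: profs[g].walk for g in GROUPS})
    ee = _assign_by_group(rng, draw_group, {g: profs[g].ee_ratio for g in GROUPS})
    velocity = np.empty(n)
    for sev in ("none", "mild", "moderate", "severe"):
        mask = severity == sev
        if mask.any():
            velocity[mask] = config.peak_velocity[sev].draw(rng, int(mask.sum()))

    # --- survival ------------------------------------------------------ #
    hz = dict(zip(STAGES, config.stage_hazards))
    hazard = np.where(
        is_control, config.control_hazard, [hz.get(s, 0.0) for s in stage]
    ).astype(float)
    u_t = rng.random(n)
    with np.errstate(divide="ignore"):
        event_time = np.where(hazard > 0, -np.log1p(-u_t) / np.maximum(hazard, 1e-300), np.inf)
    lo, hi = config.followup_window_years
    censor = rng.uniform(lo, hi, size=n)
    followup = np.minimum(event_time, censor)
    died = event_time <= censor  # deaths precede censorings at ties

    frac = dict(zip(STAGES, config.as_death_fraction))
    as_p = np.where(is_control, 0.0, [frac.get(s, 0.0) for s in stage]).astype(float)
    as_related = died & (rng.random(n) < as_p)

    ids = [f"C{i + 1:03d}" for i in range(n_c)] + [f"AS{i + 1:03d}" for i in range(n_a)]
    df = pd.DataFrame({"subject_id": ids})
    df["group"] = np.where(is_control, "control", "as")
    df["severity"] = severity
    df["age"] = np.round(age, 1)
    df["sex"] = np.where(male, "male", "female")
    df["height_cm"] = height
    df["weight_kg"] = weight
    df["hematocrit"] = hct
    df["lv_mass_g"] = lv_mass
    df["edv_ml"] = edv
    df["blood_native_t1_ms"] = blood_nat
    df["blood_post_t1_ms"] = blood_post
    for i in range(6):
        df[f"seg{i + 1}_native_t1_ms"] = seg_native[:, i]
    for i in range(6):
        df[f"seg{i + 1}_post_t1_ms"] = seg_post[:, i]
    for i in range(6):
        df[f"seg{i + 1}_lge"] = seg_lge[:, i]
    df["peak_velocity_m_s"] = velocity
    df["log_tni"] = log_tni
    df["log_bnp"] = log_bnp
    df["walk_distance_m"] = walk
    df["ee_ratio"] = ee
    df["followup_years"] = followup
    df["died"] = died.astype(int)
    df["as_related_death"] = as_related.astype(int)
    df["true_stage"] = stage
    df["true_iecv"] = iecv
    df["true_ecv_fraction"] = ecv
    df["excluded_infarct"] = infarct.astype(int)
    df["missing_t1"] = missing_t1.astype(int)
    return df[list(COHORT_COLUMNS)]


def generate_biopsy_subset(
    cohort: pd.DataFrame, config: CohortConfig, seed: int | None = None
) -> pd.DataFrame:
    """Sample AS patients for intraoperative biopsy and simulate histology.

    Histological %fibrosis is linear in the subject's (latent) iECV plus
    Gaussian noise, truncated to [0, 100].  Sampling is restricted to
    stageable AS patients (no infarct-pattern LGE, complete T1 data),
    matching the population that carries a CMR fibrosis stage.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    config.validate()
    eligible = cohort[
        (cohort["group"] == "as")
        & (cohort["excluded_infarct"] == 0)
        & (cohort["missing_t1"] == 0)
    ]
    if config.biopsy_n > len(eligible):
        raise ValueError(
            f"biopsy_n={config.biopsy_n} exceeds eligible AS count {len(eligible)}"
        )
    rng = np.random.default_rng(
        [config.seed if seed is None else seed, 0xB10])
    idx = rng.choice(len(eligible), size=config.biopsy_n, replace=False)
    sub = eligible.iloc[np.sort(idx)]
    link = config.biopsy_link
    fib = link.intercept + link.slope * sub["true_iecv"].to_numpy()
    fib = fib + rng.normal(0.0, link.noise_sd, size=len(sub)) if link.noise_sd > 0 else fib
    fib = np.clip(fib, 0.0, 100.0)
    return pd.DataFrame(
        {
            "subject_id": sub["subject_id"].to_numpy(),
            "true_iecv": sub["true_iecv"].to_numpy(),
            "true_stage": sub["true_stage"].to_numpy(),
            "histology_fibrosis_pct": fib,
        }
    )
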