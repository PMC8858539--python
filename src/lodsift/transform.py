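"""Medication adjustment, covariate residualization and the rescaled
inverse-normal transformation (R-INT).

Treated individuals' observed pressures understate the latent trait, so
+15 mmHg (SBP) and +10 mmHg (DBP) are added before analysis; pulse pressure
is derived from the adjusted pressures.  Within each ancestry group the
adjusted trait is residualized on age, age^2, sex, BMI, center, PCs (and any
optional extra covariates) by OLS, rank-inverse-normal transformed with
``z_i = Phi^-1((rank_i - 0.5) / n)`` (average ranks for ties; Blom offsets
available), and rescaled by each study's standard deviation of the *raw*
pre-adjustment measurement — restoring the mmHg scale while normalizing the
shape.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .datatypes import ConfigError, InputError

TREATMENT_EFFECT_SBP = 15.0
TREATMENT_EFFECT_DBP = 10.0


def adjust_medication(pheno: pd.DataFrame) -> pd.DataFrame:
    """Add +15/+10 mmHg to treated SBP/DBP; derive pulse pressure.

    Returns a copy with adj_sbp, adj_dbp and pp columns.  Rows with a missing
    medication flag are dropped (logged).  Calling twice is an error: the
    adjustment is not idempotent.
    """
    if "adj_sbp" in pheno.columns:
        raise ConfigError("medication adjustment already applied")
    for col in ("sbp", "dbp", "med"):
        if col not in pheno.columns:
            raise InputError(f"phenotype table missing column {col!r}")
    out = pheno.copy()
    missing = out["med"].isna()
    if missing.any():
        warnings.warn(f"{int(missing.sum())} individuals lack a medication "
                      "flag; excluded")
        out = out[~missing].copy()
    treated = out["med"].astype(float) > 0
    out["adj_sbp"] = out["sbp"] + np.where(treated, TREATMENT_EFFECT_SBP, 0.0)
    out["adj_dbp"] = out["dbp"] + np.where(treated, TREATMENT_EFFECT_DBP, 0.0)
    out["pp"] = out["adj_sbp"] - out["adj_dbp"]
    return out


_TRAIT_ADJ = {"sbp": "adj_sbp", "dbp": "adj_dbp", "pp": "pp"}


def _raw_trait(pheno: pd.DataFrame, trait: str) -> pd.Series:
    """Raw pre-adjustment measurement used for the per-study SD rescaling."""
    if trait == "pp":
        return pheno["sbp"] - pheno["dbp"]
    return pheno[trait]


def inverse_normal(values: np.ndarray, offset: str = "half") -> np.ndarray:
    """Rank-based inverse normal; ties get average ranks."""
    n = len(values)
    ranks = rankdata(values, method="average")
    if offset == "half":
        q = (ranks - 0.5) / n
    elif offset == "blom":
        q = (ranks - 0.375) / (n + 0.25)
    else:
        raise ConfigError(f"unknown INT offset {offset!r}")
    return norm.ppf(q)


def _design(sub: pd.DataFrame, covariates, pc_cols) -> np.ndarray:
    cols = [np.ones(len(sub))]
    for c in covariates:
        if c == "age2":
            v = sub["age"].to_numpy(dtype=float) ** 2
        elif c == "center":
            dummies = pd.get_dummies(sub["center"].astype(str), drop_first=True)
            for dc in dummies.columns:
                cols.append(dummies[dc].to_numpy(dtype=float))
            continue
        else:
            v = sub[c].to_numpy(dtype=float)
        cols.append(v)
    for c in pc_cols:
        cols.append(sub[c].to_numpy(dtype=float))
    X = np.column_stack(cols)
    keep, dropped = [0], []
    for j in range(1, X.shape[1]):
        if np.nanstd(X[:, j]) == 0:
            dropped.append(j)
        else:
            keep.append(j)
    if dropped:
        warnings.warn(f"dropped {len(dropped)} zero-variance covariate column(s)")
    return X[:, keep]


def residualize_and_rint(pheno: pd.DataFrame, trait: str,
                         covariates=("age", "age2", "sex", "bmi", "center"),
                         pc_prefix: str = "PC", group_col: str = "ancestry",
                         study_col: str = "study", offset: str = "half",
                         min_group: int = 30) -> pd.DataFrame:
    """Residualize within ancestry, INT, and rescale by per-study raw SD.

    Returns a DataFrame (iid, trait, residual, int, rint, study, ancestry)
    aligned to the input rows.  Requires the medication-adjusted columns from
    :func:`adjust_medication`.
    """
    trait = trait.lower()
    if trait not in _TRAIT_ADJ:
        raise ConfigError(f"unknown trait {trait!r}; expected sbp/dbp/pp")
    col = _TRAIT_ADJ[trait]
    if col not in pheno.columns:
        raise InputError("run adjust_medication before residualize_and_rint")
    pc_cols = [c for c in pheno.columns if c.startswith(pc_prefix)
               and c[len(pc_prefix):].isdigit()]

    # per-study SD of the raw (pre-adjustment) measurement
    raw = _raw_trait(pheno, trait)
    sd_by_study = raw.groupby(pheno[study_col]).std(ddof=1)
    singleton = sd_by_study.index[sd_by_study.isna() | (sd_by_study == 0)]
    if len(singleton):
        raise InputError(f"study SD undefined for: {list(singleton)}")

    frames = []
    for group, sub in pheno.groupby(group_col):
        if len(sub) < min_group:
            raise InputError(
                f"ancestry group {group!r} has {len(sub)} < {min_group} individuals")
        y = sub[col].to_numpy(dtype=float)
        X = _design(sub, covariates, pc_cols)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        z = inverse_normal(resid, offset=offset)
        sd = sd_by_study[sub[study_col]].to_numpy(dtype=float)
        frames.append(pd.DataFrame({
            "iid": sub["iid"].to_numpy(),
            "trait": trait,
            "residual": resid,
            "int": z,
            "rint": z * sd,
            "study": sub[study_col].to_numpy(),
            "ancestry": group,
        }, index=sub.index))
    out = pd.concat(frames).loc[pheno.index]
    return out
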