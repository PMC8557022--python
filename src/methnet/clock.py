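"""Epigenetic clock application and age acceleration.

A clock is a weighted linear predictor over probe betas followed by the
standard piecewise calibration transform that is logarithmic in childhood
and linear in adulthood:

    F(age)   = log(age + 1) - log(adult + 1)      for age <= adult
             = (age - adult) / (adult + 1)        for age >  adult
    F^-1(x)  = (adult + 1) * exp(x) - 1           for x < 0
             = (adult + 1) * x + adult            for x >= 0

Age acceleration (AA) is reported both as the raw difference
(DNAm age - chronological age) and as the residual of the cohort-level
OLS regression of DNAm age on chronological age.  Coefficients are not
bundled; the model is a file format (probe_id, weight CSV with an
``(Intercept)`` row) so users may supply any published clock.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    InsufficientSamplesError,
    InvalidArgumentError,
    MissingProbesError,
)


@dataclass
class ClockModel:
    intercept: float
    coefficients: dict[str, float] = field(default_factory=dict)
    adult_age: float = 20.0

    def __post_init__(self):
        if len(self.coefficients) < 1:
            raise InvalidArgumentError("clock needs at least one coefficient")
        if self.adult_age <= 0:
            raise InvalidArgumentError("adult_age must be > 0")

    # ---- calibration transform -------------------------------------
    def transform_age(self, age) -> np.ndarray:
        """F(age): log-linear calibration, continuous at adult_age."""
        age = np.asarray(age, dtype=float)
        a = self.adult_age
        return np.where(
            age <= a,
            np.log(age + 1.0) - np.log(a + 1.0),
            (age - a) / (a + 1.0),
        )

    def inverse_transform(self, x) -> np.ndarray:
        """F^-1(x); exact inverse of :meth:`transform_age`."""
        x = np.asarray(x, dtype=float)
        a = self.adult_age
        return np.where(x < 0, (a + 1.0) * np.exp(x) - 1.0, (a + 1.0) * x + a)

    # ---- file format ------------------------------------------------
    @classmethod
    def from_csv(cls, path, adult_age: float = 20.0) -> "ClockModel":
        tab = pd.read_csv(path)
        tab.columns = [c.strip() for c in tab.columns]
        probe_col, weight_col = tab.columns[:2]
        intercept = 0.0
        coefs = {}
        for _, row in tab.iterrows():
            pid = str(row[probe_col])
            if pid == "(Intercept)":
                intercept = float(row[weight_col])
            else:
                coefs[pid] = float(row[weight_col])
        return cls(intercept=intercept, coefficients=coefs, adult_age=adult_age)

    def to_csv(self, path) -> None:
        rows = [("(Intercept)", self.intercept)]
        rows += sorted(self.coefficients.items())
        pd.DataFrame(rows, columns=["probe_id", "weight"]).to_csv(path, index=False)


def predict_age(
    beta: pd.DataFrame, model: ClockModel, missing: str = "error"
) -> pd.Series:
    """DNAm age per sample from a beta matrix.

    ``missing`` policy for clock probes absent from the matrix:
    ``error`` raises listing the ids; ``mean_impute`` substitutes beta=0.5
    (an uninformative methylation fraction) for the absent probes.
    """
    if missing not in ("error", "mean_impute"):
        raise InvalidArgumentError("missing must be 'error' or 'mean_impute'")
    probes = list(model.coefficients)
    absent = [p for p in probes if p not in beta.index]
    if absent and missing == "error":
        raise MissingProbesError(absent)
    w = np.array([model.coefficients[p] for p in probes])
    vals = np.empty((len(probes), beta.shape[1]))
    for i, p in enumerate(probes):
        vals[i] = beta.loc[p].to_numpy(float) if p not in absent else 0.5
    x = model.intercept + w @ vals
    ages = model.inverse_transform(x)
    return pd.Series(ages, index=beta.columns, name="dnam_age")


def age_acceleration(dnam: pd.Series, chrono: pd.Series) -> pd.DataFrame:
    """Per-sample AA difference and cohort-level AA residual.

    The residual comes from one OLS fit of dnam_age ~ 1 + chrono_age over
    the samples supplied to this call; residuals are mean-zero over that
    cohort by construction.  With fewer than 3 samples the residual column
    is NaN (the difference is still returned).
    """
    if len(dnam) != len(chrono):
        raise InvalidArgumentError("dnam and chrono must have equal length")
    chrono = chrono.loc[dnam.index]
    out = pd.DataFrame(
        {
            "dnam_age": dnam.to_numpy(float),
            "chrono_age": chrono.to_numpy(float),
        },
        index=dnam.index,
    )
    out["aa_diff"] = out["dnam_age"] - out["chrono_age"]
    if len(out) >= 3:
        x = np.column_stack([np.ones(len(out)), out["chrono_age"].to_numpy()])
        coef, *_ = np.linalg.lstsq(x, out["dnam_age"].to_numpy(), rcond=None)
        out["aa_residual"] = out["dnam_age"].to_numpy() - x @ coef
    else:
        out["aa_residual"] = np.nan
    out.index.name = "sample_id"
    return out


def compare_groups_aa(results: pd.DataFrame, sheet: pd.DataFrame) -> dict:
    """Welch t-test of AA (difference and residual) between case/control.

    Returns per-group means/SDs and two-sided p-values.  Raises when either
    group has fewer than 2 samples.
    """
    groups = sheet.loc[results.index, "group"]
    if groups.nunique() < 2:
        raise InvalidArgumentError("need both case and control groups")
    out: dict = {}
    for metric in ("aa_diff", "aa_residual"):
        case = results.loc[groups == "case", metric].dropna().to_numpy(float)
        ctrl = results.loc[groups == "control", metric].dropna().to_numpy(float)
        if len(case) < 2 or len(ctrl) < 2:
            raise InsufficientSamplesError("need >= 2 samples per group")
        if np.allclose(case.var(ddof=1) + ctrl.var(ddof=1), 0.0):
            p = 1.0 if np.isclose(case.mean(), ctrl.mean()) else 0.0
        else:
            p = float(stats.ttest_ind(case, ctrl, equal_var=False).pvalue)
        out[metric] = {
            "case_mean": float(case.mean()),
            "case_sd": float(case.std(ddof=1)),
            "control_mean": float(ctrl.mean()),
            "control_sd": float(ctrl.std(ddof=1)),
            "p": p,
        }
    return out
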