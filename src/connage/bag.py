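"""Brain-age gaps and covariate-adjusted association with cognition.

The brain-age gap (BAG) is predicted minus chronological age, in years. Each
BAG (wide-brain or per-network, from static or dynamic connectivity) is
tested against a cognitive outcome in an ordinary-least-squares GLM that
adjusts for age, sex, site, age squared, the age-by-sex interaction and
diagnosis. The reported effect is the BAG coefficient (beta, SE, t, p, 95%
CI) together with the partial correlation r = t / sqrt(t^2 + df) of BAG and
outcome given the covariates. P-values are Benjamini-Hochberg FDR-corrected
within their declared family: the two modalities for wide-brain tests, the
7 networks x 2 modalities for sub-network tests, separately per outcome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InvalidInputError

__all__ = [
    "GLMDesign",
    "AssociationResult",
    "compute_bag",
    "correct_bag_bias",
    "fit_association_glm",
    "fdr_correct",
    "run_association_suite",
]


@dataclass(frozen=True)
class GLMDesign:
    """Covariate structure of the association GLM.

    ``age_filter_min`` restricts the sample to participants strictly older
    than the threshold (brain-age models are unreliable in the youngest
    adults, who are underrepresented in aging training cohorts). Age is
    mean-centered before squaring and interacting, which changes nothing
    about the BAG coefficient but conditions the design matrix.
    """

    age_filter_min: float = 38.0
    min_extra_dof: int = 10
    bias_correct: bool = False


@dataclass(frozen=True)
class AssociationResult:
    """One BAG-outcome test."""

    outcome: str
    scope: str
    modality: str
    beta: float
    se: float
    ci95: tuple[float, float]
    t: float
    df: int
    p: float
    partial_r: float
    n: int
    p_fdr: float = field(default=float("nan"))

    def to_dict(self) -> dict:
        d = {
            "outcome": self.outcome, "scope": self.scope,
            "modality": self.modality, "beta": self.beta, "se": self.se,
            "ci_low": self.ci95[0], "ci_high": self.ci95[1], "t": self.t,
            "df": self.df, "p": self.p, "p_fdr": self.p_fdr,
            "partial_r": self.partial_r, "n": self.n,
        }
        return d


def compute_bag(predictions: pd.DataFrame, phenotypes: pd.DataFrame,
                scope: str = "wide", modality: str = "sfnc") -> pd.DataFrame:
    """Join predictions with phenotypes and compute bag = predicted - chronological.

    ``predictions`` needs columns subject_id and predicted_age; the join must
    be one-to-one on subject_id.
    """
    for col in ("subject_id", "predicted_age"):
        if col not in predictions.columns:
            raise InvalidInputError(f"predictions missing column {col!r}")
    if "age" not in phenotypes.columns:
        raise InvalidInputError("phenotypes missing column 'age'")
    unmatched = set(predictions["subject_id"]) - set(phenotypes["subject_id"])
    if unmatched:
        raise InvalidInputError(f"subject ids without phenotypes: {sorted(unmatched)}")
    merged = predictions.merge(
        phenotypes[["subject_id", "age"]], on="subject_id", validate="one_to_one"
    )
    return pd.DataFrame(
        {
            "subject_id": merged["subject_id"],
            "chronological_age": merged["age"],
            "predicted_age": merged["predicted_age"],
            "bag": merged["predicted_age"] - merged["age"],
            "scope": scope,
            "modality": modality,
        }
    )


def correct_bag_bias(bag_table: pd.DataFrame) -> pd.DataFrame:
    """Residualize BAG on chronological age (optional sensitivity analysis).

    Brain-age predictions regress toward the training mean, inducing a
    negative BAG-age slope; this removes the linear component. Off by
    default because the primary analysis already includes age terms as
    covariates.
    """
    out = bag_table.copy()
    age = out["chronological_age"].to_numpy(dtype=float)
    bag = out["bag"].to_numpy(dtype=float)
    slope, intercept = np.polyfit(age, bag, 1)
    out["bag"] = bag - (intercept + slope * age)
    return out


def _design_matrix(df: pd.DataFrame) -> tuple[np.ndarray, list]:
    age_c = df["age"] - df["age"].mean()
    sex = (df["sex"].astype(str) == "M").astype(float)
    cols = {
        "bag": df["bag"].astype(float),
        "age": age_c,
        "sex": sex,
        "age_sq": age_c**2,
        "age_x_sex": age_c * sex,
        "diagnosis": df["diagnosis"].astype(float),
    }
    site_dummies = pd.get_dummies(df["site"].astype(str), prefix="site",
                                  drop_first=True, dtype=float)
    for name in site_dummies.columns:
        cols[name] = site_dummies[name]
    X = pd.DataFrame(cols)
    names = ["intercept"] + list(X.columns)
    mat = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    return mat, names


def fit_association_glm(bag_table: pd.DataFrame, phenotypes: pd.DataFrame,
                        outcome: str,
                        design: GLMDesign = GLMDesign()) -> AssociationResult:
    """OLS of one cognitive outcome on BAG plus covariates."""
    if outcome not in phenotypes.columns:
        raise InvalidInputError(f"phenotypes missing outcome column {outcome!r}")
    needed = ["subject_id", "age", "sex", "site", "diagnosis", outcome]
    df = bag_table.merge(phenotypes[needed], on="subject_id", validate="one_to_one")
    df = df[df["age"] > design.age_filter_min].reset_index(drop=True)
    if design.bias_correct and len(df) > 2:
        tmp = pd.DataFrame({"chronological_age": df["age"], "bag": df["bag"]})
        df["bag"] = correct_bag_bias(tmp)["bag"].to_numpy()
    y = df[outcome].to_numpy(dtype=float)
    X, names = _design_matrix(df)
    n, k = X.shape
    if n <= k + design.min_extra_dof:
        raise InvalidInputError(
            f"only {n} subjects after the age filter for {k} design columns"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        dropped = []
        for j in range(k):
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank:
                dropped.append(names[j])
        raise InvalidInputError(f"rank-deficient design; collinear columns: {dropped}")

    fit = sm.OLS(y, X).fit()
    j = names.index("bag")
    beta = float(fit.params[j])
    se = float(fit.bse[j])
    t = float(fit.tvalues[j])
    dof = int(fit.df_resid)
    p = float(fit.pvalues[j])
    tcrit = float(stats.t.ppf(0.975, dof))
    partial_r = t / math.sqrt(t * t + dof)
    return AssociationResult(
        outcome=outcome,
        scope=str(bag_table["scope"].iloc[0]) if "scope" in bag_table else "wide",
        modality=str(bag_table["modality"].iloc[0]) if "modality" in bag_table else "sfnc",
        beta=beta, se=se, ci95=(beta - tcrit * se, beta + tcrit * se),
        t=t, df=dof, p=p, partial_r=partial_r, n=n,
    )


def fdr_correct(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise InvalidInputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_association_suite(bag_tables: list, phenotypes: pd.DataFrame,
                          outcomes=("attention", "working_memory"),
                          design: GLMDesign = GLMDesign(),
                          alpha: float = 0.05) -> pd.DataFrame:
    """All BAG-outcome tests with family-wise FDR correction.

    ``bag_tables`` is a list of BAG tables, each carrying its scope ("wide"
    or a network label) and modality ("sfnc"/"dfnc"). Wide-brain tests form
    one FDR family per outcome (across modalities); sub-network tests form
    another (networks x modalities).
    """
    for outcome in outcomes:
        if outcome not in phenotypes.columns:
            raise InvalidInputError(f"phenotypes missing outcome column {outcome!r}")
    results = []
    for outcome in outcomes:
        for family, tables in (
            ("wide", [t for t in bag_tables if t["scope"].iloc[0] == "wide"]),
            ("subnetwork", [t for t in bag_tables if t["scope"].iloc[0] != "wide"]),
        ):
            fits = [fit_association_glm(t, phenotypes, outcome, design) for t in tables]
            if not fits:
                continue
            adjusted = fdr_correct([f.p for f in fits])
            for f, padj in zip(fits, adjusted):
                row = f.to_dict()
                row["p_fdr"] = float(padj)
                row["family"] = family
                row["significant"] = bool(padj < alpha)
                results.append(row)
    return pd.DataFrame(results)
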