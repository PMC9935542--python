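"""Second-level, per-edge inference on connectivity matrices.

Fisher-z connectivity values are the responses of an ordinary least squares
model per edge.  For the genetic analyses the predictor of interest is the
risk-allele count (additive model; a dominant recode is available for
exploratory use) with gender and antipsychotic dose (haloperidol
equivalents) as nuisance covariates.  Pharmacological effects are paired
within-subject contrasts of session differences, tested with paired t-tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import ConnMatrix, vectorize_lower

__all__ = [
    "DesignMatrix",
    "EffectMatrix",
    "ContrastSpec",
    "PHARM_CONTRASTS",
    "build_design",
    "stack_conn",
    "fit_edge_glm",
    "paired_contrast",
    "levene_homogeneity",
    "edges_to_matrix",
]

P_FLOOR = np.finfo(float).tiny  # reported p for numerically exact fits


@dataclass
class DesignMatrix:
    """Subjects x predictors design with a designated column of interest."""

    matrix: np.ndarray
    columns: list[str]
    interest: str
    allele_model: str = "additive"
    subject_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[1] != len(self.columns):
            raise ValueError("column names do not match design width")
        if self.interest not in self.columns:
            raise ValueError(f"interest column {self.interest!r} not in design")

    @property
    def interest_index(self) -> int:
        return self.columns.index(self.interest)


def build_design(
    cohort: pd.DataFrame,
    predictor: str = "allele_count",
    covariates: tuple[str, ...] = ("gender", "dose"),
    allele_model: str = "additive",
) -> DesignMatrix:
    """Intercept + predictor of interest + covariates from a cohort table.

    ``predictor='group'`` codes patients as 1 and controls as 0 (case-control
    contrast); ``allele_model='dominant'`` recodes allele counts {0}->0,
    {1,2}->1.
    """
    n = len(cohort)
    cols = [np.ones(n)]
    names = ["intercept"]
    if predictor == "group":
        x = (cohort["group"] == "patient").astype(float).to_numpy()
    else:
        x = cohort[predictor].astype(float).to_numpy()
        if predictor == "allele_count" and allele_model == "dominant":
            x = (x > 0).astype(float)
        elif allele_model != "additive" and predictor == "allele_count":
            raise ValueError(f"unknown allele model {allele_model!r}")
    cols.append(x)
    names.append(predictor)
    for c in covariates:
        cols.append(cohort[c].astype(float).to_numpy())
        names.append(c)
    return DesignMatrix(
        matrix=np.column_stack(cols),
        columns=names,
        interest=predictor,
        allele_model=allele_model,
        subject_ids=list(cohort["subject_id"]) if "subject_id" in cohort else None,
    )


@dataclass
class EffectMatrix:
    """Symmetric per-edge second-level effect with t and p matrices."""

    region_labels: list[str]
    effect: np.ndarray
    t: np.ndarray
    p: np.ndarray
    contrast_name: str = ""
    df: float = np.nan
    sided: str = "two-sided"

    def edge_vector(self) -> np.ndarray:
        return vectorize_lower(self.effect)


@dataclass(frozen=True)
class ContrastSpec:
    """A signed combination of session keys, e.g. the ketamine > placebo
    contrast (ketamine post - ketamine pre) - (placebo post - placebo pre)."""

    name: str
    weights: dict[str, float] = field(hash=False)


PHARM_CONTRASTS: dict[str, ContrastSpec] = {
    "ket_gt_pla": ContrastSpec(
        "ket_gt_pla",
        {"ketamine_post": 1, "ketamine_pre": -1, "placebo_post": -1, "placebo_pre": 1},
    ),
    "mdz_gt_pla": ContrastSpec(
        "mdz_gt_pla",
        {"midazolam_post": 1, "midazolam_pre": -1, "placebo_post": -1, "placebo_pre": 1},
    ),
    "ket_gt_mdz": ContrastSpec(
        "ket_gt_mdz",
        {"ketamine_post": 1, "ketamine_pre": -1, "midazolam_post": -1, "midazolam_pre": 1},
    ),
}


def stack_conn(conns: list[ConnMatrix]) -> tuple[np.ndarray, list[str]]:
    """Stack connectivity matrices into a subjects x edges array."""
    if not conns:
        raise ValueError("empty connectivity list")
    labels = conns[0].region_labels
    for c in conns[1:]:
        if c.region_labels != labels:
            raise ValueError("connectivity matrices have inconsistent region labels")
    return np.vstack([vectorize_lower(c.z) for c in conns]), list(labels)


def edges_to_matrix(vec: np.ndarray, region_labels: list[str]) -> np.ndarray:
    """Rebuild a symmetric matrix (zero diagonal) from a lower-triangle vector."""
    r = len(region_labels)
    m = np.zeros((r, r))
    i, j = np.tril_indices(r, k=-1)
    m[i, j] = vec
    m[j, i] = vec
    return m


def _p_from_t(t: np.ndarray, df: float, sided: str) -> np.ndarray:
    if sided == "two-sided":
        p = 2.0 * stats.t.sf(np.abs(t), df)
    elif sided == "greater":
        p = stats.t.sf(t, df)
    elif sided == "less":
        p = stats.t.cdf(t, df)
    else:
        raise ValueError(f"unknown sidedness {sided!r}")
    return np.clip(p, P_FLOOR, 1.0)


def _collinear_columns(x: np.ndarray, columns: list[str]) -> list[str]:
    rank = np.linalg.matrix_rank(x)
    bad = []
    for j in range(x.shape[1]):
        rest = np.delete(x, j, axis=1)
        if np.linalg.matrix_rank(rest) == rank:
            bad.append(columns[j])
    return bad


def fit_edge_glm(
    conn_stack: np.ndarray,
    design: DesignMatrix,
    region_labels: list[str],
    contrast_name: str = "snp",
    sided: str = "two-sided",
) -> EffectMatrix:
    """Vectorized OLS per edge; effect = coefficient of the interest column.

    t statistics use residual df = n - rank(X); p-values are two-sided by
    default (one-sided on request for verification analyses) with a tiny-p
    floor so exact fits stay representable.
    """
    y = np.atleast_2d(np.asarray(conn_stack, dtype=float))
    x = design.matrix
    n, k = x.shape
    if y.shape[0] != n:
        raise ValueError("conn_stack rows must match design rows")
    rank = np.linalg.matrix_rank(x)
    if rank < k:
        raise ValueError(
            f"rank-deficient design; collinear columns: {_collinear_columns(x, design.columns)}"
        )
    if n <= k + 2:
        raise ValueError("too few subjects for the design")

    pinv = np.linalg.pinv(x)
    beta = pinv @ y  # k x E
    resid = y - x @ beta
    df = int(n - rank)
    sigma2 = (resid**2).sum(axis=0) / df
    xtx_inv_jj = float((pinv @ pinv.T)[design.interest_index, design.interest_index])
    se = np.sqrt(sigma2 * xtx_inv_jj)
    b = beta[design.interest_index]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, b / np.where(se > 0, se, 1.0), np.sign(b) * np.inf)
    t = np.where((se == 0) & (b == 0), 0.0, t)
    p = _p_from_t(t, df, sided)
    return EffectMatrix(
        region_labels=list(region_labels),
        effect=edges_to_matrix(b, region_labels),
        t=edges_to_matrix(t, region_labels),
        p=edges_to_matrix(np.where(np.isfinite(t), p, P_FLOOR), region_labels),
        contrast_name=contrast_name,
        df=df,
        sided=sided,
    )


def paired_contrast(
    conn_by_session: dict[str, dict[str, ConnMatrix]],
    spec: ContrastSpec,
    sided: str = "two-sided",
) -> EffectMatrix:
    """Within-subject signed session combination tested by a paired t-test.

    ``conn_by_session`` maps subject -> session key -> ConnMatrix; every
    subject must provide all sessions the contrast references.
    """
    subjects = sorted(conn_by_session)
    if not subjects:
        raise ValueError("no subjects")
    labels = None
    rows = []
    for sid in subjects:
        sess = conn_by_session[sid]
        for key in spec.weights:
            if key not in sess:
                raise ValueError(f"subject {sid} is missing session {key!r}")
        if labels is None:
            labels = next(iter(sess.values())).region_labels
        combo = sum(w * vectorize_lower(sess[key].z) for key, w in spec.weights.items())
        rows.append(combo)
    y = np.vstack(rows)  # subjects x edges
    n = len(subjects)
    if n < 2:
        raise ValueError("paired contrast needs at least 2 subjects")
    mean = y.mean(axis=0)
    sd = y.std(axis=0, ddof=1)
    se = sd / np.sqrt(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, mean / np.where(se > 0, se, 1.0), np.sign(mean) * np.inf)
    t = np.where((se == 0) & (mean == 0), 0.0, t)
    df = n - 1
    p = _p_from_t(t, df, sided)
    return EffectMatrix(
        region_labels=list(labels),
        effect=edges_to_matrix(mean, labels),
        t=edges_to_matrix(t, labels),
        p=edges_to_matrix(p, labels),
        contrast_name=spec.name,
        df=df,
        sided=sided,
    )


def levene_homogeneity(*groups: np.ndarray) -> tuple[float, float]:
    """Levene's test (mean-centred variant) for homogeneity of variance."""
    if len(groups) < 2:
        raise ValueError("Levene's test needs at least 2 groups")
    for g in groups:
        if len(np.asarray(g)) < 2:
            raise ValueError("each group needs at least 2 observations")
    w, p = stats.levene(*groups, center="mean")
    return float(w), float(p)


def save_effect(effect: EffectMatrix, prefix) -> None:
    """Write an effect matrix as an effect/t/p TSV trio plus JSON metadata."""
    for name, mat in (("effect", effect.effect), ("t", effect.t), ("p", effect.p)):
        pd.DataFrame(mat, index=effect.region_labels, columns=effect.region_labels).to_csv(
            f"{prefix}.{name}.tsv", sep="\t"
        )
    with open(f"{prefix}.meta.json", "w") as fh:
        json.dump(
            {"contrast": effect.contrast_name, "df": effect.df, "sided": effect.sided},
            fh,
            indent=2,
        )
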