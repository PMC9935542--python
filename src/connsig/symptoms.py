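"""Symptom-association statistics for bipolar-axis clinical ratings.

Each symptom domain (language, affective, motor) is scored as integer sums
of items rated on a -1/0/+1 axis, per subcategory.  The association of a
domain with the allele count is tested by a multivariate GLM: Wilks' lambda
for the single-df allele hypothesis with gender and dose covariates,
converted to an exact F via Rao's formula, and Benjamini-Hochberg-corrected
across domains.  Post-hoc partial correlations (residualizing on the same
covariates) localize the effect to subcategories, and the same machinery
couples symptom sums to connectivity of genotype-selected edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .curves import fdr_bh
from .glm import DesignMatrix

__all__ = [
    "SymptomTestResult",
    "domain_manova",
    "wilks_to_f",
    "partial_corr",
    "edge_symptom_coupling",
]


@dataclass
class SymptomTestResult:
    """Wilks-lambda test for one symptom domain plus optional post-hocs."""

    domain: str
    wilks_lambda: float
    f_stat: float
    df: tuple[int, int]
    p: float
    p_fdr: float = np.nan
    partial_r: dict[str, tuple[float, int, float]] = field(default_factory=dict)


def wilks_to_f(lam: float, p_responses: int, error_df: int) -> tuple[float, int, int]:
    """Exact F transform of Wilks' lambda for a single-df hypothesis (Rao).

    ``F = ((1 - lam) / lam) * ((v_e - p + 1) / p)`` on (p, v_e - p + 1)
    degrees of freedom, where p is the number of response variables and
    v_e the error degrees of freedom.
    """
    if not 0 < lam <= 1:
        raise ValueError("Wilks' lambda must lie in (0, 1]")
    df1 = p_responses
    df2 = error_df - p_responses + 1
    if df2 <= 0:
        raise ValueError("non-positive denominator degrees of freedom")
    f = ((1.0 - lam) / lam) * (df2 / df1)
    return float(f), df1, df2


def domain_manova(
    scores: pd.DataFrame | np.ndarray, design: DesignMatrix, domain: str = ""
) -> SymptomTestResult:
    """Wilks-lambda MANOVA of subcategory sums on the allele count.

    ``scores`` is n x p (one column per subcategory).  The hypothesis is the
    single coefficient of the design's interest column; covariates are
    whatever else the design carries.  Error df = n - rank(X).
    """
    y = np.asarray(scores, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    x = design.matrix
    n, k = x.shape
    p = y.shape[1]
    if y.shape[0] != n:
        raise ValueError("scores and design have different row counts")
    if n <= p + k + 1:
        raise ValueError("too few subjects for the multivariate model")
    rank = np.linalg.matrix_rank(x)
    if rank < k:
        raise ValueError("rank-deficient design")

    pinv = np.linalg.pinv(x)
    beta = pinv @ y
    resid = y - x @ beta
    e = resid.T @ resid  # error SSCP
    j = design.interest_index
    lb = beta[j]  # 1 x p hypothesis estimate
    # var factor of the single coefficient: (X'X)^{-1}_{jj}
    c_jj = float((pinv @ pinv.T)[j, j])
    h = np.outer(lb, lb) / c_jj  # hypothesis SSCP (single df)
    w_e = np.linalg.eigvalsh(e)
    if w_e.min() <= 1e-10 * max(w_e.max(), 1e-30):
        raise ValueError("singular residual covariance")
    sign_e, logdet_e = np.linalg.slogdet(e)
    sign_eh, logdet_eh = np.linalg.slogdet(e + h)
    if sign_e <= 0 or sign_eh <= 0:
        raise ValueError("singular residual covariance")
    lam = float(np.exp(logdet_e - logdet_eh))
    lam = min(lam, 1.0)
    v_e = n - rank
    f, df1, df2 = wilks_to_f(lam, p, v_e)
    pval = float(stats.f.sf(f, df1, df2))
    return SymptomTestResult(
        domain=domain, wilks_lambda=lam, f_stat=f, df=(df1, df2), p=max(pval, np.finfo(float).tiny)
    )


def partial_corr(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    sided: str = "two-sided",
) -> tuple[float, int, float]:
    """Partial Pearson correlation of x and y given covariates.

    Both variables are residualized by OLS on [1, covariates] and the
    residuals correlated; df = n - c - 2 where c is the covariate count.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = len(x)
    if len(y) != n:
        raise ValueError("x and y differ in length")
    if covariates is None:
        z = np.ones((n, 1))
        c = 0
    else:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        z = np.c_[np.ones(n), cov]
        c = z.shape[1] - 1
    if n <= c + 2:
        raise ValueError("too few observations for the covariate count")
    q = np.linalg.pinv(z)
    rx = x - z @ (q @ x)
    ry = y - z @ (q @ y)
    # relative tolerance: a residual that is numerically zero compared with
    # the variable's own scale means the covariates explain it completely
    if rx.std() <= 1e-10 * (x.std() + 1e-30) or ry.std() <= 1e-10 * (y.std() + 1e-30):
        raise ValueError("zero residual variance")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - c - 2
    r_c = min(max(r, -1 + 1e-15), 1 - 1e-15)
    t = r_c * np.sqrt(df / (1 - r_c**2))
    if sided == "two-sided":
        p = 2 * stats.t.sf(abs(t), df)
    elif sided == "greater":
        p = stats.t.sf(t, df)
    elif sided == "less":
        p = stats.t.cdf(t, df)
    else:
        raise ValueError(f"unknown sidedness {sided!r}")
    return r, df, float(max(p, np.finfo(float).tiny))


def domain_tests(
    symptom_table: pd.DataFrame,
    design: DesignMatrix,
    domains: tuple[str, ...] = ("language", "affective", "motor"),
) -> list[SymptomTestResult]:
    """Run the MANOVA for each domain and BH-correct across domains.

    Expects wide columns named ``<domain>_<subcategory>``; post-hoc partial
    correlations (allele count vs. each subcategory sum, residualized on the
    non-interest covariates) are attached per domain.
    """
    results = []
    allele = design.matrix[:, design.interest_index]
    cov_idx = [
        i
        for i, c in enumerate(design.columns)
        if c not in ("intercept", design.interest)
    ]
    covs = design.matrix[:, cov_idx] if cov_idx else None
    for dom in domains:
        cols = [c for c in symptom_table.columns if c.startswith(f"{dom}_")]
        if not cols:
            raise ValueError(f"no subcategory columns for domain {dom!r}")
        res = domain_manova(symptom_table[cols], design, domain=dom)
        for c in cols:
            r, df, pv = partial_corr(allele, symptom_table[c].to_numpy(), covs)
            res.partial_r[c.split("_", 1)[1]] = (r, df, pv)
        results.append(res)
    adj, _ = fdr_bh(np.array([r.p for r in results]))
    for r, a in zip(results, adj):
        r.p_fdr = float(a)
    return results


def edge_symptom_coupling(
    edge_values: pd.DataFrame,
    scores: np.ndarray,
    covariates: np.ndarray | None = None,
    q: float = 0.05,
    sided: str = "two-sided",
) -> pd.DataFrame:
    """Partial correlation of selected edges' connectivity with a symptom sum.

    ``edge_values`` is subjects x edges (one column per genotype-selected
    edge, e.g. from a seed profile); p-values are BH-corrected over the
    selected edges.
    """
    rows = []
    for col in edge_values.columns:
        r, df, pv = partial_corr(edge_values[col].to_numpy(), scores, covariates, sided=sided)
        rows.append((col, r, df, pv))
    out = pd.DataFrame(rows, columns=["edge", "r", "df", "p"]).set_index("edge")
    adj, rej = fdr_bh(out["p"].to_numpy(), q=q)
    out["p_fdr"] = adj
    out["significant"] = rej
    return out
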