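"""Expression-ranked correlation curves between effect matrices, with AUC
permutation inference.

The similarity between two region x region effect matrices (e.g. the
allele-dose coefficient matrix and a drug contrast matrix) is summarized by
a curve: regions are ordered by their marker-gene expression rank, and at
each step the lowest-expressing region is removed and the Pearson
correlation between the lower triangles of the two remaining submatrices is
recorded, from the full matrix down to the three highest-expressing regions.
The area under the curve (AUC; discrete unit-spacing sum of the r values)
condenses the curve into one number whose null distribution is obtained by
re-assigning genotype labels across patients and re-running the entire
second level (GLM re-fit, curve, AUC) per permutation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .expression import RegionExpressionProfile
from .glm import DesignMatrix, EffectMatrix, fit_edge_glm

__all__ = [
    "CorrelationCurve",
    "PermutationResult",
    "correlation_curve",
    "permutation_test",
    "fdr_bh",
    "DEFAULT_DIRECTIONS",
]

# one-sided test directions: ketamine-like contrasts are expected to
# correlate positively with the allele effect, midazolam negatively
DEFAULT_DIRECTIONS = {"ket_gt_pla": "greater", "ket_gt_mdz": "greater", "mdz_gt_pla": "less"}


@dataclass
class CorrelationCurve:
    """Correlation over nested expression-ranked submatrices.

    ``sizes`` runs from the full region count down to 3; ``auc`` is the sum
    of the r values (unit spacing).  ``degenerate`` flags sizes where an
    edge vector had zero variance and r was recorded as 0.
    """

    sizes: np.ndarray
    r_values: np.ndarray
    auc: float
    contrast_name: str = ""
    auc_rule: str = "sum"
    degenerate: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=int)
        self.r_values = np.asarray(self.r_values, dtype=float)
        if len(self.sizes) != len(self.r_values):
            raise ValueError("sizes and r_values differ in length")


@dataclass
class PermutationResult:
    """Observed AUC against a genotype-permutation null distribution."""

    observed_auc: float
    null_aucs: np.ndarray
    direction: str
    p_raw: float
    n_perm: int
    contrast_name: str = ""
    p_fdr: float = np.nan


def _ranked_order(ranking: RegionExpressionProfile, labels: list[str]) -> list[int]:
    """Indices of ``labels`` sorted by expression rank (rank 1 first)."""
    rank = ranking.rank_of()
    missing = [r for r in labels if r not in rank.index]
    if missing:
        raise ValueError(f"ranking does not cover regions: {missing[:5]}")
    return sorted(range(len(labels)), key=lambda i: int(rank[labels[i]]))


def _ranked_tril(matrix: np.ndarray, order: list[int]) -> np.ndarray:
    """Lower-triangle vector of the matrix reordered by expression rank.

    With row-major lower-triangle ordering, the edges among the ``s``
    top-ranked regions are exactly the first s(s-1)/2 entries.
    """
    m = np.asarray(matrix)[np.ix_(order, order)]
    i, j = np.tril_indices(m.shape[0], k=-1)
    return m[i, j]


def correlation_curve(
    effect_a: EffectMatrix,
    effect_b: EffectMatrix,
    ranking: RegionExpressionProfile,
    auc_rule: str = "sum",
    contrast_name: str | None = None,
) -> CorrelationCurve:
    """Correlation curve between two effect matrices over ranked submatrices.

    At iteration k the Pearson correlation is computed between the
    lower-triangle vectors of both matrices restricted to the
    (R - k + 1) highest-expressing regions, down to 3 regions.

    A submatrix whose edge vector is constant yields r = 0 with a warning
    (recorded in ``degenerate``) rather than an error.
    """
    if effect_a.region_labels != effect_b.region_labels:
        raise ValueError("effect matrices must share region labels")
    labels = effect_a.region_labels
    r_full = len(labels)
    if r_full < 3:
        raise ValueError("need at least 3 regions")
    order = _ranked_order(ranking, labels)

    sizes = np.arange(r_full, 2, -1)
    rs = np.empty(len(sizes))
    degenerate = []
    for k, s in enumerate(sizes):
        sub = order[:s]
        xa = _ranked_tril(effect_a.effect, sub)
        xb = _ranked_tril(effect_b.effect, sub)
        if xa.std() == 0 or xb.std() == 0:
            warnings.warn(f"zero-variance edge vector at size {s}; recording r = 0")
            rs[k] = 0.0
            degenerate.append(int(s))
        else:
            rs[k] = float(np.corrcoef(xa, xb)[0, 1])
    auc = _auc(rs, auc_rule)
    return CorrelationCurve(
        sizes=sizes,
        r_values=rs,
        auc=auc,
        contrast_name=contrast_name
        or f"{effect_a.contrast_name}~{effect_b.contrast_name}",
        auc_rule=auc_rule,
        degenerate=tuple(degenerate),
    )


def _auc(rs: np.ndarray, rule: str) -> float:
    if rule == "sum":
        return float(np.sum(rs))
    if rule == "trapezoid":
        return float(np.trapezoid(rs))
    raise ValueError(f"unknown AUC rule {rule!r}")


def _prefix_correlations(
    x: np.ndarray, y: np.ndarray, edge_counts: np.ndarray
) -> np.ndarray:
    """Pearson r between prefixes of two (batched) ranked edge vectors.

    ``x`` may be (n_perm, E); ``y`` is (E,).  Returns r with shape
    (..., len(edge_counts)).  Zero-variance prefixes yield r = 0.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float)
    cx, cy = np.cumsum(x, axis=1), np.cumsum(y)
    cxx, cyy = np.cumsum(x * x, axis=1), np.cumsum(y * y)
    cxy = np.cumsum(x * y[None, :], axis=1)
    idx = edge_counts - 1
    n = edge_counts.astype(float)
    sx, sy = cx[:, idx], cy[idx]
    vx = cxx[:, idx] - sx * sx / n
    vy = cyy[idx] - sy * sy / n
    cov = cxy[:, idx] - sx * sy[None, :] / n
    denom = np.sqrt(np.clip(vx, 0, None) * np.clip(vy, 0, None)[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), 0.0)
    return np.clip(r, -1.0, 1.0)


def permutation_test(
    conn_stack: np.ndarray,
    design: DesignMatrix,
    pharm_effects: dict[str, EffectMatrix],
    ranking: RegionExpressionProfile,
    region_labels: list[str],
    n_perm: int = 10000,
    seed: int = 0,
    directions: dict[str, str] | None = None,
    auc_rule: str = "sum",
) -> dict[str, PermutationResult]:
    """Genotype-permutation AUC test of curve similarity, per drug contrast.

    For each permutation the genotype column of the design is shuffled
    across patients (gender and dose stay with their subject), the per-edge
    GLM is refit, and the full correlation curve and its AUC are recomputed
    against each (fixed) pharmacological effect matrix.  The one-sided
    permutation p uses the add-one estimator
    ``p = (1 + #{null at least as extreme}) / (1 + n_perm)`` and is
    Benjamini-Hochberg-corrected across the contrasts.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    directions = dict(DEFAULT_DIRECTIONS if directions is None else directions)
    rng = np.random.default_rng(seed)
    y = np.asarray(conn_stack, dtype=float)
    n, n_edges = y.shape
    r_full = len(region_labels)
    if n_edges != r_full * (r_full - 1) // 2:
        raise ValueError("edge count does not match region labels")

    order = _ranked_order(ranking, list(region_labels))
    # reorder edge columns into ranked-prefix layout once
    edge_id = np.zeros((r_full, r_full), dtype=int)
    ti, tj = np.tril_indices(r_full, k=-1)
    edge_id[ti, tj] = edge_id[tj, ti] = np.arange(n_edges)
    oi = np.asarray(order)
    col_map = edge_id[oi[ti], oi[tj]]
    yr = y[:, col_map]

    sizes = np.arange(r_full, 2, -1)
    edge_counts = sizes * (sizes - 1) // 2
    pharm_ranked = {
        name: _ranked_tril(eff.effect, order) for name, eff in pharm_effects.items()
    }

    # observed statistic via the public curve operation
    observed_fit = fit_edge_glm(y, design, list(region_labels), contrast_name="snp")
    observed = {
        name: correlation_curve(observed_fit, eff, ranking, auc_rule=auc_rule).auc
        for name, eff in pharm_effects.items()
    }

    # permutation engine: shuffled-genotype GLM coefficient per edge, then
    # prefix correlations of the ranked edge vector; chunked to bound memory
    x = design.matrix
    j = design.interest_index
    null_aucs = {name: np.empty(n_perm) for name in pharm_ranked}
    chunk = max(1, min(n_perm, 8_000_000 // max(n_edges, 1)))
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        coef_rows = np.empty((b, n))
        for i in range(b):
            xp = x.copy()
            xp[:, j] = x[rng.permutation(n), j]
            coef_rows[i] = np.linalg.pinv(xp)[j]
        beta_perm = coef_rows @ yr  # b x E, ranked layout
        for name, vec in pharm_ranked.items():
            r_mat = _prefix_correlations(beta_perm, vec, edge_counts)
            if auc_rule == "sum":
                null_aucs[name][done : done + b] = r_mat.sum(axis=1)
            else:
                null_aucs[name][done : done + b] = np.trapezoid(r_mat, axis=1)
        done += b

    results: dict[str, PermutationResult] = {}
    for name in pharm_ranked:
        null = null_aucs[name]
        direction = directions.get(name, "greater")
        obs = observed[name]
        if direction == "greater":
            extreme = int(np.sum(null >= obs))
        elif direction == "less":
            extreme = int(np.sum(null <= obs))
        else:
            raise ValueError(f"unknown direction {direction!r}")
        p_raw = (1 + extreme) / (1 + n_perm)
        results[name] = PermutationResult(
            observed_auc=obs,
            null_aucs=null,
            direction=direction,
            p_raw=p_raw,
            n_perm=n_perm,
            contrast_name=name,
        )

    names = list(results)
    adj, _ = fdr_bh(np.array([results[c].p_raw for c in names]))
    for c, a in zip(names, adj):
        results[c].p_fdr = float(a)
    return results


def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: adjusted p-values and rejection flags."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return adjusted, reject


def save_curve(curve: CorrelationCurve, result: PermutationResult | None, prefix) -> None:
    """Write a curve as TSV (size, r) plus a JSON summary."""
    pd.DataFrame({"size": curve.sizes, "r": curve.r_values}).to_csv(
        f"{prefix}.tsv", sep="\t", index=False
    )
    meta = {"auc": curve.auc, "auc_rule": curve.auc_rule, "contrast": curve.contrast_name}
    if result is not None:
        meta.update(
            {
                "p_raw": result.p_raw,
                "p_fdr": result.p_fdr,
                "direction": result.direction,
                "n_perm": result.n_perm,
            }
        )
    with open(f"{prefix}.json", "w") as fh:
        json.dump(meta, fh, indent=2)


def load_curve(prefix) -> CorrelationCurve:
    df = pd.read_csv(f"{prefix}.tsv", sep="\t")
    with open(f"{prefix}.json") as fh:
        meta = json.load(fh)
    return CorrelationCurve(
        sizes=df["size"].to_numpy(),
        r_values=df["r"].to_numpy(),
        auc=meta["auc"],
        contrast_name=meta.get("contrast", ""),
        auc_rule=meta.get("auc_rule", "sum"),
    )
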