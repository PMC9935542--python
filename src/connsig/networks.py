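"""Set-level (functional network) connectivity tests and seed analyses.

A functional-network-connectivity (FNC) test asks whether the overall
connectivity between two sets of regions (or within one set) depends on a
predictor.  The set-level response of a subject is the mean Fisher-z value
over all edges spanning the pair, which is entered into the same GLM (or
paired t-test) as a single-edge analysis; edges driving a significant
set-level effect are listed post hoc at uncorrected p < 0.05.

Networks can be defined a priori (striato-pallido-thalamic vs.
auditory-sensory-motor sets) or data-driven, by average-linkage hierarchical
clustering of the regions' group-mean connectivity profiles with
correlation distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .connectivity import ConnMatrix
from .curves import fdr_bh
from .glm import ContrastSpec, DesignMatrix, EffectMatrix, fit_edge_glm, paired_contrast

__all__ = [
    "NetworkDef",
    "FncResult",
    "fnc_test",
    "fnc_test_paired",
    "cluster_networks",
    "fnc_all_pairs",
    "seed_profile",
]


@dataclass(frozen=True)
class NetworkDef:
    """A named set of atlas regions."""

    name: str
    regions: tuple[str, ...]
    source: str = "a_priori"  # or "clustered"

    def __init__(self, name, regions, source="a_priori"):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "regions", tuple(regions))
        object.__setattr__(self, "source", source)
        if not self.regions:
            raise ValueError(f"network {name!r} is empty")


@dataclass
class FncResult:
    """Outcome of one set-level connectivity test."""

    name_a: str
    name_b: str
    effect: float
    statistic: float
    df: float
    p: float
    p_fdr: float = np.nan
    contributing_edges: pd.DataFrame = field(default_factory=pd.DataFrame)


def _edge_mask(
    region_labels: list[str], set_a: tuple[str, ...], set_b: tuple[str, ...]
) -> np.ndarray:
    """Boolean mask over the lower-triangle edge vector for a set pair."""
    index = {name: i for i, name in enumerate(region_labels)}
    for name in (*set_a, *set_b):
        if name not in index:
            raise ValueError(f"region {name!r} not in atlas labels")
    sa, sb = set(set_a), set(set_b)
    if sa != sb and sa & sb:
        raise ValueError("between-network sets must be disjoint")
    r = len(region_labels)
    m = np.zeros((r, r), dtype=bool)
    ia = [index[n] for n in sa]
    ib = [index[n] for n in sb]
    m[np.ix_(ia, ib)] = True
    m |= m.T
    np.fill_diagonal(m, False)
    i, j = np.tril_indices(r, k=-1)
    mask = m[i, j]
    if not mask.any():
        raise ValueError("empty edge set for the requested networks")
    return mask


def _edge_names(region_labels: list[str], mask: np.ndarray) -> list[tuple[str, str]]:
    i, j = np.tril_indices(len(region_labels), k=-1)
    return [(region_labels[a], region_labels[b]) for a, b in zip(i[mask], j[mask])]


def _contributing(
    conn_stack: np.ndarray,
    design: DesignMatrix,
    region_labels: list[str],
    mask: np.ndarray,
) -> pd.DataFrame:
    """Per-edge post-hoc GLMs over the masked edges, kept at p_unc < 0.05."""
    fit = fit_edge_glm(conn_stack, design, region_labels)
    i, j = np.tril_indices(len(region_labels), k=-1)
    t = fit.t[i, j][mask]
    p = fit.p[i, j][mask]
    eff = fit.effect[i, j][mask]
    names = _edge_names(region_labels, mask)
    df = pd.DataFrame(
        {
            "region_a": [a for a, _ in names],
            "region_b": [b for _, b in names],
            "effect": eff,
            "t": t,
            "p_unc": p,
        }
    )
    return df[df["p_unc"] < 0.05].reset_index(drop=True)


def fnc_test(
    conn_stack: np.ndarray,
    design: DesignMatrix,
    set_a: NetworkDef,
    set_b: NetworkDef,
    region_labels: list[str],
    sided: str = "two-sided",
    with_contributions: bool = True,
) -> FncResult:
    """GLM on the edge-mean scalar response for a network pair.

    Identical sets test within-network connectivity; distinct sets must be
    disjoint and test between-network connectivity.  Because OLS is linear
    in the response, the set-level effect equals the mean of the per-edge
    GLM effects over the same edges.
    """
    mask = _edge_mask(region_labels, set_a.regions, set_b.regions)
    scalar = np.asarray(conn_stack, dtype=float)[:, mask].mean(axis=1)
    fit = _scalar_glm(scalar, design, sided)
    contrib = (
        _contributing(conn_stack[:, :], design, region_labels, mask)
        if with_contributions
        else pd.DataFrame()
    )
    return FncResult(
        name_a=set_a.name,
        name_b=set_b.name,
        effect=fit[0],
        statistic=fit[1],
        df=fit[2],
        p=fit[3],
        contributing_edges=contrib,
    )


def _scalar_glm(
    y: np.ndarray, design: DesignMatrix, sided: str
) -> tuple[float, float, float, float]:
    """OLS of a single scalar response; reuses the edge-GLM machinery by
    treating the scalar as a one-edge stack on a 2-region dummy atlas."""
    dummy = ["a", "b"]
    fit = fit_edge_glm(y[:, None], design, dummy, sided=sided)
    return float(fit.effect[1, 0]), float(fit.t[1, 0]), float(fit.df), float(fit.p[1, 0])


def fnc_test_paired(
    conn_by_session: dict[str, dict[str, ConnMatrix]],
    spec: ContrastSpec,
    set_a: NetworkDef,
    set_b: NetworkDef,
    sided: str = "two-sided",
) -> FncResult:
    """Paired-contrast version of the set-level test (crossover sample)."""
    eff = paired_contrast(conn_by_session, spec, sided=sided)
    labels = eff.region_labels
    mask = _edge_mask(labels, set_a.regions, set_b.regions)
    # per-subject scalar: mean over masked edges of the signed session combo
    from .connectivity import vectorize_lower

    subjects = sorted(conn_by_session)
    vals = np.array(
        [
            np.mean(
                sum(
                    w * vectorize_lower(conn_by_session[s][k].z)
                    for k, w in spec.weights.items()
                )[mask]
            )
            for s in subjects
        ]
    )
    n = len(vals)
    mean = vals.mean()
    se = vals.std(ddof=1) / np.sqrt(n)
    from scipy import stats

    t = mean / se if se > 0 else np.sign(mean) * np.inf
    if sided == "two-sided":
        p = 2 * stats.t.sf(abs(t), n - 1)
    elif sided == "greater":
        p = stats.t.sf(t, n - 1)
    else:
        p = stats.t.cdf(t, n - 1)
    return FncResult(
        name_a=set_a.name,
        name_b=set_b.name,
        effect=float(mean),
        statistic=float(t),
        df=n - 1,
        p=float(max(p, np.finfo(float).tiny)),
    )


def cluster_networks(group_mean_conn: ConnMatrix, k: int) -> list[NetworkDef]:
    """Data-driven networks by average-linkage hierarchical clustering.

    Distance between regions i and j is 1 - Pearson correlation of their
    connectivity profiles (rows of the group-mean matrix), computed over all
    other regions (both self-columns masked).  Deterministic; invariant to
    region input order up to network numbering.
    """
    r = group_mean_conn.n_regions
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > r:
        raise ValueError("more clusters than regions")
    z = group_mean_conn.z
    d = np.zeros((r, r))
    for i in range(r):
        for j in range(i + 1, r):
            keep = np.ones(r, dtype=bool)
            keep[[i, j]] = False
            a, b = z[i, keep], z[j, keep]
            if a.std() == 0 or b.std() == 0:
                corr = 0.0
            else:
                corr = float(np.corrcoef(a, b)[0, 1])
            d[i, j] = d[j, i] = 1.0 - corr
    labels = fcluster(linkage(squareform(d, checks=False), method="average"), k, criterion="maxclust")
    nets = []
    for c in sorted(set(labels)):
        regions = [group_mean_conn.region_labels[i] for i in np.flatnonzero(labels == c)]
        nets.append(NetworkDef(name=f"net{c:02d}", regions=regions, source="clustered"))
    return nets


def fnc_all_pairs(
    conn_stack: np.ndarray,
    design: DesignMatrix,
    networks: list[NetworkDef],
    region_labels: list[str],
    q: float = 0.05,
    sided: str = "two-sided",
    with_contributions: bool = False,
) -> list[FncResult]:
    """All within- and between-network set-level tests, BH-corrected.

    For k networks this enters k(k+1)/2 tests into the FDR correction.
    """
    if len(networks) < 2:
        raise ValueError("need at least 2 networks")
    results = []
    for a in range(len(networks)):
        for b in range(a, len(networks)):
            if a == b and len(networks[a].regions) < 2:
                continue  # singleton network has no within-network edges
            results.append(
                fnc_test(
                    conn_stack,
                    design,
                    networks[a],
                    networks[b],
                    region_labels,
                    sided=sided,
                    with_contributions=with_contributions,
                )
            )
    adj, _ = fdr_bh(np.array([r.p for r in results]), q=q)
    for r, a in zip(results, adj):
        r.p_fdr = float(a)
    return results


def seed_profile(
    conn_stack: np.ndarray,
    design: DesignMatrix,
    seed_region: str,
    region_labels: list[str],
    q: float = 0.05,
    sided: str = "two-sided",
) -> pd.DataFrame:
    """Per-target GLM for one seed region, BH-corrected across targets.

    The ROI-level analogue of a seed-based analysis: one GLM per
    seed-target edge, with FDR control over the R - 1 target regions.
    Supports one-sided mode for verification re-tests.
    """
    if seed_region not in region_labels:
        raise ValueError(f"unknown seed region {seed_region!r}")
    fit = fit_edge_glm(conn_stack, design, region_labels, sided=sided)
    s = region_labels.index(seed_region)
    targets = [r for i, r in enumerate(region_labels) if i != s]
    idx = [i for i in range(len(region_labels)) if i != s]
    eff = fit.effect[s, idx]
    t = fit.t[s, idx]
    p = fit.p[s, idx]
    adj, rej = fdr_bh(p, q=q)
    return pd.DataFrame(
        {
            "target": targets,
            "effect": eff,
            "t": t,
            "p": p,
            "p_fdr": adj,
            "significant": rej,
        }
    ).set_index("target")
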