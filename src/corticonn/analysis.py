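"""Structure-function analyses: FLN-GPDC correlations, estimate variability
vs. nodal centrality, activity-flow estimates, and partial-observation
cluster experiments with multiple-comparison-corrected tests.

The central object is the edge table: one row per directed edge per
simulation with the structural weight (FLN) and the GPDC summaries.
Edges are oriented like the connectome (row/target ``target``, column/source
``source``: values flow source -> target).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .connectome import CentralityResult, FLNMatrix
from .mvar import conditioned_gpdc, edge_summary, gpdc, select_order

__all__ = [
    "build_edge_table",
    "pearson",
    "fln_gpdc_correlation",
    "bootstrap_edges",
    "EdgeVariability",
    "cv_analysis",
    "ActivityEstimate",
    "estimated_activity",
    "ClusterExperimentResult",
    "cluster_experiment",
    "welch_holm",
]


def pearson(x, y) -> float:
    """Product-moment correlation; raises on degenerate input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in correlation input")
    return float(scipy.stats.pearsonr(x, y).statistic)


def build_edge_table(fln: FLNMatrix, summaries_by_sim: dict) -> pd.DataFrame:
    """Tidy edge table from per-simulation GPDC summary matrices.

    ``summaries_by_sim`` maps simulation id -> dict with any of the keys
    'peak', 'mean', 'auc' holding N x N matrices (row = target).  Self-edges
    are dropped.
    """
    n = fln.n_areas
    tgt, src = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    off = tgt != src
    rows = []
    for sim_id, mats in summaries_by_sim.items():
        rec = {
            "simulation": sim_id,
            "target": tgt[off],
            "source": src[off],
            "fln": fln.values[off],
        }
        for key, mat in mats.items():
            rec[f"gpdc_{key}"] = np.asarray(mat)[off]
        rows.append(pd.DataFrame(rec))
    return pd.concat(rows, ignore_index=True)


def _edge_filter(table: pd.DataFrame, positive_fln_only: bool) -> pd.DataFrame:
    return table[table["fln"] > 0] if positive_fln_only else table


def fln_gpdc_correlation(
    table: pd.DataFrame,
    scope: str = "per-simulation",
    value: str = "gpdc_peak",
    positive_fln_only: bool = True,
):
    """Pearson correlation between FLN and a GPDC summary.

    ``scope='pooled'`` returns one r over all (edge, simulation) points;
    ``'per-simulation'`` returns a pandas Series of r per simulation.
    """
    if table.empty:
        raise ValueError("empty edge table")
    t = _edge_filter(table, positive_fln_only)
    if scope == "pooled":
        return pearson(t["fln"], t[value])
    if scope == "per-simulation":
        return t.groupby("simulation").apply(
            lambda g: pearson(g["fln"], g[value]), include_groups=False
        )
    raise ValueError(f"unknown scope {scope!r}")


def bootstrap_edges(
    table: pd.DataFrame,
    n_edges: int = 80,
    n_boot: int = 1000,
    seed: int = 0,
    value: str = "gpdc_peak",
):
    """Bootstrap the FLN-GPDC correlation over random edge subsets.

    Samples ``n_edges`` directed edges with replacement, pools their points
    across simulations, computes r per resample; returns
    (mean_r, (ci_low, ci_high), all_r) with a 95% percentile interval.
    """
    edges = table[["source", "target"]].drop_duplicates().to_numpy()
    if edges.shape[0] < n_edges:
        raise ValueError(f"only {edges.shape[0]} edges available, need {n_edges}")
    rng = np.random.default_rng(seed)
    idx = table.set_index(["source", "target"])
    rs = np.empty(n_boot)
    for b in range(n_boot):
        pick = edges[rng.integers(edges.shape[0], size=n_edges)]
        sub = idx.loc[[tuple(e) for e in pick]]
        rs[b] = pearson(sub["fln"], sub[value])
    return float(rs.mean()), (float(np.percentile(rs, 2.5)), float(np.percentile(rs, 97.5))), rs


@dataclass(frozen=True)
class EdgeVariability:
    """Per-edge coefficient of variation of GPDC across simulations and its
    per-area aggregates.  ``cv`` is N x N (row = target); ``flagged`` marks
    edges with zero mean GPDC (CV undefined, excluded from sums).
    ``source_sum``/``target_sum`` are column/row sums of CV; ``sd_*`` the
    analogous raw-standard-deviation sums."""

    cv: np.ndarray
    flagged: np.ndarray
    source_sum: np.ndarray
    target_sum: np.ndarray
    sd_source_sum: np.ndarray
    sd_target_sum: np.ndarray
    correlations: dict = field(default_factory=dict)


def cv_analysis(
    table: pd.DataFrame,
    centrality: CentralityResult,
    value: str = "gpdc_peak",
) -> EdgeVariability:
    """Variability of GPDC estimates vs. structural centrality.

    Computes the per-edge CV (SD/mean across simulations) of the GPDC
    summary, sums it per source area (columns) and per target area (rows),
    and correlates both sums with nodal in-strength and eigenvector
    centrality.  Requires >= 3 simulations.
    """
    n_sims = table["simulation"].nunique()
    if n_sims < 3:
        raise ValueError("need at least 3 simulations for CV analysis")
    n = int(max(table["source"].max(), table["target"].max())) + 1
    g = table.groupby(["target", "source"])[value]
    mean = np.zeros((n, n))
    sd = np.zeros((n, n))
    for (i, j), vals in g:
        mean[i, j] = vals.mean()
        sd[i, j] = vals.std(ddof=1)
    # snap numerically-zero spread (identical replicates) to exactly zero
    sd[sd < 1e-12 * np.maximum(mean, 1e-300)] = 0.0
    flagged = (mean == 0) & ~np.eye(n, dtype=bool)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, sd / np.where(mean > 0, mean, 1.0), 0.0)
    res = {}
    sums = {
        "source_sum": cv.sum(axis=0),  # per source j: sum over targets (columns of CV)
        "target_sum": cv.sum(axis=1),  # per target i: sum over sources (rows)
        "sd_source_sum": sd.sum(axis=0),
        "sd_target_sum": sd.sum(axis=1),
    }
    for name, vec in sums.items():
        for cname, cvec in (
            ("in_strength", centrality.in_strength),
            ("eigenvector", centrality.eigenvector),
        ):
            try:
                res[(name, cname)] = pearson(vec, cvec)
            except ValueError:
                res[(name, cname)] = float("nan")  # flagged: undefined
    return EdgeVariability(
        cv, flagged, sums["source_sum"], sums["target_sum"],
        sums["sd_source_sum"], sums["sd_target_sum"], res,
    )


@dataclass(frozen=True)
class ActivityEstimate:
    """Activity-flow estimates: P_i = sum_{j != i} W_ij r_j with W the FLN
    matrix (structural pathway) or the GPDC peak matrix (functional
    pathway)."""

    p_fln: np.ndarray
    p_gpdc: np.ndarray
    rates: np.ndarray
    r_fln: float
    r_gpdc: float


def estimated_activity(
    fln: FLNMatrix, gpdc_matrix: np.ndarray, rates: np.ndarray
) -> ActivityEstimate:
    """Estimated incoming activity per target area through structural and
    functional pathways, and the correlation of each with the areas' own
    firing rates."""
    rates = np.asarray(rates, dtype=float)
    g = np.asarray(gpdc_matrix, dtype=float).copy()
    np.fill_diagonal(g, 0.0)
    if g.shape != fln.values.shape or rates.shape[0] != fln.n_areas:
        raise ValueError("inconsistent dimensions")
    p_fln = fln.values @ rates  # diagonal of FLN is zero
    p_gpdc = g @ rates
    try:
        r_f = pearson(p_fln, rates)
        r_g = pearson(p_gpdc, rates)
    except ValueError:  # e.g. uniform rates: correlation undefined
        r_f = r_g = float("nan")
    return ActivityEstimate(p_fln, p_gpdc, rates, r_f, r_g)


def welch_holm(groups_a, groups_b, alpha: float = 0.05) -> pd.DataFrame:
    """Welch unequal-variance t-tests for paired lists of groups with Holm
    step-down correction across the family.

    ``groups_a[k]`` vs ``groups_b[k]`` per condition k; returns a DataFrame
    with t, Welch-Satterthwaite p, Holm-adjusted p and rejection decisions.
    """
    if len(groups_a) != len(groups_b):
        raise ValueError("group lists must have equal length")
    t_stats, pvals = [], []
    for a, b in zip(groups_a, groups_b):
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.size < 2 or b.size < 2:
            raise ValueError("each group needs at least 2 observations")
        if a.std() == 0 and b.std() == 0:
            if np.allclose(a.mean(), b.mean()):
                t_stats.append(0.0)
                pvals.append(1.0)
                continue
            raise ValueError("zero variance in both groups with distinct means")
        res = scipy.stats.ttest_ind(a, b, equal_var=False)
        t_stats.append(float(res.statistic))
        pvals.append(float(res.pvalue))
    reject, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="holm")
    return pd.DataFrame(
        {"t": t_stats, "p": pvals, "p_holm": p_adj, "reject": reject}
    )


@dataclass(frozen=True)
class ClusterExperimentResult:
    """Partial-observation experiment output.

    ``correlations`` is a tidy DataFrame (size, mode, simulation, cluster,
    r); ``tests`` maps comparison mode ('subset', 'pairwise') to the Holm-
    corrected Welch test table against 'full' across sizes."""

    correlations: pd.DataFrame
    tests: dict


def cluster_experiment(
    signals_by_sim,
    fln: FLNMatrix,
    sizes=range(3, 16),
    n_clusters: int = 150,
    modes=("full", "subset", "pairwise"),
    p_max: int = 50,
    n_freq: int = 512,
    seed: int = 0,
    alpha: float = 0.05,
    positive_fln_only: bool = True,
) -> ClusterExperimentResult:
    """FLN-GPDC correlation over random area clusters under different MVAR
    conditioning.

    ``signals_by_sim`` maps simulation id -> (M, T) LFP array over all areas.
    For each cluster size, ``n_clusters`` uniform random area subsets are
    drawn (without replacement within a subset; clusters may repeat across
    draws) and the FLN-GPDC Pearson r is computed per simulation under each
    conditioning mode.  Welch t-tests compare subset and pairwise modes
    against full per size, Holm-corrected across sizes.
    """
    sizes = list(sizes)
    n = fln.n_areas
    if min(sizes) < 3:
        raise ValueError("cluster sizes below 3 give too few edges for correlation")
    if max(sizes) > n:
        raise ValueError("cluster size exceeds number of areas")
    rng = np.random.default_rng(seed)
    # one full-connectome fit per simulation, reused by every cluster
    full_mats = {}
    if "full" in modes:
        for sim, x in signals_by_sim.items():
            _, model = select_order(np.asarray(x, dtype=float), p_max)
            full_mats[sim] = edge_summary(gpdc(model, n_freq), "peak")
    rows = []
    for size in sizes:
        clusters = [rng.choice(n, size=size, replace=False) for _ in range(n_clusters)]
        for c_id, cl in enumerate(clusters):
            sub_fln = fln.values[np.ix_(cl, cl)]
            off = ~np.eye(size, dtype=bool)
            keep = off & (sub_fln > 0) if positive_fln_only else off
            for sim, x in signals_by_sim.items():
                x = np.asarray(x, dtype=float)
                for mode in modes:
                    if mode == "full":
                        mat = full_mats[sim][np.ix_(cl, cl)]
                    else:
                        mat = conditioned_gpdc(
                            x, cl, mode=mode, p_max=p_max, n_freq=n_freq
                        )
                    rows.append(
                        {
                            "size": size,
                            "mode": mode,
                            "simulation": sim,
                            "cluster": c_id,
                            "r": pearson(sub_fln[keep], mat[keep]),
                        }
                    )
    corr = pd.DataFrame(rows)
    tests = {}
    if "full" in modes:
        ref = [
            corr.loc[(corr["mode"] == "full") & (corr["size"] == s), "r"].to_numpy()
            for s in sizes
        ]
        for mode in modes:
            if mode == "full":
                continue
            other = [
                corr.loc[(corr["mode"] == mode) & (corr["size"] == s), "r"].to_numpy()
                for s in sizes
            ]
            tab = welch_holm(other, ref, alpha=alpha)
            tab.insert(0, "size", sizes)
            tests[mode] = tab
    return ClusterExperimentResult(corr, tests)
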