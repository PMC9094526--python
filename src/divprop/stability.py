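"""Stability of extracted predictive patterns across training-set diversity.

Given the weight vectors of many model instances (one per train/holdout
draw) and each draw's within-distribution diversity, this module measures
how the predictive pattern drifts as diversity grows:

- a draw-by-draw *consistency matrix* of Pearson correlations between
  weight vectors, ordered by diversity;
- per-region one-way ANOVA of node coefficients over diversity groups
  (draws chunked into near-equal groups from lowest to highest diversity);
- family-wise correction of the per-node ANOVA statistics by threshold-free
  cluster enhancement (TFCE) on the parcel adjacency graph with a
  permutation null that shuffles the diversity-group labels;
- per-network Pearson correlation between network-aggregated coefficients
  and diversity.

For connectivity features, edge weights are first collapsed to node values
(mean over a node's incident edges, optionally split by coefficient sign).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

from .features import edge_labels
from .stratification import chunk_sizes

__all__ = [
    "CoefficientCollection",
    "consistency_matrix",
    "node_coefficients",
    "diversity_groups",
    "diversity_anova",
    "tfce_enhance",
    "permutation_cluster_correct",
    "network_correlation",
]


@dataclass
class CoefficientCollection:
    """D draws x F features of fitted weights plus per-draw diversity."""

    weights: np.ndarray
    wd: np.ndarray
    feature_labels: list = field(default=None)
    modality: str = "connectivity"

    def __post_init__(self) -> None:
        self.weights = np.atleast_2d(np.asarray(self.weights, float))
        self.wd = np.asarray(self.wd, float).ravel()
        if self.wd.shape[0] != self.weights.shape[0]:
            raise ValueError("wd does not match number of draws")
        if not np.isfinite(self.wd).all():
            raise ValueError("diversity values must be finite")

    @property
    def n_draws(self) -> int:
        return self.weights.shape[0]

    def node_matrix(self, n_parcels: int | None = None, mode: str = "all") -> np.ndarray:
        """Draw x parcel matrix of node-collapsed coefficients."""
        if self.modality == "thickness":
            return self.weights.copy()
        if n_parcels is None:
            # F = P(P-1)/2  =>  P = (1 + sqrt(1 + 8F)) / 2
            n_parcels = int(round((1 + np.sqrt(1 + 8 * self.weights.shape[1])) / 2))
        if mode != "all":
            raise ValueError("node_matrix collapses with mode='all' only")
        return np.vstack([node_coefficients(w, n_parcels, "all") for w in self.weights])


def consistency_matrix(collection: CoefficientCollection) -> np.ndarray:
    """Pairwise Pearson correlation of weight vectors, diversity-ordered.

    Rows/columns follow ascending within-distribution diversity. A draw
    whose weight vector has zero variance yields NaN entries (reported as
    missing) rather than an error.
    """
    if collection.n_draws < 2:
        raise ValueError("need at least 2 draws")
    order = np.argsort(collection.wd, kind="stable")
    W = collection.weights[order]
    sd = W.std(axis=1)
    degenerate = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(W)
    C = np.atleast_2d(C)
    if degenerate.any():
        warnings.warn("zero-variance weight vector(s): entries reported as NaN",
                      stacklevel=2)
        C[degenerate, :] = np.nan
        C[:, degenerate] = np.nan
    np.fill_diagonal(C, np.where(degenerate, np.nan, 1.0))
    return C


def node_coefficients(
    edge_weights: np.ndarray, n_parcels: int, mode: str = "all"
):
    """Collapse edge weights to per-node values.

    ``mode="all"`` returns the mean over each node's P-1 incident edges.
    ``mode="signed"`` returns (positive_means, negative_means), averaging
    only the incident edges of each sign; a node with no edges of a sign
    gets NaN for that sign.
    """
    w = np.asarray(edge_weights, float).ravel()
    expected = n_parcels * (n_parcels - 1) // 2
    if w.size != expected:
        raise ValueError(
            f"{w.size} edge weights do not cover all {expected} edges of "
            f"{n_parcels} parcels"
        )
    labels = edge_labels(n_parcels)
    incident: list[list[float]] = [[] for _ in range(n_parcels)]
    for (i, j), val in zip(labels, w):
        incident[i].append(val)
        incident[j].append(val)
    if mode == "all":
        return np.array([np.mean(v) for v in incident])
    if mode == "signed":
        pos = np.array(
            [np.mean([x for x in v if x > 0]) if any(x > 0 for x in v) else np.nan
             for v in incident]
        )
        neg = np.array(
            [np.mean([x for x in v if x < 0]) if any(x < 0 for x in v) else np.nan
             for v in incident]
        )
        return pos, neg
    raise ValueError(f"unknown mode {mode!r}")


def diversity_groups(wd: np.ndarray, n_groups: int = 5) -> np.ndarray:
    """Group labels 0..n_groups-1 from chunking draws sorted by diversity."""
    wd = np.asarray(wd, float).ravel()
    if wd.size < 2 * n_groups:
        raise ValueError("every diversity group needs at least 2 draws")
    order = np.argsort(wd, kind="stable")
    sizes = chunk_sizes(wd.size, n_groups)
    labels = np.empty(wd.size, int)
    start = 0
    for g, size in enumerate(sizes):
        labels[order[start : start + size]] = g
        start += size
    return labels


def _anova_f(values: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Vectorized one-way ANOVA F per column of a draws x regions matrix."""
    levels = np.unique(groups)
    n = values.shape[0]
    grand = values.mean(axis=0)
    ss_between = np.zeros(values.shape[1])
    ss_within = np.zeros(values.shape[1])
    for lvl in levels:
        block = values[groups == lvl]
        ss_between += block.shape[0] * (block.mean(axis=0) - grand) ** 2
        ss_within += ((block - block.mean(axis=0)) ** 2).sum(axis=0)
    df_b = levels.size - 1
    df_w = n - levels.size
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_between / df_b) / (ss_within / df_w)
    F = np.where(ss_within == 0, np.where(ss_between == 0, 0.0, np.inf), F)
    return F


def diversity_anova(
    node_values: np.ndarray, wd: np.ndarray, n_groups: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Per-region F and uncorrected p over diversity groups.

    ``node_values`` is draws x regions (node-collapsed coefficients for
    connectivity, raw parcel weights for thickness). Draws are chunked into
    ``n_groups`` near-equal groups from lowest to highest diversity.
    Degenerate regions (zero within-group variance, unequal means) report
    F = inf, p = 0 without raising.
    """
    node_values = np.atleast_2d(np.asarray(node_values, float))
    groups = diversity_groups(wd, n_groups)
    F = _anova_f(node_values, groups)
    df_b = np.unique(groups).size - 1
    df_w = node_values.shape[0] - np.unique(groups).size
    p = np.where(np.isinf(F), 0.0, stats.f.sf(np.where(np.isinf(F), 1.0, F), df_b, df_w))
    return F, p


def tfce_enhance(
    node_stats: np.ndarray,
    adjacency: sparse.spmatrix | np.ndarray | None,
    E: float = 0.5,
    H: float = 2.0,
    n_steps: int = 100,
    dh: float | None = None,
) -> np.ndarray:
    """Threshold-free cluster enhancement of node statistics on a graph.

    Integrates cluster extent^E x height^H over thresholds from 0 to the
    maximum statistic in ``n_steps`` increments (or an explicit step
    ``dh``). With no adjacency every node is its own cluster, which reduces
    to a monotone transform of the plain statistic (max-statistic
    correction downstream).
    """
    s = np.asarray(node_stats, float).ravel()
    finite_max = np.nanmax(np.where(np.isinf(s), np.nan, s)) if s.size else 0.0
    s = np.where(np.isinf(s), finite_max if np.isfinite(finite_max) else 1.0, s)
    n = s.size
    top = s.max(initial=0.0)
    if top <= 0:
        return np.zeros_like(s)
    if dh is None:
        dh = top / n_steps
    if adjacency is None:
        u = np.empty(0, int)
        v = np.empty(0, int)
    else:
        coo = sparse.coo_matrix(sparse.csr_matrix(adjacency))
        keep = coo.row < coo.col
        u, v = coo.row[keep], coo.col[keep]

    enhanced = np.zeros_like(s)
    ones = np.ones(u.size)
    for h in np.arange(dh, top + dh / 2, dh):
        active = s >= h
        if not active.any():
            break
        if u.size:
            keep = active[u] & active[v]
            g = sparse.csr_matrix((ones[: keep.sum()], (u[keep], v[keep])), shape=(n, n))
            _, comp = connected_components(g, directed=False)
        else:
            comp = np.arange(n)
        sizes = np.bincount(comp)
        enhanced[active] += sizes[comp[active]] ** E * h**H * dh
    return enhanced


def permutation_cluster_correct(
    node_values: np.ndarray,
    group_labels: np.ndarray,
    adjacency,
    n_perm: int = 1000,
    seed: int = 0,
    E: float = 0.5,
    H: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """TFCE-corrected p per node for the diversity-group ANOVA.

    The observed per-node F statistics are enhanced on the adjacency graph;
    the null distribution of the maximum enhanced statistic is built from
    ``n_perm`` seeded permutations of the draws' group labels. Corrected
    p = (1 + #{null max >= observed}) / (n_perm + 1). An empty adjacency
    falls back to max-statistic correction (warning).

    Returns (enhanced_statistics, corrected_p).
    """
    node_values = np.atleast_2d(np.asarray(node_values, float))
    group_labels = np.asarray(group_labels).ravel()
    if adjacency is None or (sparse.csr_matrix(adjacency).nnz == 0):
        warnings.warn(
            "empty adjacency: falling back to max-statistic correction",
            stacklevel=2,
        )
        adjacency = None

    obs_F = _anova_f(node_values, group_labels)
    obs_enh = tfce_enhance(obs_F, adjacency, E=E, H=H)

    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(group_labels)
        F = _anova_f(node_values, perm)
        null_max[b] = tfce_enhance(F, adjacency, E=E, H=H).max(initial=0.0)
    p_corr = (1 + (null_max[None, :] >= obs_enh[:, None]).sum(axis=1)) / (n_perm + 1)
    return obs_enh, np.clip(p_corr, 0.0, 1.0)


def network_correlation(
    node_values: np.ndarray,
    wd: np.ndarray,
    network_map: Mapping[int, str] | Sequence[str],
) -> dict[str, float]:
    """Pearson r between network-aggregated coefficients and diversity.

    ``network_map`` assigns each parcel to one named network (mapping of
    parcel index -> network, or a per-parcel sequence). Per draw, node
    values are averaged within each network (NaNs excluded pairwise); the
    resulting per-network series is correlated with the draws' diversity.
    An empty network reports NaN; with only 2 draws |r| = 1 trivially
    (warning).
    """
    node_values = np.atleast_2d(np.asarray(node_values, float))
    wd = np.asarray(wd, float).ravel()
    if isinstance(network_map, Mapping):
        assignment = [network_map[k] for k in range(node_values.shape[1])]
    else:
        assignment = list(network_map)
    if len(assignment) != node_values.shape[1]:
        raise ValueError("network map does not cover every parcel")
    if wd.size == 2:
        warnings.warn("two draws only: correlations are degenerately +/-1",
                      stacklevel=2)
    networks = sorted(set(assignment))
    assignment = np.array(assignment)
    out: dict[str, float] = {}
    for net in networks:
        cols = assignment == net
        if not cols.any():
            out[net] = float("nan")
            continue
        series = np.nanmean(node_values[:, cols], axis=1)
        if np.std(series) == 0 or np.std(wd) == 0:
            out[net] = float("nan")
        else:
            out[net] = float(stats.pearsonr(series, wd)[0])
    return out
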