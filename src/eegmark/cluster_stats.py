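"""Covariate-adjusted group statistics with cluster-based permutation correction.

The group comparison at every feature (electrode, or time-frequency point)
is an ANCOVA: response ~ intercept + group (3 levels, dummy-coded) + age.
The group F statistic has (2, n - 4) degrees of freedom and the effect size
is partial eta squared, SS_group / (SS_group + SSE_full).

Multiple comparisons over features are corrected nonparametrically:
features with uncorrected p < 0.05 are grouped into clusters under a
predefined adjacency (electrode layout distance, or 4-neighborhood on a
time-frequency grid), the cluster statistic is the sum of F values over
members, and its corrected p value compares it against the null
distribution of the *maximum* cluster statistic over 1000 label
permutations (ages stay attached to their subjects; only group labels are
shuffled).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GLMDesign",
    "Adjacency",
    "Cluster",
    "ClusterTestResult",
    "ancova_f",
    "build_adjacency_montage",
    "grid_adjacency",
    "find_clusters",
    "permutation_cluster_test",
    "posthoc_pairwise",
]


@dataclass
class GLMDesign:
    """Per-subject design: 3-level group factor, age covariate, responses."""

    group: np.ndarray  # (n,) str labels
    age: np.ndarray  # (n,) years
    response: np.ndarray  # (n,) or (n, n_features)

    def __post_init__(self) -> None:
        self.group = np.asarray(self.group)
        self.age = np.asarray(self.age, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        n = len(self.group)
        if len(self.age) != n or self.response.shape[0] != n:
            raise ValueError("group, age and response must share the subject axis")
        levels, counts = np.unique(self.group, return_counts=True)
        if len(levels) < 2:
            raise ValueError("need at least 2 group levels")
        if counts.min() < 2:
            raise ValueError("every group level needs >= 2 subjects")
        if np.isnan(self.response).any():
            raise ValueError("missing responses: drop subjects listwise first")


@dataclass
class Adjacency:
    """Symmetric, irreflexive neighbor structure over features."""

    neighbors: list[np.ndarray]  # neighbors[i] = sorted indices adjacent to i

    def __post_init__(self) -> None:
        for i, nb in enumerate(self.neighbors):
            nb = np.asarray(nb, dtype=int)
            if i in nb:
                raise ValueError("adjacency must be irreflexive")
            self.neighbors[i] = nb

    @property
    def n_features(self) -> int:
        return len(self.neighbors)

    def mean_degree(self) -> float:
        return float(np.mean([len(nb) for nb in self.neighbors]))


@dataclass
class Cluster:
    members: np.ndarray  # feature indices
    f_sum: float
    p_corrected: float = np.nan
    max_partial_eta_sq: float = np.nan
    argmax_feature: int = -1


@dataclass
class ClusterTestResult:
    f_map: np.ndarray
    p_uncorr_map: np.ndarray
    eta_map: np.ndarray
    clusters: list[Cluster]
    n_permutations: int
    threshold: float
    null_max_fsum: np.ndarray = field(default_factory=lambda: np.empty(0))

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p_corrected <= alpha]


def _design_matrices(group: np.ndarray, age: np.ndarray):
    """Full (intercept + 2 group dummies + age) and reduced (no group) designs."""
    levels = np.unique(group)
    dummies = np.column_stack([(group == lv).astype(float) for lv in levels[1:]])
    x_full = np.column_stack([np.ones(len(group)), dummies, age])
    x_red = np.column_stack([np.ones(len(group)), age])
    return x_full, x_red


def _sse(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Residual sum of squares per response column via QR projection."""
    q, _ = np.linalg.qr(x)
    y2 = y if y.ndim == 2 else y[:, None]
    tot = np.einsum("ij,ij->j", y2, y2)
    proj = q.T @ y2
    return tot - np.einsum("ij,ij->j", proj, proj)


def ancova_f(design: GLMDesign):
    """Group F test adjusting for age, vectorized over feature columns.

    Returns (F, p_uncorrected, partial_eta_sq), scalars for a 1-D response
    and arrays for an (n, n_features) response. F has (k-1, n-k-1) degrees
    of freedom for k groups (so (2, n-4) in the 3-group design).
    """
    x_full, x_red = _design_matrices(design.group, design.age)
    n, p_full = x_full.shape
    if np.linalg.matrix_rank(x_full) < p_full:
        raise ValueError(
            "rank-deficient design: group dummies and age are collinear "
            "(e.g. age constant within a fully confounded layout)"
        )
    df1 = p_full - x_red.shape[1]
    df2 = n - p_full
    if df2 <= 0:
        raise ValueError(f"not enough subjects: need more than {p_full}")
    sse_full = _sse(x_full, design.response)
    sse_red = _sse(x_red, design.response)
    ss_group = np.maximum(sse_red - sse_full, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_group / df1) / (sse_full / df2)
        eta = ss_group / (ss_group + sse_full)
    p = stats.f.sf(f, df1, df2)
    if design.response.ndim == 1:
        return float(f[0]), float(p[0]), float(eta[0])
    return f, p, eta


def build_adjacency_montage(
    montage: dict[str, tuple[float, float]],
    labels: list[str],
    max_dist: float,
) -> Adjacency:
    """Neighbors = electrode pairs within ``max_dist`` layout distance."""
    pos = np.array([montage[c] for c in labels], dtype=float)
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    neighbors = []
    isolated = []
    for i in range(len(labels)):
        nb = np.flatnonzero((d[i] <= max_dist) & (np.arange(len(labels)) != i))
        if len(nb) == 0:
            isolated.append(labels[i])
        neighbors.append(nb)
    if isolated:
        warnings.warn(f"isolated electrodes at max_dist={max_dist}: {isolated}", stacklevel=2)
    return Adjacency(neighbors=neighbors)


def grid_adjacency(shape: tuple[int, int]) -> Adjacency:
    """4-neighborhood (no diagonals) over a row-major flattened 2-D grid."""
    nr, nc = shape
    neighbors = []
    for r in range(nr):
        for c in range(nc):
            nb = []
            if r > 0:
                nb.append((r - 1) * nc + c)
            if r < nr - 1:
                nb.append((r + 1) * nc + c)
            if c > 0:
                nb.append(r * nc + c - 1)
            if c < nc - 1:
                nb.append(r * nc + c + 1)
            neighbors.append(np.array(sorted(nb), dtype=int))
    return Adjacency(neighbors=neighbors)


def find_clusters(
    sig_mask: np.ndarray, adjacency: Adjacency, f_map: np.ndarray | None = None
) -> list[np.ndarray]:
    """Connected components of the supra-threshold subgraph.

    Returned as arrays of member indices, ordered by descending sum of F
    over members (insertion order if ``f_map`` is None).
    """
    mask = np.asarray(sig_mask, dtype=bool)
    seen = np.zeros_like(mask)
    comps = []
    for start in np.flatnonzero(mask):
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        comp = []
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in adjacency.neighbors[u]:
                if mask[v] and not seen[v]:
                    seen[v] = True
                    stack.append(v)
        comps.append(np.array(sorted(comp), dtype=int))
    if f_map is not None:
        comps.sort(key=lambda m: -float(np.sum(np.asarray(f_map)[m])))
    return comps


def _max_cluster_fsum(
    f: np.ndarray, p: np.ndarray, adjacency: Adjacency, threshold: float
) -> float:
    mask = p < threshold
    if not mask.any():
        return 0.0
    comps = find_clusters(mask, adjacency)
    return max(float(f[m].sum()) for m in comps)


def permutation_cluster_test(
    design: GLMDesign,
    adjacency: Adjacency,
    n_perm: int = 1000,
    threshold: float = 0.05,
    alpha_cluster: float = 0.05,
    seed=None,
) -> ClusterTestResult:
    """Max-cluster-statistic permutation ANCOVA over a feature map.

    Group labels are permuted across subjects (each subject keeps its age
    and response); cluster mass is the sum of F values; the corrected p of
    an observed cluster is ``(1 + #{null max-mass >= observed}) / (1 +
    n_perm)``, so it can never be exactly zero.
    """
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} gives p-value resolution of only {1 / (n_perm + 1):.3f}",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    y = design.response if design.response.ndim == 2 else design.response[:, None]
    f_map, p_map, eta_map = ancova_f(
        GLMDesign(design.group, design.age, y)
    )
    mask = p_map < threshold
    comps = find_clusters(mask, adjacency, f_map)
    clusters = [
        Cluster(
            members=m,
            f_sum=float(f_map[m].sum()),
            max_partial_eta_sq=float(eta_map[m].max()),
            argmax_feature=int(m[np.argmax(eta_map[m])]),
        )
        for m in comps
    ]
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(len(design.group))
        fb, pb, _ = ancova_f(GLMDesign(design.group[perm], design.age, y))
        null[b] = _max_cluster_fsum(fb, pb, adjacency, threshold)
    for c in clusters:
        c.p_corrected = float((1 + np.sum(null >= c.f_sum)) / (1 + n_perm))
    return ClusterTestResult(
        f_map=f_map,
        p_uncorr_map=p_map,
        eta_map=eta_map,
        clusters=clusters,
        n_permutations=n_perm,
        threshold=threshold,
        null_max_fsum=null,
    )


def posthoc_pairwise(design: GLMDesign, cluster: Cluster | np.ndarray) -> pd.DataFrame:
    """Welch two-sample t tests between group pairs on cluster-mean responses.

    The response is averaged over cluster members per subject; raw pairwise
    p values are reported without further multiplicity correction. Pairs
    involving a group with < 2 subjects are skipped with a warning.
    """
    members = cluster.members if isinstance(cluster, Cluster) else np.asarray(cluster)
    if len(members) == 0:
        raise ValueError("cluster is empty")
    y = design.response if design.response.ndim == 2 else design.response[:, None]
    means = y[:, members].mean(axis=1)
    rows = []
    for a, b in combinations(sorted(np.unique(design.group)), 2):
        ya, yb = means[design.group == a], means[design.group == b]
        if len(ya) < 2 or len(yb) < 2:
            warnings.warn(f"pair {a}-{b} skipped: group with < 2 subjects", stacklevel=2)
            continue
        t, p = stats.ttest_ind(ya, yb, equal_var=False)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "mean_a": float(ya.mean()),
                "mean_b": float(yb.mean()),
                "t": float(t),
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)
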