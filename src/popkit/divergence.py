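"""Population differentiation, informativeness, ordination and trees.

Distances between populations are computed from insertion-allele
frequencies: Nei-style G_ST (default F_ST estimator, with Weir-Cockerham
theta available), and Nei's D_A genetic distance.  Marker informativeness
for assignment follows Rosenberg's I_n statistic (in nats; divided by ln 2
it is the PSD value).  Ordination and trees: PCA with cos2/contribution
diagnostics in the correlation-circle convention, classical (Torgerson)
MDS on a distance matrix, neighbor-joining on D_A, and average-linkage
hierarchical clustering for heatmap ordering.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import nj as _skbio_nj

from .forensic import LocusFrequencies

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "pairwise_fst",
    "fst_matrix",
    "nei_da",
    "da_matrix",
    "informativeness_in",
    "informativeness_table",
    "cumulative_in",
    "pca",
    "classical_mds",
    "nj_tree",
    "hclust_order",
]


# ---------------------------------------------------------------------------
# Distance container
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric, zero-diagonal, non-negative labeled distance matrix."""

    labels: list[str]
    values: np.ndarray
    metric_name: str = "euclidean"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-10):
            raise ValueError("distance matrix diagonal is not zero")
        if (v < -1e-10).any():
            raise ValueError("distance matrix has negative entries")
        self.values = np.clip((v + v.T) / 2.0, 0.0, None)
        np.fill_diagonal(self.values, 0.0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, float_format="%.6f")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, metric_name: str = "euclidean"):
        return cls(list(df.index), df.to_numpy(dtype=float), metric_name)


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------

def _pair_freqs(
    freqs: LocusFrequencies, pop_a: str, pop_b: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    sub = freqs.df[freqs.df["population"].isin([pop_a, pop_b])]
    wide_p = sub.pivot(index="locus_id", columns="population", values="p_ins")
    wide_n = sub.pivot(index="locus_id", columns="population", values="n")
    wide_p = wide_p.dropna()
    if pop_a not in wide_p.columns or pop_b not in wide_p.columns or wide_p.empty:
        raise ValueError(f"no shared loci between {pop_a!r} and {pop_b!r}")
    wide_n = wide_n.loc[wide_p.index]
    return (
        wide_p[pop_a].to_numpy(), wide_p[pop_b].to_numpy(),
        wide_n[pop_a].to_numpy(dtype=float), wide_n[pop_b].to_numpy(dtype=float),
    )


def pairwise_fst(
    freqs: LocusFrequencies,
    pop_a: str,
    pop_b: str,
    estimator: Literal["gst", "wc"] = "gst",
) -> float:
    """Pairwise F_ST between two populations over their shared loci.

    ``"gst"`` (default) is the Nei-style two-population G_ST with
    unweighted means and a ratio of per-locus sums:
    per locus Hs = mean of 2 p_i q_i, Ht = 2 p-bar q-bar;
    F_ST = (sum Ht - sum Hs) / sum Ht, clamped at 0.

    ``"wc"`` is the Weir-Cockerham theta variance-components estimator
    (sample-size weighted; heterozygote frequencies taken at their HWE
    expectation since only allele frequencies are carried).  Under the
    Balding-Nichols model with both populations at divergence F from a
    common ancestor, theta estimates F itself while the two-population
    G_ST converges to F/(2-F); both mappings are exercised by the test
    suite.
    """
    pa, pb, na, nb = _pair_freqs(freqs, pop_a, pop_b)
    if estimator == "gst":
        hs = 0.5 * (2 * pa * (1 - pa) + 2 * pb * (1 - pb))
        pbar = 0.5 * (pa + pb)
        ht = 2 * pbar * (1 - pbar)
        tot = ht.sum()
        if tot <= 0:
            return 0.0
        return float(max((tot - hs.sum()) / tot, 0.0))
    if estimator == "wc":
        return _wc_theta(pa, pb, na, nb)
    raise ValueError(f"unknown estimator {estimator!r}")


def _wc_theta(pa, pb, na, nb) -> float:
    """Weir-Cockerham (1984) theta for r = 2 populations, biallelic loci."""
    r = 2.0
    nbar = (na + nb) / r
    nc = (r * nbar - (na**2 + nb**2) / (r * nbar)) / (r - 1)
    pbar = (na * pa + nb * pb) / (r * nbar)
    s2 = (na * (pa - pbar) ** 2 + nb * (pb - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (na * 2 * pa * (1 - pa) + nb * 2 * pb * (1 - pb)) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    denom = (a + b + c).sum()
    if denom <= 0:
        return 0.0
    return float(max(a.sum() / denom, 0.0))


def fst_matrix(
    freqs: LocusFrequencies, estimator: Literal["gst", "wc"] = "gst"
) -> DistanceMatrix:
    """All pairwise F_ST values as a :class:`DistanceMatrix`."""
    pops = freqs.populations
    m = np.zeros((len(pops), len(pops)))
    for (i, pa), (j, pb) in combinations(enumerate(pops), 2):
        m[i, j] = m[j, i] = pairwise_fst(freqs, pa, pb, estimator)
    return DistanceMatrix(pops, m, "FST")


# ---------------------------------------------------------------------------
# Nei's D_A
# ---------------------------------------------------------------------------

def nei_da(freqs: LocusFrequencies, pop_a: str, pop_b: str) -> float:
    """Nei's D_A distance over shared loci.

    D_A = (1/L) sum over loci of (1 - sum over alleles sqrt(x y)), the
    alleles being insertion and deletion.
    """
    pa, pb, _, _ = _pair_freqs(freqs, pop_a, pop_b)
    shared = np.sqrt(pa * pb) + np.sqrt((1 - pa) * (1 - pb))
    return float(np.mean(1.0 - shared))


def da_matrix(freqs: LocusFrequencies) -> DistanceMatrix:
    """All pairwise D_A distances as a :class:`DistanceMatrix`."""
    pops = freqs.populations
    m = np.zeros((len(pops), len(pops)))
    for (i, pa), (j, pb) in combinations(enumerate(pops), 2):
        m[i, j] = m[j, i] = nei_da(freqs, pa, pb)
    return DistanceMatrix(pops, m, "DA")


# ---------------------------------------------------------------------------
# Rosenberg informativeness for assignment
# ---------------------------------------------------------------------------

def informativeness_in(group_freqs: Sequence[float]) -> float:
    """Rosenberg's I_n (nats) for one biallelic locus across K groups.

    I_n = sum over alleles j of [ -pbar_j ln pbar_j
                                  + sum_i (p_ij ln p_ij) / K ]
    with pbar_j the unweighted mean frequency over groups and 0 ln 0 = 0.
    Bounded by ln K; zero iff all groups share the same frequencies.
    """
    p = np.asarray(group_freqs, dtype=float)
    if p.ndim != 1 or p.size < 2:
        raise ValueError("need frequencies for K >= 2 groups")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("frequencies must lie in [0, 1]")

    def xlogx(x: np.ndarray) -> np.ndarray:
        return np.where(x > 0, x * np.log(np.where(x > 0, x, 1.0)), 0.0)

    total = 0.0
    for allele in (p, 1.0 - p):
        pbar = allele.mean()
        total += float(-xlogx(np.array(pbar)) + xlogx(allele).mean())
    return max(total, 0.0)


def informativeness_table(
    freqs: LocusFrequencies, groups: Sequence[str] | None = None
) -> pd.Series:
    """Per-locus I_n across the given groups (default: all populations)."""
    m = freqs.matrix()
    if groups is not None:
        m = m.loc[list(groups)]
    m = m.dropna(axis=1)
    return pd.Series(
        {loc: informativeness_in(m[loc].to_numpy()) for loc in m.columns},
        name="I_n",
    )


def cumulative_in(
    freqs: LocusFrequencies,
    grouping: str | tuple[str, str],
) -> tuple[float, pd.Series]:
    """Cumulative (summed over loci) I_n for a grouping of superpopulations.

    ``grouping`` is either a focal group name (one-vs-rest: the focal
    group's frequencies against the unweighted mean of the remaining
    groups, K = 2 — the sense of "distinguishing one continental group
    from the others") or a pair of group names (pairwise mode).  ``freqs``
    must already be at the group level (see
    :meth:`LocusFrequencies.mean_by_group`).  Returns the cumulative value
    and the per-locus series; I_n is additive over loci.
    """
    m = freqs.matrix().dropna(axis=1)
    if isinstance(grouping, str):
        if grouping not in m.index:
            raise ValueError(f"group {grouping!r} not in frequency table")
        rest = m.drop(index=grouping)
        if rest.empty:
            raise ValueError("one-vs-rest grouping needs >= 2 groups")
        pairs = np.vstack([m.loc[grouping].to_numpy(), rest.mean(axis=0).to_numpy()])
    else:
        a, b = grouping
        pairs = np.vstack([m.loc[a].to_numpy(), m.loc[b].to_numpy()])
    per_locus = pd.Series(
        [informativeness_in(pairs[:, j]) for j in range(pairs.shape[1])],
        index=m.columns, name="I_n",
    )
    return float(per_locus.sum()), per_locus


# ---------------------------------------------------------------------------
# Ordination
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    """Coordinates of entities on components, with PCA diagnostics.

    ``coordinates``: entities x components scores.  ``explained_fraction``:
    per-component fraction of total variance (non-increasing).  For PCA,
    ``cos2`` holds the squared quality of representation of each feature
    on each component (squared feature-score correlations, correlation
    circle convention) and ``contributions`` the per-component normalized
    feature contributions; both are None for MDS.
    """

    coordinates: pd.DataFrame
    explained_fraction: np.ndarray
    cos2: pd.DataFrame | None = None
    contributions: pd.DataFrame | None = None


def pca(
    matrix: pd.DataFrame, standardize: bool = True, n_components: int | None = None
) -> OrdinationResult:
    """Principal component analysis with cos2 / contribution diagnostics.

    Rows are entities (populations or individuals), columns features (loci:
    insertion frequencies at population level, dosages with mean imputation
    at individual level).  Columns are centered, and scaled to unit
    variance when ``standardize``; zero-variance features are dropped with
    a warning under standardization.
    """
    X = matrix.to_numpy(dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA needs >= 2 entities and >= 2 features")
    if np.isnan(X).any():  # mean imputation, per feature
        mu = np.nanmean(X, axis=0)
        X = np.where(np.isnan(X), mu[None, :], X)
    cols = list(matrix.columns)
    sd = X.std(axis=0, ddof=0)
    if standardize:
        keep = sd > 0
        if not keep.all():
            warnings.warn(
                f"dropping {int((~keep).sum())} zero-variance features under "
                "standardization"
            )
            X, cols, sd = X[:, keep], [c for c, k in zip(cols, keep) if k], sd[keep]
        X = (X - X.mean(axis=0)) / sd
    else:
        X = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    # sign convention: largest-magnitude loading positive, for determinism
    flip = np.sign(Vt[np.arange(Vt.shape[0]), np.abs(Vt).argmax(axis=1)])
    Vt *= flip[:, None]
    U *= flip[None, :]
    var = S**2 / X.shape[0]
    total = var.sum()
    k = n_components or int((S > 1e-10).sum())
    k = min(k, S.size)
    scores = U[:, :k] * S[:k]
    comp_names = [f"PC{i + 1}" for i in range(k)]
    coords = pd.DataFrame(scores, index=matrix.index, columns=comp_names)
    # cos2: squared correlation between each feature and each score vector
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.array([
            [_safe_corr(X[:, j], scores[:, c]) for c in range(k)]
            for j in range(X.shape[1])
        ])
    cos2 = pd.DataFrame(corr**2, index=cols, columns=comp_names)
    load2 = (Vt[:k].T) ** 2
    contributions = pd.DataFrame(
        100.0 * load2 / load2.sum(axis=0, keepdims=True), index=cols,
        columns=comp_names,
    )
    return OrdinationResult(coords, var[:k] / total, cos2, contributions)


def _safe_corr(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def classical_mds(d: DistanceMatrix, k: int = 2) -> OrdinationResult:
    """Classical (Torgerson) multidimensional scaling.

    Double-centers the squared distances, B = -1/2 J D^2 J, and embeds on
    the top-k eigenpairs with coordinates eigvec * sqrt(eigval); negative
    eigenvalues (non-Euclidean input) are truncated.  If fewer than ``k``
    positive eigenvalues exist, fewer components are returned with a
    warning.
    """
    D = d.values
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(vals.max(), 0) * 1e-12 if vals.size else vals > 0
    n_pos = int(pos.sum())
    if n_pos < k:
        warnings.warn(f"only {n_pos} positive eigenvalues; returning {n_pos} "
                      f"components instead of {k}")
    k_eff = min(k, n_pos)
    if k_eff == 0:
        coords = np.zeros((n, 1))
        expl = np.zeros(1)
    else:
        coords = vecs[:, :k_eff] * np.sqrt(vals[:k_eff])
        expl = vals[:k_eff] / vals[pos].sum()
    names = [f"Dim{i + 1}" for i in range(coords.shape[1])]
    return OrdinationResult(
        pd.DataFrame(coords, index=d.labels, columns=names), expl
    )


# ---------------------------------------------------------------------------
# Trees and clustering
# ---------------------------------------------------------------------------

def nj_tree(d: DistanceMatrix) -> str:
    """Neighbor-joining (Saitou-Nei) tree from a distance matrix, as Newick.

    Negative branch lengths produced by the agglomeration are clamped to
    zero.  Requires at least three labels; the leaf label set is preserved.
    """
    if len(d.labels) < 3:
        raise ValueError("neighbor-joining needs >= 3 labels")
    tree = _skbio_nj(_SkbioDM(d.values, ids=d.labels), neg_as_zero=True)
    return str(tree).strip()


def hclust_order(matrix: pd.DataFrame, linkage: str = "average") -> dict:
    """Hierarchical clustering of rows and columns for heatmap rendering.

    Average-linkage (UPGMA) on Euclidean row/column distances.  Returns a
    dict with row/column leaf orders and the scipy linkage matrices
    (``None`` when that axis has a single entry).
    """
    out = {"row_order": list(matrix.index), "col_order": list(matrix.columns),
           "row_linkage": None, "col_linkage": None}
    X = matrix.to_numpy(dtype=float)
    if X.shape[0] >= 2:
        Z = sch.linkage(X, method=linkage, metric="euclidean")
        out["row_linkage"] = Z
        out["row_order"] = [matrix.index[i] for i in sch.leaves_list(Z)]
    if X.shape[1] >= 2:
        Z = sch.linkage(X.T, method=linkage, metric="euclidean")
        out["col_linkage"] = Z
        out["col_order"] = [matrix.columns[i] for i in sch.leaves_list(Z)]
    return out
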