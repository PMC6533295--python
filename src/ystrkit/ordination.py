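"""Ordination and phylogeny: PCA on one-hot genotypes, classical MDS, NJ.

These are the three visual-analysis inputs used to relate populations:
principal components of the one-hot-encoded raw genotypes (individual
level), Torgerson's classical multidimensional scaling of a Phi-distance
matrix, and a neighbor-joining tree over the population labels.

Neighbor-joining is implemented here rather than delegated so that ties
in the Q-criterion resolve deterministically (lexicographically smallest
label pair); trees are built as and serialized through scikit-bio
``TreeNode`` objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .profiles import PopulationSample

__all__ = [
    "OrdinationResult",
    "one_hot_encode",
    "pca",
    "classical_mds",
    "nj_tree",
    "write_newick",
    "read_newick",
]


@dataclass
class OrdinationResult:
    """Low-dimensional coordinates with per-axis variance explained."""

    labels: list[str]
    coordinates: np.ndarray  # n x k
    variance_explained: np.ndarray  # length k, non-increasing, sums <= 1
    method: str
    warnings: list[str] = field(default_factory=list)

    def to_frame(self, include_variance: bool = False) -> pd.DataFrame:
        """Coordinates as a DataFrame (label x axis1..axisK).

        With ``include_variance`` a final row ``variance_explained`` holds
        the per-axis fractions.
        """
        k = self.coordinates.shape[1]
        df = pd.DataFrame(
            self.coordinates,
            index=pd.Index(self.labels, name="label"),
            columns=[f"axis{i + 1}" for i in range(k)],
        )
        if include_variance:
            df.loc["variance_explained"] = self.variance_explained[:k]
        return df


def one_hot_encode(
    samples: Sequence[PopulationSample],
    subset: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """One-hot encode genotypes: one row per male, one 0/1 column per
    (locus, allele-or-combination).

    Multi-allele calls encode as one combination column (``DYS385=13,18``),
    matching how combination frequencies are counted. Zero-variance
    columns are dropped; returns the 0/1 DataFrame and a column-centered
    float copy ready for PCA. Profiles must be complete (apply
    ``filter_for_distance`` first).
    """
    profiles = [p for s in samples for p in s.profiles]
    if not profiles:
        raise ValueError("no profiles to encode")
    loci = list(profiles[0].panel.loci if subset is None else subset)
    rows = []
    index = []
    for p in profiles:
        row = {}
        for locus in loci:
            call = p.call(locus)
            if call.is_null:
                raise ValueError(
                    f"profile {p.sample_id} has a null call at {locus}; "
                    "filter before encoding"
                )
            row[f"{locus}={call}"] = 1
        rows.append(row)
        index.append(p.sample_id)
    mat = pd.DataFrame(rows, index=pd.Index(index, name="sample_id")).fillna(0)
    mat = mat.astype(np.int8)
    keep = mat.columns[mat.nunique() > 1]
    if keep.empty:
        raise ValueError("no variable columns after encoding (all profiles identical)")
    mat = mat[sorted(keep)]
    centered = mat.to_numpy(dtype=float)
    centered -= centered.mean(axis=0, keepdims=True)
    return mat, centered


def pca(
    matrix: np.ndarray | pd.DataFrame,
    labels: Sequence[str] | None = None,
    n_components: int | None = None,
) -> OrdinationResult:
    """Principal component analysis by SVD of the column-centered matrix.

    ``variance_explained[i]`` is the i-th covariance eigenvalue over the
    total; the sign of each component is fixed so its largest-magnitude
    loading is positive.
    """
    if isinstance(matrix, pd.DataFrame):
        if labels is None:
            labels = [str(i) for i in matrix.index]
        matrix = matrix.to_numpy(dtype=float)
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 1:
        raise ValueError("need a 2-D matrix with >= 2 rows and >= 1 column")
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    if not np.any(s > 1e-12):
        raise ValueError("matrix has rank 0 after centering")
    # deterministic sign: largest-|loading| entry of each PC made positive
    for i in range(len(s)):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] *= -1
            u[:, i] *= -1
    lam = s**2
    var_exp = lam / lam.sum()
    scores = u * s
    if n_components is not None:
        scores = scores[:, :n_components]
        var_exp = var_exp[:n_components]
    if labels is None:
        labels = [str(i) for i in range(x.shape[0])]
    return OrdinationResult(list(labels), scores, var_exp, "PCA")


def classical_mds(
    dist: np.ndarray | pd.DataFrame,
    k: int = 2,
    labels: Sequence[str] | None = None,
) -> OrdinationResult:
    """Torgerson's classical (metric) MDS of a distance matrix.

    Double-centers the squared distances, ``B = -1/2 J D^2 J``, and embeds
    on the top-k non-negative eigenpairs; negative eigenvalues (the matrix
    not being exactly Euclidean) are dropped and recorded as a warning.
    """
    if isinstance(dist, pd.DataFrame):
        if labels is None:
            labels = [str(i) for i in dist.index]
        dist = dist.to_numpy(dtype=float)
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    lam, vec = np.linalg.eigh(b)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    warnings = []
    neg = lam < -1e-9 * max(1.0, abs(lam[0]))
    if neg.any():
        warnings.append(
            f"{int(neg.sum())} negative eigenvalues dropped "
            f"(most negative {lam[neg].min():.3g}); distances not Euclidean"
        )
    pos = np.clip(lam, 0.0, None)
    k = min(k, n)
    coords = vec[:, :k] * np.sqrt(pos[:k])
    total = pos.sum()
    var_exp = pos[:k] / total if total > 0 else np.zeros(k)
    if labels is None:
        labels = [str(i) for i in range(n)]
    return OrdinationResult(list(labels), coords, var_exp, "MDS", warnings)


def _finish_star(nodes: list[TreeNode], d: np.ndarray) -> TreeNode:
    """Attach the last three subtrees via the three-point formulas."""
    la = (d[0, 1] + d[0, 2] - d[1, 2]) / 2
    lb = (d[0, 1] + d[1, 2] - d[0, 2]) / 2
    lc = (d[0, 2] + d[1, 2] - d[0, 1]) / 2
    for node, length in zip(nodes, (la, lb, lc)):
        node.length = length
    return TreeNode(children=list(nodes))


def nj_tree(
    dist: np.ndarray | pd.DataFrame,
    labels: Sequence[str] | None = None,
) -> TreeNode:
    """Saitou-Nei neighbor-joining tree (unrooted; trifurcating root node).

    Joins the pair minimizing Q_ij = (n-2) d_ij - r_i - r_j; Q ties break
    on the lexicographically smallest (sorted) label pair, so the result
    is independent of input ordering. Additive distance matrices are
    recovered exactly (topology and branch lengths). Negative branch
    lengths (possible for non-additive input) are kept.
    """
    if isinstance(dist, pd.DataFrame):
        if labels is None:
            labels = [str(i) for i in dist.index]
        dist = dist.to_numpy(dtype=float)
    d = np.array(dist, dtype=float)
    if labels is None:
        labels = [str(i) for i in range(d.shape[0])]
    n = d.shape[0]
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if d.shape != (n, n) or len(labels) != n:
        raise ValueError("labels must match the distance matrix")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")

    nodes = [TreeNode(name=l) for l in labels]
    # tie-break tag: smallest leaf label under each working node
    tags = [str(l) for l in labels]
    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                pair_tag = tuple(sorted((tags[i], tags[j])))
                key = (q, pair_tag)
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = d[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        nodes[i].length = li
        nodes[j].length = lj
        parent = TreeNode(children=[nodes[i], nodes[j]])
        new_d = (d[i] + d[j] - d[i, j]) / 2
        keep = [x for x in range(m) if x not in (i, j)]
        d2 = np.zeros((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = new_d[keep]
        d = d2
        new_tag = min(tags[i], tags[j])
        nodes = [nodes[x] for x in keep] + [parent]
        tags = [tags[x] for x in keep] + [new_tag]
    return _finish_star(nodes, d)


def write_newick(tree: TreeNode, path: str | Path) -> None:
    """Write the tree as Newick, branch lengths at 6 significant digits."""
    clone = tree.copy()
    for node in clone.traverse(include_self=True):
        if node.length is not None:
            node.length = float(f"{node.length:.6g}")
    clone.write(str(path), format="newick")


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")
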