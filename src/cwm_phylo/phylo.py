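"""Phylogenetic covariance matrices and related linear algebra.

Under Brownian-motion trait evolution on a rooted tree, the covariance
between two tips is the shared branch length from the root to their most
recent common ancestor; the variance of a tip is its root-to-tip
distance.  This matrix C is the workhorse of every phylogenetic method
in the package (signal statistics, PGLS, the Bayesian mixed model).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky

logger = logging.getLogger("cwm_phylo")

JITTER = 1e-8


@dataclass
class PhyloCovariance:
    """Tip-to-tip shared-branch-length matrix with its tip ordering."""

    matrix: np.ndarray
    tip_labels: list[str]

    def __post_init__(self) -> None:
        C = np.asarray(self.matrix, dtype=float)
        if C.shape[0] != C.shape[1] or C.shape[0] != len(self.tip_labels):
            raise ValueError("covariance matrix shape does not match tip labels")
        if not np.allclose(C, C.T, atol=1e-10):
            raise ValueError("covariance matrix must be symmetric")
        self.matrix = C

    @property
    def n(self) -> int:
        return len(self.tip_labels)

    def index_of(self, labels: list[str]) -> np.ndarray:
        pos = {lab: i for i, lab in enumerate(self.tip_labels)}
        try:
            return np.array([pos[lab] for lab in labels])
        except KeyError as exc:
            raise KeyError(f"tip label {exc.args[0]!r} not in tree") from exc

    def subset(self, labels: list[str]) -> "PhyloCovariance":
        idx = self.index_of(labels)
        return PhyloCovariance(self.matrix[np.ix_(idx, idx)], list(labels))

    def normalized(self) -> "PhyloCovariance":
        """Scale so the maximum diagonal entry is 1 (tree-height units out)."""
        scale = float(self.matrix.diagonal().max())
        if scale <= 0:
            raise ValueError("degenerate covariance: max diagonal entry <= 0")
        return PhyloCovariance(self.matrix / scale, list(self.tip_labels))


def phylo_covariance(tree: dendropy.Tree) -> PhyloCovariance:
    """Build the Brownian covariance matrix C from a rooted tree.

    ``C[i, j]`` is the root-to-MRCA path length of tips i and j;
    ``C[i, i]`` the root-to-tip distance.  Raises for an unrooted tree
    (root polytomy with ``is_rooted`` unset), since the root placement
    defines the matrix.
    """
    root = tree.seed_node
    if not tree.is_rooted and len(root.child_nodes()) > 2:
        raise ValueError("tree must be rooted to define a phylogenetic covariance")
    leaves = tree.leaf_nodes()
    labels = [lf.taxon.label for lf in leaves]
    n = len(labels)
    index = {id(lf): i for i, lf in enumerate(leaves)}
    C = np.zeros((n, n))

    # Depth-first accumulation: each internal node at depth d contributes
    # covariance d to every tip pair split across its children.
    depth: dict[int, float] = {id(root): root.edge.length or 0.0}
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        depth[id(node)] = depth[id(node.parent_node)] + (node.edge.length or 0.0)

    tips_below: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[id(node)]
            tips_below[id(node)] = [i]
            C[i, i] = depth[id(node)]
            continue
        child_lists = [tips_below.pop(id(ch)) for ch in node.child_nodes()]
        d = depth[id(node)]
        for a in range(len(child_lists)):
            for b in range(a + 1, len(child_lists)):
                for i in child_lists[a]:
                    C[i, child_lists[b]] = d
                    C[np.array(child_lists[b]), i] = d
        tips_below[id(node)] = [i for lst in child_lists for i in lst]
    return PhyloCovariance(C, labels)


def lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    """Pagel's lambda transform: scale off-diagonal entries by ``lam``."""
    out = C * lam
    np.fill_diagonal(out, C.diagonal())
    return out


def lambda_upper_bound(C: np.ndarray, cap: float = 1.2) -> float:
    """Largest lambda keeping every off-diagonal below both tip variances.

    A necessary condition for positive-definiteness of the transformed
    matrix; values slightly above 1 are legitimate on non-ultrametric or
    near-ultrametric trees, so the bound is capped rather than clamped
    to 1.
    """
    d = C.diagonal()
    n = C.shape[0]
    bound = cap
    for i in range(n):
        for j in range(i + 1, n):
            cij = C[i, j]
            if cij > 0:
                bound = min(bound, min(d[i], d[j]) / cij)
    return bound


def safe_cho_factor(V: np.ndarray, jitter: float = JITTER):
    """Cholesky factorisation with one diagonal-jitter retry.

    Repeated rows (for example from zero-length terminal branches) make
    V singular; a relative jitter restores positive-definiteness and is
    logged so the user knows the matrix was perturbed.
    """
    try:
        return cho_factor(V, lower=True)
    except np.linalg.LinAlgError:
        eps = jitter * max(float(V.diagonal().max()), 1.0)
        logger.warning("covariance matrix singular; adding %.2e diagonal jitter", eps)
        return cho_factor(V + eps * np.eye(V.shape[0]), lower=True)


def safe_cholesky_lower(V: np.ndarray, jitter: float = JITTER) -> np.ndarray:
    try:
        return cholesky(V, lower=True)
    except np.linalg.LinAlgError:
        eps = jitter * max(float(V.diagonal().max()), 1.0)
        logger.warning("covariance matrix singular; adding %.2e diagonal jitter", eps)
        return cholesky(V + eps * np.eye(V.shape[0]), lower=True)


def mvn_logpdf_chol(resid: np.ndarray, V: np.ndarray) -> float:
    """Log density of N(0, V) at ``resid`` via Cholesky."""
    cf = safe_cho_factor(V)
    n = resid.shape[0]
    logdet = 2.0 * np.sum(np.log(np.diagonal(cf[0])))
    quad = float(resid @ cho_solve(cf, resid))
    return -0.5 * (n * np.log(2 * np.pi) + logdet + quad)


def solve_spd(V: np.ndarray, B: np.ndarray) -> np.ndarray:
    return cho_solve(safe_cho_factor(V), B)
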