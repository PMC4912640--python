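"""Phylogenetic signal and distance-matrix correlation statistics.

Blomberg's K with a tip-shuffling randomization P-value, plus Mantel and
partial Mantel tests. K compares the observed ratio of trait variance to
phylogenetically corrected variance against its Brownian-motion expectation
on the same tree; K = 1 under Brownian motion, K -> 0 for convergent or
random evolution, K > 1 for conservatism.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "SignalResult",
    "phylo_covariance",
    "blombergs_k",
    "mantel",
    "partial_mantel",
    "identity_distance",
]


@dataclass
class SignalResult:
    statistic: float
    p_value: float
    n_permutations: int
    seed: int
    name: str = ""

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }


def phylo_covariance(tree: dendropy.Tree) -> pd.DataFrame:
    """Phylogenetic covariance matrix: shared root-to-MRCA path lengths.

    V_ij = (d(root,i) + d(root,j) - d(i,j)) / 2 from patristic distances, so
    the diagonal is each tip's root-to-tip depth.
    """
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate tip labels")
    depth = {}
    for leaf in tree.leaf_node_iter():
        d, node = 0.0, leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depth[leaf.taxon.label] = d
    n = len(taxa)
    v = np.empty((n, n))
    for a in range(n):
        v[a, a] = depth[labels[a]]
        for b in range(a + 1, n):
            dab = pdm.patristic_distance(taxa[a], taxa[b])
            v[a, b] = v[b, a] = 0.5 * (depth[labels[a]] + depth[labels[b]] - dab)
    return pd.DataFrame(v, index=labels, columns=labels)


def _k_statistic(x: np.ndarray, vinv: np.ndarray, expected_ratio: float) -> tuple:
    n = x.size
    ones = np.ones(n)
    denom_hat = ones @ vinv @ ones
    a_hat = (ones @ vinv @ x) / denom_hat
    dev = x - a_hat
    mse0 = float(dev @ dev) / (n - 1)
    mse = float(dev @ vinv @ dev) / (n - 1)
    if mse <= 0:
        raise ValueError("degenerate phylogenetic variance")
    return (mse0 / mse) / expected_ratio, mse


def blombergs_k(
    tree: dendropy.Tree, trait: pd.Series, n_perm: int = 999, seed: int = 0
) -> SignalResult:
    """Blomberg's K with a permutation P-value.

    K = [MSE0/MSE]_obs / [MSE0/MSE]_BM where MSE0 is the variance of the
    trait about its phylogenetically weighted mean, MSE the V^-1-weighted
    version, and the Brownian-motion expectation of their ratio is
    [tr(V) - n / sum(V^-1)] / (n - 1). P is the rank of the observed MSE
    (small MSE = strong signal) among tip-shuffled permutations, with the
    never-zero convention (1 + #{perm <= obs}) / (1 + n_perm).
    """
    v = phylo_covariance(tree)
    x = trait.reindex(v.index)
    if x.isna().any():
        missing = list(x.index[x.isna()])
        raise ValueError(f"trait missing for tips {missing[:5]}")
    x = x.to_numpy(dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("zero-variance trait: K undefined")
    vm = v.to_numpy()
    try:
        vinv = np.linalg.inv(vm)
    except np.linalg.LinAlgError:
        raise ValueError("singular phylogenetic covariance matrix") from None
    n = x.size
    expected_ratio = (np.trace(vm) - n / np.sum(vinv)) / (n - 1)
    k_obs, mse_obs = _k_statistic(x, vinv, expected_ratio)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        _, mse_p = _k_statistic(rng.permutation(x), vinv, expected_ratio)
        if mse_p <= mse_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return SignalResult(float(k_obs), float(p), n_perm, seed, name="blombergs_k")


def _offdiag(d: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(d.shape[0], k=1)
    return d[iu]


def _as_matrix(d) -> np.ndarray:
    m = d.to_numpy(dtype=float) if isinstance(d, pd.DataFrame) else np.asarray(d, float)
    if m.shape[0] != m.shape[1] or not np.allclose(m, m.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    return m


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        raise ValueError("zero-variance distances")
    return float((a @ b) / denom)


def mantel(d1, d2, n_perm: int = 999, seed: int = 0) -> SignalResult:
    """Mantel test: Pearson correlation of off-diagonal distances.

    P-values permute the row/column labels of the first matrix jointly, with
    the one-sided (greater) alternative and the never-zero convention.
    """
    m1, m2 = _as_matrix(d1), _as_matrix(d2)
    if m1.shape != m2.shape:
        raise ValueError("distance matrices differ in size")
    n = m1.shape[0]
    r_obs = _pearson(_offdiag(m1), _offdiag(m2))
    rng = np.random.default_rng(seed)
    v2 = _offdiag(m2)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_p = _pearson(_offdiag(m1[np.ix_(perm, perm)]), v2)
        if r_p >= r_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return SignalResult(float(r_obs), float(p), n_perm, seed, name="mantel")


def _residualize(y: np.ndarray, z: np.ndarray) -> np.ndarray:
    zc = z - z.mean()
    denom = zc @ zc
    if denom == 0:
        return y - y.mean()
    beta = (zc @ (y - y.mean())) / denom
    return y - y.mean() - beta * zc


def partial_mantel(d1, d2, d3, n_perm: int = 999, seed: int = 0) -> SignalResult:
    """Partial Mantel: correlation of D1 and D2 after removing D3 from both.

    Both matrices are residualized on the conditioning distances and the
    residuals correlated; the null distribution permutes D1's labels and
    re-residualizes.
    """
    m1, m2, m3 = _as_matrix(d1), _as_matrix(d2), _as_matrix(d3)
    n = m1.shape[0]
    v2 = _offdiag(m2)
    v3 = _offdiag(m3)
    r2 = _residualize(v2, v3)
    if np.allclose(r2, 0.0):
        # the conditioning matrix explains D2 exactly; nothing left to correlate
        return SignalResult(0.0, 1.0, n_perm, seed, name="partial_mantel")
    r_obs = _pearson(_residualize(_offdiag(m1), v3), r2)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        v1p = _offdiag(m1[np.ix_(perm, perm)])
        r_p = _pearson(_residualize(v1p, v3), r2)
        if r_p >= r_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return SignalResult(float(r_obs), float(p), n_perm, seed, name="partial_mantel")


def identity_distance(labels: pd.Series) -> pd.DataFrame:
    """0/1 'same group' distance: 0 within a host species, 1 between.

    The encoding used as the host-identity matrix in partial Mantel tests.
    """
    lab = labels.to_numpy()
    d = (lab[:, None] != lab[None, :]).astype(float)
    return pd.DataFrame(d, index=labels.index, columns=labels.index)
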