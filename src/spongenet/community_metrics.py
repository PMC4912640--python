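"""Alpha/beta diversity and multivariate dispersion.

Richness estimators (observed, Chao1, ACE), inverse Simpson diversity,
hypergeometric rarefaction, Bray-Curtis dissimilarity with optional
proportion/Hellinger transforms, and distance-to-group-centroid dispersion in
principal-coordinate space with the Anderson (2006) correction for negative
eigenvalues (the ``betadisper`` convention).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.special import gammaln

from spongenet.io_prep import CountTable

__all__ = [
    "rarefaction_expected",
    "chao1",
    "ace",
    "shannon",
    "inverse_simpson",
    "diversity_table",
    "bray_curtis",
    "dispersion_to_centroid",
]


def _counts(x) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    if (a < 0).any():
        raise ValueError("negative counts")
    return a


def rarefaction_expected(counts, n: int) -> float:
    """Expected richness in a random subsample of ``n`` reads.

    E[S_n] = sum_i [1 - C(N - N_i, n) / C(N, n)], evaluated with log-gamma
    arithmetic so deep samples do not overflow.
    """
    a = _counts(counts)
    a = a[a > 0]
    N = a.sum()
    if n < 0 or n > N:
        raise ValueError(f"subsample size {n} outside [0, {int(N)}]")
    if n == 0:
        return 0.0

    def logC(top, k):
        return gammaln(top + 1) - gammaln(k + 1) - gammaln(top - k + 1)

    keep = (N - a) >= n
    p_missing = np.zeros_like(a)
    p_missing[keep] = np.exp(logC(N - a[keep], n) - logC(N, n))
    return float(np.sum(1.0 - p_missing))


def chao1(counts) -> float:
    """Chao1 richness: S_obs + f1^2/(2 f2), bias-corrected when f2 = 0."""
    a = _counts(counts)
    a = a[a > 0]
    sobs = a.size
    f1 = int((a == 1).sum())
    f2 = int((a == 2).sum())
    if f1 == 0:
        return float(sobs)
    if f2 == 0:
        return sobs + f1 * (f1 - 1) / 2.0
    return sobs + f1 * f1 / (2.0 * f2)


def ace(counts, rare_cutoff: int = 10) -> float:
    """Abundance-based coverage estimator with the standard 10-count split."""
    a = _counts(counts)
    a = a[a > 0]
    rare = a[a <= rare_cutoff]
    s_abund = int((a > rare_cutoff).sum())
    s_rare = rare.size
    if s_rare == 0:
        return float(s_abund)
    n_rare = rare.sum()
    f1 = int((rare == 1).sum())
    if n_rare == f1:  # all rare species are singletons; fall back to Chao1
        return chao1(a)
    c_ace = 1.0 - f1 / n_rare
    ks = np.arange(1, rare_cutoff + 1)
    fk = np.array([(rare == k).sum() for k in ks])
    gamma2 = max(
        (s_rare / c_ace) * np.sum(ks * (ks - 1) * fk) / (n_rare * (n_rare - 1)) - 1.0,
        0.0,
    )
    return float(s_abund + s_rare / c_ace + (f1 / c_ace) * gamma2)


def shannon(counts) -> float:
    a = _counts(counts)
    a = a[a > 0]
    p = a / a.sum()
    return float(-np.sum(p * np.log(p)))


def inverse_simpson(counts) -> float:
    """Inverse Simpson diversity D = 1 / sum p_i^2."""
    a = _counts(counts)
    a = a[a > 0]
    if a.size == 0:
        raise ValueError("empty sample")
    p = a / a.sum()
    return float(1.0 / np.sum(p * p))


def diversity_table(table: CountTable) -> pd.DataFrame:
    """Per-sample diversity record: sobs, chao1, ace, shannon, inv_simpson."""
    rows = []
    for sample, row in table.counts.iterrows():
        a = row.to_numpy(dtype=float)
        if (a > 0).sum() == 0:  # sample emptied by upstream filters
            rows.append(
                {"sample_id": sample, "sobs": 0, "chao1": np.nan, "ace": np.nan,
                 "shannon": np.nan, "inv_simpson": np.nan}
            )
            continue
        rows.append(
            {
                "sample_id": sample,
                "sobs": int((a > 0).sum()),
                "chao1": chao1(a),
                "ace": ace(a),
                "shannon": shannon(a),
                "inv_simpson": inverse_simpson(a),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def bray_curtis(table: CountTable, transform: str = "proportion") -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between samples.

    ``transform`` is one of ``none`` (raw counts), ``proportion`` (rows scaled
    to sum 1) or ``hellinger`` (square root of proportions).
    """
    x = table.counts.to_numpy(dtype=float)
    if transform in ("proportion", "hellinger"):
        totals = x.sum(axis=1, keepdims=True)
        totals[totals == 0] = 1.0
        x = x / totals
        if transform == "hellinger":
            x = np.sqrt(x)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    d = squareform(pdist(x, metric="braycurtis"))
    ids = table.sample_ids
    return pd.DataFrame(d, index=ids, columns=ids)


def dispersion_to_centroid(dist: pd.DataFrame, groups: pd.Series) -> pd.Series:
    """Distance of each sample to its group centroid in PCoA space.

    The distance matrix is embedded by principal coordinates; axes with
    negative eigenvalues are kept separately and their squared distances are
    *subtracted* (Anderson 2006), flooring the squared distance at zero before
    the square root. Groups of size 1 get distance 0 with a warning.
    """
    ids = dist.index
    d = dist.to_numpy(dtype=float)
    n = d.shape[0]
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix not symmetric")
    # Gower double-centering
    a = -0.5 * d**2
    centering = np.eye(n) - np.ones((n, n)) / n
    g = centering @ a @ centering
    eigval, eigvec = np.linalg.eigh(g)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    keep = np.abs(eigval) > 1e-10 * max(np.abs(eigval).max(), 1.0)
    eigval, eigvec = eigval[keep], eigvec[:, keep]
    axes = eigvec * np.sqrt(np.abs(eigval))
    pos = eigval > 0

    groups = pd.Series(groups).reindex(ids)
    out = pd.Series(np.zeros(n), index=ids, name="dist_to_centroid")
    for _, members in groups.groupby(groups).groups.items():
        idx = ids.get_indexer(members)
        if len(idx) == 1:
            warnings.warn("group of size 1: dispersion set to 0")
            continue
        cen = axes[idx].mean(axis=0)
        delta2 = (axes[idx] - cen) ** 2
        sq = delta2[:, pos].sum(axis=1) - delta2[:, ~pos].sum(axis=1)
        out.iloc[idx] = np.sqrt(np.maximum(sq, 0.0))
    return out


def write_distance_tsv(dist: pd.DataFrame, path) -> None:
    dist.to_csv(path, sep="\t", lineterminator="\n")


def read_distance_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.columns = df.index
    return df
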