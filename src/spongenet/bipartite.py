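"""Global host-OTU bipartite network and degree-distribution analyses.

The network links a host species to an OTU when that OTU occurs in at least
one replicate of the species; OTUs enter only if seen in a minimum number of
distinct samples overall. The OTU-side complementary cumulative degree
distribution is fitted with a truncated power law Pc(k) = k^-a * exp(-k/b)
and the host side with an exponential Pc(k) = exp(-k/lambda), both by
nonlinear least squares on the untransformed Pc. Degree-based
specialist/generalist classes, the prevalence-versus-degree smoothing spline,
degree-preserving random null networks and the core-versus-global degree
enrichment curve complete the toolkit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from scipy.optimize import least_squares

from spongenet.io_prep import CountTable, SampleMetadata, aggregate_presence_by_species

__all__ = [
    "BipartiteNetwork",
    "DegreeFit",
    "build_network",
    "ccdf",
    "fit_truncated_power_law",
    "fit_exponential",
    "null_network",
    "classify_otus",
    "prevalence_spline",
    "core_degree_enrichment",
]


@dataclass
class BipartiteNetwork:
    """Host species and OTU node sets with presence links."""

    host_nodes: list
    otu_nodes: list
    links: set  # of (host, otu) tuples

    def __post_init__(self) -> None:
        self.links = set(self.links)
        hosts, otus = set(self.host_nodes), set(self.otu_nodes)
        for h, o in self.links:
            if h not in hosts or o not in otus:
                raise ValueError(f"link ({h!r}, {o!r}) references unknown node")

    @property
    def n_links(self) -> int:
        return len(self.links)

    def otu_degrees(self) -> pd.Series:
        """Number of host species each OTU is found in (k)."""
        deg = {o: 0 for o in self.otu_nodes}
        for _, o in self.links:
            deg[o] += 1
        return pd.Series(deg, name="degree").loc[list(self.otu_nodes)]

    def host_degrees(self) -> pd.Series:
        deg = {h: 0 for h in self.host_nodes}
        for h, _ in self.links:
            deg[h] += 1
        return pd.Series(deg, name="degree").loc[list(self.host_nodes)]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.host_nodes, bipartite="host")
        g.add_nodes_from(self.otu_nodes, bipartite="otu")
        g.add_edges_from(self.links)
        return g

    def write_edgelist(self, path) -> None:
        rows = sorted(self.links)
        pd.DataFrame(rows, columns=["host_species", "otu_id"]).to_csv(
            path, sep="\t", index=False, lineterminator="\n"
        )

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)


@dataclass
class DegreeFit:
    """Least-squares fit of a decreasing form to CCDF points."""

    side: str  # "otu" | "host"
    form: str  # "truncated_power_law" | "exponential"
    params: dict
    rss: float
    converged: bool
    flags: list = field(default_factory=list)

    def predict(self, k) -> np.ndarray:
        k = np.asarray(k, dtype=float)
        if self.form == "truncated_power_law":
            return k ** (-self.params["a"]) * np.exp(-k / self.params["b"])
        return np.exp(-k / self.params["scale"])

    def to_json(self, path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            json.dump(
                {
                    "side": self.side,
                    "form": self.form,
                    "params": self.params,
                    "rss": self.rss,
                    "converged": self.converged,
                    "flags": self.flags,
                },
                fh,
                indent=2,
            )


def build_network(
    table: CountTable, meta: SampleMetadata, min_samples: int = 25
) -> BipartiteNetwork:
    """Build the host-OTU presence network.

    OTUs must occur (count > 0) in at least ``min_samples`` distinct samples
    across the whole dataset to become nodes; a link (species, OTU) exists
    when the OTU occurs in >=1 replicate of that species. Only sponge samples
    contribute links, but the sample-count filter sees every sample.
    """
    present = table.counts > 0
    eligible = present.sum(axis=0) >= min_samples
    otus = list(table.otu_ids[eligible])
    if not otus:
        raise ValueError(
            f"no OTU present in >= {min_samples} samples; network would be empty"
        )
    sponge = [s for s in meta.sponge_samples if s in table.sample_ids]
    sub = CountTable(table.counts.loc[sponge, otus])
    sub_meta = SampleMetadata(meta.table.loc[sponge])
    presence, _ = aggregate_presence_by_species(sub, sub_meta)
    hosts = list(presence.index)
    links = {
        (h, o)
        for h in hosts
        for o in presence.columns[presence.loc[h].to_numpy()]
    }
    # drop OTUs that pass the sample filter but never occur in a sponge sample
    linked_otus = {o for _, o in links}
    otus = [o for o in otus if o in linked_otus]
    return BipartiteNetwork(hosts, otus, links)


def ccdf(degrees) -> pd.DataFrame:
    """Complementary cumulative degree distribution.

    Pc(k) = fraction of nodes with degree >= k, evaluated at each observed
    degree. Pc at the minimum observed degree is 1 and the curve is
    non-increasing.
    """
    deg = np.asarray(degrees, dtype=float)
    deg = deg[deg > 0]
    if deg.size == 0:
        raise ValueError("no positive degrees")
    ks = np.unique(deg)
    pc = np.array([(deg >= k).mean() for k in ks])
    return pd.DataFrame({"k": ks, "pc": pc})


def cdf(degrees) -> pd.DataFrame:
    """The <=k variant (probability of degree at most k)."""
    deg = np.asarray(degrees, dtype=float)
    ks = np.unique(deg)
    pc = np.array([(deg <= k).mean() for k in ks])
    return pd.DataFrame({"k": ks, "pc": pc})


def _ls_fit(residual_fn, starts, bounds):
    best = None
    for x0 in starts:
        try:
            res = least_squares(residual_fn, x0, bounds=bounds, method="trf")
        except ValueError:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("degree-distribution fit failed from every start")
    return best


def fit_truncated_power_law(points: pd.DataFrame, side: str = "otu") -> DegreeFit:
    """Fit Pc(k) = k^-a * exp(-k/b) by least squares on untransformed Pc.

    Levenberg-Marquardt-style trust-region fits from a small grid of starts
    (a in {0.1, 0.5, 1}, b in {mean k, 2 mean k}); a cutoff estimate beyond
    10x the largest observed degree is flagged as "no cutoff support".
    """
    k = np.asarray(points["k"], dtype=float)
    pc = np.asarray(points["pc"], dtype=float)
    if k.size < 4:
        raise ValueError(f"need >=4 CCDF points to fit, got {k.size}")
    kbar = k.mean()

    def resid(theta):
        a, b = theta
        return k ** (-a) * np.exp(-k / b) - pc

    starts = [(a0, b0) for a0 in (0.1, 0.5, 1.0) for b0 in (kbar, 2 * kbar)]
    best = _ls_fit(resid, starts, bounds=([0.0, 1e-9], [np.inf, np.inf]))
    a, b = best.x
    flags = []
    if b > 10 * k.max():
        flags.append("no cutoff support")
    return DegreeFit(
        side=side,
        form="truncated_power_law",
        params={"a": float(a), "b": float(b)},
        rss=float(2 * best.cost),
        converged=bool(best.success),
        flags=flags,
    )


def fit_exponential(points: pd.DataFrame, side: str = "host") -> DegreeFit:
    """Fit Pc(k) = exp(-k/scale) by least squares on untransformed Pc."""
    k = np.asarray(points["k"], dtype=float)
    pc = np.asarray(points["pc"], dtype=float)
    if k.size < 3:
        raise ValueError(f"need >=3 CCDF points to fit, got {k.size}")
    kbar = k.mean()

    def resid(theta):
        return np.exp(-k / theta[0]) - pc

    best = _ls_fit(resid, [(kbar,), (2 * kbar,), (k.max(),)], bounds=([1e-9], [np.inf]))
    scale = float(best.x[0])
    flags = []
    if scale > 100 * k.max():
        flags.append("divergent scale (near-constant Pc)")
    return DegreeFit(
        side=side,
        form="exponential",
        params={"scale": scale},
        rss=float(2 * best.cost),
        converged=bool(best.success),
        flags=flags,
    )


def null_network(net: BipartiteNetwork, seed: int) -> BipartiteNetwork:
    """Degree-free random null: same node sets, same link count, links drawn
    uniformly without replacement from all host x OTU pairs."""
    rng = np.random.default_rng(seed)
    n_h, n_o = len(net.host_nodes), len(net.otu_nodes)
    total = n_h * n_o
    if net.n_links > total:
        raise ValueError("more links than possible pairs")
    flat = rng.choice(total, size=net.n_links, replace=False)
    links = {
        (net.host_nodes[i // n_o], net.otu_nodes[i % n_o]) for i in np.sort(flat)
    }
    return BipartiteNetwork(list(net.host_nodes), list(net.otu_nodes), links)


def classify_otus(
    net: BipartiteNetwork,
    table: CountTable,
    meta: SampleMetadata,
    spec_max: int = 5,
    gen_min: int = 50,
) -> pd.DataFrame:
    """Classify network OTUs as specialist / intermediate / generalist.

    Specialists occur in fewer than ``spec_max`` host species (strict <) and
    generalists in more than ``gen_min`` (strict >). Each OTU also gets its
    prevalence fraction: the share of all replicates of its linked host
    species that contain it. Attached to the frame (``.attrs['diagnostics']``)
    are the mean network degree, per-class mean degrees and their ratios to
    the overall mean.
    """
    deg = net.otu_degrees()
    host = meta.host_of().reindex(table.sample_ids)
    present = table.counts > 0
    otu_hosts: dict = {o: set() for o in net.otu_nodes}
    for h, o in net.links:
        otu_hosts[o].add(h)
    n_samples_of_host = host.value_counts()
    rows = []
    for o in net.otu_nodes:
        k = int(deg[o])
        if k < spec_max:
            cls = "specialist"
        elif k > gen_min:
            cls = "generalist"
        else:
            cls = "intermediate"
        hosts = sorted(otu_hosts[o])
        samples = host.isin(hosts)
        denom = int(n_samples_of_host.reindex(hosts).fillna(0).sum())
        if o in present.columns and denom > 0:
            num = int(present.loc[samples.to_numpy(), o].sum())
            prev = num / denom
        else:
            prev = 0.0
        rows.append({"otu_id": o, "degree": k, "otu_class": cls, "prevalence_fraction": prev})
    out = pd.DataFrame(rows).set_index("otu_id")
    mean_all = float(out["degree"].mean())
    per_class = out.groupby("otu_class")["degree"].mean().to_dict()
    out.attrs["diagnostics"] = {
        "mean_degree": mean_all,
        "mean_degree_by_class": per_class,
        "ratio_to_mean": {c: (mean_all / v if v else np.nan) for c, v in per_class.items()},
    }
    return out


def prevalence_spline(
    classifications: pd.DataFrame,
    smoothing: str = "cv",
    lam: float | None = None,
    grid_size: int = 200,
) -> pd.DataFrame:
    """Cubic smoothing spline of prevalence fraction against degree.

    Ties in degree are collapsed to their mean prevalence with weights equal
    to the tie count, after which the spline's smoothing parameter is chosen
    by generalized cross-validation (``smoothing="cv"``) or fixed at ``lam``.
    Returns curve samples on an even grid spanning the observed degree range.
    """
    df = classifications[["degree", "prevalence_fraction"]].astype(float)
    grouped = df.groupby("degree")["prevalence_fraction"]
    x = np.array(sorted(grouped.groups))
    y = grouped.mean().loc[x].to_numpy()
    w = grouped.size().loc[x].to_numpy(dtype=float)
    if x.size < 4:
        raise ValueError("need >=4 distinct degrees for a cubic spline")
    if smoothing == "cv":
        spl = make_smoothing_spline(x, y, w=w)
    elif smoothing == "fixed":
        spl = make_smoothing_spline(x, y, w=w, lam=lam)
    else:
        raise ValueError(f"unknown smoothing {smoothing!r}")
    grid = np.linspace(x.min(), x.max(), grid_size)
    return pd.DataFrame({"degree": grid, "prevalence_fit": spl(grid)})


def core_degree_enrichment(net: BipartiteNetwork, core_otu_ids) -> dict:
    """Compare the degree distribution of aggregated core OTUs to the global set.

    For each observed degree d the curve pairs (fraction of all network OTUs
    with degree >= d, fraction of core OTUs with degree >= d); points above
    the 1:1 line mean high-degree enrichment of the core. ``break_k`` is the
    smallest degree at which the core fraction first exceeds the global
    fraction (ascending scan).
    """
    core = [o for o in core_otu_ids if o in set(net.otu_nodes)]
    if not core:
        raise ValueError("core OTU set is empty or disjoint from the network")
    deg = net.otu_degrees()
    core_deg = deg.loc[core].to_numpy(dtype=float)
    all_deg = deg.to_numpy(dtype=float)
    ks = np.unique(all_deg)
    global_frac = np.array([(all_deg >= d).mean() for d in ks])
    core_frac = np.array([(core_deg >= d).mean() for d in ks])
    above = core_frac > global_frac
    break_k = float(ks[above][0]) if above.any() else None
    return {
        "curve": pd.DataFrame(
            {"degree": ks, "global_fraction": global_frac, "core_fraction": core_frac}
        ),
        "break_k": break_k,
        "mean_degree_global": float(all_deg.mean()),
        "mean_degree_core": float(core_deg.mean()),
    }
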