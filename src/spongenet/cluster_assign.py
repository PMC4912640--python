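"""Membership of OTU sequences in sponge-specific (SC) and sponge/coral-
specific (SCC) sequence clusters, decided from a top-hits similarity table.

The decision rule: among the 10 best hits of a query, if the single most
similar reference carries a cluster label, exceeds 75% identity and no
equally similar reference disagrees, the query joins that cluster
(``best_hit``). If the top is ambiguous (identity ties with conflicting
labels), a majority rule applies: the cluster must hold at least 60% of the
retained hits and its best in-cluster identity must exceed 75%
(``majority``). Anything else stays unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from spongenet.io_prep import CountTable

__all__ = ["ClusterAssignment", "read_hit_table", "assign", "assign_all", "summarize"]

BLAST12_COLUMNS = [
    "query_id",
    "ref_id",
    "percent_identity",
    "alignment_length",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "evalue",
    "bit_score",
]


@dataclass
class ClusterAssignment:
    query_id: str
    assigned_cluster: str | None
    rule_fired: str  # best_hit | majority | below_threshold | inconsistent


def read_hit_table(path, cluster_map_path) -> pd.DataFrame:
    """Read a 12-column tabular alignment file plus a ref -> cluster TSV.

    The cluster map has columns ``ref_id`` and ``cluster`` (empty cluster =
    unaffiliated reference). Returns the columns :func:`assign` consumes.
    """
    hits = pd.read_csv(path, sep="\t", names=BLAST12_COLUMNS)
    cmap = pd.read_csv(cluster_map_path, sep="\t", dtype=str).fillna("")
    merged = hits.merge(cmap, on="ref_id", how="left")
    merged["ref_cluster"] = merged["cluster"].fillna("")
    return merged[["query_id", "ref_id", "percent_identity", "ref_cluster"]]


def assign(
    hits: pd.DataFrame,
    id_threshold: float = 75.0,
    majority: float = 0.60,
    top_n: int = 10,
) -> ClusterAssignment:
    """Decide cluster membership for one query's hits.

    ``hits`` must have columns ``query_id, ref_id, percent_identity,
    ref_cluster`` (empty string = no cluster). Deterministic under row
    permutation: hits are re-ranked by identity with the reference id as the
    final tie-break.
    """
    if hits.empty:
        raise ValueError("empty hit table")
    ident = hits["percent_identity"].to_numpy(dtype=float)
    if (ident < 0).any() or (ident > 100).any():
        raise ValueError("percent identity outside [0, 100]")
    qid = str(hits["query_id"].iloc[0])
    ranked = hits.sort_values(
        ["percent_identity", "ref_id"], ascending=[False, True]
    ).head(top_n)
    best_ident = ranked["percent_identity"].iloc[0]
    top_ties = ranked[ranked["percent_identity"] == best_ident]
    top_clusters = set(top_ties["ref_cluster"].fillna(""))

    if len(top_clusters) == 1:
        cluster = top_clusters.pop()
        if not cluster:
            return ClusterAssignment(qid, None, "inconsistent")
        if best_ident > id_threshold:
            return ClusterAssignment(qid, cluster, "best_hit")
        return ClusterAssignment(qid, None, "below_threshold")

    # ties at the top with conflicting labels -> majority rule over the
    # retained hits
    labels = ranked["ref_cluster"].fillna("")
    counts = labels[labels != ""].value_counts()
    if len(counts):
        cluster = counts.index[0]
        frac = counts.iloc[0] / len(ranked)
        best_in_cluster = ranked.loc[labels == cluster, "percent_identity"].max()
        if frac >= majority and best_in_cluster > id_threshold:
            return ClusterAssignment(qid, cluster, "majority")
    return ClusterAssignment(qid, None, "inconsistent")


def assign_all(hits: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Apply :func:`assign` per query; returns a query-indexed frame."""
    rows = []
    for qid, sub in hits.groupby("query_id", sort=True):
        a = assign(sub, **kwargs)
        rows.append(
            {
                "query_id": qid,
                "assigned_cluster": a.assigned_cluster or "",
                "rule_fired": a.rule_fired,
            }
        )
    return pd.DataFrame(rows).set_index("query_id")


def summarize(
    assignments: pd.DataFrame,
    table: CountTable,
    meta=None,
) -> pd.DataFrame:
    """Read-weighted and OTU-weighted cluster fractions, overall and per habitat.

    ``assignments`` is indexed by OTU id (queries are OTU representative
    sequences). Rows are habitats (plus ``overall``); columns are the
    fraction of reads and of OTUs assigned to any cluster.
    """
    assigned = assignments["assigned_cluster"] != ""
    otus = [o for o in table.otu_ids if o in assignments.index]
    flags = assignments.loc[otus, "assigned_cluster"].ne("")

    def _fracs(counts: pd.DataFrame) -> dict:
        total_reads = counts.to_numpy().sum()
        reads_assigned = counts.loc[:, flags[flags].index].to_numpy().sum()
        n_otus = len(otus)
        return {
            "read_fraction": reads_assigned / total_reads if total_reads else 0.0,
            "otu_fraction": flags.mean() if n_otus else 0.0,
            "n_reads": int(total_reads),
        }

    sub = table.counts[otus]
    rows = {"overall": _fracs(sub)}
    if meta is not None:
        for habitat in sorted(meta.table["habitat"].unique()):
            samples = [s for s in meta.habitat_samples(habitat) if s in sub.index]
            if samples:
                rows[habitat] = _fracs(sub.loc[samples])
    out = pd.DataFrame(rows).T
    out.index.name = "habitat"
    out.attrs["per_cluster"] = (
        assignments.loc[assigned.index[assigned], "assigned_cluster"]
        .value_counts()
        .to_dict()
    )
    return out
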