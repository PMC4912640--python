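"""Count-table I/O and dataset-level filters.

The working container is :class:`CountTable`, a thin wrapper over a samples x
OTUs integer DataFrame. Readers cover the mothur ``.shared`` dialect and plain
TSV; filters implement the dataset-level cleaning applied before any network
or diversity analysis: drop OTUs below a global relative-abundance floor, drop
OTUs whose lineage matches an unwanted taxon (chloroplasts), and zero out
seawater-derived OTUs in host samples.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "SampleMetadata",
    "read_shared",
    "write_shared",
    "read_counts_tsv",
    "read_metadata",
    "read_taxonomy",
    "filter_low_abundance",
    "remove_seawater_like",
    "remove_taxon",
    "aggregate_presence_by_species",
]


class ParseError(ValueError):
    """Malformed input table."""


@dataclass
class CountTable:
    """Samples x OTUs matrix of non-negative integer counts.

    Parameters
    ----------
    counts
        DataFrame indexed by sample id with one column per OTU id.
    provenance
        Ordered record of the filters already applied, for output manifests.
    """

    counts: pd.DataFrame
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ParseError("duplicate sample ids")
        if self.counts.columns.has_duplicates:
            raise ParseError("duplicate OTU ids")
        arr = self.counts.to_numpy()
        if arr.size and (not np.issubdtype(arr.dtype, np.integer)):
            if not np.allclose(arr, np.round(arr)):
                raise ParseError("non-integer counts")
            self.counts = self.counts.astype(np.int64)
        if arr.size and (self.counts.to_numpy() < 0).any():
            raise ParseError("negative counts")

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def otu_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def sample_totals(self) -> pd.Series:
        """Per-sample read totals N_m, always recomputed from the matrix."""
        return self.counts.sum(axis=1)

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def subset_samples(self, sample_ids) -> "CountTable":
        return CountTable(self.counts.loc[list(sample_ids)], list(self.provenance))

    def subset_otus(self, otu_ids) -> "CountTable":
        return CountTable(self.counts[list(otu_ids)], list(self.provenance))

    def copy(self) -> "CountTable":
        return CountTable(self.counts.copy(), list(self.provenance))


@dataclass
class SampleMetadata:
    """Sample -> host species / habitat mapping.

    ``habitat`` distinguishes host-associated samples (``sponge``) from the
    environmental references (``seawater``, ``sediment``).
    """

    table: pd.DataFrame  # index sample_id; columns host_species, habitat

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ParseError("duplicate sample ids in metadata")
        for col in ("host_species", "habitat"):
            if col not in self.table.columns:
                raise ParseError(f"metadata missing column {col!r}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def samples_of(self, host_species: str) -> list:
        t = self.table
        return list(t.index[t["host_species"] == host_species])

    def habitat_samples(self, habitat: str) -> list:
        t = self.table
        return list(t.index[t["habitat"] == habitat])

    @property
    def sponge_samples(self) -> list:
        return self.habitat_samples("sponge")

    def host_of(self) -> pd.Series:
        return self.table["host_species"]


# ---------------------------------------------------------------------------
# readers / writers


def read_shared(path) -> CountTable:
    """Parse a mothur ``.shared`` table.

    Columns are ``label, Group, numOtus, <otu ids...>``; ``Group`` becomes the
    sample id. The declared ``numOtus`` is validated against the actual row
    width and ragged or non-integer rows raise :class:`ParseError` naming the
    offending line.
    """
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 3 or header[1] != "Group":
            raise ParseError(f"{path}: not a .shared header: {header[:3]}")
        otu_ids = header[3:]
        width = len(header)
        rows, groups = [], []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != width:
                raise ParseError(
                    f"{path}:{lineno}: ragged row ({len(parts)} fields, expected {width})"
                )
            group = parts[1]
            if group in groups:
                raise ParseError(f"{path}:{lineno}: duplicate Group {group!r}")
            try:
                declared = int(parts[2])
                vals = [int(v) for v in parts[3:]]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer count ({exc})") from None
            if declared != len(otu_ids):
                raise ParseError(
                    f"{path}:{lineno}: numOtus={declared} but header lists {len(otu_ids)} OTUs"
                )
            groups.append(group)
            rows.append(vals)
    counts = pd.DataFrame(rows, index=pd.Index(groups, name="sample_id"), columns=otu_ids)
    return CountTable(counts)


def write_shared(table: CountTable, path, label: str = "0.03") -> None:
    """Write the mothur ``.shared`` dialect (UTF-8, tab-delimited, LF)."""
    otus = list(table.otu_ids)
    buf = io.StringIO()
    buf.write("\t".join(["label", "Group", "numOtus"] + otus) + "\n")
    for sample, row in table.counts.iterrows():
        buf.write(
            "\t".join([label, str(sample), str(len(otus))] + [str(int(v)) for v in row])
            + "\n"
        )
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        fh.write(buf.getvalue())


def read_counts_tsv(path) -> CountTable:
    """Plain TSV count matrix; orientation auto-detected from the header.

    A header cell of ``sample_id`` (first column) means samples x OTUs as
    written; ``otu_id`` means OTUs x samples and the table is transposed.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.name == "otu_id":
        df = df.T
    df.index.name = "sample_id"
    return CountTable(df)


def write_counts_tsv(table: CountTable, path) -> None:
    out = table.counts.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", lineterminator="\n")


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype=str).set_index("sample_id")
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.table.to_csv(path, sep="\t", lineterminator="\n")


def read_taxonomy(path) -> pd.DataFrame:
    """Taxonomy TSV with columns ``otu_id`` and ``lineage`` (one row per OTU)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df["otu_id"].duplicated().any():
        raise ParseError("duplicate otu_id in taxonomy")
    return df.set_index("otu_id")


# ---------------------------------------------------------------------------
# filters


def filter_low_abundance(table: CountTable, frac: float = 1e-5) -> CountTable:
    """Drop OTUs whose dataset-wide relative abundance is below ``frac``.

    The threshold is strict (< frac, i.e. exactly 0.001% of the grand total is
    kept at the default) and the grand total is the pre-filter total.
    """
    grand = table.grand_total
    if grand <= 0:
        raise ValueError("grand total must be positive")
    rel = table.counts.sum(axis=0) / grand
    keep = rel >= frac
    if not keep.any():
        warnings.warn("all OTUs below abundance threshold; table is now empty")
    out = CountTable(table.counts.loc[:, keep], list(table.provenance))
    out.provenance.append({"filter": "low_abundance", "frac": frac, "dropped": int((~keep).sum())})
    return out


def remove_taxon(table: CountTable, taxonomy: pd.DataFrame, label: str = "Chloroplast") -> CountTable:
    """Drop OTUs whose lineage contains ``label`` at any rank (case-insensitive)."""
    lineages = taxonomy["lineage"].reindex(table.otu_ids).fillna("")
    hit = lineages.str.contains(label, case=False, regex=False)
    out = CountTable(table.counts.loc[:, ~hit.to_numpy()], list(table.provenance))
    out.provenance.append({"filter": "remove_taxon", "label": label, "dropped": int(hit.sum())})
    return out


def remove_seawater_like(
    table: CountTable,
    meta: SampleMetadata,
    frac: float = 1e-4,
    pooled: bool = True,
) -> CountTable:
    """Zero out seawater-derived OTUs in sponge samples.

    An OTU counts as seawater-like when its pooled relative abundance across
    all seawater samples exceeds ``frac`` (strict >). Counts are zeroed in
    sponge columns only -- seawater and sediment samples are untouched and the
    table keeps its shape, so cross-habitat comparisons stay aligned.
    ``pooled=False`` switches the criterion to the mean of per-sample
    proportions.
    """
    sw = [s for s in meta.habitat_samples("seawater") if s in table.sample_ids]
    if not sw:
        raise ValueError("no seawater samples in metadata/table")
    sw_counts = table.counts.loc[sw]
    if pooled:
        tot = sw_counts.to_numpy().sum()
        rel = sw_counts.sum(axis=0) / tot if tot else sw_counts.sum(axis=0) * 0.0
    else:
        props = sw_counts.div(sw_counts.sum(axis=1).replace(0, 1), axis=0)
        rel = props.mean(axis=0)
    seawater_like = rel > frac
    sponge = [s for s in meta.sponge_samples if s in table.sample_ids]
    counts = table.counts.copy()
    counts.loc[sponge, seawater_like[seawater_like].index] = 0
    out = CountTable(counts, list(table.provenance))
    out.provenance.append(
        {"filter": "seawater_like", "frac": frac, "pooled": pooled, "zeroed": int(seawater_like.sum())}
    )
    return out


def default_filter_chain(
    table: CountTable,
    meta: SampleMetadata,
    taxonomy: pd.DataFrame | None = None,
    low_abundance_frac: float = 1e-5,
    seawater_frac: float = 1e-4,
) -> CountTable:
    """Dataset-level cleaning in the canonical order.

    Low-abundance floor first, then chloroplast removal (when a taxonomy is
    supplied), then seawater-like zeroing; the order is recorded in the
    table's provenance.
    """
    out = filter_low_abundance(table, low_abundance_frac)
    if taxonomy is not None:
        out = remove_taxon(out, taxonomy)
    out = remove_seawater_like(out, meta, seawater_frac)
    return out


# ---------------------------------------------------------------------------
# aggregation


def aggregate_presence_by_species(table: CountTable, meta: SampleMetadata):
    """Collapse replicate samples to species-level presence and prevalence.

    Returns ``(presence, prevalence)`` DataFrames (species x OTU). Presence is
    a boolean: the OTU has a nonzero count in at least one replicate of the
    species. Prevalence is the fraction of the species' replicates containing
    the OTU.
    """
    host = meta.host_of().reindex(table.sample_ids)
    present = table.counts > 0
    grouped = present.groupby(host)
    prevalence = grouped.mean()
    presence = grouped.any()
    prevalence.index.name = presence.index.name = "host_species"
    return presence, prevalence
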