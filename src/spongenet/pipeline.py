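"""End-to-end orchestration: filters -> metrics -> network -> classification
-> cores -> interaction inference -> reports, with a hashed output manifest.

Stages never mutate their inputs on disk; every artifact is written under the
run's output directory and recorded (path + SHA-256 + stage) in
``manifest.json`` alongside a snapshot of the configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from spongenet import bipartite, community_metrics, core_lv, io_prep, synthetic

__all__ = ["RunConfig", "run_pipeline", "make_fixtures"]


@dataclass
class RunConfig:
    """Inputs, thresholds and seeds for one pipeline run."""

    shared_path: str
    metadata_path: str
    out_dir: str
    taxonomy_path: str | None = None
    low_abundance_frac: float = 1e-5
    seawater_frac: float = 1e-4
    network_min_samples: int = 25
    core_min_reps: int = 47
    core_prevalence: float = 0.85
    core_min_rel_abund: float = 0.01
    lv: core_lv.LVConfig = field(default_factory=core_lv.LVConfig)
    run_lv: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


class _Manifest:
    def __init__(self, out_dir: Path, cfg: RunConfig):
        self.out_dir = out_dir
        self.entries: list = []
        self.cfg = cfg

    def add(self, path: Path, stage: str) -> None:
        self.entries.append(
            {"path": str(path.relative_to(self.out_dir)), "stage": stage, "sha256": _sha256(path)}
        )
        self.write(partial=True)

    def write(self, partial: bool = False) -> Path:
        target = self.out_dir / "manifest.json"
        with open(target, "wt", encoding="utf-8") as fh:
            json.dump(
                {"config": self.cfg.to_dict(), "partial": partial, "artifacts": self.entries},
                fh,
                indent=2,
            )
        return target


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis flow; returns the manifest dict.

    Any stage failure re-raises with the stage name prepended; the partial
    manifest written so far is retained on disk.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out, cfg)
    stage = "read_inputs"
    try:
        table = io_prep.read_shared(cfg.shared_path)
        meta = io_prep.read_metadata(cfg.metadata_path)
        taxonomy = io_prep.read_taxonomy(cfg.taxonomy_path) if cfg.taxonomy_path else None

        stage = "filters"
        table = io_prep.default_filter_chain(
            table, meta, taxonomy, cfg.low_abundance_frac, cfg.seawater_frac
        )
        p = out / "filtered_counts.tsv"
        io_prep.write_counts_tsv(table, p)
        manifest.add(p, stage)

        stage = "metrics"
        div = community_metrics.diversity_table(table)
        p = out / "diversity.tsv"
        div.to_csv(p, sep="\t", lineterminator="\n")
        manifest.add(p, stage)
        bc = community_metrics.bray_curtis(table)
        p = out / "bray_curtis.tsv"
        community_metrics.write_distance_tsv(bc, p)
        manifest.add(p, stage)
        disp = community_metrics.dispersion_to_centroid(bc, meta.host_of())
        p = out / "dispersion.tsv"
        disp.to_frame().to_csv(p, sep="\t", lineterminator="\n")
        manifest.add(p, stage)

        stage = "network"
        net = bipartite.build_network(table, meta, cfg.network_min_samples)
        p = out / "network_edges.tsv"
        net.write_edgelist(p)
        manifest.add(p, stage)
        fits = {}
        for side, fitter, degrees in (
            ("otu", bipartite.fit_truncated_power_law, net.otu_degrees()),
            ("host", bipartite.fit_exponential, net.host_degrees()),
        ):
            try:
                fit = fitter(bipartite.ccdf(degrees))
                fits[side] = {"params": fit.params, "rss": fit.rss, "flags": fit.flags}
            except ValueError as err:  # too few distinct degrees on tiny studies
                fits[side] = {"params": None, "error": str(err)}
        p = out / "degree_fits.json"
        with open(p, "wt", encoding="utf-8") as fh:
            json.dump(fits, fh, indent=2)
        manifest.add(p, stage)

        stage = "classification"
        classes = bipartite.classify_otus(net, table, meta)
        p = out / "otu_classes.tsv"
        classes.to_csv(p, sep="\t", lineterminator="\n")
        manifest.add(p, stage)

        stage = "cores"
        per_host = core_lv.select_hosts(table, meta, cfg.core_min_reps, cfg.seed)
        cores = {}
        for species, sub in sorted(per_host.items()):
            try:
                cores[species] = core_lv.extract_core(
                    sub, species, cfg.core_prevalence, cfg.core_min_rel_abund
                )
            except ValueError:
                continue
        core_sizes = {sp: c.n_otus for sp, c in cores.items()}
        p = out / "core_sizes.json"
        with open(p, "wt", encoding="utf-8") as fh:
            json.dump(core_sizes, fh, indent=2)
        manifest.add(p, stage)
        if cores:
            agg = sorted({o for c in cores.values() for o in c.otu_ids})
            enrich = bipartite.core_degree_enrichment(net, [o for o in agg if o in set(net.otu_nodes)])
            p = out / "core_enrichment.tsv"
            enrich["curve"].to_csv(p, sep="\t", index=False, lineterminator="\n")
            manifest.add(p, stage)

        if cfg.run_lv and cores:
            stage = "core_lv"
            for species, core in sorted(cores.items()):
                # sampler preconditions: >=2 core OTUs and >=10 replicates
                if core.n_otus < 2 or len(core.sample_ids) < 10:
                    continue
                order = core_lv.order_replicates(core, cfg.lv.replicate_order, cfg.seed)
                post = core_lv.sample_posterior(core.counts, cfg.lv, sample_order=order)
                rep = core_lv.representative_network(post)
                safe = species.replace(" ", "_")
                p = out / f"lv_{safe}_posterior.json"
                post.to_json(p)
                manifest.add(p, stage)
                p = out / f"lv_{safe}_network.tsv"
                rep.write_edgelist(p)
                manifest.add(p, stage)
                p = out / f"lv_{safe}_variance_shares.tsv"
                try:
                    shares = core_lv.variance_decomposition(post)
                    shares.shares.to_csv(p, sep="\t", lineterminator="\n")
                except RuntimeError as err:
                    # posterior dynamics too unstable to linearize; keep a record
                    p.write_text(f"# variance decomposition unavailable: {err}\n")
                manifest.add(p, stage)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    path = manifest.write(partial=False)
    with open(path, "rt", encoding="utf-8") as fh:
        return json.load(fh)


def make_fixtures(out_dir, seed: int = 0) -> Path:
    """Write the small synthetic study used by the test suite.

    Six host species with eight replicates each plus seawater background,
    written as a mothur-dialect ``.shared`` file, metadata TSV, taxonomy TSV
    and ground-truth JSON; layout is stable across calls with the same seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = synthetic.CommunitySpec(
        n_hosts=6,
        n_otus=120,
        replicates_per_host=8,
        otu_degree_law=(0.32, 2.0),
        depth=3000,
        n_seawater_samples=4,
        n_seawater_otus=20,
        seed=seed,
    )
    table, meta, truth = synthetic.gen_bipartite_community(spec)
    io_prep.write_shared(table, out / "counts.shared")
    io_prep.write_metadata(meta, out / "metadata.tsv")
    lineages = []
    for i, otu in enumerate(table.otu_ids):
        lineage = "Bacteria;Proteobacteria;Gammaproteobacteria"
        if i % 17 == 3:
            lineage = "Bacteria;Cyanobacteria;Chloroplast"
        lineages.append({"otu_id": otu, "lineage": lineage})
    pd.DataFrame(lineages).to_csv(out / "taxonomy.tsv", sep="\t", index=False, lineterminator="\n")
    truth.to_csv(out / "truth.tsv", sep="\t", lineterminator="\n")
    with open(out / "spec.json", "wt", encoding="utf-8") as fh:
        json.dump({"seed": seed, "n_hosts": spec.n_hosts, "n_otus": spec.n_otus}, fh, indent=2)
    return out
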