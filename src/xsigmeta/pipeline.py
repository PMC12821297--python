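"""Config-driven orchestration of the full analysis.

``run_all`` executes: simulate (or ingest) -> DEG counting -> normalization
-> correlation clustering -> rank aggregation / recurrence -> gene-set
over-representation -> marker-set enrichment -> key-driver analysis, writing
each stage's TSV outputs plus a machine-readable JSON summary.  Identical
config + seed yields identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import clustering, enrichment, meta, msea, network_kda, normalization
from . import signature_io as sio
from . import synthetic
from .errors import ConfigurationError, PipelineError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Thresholds default to the pipeline's canonical values; any deviation
    is recorded in the run report."""

    out_dir: str = "xsigmeta_run"
    input_dir: str | None = None  # ingest signatures from here instead of simulating
    network_path: str | None = None
    gmt_path: str | None = None
    simulation: synthetic.SyntheticConfig = field(
        default_factory=synthetic.SyntheticConfig
    )
    fdr_deg: float = 0.05
    fdr_pathway: float = 0.05
    min_overlap: int = 5
    rra_threshold: float = 0.05
    consistency_threshold: float = 0.70
    presence_threshold: float = 0.70
    top_k: int = 2500
    msea_perm: int = 10_000
    wkda_perm: int = 1_000
    wkda_fdr: float = 0.05
    min_cluster_size: int = 3
    dominance: float = 0.9
    seed: int = 0

    DEFAULTS = {
        "fdr_deg": 0.05,
        "fdr_pathway": 0.05,
        "min_overlap": 5,
        "rra_threshold": 0.05,
        "consistency_threshold": 0.70,
        "presence_threshold": 0.70,
        "top_k": 2500,
        "msea_perm": 10_000,
        "wkda_fdr": 0.05,
    }

    def validate(self) -> None:
        for name in ("fdr_deg", "fdr_pathway", "rra_threshold", "wkda_fdr"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ConfigurationError(f"{name} must lie in (0, 1)")
        for name in ("consistency_threshold", "dominance"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if not (0.0 <= self.presence_threshold <= 1.0):
            raise ConfigurationError("presence_threshold must lie in [0, 1]")
        if self.top_k < 2 or self.min_overlap < 0:
            raise ConfigurationError("top_k must be >= 2 and min_overlap >= 0")

    def deviations(self) -> dict[str, tuple[float, float]]:
        return {
            name: (getattr(self, name), default)
            for name, default in self.DEFAULTS.items()
            if getattr(self, name) != default
        }


def config_from_dict(raw: dict) -> RunConfig:
    raw = dict(raw)
    sim_raw = raw.pop("simulation", {})
    sim = synthetic.SyntheticConfig(**sim_raw) if isinstance(sim_raw, dict) else sim_raw
    config = RunConfig(simulation=sim, **raw)
    config.validate()
    return config


def _stage(report: dict, name: str):
    class _StageContext:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                logger.error("stage %s: failed (%s)", name, exc)
                report["stages"][name] = {"status": "failed", "error": str(exc)}
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done", name)
            return False

    return _StageContext()


def run_all(config: RunConfig) -> dict:
    """Run every stage whose inputs are available; returns the run report."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "thresholds_deviating_from_defaults": {
        k: {"value": v, "default": d} for k, (v, d) in config.deviations().items()
    }}

    # --- inputs -----------------------------------------------------------
    truth = None
    with _stage(report, "input"):
        if config.input_dir is not None:
            collection = sio.read_collection(config.input_dir)
            report["stages"]["input"] = {
                "status": "ok", "mode": "ingest", "n_datasets": len(collection)
            }
        else:
            sim = config.simulation
            sim.seed = config.seed
            collection, truth = synthetic.generate_collection(sim)
            sio.write_collection(collection, out / "signatures")
            report["stages"]["input"] = {
                "status": "ok", "mode": "simulate", "n_datasets": len(collection),
                "n_genes": sim.n_genes,
            }

    # --- per-dataset DEG counts ------------------------------------------
    with _stage(report, "deg_counts"):
        rows = []
        for did in collection.dataset_ids:
            n_up, n_down = sio.count_significant(
                collection.tables[did], fdr_threshold=config.fdr_deg
            )
            rows.append({"dataset_id": did, "n_up": n_up, "n_down": n_down})
        counts = pd.DataFrame(rows)
        counts.to_csv(out / "deg_counts.tsv", sep="\t", index=False)
        chem = collection.metadata.set_index("dataset_id")["chemical"]
        groups = {
            c: (counts.set_index("dataset_id").loc[ids, ["n_up", "n_down"]].sum(axis=1))
            for c, ids in chem.groupby(chem).groups.items()
        }
        ks = None
        if len(groups) == 2:
            (name_a, a), (name_b, b) = sorted(groups.items())
            d_stat, p = meta.ks_compare(list(a), list(b))
            ks = {"groups": [name_a, name_b], "D": d_stat, "p": p}
        report["stages"]["deg_counts"] = {
            "status": "ok", "n_rows": len(counts), "ks_by_chemical": ks
        }

    # --- normalization ----------------------------------------------------
    with _stage(report, "normalize"):
        matrix = normalization.build_matrix(
            collection,
            presence_threshold=config.presence_threshold,
            top_k=config.top_k,
        )
        matrix = normalization.impute(matrix, method="median")
        normalization.write_matrix(matrix, out / "normalized_matrix.tsv")
        report["stages"]["normalize"] = {
            "status": "ok", "n_genes": int(matrix.shape[0]),
            "n_datasets": int(matrix.shape[1]),
        }

    # --- clustering -------------------------------------------------------
    with _stage(report, "cluster"):
        corr = clustering.spearman_matrix(matrix)
        corr.to_csv(out / "correlation_matrix.tsv", sep="\t", index_label="dataset_id")
        clusters = clustering.call_clusters(
            corr, min_size=config.min_cluster_size, dominance=config.dominance
        )
        clustering.clusters_to_frame(clusters).to_csv(
            out / "clusters.tsv", sep="\t", index=False
        )
        report["stages"]["cluster"] = {
            "status": "ok",
            "clusters": {c.label: sorted(c.members) for c in clusters},
        }

    # --- rank aggregation / consistency ----------------------------------
    with _stage(report, "rra"):
        overall = meta.run_rra(
            collection, mode="any_direction", score_threshold=config.rra_threshold
        )
        meta.rra_to_frame(overall).to_csv(out / "rra_overall.tsv", sep="\t", index=False)
        robust_genes = sorted({r.gene for r in overall if r.robust})
        per_cluster = {}
        for cluster in clusters:
            members = {d: collection.tables[d] for d in cluster.members}
            res = meta.run_rra(
                members, mode="per_direction", score_threshold=config.rra_threshold
            )
            meta.rra_to_frame(res).to_csv(
                out / f"rra_{cluster.label}.tsv", sep="\t", index=False
            )
            per_cluster[cluster.label] = {
                "up": sum(1 for r in res if r.robust and r.direction == "up"),
                "down": sum(1 for r in res if r.robust and r.direction == "down"),
            }
        records = meta.recurrence(
            collection,
            fdr_threshold=config.fdr_deg,
            consistency_threshold=config.consistency_threshold,
        )
        meta.consistency_to_frame(records).to_csv(
            out / "consistency.tsv", sep="\t", index=False
        )
        report["stages"]["rra"] = {
            "status": "ok",
            "n_meta_degs": len(robust_genes),
            "per_cluster_robust": per_cluster,
            "n_consistent_genes": sum(1 for r in records if r.consistent),
        }

    # --- over-representation ---------------------------------------------
    with _stage(report, "enrich"):
        if config.gmt_path is not None:
            library = enrichment.read_gmt(config.gmt_path)
        elif truth is not None:
            genes = synthetic._gene_names(config.simulation.n_genes)
            library = synthetic.generate_gene_sets(
                genes, n_sets=50, set_size=50, enriched_fraction=0.1,
                truth=truth, seed=config.seed + 1,
            )
            enrichment.write_gmt(library, out / "genesets.gmt")
        else:
            library = None
        if library is None:
            report["stages"]["enrich"] = {"status": "skipped", "reason": "no GMT"}
        else:
            per_dataset: dict[tuple[str, str], list[enrichment.ORAResult]] = {}
            for did in collection.dataset_ids:
                table = collection.tables[did]
                universe = list(table.genes)
                for direction in ("up", "down"):
                    degs = sio.significant_genes(
                        table, fdr_threshold=config.fdr_deg, direction=direction
                    )
                    per_dataset[(did, direction)] = enrichment.enrich_library(
                        degs, library, universe=universe,
                        fdr_threshold=config.fdr_pathway,
                        min_overlap=config.min_overlap,
                    )
            recur = enrichment.pathway_recurrence(per_dataset)
            recur.to_csv(out / "pathway_recurrence.tsv", sep="\t", index=False)
            meta_ora = enrichment.enrich_library(
                robust_genes, library,
                fdr_threshold=config.fdr_pathway, min_overlap=config.min_overlap,
            )
            enrichment.ora_to_frame(meta_ora).to_csv(
                out / "ora_meta_degs.tsv", sep="\t", index=False
            )
            report["stages"]["enrich"] = {
                "status": "ok",
                "n_recurrent_sets": int(recur["set_name"].nunique()) if len(recur) else 0,
                "meta_deg_significant_sets": sorted(
                    r.name for r in meta_ora if r.tier == "significant"
                ),
            }

    # --- marker-set enrichment -------------------------------------------
    with _stage(report, "msea"):
        if truth is None:
            report["stages"]["msea"] = {"status": "skipped", "reason": "no marker data"}
        else:
            genes = synthetic._gene_names(config.simulation.n_genes)
            # plant marker associations around the recovered meta-DEGs so the
            # downstream enrichment is recoverable at desk scale
            trait_genes = sorted(robust_genes)[:200] or sorted(truth.consistent_genes)
            truth.trait_gene_set = trait_genes
            markers, gene_models = synthetic.generate_marker_data(
                genes,
                genome_length=300_000_000,
                trait_gene_set=trait_genes,
                effect=3.0,
                n_markers=20_000,
                seed=config.seed + 2,
            )
            markers.to_csv(out / "markers.tsv", sep="\t", index=False)
            gene_models.to_csv(out / "gene_models.tsv", sep="\t", index=False)
            gene_scores = msea.map_markers(markers, gene_models)
            deg_for_msea = [g for g in robust_genes if g in gene_scores.index]
            if len(deg_for_msea) < 5:
                report["stages"]["msea"] = {
                    "status": "skipped", "reason": "too few scored meta-DEGs"
                }
            else:
                results = msea.msea_test(
                    {"meta_degs": deg_for_msea},
                    {"planted_trait": gene_scores},
                    n_perm=config.msea_perm,
                    seed=config.seed + 3,
                )
                msea.msea_to_frame(results).to_csv(
                    out / "msea.tsv", sep="\t", index=False
                )
                report["stages"]["msea"] = {
                    "status": "ok",
                    "results": [
                        {"deg_set": r.deg_set, "trait": r.trait,
                         "z": round(r.z, 6), "fdr": round(r.fdr, 6),
                         "significant": r.significant}
                        for r in results
                    ],
                }

    # --- key-driver analysis ---------------------------------------------
    with _stage(report, "wkda"):
        graph = None
        if config.network_path is not None:
            graph = network_kda.read_network(config.network_path)
        elif truth is not None and robust_genes:
            genes = synthetic._gene_names(config.simulation.n_genes)
            hubs = [(g, 20, 0.8) for g in genes if g not in set(robust_genes)][:2]
            truth.key_drivers = [h for h, _, _ in hubs]
            graph = synthetic.generate_network(
                genes, n_edges=4 * config.simulation.n_genes,
                planted_hubs=hubs, deg_set=robust_genes, seed=config.seed + 4,
            )
            network_kda.write_network(graph, out / "network.tsv")
        if graph is None:
            report["stages"]["wkda"] = {"status": "skipped", "reason": "no network"}
        else:
            kd = network_kda.run_wkda(
                graph, {"meta_degs": robust_genes},
                n_perm=config.wkda_perm, seed=config.seed + 5,
                fdr_threshold=config.wkda_fdr,
            )
            network_kda.kda_to_frame(kd).to_csv(out / "wkda.tsv", sep="\t", index=False)
            top_by_z = [r.node for r in sorted(kd, key=lambda r: -r.z)[:5]]
            report["stages"]["wkda"] = {
                "status": "ok",
                "n_candidates": len(kd),
                "significant_kds": sorted(r.node for r in kd if r.significant),
                "top_kds_by_z": top_by_z,
                "planted_hubs_in_top": sorted(
                    set(truth.key_drivers) & set(top_by_z)
                ) if truth is not None else [],
            }

    if truth is not None:
        report["truth"] = {
            "cluster_assignment": truth.cluster_assignment,
            "consistent_genes": truth.consistent_genes,
            "enriched_sets": truth.enriched_sets,
            "key_drivers": truth.key_drivers,
        }
    report["config"] = {
        k: v for k, v in asdict(config).items() if k != "simulation"
    }
    report["config"]["simulation"] = asdict(config.simulation)
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
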