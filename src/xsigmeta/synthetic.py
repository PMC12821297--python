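"""Synthetic signature collections with planted, recoverable structure.

Every downstream stage is testable without any external download: the
generators plant dataset clusters (shared latent fold-change templates),
globally consistent genes, enriched gene sets, network hub genes, and
marker associations around trait genes, and return the ground truth next to
the generated artifacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .enrichment import GeneSetLibrary
from .errors import ConfigurationError
from .network_kda import validate_edge
from .signature_io import SignatureCollection, SignatureTable


@dataclass
class SyntheticConfig:
    """Parameters of a synthetic signature collection.

    ``cluster_spec`` lists (label, member count, signal scale); a negative
    scale plants a cluster anti-correlated with a positive-scale cluster
    sharing the same template sign convention.  ``noise_sd`` is the
    per-replicate expression noise; the sampling noise on a dataset's log2FC
    estimate is ``noise_sd / sqrt(group_size)`` so that null p-values from
    the z-model are uniform.
    """

    n_datasets: int = 24
    n_genes: int = 2000
    cluster_spec: list[tuple[str, int, float]] = field(
        default_factory=lambda: [("A", 8, 1.0), ("B", 8, 1.0)]
    )
    n_template_genes: int = 400
    noise_sd: float = 0.5
    missing_rate_by_platform: dict[str, float] = field(
        default_factory=lambda: {"rnaseq": 0.0, "microarray": 0.15}
    )
    n_consistent_genes: int = 20
    consistent_effect: float = 2.0
    group_size: int = 4
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_datasets, self.n_genes, self.group_size) <= 0:
            raise ConfigurationError("all counts must be positive")
        if self.n_template_genes <= 0 or self.n_template_genes > self.n_genes:
            raise ConfigurationError("n_template_genes must be in 1..n_genes")
        if self.n_consistent_genes < 0 or self.n_consistent_genes > self.n_genes:
            raise ConfigurationError("n_consistent_genes must be in 0..n_genes")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        for platform, rate in self.missing_rate_by_platform.items():
            if not (0.0 <= rate < 1.0):
                raise ConfigurationError(
                    f"missing rate for {platform!r} must be in [0, 1)"
                )
        labels = [label for label, _, _ in self.cluster_spec]
        if len(labels) != len(set(labels)):
            raise ConfigurationError("duplicate cluster label")
        n_members = sum(n for _, n, _ in self.cluster_spec)
        if n_members > self.n_datasets:
            raise ConfigurationError(
                f"cluster members ({n_members}) exceed n_datasets ({self.n_datasets})"
            )


@dataclass
class SyntheticTruth:
    """Planted structure of a generated collection."""

    cluster_assignment: dict[str, str | None]
    consistent_genes: dict[str, str]  # gene -> "up" | "down"
    enriched_sets: list[str] = field(default_factory=list)
    key_drivers: list[str] = field(default_factory=list)
    trait_gene_set: list[str] = field(default_factory=list)


def _gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def _dataset_ids(n: int) -> list[str]:
    return [f"DS{i:03d}" for i in range(n)]


def generate_collection(
    config: SyntheticConfig,
) -> tuple[SignatureCollection, SyntheticTruth]:
    """Simulate per-dataset DE summary tables with planted structure.

    For dataset d in cluster c: ``log2fc(g, d) = scale_c * T_c(g) + eps``
    with the template T_c nonzero on a random subset of genes.  Planted
    consistent genes receive an additive directional effect in >= 90% of
    datasets.  p-values follow the Gaussian z-model
    ``p = 2 * Phi(-|log2fc| * sqrt(group_size) / noise_sd)`` and FDR is BH
    within each dataset.  Identical seeds give identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _gene_names(config.n_genes)
    datasets = _dataset_ids(config.n_datasets)

    # dataset -> cluster label (remainder unclustered noise datasets)
    assignment: dict[str, str | None] = {d: None for d in datasets}
    scales: dict[str, float] = {}
    cursor = 0
    templates: dict[str, np.ndarray] = {}
    for label, n_members, scale in config.cluster_spec:
        template = np.zeros(config.n_genes)
        support = rng.choice(config.n_genes, size=config.n_template_genes, replace=False)
        template[support] = rng.normal(0.0, 1.0, size=config.n_template_genes)
        templates[label] = template
        for d in datasets[cursor : cursor + n_members]:
            assignment[d] = label
            scales[d] = float(scale)
        cursor += n_members

    # planted consistent genes: fixed direction, effect in >=90% of datasets
    consistent_idx = rng.choice(
        config.n_genes, size=config.n_consistent_genes, replace=False
    )
    directions = rng.choice([1.0, -1.0], size=config.n_consistent_genes)
    n_carriers = math.ceil(0.9 * config.n_datasets)
    carrier_sets = [
        rng.choice(config.n_datasets, size=n_carriers, replace=False)
        for _ in range(config.n_consistent_genes)
    ]

    # sampling noise on the fold-change estimate (SE of group_size replicates)
    estimate_sd = config.noise_sd / math.sqrt(config.group_size)
    fc = rng.normal(0.0, estimate_sd, size=(config.n_genes, config.n_datasets))
    for j, d in enumerate(datasets):
        label = assignment[d]
        if label is not None:
            fc[:, j] += scales[d] * templates[label]
    for gi, direction, carriers in zip(consistent_idx, directions, carrier_sets):
        fc[gi, carriers] += direction * config.consistent_effect

    zscale = math.sqrt(config.group_size) / config.noise_sd
    pvals = 2.0 * stats.norm.sf(np.abs(fc) * zscale)

    platforms = ["rnaseq", "microarray"]
    chemicals = ["THC", "CBD"]
    tissues = ["brain", "liver", "blood"]
    tables: dict[str, SignatureTable] = {}
    meta_rows = []
    for j, d in enumerate(datasets):
        platform = platforms[j % len(platforms)]
        rate = config.missing_rate_by_platform.get(platform, 0.0)
        n_missing = int(round(rate * config.n_genes))
        present = np.ones(config.n_genes, dtype=bool)
        if n_missing:
            present[rng.choice(config.n_genes, size=n_missing, replace=False)] = False
        p = pvals[present, j]
        fdr = multipletests(p, method="fdr_bh")[1]
        df = pd.DataFrame(
            {
                "gene": np.asarray(genes, dtype=object)[present],
                "log2fc": fc[present, j],
                "pvalue": p,
                "fdr": fdr,
            }
        )
        tables[d] = SignatureTable(dataset_id=d, data=df)
        meta_rows.append(
            {
                "dataset_id": d,
                "study_accession": f"SIM{j // 4:03d}",
                "chemical": chemicals[j % 2],
                "species": "human",
                "tissue": tissues[j % len(tissues)],
                "platform": platform,
                "exposure": "in_vivo" if j % 2 == 0 else "in_vitro",
                "route": "injection",
                "sex": "mixed",
                "dose": "10mg/kg",
                "duration": "24h",
                "n_treatment": config.group_size,
                "n_control": config.group_size,
            }
        )
    collection = SignatureCollection(metadata=pd.DataFrame(meta_rows), tables=tables)
    truth = SyntheticTruth(
        cluster_assignment=assignment,
        consistent_genes={
            genes[gi]: ("up" if direction > 0 else "down")
            for gi, direction in zip(consistent_idx, directions)
        },
    )
    return collection, truth


def generate_gene_sets(
    genes,
    n_sets: int,
    set_size: int,
    enriched_fraction: float,
    truth: SyntheticTruth,
    seed: int = 0,
    planted_fraction: float = 0.8,
) -> GeneSetLibrary:
    """Random gene sets; a fraction are enriched for planted consistent
    genes (recorded into ``truth.enriched_sets``)."""
    genes = list(genes)
    if set_size > len(genes):
        raise ConfigurationError("set_size exceeds number of genes")
    rng = np.random.default_rng(seed)
    planted = [g for g in truth.consistent_genes if g in set(genes)]
    n_enriched = int(round(n_sets * enriched_fraction))
    sets: dict[str, list[str]] = {}
    truth.enriched_sets = []
    gene_arr = np.asarray(genes, dtype=object)
    for i in range(n_sets):
        name = f"SET_{i:04d}"
        if i < n_enriched and planted:
            n_from_planted = min(int(round(planted_fraction * set_size)), len(planted))
            chosen = list(
                rng.choice(np.asarray(planted, dtype=object), size=n_from_planted, replace=False)
            )
            remainder = [g for g in genes if g not in set(chosen)]
            chosen += list(
                rng.choice(
                    np.asarray(remainder, dtype=object),
                    size=set_size - n_from_planted,
                    replace=False,
                )
            )
            truth.enriched_sets.append(name)
        else:
            chosen = list(rng.choice(gene_arr, size=set_size, replace=False))
        sets[name] = [str(g) for g in chosen]
    return GeneSetLibrary(sets=sets)


def generate_network(
    genes,
    n_edges: int,
    planted_hubs: list[tuple[str, int, float]],
    deg_set,
    seed: int = 0,
) -> nx.Graph:
    """Uniform background edges (weight 1) plus planted hubs whose
    neighborhoods contain a controlled fraction of DEG-set members."""
    genes = list(genes)
    deg = [g for g in deg_set if g in set(genes)]
    hub_names = [h for h, _, _ in planted_hubs]
    if len(hub_names) != len(set(hub_names)):
        raise ConfigurationError("duplicate planted hub")
    for hub, size, frac in planted_hubs:
        if size > len(genes) - 1:
            raise ConfigurationError(f"hub {hub!r}: neighborhood exceeds n_genes - 1")
        if not (0.0 <= frac <= 1.0):
            raise ConfigurationError(f"hub {hub!r}: deg_fraction outside [0, 1]")
    rng = np.random.default_rng(seed)
    graph = nx.Graph()
    graph.add_nodes_from(genes)
    n = len(genes)
    seen: set[tuple[int, int]] = set()
    while len(seen) < n_edges:
        i, j = rng.integers(0, n, size=2)
        if i == j:
            continue
        key = (min(i, j), max(i, j))
        if key in seen:
            continue
        seen.add(key)
        graph.add_edge(genes[key[0]], genes[key[1]], weight=1.0)
    deg_lookup = set(deg)
    for hub, size, frac in planted_hubs:
        n_deg = int(round(frac * size))
        deg_pool = [g for g in deg if g != hub]
        bg_pool = [g for g in genes if g not in deg_lookup and g != hub]
        if n_deg > len(deg_pool) or size - n_deg > len(bg_pool):
            raise ConfigurationError(f"hub {hub!r}: not enough genes for neighborhood")
        chosen = list(
            rng.choice(np.asarray(deg_pool, dtype=object), size=n_deg, replace=False)
        ) + list(
            rng.choice(np.asarray(bg_pool, dtype=object), size=size - n_deg, replace=False)
        )
        for neighbor in chosen:
            if not graph.has_edge(hub, str(neighbor)):
                validate_edge(graph, hub, str(neighbor), 1.0)
                graph.add_edge(hub, str(neighbor), weight=1.0)
    return graph


def generate_marker_data(
    genes,
    genome_length: int,
    window_layout: tuple[int, int] = (10_000, 120_000),
    trait_gene_set=(),
    effect: float = 0.0,
    n_markers: int = 5_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic chromosome with non-overlapping gene intervals and uniform
    markers.

    ``window_layout`` is (gene length, inter-gene gap); markers within 50 kb
    of a trait gene draw their -log10 p score from the null distribution
    shifted by ``effect``, all others from the null (p ~ U(0,1)).
    Returns (marker table, gene model table).
    """
    genes = list(genes)
    gene_length, gap = window_layout
    span = gene_length + gap
    if span * len(genes) > genome_length:
        raise ConfigurationError(
            "genome_length too small for non-overlapping gene layout"
        )
    rng = np.random.default_rng(seed)
    starts = np.arange(len(genes), dtype=np.int64) * span
    gene_models = pd.DataFrame(
        {
            "gene": genes,
            "chrom": "chr1",
            "start": starts,
            "end": starts + gene_length,
        }
    )[["chrom", "start", "end", "gene"]]
    pos = np.sort(rng.integers(0, genome_length, size=n_markers))
    scores = -np.log10(rng.uniform(size=n_markers))  # null: p ~ U(0,1)
    trait = set(trait_gene_set)
    if trait and effect != 0.0:
        near_trait = np.zeros(n_markers, dtype=bool)
        for row in gene_models.itertuples(index=False):
            if row.gene not in trait:
                continue
            lo = np.searchsorted(pos, row.start - 50_000, side="left")
            hi = np.searchsorted(pos, row.end + 50_000, side="left")
            near_trait[lo:hi] = True
        scores[near_trait] += effect
    markers = pd.DataFrame(
        {
            "marker_id": [f"M{i:06d}" for i in range(n_markers)],
            "chrom": "chr1",
            "pos": pos,
            "score": scores,
        }
    )
    return markers, gene_models
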