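"""Fisher-exact over-representation of DEG lists against gene-set libraries.

Pathway mode applies the joint FDR < threshold / minimum-overlap filter;
the targeted-panel mode labels each dataset's test significant (p < 0.05),
suggestive (p < 0.10) or not significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError


@dataclass
class GeneSetLibrary:
    """Named gene sets plus an optional explicit universe."""

    sets: dict[str, list[str]]
    universe: list[str] | None = None

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValidationError(f"gene set {name!r} has duplicate genes")


@dataclass
class ORAResult:
    name: str
    overlap: int
    set_size: int
    list_size: int
    universe_size: int
    pvalue: float
    fdr: float = float("nan")
    tier: str = "ns"
    overlap_genes: list[str] = field(default_factory=list)


def read_gmt(path) -> GeneSetLibrary:
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(f"GMT line with fewer than 3 fields: {line!r}")
            name, genes = fields[0], [g for g in fields[2:] if g]
            sets[name] = genes
    return GeneSetLibrary(sets=sets)


def write_gmt(library: GeneSetLibrary, path, description: str = "na") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in library.sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def hypergeom_tail(overlap: int, n_universe: int, n_set: int, n_list: int) -> float:
    """One-sided enrichment tail P(X >= overlap), X hypergeometric.

    ``p = sum_{k >= overlap} C(K, k) C(N-K, n-k) / C(N, n)`` with N the
    universe size, K the set size and n the list size.
    """
    if overlap <= 0:
        return 1.0  # P(X >= 0) for the one-sided >= tail
    return float(stats.hypergeom.sf(overlap - 1, n_universe, n_set, n_list))


def fisher_ora(deg_list, gene_set, universe, name: str = "") -> ORAResult:
    """One-sided hypergeometric (enrichment) tail p for one list vs one set."""
    universe = set(universe)
    if not universe:
        raise ValidationError("fisher_ora: empty universe")
    deg = set(deg_list) & universe
    members = set(gene_set) & universe
    overlap_genes = sorted(deg & members)
    n_universe, n_set, n_list = len(universe), len(members), len(deg)
    overlap = len(overlap_genes)
    p = hypergeom_tail(overlap, n_universe, n_set, n_list)
    return ORAResult(
        name=name,
        overlap=overlap,
        set_size=n_set,
        list_size=n_list,
        universe_size=n_universe,
        pvalue=min(1.0, p),
        overlap_genes=overlap_genes,
    )


def enrich_library(
    deg_list,
    library: GeneSetLibrary,
    universe=None,
    fdr_threshold: float = 0.05,
    min_overlap: int = 5,
) -> list[ORAResult]:
    """Test a DEG list against every set in a library with BH adjustment.

    Significance requires both ``fdr < fdr_threshold`` and at least
    ``min_overlap`` overlapping genes.  The default universe is the library's
    explicit universe, else the union of all set genes and the DEG list
    (callers should pass the dataset's measured genes when available).
    """
    if universe is None:
        if library.universe is not None:
            universe = library.universe
        else:
            universe = set(deg_list)
            for genes in library.sets.values():
                universe |= set(genes)
    results = [
        fisher_ora(deg_list, genes, universe, name=name)
        for name, genes in library.sets.items()
    ]
    if results:
        fdrs = multipletests([r.pvalue for r in results], method="fdr_bh")[1]
        for r, fdr in zip(results, fdrs):
            r.fdr = float(fdr)
            r.tier = (
                "significant"
                if (r.fdr < fdr_threshold and r.overlap >= min_overlap)
                else "ns"
            )
    return sorted(results, key=lambda r: (r.pvalue, r.name))


def ecs_tiers(
    per_dataset_results: dict[str, ORAResult],
    tissue_class: dict[str, str] | None = None,
    significant_p: float = 0.05,
    suggestive_p: float = 0.10,
) -> pd.DataFrame:
    """Tier each dataset's targeted-panel test by raw p-value."""
    rows = []
    for dataset, result in per_dataset_results.items():
        p = result.pvalue
        if p < significant_p:
            tier = "significant"
        elif p < suggestive_p:
            tier = "suggestive"
        else:
            tier = "ns"
        rows.append(
            {
                "dataset_id": dataset,
                "pvalue": p,
                "overlap": result.overlap,
                "tier": tier,
                "tissue_class": (tissue_class or {}).get(dataset, "unknown"),
            }
        )
    return pd.DataFrame(
        rows, columns=["dataset_id", "pvalue", "overlap", "tier", "tissue_class"]
    )


def tier_summary(tiers: pd.DataFrame) -> pd.DataFrame:
    """Counts of datasets per (tissue_class, tier)."""
    return (
        tiers.groupby(["tissue_class", "tier"])
        .size()
        .rename("n_datasets")
        .reset_index()
    )


def pathway_recurrence(
    per_dataset_enrichments: dict[tuple[str, str], list[ORAResult]],
) -> pd.DataFrame:
    """Count datasets where each set passed the significance filter, by
    DEG direction.  Keys are (dataset_id, direction); sets never significant
    are absent."""
    counts: dict[tuple[str, str], int] = {}
    for (_dataset, direction), results in per_dataset_enrichments.items():
        for r in results:
            if r.tier == "significant":
                key = (r.name, direction)
                counts[key] = counts.get(key, 0) + 1
    rows = [
        {"set_name": name, "direction": direction, "n_datasets": n}
        for (name, direction), n in counts.items()
    ]
    frame = pd.DataFrame(rows, columns=["set_name", "direction", "n_datasets"])
    if len(frame):
        totals = frame.groupby("set_name")["n_datasets"].transform("sum")
        frame = (
            frame.assign(_total=totals)
            .sort_values(["_total", "set_name", "direction"], ascending=[False, True, True], kind="mergesort")
            .drop(columns="_total")
            .reset_index(drop=True)
        )
    return frame


def ora_to_frame(results: list[ORAResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set_name": r.name,
                "overlap": r.overlap,
                "set_size": r.set_size,
                "list_size": r.list_size,
                "universe_size": r.universe_size,
                "pvalue": r.pvalue,
                "fdr": r.fdr,
                "tier": r.tier,
            }
            for r in results
        ],
        columns=[
            "set_name",
            "overlap",
            "set_size",
            "list_size",
            "universe_size",
            "pvalue",
            "fdr",
            "tier",
        ],
    )
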