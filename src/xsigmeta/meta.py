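"""Cross-dataset gene consistency.

Rank aggregation is implemented from its order-statistic definition: for a
gene with sorted normalized ranks r(1) <= ... <= r(k) out of ``n_lists``
lists, rho is the minimum over j of P(Beta(j, n_lists - j + 1) <= r(j)) --
equivalently the binomial tail P(X >= j), X ~ Binomial(n_lists, r(j)).  The
reported score is rho Bonferroni-multiplied by the number of lists the gene
was observed in, capped at 1; scores below the threshold (default 0.05)
flag robust, consistently ranked genes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import PipelineError, ValidationError
from .signature_io import SignatureCollection, SignatureTable


@dataclass
class RRAResult:
    gene: str
    rho: float
    score: float
    direction: str  # up | down | any
    n_lists: int
    robust: bool


@dataclass
class ConsistencyRecord:
    gene: str
    n_up: int
    n_down: int
    total: int
    consistency: float
    consistent: bool


def rra_rho(normalized_ranks, n_lists: int) -> float:
    """Minimum beta order-statistic probability of the observed ranks."""
    r = np.asarray(list(normalized_ranks), dtype=float)
    if r.size == 0:
        return 1.0
    if np.any((r <= 0.0) | (r > 1.0)):
        raise ValidationError("normalized ranks must lie in (0, 1]")
    if r.size > n_lists:
        raise ValidationError("more ranks than lists")
    r = np.sort(r)
    j = np.arange(1, r.size + 1, dtype=float)
    probs = stats.beta.cdf(r, j, n_lists - j + 1)
    return float(probs.min())


def rra_score(rho: float, n_lists: int) -> float:
    """Bonferroni correction by the effective list length, capped at 1."""
    return min(1.0, rho * n_lists)


def _rank_matrix(
    tables: dict[str, SignatureTable], mode: str, direction: str
) -> pd.DataFrame:
    """Genes x datasets normalized ranks in (0, 1]; NaN where unobserved."""
    cols = []
    for did, table in tables.items():
        df = table.data
        if mode == "per_direction":
            ascending = direction == "down"
            ranks = df["log2fc"].rank(ascending=ascending, method="average")
        else:
            ranks = df["pvalue"].rank(ascending=True, method="average")
        cols.append(
            pd.Series(
                ranks.to_numpy(dtype=float) / len(df),
                index=pd.Index(df["gene"]),
                name=did,
            )
        )
    return pd.concat(cols, axis=1)


def aggregate_ranks(rank_matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-gene rho and Bonferroni score from a normalized-rank matrix.

    Genes missing from a dataset contribute no rank there; the effective
    list length is the per-gene count of observed ranks.
    """
    genes, rhos, scores, n_obs = [], [], [], []
    values = rank_matrix.to_numpy(dtype=float)
    for i, gene in enumerate(rank_matrix.index):
        row = values[i]
        observed = row[~np.isnan(row)]
        k = observed.size
        if k == 0:
            continue
        rho = rra_rho(observed, n_lists=k)
        genes.append(gene)
        rhos.append(rho)
        scores.append(rra_score(rho, k))
        n_obs.append(k)
    return pd.DataFrame(
        {"gene": genes, "rho": rhos, "score": scores, "n_lists": n_obs}
    )


def run_rra(
    collection_or_tables,
    mode: str = "per_direction",
    score_threshold: float = 0.05,
) -> list[RRAResult]:
    """Rank aggregation across datasets.

    ``per_direction`` aggregates two lists per dataset: genes ordered by
    log2fc descending (up) and ascending (down).  ``any_direction`` orders by
    p-value ascending, direction-agnostic.
    """
    if isinstance(collection_or_tables, SignatureCollection):
        tables = collection_or_tables.tables
    else:
        tables = dict(collection_or_tables)
    if len(tables) < 2:
        raise PipelineError("run_rra requires at least 2 datasets")
    if mode not in {"per_direction", "any_direction"}:
        raise ValueError(f"unknown mode {mode!r}")
    directions = ["up", "down"] if mode == "per_direction" else ["any"]
    results: list[RRAResult] = []
    for direction in directions:
        agg = aggregate_ranks(_rank_matrix(tables, mode, direction))
        for row in agg.itertuples(index=False):
            results.append(
                RRAResult(
                    gene=str(row.gene),
                    rho=float(row.rho),
                    score=float(row.score),
                    direction=direction,
                    n_lists=int(row.n_lists),
                    robust=bool(row.score < score_threshold),
                )
            )
    results.sort(key=lambda r: (r.direction, r.score, r.gene))
    return results


def recurrence(
    collection: SignatureCollection,
    fdr_threshold: float = 0.05,
    consistency_threshold: float = 0.70,
) -> list[ConsistencyRecord]:
    """Directional recurrence of significant DEGs across datasets.

    Direction agreement is not enforced when counting; the consistency
    fraction max(n_up, n_down) / total is evaluated afterwards against the
    threshold (strict >).
    """
    up_counts: dict[str, int] = {}
    down_counts: dict[str, int] = {}
    for table in collection.tables.values():
        sig = table.data["fdr"].to_numpy(dtype=float) < fdr_threshold
        fc = table.data["log2fc"].to_numpy(dtype=float)
        for gene in table.data.loc[sig & (fc > 0), "gene"]:
            up_counts[gene] = up_counts.get(gene, 0) + 1
        for gene in table.data.loc[sig & (fc < 0), "gene"]:
            down_counts[gene] = down_counts.get(gene, 0) + 1
    records = []
    for gene in set(up_counts) | set(down_counts):
        n_up = up_counts.get(gene, 0)
        n_down = down_counts.get(gene, 0)
        total = n_up + n_down
        consistency = max(n_up, n_down) / total
        records.append(
            ConsistencyRecord(
                gene=str(gene),
                n_up=n_up,
                n_down=n_down,
                total=total,
                consistency=consistency,
                consistent=bool(consistency > consistency_threshold),
            )
        )
    records.sort(key=lambda r: (-r.total, r.gene))
    return records


def classify_consistency(
    n_up: int, n_down: int, consistency_threshold: float = 0.70
) -> bool:
    """Directional-consistency rule for a single gene's recurrence counts."""
    total = n_up + n_down
    if total == 0:
        return False
    return max(n_up, n_down) / total > consistency_threshold


def ks_compare(counts_a, counts_b) -> tuple[float, float]:
    """Two-sample KS test of DEG-count distributions.

    Exact p by full enumeration of label arrangements when n_a + n_b <= 12,
    asymptotic otherwise.
    """
    a = np.asarray(list(counts_a), dtype=float)
    b = np.asarray(list(counts_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("ks_compare: empty sample")
    d_obs = _ks_statistic(a, b)
    n = a.size + b.size
    if n <= 12:
        pooled = np.concatenate([a, b])
        total = 0
        hits = 0
        for idx in itertools.combinations(range(n), a.size):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
            d = _ks_statistic(pooled[mask], pooled[~mask])
            total += 1
            if d >= d_obs - 1e-12:
                hits += 1
        p = hits / total
    else:
        p = float(stats.ks_2samp(a, b, method="asymp").pvalue)
    return float(d_obs), float(p)


def _ks_statistic(a: np.ndarray, b: np.ndarray) -> float:
    grid = np.concatenate([a, b])
    cdf_a = np.searchsorted(np.sort(a), grid, side="right") / a.size
    cdf_b = np.searchsorted(np.sort(b), grid, side="right") / b.size
    return float(np.abs(cdf_a - cdf_b).max())


def rra_to_frame(results: list[RRAResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "rho": r.rho,
                "score": r.score,
                "direction": r.direction,
                "n_lists": r.n_lists,
                "robust": r.robust,
            }
            for r in results
        ],
        columns=["gene", "rho", "score", "direction", "n_lists", "robust"],
    )


def consistency_to_frame(records: list[ConsistencyRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "n_up": r.n_up,
                "n_down": r.n_down,
                "total": r.total,
                "consistency": r.consistency,
                "consistent": r.consistent,
            }
            for r in records
        ],
        columns=["gene", "n_up", "n_down", "total", "consistency", "consistent"],
    )
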