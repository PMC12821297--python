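"""Marker-set enrichment: map genomic markers to genes within a distance
window, score gene sets with a quantile-threshold chi-square-like statistic,
and calibrate against size-matched permuted gene sets.

A marker maps to a gene when it falls in [start - window, end + window) on
the same chromosome (default window 50 kb); a gene's association score is
the maximum score over its assigned markers.  For thresholds t_j at the
requested quantiles of the score distribution the statistic is
``sum_j (O_j - E_j) / sqrt(E_j + kappa)`` where O_j counts set genes with
score >= t_j and E_j is the expectation under uniform membership.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import PipelineError, ValidationError

DEFAULT_WINDOW = 50_000
DEFAULT_QUANTILES = tuple(np.round(np.arange(0.1, 1.0, 0.1), 10))


@dataclass
class MSEAResult:
    deg_set: str
    trait: str
    chi: float
    z: float
    pvalue: float
    fdr: float = float("nan")
    significant: bool = False


def validate_marker_table(markers: pd.DataFrame) -> None:
    required = ("marker_id", "chrom", "pos", "score")
    missing = [c for c in required if c not in markers.columns]
    if missing:
        raise ValidationError(f"marker table: missing column(s) {missing}")
    if (markers["pos"] < 0).any():
        raise ValidationError("marker table: negative position")
    if (markers["score"] < 0).any():
        raise ValidationError("marker table: negative score")


def validate_gene_models(genes: pd.DataFrame) -> None:
    required = ("gene", "chrom", "start", "end")
    missing = [c for c in required if c not in genes.columns]
    if missing:
        raise ValidationError(f"gene model table: missing column(s) {missing}")
    if (genes["start"] >= genes["end"]).any():
        raise ValidationError("gene model table: start must be < end (0-based half-open)")


def map_markers(
    markers: pd.DataFrame, genes: pd.DataFrame, window: int = DEFAULT_WINDOW
) -> pd.Series:
    """Gene -> max assigned marker score; unassigned genes are absent.

    Assignment rule: same chromosome and ``start - window <= pos < end + window``
    (inclusive on the extended start, half-open on the extended end).
    """
    if window < 0:
        raise ValidationError("window must be >= 0")
    validate_marker_table(markers)
    validate_gene_models(genes)
    scores: dict[str, float] = {}
    for chrom, chrom_markers in markers.groupby("chrom"):
        chrom_genes = genes[genes["chrom"] == chrom]
        if not len(chrom_genes):
            continue
        order = np.argsort(chrom_markers["pos"].to_numpy())
        pos = chrom_markers["pos"].to_numpy()[order]
        sc = chrom_markers["score"].to_numpy(dtype=float)[order]
        for row in chrom_genes.itertuples(index=False):
            lo = np.searchsorted(pos, row.start - window, side="left")
            hi = np.searchsorted(pos, row.end + window, side="left")
            if hi > lo:
                scores[str(row.gene)] = float(sc[lo:hi].max())
    return pd.Series(scores, dtype=float).sort_index()


def msea_statistic(
    deg_set,
    gene_scores: pd.Series,
    quantiles=DEFAULT_QUANTILES,
    kappa: float = 1.0,
) -> float:
    """Quantile-threshold enrichment statistic for one gene set."""
    deg = list(deg_set)
    if not deg:
        raise ValidationError("msea_statistic: empty deg_set")
    missing = set(deg) - set(gene_scores.index)
    if missing:
        raise ValidationError(
            f"msea_statistic: deg_set not a subset of the scored universe "
            f"(e.g. {sorted(missing)[:5]})"
        )
    scores = gene_scores.to_numpy(dtype=float)
    thresholds = np.quantile(scores, np.asarray(quantiles, dtype=float))
    member = gene_scores.index.isin(set(deg))
    set_scores = scores[member]
    chi = 0.0
    m = len(deg)
    for t in thresholds:
        observed = float(np.sum(set_scores >= t))
        expected = m * float(np.mean(scores >= t))
        chi += (observed - expected) / np.sqrt(expected + kappa)
    return float(chi)


def _permuted_chis(
    indicator: np.ndarray,
    set_size: int,
    n_perm: int,
    rng: np.random.Generator,
    kappa: float,
    chunk: int = 250,
) -> np.ndarray:
    """Statistics for size-matched uniform draws from the scored universe."""
    n_genes, n_thresh = indicator.shape
    col_frac = indicator.mean(axis=0)
    expected = set_size * col_frac
    denom = np.sqrt(expected + kappa)
    chis = np.empty(n_perm, dtype=float)
    done = 0
    ind_f = indicator.astype(np.float64)
    while done < n_perm:
        take = min(chunk, n_perm - done)
        keys = rng.random((take, n_genes))
        idx = np.argpartition(keys, set_size - 1, axis=1)[:, :set_size]
        observed = ind_f[idx].sum(axis=1)  # (take, n_thresh)
        chis[done : done + take] = ((observed - expected) / denom).sum(axis=1)
        done += take
    return chis


def msea_test(
    deg_sets: dict[str, list],
    gene_scores,
    n_perm: int = 10_000,
    seed: int | None = None,
    quantiles=DEFAULT_QUANTILES,
    kappa: float = 1.0,
    fdr_threshold: float = 0.05,
) -> list[MSEAResult]:
    """Permutation-calibrated enrichment of each DEG set for each trait.

    ``gene_scores`` is either one pd.Series (single trait, labeled "trait")
    or a dict trait -> Series.  z is computed against size-matched uniform
    permuted sets, the one-sided p from the Gaussian tail, and BH adjustment
    runs across all (set, trait) pairs.
    """
    if n_perm < 100:
        raise ValidationError("msea_test: n_perm must be >= 100")
    if isinstance(gene_scores, pd.Series):
        gene_scores = {"trait": gene_scores}
    rng = np.random.default_rng(seed)
    results: list[MSEAResult] = []
    for trait, scores in gene_scores.items():
        values = scores.to_numpy(dtype=float)
        thresholds = np.quantile(values, np.asarray(quantiles, dtype=float))
        indicator = values[:, None] >= thresholds[None, :]
        for label, deg in deg_sets.items():
            chi_obs = msea_statistic(deg, scores, quantiles=quantiles, kappa=kappa)
            chi_perm = _permuted_chis(indicator, len(list(deg)), n_perm, rng, kappa)
            sd = float(chi_perm.std(ddof=1))
            if sd == 0.0:
                raise PipelineError(
                    f"msea_test: degenerate permutation distribution for "
                    f"({label}, {trait}); scores carry no variation"
                )
            z = (chi_obs - float(chi_perm.mean())) / sd
            results.append(
                MSEAResult(
                    deg_set=label,
                    trait=trait,
                    chi=chi_obs,
                    z=float(z),
                    pvalue=float(stats.norm.sf(z)),
                )
            )
    if results:
        fdrs = multipletests([r.pvalue for r in results], method="fdr_bh")[1]
        for r, fdr in zip(results, fdrs):
            r.fdr = float(fdr)
            r.significant = bool(r.fdr < fdr_threshold)
    return results


def msea_to_frame(results: list[MSEAResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "deg_set": r.deg_set,
                "trait": r.trait,
                "chi": r.chi,
                "z": r.z,
                "pvalue": r.pvalue,
                "fdr": r.fdr,
                "significant": r.significant,
            }
            for r in results
        ],
        columns=["deg_set", "trait", "chi", "z", "pvalue", "fdr", "significant"],
    )
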