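"""Rank-based normalization of log2 fold changes onto [-1, 1].

Within each dataset, positive log2FCs are ranked ascending and scaled into
(0, 1] (largest fold change -> 1); negative log2FCs are ranked from the one
closest to zero downwards and scaled into [-1, 0) (most negative -> -1);
zeros map to 0.  The transform depends on ranks only, so it is invariant to
any strictly monotone sign-preserving rescaling, making signatures
comparable across platforms whose fold changes live on different scales.
"""

from __future__ import annotations

import pandas as pd

from .errors import PipelineError, ValidationError
from .signature_io import SignatureCollection, SignatureTable


def rank_normalize(table: SignatureTable) -> pd.Series:
    """Map one signature's log2fc to rank-normalized scores in [-1, 1]."""
    fc = pd.Series(
        table.data["log2fc"].to_numpy(dtype=float),
        index=pd.Index(table.data["gene"]),
        name=table.dataset_id,
    )
    out = pd.Series(0.0, index=fc.index, name=table.dataset_id)
    pos = fc[fc > 0]
    if len(pos):
        # ascending ranks, ties share the mean rank; max rank / n -> 1
        out[pos.index] = pos.rank(method="average") / len(pos)
    neg = fc[fc < 0]
    if len(neg):
        # rank 1 = negative closest to zero ("descending"); most negative -> -1
        out[neg.index] = -neg.rank(method="average", ascending=False) / len(neg)
    return out


def build_matrix(
    collection: SignatureCollection,
    presence_threshold: float | None = 0.70,
    top_k: int = 2500,
) -> pd.DataFrame:
    """Genes x datasets matrix of rank-normalized fold changes.

    Genes non-missing in at least ``presence_threshold`` of the datasets are
    retained (pass ``None`` to skip presence filtering, e.g. for a
    single-chemical analysis), then the ``top_k`` most variable genes by
    variance of the normalized values (missing cells excluded) are kept.
    """
    if len(collection) < 2:
        raise PipelineError("build_matrix requires at least 2 datasets")
    columns = [rank_normalize(collection.tables[d]) for d in collection.dataset_ids]
    matrix = pd.concat(columns, axis=1)
    matrix = matrix.sort_index(kind="mergesort")
    if presence_threshold is not None:
        presence = matrix.notna().sum(axis=1) / matrix.shape[1]
        matrix = matrix.loc[presence >= presence_threshold]
    variances = matrix.var(axis=1, ddof=1, skipna=True)
    keep = variances.sort_values(ascending=False, kind="mergesort").index[:top_k]
    matrix = matrix.loc[matrix.index.isin(set(keep))]
    if matrix.shape[0] < 2:
        raise PipelineError(
            f"build_matrix: only {matrix.shape[0]} gene(s) retained after filtering"
        )
    return matrix


def impute(matrix: pd.DataFrame, method: str = "median", k: int = 5) -> pd.DataFrame:
    """Fill missing cells; never touches observed cells.

    ``median``: gene-wise median of observed values.  ``knn``: weighted mean
    over the ``k`` most-correlated datasets (Spearman, positive correlations
    as weights) that observed the gene, falling back to the gene median when
    no positively correlated dataset observed it.
    """
    all_missing = matrix.index[matrix.isna().all(axis=1)]
    if len(all_missing):
        raise ValidationError(
            f"impute: gene(s) entirely missing: {list(all_missing[:5])}"
        )
    if not matrix.isna().any().any():
        return matrix.copy()
    if method == "median":
        medians = matrix.median(axis=1, skipna=True)
        out = matrix.T.fillna(medians).T
    elif method == "knn":
        out = matrix.copy()
        corr = matrix.rank(axis=0).corr(min_periods=3)
        medians = matrix.median(axis=1, skipna=True)
        for col in matrix.columns:
            missing_genes = matrix.index[matrix[col].isna()]
            if not len(missing_genes):
                continue
            weights = corr[col].drop(index=col).clip(lower=0.0)
            for gene in missing_genes:
                observed = matrix.loc[gene].dropna()
                w = weights.reindex(observed.index).fillna(0.0)
                w = w.sort_values(ascending=False, kind="mergesort").iloc[:k]
                w = w[w > 0]
                if len(w):
                    value = float((observed[w.index] * w).sum() / w.sum())
                else:
                    value = float(medians[gene])
                out.loc[gene, col] = max(-1.0, min(1.0, value))
    else:
        raise ValueError(f"unknown imputation method {method!r}")
    return out


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene", na_rep="")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")
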