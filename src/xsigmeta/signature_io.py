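"""Data model and I/O for per-dataset differential-expression signatures.

A *signature* is one dataset's gene-level DE summary: gene identifier,
log2 fold change, p-value and BH-adjusted FDR.  Collections bundle many
signatures with a study-metadata table.  Ortholog harmonization maps all
gene identifiers onto human symbols so signatures are comparable across
species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

SIGNATURE_COLUMNS = ("gene", "log2fc", "pvalue", "fdr")

METADATA_COLUMNS = (
    "dataset_id",
    "study_accession",
    "chemical",
    "species",
    "tissue",
    "platform",
    "exposure",
    "route",
    "sex",
    "dose",
    "duration",
    "n_treatment",
    "n_control",
)

PLATFORMS = frozenset({"rnaseq", "microarray"})
EXPOSURES = frozenset({"in_vivo", "in_vitro"})
SEXES = frozenset({"male", "female", "mixed", "unknown"})


@dataclass
class SignatureTable:
    """One dataset's DE summary: columns gene, log2fc, pvalue, fdr."""

    dataset_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = self.data.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        missing = [c for c in SIGNATURE_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(
                f"signature {self.dataset_id!r}: missing column(s) {missing}"
            )
        genes = self.data["gene"]
        dup = genes[genes.duplicated()]
        if len(dup):
            raise ValidationError(
                f"signature {self.dataset_id!r}: duplicated gene(s) "
                f"{sorted(set(dup))[:5]}"
            )
        fc = self.data["log2fc"].to_numpy(dtype=float)
        if not np.all(np.isfinite(fc)):
            bad = self.data.loc[~np.isfinite(fc), "gene"].tolist()[:5]
            raise ValidationError(
                f"signature {self.dataset_id!r}: non-finite log2fc for {bad}"
            )
        for col in ("pvalue", "fdr"):
            vals = self.data[col].to_numpy(dtype=float)
            bad_mask = ~((vals >= 0.0) & (vals <= 1.0))
            if bad_mask.any():
                bad = self.data.loc[bad_mask, "gene"].tolist()[:5]
                raise ValidationError(
                    f"signature {self.dataset_id!r}: {col} outside [0,1] for {bad}"
                )

    @property
    def genes(self) -> pd.Index:
        return pd.Index(self.data["gene"])

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class SignatureCollection:
    """Metadata table plus one SignatureTable per dataset."""

    metadata: pd.DataFrame
    tables: dict[str, SignatureTable] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        missing = [c for c in METADATA_COLUMNS if c not in self.metadata.columns]
        if missing:
            raise FormatError(f"metadata: missing column(s) {missing}")
        ids = self.metadata["dataset_id"]
        if ids.duplicated().any():
            raise ValidationError("metadata: duplicated dataset_id")
        meta_ids = set(ids)
        table_ids = set(self.tables)
        if meta_ids != table_ids:
            raise ValidationError(
                f"collection: metadata/table dataset_id mismatch "
                f"(only in metadata: {sorted(meta_ids - table_ids)[:5]}, "
                f"only in tables: {sorted(table_ids - meta_ids)[:5]})"
            )
        bad_platform = set(self.metadata["platform"]) - PLATFORMS
        if bad_platform:
            raise ValidationError(f"metadata: unknown platform(s) {sorted(bad_platform)}")
        bad_exposure = set(self.metadata["exposure"]) - EXPOSURES
        if bad_exposure:
            raise ValidationError(f"metadata: unknown exposure(s) {sorted(bad_exposure)}")

    @property
    def dataset_ids(self) -> list[str]:
        return list(self.metadata["dataset_id"])

    def species_of(self, dataset_id: str) -> str:
        row = self.metadata.loc[self.metadata["dataset_id"] == dataset_id]
        return str(row["species"].iloc[0])

    def __len__(self) -> int:
        return len(self.tables)


@dataclass
class OrthologMap:
    """Mapping (source_gene, source_species) -> human gene symbol."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = ("source_gene", "source_species", "human_gene")
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise FormatError(f"ortholog map: missing column(s) {missing}")
        if (self.data["human_gene"].astype(str).str.len() == 0).any():
            raise ValidationError("ortholog map: empty human_gene target")
        self._lookup = {
            (str(g), str(s)): str(h)
            for g, s, h in zip(
                self.data["source_gene"],
                self.data["source_species"],
                self.data["human_gene"],
            )
        }
        self._human_targets = frozenset(self.data["human_gene"].astype(str))

    def get(self, gene: str, species: str) -> str | None:
        return self._lookup.get((gene, species))

    @property
    def human_targets(self) -> frozenset[str]:
        return self._human_targets


# ---------------------------------------------------------------------------
# Readers / writers (TSV dialect: tab-separated, header, UTF-8, '.' decimal)
# ---------------------------------------------------------------------------

def read_signature(path, dataset_id: str | None = None) -> SignatureTable:
    """Read a signature TSV; malformed rows raise with row indices."""
    try:
        raw = pd.read_csv(path, sep="\t", dtype={"gene": str})
    except Exception as exc:  # noqa: BLE001 - wrap parser errors uniformly
        raise FormatError(f"{path}: cannot parse TSV ({exc})") from exc
    missing = [c for c in SIGNATURE_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    for col in ("log2fc", "pvalue", "fdr"):
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad = coerced.isna() & raw[col].notna()
        if bad.any():
            rows = list(raw.index[bad][:5])
            raise FormatError(
                f"{path}: non-numeric {col} at row(s) {rows} "
                f"(value {raw.loc[rows[0], col]!r})"
            )
        raw[col] = coerced
    if raw[["log2fc", "pvalue", "fdr"]].isna().any().any():
        rows = list(raw.index[raw[["log2fc", "pvalue", "fdr"]].isna().any(axis=1)][:5])
        raise FormatError(f"{path}: missing numeric value at row(s) {rows}")
    if dataset_id is None:
        import os

        dataset_id = os.path.splitext(os.path.basename(str(path)))[0]
    return SignatureTable(dataset_id=dataset_id, data=raw[list(SIGNATURE_COLUMNS)])


def write_signature(table: SignatureTable, path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"dataset_id": str})
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"{path}: metadata missing column(s) {missing}")
    return meta


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def read_ortholog_map(path) -> OrthologMap:
    return OrthologMap(pd.read_csv(path, sep="\t", dtype=str))


def read_collection(directory) -> SignatureCollection:
    """Read ``metadata.tsv`` plus one ``<dataset_id>.tsv`` per dataset."""
    from pathlib import Path

    directory = Path(directory)
    metadata = read_metadata(directory / "metadata.tsv")
    tables = {
        did: read_signature(directory / f"{did}.tsv", dataset_id=did)
        for did in metadata["dataset_id"]
    }
    return SignatureCollection(metadata=metadata, tables=tables)


def write_collection(collection: SignatureCollection, directory) -> None:
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_metadata(collection.metadata, directory / "metadata.tsv")
    for did, table in collection.tables.items():
        write_signature(table, directory / f"{did}.tsv")


# ---------------------------------------------------------------------------
# Harmonization and DEG counting
# ---------------------------------------------------------------------------

def _collapse_duplicates(df: pd.DataFrame) -> pd.DataFrame:
    # many-to-one ortholog collapse: min pvalue, then max |log2fc|, then
    # lexicographically smallest original gene
    df = df.assign(_absfc=df["log2fc"].abs())
    df = df.sort_values(
        ["pvalue", "_absfc", "_source"], ascending=[True, False, True], kind="mergesort"
    )
    df = df.drop_duplicates("gene", keep="first").drop(columns=["_absfc", "_source"])
    return df.sort_index(kind="mergesort").reset_index(drop=True)


def harmonize(
    collection: SignatureCollection,
    ortholog_map: OrthologMap,
    human_species: str = "human",
) -> SignatureCollection:
    """Map every gene identifier to a human symbol.

    Genes without a mapping are dropped (logged, not an error).  Genes that
    are already valid human targets pass through unchanged, which makes the
    operation idempotent.  When several source genes collapse onto one human
    gene the row with the smallest p-value wins (tie: largest \\|log2fc\\|,
    then lexicographic source gene).
    """
    new_tables: dict[str, SignatureTable] = {}
    for did, table in collection.tables.items():
        species = collection.species_of(did)
        if species == human_species:
            new_tables[did] = table
            continue
        df = table.data.copy()
        mapped = [
            ortholog_map.get(g, species)
            or (g if g in ortholog_map.human_targets else None)
            for g in df["gene"]
        ]
        df["_source"] = df["gene"]
        df["gene"] = mapped
        n_dropped = sum(m is None for m in mapped)
        if n_dropped:
            logger.warning(
                "harmonize: dropped %d unmapped gene(s) from %s", n_dropped, did
            )
        df = df[df["gene"].notna()]
        df = _collapse_duplicates(df)
        new_tables[did] = SignatureTable(dataset_id=did, data=df)
    return SignatureCollection(metadata=collection.metadata.copy(), tables=new_tables)


def count_significant(
    table: SignatureTable, fdr_threshold: float = 0.05
) -> tuple[int, int]:
    """(n_up, n_down) at ``fdr < fdr_threshold``; log2fc == 0 counts in neither."""
    sig = table.data["fdr"].to_numpy(dtype=float) < fdr_threshold
    fc = table.data["log2fc"].to_numpy(dtype=float)
    return int(np.sum(sig & (fc > 0))), int(np.sum(sig & (fc < 0)))


def significant_genes(
    table: SignatureTable, fdr_threshold: float = 0.05, direction: str = "any"
) -> list[str]:
    """Genes significant at the FDR threshold, optionally by direction."""
    sig = table.data["fdr"].to_numpy(dtype=float) < fdr_threshold
    fc = table.data["log2fc"].to_numpy(dtype=float)
    if direction == "up":
        mask = sig & (fc > 0)
    elif direction == "down":
        mask = sig & (fc < 0)
    elif direction == "any":
        mask = sig & (fc != 0)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return list(table.data.loc[mask, "gene"])
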