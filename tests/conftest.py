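import numpy as np
import pandas as pd
import pytest

from xsigmeta.signature_io import SignatureCollection, SignatureTable


def make_table(dataset_id, genes, log2fc, pvalue=None, fdr=None):
    n = len(genes)
    if pvalue is None:
        pvalue = [0.5] * n
    if fdr is None:
        fdr = pvalue
    return SignatureTable(
        dataset_id=dataset_id,
        data=pd.DataFrame(
            {"gene": genes, "log2fc": log2fc, "pvalue": pvalue, "fdr": fdr}
        ),
    )


def make_metadata(dataset_ids, species="human", chemical="THC"):
    return pd.DataFrame(
        [
            {
                "dataset_id": did,
                "study_accession": "SIM000",
                "chemical": chemical,
                "species": species,
                "tissue": "brain",
                "platform": "rnaseq",
                "exposure": "in_vivo",
                "route": "injection",
                "sex": "mixed",
                "dose": "10mg/kg",
                "duration": "24h",
                "n_treatment": 4,
                "n_control": 4,
            }
            for did in dataset_ids
        ]
    )


def make_collection(tables, species="human"):
    return SignatureCollection(
        metadata=make_metadata([t.dataset_id for t in tables], species=species),
        tables={t.dataset_id: t for t in tables},
    )


@pytest.fixture
def four_gene_table():
    return make_table("ds1", ["g1", "g2", "g3", "g4"], [2.0, 1.0, -0.5, -3.0])


@pytest.fixture
def rng():
    return np.random.default_rng(0)
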