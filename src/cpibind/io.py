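"""Readers/writers for the plain-text formats the pipeline exchanges.

Count matrices travel as MatrixMarket (.mtx) with features/barcodes TSV
sidecars (the 10x convention); metadata, coordinates, truth tables and
results as CSV; configs as YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import io as sio
from scipy import sparse


def write_counts_mtx(outdir, counts, feature_names, barcodes, prefix: str = ""):
    """Write a cells x features count matrix as MTX + TSV sidecars.

    The matrix is stored features x cells (genes-in-rows convention).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    m = sparse.csr_matrix(np.asarray(counts).T)
    sio.mmwrite(str(outdir / f"{prefix}matrix.mtx"), m)
    pd.Series(list(feature_names)).to_csv(
        outdir / f"{prefix}features.tsv", sep="\t", index=False, header=False
    )
    pd.Series(list(barcodes)).to_csv(
        outdir / f"{prefix}barcodes.tsv", sep="\t", index=False, header=False
    )


def read_counts_mtx(indir, prefix: str = "") -> pd.DataFrame:
    """Read an MTX + sidecars directory back into a cells x features frame."""
    indir = Path(indir)
    m = sio.mmread(str(indir / f"{prefix}matrix.mtx")).tocsr().T
    features = pd.read_csv(indir / f"{prefix}features.tsv", sep="\t",
                           header=None)[0].tolist()
    barcodes = pd.read_csv(indir / f"{prefix}barcodes.tsv", sep="\t",
                           header=None)[0].tolist()
    return pd.DataFrame(m.toarray(), index=barcodes, columns=features)


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_yaml(obj: dict, path):
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)


def dump_json(obj: dict, path):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=float)
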