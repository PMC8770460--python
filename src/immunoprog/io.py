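"""Tabular I/O and run manifests.

All tables are UTF-8 TSV with a header row; missing values are empty
fields. Every CLI stage writes a manifest (config echo, seed, SHA-256 of
each input file) next to its output so a pipeline run is reproducible from
the manifests alone.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .simulate import ANNOTATION_COLUMNS


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_annotation(annotation: pd.DataFrame, path) -> None:
    out = annotation.reset_index()
    cols = [c for c in ANNOTATION_COLUMNS if c in out.columns]
    out[cols].to_csv(path, sep="\t", index=False)


def read_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t")
    for col in ("event", "lymphovascular_invasion", "adjuvant_chemotherapy"):
        if col in ann:
            ann[col] = ann[col].astype(bool)
    return ann.set_index("sample_id")


def read_matrix_tsv(path) -> pd.DataFrame:
    """Samples x probes normalized matrix (sample_id index)."""
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, stage: str, seed: int | None, params: dict,
                   inputs: list[str | Path]) -> None:
    manifest = {
        "stage": stage,
        "seed": seed,
        "params": {k: _jsonable(v) for k, v in params.items()},
        "inputs": {str(p): file_sha256(p) for p in inputs if Path(p).exists()},
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _jsonable(v):
    try:
        json.dumps(v)
        return v
    except TypeError:
        return str(v)
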