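"""Readers and writers for the package's plain-text formats.

Beta and detection-p matrices are TSV with probes as rows (first column
``probe_id``) and samples as columns; manifests are CSV; labels are a
two-column CSV (sample_id, label); signatures and truth sets are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .dmc import DMCEpisignature
from .dmr import DMREpisignature

__all__ = [
    "read_beta_tsv", "write_beta_tsv",
    "read_manifest_csv", "write_manifest_csv",
    "read_labels_csv", "write_labels_csv",
    "read_signature_json", "write_signature_json",
]


def read_beta_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="probe_id")


def write_beta_tsv(betas: pd.DataFrame, path: str | Path) -> None:
    betas.rename_axis("probe_id").to_csv(path, sep="\t")


def read_manifest_csv(path: str | Path) -> pd.DataFrame:
    man = pd.read_csv(path, index_col="probe_id")
    for flag in ("snp_overlap", "cross_reactive", "sex_chrom"):
        man[flag] = man[flag].astype(bool)
    return man


def write_manifest_csv(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest.rename_axis("probe_id").to_csv(path)


def read_labels_csv(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, index_col="sample_id")
    return df["label"]


def write_labels_csv(labels: pd.Series, path: str | Path) -> None:
    labels.rename("label").rename_axis("sample_id").to_csv(path)


def write_signature_json(signature, path: str | Path) -> None:
    Path(path).write_text(signature.to_json())


def read_signature_json(path: str | Path):
    text = Path(path).read_text()
    paradigm = json.loads(text).get("paradigm")
    if paradigm == "dmc":
        return DMCEpisignature.from_json(text)
    if paradigm == "dmr":
        return DMREpisignature.from_json(text)
    raise ValueError(f"unrecognized signature paradigm {paradigm!r} in {path}")
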