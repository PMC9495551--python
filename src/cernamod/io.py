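"""Readers, writers and configuration shared by every pipeline stage.

All tabular formats are tab-separated UTF-8 without quoting (gene symbols
never contain tabs); identifiers are opaque strings. Expression matrices are
features x samples with the feature id in the first column; sample metadata
carries ``sample_id``, ``condition`` (``tumor``/``normal``) and ``pair_id``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

logger = logging.getLogger("cernamod")

CONDITIONS = ("tumor", "normal")


class FormatError(ValueError):
    """A file violates the expected schema."""


@dataclass
class PipelineConfig:
    """All thresholds and settings of the module-discovery pipeline.

    Defaults are the operating point of the published workflow this package
    implements: fold-change gate ``|log2FC| > 1`` with BH FDR < 0.05, fifty
    rounds of 4/5 pair subsampling for mRNA/lncRNA, STRING-style confidence
    > 700 with co-expression p < 0.05 for interaction edges, joint selection
    at MCC > 8 and mean-|SHAP| > 1e-4, and the 70/30 split protocol.
    """

    # differential expression
    de_log2fc: float = 1.0
    de_fdr: float = 0.05
    stability_rounds: int = 50
    stability_fraction: float = 0.8
    # interaction network
    confidence: float = 700.0
    corr_p: float = 0.05
    # candidate / potential selection
    shap_threshold: float = 1e-4
    mcc_threshold: float = 8.0
    # classifier
    hidden_sizes: tuple = (400, 100)
    cerna_hidden_sizes: tuple = (400, 100, 40)
    use_regularization: bool = True
    batch_size: int = 16
    epochs: int = 200          # desk-scale default; the reference protocol uses >= 1000
    learning_rate: float = 1e-4
    split_fraction: float = 0.7
    n_repeats: int = 50
    background_size: int = 100
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        for key in ("hidden_sizes", "cerna_hidden_sizes"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["hidden_sizes"] = list(self.hidden_sizes)
        d["cerna_hidden_sizes"] = list(self.cerna_hidden_sizes)
        return d


def read_expression(path, samples: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read a feature x sample expression TSV.

    Raises :class:`FormatError` on duplicate feature ids, and on sample
    mismatch when a metadata frame is supplied.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise FormatError(f"{path}: duplicated feature id {dup[0]!r}")
    if df.columns.duplicated().any():
        raise FormatError(f"{path}: duplicated sample columns")
    if samples is not None:
        expected = list(samples["sample_id"].astype(str))
        if sorted(df.columns) != sorted(expected):
            raise FormatError(
                f"{path}: sample columns do not match metadata "
                f"({len(df.columns)} vs {len(expected)} samples)"
            )
        df = df[expected]
    return df


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="feature_id")


def read_samples(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "condition", "pair_id"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing metadata columns {sorted(missing)}")
    bad = set(df["condition"]) - set(CONDITIONS)
    if bad:
        raise FormatError(f"{path}: unknown condition values {sorted(bad)}")
    if df["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicated sample ids")
    return df


def write_samples(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_targets(path) -> pd.DataFrame:
    """Read a two-column miRNA -> target table; duplicates collapse to one row."""
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
        if header and len(header.rstrip("\n").split("\t")) != 2:
            raise FormatError(f"{path}: line 1: expected 2 tab-separated columns")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise FormatError(
                    f"{path}: line {lineno}: expected 2 tab-separated columns, "
                    f"got {len(parts)}"
                )
            rows.append(parts)
    df = pd.DataFrame(rows, columns=["mirna_id", "target_id"], dtype=str)
    if df.empty:
        logger.warning("%s: empty target table", path)
    n_raw = len(df)
    df = df.drop_duplicates(ignore_index=True)
    if len(df) < n_raw:
        logger.info("%s: collapsed %d duplicate target rows", path, n_raw - len(df))
    return df


def write_targets(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_edge_list(path) -> pd.DataFrame:
    """Read an interaction edge list (node_a, node_b, confidence[, r, p])."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"node_a": str, "node_b": str})
    except pd.errors.ParserError as exc:  # pandas reports the offending line
        raise FormatError(f"{path}: malformed edge list: {exc}") from exc
    required = {"node_a", "node_b", "confidence"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing edge columns {sorted(missing)}")
    return df


def write_edge_list(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_json(obj, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        stream=None,  # stderr
    )
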