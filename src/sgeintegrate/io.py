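"""Tab-separated readers/writers for the pipeline's tables.

All tables are plain TSV with a header row. Missing numeric annotations
(BayesDel, FAF) are empty fields; the ``spliceai_flag`` column holds
``True``/``False``; ``preassigned_codes`` is a semicolon-separated list of
``CODE:strength`` tokens.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .simulate import SCORE_COLUMNS, TRUTH_COLUMNS, VARIANT_COLUMNS

CALL_COLUMNS = ["variant_id", "pp", "bf", "category", "model_tag"]


def _require(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def read_variants(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "exon": str})
    _require(df, VARIANT_COLUMNS, path)
    df["spliceai_flag"] = df["spliceai_flag"].astype(bool)
    df["preassigned_codes"] = df["preassigned_codes"].fillna("")
    for col in ("clinvar_standard", "hdr_standard"):
        df[col] = df[col].fillna("none")
    if df["variant_id"].duplicated().any():
        dup = df.loc[df["variant_id"].duplicated(), "variant_id"].iloc[0]
        raise ValueError(f"{path}: duplicate variant_id {dup!r}")
    return df


def read_scores(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"exon": str, "assay": str})
    _require(df, SCORE_COLUMNS, path)
    if df.duplicated(["variant_id", "assay", "replicate"]).any():
        raise ValueError(f"{path}: duplicate (variant_id, assay, replicate) rows")
    return df


def read_truth(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require(df, TRUTH_COLUMNS, path)
    return df


def read_calls(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require(df, CALL_COLUMNS, path)
    return df


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_screen(dir_path, variants, scores, truth) -> dict[str, str]:
    """Write the three screen tables; returns the paths written."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    paths = {
        "variants": dir_path / "variants.tsv",
        "scores": dir_path / "scores.tsv",
        "truth": dir_path / "truth.tsv",
    }
    _write_tsv(variants.reindex(columns=VARIANT_COLUMNS), paths["variants"])
    _write_tsv(scores.reindex(columns=SCORE_COLUMNS), paths["scores"])
    _write_tsv(truth.reindex(columns=TRUTH_COLUMNS), paths["truth"])
    return {k: str(v) for k, v in paths.items()}


def read_screen(dir_path) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    dir_path = Path(dir_path)
    return (
        read_variants(dir_path / "variants.tsv"),
        read_scores(dir_path / "scores.tsv"),
        read_truth(dir_path / "truth.tsv"),
    )


def write_calls(calls: pd.DataFrame, path) -> None:
    _write_tsv(calls.reindex(columns=CALL_COLUMNS), Path(path))


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=float) + "\n")
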