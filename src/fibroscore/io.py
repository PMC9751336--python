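"""Readers and writers for the tab-separated tables used throughout.

All tables are UTF-8 TSV; lines starting with ``#`` are comments; the decimal
separator is ``.``. Matrices are features x samples with the feature
identifier in the first column. Identifiers are opaque strings: no case
folding, no alias resolution.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

REQUIRED_SHEET_COLUMNS = ("sample_id", "source", "condition", "replicate")
CONDITIONS = ("control", "treated")
FIBROSIS_DISEASES = (
    "pulmonary fibrosis",
    "cardiac fibrosis",
    "hepatic fibrosis",
    "renal fibrosis",
)
LOCATIONS = (
    "extracellular space",
    "plasma membrane",
    "cytoplasm",
    "nucleus",
    "other",
)


class TableFormatError(ValueError):
    """A table violates the expected dialect or content constraints."""


def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise TableFormatError(f"{path}: malformed TSV: {exc}") from exc


def read_matrix(path, kind: str = "counts") -> pd.DataFrame:
    """Read a features x samples matrix.

    ``kind='counts'`` validates non-negative integers; ``kind='intensities'``
    validates strictly positive reals. Duplicate feature identifiers and
    ragged rows are hard errors naming the offender.
    """
    if kind not in ("counts", "intensities"):
        raise ValueError(f"unknown matrix kind {kind!r}")
    raw = _read_tsv(path)
    if raw.shape[1] < 2:
        raise TableFormatError(f"{path}: need a feature column plus >=1 sample column")
    feat_col = raw.columns[0]
    ids = raw[feat_col].astype(str)
    dup = ids[ids.duplicated()]
    if len(dup):
        raise TableFormatError(f"{path}: duplicate feature id {dup.iloc[0]!r}")
    try:
        values = raw.iloc[:, 1:].astype(float)
    except ValueError as exc:
        raise TableFormatError(f"{path}: non-numeric value: {exc}") from exc
    if values.isna().any().any():
        bad = values.index[values.isna().any(axis=1)][0]
        # +2: header line plus 1-based indexing (comment lines shift this).
        raise TableFormatError(
            f"{path}: missing/ragged value at feature {ids.iloc[bad]!r} (data line {bad + 2})"
        )
    mat = values.to_numpy()
    if kind == "counts":
        if (mat < 0).any() or not np.allclose(mat, np.round(mat)):
            bad = ids.iloc[int(np.where((mat < 0) | ~np.isclose(mat, np.round(mat)))[0][0])]
            raise TableFormatError(f"{path}: counts must be non-negative integers (feature {bad!r})")
        values = values.round().astype(np.int64)
    else:
        if (mat <= 0).any():
            bad = ids.iloc[int(np.where((mat <= 0).any(axis=1))[0][0])]
            raise TableFormatError(f"{path}: intensities must be strictly positive (feature {bad!r})")
    out = values.copy()
    out.index = pd.Index(ids.to_numpy(), name=feat_col)
    return out


def write_matrix(matrix: pd.DataFrame, path, feature_col: str = "feature_id") -> None:
    df = matrix.copy()
    df.index.name = df.index.name or feature_col
    # shortest-repr floats: lossless round trip, still deterministic
    df.to_csv(path, sep="\t")


def read_sample_sheet(path) -> pd.DataFrame:
    df = _read_tsv(path)
    missing = [c for c in REQUIRED_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: sample sheet missing columns {missing}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise TableFormatError(f"{path}: duplicate sample_id {dup!r}")
    bad = set(df["condition"]) - set(CONDITIONS)
    if bad:
        raise TableFormatError(f"{path}: condition must be in {CONDITIONS}, got {sorted(bad)}")
    df["replicate"] = df["replicate"].astype(int)
    return df.reset_index(drop=True)


def write_sample_sheet(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False)


def validate_design(matrix: pd.DataFrame, design: pd.DataFrame) -> None:
    """Matrix columns and sample sheet must name the same samples."""
    mcols, scols = list(matrix.columns), list(design["sample_id"])
    if sorted(mcols) != sorted(scols):
        only_m = sorted(set(mcols) - set(scols))[:3]
        only_s = sorted(set(scols) - set(mcols))[:3]
        raise TableFormatError(
            f"matrix columns and sample sheet disagree (matrix-only {only_m}, sheet-only {only_s})"
        )


def read_panel(path) -> list[str]:
    genes: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        genes.append(line)
    if not genes:
        raise TableFormatError(f"{path}: empty gene panel")
    if len(set(genes)) != len(genes):
        seen = set()
        dup = next(g for g in genes if g in seen or seen.add(g))
        raise TableFormatError(f"{path}: duplicate panel gene {dup!r}")
    return genes


def default_panel_path() -> Path:
    return Path(__file__).parent / "panels" / "cf_activation_28.txt"


def read_mapping(path) -> pd.DataFrame:
    df = _read_tsv(path)
    for col in ("gene_id", "protein_id"):
        if col not in df.columns:
            raise TableFormatError(f"{path}: mapping needs column {col!r}")
    if df["protein_id"].duplicated().any():
        dup = df.loc[df["protein_id"].duplicated(), "protein_id"].iloc[0]
        raise TableFormatError(f"{path}: duplicate protein_id {dup!r} in mapping")
    return df[["gene_id", "protein_id"]].reset_index(drop=True)


def read_gda(path) -> pd.DataFrame:
    df = _read_tsv(path)
    for col in ("gene_id", "disease", "score"):
        if col not in df.columns:
            raise TableFormatError(f"{path}: gene-disease table needs column {col!r}")
    df["score"] = df["score"].astype(float)
    if ((df["score"] <= 0) | (df["score"] > 1)).any():
        raise TableFormatError(f"{path}: GDA scores must lie in (0, 1]")
    if df.duplicated(["gene_id", "disease"]).any():
        raise TableFormatError(f"{path}: duplicate (gene, disease) row")
    return df.reset_index(drop=True)


def read_network(path) -> pd.DataFrame:
    df = _read_tsv(path)
    for col in ("node_a", "node_b", "combined_score"):
        if col not in df.columns:
            raise TableFormatError(f"{path}: network table needs column {col!r}")
    df["combined_score"] = df["combined_score"].astype(float)
    if ((df["combined_score"] < 0) | (df["combined_score"] > 1)).any():
        raise TableFormatError(f"{path}: combined scores must lie in [0, 1]")
    if (df["node_a"] == df["node_b"]).any():
        loop = df.loc[df["node_a"] == df["node_b"], "node_a"].iloc[0]
        raise TableFormatError(f"{path}: self-loop on {loop!r}")
    key = df.apply(lambda r: tuple(sorted((r["node_a"], r["node_b"]))), axis=1)
    if key.duplicated().any():
        a, b = key[key.duplicated()].iloc[0]
        raise TableFormatError(f"{path}: duplicate undirected edge {a!r}-{b!r}")
    return df.reset_index(drop=True)


def read_locations(path) -> pd.DataFrame:
    df = _read_tsv(path)
    for col in ("feature_id", "location"):
        if col not in df.columns:
            raise TableFormatError(f"{path}: location table needs column {col!r}")
    bad = set(df["location"]) - set(LOCATIONS)
    if bad:
        raise TableFormatError(f"{path}: unknown locations {sorted(bad)}")
    if df["feature_id"].duplicated().any():
        dup = df.loc[df["feature_id"].duplicated(), "feature_id"].iloc[0]
        raise TableFormatError(f"{path}: feature {dup!r} assigned more than one location")
    return df.reset_index(drop=True)


def read_drugs(path) -> pd.DataFrame:
    df = _read_tsv(path)
    for col in ("gene_id", "drug_name", "status"):
        if col not in df.columns:
            raise TableFormatError(f"{path}: drug table needs column {col!r}")
    return df.reset_index(drop=True)


def read_regulators(path) -> pd.DataFrame:
    df = _read_tsv(path)
    for col in ("regulator", "target", "sign"):
        if col not in df.columns:
            raise TableFormatError(f"{path}: regulator table needs column {col!r}")
    df["sign"] = df["sign"].astype(int)
    if (~df["sign"].isin((1, -1))).any():
        raise TableFormatError(f"{path}: regulator edge sign must be +1 or -1")
    if df.duplicated(["regulator", "target"]).any():
        raise TableFormatError(f"{path}: duplicate (regulator, target) row")
    return df.reset_index(drop=True)


def read_gmt(path) -> dict[str, dict]:
    """Read GMT term sets: term_id <tab> description <tab> gene1 <tab> ..."""
    terms: dict[str, dict] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise TableFormatError(f"{path}: GMT line needs id, description and >=1 member")
        term_id, label, members = parts[0], parts[1], [g for g in parts[2:] if g]
        if term_id in terms:
            raise TableFormatError(f"{path}: duplicate term {term_id!r}")
        if not members:
            raise TableFormatError(f"{path}: term {term_id!r} has no members")
        terms[term_id] = {"label": label, "genes": sorted(set(members))}
    return terms


def write_gmt(terms: dict[str, dict], path) -> None:
    lines = [
        "\t".join([tid, info["label"], *sorted(info["genes"])])
        for tid, info in sorted(terms.items())
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
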