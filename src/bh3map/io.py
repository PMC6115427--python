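"""Readers and writers for the pipeline's plain-text tables.

Everything is tab-separated with documented headers; expression
matrices can additionally be read from the GCT 1.2 dialect.  Cell-line
identifiers are opaque strings matched exactly after whitespace
trimming; gene symbols pass through the alias table (SNAIL -> SNAI1,
NOXA -> PMAIP1, ...) on read.  Every writer's output is re-parseable by
its matching reader with identical values.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .conditions import normalize_condition, normalize_gene


def write_panel(panel: pd.DataFrame, path: str | Path) -> None:
    panel.to_csv(path, sep="\t", index=False)


def read_panel(path: str | Path) -> pd.DataFrame:
    panel = pd.read_csv(path, sep="\t")
    required = {"cell_line", "condition", "replicate", "signal"}
    missing = required - set(panel.columns)
    if missing:
        raise ValueError(f"{path}: panel missing columns {sorted(missing)}")
    panel["cell_line"] = panel["cell_line"].astype(str).str.strip()
    panel["condition"] = panel["condition"].astype(str).map(normalize_condition)
    return panel


def _read_matrix_tsv(path: str | Path, index_name: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str).str.strip()
    df.index.name = index_name
    df.columns = [str(c).strip() for c in df.columns]
    return df


def write_expression(expression: pd.DataFrame, path: str | Path) -> None:
    expression.to_csv(path, sep="\t", index_label="gene")


def read_expression(path: str | Path, dialect: str = "tsv") -> pd.DataFrame:
    """Read a gene x cell-line log2 expression matrix (TSV or GCT 1.2).

    Gene symbols are resolved through the alias table; duplicated gene
    rows (after aliasing) and non-numeric cells are rejected with their
    location named.
    """
    if dialect == "tsv":
        df = _read_matrix_tsv(path, "gene")
    elif dialect == "gct":
        df = _read_gct(path)
    else:
        raise ValueError(f"unknown expression dialect {dialect!r}")
    df.index = [normalize_gene(g) for g in df.index]
    df.index.name = "gene"
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicated gene row(s): {sorted(set(dup))}")
    try:
        return df.astype(float)
    except ValueError as exc:
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                raise ValueError(
                    f"{path}: non-numeric value at gene {df.index[bad.argmax()]!r}, "
                    f"column {col!r}"
                ) from exc
        raise


def _read_gct(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise ValueError(f"{path}: expected GCT header '#1.2', got {version!r}")
        dims = fh.readline().split()
        if len(dims) != 2:
            raise ValueError(f"{path}: malformed GCT dimension line")
        n_rows, n_cols = int(dims[0]), int(dims[1])
        df = pd.read_csv(fh, sep="\t")
    if df.shape[0] != n_rows or df.shape[1] - 2 != n_cols:
        raise ValueError(
            f"{path}: GCT dims {n_rows}x{n_cols} disagree with table "
            f"{df.shape[0]}x{df.shape[1] - 2}"
        )
    df = df.set_index(df.columns[0]).drop(columns=df.columns[1])
    df.index = df.index.astype(str).str.strip()
    df.index.name = "gene"
    return df


def write_mutations(mutations: pd.DataFrame, path: str | Path) -> None:
    mutations.astype(int).to_csv(path, sep="\t", index_label="gene")


def read_mutations(path: str | Path) -> pd.DataFrame:
    df = _read_matrix_tsv(path, "gene").astype(int)
    if not df.isin([0, 1]).all().all():
        raise ValueError(f"{path}: mutation table must be binary 0/1")
    return df


def write_tissues(tissue_labels: pd.Series, path: str | Path) -> None:
    tissue_labels.rename("tissue").to_csv(path, sep="\t", index_label="cell_line")


def read_tissues(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if not {"cell_line", "tissue"} <= set(df.columns):
        raise ValueError(f"{path}: tissue map needs cell_line and tissue columns")
    s = pd.Series(
        df["tissue"].astype(str).str.strip().to_numpy(),
        index=df["cell_line"].astype(str).str.strip(),
        name="tissue",
    )
    s.index.name = "cell_line"
    return s


def write_profiles(profiles_long: pd.DataFrame, path: str | Path) -> None:
    profiles_long.to_csv(path, sep="\t", index=False)


def read_profiles(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"cell_line", "condition", "score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: profile table missing {sorted(missing)}")
    df["cell_line"] = df["cell_line"].astype(str).str.strip()
    df["condition"] = df["condition"].astype(str).map(normalize_condition)
    return df


def profiles_to_matrix(profiles_long: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long profile table to the wide (lines x conditions) matrix."""
    return profiles_long.pivot(index="cell_line", columns="condition", values="score")


def write_counts(
    counts: pd.DataFrame, library: pd.DataFrame, path: str | Path
) -> None:
    """Counts TSV: sgrna_id, gene, is_control, then one column per sample."""
    merged = library.set_index("sgrna_id").join(counts, how="right")
    merged.to_csv(path, sep="\t", index_label="sgrna_id")


def read_counts(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a counts TSV back into (counts, library)."""
    df = pd.read_csv(path, sep="\t")
    required = {"sgrna_id", "gene", "is_control"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: counts table missing {sorted(missing)}")
    library = df[["sgrna_id", "gene", "is_control"]].copy()
    library["is_control"] = library["is_control"].astype(bool)
    counts = df.drop(columns=["gene", "is_control"]).set_index("sgrna_id")
    return counts, library


def write_truth(truth: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)


def read_truth(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
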