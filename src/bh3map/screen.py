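"""Negative-selection pooled CRISPR screen scoring.

Knockouts that sensitise cells to the drug drop out of the treated
population, so sensitisers are the most *depleted* genes.  The pipeline
is: reads-per-million normalisation with a pseudocount, per-sgRNA log2
fold change of treated vs vehicle (DMSO), then per gene the depletion
metric (DM) — the "three-score", the mean of that gene's 3 most
depleted sgRNA fold changes.  Control sgRNAs are chunked into
pseudo-genes of the same size as real genes to give a null DM
distribution against which hits are contextualised.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


def validate_library(library: pd.DataFrame) -> pd.DataFrame:
    """Check a library annotation (sgrna_id, gene, is_control)."""
    required = {"sgrna_id", "gene", "is_control"}
    missing = required - set(library.columns)
    if missing:
        raise ValueError(f"library missing columns: {sorted(missing)}")
    if library["sgrna_id"].duplicated().any():
        dup = library.loc[library["sgrna_id"].duplicated(), "sgrna_id"].iloc[0]
        raise ValueError(f"duplicate sgrna_id in library: {dup!r}")
    per_gene = library.loc[~library["is_control"].astype(bool)].groupby("gene").size()
    short = per_gene[per_gene < 3]
    if len(short):
        raise ValueError(
            f"genes with fewer than 3 sgRNAs (three-score undefined): {list(short.index)}"
        )
    return library


def normalize_counts(counts: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Reads-per-million with a pseudocount.

    RPM = (count + pc) / (sample total + pc * n_sgRNA) * 1e6, so the
    normalised columns still sum to one million and a zero count maps to
    a small positive value instead of breaking the log.
    """
    counts = counts.astype(float)
    if (counts < 0).any().any():
        raise ValueError("counts must be non-negative")
    totals = counts.sum(axis=0)
    dead = totals.index[totals == 0]
    if len(dead):
        raise ValueError(f"all-zero count sample(s): {list(dead)}")
    denom = totals + pseudocount * counts.shape[0]
    return (counts + pseudocount) / denom * 1e6


def sgrna_lfc(
    normalized: pd.DataFrame,
    dmso_samples: Sequence[str],
    treated_samples: Sequence[str],
) -> pd.Series:
    """Per-sgRNA log2 fold change, treated vs DMSO.

    Replicates are averaged on the RPM scale first, then logged
    (mean-then-log), which stabilises constructs with a zero in one
    replicate: lfc = log2(mean treated RPM) - log2(mean DMSO RPM).
    """
    for group, name in ((dmso_samples, "DMSO"), (treated_samples, "treated")):
        if len(group) < 1:
            raise ValueError(f"need at least one {name} replicate")
        absent = [s for s in group if s not in normalized.columns]
        if absent:
            raise ValueError(f"{name} sample(s) missing from table: {absent}")
    mean_dmso = normalized[list(dmso_samples)].mean(axis=1)
    mean_trt = normalized[list(treated_samples)].mean(axis=1)
    lfc = np.log2(mean_trt) - np.log2(mean_dmso)
    lfc.name = "lfc"
    return lfc


def three_score(lfcs: Sequence[float]) -> float:
    """Mean of the 3 most depleted (smallest) sgRNA log2 fold changes."""
    arr = np.asarray(list(lfcs), dtype=float)
    if arr.size < 3:
        raise ValueError(f"three-score needs >= 3 sgRNA fold changes, got {arr.size}")
    return float(np.sort(arr)[:3].mean())


@dataclass
class ScreenResult:
    """Ranked per-gene depletion metrics plus supporting per-sgRNA detail."""

    genes: pd.DataFrame  # gene, dm, mean_lfc, n_sgrna, z, rank, hit
    sgrna_lfcs: pd.DataFrame  # sgrna_id, gene, is_control, lfc
    control_dms: np.ndarray  # pseudo-gene DM null distribution


def score_screen(
    counts: pd.DataFrame,
    library: pd.DataFrame,
    dmso_samples: Sequence[str],
    treated_samples: Sequence[str],
    pseudocount: float = 1.0,
    hit_percentile: float = 5.0,
) -> ScreenResult:
    """Full screen pipeline: normalise, fold-change, three-score, rank.

    ``counts`` is sgRNA x sample (indexed by sgrna_id).  The gene table
    is ranked ascending by DM (rank 1 = most depleted = strongest
    sensitiser).  Control sgRNAs are chunked, in annotation order, into
    pseudo-genes of the modal real-gene size; a gene is flagged a hit
    when its DM falls below the ``hit_percentile`` of that control DM
    distribution.  The hit rule is a convention of this package, not a
    published cutoff.
    """
    library = validate_library(library)
    absent = set(library["sgrna_id"]) - set(counts.index)
    if absent:
        raise ValueError(f"library sgRNAs missing from counts: {sorted(absent)[:5]}...")
    rpm = normalize_counts(counts, pseudocount=pseudocount)
    lfc = sgrna_lfc(rpm, dmso_samples, treated_samples)
    lib = library.set_index("sgrna_id")
    detail = pd.DataFrame(
        {
            "gene": lib["gene"].reindex(lfc.index),
            "is_control": lib["is_control"].reindex(lfc.index).astype(bool),
            "lfc": lfc,
        }
    ).dropna(subset=["gene"])

    real = detail.loc[~detail["is_control"]]
    rows = [
        {
            "gene": gene,
            "dm": three_score(sub["lfc"].to_numpy()),
            "mean_lfc": float(sub["lfc"].mean()),
            "n_sgrna": int(len(sub)),
        }
        for gene, sub in real.groupby("gene", sort=True)
    ]
    genes = pd.DataFrame(rows)

    # chunk controls in sgrna_id order so results are row-order invariant
    ctrl = detail.loc[detail["is_control"], "lfc"].sort_index().to_numpy()
    group = int(real.groupby("gene").size().mode().iloc[0]) if len(real) else 5
    control_dms = np.array(
        [
            three_score(ctrl[i : i + group])
            for i in range(0, len(ctrl) - group + 1, group)
        ]
    )
    if control_dms.size:
        mu, sd = control_dms.mean(), control_dms.std(ddof=1) if control_dms.size > 1 else 0.0
        genes["z"] = (genes["dm"] - mu) / sd if sd > 0 else np.nan
        cutoff = float(np.percentile(control_dms, hit_percentile))
        genes["hit"] = genes["dm"] < cutoff
    else:
        genes["z"] = np.nan
        genes["hit"] = False
    genes = genes.sort_values(["dm", "gene"], kind="stable").reset_index(drop=True)
    genes["rank"] = np.arange(1, len(genes) + 1)
    return ScreenResult(genes=genes, sgrna_lfcs=detail.reset_index(), control_dms=control_dms)
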