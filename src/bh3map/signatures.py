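"""Epithelial / mesenchymal marker-sum signature scoring.

A cell line's signature score is the plain sum of the log2 expression
of a fixed, small set of canonical markers — epithelial: MUC1, CDH1,
EPCAM, CLDN3; mesenchymal: SNAI1 (Snail), SNAI2 (Slug), TWIST1,
TWIST2, VIM, CDH2.  No z-scoring or imputation: an absent marker simply
drops out of the sum and is reported, so cross-matrix comparisons can
be restricted to complete cases.  A standardised (per-gene z-scored)
variant is available behind a flag for cross-dataset use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .conditions import normalize_gene

logger = logging.getLogger(__name__)

EPITHELIAL_MARKERS: tuple[str, ...] = ("MUC1", "CDH1", "EPCAM", "CLDN3")
MESENCHYMAL_MARKERS: tuple[str, ...] = (
    "SNAI1",
    "SNAI2",
    "TWIST1",
    "TWIST2",
    "VIM",
    "CDH2",
)


@dataclass(frozen=True)
class SignatureDefinition:
    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"signature {self.name!r} has no genes")
        canon = tuple(normalize_gene(g) for g in self.genes)
        if len(set(canon)) != len(canon):
            raise ValueError(f"signature {self.name!r} has duplicate genes")
        object.__setattr__(self, "genes", canon)


EPITHELIAL = SignatureDefinition("epithelial", EPITHELIAL_MARKERS)
MESENCHYMAL = SignatureDefinition("mesenchymal", MESENCHYMAL_MARKERS)


@dataclass
class SignatureScores:
    """Per-line marker-sum scores with explicit bookkeeping of absent genes."""

    name: str
    scores: pd.Series
    present_genes: list[str] = field(default_factory=list)
    missing_genes: list[str] = field(default_factory=list)


def signature_score(
    expression: pd.DataFrame,
    definition: SignatureDefinition,
    standardize: bool = False,
) -> SignatureScores:
    """Sum the log2 expression of a signature's member genes per cell line.

    ``standardize=True`` z-scores each gene across lines before summing
    (off by default; the canonical score is the raw sum).  Raises if no
    member gene is present in the matrix.
    """
    present = [g for g in definition.genes if g in expression.index]
    missing = [g for g in definition.genes if g not in expression.index]
    if not present:
        raise ValueError(
            f"no gene of signature {definition.name!r} present in the matrix"
        )
    if missing:
        logger.info("signature %s missing genes: %s", definition.name, missing)
    block = expression.loc[present].astype(float)
    if standardize:
        block = block.sub(block.mean(axis=1), axis=0).div(block.std(axis=1, ddof=1), axis=0)
    scores = block.sum(axis=0)
    scores.name = definition.name
    return SignatureScores(
        name=definition.name,
        scores=scores,
        present_genes=present,
        missing_genes=missing,
    )


def tissue_average(values: pd.Series, tissue_labels: pd.Series) -> pd.Series:
    """Equal-weight arithmetic mean of a per-line quantity within each tissue.

    Lines with missing values are dropped from their tissue's mean;
    tissues left empty are dropped with a log entry.
    """
    shared = values.index.intersection(tissue_labels.index)
    v = values.loc[shared]
    t = tissue_labels.loc[shared]
    means = v.groupby(t).mean()
    empty = means.index[means.isna()]
    if len(empty):
        logger.info("tissues with no usable lines dropped: %s", list(empty))
    return means.dropna()


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson r with a two-sided p from the t transform (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("Pearson correlation needs n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("first vector is constant")
    if np.ptp(y) == 0:
        raise ValueError("second vector is constant")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def densitometry_normalize(target_band: float, loading_band: float) -> float:
    """Target-protein band intensity normalised to its loading control.

    The ratio (e.g. SLUG / beta-actin) feeds Pearson correlation against
    dependence scores for protein-level validation.
    """
    if loading_band <= 0:
        raise ValueError("loading-control band intensity must be > 0")
    if target_band < 0:
        raise ValueError("band intensity cannot be negative")
    return float(target_band) / float(loading_band)
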