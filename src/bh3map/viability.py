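"""Dependency scoring from raw viability-panel signals.

A cell line's dependence on an anti-apoptotic protein is quantified as
the percentage viability loss under the corresponding inhibitor
condition:

    loss = 100 * (1 - mean(treated signal) / mean(vehicle signal))

clamped to [0, 99], so 0 means no apparent viability loss and the score
never reaches 100 (downstream rescaling to the 0-1 dependence scale
therefore never reaches exactly 1).  Sensitivity classes use the strict
cutoffs quoted in the field: sensitive (>50), dependent (>25),
non-responding (<20), innately resistant (<10).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .conditions import CONDITIONS, TREATMENT_CONDITIONS, VEHICLE, normalize_condition

#: Classification rules: name -> (comparison, cutoff).  All strict.
CLASS_RULES: dict[str, tuple[str, float]] = {
    "sensitive>50": (">", 50.0),
    "dependent>25": (">", 25.0),
    "nonresponse<20": ("<", 20.0),
    "resistant<10": ("<", 10.0),
}

SCORE_MAX = 99.0


def viability_loss(
    treated_signals: Iterable[float], untreated_signals: Iterable[float]
) -> float:
    """Percentage viability loss of a treated well set vs its vehicle wells.

    Replicates are aggregated mean-first: the ratio of replicate means,
    not the mean of per-replicate ratios.  The result is clamped to
    [0, 99]; negative losses (treated brighter than vehicle) read as 0.
    """
    treated = np.asarray(list(treated_signals), dtype=float)
    untreated = np.asarray(list(untreated_signals), dtype=float)
    if treated.size == 0 or untreated.size == 0:
        raise ValueError("treated and untreated replicate lists must be non-empty")
    mu_untreated = untreated.mean()
    if mu_untreated <= 0:
        raise ZeroDivisionError("untreated mean signal must be > 0")
    raw = 100.0 * (1.0 - treated.mean() / mu_untreated)
    return float(min(max(raw, 0.0), SCORE_MAX))


def classify(score: float, rule: str) -> bool:
    """Strictly compare a dependency score against a named cutoff rule."""
    if not 0.0 <= score <= SCORE_MAX:
        raise ValueError(f"score {score} outside [0, {SCORE_MAX}]")
    try:
        op, cutoff = CLASS_RULES[rule]
    except KeyError:
        raise ValueError(
            f"unknown rule {rule!r}; choose from {sorted(CLASS_RULES)}"
        ) from None
    return score > cutoff if op == ">" else score < cutoff


def class_label(score: float) -> str:
    """Primary sensitivity label for a score.

    Scores between 20 and 25 fall in none of the named strict bands and
    are labelled ``intermediate``.
    """
    if math.isnan(score):
        return "missing"
    if classify(score, "sensitive>50"):
        return "sensitive>50"
    if classify(score, "dependent>25"):
        return "dependent>25"
    if classify(score, "resistant<10"):
        return "resistant<10"
    if classify(score, "nonresponse<20"):
        return "nonresponse<20"
    return "intermediate"


@dataclass
class DependencyProfile:
    """Per-cell-line dependency scores across the seven treatment conditions."""

    cell_line: str
    scores: dict[str, float] = field(default_factory=dict)
    n_replicates: dict[str, int] = field(default_factory=dict)
    classes: dict[str, str] = field(default_factory=dict)

    def score(self, condition: str) -> float:
        return self.scores.get(normalize_condition(condition), float("nan"))


def _validate_panel(panel: pd.DataFrame) -> pd.DataFrame:
    required = {"cell_line", "condition", "replicate", "signal"}
    missing = required - set(panel.columns)
    if missing:
        raise ValueError(f"panel table missing columns: {sorted(missing)}")
    panel = panel.copy()
    panel["condition"] = panel["condition"].map(normalize_condition)
    if (panel["signal"] < 0).any():
        bad = panel.loc[panel["signal"] < 0, "cell_line"].iloc[0]
        raise ValueError(f"negative signal for cell line {bad!r}")
    return panel


def build_profiles(panel: pd.DataFrame) -> list[DependencyProfile]:
    """Score every cell line in a tidy panel table.

    ``panel`` holds columns (cell_line, condition, replicate, signal).
    Each treatment condition is scored against that line's own vehicle
    wells.  A condition with no replicates yields a missing (NaN) score,
    never an imputed one.
    """
    panel = _validate_panel(panel)
    profiles: list[DependencyProfile] = []
    for line, sub in panel.groupby("cell_line", sort=True):
        veh = sub.loc[sub["condition"] == VEHICLE, "signal"].to_numpy()
        if veh.size == 0:
            raise ValueError(f"cell line {line!r} has no {VEHICLE} replicates")
        prof = DependencyProfile(cell_line=str(line))
        for cond in TREATMENT_CONDITIONS:
            treated = sub.loc[sub["condition"] == cond, "signal"].to_numpy()
            prof.n_replicates[cond] = int(treated.size)
            if treated.size == 0:
                prof.scores[cond] = float("nan")
                prof.classes[cond] = "missing"
            else:
                s = viability_loss(treated, veh)
                prof.scores[cond] = s
                prof.classes[cond] = class_label(s)
        profiles.append(prof)
    return profiles


def profiles_frame(profiles: Iterable[DependencyProfile]) -> pd.DataFrame:
    """Tidy (long) table of scores: cell_line, condition, score, n, class."""
    rows = [
        {
            "cell_line": p.cell_line,
            "condition": cond,
            "score": p.scores.get(cond, float("nan")),
            "n": p.n_replicates.get(cond, 0),
            "class": p.classes.get(cond, "missing"),
        }
        for p in profiles
        for cond in TREATMENT_CONDITIONS
    ]
    return pd.DataFrame(rows)


def score_matrix(profiles: Iterable[DependencyProfile]) -> pd.DataFrame:
    """Heatmap-ready wide matrix: cell lines x 7 treatment conditions."""
    profiles = list(profiles)
    mat = pd.DataFrame(
        {cond: [p.scores.get(cond, float("nan")) for p in profiles] for cond in TREATMENT_CONDITIONS},
        index=pd.Index([p.cell_line for p in profiles], name="cell_line"),
    )
    return mat


def tumor_volume(length_mm: float, width_mm: float) -> float:
    """Caliper tumour volume in mm^3: V = (L^2 x W) / 2.

    ``length_mm`` is the longest diameter and ``width_mm`` the shortest;
    swapped roles are rejected rather than silently corrected.
    """
    if width_mm <= 0 or length_mm <= 0:
        raise ValueError("diameters must be positive")
    if width_mm > length_mm:
        raise ValueError("W > L: length must be the longest diameter")
    return (length_mm**2 * width_mm) / 2.0
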