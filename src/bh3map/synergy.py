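"""Bliss synergy scoring for BCL-X_L + MCL-1 co-inhibition.

Dependence scores enter on the 0-1 scale (0-99 viability-loss points
divided by 100).  Two variants are computed side by side:

``bliss_synergy_printed``
    (1 - x)(1 - m) - c, the formula as printed in the source protocol.

``bliss_synergy_excess``
    c - [1 - (1 - x)(1 - m)], the canonical Bliss excess: observed
    combination effect minus the Bliss-independent expectation.

The printed formula assigns +1 to a line with no response to anything,
which cannot coexist with an "insensitive" response group, so the
excess variant is the default for grouping and correlation analyses;
the printed value is always emitted alongside for fidelity.  The two
are algebraically linked: printed + excess = 2(1-x)(1-m) - 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .viability import DependencyProfile, classify

GROUPS = ("single-dependent", "synergistic co-dependent", "insensitive")


def _check_unit(name: str, v: float) -> None:
    if not 0.0 <= v <= 1.0:
        raise ValueError(f"{name}={v} outside [0, 1]")


def bliss_synergy_printed(x_dep: float, m_dep: float, combo_dep: float) -> float:
    """Synergy = (1 - BCL-X_L dep) * (1 - MCL-1 dep) - observed co-dependence."""
    _check_unit("x_dep", x_dep)
    _check_unit("m_dep", m_dep)
    _check_unit("combo_dep", combo_dep)
    return (1.0 - x_dep) * (1.0 - m_dep) - combo_dep


def bliss_expected(x_dep: float, m_dep: float) -> float:
    """Bliss-independent expected combination dependence: 1 - (1-x)(1-m)."""
    _check_unit("x_dep", x_dep)
    _check_unit("m_dep", m_dep)
    return 1.0 - (1.0 - x_dep) * (1.0 - m_dep)


def bliss_synergy_excess(x_dep: float, m_dep: float, combo_dep: float) -> float:
    """Observed co-dependence minus the Bliss-independent expectation.

    Zero on exactly Bliss-additive triples, positive when the
    combination kills more than independence predicts.
    """
    _check_unit("combo_dep", combo_dep)
    return combo_dep - bliss_expected(x_dep, m_dep)


def assign_group(
    profile: DependencyProfile,
    synergy: float,
    single_cutoff: float = 0.25,
    synergy_cutoff: float = 0.25,
) -> str:
    """Response-group label for one cell line.

    Single-dependent if either single-agent dependence exceeds
    ``single_cutoff`` (0-1 scale); otherwise synergistically
    co-dependent if the synergy score exceeds ``synergy_cutoff`` and the
    combination itself clears the dependent>25 class; otherwise
    insensitive.
    """
    x = profile.score("W539") / 100.0
    m = profile.score("A121") / 100.0
    combo_score = profile.score("W539+A121")
    if combo_score != combo_score:  # NaN
        raise ValueError(f"cell line {profile.cell_line!r} missing W539+A121 score")
    if x > single_cutoff or m > single_cutoff:
        return "single-dependent"
    if synergy > synergy_cutoff and classify(combo_score, "dependent>25"):
        return "synergistic co-dependent"
    return "insensitive"


@dataclass
class SynergyResult:
    cell_line: str
    x_dep: float
    m_dep: float
    combo_dep: float
    synergy_printed: float
    synergy_excess: float
    group: str


def score_synergy(
    profiles: Iterable[DependencyProfile],
    formula: str = "excess",
    single_cutoff: float = 0.25,
    synergy_cutoff: float = 0.25,
) -> pd.DataFrame:
    """Synergy table for a cohort of dependency profiles.

    ``formula`` selects which variant drives group assignment
    ("excess", the default, or "printed"); both are reported.
    """
    if formula not in {"excess", "printed"}:
        raise ValueError(f"formula must be 'excess' or 'printed', got {formula!r}")
    rows = []
    for prof in profiles:
        x = prof.score("W539") / 100.0
        m = prof.score("A121") / 100.0
        c = prof.score("W539+A121") / 100.0
        printed = bliss_synergy_printed(x, m, c)
        excess = bliss_synergy_excess(x, m, c)
        chosen = excess if formula == "excess" else printed
        rows.append(
            SynergyResult(
                cell_line=prof.cell_line,
                x_dep=x,
                m_dep=m,
                combo_dep=c,
                synergy_printed=printed,
                synergy_excess=excess,
                group=assign_group(prof, chosen, single_cutoff, synergy_cutoff),
            )
        )
    return pd.DataFrame([vars(r) for r in rows])
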