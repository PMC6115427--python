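"""Seeded synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates the study design end to end: ~78 cell lines from
ten tissues screened in triplicate against the 8-condition BH3-mimetic
panel, a log2 expression matrix over BCL-2-family drivers, EMT markers
and filler genes, a binary mutation table, and a 398-gene / 5-sgRNA /
50-control pooled CRISPR screen in duplicate.

Planted structure (all recorded in the returned truth record):

* per-tissue base dependency rates on BCL-2, BCL-X_L and MCL-1;
* expression-threshold dependency rules (e.g. NOXA above a log2
  cutpoint adds points of BCL-X_L dependence), mirroring the
  expression-driven biology the biomarker layer is meant to recover;
* optional mutation-driven dependency rules (the mirror case for
  predictor comparison);
* a latent epithelial/mesenchymal class per line that shifts marker
  expression and couples to the drug response: epithelial lines get a
  planted synergy bonus on BCL-X_L + MCL-1 co-inhibition, mesenchymal
  lines extra single-agent BCL-X_L dependence;
* CRISPR sensitiser genes whose sgRNAs (a random >= 3 of them) are
  depleted by a planted log2 effect under treatment.

Combination-condition losses compose Bliss-independently by default
(combo survival = product of single-agent survivals) plus the planted
synergy term, which makes the synergy scorer's null behaviour testable.
Counts are negative binomial (pooled screens are overdispersed; the
dispersion is a knob).  With every noise term at zero the downstream
recomputed scores equal 100 x the planted losses exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .conditions import CONDITION_TARGETS, PHENOTYPES, TREATMENT_CONDITIONS, VEHICLE

#: Default tissue composition: 78 lines over the ten profiled cancer types.
DEFAULT_TISSUES: dict[str, int] = {
    "LAML": 8,
    "OV": 8,
    "COAD": 8,
    "PAAD": 8,
    "LUAD": 8,
    "SKCM": 8,
    "LIHC": 8,
    "BLCA": 8,
    "BRCA": 8,
    "GBM": 6,
}

#: Per-tissue base dependency rates (fraction of viability lost) shaped
#: after the qualitative pan-cancer pattern: leukaemias lean on BCL-2 and
#: MCL-1, bladder/pancreas/melanoma show single-agent BCL-X_L dependence,
#: breast on MCL-1, and colorectal/ovarian/lung are broadly insensitive.
DEFAULT_BASE_DEPENDENCY: dict[str, dict[str, float]] = {
    "LAML": {"BCL2": 0.35, "BCLXL": 0.02, "MCL1": 0.35},
    "OV": {"BCL2": 0.02, "BCLXL": 0.06, "MCL1": 0.08},
    "COAD": {"BCL2": 0.02, "BCLXL": 0.08, "MCL1": 0.06},
    "PAAD": {"BCL2": 0.04, "BCLXL": 0.22, "MCL1": 0.12},
    "LUAD": {"BCL2": 0.02, "BCLXL": 0.08, "MCL1": 0.10},
    "SKCM": {"BCL2": 0.12, "BCLXL": 0.20, "MCL1": 0.15},
    "LIHC": {"BCL2": 0.08, "BCLXL": 0.10, "MCL1": 0.10},
    "BLCA": {"BCL2": 0.03, "BCLXL": 0.30, "MCL1": 0.08},
    "BRCA": {"BCL2": 0.03, "BCLXL": 0.08, "MCL1": 0.22},
    "GBM": {"BCL2": 0.02, "BCLXL": 0.10, "MCL1": 0.10},
}

#: Epithelial-class probability per tissue (suspension leukaemias and
#: melanoma/glioma skew mesenchymal-like; carcinomas epithelial).
DEFAULT_EPITHELIAL_PROB: dict[str, float] = {
    "LAML": 0.2,
    "OV": 0.7,
    "COAD": 0.8,
    "PAAD": 0.6,
    "LUAD": 0.6,
    "SKCM": 0.3,
    "LIHC": 0.5,
    "BLCA": 0.6,
    "BRCA": 0.7,
    "GBM": 0.3,
}

DRIVER_GENES = ("BCL2", "BCL2L1", "MCL1", "PMAIP1", "BCL2L2", "BCL2A1")
EPITHELIAL_GENES = ("MUC1", "CDH1", "EPCAM", "CLDN3")
MESENCHYMAL_GENES = ("SNAI1", "SNAI2", "TWIST1", "TWIST2", "VIM", "CDH2")
MUTATION_GENES = (
    "TP53", "PIK3CA", "PTEN", "KRAS", "EGFR", "NF1",
    "BRAF", "RB1", "ATM", "BRCA2", "BRCA1",
)

#: Anchored log2 expression means for genes whose planted thresholds must
#: sit inside the population spread; other genes draw means at random.
DEFAULT_EXPR_MEANS: dict[str, float] = {"PMAIP1": 9.2, "BCL2L1": 7.3, "BCL2": 8.3}


@dataclass(frozen=True)
class DependencyRule:
    """Expression-threshold rule: lines on ``direction`` side of
    ``threshold`` (log2 units) gain ``effect`` viability-loss points of
    ``phenotype`` dependence."""

    gene: str
    phenotype: str
    direction: str  # "above" | "below"
    threshold: float
    effect: float

    def applies(self, expr_value: float) -> bool:
        if self.direction == "above":
            return expr_value > self.threshold
        if self.direction == "below":
            return expr_value < self.threshold
        raise ValueError(f"direction must be 'above' or 'below', got {self.direction!r}")


@dataclass(frozen=True)
class MutationRule:
    """Mutant lines for ``gene`` gain ``effect`` points of ``phenotype``
    dependence."""

    gene: str
    phenotype: str
    effect: float


#: Default planted rules: high NOXA drives BCL-X_L dependence; low
#: BCL-X_L expression drives MCL-1 dependence (the anti-correlation);
#: high BCL-2 expression drives BCL-2 dependence.
DEFAULT_DEPENDENCY_RULES: tuple[DependencyRule, ...] = (
    DependencyRule("PMAIP1", "BCLXL", "above", 10.0, 40.0),
    DependencyRule("BCL2L1", "MCL1", "below", 6.5, 40.0),
    DependencyRule("BCL2", "BCL2", "above", 9.0, 30.0),
)


@dataclass
class EMTConfig:
    """Coupling of the latent epithelial/mesenchymal class to expression
    and drug response."""

    epithelial_prob: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EPITHELIAL_PROB)
    )
    marker_shift: float = 1.0  # log2 shift on the class's own markers
    synergy_boost: float = 0.40  # extra combo loss for epithelial lines
    mesenchymal_xl_boost: float = 15.0  # extra BCL-X_L points for mesenchymal lines


@dataclass
class CrisprConfig:
    """Negative-selection screen design: 398 genes x 5 sgRNA + 50 controls,
    duplicate DMSO and treated conditions."""

    n_genes: int = 398
    sgrna_per_gene: int = 5
    n_controls: int = 50
    replicates: int = 2
    dispersion: float = 0.005  # NB dispersion alpha; 0 => Poisson
    baseline_log_mean: float = float(np.log(2000.0))
    baseline_log_sd: float = 0.5
    sensitizers: tuple[str, ...] = ("BCL2L2", "BCL2A1")
    depletion_log2: float = -2.0
    n_affected_sgrnas: int = 3

    def __post_init__(self) -> None:
        if self.sgrna_per_gene < 3:
            raise ValueError("sgrna_per_gene < 3: three-score undefined")
        if not 3 <= self.n_affected_sgrnas <= self.sgrna_per_gene:
            raise ValueError("n_affected_sgrnas must be in [3, sgrna_per_gene]")


@dataclass
class SimConfig:
    """Full simulation design; defaults mirror the emulated study."""

    tissues: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_TISSUES))
    replicates: int = 3
    noise_sd_viability: float = 0.05  # replicate noise, fraction of signal
    line_sd: float = 0.05  # biological jitter on the loss scale
    untreated_log_mean: float = float(np.log(1e6))  # luminescence scale
    untreated_log_sd: float = 0.2
    base_dependency: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {t: dict(v) for t, v in DEFAULT_BASE_DEPENDENCY.items()}
    )
    dependency_rules: tuple[DependencyRule, ...] = DEFAULT_DEPENDENCY_RULES
    mutation_rules: tuple[MutationRule, ...] = ()
    mutation_rate: float = 0.3
    expr_means: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EXPR_MEANS)
    )
    expr_sd: float = 1.2  # per-line spread around the gene/tissue mean
    tissue_expr_sd: float = 0.4  # tissue-level offsets for unanchored genes
    n_filler_genes: int = 20
    emt: EMTConfig | None = field(default_factory=EMTConfig)
    crispr: CrisprConfig | None = field(default_factory=CrisprConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.tissues.values()):
            raise ValueError("every tissue must contribute at least one line")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_sd_viability < 0 or self.line_sd < 0:
            raise ValueError("noise magnitudes must be >= 0")
        for t in self.tissues:
            if t not in self.base_dependency:
                raise ValueError(f"tissue {t!r} has no base dependency rates")

    @property
    def n_cell_lines(self) -> int:
        return int(sum(self.tissues.values()))


@dataclass
class SyntheticBundle:
    """Everything a downstream stage needs, plus the planted truth."""

    viability_panel: pd.DataFrame  # cell_line, condition, replicate, signal
    expression: pd.DataFrame  # gene x cell line, log2
    mutations: pd.DataFrame  # gene x cell line, 0/1
    tissue_labels: pd.Series  # cell line -> tissue
    crispr_counts: pd.DataFrame | None  # sgrna x sample
    crispr_library: pd.DataFrame | None  # sgrna_id, gene, is_control
    truth: dict


def _gene_universe(config: SimConfig) -> list[str]:
    fillers = [f"GF{i:03d}" for i in range(1, config.n_filler_genes + 1)]
    return list(DRIVER_GENES + EPITHELIAL_GENES + MESENCHYMAL_GENES) + fillers


def _simulate_expression(
    config: SimConfig,
    lines: list[str],
    tissue_of: pd.Series,
    epithelial: pd.Series | None,
    rng: np.random.Generator,
) -> pd.DataFrame:
    genes = _gene_universe(config)
    tissues = list(config.tissues)
    base = {
        g: config.expr_means.get(g, float(rng.normal(8.0, 1.0))) for g in genes
    }
    # Anchored genes carry no tissue offset so planted thresholds cut the
    # population at the intended point in every tissue.
    offsets = {
        (g, t): 0.0 if g in config.expr_means else float(rng.normal(0.0, config.tissue_expr_sd))
        for g in genes
        for t in tissues
    }
    mat = np.empty((len(genes), len(lines)))
    for j, line in enumerate(lines):
        t = tissue_of[line]
        for i, g in enumerate(genes):
            mu = base[g] + offsets[(g, t)]
            if epithelial is not None and config.emt is not None:
                if g in EPITHELIAL_GENES and epithelial[line]:
                    mu += config.emt.marker_shift
                elif g in MESENCHYMAL_GENES and not epithelial[line]:
                    mu += config.emt.marker_shift
            mat[i, j] = mu + rng.normal(0.0, config.expr_sd)
    return pd.DataFrame(mat, index=pd.Index(genes, name="gene"), columns=lines)


def _true_losses(
    config: SimConfig,
    lines: list[str],
    tissue_of: pd.Series,
    expression: pd.DataFrame,
    mutations: pd.DataFrame,
    epithelial: pd.Series | None,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Latent single-protein losses and per-condition composed losses."""
    dep = pd.DataFrame(index=lines, columns=list(PHENOTYPES), dtype=float)
    for line in lines:
        t = tissue_of[line]
        loss = {p: float(config.base_dependency[t][p]) for p in PHENOTYPES}
        for rule in config.dependency_rules:
            if rule.gene in expression.index and rule.applies(
                float(expression.loc[rule.gene, line])
            ):
                loss[rule.phenotype] += rule.effect / 100.0
        for mrule in config.mutation_rules:
            if mrule.gene in mutations.index and mutations.loc[mrule.gene, line]:
                loss[mrule.phenotype] += mrule.effect / 100.0
        if epithelial is not None and config.emt is not None and not epithelial[line]:
            loss["BCLXL"] += config.emt.mesenchymal_xl_boost / 100.0
        for p in PHENOTYPES:
            loss[p] += float(rng.normal(0.0, config.line_sd)) if config.line_sd > 0 else 0.0
            dep.loc[line, p] = min(max(loss[p], 0.0), 0.99)

    cond_loss = pd.DataFrame(index=lines, columns=list(TREATMENT_CONDITIONS), dtype=float)
    for line in lines:
        synergy = 0.0
        if epithelial is not None and config.emt is not None and epithelial[line]:
            synergy = config.emt.synergy_boost
        for cond in TREATMENT_CONDITIONS:
            targets = CONDITION_TARGETS[cond]
            survival = 1.0
            for p in targets:
                survival *= 1.0 - float(dep.loc[line, p])
            loss = 1.0 - survival
            if {"BCLXL", "MCL1"} <= targets:
                loss += synergy
            cond_loss.loc[line, cond] = min(max(loss, 0.0), 0.99)
    return dep, cond_loss


def _simulate_panel(
    config: SimConfig,
    lines: list[str],
    cond_loss: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict[str, float]]:
    records = []
    untreated: dict[str, float] = {}
    for line in lines:
        u = float(np.exp(rng.normal(config.untreated_log_mean, config.untreated_log_sd)))
        untreated[line] = u
        for rep in range(1, config.replicates + 1):
            eps = rng.normal(0.0, config.noise_sd_viability) if config.noise_sd_viability > 0 else 0.0
            records.append((line, VEHICLE, rep, max(u * (1.0 + eps), 0.0)))
        for cond in TREATMENT_CONDITIONS:
            mean_signal = u * (1.0 - float(cond_loss.loc[line, cond]))
            for rep in range(1, config.replicates + 1):
                eps = rng.normal(0.0, config.noise_sd_viability) if config.noise_sd_viability > 0 else 0.0
                records.append((line, cond, rep, max(mean_signal * (1.0 + eps), 0.0)))
    panel = pd.DataFrame(records, columns=["cell_line", "condition", "replicate", "signal"])
    return panel, untreated


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Negative binomial with mean mu and variance mu + alpha * mu^2."""
    mu = np.maximum(mu, 1e-9)
    if alpha <= 0:
        return rng.poisson(mu)
    size = 1.0 / alpha
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def simulate_crispr_counts(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate the pooled screen count table.

    Returns (counts, library, truth): counts indexed by sgrna_id with
    DMSO_1..r and TRT_1..r columns; library carrying (sgrna_id, gene,
    is_control); truth recording the planted per-sgRNA log2 effects.
    """
    if config.crispr is None:
        raise ValueError("SimConfig.crispr is not set")
    cc = config.crispr
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    gene_names = list(cc.sensitizers) + [
        f"CG{i:04d}" for i in range(1, cc.n_genes - len(cc.sensitizers) + 1)
    ]
    rows = []
    effects: dict[str, float] = {}
    for gene in gene_names:
        affected: set[int] = set()
        if gene in cc.sensitizers:
            affected = set(
                rng.choice(cc.sgrna_per_gene, size=cc.n_affected_sgrnas, replace=False)
            )
        for k in range(cc.sgrna_per_gene):
            sg = f"{gene}_sg{k + 1}"
            eff = cc.depletion_log2 if k in affected else 0.0
            effects[sg] = eff
            rows.append((sg, gene, False, eff))
    for k in range(cc.n_controls):
        sg = f"CTRL_sg{k + 1:03d}"
        effects[sg] = 0.0
        rows.append((sg, "CONTROL", True, 0.0))
    library = pd.DataFrame(rows, columns=["sgrna_id", "gene", "is_control", "effect"])

    n = len(library)
    baseline = np.exp(rng.normal(cc.baseline_log_mean, cc.baseline_log_sd, size=n))
    eff = library["effect"].to_numpy()
    counts = {}
    for r in range(1, cc.replicates + 1):
        counts[f"DMSO_{r}"] = _nb_draw(rng, baseline, cc.dispersion)
    for r in range(1, cc.replicates + 1):
        counts[f"TRT_{r}"] = _nb_draw(rng, baseline * 2.0**eff, cc.dispersion)
    count_df = pd.DataFrame(counts, index=pd.Index(library["sgrna_id"], name="sgrna_id"))
    truth = {
        "sensitizers": list(cc.sensitizers),
        "depletion_log2": cc.depletion_log2,
        "sgrna_effects": effects,
        "dmso_samples": [f"DMSO_{r}" for r in range(1, cc.replicates + 1)],
        "treated_samples": [f"TRT_{r}" for r in range(1, cc.replicates + 1)],
    }
    return count_df, library.drop(columns="effect"), truth


def simulate_screen(config: SimConfig) -> SyntheticBundle:
    """Generate a complete synthetic study bundle from one seed.

    The same config and seed always yield byte-identical tables.
    """
    rng = np.random.default_rng(config.seed)
    lines: list[str] = []
    tissue_of: dict[str, str] = {}
    for tissue, n in config.tissues.items():
        for i in range(1, n + 1):
            name = f"{tissue}_{i:02d}"
            lines.append(name)
            tissue_of[name] = tissue
    tissue_labels = pd.Series(tissue_of, name="tissue")
    tissue_labels.index.name = "cell_line"

    epithelial = None
    if config.emt is not None:
        epithelial = pd.Series(
            {
                line: bool(
                    rng.random() < config.emt.epithelial_prob.get(tissue_of[line], 0.5)
                )
                for line in lines
            },
            name="epithelial",
        )

    expression = _simulate_expression(config, lines, tissue_labels, epithelial, rng)

    mutations = pd.DataFrame(
        (rng.random((len(MUTATION_GENES), len(lines))) < config.mutation_rate).astype(int),
        index=pd.Index(MUTATION_GENES, name="gene"),
        columns=lines,
    )

    dep, cond_loss = _true_losses(
        config, lines, tissue_labels, expression, mutations, epithelial, rng
    )
    panel, untreated = _simulate_panel(config, lines, cond_loss, rng)

    crispr_counts = crispr_library = None
    crispr_truth: dict = {}
    if config.crispr is not None:
        crispr_counts, crispr_library, crispr_truth = simulate_crispr_counts(
            config, rng
        )

    truth = {
        "seed": config.seed,
        "tissues": dict(config.tissues),
        "epithelial": None if epithelial is None else {k: bool(v) for k, v in epithelial.items()},
        "true_dependency": {line: {p: float(dep.loc[line, p]) for p in PHENOTYPES} for line in lines},
        "true_condition_loss": {
            line: {c: float(cond_loss.loc[line, c]) for c in TREATMENT_CONDITIONS}
            for line in lines
        },
        "untreated_signal": untreated,
        "dependency_rules": [asdict(r) for r in config.dependency_rules],
        "mutation_rules": [asdict(r) for r in config.mutation_rules],
        "emt": None if config.emt is None else {
            "marker_shift": config.emt.marker_shift,
            "synergy_boost": config.emt.synergy_boost,
            "mesenchymal_xl_boost": config.emt.mesenchymal_xl_boost,
        },
        "crispr": crispr_truth,
    }
    return SyntheticBundle(
        viability_panel=panel,
        expression=expression,
        mutations=mutations,
        tissue_labels=tissue_labels,
        crispr_counts=crispr_counts,
        crispr_library=crispr_library,
        truth=truth,
    )
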