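"""End-to-end orchestration: simulate -> score -> synergy -> biomarkers
-> signatures -> screen, with every intermediate written to disk and a
manifest (inputs, parameters, seed, output hashes) that suffices to
reproduce a run bit-identically with the same package version.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .biomarkers import (
    DEFAULT_ASSOCIATION_DIRECTIONS,
    compare_predictors,
    expression_association,
    find_threshold,
    outlier_analysis,
)
from .conditions import TREATMENT_CONDITIONS
from .io import (
    profiles_to_matrix,
    write_counts,
    write_expression,
    write_mutations,
    write_panel,
    write_profiles,
    write_tissues,
    write_truth,
)
from .screen import score_screen
from .signatures import EPITHELIAL, MESENCHYMAL, pearson, signature_score, tissue_average
from .simulate import SimConfig, simulate_screen
from .synergy import score_synergy
from .viability import build_profiles, profiles_frame

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "score", "synergy", "biomarkers", "signatures", "screen")


@dataclass
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    out_dir: str | Path = "bh3map_run"
    stages: tuple[str, ...] = ALL_STAGES
    synergy_formula: str = "excess"
    single_cutoff: float = 0.25
    synergy_cutoff: float = 0.25
    min_group_size: int = 3
    equal_var: bool = True
    pseudocount: float = 1.0
    seed: int | None = None  # overrides sim.seed when given
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        if self.synergy_formula not in {"excess", "printed"}:
            raise ValueError("synergy_formula must be 'excess' or 'printed'")
        if self.seed is not None:
            self.sim.seed = int(self.seed)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order and return the manifest.

    A stage failure aborts the run with the failing stage named; outputs
    written before the failure stay on disk.  Skipped stages are noted
    in the manifest.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.sim.seed,
        "parameters": {
            "synergy_formula": config.synergy_formula,
            "single_cutoff": config.single_cutoff,
            "synergy_cutoff": config.synergy_cutoff,
            "min_group_size": config.min_group_size,
            "equal_var": config.equal_var,
            "pseudocount": config.pseudocount,
            "replicates": config.sim.replicates,
            "noise_sd_viability": config.sim.noise_sd_viability,
            "tissues": dict(config.sim.tissues),
        },
        "stages_run": [],
        "stages_skipped": [s for s in ALL_STAGES if s not in config.stages],
        "outputs": {},
        "warnings": [],
    }
    summary_lines: list[str] = []

    def _emit(name: str, writer, *args) -> None:
        path = out / name
        writer(*args, path)
        manifest["outputs"][name] = _sha256(path)

    stage = "simulate"
    try:
        t0 = time.perf_counter()
        bundle = simulate_screen(config.sim)
        _emit("panel.tsv", write_panel, bundle.viability_panel)
        _emit("expression.tsv", write_expression, bundle.expression)
        _emit("mutations.tsv", write_mutations, bundle.mutations)
        _emit("tissues.tsv", write_tissues, bundle.tissue_labels)
        if bundle.crispr_counts is not None:
            _emit("crispr_counts.tsv", write_counts, bundle.crispr_counts, bundle.crispr_library)
        _emit("truth.json", write_truth, bundle.truth)
        manifest["stages_run"].append(stage)
        logger.info("simulate: %d lines in %.2fs", config.sim.n_cell_lines, time.perf_counter() - t0)

        profiles = None
        scores = None
        if "score" in config.stages:
            stage = "score"
            profiles = build_profiles(bundle.viability_panel)
            long = profiles_frame(profiles)
            _emit("profiles.tsv", write_profiles, long)
            scores = profiles_to_matrix(long)
            _emit("score_matrix.tsv", lambda df, p: df.to_csv(p, sep="\t"), scores[list(TREATMENT_CONDITIONS)])
            manifest["stages_run"].append(stage)
            summary_lines.append(
                f"{(scores['W539+A121'] > 50).sum()} of {len(scores)} lines sensitive "
                "(>50 points viability loss) to BCL-XL+MCL-1 co-inhibition"
            )

        synergy_df = None
        if "synergy" in config.stages:
            stage = "synergy"
            if profiles is None:
                raise RuntimeError("synergy stage requires the score stage")
            synergy_df = score_synergy(
                profiles,
                formula=config.synergy_formula,
                single_cutoff=config.single_cutoff,
                synergy_cutoff=config.synergy_cutoff,
            )
            _emit("synergy.tsv", lambda df, p: df.to_csv(p, sep="\t", index=False), synergy_df)
            manifest["stages_run"].append(stage)
            counts = synergy_df["group"].value_counts().to_dict()
            summary_lines.append(f"synergy groups: {counts}")

        if "biomarkers" in config.stages and scores is not None:
            stage = "biomarkers"
            comp = compare_predictors(scores, bundle.tissue_labels, bundle.mutations)
            _emit("predictor_comparison.tsv", lambda df, p: df.to_csv(p, sep="\t", index=False), comp)
            assoc = expression_association(scores, bundle.expression)
            _emit("expression_association.tsv", lambda df, p: df.to_csv(p, sep="\t", index=False), assoc)
            thresholds = {}
            for phen, (gene, _sign) in DEFAULT_ASSOCIATION_DIRECTIONS.items():
                if gene not in bundle.expression.index:
                    continue
                shared = scores.index.intersection(bundle.expression.columns)
                res = find_threshold(
                    bundle.expression.loc[gene, shared],
                    scores.loc[shared, phen],
                    min_group_size=config.min_group_size,
                    equal_var=config.equal_var,
                    gene=gene,
                    phenotype=phen,
                )
                thresholds[f"{phen}:{gene}"] = asdict(res)
            _emit("thresholds.json", lambda d, p: Path(p).write_text(json.dumps(d, indent=1, sort_keys=True)), thresholds)
            outliers = outlier_analysis(scores, bundle.expression, bundle.tissue_labels)
            _emit("outliers.tsv", lambda df, p: df.to_csv(p, sep="\t", index=False), outliers)
            manifest["stages_run"].append(stage)
            for key, res in thresholds.items():
                summary_lines.append(
                    f"best cutpoint {key}: {res['threshold']:.3f} log2 "
                    f"({res['direction']}, p={res['p_value']:.2e})"
                )

        if "signatures" in config.stages and synergy_df is not None:
            stage = "signatures"
            epi = signature_score(bundle.expression, EPITHELIAL)
            mes = signature_score(bundle.expression, MESENCHYMAL)
            sig = pd.DataFrame(
                {"epithelial": epi.scores, "mesenchymal": mes.scores}
            )
            _emit("signatures.tsv", lambda df, p: df.to_csv(p, sep="\t", index_label="cell_line"), sig)
            syn = synergy_df.set_index("cell_line")
            shared = sig.index.intersection(syn.index)
            r_syn, p_syn = pearson(sig.loc[shared, "mesenchymal"], syn.loc[shared, "synergy_excess"])
            r_xl, p_xl = pearson(sig.loc[shared, "mesenchymal"], syn.loc[shared, "x_dep"])
            tiss_sig = tissue_average(sig["mesenchymal"], bundle.tissue_labels)
            tiss_syn = tissue_average(syn["synergy_excess"], bundle.tissue_labels)
            corr = {
                "mesenchymal_vs_synergy_excess": {"r": r_syn, "p": p_syn},
                "mesenchymal_vs_bclxl_dependence": {"r": r_xl, "p": p_xl},
            }
            if len(tiss_sig) >= 3:
                corr["tissue_mesenchymal_vs_tissue_synergy"] = dict(
                    zip(("r", "p"), pearson(tiss_sig, tiss_syn.loc[tiss_sig.index]))
                )
            else:
                manifest["warnings"].append(
                    "tissue-level correlation skipped: fewer than 3 tissues"
                )
            _emit("signature_correlations.json", lambda d, p: Path(p).write_text(json.dumps(d, indent=1, sort_keys=True)), corr)
            manifest["stages_run"].append(stage)
            summary_lines.append(
                f"mesenchymal score vs synergy r={r_syn:.2f}, vs BCL-XL dependence r={r_xl:.2f}"
            )

        if "screen" in config.stages and bundle.crispr_counts is not None:
            stage = "screen"
            ct = bundle.truth["crispr"]
            result = score_screen(
                bundle.crispr_counts,
                bundle.crispr_library,
                dmso_samples=ct["dmso_samples"],
                treated_samples=ct["treated_samples"],
                pseudocount=config.pseudocount,
            )
            _emit("screen_dm.tsv", lambda df, p: df.to_csv(p, sep="\t", index=False), result.genes)
            manifest["stages_run"].append(stage)
            top = result.genes.head(5)["gene"].tolist()
            summary_lines.append(f"most depleted screen genes: {top}")

    except Exception as exc:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "summary.txt").write_text("\n".join(summary_lines) + "\n")
    manifest["outputs"]["summary.txt"] = _sha256(out / "summary.txt")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
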