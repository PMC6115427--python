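import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bh3map import normalize_counts, score_screen, sgrna_lfc, three_score
from bh3map.screen import validate_library
from bh3map.simulate import CrisprConfig, SimConfig, simulate_crispr_counts


def _counts(data, samples=("DMSO_1", "TRT_1")):
    return pd.DataFrame(
        data, index=pd.Index([f"sg{i}" for i in range(len(data))], name="sgrna_id"),
        columns=list(samples),
    )


def test_rpm_equal_counts_equal_rpm():
    rpm = normalize_counts(_counts([[100, 50], [100, 50]]))
    assert rpm.iloc[0, 0] == rpm.iloc[1, 0]
    assert rpm["DMSO_1"].sum() == pytest.approx(1e6)


def test_rpm_scale_invariance_at_zero_pseudocount():
    base = _counts([[100, 10], [300, 20], [600, 30]])
    doubled = base * 2
    rpm1 = normalize_counts(base, pseudocount=0)
    rpm2 = normalize_counts(doubled, pseudocount=0)
    pd.testing.assert_frame_equal(rpm1, rpm2)


def test_rpm_arithmetic():
    rpm = normalize_counts(_counts([[0, 1], [999999, 1]]), pseudocount=1)
    assert rpm.iloc[0, 0] == pytest.approx(1 / (1e6 + 2) * 1e6)
    assert rpm.iloc[1, 0] == pytest.approx(1e6 * 1e6 / (1e6 + 2))


def test_rpm_all_zero_sample_errors():
    with pytest.raises(ValueError, match="all-zero"):
        normalize_counts(_counts([[0, 5], [0, 5]]))


def test_lfc_identity_and_quartering():
    rpm = normalize_counts(
        _counts([[400, 400, 100, 100], [400, 400, 400, 400]],
                samples=("DMSO_1", "DMSO_2", "TRT_1", "TRT_2")),
        pseudocount=0,
    )
    lfc = sgrna_lfc(rpm, ["DMSO_1", "DMSO_2"], ["TRT_1", "TRT_2"])
    # library-size renormalisation makes the unchanged construct rise as
    # the depleted one falls; their difference preserves the planted -2
    assert lfc["sg0"] - lfc["sg1"] == pytest.approx(-2.0)
    same = normalize_counts(_counts([[7, 7], [3, 3]]), pseudocount=0)
    assert sgrna_lfc(same, ["DMSO_1"], ["TRT_1"]).to_numpy() == pytest.approx([0, 0])


def test_lfc_mean_then_log_not_mean_of_logs():
    # duplicates (100, 300) vs DMSO (200, 200): mean-then-log gives exactly 0
    rpm = pd.DataFrame(
        {"DMSO_1": [200.0], "DMSO_2": [200.0], "TRT_1": [100.0], "TRT_2": [300.0]},
        index=pd.Index(["sg0"], name="sgrna_id"),
    )
    lfc = sgrna_lfc(rpm, ["DMSO_1", "DMSO_2"], ["TRT_1", "TRT_2"])
    assert lfc["sg0"] == pytest.approx(0.0)
    mean_of_logs = np.mean([np.log2(100 / 200), np.log2(300 / 200)])
    assert lfc["sg0"] != pytest.approx(mean_of_logs)


def test_lfc_missing_sample_errors():
    rpm = normalize_counts(_counts([[1, 1]]))
    with pytest.raises(ValueError, match="missing"):
        sgrna_lfc(rpm, ["DMSO_1"], ["TRT_9"])


@pytest.mark.parametrize(
    "lfcs, expected",
    [
        ([-3, -2, -1, 0, 0], -2.0),
        ([0, 0, 0, 0, 0], 0.0),
        ([5, 4, 3], 4.0),  # no depletion: positive three-score allowed
    ],
)
def test_three_score(lfcs, expected):
    assert three_score(lfcs) == pytest.approx(expected)


def test_three_score_needs_three():
    with pytest.raises(ValueError, match=">= 3"):
        three_score([-1.0, -2.0])


@given(st.lists(st.floats(-5, 5), min_size=3, max_size=8))
@settings(max_examples=100, deadline=None)
def test_three_score_permutation_invariant_and_bounded(lfcs):
    rng = np.random.default_rng(0)
    base = three_score(lfcs)
    assert three_score(rng.permutation(lfcs)) == base
    assert base <= np.mean(lfcs) + 1e-12


def test_three_score_monotone():
    lfcs = [-3.0, -2.0, -1.0, 0.0, 1.0]
    lowered = [-4.0, -2.0, -1.0, 0.0, 1.0]
    assert three_score(lowered) < three_score(lfcs)


def _library(genes, sgrna_per_gene=5, n_controls=0):
    rows = [
        (f"{g}_sg{k}", g, False)
        for g in genes
        for k in range(1, sgrna_per_gene + 1)
    ]
    rows += [(f"CTRL_sg{k}", "CONTROL", True) for k in range(n_controls)]
    return pd.DataFrame(rows, columns=["sgrna_id", "gene", "is_control"])


def test_validate_library_rejects_short_genes():
    lib = _library(["G1"])
    lib = lib.iloc[:2]
    with pytest.raises(ValueError, match="fewer than 3"):
        validate_library(lib)


def test_score_screen_end_to_end_hand_oracle():
    """Single gene, hand-set counts: DM equals manual three-stage arithmetic."""
    lib = _library(["G1"])
    counts = pd.DataFrame(
        {
            "DMSO_1": [100, 100, 100, 100, 100],
            "TRT_1": [25, 50, 100, 200, 100],
        },
        index=pd.Index(lib["sgrna_id"], name="sgrna_id"),
    )
    res = score_screen(counts, lib, ["DMSO_1"], ["TRT_1"], pseudocount=0)
    # manual: RPM divides by column totals (500 vs 475), then log2 ratio
    rpm_d = counts["DMSO_1"] / 500 * 1e6
    rpm_t = counts["TRT_1"] / 475 * 1e6
    lfc = np.log2(rpm_t / rpm_d)
    expected_dm = np.sort(lfc.to_numpy())[:3].mean()
    assert res.genes.loc[0, "dm"] == pytest.approx(expected_dm)
    assert res.genes.loc[0, "gene"] == "G1"


def test_score_screen_sgrna_order_invariance():
    cfg = SimConfig(crispr=CrisprConfig(n_genes=20, n_controls=10), seed=3)
    counts, lib, truth = simulate_crispr_counts(cfg)
    res1 = score_screen(counts, lib, truth["dmso_samples"], truth["treated_samples"])
    perm = np.random.default_rng(1).permutation(len(counts))
    res2 = score_screen(
        counts.iloc[perm], lib.iloc[perm].reset_index(drop=True),
        truth["dmso_samples"], truth["treated_samples"],
    )
    pd.testing.assert_frame_equal(res1.genes, res2.genes)


def test_planted_sensitizers_rank_first():
    cfg = SimConfig(crispr=CrisprConfig(n_genes=100, n_controls=50), seed=17)
    counts, lib, truth = simulate_crispr_counts(cfg)
    res = score_screen(counts, lib, truth["dmso_samples"], truth["treated_samples"])
    top = set(res.genes.head(len(truth["sensitizers"]))["gene"])
    assert top == set(truth["sensitizers"])
    assert res.genes.set_index("gene").loc[truth["sensitizers"], "hit"].all()


def test_control_pseudogenes_center_near_zero():
    """Null screens: control pseudo-gene DM distribution centres at 0."""
    means = []
    for seed in range(10):
        cfg = SimConfig(
            crispr=CrisprConfig(n_genes=50, n_controls=50, sensitizers=()), seed=seed
        )
        counts, lib, truth = simulate_crispr_counts(cfg)
        res = score_screen(counts, lib, truth["dmso_samples"], truth["treated_samples"])
        means.append(res.control_dms.mean())
    assert abs(np.mean(means)) < 0.1
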