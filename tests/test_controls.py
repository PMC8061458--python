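"""Control-metric computation, outcome evaluation and intrinsic dimension."""

import numpy as np
import pandas as pd
import pytest

from methcompass.controls import (
    BACKGROUND,
    ControlMetric,
    ControlMetricRegistry,
    MetricGroup,
    compute_control_metrics,
    evaluate_outcomes,
    load_default_registry,
    outcome_intrinsic_dimension,
)
from methcompass.synthdata import SimScenario, generate_control_signals


def _table(rows):
    return pd.DataFrame(
        rows, columns=["sample_id", "control_type", "address", "channel", "intensity"]
    )


def test_default_registry_has_17_uniquely_named_metrics():
    reg = load_default_registry()
    assert len(reg.metrics) == 17
    assert len(set(reg.names)) == 17


def test_background_ratio_metric():
    """Numerator mean 200 over extension-green background 100 gives 2.0."""
    reg = ControlMetricRegistry(
        [
            ControlMetric(
                "staining green",
                MetricGroup("biotin_staining_high", "green", "mean"),
                BACKGROUND,
                5.0,
            )
        ]
    )
    rows = [
        ("s1", "extension_cg", 0, "green", 100.0),
        ("s1", "extension_at", 0, "green", 100.0),
        ("s1", "biotin_staining_high", 0, "green", 150.0),
        ("s1", "biotin_staining_high", 1, "green", 250.0),
    ]
    res = compute_control_metrics(_table(rows), reg)
    assert res.loc[0, "value"] == pytest.approx(2.0)
    assert res.loc[0, "background"] == pytest.approx(100.0)


def test_zero_denominator_gets_plus_one_offset():
    reg = ControlMetricRegistry(
        [
            ControlMetric(
                "hybridization high/medium",
                MetricGroup("hybridization_high", "green", "mean"),
                MetricGroup("hybridization_medium", "green", "mean"),
                1.0,
            )
        ]
    )
    rows = [
        ("s1", "extension_cg", 0, "green", 100.0),
        ("s1", "hybridization_high", 0, "green", 50.0),
        ("s1", "hybridization_medium", 0, "green", 0.0),
    ]
    res = compute_control_metrics(_table(rows), reg)
    assert res.loc[0, "value"] == pytest.approx(50.0)


def test_metrics_match_brute_force_reaggregation():
    """A random small table agrees with a straightforward per-group oracle."""
    rng = np.random.default_rng(5)
    scenario = SimScenario(
        seed=7,
        tissues=("blood",),
        n_studies=2,
        samples_per_study=(5, 5),
        fail_fraction=0.3,
        n_probes=200,
        n_low_var_probes=5,
        n_tissue_specific_per_tissue=5,
        n_shared_high_probes=10,
        n_age_probes=5,
        n_sex_probes=5,
        n_cell_probes=10,
        n_x_probes=12,
        n_y_probes=10,
    )
    table, _ = generate_control_signals(scenario)
    # perturb intensities so values are not round numbers
    table = table.copy()
    table["intensity"] *= rng.uniform(0.9, 1.1, size=len(table))
    reg = load_default_registry()
    res = compute_control_metrics(table, reg).set_index(["sample_id", "metric"])

    aggs = {"mean": np.mean, "min": np.min, "max": np.max}
    for sample in table["sample_id"].unique()[:4]:
        sub = table[table["sample_id"] == sample]
        bg = sub[
            sub["control_type"].isin(["extension_cg", "extension_at"])
            & (sub["channel"] == "green")
        ]["intensity"].mean()
        for metric in reg.metrics:

            def agg_of(group):
                if group == BACKGROUND:
                    return bg
                vals = sub[
                    (sub["control_type"] == group.control_type)
                    & (sub["channel"] == group.channel)
                ]["intensity"]
                return aggs[group.aggregate](vals)

            num = agg_of(metric.numerator)
            den = agg_of(metric.denominator)
            expected = num / (den if den != 0 else den + 1.0)
            assert res.loc[(sample, metric.name), "value"] == pytest.approx(expected)


def test_metric_values_invariant_to_duplicating_probe_rows():
    scenario = SimScenario(
        seed=3,
        tissues=("blood",),
        n_studies=2,
        samples_per_study=(3, 3),
        n_probes=200,
        n_low_var_probes=5,
        n_tissue_specific_per_tissue=5,
        n_shared_high_probes=10,
        n_age_probes=5,
        n_sex_probes=5,
        n_cell_probes=10,
        n_x_probes=12,
        n_y_probes=10,
    )
    table, _ = generate_control_signals(scenario)
    res1 = compute_control_metrics(table)
    doubled = pd.concat([table, table], ignore_index=True)
    res2 = compute_control_metrics(doubled)
    assert np.allclose(
        res1.sort_values(["sample_id", "metric"])["value"].to_numpy(),
        res2.sort_values(["sample_id", "metric"])["value"].to_numpy(),
    )


def test_missing_control_marked_unavailable_and_fails_conservatively():
    reg = ControlMetricRegistry(
        [
            ControlMetric(
                "specificity II",
                MetricGroup("specificity_II", "red", "min"),
                MetricGroup("specificity_II", "green", "max"),
                1.0,
            )
        ]
    )
    rows = [
        ("s1", "extension_cg", 0, "green", 100.0),
        ("s1", "extension_at", 0, "green", 100.0),
    ]
    with pytest.warns(RuntimeWarning, match="missing control"):
        res = compute_control_metrics(_table(rows), reg)
    assert not res.loc[0, "available"]
    outcomes = evaluate_outcomes(res, reg)
    assert outcomes.loc["s1", "specificity II"] == 0


def test_all_passing_sample_has_all_ones_row(small_scenario):
    table, _ = generate_control_signals(small_scenario)  # fail_fraction 0
    outcomes = evaluate_outcomes(compute_control_metrics(table))
    assert (outcomes.to_numpy() == 1).all()
    assert not outcomes.attrs["any_failure"].any()


def test_single_control_full_fail_fraction():
    scenario = SimScenario(
        seed=5,
        tissues=("blood",),
        n_studies=2,
        samples_per_study=(10, 10),
        fail_fraction={"non-polymorphic green": 1.0},
        n_probes=200,
        n_low_var_probes=5,
        n_tissue_specific_per_tissue=5,
        n_shared_high_probes=10,
        n_age_probes=5,
        n_sex_probes=5,
        n_cell_probes=10,
        n_x_probes=12,
        n_y_probes=10,
    )
    table, _ = generate_control_signals(scenario)
    outcomes = evaluate_outcomes(compute_control_metrics(table))
    assert (outcomes["non-polymorphic green"] == 0).all()
    others = outcomes.drop(columns="non-polymorphic green")
    assert (others.to_numpy() == 1).all()


def test_restoration_threshold_raise_flips_low_ratio_samples():
    """Raising the restoration threshold from 0 to 1 fails values in [0, 1)."""
    scenario = SimScenario(
        seed=9,
        tissues=("blood",),
        n_studies=2,
        samples_per_study=(25, 25),
        fail_fraction={"restoration": 0.5},
        n_probes=200,
        n_low_var_probes=5,
        n_tissue_specific_per_tissue=5,
        n_shared_high_probes=10,
        n_age_probes=5,
        n_sex_probes=5,
        n_cell_probes=10,
        n_x_probes=12,
        n_y_probes=10,
    )
    table, gt = generate_control_signals(scenario)
    reg = load_default_registry()
    metrics = compute_control_metrics(table, reg)
    default = evaluate_outcomes(metrics, reg)
    assert (default["restoration"] == 1).all()  # nonneg ratio never fails 0
    raised = evaluate_outcomes(metrics, reg.with_threshold("restoration", 1.0))
    flipped = raised["restoration"] == 0
    expected = gt.planted_restoration_low.reindex(flipped.index)
    assert (flipped == expected).all()
    values = metrics.set_index(["sample_id", "metric"])["value"]
    for sample in flipped.index[flipped]:
        assert 0 <= values[(sample, "restoration")] < 1


def test_outcome_evaluation_is_idempotent(small_scenario):
    table, _ = generate_control_signals(small_scenario)
    metrics = compute_control_metrics(table)
    o1 = evaluate_outcomes(metrics)
    o2 = evaluate_outcomes(metrics)
    pd.testing.assert_frame_equal(o1, o2)


# --- intrinsic dimension ----------------------------------------------------


def _outcomes_with_informative(n, informative, rng, fail_p=0.3):
    reg = load_default_registry()
    data = np.ones((n, 17), dtype=int)
    for name in informative:
        j = reg.names.index(name)
        data[:, j] = (rng.random(n) > fail_p).astype(int)
    return pd.DataFrame(data, columns=reg.names)


def test_single_varying_control_explains_all_pc1_variance():
    rng = np.random.default_rng(0)
    outcomes = _outcomes_with_informative(200, ["staining green"], rng)
    report = outcome_intrinsic_dimension(outcomes)
    fractions = report["per_component_control_fractions"].iloc[0]
    assert fractions["staining green"] == pytest.approx(1.0, abs=1e-9)
    assert report["majority_subset"] == ["staining green"]


def test_five_planted_informative_controls_recovered():
    rng = np.random.default_rng(1)
    planted = [
        "staining green",
        "staining red",
        "non-polymorphic green",
        "non-polymorphic red",
        "bisulfite conversion I red",
    ]
    outcomes = _outcomes_with_informative(400, planted, rng)
    report = outcome_intrinsic_dimension(outcomes)
    assert sorted(report["majority_subset"]) == sorted(planted)


def test_variance_fractions_invariant_to_sample_permutation():
    rng = np.random.default_rng(2)
    outcomes = _outcomes_with_informative(150, ["extension green", "specificity II"], rng)
    report = outcome_intrinsic_dimension(outcomes)
    perm = outcomes.sample(frac=1.0, random_state=4)
    report_p = outcome_intrinsic_dimension(perm)
    assert np.allclose(
        report["component_variance_fractions"], report_p["component_variance_fractions"]
    )
    pd.testing.assert_frame_equal(
        report["per_component_control_fractions"].abs(),
        report_p["per_component_control_fractions"].abs(),
        atol=1e-8,
        check_exact=False,
    )


def test_constant_outcome_matrix_is_degenerate():
    outcomes = pd.DataFrame(np.ones((10, 17)), columns=load_default_registry().names)
    with pytest.raises(ValueError, match="constant"):
        outcome_intrinsic_dimension(outcomes)
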