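"""Sample filtering, covariate filtering, two-step selection, enrichment."""

from math import ceil

import numpy as np
import pandas as pd
import pytest

from methcompass.varpipe import (
    VarianceFilterConfig,
    covariate_probe_filter,
    filter_low_quality_samples,
    region_enrichment,
    select_low_variance_shared,
    select_tissue_specific,
    two_step_select,
)

CFG = VarianceFilterConfig()


def _matrix(rng, n_probes=1000, n_samples=60, sd=None, means=None):
    means = rng.uniform(0.05, 0.95, n_probes) if means is None else means
    sd = rng.uniform(0.01, 0.08, n_probes) if sd is None else sd
    beta = np.clip(
        means[:, None] + rng.standard_normal((n_probes, n_samples)) * sd[:, None], 0, 1
    )
    return pd.DataFrame(
        beta,
        index=[f"cg{i:05d}" for i in range(n_probes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )


class TestTwoStepSelect:
    def test_matches_brute_force_sort_per_bin_oracle(self):
        rng = np.random.default_rng(0)
        mat = _matrix(rng, n_probes=1000)
        for direction in ("low", "high"):
            got = two_step_select(mat, direction, CFG)
            var = mat.var(axis=1, ddof=1)
            mean = mat.mean(axis=1)
            ids = mat.index.to_numpy()
            # brute force: rank by (variance, id), take ceil(q*n) per scope
            def extreme(mask):
                sub_ids = ids[mask]
                sub_var = var.to_numpy()[mask]
                key = -sub_var if direction == "high" else sub_var
                order = sorted(range(len(sub_ids)), key=lambda i: (key[i], sub_ids[i]))
                k = ceil(CFG.quantile * len(sub_ids))
                return set(sub_ids[order[i]] for i in range(k))

            abs_set = extreme(np.ones(len(ids), dtype=bool))
            bins = np.minimum((mean.to_numpy() / CFG.bin_width).astype(int), 9)
            bin_set = set()
            for b in range(10):
                m = bins == b
                if m.any():
                    bin_set |= extreme(m)
            expected = abs_set & bin_set
            assert set(got.index[got]) == expected

    def test_equal_variances_tie_rule_takes_first_decile_by_probe_id(self):
        beta = pd.DataFrame(
            0.5, index=[f"cg{i:03d}" for i in range(100)], columns=list("abcd")
        )
        beta += np.zeros((100, 4))  # identical variance (zero) everywhere
        got = two_step_select(beta, "low", CFG)
        assert list(got.index[got]) == [f"cg{i:03d}" for i in range(10)]

    def test_low_and_high_selections_disjoint(self):
        rng = np.random.default_rng(1)
        mat = _matrix(rng)
        low = two_step_select(mat, "low", CFG)
        high = two_step_select(mat, "high", CFG)
        assert not (low & high).any()

    def test_binned_step_rescues_mid_mean_probes(self):
        """High-variance probes in a mid-mean bin pass even when boundary-mean
        probes dominate the global variance ranking."""
        rng = np.random.default_rng(2)
        n = 1000
        means = np.concatenate([np.full(500, 0.5), rng.uniform(0, 0.2, 250),
                                rng.uniform(0.8, 1.0, 250)])
        sd = np.concatenate([np.full(500, 0.02), np.full(500, 0.2)])
        planted = np.arange(10)  # mid-mean, locally high variance
        sd[planted] = 0.08
        mat = _matrix(rng, n_probes=n, means=means, sd=sd)
        planted_ids = [f"cg{i:05d}" for i in planted]
        # globally the boundary probes dominate, but within the 0.5 bin the
        # planted probes are the extreme decile of variance
        from methcompass.varpipe import TwoStepVarianceSelector

        sel = TwoStepVarianceSelector("high", CFG).fit(mat.T)
        assert not sel.absolute_mask_[planted_ids].any()
        assert sel.binned_mask_[planted_ids].all()

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(3)
        mat = _matrix(rng, n_probes=300, n_samples=40)
        got = two_step_select(mat, "high", CFG)
        shuffled = mat[list(rng.permutation(mat.columns))]
        assert two_step_select(shuffled, "high", CFG).equals(got)


class TestCovariateFilter:
    def _inputs(self, rng, n=800, n_samples=120):
        mat = _matrix(rng, n_probes=n, n_samples=n_samples)
        cov = pd.DataFrame(
            {
                "age": rng.uniform(1, 90, n_samples),
                "sex": rng.choice(["female", "male"], n_samples),
                "frac_a": 0.0,
                "frac_b": 0.0,
            },
            index=mat.columns,
        )
        fr = rng.dirichlet((5, 3), size=n_samples)
        cov["frac_a"], cov["frac_b"] = fr[:, 0], fr[:, 1]
        return mat, cov

    def test_planted_age_driven_probe_dropped_independent_retained(self):
        rng = np.random.default_rng(4)
        mat, cov = self._inputs(rng)
        # plant a strong age effect on the first 30 probes (~25%+ variance)
        slope = 0.0015
        mat.iloc[:30] = np.clip(
            mat.iloc[:30] + slope * (cov["age"].to_numpy() - 45.0)[None, :], 0, 1
        )
        retained = covariate_probe_filter(mat, cov, CFG)
        assert not retained.iloc[:30].any()
        assert retained.iloc[30:].mean() > 0.95

    def test_constant_covariate_skipped_with_warning(self):
        rng = np.random.default_rng(5)
        mat, cov = self._inputs(rng, n=200, n_samples=40)
        cov["sex"] = "male"
        with pytest.warns(RuntimeWarning, match="constant or aliased"):
            retained = covariate_probe_filter(mat, cov, CFG)
        assert retained.mean() > 0.9

    def test_drop_fraction_in_planted_band(self, small_panel, small_models):
        """With ~12% of probes planted as covariate-driven, the per-tissue
        drop fraction lands inside the 8-40% range the filter is built for."""
        panel, gt = small_panel
        _, _, annotation = small_models
        autosomal = annotation.index[
            (annotation["probe_type"] == "cg")
            & ~annotation["chrom"].isin(["chrX", "chrY"])
        ]
        tissue = "blood"
        ids = panel.tissue_samples(tissue)
        mat = panel.betas.loc[autosomal, ids]
        cov = panel.samples.loc[
            ids, ["age", "sex", "neutrophil", "lymphocyte", "monocyte"]
        ]
        retained = covariate_probe_filter(mat, cov, CFG)
        frac = (~retained).mean()
        assert 0.08 <= frac <= 0.40


class TestSampleFilter:
    def _panel(self, rng, n_samples=40):
        from methcompass.containers import TissueBetaPanel

        n_probes = 50
        betas = pd.DataFrame(
            rng.uniform(0.2, 0.8, size=(n_probes, n_samples)),
            index=[f"cg{i:04d}" for i in range(n_probes - 10)]
            + [f"rs{i:04d}" for i in range(10)],
            columns=[f"s{j}" for j in range(n_samples)],
        )
        genotypes = rng.choice([0.05, 0.5, 0.95], size=(10, n_samples))
        betas.iloc[-10:] = genotypes
        samples = pd.DataFrame(
            {
                "tissue": ["blood"] * n_samples,
                "study": ["A"] * (n_samples // 2) + ["B"] * (n_samples - n_samples // 2),
            },
            index=betas.columns,
        )
        return TissueBetaPanel(betas=betas, samples=samples)

    def _qc(self, rng, samples, low=(), ctrl=()):
        summ = pd.DataFrame(
            {
                "log2_median_meth": rng.normal(12, 0.1, len(samples)),
                "log2_median_unmeth": rng.normal(12, 0.1, len(samples)),
            },
            index=samples,
        )
        for s in low:
            summ.loc[s] = (9.0, 9.0)
        out = pd.DataFrame(1, index=samples, columns=[f"c{i}" for i in range(17)])
        for s in ctrl:
            out.loc[s, "c3"] = 0
        return summ, out

    def test_control_failure_removed_with_reason(self):
        rng = np.random.default_rng(6)
        panel = self._panel(rng)
        summ, out = self._qc(rng, panel.samples.index, ctrl=["s0"])
        filtered, log = filter_low_quality_samples(panel, summ, out)
        assert "s0" not in filtered.samples.index
        assert log.set_index("sample_id").loc["s0", "reason"] == "failed BeadArray control"

    def test_low_on_one_channel_only_retained(self):
        rng = np.random.default_rng(7)
        panel = self._panel(rng)
        summ, out = self._qc(rng, panel.samples.index)
        summ.loc["s1", "log2_median_meth"] = 9.0  # unmeth stays high
        filtered, _ = filter_low_quality_samples(panel, summ, out)
        assert "s1" in filtered.samples.index

    def test_planted_low_signal_samples_removed_exactly(self):
        rng = np.random.default_rng(8)
        panel = self._panel(rng, n_samples=60)
        low = ["s2", "s30"]
        summ, out = self._qc(rng, panel.samples.index, low=low)
        filtered, log = filter_low_quality_samples(panel, summ, out)
        removed_low = set(log[log["reason"].str.contains("percentile")]["sample_id"])
        assert removed_low == set(low)

    def test_replicates_keep_first_sample_only(self):
        rng = np.random.default_rng(9)
        panel = self._panel(rng)
        panel.betas.iloc[-10:, 5] = panel.betas.iloc[-10:, 3]  # s5 duplicates s3
        summ, out = self._qc(rng, panel.samples.index)
        filtered, log = filter_low_quality_samples(panel, summ, out)
        assert "s3" in filtered.samples.index
        assert "s5" not in filtered.samples.index
        assert "replicate of s3" in log["reason"].to_list()


class TestCrossTissueSelections:
    def _tissues(self, rng, n_probes=2000, low_ids=range(8)):
        per_tissue = {}
        means = rng.uniform(0.02, 0.92, n_probes)
        sd = rng.uniform(0.02, 0.08, n_probes)
        low_ids = list(low_ids)
        means[low_ids] = rng.uniform(0.01, 0.03, len(low_ids))
        sd[low_ids] = 0.002
        # every background probe gets a deterministic cross-tissue spread of
        # 0.06 so only the planted probes truly satisfy the mean-range rule
        for t, offset in (("t1", -0.03), ("t2", 0.0), ("t3", 0.03)):
            shift = np.full(n_probes, offset)
            shift[low_ids] = 0.0
            per_tissue[t] = _matrix(
                rng, n_probes=n_probes, n_samples=80, means=means + shift, sd=sd
            )
        return per_tissue, [f"cg{i:05d}" for i in low_ids]

    def test_planted_shared_low_recovered(self):
        rng = np.random.default_rng(10)
        per_tissue, low_ids = self._tissues(rng)
        table = select_low_variance_shared(per_tissue, CFG)
        selected = set(table.index[table["selected"]])
        planted = set(low_ids)
        assert len(selected & planted) / len(planted) >= 0.9
        assert len(selected & planted) / max(len(selected), 1) >= 0.9

    def test_low_in_six_of_seven_tissues_excluded(self):
        rng = np.random.default_rng(11)
        per_tissue, low_ids = self._tissues(rng)
        # make the planted probes noisy in one tissue only
        noisy = per_tissue["t3"].copy()
        noisy.loc[low_ids] = np.clip(
            0.3 + rng.standard_normal((len(low_ids), noisy.shape[1])) * 0.1, 0, 1
        )
        per_tissue["t3"] = noisy
        table = select_low_variance_shared(per_tissue, CFG)
        assert not table.loc[low_ids, "selected"].any()

    def test_mean_range_above_cut_excluded_despite_low_variance(self):
        rng = np.random.default_rng(12)
        per_tissue, low_ids = self._tissues(rng)
        shifted = per_tissue["t2"].copy()
        shifted.loc[low_ids[0]] += 0.02  # range 0.02 > 0.01
        per_tissue["t2"] = shifted
        table = select_low_variance_shared(per_tissue, CFG)
        assert not table.loc[low_ids[0], "selected"]
        assert table.loc[low_ids[0], "low_everywhere"]

    def test_tissue_specific_exclusive_and_topk(self):
        rng = np.random.default_rng(13)
        n = 600
        per_tissue = {}
        base_means = rng.uniform(0.3, 0.7, n)
        base_sd = rng.uniform(0.01, 0.04, n)
        for t in ("t1", "t2", "t3"):
            sd = base_sd.copy()
            if t == "t1":
                sd[:30] = 0.25  # t1-specific block
                sd[30:40] = 0.20  # shared with t2
            if t == "t2":
                sd[30:40] = 0.20
            per_tissue[t] = _matrix(rng, n_probes=n, n_samples=80, means=base_means, sd=sd)
        cfg = VarianceFilterConfig(top_k_per_tissue=20)
        with pytest.warns(RuntimeWarning):
            out = select_tissue_specific(per_tissue, cfg)
        t1_ids = set(out["t1"].index)
        shared = {f"cg{i:05d}" for i in range(30, 40)}
        assert not t1_ids & shared  # two-tissue probes in neither set
        assert not set(out["t2"].index) & shared
        assert len(out["t1"]) == 20  # top_k truncation by descending variance
        assert out["t1"]["variance"].is_monotonic_decreasing


class TestRegionEnrichment:
    def _annotation(self, rng, n=5000):
        return pd.DataFrame(
            {
                "island_relation": rng.choice(
                    ["island", "shore", "shelf", "open sea"], n, p=(0.3, 0.23, 0.1, 0.37)
                ),
                "gene_relation": rng.choice(
                    ["promoter", "body", "intergenic"], n, p=(0.3, 0.4, 0.3)
                ),
            },
            index=pd.Index([f"cg{i:05d}" for i in range(n)]),
        )

    def test_uniform_selection_yields_no_significant_classes(self):
        rng = np.random.default_rng(14)
        ann = self._annotation(rng)
        sel = rng.choice(ann.index, 2000, replace=False)
        table = region_enrichment(sel, ann, ann.index)
        assert not table["significant"].any()

    def test_planted_island_selection_enriched(self):
        rng = np.random.default_rng(15)
        ann = self._annotation(rng)
        islands = ann.index[ann["island_relation"] == "island"]
        others = ann.index[ann["island_relation"] != "island"]
        sel = np.concatenate(
            [rng.choice(islands, 900, replace=False), rng.choice(others, 100, replace=False)]
        )
        table = region_enrichment(sel, ann, ann.index)
        row = table.loc[("island_relation", "island")]
        assert row["significant"] and row["direction"] == "enriched"

    def test_background_equal_to_selection_no_enrichment(self):
        rng = np.random.default_rng(16)
        ann = self._annotation(rng)
        sel = rng.choice(ann.index, 500, replace=False)
        table = region_enrichment(sel, ann, sel)
        assert np.allclose(table["selection_fraction"], table["background_fraction"])
        assert not table["significant"].any()

    def test_empty_selection_raises(self):
        rng = np.random.default_rng(17)
        ann = self._annotation(rng, n=100)
        with pytest.raises(ValueError):
            region_enrichment([], ann, ann.index)
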