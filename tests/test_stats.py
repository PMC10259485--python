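"""Transfer statistics against worked examples and independent oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import transferome as tf
from transferome.config import SimulationParams
from transferome.errors import TransferomeError
from transferome.stats import TransferParams, detect_transferred

from oracles import (
    bky_two_stage_rejections,
    hypergeometric_tail_enumeration,
    hypergeometric_tail_sum,
    permutation_one_sided_p,
)


class TestCorrectedForeignProportion:
    def test_study_replicate_percentages(self):
        """The printed replicate percentages give 0.075% / 0.495%, ratio 6.6."""
        corr = tf.corrected_foreign_proportion(
            [1.11, 1.15], [1.71, 1.39], [1.04, 1.07]
        )
        assert corr.corrected_mix == pytest.approx(0.075)
        assert corr.corrected_coculture == pytest.approx(0.495)
        assert corr.ratio == pytest.approx(6.6)

    def test_all_equal_inputs_zero_corrected_undefined_ratio(self):
        corr = tf.corrected_foreign_proportion([1.0, 1.0], [1.0], [1.0, 1.0])
        assert corr.corrected_mix == 0.0
        assert corr.corrected_coculture == 0.0
        assert math.isnan(corr.ratio)
        assert "undefined" in corr.note

    def test_zero_background_returns_raw_means(self):
        corr = tf.corrected_foreign_proportion([1.0, 2.0], [3.0, 5.0], [0.0])
        assert corr.corrected_mix == 1.5
        assert corr.corrected_coculture == 4.0

    @settings(max_examples=50, deadline=None)
    @given(
        mix=st.lists(st.floats(0, 10), min_size=2, max_size=4),
        co=st.lists(st.floats(0, 10), min_size=2, max_size=4),
        single=st.lists(st.floats(0, 10), min_size=2, max_size=4),
        shift=st.floats(0, 5),
    )
    def test_invariance_to_order_and_common_shift(self, mix, co, single, shift):
        base = tf.corrected_foreign_proportion(mix, co, single)
        perm = tf.corrected_foreign_proportion(mix[::-1], co[::-1], single[::-1])
        shifted = tf.corrected_foreign_proportion(
            [v + shift for v in mix], [v + shift for v in co],
            [v + shift for v in single],
        )
        assert perm.corrected_mix == pytest.approx(base.corrected_mix)
        assert shifted.corrected_mix == pytest.approx(base.corrected_mix, abs=1e-9)
        assert shifted.corrected_coculture == pytest.approx(
            base.corrected_coculture, abs=1e-9
        )


class TestOneTailedT:
    def test_no_signal_convention_p_one(self):
        t, p = tf.one_tailed_unpaired_t([10, 10], [10, 10])
        assert p == 1.0

    def test_strong_separation_significant_and_extreme_under_permutation(self):
        t, p = tf.one_tailed_unpaired_t([100, 110], [1, 2])
        assert p < 0.05
        # the observed labeling is the most extreme of the 6 relabelings
        assert permutation_one_sided_p([100, 110], [1, 2]) == pytest.approx(1 / 6)

    def test_swapped_inputs_with_negated_alternative_identical_p(self):
        from scipy import stats as sps

        co, mix = [3.0, 5.0, 4.0], [1.0, 2.0, 2.5]
        _, p = tf.one_tailed_unpaired_t(co, mix)
        _, p_swap = sps.ttest_ind(mix, co, equal_var=True, alternative="less")
        assert p == pytest.approx(p_swap)

    def test_rank_agreement_with_permutation_oracle(self, rng):
        from scipy.stats import spearmanr

        t_ps, perm_ps = [], []
        for _ in range(40):
            co = rng.normal(rng.uniform(0, 2), 1.0, size=3)
            mix = rng.normal(0, 1.0, size=3)
            t_ps.append(tf.one_tailed_unpaired_t(co, mix)[1])
            perm_ps.append(permutation_one_sided_p(co, mix))
        rho = spearmanr(t_ps, perm_ps).statistic
        assert rho > 0.9

    def test_requires_two_values_per_group(self):
        with pytest.raises(TransferomeError):
            tf.one_tailed_unpaired_t([1.0], [2.0, 3.0])


class TestBky:
    def test_all_p_one_no_discoveries(self):
        q, rej = tf.bky_adjust(np.ones(10), 0.05)
        assert not rej.any()

    def test_single_p_below_alpha_discovered(self):
        q, rej = tf.bky_adjust([0.025], 0.05)
        assert rej.tolist() == [True]

    def test_empty_input_empty_output(self):
        q, rej = tf.bky_adjust([], 0.05)
        assert q.size == 0 and rej.size == 0

    def test_oracle_equivalence_random_vectors(self, rng):
        """Discovery set equals the literal two-stage transcription and the
        statsmodels two-stage implementation on random p-vectors."""
        from statsmodels.stats.multitest import multipletests

        for _ in range(100):
            m = int(rng.integers(1, 250))
            p = rng.random(m)
            k = int(rng.integers(0, m + 1))
            p[:k] = p[:k] * 1e-3
            alpha = float(rng.choice([0.01, 0.05, 0.1]))
            _, rej = tf.bky_adjust(p, alpha)
            assert (rej == bky_two_stage_rejections(p, alpha)).all()
            sm_rej = multipletests(p, alpha=alpha, method="fdr_tsbky")[0]
            assert (rej == sm_rej).all()

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_q_monotone_in_ranked_p(self, p):
        q, _ = tf.bky_adjust(p, 0.05)
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_q_matches_discovery_set(self, rng):
        p = rng.random(80) * rng.choice([1, 1e-3], size=80)
        for alpha in (0.01, 0.05, 0.2):
            q, rej = tf.bky_adjust(p, alpha)
            assert ((q <= alpha) == rej).all()


def _rpm_frame(co, mix, genes=None):
    genes = genes or [f"g{i}" for i in range(len(co))]
    co = np.atleast_2d(np.asarray(co, float).reshape(len(genes), -1))
    mix = np.atleast_2d(np.asarray(mix, float).reshape(len(genes), -1))
    cols = {}
    for r in range(co.shape[1]):
        cols[f"coculture_r{r+1}"] = co[:, r]
    for r in range(mix.shape[1]):
        cols[f"mix_r{r+1}"] = mix[:, r]
    return pd.DataFrame(cols, index=pd.Index(genes, name="gene"))


def _design_for(frame):
    rows = []
    for s in frame.columns:
        cond, rep = s.rsplit("_r", 1)
        rows.append({"sample": s, "condition": cond, "replicate": int(rep),
                     "enriched_species": "mouse", "library_size": 10_000})
    return pd.DataFrame(rows)


class TestDetectTransferred:
    def test_single_transferred_gene_detected(self):
        params = SimulationParams(n_genes=50, library_size=100_000,
                                  contamination_fraction=0.0, hop_rate=0.01)
        # put the transfer on the most strongly expressed donor gene
        # (the expression draw is deterministic in the seed)
        from transferome.simulate import build_truth

        expr = build_truth(params, None, seed=71).expression_donor
        gene = expr.idxmax()
        f = np.where(expr.index == gene, 0.05, 0.0)
        counts, truth = tf.simulate_count_matrix(params, seed=71,
                                                 transfer_fraction=f)
        rpm = tf.rpm_normalize(counts, truth.design.set_index("sample")["library_size"])
        fr = tf.foreign_rpm(rpm, truth.design, "human")
        table = detect_transferred(fr, truth.design)
        assert table.loc[gene, "robust"]
        false_calls = table["robust"].sum() - 1
        assert false_calls <= 2

    def test_all_zero_foreign_counts_empty_robust_set(self):
        frame = _rpm_frame(np.zeros((5, 2)), np.zeros((5, 2)))
        table = detect_transferred(frame, _design_for(frame))
        assert not table["robust"].any()

    def test_fc_threshold_one_admits_superset_of_two(self, rng):
        co = rng.gamma(2, 50, size=(40, 2))
        mix = rng.gamma(2, 20, size=(40, 2))
        frame = _rpm_frame(co, mix)
        design = _design_for(frame)
        robust1 = detect_transferred(frame, design, fc_threshold=1.0)["robust"]
        robust2 = detect_transferred(frame, design, fc_threshold=2.0)["robust"]
        assert (robust2 <= robust1).all()

    def test_prefilter_requires_min_rpm_in_all_coculture_replicates(self):
        frame = _rpm_frame(np.array([[100.0, 9.0], [100.0, 90.0]]),
                           np.array([[1.0, 1.0], [1.0, 1.0]]))
        table = detect_transferred(frame, _design_for(frame), min_rpm=10.0)
        assert not table.loc["g0", "prefilter_pass"]
        assert table.loc["g1", "prefilter_pass"]

    def test_zero_mix_mean_reports_infinite_fold_change(self):
        frame = _rpm_frame(np.array([[50.0, 60.0]]), np.array([[0.0, 0.0]]))
        table = detect_transferred(frame, _design_for(frame))
        assert np.isinf(table.loc["g0", "fold_change"])


class TestPercentTransfer:
    def test_printed_formula_arithmetic(self):
        result = tf.percent_transfer(2.0, 1.0, 100.0, fc_threshold=2.0,
                                     coculture_rpm_min=0.0)
        assert result.value == pytest.approx(1.0)

    def test_low_single_expression_filtered(self):
        result = tf.percent_transfer(20.0, 1.0, 50.0)
        assert result.value is None
        assert "low_single_expression" in result.filtered

    def test_low_coculture_and_low_fc_filters(self):
        r = tf.percent_transfer(5.0, 1.0, 200.0)
        assert "low_coculture_signal" in r.filtered
        r = tf.percent_transfer(30.0, 20.0, 200.0)
        assert r.filtered == ("low_fc",)

    def test_co_equal_mix_gives_zero(self):
        r = tf.percent_transfer(50.0, 50.0, 100.0, fc_threshold=1.0)
        assert r.value == 0.0

    def test_zero_single_rpm_undefined(self):
        r = tf.percent_transfer(50.0, 1.0, 0.0, single_rpm_min=0.0)
        assert r.value is None
        assert r.filtered == ("undefined_zero_single",)

    def test_monotone_in_coculture_rpm(self):
        """Raising co-culture RPM never decreases percent transfer."""
        lo = tf.percent_transfer(120.0, 10.0, 500.0)
        hi = tf.percent_transfer(180.0, 10.0, 500.0)
        assert hi.value > lo.value


class TestTransferRecovery:
    @staticmethod
    def _estimate(f_true, library_size, seed):
        """Median percent transfer over truth-selected strong genes."""
        params = SimulationParams(n_genes=60, library_size=library_size,
                                  transfer_fraction=f_true)
        counts, truth = tf.simulate_count_matrix(params, seed=seed)
        design = truth.design
        rpm = tf.rpm_normalize(counts, design.set_index("sample")["library_size"])
        fr = tf.foreign_rpm(rpm, design, "human")
        single = tf.donor_single_rpm(rpm, design, "human")
        co_cols = [s for s in fr.columns if s.startswith("coculture")]
        mix_cols = [s for s in fr.columns if s.startswith("mix")]
        exp_co = truth.expected_rpm("coculture_r1").loc["human"]
        strong = exp_co[exp_co >= 30].index
        vals = [
            tf.percent_transfer(
                fr.loc[g, co_cols].mean(), fr.loc[g, mix_cols].mean(),
                single.loc[g], fc_threshold=0.0, single_rpm_min=0.0,
                coculture_rpm_min=0.0,
            ).value
            for g in strong
        ]
        return float(np.median(vals))

    def test_bias_shrinks_with_library_size(self):
        """Percent transfer estimates f x 100 with bias -> 0 as the
        library grows (three library sizes, fixed seeds)."""
        f_true = 0.01
        biases = {}
        for lib in (20_000, 100_000, 500_000):
            ests = [self._estimate(f_true, lib, seed) for seed in range(5)]
            biases[lib] = abs(np.mean(ests) - 100 * f_true)
        assert biases[500_000] < 0.1 * (100 * f_true)
        assert biases[500_000] <= biases[20_000] + 0.02


class TestMonotonicity:
    def test_additive_coculture_increase_never_shrinks_results(self, rng):
        """Raising every co-culture RPM leaves no percent transfer lower
        and no robust gene dropped."""
        co = rng.gamma(2, 40, size=(30, 2))
        mix = rng.gamma(2, 10, size=(30, 2))
        frame = _rpm_frame(co, mix)
        design = _design_for(frame)
        single = pd.Series(500.0, index=frame.index)
        base = tf.build_transfer_table(frame, single, design)
        bumped_frame = frame.copy()
        co_cols = [c for c in frame.columns if c.startswith("coculture")]
        bumped_frame[co_cols] = bumped_frame[co_cols] + 25.0
        bumped = tf.build_transfer_table(bumped_frame, single, design)
        assert (base["robust"] <= bumped["robust"]).all()
        both = base["percent_transfer"].notna() & bumped["percent_transfer"].notna()
        assert (
            bumped.loc[both, "percent_transfer"]
            >= base.loc[both, "percent_transfer"] - 1e-9
        ).all()
        assert base["percent_transfer"].notna().sum() <= bumped[
            "percent_transfer"
        ].notna().sum()


class TestMedianPercentTransfer:
    def _table(self, values):
        return pd.DataFrame({"percent_transfer": values})

    def test_median_of_three(self):
        out = tf.median_percent_transfer(self._table([0.1, 0.3, 0.5]))
        assert out["median"] == pytest.approx(0.3)
        assert out["log10_median"] == pytest.approx(math.log10(0.3))

    def test_single_unfiltered_gene(self):
        out = tf.median_percent_transfer(self._table([0.7, np.nan]))
        assert out["median"] == pytest.approx(0.7)
        assert out["n_genes"] == 1

    def test_all_filtered_is_error(self):
        with pytest.raises(TransferomeError):
            tf.median_percent_transfer(self._table([np.nan, np.nan]))


class TestSpotPercentTransfer:
    def test_low_expression_example(self):
        out = tf.spot_percent_transfer(7, 429)
        assert out["percent_2sf"] == pytest.approx(1.6)
        assert out["percent"] == pytest.approx(100 * 7 / 429)

    def test_high_expression_example(self):
        out = tf.spot_percent_transfer(25, 1250)
        assert out["percent_2sf"] == pytest.approx(2.0)

    def test_zero_acceptor_spots(self):
        assert tf.spot_percent_transfer(0, 100)["percent"] == 0.0

    def test_zero_donor_mean_rejected(self):
        with pytest.raises(TransferomeError):
            tf.spot_percent_transfer(5, 0)


class TestExpressionDependence:
    def test_perfect_linearity(self):
        x = np.array([1.0, 2.0, 5.0, 10.0, 20.0])
        out = tf.expression_dependence(0.01 * x, x, log_transform=False)
        assert out["pearson"] == pytest.approx(1.0)
        assert out["spearman"] == pytest.approx(1.0)
        assert out["slope"] == pytest.approx(0.01)

    def test_reversed_ranks_spearman_minus_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([9.0, 7.0, 4.0, 2.0])
        out = tf.expression_dependence(y, x, log_transform=False)
        assert out["spearman"] == pytest.approx(-1.0)

    def test_constant_x_rejected(self):
        with pytest.raises(TransferomeError):
            tf.expression_dependence([1, 2, 3], [5, 5, 5], log_transform=False)

    def test_ci_band_contains_fit_and_widens_at_extremes(self, rng):
        x = rng.uniform(0, 4, size=50)
        y = 0.8 * x + rng.normal(0, 0.3, size=50)
        out = tf.expression_dependence(10**y, 10**x, log_transform=True)
        assert (out["ci_low"] <= out["fitted"]).all()
        assert (out["ci_high"] >= out["fitted"]).all()
        half = out["ci_high"] - out["ci_low"]
        mid = np.argmin(np.abs(out["x"] - out["x"].mean()))
        assert half[np.argmax(out["x"])] > half[mid]

    def test_expression_proportional_transfer_recovered(self, rng):
        """NB-noised transfer proportional to expression: log-scale Pearson
        above 0.9, as in the expression-dependence regime of the study."""
        expr = 10 ** rng.uniform(1, 5, size=300)
        mu = 0.005 * expr
        n = 1 / 0.05
        y = rng.negative_binomial(n, n / (n + mu))
        out = tf.expression_dependence(y, expr, log_transform=True)
        assert out["pearson"] > 0.9
        assert out["spearman"] > 0.9


class TestFitLogGaussian:
    def test_identical_vectors(self):
        v = np.array([1.0, 10.0, 100.0, 1000.0])
        out = tf.fit_log_gaussian(v, v)
        assert out["coculture"] == out["mix"]
        assert out["shift"]["p_value"] > 0.99

    def test_tenfold_scaling_shifts_log_mean_by_one(self):
        v = np.array([5.0, 50.0, 500.0, 5000.0]) * 2
        out = tf.fit_log_gaussian(v * 10, v, pseudocount=1e-9)
        assert out["shift"]["delta_log10"] == pytest.approx(1.0, abs=1e-6)

    def test_lognormal_parameter_recovery(self, rng):
        mu, sigma, n = 1.0, 0.5, 2000
        v = 10 ** rng.normal(mu, sigma, size=n)
        out = tf.fit_log_gaussian(v, v, pseudocount=1e-9)
        se_mu = sigma / math.sqrt(n)
        se_sd = sigma / math.sqrt(2 * n)
        assert abs(out["coculture"]["mean"] - mu) < 3 * se_mu
        assert abs(out["coculture"]["sd"] - sigma) < 4 * se_sd

    def test_too_few_positive_entries_rejected(self):
        with pytest.raises(TransferomeError):
            tf.fit_log_gaussian([1.0, 2.0, 0.0], [1.0, 2.0, 3.0])


class TestHypergeometricOverlap:
    def test_enumeration_example(self):
        out = tf.hypergeometric_overlap(10, range(4), range(5))
        expected = hypergeometric_tail_enumeration(10, 4, 5, 4)
        assert out["overlap"] == 4
        assert out["p_value"] == pytest.approx(expected)

    def test_partial_overlap_against_enumeration(self):
        a = {0, 1, 2, 3}
        b = {2, 3, 4, 5, 6}
        out = tf.hypergeometric_overlap(10, a, b)
        assert out["overlap"] == 2
        assert out["p_value"] == pytest.approx(
            hypergeometric_tail_enumeration(10, 4, 5, 2)
        )

    def test_disjoint_sets_p_one(self):
        out = tf.hypergeometric_overlap(20, {1, 2}, {3, 4})
        assert out["p_value"] == pytest.approx(1.0)

    def test_identical_sets_minimal_tail(self):
        out = tf.hypergeometric_overlap(12, {1, 2, 3}, {1, 2, 3})
        assert out["p_value"] == pytest.approx(
            hypergeometric_tail_sum(12, 3, 3, 3)
        )

    def test_element_outside_universe_rejected(self):
        with pytest.raises(TransferomeError):
            tf.hypergeometric_overlap_sets({1, 2, 3}, {1, 9}, {2})

    def test_random_instances_match_coefficient_sum(self, rng):
        for _ in range(100):
            m = int(rng.integers(5, 60))
            ka = int(rng.integers(1, m + 1))
            kb = int(rng.integers(1, m + 1))
            a = set(rng.choice(m, size=ka, replace=False).tolist())
            b = set(rng.choice(m, size=kb, replace=False).tolist())
            out = tf.hypergeometric_overlap(m, a, b)
            assert out["p_value"] == pytest.approx(
                hypergeometric_tail_sum(m, ka, kb, out["overlap"]), rel=1e-9
            )


class TestFilterDeGenes:
    def _table(self, rows):
        return pd.DataFrame(
            rows, columns=["gene", "log2fc", "padj", "s1", "s2", "s3", "s4"]
        )

    def test_strict_lfc_threshold_excludes(self):
        up, down = tf.filter_de_genes(
            self._table([("g", 0.99, 0.001, 60, 60, 60, 60)])
        )
        assert up == set() and down == set()

    def test_two_samples_at_fifty_counts_included(self):
        up, _ = tf.filter_de_genes(self._table([("g", 2.0, 0.01, 60, 55, 0, 0)]))
        assert up == {"g"}

    def test_count_rule_excludes_regardless_of_fc(self):
        up, down = tf.filter_de_genes(
            self._table([("g", 5.0, 1e-8, 49, 49, 49, 49)])
        )
        assert up == set() and down == set()

    def test_downregulated_mirror(self):
        _, down = tf.filter_de_genes(self._table([("g", -1.5, 0.01, 60, 60, 0, 0)]))
        assert down == {"g"}

    def test_missing_column_rejected(self):
        with pytest.raises(TransferomeError):
            tf.filter_de_genes(pd.DataFrame({"gene": ["g"], "padj": [0.1]}))
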