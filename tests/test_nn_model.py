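"""Design matrix, weighted fit, prediction, and parameter bookkeeping."""

import logging
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pnathermo as pt
from pnathermo.nn_model import TERM_ORDER

from conftest import brute_force_wls

seq_text = st.text(alphabet="ACGT", min_size=2, max_size=18)


def _col(term):
    return TERM_ORDER.index(term)


class TestDesignMatrix:
    def test_cgatcg_row(self):
        row = pt.build_design_matrix([pt.describe_duplex("CGATCG")])[0]
        assert row[_col("CG")] == 2 and row[_col("GA")] == 2 and row[_col("AT")] == 1
        assert row[_col("Init")] == 1 and row[_col("T.GC")] == 1

    def test_aacgtt_row_has_no_terminal_gc(self):
        row = pt.build_design_matrix([pt.describe_duplex("AACGTT")])[0]
        assert row[_col("AA")] == 2 and row[_col("AC")] == 2 and row[_col("CG")] == 1
        assert row[_col("T.GC")] == 0

    def test_single_gc_terminus_gives_zero_indicator(self):
        row = pt.build_design_matrix([pt.describe_duplex("GTAGATCACT")])[0]
        assert row[_col("T.GC")] == 0

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(seq_text, min_size=1, max_size=8))
    def test_row_sums_and_init_column(self, seqs):
        descs = [pt.describe_duplex(s) for s in seqs]
        m = pt.build_design_matrix(descs)
        assert np.all(m[:, _col("Init")] == 1)
        np.testing.assert_array_equal(
            m[:, :10].sum(axis=1), [len(s) - 1 for s in seqs]
        )


def _synthetic_obs(n, seed, noise_sd, truth):
    cfg = pt.GeneratorConfig(seed=seed, n_sequences=n, noise_sd_enthalpy=noise_sd)
    return pt.generate_observations(pt.generate_sequences(cfg), truth, cfg)


class TestFit:
    def test_noise_free_recovery_is_exact(self, ref_params):
        obs = _synthetic_obs(49, seed=3, noise_sd=0.0, truth=ref_params)
        fitted = pt.fit_nn(obs, weighting="unweighted")
        np.testing.assert_allclose(fitted.vector, ref_params.vector, rtol=1e-8)

    def test_uniform_weights_equal_unweighted(self, ref_params):
        obs = _synthetic_obs(20, seed=4, noise_sd=1.0, truth=ref_params)
        same_se = pt.ObservationSet(
            tuple((d, v, 0.5) for d, v, _ in obs.entries), obs.observable_kind
        )
        w = pt.fit_nn(same_se, weighting="reciprocal_se")
        u = pt.fit_nn(same_se, weighting="unweighted")
        np.testing.assert_allclose(w.vector, u.vector, rtol=1e-10)

    def test_zero_se_clamped_with_warning(self, ref_params, caplog):
        obs = _synthetic_obs(20, seed=5, noise_sd=1.0, truth=ref_params)
        entries = list(obs.entries)
        d, v, _ = entries[0]
        entries[0] = (d, v, 0.0)
        with caplog.at_level(logging.WARNING, logger="pnathermo.nn_model"):
            pt.fit_nn(pt.ObservationSet(tuple(entries)), weighting="reciprocal_se")
        assert any("clamped" in r.message for r in caplog.records)

    def test_too_few_observations(self, ref_params):
        obs = _synthetic_obs(5, seed=6, noise_sd=0.0, truth=ref_params)
        with pytest.raises(ValueError, match="at least 12"):
            pt.fit_nn(obs)

    def test_rank_deficiency_names_columns(self, ref_params):
        d = pt.describe_duplex("CGATCG")
        obs = pt.ObservationSet(tuple((d, -53.4, 1.0) for _ in range(15)))
        with pytest.raises(ValueError, match="unidentifiable"):
            pt.fit_nn(obs, weighting="unweighted")

    @pytest.mark.parametrize("weighting", ["unweighted", "reciprocal_se"])
    def test_matches_normal_equations_oracle(self, ref_params, weighting):
        """Production solver vs explicit (S'WS)^-1 S'W chi on small N."""
        rng = np.random.default_rng(11)
        obs = _synthetic_obs(20, seed=7, noise_sd=1.0, truth=ref_params)
        if weighting == "reciprocal_se":
            entries = tuple(
                (d, v, float(rng.uniform(0.3, 2.0))) for d, v, _ in obs.entries
            )
            obs = pt.ObservationSet(entries)
            weights = 1.0 / obs.standard_errors**2
        else:
            weights = np.ones(len(obs))
        fitted = pt.fit_nn(obs, weighting=weighting)
        design = pt.build_design_matrix(obs.descriptors)
        beta, se = brute_force_wls(design, obs.values, weights)
        np.testing.assert_allclose(fitted.vector, beta, rtol=1e-10)
        np.testing.assert_allclose(fitted.se_vector, se, rtol=1e-8)

    def test_monte_carlo_parameter_coverage(self, ref_params):
        """Each term lands within 3 reported SEs of truth in >=95% of runs."""
        hits = np.zeros(12)
        n_runs = 100
        for seed in range(n_runs):
            obs = _synthetic_obs(49, seed=seed, noise_sd=1.0, truth=ref_params)
            fitted = pt.fit_nn(obs, weighting="unweighted")
            z = np.abs(fitted.vector - ref_params.vector) / fitted.se_vector
            hits += z <= 3
        assert (hits / n_runs >= 0.95).all()


class TestPredict:
    @pytest.mark.parametrize(
        "seq,expected", [("CGATCG", 53.40), ("AACGTT", 49.07)]
    )
    def test_published_worked_examples(self, ref_params, seq, expected):
        value, _ = pt.predict(pt.describe_duplex(seq), ref_params)
        assert -value == pytest.approx(expected, abs=0.05)

    def test_se_propagation_independent_terms(self, ref_params):
        d = pt.describe_duplex("CGATCG")
        _, se = pt.predict(d, ref_params)
        # CG:2, GA:2, AT:1, Init, T.GC
        ses = {t: ref_params.term(t)[1] for t in TERM_ORDER}
        expected = math.sqrt(
            (2 * ses["CG"]) ** 2 + (2 * ses["GA"]) ** 2 + ses["AT"] ** 2
            + ses["Init"] ** 2 + ses["T.GC"] ** 2
        )
        assert se == pytest.approx(expected, rel=1e-12)

    def test_covariance_propagation_from_fit(self, ref_params):
        obs = _synthetic_obs(30, seed=8, noise_sd=1.0, truth=ref_params)
        fitted = pt.fit_nn(obs, weighting="unweighted")
        d = pt.describe_duplex("CGATCG")
        x = pt.build_design_matrix([d])[0]
        _, se = pt.predict(d, fitted, use_covariance=True)
        assert se == pytest.approx(math.sqrt(x @ fitted.covariance @ x))

    @settings(max_examples=60, derandomize=True)
    @given(seq_text)
    def test_invariant_under_antiparallel_complement(self, ref_params, s):
        v1, _ = pt.predict(pt.describe_duplex(s), ref_params)
        v2, _ = pt.predict(
            pt.describe_duplex(pt.antiparallel_complement(s)), ref_params
        )
        assert v1 == pytest.approx(v2, rel=1e-12)

    @settings(max_examples=60, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=3, max_size=18))
    def test_additivity_on_terminal_truncation(self, ref_params, s):
        """Dropping the last base removes exactly one stack term plus any
        change in the terminal-GC indicator."""
        full = pt.describe_duplex(s)
        trunc = pt.describe_duplex(s[:-1])
        v_full, _ = pt.predict(full, ref_params)
        v_trunc, _ = pt.predict(trunc, ref_params)
        lost_stack = pt.canonical_stack(s[-2:]).label
        delta = ref_params.stack_terms[lost_stack][0] + (
            full.terminal_gc_indicator - trunc.terminal_gc_indicator
        ) * ref_params.terminal_gc_term[0]
        assert v_full - v_trunc == pytest.approx(delta, abs=1e-10)


class TestEntropySymmetryCorrection:
    @pytest.mark.parametrize(
        "ds,selfc,expected",
        [(-35.0, True, -36.4), (-35.0, False, -35.0), (0.0, True, -1.4)],
    )
    def test_decrement(self, ds, selfc, expected):
        assert pt.apply_symmetry_correction(ds, selfc) == pytest.approx(expected)


class TestGroupSummary:
    def test_reference_group_means(self, ref_params):
        means = pt.group_stack_summary(ref_params)
        assert means[4] == pytest.approx(8.76, abs=0.005)
        assert means[6] == pytest.approx(10.91, abs=0.005)

    def test_means_increase_with_wc_bond_count(self, ref_params):
        means = pt.group_stack_summary(ref_params)
        assert means[4] <= means[5] <= means[6]

    def test_constant_terms_give_constant_means(self, ref_params):
        flat = pt.NnParameterSet(
            stack_terms={s: (-7.0, 0.1) for s in pt.CANONICAL_STACKS},
            init_term=(-1.0, 0.1),
            terminal_gc_term=(-1.0, 0.1),
        )
        assert set(pt.group_stack_summary(flat).values()) == {7.0}


class TestParameterIO:
    def test_csv_round_trip(self, ref_params, tmp_path):
        p = tmp_path / "params.csv"
        pt.write_parameters(ref_params, p)
        back = pt.read_parameters(p)
        np.testing.assert_allclose(back.vector, ref_params.vector)
        np.testing.assert_allclose(back.se_vector, ref_params.se_vector)

    def test_missing_term_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("term,value,se\nAA,8.65,0.16\n")
        with pytest.raises(ValueError, match="missing term"):
            pt.read_parameters(p)
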