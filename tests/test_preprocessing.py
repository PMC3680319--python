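"""Signal-score QC, dye-bias correction, and quantile normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_probe_set, make_sample
from meklchip import synthetic_data as sd
from meklchip.preprocessing import (
    correct_dye_bias,
    quantile_normalize,
    relative_methylation,
    signal_score,
)


class TestSignalScore:
    def test_full_separation_scores_one(self):
        ps = make_probe_set(range(0, 100 * 35, 35), n_antigenomic=50)
        inp = np.concatenate([np.full(100, 1000.0), np.full(50, 10.0)])
        s = make_sample(ps, inp, inp)
        assert signal_score(s, ps) == 1.0

    def test_identical_distributions_score_near_one_minus_quantile(self):
        """Genomic and background drawn from one distribution: the score
        estimates 1 - background_quantile."""
        rng = np.random.default_rng(21)
        n = 10_000
        ps = make_probe_set(range(0, n * 35, 35), n_antigenomic=n)
        inp = np.exp2(rng.normal(10, 1, 2 * n))
        s = make_sample(ps, inp, inp)
        assert signal_score(s, ps, background_quantile=0.9) == pytest.approx(
            0.10, abs=0.02
        )

    def test_no_antigenomic_probes_error(self):
        ps = make_probe_set([0, 35, 70])
        s = make_sample(ps, np.ones(3), np.ones(3))
        with pytest.raises(ValueError, match="anti-genomic"):
            signal_score(s, ps)

    def test_flag_semantics_flagged_not_dropped(self, genome, probes, truth):
        bundle = sd.simulate_bundle(genome, probes, truth, 2, 250, seed=31)
        # force a poor sample: push most genomic intensities to background
        s = bundle.samples[0]
        rng = np.random.default_rng(0)
        s.input_intensity = np.exp2(rng.normal(6.0, 0.7, len(s.input_intensity)))
        matrix = relative_methylation(bundle)
        assert bundle.samples[0].qc_flag is True
        assert bundle.samples[0].signal_score < 0.85
        # flagged sample still present in the matrix
        assert s.sample_id in matrix.values.columns

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(shift=st.floats(0.0, 1000.0))
    def test_score_monotone_in_genomic_shift(self, shift):
        rng = np.random.default_rng(5)
        n = 400
        ps = make_probe_set(range(0, n * 35, 35), n_antigenomic=n)
        inp = np.exp2(rng.normal(10, 1, 2 * n))
        base = signal_score(make_sample(ps, inp, inp), ps)
        shifted = inp.copy()
        shifted[:n] += shift
        assert signal_score(make_sample(ps, shifted, shifted), ps) >= base


class TestDyeBiasCorrection:
    def _bias_sample(self, strength, noise=False):
        genome = sd.generate_genome(60_000, 0.08, seed=41)
        probes = sd.tile_probes(genome, n_control=800, n_antigenomic=100)
        noise_map = {250: 0.2 if noise else 0.0}
        drop_map = {250: 0.0}
        truth = sd.plant_dmrs(
            genome, 2, seed=42,
            noise_sd_by_input_ng=noise_map, dropout_by_input_ng=drop_map,
        )
        s = sd.simulate_experiment(
            None, probes, truth, 1, 250, seed=43, dye_bias_strength=strength
        )[0]
        return s, probes

    def test_identity_input_gives_zero_m(self):
        ps = make_probe_set(range(0, 300 * 35, 35), n_control=200)
        rng = np.random.default_rng(1)
        inp = np.exp2(rng.normal(10, 1, 500))
        s = make_sample(ps, inp, inp.copy())
        for method in ("spline", "lowess"):
            c = correct_dye_bias(s, ps, method=method)
            m = np.log2(c.enriched_intensity / c.input_intensity)
            np.testing.assert_allclose(m, 0.0, atol=1e-9)

    @pytest.mark.parametrize("method", ["spline", "lowess"])
    def test_banana_bias_removed_noise_free(self, method):
        """Simulator-injected smooth bias: corrected control M within 0.05."""
        s, probes = self._bias_sample(0.4)
        c = correct_dye_bias(s, probes, method=method)
        ctrl = probes.table["is_control"].to_numpy()
        m = np.log2(c.enriched_intensity / c.input_intensity)
        assert np.abs(m[ctrl]).max() < 0.05
        assert abs(m[ctrl].mean()) < 0.01

    def test_spline_correction_idempotent(self):
        """Second correction pass changes M by < 1e-6 even on noisy data."""
        s, probes = self._bias_sample(0.4, noise=True)
        c1 = correct_dye_bias(s, probes)
        c2 = correct_dye_bias(c1, probes)
        m1 = np.log2(c1.enriched_intensity / c1.input_intensity)
        m2 = np.log2(c2.enriched_intensity / c2.input_intensity)
        assert np.abs(m2 - m1).max() < 1e-6

    def test_invalid_span_rejected(self):
        ps = make_probe_set(range(0, 100 * 35, 35), n_control=100)
        s = make_sample(ps, np.ones(200), np.ones(200))
        with pytest.raises(ValueError, match="span"):
            correct_dye_bias(s, ps, span=0.0)

    def test_too_few_controls_rejected(self):
        ps = make_probe_set(range(0, 100 * 35, 35), n_control=10)
        s = make_sample(ps, np.ones(110), np.ones(110))
        with pytest.raises(ValueError, match="control probes"):
            correct_dye_bias(s, ps)


class TestQuantileNormalize:
    def test_identical_samples_fixed_point(self):
        x = np.tile(np.array([[3.0], [1.0], [2.0]]), (1, 4))
        np.testing.assert_allclose(quantile_normalize(x), x)

    def test_hand_example(self):
        x = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]])
        expected = np.array([[1.5, 1.5], [3.0, 3.0], [4.5, 4.5]])
        np.testing.assert_allclose(quantile_normalize(x), expected)

    def test_tie_rule_matches_limma_reference(self):
        """Frozen oracle: R limma::normalizeQuantiles(ties=TRUE) on the
        same 5x3 matrix (values computed independently in R)."""
        x = np.array(
            [[1, 2, 5], [2, 2, 4], [3, 6, 3], [4, 4, 2], [5, 10, 1]], float
        )
        expected = (
            np.array(
                [
                    [4, 5, 20],
                    [6, 5, 14],
                    [10, 14, 10],
                    [14, 10, 6],
                    [20, 20, 4],
                ],
                float,
            )
            / 3.0
        )
        np.testing.assert_allclose(quantile_normalize(x), expected, atol=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        n=st.integers(2, 40),
        k=st.integers(2, 6),
        seed=st.integers(0, 10_000),
    )
    def test_sorted_columns_identical(self, n, k, seed):
        """Conservation: every column shares one value multiset afterward.

        (Holds for tie-free columns; tied values are averaged by design,
        see the limma-reference test.)"""
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(n, k))
        out = quantile_normalize(x)
        ref = np.sort(out[:, 0])
        for j in range(1, k):
            np.testing.assert_allclose(np.sort(out[:, j]), ref, atol=1e-12)

    def test_rank_order_preserved(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(30, 3))
        out = quantile_normalize(x)
        for j in range(3):
            assert (np.argsort(x[:, j]) == np.argsort(out[:, j])).all()

    def test_single_sample_unchanged_with_warning(self, caplog):
        x = np.array([[1.0], [5.0]])
        with caplog.at_level("WARNING"):
            out = quantile_normalize(x)
        np.testing.assert_array_equal(out, x)
        assert "single sample" in caplog.text

    def test_dataframe_round_trip(self):
        df = pd.DataFrame({"a": [1.0, 3.0], "b": [2.0, 8.0]}, index=["p1", "p2"])
        out = quantile_normalize(df)
        assert isinstance(out, pd.DataFrame)
        assert list(out.index) == ["p1", "p2"]


class TestRelativeMethylation:
    def test_noise_free_matrix_matches_planted_expectations(
        self, genome, probes, clean_truth, clean_bundle
    ):
        """With noise and bias off: (a) raw M equals the planted log2
        capture ratios probe-wise; (b) the pipeline matrix equals the
        quantile normalization of that raw M (preprocessing adds nothing
        else)."""
        meth = sd.probe_methylation(probes, clean_truth)
        gen = probes.genomic_mask
        cpg = probes.table["cpg_count"].to_numpy()[gen]
        raw_cols = []
        for s in clean_bundle.samples:
            raw = np.log2(s.enriched_intensity[gen]) - np.log2(
                s.input_intensity[gen]
            )
            planted = np.log2(sd.capture_ratio(meth[s.tissue][gen] * cpg))
            np.testing.assert_allclose(raw, planted, atol=1e-9)
            raw_cols.append(raw)
        matrix = relative_methylation(clean_bundle)
        expected = quantile_normalize(np.column_stack(raw_cols))
        np.testing.assert_allclose(
            matrix.values.to_numpy(), expected, atol=1e-6
        )

    def test_no_genomic_probes_error(self):
        ps = make_probe_set([], n_control=60, n_antigenomic=10)
        from meklchip.types import ExperimentBundle

        s = make_sample(ps, np.ones(70), np.ones(70))
        bundle = ExperimentBundle(probes=ps, samples=[s])
        with pytest.raises(ValueError, match="no genomic probes"):
            relative_methylation(bundle)

    def test_deterministic(self, noisy_bundle):
        a = relative_methylation(noisy_bundle)
        b = relative_methylation(noisy_bundle)
        assert a.values.equals(b.values)
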