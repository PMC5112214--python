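"""Parameter-recovery and goodness-of-fit tests for the TMC fits."""

import numpy as np
import pandas as pd
import pytest

from mocgain import (
    CochlearIOParams,
    ElicitorEffect,
    MaskingContext,
)
from mocgain import synthetic_data as sd
from mocgain import tmc_fit
from mocgain.tmc_fit import (
    fit_baseline,
    fit_elicitor,
    fit_subject,
    predict_missing_off_tmc,
    rmsd,
)

from conftest import make_subject


@pytest.fixture(scope="module")
def demo_subject(demo_params, demo_ctx):
    """Noiseless subject with known gain reduction of 10 dB."""
    return make_subject(demo_params, demo_ctx, delta_g=10.0)


#: Gap grid whose required masker outputs traverse both break points of the
#: demo subject's IO function (identifiability needs the upper knee too).
DEMO_GAPS = np.arange(5.0, 46.0, 5.0)


@pytest.fixture(scope="module")
def demo_table(demo_subject):
    """Noise-free full-design TMC table, gaps 5-45 ms in 5-ms steps."""
    return sd.generate_tmc_dataset(
        demo_subject, sd.default_design(gaps_ms=DEMO_GAPS)
    )


class TestRmsd:
    def test_identical_sequences(self):
        assert rmsd([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_closed_form(self):
        assert rmsd([0.0, 0.0], [3.0, -3.0]) == pytest.approx(3.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            rmsd([1.0], [1.0, 2.0])


class TestBaselineFit:
    def test_noiseless_recovery(self, demo_table, demo_params, demo_ctx):
        """All six parameters recovered from noise-free thresholds."""
        fit = fit_baseline(demo_table[demo_table.elicitor == "without"])
        assert fit.converged
        assert fit.rmsd_db < 1e-6
        assert fit.params.g_max == pytest.approx(demo_params.g_max, abs=0.1)
        assert fit.params.c == pytest.approx(demo_params.c, abs=0.01)
        assert fit.params.bp_ctr == pytest.approx(demo_params.bp_ctr, abs=0.1)
        assert fit.params.p == pytest.approx(demo_params.p, abs=0.1)
        assert fit.ctx.k == pytest.approx(demo_ctx.k, abs=0.01)
        assert fit.ctx.mu == pytest.approx(demo_ctx.mu, abs=0.01)

    def test_rmsd_invariant(self, demo_table):
        fit = fit_baseline(demo_table[demo_table.elicitor == "without"])
        assert fit.rmsd_db == pytest.approx(
            np.sqrt(fit.sse / fit.n_points)
        )

    def test_deterministic(self, demo_table):
        without = demo_table[demo_table.elicitor == "without"]
        a, b = fit_baseline(without), fit_baseline(without)
        assert a.params == b.params
        assert a.ctx == b.ctx
        assert a.sse == b.sse

    def test_on_only_fixes_p(self, demo_table):
        on_rows = demo_table[
            (demo_table.elicitor == "without") & (demo_table.masker == "on")
        ]
        fit = fit_baseline(on_rows, fixed_p=17.5)
        assert fit.p_fixed
        assert fit.params.p == pytest.approx(17.5, abs=1e-6)

    def test_insufficient_rows(self, demo_table):
        tiny = demo_table[
            (demo_table.elicitor == "without") & (demo_table.masker == "on")
        ].head(2)
        with pytest.raises(ValueError):
            fit_baseline(tiny)

    def test_rejects_with_elicitor_rows(self, demo_table):
        with pytest.raises(ValueError):
            fit_baseline(demo_table)

    def test_duplicate_gaps_rejected(self, demo_table):
        without = demo_table[demo_table.elicitor == "without"]
        dup = pd.concat([without, without.head(1)], ignore_index=True)
        with pytest.raises(ValueError):
            fit_baseline(dup)


class TestElicitorFit:
    def test_noiseless_delta_g_recovery(self, demo_table):
        baseline = fit_baseline(demo_table[demo_table.elicitor == "without"])
        fit = fit_elicitor(
            demo_table[demo_table.elicitor == "with"], baseline
        )
        assert fit.effect.delta_g == pytest.approx(10.0, abs=0.05)

    def test_identical_data_gives_zero(self, demo_table):
        without = demo_table[demo_table.elicitor == "without"]
        baseline = fit_baseline(without)
        relabeled = without.assign(elicitor="with")
        fit = fit_elicitor(relabeled, baseline)
        assert fit.effect.delta_g == pytest.approx(0.0, abs=1e-6)

    def test_published_s1_ctilde(self):
        """A 4.04-dB gain reduction on S1's fitted tip function raises the
        compression exponent from 0.43 to 0.56."""
        params = CochlearIOParams.from_bp_ctr(17.80, 0.43, 42.68)
        eff = ElicitorEffect.from_params(params, 4.04)
        assert round(eff.c_tilde, 2) == 0.56

    def test_reduced_design_equals_full(self, demo_subject, demo_table):
        """Omitting off-frequency rows leaves the dG estimate unchanged on
        noise-free data."""
        baseline = fit_baseline(demo_table[demo_table.elicitor == "without"])
        with_rows = demo_table[demo_table.elicitor == "with"]
        full = fit_elicitor(with_rows, baseline)
        on_only = fit_elicitor(with_rows[with_rows.masker == "on"], baseline)
        assert on_only.effect.delta_g == pytest.approx(
            full.effect.delta_g, abs=1e-6
        )

    def test_no_rows_rejected(self, demo_table):
        baseline = fit_baseline(demo_table[demo_table.elicitor == "without"])
        with pytest.raises(ValueError):
            fit_elicitor(demo_table[demo_table.elicitor == "never"], baseline)


class TestPredictMissingOff:
    def test_linear_with_fitted_slope(self, demo_table):
        baseline = fit_baseline(demo_table[demo_table.elicitor == "without"])
        gaps = np.array([5.0, 10.0, 15.0])
        pred = predict_missing_off_tmc(baseline, gaps)
        assert np.allclose(np.diff(pred), 5.0 * baseline.ctx.mu)

    def test_empty_gaps(self, demo_table):
        baseline = fit_baseline(demo_table[demo_table.elicitor == "without"])
        assert predict_missing_off_tmc(baseline, []).size == 0

    def test_reduced_design_io_function_matches_full(self, demo_subject):
        """The group-2 workflow (predicted with-elicitor off TMC) infers the
        same IO function as measuring the full design, on noise-free data."""
        from mocgain import infer_io_function, predict_tmc

        full = sd.generate_tmc_dataset(
            demo_subject, sd.default_design(gaps_ms=DEMO_GAPS)
        )
        reduced = sd.generate_tmc_dataset(
            demo_subject, sd.default_design(gaps_ms=DEMO_GAPS, full=False)
        )
        fit_full = fit_subject(full)
        fit_red = fit_subject(reduced)
        gaps = DEMO_GAPS
        on_with = reduced[
            (reduced.masker == "on") & (reduced.elicitor == "with")
        ].threshold_db_spl.to_numpy()
        off_pred = predict_missing_off_tmc(fit_red, gaps, fit_red.effect)
        io_red = infer_io_function(on_with, off_pred, fit_red.params.p)
        off_meas = full[
            (full.masker == "off") & (full.elicitor == "with")
        ].threshold_db_spl.to_numpy()
        io_full = infer_io_function(on_with, off_meas, fit_full.params.p)
        for a, b in zip(io_red, io_full):
            assert a.input_level == pytest.approx(b.input_level, abs=1e-6)
            assert a.output_level == pytest.approx(b.output_level, abs=1e-6)


class TestCohortRecovery:
    def test_noiseless_recovery_across_population(self):
        """Baseline parameters and dG recovered to 0.1 dB / 0.01 for random
        subjects across the population ranges (gap grids spanning the
        compressive range)."""
        rng = np.random.default_rng(42)
        spec = sd.PopulationSpec(noise_sd=0.0)
        for i in range(5):
            subject = sd.sample_subject(spec, rng, f"R{i}")
            table = sd.generate_tmc_dataset(
                subject, sd.identifiable_design(subject)
            )
            fit = fit_subject(table)
            assert fit.params.g_max == pytest.approx(
                subject.params.g_max, abs=0.1
            )
            assert fit.params.c == pytest.approx(subject.params.c, abs=0.01)
            assert fit.params.bp_ctr == pytest.approx(
                subject.params.bp_ctr, abs=0.1
            )
            assert fit.params.p == pytest.approx(subject.params.p, abs=0.1)
            assert fit.ctx.k == pytest.approx(subject.ctx.k, abs=0.01)
            assert fit.ctx.mu == pytest.approx(subject.ctx.mu, abs=0.01)
            assert fit.effect.delta_g == pytest.approx(
                subject.delta_g, abs=0.1
            )

    def test_noisy_gmax_recovery(self, noisy_recovery_study):
        """Median |G_max error| stays below 3 dB at 2-dB observer noise."""
        errs = [
            abs(fit.params.g_max - subject.params.g_max)
            for subject, fit in noisy_recovery_study
        ]
        assert np.median(errs) < 3.0


class TestReportIO:
    def test_roundtrip_table(self, demo_table, tmp_path):
        path = tmp_path / "tmc.csv"
        tmc_fit.write_tmc_table(demo_table, path, header_comment="demo")
        back = tmc_fit.read_tmc_table(path)
        pd.testing.assert_frame_equal(back, demo_table)

    def test_fit_report_median_row(self, demo_table):
        fit = fit_subject(demo_table)
        report = tmc_fit.fit_report({"S1": fit})
        assert list(report.subject_id) == ["S1", "median"]
        assert report.iloc[1]["G_max"] == pytest.approx(
            report.iloc[0]["G_max"]
        )
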