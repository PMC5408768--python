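import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from porecall import (
    PoreModel,
    ScalingParams,
    index_to_kmer,
    kmer_index,
    log_emission,
    log_emission_matrix,
    read_model_table,
    scaled_params,
    simulate_pore_model,
    write_model_table,
)
from tests.conftest import random_events


class TestKmerIndex:
    @pytest.mark.parametrize(
        "kmer,idx",
        [("AAAAAA", 0), ("TTTTTT", 4095), ("AAAAAC", 1), ("A", 0), ("T", 3), ("CA", 4)],
    )
    def test_examples(self, kmer, idx):
        assert kmer_index(kmer) == idx

    @given(st.text(alphabet="ACGT", min_size=1, max_size=8))
    @settings(max_examples=200, deadline=None)
    def test_roundtrip(self, kmer):
        assert index_to_kmer(kmer_index(kmer), len(kmer)) == kmer

    def test_bijective_at_k2(self):
        assert sorted(kmer_index(index_to_kmer(i, 2)) for i in range(16)) == list(range(16))

    def test_invalid_base(self):
        with pytest.raises(ValueError):
            kmer_index("ACGTXN")

    def test_index_out_of_range(self):
        with pytest.raises(ValueError):
            index_to_kmer(16, 2)


class TestScaledParams:
    def test_neutral_is_fixed_point(self, k2_model, neutral):
        for k in range(k2_model.n_states):
            m, sd, igm, igl = scaled_params(k2_model, k, neutral, t=12.3)
            assert m == k2_model.level_mean[k]
            assert sd == k2_model.level_stdv[k]
            assert igm == k2_model.sd_mean[k]
            assert igl == k2_model.sd_stdv[k]

    def test_shift_is_additive(self, k2_model):
        s = ScalingParams(shift=10.0)
        m, *_ = scaled_params(k2_model, 3, s, t=0.0)
        assert m == pytest.approx(k2_model.level_mean[3] + 10.0)

    def test_affine_evaluation(self):
        # scale 1.2, shift 5, drift 0.01 at t=100 applied to a 60 pA level
        model = PoreModel("m", 1, [60, 61, 62, 63], [1] * 4, [1] * 4, [1] * 4)
        s = ScalingParams(shift=5.0, scale=1.2, drift=0.01)
        m, *_ = scaled_params(model, 0, s, t=100.0)
        assert m == pytest.approx(1.2 * 60 + 5 + 0.01 * 100)  # = 78


class TestLogEmission:
    def test_against_scipy_densities(self, k2_model):
        s = ScalingParams(shift=3, scale=1.1, drift=0.02, var=1.2, scale_sd=0.9, var_sd=1.3)
        ev = random_events(0, 6)
        M = log_emission_matrix(ev, k2_model, s)
        for i in range(len(ev)):
            for k in range(k2_model.n_states):
                m, sd, igm, igl = scaled_params(k2_model, k, s, ev.start[i])
                expect = stats.norm.logpdf(ev.mean[i], m, sd) + stats.invgauss.logpdf(
                    ev.stdv[i], igm / igl, scale=igl
                )
                assert M[i, k] == pytest.approx(expect, abs=1e-10)
                assert log_emission(
                    ev.mean[i], ev.stdv[i], ev.start[i], k, k2_model, s
                ) == pytest.approx(expect, abs=1e-10)

    def test_gaussian_part_at_mode_unit_sd(self):
        # with sd=1 the Gaussian contributes -0.5*ln(2*pi) at its mode and
        # the IG part at x = mean equals 0.5*ln(shape/(2*pi*mean**3))
        model = PoreModel("m", 1, [70.0] * 4, [1.0] * 4, [2.0] * 4, [5.0] * 4)
        v = log_emission(70.0, 2.0, 0.0, 0, model, ScalingParams())
        expect = -0.5 * math.log(2 * math.pi) + 0.5 * math.log(5.0 / (2 * math.pi * 8.0))
        assert v == pytest.approx(expect, abs=1e-12)

    def test_wider_sd_lowers_mode_density(self):
        model = PoreModel("m", 1, [70.0] * 4, [1.0] * 4, [2.0] * 4, [5.0] * 4)
        at_mode = lambda var: log_emission(70.0, 2.0, 0.0, 0, model, ScalingParams(var=var))
        assert at_mode(2.0) < at_mode(1.0)

    def test_maximized_at_scaled_mean(self, k2_model):
        s = ScalingParams(shift=4.0, scale=1.05)
        m, *_ = scaled_params(k2_model, 5, s, 0.0)
        f = lambda x: log_emission(x, 2.0, 0.0, 5, k2_model, s)
        assert f(m) > f(m + 0.5) and f(m) > f(m - 0.5)

    def test_both_densities_normalize(self, k2_model):
        s = ScalingParams(shift=2, scale=1.1, var=1.3, scale_sd=1.2, var_sd=0.8)
        k = 7
        m, sd, igm, igl = scaled_params(k2_model, k, s, 0.0)
        gauss, _ = integrate.quad(lambda x: math.exp(stats.norm.logpdf(x, m, sd)), m - 12 * sd, m + 12 * sd)
        # isolate each factor of the product density via log_emission
        x0 = igm
        ig_log = log_emission(m, x0, 0.0, k, k2_model, s) - stats.norm.logpdf(m, m, sd)
        ig_direct = stats.invgauss.logpdf(x0, igm / igl, scale=igl)
        assert gauss == pytest.approx(1.0, abs=1e-6)
        assert ig_log == pytest.approx(ig_direct, abs=1e-10)
        ig_total, _ = integrate.quad(
            lambda x: math.exp(stats.invgauss.logpdf(x, igm / igl, scale=igl)), 0, np.inf
        )
        assert ig_total == pytest.approx(1.0, abs=1e-6)

    def test_nonfinite_event_rejected(self, k2_model, neutral):
        with pytest.raises(ValueError):
            log_emission(np.nan, 2.0, 0.0, 0, k2_model, neutral)


class TestModelTable:
    def test_roundtrip(self, tmp_path):
        model = simulate_pore_model(3, 2, "rt")
        p = tmp_path / "m.tsv"
        write_model_table(model, p)
        back = read_model_table(p, name="rt")
        for field in ("level_mean", "level_stdv", "sd_mean", "sd_stdv"):
            assert np.array_equal(getattr(model, field), getattr(back, field))
        assert back.K == 2

    def test_missing_kmer_is_error(self, tmp_path, k2_model):
        p = tmp_path / "m.tsv"
        write_model_table(k2_model, p)
        lines = p.read_text().splitlines()
        p.write_text("\n".join(lines[:-1]) + "\n")  # drop one kmer row
        with pytest.raises(ValueError, match="expected 16"):
            read_model_table(p)

    def test_bad_alphabet(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("kmer\tlevel_mean\tlevel_stdv\tsd_mean\tsd_stdv\nAX\t60\t1\t2\t3\n")
        with pytest.raises(ValueError, match="invalid base"):
            read_model_table(p)

    def test_duplicate_kmer(self, tmp_path, k2_model):
        p = tmp_path / "m.tsv"
        write_model_table(k2_model, p)
        with open(p, "a") as fh:
            fh.write("AA\t60\t1\t2\t3\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_model_table(p)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError, match="level_stdv"):
            PoreModel("m", 1, [60] * 4, [1, 0, 1, 1], [2] * 4, [3] * 4)
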