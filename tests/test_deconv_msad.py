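import numpy as np
import pytest

from assrdeconv.core import ValidationError
from assrdeconv.deconv_msad import (
    build_fold_system,
    msad_deconvolve,
    recovery_report,
)
from assrdeconv.sequences import CLAD_ISIS_MS
from assrdeconv.synthdata import NoiseSpec, band_limited_noise

FS = 2500.0
PERIODS = [int(round(i * FS / 1000)) for i in CLAD_ISIS_MS]


def brute_force_overlap(x, period):
    """Oracle: one-cycle steady-state response by explicit copy-and-add."""
    x = np.asarray(x, float)
    out = np.zeros(period)
    for m, v in enumerate(x):
        out[m % period] += v
    return out


class TestBuildFoldSystem:
    def test_single_period_equals_identity(self):
        system = build_fold_system([8], 8, FS)
        assert np.array_equal(system.matrix, np.eye(8))

    def test_tiny_hand_checked_system(self):
        system = build_fold_system([2], 4, FS)
        assert np.array_equal(system.matrix,
                              np.array([[1, 0, 1, 0], [0, 1, 0, 1]], float))

    def test_support_shorter_than_period_error(self):
        with pytest.raises(ValidationError):
            build_fold_system([10], 5, FS)

    def test_matches_brute_force_on_random_templates(self, rng):
        system = build_fold_system(PERIODS, 512, FS)
        for _ in range(100):
            x = rng.standard_normal(512)
            expected = np.concatenate([brute_force_overlap(x, p) for p in PERIODS])
            assert np.allclose(system.matrix @ x, expected, atol=1e-9)

    def test_paper_periods_square_but_rank_deficient(self):
        # the 8-period set folds a full-sweep support to a square system of
        # rank 392 < 512: full-support recovery is not identifiable
        system = build_fold_system(PERIODS, 512, FS)
        assert system.matrix.shape == (512, 512)
        s = np.linalg.svd(system.matrix, compute_uv=False)
        assert int(np.sum(s > 1e-10 * s[0])) == 392

    def test_restricted_support_is_full_rank(self):
        system = build_fold_system(PERIODS, 200, FS)
        s = np.linalg.svd(system.matrix, compute_uv=False)
        assert int(np.sum(s > 1e-10 * s[0])) == 200


class TestMsadDeconvolve:
    def test_zero_record_zero_estimate(self):
        system = build_fold_system(PERIODS, 200, FS)
        solution = msad_deconvolve(np.zeros(sum(PERIODS)), system,
                                   method="tikhonov", parameter=0.0)
        assert np.allclose(solution.estimate.waveform, 0.0)

    @pytest.mark.parametrize("method,parameter", [("tikhonov", 0.0), ("tsvd", 200)])
    def test_noiseless_exact_recovery(self, method, parameter, rng):
        system = build_fold_system(PERIODS, 200, FS)
        x = rng.standard_normal(200)
        b = system.matrix @ x
        solution = msad_deconvolve(b, system, method=method, parameter=parameter)
        assert np.allclose(solution.estimate.waveform, x, atol=1e-9)

    def test_length_mismatch_error(self):
        system = build_fold_system(PERIODS, 200, FS)
        with pytest.raises(ValidationError):
            msad_deconvolve(np.zeros(100), system)

    def test_bad_parameters(self):
        system = build_fold_system([4], 8, FS)
        with pytest.raises(ValidationError):
            msad_deconvolve(np.zeros(4), system, method="tsvd", parameter=99)
        with pytest.raises(ValidationError):
            msad_deconvolve(np.zeros(4), system, method="tikhonov", parameter=-1.0)
        with pytest.raises(ValidationError):
            msad_deconvolve(np.zeros(4), system, method="nope")

    def test_lcurve_monotonicity(self, template, rng):
        # solution norm non-increasing, residual norm non-decreasing in lambda
        system = build_fold_system(PERIODS, template.n, FS)
        b = system.matrix @ template.waveform + 0.05 * rng.standard_normal(512)
        sol_norms, res_norms = [], []
        for lam in np.logspace(-3, 1, 9):
            sol = msad_deconvolve(b, system, method="tikhonov", parameter=lam)
            sol_norms.append(sol.solution_norm)
            res_norms.append(sol.residual_norm)
        assert all(a >= b_ - 1e-12 for a, b_ in zip(sol_norms, sol_norms[1:]))
        assert all(a <= b_ + 1e-12 for a, b_ in zip(res_norms, res_norms[1:]))

    def test_estimate_converges_with_noise(self, template, rng):
        system = build_fold_system(PERIODS, template.n, FS)
        b0 = system.matrix @ template.waveform
        for sigma, tol in ((1e-3, 0.1), (0.0, 1e-6)):
            b = b0 + sigma * rng.standard_normal(512)
            sol = msad_deconvolve(b, system, method="tikhonov", parameter=0.0)
            err = np.abs(sol.estimate.waveform - template.waveform).max()
            assert err < tol

    def test_auto_regularization_beats_unregularized(self, template):
        # seeded replicates: GCV-chosen lambda reduces RMSE vs lambda = 0
        system = build_fold_system(PERIODS, template.n, FS)
        b0 = system.matrix @ template.waveform
        spec = NoiseSpec(rms_uv=1.0 / np.sqrt(1500))
        wins = 0
        for seed in range(20):
            seed_rng = np.random.default_rng(seed)
            noise = np.concatenate(
                [band_limited_noise(p, FS, spec, seed_rng) for p in PERIODS])
            b = b0 + noise
            reg = msad_deconvolve(b, system, method="tikhonov", parameter="auto")
            unreg = msad_deconvolve(b, system, method="tikhonov", parameter=0.0)
            rmse = lambda s: np.sqrt(np.mean((s.estimate.waveform - template.waveform) ** 2))
            wins += rmse(reg) < rmse(unreg)
        assert wins >= 18

    def test_isochronic_full_period_equals_clad(self, rng):
        # single rate with P = N: the fold system is circulant-free identity
        # folding, so the SVD solve and the frequency-domain inverse agree
        from assrdeconv.deconv_clad import clad_deconvolve
        from assrdeconv.sequences import ImpulseTrain

        n = 64
        samples = np.zeros(n)
        samples[0] = 1
        train = ImpulseTrain(samples=samples, fs=FS, onsets=(0,))
        system = build_fold_system([n], n, FS)
        y = rng.standard_normal(n)
        via_msad = msad_deconvolve(y, system, method="tikhonov", parameter=0.0)
        via_clad = clad_deconvolve(y, train)
        assert np.allclose(via_msad.estimate.waveform, via_clad.waveform, atol=1e-10)


class TestRecoveryReport:
    def test_perfect_estimate_zero_errors(self, template):
        system = build_fold_system(PERIODS, template.n, FS)
        sol = msad_deconvolve(system.matrix @ template.waveform, system,
                              method="tikhonov", parameter=0.0)
        report = recovery_report(sol, x_true=template,
                                 windows_ms={"Pa": (22.0, 35.0)})
        assert report["rmse_uv"] < 1e-9
        assert report["components"]["Pa"]["peak_latency_error_ms"] == 0.0

    def test_identity_condition_number(self):
        system = build_fold_system([8], 8, FS)
        sol = msad_deconvolve(np.zeros(8), system, method="tsvd", parameter=8)
        assert recovery_report(sol)["condition_number"] == pytest.approx(1.0)

    def test_paper_periods_condition_number(self, template):
        system = build_fold_system(PERIODS, template.n, FS)
        sol = msad_deconvolve(np.zeros(512), system, method="tikhonov",
                              parameter=0.0)
        report = recovery_report(sol)
        assert 1.0 < report["condition_number"] < np.inf
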