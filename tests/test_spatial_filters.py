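"""CSP-family contracts: covariance arithmetic, whitening, Takagi
factorization, SUT identities, and filter behavior on fixtures."""

import warnings

import numpy as np
import pytest
import scipy.linalg

from emdcsp.data import DataError
from emdcsp.spatial_filters import (
    ComplexTrialSet,
    DegenerateInputError,
    FittingError,
    apply_filters,
    build_complex_trials,
    build_real_trials,
    ccsp_fit,
    compute_sut,
    csp_fit,
    estimate_class_covariances,
    sutccsp_fit,
    takagi_factorize,
    whiten,
)


def _random_complex_trials(rng, n_trials=8, n_ch=4, n_samp=64,
                           noncircular=True) -> ComplexTrialSet:
    mu = rng.standard_normal((n_trials, n_ch, n_samp))
    scale = 2.0 if noncircular else 1.0
    beta = scale * rng.standard_normal((n_trials, n_ch, n_samp))
    labels = np.array(["L", "R"] * (n_trials // 2))
    return build_complex_trials(mu, beta, labels)


# ---------------------------------------------------------------------------
# trial construction


def test_build_complex_centers_both_parts():
    rng = np.random.default_rng(0)
    mu = rng.standard_normal((4, 3, 50)) + 5.0
    beta = rng.standard_normal((4, 3, 50)) - 2.0
    trials = build_complex_trials(mu, beta, ["L", "L", "R", "R"])
    assert np.abs(trials.data.real.mean(axis=2)).max() < 1e-12
    assert np.abs(trials.data.imag.mean(axis=2)).max() < 1e-12


def test_build_complex_beta_zero_gives_real_pseudocov():
    rng = np.random.default_rng(1)
    mu = rng.standard_normal((4, 3, 200))
    trials = build_complex_trials(mu, np.zeros_like(mu), ["L", "L", "R", "R"])
    cov = estimate_class_covariances(trials, normalization="none")
    np.testing.assert_allclose(cov.P_L, cov.C_L, atol=1e-12)
    assert np.abs(cov.C_L.imag).max() < 1e-12


def test_build_complex_mu_equals_beta_power_difference_zero():
    rng = np.random.default_rng(2)
    mu = rng.standard_normal((4, 3, 100))
    trials = build_complex_trials(mu, mu, ["L", "L", "R", "R"])
    cov = estimate_class_covariances(trials, normalization="none")
    # E[z_mu^2 - z_beta^2] = 0: the real part of P vanishes
    assert np.abs(cov.P_L.real).max() < 1e-12


def test_build_complex_shape_mismatch():
    with pytest.raises(DataError):
        build_complex_trials(np.zeros((2, 3, 10)), np.zeros((2, 3, 11)), ["L", "R"])


def test_build_real_trials_variance_identity():
    rng = np.random.default_rng(3)
    mu = rng.standard_normal((4, 2, 80))
    beta = rng.standard_normal((4, 2, 80))
    trials = build_real_trials(mu, beta, ["L", "L", "R", "R"])
    mu_c = mu - mu.mean(axis=2, keepdims=True)
    beta_c = beta - beta.mean(axis=2, keepdims=True)
    expected = mu_c.var(axis=2) + beta_c.var(axis=2) + \
        2 * (mu_c * beta_c).mean(axis=2)
    np.testing.assert_allclose(trials.data.var(axis=2), expected, atol=1e-10)


def test_build_real_trials_zero_inputs():
    trials = build_real_trials(np.zeros((2, 2, 70)), np.zeros((2, 2, 70)),
                               ["L", "R"])
    assert not trials.data.any()


# ---------------------------------------------------------------------------
# covariance estimation


def test_covariance_hand_case_real():
    # single channel z = [1, -1]: C = 1, P = 1
    data = np.array([[[1.0, -1.0]], [[1.0, -1.0]],
                     [[1.0, -1.0]], [[1.0, -1.0]]], dtype=complex)
    trials = ComplexTrialSet(data, ["L", "L", "R", "R"])
    cov = estimate_class_covariances(trials, normalization="none")
    assert cov.C_L[0, 0] == pytest.approx(1.0)
    assert cov.P_L[0, 0] == pytest.approx(1.0)


def test_covariance_hand_case_imaginary():
    # single channel z = [j, -j]: C = 1, P = -1
    data = np.array([[[1j, -1j]], [[1j, -1j]],
                     [[1j, -1j]], [[1j, -1j]]])
    trials = ComplexTrialSet(data, ["L", "L", "R", "R"])
    cov = estimate_class_covariances(trials, normalization="none")
    assert cov.C_L[0, 0] == pytest.approx(1.0)
    assert cov.P_L[0, 0] == pytest.approx(-1.0)


def test_covariance_brute_force_oracle():
    rng = np.random.default_rng(4)
    data = rng.standard_normal((4, 2, 4)) + 1j * rng.standard_normal((4, 2, 4))
    trials = ComplexTrialSet(data, ["L", "L", "R", "R"])
    cov = estimate_class_covariances(trials, normalization="none")
    # brute force: sum of outer products, sample by sample
    C = np.zeros((2, 2), dtype=complex)
    P = np.zeros((2, 2), dtype=complex)
    for t in (0, 1):
        for s in range(4):
            z = data[t, :, s]
            C += np.outer(z, z.conj()) / 4
            P += np.outer(z, z) / 4
    np.testing.assert_allclose(cov.C_L, C / 2, atol=1e-12)
    np.testing.assert_allclose(cov.P_L, P / 2, atol=1e-12)


def test_covariance_needs_two_trials_per_class():
    data = np.zeros((3, 2, 8), dtype=complex)
    trials = ComplexTrialSet(data, ["L", "L", "R"])
    with pytest.raises(FittingError):
        estimate_class_covariances(trials)


# ---------------------------------------------------------------------------
# whitening


def test_whiten_identity():
    white = whiten(np.eye(3, dtype=complex))
    np.testing.assert_allclose(white.G @ np.eye(3) @ white.G.conj().T,
                               np.eye(3), atol=1e-10)


def test_whiten_diagonal_closed_form():
    white = whiten(np.diag([4.0, 1.0]).astype(complex))
    G = np.abs(white.G)
    # up to permutation/sign: diag(1/2, 1)
    assert sorted(np.round(G[G > 1e-12], 6)) == [0.5, 1.0]


def test_whiten_random_psd_property():
    rng = np.random.default_rng(5)
    for _ in range(10):
        M = rng.standard_normal((5, 5)) + 1j * rng.standard_normal((5, 5))
        C = M @ M.conj().T
        white = whiten(C)
        np.testing.assert_allclose(white.G @ C @ white.G.conj().T,
                                   np.eye(white.rank), atol=1e-10)


def test_whiten_zero_matrix_rejected():
    with pytest.raises(DegenerateInputError):
        whiten(np.zeros((3, 3)))


def test_whiten_rank_reduction():
    # rank-2 PSD 3x3
    v = np.array([[1.0, 0, 0], [0, 1.0, 0]]).T
    C = v @ v.T
    white = whiten(C)
    assert white.rank == 2


# ---------------------------------------------------------------------------
# Takagi factorization


def test_takagi_real_diagonal():
    tak = takagi_factorize(np.diag([3.0, 1.0]).astype(complex))
    np.testing.assert_allclose(tak.lam, [3.0, 1.0])
    np.testing.assert_allclose(np.abs(tak.Y), np.eye(2), atol=1e-12)


def test_takagi_1x1_imaginary():
    tak = takagi_factorize(np.array([[1j]]))
    assert tak.lam[0] == pytest.approx(1.0)
    y = tak.Y[0, 0]
    assert abs(y) == pytest.approx(1.0)
    assert (y * tak.lam[0] * y) == pytest.approx(1j)


def test_takagi_generative_oracle():
    rng = np.random.default_rng(6)
    for _ in range(20):
        Y0 = scipy.linalg.qr(rng.standard_normal((4, 4))
                             + 1j * rng.standard_normal((4, 4)))[0]
        lam0 = np.sort(rng.uniform(0.1, 3.0, 4))[::-1]
        P = Y0 @ np.diag(lam0) @ Y0.T
        tak = takagi_factorize(P)
        np.testing.assert_allclose(tak.lam, lam0, atol=1e-8)
        np.testing.assert_allclose(tak.Y @ np.diag(tak.lam) @ tak.Y.T, P,
                                   atol=1e-8)
        np.testing.assert_allclose(tak.Y.conj().T @ tak.Y, np.eye(4),
                                   atol=1e-10)


def test_takagi_degenerate_and_rank_deficient():
    rng = np.random.default_rng(7)
    Y0 = scipy.linalg.qr(rng.standard_normal((5, 5))
                         + 1j * rng.standard_normal((5, 5)))[0]
    lam0 = np.array([2.0, 2.0, 2.0, 1.0, 0.0])
    P = Y0 @ np.diag(lam0) @ Y0.T
    tak = takagi_factorize(P)
    np.testing.assert_allclose(tak.lam, lam0, atol=1e-8)
    np.testing.assert_allclose(tak.Y @ np.diag(tak.lam) @ tak.Y.T, P, atol=1e-8)
    np.testing.assert_allclose(tak.Y.conj().T @ tak.Y, np.eye(5), atol=1e-10)


def test_takagi_asymmetric_rejected():
    M = np.array([[0.0, 1.0], [2.0, 0.0]], dtype=complex)
    with pytest.raises(DataError, match="symmetric"):
        takagi_factorize(M)


def test_takagi_deterministic():
    rng = np.random.default_rng(8)
    M = rng.standard_normal((4, 4)) + 1j * rng.standard_normal((4, 4))
    P = M + M.T
    a = takagi_factorize(P)
    b = takagi_factorize(P)
    np.testing.assert_array_equal(a.Y, b.Y)


# ---------------------------------------------------------------------------
# SUT


def test_sut_identities_on_fixture():
    rng = np.random.default_rng(9)
    trials = _random_complex_trials(rng, n_trials=12, n_ch=5)
    cov = estimate_class_covariances(trials)
    white = whiten(cov.C_c)
    tak = takagi_factorize(white.G @ cov.P_c @ white.G.T)
    sut = compute_sut(white, tak)
    r = white.rank
    np.testing.assert_allclose(sut.Q @ cov.C_c @ sut.Q.conj().T, np.eye(r),
                               atol=1e-8)
    np.testing.assert_allclose(sut.Q @ cov.P_c @ sut.Q.T, np.diag(tak.lam),
                               atol=1e-8)
    np.testing.assert_allclose(sut.Q_hat @ cov.P_c @ sut.Q_hat.T, np.eye(r),
                               atol=1e-8)


def test_sut_circular_data_warns():
    # independent equal-power real/imag parts: pseudocovariance ~ 0
    rng = np.random.default_rng(10)
    n = 400
    mu = rng.standard_normal((8, 2, n))
    beta = rng.standard_normal((8, 2, n))
    trials = build_complex_trials(mu, beta, ["L"] * 4 + ["R"] * 4)
    cov = estimate_class_covariances(trials)
    white = whiten(cov.C_c)
    P_bar = white.G @ cov.P_c @ white.G.T
    # force the degenerate branch deterministically
    tak = takagi_factorize(np.zeros_like(P_bar))
    with pytest.warns(RuntimeWarning, match="circular"):
        sut = compute_sut(white, tak)
    assert np.all(sut.Q_hat == 0)


# ---------------------------------------------------------------------------
# CSP fits


def _axis_trials(var1, var2, n_rep=2):
    """Two orthogonal unit-variance carriers scaled per channel."""
    a = np.tile([1.0, -1.0], 2)          # var 1, mean 0
    b = np.array([1.0, 1.0, -1.0, -1.0])  # orthogonal, var 1
    trial = np.stack([np.sqrt(var1) * a, np.sqrt(var2) * b])
    return [trial.copy() for _ in range(n_rep)]


def test_csp_closed_form_two_channel():
    # class L covariance diag(4, 1), class R diag(1, 4):
    # whitened eigenvalues are 0.8 / 0.2 and filters align with the axes
    trials_l = _axis_trials(4.0, 1.0)
    trials_r = _axis_trials(1.0, 4.0)
    data = np.stack(trials_l + trials_r)
    from emdcsp.data import EEGTrialSet
    trials = EEGTrialSet(data, ["L", "L", "R", "R"], ["c1", "c2"], fs=1.0)
    bank = csp_fit(trials, normalization="none")
    np.testing.assert_allclose(bank.eigvals, [0.8, 0.2], atol=1e-10)
    for row in bank.W:
        w = np.abs(row) / np.abs(row).max()
        assert sorted(np.round(w, 6)) == [0.0, 1.0]


def test_csp_identical_classes_half_eigvals():
    trials_l = _axis_trials(2.0, 3.0)
    data = np.stack(trials_l + trials_l)
    from emdcsp.data import EEGTrialSet
    trials = EEGTrialSet(data, ["L", "L", "R", "R"], ["c1", "c2"], fs=1.0)
    bank = csp_fit(trials, normalization="none")
    np.testing.assert_allclose(bank.eigvals, [0.5, 0.5], atol=1e-10)


def test_csp_generalized_eigenproblem_oracle():
    rng = np.random.default_rng(11)
    data = rng.standard_normal((10, 4, 100))
    from emdcsp.data import EEGTrialSet
    trials = EEGTrialSet(data, ["L"] * 5 + ["R"] * 5,
                         [f"c{i}" for i in range(4)], fs=1.0)
    bank = csp_fit(trials, normalization="none")
    # oracle: generalized eigenproblem C_L v = lambda (C_L + C_R) v
    C = {lab: np.mean([data[t] @ data[t].T / 100
                       for t in np.flatnonzero(trials.labels == lab)], axis=0)
         for lab in "LR"}
    vals = scipy.linalg.eigh(C["L"], C["L"] + C["R"], eigvals_only=True)
    np.testing.assert_allclose(bank.eigvals, np.sort(vals)[::-1], atol=1e-8)
    np.testing.assert_allclose(bank.W @ (C["L"] + C["R"]) @ bank.W.T,
                               np.eye(4), atol=1e-8)


def test_sutccsp_identical_classes():
    rng = np.random.default_rng(12)
    mu = rng.standard_normal((2, 3, 120))
    beta = 0.5 * rng.standard_normal((2, 3, 120))
    mu = np.concatenate([mu, mu])
    beta = np.concatenate([beta, beta])
    trials = build_complex_trials(mu, beta, ["L", "L", "R", "R"])
    bank = sutccsp_fit(trials)
    np.testing.assert_allclose(bank.eigvals, 0.5 * np.ones(3), atol=1e-10)
    np.testing.assert_allclose(bank.eigvals_hat, 0.5 * np.ones(3), atol=1e-8)


def test_sutccsp_internal_identities(diff_only_rhythms):
    trials, mu, beta = diff_only_rhythms
    ct = build_complex_trials(mu, beta, trials.labels)
    bank = sutccsp_fit(ct)
    for key, value in bank.diagnostics.items():
        assert value < 1e-8, f"{key} residual {value}"


def test_sutccsp_difference_only_eigval_spreads(diff_only_rhythms):
    trials, mu, beta = diff_only_rhythms
    ct = build_complex_trials(mu, beta, trials.labels)
    bank = sutccsp_fit(ct)
    assert bank.eigvals.max() - bank.eigvals.min() < 0.1
    assert bank.eigvals_hat.max() - bank.eigvals_hat.min() > 0.3


def test_ccsp_same_w_as_sutccsp(diff_only_rhythms):
    trials, mu, beta = diff_only_rhythms
    ct = build_complex_trials(mu, beta, trials.labels)
    bank_full = sutccsp_fit(ct)
    bank_ccsp = ccsp_fit(ct)
    assert bank_ccsp.W_hat is None
    np.testing.assert_allclose(bank_ccsp.W, bank_full.W, atol=1e-10)
    np.testing.assert_allclose(bank_ccsp.eigvals, bank_full.eigvals, atol=1e-12)


def test_ccsp_real_only_reduces_to_csp():
    rng = np.random.default_rng(13)
    mu = rng.standard_normal((8, 3, 150))
    mu[:4] *= 1.6  # class-dependent power
    labels = ["L"] * 4 + ["R"] * 4
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        bank_c = ccsp_fit(build_complex_trials(mu, np.zeros_like(mu), labels))
    bank_r = csp_fit(build_real_trials(mu, np.zeros_like(mu), labels))
    np.testing.assert_allclose(np.sort(bank_c.eigvals),
                               np.sort(bank_r.eigvals), atol=1e-8)


def test_lateralized_fixture_contralateral_weight():
    # class L has high power on left-hemisphere channels; the top class-L
    # filter should concentrate its weight on one hemisphere.  Montage
    # without midline channels so hemisphere masses partition the weight.
    from emdcsp.io_cli import bandpass_rhythms
    from emdcsp.synthgen import (MU_BAND, BETA_BAND, SourceSpec, SynthConfig,
                                 generate_dataset)
    hemis = ("L", "L", "L", "L", "R", "R", "R", "R")
    sources = (
        SourceSpec(*MU_BAND, amp_left_class=(1.5, 0.4),
                   amp_right_class=(0.4, 1.5)),
        SourceSpec(*BETA_BAND, amp_left_class=(1.5, 0.4),
                   amp_right_class=(0.4, 1.5)),
    )
    cfg = SynthConfig(n_channels=8, n_trials_per_class=30, noise_sd=0.2,
                      seed=21, sources=sources,
                      channel_names=tuple(f"c{i}" for i in range(8)),
                      hemispheres=hemis)
    trials, _ = generate_dataset(cfg)
    mu, beta = bandpass_rhythms(trials)
    ct = build_complex_trials(mu, beta, trials.labels)
    bank = sutccsp_fit(ct)
    w = np.abs(bank.W[0]) ** 2
    left_mass = w[:4].sum() / w.sum()
    right_mass = w[4:].sum() / w.sum()
    assert max(left_mass, right_mass) > 0.5


# ---------------------------------------------------------------------------
# filter application


def test_apply_identity_bank():
    from emdcsp.spatial_filters import FilterBank
    bank = FilterBank(W=np.eye(3), W_hat=None, eigvals=np.ones(3),
                      eigvals_hat=None, variant="CSP", rank=3)
    data = np.arange(2 * 3 * 5, dtype=float).reshape(2, 3, 5)
    V, V_hat = apply_filters(bank, data)
    np.testing.assert_array_equal(V, data)
    assert V_hat is None


def test_apply_zero_trial():
    from emdcsp.spatial_filters import FilterBank
    bank = FilterBank(W=np.eye(2), W_hat=None, eigvals=np.ones(2),
                      eigvals_hat=None, variant="CSP", rank=2)
    V, _ = apply_filters(bank, np.zeros((1, 2, 10)))
    assert not V.any()


def test_apply_linearity(diff_only_rhythms):
    trials, mu, beta = diff_only_rhythms
    ct = build_complex_trials(mu, beta, trials.labels)
    bank = ccsp_fit(ct)
    V1, _ = apply_filters(bank, ct.data)
    V2, _ = apply_filters(bank, 3.0 * ct.data)
    np.testing.assert_allclose(V2, 3.0 * V1, atol=1e-10)


def test_apply_channel_mismatch():
    from emdcsp.spatial_filters import FilterBank
    bank = FilterBank(W=np.eye(3), W_hat=None, eigvals=np.ones(3),
                      eigvals_hat=None, variant="CSP", rank=3)
    with pytest.raises(DataError, match="channel mismatch"):
        apply_filters(bank, np.zeros((1, 4, 10)))


def test_training_round_trip_variances_match_eigvals():
    rng = np.random.default_rng(14)
    data = rng.standard_normal((20, 4, 200))
    data[:10, 0] *= 2.0
    from emdcsp.data import EEGTrialSet
    trials = EEGTrialSet(data, ["L"] * 10 + ["R"] * 10,
                         [f"c{i}" for i in range(4)], fs=1.0)
    bank = csp_fit(trials, normalization="none")
    V, _ = apply_filters(bank, trials)
    mean_var_L = V[:10].var(axis=2).mean(axis=0)
    np.testing.assert_allclose(mean_var_L, bank.eigvals, rtol=0.05)


# ---------------------------------------------------------------------------
# properties


def test_permutation_equivariance(diff_only_rhythms):
    trials, mu, beta = diff_only_rhythms
    perm = np.random.default_rng(15).permutation(mu.shape[1])
    ct = build_complex_trials(mu, beta, trials.labels)
    ct_p = build_complex_trials(mu[:, perm], beta[:, perm], trials.labels)
    bank = sutccsp_fit(ct)
    bank_p = sutccsp_fit(ct_p)
    np.testing.assert_allclose(np.sort(bank.eigvals), np.sort(bank_p.eigvals),
                               atol=1e-8)
    V, _ = apply_filters(bank, ct.data)
    V_p, _ = apply_filters(bank_p, ct_p.data)
    # features (component variances) are permutation invariant
    np.testing.assert_allclose(np.sort(V.var(axis=2), axis=1),
                               np.sort(V_p.var(axis=2), axis=1), rtol=1e-6)


def test_scale_invariance_with_trace_normalization(diff_only_rhythms):
    trials, mu, beta = diff_only_rhythms
    ct = build_complex_trials(mu, beta, trials.labels)
    ct_scaled = build_complex_trials(7.5 * mu, 7.5 * beta, trials.labels)
    bank = sutccsp_fit(ct)
    bank_s = sutccsp_fit(ct_scaled)
    np.testing.assert_allclose(bank.eigvals, bank_s.eigvals, atol=1e-10)
    np.testing.assert_allclose(bank.eigvals_hat, bank_s.eigvals_hat, atol=1e-8)


def test_filterbank_serialization_round_trip(tmp_path, diff_only_rhythms):
    from emdcsp.spatial_filters import load_filterbank, save_filterbank
    trials, mu, beta = diff_only_rhythms
    bank = sutccsp_fit(build_complex_trials(mu, beta, trials.labels,
                                            channel_names=trials.channel_names))
    path = save_filterbank(tmp_path / "bank.npz", bank)
    back = load_filterbank(path)
    np.testing.assert_array_equal(back.W, bank.W)
    np.testing.assert_array_equal(back.W_hat, bank.W_hat)
    np.testing.assert_array_equal(back.eigvals, bank.eigvals)
    assert back.variant == bank.variant
    assert back.channel_names == bank.channel_names
    assert back.rank == bank.rank


def test_type_invariants_on_random_instances():
    rng = np.random.default_rng(16)
    for _ in range(20):
        trials = _random_complex_trials(rng, n_trials=8,
                                        n_ch=int(rng.integers(2, 6)))
        cov = estimate_class_covariances(trials)
        for C in (cov.C_L, cov.C_R):
            assert np.linalg.norm(C - C.conj().T) < 1e-10
            assert np.linalg.eigvalsh(C).min() > -1e-10
        for P in (cov.P_L, cov.P_R):
            assert np.linalg.norm(P - P.T) < 1e-10
        bank = sutccsp_fit(trials)
        r = bank.rank
        np.testing.assert_allclose(
            bank.W @ cov.C_c @ bank.W.conj().T, np.eye(r), atol=1e-8)
        np.testing.assert_allclose(
            bank.W_hat @ cov.P_c @ bank.W_hat.T, np.eye(r), atol=1e-8)
        assert np.all(np.diff(bank.eigvals) <= 1e-10)
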