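"""Eigen-accelerated GLS scans: decomposition, fits, 1D/2D Wald tests,
chunking determinism and slicing."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from omescan import (MarkerMatrix, TraitVector, ValidationError,
                     build_eigen_context, compute_kinships, conditional_slice,
                     fit_gls, scan_1d, scan_2d, simulate_ril_genotypes,
                     simulate_trait, threshold_pairs)
from omescan.reml import VarianceComponents
from omescan.scan import EigenContext, all_pairs


def _vc(lam_a, lam_aa):
    return VarianceComponents(sigma2_a=lam_a, sigma2_aa=lam_aa, sigma2_e=1.0,
                              lambda_a=lam_a, lambda_aa=lam_aa,
                              loglik=0.0, converged=True)


def _identity_ec(y):
    n = y.n
    return EigenContext(U=np.eye(n), delta=np.zeros(n), wdiag=np.ones(n),
                        y_star=y.values.copy(), lambda_a=0.0, lambda_aa=0.0,
                        individual_ids=list(y.individual_ids))


@pytest.fixture(scope="module")
def setup30():
    Z = simulate_ril_genotypes(n=30, m=10, n_chrom=2, switch_prob=0.25,
                               seed=77)
    K = compute_kinships(Z)
    y, _ = simulate_trait(Z, 0.4, 0.3, 0.3, seed=78)
    vc = _vc(0.7, 0.3)
    ec = build_eigen_context(K, vc, y)
    return Z, K, y, vc, ec


class TestEigenContext:
    def test_zero_lambdas(self, small_kinships, small_trait):
        ec = build_eigen_context(small_kinships, _vc(0.0, 0.0), small_trait)
        np.testing.assert_allclose(ec.delta, 0.0, atol=1e-12)
        np.testing.assert_allclose(ec.wdiag, 1.0, atol=1e-12)
        np.testing.assert_allclose(ec.U.T @ small_trait.values, ec.y_star)

    def test_reconstruction(self, setup30):
        Z, K, y, vc, ec = setup30
        H = K.hmat(vc.lambda_a, vc.lambda_aa)
        recon = ec.U @ np.diag(ec.delta) @ ec.U.T
        assert np.max(np.abs(recon - H)) < 1e-8

    def test_inverse_matches_direct(self, setup30):
        Z, K, y, vc, ec = setup30
        H = K.hmat(vc.lambda_a, vc.lambda_aa)
        direct = np.linalg.inv(H + np.eye(K.n))
        via_eigen = ec.U @ np.diag(ec.wdiag) @ ec.U.T
        assert np.max(np.abs(direct - via_eigen)) < 1e-8

    def test_wdiag_range(self, setup30):
        ec = setup30[4]
        assert np.all(ec.wdiag > 0) and np.all(ec.wdiag <= 1.0)


class TestFitGls:
    def test_identity_weights_equal_ols(self, rng):
        n = 25
        y = TraitVector(rng.normal(size=n), [f"s{i}" for i in range(n)], "t")
        ec = _identity_ec(y)
        P = np.column_stack([np.ones(n), rng.normal(size=n)])
        b, var_b, s2, status = fit_gls(P, ec)
        assert status == "ok"
        ols, *_ = np.linalg.lstsq(P, y.values, rcond=None)
        np.testing.assert_allclose(b, ols, atol=1e-10)

    def test_matches_direct_gls(self, setup30, rng):
        """Eigen-path fit equals (Pᵀ(H+I)⁻¹P)⁻¹Pᵀ(H+I)⁻¹y with explicit
        inversion, for both design widths."""
        Z, K, y, vc, ec = setup30
        Cinv = np.linalg.inv(K.hmat(vc.lambda_a, vc.lambda_aa) + np.eye(K.n))
        for ncol in (2, 4):
            P = np.column_stack([np.ones(K.n),
                                 rng.normal(size=(K.n, ncol - 1))])
            b, var_b, s2, status = fit_gls(P, ec)
            A = P.T @ Cinv @ P
            b_direct = np.linalg.solve(A, P.T @ Cinv @ y.values)
            np.testing.assert_allclose(b, b_direct, atol=1e-8)
            r = y.values - P @ b_direct
            s2_direct = (r @ Cinv @ r) / (K.n - ncol)
            assert s2 == pytest.approx(s2_direct, abs=1e-8)
            np.testing.assert_allclose(var_b,
                                       np.linalg.inv(A) * s2_direct,
                                       atol=1e-8)

    def test_duplicated_column_singular(self, setup30, rng):
        Z, K, y, vc, ec = setup30
        col = rng.normal(size=K.n)
        P = np.column_stack([np.ones(K.n), col, col, rng.normal(size=K.n)])
        *_, status = fit_gls(P, ec)
        assert status == "singular"


class TestScan1D:
    def test_planted_signal_is_top_hit(self, rng):
        Z = simulate_ril_genotypes(n=60, m=15, n_chrom=2, switch_prob=0.45,
                                   seed=91)
        k = 7
        y = TraitVector(2.0 * Z.values[k] + 0.01 * rng.normal(size=60),
                        Z.individual_ids, "t")
        res = scan_1d(Z, _identity_ec(y))
        top = res.table.loc[res.table["neglog10p"].idxmax(), "marker_id"]
        assert top == Z.marker_ids[k]

    def test_matches_ols_zscore_oracle(self, rng):
        """With unit weights every Wald statistic equals the squared z-score
        of an explicit two-column regression."""
        Z = simulate_ril_genotypes(n=40, m=12, n_chrom=2, switch_prob=0.3,
                                   seed=92)
        y = TraitVector(rng.normal(size=40), Z.individual_ids, "t")
        res = scan_1d(Z, _identity_ec(y))
        n = 40
        for i in range(Z.m):
            P = np.column_stack([np.ones(n), Z.values[i]])
            b, *_ = np.linalg.lstsq(P, y.values, rcond=None)
            r = y.values - P @ b
            s2 = (r @ r) / (n - 2)
            cov = np.linalg.inv(P.T @ P) * s2
            wald = b[1] ** 2 / cov[1, 1]
            assert res.table["wald"].iloc[i] == pytest.approx(wald, abs=1e-8)

    def test_constant_marker_flagged_not_fatal(self, rng):
        n = 20
        vals = np.vstack([np.ones(n), np.sign(rng.normal(size=n))])
        vals[1, 0] = 1.0
        Z = MarkerMatrix(vals, ["const", "var"], [f"s{i}" for i in range(n)])
        y = TraitVector(rng.normal(size=n), Z.individual_ids, "t")
        res = scan_1d(Z, _identity_ec(y))
        assert list(res.table["status"]) == ["singular", "ok"]

    def test_p_and_neglog10p_consistent(self, setup30):
        Z, K, y, vc, ec = setup30
        t = scan_1d(Z, ec).table
        ok = t[t["status"] == "ok"]
        np.testing.assert_allclose(ok["neglog10p"],
                                   -np.log10(np.maximum(ok["p"], 1e-300)),
                                   atol=1e-10)
        assert (ok["p"] >= 0).all() and (ok["p"] <= 1).all()
        assert (ok["wald"] >= 0).all()


class TestScan2D:
    def test_matches_pairwise_gls_oracle(self, setup30):
        """Every pair row reproduces an explicit direct-inverse GLS fit."""
        Z, K, y, vc, ec = setup30
        res = scan_2d(Z, ec, chunk_size=7)
        Cinv = np.linalg.inv(K.hmat(vc.lambda_a, vc.lambda_aa) + np.eye(K.n))
        t = res.table.set_index(["marker_i", "marker_j"])
        for i, j in all_pairs(Z.m):
            P = np.column_stack([np.ones(K.n), Z.values[i], Z.values[j],
                                 Z.values[i] * Z.values[j]])
            A = P.T @ Cinv @ P
            row = t.loc[(Z.marker_ids[i], Z.marker_ids[j])]
            if row["status"] == "singular":
                assert np.linalg.cond(A) > 1e10
                continue
            b = np.linalg.solve(A, P.T @ Cinv @ y.values)
            r = y.values - P @ b
            s2 = (r @ Cinv @ r) / (K.n - 4)
            var_g = (np.linalg.inv(A) * s2)[3, 3]
            wald = b[3] ** 2 / var_g
            assert row["gamma"] == pytest.approx(b[3], abs=1e-8)
            assert row["wald"] == pytest.approx(wald, abs=1e-6)
            assert row["p"] == pytest.approx(float(stats.chi2.sf(wald, 1)),
                                             abs=1e-10)

    def test_chunk_size_never_changes_output(self, setup30):
        Z, K, y, vc, ec = setup30
        base = scan_2d(Z, ec, chunk_size=1000).table
        for cs in (1, 7, 45):
            pd.testing.assert_frame_equal(scan_2d(Z, ec, chunk_size=cs).table,
                                          base)

    def test_duplicate_marker_pair_singular(self, rng):
        n = 20
        z = np.sign(rng.normal(size=n))
        Z = MarkerMatrix(np.vstack([z, z, np.sign(rng.normal(size=n))]),
                         ["a", "b", "c"], [f"s{i}" for i in range(n)])
        y = TraitVector(rng.normal(size=n), Z.individual_ids, "t")
        res = scan_2d(Z, _identity_ec(y), chunk_size=10)
        t = res.table.set_index(["marker_i", "marker_j"])
        # W_ab = z∗z = 1 under ±1 coding: collinear with the intercept
        assert t.loc[("a", "b"), "status"] == "singular"

    def test_store_threshold_matches_naive_filter(self, setup30):
        Z, K, y, vc, ec = setup30
        dense = scan_2d(Z, ec, chunk_size=11).table
        th = float(np.median(dense["neglog10p"].dropna()))
        sparse = scan_2d(Z, ec, chunk_size=11, store_threshold=th).table
        naive = dense[(dense["status"] == "ok")
                      & (dense["neglog10p"] >= th)].reset_index(drop=True)
        pd.testing.assert_frame_equal(sparse, naive)

    def test_dense_cap_enforced(self, small_trait):
        ec = _identity_ec(small_trait)
        rng = np.random.default_rng(0)
        big = MarkerMatrix(rng.choice([-1.0, 1.0], (2001, small_trait.n)),
                           [f"m{i}" for i in range(2001)],
                           small_trait.individual_ids)
        with pytest.raises(ValidationError, match="store_threshold"):
            scan_2d(big, ec)

    def test_permutation_invariance(self, setup30, rng):
        Z, K, y, vc, ec = setup30
        base = scan_1d(Z, ec).table
        perm = rng.permutation(K.n)
        ids = [y.individual_ids[i] for i in perm]
        Zp = Z.reorder_individuals(ids)
        yp = y.reorder(ids)
        ecp = build_eigen_context(K.permuted(perm), vc, yp)
        pt = scan_1d(Zp, ecp).table
        np.testing.assert_allclose(pt["p"], base["p"], atol=1e-8)


class TestSliceAndThreshold:
    def test_slice_matches_dense(self, setup30):
        Z, K, y, vc, ec = setup30
        res = scan_2d(Z, ec, chunk_size=13)
        mid = Z.marker_ids[4]
        sl = conditional_slice(res, mid)
        assert len(sl) == Z.m - 1
        partners = [m for m in Z.marker_ids if m != mid]
        assert list(sl["partner_id"]) == partners
        t = res.table
        for _, row in sl.iterrows():
            a, b = sorted([mid, row["partner_id"]],
                          key=Z.marker_ids.index)
            match = t[(t["marker_i"] == a) & (t["marker_j"] == b)]
            assert row["p"] == pytest.approx(match["p"].iloc[0])

    def test_slice_m3(self, rng):
        Z = MarkerMatrix(rng.choice([-1.0, 1.0], (3, 20)),
                         ["m1", "m2", "m3"], [f"s{i}" for i in range(20)])
        y = TraitVector(rng.normal(size=20), Z.individual_ids, "t")
        res = scan_2d(Z, _identity_ec(y), chunk_size=2)
        sl = conditional_slice(res, "m2")
        assert list(sl["partner_id"]) == ["m1", "m3"]

    def test_unknown_marker_rejected(self, setup30):
        res = scan_2d(setup30[0], setup30[4], chunk_size=10)
        with pytest.raises(KeyError):
            conditional_slice(res, "nope")

    def test_threshold_zero_and_inf(self, setup30):
        Z, K, y, vc, ec = setup30
        res = scan_2d(Z, ec, chunk_size=10)
        n_ok = int((res.table["status"] == "ok").sum())
        assert len(threshold_pairs(res, 0.0)) == n_ok
        assert len(threshold_pairs(res, np.inf)) == 0

    def test_threshold_count_matches_naive(self, setup30):
        Z, K, y, vc, ec = setup30
        res = scan_2d(Z, ec, chunk_size=10)
        th = 1.0
        got = threshold_pairs(res, th)
        naive = res.table[(res.table["status"] == "ok")
                          & (res.table["neglog10p"] >= th)]
        assert len(got) == len(naive)
        assert (np.diff(got["neglog10p"]) <= 1e-12).all()
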