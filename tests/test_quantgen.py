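import numpy as np
import pandas as pd
import pytest

import meiokit as mk
from meiokit.quantgen import (
    GRM,
    VarianceComponents,
    fit_bivariate,
    fit_repeatability,
    moment_inbreeding,
    vanraden_grm,
)


def _geno(dos, panel=None):
    dos = np.asarray(dos, dtype=np.int8)
    n, m = dos.shape
    panel = panel or mk.MarkerPanel(
        tuple(f"m{j}" for j in range(m)), ("c1",) * m, tuple(range(10, 10 * (m + 1), 10))
    )
    return mk.GenotypeMatrix([f"i{k}" for k in range(n)], panel, dos)


def _sib_pair_genotypes(rng, npair, m):
    """Two groups of npair individuals; pair i across groups are full sibs."""
    p = rng.uniform(0.2, 0.8, m)
    par1 = rng.binomial(2, p, size=(npair, m))
    par2 = rng.binomial(2, p, size=(npair, m))

    def child():
        a = (rng.random((npair, m)) < par1 / 2.0).astype(np.int8)
        b = (rng.random((npair, m)) < par2 / 2.0).astype(np.int8)
        return a + b

    return np.vstack([child(), child()]).astype(np.int8)


class TestVanRadenGrm:
    def test_toy_matches_hand_computed_formula(self):
        # X = [[0,1],[1,1],[2,0]]; p = (0.5, 1/3); denominator 17/18
        g = vanraden_grm(_geno([[0, 1], [1, 1], [2, 0]]))
        expected = np.array(
            [
                [1.17647059, 0.11764706, -1.29411765],
                [0.11764706, 0.11764706, -0.23529412],
                [-1.29411765, -0.23529412, 1.52941176],
            ]
        )
        np.testing.assert_allclose(g.matrix, expected, atol=1e-8)

    def test_duplicate_individuals_share_diagonal(self):
        g = vanraden_grm(_geno([[0, 1, 2, 1], [0, 1, 2, 1], [2, 1, 0, 0]]))
        assert g.matrix[0, 1] == pytest.approx(g.matrix[0, 0])
        assert g.matrix[0, 1] == pytest.approx(g.matrix[1, 1])

    def test_hwe_population_mean_diagonal_near_one(self):
        rng = np.random.default_rng(8)
        n, m = 400, 1500
        dos = rng.binomial(2, rng.uniform(0.1, 0.9, m), size=(n, m)).astype(np.int8)
        g = vanraden_grm(_geno(dos))
        diag = np.diag(g.matrix)
        se = diag.std(ddof=1) / np.sqrt(n)
        assert abs(diag.mean() - 1.0) < 3 * se + 0.01

    def test_all_monomorphic_rejected(self):
        with pytest.raises(ValueError):
            vanraden_grm(_geno([[2, 2], [2, 2]]))

    def test_symmetry_and_finiteness(self):
        rng = np.random.default_rng(1)
        dos = rng.integers(0, 3, size=(30, 50)).astype(np.int8)
        dos[rng.random(dos.shape) < 0.05] = -1
        g = vanraden_grm(_geno(dos))
        assert np.isfinite(g.matrix).all()
        np.testing.assert_allclose(g.matrix, g.matrix.T)


class TestMomentInbreeding:
    def test_fully_homozygous_individual_is_one(self):
        f = moment_inbreeding(_geno([[0, 2, 0, 2], [1, 1, 1, 1], [0, 1, 2, 1]]))
        assert f["i0"] == pytest.approx(1.0)

    def test_fully_heterozygous_at_half_frequency_is_minus_one(self):
        # p = 0.5 at every marker; E_hom = m/2 -> F = (0 - m/2)/(m - m/2) = -1
        f = moment_inbreeding(_geno([[1, 1, 1, 1], [0, 2, 0, 2], [2, 0, 2, 0]]))
        assert f["i0"] == pytest.approx(-1.0)

    def test_hwe_population_mean_near_zero(self):
        rng = np.random.default_rng(12)
        dos = rng.binomial(2, rng.uniform(0.2, 0.8, 2000), size=(300, 2000)).astype(np.int8)
        f = moment_inbreeding(_geno(dos))
        se = f.std(ddof=1) / np.sqrt(len(f))
        assert abs(f.mean()) < 3 * se + 0.005

    def test_no_data_individual_is_missing(self):
        f = moment_inbreeding(_geno([[-1, -1], [0, 1], [2, 1]]))
        assert np.isnan(f["i0"])


class TestRepeatabilityModel:
    def _simulate(self, rng, grm_matrix, ids, va, vpe, ve, nrep):
        q = len(ids)
        L = np.linalg.cholesky(grm_matrix + 1e-4 * np.eye(q))
        a = L @ rng.normal(0, np.sqrt(va), q) if va > 0 else np.zeros(q)
        pe = rng.normal(0, np.sqrt(vpe), q) if vpe > 0 else np.zeros(q)
        y = np.repeat(a + pe, nrep) + rng.normal(0, np.sqrt(ve), q * nrep)
        return pd.DataFrame({"fid": np.repeat(ids, nrep), "value": y})

    def test_pure_noise_with_identity_grm_has_null_h2(self):
        rng = np.random.default_rng(3)
        ids = [f"F{i}" for i in range(300)]
        grm = GRM(ids, np.eye(300), np.array([]))
        obs = self._simulate(rng, np.eye(300), ids, 0.0, 0.0, 1.0, 6)
        vc = fit_repeatability(obs, grm)
        assert vc.h2 < 2 * max(vc.h2_se, 0.02)

    def test_parameter_recovery_single_replicate(self):
        rng = np.random.default_rng(17)
        q, m = 300, 700
        dos = rng.binomial(2, rng.uniform(0.2, 0.8, m), size=(q, m)).astype(np.int8)
        grm = vanraden_grm(dos, ids=[f"F{i}" for i in range(q)])
        obs = self._simulate(rng, grm.matrix, grm.ids, 0.3, 0.1, 0.6, 8)
        vc = fit_repeatability(obs, grm)
        assert vc.converged
        assert abs(vc.v_a - 0.3) < 2.5 * vc.se_a
        assert abs(vc.v_pe - 0.1) < 2.5 * vc.se_pe
        assert abs(vc.v_e - 0.6) < 2.5 * vc.se_e

    def test_component_arithmetic_matches_published_row(self):
        """Va=1.56, Vpe=0.94, Ve=11.7 reproduce the printed Vp=14.2 and
        h2=0.11 (repeatability 0.176)."""
        vc = VarianceComponents(
            v_a=1.56, v_pe=0.94, v_e=11.7,
            se_a=0, se_pe=0, se_e=0, h2=1.56 / 14.2, h2_se=0,
            repeatability=2.5 / 14.2, repeatability_se=0,
            beta=np.array([0.0]), beta_se=np.array([0.0]),
            converged=True, n_iter=0, loglik=0.0,
        )
        assert vc.v_p == pytest.approx(14.2)
        assert round(vc.h2, 2) == 0.11
        assert vc.repeatability == pytest.approx(0.176, abs=5e-4)

    def test_components_nonnegative_and_h2_below_repeatability(self):
        rng = np.random.default_rng(23)
        ids = [f"F{i}" for i in range(150)]
        grm = GRM(ids, np.eye(150), np.array([]))
        obs = self._simulate(rng, np.eye(150), ids, 0.1, 0.2, 0.7, 5)
        vc = fit_repeatability(obs, grm)
        assert vc.v_a >= 0 and vc.v_pe >= 0 and vc.v_e >= 0
        assert 0 <= vc.h2 <= vc.repeatability <= 1

    def test_inbreeding_covariate_consumed(self):
        rng = np.random.default_rng(29)
        ids = [f"F{i}" for i in range(100)]
        grm = GRM(ids, np.eye(100), np.array([]))
        obs = self._simulate(rng, np.eye(100), ids, 0.0, 0.1, 0.9, 4)
        f = pd.Series(rng.normal(0, 0.05, 100), index=ids)
        vc = fit_repeatability(obs, grm, inbreeding=f)
        assert len(vc.beta) == 2  # intercept + regression on F


class TestBivariate:
    def test_duplicated_trait_drives_genetic_correlation_to_one(self):
        rng = np.random.default_rng(31)
        dos = _sib_pair_genotypes(rng, 80, 400)
        ids = [f"A{i}" for i in range(80)] + [f"B{i}" for i in range(80)]
        grm = vanraden_grm(dos, ids=ids)
        L = np.linalg.cholesky(grm.matrix[:80, :80] + 1e-4 * np.eye(80))
        a = L @ rng.normal(0, np.sqrt(0.4), 80)
        y = np.repeat(a, 6) + rng.normal(0, np.sqrt(0.6), 480)
        obs = pd.DataFrame({"fid": np.repeat(ids[:80], 6), "value": y})
        res = fit_bivariate(obs, obs.copy(), grm)
        assert res.r_g == pytest.approx(1.0, abs=0.02)

    @pytest.mark.parametrize("rg_true", [0.0, 0.8])
    def test_cross_group_genetic_correlation_recovery(self, rg_true):
        """Disjoint FID groups linked by cross-group full sibs recover the
        simulated genetic correlation within 2 SE."""
        rng = np.random.default_rng(200 + int(10 * rg_true))
        npair, nrep = 250, 8
        dos = _sib_pair_genotypes(rng, npair, 600)
        ids = [f"A{i}" for i in range(npair)] + [f"B{i}" for i in range(npair)]
        grm = vanraden_grm(dos, ids=ids)
        q = 2 * npair
        L = np.linalg.cholesky(grm.matrix + 1e-4 * np.eye(q))
        va = 0.3
        C = np.array([[va, rg_true * va], [rg_true * va, va]])
        a = L @ (rng.normal(size=(q, 2)) @ np.linalg.cholesky(C + 1e-12 * np.eye(2)).T)
        y1 = np.repeat(a[:npair, 0] + rng.normal(0, np.sqrt(0.1), npair), nrep)
        y1 = y1 + rng.normal(0, np.sqrt(0.6), npair * nrep)
        y2 = np.repeat(a[npair:, 1] + rng.normal(0, np.sqrt(0.1), npair), nrep)
        y2 = y2 + rng.normal(0, np.sqrt(0.6), npair * nrep)
        o1 = pd.DataFrame({"fid": np.repeat(ids[:npair], nrep), "value": y1})
        o2 = pd.DataFrame({"fid": np.repeat(ids[npair:], nrep), "value": y2})
        res = fit_bivariate(o1, o2, grm)
        assert res.r_g_defined
        assert abs(res.r_g - rg_true) < 2 * res.r_g_se

    def test_unlinked_groups_reduce_to_univariate_fits(self):
        """With a block-diagonal GRM the bivariate likelihood factorizes, so
        the bivariate diagonal equals the univariate fits."""
        rng = np.random.default_rng(41)
        q, m = 120, 500
        ids = [f"A{i}" for i in range(q)] + [f"B{i}" for i in range(q)]
        g1 = vanraden_grm(
            rng.binomial(2, rng.uniform(0.2, 0.8, m), size=(q, m)).astype(np.int8),
            ids=ids[:q],
        )
        g2 = vanraden_grm(
            rng.binomial(2, rng.uniform(0.2, 0.8, m), size=(q, m)).astype(np.int8),
            ids=ids[q:],
        )
        G = np.zeros((2 * q, 2 * q))
        G[:q, :q] = g1.matrix
        G[q:, q:] = g2.matrix
        grm = GRM(ids, G, np.array([]))

        def mk_obs(group_ids, gmat):
            L = np.linalg.cholesky(gmat + 1e-4 * np.eye(q))
            a = L @ rng.normal(0, np.sqrt(0.3), q)
            y = np.repeat(a + rng.normal(0, np.sqrt(0.15), q), 5)
            return pd.DataFrame(
                {"fid": np.repeat(group_ids, 5), "value": y + rng.normal(0, 1, 5 * q)}
            )

        o1, o2 = mk_obs(ids[:q], g1.matrix), mk_obs(ids[q:], g2.matrix)
        biv = fit_bivariate(o1, o2, grm)
        uni1 = fit_repeatability(o1, g1)
        uni2 = fit_repeatability(o2, g2)
        assert biv.v_a1 == pytest.approx(uni1.v_a, rel=1e-3, abs=1e-5)
        assert biv.v_e1 == pytest.approx(uni1.v_e, rel=1e-3, abs=1e-5)
        assert biv.v_a2 == pytest.approx(uni2.v_a, rel=1e-3, abs=1e-5)
        assert biv.v_e2 == pytest.approx(uni2.v_e, rel=1e-3, abs=1e-5)
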