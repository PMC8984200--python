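"""Pedigree relationship matrices and the Gibbs-sampling animal model."""

import numpy as np
import pandas as pd
import pytest

import keelscan as ks
from keelscan.animal_model import inbreeding_coefficients, _recode_pedigree


def tabular_a(ped):
    """Independent dense tabular construction of A (oracle)."""
    ids = ped["id"].tolist()
    idx = {i: k for k, i in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n))
    sires = [idx.get(s, -1) for s in ped["sire"]]
    dams = [idx.get(d, -1) for d in ped["dam"]]
    for i in range(n):
        s, d = sires[i], dams[i]
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
        for j in range(i):
            A[i, j] = A[j, i] = 0.5 * (
                (A[j, s] if s >= 0 else 0.0) + (A[j, d] if d >= 0 else 0.0)
            )
    return A


class TestAInverse:
    def test_founders_only_identity(self):
        ped = pd.DataFrame({"id": [1, 2], "sire": [0, 0], "dam": [0, 0]})
        assert np.array_equal(ks.build_a_inverse(ped).toarray(), np.eye(2))

    def test_trio_matches_textbook(self, trio_pedigree):
        ainv = ks.build_a_inverse(trio_pedigree).toarray()
        expected = np.array(
            [[1.5, 0.5, -1.0], [0.5, 1.5, -1.0], [-1.0, -1.0, 2.0]]
        )
        assert np.allclose(ainv, expected)
        # and it is the inverse of the directly-constructed A
        A = tabular_a(trio_pedigree)
        assert np.allclose(ainv, np.linalg.inv(A))

    def test_500_individual_pedigree_inverse_oracle(self, random_pedigree):
        """A^-1 A = I to 1e-8 on a 500-individual half-sib pedigree."""
        A = tabular_a(random_pedigree)
        ainv = ks.build_a_inverse(random_pedigree).toarray()
        assert np.abs(ainv @ A - np.eye(len(A))).max() < 1e-8

    def test_relationship_matrix_matches_oracle(self, random_pedigree):
        ped = random_pedigree.head(200)
        assert np.allclose(ks.relationship_matrix(ped), tabular_a(ped))

    def test_unordered_pedigree_rejected(self):
        ped = pd.DataFrame({"id": [3, 1, 2], "sire": [1, 0, 0], "dam": [2, 0, 0]})
        with pytest.raises(ValueError, match="topologically ordered"):
            ks.build_a_inverse(ped)

    def test_self_parent_rejected(self):
        ped = pd.DataFrame({"id": [1], "sire": [1], "dam": [0]})
        with pytest.raises(ValueError, match="its own"):
            ks.build_a_inverse(ped)

    def test_inbreeding_coefficients_full_sib_mating(self):
        ped = pd.DataFrame(
            {
                "id": [1, 2, 3, 4, 5],
                "sire": [0, 0, 1, 1, 3],
                "dam": [0, 0, 2, 2, 4],
            }
        )
        _, sire, dam = _recode_pedigree(ped)
        F = inbreeding_coefficients(sire, dam)
        assert np.allclose(F, [0, 0, 0, 0, 0.25])
        # with inbreeding accounted for, A^-1 still inverts the tabular A
        # (whose diagonal is 1 + F)
        A = tabular_a(ped)
        assert A[4, 4] == pytest.approx(1.25)
        ainv = ks.build_a_inverse(ped, inbreeding=True).toarray()
        assert np.abs(ainv @ A - np.eye(5)).max() < 1e-10


class TestHeritability:
    @pytest.mark.parametrize(
        "sa, se, expected_2dp",
        [(0.043, 0.120, 0.26), (0.063, 0.201, 0.24)],
    )
    def test_printed_variance_components(self, sa, se, expected_2dp):
        assert round(ks.heritability(sa, se), 2) == expected_2dp

    def test_symmetry_half(self):
        for c in (0.01, 1.0, 37.5):
            assert ks.heritability(c, c) == pytest.approx(0.5)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            ks.heritability(0.0, 1.0)
        with pytest.raises(ValueError):
            ks.heritability(0.1, -1.0)


@pytest.fixture(scope="module")
def small_dataset():
    cfg = ks.QuantGenConfig(
        n_founders=250, n_generations=3, family_size=3,
        sigma2_a=0.043, sigma2_e=0.120, seed=11,
    )
    return ks.simulate_pedigree_phenotypes(cfg), cfg


class TestGibbsFit:
    def test_determinism_same_seed(self, small_dataset):
        (ped, phen), _ = small_dataset
        spec = ks.ModelSpec(response="latent", n_iter=400, burn_in=100, thin=2, seed=9)
        r1 = ks.gibbs_fit(phen, ped, spec)
        r2 = ks.gibbs_fit(phen, ped, spec)
        pd.testing.assert_frame_equal(r1.samples, r2.samples)

    def test_every_draw_positive(self, small_dataset):
        (ped, phen), _ = small_dataset
        spec = ks.ModelSpec(response="latent", n_iter=600, burn_in=100, thin=2, seed=1)
        res = ks.gibbs_fit(phen, ped, spec)
        assert (res.samples["sigma2_a"] > 0).all()
        assert (res.samples["sigma2_e"] > 0).all()
        assert res.samples["h2"].between(0, 1).all()

    def test_two_seeds_agree_within_mc_error(self, small_dataset):
        (ped, phen), _ = small_dataset
        spec_a = ks.ModelSpec(response="latent", n_iter=4000, burn_in=1000, thin=5, seed=21)
        spec_b = ks.ModelSpec(response="latent", n_iter=4000, burn_in=1000, thin=5, seed=22)
        ra = ks.gibbs_fit(phen, ped, spec_a)
        rb = ks.gibbs_fit(phen, ped, spec_b)
        # conservative MC error: posterior sd (ignores the effective-sample
        # discount, but the two chains share the posterior spread)
        tol = 2 * np.hypot(ra.components.se_h2, rb.components.se_h2)
        assert abs(ra.components.h2 - rb.components.h2) < tol

    def test_null_additive_variance_recovered(self):
        cfg = ks.QuantGenConfig(
            n_founders=600, n_generations=3, family_size=3,
            sigma2_a=0.0, sigma2_e=0.163, seed=13,
        )
        ped, phen = ks.simulate_pedigree_phenotypes(cfg)
        assert len(phen) >= 5000
        spec = ks.ModelSpec(response="latent", n_iter=3000, burn_in=1000, thin=4, seed=2)
        res = ks.gibbs_fit(phen, ped, spec)
        upper95 = float(res.samples["h2"].quantile(0.95))
        assert upper95 < 0.1

    def test_agrees_with_em_reml(self):
        """Posterior means track REML point estimates on a fixed dataset."""
        cfg = ks.QuantGenConfig(
            n_founders=220, n_generations=3, family_size=3,
            sigma2_a=0.043, sigma2_e=0.120, seed=17,
        )
        ped, phen = ks.simulate_pedigree_phenotypes(cfg)
        assert len(phen) >= 2000
        sa, se = ks.em_reml(phen, ped, response="latent", max_iter=60, tol=1e-5)
        spec = ks.ModelSpec(response="latent", n_iter=5000, burn_in=1500, thin=5, seed=3)
        res = ks.gibbs_fit(phen, ped, spec)
        h2_reml = sa / (sa + se)
        assert abs(res.components.h2 - h2_reml) < 3 * res.components.se_h2

    def test_single_category_threshold_rejected(self, small_dataset):
        (ped, phen), _ = small_dataset
        phen2 = phen.copy()
        phen2["kb_level"] = 2
        spec = ks.ModelSpec(mode="threshold", n_iter=100, burn_in=10)
        with pytest.raises(ValueError, match="categories"):
            ks.gibbs_fit(phen2, ped, spec)

    def test_threshold_mode_runs_and_bounds(self, small_dataset):
        (ped, phen), _ = small_dataset
        spec = ks.ModelSpec(mode="threshold", n_iter=600, burn_in=200, thin=4, seed=5)
        res = ks.gibbs_fit(phen, ped, spec)
        assert np.allclose(res.samples["sigma2_e"], 1.0)
        assert 0 < res.components.h2 < 1

    def test_chain_too_short_rejected(self, small_dataset):
        (ped, phen), _ = small_dataset
        with pytest.raises(ValueError, match="burn_in"):
            ks.gibbs_fit(phen, ped, ks.ModelSpec(n_iter=100, burn_in=100))

    def test_phenotype_not_in_pedigree_rejected(self, trio_pedigree):
        phen = pd.DataFrame(
            {"id": [99], "cage_tier": ["down"], "kb_level": [2]}
        )
        with pytest.raises(ValueError, match="not in pedigree"):
            ks.gibbs_fit(phen, trio_pedigree, ks.ModelSpec(n_iter=10, burn_in=1, use_cage_effect=False))

    def test_single_tier_with_cage_effect_rejected(self, small_dataset):
        (ped, phen), _ = small_dataset
        phen2 = phen.copy()
        phen2["cage_tier"] = "down"
        with pytest.raises(ValueError, match="tiers"):
            ks.gibbs_fit(phen2, ped, ks.ModelSpec(n_iter=10, burn_in=1))
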