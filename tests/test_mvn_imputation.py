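"""Block partitioning, conditional-mean imputation and carry-over filling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from famimpute.mvn_imputation import (
    ImputedPanel,
    PhenotypePanel,
    carryover_fill,
    conditional_mean,
    conditional_variance,
    impute_panel,
    partition_blocks,
)
from famimpute.pedigree_io import RelationshipMatrix, compute_phi
from famimpute.variance_components import (
    MeanVector,
    VarianceComponents,
    build_joint_covariance,
    observed_means,
)

from conftest import make_random_pedigree


def brute_force_conditional(mu, sigma, y, miss):
    """Oracle: condition the full joint MVN by explicit matrix inversion."""
    m = np.flatnonzero(miss)
    o = np.flatnonzero(~miss)
    s_oo_inv = np.linalg.inv(sigma[np.ix_(o, o)])
    return mu[m] + sigma[np.ix_(m, o)] @ s_oo_inv @ (y[o] - mu[o])


def random_vc(rng):
    A = rng.normal(size=(2, 2))
    E = rng.normal(size=(2, 2))
    return VarianceComponents(A @ A.T + 0.05 * np.eye(2), E @ E.T + 0.05 * np.eye(2))


class TestPartitionBlocks:
    def test_nothing_missing_gives_full_sigma(self, nuclear_phi, rng):
        panel = PhenotypePanel(nuclear_phi.ids, rng.normal(size=(2, 4)))
        cov = build_joint_covariance(random_vc(rng), nuclear_phi)
        b = partition_blocks(panel, observed_means(panel), cov)
        assert b.idx_m.size == 0
        assert np.array_equal(b.sigma_oo, cov.sigma)

    def test_whole_phenotype_missing_extracts_cross_block(self, nuclear_phi, rng):
        values = rng.normal(size=(2, 4))
        values[1] = np.nan
        panel = PhenotypePanel(nuclear_phi.ids, values)
        mu = MeanVector(np.zeros(2), 4)
        cov = build_joint_covariance(random_vc(rng), nuclear_phi)
        b = partition_blocks(panel, mu, cov)
        assert np.array_equal(b.sigma_mo, cov.block(2, 1))

    def test_blocks_reassemble_sigma_exactly(self, rng):
        for _ in range(10):
            n = 5
            phi = RelationshipMatrix(
                [f"s{i}" for i in range(n)], np.eye(n)
            )
            values = rng.normal(size=(2, n))
            values[rng.random((2, n)) < 0.4] = np.nan
            if np.isnan(values).all():
                values[0, 0] = 0.0
            panel = PhenotypePanel(phi.ids, values)
            cov = build_joint_covariance(random_vc(rng), phi)
            mu = MeanVector(rng.normal(size=2), n)
            b = partition_blocks(panel, mu, cov)
            rebuilt = np.empty_like(cov.sigma)
            rebuilt[np.ix_(b.idx_m, b.idx_m)] = b.sigma_mm
            rebuilt[np.ix_(b.idx_m, b.idx_o)] = b.sigma_mo
            rebuilt[np.ix_(b.idx_o, b.idx_m)] = b.sigma_mo.T
            rebuilt[np.ix_(b.idx_o, b.idx_o)] = b.sigma_oo
            assert np.array_equal(rebuilt, cov.sigma)

    def test_all_missing_rejected(self, nuclear_phi, rng):
        panel = PhenotypePanel(nuclear_phi.ids, np.full((2, 4), np.nan))
        cov = build_joint_covariance(random_vc(rng), nuclear_phi)
        with pytest.raises(ValueError, match="observed"):
            partition_blocks(panel, MeanVector(np.zeros(2), 4), cov)


class TestConditionalMean:
    def test_zero_cross_covariance_returns_prior_mean(self):
        out = conditional_mean(
            mu_m=np.array([1.5]),
            mu_o=np.array([0.0]),
            sigma_mo=np.zeros((1, 1)),
            sigma_oo=np.eye(1),
            y_o=np.array([3.0]),
        )
        assert out == pytest.approx([1.5])

    def test_bivariate_regression_closed_form(self):
        # one person, phenotype 1 missing: E(y1|y2) = mu1 + rho*s1/s2*(y2-mu2)
        out = conditional_mean(
            mu_m=np.array([0.0]),
            mu_o=np.array([0.0]),
            sigma_mo=np.array([[0.8]]),
            sigma_oo=np.array([[1.0]]),
            y_o=np.array([1.0]),
        )
        assert out == pytest.approx([0.8], abs=1e-12)

    def test_matches_brute_force_on_family(self, rng, nuclear_phi):
        vc = random_vc(rng)
        cov = build_joint_covariance(vc, nuclear_phi)
        mu = np.repeat(rng.normal(size=2), 4)
        y = rng.multivariate_normal(mu, cov.sigma)
        miss = np.zeros(8, dtype=bool)
        miss[rng.choice(8, size=3, replace=False)] = True
        m, o = np.flatnonzero(miss), np.flatnonzero(~miss)
        got = conditional_mean(
            mu[m], mu[o], cov.sigma[np.ix_(m, o)], cov.sigma[np.ix_(o, o)], y[o]
        )
        assert np.allclose(got, brute_force_conditional(mu, cov.sigma, y, miss), atol=1e-10)


class TestImputePanel:
    def test_fully_observed_is_identity(self, nuclear_phi, rng):
        panel = PhenotypePanel(nuclear_phi.ids, rng.normal(size=(2, 4)))
        out = impute_panel(panel, random_vc(rng), nuclear_phi)
        assert np.array_equal(out.values, panel.values)
        assert (out.provenance == "observed").all()

    def test_isolated_individual_gets_the_means(self, rng):
        phi = RelationshipMatrix(["a", "b", "c"], np.eye(3))
        values = np.array([[1.0, 3.0, np.nan], [10.0, 30.0, np.nan]])
        panel = PhenotypePanel(phi.ids, values)
        out = impute_panel(panel, random_vc(rng), phi)
        assert out.values[0, 2] == pytest.approx(2.0)
        assert out.values[1, 2] == pytest.approx(20.0)
        assert out.provenance[0, 2] == "mvn_imputed"

    def test_oracle_equivalence_small_panels(self, rng):
        """impute_panel equals brute-force full-joint conditioning (2n <= 24)."""
        for _ in range(25):
            ped = make_random_pedigree(rng, int(rng.integers(3, 13)))
            phi = compute_phi(ped)
            n = phi.n
            vc = random_vc(rng)
            values = rng.normal(size=(2, n))
            values[rng.random((2, n)) < 0.35] = np.nan
            values[0, 0] = 0.0  # keep both phenotypes observed somewhere
            values[1, 0] = 0.0
            panel = PhenotypePanel(phi.ids, values)
            out = impute_panel(panel, vc, phi)
            mu = observed_means(panel).mu
            cov = build_joint_covariance(vc, phi)
            expect = panel.y_stacked.copy()
            miss = panel.mask_stacked
            expect[miss] = brute_force_conditional(mu, cov.sigma, panel.y_stacked, miss)
            assert np.allclose(out.values.reshape(-1), expect, atol=1e-8)

    def test_masked_truth_positively_correlated_at_high_rho(self, rng):
        n = 400
        phi = RelationshipMatrix([f"s{i}" for i in range(n)], np.eye(n))
        vc = VarianceComponents(np.zeros((2, 2)), np.array([[1.0, 0.9], [0.9, 1.0]]))
        y = rng.multivariate_normal(np.zeros(2), vc.sigma_e, size=n).T
        truth = y[1].copy()
        values = y.copy()
        hidden = rng.choice(n, size=100, replace=False)
        values[1, hidden] = np.nan
        out = impute_panel(PhenotypePanel(phi.ids, values), vc, phi)
        r = np.corrcoef(out.values[1, hidden], truth[hidden])[0, 1]
        assert r > 0.7

    def test_monotone_information_under_nested_masks(self, rng, nuclear_phi):
        """Observing an extra relative never increases conditional variance."""
        vc = random_vc(rng)
        cov = build_joint_covariance(vc, nuclear_phi)
        target = 2  # stacked position: phenotype 1 of c1
        rest = [i for i in range(8) if i != target]
        for _ in range(10):
            obs_small = list(rng.choice(rest, size=3, replace=False))
            extra = rng.choice([i for i in rest if i not in obs_small])
            obs_big = obs_small + [int(extra)]
            v = []
            for obs in (obs_small, obs_big):
                o = np.array(sorted(obs))
                cvar = conditional_variance(
                    cov.sigma[np.ix_([target], [target])],
                    cov.sigma[np.ix_([target], o)],
                    cov.sigma[np.ix_(o, o)],
                )
                v.append(cvar[0, 0])
            assert v[1] <= v[0] + 1e-10

    def test_unrelated_imputation_is_local(self, rng):
        """With phi = I, an individual's imputed value depends only on their
        own observed phenotype; perturbing other samples (but not the means)
        leaves it unchanged."""
        n = 6
        phi = RelationshipMatrix([f"s{i}" for i in range(n)], np.eye(n))
        vc = random_vc(rng)
        values = rng.normal(size=(2, n))
        values[0, 3] = np.nan
        panel = PhenotypePanel(phi.ids, values)
        mu = MeanVector(np.zeros(2), n)
        out1 = impute_panel(panel, vc, phi, mu=mu)
        perturbed = values.copy()
        perturbed[0, 1] += 2.7
        perturbed[1, 5] -= 1.3
        out2 = impute_panel(PhenotypePanel(phi.ids, perturbed), vc, phi, mu=mu)
        assert out1.values[0, 3] == pytest.approx(out2.values[0, 3], abs=1e-12)

    def test_imputed_panel_rejects_remaining_nan(self):
        with pytest.raises(ValueError, match="missing"):
            ImputedPanel(["a"], np.array([[np.nan], [1.0]]), np.full((2, 1), "observed"))

    def test_tsv_output_with_provenance_sidecar(self, tmp_path, nuclear_phi, rng):
        values = rng.normal(size=(2, 4))
        values[1, 0] = np.nan
        panel = PhenotypePanel(nuclear_phi.ids, values)
        out = impute_panel(panel, random_vc(rng), nuclear_phi)
        path = tmp_path / "imp.tsv"
        out.to_tsv(path)
        back = PhenotypePanel.from_tsv(path)
        assert np.allclose(back.values, out.values)
        prov = pd.read_csv(f"{path}.provenance.tsv", sep="\t")
        assert prov.loc[0, "pheno2"] == "mvn_imputed"


class TestImputeProperties:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        data=st.data(),
        n=st.integers(min_value=2, max_value=6),
    )
    def test_observed_entries_bit_identical_and_output_complete(self, data, n):
        """For any finite panel and missingness pattern with at least one
        observed value per phenotype, imputation never touches observed
        entries and leaves no gaps."""
        finite = st.floats(min_value=-50, max_value=50, allow_nan=False, width=64)
        values = np.array(
            [[data.draw(finite) for _ in range(n)] for _ in range(2)]
        )
        mask = np.array(
            [[data.draw(st.booleans()) for _ in range(n)] for _ in range(2)]
        )
        mask[:, 0] = False  # keep each phenotype observed somewhere
        vals = values.copy()
        vals[mask] = np.nan
        phi = RelationshipMatrix([f"s{i}" for i in range(n)], np.eye(n))
        panel = PhenotypePanel(phi.ids, vals)
        vc = VarianceComponents(
            np.array([[0.5, 0.2], [0.2, 0.5]]), np.array([[0.5, 0.1], [0.1, 0.5]])
        )
        out = impute_panel(panel, vc, phi)
        obs = ~mask
        assert np.array_equal(out.values[obs], values[obs])
        assert np.isfinite(out.values).all()
        assert set(np.unique(out.provenance[mask])) <= {"mvn_imputed"}


class TestCarryoverFill:
    def test_visit1_gap_filled_from_visit2(self):
        df = pd.DataFrame(
            {"visit1": [np.nan, 4.0], "visit2": [4.7, 4.1], "visit3": [1.0, 1.0], "visit4": [1.0, 1.0]},
            index=["a", "b"],
        )
        out, prov = carryover_fill(df)
        assert out.loc["a", "visit1"] == pytest.approx(4.7)
        assert prov.loc["a", "visit1"] == "carryover_filled"
        assert prov.loc["b", "visit1"] == "observed"

    def test_visit2_gap_filled_from_visit1(self):
        df = pd.DataFrame({"visit1": [3.3], "visit2": [np.nan]}, index=["a"])
        out, prov = carryover_fill(df)
        assert out.loc["a", "visit2"] == pytest.approx(3.3)
        assert prov.loc["a", "visit2"] == "carryover_filled"

    def test_no_gaps_unchanged(self):
        df = pd.DataFrame({"visit1": [1.0, 2.0], "visit2": [3.0, 4.0]}, index=["a", "b"])
        out, prov = carryover_fill(df)
        pd.testing.assert_frame_equal(out, df)
        assert (prov == "observed").all().all()

    def test_both_visits_missing_is_an_error(self):
        df = pd.DataFrame({"visit1": [np.nan], "visit2": [np.nan]}, index=["a"])
        with pytest.raises(ValueError, match="both visit 1 and visit 2"):
            carryover_fill(df)
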