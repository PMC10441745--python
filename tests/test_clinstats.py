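"""Demographic tests and partial correlation against independent oracles."""

import numpy as np
import pytest
from scipy import stats

from exocerna import cerna, clinstats, diffexpr
from exocerna import synthetic_data as sd
from exocerna.clinstats import (
    chisq_proportions,
    correlate_network_features,
    partial_correlation,
)


class TestChiSquare:
    def test_balanced_sexes_give_p1(self):
        chi2, p = chisq_proportions([[5, 5], [5, 5]])
        assert chi2 == 0.0 and round(p, 4) == 1.0
        _, p_corr = chisq_proportions([[5, 5], [5, 5]], correction=True)
        assert round(p_corr, 4) == 1.0  # zero statistic: correction irrelevant

    def test_perfect_association_closed_form(self):
        chi2, _ = chisq_proportions([[10, 0], [0, 10]], correction=False)
        assert chi2 == pytest.approx(20.0)

    def test_matches_closed_form_statistic(self):
        """chi2 = n(ad-bc)^2 / (row and column products) on random tables."""
        rng = np.random.default_rng(1)
        for _ in range(100):
            a, b, c, d = rng.integers(1, 30, 4)
            chi2, p = chisq_proportions([[a, b], [c, d]], correction=False)
            n = a + b + c + d
            expected = n * (a * d - b * c) ** 2 / (
                (a + b) * (c + d) * (a + c) * (b + d)
            )
            assert chi2 == pytest.approx(expected, rel=1e-12)
            assert p == pytest.approx(stats.chi2.sf(expected, 1), rel=1e-12)

    def test_zero_marginal_raises(self):
        with pytest.raises(ValueError, match="marginal"):
            chisq_proportions([[0, 0], [3, 4]])


def _recursion_oracle(x, y, covs):
    """Iterated first-order partial-correlation recursion over the covariates."""
    variables = [x, y] + [covs[:, j] for j in range(covs.shape[1])]
    m = len(variables)
    r = np.corrcoef(np.vstack(variables))
    # r_partial[i][j] controlling variables 2..k progressively
    for c in range(m - 1, 1, -1):
        r_new = r.copy()
        for i in range(c):
            for j in range(c):
                if i != j:
                    r_new[i, j] = (r[i, j] - r[i, c] * r[j, c]) / np.sqrt(
                        (1 - r[i, c] ** 2) * (1 - r[j, c] ** 2)
                    )
        r = r_new
    return r[0, 1]


def _inverse_matrix_oracle(x, y, covs):
    """Partial correlation via the inverse correlation (precision) matrix."""
    m = np.corrcoef(np.vstack([x, y] + [covs[:, j] for j in range(covs.shape[1])]))
    prec = np.linalg.inv(m)
    return -prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1])


class TestPartialCorrelation:
    def test_no_covariates_reduces_to_pearson(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=(2, 15))
        r, p = partial_correlation(x, y)
        r_ref, p_ref = stats.pearsonr(x, y)
        assert r == pytest.approx(r_ref, abs=1e-12)
        assert p == pytest.approx(p_ref, abs=1e-10)

    def test_identity_gives_r1(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=12)
        covs = rng.normal(size=(12, 2))
        r, p = partial_correlation(x, x.copy(), covs)
        assert r == pytest.approx(1.0, abs=1e-12) and p == 0.0

    def test_matches_recursion_oracle(self):
        """n=10, k=3 random instances agree with the recursion to 1e-8."""
        rng = np.random.default_rng(4)
        for _ in range(100):
            x, y = rng.normal(size=(2, 10))
            covs = rng.normal(size=(10, 3))
            r, _ = partial_correlation(x, y, covs)
            assert r == pytest.approx(_recursion_oracle(x, y, covs), abs=1e-8)

    def test_matches_inverse_matrix_method(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n, k = rng.integers(8, 20), rng.integers(1, 4)
            x, y = rng.normal(size=(2, n))
            covs = rng.normal(size=(n, k))
            r, _ = partial_correlation(x, y, covs)
            assert r == pytest.approx(_inverse_matrix_oracle(x, y, covs), abs=1e-8)

    def test_matches_pingouin(self):
        """Cross-check r and p against pingouin.partial_corr."""
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(6)
        for _ in range(10):
            df = pd.DataFrame(
                rng.normal(size=(12, 5)), columns=["x", "y", "c1", "c2", "c3"]
            )
            r, p = partial_correlation(
                df["x"], df["y"], df[["c1", "c2", "c3"]].to_numpy()
            )
            ref = pg.partial_corr(df, x="x", y="y", covar=["c1", "c2", "c3"])
            assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)
            p_col = "p_val" if "p_val" in ref.columns else "p-val"
            assert p == pytest.approx(float(ref[p_col].iloc[0]), abs=1e-8)

    def test_symmetry(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=(2, 10))
        covs = rng.normal(size=(10, 3))
        assert partial_correlation(x, y, covs)[0] == pytest.approx(
            partial_correlation(y, x, covs)[0], abs=1e-12
        )

    def test_orthogonal_covariate_leaves_r_unchanged(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=(2, 20))
        z = rng.normal(size=20)
        # orthogonalize z against intercept, x and y
        design = np.column_stack([np.ones(20), x, y])
        z = z - design @ np.linalg.lstsq(design, z, rcond=None)[0]
        r0, _ = partial_correlation(x, y)
        r1, _ = partial_correlation(x, y, z[:, None])
        assert r1 == pytest.approx(r0, abs=1e-8)

    def test_collinear_covariates_raise(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=(2, 10))
        c = rng.normal(size=10)
        covs = np.column_stack([c, 2 * c])
        with pytest.raises(clinstats.CollinearityError):
            partial_correlation(x, y, covs)

    def test_constant_input_raises(self):
        with pytest.raises(ValueError, match="constant"):
            partial_correlation(np.ones(10), np.arange(10.0))

    def test_insufficient_df_raises(self):
        rng = np.random.default_rng(10)
        with pytest.raises(ValueError, match="df"):
            partial_correlation(
                rng.normal(size=5), rng.normal(size=5), rng.normal(size=(5, 3))
            )


class TestCorrelateNetworkFeatures:
    def test_empty_network_gives_empty_table(self, small_data):
        net = cerna.CeRNANetwork(polarity=cerna.UP_MIR)
        out = correlate_network_features(net, small_data.bundle, small_data.clinical)
        assert len(out) == 0

    def test_one_row_per_feature_and_score(self, small_data, small_de_sets):
        net = cerna.build_network(small_de_sets, small_data.targets, cerna.DOWN_MIR)
        out = correlate_network_features(net, small_data.bundle, small_data.clinical)
        assert len(out) == net.graph.number_of_nodes() * 4
        assert out["n"].eq(10).all() and out["k"].eq(3).all()
        assert out["r"].between(-1, 1).all() and out["p"].between(0, 1).all()

    def test_missing_feature_raises(self, small_data, small_de_sets):
        net = cerna.build_network(small_de_sets, small_data.targets, cerna.DOWN_MIR)
        net.graph.add_node("ghost", rna_class="mRNA", direction="up")
        net.graph.add_edge("ghost", sorted(net.mirnas)[0])
        with pytest.raises(KeyError, match="ghost"):
            correlate_network_features(net, small_data.bundle, small_data.clinical)

    def test_strong_clinical_link_flagged(self):
        """clinical_link_r=0.9 features flag significant in >=90% of seeds;
        a null link flags at roughly the 5% type-I rate."""
        strong = null = 0
        n_seeds = 50
        for seed in range(n_seeds):
            for link, counter in ((0.9, "strong"), (0.0, "null")):
                cfg = sd.SimulationConfig(
                    n_lncrna=5, n_mirna=5, n_mrna=5, n_triplets=1, n_terms=2, genes_per_term=3,
                    clinical_link_r=link, seed=seed,
                )
                d = sd.generate_bundle(cfg)
                case = d.clinical[d.clinical["group"] == sd.CASE]
                lnc = d.planted[0][0]
                x = np.log2(d.bundle.lncrna.loc[lnc, case.index].to_numpy() + 1)
                cov = case[["age", "sex", "education"]].to_numpy(float)
                _, p = partial_correlation(
                    x, case["panss_total"].to_numpy(float), cov
                )
                if counter == "strong":
                    strong += p < 0.05
                else:
                    null += p < 0.05
        assert strong / n_seeds >= 0.9
        assert null / n_seeds <= 0.2


def test_demographics_table(small_data):
    demo = clinstats.demographics_table(small_data.clinical)
    assert list(demo["variable"]) == ["age", "education", "sex"]
    assert demo["p"].between(0, 1).all()
    # arms are sex-balanced by construction, so the chi-square p is 1
    assert demo.loc[demo["variable"] == "sex", "p"].iloc[0] == pytest.approx(1.0)
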