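import numpy as np
import pandas as pd
import pytest

from pedlod.mixed_assoc import (
    AdjustedTrait,
    SmallSampleError,
    adjust_phenotype,
    ld_r2,
    mixed_assoc,
    region_scan,
)
from pedlod.relatedness import KinshipMatrix, kinship_matrix
from pedlod.synthetic_data import SimConfig, simulate_dataset


def _identity_kinship(ids):
    return KinshipMatrix(
        {f"fam{i}": ([s], np.array([[0.5]])) for i, s in enumerate(ids)}
    )


# -- adjust_phenotype -------------------------------------------------------


def test_adjust_identity_no_covariates():
    df = pd.DataFrame({"sample": list("abcd"), "t": [1.0, 2.0, 3.0, 4.0]})
    adj = adjust_phenotype(df, "t", [], transform="identity")
    assert np.allclose(adj.residual, [-1.5, -0.5, 0.5, 1.5])
    assert abs(adj.residual.mean()) < 1e-10


def test_adjust_log_scale():
    df = pd.DataFrame({"sample": ["a", "b"], "t": [100.0, 100.0]})
    adj = adjust_phenotype(df, "t", [], transform="log")
    # ln(100) = 4.6052 before centering; residuals center it away
    assert np.allclose(adj.residual, 0.0)
    assert np.log(100.0) == pytest.approx(4.6052, abs=1e-4)


def test_adjust_log_rejects_nonpositive():
    df = pd.DataFrame({"sample": ["a", "b"], "t": [10.0, -1.0]})
    with pytest.raises(ValueError, match="b"):
        adjust_phenotype(df, "t", [], transform="log")


def test_adjust_duplicated_covariate_dropped():
    rng = np.random.default_rng(0)
    df = pd.DataFrame({
        "sample": [f"s{i}" for i in range(50)],
        "t": rng.standard_normal(50) + 5,
        "x": rng.standard_normal(50),
    })
    df["x_copy"] = df["x"]
    a = adjust_phenotype(df, "t", ["x"], transform="identity")
    b = adjust_phenotype(df, "t", ["x", "x_copy"], transform="identity")
    assert np.allclose(a.residual, b.residual)
    assert "x_copy" not in b.covariates


def test_adjust_categorical_expansion():
    rng = np.random.default_rng(1)
    df = pd.DataFrame({
        "sample": [f"s{i}" for i in range(60)],
        "t": rng.standard_normal(60) + 4,
        "center": rng.choice(["A", "B", "C"], 60),
    })
    adj = adjust_phenotype(df, "t", ["center"], transform="identity")
    # per-level means removed
    for lvl in "ABC":
        assert abs(adj.residual[(df["center"] == lvl).to_numpy()].mean()) < 1e-10


# -- mixed_assoc ------------------------------------------------------------


def test_matches_ols_when_kinship_uninformative():
    import statsmodels.api as sm

    rng = np.random.default_rng(2)
    n = 120
    ids = [f"s{i}" for i in range(n)]
    dos = rng.binomial(2, 0.3, n).astype(float)
    y = 0.3 * dos + rng.standard_normal(n)
    y -= y.mean()
    trait = AdjustedTrait(ids, y, "identity", [])
    res = mixed_assoc(trait, dos, _identity_kinship(ids), variant_id="v")
    ols = sm.OLS(y, sm.add_constant(dos)).fit()
    assert res.beta == pytest.approx(ols.params[1], abs=1e-6)
    assert res.se == pytest.approx(ols.bse[1], abs=1e-6)
    assert res.p == pytest.approx(ols.pvalues[1], abs=1e-6)


def test_gls_oracle_with_family_structure():
    """beta from the ML mixed model at the optimum equals closed-form GLS
    at those same variance estimates."""
    from pedlod.vclinkage import VCData, fit_polygenic

    ds = simulate_dataset(SimConfig(n_families=15, n_variants=20, seed=4))
    kin = kinship_matrix(ds.pedigrees)
    ids = ds.genotypes.samples
    rng = np.random.default_rng(0)
    y = rng.standard_normal(len(ids))
    dos = ds.genotypes.dosage[:, 0]
    X = np.column_stack([np.ones(len(ids)), dos])
    data = VCData(ids, y, X, kin)
    fit = fit_polygenic(data)
    V = fit.sigma2_a * 2 * kin.dense(ids) + fit.sigma2_e * np.eye(len(ids))
    Vi = np.linalg.inv(V)
    gls = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    assert np.abs(fit.beta - gls).max() < 1e-8


def test_dosage_scaling_equivariance():
    ds = simulate_dataset(SimConfig(n_families=12, n_variants=10, seed=6))
    kin = kinship_matrix(ds.pedigrees)
    ids = ds.genotypes.samples
    y = ds.phenotypes.set_index("sample").loc[ids, "trait_log"].to_numpy()
    y = y - y.mean()
    trait = AdjustedTrait(ids, y, "identity", [])
    dos = ds.genotypes.dosage[:, 3]
    r1 = mixed_assoc(trait, dos, kin)
    r2 = mixed_assoc(trait, 2.0 * dos, kin)
    assert r2.beta == pytest.approx(r1.beta / 2.0, rel=1e-4)
    assert r2.p == pytest.approx(r1.p, rel=1e-3)


def test_monomorphic_and_small_n_errors():
    ids = [f"s{i}" for i in range(12)]
    trait = AdjustedTrait(ids, np.arange(12.0) - 5.5, "identity", [])
    kin = _identity_kinship(ids)
    with pytest.raises(ValueError, match="monomorphic"):
        mixed_assoc(trait, np.ones(12), kin)
    small = AdjustedTrait(ids[:5], np.arange(5.0), "identity", [])
    with pytest.raises(SmallSampleError):
        mixed_assoc(small, np.array([0, 1, 2, 0, 1.0]),
                    _identity_kinship(ids[:5]))


def test_permutation_invariance():
    ds = simulate_dataset(SimConfig(n_families=10, n_variants=8, seed=8))
    kin = kinship_matrix(ds.pedigrees)
    ids = list(ds.genotypes.samples)
    rng = np.random.default_rng(1)
    y = rng.standard_normal(len(ids))
    dos = ds.genotypes.dosage[:, 2]
    trait = AdjustedTrait(ids, y, "identity", [])
    r1 = mixed_assoc(trait, dos, kin)
    perm = rng.permutation(len(ids))
    trait_p = AdjustedTrait([ids[i] for i in perm], y[perm], "identity", [])
    r2 = mixed_assoc(trait_p, dos[perm], kin)
    assert r2.beta == pytest.approx(r1.beta, rel=1e-6)
    assert r2.p == pytest.approx(r1.p, rel=1e-4)


def test_null_p_values_uniform():
    """Wald P under the null is uniform: KS test over 1000 variants."""
    from scipy import stats

    rng = np.random.default_rng(5)
    n = 150
    ids = [f"s{i}" for i in range(n)]
    kin = _identity_kinship(ids)
    y = rng.standard_normal(n)
    trait = AdjustedTrait(ids, y - y.mean(), "identity", [])
    ps = []
    for _ in range(1000):
        dos = rng.binomial(2, 0.3, n).astype(float)
        ps.append(mixed_assoc(trait, dos, kin).p)
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_region_scan_subset_and_monomorphic(qtl_dataset):
    ds = qtl_dataset
    kin = kinship_matrix(ds.pedigrees)
    ids = ds.genotypes.samples
    y = ds.phenotypes.set_index("sample").loc[ids, "trait_log"].to_numpy()
    trait = AdjustedTrait(list(ids), y - y.mean(), "identity", [])
    res = region_scan(trait, ds.genotypes, (40.0, 60.0), kin,
                      subset_ids=None, subset_label="all")
    in_window = [v for v in ds.genotypes.variants if 40.0 <= v.cM <= 60.0]
    assert 0 < len(res) <= len(in_window)
    with pytest.raises(ValueError, match="empty"):
        region_scan(trait, ds.genotypes, (40.0, 60.0), kin, subset_ids=[])


# -- LD ---------------------------------------------------------------------


def test_ld_r2_basic():
    a = np.array([0, 1, 2, 0, 1, 2.0])
    assert ld_r2(a, a) == pytest.approx(1.0)
    x = np.array([1, 1, -1, -1.0])
    ortho = np.array([1, -1, 1, -1.0])
    assert ld_r2(x, ortho) == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError):
        ld_r2(a, np.ones(6))


def test_ld_r2_ignores_missing():
    a = np.array([0, 1, 2, np.nan, 1.0])
    b = np.array([0, 1, 2, 0, np.nan])
    assert ld_r2(a, b) == pytest.approx(1.0)


def test_block_ld_simulation_matches_copy_prob():
    """Copy probability c gives dosage correlation ~c, so r2 ~ c^2 = 0.56
    at c = 0.75 -- the moderate-LD regime of linked variant pairs."""
    from pedlod.synthetic_data import gene_drop, simulate_pedigrees

    cfg = SimConfig(n_families=120, n_variants=20, seed=17,
                    ld_blocks=(4, 0.75))
    peds = simulate_pedigrees(cfg)
    g, _, _ = gene_drop(peds, cfg)
    r2s = []
    for s in range(0, 20, 4):
        r2s.append(ld_r2(g.dosage[:, s], g.dosage[:, s + 1]))
    assert np.mean(r2s) == pytest.approx(0.5625, abs=0.06)
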