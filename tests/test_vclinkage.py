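import math

import numpy as np
import pytest

from pedlod.mixed_assoc import adjust_phenotype
from pedlod.relatedness import KinshipMatrix, ibd_from_truth, kinship_matrix
from pedlod.synthetic_data import SimConfig, simulate_dataset
from pedlod.vclinkage import (
    LN10,
    LinkageScan,
    UnidentifiableError,
    VarianceComponents,
    VCData,
    conditional_lod,
    fit_linkage,
    fit_polygenic,
    genome_scan,
    lod_score,
    percent_explained,
    support_interval,
)


def _adjusted(ds):
    ph = ds.phenotypes.copy()
    ph["age_sq"] = ph["age"] ** 2
    covs = ["age", "age_sq", "sex", "center", "education"] + [
        f"PC{i}" for i in range(1, 11)
    ]
    return adjust_phenotype(ph, "trait_seconds", covs)


def _vcdata(ds, trait=None):
    trait = trait or _adjusted(ds)
    kin = kinship_matrix(ds.pedigrees)
    return VCData(
        trait.sample_ids,
        trait.residual,
        np.ones((len(trait.sample_ids), 1)),
        kin,
    ), trait, kin


@pytest.fixture(scope="module")
def small_fit(null_dataset_mod):
    data, trait, kin = _vcdata(null_dataset_mod)
    return null_dataset_mod, data, trait, kin


@pytest.fixture(scope="module")
def null_dataset_mod():
    return simulate_dataset(SimConfig(n_families=25, n_variants=60, seed=13))


# -- GLS oracle -------------------------------------------------------------


def test_profiled_beta_equals_closed_form_gls(small_fit):
    """With variances held fixed, the profiled beta must equal the direct
    generalized-least-squares solution computed on the dense covariance."""
    ds, data, trait, kin = small_fit
    rng = np.random.default_rng(0)
    X = np.column_stack(
        [np.ones(data.n), rng.standard_normal(data.n)]
    )
    d2 = VCData(trait.sample_ids, trait.residual, X, kin)
    sa, se = 0.07, 0.13
    nll, beta, beta_cov = d2.profiled_negloglik(0.0, sa, se)
    V = sa * 2 * kin.dense(trait.sample_ids) + se * np.eye(data.n)
    Vi = np.linalg.inv(V)
    gls = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ trait.residual)
    assert np.abs(beta - gls).max() < 1e-8


def test_loglik_matches_dense_mvn(small_fit):
    from scipy.stats import multivariate_normal

    ds, data, trait, kin = small_fit
    sa, se = 0.1, 0.12
    nll, beta, _ = data.profiled_negloglik(0.0, sa, se)
    V = sa * 2 * kin.dense(trait.sample_ids) + se * np.eye(data.n)
    mu = np.full(data.n, beta[0])
    expected = -multivariate_normal.logpdf(trait.residual, mu, V)
    assert nll == pytest.approx(expected, abs=1e-6)


# -- polygenic fit ----------------------------------------------------------


def test_polygenic_null_noise_gives_low_h2():
    ds = simulate_dataset(SimConfig(n_families=40, n_variants=5, h2=0.0,
                                    seed=3, covariate_effects={}))
    data, _, _ = _vcdata(ds)
    fit = fit_polygenic(data)
    assert fit.h2 <= 0.05


def test_polygenic_unidentifiable_error():
    ids = [f"s{i}" for i in range(30)]
    kin = KinshipMatrix({f"fam{i}": ([ids[i]], np.array([[0.5]]))
                         for i in range(30)})
    y = np.random.default_rng(0).standard_normal(30)
    data = VCData(ids, y, np.ones((30, 1)), kin)
    with pytest.raises(UnidentifiableError):
        fit_polygenic(data)


def test_multistart_agreement(small_fit):
    ds, data, trait, kin = small_fit
    fits = [fit_polygenic(data, seed=s) for s in (0, 1, 2)]
    lls = [f.loglik for f in fits]
    assert max(lls) - min(lls) < 1e-5


# -- LOD arithmetic ---------------------------------------------------------


def _vc(loglik, n=100):
    return VarianceComponents(0.0, 0.1, 0.1, np.zeros(1), np.eye(1),
                              loglik, n)


def test_lod_identities():
    assert lod_score(_vc(-50.0), _vc(-50.0)) == 0.0
    assert lod_score(_vc(-50.0 + LN10), _vc(-50.0)) == pytest.approx(1.0)
    # 2 ln10 LOD equals the likelihood-ratio statistic exactly
    full, null = _vc(-47.3), _vc(-50.0)
    assert 2 * LN10 * lod_score(full, null) == pytest.approx(
        2 * (full.loglik - null.loglik)
    )
    # numerical jitter below the null is floored at 0
    assert lod_score(_vc(-50.0000001), _vc(-50.0)) == 0.0
    with pytest.raises(ValueError, match="different sample"):
        lod_score(_vc(-1.0, n=10), _vc(-1.0, n=11))


def test_linkage_collapses_when_ibd_equals_prior(small_fit):
    """Pi = 2*Phi carries no locus information: the full model cannot beat
    the polygenic null."""
    ds, data, trait, kin = small_fit
    blocks = {
        fam: (ids, 2.0 * phi) for fam, (ids, phi) in kin.blocks.items()
    }
    null = fit_polygenic(data)
    full = fit_linkage(data.with_ibd(blocks), null=null)
    assert abs(full.loglik - null.loglik) < 1e-6


# -- scan -------------------------------------------------------------------


@pytest.fixture(scope="module")
def qtl_scan():
    ds = simulate_dataset(
        SimConfig(n_families=25, n_variants=60, seed=7,
                  qtl=(__import__("pedlod.synthetic_data", fromlist=["QTL"])
                       .QTL(cM=50.0, var_frac=0.25),))
    )
    trait = _adjusted(ds)
    kin = kinship_matrix(ds.pedigrees)
    data = VCData(trait.sample_ids, trait.residual,
                  np.ones((len(trait.sample_ids), 1)), kin)
    grid = np.arange(0.0, 101.0, 5.0)
    ibd = ibd_from_truth(ds.truth, ds.pedigrees, grid)
    scan = genome_scan(data, ibd, seed=0)
    return ds, data, trait, kin, ibd, scan


def test_per_pedigree_lods_sum_to_total(qtl_scan):
    ds, data, trait, kin, ibd, scan = qtl_scan
    total = np.zeros_like(scan.lod)
    for v in scan.per_pedigree_lod.values():
        total += v
    # additivity holds before the >=0 floor on the reported total
    assert np.all(np.abs(np.maximum(total, 0.0) - scan.lod) < 1e-6)


def test_qtl_variance_detected_at_peak(qtl_scan):
    ds, data, trait, kin, ibd, scan = qtl_scan
    assert scan.components[scan.peak_index].sigma2_q > 0


def test_single_family_scan_equals_total():
    ds = simulate_dataset(SimConfig(n_families=1, n_variants=20, seed=5))
    trait = _adjusted(ds)
    kin = kinship_matrix(ds.pedigrees)
    data = VCData(trait.sample_ids, trait.residual,
                  np.ones((len(trait.sample_ids), 1)), kin)
    grid = np.array([25.0, 75.0])
    ibd = ibd_from_truth(ds.truth, ds.pedigrees, grid)
    scan = genome_scan(data, ibd, seed=0)
    fam = ds.pedigrees[0].family_id
    assert np.allclose(
        np.maximum(scan.per_pedigree_lod[fam], 0.0), scan.lod, atol=1e-6
    )


def test_empty_grid_is_error(small_fit):
    from pedlod.relatedness import IBDSet

    ds, data, trait, kin = small_fit
    with pytest.raises(ValueError, match="empty"):
        genome_scan(data, IBDSet(np.array([]), {}), seed=0)


# -- support interval -------------------------------------------------------


def _scan_of(lods, grid):
    return LinkageScan(
        grid=np.asarray(grid, dtype=float), lod=np.asarray(lods, dtype=float),
        per_pedigree_lod={}, components=[], null=None,
    )


@pytest.mark.parametrize(
    "lods, grid, expected",
    [
        ([2, 4.5, 5, 4.6, 2], [0, 10, 20, 30, 40], (10.0, 30.0)),
        ([1, 1, 1, 1], [0, 5, 10, 15], (0.0, 15.0)),       # flat: whole grid
        ([5, 4.5, 2, 1], [0, 10, 20, 30], (0.0, 10.0)),    # peak at the edge
    ],
)
def test_support_interval(lods, grid, expected):
    assert support_interval(_scan_of(lods, grid), drop=1.0) == expected


# -- conditional LOD --------------------------------------------------------


def test_conditional_lod_affine_invariance(qtl_scan):
    ds, data, trait, kin, ibd, scan = qtl_scan
    j = ds.truth.qtl_variant_idx[0]
    gpos = {s: i for i, s in enumerate(ds.genotypes.samples)}
    dos = ds.genotypes.dosage[[gpos[s] for s in trait.sample_ids], j]
    peak = ibd.at(scan.peak_cM)
    pre = None
    r1 = conditional_lod(data, peak, dos, seed=0)
    r2 = conditional_lod(data, peak, 2.0 * dos + 5.0, seed=0)
    assert r1[2] == pytest.approx(r2[2], abs=1e-4)


def test_conditional_lod_constant_dosage_error(small_fit):
    ds, data, trait, kin = small_fit
    blocks = {fam: (ids, 2.0 * phi) for fam, (ids, phi) in kin.blocks.items()}
    with pytest.raises(ValueError, match="constant"):
        conditional_lod(data, blocks, np.ones(data.n))


def test_conditioning_on_causal_drops_lod(qtl_scan):
    ds, data, trait, kin, ibd, scan = qtl_scan
    j = ds.truth.qtl_variant_idx[0]
    gpos = {s: i for i, s in enumerate(ds.genotypes.samples)}
    dos = ds.genotypes.dosage[[gpos[s] for s in trait.sample_ids], j]
    qcm = float(ds.truth.variant_cM[j])
    gi = int(np.argmin(np.abs(ibd.grid_cM - qcm)))
    pre_, post_, drop = conditional_lod(
        data, ibd.at(float(ibd.grid_cM[gi])), dos, seed=0
    )
    assert drop >= 0 and post_ <= pre_ + 1e-9


# -- percent explained ------------------------------------------------------


@pytest.mark.parametrize(
    "pre, post, expected",
    [
        (16.08, 11.27, 29.91),   # ~30% of the peak
        (4.2, 4.2, 0.0),
        (6.02, 1.46, 75.75),
    ],
)
def test_percent_explained(pre, post, expected):
    assert percent_explained(pre, post) == pytest.approx(expected, abs=0.005)


def test_percent_explained_needs_positive_peak():
    with pytest.raises(ValueError):
        percent_explained(0.0, 0.0)
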