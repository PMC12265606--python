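import numpy as np
import pytest

from pedlod.pedio import GenotypeMatrix, VariantRecord
from pedlod.relatedness import (
    CapabilityError,
    IBDSet,
    haldane_theta,
    ibd_from_truth,
    ibd_hmm,
    kinship_coefficients,
    kinship_matrix,
    multipoint_ibd,
    select_markers,
    write_ibd_tsv,
)
from pedlod.synthetic_data import SimConfig, gene_drop, simulate_pedigrees

from _oracles import NaiveLanderGreen, mc_kinship
from conftest import geno_for, make_nuclear, make_three_gen_12


# -- kinship ----------------------------------------------------------------


def test_kinship_closed_forms(three_gen_12):
    ids, phi = kinship_coefficients(three_gen_12)
    ix = {s: i for i, s in enumerate(ids)}
    assert phi[ix["GP1"], ix["GP2"]] == 0.0          # unrelated founders
    assert phi[ix["GP1"], ix["K1"]] == 0.25          # parent-offspring
    assert phi[ix["K1"], ix["K2"]] == 0.25           # full sibs
    assert phi[ix["G1"], ix["G2"]] == 0.25           # full sibs (gen 3)
    assert phi[ix["G1"], ix["G4"]] == 0.0625         # first cousins
    assert phi[ix["GP1"], ix["G1"]] == 0.125         # grandparent
    assert phi[ix["K1"], ix["G4"]] == 0.125          # avuncular
    assert np.allclose(np.diag(phi), 0.5)            # non-inbred diagonal
    assert np.allclose(phi, phi.T)
    # 2*phi positive semidefinite
    assert np.linalg.eigvalsh(2 * phi).min() > -1e-12


def test_kinship_matches_gene_dropping(three_gen_12):
    ids, phi = kinship_coefficients(three_gen_12)
    est = mc_kinship(three_gen_12, 20000, np.random.default_rng(0))
    assert np.abs(est - phi).max() < 0.02


def test_kinship_block_structure():
    peds = [make_nuclear("F1"), make_three_gen_12("F2")]
    kin = kinship_matrix(peds)
    dense = kin.dense()
    n1 = len(peds[0])
    assert np.all(dense[:n1, n1:] == 0.0)


# -- marker thinning --------------------------------------------------------


def _thin_fixture(n, cms, freqs, n_samples=40, seed=0):
    rng = np.random.default_rng(seed)
    d = rng.binomial(2, freqs, size=(n_samples, n)).astype(float)
    variants = [
        VariantRecord("1", j + 1, "A", "G", f"v{j}", cM=cms[j])
        for j in range(n)
    ]
    return GenotypeMatrix(variants, [f"s{i}" for i in range(n_samples)], d)


def test_select_markers_keeps_small_windows():
    g = _thin_fixture(3, [0.1, 0.2, 0.3], np.full(3, 0.5))
    out = select_markers(g)
    assert out.n_variants == 3


def test_select_markers_takes_most_heterozygous():
    # 12 variants in one window; the 5 with highest founder 2p(1-p) survive
    freqs = np.linspace(0.02, 0.5, 12)
    cms = np.linspace(0.0, 0.49, 12)
    g = _thin_fixture(12, cms, freqs, n_samples=4000, seed=1)
    out = select_markers(g, window_cM=0.5, max_per_window=5)
    p = g.allele_freq()
    het = 2 * p * (1 - p)
    expected = sorted(np.argsort(-het)[:5])
    kept = [g.variants.index(v) for v in out.variants]
    assert kept == expected


def test_select_markers_half_open_boundary():
    g = _thin_fixture(2, [0.5, 0.999], np.full(2, 0.5))
    out = select_markers(g, window_cM=0.5, max_per_window=1)
    # both land in the second window [0.5, 1.0): only one survives
    assert out.n_variants == 1


# -- inheritance-vector HMM -------------------------------------------------


def test_haldane_limits():
    assert haldane_theta(0.0) == 0.0
    assert haldane_theta(1e9) == pytest.approx(0.5)


def test_hmm_no_data_equals_prior(nuclear5):
    ids, phi = kinship_coefficients(nuclear5)
    g = geno_for(nuclear5, np.full((5, 2), np.nan), [1.0, 3.0])
    mids, pis = multipoint_ibd(nuclear5, g, [0.0, 2.0, 4.0])
    for gi in range(3):
        assert np.abs(pis[gi] - 2 * phi).max() < 1e-12


def test_hmm_parent_offspring_always_half(nuclear5):
    rng = np.random.default_rng(3)
    g = geno_for(nuclear5, rng.integers(0, 3, size=(5, 4)), [0.5, 1.0, 2.0, 3.0])
    mids, pis = multipoint_ibd(nuclear5, g, [0.0, 1.5, 3.0],
                               allele_freqs=np.full(4, 0.5))
    i_p, i_c = mids.index("P1"), mids.index("C1")
    assert np.allclose(pis[:, i_p, i_c], 0.5, atol=1e-12)


def test_hmm_matches_naive_enumeration(nuclear5):
    """Forward-backward posterior equals brute force over all 64
    inheritance vectors, at markers and midpoints, to 1e-10."""
    cms = [0.0, 1.0, 2.5, 4.0, 5.0]
    genos = {
        "P1": [1, 1, 0, 1, 1],
        "P2": [1, 0, 1, 1, 2],
        "C1": [2, 1, 1, 2, 2],
        "C2": [0, 0, 0, 1, 1],
        "C3": [1, 1, 1, 1, 2],
    }
    dos = np.array([genos[s] for s in nuclear5.ids], dtype=float)
    g = geno_for(nuclear5, dos, cms)
    p_alt = 0.4
    grid = [0.0, 0.5, 1.0, 1.75, 2.5, 3.25, 4.0, 4.5, 5.0]
    ids, pis = multipoint_ibd(nuclear5, g, grid,
                              allele_freqs=np.full(5, p_alt))
    oracle = NaiveLanderGreen(
        nuclear5, cms, {s: genos[s] for s in genos}, p_alt
    )
    for gi, t in enumerate(grid):
        expected = oracle.pi_hat(t)
        assert np.abs(pis[gi] - expected).max() < 1e-10


def test_hmm_bit_limit():
    cfg = SimConfig(n_families=1, n_variants=4, seed=0)
    ped = simulate_pedigrees(cfg)[0]  # default sibships: far over 16 meioses
    g = geno_for(ped, np.zeros((len(ped), 1)), [1.0])
    with pytest.raises(CapabilityError, match="bit limit"):
        multipoint_ibd(ped, g, [0.0])


def test_hmm_cross_family_zero(nuclear5):
    other = make_nuclear("F2", n_children=1)
    g1 = geno_for(nuclear5, np.ones((5, 1)), [1.0])
    ibd = ibd_hmm([nuclear5, other],
                  GenotypeMatrix(g1.variants, nuclear5.ids + other.ids,
                                 np.ones((8, 1))),
                  [0.0, 1.0])
    # block container: no cross-family entries exist at all
    assert set(ibd.blocks) == {"F1", "F2"}
    at = ibd.at(1.0)
    assert at["F1"][1].shape == (5, 5)


def test_ibd_set_subset_and_tsv(tmp_path, nuclear5):
    g = geno_for(nuclear5, np.full((5, 1), np.nan), [1.0])
    ibd = ibd_hmm([nuclear5], g, [0.0, 1.0])
    sub = ibd.subset(["F1"])
    assert set(sub.blocks) == {"F1"}
    path = tmp_path / "ibd.tsv"
    write_ibd_tsv(ibd, path)
    lines = path.read_text().strip().splitlines()
    assert lines[0] == "position_cM\tid1\tid2\tpi_hat"
    assert len(lines) == 1 + 2 * (5 * 6 // 2)


# -- truth IBD --------------------------------------------------------------


def test_truth_ibd_sib_extremes_and_mean():
    """Sib-pair pi is 0, 1/2 or 1 pointwise and averages 2*phi = 1/2 over
    ~1e5 independent meiosis draws."""
    from pedlod.synthetic_data import true_ibd

    base = SimConfig(n_families=40, n_variants=10, seed=21)
    peds = simulate_pedigrees(base)
    sib_idx = []
    for ped in peds:
        kids = {}
        for m in ped.nonfounders:
            kids.setdefault((m.father_id, m.mother_id), []).append(m.id)
        pairs = []
        for sibs in kids.values():
            for i, a in enumerate(sibs):
                for b in sibs[i + 1:]:
                    pairs.append((ped.ids.index(a), ped.ids.index(b)))
        sib_idx.append((ped, pairs))
    vals = []
    for seed in range(100):
        cfg = SimConfig(n_families=40, n_variants=10, seed=seed)
        _, _, truth = gene_drop(peds[:10], cfg)
        for ped, pairs in sib_idx[:10]:
            pis = true_ibd(truth, ped.ids, np.array([60.0]))
            vals.extend(pis[0, ia, ib] for ia, ib in pairs)
    vals = np.array(vals)
    assert vals.size > 2e4
    assert set(np.round(np.unique(vals), 6)) <= {0.0, 0.5, 1.0}
    assert abs(vals.mean() - 0.5) < 0.01


def test_truth_ibd_grid_outside_map_is_error():
    cfg = SimConfig(n_families=1, n_variants=5, map_length_cM=50.0, seed=2)
    peds = simulate_pedigrees(cfg)
    _, _, truth = gene_drop(peds, cfg)
    from pedlod.synthetic_data import true_ibd

    with pytest.raises(ValueError, match="outside"):
        true_ibd(truth, peds[0].ids, np.array([60.0]))


def test_hmm_expected_pi_converges_to_twice_kinship(nuclear5):
    """E over gene drops of the HMM posterior pi matches 2*phi."""
    ids, phi = kinship_coefficients(nuclear5)
    i, j = ids.index("C1"), ids.index("C2")
    acc = []
    for seed in range(40):
        cfg = SimConfig(n_families=1, n_variants=6, map_length_cM=10.0,
                        maf_range=(0.5, 0.5), seed=seed)
        g, _, _ = gene_drop([nuclear5], cfg)
        _, pis = multipoint_ibd(nuclear5, g, [5.0],
                                allele_freqs=np.full(6, 0.5))
        acc.append(pis[0, i, j])
    # posterior mean over drops approaches the prior expectation 0.5
    assert abs(np.mean(acc) - 2 * phi[i, j]) < 0.1
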