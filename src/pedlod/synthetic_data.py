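"""Gene-dropping simulator for multigenerational families.

Emulates the structure of a family study of a timed cognitive trait:
three-generation pedigrees (a grandparent couple, their children with
married-in spouses, and grandchildren), diallelic variant dosages dropped
through the pedigree with Haldane (no-interference) recombination, and a
quantitative trait built from covariate effects, optional planted QTL
variants, a kinship-structured polygenic component, and independent noise.

The trait is generated on a log scale (log-seconds for a timed test, with
heritability defaulting to 0.29) and exponentiated to a "seconds" scale, so
the analysis side can exercise its log transform.  Every output is a pure
function of :class:`SimConfig` (including the seed), and :class:`SimTruth`
records the founder-haplotype label of every allele at every position, from
which exact identity-by-descent can be computed for testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .pedio import (
    GeneticMap,
    GenotypeMatrix,
    Individual,
    Pedigree,
    VariantRecord,
)

__all__ = ["QTL", "SimConfig", "SimTruth", "SimDataset", "simulate_pedigrees",
           "gene_drop", "simulate_phenotype", "simulate_dataset"]


@dataclass(frozen=True)
class QTL:
    """A planted causal variant: position (cM) and trait-variance fraction."""

    cM: float
    var_frac: float
    sign: int = -1  # negative = protective (shorter completion time)


@dataclass
class SimConfig:
    n_families: int = 76
    gen2_sibship: tuple[int, int] = (4, 6)   # children of the founder couple
    gen3_sibship: tuple[int, int] = (2, 4)   # grandchildren per gen-2 couple
    n_variants: int = 300
    maf_range: tuple[float, float] = (0.05, 0.5)
    map_length_cM: float = 100.0
    chrom: str = "15"
    h2: float = 0.29                  # polygenic fraction of sigma2_trait
    sigma2_trait: float = 0.25        # genetic+environmental variance, log scale
    mean_log: float = 4.5             # ~90 s geometric-mean completion time
    qtl: tuple[QTL, ...] = ()
    covariate_effects: dict = field(default_factory=lambda: {
        "age": 0.010, "age2": 1e-4, "sex": 0.05, "education": -0.08,
        "center": (0.0, -0.05, 0.08, 0.02),
    })
    ld_blocks: tuple[int, float] | None = None  # (block size, copy prob)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if self.gen2_sibship[0] < 1:
            raise ValueError("generation-2 sibship size must be >= 1")
        qfrac = sum(q.var_frac for q in self.qtl)
        if self.h2 + qfrac > 1.0 + 1e-12:
            raise ValueError(
                f"h2 ({self.h2}) + QTL variance fraction ({qfrac}) exceeds 1"
            )
        if self.map_length_cM < 0:
            raise ValueError("map_length_cM must be >= 0")


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


# ---------------------------------------------------------------------------
# pedigree simulation
# ---------------------------------------------------------------------------


def simulate_pedigrees(cfg: SimConfig) -> list[Pedigree]:
    """Three-generation families; deterministic given ``cfg.seed``."""
    rng = _rng(cfg, 0)
    pedigrees = []
    for k in range(cfg.n_families):
        fam = f"F{k + 1:03d}"
        counter = [0]

        def nid() -> str:
            counter[0] += 1
            return f"{fam}_{counter[0]:02d}"

        members: list[Individual] = []
        gp_f = Individual(nid(), None, None, "male", fam)
        gp_m = Individual(nid(), None, None, "female", fam)
        members += [gp_f, gp_m]
        n_children = int(rng.integers(cfg.gen2_sibship[0], cfg.gen2_sibship[1] + 1))
        for _ in range(n_children):
            child_sex = "male" if rng.random() < 0.5 else "female"
            child = Individual(nid(), gp_f.id, gp_m.id, child_sex, fam)
            spouse_sex = "female" if child_sex == "male" else "male"
            spouse = Individual(nid(), None, None, spouse_sex, fam)
            members += [child, spouse]
            father = child if child_sex == "male" else spouse
            mother = spouse if child_sex == "male" else child
            n_gc = int(rng.integers(cfg.gen3_sibship[0], cfg.gen3_sibship[1] + 1))
            for _ in range(n_gc):
                gc_sex = "male" if rng.random() < 0.5 else "female"
                members.append(Individual(nid(), father.id, mother.id, gc_sex, fam))
        pedigrees.append(Pedigree(fam, members))
    return pedigrees


def pedigree_generations(ped: Pedigree) -> dict[str, int]:
    """Generation number per member (1 = grandparents; married-in spouses
    take the generation of their co-parent)."""
    gen: dict[str, int] = {}
    for m in ped.members:
        if not m.is_founder:
            gen[m.id] = max(gen.get(m.father_id, 1), gen.get(m.mother_id, 1)) + 1
    for m in ped.members:
        if m.id in gen:
            continue
        partner_gen = None
        for c in ped.members:
            if c.father_id == m.id and c.mother_id in gen:
                partner_gen = gen[c.mother_id]
            elif c.mother_id == m.id and c.father_id in gen:
                partner_gen = gen[c.father_id]
        gen[m.id] = partner_gen if partner_gen is not None else 1
    return gen


# ---------------------------------------------------------------------------
# gene dropping
# ---------------------------------------------------------------------------


@dataclass
class _Gamete:
    """One meiosis: phase 0/1 between crossover points (Haldane process)."""

    start: int
    crossovers: np.ndarray  # sorted cM positions

    def phase_at(self, pos_cM: np.ndarray) -> np.ndarray:
        k = np.searchsorted(self.crossovers, pos_cM, side="right")
        return (self.start + k) % 2


@dataclass
class SimTruth:
    """Ground truth of a gene drop.

    Founder-haplotype labels are global integers (two per founder); a
    child's paternal label at any position is one of its father's two
    labels, switching only at that meiosis' crossover points.
    """

    pedigrees: list[Pedigree]
    sample_ids: list[str]
    founder_labels: dict[str, tuple[int, int]]
    gametes: dict[tuple[str, str], _Gamete]  # (individual id, "pat"|"mat")
    hap_alleles: np.ndarray  # (n_labels, n_variants) founder haplotype alleles
    variant_cM: np.ndarray
    variant_freqs: np.ndarray
    map_length_cM: float
    qtl_variant_idx: list[int] = field(default_factory=list)
    qtl_beta: list[float] = field(default_factory=list)
    true_components: dict = field(default_factory=dict)

    def labels_at(self, pos_cM: np.ndarray) -> np.ndarray:
        """Founder-haplotype labels, shape (n_samples, 2, n_positions)."""
        pos_cM = np.asarray(pos_cM, dtype=float)
        out = np.empty((len(self.sample_ids), 2, pos_cM.size), dtype=np.int32)
        row = {s: i for i, s in enumerate(self.sample_ids)}
        for ped in self.pedigrees:
            for m in ped.members:  # topological order
                i = row[m.id]
                if m.is_founder:
                    lp, lm = self.founder_labels[m.id]
                    out[i, 0] = lp
                    out[i, 1] = lm
                else:
                    for hap, parent in ((0, m.father_id), (1, m.mother_id)):
                        g = self.gametes[(m.id, "pat" if hap == 0 else "mat")]
                        phase = g.phase_at(pos_cM)
                        j = row[parent]
                        out[i, hap] = np.where(phase == 0, out[j, 0], out[j, 1])
        return out

    def to_json_dict(self) -> dict:
        return {
            "sample_ids": self.sample_ids,
            "qtl_variant_idx": self.qtl_variant_idx,
            "qtl_beta": self.qtl_beta,
            "true_components": self.true_components,
            "map_length_cM": self.map_length_cM,
        }


def _draw_variant_sites(cfg: SimConfig, rng: np.random.Generator):
    length_bp = max(int(cfg.map_length_cM * 1e6), cfg.n_variants + 1)
    pos_bp = np.unique(rng.integers(1, length_bp + 1, size=2 * cfg.n_variants + 16))
    while pos_bp.size < cfg.n_variants:  # collisions are rare at 1e6 bp/cM
        extra = rng.integers(1, length_bp + 1, size=cfg.n_variants)
        pos_bp = np.unique(np.concatenate([pos_bp, extra]))
    pos_bp = np.sort(rng.choice(pos_bp, size=cfg.n_variants, replace=False))
    gmap = GeneticMap(
        cfg.chrom, [(1, 0.0), (length_bp, float(cfg.map_length_cM))]
    )
    cms = (pos_bp - 1) / max(length_bp - 1, 1) * cfg.map_length_cM
    return pos_bp, cms.astype(float), gmap


def gene_drop(
    pedigrees: Sequence[Pedigree], cfg: SimConfig
) -> tuple[GenotypeMatrix, GeneticMap, SimTruth]:
    """Drop founder haplotypes through the pedigrees.

    Founder haplotypes are drawn in linkage equilibrium (or in LD blocks
    when ``cfg.ld_blocks`` is set); crossovers per meiosis follow a Poisson
    process at 1 per Morgan (Haldane, no interference).
    """
    rng = _rng(cfg, 1)
    pos_bp, cms, gmap = _draw_variant_sites(cfg, rng)
    nv = cfg.n_variants

    freqs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=nv)
    if cfg.ld_blocks is not None:
        bs, _ = cfg.ld_blocks
        for s in range(0, nv, bs):
            freqs[s:s + bs] = freqs[s]  # block shares the anchor frequency

    sample_ids: list[str] = []
    founder_labels: dict[str, tuple[int, int]] = {}
    gametes: dict[tuple[str, str], _Gamete] = {}
    label_count = 0
    for ped in pedigrees:
        sample_ids += ped.ids
        for m in ped.members:
            if m.is_founder:
                founder_labels[m.id] = (label_count, label_count + 1)
                label_count += 2
            else:
                for which in ("pat", "mat"):
                    ncx = rng.poisson(cfg.map_length_cM / 100.0)
                    cx = np.sort(rng.uniform(0, cfg.map_length_cM, size=ncx))
                    gametes[(m.id, which)] = _Gamete(int(rng.integers(2)), cx)

    # founder haplotype alleles
    hap = np.empty((label_count, nv), dtype=np.int8)
    if cfg.ld_blocks is None:
        hap[:] = rng.random((label_count, nv)) < freqs
    else:
        bs, copy_p = cfg.ld_blocks
        for s in range(0, nv, bs):
            e = min(s + bs, nv)
            anchor = (rng.random(label_count) < freqs[s]).astype(np.int8)
            hap[:, s] = anchor
            for j in range(s + 1, e):
                fresh = (rng.random(label_count) < freqs[j]).astype(np.int8)
                copy = rng.random(label_count) < copy_p
                hap[:, j] = np.where(copy, anchor, fresh)

    truth = SimTruth(
        pedigrees=list(pedigrees),
        sample_ids=sample_ids,
        founder_labels=founder_labels,
        gametes=gametes,
        hap_alleles=hap,
        variant_cM=cms,
        variant_freqs=freqs,
        map_length_cM=float(cfg.map_length_cM),
    )
    labels = truth.labels_at(cms)  # (n, 2, nv)
    col = np.arange(nv)[None, :]
    dosage = (hap[labels[:, 0, :], col] + hap[labels[:, 1, :], col]).astype(float)

    variants = [
        VariantRecord(
            chrom=cfg.chrom,
            pos_bp=int(pos_bp[j]),
            ref="A",
            alt="G",
            id=f"{cfg.chrom}:{int(pos_bp[j])}",
            cM=float(cms[j]),
        )
        for j in range(nv)
    ]
    g = GenotypeMatrix(variants, sample_ids, dosage)
    return g, gmap, truth


def pi_from_labels(lab: np.ndarray) -> np.ndarray:
    """IBD-sharing proportions from inheritance labels (n, 2, P) ->
    (P, n, n); diagonal is 1 + locus inbreeding, matching 2*phi."""
    n, _, P = lab.shape
    pat = lab[:, 0, :]
    mat = lab[:, 1, :]
    a = (pat[:, None, :] == pat[None, :, :]).astype(np.int8) + (
        mat[:, None, :] == mat[None, :, :]
    )
    b = (pat[:, None, :] == mat[None, :, :]).astype(np.int8) + (
        mat[:, None, :] == pat[None, :, :]
    )
    shared = np.maximum(a, b)  # alleles IBD per pair, in {0, 1, 2}
    pi = shared.astype(float) / 2.0
    idx = np.arange(n)
    pi[idx, idx, :] = 1.0 + (pat == mat)
    return np.moveaxis(pi, 2, 0)


def true_ibd(truth: SimTruth, ids: Sequence[str], grid_cM: np.ndarray) -> np.ndarray:
    """Exact IBD-sharing proportions pi from inheritance labels.

    Returns an array (n_grid, n, n); pi_ij is the proportion of the pair's
    alleles shared identical by descent (0, 1/2 or 1 for non-inbred pairs).
    """
    grid_cM = np.asarray(grid_cM, dtype=float)
    if grid_cM.size and (
        grid_cM.min() < -1e-9 or grid_cM.max() > truth.map_length_cM + 1e-9
    ):
        raise ValueError("grid position outside the simulated map")
    all_labels = truth.labels_at(grid_cM)
    row = {s: i for i, s in enumerate(truth.sample_ids)}
    lab = all_labels[[row[s] for s in ids]]  # (n, 2, P)
    return pi_from_labels(lab)


# ---------------------------------------------------------------------------
# phenotype simulation
# ---------------------------------------------------------------------------


def simulate_phenotype(
    pedigrees: Sequence[Pedigree],
    truth: SimTruth,
    g: GenotypeMatrix,
    cfg: SimConfig,
) -> pd.DataFrame:
    """Simulate the trait and covariates.

    y_log = mean + covariate effects + sum_v beta_v (dosage_v - 2 p_v)
            + polygenic + noise, with the polygenic vector drawn per family
    from N(0, sigma2_a * 2 Phi) and QTL effects centred so planted variants
    do not shift the trait mean.
    """
    from .relatedness import kinship_matrix

    rng = _rng(cfg, 2)
    qfrac = sum(q.var_frac for q in cfg.qtl)
    s2 = cfg.sigma2_trait
    s2_a = cfg.h2 * s2
    s2_e = max((1.0 - cfg.h2 - qfrac), 0.0) * s2

    ids = list(g.samples)
    n = len(ids)
    row = {s: i for i, s in enumerate(ids)}

    # --- covariates -------------------------------------------------------
    age = np.empty(n)
    sex = np.empty(n)
    center = np.empty(n, dtype=object)
    centers = ["Boston", "Columbia", "Denmark", "Pittsburgh"]
    center_p = [0.27, 0.17, 0.32, 0.24]
    for ped in pedigrees:
        gens = pedigree_generations(ped)
        fam_center = centers[rng.choice(4, p=center_p)]
        for m in ped.members:
            i = row[m.id]
            lo, hi = {1: (75, 95), 2: (50, 75)}.get(gens[m.id], (25, 50))
            age[i] = rng.uniform(lo, hi)
            sex[i] = 1.0 if m.sex == "female" else 0.0
            center[i] = fam_center
    education = (rng.random(n) < 0.85).astype(float)
    pcs = rng.standard_normal((n, 10))

    eff = cfg.covariate_effects
    center_off = dict(zip(centers, eff.get("center", (0, 0, 0, 0))))
    lp = (
        cfg.mean_log
        + eff.get("age", 0.0) * (age - 70.0)
        + eff.get("age2", 0.0) * ((age - 70.0) ** 2 - np.mean((age - 70.0) ** 2))
        + eff.get("sex", 0.0) * sex
        + eff.get("education", 0.0) * education
        + np.array([center_off[c] for c in center])
    )

    # --- planted QTL effects ---------------------------------------------
    truth.qtl_variant_idx = []
    truth.qtl_beta = []
    qtl_term = np.zeros(n)
    for q in cfg.qtl:
        j = int(np.argmin(np.abs(truth.variant_cM - q.cM)))
        p = float(truth.variant_freqs[j])
        beta = q.sign * float(np.sqrt(q.var_frac * s2 / (2 * p * (1 - p))))
        dos = g.dosage[:, j]
        qtl_term += beta * (np.nan_to_num(dos, nan=2 * p) - 2 * p)
        truth.qtl_variant_idx.append(j)
        truth.qtl_beta.append(beta)

    # --- polygenic + environmental ---------------------------------------
    kin = kinship_matrix(pedigrees)
    a = np.zeros(n)
    if s2_a > 0:
        for fam, (fids, phi) in kin.blocks.items():
            L = np.linalg.cholesky(2.0 * phi + 1e-10 * np.eye(len(fids)))
            z = rng.standard_normal(len(fids))
            vals = np.sqrt(s2_a) * (L @ z)
            for s, v in zip(fids, vals):
                a[row[s]] = v
    e = np.sqrt(s2_e) * rng.standard_normal(n)

    y_log = lp + qtl_term + a + e
    truth.true_components = {
        "sigma2_a": s2_a,
        "sigma2_e": s2_e,
        "sigma2_qtl": qfrac * s2,
        "h2": cfg.h2,
    }

    df = pd.DataFrame({
        "sample": ids,
        "family": [s.split("_")[0] for s in ids],
        "trait_seconds": np.exp(y_log),
        "trait_log": y_log,
        "age": age,
        "sex": sex,
        "center": center,
        "education": education,
    })
    for k in range(10):
        df[f"PC{k + 1}"] = pcs[:, k]
    return df


@dataclass
class SimDataset:
    config: SimConfig
    pedigrees: list[Pedigree]
    genotypes: GenotypeMatrix
    gmap: GeneticMap
    phenotypes: pd.DataFrame
    truth: SimTruth


def simulate_dataset(cfg: SimConfig) -> SimDataset:
    """Full simulated study: pedigrees, genotypes, map, phenotypes, truth."""
    peds = simulate_pedigrees(cfg)
    g, gmap, truth = gene_drop(peds, cfg)
    pheno = simulate_phenotype(peds, truth, g, cfg)
    return SimDataset(cfg, peds, g, gmap, pheno, truth)
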