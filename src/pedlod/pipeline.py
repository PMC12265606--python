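"""End-to-end orchestration: simulate or load -> adjust -> kinship -> IBD ->
scan -> family subsets -> regional association -> conditional LOD ->
nomination -> stepwise -> joint conditional LOD -> report.

The stages and their thresholds follow the family-based linkage-plus-
fine-mapping design: a variance-components LOD scan declares a peak
significant at LOD >= 3, the 1-LOD support interval defines the
fine-mapping window, families are subset by pedigree-specific LOD
(linked > 0.1; top-linked = ranked LODs summing to >= 6), and candidate
variants are nominated by the three-part association/LOD-drop rule before
stepwise joint selection.  Fixed thresholds are applied without
genome-wide correction, and the report records every threshold used.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .finemap import (
    CandidateVariant,
    family_subsets,
    joint_conditional_lod,
    nominate,
    stepwise_select,
    write_candidates_tsv,
)
from .mixed_assoc import adjust_phenotype, region_scan, write_assoc_tsv
from .pedio import (
    filter_variants,
    read_genetic_map,
    read_genotypes,
    read_pedigree,
    read_phenotypes,
    write_report,
    write_scan,
)
from .relatedness import ibd_from_truth, ibd_hmm, kinship_matrix, select_markers
from .synthetic_data import QTL, SimConfig, simulate_dataset
from .vclinkage import (
    VCData,
    fit_linkage,
    fit_polygenic,
    genome_scan,
    lod_score,
    support_interval,
)

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = (
    ["age", "age_sq", "sex", "center", "education"]
    + [f"PC{i}" for i in range(1, 11)]
)


@dataclass
class PipelineConfig:
    simulate: SimConfig | None = None
    paths: dict | None = None          # ped, vcf, map, pheno
    trait: str = "trait_seconds"
    transform: str = "log"
    covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    grid_step_cM: float = 2.0
    window_cM: float = 0.5
    max_per_window: int = 5
    min_call_rate: float = 0.90
    hwe_p_min: float = 1e-6
    maf_min: float | None = None
    significance_lod: float = 3.0
    support_drop: float = 1.0
    linked_threshold: float = 0.1
    top_cum_threshold: float = 6.0
    nominate_p_strong: float = 1e-4
    nominate_p_both: float = 0.05
    nominate_min_drop: float = 0.5
    stepwise_entry_p: float = 0.1
    stepwise_stay_p: float = 0.05
    ibd_mode: str = "auto"             # "truth" | "hmm" | "auto"
    bit_limit: int = 16
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.paths is None):
            raise ValueError("config needs exactly one of 'simulate' or 'paths'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        if sim is not None:
            qtl = tuple(QTL(**q) for q in sim.pop("qtl", []))
            for tup in ("gen2_sibship", "gen3_sibship", "maf_range", "ld_blocks"):
                if tup in sim and sim[tup] is not None:
                    sim[tup] = tuple(sim[tup])
            sim = SimConfig(qtl=qtl, **sim)
        return cls(simulate=sim, **raw)

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)  # not part of the scientific configuration
        if self.simulate is not None:
            d["simulate"] = dataclasses.asdict(self.simulate)
        return d


def _load(cfg: PipelineConfig):
    if cfg.simulate is not None:
        ds = simulate_dataset(cfg.simulate)
        return ds.pedigrees, ds.genotypes, ds.gmap, ds.phenotypes, ds.truth
    p = cfg.paths
    peds = read_pedigree(p["ped"])
    g = read_genotypes(p["vcf"])
    gmap = read_genetic_map(p["map"])
    g = g.with_cM(gmap)
    pheno = read_phenotypes(p["pheno"])
    return peds, g, gmap, pheno, None


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the whole analysis and return (and optionally write) the report."""
    out = Path(cfg.out_dir) if cfg.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    peds, g, gmap, pheno, truth = _load(cfg)
    founder_ids = [m.id for ped in peds for m in ped.founders]
    logger.info("loaded %d families, %d samples, %d variants",
                len(peds), g.n_samples, g.n_variants)

    g = filter_variants(
        g, cfg.min_call_rate, cfg.hwe_p_min, cfg.maf_min, founder_ids=founder_ids
    )
    logger.info("variant QC (call rate >= %.2f, HWE P >= %g): %d variants kept",
                cfg.min_call_rate, cfg.hwe_p_min, g.n_variants)

    pheno = pheno.copy()
    if "age" in pheno.columns and "age_sq" not in pheno.columns:
        pheno["age_sq"] = pheno["age"].astype(float) ** 2
    covs = [c for c in cfg.covariates if c in pheno.columns]
    trait = adjust_phenotype(pheno, cfg.trait, covs, transform=cfg.transform)
    logger.info("adjusted trait (%s) on %s; n=%d",
                cfg.transform, ",".join(covs), len(trait.sample_ids))

    kin = kinship_matrix(peds)

    markers = select_markers(g, cfg.window_cM, cfg.max_per_window, founder_ids)
    map_len = max(v.cM for v in g.variants) if g.n_variants else 0.0
    grid = np.round(np.arange(0.0, map_len + 1e-9, cfg.grid_step_cM), 10)

    mode = cfg.ibd_mode
    if mode == "auto":
        mode = "truth" if truth is not None else "hmm"
    if mode == "truth":
        if truth is None:
            raise ValueError("truth IBD requested but no simulation truth")
        ibd = ibd_from_truth(truth, peds, grid)
    else:
        ibd = ibd_hmm(peds, markers, grid, bit_limit=cfg.bit_limit)
    logger.info("IBD (%s mode) on %d grid points (step %.3g cM), %d markers",
                mode, grid.size, cfg.grid_step_cM, markers.n_variants)

    # analysis sample set: phenotyped, genotyped and in a pedigree
    genotyped = set(g.samples)
    in_kin = set(kin.sample_ids)
    ids = [s for s in trait.sample_ids if s in genotyped and s in in_kin]
    tpos = {s: i for i, s in enumerate(trait.sample_ids)}
    y = trait.residual[[tpos[s] for s in ids]]
    X = np.ones((len(ids), 1))
    data = VCData(ids, y, X, kin)

    null = fit_polygenic(data, seed=cfg.seed)
    logger.info("polygenic fit: h2=%.4f (sigma2_a=%.4g, sigma2_e=%.4g)",
                null.h2, null.sigma2_a, null.sigma2_e)

    scan = genome_scan(data, ibd, seed=cfg.seed, chrom=gmap.chrom)
    peak_cm, peak_lod = scan.peak_cM, scan.peak_lod
    logger.info("scan: peak LOD %.4f at %.2f cM", peak_lod, peak_cm)
    if out:
        write_scan(scan, out / "scan.tsv", gmap)

    report: dict = {
        "version": __version__,
        "config": cfg.echo(),
        "status": "ok",
        "heritability": null.h2,
        "scan": {
            "chrom": gmap.chrom,
            "n_grid": int(grid.size),
            "peak_cM": peak_cm,
            "peak_lod": peak_lod,
        },
        "n_variants_qc": g.n_variants,
        "n_markers_ibd": markers.n_variants,
        "thresholds": {
            "significance_lod": cfg.significance_lod,
            "support_drop": cfg.support_drop,
            "linked_threshold": cfg.linked_threshold,
            "top_cum_threshold": cfg.top_cum_threshold,
            "nominate_p_strong": cfg.nominate_p_strong,
            "nominate_p_both": cfg.nominate_p_both,
            "nominate_min_drop": cfg.nominate_min_drop,
            "stepwise_entry_p": cfg.stepwise_entry_p,
            "stepwise_stay_p": cfg.stepwise_stay_p,
            "multiple_testing": "fixed thresholds, no genome-wide correction",
        },
        "family_subsets": None,
        "candidates": [],
        "stepwise": {},
    }

    if peak_lod < cfg.significance_lod:
        report["status"] = "no_significant_linkage"
        logger.info("no peak reaches LOD %.2f; fine-mapping skipped",
                    cfg.significance_lod)
        if out:
            write_report(report, out / "report.json")
        return report

    lo, hi = support_interval(scan, cfg.support_drop)
    report["scan"]["support_interval_cM"] = [lo, hi]
    # the LOD curve crosses peak-drop between grid points, so the true
    # support region extends past the last in-run grid position; bracket
    # the fine-mapping window by one grid step on each side
    lo = max(float(grid.min()), lo - cfg.grid_step_cM)
    hi = min(float(grid.max()), hi + cfg.grid_step_cM)
    report["scan"]["finemap_window_cM"] = [lo, hi]
    subsets = family_subsets(
        scan.pedigree_lods_at_peak(), cfg.linked_threshold, cfg.top_cum_threshold
    )
    report["family_subsets"] = {
        "linked": subsets.linked,
        "top_linked": subsets.top_linked,
        "pedigree_lods_at_peak": {
            f: round(v, 6) for f, v in subsets.pedigree_lods.items()
        },
        "threshold_not_reached": subsets.threshold_not_reached,
    }
    logger.info("family subsets: %d linked, %d top-linked",
                len(subsets.linked), len(subsets.top_linked))

    fam_of = kin.family_of()
    subset_ids = {
        "linked": [s for s in ids if fam_of[s] in set(subsets.linked)],
        "top_linked": [s for s in ids if fam_of[s] in set(subsets.top_linked)],
    }
    peak_blocks = ibd.at(scan.peak_cM)

    # per-subset association over the support interval
    assoc = {}
    for label in ("linked", "top_linked"):
        res = region_scan(
            trait, g, (lo, hi), kin, subset_ids[label], label, seed=cfg.seed
        )
        assoc[label] = {r.variant_id: r for r in res}
        logger.info("association (%s): %d variants tested", label, len(res))
        if out:
            write_assoc_tsv(res, out / f"assoc_{label}.tsv")

    # per-subset VC data and baseline peak fits, used for conditional LODs
    sub_data, sub_pre, lod_pre_subset = {}, {}, {}
    for label in ("linked", "top_linked"):
        sids = subset_ids[label]
        sy = trait.residual[[tpos[s] for s in sids]]
        sd = VCData(sids, sy, np.ones((len(sids), 1)), kin)
        n0 = fit_polygenic(sd, seed=cfg.seed)
        f0 = fit_linkage(sd.with_ibd(peak_blocks), null=n0, seed=cfg.seed)
        sub_data[label] = sd
        sub_pre[label] = (f0, n0)
        lod_pre_subset[label] = lod_score(f0, n0)
    report["peak_lod_by_subset"] = {
        k: round(v, 6) for k, v in lod_pre_subset.items()
    }

    # conditional LOD drops for variants strong in at least one subset
    strong = sorted(
        v for v in set(assoc["linked"]) | set(assoc["top_linked"])
        if min(
            assoc["linked"].get(v, _NOP).p, assoc["top_linked"].get(v, _NOP).p
        ) < cfg.nominate_p_strong
    )
    gpos = {s: i for i, s in enumerate(g.samples)}
    vidx = {v.id: j for j, v in enumerate(g.variants)}
    candidates = []
    for v in strong:
        drops = {}
        for label in ("linked", "top_linked"):
            sids = subset_ids[label]
            dos = g.dosage[[gpos[s] for s in sids], vidx[v]]
            vals = dos[~np.isnan(dos)]
            if vals.size == 0 or np.ptp(vals) == 0:
                drops[label] = None
                continue
            from .vclinkage import conditional_lod

            _, _, drop = conditional_lod(
                sub_data[label], peak_blocks, dos,
                seed=cfg.seed, pre=sub_pre[label],
            )
            drops[label] = drop
        candidates.append(
            CandidateVariant(
                variant_id=v,
                linked=assoc["linked"].get(v),
                top_linked=assoc["top_linked"].get(v),
                lod_drop_linked=drops["linked"],
                lod_drop_top=drops["top_linked"],
            )
        )
    nominate(candidates, cfg.nominate_p_strong, cfg.nominate_p_both,
             cfg.nominate_min_drop)
    report["candidates"] = [
        {
            "variant_id": c.variant_id,
            "p_linked": c.linked.p if c.linked else None,
            "p_top": c.top_linked.p if c.top_linked else None,
            "lod_drop_linked": c.lod_drop_linked,
            "lod_drop_top": c.lod_drop_top,
            "c1": c.c1, "c2": c.c2, "c3": c.c3,
            "nominated": c.nominated,
        }
        for c in candidates
    ]
    nominated_ids = [c.variant_id for c in candidates if c.nominated]
    logger.info("nomination: %d candidates, %d nominated",
                len(candidates), len(nominated_ids))
    if out:
        write_candidates_tsv(candidates, out / "candidates.tsv")

    # stepwise selection + joint conditional LOD, per subset
    for label in ("linked", "top_linked"):
        sids = subset_ids[label]
        entry = {"selected": [], "lod_pre": lod_pre_subset[label],
                 "lod_post": lod_pre_subset[label], "percent_explained": 0.0,
                 "steps": []}
        if nominated_ids:
            tsub = _subset_trait(trait, sids)
            dosages = {
                v: g.dosage[[gpos[s] for s in sids], vidx[v]]
                for v in nominated_ids
            }
            dosages = {
                v: d for v, d in dosages.items()
                if np.ptp(d[~np.isnan(d)]) > 0
            }
            if dosages:
                sel = stepwise_select(
                    tsub, dosages, cfg.stepwise_entry_p, cfg.stepwise_stay_p
                )
                entry["selected"] = sel.selected
                entry["steps"] = sel.steps
                if sel.selected:
                    mat = np.column_stack([dosages[v] for v in sel.selected])
                    pre_, post_, pct = joint_conditional_lod(
                        sub_data[label], peak_blocks, mat,
                        seed=cfg.seed, pre=sub_pre[label],
                    )
                    entry.update(
                        lod_pre=pre_, lod_post=post_, percent_explained=pct
                    )
        report["stepwise"][label] = entry
        logger.info(
            "stepwise (%s): selected %s; LOD %.3f -> %.3f (%.1f%% explained)",
            label, entry["selected"] or "nothing", entry["lod_pre"],
            entry["lod_post"], entry["percent_explained"],
        )

    if out:
        write_report(report, out / "report.json")
    return report


class _Nop:
    p = 1.0


_NOP = _Nop()


def _subset_trait(trait, ids):
    from .mixed_assoc import AdjustedTrait

    tpos = {s: i for i, s in enumerate(trait.sample_ids)}
    idx = [tpos[s] for s in ids]
    return AdjustedTrait(
        sample_ids=list(ids),
        residual=trait.residual[idx],
        transform=trait.transform,
        covariates=trait.covariates,
    )
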