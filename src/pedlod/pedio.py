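"""Readers, writers and data model for pedigrees, genotypes, maps and phenotypes.

The containers here are deliberately thin: a :class:`Pedigree` is a list of
:class:`Individual` with validated parent links, a :class:`GenotypeMatrix`
holds diallelic ALT-allele dosages as a dense ``samples x variants`` float
array (NaN = missing), and a :class:`GeneticMap` is a set of (bp, cM)
anchors interpolated linearly.  Everything downstream (kinship, IBD,
variance components) consumes these containers.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

MISSING = float("nan")


class PedigreeError(ValueError):
    """Structural problem in a pedigree file (cycles, missing parents...)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Individual:
    id: str
    father_id: str | None
    mother_id: str | None
    sex: str  # "male" | "female" | "unknown"
    family_id: str

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass
class Pedigree:
    """One family: members ordered so that parents precede their children."""

    family_id: str
    members: list[Individual]

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        ids = [m.id for m in self.members]
        if len(ids) != len(set(ids)):
            raise PedigreeError(
                f"family {self.family_id}: duplicate individual id"
            )
        known = set(ids)
        for m in self.members:
            for pid in (m.father_id, m.mother_id):
                if pid is not None and pid not in known:
                    raise PedigreeError(
                        f"family {self.family_id}: parent {pid!r} of {m.id!r} "
                        "not present in the family"
                    )
        self.members = _topological_order(self.family_id, self.members)
        if not any(m.is_founder for m in self.members):
            raise PedigreeError(f"family {self.family_id}: no founder")

    @property
    def ids(self) -> list[str]:
        return [m.id for m in self.members]

    @property
    def founders(self) -> list[Individual]:
        return [m for m in self.members if m.is_founder]

    @property
    def nonfounders(self) -> list[Individual]:
        return [m for m in self.members if not m.is_founder]

    def __len__(self) -> int:
        return len(self.members)


def _topological_order(
    family_id: str, members: Sequence[Individual]
) -> list[Individual]:
    """Order members parents-first; raise PedigreeError on a cycle."""
    by_id = {m.id: m for m in members}
    state: dict[str, int] = {}  # 0 visiting, 1 done
    order: list[Individual] = []

    def visit(mid: str, stack: list[str]) -> None:
        if state.get(mid) == 1:
            return
        if state.get(mid) == 0:
            raise PedigreeError(
                f"family {family_id}: cycle in parent links involving {mid!r}"
            )
        state[mid] = 0
        m = by_id[mid]
        for pid in (m.father_id, m.mother_id):
            if pid is not None:
                visit(pid, stack + [mid])
        state[mid] = 1
        order.append(m)

    for m in members:
        visit(m.id, [])
    return order


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos_bp: int
    ref: str
    alt: str
    id: str
    cM: float = 0.0

    def __post_init__(self) -> None:
        if self.pos_bp <= 0:
            raise ValueError(f"variant {self.id}: pos_bp must be positive")


def variant_display_id(chrom: str, pos_bp: int, ref: str, alt: str,
                       vcf_id: str | None) -> str:
    """rsID when present; otherwise chrom:pos (``chrom:pos:IND`` for indels)."""
    if vcf_id and vcf_id != ".":
        return vcf_id
    if len(ref) != len(alt):
        return f"{chrom}:{pos_bp}:IND"
    return f"{chrom}:{pos_bp}"


@dataclass
class GenotypeMatrix:
    """Diallelic dosages, ``samples x variants``; NaN marks a missing call."""

    variants: list[VariantRecord]
    samples: list[str]
    dosage: np.ndarray  # float (n_samples, n_variants)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def allele_freq(self, sample_idx: np.ndarray | None = None) -> np.ndarray:
        """ALT allele frequency per variant over non-missing calls."""
        d = self.dosage if sample_idx is None else self.dosage[sample_idx]
        n_obs = (~np.isnan(d)).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n_obs > 0, np.nansum(d, axis=0) / (2 * np.maximum(n_obs, 1)), np.nan)

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.dosage), axis=0)

    def subset_samples(self, ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        idx = [pos[s] for s in ids]
        return GenotypeMatrix(self.variants, list(ids), self.dosage[idx])

    def subset_variants(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = list(idx)
        return GenotypeMatrix(
            [self.variants[i] for i in idx], self.samples, self.dosage[:, idx]
        )

    def with_cM(self, gmap: "GeneticMap") -> "GenotypeMatrix":
        """Return a copy whose variants carry interpolated cM coordinates."""
        pos = np.array([v.pos_bp for v in self.variants], dtype=float)
        cms = interpolate_cM(gmap, pos)
        new = [replace(v, cM=float(c)) for v, c in zip(self.variants, cms)]
        return GenotypeMatrix(new, self.samples, self.dosage)


@dataclass
class GeneticMap:
    chrom: str
    anchors: list[tuple[int, float]]  # (pos_bp, cM), pos strictly increasing

    def __post_init__(self) -> None:
        pos = [a[0] for a in self.anchors]
        cm = [a[1] for a in self.anchors]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("genetic map: pos_bp must be strictly increasing")
        if any(b < a for a, b in zip(cm, cm[1:])):
            raise ValueError("genetic map: cM must be non-decreasing")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

_SEX_CODE = {"1": "male", "2": "female"}


def read_pedigree(path: str | Path) -> list[Pedigree]:
    """Read a 6+ column PED/FAM file into one :class:`Pedigree` per family.

    Columns: family, id, father, mother, sex, phenotype-placeholder.
    A parent id of ``0`` means absent (founder side).
    """
    rows: dict[str, list[Individual]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise PedigreeError(
                    f"{path}:{ln}: expected >=6 columns, got {len(parts)}"
                )
            fam, iid, fa, mo, sex = parts[:5]
            rows.setdefault(fam, []).append(
                Individual(
                    id=iid,
                    father_id=None if fa == "0" else fa,
                    mother_id=None if mo == "0" else mo,
                    sex=_SEX_CODE.get(sex, "unknown"),
                    family_id=fam,
                )
            )
    return [Pedigree(fam, members) for fam, members in rows.items()]


def write_pedigree(pedigrees: Iterable[Pedigree], path: str | Path) -> None:
    sex_out = {"male": "1", "female": "2", "unknown": "0"}
    with open(path, "w") as fh:
        for ped in pedigrees:
            for m in ped.members:
                fh.write(
                    f"{ped.family_id}\t{m.id}\t{m.father_id or '0'}\t"
                    f"{m.mother_id or '0'}\t{sex_out[m.sex]}\t-9\n"
                )


def _parse_region(region: str) -> tuple[str, int, int]:
    chrom, _, span = region.partition(":")
    if not span:
        return chrom, 1, 2**62
    start, _, end = span.partition("-")
    return chrom, int(start), int(end)


def read_genotypes(
    path: str | Path, region: str | None = None
) -> GenotypeMatrix:
    """Read diallelic GT dosages from a VCF.

    Dosage is the ALT-allele count; multi-allelic records are skipped (with
    a logged count); ``region`` is ``chrom`` or ``chrom:start-end`` with
    1-based inclusive bounds, the VCF convention.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF has no samples")
    want = _parse_region(region) if region else None

    variants: list[VariantRecord] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_skipped += 1
            continue
        if want is not None:
            chrom, lo, hi = want
            if rec.CHROM != chrom or not (lo <= rec.POS <= hi):
                continue
        gts = np.asarray(rec.genotypes, dtype=object)
        dose = np.empty(len(samples), dtype=float)
        for i, g in enumerate(gts):
            a, b = g[0], g[1]
            if a < 0 or b < 0:
                dose[i] = MISSING
            else:
                dose[i] = float((a > 0) + (b > 0))
        variants.append(
            VariantRecord(
                chrom=rec.CHROM,
                pos_bp=rec.POS,
                ref=rec.REF,
                alt=rec.ALT[0],
                id=variant_display_id(
                    rec.CHROM, rec.POS, rec.REF, rec.ALT[0], rec.ID
                ),
            )
        )
        rows.append(dose)
    vcf.close()
    if n_skipped:
        logger.info("read_genotypes: skipped %d multi-allelic records", n_skipped)
    dosage = (
        np.array(rows).T if rows else np.empty((len(samples), 0))
    )
    return GenotypeMatrix(variants, samples, dosage)


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write dosages back to a minimal unphased VCF 4.2."""
    gt_of = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.samples)
            + "\n"
        )
        for j, v in enumerate(g.variants):
            calls = [
                "./." if math.isnan(d) else gt_of[d] for d in g.dosage[:, j]
            ]
            fh.write(
                f"{v.chrom}\t{v.pos_bp}\t{v.id}\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t"
                + "\t".join(calls)
                + "\n"
            )


def read_genetic_map(path: str | Path) -> GeneticMap:
    """Read a 3-column TSV (chrom, pos_bp, cM); single chromosome per file."""
    chroms: list[str] = []
    anchors: list[tuple[int, float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("chrom"):
                continue
            c, bp, cm = line.split()[:3]
            chroms.append(c)
            anchors.append((int(bp), float(cm)))
    if not anchors:
        raise ValueError(f"{path}: empty genetic map")
    if len(set(chroms)) > 1:
        raise ValueError(f"{path}: more than one chromosome in map file")
    return GeneticMap(chroms[0], anchors)


def write_genetic_map(gmap: GeneticMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos_bp\tcM\n")
        for bp, cm in gmap.anchors:
            fh.write(f"{gmap.chrom}\t{bp}\t{cm:.6f}\n")


def interpolate_cM(
    gmap: GeneticMap, pos_bp: float | np.ndarray
) -> float | np.ndarray:
    """Linear interpolation of cM at bp positions, clamped at the map ends."""
    if not gmap.anchors:
        raise ValueError("empty genetic map")
    xs = np.array([a[0] for a in gmap.anchors], dtype=float)
    ys = np.array([a[1] for a in gmap.anchors], dtype=float)
    out = np.interp(np.asarray(pos_bp, dtype=float), xs, ys)
    if np.isscalar(pos_bp) or np.ndim(pos_bp) == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# variant QC
# ---------------------------------------------------------------------------


def hwe_exact_p(n_het: int, n_hom_ref: int, n_hom_alt: int) -> float:
    """Exact Hardy-Weinberg test P-value (two-sided, by enumeration).

    Sums the probabilities of all heterozygote counts, conditional on the
    observed allele counts, that are no more likely than the observed one.
    """
    n = n_het + n_hom_ref + n_hom_alt
    if n == 0:
        return 1.0
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    # log P(het = h | n, n_rare) up to a shared constant
    hs = np.arange(n_rare % 2, n_rare + 1, 2)
    hs = hs[(2 * n - n_rare - hs) >= 0]
    logp = np.array(
        [
            h * math.log(2)
            - math.lgamma(h + 1)
            - math.lgamma((n_rare - h) // 2 + 1)
            - math.lgamma((2 * n - n_rare - h) // 2 + 1)
            for h in hs
        ]
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[hs == n_het]
    if obs.size == 0:  # inconsistent counts
        return 1.0
    p = probs[probs <= obs[0] * (1 + 1e-12)].sum()
    return float(min(1.0, p))


def filter_variants(
    g: GenotypeMatrix,
    min_call_rate: float = 0.90,
    hwe_p_min: float = 1e-6,
    maf_min: float | None = None,
    founder_ids: Sequence[str] | None = None,
) -> GenotypeMatrix:
    """Drop variants failing call rate, exact HWE, or (optionally) MAF.

    The HWE test is computed on founders only when ``founder_ids`` is given:
    related genotypes violate the random-mating assumption behind the test
    and would inflate it.
    """
    keep = g.call_rate() >= min_call_rate

    if founder_ids is not None:
        pos = {s: i for i, s in enumerate(g.samples)}
        fidx = np.array([pos[s] for s in founder_ids if s in pos], dtype=int)
    else:
        fidx = np.arange(g.n_samples)
    sub = g.dosage[fidx]
    for j in range(g.n_variants):
        if not keep[j]:
            continue
        col = sub[:, j]
        col = col[~np.isnan(col)]
        n_het = int(np.sum(col == 1))
        n_rr = int(np.sum(col == 0))
        n_aa = int(np.sum(col == 2))
        if hwe_exact_p(n_het, n_rr, n_aa) < hwe_p_min:
            keep[j] = False

    if maf_min is not None:
        af = g.allele_freq()
        maf = np.minimum(af, 1 - af)
        with np.errstate(invalid="ignore"):
            keep &= ~np.isnan(maf) & (maf >= maf_min)

    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("filter_variants: removed %d of %d variants", n_drop, g.n_variants)
    return g.subset_variants(np.flatnonzero(keep))


def mean_impute(dosage: np.ndarray) -> np.ndarray:
    """Column-wise mean imputation of missing dosages (documented default)."""
    d = np.array(dosage, dtype=float)
    if d.ndim == 1:
        d = d[:, None]
        squeeze = True
    else:
        squeeze = False
    miss = np.isnan(d)
    if miss.any():
        with np.errstate(invalid="ignore"):
            col_mean = np.nanmean(d, axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        d[miss] = np.broadcast_to(col_mean, d.shape)[miss]
        logger.debug("mean_impute: filled %d missing cells", int(miss.sum()))
    return d[:, 0] if squeeze else d


# ---------------------------------------------------------------------------
# phenotypes and results
# ---------------------------------------------------------------------------


def read_phenotypes(path: str | Path):
    """Phenotype/covariate TSV with a header and a ``sample`` id column."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    if "sample" not in df.columns:
        raise ValueError(f"{path}: phenotype table needs a 'sample' column")
    if df["sample"].duplicated().any():
        raise ValueError(f"{path}: duplicated sample ids")
    return df


def write_phenotypes(df, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_scan(scan, path: str | Path, gmap: GeneticMap | None = None) -> None:
    """Scan TSV: one row per grid position (chrom, cM, bp, LOD[, cond])."""
    chrom = scan.chrom if getattr(scan, "chrom", None) else "."
    with open(path, "w") as fh:
        cols = ["chrom", "cM", "bp", "LOD"]
        has_cond = getattr(scan, "lod_conditional", None) is not None
        if has_cond:
            cols.append("LOD_conditional")
        fh.write("\t".join(cols) + "\n")
        for i, cm in enumerate(scan.grid):
            if gmap is not None:
                xs = np.array([a[1] for a in gmap.anchors])
                ys = np.array([a[0] for a in gmap.anchors], dtype=float)
                bp = int(round(float(np.interp(cm, xs, ys))))
            else:
                bp = 0
            row = [chrom, f"{cm:.6g}", str(bp), f"{scan.lod[i]:.6f}"]
            if has_cond:
                row.append(f"{scan.lod_conditional[i]:.6f}")
            fh.write("\t".join(row) + "\n")


def _json_default(o):
    if isinstance(o, np.bool_):
        return bool(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, set):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_report(report: dict, path: str | Path) -> None:
    """Serialize a report dict to JSON, byte-stable for identical inputs."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
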