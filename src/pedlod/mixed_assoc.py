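"""Phenotype adjustment and kinship-aware mixed-model association.

The workflow mirrors the two-stage practice common in family studies:
the raw trait (log-transformed when it is a positive timed score) is first
residualized on covariates by ordinary least squares, and the residual is
then tested against each variant dosage in a linear mixed model

    y = b0 + b * dosage + a + e,    a ~ N(0, sigma2_a * 2 Phi),

whose kinship random effect keeps family structure from inflating the
test.  Variances are estimated by ML; the reported effect is the profiled
GLS estimate with a two-sided Wald P-value.  The same engine serves trait,
expression-residual (eQTL-style) and metabolite-residual (mQTL-style)
associations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pedio import GenotypeMatrix, mean_impute
from .relatedness import KinshipMatrix
from .vclinkage import VCData, fit_polygenic

logger = logging.getLogger(__name__)


@dataclass
class AdjustedTrait:
    sample_ids: list[str]
    residual: np.ndarray
    transform: str  # "log" | "identity"
    covariates: list[str]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample": self.sample_ids, "residual": self.residual})


@dataclass
class AssocResult:
    variant_id: str
    subset: str
    n: int
    af: float
    beta: float
    se: float
    p: float


class SmallSampleError(ValueError):
    """Fewer than the minimum number of samples for a mixed-model fit."""


def _design_from_covariates(
    df: pd.DataFrame, covariate_names: list[str]
) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for c in covariate_names:
        s = df[c]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(s, prefix=c, drop_first=True)
            for dc in dummies.columns:
                cols.append(dummies[dc].to_numpy(dtype=float))
                names.append(dc)
        else:
            cols.append(s.to_numpy(dtype=float))
            names.append(c)
    X = np.column_stack(cols)
    # drop collinear columns (keep the earliest of each dependent set)
    keep = [0]
    for j in range(1, X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial) > len(keep):
            keep.append(j)
        else:
            logger.warning("adjust_phenotype: dropping collinear column %r",
                           names[j])
    return X[:, keep], [names[j] for j in keep]


def adjust_phenotype(
    pheno: pd.DataFrame,
    trait: str,
    covariate_names: list[str] | None = None,
    transform: str = "log",
) -> AdjustedTrait:
    """OLS residuals of the (optionally log) trait on intercept + covariates.

    Rows with a missing trait or covariate are dropped; categorical
    covariates are expanded to indicators; collinear columns are dropped
    with a warning.  Residuals are exactly mean zero.
    """
    covariate_names = covariate_names or []
    cols = ["sample", trait] + covariate_names
    df = pheno[cols].dropna().reset_index(drop=True)
    y = df[trait].to_numpy(dtype=float)
    if transform == "log":
        bad = df.loc[y <= 0, "sample"].tolist()
        if bad:
            raise ValueError(
                f"log transform needs positive trait values; offending "
                f"samples: {bad[:10]}"
            )
        y = np.log(y)
    elif transform != "identity":
        raise ValueError(f"unknown transform {transform!r}")
    X, used = _design_from_covariates(df, covariate_names)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return AdjustedTrait(
        sample_ids=df["sample"].tolist(),
        residual=resid,
        transform=transform,
        covariates=used,
    )


def mixed_assoc(
    trait: AdjustedTrait,
    dosage: np.ndarray,
    kinship: KinshipMatrix,
    variant_id: str = ".",
    subset: str = "all",
    min_n: int = 10,
    seed: int | None = 0,
    starts: list[tuple[float, float]] | None = None,
) -> AssocResult:
    """Single-variant mixed-model association on the adjusted trait.

    ``dosage`` must align with ``trait.sample_ids``; missing dosages are
    mean-imputed.  Raises for constant dosage or n < ``min_n``.
    """
    dosage = mean_impute(np.asarray(dosage, dtype=float))
    n = len(trait.sample_ids)
    if n < min_n:
        raise SmallSampleError(f"n={n} below the minimum of {min_n}")
    if np.ptp(dosage) == 0:
        raise ValueError(f"variant {variant_id}: monomorphic dosage")
    X = np.column_stack([np.ones(n), dosage])
    data = VCData(trait.sample_ids, trait.residual, X, kinship)
    if data.identifiable():
        fit = fit_polygenic(data, seed=seed, starts=starts)
        beta = float(fit.beta[1])
        se = float(np.sqrt(fit.beta_cov[1, 1]))
        z = beta / se
        p = float(2.0 * stats.norm.sf(abs(z)))
    else:
        # kinship carries no information here: the mixed model degenerates
        # to ordinary least squares (exact t-based inference)
        y = trait.residual
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ coef
        df = n - X.shape[1]
        s2 = float(r @ r) / df
        cov = s2 * np.linalg.inv(X.T @ X)
        beta = float(coef[1])
        se = float(np.sqrt(cov[1, 1]))
        p = float(2.0 * stats.t.sf(abs(beta / se), df))
    return AssocResult(
        variant_id=variant_id,
        subset=subset,
        n=n,
        af=float(np.mean(dosage) / 2.0),
        beta=beta,
        se=se,
        p=max(p, np.finfo(float).tiny),
    )


def region_scan(
    trait: AdjustedTrait,
    g: GenotypeMatrix,
    interval_cM: tuple[float, float],
    kinship: KinshipMatrix,
    subset_ids: list[str] | None = None,
    subset_label: str = "all",
    seed: int | None = 0,
) -> list[AssocResult]:
    """Mixed-model association for every variant inside a cM interval,
    restricted to a sample subset; variants monomorphic within the subset
    are skipped with a log entry."""
    lo, hi = interval_cM
    if hi < lo:
        raise ValueError("empty interval")
    ids = subset_ids if subset_ids is not None else trait.sample_ids
    ids = [s for s in ids if s in set(trait.sample_ids)]
    if not ids:
        raise ValueError("empty sample subset")
    tpos = {s: i for i, s in enumerate(trait.sample_ids)}
    tidx = np.array([tpos[s] for s in ids])
    sub_trait = AdjustedTrait(
        sample_ids=ids,
        residual=trait.residual[tidx],
        transform=trait.transform,
        covariates=trait.covariates,
    )
    gpos = {s: i for i, s in enumerate(g.samples)}
    gidx = np.array([gpos[s] for s in ids])
    kin = kinship.subset(ids)

    # variance components of the covariate-free subset model are an
    # excellent warm start for every per-variant fit
    base = VCData(ids, sub_trait.residual, np.ones((len(ids), 1)), kin)
    if base.identifiable():
        fit0 = fit_polygenic(base, seed=seed)
        warm = [(fit0.sigma2_a, fit0.sigma2_e)]
    else:
        warm = None

    out: list[AssocResult] = []
    for j, v in enumerate(g.variants):
        if not (lo <= v.cM <= hi):
            continue
        dos = g.dosage[gidx, j]
        vals = dos[~np.isnan(dos)]
        if vals.size == 0 or np.ptp(vals) == 0:
            logger.info("region_scan: %s monomorphic in subset %s, skipped",
                        v.id, subset_label)
            continue
        out.append(
            mixed_assoc(sub_trait, dos, kin, variant_id=v.id,
                        subset=subset_label, seed=None if warm else seed,
                        starts=warm)
        )
    return out


def ld_r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors on shared
    non-missing samples."""
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("ld_r2 needs two non-constant vectors")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def write_assoc_tsv(results: list[AssocResult], path) -> None:
    """Association TSV with the published column names
    (beta = effect size estimate, se = standard error, pval = two-sided P)."""
    with open(path, "w") as fh:
        fh.write("variant_id\tsubset\tn\taf\tbeta\tse\tpval\n")
        for r in results:
            fh.write(
                f"{r.variant_id}\t{r.subset}\t{r.n}\t{r.af:.6g}\t"
                f"{r.beta:.6g}\t{r.se:.6g}\t{r.p:.6g}\n"
            )
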