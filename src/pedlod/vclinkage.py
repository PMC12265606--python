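"""Maximum-likelihood variance-components linkage engine.

The trait is modelled as multivariate normal within each family,

    y ~ N(X beta,  sigma2_q * Pi_c + sigma2_a * 2 Phi + sigma2_e * I),

where ``Pi_c`` is the locus-specific expected IBD-sharing matrix, ``Phi``
the pedigree kinship, and the likelihood factorizes over families.  The
LOD score at a locus is the log10 likelihood ratio of this model against
the polygenic null (sigma2_q = 0), floored at zero because the null sits
on the boundary of the parameter space.  ML (not REML) is used throughout
so that full and null log-likelihoods are directly comparable; variance
estimates are therefore slightly biased downward in small samples.

Fitting maximizes over the variance parameters with the fixed effects
profiled out by generalized least squares at each trial point; the
optimizer runs bounded L-BFGS-B from several documented start points (plus
one randomized start under a seed), and the polygenic-null solution is
always evaluated as a candidate so the full-model likelihood can never
fall below the null.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from .relatedness import IBDSet, KinshipMatrix

logger = logging.getLogger(__name__)

LN10 = math.log(10.0)


class UnidentifiableError(ValueError):
    """All analysis samples mutually unrelated: heritability has no
    information in the data."""


@dataclass
class VarianceComponents:
    sigma2_q: float
    sigma2_a: float
    sigma2_e: float
    beta: np.ndarray
    beta_cov: np.ndarray
    loglik: float
    n: int
    per_family_loglik: dict[str, float] = field(default_factory=dict)

    @property
    def h2(self) -> float:
        tot = self.sigma2_q + self.sigma2_a + self.sigma2_e
        return self.sigma2_a / tot if tot > 0 else 0.0


# ---------------------------------------------------------------------------
# data container: per-family blocks batched by family size
# ---------------------------------------------------------------------------


class VCData:
    """Trait, design, kinship and (optional) IBD arranged per family.

    Families are zero-padded to a common size and stacked, so every
    likelihood evaluation runs as a single batched Cholesky/inverse.
    Padding dimensions carry y = 0, X = 0 and V = sigma2_e on the
    diagonal; their (closed-form) contributions to the log-determinant and
    the sigma2_e gradient are subtracted analytically.
    """

    def __init__(
        self,
        ids: Sequence[str],
        y: np.ndarray,
        X: np.ndarray,
        kinship: KinshipMatrix,
        ibd_blocks: Mapping[str, tuple[list[str], np.ndarray]] | None = None,
    ) -> None:
        y = np.asarray(y, dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if len(ids) != y.size or X.shape[0] != y.size:
            raise ValueError("ids, y and X must agree in length")
        self.ids = list(ids)
        self.k = X.shape[1]
        self.n = y.size

        pos = {s: i for i, s in enumerate(self.ids)}
        fam_of = kinship.family_of()
        missing = [s for s in self.ids if s not in fam_of]
        if missing:
            raise ValueError(f"samples absent from kinship: {missing[:5]}")

        fams: dict[str, list[str]] = {}
        for s in self.ids:
            fams.setdefault(fam_of[s], []).append(s)
        self.family_ids = sorted(fams)
        self._members = [fams[f] for f in self.family_ids]
        self._idx = [
            np.array([pos[t] for t in members]) for members in self._members
        ]
        self._sizes = np.array([len(m) for m in self._members])
        F = len(self.family_ids)
        smax = int(self._sizes.max())
        self._smax = smax
        self._pad = (smax - self._sizes).astype(float)

        self._K = np.zeros((F, smax, smax))
        for b, (fam, members) in enumerate(zip(self.family_ids, self._members)):
            kin_ids, phi = kinship.blocks[fam]
            kpos = {t: i for i, t in enumerate(kin_ids)}
            kidx = np.array([kpos[t] for t in members])
            s = len(members)
            self._K[b, :s, :s] = 2.0 * phi[np.ix_(kidx, kidx)]

        self._Pi = self._pack_ibd(ibd_blocks) if ibd_blocks is not None else None
        self._y = y
        self._X = X
        self._Y, self._Xp = self._pack_yX(y, X)
        self.has_ibd = ibd_blocks is not None
        self.var_y = float(np.var(y)) if self.n > 1 else 1.0

    def _pack_yX(self, y, X):
        F, smax = len(self.family_ids), self._smax
        Y = np.zeros((F, smax))
        Xp = np.zeros((F, smax, X.shape[1]))
        for b, gi in enumerate(self._idx):
            Y[b, : gi.size] = y[gi]
            Xp[b, : gi.size] = X[gi]
        return Y, Xp

    def _pack_ibd(self, ibd_blocks):
        F, smax = len(self.family_ids), self._smax
        Pi = np.zeros((F, smax, smax))
        for b, (fam, members) in enumerate(zip(self.family_ids, self._members)):
            if fam not in ibd_blocks:
                raise ValueError(f"family {fam} missing from IBD blocks")
            ibd_ids, mat = ibd_blocks[fam]
            ipos = {t: i for i, t in enumerate(ibd_ids)}
            iidx = np.array([ipos[t] for t in members])
            s = len(members)
            Pi[b, :s, :s] = mat[np.ix_(iidx, iidx)]
        return Pi

    # -- construction helpers ------------------------------------------------

    def with_ibd(self, ibd_blocks) -> "VCData":
        new = VCData.__new__(VCData)
        new.__dict__.update(self.__dict__)
        new._Pi = new._pack_ibd(ibd_blocks)
        new.has_ibd = True
        return new

    def with_covariates(self, extra: np.ndarray) -> "VCData":
        """Append fixed-effect columns (e.g. a variant dosage) to X."""
        extra = np.asarray(extra, dtype=float)
        if extra.ndim == 1:
            extra = extra[:, None]
        new = VCData.__new__(VCData)
        new.__dict__.update(self.__dict__)
        new._X = np.hstack([self._X, extra])
        new.k = new._X.shape[1]
        new._Y, new._Xp = new._pack_yX(new._y, new._X)
        return new

    def identifiable(self) -> bool:
        off = self._K * (1.0 - np.eye(self._smax))
        return bool(np.any(np.abs(off) > 1e-12))

    # -- likelihood ----------------------------------------------------------

    def profiled_negloglik(
        self,
        sq: float,
        sa: float,
        se: float,
        per_family: bool = False,
        grad: bool = False,
    ):
        """-loglik at (sq, sa, se) with beta profiled by GLS.

        Returns (nll, beta, beta_cov); with ``per_family`` additionally a
        dict of per-family log-likelihood contributions at the global
        profiled beta; with ``grad`` additionally the analytic gradient of
        the profiled -loglik in (sq, sa, se) order (the beta term vanishes
        at the GLS optimum by the envelope theorem).
        """
        V = se * np.eye(self._smax)[None] + sa * self._K
        if sq != 0.0:
            if self._Pi is None:
                raise ValueError("sigma2_q > 0 but no IBD matrices loaded")
            V = V + sq * self._Pi
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return None
        # padding dims have V = se on the diagonal; remove their closed-form
        # log-determinant contribution per family
        logdet = (
            2.0 * np.sum(np.log(np.diagonal(L, axis1=1, axis2=2)), axis=1)
            - self._pad * math.log(se)
        )
        Vi = np.linalg.inv(V)
        Viy = np.einsum("bij,bj->bi", Vi, self._Y)
        ViX = Vi @ self._Xp
        xvx = np.einsum("bsk,bsl->bkl", self._Xp, ViX)
        xvy = np.einsum("bsk,bs->bk", self._Xp, Viy)
        yvy = np.einsum("bs,bs->b", self._Y, Viy)
        try:
            beta_cov = np.linalg.inv(xvx.sum(axis=0))
        except np.linalg.LinAlgError:
            return None
        beta = beta_cov @ xvy.sum(axis=0)

        quad = yvy - 2.0 * xvy @ beta + np.einsum(
            "k,bkl,l->b", beta, xvx, beta
        )
        ll = -0.5 * (logdet + quad + self._sizes * math.log(2 * math.pi))
        nll = -float(ll.sum())

        out = [nll, beta, beta_cov]
        if per_family:
            out.append({f: float(v) for f, v in zip(self.family_ids, ll)})
        if grad:
            g = np.zeros(3)  # d(-loglik)/d(sq, sa, se)
            Vir = Viy - np.einsum("bsk,k->bs", ViX, beta)
            if self._Pi is not None:
                tr = np.einsum("bij,bji->b", Vi, self._Pi)
                qf = np.einsum("bi,bij,bj->b", Vir, self._Pi, Vir)
                g[0] = 0.5 * float((tr - qf).sum())
            tr = np.einsum("bij,bji->b", Vi, self._K)
            qf = np.einsum("bi,bij,bj->b", Vir, self._K, Vir)
            g[1] = 0.5 * float((tr - qf).sum())
            # identity direction: padding dims contribute exactly 1/se each
            tr = np.einsum("bii->b", Vi) - self._pad / se
            qf = np.einsum("bs,bs->b", Vir, Vir)
            g[2] = 0.5 * float((tr - qf).sum())
            out.append(g)
        return tuple(out)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _optimize(
    data: VCData,
    include_qtl: bool,
    starts: list[tuple[float, ...]],
    seed: int | None = 0,
    ftol: float = 1e-10,
) -> VarianceComponents:
    vy = data.var_y
    lo = 0.0
    se_floor = 1e-8 * max(vy, 1e-12)
    hi = 20.0 * max(vy, 1e-12)

    def pack_nll(theta: np.ndarray):
        if include_qtl:
            sq, sa, se = theta
        else:
            sq = 0.0
            sa, se = theta
        out = data.profiled_negloglik(
            float(sq), float(sa), float(max(se, se_floor)), grad=True
        )
        if out is None:  # non-PSD trial point: optimizer retreats
            return 1e12, np.zeros(len(theta))
        nll, _, _, g = out
        return nll, (g if include_qtl else g[1:])

    if seed is not None:
        rng = np.random.default_rng(seed)
        rand = tuple(rng.uniform(0.05, 0.9, size=3 if include_qtl else 2) * vy)
        starts = starts + [rand]

    if include_qtl:
        bounds = [(lo, hi), (lo, hi), (se_floor, hi)]
    else:
        bounds = [(lo, hi), (se_floor, hi)]
    best = None
    for st in starts:
        res = minimize(
            pack_nll, np.asarray(st, dtype=float), method="L-BFGS-B",
            jac=True, bounds=bounds,
            options={"ftol": ftol, "gtol": 1e-9, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    theta = best.x
    if include_qtl:
        sq, sa, se = (float(theta[0]), float(theta[1]), float(max(theta[2], se_floor)))
    else:
        sq, sa, se = 0.0, float(theta[0]), float(max(theta[1], se_floor))
    out = data.profiled_negloglik(sq, sa, se, per_family=True)
    nll, beta, beta_cov, per_fam = out
    return VarianceComponents(
        sigma2_q=sq, sigma2_a=sa, sigma2_e=se,
        beta=beta, beta_cov=beta_cov, loglik=-nll, n=data.n,
        per_family_loglik=per_fam,
    )


def fit_polygenic(
    data: VCData,
    seed: int | None = 0,
    starts: list[tuple[float, float]] | None = None,
) -> VarianceComponents:
    """Polygenic model: y ~ N(X beta, sigma2_a 2Phi + sigma2_e I)."""
    if data.n < data.k + 2:
        raise ValueError("too few samples for the fixed-effect design")
    if not data.identifiable():
        raise UnidentifiableError(
            "all samples mutually unrelated: heritability unidentifiable"
        )
    vy = data.var_y
    if starts is None:
        starts = [(0.3 * vy, 0.7 * vy), (0.05 * vy, 0.95 * vy),
                  (0.7 * vy, 0.3 * vy)]
    return _optimize(data, include_qtl=False, starts=starts, seed=seed)


def fit_linkage(
    data: VCData,
    null: VarianceComponents | None = None,
    seed: int | None = 0,
    starts: list[tuple[float, float, float]] | None = None,
) -> VarianceComponents:
    """Full locus model with the sigma2_q * Pi component, bounded at 0.

    The null optimum (sigma2_q = 0) is always one of the candidate starts,
    so ``loglik(full) >= loglik(null)`` holds by construction.
    """
    if not data.has_ibd:
        raise ValueError("fit_linkage requires IBD matrices")
    if null is None:
        null = fit_polygenic(data, seed=seed)
    vy = data.var_y
    base = [(0.0, null.sigma2_a, null.sigma2_e)]
    if starts is None:
        starts = [
            (0.2 * vy, max(null.sigma2_a - 0.2 * vy, 0.0), null.sigma2_e),
            (0.5 * vy, 0.1 * vy, 0.4 * vy),
        ]
    return _optimize(data, include_qtl=True, starts=base + starts, seed=seed)


def lod_score(full: VarianceComponents, null: VarianceComponents) -> float:
    """LOD = (loglik_full - loglik_null) / ln 10, floored at 0."""
    if full.n != null.n:
        raise ValueError("full and null models fit on different sample sets")
    return max(0.0, (full.loglik - null.loglik) / LN10)


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------


@dataclass
class LinkageScan:
    grid: np.ndarray
    lod: np.ndarray
    per_pedigree_lod: dict[str, np.ndarray]  # family -> lod per position
    components: list[VarianceComponents]
    null: VarianceComponents
    chrom: str | None = None
    lod_conditional: np.ndarray | None = None

    @property
    def peak_index(self) -> int:
        return int(np.argmax(self.lod))

    @property
    def peak_cM(self) -> float:
        return float(self.grid[self.peak_index])

    @property
    def peak_lod(self) -> float:
        return float(self.lod[self.peak_index])

    def pedigree_lods_at_peak(self) -> dict[str, float]:
        i = self.peak_index
        return {f: float(v[i]) for f, v in self.per_pedigree_lod.items()}


def genome_scan(
    data: VCData,
    ibd: IBDSet,
    seed: int | None = 0,
    chrom: str | None = None,
) -> LinkageScan:
    """LOD and per-pedigree LOD at every grid position.

    Per-pedigree LODs are each family's log-likelihood contribution at the
    *global* full and null optima, divided by ln 10; they sum to the total
    LOD exactly (before the >=0 floor on the total).
    """
    grid = np.asarray(ibd.grid_cM, dtype=float)
    if grid.size == 0:
        raise ValueError("empty scan grid")
    null = fit_polygenic(data, seed=seed)
    lods = np.zeros(grid.size)
    per_fam = {f: np.zeros(grid.size) for f in data.family_ids}
    comps: list[VarianceComponents] = []
    prev: VarianceComponents | None = None
    vy = data.var_y
    for gi in range(grid.size):
        d = data.with_ibd(ibd.at(grid[gi]))
        if prev is not None and prev.sigma2_q > 1e-8 * vy:
            starts = [(prev.sigma2_q, prev.sigma2_a, prev.sigma2_e),
                      (0.0, null.sigma2_a, null.sigma2_e)]
        else:
            starts = [
                (0.0, null.sigma2_a, null.sigma2_e),
                (0.2 * vy, max(null.sigma2_a - 0.2 * vy, 0.0), null.sigma2_e),
            ]
        full = _optimize(d, include_qtl=True, starts=starts, seed=None)
        lods[gi] = lod_score(full, null)
        for f in data.family_ids:
            per_fam[f][gi] = (
                full.per_family_loglik[f] - null.per_family_loglik[f]
            ) / LN10
        comps.append(full)
        prev = full
    return LinkageScan(
        grid=grid, lod=lods, per_pedigree_lod=per_fam,
        components=comps, null=null, chrom=chrom,
    )


def support_interval(scan: LinkageScan, drop: float = 1.0) -> tuple[float, float]:
    """Contiguous grid run around the peak with LOD >= peak - drop."""
    if scan.grid.size == 0:
        raise ValueError("empty scan")
    thr = scan.peak_lod - drop
    ok = scan.lod >= thr
    i = scan.peak_index
    lo = i
    while lo > 0 and ok[lo - 1]:
        lo -= 1
    hi = i
    while hi < len(ok) - 1 and ok[hi + 1]:
        hi += 1
    return float(scan.grid[lo]), float(scan.grid[hi])


# ---------------------------------------------------------------------------
# conditional LOD
# ---------------------------------------------------------------------------


def conditional_lod(
    data: VCData,
    peak_ibd: Mapping[str, tuple[list[str], np.ndarray]],
    dosages: np.ndarray,
    seed: int | None = 0,
    pre: tuple[VarianceComponents, VarianceComponents] | None = None,
) -> tuple[float, float, float]:
    """LOD at the peak before and after conditioning on dosage covariates.

    The dosage columns (mean-imputed) are appended to the fixed effects of
    BOTH the full and the null model; returns (lod_pre, lod_post, drop).
    """
    from .pedio import mean_impute

    dosages = np.asarray(dosages, dtype=float)
    if dosages.ndim == 1:
        dosages = dosages[:, None]
    dosages = mean_impute(dosages)
    for j in range(dosages.shape[1]):
        if np.ptp(dosages[:, j]) == 0:
            raise ValueError(f"conditioning dosage {j} is constant")

    base = data.with_ibd(peak_ibd)
    if pre is None:
        null0 = fit_polygenic(data, seed=seed)
        full0 = fit_linkage(base, null=null0, seed=seed)
    else:
        full0, null0 = pre
    lod_pre = lod_score(full0, null0)

    cond = base.with_covariates(dosages)
    if pre is not None:
        # the unconditioned optima are excellent warm starts
        null1 = fit_polygenic(
            cond, seed=None, starts=[(null0.sigma2_a, null0.sigma2_e)]
        )
        full1 = fit_linkage(
            cond, null=null1, seed=None,
            starts=[(full0.sigma2_q, full0.sigma2_a, full0.sigma2_e)],
        )
    else:
        null1 = fit_polygenic(cond, seed=seed)
        full1 = fit_linkage(cond, null=null1, seed=seed)
    lod_post = lod_score(full1, null1)
    return lod_pre, lod_post, lod_pre - lod_post


def percent_explained(lod_pre: float, lod_post: float) -> float:
    """Percent of the linkage peak explained: 100 (pre - post) / pre."""
    if lod_pre <= 0:
        raise ValueError("lod_pre must be positive")
    return 100.0 * (lod_pre - lod_post) / lod_pre
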