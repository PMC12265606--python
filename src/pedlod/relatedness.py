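"""Pedigree kinship, marker thinning, and multipoint IBD matrices.

Multipoint identity-by-descent is computed with an exact inheritance-vector
hidden Markov model (Lander-Green): a pedigree with ``m`` meioses has
``2**m`` equally likely inheritance vectors a priori; marker genotypes
re-weight them (summing founder-allele assignments), and transitions
between map positions flip each meiosis bit independently with the Haldane
recombination fraction.  The forward-backward posterior yields the expected
proportion of alleles shared IBD, ``pi``, for every pair at every grid
point.  Pedigrees beyond the bit limit are served by simulator-truth IBD
(:func:`pedlod.synthetic_data.true_ibd`) instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .pedio import GenotypeMatrix, Pedigree

logger = logging.getLogger(__name__)


class CapabilityError(RuntimeError):
    """Pedigree too large for exact inheritance-vector enumeration."""


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------


@dataclass
class KinshipMatrix:
    """Block-diagonal kinship: ``blocks[family] = (ids, phi)``."""

    blocks: dict[str, tuple[list[str], np.ndarray]]

    @property
    def sample_ids(self) -> list[str]:
        out: list[str] = []
        for ids, _ in self.blocks.values():
            out.extend(ids)
        return out

    def family_of(self) -> dict[str, str]:
        return {s: fam for fam, (ids, _) in self.blocks.items() for s in ids}

    def dense(self, ids: Sequence[str] | None = None) -> np.ndarray:
        """Full matrix over ``ids`` (zero between families)."""
        ids = list(ids) if ids is not None else self.sample_ids
        pos = {s: i for i, s in enumerate(ids)}
        out = np.zeros((len(ids), len(ids)))
        for fids, phi in self.blocks.values():
            keep = [(k, pos[s]) for k, s in enumerate(fids) if s in pos]
            if not keep:
                continue
            loc, glob = zip(*keep)
            loc = np.array(loc)
            glob = np.array(glob)
            out[np.ix_(glob, glob)] = phi[np.ix_(loc, loc)]
        return out

    def subset(self, ids: Sequence[str]) -> "KinshipMatrix":
        ids_set = set(ids)
        blocks = {}
        for fam, (fids, phi) in self.blocks.items():
            keep = [k for k, s in enumerate(fids) if s in ids_set]
            if keep:
                idx = np.array(keep)
                blocks[fam] = ([fids[k] for k in keep], phi[np.ix_(idx, idx)])
        return KinshipMatrix(blocks)


def kinship_coefficients(ped: Pedigree) -> tuple[list[str], np.ndarray]:
    """Recursive kinship within one family (founders unrelated, non-inbred).

    phi(i,i) = (1 + phi(father, mother)) / 2 and, for j computed before i,
    phi(i,j) = (phi(father_i, j) + phi(mother_i, j)) / 2.
    """
    ids = ped.ids  # topological order: parents first
    pos = {s: k for k, s in enumerate(ids)}
    n = len(ids)
    phi = np.zeros((n, n))
    for k, m in enumerate(ped.members):
        if m.is_founder:
            phi[k, k] = 0.5
        else:
            fa, mo = pos[m.father_id], pos[m.mother_id]
            phi[k, k] = 0.5 * (1.0 + phi[fa, mo])
            for j in range(n):
                if j == k:
                    continue
                val = 0.5 * (phi[fa, j] + phi[mo, j])
                phi[k, j] = phi[j, k] = val
    return ids, phi


def kinship_matrix(pedigrees: Sequence[Pedigree]) -> KinshipMatrix:
    return KinshipMatrix(
        {p.family_id: kinship_coefficients(p) for p in pedigrees}
    )


# ---------------------------------------------------------------------------
# marker thinning
# ---------------------------------------------------------------------------


def select_markers(
    g: GenotypeMatrix,
    window_cM: float = 0.5,
    max_per_window: int = 5,
    founder_ids: Sequence[str] | None = None,
) -> GenotypeMatrix:
    """Keep at most ``max_per_window`` variants per half-open cM window.

    Within a window the most informative variants are kept, informativeness
    being founder heterozygosity 2p(1-p); input order is preserved.
    """
    if g.n_variants == 0:
        return g
    cms = np.array([v.cM for v in g.variants])
    if founder_ids is not None:
        pos = {s: i for i, s in enumerate(g.samples)}
        fidx = np.array([pos[s] for s in founder_ids if s in pos], dtype=int)
    else:
        fidx = None
    p = g.allele_freq(fidx)
    het = 2.0 * p * (1.0 - p)
    het = np.where(np.isnan(het), -1.0, het)

    windows = np.floor(cms / window_cM).astype(int)
    keep: list[int] = []
    for w in np.unique(windows):
        idx = np.flatnonzero(windows == w)
        if len(idx) > max_per_window:
            # stable: ties keep the earlier variant
            order = np.argsort(-het[idx], kind="stable")
            idx = np.sort(idx[order[:max_per_window]])
        keep.extend(idx.tolist())
    keep = sorted(keep)
    logger.info(
        "select_markers: kept %d of %d variants (window %.2f cM, max %d)",
        len(keep), g.n_variants, window_cM, max_per_window,
    )
    return g.subset_variants(keep)


# ---------------------------------------------------------------------------
# inheritance-vector HMM
# ---------------------------------------------------------------------------


def haldane_theta(d_cM: float) -> float:
    """Recombination fraction for a map distance in cM (no interference)."""
    return 0.5 * (1.0 - np.exp(-2.0 * d_cM / 100.0))


def _transmit(vec: np.ndarray, theta: float, m: int) -> np.ndarray:
    """Apply the per-meiosis transition operator to a 2**m vector."""
    if theta <= 0:
        return vec.copy()
    arr = vec.reshape((2,) * m)
    for ax in range(m):
        arr = (1.0 - theta) * arr + theta * np.flip(arr, axis=ax)
    return arr.reshape(-1)


def _descent_slots(ped: Pedigree, m: int) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Founder-allele slot carried by each individual's two haplotypes,
    for every inheritance vector; slot arrays have shape (2**m,)."""
    V = 1 << m
    vs = np.arange(V, dtype=np.int64)
    slots: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    founder_slot = 0
    meiosis = 0
    for mem in ped.members:  # topological order
        if mem.is_founder:
            pat = np.full(V, founder_slot, dtype=np.int16)
            mat = np.full(V, founder_slot + 1, dtype=np.int16)
            founder_slot += 2
        else:
            fp, fm = slots[mem.father_id]
            mp, mm = slots[mem.mother_id]
            bit_p = (vs >> meiosis) & 1
            bit_m = (vs >> (meiosis + 1)) & 1
            pat = np.where(bit_p == 0, fp, fm).astype(np.int16)
            mat = np.where(bit_m == 0, mp, mm).astype(np.int16)
            meiosis += 2
        slots[mem.id] = (pat, mat)
    return slots


def _emission(
    slots: Mapping[str, tuple[np.ndarray, np.ndarray]],
    obs: list[tuple[str, int]],
    n_founder_slots: int,
    p_alt: float,
    V: int,
) -> np.ndarray:
    """P(observed genotypes | inheritance vector), summed over the
    2**(2f) founder-allele assignments (alleles i.i.d. Bernoulli(p))."""
    if not obs:
        return np.ones(V)
    out = np.zeros(V)
    for config in range(1 << n_founder_slots):
        k = int(config).bit_count()
        prior = (p_alt ** k) * ((1.0 - p_alt) ** (n_founder_slots - k))
        if prior == 0.0:
            continue
        match = np.ones(V, dtype=bool)
        for sid, gt in obs:
            pat, mat = slots[sid]
            dose = ((config >> pat) & 1) + ((config >> mat) & 1)
            match &= dose == gt
            if not match.any():
                break
        else:
            out += prior * match
    return out


def _pair_pi_vectors(
    ids: Sequence[str], slots: Mapping[str, tuple[np.ndarray, np.ndarray]]
) -> tuple[list[tuple[int, int]], np.ndarray]:
    """pi(i,j) as a function of the inheritance vector, one row per pair."""
    pairs = []
    rows = []
    for a in range(len(ids)):
        for b in range(a, len(ids)):
            pa, ma = slots[ids[a]]
            pb, mb = slots[ids[b]]
            if a == b:
                pi = 1.0 + (pa == ma)
            else:
                s1 = (pa == pb).astype(np.int8) + (ma == mb)
                s2 = (pa == mb).astype(np.int8) + (ma == pb)
                pi = np.maximum(s1, s2) / 2.0
            pairs.append((a, b))
            rows.append(pi.astype(np.float64))
    return pairs, np.vstack(rows)


def multipoint_ibd(
    ped: Pedigree,
    g: GenotypeMatrix,
    grid_cM: Sequence[float],
    allele_freqs: np.ndarray | None = None,
    bit_limit: int = 16,
) -> tuple[list[str], np.ndarray]:
    """Posterior expected IBD-sharing matrices for one pedigree.

    Returns ``(ids, pis)`` with ``pis`` of shape (n_grid, n, n).  Raises
    :class:`CapabilityError` when 2x(non-founders) exceeds ``bit_limit``
    (use truth-IBD mode for such pedigrees).
    """
    m = 2 * len(ped.nonfounders)
    if m > bit_limit:
        raise CapabilityError(
            f"family {ped.family_id}: {m} meioses exceed the bit limit "
            f"({bit_limit}); use simulator-truth IBD for this pedigree"
        )
    n_slots = 2 * len(ped.founders)
    if n_slots > 20:
        raise CapabilityError(
            f"family {ped.family_id}: {n_slots} founder alleles exceed the "
            "emission enumeration cap"
        )
    V = 1 << m
    ids = ped.ids
    slots = _descent_slots(ped, m)
    grid = np.asarray(grid_cM, dtype=float)

    # markers carried by this pedigree, in map order
    sample_pos = {s: i for i, s in enumerate(g.samples)}
    present = [s for s in ids if s in sample_pos]
    order = np.argsort([v.cM for v in g.variants], kind="stable")
    if allele_freqs is None:
        allele_freqs = np.clip(g.allele_freq(), 0.01, 0.99)

    marker_cm: list[float] = []
    emissions: list[np.ndarray] = []
    for j in order:
        obs = []
        for s in present:
            d = g.dosage[sample_pos[s], j]
            if not np.isnan(d):
                obs.append((s, int(d)))
        if not obs:
            continue
        e = _emission(slots, obs, n_slots, float(allele_freqs[j]), V)
        if e.sum() <= 0:  # genotypes inconsistent with any vector; skip marker
            logger.warning(
                "multipoint_ibd: marker %s inconsistent in family %s, skipped",
                g.variants[j].id, ped.family_id,
            )
            continue
        marker_cm.append(float(g.variants[j].cM))
        emissions.append(e)

    K = len(marker_cm)
    if K == 0:
        post_at = lambda t: np.full(V, 1.0 / V)  # prior: no data
    else:
        # forward (F includes the emission at its marker) and A = E * B
        F = []
        prev = np.full(V, 1.0 / V)
        for k in range(K):
            if k > 0:
                prev = _transmit(prev, haldane_theta(marker_cm[k] - marker_cm[k - 1]), m)
            cur = prev * emissions[k]
            cur = cur / cur.sum()
            F.append(cur)
            prev = cur
        A = [None] * K
        nxt = np.ones(V)
        for k in range(K - 1, -1, -1):
            cur = emissions[k] * nxt
            cur = cur / cur.sum()
            A[k] = cur
            nxt = _transmit(cur, haldane_theta(marker_cm[k] - marker_cm[k - 1]), m) \
                if k > 0 else cur

        def post_at(t: float) -> np.ndarray:
            if t <= marker_cm[0]:
                p = _transmit(A[0], haldane_theta(marker_cm[0] - t), m)
            elif t >= marker_cm[-1]:
                p = _transmit(F[-1], haldane_theta(t - marker_cm[-1]), m)
            else:
                k = int(np.searchsorted(marker_cm, t, side="right")) - 1
                left = _transmit(F[k], haldane_theta(t - marker_cm[k]), m)
                right = _transmit(A[k + 1], haldane_theta(marker_cm[k + 1] - t), m)
                p = left * right
            return p / p.sum()

    pairs, pivec = _pair_pi_vectors(ids, slots)
    n = len(ids)
    out = np.zeros((grid.size, n, n))
    for gi, t in enumerate(grid):
        post = post_at(float(t))
        vals = pivec @ post
        for (a, b), v in zip(pairs, vals):
            out[gi, a, b] = out[gi, b, a] = v
    return ids, out


# ---------------------------------------------------------------------------
# IBD containers
# ---------------------------------------------------------------------------


@dataclass
class IBDSet:
    """Per-family IBD matrices over a common cM grid."""

    grid_cM: np.ndarray
    blocks: dict[str, tuple[list[str], np.ndarray]]  # fam -> (ids, [P,s,s])

    def at(self, position: float) -> dict[str, tuple[list[str], np.ndarray]]:
        """Single-position slice: fam -> (ids, matrix)."""
        gi = int(np.argmin(np.abs(self.grid_cM - position)))
        if abs(self.grid_cM[gi] - position) > 1e-6:
            raise KeyError(f"position {position} not on the IBD grid")
        return {f: (ids, pis[gi]) for f, (ids, pis) in self.blocks.items()}

    def subset(self, families: Sequence[str]) -> "IBDSet":
        return IBDSet(
            self.grid_cM,
            {f: self.blocks[f] for f in families if f in self.blocks},
        )


def ibd_hmm(
    pedigrees: Sequence[Pedigree],
    g: GenotypeMatrix,
    grid_cM: Sequence[float],
    allele_freqs: np.ndarray | None = None,
    bit_limit: int = 16,
) -> IBDSet:
    """HMM IBD for every pedigree, assembled into an :class:`IBDSet`."""
    grid = np.asarray(grid_cM, dtype=float)
    blocks = {}
    for ped in pedigrees:
        ids, pis = multipoint_ibd(ped, g, grid, allele_freqs, bit_limit)
        blocks[ped.family_id] = (ids, pis)
    return IBDSet(grid, blocks)


def ibd_from_truth(truth, pedigrees: Sequence[Pedigree],
                   grid_cM: Sequence[float]) -> IBDSet:
    """Exact IBD from simulator inheritance labels (any pedigree size)."""
    from .synthetic_data import pi_from_labels

    grid = np.asarray(grid_cM, dtype=float)
    if grid.size and (
        grid.min() < -1e-9 or grid.max() > truth.map_length_cM + 1e-9
    ):
        raise ValueError("grid position outside the simulated map")
    all_labels = truth.labels_at(grid)  # one pass for every sample
    row = {s: i for i, s in enumerate(truth.sample_ids)}
    blocks = {}
    for ped in pedigrees:
        lab = all_labels[[row[s] for s in ped.ids]]
        blocks[ped.family_id] = (ped.ids, pi_from_labels(lab))
    return IBDSet(grid, blocks)


def write_ibd_tsv(ibd: IBDSet, path) -> None:
    """(position_cM, id1, id2, pi_hat) rows, within-family pairs only."""
    with open(path, "w") as fh:
        fh.write("position_cM\tid1\tid2\tpi_hat\n")
        for fam in sorted(ibd.blocks):
            ids, pis = ibd.blocks[fam]
            for gi, t in enumerate(ibd.grid_cM):
                for a in range(len(ids)):
                    for b in range(a, len(ids)):
                        fh.write(
                            f"{t:.6g}\t{ids[a]}\t{ids[b]}\t{pis[gi, a, b]:.8g}\n"
                        )
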