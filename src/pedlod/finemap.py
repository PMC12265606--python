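"""Fine-mapping of a linkage peak: family subsetting, candidate
nomination, stepwise joint selection, and joint conditional LOD.

Families are split by their contribution to the peak: *linked* families
have a pedigree-specific LOD above 0.1, and *top-linked* families are the
smallest ranked set whose pedigree-specific LODs sum to at least 6.  A
variant under the peak is nominated when it (1) reaches P < 1e-4 in at
least one family set, (2) has P < 0.05 in both sets, and (3) drops the
conditional LOD by more than 0.5 in both sets.  A classical stepwise
regression (enter P < 0.1, stay P < 0.05) then selects a joint set of
variants whose combined conditional LOD quantifies how much of the peak
they explain.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .mixed_assoc import AdjustedTrait, AssocResult
from .pedio import mean_impute
from .vclinkage import VCData, conditional_lod, percent_explained

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# family subsets
# ---------------------------------------------------------------------------


@dataclass
class FamilySubsets:
    linked: list[str]
    top_linked: list[str]
    pedigree_lods: dict[str, float]
    threshold_not_reached: bool = False


def linked_families(
    pedigree_lods: dict[str, float], threshold: float = 0.1
) -> list[str]:
    """Families whose pedigree-specific LOD strictly exceeds the threshold."""
    return sorted(f for f, v in pedigree_lods.items() if v > threshold)


def top_linked_families(
    pedigree_lods: dict[str, float], cum_threshold: float = 6.0
) -> tuple[list[str], bool]:
    """Shortest prefix of LOD-ranked families whose cumulative LOD reaches
    the threshold (ties broken by family id).

    When the total never reaches the threshold, all positive-LOD families
    are returned with a ``threshold_not_reached`` flag.
    """
    ranked = sorted(pedigree_lods.items(), key=lambda kv: (-kv[1], kv[0]))
    out: list[str] = []
    cum = 0.0
    for fam, v in ranked:
        out.append(fam)
        cum += v
        if cum >= cum_threshold:
            return sorted(out), False
    positive = sorted(f for f, v in pedigree_lods.items() if v > 0)
    return positive, True


def family_subsets(
    pedigree_lods: dict[str, float],
    linked_threshold: float = 0.1,
    top_cum_threshold: float = 6.0,
) -> FamilySubsets:
    top, flag = top_linked_families(pedigree_lods, top_cum_threshold)
    return FamilySubsets(
        linked=linked_families(pedigree_lods, linked_threshold),
        top_linked=top,
        pedigree_lods=dict(pedigree_lods),
        threshold_not_reached=flag,
    )


# ---------------------------------------------------------------------------
# nomination
# ---------------------------------------------------------------------------


@dataclass
class CandidateVariant:
    variant_id: str
    linked: AssocResult | None
    top_linked: AssocResult | None
    lod_drop_linked: float | None
    lod_drop_top: float | None
    c1: bool = False
    c2: bool = False
    c3: bool = False
    nominated: bool = False
    evaluable: bool = True


def nominate(
    candidates: list[CandidateVariant],
    p_strong: float = 1e-4,
    p_both: float = 0.05,
    min_lod_drop: float = 0.5,
) -> list[CandidateVariant]:
    """Apply the three nomination criteria in place and return the list.

    c1: P < ``p_strong`` in at least one family set; c2: P < ``p_both`` in
    both sets; c3: conditional LOD drop > ``min_lod_drop`` in both sets.
    A variant missing any of the four statistics is unevaluable and never
    nominated.
    """
    for c in candidates:
        stats_present = (
            c.linked is not None
            and c.top_linked is not None
            and c.lod_drop_linked is not None
            and c.lod_drop_top is not None
        )
        if not stats_present:
            c.evaluable = False
            c.c1 = c.c2 = c.c3 = c.nominated = False
            continue
        c.evaluable = True
        c.c1 = min(c.linked.p, c.top_linked.p) < p_strong
        c.c2 = c.linked.p < p_both and c.top_linked.p < p_both
        c.c3 = c.lod_drop_linked > min_lod_drop and c.lod_drop_top > min_lod_drop
        c.nominated = c.c1 and c.c2 and c.c3
    return candidates


# ---------------------------------------------------------------------------
# stepwise selection
# ---------------------------------------------------------------------------


@dataclass
class StepwiseResult:
    selected: list[str]
    steps: list[dict] = field(default_factory=list)
    lod_pre: float | None = None
    lod_post: float | None = None
    percent_explained: float | None = None


def _partial_p(y: np.ndarray, X: np.ndarray) -> float:
    """Two-sided t-test P for the LAST column of X in an OLS fit."""
    n, k = X.shape
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < k or n <= k:
        return 1.0
    r = y - X @ coef
    s2 = float(r @ r) / (n - k)
    try:
        cov = s2 * np.linalg.inv(X.T @ X)
    except np.linalg.LinAlgError:
        return 1.0
    se = math.sqrt(max(cov[-1, -1], 0.0))
    if se == 0:
        return 1.0
    return float(2.0 * stats.t.sf(abs(coef[-1]) / se, n - k))


def stepwise_select(
    trait: AdjustedTrait,
    dosages: dict[str, np.ndarray],
    entry_p: float = 0.1,
    stay_p: float = 0.05,
) -> StepwiseResult:
    """Forward selection with backward elimination on ordinary regression.

    At each step the candidate with the smallest partial P enters if below
    ``entry_p`` (ties by variant id); any retained variable whose partial P
    rises above ``stay_p`` is then removed.  Deterministic for fixed input.
    """
    if not dosages:
        raise ValueError("stepwise_select needs at least one candidate")
    y = trait.residual
    n = y.size
    cols = {v: mean_impute(np.asarray(d, dtype=float)) for v, d in dosages.items()}
    for v, d in cols.items():
        if d.size != n:
            raise ValueError(f"dosage {v} length mismatch")

    selected: list[str] = []
    steps: list[dict] = []
    # a variable with entry_p > partial p > stay_p can enter and be removed
    # forever; stop as soon as a selection state repeats (standard guard)
    seen_states = {frozenset()}
    while True:
        changed = False
        # forward step
        remaining = [v for v in sorted(cols) if v not in selected]
        best_v, best_p = None, None
        for v in remaining:
            X = np.column_stack(
                [np.ones(n)] + [cols[u] for u in selected] + [cols[v]]
            )
            p = _partial_p(y, X)
            if best_p is None or p < best_p - 1e-15:
                best_v, best_p = v, p
        if best_v is not None and best_p < entry_p:
            selected.append(best_v)
            steps.append({"action": "add", "variant": best_v, "p": best_p})
            changed = True
        # backward step(s)
        while True:
            worst_v, worst_p = None, None
            for v in selected:
                others = [u for u in selected if u != v]
                X = np.column_stack(
                    [np.ones(n)] + [cols[u] for u in others] + [cols[v]]
                )
                p = _partial_p(y, X)
                if worst_p is None or p > worst_p + 1e-15:
                    worst_v, worst_p = v, p
            if worst_v is not None and worst_p > stay_p:
                selected.remove(worst_v)
                steps.append({"action": "remove", "variant": worst_v,
                              "p": worst_p})
                changed = True
            else:
                break
        if not changed:
            break
        state = frozenset(selected)
        if state in seen_states:
            break
        seen_states.add(state)
    return StepwiseResult(selected=selected, steps=steps)


# ---------------------------------------------------------------------------
# joint conditional LOD
# ---------------------------------------------------------------------------


def joint_conditional_lod(
    data: VCData,
    peak_ibd,
    selected_dosages: np.ndarray | None,
    seed: int | None = 0,
    pre=None,
) -> tuple[float, float, float]:
    """Conditional LOD with all selected dosages as joint fixed covariates.

    Returns (lod_pre, lod_post, percent_explained).  An empty selection is
    an explicit no-op: lod_post = lod_pre and percent 0.
    """
    if selected_dosages is None or (
        hasattr(selected_dosages, "shape")
        and (selected_dosages.size == 0)
    ):
        from .vclinkage import fit_linkage, fit_polygenic, lod_score

        if pre is not None:
            full0, null0 = pre
        else:
            null0 = fit_polygenic(data, seed=seed)
            full0 = fit_linkage(data.with_ibd(peak_ibd), null=null0, seed=seed)
        lod_pre = lod_score(full0, null0)
        return lod_pre, lod_pre, 0.0
    lod_pre, lod_post, _ = conditional_lod(
        data, peak_ibd, selected_dosages, seed=seed, pre=pre
    )
    pct = percent_explained(lod_pre, lod_post) if lod_pre > 0 else 0.0
    return lod_pre, lod_post, pct


def load_published_candidates() -> list[CandidateVariant]:
    """The five published chromosome-15 candidate variants (per-family-set
    af, n, beta, se, pval, lod_drop), as :class:`CandidateVariant` inputs
    for the nomination filter."""
    from importlib import resources

    candidates = []
    path = resources.files("pedlod").joinpath("data/tmtb_chr15_candidates.tsv")
    with path.open() as fh:
        header = None
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                continue
            row = dict(zip(header, line.split("\t")))
            candidates.append(
                CandidateVariant(
                    variant_id=row["variant_id"],
                    linked=AssocResult(
                        row["variant_id"], "linked", int(row["n_linked"]),
                        float(row["af_linked"]), float(row["beta_linked"]),
                        float(row["se_linked"]), float(row["pval_linked"]),
                    ),
                    top_linked=AssocResult(
                        row["variant_id"], "top_linked", int(row["n_top"]),
                        float(row["af_top"]), float(row["beta_top"]),
                        float(row["se_top"]), float(row["pval_top"]),
                    ),
                    lod_drop_linked=float(row["lod_drop_linked"]),
                    lod_drop_top=float(row["lod_drop_top"]),
                )
            )
    return candidates


def write_candidates_tsv(candidates: list[CandidateVariant], path) -> None:
    """Candidate table mirroring the published layout: per-family-set
    af, n, beta, se, pval and lod_drop columns."""
    cols = [
        "variant_id",
        "af_linked", "n_linked", "beta_linked", "se_linked", "pval_linked",
        "lod_drop_linked",
        "af_top", "n_top", "beta_top", "se_top", "pval_top", "lod_drop_top",
        "c1", "c2", "c3", "nominated",
    ]

    def fmt(x, spec="%.6g"):
        return "NA" if x is None else spec % x

    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for c in candidates:
            la, to = c.linked, c.top_linked
            row = [
                c.variant_id,
                fmt(la.af if la else None), fmt(la.n if la else None, "%d"),
                fmt(la.beta if la else None), fmt(la.se if la else None),
                fmt(la.p if la else None), fmt(c.lod_drop_linked),
                fmt(to.af if to else None), fmt(to.n if to else None, "%d"),
                fmt(to.beta if to else None), fmt(to.se if to else None),
                fmt(to.p if to else None), fmt(c.lod_drop_top),
                str(int(c.c1)), str(int(c.c2)), str(int(c.c3)),
                str(int(c.nominated)),
            ]
            fh.write("\t".join(row) + "\n")
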