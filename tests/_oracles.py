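"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (pure-Python loops, dense matrices,
explicit enumeration) kept separate from the package's fast code paths.
"""

import itertools

import numpy as np


def mc_kinship(ped, n_drops: int, rng: np.random.Generator) -> np.ndarray:
    """Monte-Carlo kinship via single-locus gene dropping.

    Drops one unlinked locus ``n_drops`` times and estimates phi(i,j) as
    the probability a random allele from i is identical by descent to a
    random allele from j.
    """
    ids = ped.ids
    labels = {}
    next_label = 0
    for m in ped.members:  # topological order
        if m.is_founder:
            a = np.full(n_drops, next_label)
            b = np.full(n_drops, next_label + 1)
            next_label += 2
        else:
            fa, fb = labels[m.father_id]
            a = np.where(rng.integers(2, size=n_drops) == 0, fa, fb)
            ma, mb = labels[m.mother_id]
            b = np.where(rng.integers(2, size=n_drops) == 0, ma, mb)
        labels[m.id] = (a, b)
    n = len(ids)
    phi = np.zeros((n, n))
    for i in range(n):
        ai, bi = labels[ids[i]]
        for j in range(i, n):
            aj, bj = labels[ids[j]]
            if i == j:
                # phi(i,i) = (1 + P(the two alleles of i are IBD)) / 2
                phi[i, i] = 0.5 * (1 + np.mean(ai == bi))
            else:
                s = (
                    np.mean(ai == aj) + np.mean(ai == bj)
                    + np.mean(bi == aj) + np.mean(bi == bj)
                ) / 4.0
                phi[i, j] = phi[j, i] = s
    return phi


class NaiveLanderGreen:
    """Dense, loop-based inheritance-vector HMM for tiny pedigrees.

    Everything is enumerated explicitly: descent per vector by recursion,
    emissions by iterating all founder-allele assignments, transitions as
    dense 2^m x 2^m matrices built from Hamming distances.
    """

    def __init__(self, ped, marker_cms, genotypes, p_alt):
        # genotypes: {sample_id: [dosage per marker]} (may omit samples)
        self.ped = ped
        self.cms = list(marker_cms)
        self.genos = genotypes
        self.p = p_alt
        self.nonfounders = ped.nonfounders
        self.m = 2 * len(self.nonfounders)
        self.V = 2 ** self.m
        self.founder_slots = {}
        s = 0
        for mem in ped.founders:
            self.founder_slots[mem.id] = (s, s + 1)
            s += 2
        self.n_slots = s
        self.meiosis_index = {}
        for t, mem in enumerate(self.nonfounders):
            self.meiosis_index[mem.id] = (2 * t, 2 * t + 1)

    def slots_of(self, sid, v):
        mem = next(m for m in self.ped.members if m.id == sid)
        if mem.is_founder:
            return self.founder_slots[sid]
        bp, bm = self.meiosis_index[sid]
        fpat, fmat = self.slots_of(mem.father_id, v)
        mpat, mmat = self.slots_of(mem.mother_id, v)
        pat = fpat if ((v >> bp) & 1) == 0 else fmat
        mat = mpat if ((v >> bm) & 1) == 0 else mmat
        return pat, mat

    def emission(self, k, v):
        total = 0.0
        for alleles in itertools.product((0, 1), repeat=self.n_slots):
            pr = 1.0
            for a in alleles:
                pr *= self.p if a == 1 else 1.0 - self.p
            ok = True
            for sid, doses in self.genos.items():
                d = doses[k]
                if d is None:
                    continue
                pat, mat = self.slots_of(sid, v)
                if alleles[pat] + alleles[mat] != d:
                    ok = False
                    break
            if ok:
                total += pr
        return total

    def emission_vec(self, k):
        return np.array([self.emission(k, v) for v in range(self.V)])

    def transition(self, d_cm):
        theta = 0.5 * (1.0 - np.exp(-2.0 * d_cm / 100.0))
        T = np.zeros((self.V, self.V))
        for u in range(self.V):
            for v in range(self.V):
                flips = bin(u ^ v).count("1")
                T[u, v] = theta ** flips * (1 - theta) ** (self.m - flips)
        return T

    def posterior(self, t):
        left = [k for k, c in enumerate(self.cms) if c <= t]
        right = [k for k, c in enumerate(self.cms) if c > t]
        alpha = np.full(self.V, 1.0 / self.V)
        pos = None
        for k in left:
            if pos is not None:
                alpha = self.transition(self.cms[k] - pos) @ alpha
            alpha = alpha * self.emission_vec(k)
            pos = self.cms[k]
        if pos is not None and pos != t:
            alpha = self.transition(t - pos) @ alpha
        beta = np.ones(self.V)
        pos = None
        for k in reversed(right):
            if pos is not None:
                beta = self.transition(pos - self.cms[k]) @ beta
            beta = beta * self.emission_vec(k)
            pos = self.cms[k]
        if pos is not None:
            beta = self.transition(pos - t) @ beta
        post = alpha * beta
        return post / post.sum()

    def pi_hat(self, t):
        ids = self.ped.ids
        post = self.posterior(t)
        n = len(ids)
        out = np.zeros((n, n))
        for v in range(self.V):
            if post[v] == 0:
                continue
            slot = {sid: self.slots_of(sid, v) for sid in ids}
            for i in range(n):
                pi_, mi_ = slot[ids[i]]
                for j in range(i, n):
                    pj_, mj_ = slot[ids[j]]
                    if i == j:
                        val = 1.0 + (pi_ == mi_)
                    else:
                        s1 = (pi_ == pj_) + (mi_ == mj_)
                        s2 = (pi_ == mj_) + (mi_ == pj_)
                        val = max(s1, s2) / 2.0
                    out[i, j] += post[v] * val
        return out + np.triu(out, 1).T
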