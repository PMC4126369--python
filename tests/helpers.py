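"""Shared test utilities: independent brute-force oracles and random-data
factories.

The oracles here deliberately re-implement the statistics from their
definitions (plain double/quadruple loops over members), independent of the
package's vectorized code paths, so agreement is a genuine cross-check.
"""

from __future__ import annotations

import numpy as np

from gdtpoly import simulator
from gdtpoly.pedio import FamilySample


def random_family(
    rng: np.random.Generator,
    K: int = 2,
    min_n: int = 2,
    max_n: int = 10,
    maf: float = 0.4,
    with_x1: bool = False,
    fam: str = "f",
) -> FamilySample:
    """A random nuclear-family sample: gene-dropped genotypes with exact IBD,
    arbitrary category assignment."""
    n = int(rng.integers(min_n, max_n + 1))
    ped = simulator.nuclear_pedigree(max(1, n - 2))
    d = simulator.GeneDropper(ped)
    L2 = d.drop(1, rng)
    x2 = d.genotype_proportions(L2, d.founder_contents(1, maf, rng))[0]
    pi2 = d.ibd_matrix(L2)[0].astype(float)
    x1 = pi1 = None
    if with_x1:
        L1 = d.drop(1, rng)
        x1 = d.genotype_proportions(L1, d.founder_contents(1, maf, rng))[0]
        pi1 = d.ibd_matrix(L1)[0].astype(float)
    y = np.sort(rng.integers(1, K + 1, size=ped.n))
    return FamilySample(
        fam=fam, ids=ped.ids, y=y, K=K, kin2=2 * d.phi,
        x1=x1, x2=x2, pi1=pi1, pi2=pi2,
    )


def gdt_pairwise_oracle(samples) -> tuple[float, float]:
    """Dichotomous within-family disequilibrium test, written from its
    definition: S = sum_f (1/n_f) sum_{i affected} sum_{j unaffected}
    (X_i - X_j); variance by the plain quadruple sum over the IBD kernel
    with the pooled within-family variance of X."""
    num = den = 0.0
    for s in samples:
        if s.n < 2:
            continue
        xc = s.x2 - s.x2.mean()
        num += float((xc**2).sum())
        den += s.n - 1
    sigma2 = num / den
    S = 0.0
    V = 0.0
    for s in samples:
        aff = np.flatnonzero(s.y == 1)
        un = np.flatnonzero(s.y == 2)
        for i in aff:
            for j in un:
                S += (s.x2[i] - s.x2[j]) / s.n
        for i in aff:
            for j in un:
                for k in aff:
                    for l in un:
                        V += (
                            s.pi2[i, k] + s.pi2[j, l] - s.pi2[i, l] - s.pi2[j, k]
                        ) * sigma2 / s.n**2
    return S, V


def weighted_cov_oracle(sample, f_g, cats_g, f_h, cats_h, C, R) -> float:
    """Kernel part of Cov[S^(g), S^(h)] for one family by explicit quadruple
    loops over every category pair (no sigma factor)."""
    total = 0.0
    for a in cats_g:
        ma = sample.y == a
        if not ma.any() or ma.all():
            continue
        for b in cats_h:
            mb = sample.y == b
            if not mb.any() or mb.all():
                continue
            for i in np.flatnonzero(ma):
                for j in np.flatnonzero(~ma):
                    for k in np.flatnonzero(mb):
                        for l in np.flatnonzero(~mb):
                            total += C[i, j] * C[k, l] * (
                                R[i, k] + R[j, l] - R[i, l] - R[j, k]
                            )
    return total


def pooled_score_oracle(sample, col, cats, C) -> float:
    """Score for a (possibly shared) coefficient by summing per-category
    double loops of weighted pairwise differences."""
    S = 0.0
    for a in cats:
        ma = sample.y == a
        if not ma.any() or ma.all():
            continue
        for i in np.flatnonzero(ma):
            for j in np.flatnonzero(~ma):
                S += C[i, j] * (col[i] - col[j])
    return S
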