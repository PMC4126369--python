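"""Gene-dropping pedigree simulator with a two-step phenotype model.

Genotypes at two unlinked biallelic loci are simulated by gene dropping:
founder alleles are drawn under Hardy-Weinberg equilibrium at the scenario's
risk allele frequencies and transmitted by Mendelian rules, with distinct
founder-allele labels tracked so that the realized identity-by-descent
sharing proportion of every member pair is known exactly.  A null marker is
placed at locus 2: it segregates on exactly the same meioses as the locus-2
causal variant (hence is genetically linked to it) but its founder alleles
are drawn independently (linkage equilibrium), at a population-specific
frequency under the two-population mixture.

Phenotypes are generated in two steps.  The endophenotype indicator Y1 of
each member is Bernoulli with success probability P[(1,0)|X] + P[(1,1)|X]
from a four-category polytomous model with proportion-coded genotypes.  The
disease indicator Y2 is then Bernoulli on the logit scale,

    logit P[Y2_i = 1] = gamma(X_i, Y1_i) + U_i
                        + alpha * sum_{h != i} (Y1_h - nu) * phi_ih

where gamma(X, y1) is the within-stratum log-odds implied by the polytomous
model (so that with sigma^2 = alpha = 0 the joint (Y1, Y2) distribution is
exactly the polytomous model), U ~ N(0, sigma^2 * Phi) is an additive
polygenic effect with Phi the family kinship matrix, and the alpha term
couples a member's disease risk to relatives' endophenotype status, with nu
balancing the risk increase (1 - nu) from an impaired relative against the
decrease (-nu) from an unimpaired one.

Families are retained when at least one first-cousin pair (kinship 1/16) is
disease-affected in both members, mimicking ascertainment in family studies
of severe disease.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from . import pedio
from .pedio import FamilySample, Pedigree

FIRST_COUSIN_KINSHIP = 1.0 / 16.0


def default_coefficients() -> np.ndarray:
    """Coefficient table of the example polytomous model, rows are the
    contrasts (Y1,Y2) = (1,0), (0,1), (1,1) vs (0,0); columns intercept,
    x1, x2, x1*x2."""
    log2, log16 = np.log(2.0), np.log(16.0)
    return np.array(
        [
            [-2.0, log2, 0.0, -log2],
            [-5.5, 0.0, 0.0, 0.0],
            [-5.5, 0.0, 0.0, log16],
        ]
    )


@dataclass
class Scenario:
    """Simulation scenario: allele frequencies, model coefficients,
    population heterogeneity, polygenic parameters and ascertainment.

    ``intercept_shift`` and ``null_maf`` have one entry per population;
    with ``mixture=True`` each family's population is Bernoulli(1/2).
    Defaults: RAFs 0.1 / 0.3; homogeneous null-marker frequency equal to
    the locus-2 RAF; mixture shifts -0.5 / +0.5 with null-marker
    frequencies 0.1 / 0.5; polygenic variance sigma2 = 1 on the logit
    scale; relative-endophenotype effect alpha = 1; centering constant
    nu = 0.128 (the endophenotype population prevalence).
    """

    raf1: float = 0.1
    raf2: float = 0.3
    coef: np.ndarray = field(default_factory=default_coefficients)
    mixture: bool = False
    intercept_shift: tuple[float, ...] = (0.0,)
    null_maf: tuple[float, ...] | None = None
    sigma2: float = 1.0
    alpha: float = 1.0
    nu: float = 0.128
    n_families: int = 100

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float)
        if self.coef.shape != (3, 4):
            raise ValueError("coefficient table must be 3 contrasts x 4 terms")
        for f in (self.raf1, self.raf2):
            if not 0.0 < f < 1.0:
                raise ValueError("allele frequencies must lie in (0, 1)")
        if not 0.0 < self.nu < 1.0:
            raise ValueError("nu must lie in (0, 1)")
        if self.sigma2 < 0.0:
            raise ValueError("sigma2 must be non-negative")
        if self.null_maf is None:
            self.null_maf = (0.1, 0.5) if self.mixture else (self.raf2,)
        if self.mixture and len(self.intercept_shift) == 1:
            self.intercept_shift = (-0.5, 0.5)
        if len(self.intercept_shift) != len(self.null_maf):
            raise ValueError("intercept_shift and null_maf must align per population")

    @property
    def n_pops(self) -> int:
        return len(self.intercept_shift)


def mixture_scenario(**kwargs) -> Scenario:
    return Scenario(mixture=True, **kwargs)


# ---------------------------------------------------------------------------
# pedigree structures
# ---------------------------------------------------------------------------

def canonical_pedigree() -> Pedigree:
    """The 3-generation, 16-member family used throughout the simulations.

    Two grandparents; four of their children, each with an unrelated
    spouse (eight members in generation 2); six grandchildren, two born to
    each of three of the couples.  This yields twelve first-cousin pairs,
    the unit of the ascertainment rule.
    """
    ids = [str(i) for i in range(1, 17)]
    father = [-1, -1, 0, 0, 0, 0, -1, -1, -1, -1, 2, 2, 3, 3, 4, 4]
    mother = [-1, -1, 1, 1, 1, 1, -1, -1, -1, -1, 6, 6, 7, 7, 8, 8]
    sex = [1, 2, 1, 1, 1, 1, 2, 2, 2, 2, 1, 2, 1, 2, 1, 2]
    return Pedigree("1", ids, np.array(father), np.array(mother), np.array(sex))


def nuclear_pedigree(n_children: int = 3) -> Pedigree:
    """Two founder parents with ``n_children`` offspring."""
    n = 2 + n_children
    ids = [str(i) for i in range(1, n + 1)]
    father = [-1, -1] + [0] * n_children
    mother = [-1, -1] + [1] * n_children
    sex = [1, 2] + [1 + (i % 2) for i in range(n_children)]
    return Pedigree("1", ids, np.array(father), np.array(mother), np.array(sex))


# ---------------------------------------------------------------------------
# gene dropping
# ---------------------------------------------------------------------------

class GeneDropper:
    """Vectorized gene dropping on a fixed pedigree structure.

    Founder alleles carry distinct integer labels (two per founder) so the
    realized IBD sharing of any member pair is computed exactly from label
    identity.
    """

    def __init__(self, pedigree: Pedigree):
        self.pedigree = pedigree
        self.n = pedigree.n
        self.founder_idx = np.flatnonzero(pedigree.founder)
        self.n_founders = self.founder_idx.size
        self.nonfounders = [
            i for i in pedigree.topological_order if not pedigree.founder[i]
        ]
        self.phi = pedigree.kinship()
        frank = {int(f): r for r, f in enumerate(self.founder_idx)}
        self.founder_labels = np.array(
            [
                (2 * frank[i], 2 * frank[i] + 1) if i in frank else (0, 0)
                for i in range(self.n)
            ],
            dtype=np.int16,
        )

    def drop(self, n_fam: int, rng: np.random.Generator) -> np.ndarray:
        """(n_fam, n_members, 2) founder-allele labels after one gene drop."""
        L = np.zeros((n_fam, self.n, 2), dtype=np.int16)
        L[:, self.founder_idx, :] = self.founder_labels[self.founder_idx]
        rows = np.arange(n_fam)
        for i in self.nonfounders:
            fa, mo = self.pedigree.father[i], self.pedigree.mother[i]
            L[:, i, 0] = L[rows, fa, rng.integers(2, size=n_fam)]
            L[:, i, 1] = L[rows, mo, rng.integers(2, size=n_fam)]
        return L

    def founder_contents(
        self, n_fam: int, freq, rng: np.random.Generator
    ) -> np.ndarray:
        """(n_fam, 2 * n_founders) allele contents, 1 = counted allele.

        ``freq`` is scalar or per-family (n_fam,)."""
        freq = np.broadcast_to(np.asarray(freq, dtype=float), (n_fam,))
        return (
            rng.random((n_fam, 2 * self.n_founders)) < freq[:, None]
        ).astype(np.int8)

    @staticmethod
    def genotype_proportions(labels: np.ndarray, contents: np.ndarray) -> np.ndarray:
        """(n_fam, n_members) proportion of the counted allele in {0, 1/2, 1}."""
        rows = np.arange(labels.shape[0])[:, None, None]
        return contents[rows, labels].mean(axis=2)

    @staticmethod
    def ibd_matrix(labels: np.ndarray) -> np.ndarray:
        """Exact realized IBD sharing proportions (n_fam, n, n) from labels."""
        eq = labels[:, :, None, :, None] == labels[:, None, :, None, :]
        return eq.sum(axis=(3, 4)).astype(np.float32) / 2.0

    def cousin_pairs(self) -> list[tuple[int, int]]:
        iu = np.triu_indices(self.n, 1)
        mask = np.isclose(self.phi[iu], FIRST_COUSIN_KINSHIP)
        return list(zip(iu[0][mask], iu[1][mask]))


# ---------------------------------------------------------------------------
# phenotype model
# ---------------------------------------------------------------------------

def category_probabilities(coef: np.ndarray, x1, x2, shift=0.0) -> np.ndarray:
    """(..., 4) probabilities of categories (1,0), (0,1), (1,1), (0,0).

    ``shift`` (scalar or broadcastable) is added to every intercept."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    shift = np.asarray(shift, dtype=float)
    eta = np.stack(
        [
            coef[k, 0] + shift + coef[k, 1] * x1 + coef[k, 2] * x2
            + coef[k, 3] * x1 * x2
            for k in range(3)
        ],
        axis=-1,
    )
    e = np.exp(eta)
    den = 1.0 + e.sum(axis=-1, keepdims=True)
    p = np.concatenate([e, np.ones_like(e[..., :1])], axis=-1) / den
    return p


def analytic_prevalence(
    coef: np.ndarray | None = None,
    raf1: float = 0.1,
    raf2: float = 0.3,
    shift: float = 0.0,
) -> dict[str, float]:
    """Population prevalences by enumerating the nine HWE genotype classes.

    Returns the disease prevalence P[Y2=1] = P[(0,1)] + P[(1,1)] and the
    endophenotype-impairment prevalence P[Y1=1] = P[(1,0)] + P[(1,1)].
    """
    coef = default_coefficients() if coef is None else np.asarray(coef, dtype=float)
    x = np.array([0.0, 0.5, 1.0])
    w1 = np.array([(1 - raf1) ** 2, 2 * raf1 * (1 - raf1), raf1**2])
    w2 = np.array([(1 - raf2) ** 2, 2 * raf2 * (1 - raf2), raf2**2])
    X1, X2 = np.meshgrid(x, x, indexing="ij")
    P = category_probabilities(coef, X1, X2, shift)
    w = np.outer(w1, w2)
    disease = float((w * (P[..., 1] + P[..., 2])).sum())
    endo = float((w * (P[..., 0] + P[..., 2])).sum())
    return {"disease": disease, "endo": endo}


def stratum_logodds(coef: np.ndarray, x1, x2, y1, shift=0.0) -> np.ndarray:
    """Log-odds of Y2 = 1 within the Y1 stratum implied by the polytomous
    model: gamma(X, 1) is the (1,1)-vs-(1,0) contrast, gamma(X, 0) the
    (0,1)-vs-(0,0) contrast."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    d = coef[2] - coef[0]
    g1 = d[0] + d[1] * x1 + d[2] * x2 + d[3] * x1 * x2   # intercept shift cancels
    c = coef[1]
    g0 = c[0] + shift + c[1] * x1 + c[2] * x2 + c[3] * x1 * x2
    return np.where(np.asarray(y1, dtype=bool), g1, g0)


def simulate_phenotypes(
    scenario: Scenario,
    x1: np.ndarray,
    x2: np.ndarray,
    phi: np.ndarray,
    rng: np.random.Generator,
    shift=0.0,
    chol: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-step (Y1, Y2) simulation for batched families.

    ``x1``/``x2`` are (n_fam, n) genotype proportions, ``phi`` the family
    kinship matrix, ``shift`` scalar or per-family intercept shifts.  The
    polygenic effect uses a Cholesky factor of sigma2 * Phi (non-PSD Phi is
    rejected by the factorization).
    """
    # genotype proportions take only the values {0, 1/2, 1} and shifts come
    # from a small per-population set, so the per-member probabilities are
    # computed once on a (shift, x1, x2) grid and looked up exactly.
    shifts = np.broadcast_to(np.asarray(shift, dtype=float).reshape(-1, 1), x1.shape)
    uniq, sidx = np.unique(shifts[:, 0], return_inverse=True)
    grid = np.array([0.0, 0.5, 1.0])
    G1, G2 = np.meshgrid(grid, grid, indexing="ij")
    i1 = np.rint(2 * x1).astype(np.int8)
    i2 = np.rint(2 * x2).astype(np.int8)
    Pg = category_probabilities(
        scenario.coef, G1[None], G2[None], uniq.reshape(-1, 1, 1)
    )
    py1_tab = Pg[..., 0] + Pg[..., 2]
    y1 = (rng.random(x1.shape) < py1_tab[sidx[:, None], i1, i2]).astype(np.int8)
    g_tab = np.stack(
        [
            stratum_logodds(scenario.coef, G1[None], G2[None], y1v,
                            uniq.reshape(-1, 1, 1))
            for y1v in (0, 1)
        ]
    )
    gamma = g_tab[y1, sidx[:, None], i1, i2]
    if scenario.sigma2 > 0.0:
        if chol is None:
            chol = np.linalg.cholesky(scenario.sigma2 * phi)
        U = rng.standard_normal(x1.shape) @ chol.T
    else:
        U = 0.0
    dev = y1 - scenario.nu
    coupling = scenario.alpha * (dev @ phi - dev * np.diag(phi))
    y2 = (rng.random(x1.shape) < expit(gamma + U + coupling)).astype(np.int8)
    return y1, y2


# ---------------------------------------------------------------------------
# full sample simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedSample:
    """Batched arrays for a set of ascertained families (axis 0 = family)."""

    scenario: Scenario
    pedigree: Pedigree
    x1: np.ndarray           # causal locus 1
    x2: np.ndarray           # causal locus 2
    xnull: np.ndarray        # null marker at locus 2
    y1: np.ndarray
    y2: np.ndarray
    pi1: np.ndarray          # realized IBD at locus 1, (F, n, n)
    pi2: np.ndarray          # realized IBD at locus 2 (shared by the null marker)
    pop: np.ndarray          # population of origin per family

    @property
    def n_families(self) -> int:
        return self.x1.shape[0]

    def subset(self, idx) -> "SimulatedSample":
        return SimulatedSample(
            self.scenario, self.pedigree,
            self.x1[idx], self.x2[idx], self.xnull[idx],
            self.y1[idx], self.y2[idx], self.pi1[idx], self.pi2[idx],
            self.pop[idx],
        )


def ascertain(y2: np.ndarray, cousin_pairs) -> np.ndarray:
    """Keep indicator per family: some first-cousin pair with both members
    disease-affected."""
    if not cousin_pairs:
        return np.zeros(y2.shape[0], dtype=bool)
    keep = np.zeros(y2.shape[0], dtype=bool)
    for i, j in cousin_pairs:
        keep |= (y2[:, i] == 1) & (y2[:, j] == 1)
    return keep


def _simulate_pop(
    scenario: Scenario,
    n_families: int,
    pop: int,
    rng: np.random.Generator,
    dropper: GeneDropper,
    chol,
    apply_ascertainment: bool,
    max_raw: int,
) -> SimulatedSample:
    """Rejection-sample ascertained families from one population."""
    pairs = dropper.cousin_pairs()
    shift = scenario.intercept_shift[pop]
    maf_null = scenario.null_maf[pop]
    kept: list[SimulatedSample] = []
    n_kept = 0
    n_raw = 0
    batch = max(4096, 4 * n_families)
    while n_kept < n_families:
        if n_raw > max_raw:
            raise RuntimeError(
                f"ascertainment rule rejected {n_raw} families before "
                f"{n_families} were kept; check the scenario"
            )
        B = batch
        L1 = dropper.drop(B, rng)
        L2 = dropper.drop(B, rng)
        c1 = dropper.founder_contents(B, scenario.raf1, rng)
        c2 = dropper.founder_contents(B, scenario.raf2, rng)
        cnull = dropper.founder_contents(B, maf_null, rng)
        x1 = dropper.genotype_proportions(L1, c1)
        x2 = dropper.genotype_proportions(L2, c2)
        xnull = dropper.genotype_proportions(L2, cnull)
        y1, y2 = simulate_phenotypes(
            scenario, x1, x2, dropper.phi, rng, shift=shift, chol=chol
        )
        keep = (
            ascertain(y2, pairs)
            if apply_ascertainment
            else np.ones(B, dtype=bool)
        )
        n_raw += B
        if keep.any():
            idx = np.flatnonzero(keep)
            kept.append(
                SimulatedSample(
                    scenario, dropper.pedigree,
                    x1[idx], x2[idx], xnull[idx], y1[idx], y2[idx],
                    GeneDropper.ibd_matrix(L1[idx]),
                    GeneDropper.ibd_matrix(L2[idx]),
                    np.full(idx.size, pop),
                )
            )
            n_kept += idx.size
        # adapt the batch to the observed keep rate
        rate = max(n_kept / n_raw, 1.0 / batch)
        batch = int(min(200_000, max(4096, 1.3 * (n_families - n_kept) / rate)))
    return SimulatedSample(
        scenario, dropper.pedigree,
        *[
            np.concatenate([k.__dict__[f] for k in kept])[:n_families]
            for f in ("x1", "x2", "xnull", "y1", "y2", "pi1", "pi2", "pop")
        ],
    )


def simulate_sample(
    scenario: Scenario,
    n_families: int,
    rng: np.random.Generator,
    pedigree: Pedigree | None = None,
    apply_ascertainment: bool = True,
    max_raw: int = 200_000_000,
) -> SimulatedSample:
    """Rejection-sample ascertained families until ``n_families`` are kept.

    Under the mixture, the populations contribute equal numbers of
    ascertained families (the mixture describes the analyzed sample, so the
    population mix must survive ascertainment); the returned families
    alternate population so that any contiguous block keeps the mix.  Works
    in batches; IBD matrices are only materialized for retained families.
    Deterministic for a fixed generator state.
    """
    pedigree = canonical_pedigree() if pedigree is None else pedigree
    dropper = GeneDropper(pedigree)
    chol = (
        np.linalg.cholesky(scenario.sigma2 * dropper.phi)
        if scenario.sigma2 > 0.0
        else None
    )
    npops = scenario.n_pops
    targets = [
        n_families // npops + (1 if p < n_families % npops else 0)
        for p in range(npops)
    ]
    parts = [
        _simulate_pop(
            scenario, targets[p], p, rng, dropper, chol,
            apply_ascertainment, max_raw,
        )
        for p in range(npops)
    ]
    if npops == 1:
        return parts[0]
    order_parts = []
    for p, part in enumerate(parts):
        idx = np.arange(targets[p])
        order_parts.append((idx * npops + p, part))
    pos = np.concatenate([o for o, _ in order_parts])
    rank = np.argsort(pos, kind="stable")
    fields = ("x1", "x2", "xnull", "y1", "y2", "pi1", "pi2", "pop")
    merged = {
        f: np.concatenate([part.__dict__[f] for _, part in order_parts])[rank]
        for f in fields
    }
    return SimulatedSample(scenario, pedigree, *[merged[f] for f in fields])


# ---------------------------------------------------------------------------
# bridges to the analysis layer
# ---------------------------------------------------------------------------

def to_family_samples(
    sim: SimulatedSample,
    tested: str = "null",
    K: int = 4,
    trait: str = "disease",
    use_true_ibd: bool = True,
) -> list[FamilySample]:
    """Convert a simulated sample to per-family analysis samples.

    x1 is the causal locus-1 variant (the conditioning marker), x2 the
    tested marker ("null" or "causal", both at locus 2).  For K = 2 the
    category is built from ``trait`` ("disease" = Y2, "endo" = Y1).
    """
    kin2 = 2.0 * GeneDropper(sim.pedigree).phi
    xt = sim.xnull if tested == "null" else sim.x2
    out = []
    for f in range(sim.n_families):
        if K == 4:
            y = np.array(
                [
                    pedio.CATEGORY_OF[(int(a), int(b))]
                    for a, b in zip(sim.y1[f], sim.y2[f])
                ]
            )
        else:
            tv = sim.y2[f] if trait == "disease" else sim.y1[f]
            y = np.where(tv == 1, 1, 2)
        order = np.argsort(y, kind="stable")
        sub = np.ix_(order, order)
        out.append(
            FamilySample(
                fam=str(f + 1),
                ids=[sim.pedigree.ids[i] for i in order],
                y=y[order],
                K=K,
                kin2=kin2[sub],
                x1=sim.x1[f][order],
                x2=xt[f][order],
                pi1=sim.pi1[f][sub].astype(float) if use_true_ibd else None,
                pi2=sim.pi2[f][sub].astype(float) if use_true_ibd else None,
            )
        )
    return out


def write_merlin(
    sim: SimulatedSample, prefix, markers=("locus1", "locus2", "nullmarker")
) -> dict[str, str]:
    """Write a simulated sample as Merlin/QTDT .ped/.dat/.map plus an exact
    IBD table; returns the file paths.  Allele 1 is the counted (risk)
    allele, allele 2 the other."""
    prefix = str(prefix)
    ped = sim.pedigree
    n = ped.n
    families = {}
    for f in range(sim.n_families):
        fam = str(f + 1)
        traits = {
            "endo": sim.y1[f].astype(float),
            "disease": sim.y2[f].astype(float),
        }
        genos = {}
        for name, x in zip(markers, (sim.x1[f], sim.x2[f], sim.xnull[f])):
            cnt = np.rint(2 * x).astype(int)
            g = np.empty((n, 2), dtype=object)
            g[:, 0] = np.where(cnt >= 1, "1", "2")
            g[:, 1] = np.where(cnt == 2, "1", "2")
            genos[name] = g
        fped = Pedigree(fam, ped.ids, ped.father, ped.mother, ped.sex)
        families[fam] = pedio.FamilyData(fped, traits, genos)
    pdata = pedio.PedData(
        families,
        trait_names=["endo", "disease"],
        marker_names=list(markers),
        positions={m: ("1", float(10 * i)) for i, m in enumerate(markers)},
    )
    paths = {
        "ped": prefix + ".ped",
        "dat": prefix + ".dat",
        "map": prefix + ".map",
        "ibd": prefix + ".ibd",
    }
    pedio.write_pedigree(pdata, paths["ped"], paths["dat"], paths["map"])
    with open(paths["ibd"], "w") as fh:
        fh.write("FAMILY ID1 ID2 MARKER P0 P1 P2\n")
        for f in range(sim.n_families):
            fam = str(f + 1)
            for name, pi in zip(markers, (sim.pi1[f], sim.pi2[f], sim.pi2[f])):
                for i in range(n):
                    for j in range(i, n):
                        k = int(round(2 * float(pi[i, j])))
                        probs = ["0", "0", "0"]
                        probs[k] = "1"
                        fh.write(
                            f"{fam} {ped.ids[i]} {ped.ids[j]} {name} "
                            + " ".join(probs) + "\n"
                        )
    return paths
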