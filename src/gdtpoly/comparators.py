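"""Reference tests: GEE-based Wald tests and dichotomous GDT variants.

These are the population-level and single-trait tests the within-family
polytomous machinery is compared against:

* ``gee_wald``: Wald tests from the pooled multinomial fit (GEE with an
  independence working correlation) with a family-clustered sandwich
  variance.  Being a population-level test, it is not protected against
  population stratification.
* the dichotomous GDT family: the standard GDT on the disease trait, GDTc
  (disease restricted to endophenotype-impaired members, everyone else's
  phenotype set to missing), GDTe (the endophenotype trait), and the
  conditional 2-df tests of the dichotomous two-locus logistic model,
  "cdisease" (on the disease) and "cendo" (on the endophenotype).  All are
  the K = 2 case of the polytomous score machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import design, nuisance, scorecore
from .pedio import FamilySample

GDT_VARIANTS = ("GDT", "GDTc", "GDTe", "cdisease", "cendo")


@dataclass
class WaldResult:
    labels: tuple[str, ...]
    estimates: np.ndarray
    robust_cov: np.ndarray
    W: float
    df: int
    p: float


def gee_wald(
    samples,
    spec: design.DesignSpec,
    labels: tuple[str, ...] | None = None,
) -> WaldResult:
    """Family-clustered sandwich Wald test of a label subset.

    Fits the full pooled multinomial model, then uses the robust covariance
    B^-1 M B^-1 with B the pooled observed information and M the sum over
    families of outer products of family score sums.
    """
    samples = list(samples)
    labels = tuple(labels if labels is not None else spec.labels)
    fit = nuisance.fit_alpha(samples, spec)
    if not fit.converged:
        raise nuisance.FitError("GEE fit did not converge")
    sizes = [s.n for s in samples]
    bounds = np.cumsum([0] + sizes)
    p = fit.theta.size
    M = np.zeros((p, p))
    for f in range(len(samples)):
        gf = fit.obs_scores[bounds[f]: bounds[f + 1]].sum(axis=0)
        M += np.outer(gf, gf)
    Binv = np.linalg.pinv(fit.information)
    V = Binv @ M @ Binv
    V = (V + V.T) / 2.0
    idx = [fit.param_names.index(lab) for lab in labels]
    est = fit.theta[idx]
    Vs = V[np.ix_(idx, idx)]
    W = float(est @ np.linalg.solve(Vs, est))
    df = len(labels)
    return WaldResult(
        labels=labels,
        estimates=est,
        robust_cov=Vs,
        W=W,
        df=df,
        p=float(stats.chi2.sf(W, df)),
    )


# ---------------------------------------------------------------------------
# dichotomous GDT variants
# ---------------------------------------------------------------------------

def _recode_k2(sample: FamilySample, trait: str) -> FamilySample | None:
    """Derive a K=2 sample on one trait from a K=4 sample.

    Category decoding follows the fixed four-category mapping: the
    endophenotype is impaired in categories {1, 3}, the disease present in
    {2, 3}.  ``trait`` may be "disease", "endo", or "disease|endo" (disease
    among endophenotype-impaired members only; the rest are dropped, i.e.
    their phenotype is set to missing).
    """
    if sample.K != 4:
        raise ValueError("GDT variants expect K = 4 input samples")
    endo = np.isin(sample.y, (1, 3))
    dis = np.isin(sample.y, (2, 3))
    if trait == "disease":
        keep, aff = np.ones(sample.n, dtype=bool), dis
    elif trait == "endo":
        keep, aff = np.ones(sample.n, dtype=bool), endo
    elif trait == "disease|endo":
        keep, aff = endo, dis
    else:
        raise ValueError(f"unknown trait {trait!r}")
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        return None
    y = np.where(aff[idx], 1, 2)
    order = idx[np.argsort(y[np.arange(idx.size)], kind="stable")]
    sub = np.ix_(order, order)
    return FamilySample(
        fam=sample.fam,
        ids=[sample.ids[i] for i in order],
        y=np.sort(y, kind="stable"),
        K=2,
        kin2=sample.kin2[sub],
        x1=sample.x1[order] if sample.x1 is not None else None,
        x2=sample.x2[order] if sample.x2 is not None else None,
        pi1=sample.pi1[sub] if sample.pi1 is not None else None,
        pi2=sample.pi2[sub] if sample.pi2 is not None else None,
    )


def gdt_variants(
    samples,
    variant: str,
    weights: str = "equal",
    null_mode: str = "assoc",
    kernel: str = "auto",
) -> scorecore.ScoreTestResult:
    """Run one dichotomous comparator test on K=4 family samples.

    GDT/GDTc/GDTe are the single-marker (x2) within-family score test with
    equal weights; cdisease/cendo are the conditional 2-df tests of the
    locus-2 coefficients of the dichotomous two-locus model, with pair
    weights from the x1-only nuisance fit.
    """
    samples = list(samples)
    if variant in ("GDT", "GDTc", "GDTe"):
        trait = {"GDT": "disease", "GDTc": "disease|endo", "GDTe": "endo"}[variant]
        k2 = [s2 for s in samples if (s2 := _recode_k2(s, trait)) is not None]
        spec = design.one_locus(K=2, var="x2", prefix="b")
        return scorecore.score_test(
            k2, spec, ("b1",), weights="equal", kernel=kernel, null_mode=null_mode
        )
    if variant in ("cdisease", "cendo"):
        trait = "disease" if variant == "cdisease" else "endo"
        k2 = [s2 for s in samples if (s2 := _recode_k2(s, trait)) is not None]
        spec = design.dichotomous_two_locus()
        alpha_fit = None
        if weights != "equal":
            free = spec.restrict(spec.free_labels())
            alpha_fit = nuisance.fit_alpha(k2, free)
        return scorecore.score_test(
            k2,
            spec,
            spec.conditional_null,
            weights=weights,
            alpha_fit=alpha_fit,
            kernel=kernel,
            null_mode=null_mode,
        )
    raise ValueError(f"unknown GDT variant {variant!r}")
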