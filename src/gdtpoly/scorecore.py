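"""Family score contributions, pair weights, variances and test statistics.

The within-family score test contrasts, inside each family, the value of a
model term between members in the outcome category a coefficient belongs to
and members in all other categories.  For a coefficient h attached to
category a, the family contribution is

    S_f^(h) = sum_{i in E_a} sum_{j not in E_a} C_ij (f_h(i) - f_h(j))

where f_h is the term column and C_ij are pair weights.  Under the global
null all weights equal 1/n (the family's retained member count), recovering
the unweighted 1/n double sum; under a conditional null (some coefficients
free) the weights are functions of nuisance coefficient estimates.  Shared
coefficients (one label in several categories) pool the per-category double
sums.

Variances follow the pairwise-difference decomposition: for main-effect
terms the covariance kernel between members is the IBD sharing proportion at
the term's locus (or twice the kinship coefficient when testing the
no-linkage-and-no-association null, or when IBD is unknown) scaled by a
pooled within-family term variance; product terms use the product of the
two loci's sharing proportions.  Both a naive O(n^4) quadruple sum and an
algebraically identical O(n^2) grouped path are provided.  For joint tests
whose coefficients span several outcome categories the default
variance-covariance estimate is the empirical between-family sum
sum_f S_f S_f', consistent because each family contribution has zero
expectation under the null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import expit

from .design import DesignSpec
from .nuisance import PolytomousFit
from .pedio import FamilySample

logger = logging.getLogger(__name__)

WEIGHT_MODES = ("equal", "eq6", "eq7")


# ---------------------------------------------------------------------------
# pair weights
# ---------------------------------------------------------------------------

def pair_weights(
    sample: FamilySample,
    mode: str = "equal",
    alpha_fit: PolytomousFit | None = None,
) -> np.ndarray:
    """Full n x n matrix of pair weights C_ij for one family.

    The normalizer is the family's retained member count n, so that with all
    nuisance coefficients zero every weight reduces to 1/n and the weighted
    score equals the unweighted one.  For modes "eq6"/"eq7" the weight is a
    function of u_ij = (Xc_i - Xc_j)'(alpha_{Y_i} - alpha_{Y_j}) built from
    the free-predictor values Xc and the per-category nuisance slopes:

        eq6: C_ij = 2 / (n (1 + e^{u_ij}))
        eq7: C_ij = 8 e^{u_ij} / (n (1 + e^{u_ij})^3)
    """
    n = sample.n
    if n == 0:
        return np.zeros((0, 0))
    if mode == "equal":
        return np.full((n, n), 1.0 / n)
    if mode not in WEIGHT_MODES:
        raise ValueError(f"unknown weight mode {mode!r}")
    if alpha_fit is None:
        raise ValueError(f"weight mode {mode!r} requires nuisance estimates")
    Xc = alpha_fit.free_predictors(sample.x1, sample.x2)      # (n, q)
    A = alpha_fit.slope_array()[sample.y - 1]                 # (n, q)
    u = np.einsum(
        "ijq,ijq->ij", Xc[:, None, :] - Xc[None, :, :], A[:, None, :] - A[None, :, :]
    )
    if not np.isfinite(u).all():
        raise ValueError("non-finite pair-weight exponent")
    if mode == "eq6":
        return 2.0 * expit(-u) / n
    return 8.0 * expit(u) * expit(-u) ** 2 / n


# ---------------------------------------------------------------------------
# scores
# ---------------------------------------------------------------------------

def family_scores(
    sample: FamilySample,
    spec: DesignSpec,
    labels: tuple[str, ...],
    C: np.ndarray,
) -> np.ndarray:
    """Vector of family score contributions S_f^(h) for the given labels.

    Non-informative families (a single category among retained members)
    contribute exactly zero.
    """
    cols = spec.term_columns(sample.x1, sample.x2, labels)
    S = np.zeros(len(labels))
    if not sample.informative:
        return S
    for m, lab in enumerate(labels):
        f = cols[lab]
        for a in spec.categories(lab):
            mask = sample.y == a
            if not mask.any() or mask.all():
                continue
            diff = f[mask][:, None] - f[~mask][None, :]
            S[m] += float((C[np.ix_(mask, ~mask)] * diff).sum())
    return S


def score_unweighted(
    sample: FamilySample, spec: DesignSpec, label: str
) -> float:
    """Unweighted family score (global-null form, weights 1/n)."""
    C = pair_weights(sample, "equal")
    return float(family_scores(sample, spec, (label,), C)[0])


# ---------------------------------------------------------------------------
# pooled term moments
# ---------------------------------------------------------------------------

def pooled_term_moments(
    samples, spec: DesignSpec, labels: tuple[str, ...]
) -> np.ndarray:
    """Pooled within-family covariance matrix of the term columns.

    sigma_gh = sum_f sum_i (f_g(i) - mean_f g)(f_h(i) - mean_f h) /
               sum_f (n_f - 1), over retained members of families with
    n_f >= 2.
    """
    m = len(labels)
    num = np.zeros((m, m))
    den = 0.0
    for s in samples:
        if s.n < 2:
            continue
        cols = spec.term_columns(s.x1, s.x2, labels)
        Xm = np.column_stack([cols[lab] for lab in labels])
        Xm = Xm - Xm.mean(axis=0)
        num += Xm.T @ Xm
        den += s.n - 1
    if den == 0:
        return np.zeros((m, m))
    return num / den


# ---------------------------------------------------------------------------
# model-based variance / covariance
# ---------------------------------------------------------------------------

def _pair_kernel(
    sample: FamilySample, spec: DesignSpec, g: str, h: str, null_mode: str
) -> np.ndarray | None:
    """Member-pair relatedness kernel R for a label pair, or None when the
    model-based covariance is structurally zero (main effects at different
    unlinked loci)."""
    lg, lh = set(spec.loci(g)), set(spec.loci(h))
    shared = lg & lh
    if not shared:
        return None
    if lg == lh == {1, 2}:
        return sample.relatedness(1, null_mode) * sample.relatedness(2, null_mode)
    # a main effect against anything sharing its locus: that locus' kernel
    locus = next(iter(lg if len(lg) == 1 else lh))
    return sample.relatedness(locus, null_mode)


def _weight_margins(C: np.ndarray, mask: np.ndarray):
    r = C[np.ix_(mask, ~mask)].sum(axis=1)    # per i in E_a
    c = C[np.ix_(mask, ~mask)].sum(axis=0)    # per j in E_a^c
    return r, c


def family_cov_model(
    sample: FamilySample,
    spec: DesignSpec,
    g: str,
    h: str,
    C: np.ndarray,
    null_mode: str = "assoc",
    method: str = "fast",
) -> float:
    """One family's model-based Cov[S^(g), S^(h)] contribution, without the
    pooled sigma factor.

    ``method="fast"`` groups the quadruple sum through per-member weight
    margins (O(n^2)); ``method="naive"`` evaluates the quadruple sum
    directly and is kept as an independent cross-check.
    """
    if not sample.informative:
        return 0.0
    R = _pair_kernel(sample, spec, g, h, null_mode)
    if R is None:
        return 0.0
    total = 0.0
    for a in spec.categories(g):
        ma = sample.y == a
        if not ma.any() or ma.all():
            continue
        for b in spec.categories(h):
            mb = sample.y == b
            if not mb.any() or mb.all():
                continue
            if method == "naive":
                ia, ja = np.flatnonzero(ma), np.flatnonzero(~ma)
                ib, jb = np.flatnonzero(mb), np.flatnonzero(~mb)
                acc = 0.0
                for i in ia:
                    for j in ja:
                        for k in ib:
                            for l in jb:
                                acc += C[i, j] * C[k, l] * (
                                    R[i, k] + R[j, l] - R[i, l] - R[j, k]
                                )
                total += acc
            elif method == "fast":
                ra, ca = _weight_margins(C, ma)
                rb, cb = _weight_margins(C, mb)
                total += (
                    ra @ R[np.ix_(ma, mb)] @ rb
                    + ca @ R[np.ix_(~ma, ~mb)] @ cb
                    - ra @ R[np.ix_(ma, ~mb)] @ cb
                    - ca @ R[np.ix_(~ma, mb)] @ rb
                )
            else:
                raise ValueError(f"unknown method {method!r}")
    return float(total)


def model_covariance(
    samples,
    spec: DesignSpec,
    labels: tuple[str, ...],
    Cs: list[np.ndarray],
    null_mode: str = "assoc",
    method: str = "fast",
) -> np.ndarray:
    """Model-based v[S] over all families: kernel sums scaled by the pooled
    within-family term (co)variances.  Raises on a meaningfully negative
    diagonal entry (an IBD/kinship inconsistency)."""
    sigma = pooled_term_moments(samples, spec, labels)
    m = len(labels)
    V = np.zeros((m, m))
    for s, C in zip(samples, Cs):
        for i in range(m):
            for j in range(i, m):
                k = family_cov_model(s, spec, labels[i], labels[j], C, null_mode, method)
                V[i, j] += k * sigma[i, j]
                if i != j:
                    V[j, i] = V[i, j]
    scale = max(np.abs(V).max(), 1.0)
    if (np.diag(V) < -1e-10 * scale).any():
        raise ValueError("negative model-based variance: inconsistent IBD/kinship input")
    np.fill_diagonal(V, np.maximum(np.diag(V), 0.0))
    return V


def empirical_covariance(score_vectors: np.ndarray) -> np.ndarray:
    """Empirical between-family v[S] = sum_f S_f S_f' (valid because each
    family score has zero null expectation)."""
    Sf = np.asarray(score_vectors)
    return Sf.T @ Sf


# ---------------------------------------------------------------------------
# test statistics
# ---------------------------------------------------------------------------

@dataclass
class ScoreTestResult:
    """Scores, variance estimate and test statistics for a label set."""

    labels: tuple[str, ...]
    S: np.ndarray
    V: np.ndarray
    T: float
    df: int
    p: float
    z: np.ndarray
    z_p: np.ndarray
    kernel: str
    weight_mode: str
    null_mode: str
    n_informative: int
    untestable: bool = False
    extra: dict = field(default_factory=dict)

    def row(self, marker: str = "", model: str = "", test: str = "") -> dict:
        return {
            "marker": marker,
            "model": model,
            "test": test,
            "stat": self.T,
            "df": self.df,
            "p": self.p,
            "null_mode": self.null_mode,
            "weight_mode": self.weight_mode,
            "kernel": self.kernel,
            "n_informative": self.n_informative,
        }


def test_joint(S: np.ndarray, V: np.ndarray, rank_tol: float = 1e-8):
    """Joint chi-square statistic T = S' v[S]^+ S with rank-based df.

    Uses the eigendecomposition pseudo-inverse; df is the number of
    eigenvalues above rank_tol relative to the largest.  An all-zero V is
    untestable (T = 0, p = NaN).
    """
    S = np.atleast_1d(np.asarray(S, dtype=float))
    V = np.atleast_2d(np.asarray(V, dtype=float))
    w, Q = np.linalg.eigh((V + V.T) / 2.0)
    wmax = w.max() if w.size else 0.0
    if wmax <= 0.0:
        return 0.0, 0, np.nan, True
    keep = w > rank_tol * wmax
    df = int(keep.sum())
    coords = Q[:, keep].T @ S
    T = float((coords**2 / w[keep]).sum())
    p = float(stats.chi2.sf(T, df))
    return T, df, p, False


def test_single(S: float, v: float):
    """Z = S / sqrt(v) with a two-sided normal p-value."""
    if v <= 0.0:
        return np.nan, np.nan
    z = float(S / np.sqrt(v))
    return z, float(2.0 * stats.norm.sf(abs(z)))


def score_test(
    samples,
    spec: DesignSpec,
    labels: tuple[str, ...] | None = None,
    weights: str = "equal",
    alpha_fit: PolytomousFit | None = None,
    kernel: str = "auto",
    null_mode: str = "assoc",
    method: str = "fast",
) -> ScoreTestResult:
    """Run the within-family score test of a coefficient label set.

    ``kernel="auto"`` uses the model-based variance for a single label and
    the empirical between-family covariance for joint tests.  ``null_mode``
    selects the relatedness entering model-based variances: "assoc" (IBD
    sharing; linkage allowed under the null) or "linkage-assoc" (twice the
    kinship coefficients).
    """
    samples = list(samples)
    labels = tuple(labels if labels is not None else spec.conditional_null or spec.labels)
    if not labels:
        raise ValueError("no labels to test")
    Cs = [pair_weights(s, weights, alpha_fit) for s in samples]
    Sf = np.array([family_scores(s, spec, labels, C) for s, C in zip(samples, Cs)])
    S = Sf.sum(axis=0)
    if kernel == "auto":
        kernel = "model" if len(labels) == 1 else "empirical"
    if kernel == "empirical":
        if len(samples) < len(labels):
            logger.warning(
                "empirical covariance kernel with fewer families (%d) than "
                "tested labels (%d): rank deficiency likely",
                len(samples), len(labels),
            )
        V = empirical_covariance(Sf)
    elif kernel == "model":
        V = model_covariance(samples, spec, labels, Cs, null_mode, method)
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    T, df, p, untestable = test_joint(S, V)
    dv = np.diag(V)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(dv > 0, S / np.sqrt(np.where(dv > 0, dv, 1.0)), np.nan)
    z_p = 2.0 * stats.norm.sf(np.abs(z))
    return ScoreTestResult(
        labels=labels,
        S=S,
        V=V,
        T=T,
        df=df,
        p=p,
        z=z,
        z_p=z_p,
        kernel=kernel,
        weight_mode=weights,
        null_mode=null_mode,
        n_informative=sum(1 for s in samples if s.informative),
        untestable=untestable,
    )
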