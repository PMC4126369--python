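"""Model design: per-category predictor terms and coefficient layout.

A polytomous logistic model with reference category K is described by a
:class:`DesignSpec`: for every non-reference category k it lists terms, each
a function of the two genotype proportions (x1, x2), and assigns every term
instance a coefficient label.  A label used in a single category yields the
simplified single-contrast score; a label repeated across categories is a
shared coefficient and its score pools the per-category contrasts.

The term vocabulary is {x1, x2, x1*x2, x1*(1-x2)}; all are total on
{0, 1/2, 1}^2.  Presets cover the full two-locus model, the one-locus model,
the endophenotype-to-disease interaction model, and the usual dichotomous
two-locus logistic model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TERM_FUNCS = {
    "x1": lambda x1, x2: np.asarray(x1, dtype=float),
    "x2": lambda x1, x2: np.asarray(x2, dtype=float),
    "x1*x2": lambda x1, x2: np.asarray(x1, dtype=float) * np.asarray(x2, dtype=float),
    "x1*(1-x2)": lambda x1, x2: np.asarray(x1, dtype=float)
    * (1.0 - np.asarray(x2, dtype=float)),
}

# loci a term function depends on; drives which IBD matrices enter variances
TERM_LOCI = {"x1": (1,), "x2": (2,), "x1*x2": (1, 2), "x1*(1-x2)": (1, 2)}


@dataclass(frozen=True)
class Term:
    category: int
    func: str
    label: str


@dataclass(frozen=True)
class DesignSpec:
    """Predictor terms and coefficient labels of a polytomous model."""

    K: int
    terms: tuple[Term, ...]
    conditional_null: tuple[str, ...] = ()
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be at least 2")
        seen_cat_func = set()
        for t in self.terms:
            if not 1 <= t.category <= self.K - 1:
                raise ValueError(
                    f"term {t.label}: category {t.category} outside 1..{self.K - 1}"
                )
            if t.func not in TERM_FUNCS:
                raise ValueError(
                    f"term {t.label}: unknown term function {t.func!r} "
                    "(only two loci are supported)"
                )
            if (t.category, t.func) in seen_cat_func:
                raise ValueError(
                    f"duplicate term {t.func} in category {t.category}"
                )
            seen_cat_func.add((t.category, t.func))
        funcs: dict[str, str] = {}
        for t in self.terms:
            if funcs.setdefault(t.label, t.func) != t.func:
                raise ValueError(
                    f"label {t.label} shared across different term functions"
                )
        for lab in self.conditional_null:
            if lab not in funcs:
                raise ValueError(f"conditional-null label {lab} maps to no term")

    # -- label structure ---------------------------------------------------

    @property
    def labels(self) -> tuple[str, ...]:
        out, seen = [], set()
        for t in self.terms:
            if t.label not in seen:
                out.append(t.label)
                seen.add(t.label)
        return tuple(out)

    def categories(self, label: str) -> tuple[int, ...]:
        cats = tuple(t.category for t in self.terms if t.label == label)
        if not cats:
            raise KeyError(f"label {label!r} not in design")
        return cats

    def func(self, label: str) -> str:
        for t in self.terms:
            if t.label == label:
                return t.func
        raise KeyError(f"label {label!r} not in design")

    def is_shared(self, label: str) -> bool:
        return len(self.categories(label)) > 1

    def loci(self, label: str) -> tuple[int, ...]:
        return TERM_LOCI[self.func(label)]

    @property
    def funcs(self) -> tuple[str, ...]:
        out, seen = [], set()
        for t in self.terms:
            if t.func not in seen:
                out.append(t.func)
                seen.add(t.func)
        return tuple(out)

    @property
    def requires_x1(self) -> bool:
        return any(1 in TERM_LOCI[f] for f in self.funcs)

    @property
    def requires_x2(self) -> bool:
        return any(2 in TERM_LOCI[f] for f in self.funcs)

    def free_labels(self, tested: tuple[str, ...] | None = None) -> tuple[str, ...]:
        tested = self.conditional_null if tested is None else tested
        return tuple(lab for lab in self.labels if lab not in tested)

    def restrict(self, labels: tuple[str, ...], name: str | None = None) -> "DesignSpec":
        """Sub-design keeping only the given coefficient labels."""
        return DesignSpec(
            K=self.K,
            terms=tuple(t for t in self.terms if t.label in labels),
            name=name or f"{self.name}|{'+'.join(labels)}",
        )

    # -- evaluation --------------------------------------------------------

    def term_columns(self, x1, x2, labels=None) -> dict[str, np.ndarray]:
        """Evaluate each label's term function on the member genotypes.

        Shared labels use a single function by construction, so one column
        per label suffices.  Pure: depends only on (x1, x2).
        """
        labels = self.labels if labels is None else labels
        cols = {}
        for lab in labels:
            f = self.func(lab)
            if 1 in TERM_LOCI[f] and x1 is None:
                raise ValueError(f"label {lab} needs x1 but none supplied")
            if 2 in TERM_LOCI[f] and x2 is None:
                raise ValueError(f"label {lab} needs x2 but none supplied")
            cols[lab] = TERM_FUNCS[f](
                x1 if x1 is not None else 0.0, x2 if x2 is not None else 0.0
            )
        return cols


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def full_two_locus(K: int = 4) -> DesignSpec:
    """Full two-locus polytomous model: each non-reference category gets
    x1, x2 and x1*x2 with its own coefficients b_k1, b_k2, b_k3.

    The conditional null (test of locus 2 given locus 1) collects the six
    locus-2 coefficients {b12, b13, b22, b23, b32, b33}.
    """
    if K != 4:
        raise ValueError("the full two-locus model is defined for K = 4")
    terms = []
    for k in range(1, 4):
        terms += [
            Term(k, "x1", f"b{k}1"),
            Term(k, "x2", f"b{k}2"),
            Term(k, "x1*x2", f"b{k}3"),
        ]
    return DesignSpec(
        K=4,
        terms=tuple(terms),
        conditional_null=("b12", "b13", "b22", "b23", "b32", "b33"),
        name="full2locus",
    )


def one_locus(K: int = 4, var: str = "x2", prefix: str = "b") -> DesignSpec:
    """Single-locus polytomous model: one allele-proportion term per
    non-reference category with a distinct coefficient b1..b{K-1}."""
    if var not in ("x1", "x2"):
        raise ValueError("var must be 'x1' or 'x2'")
    terms = tuple(Term(k, var, f"{prefix}{k}") for k in range(1, K))
    return DesignSpec(
        K=K,
        terms=terms,
        conditional_null=tuple(t.label for t in terms),
        name=f"onelocus[{var}]",
    )


def endo_to_disease() -> DesignSpec:
    """Endophenotype-to-disease model (K = 4).

    Locus 1 raises endophenotype risk; locus 2 raises disease risk only in
    locus-1 carriers: category 1 gets x1 (b11) and x1*(1-x2) (be), category
    2 gets x1 (b21), category 3 gets x1 (b31) and x1*x2 (b33).  The
    conditional null is {be, b33}.
    """
    terms = (
        Term(1, "x1", "b11"),
        Term(1, "x1*(1-x2)", "be"),
        Term(2, "x1", "b21"),
        Term(3, "x1", "b31"),
        Term(3, "x1*x2", "b33"),
    )
    return DesignSpec(
        K=4, terms=terms, conditional_null=("be", "b33"), name="endo2disease"
    )


def dichotomous_two_locus() -> DesignSpec:
    """Usual two-locus logistic model for a dichotomous trait (K = 2):
    eta1*x1 + eta2*x2 + eta3*x1*x2; the 2-df conditional null is
    {eta2, eta3}."""
    terms = (
        Term(1, "x1", "eta1"),
        Term(1, "x2", "eta2"),
        Term(1, "x1*x2", "eta3"),
    )
    return DesignSpec(
        K=2, terms=terms, conditional_null=("eta2", "eta3"), name="dichot2locus"
    )


def custom(
    K: int,
    terms: list[tuple[int, str, str]],
    conditional_null: tuple[str, ...] = (),
    name: str = "custom",
) -> DesignSpec:
    """User-defined design from (category, term function, label) triples."""
    spec = DesignSpec(
        K=K,
        terms=tuple(Term(c, f, lab) for c, f, lab in terms),
        conditional_null=tuple(conditional_null),
        name=name,
    )
    cats_with_terms = {t.category for t in spec.terms}
    for k in range(1, K):
        if k not in cats_with_terms:
            raise ValueError(f"non-reference category {k} has no terms")
    return spec


PRESETS = {
    "full2locus": full_two_locus,
    "onelocus": one_locus,
    "endo2disease": endo_to_disease,
    "dichot2locus": dichotomous_two_locus,
}
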