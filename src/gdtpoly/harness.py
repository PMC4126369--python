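"""Experiment orchestration: Type-I-error and power batteries, marker scans.

The battery mirrors the tests compared in the simulation study:

* ``bvec_1L``  - joint test of all single-locus polytomous coefficients
* ``b3_1L``    - the category-3 (disease and endophenotype) coefficient alone
* ``cpoly``    - 6-df conditional test of locus 2 given locus 1 (full model)
* ``be_b33``   - 2-df conditional test under the endophenotype-to-disease model
* ``b33``      - the (1,1)-category interaction coefficient alone
* ``GDT`` / ``GDTc`` / ``GDTe`` / ``cdisease`` / ``cendo`` - dichotomous
  comparators
* ``gee_bvec_1L`` / ``gee_b3_1L`` - GEE-based Wald tests of the one-locus model

Conditional tests condition on the causal locus-1 variant, weight subject
pairs by the logistic weight expression (eq6 by default) using one pooled
nuisance fit per replicate, and use the empirical between-family covariance
for joint statistics.  Type-I-error runs test the null marker at locus 2
under the association-only null with the exact simulated IBD; power runs
test the causal locus-2 variant on the same replicates.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import comparators, design, nuisance, pedio, scorecore, simulator

logger = logging.getLogger(__name__)

WITHIN_FAMILY_TESTS = (
    "bvec_1L", "b3_1L", "b33", "be_b33", "cpoly",
    "GDT", "GDTc", "GDTe", "cdisease", "cendo",
)
GEE_TESTS = ("gee_bvec_1L", "gee_b3_1L")
ALL_TESTS = WITHIN_FAMILY_TESTS + GEE_TESTS

TSV_COLUMNS = [
    "marker", "model", "test", "stat", "df", "p",
    "null_mode", "weight_mode", "kernel", "n_informative",
]


def derive_seed(master: int, index: int) -> int:
    """Counter-based replicate seed below 2^31, stable across platforms."""
    return int(
        np.random.SeedSequence([int(master), int(index)]).generate_state(1)[0]
        % (2**31 - 1)
    )


# ---------------------------------------------------------------------------
# per-replicate battery
# ---------------------------------------------------------------------------

def replicate_pvalues(
    samples: list[pedio.FamilySample],
    tests=WITHIN_FAMILY_TESTS,
    weights: str = "eq6",
    null_mode: str = "assoc",
) -> dict[str, float]:
    """p-value of each requested test on one replicate's family samples.

    ``samples`` are K=4 samples with x1 = conditioning marker and x2 = the
    tested marker.  One nuisance fit of the outcome on x1 per replicate
    serves every conditional test.
    """
    out: dict[str, float] = {}
    alpha4 = None

    def get_alpha4():
        nonlocal alpha4
        if alpha4 is None:
            free = design.one_locus(K=4, var="x1", prefix="a")
            alpha4 = nuisance.fit_alpha(samples, free)
        return alpha4

    for test in tests:
        if test in ("GDT", "GDTc", "GDTe"):
            res = comparators.gdt_variants(samples, test, null_mode=null_mode)
            out[test] = res.p
        elif test in ("cdisease", "cendo"):
            res = comparators.gdt_variants(
                samples, test, weights=weights, null_mode=null_mode
            )
            out[test] = res.p
        elif test == "bvec_1L":
            spec = design.one_locus(K=4)
            res = scorecore.score_test(
                samples, spec, spec.labels, weights="equal",
                kernel="empirical", null_mode=null_mode,
            )
            out[test] = res.p
        elif test == "b3_1L":
            spec = design.one_locus(K=4)
            res = scorecore.score_test(
                samples, spec, ("b3",), weights="equal",
                kernel="model", null_mode=null_mode,
            )
            out[test] = res.p
        elif test == "b33":
            spec = design.full_two_locus()
            res = scorecore.score_test(
                samples, spec, ("b33",), weights=weights,
                alpha_fit=get_alpha4() if weights != "equal" else None,
                kernel="model", null_mode=null_mode,
            )
            out[test] = res.p
        elif test == "be_b33":
            spec = design.endo_to_disease()
            res = scorecore.score_test(
                samples, spec, spec.conditional_null, weights=weights,
                alpha_fit=get_alpha4() if weights != "equal" else None,
                kernel="empirical", null_mode=null_mode,
            )
            out[test] = res.p
        elif test == "cpoly":
            spec = design.full_two_locus()
            res = scorecore.score_test(
                samples, spec, spec.conditional_null, weights=weights,
                alpha_fit=get_alpha4() if weights != "equal" else None,
                kernel="empirical", null_mode=null_mode,
            )
            out[test] = res.p
        elif test == "gee_bvec_1L":
            spec = design.one_locus(K=4)
            out[test] = comparators.gee_wald(samples, spec, spec.labels).p
        elif test == "gee_b3_1L":
            spec = design.one_locus(K=4)
            out[test] = comparators.gee_wald(samples, spec, ("b3",)).p
        else:
            raise ValueError(f"unknown test {test!r}")
    return out


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------

@dataclass
class ExperimentReport:
    """Rejection proportions per test and nominal level, with binomial SEs."""

    table: pd.DataFrame
    scenario: str
    seed: int
    replicates: int
    families: int
    tested: str
    runtime_s: float
    failures: dict[str, int] = field(default_factory=dict)
    pvalues: pd.DataFrame | None = None

    def rejection(self, test: str, level: float) -> float:
        m = (self.table["test"] == test) & np.isclose(self.table["level"], level)
        return float(self.table.loc[m, "proportion"].iloc[0])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _pool_pvalues(
    pool: simulator.SimulatedSample,
    replicates: int,
    families: int,
    tests,
    tested: str,
    weights: str,
    null_mode: str,
) -> tuple[pd.DataFrame, dict[str, int]]:
    rows = []
    failures: dict[str, int] = {t: 0 for t in tests}
    for r in range(replicates):
        sl = pool.subset(slice(r * families, (r + 1) * families))
        samples = simulator.to_family_samples(sl, tested=tested)
        try:
            ps = replicate_pvalues(samples, tests, weights, null_mode)
        except nuisance.FitError:
            # whole-replicate failure: retry tests one at a time
            ps = {}
            for t in tests:
                try:
                    ps.update(replicate_pvalues(samples, (t,), weights, null_mode))
                except nuisance.FitError:
                    logger.warning("replicate %d: test %s failed; skipped", r, t)
                    failures[t] += 1
                    ps[t] = np.nan
        rows.append(ps)
    return pd.DataFrame(rows), failures


def _tally(pdf: pd.DataFrame, levels) -> pd.DataFrame:
    rows = []
    for test in pdf.columns:
        p = pdf[test].to_numpy(dtype=float)
        ok = np.isfinite(p)
        for level in levels:
            rej = int((p[ok] < level).sum())
            n = int(ok.sum())
            prop = rej / n if n else np.nan
            se = np.sqrt(prop * (1 - prop) / n) if n else np.nan
            rows.append(
                {
                    "test": test, "level": level, "replicates": n,
                    "rejections": rej, "proportion": prop, "se": se,
                }
            )
    return pd.DataFrame(rows)


def run_battery(
    pool: simulator.SimulatedSample,
    replicates: int,
    families: int,
    tests=WITHIN_FAMILY_TESTS,
    tested: str = "null",
    weights: str = "eq6",
    null_mode: str = "assoc",
    levels=(0.01, 0.05),
    scenario_name: str = "",
    seed: int = 0,
) -> ExperimentReport:
    """Tally rejection proportions over pre-simulated replicates."""
    if pool.n_families < replicates * families:
        raise ValueError("pool holds fewer families than replicates * families")
    t0 = time.perf_counter()
    pdf, failures = _pool_pvalues(
        pool, replicates, families, tests, tested, weights, null_mode
    )
    table = _tally(pdf, levels)
    return ExperimentReport(
        table=table,
        scenario=scenario_name,
        seed=seed,
        replicates=replicates,
        families=families,
        tested=tested,
        runtime_s=time.perf_counter() - t0,
        failures=failures,
        pvalues=pdf,
    )


def run_type1(
    scenario: simulator.Scenario,
    tests=WITHIN_FAMILY_TESTS,
    replicates: int = 250,
    families: int = 100,
    seed: int = 0,
    weights: str = "eq6",
    null_mode: str = "assoc",
    levels=(0.01, 0.05),
) -> ExperimentReport:
    """Type-I-error experiment: simulate ascertained families and test the
    non-associated (but linked) marker at locus 2."""
    rng = np.random.default_rng(derive_seed(seed, 0))
    pool = simulator.simulate_sample(scenario, replicates * families, rng)
    name = "mixture" if scenario.mixture else "homogeneous"
    return run_battery(
        pool, replicates, families, tests, "null", weights, null_mode,
        levels, scenario_name=name, seed=seed,
    )


def run_power(
    scenario: simulator.Scenario,
    tests=WITHIN_FAMILY_TESTS,
    replicates: int = 250,
    families: int = 100,
    seed: int = 0,
    weights: str = "eq6",
    null_mode: str = "assoc",
    levels=(0.01, 0.05),
) -> ExperimentReport:
    """Power experiment: identical loop but testing the causal locus-2
    variant."""
    rng = np.random.default_rng(derive_seed(seed, 0))
    pool = simulator.simulate_sample(scenario, replicates * families, rng)
    name = "mixture" if scenario.mixture else "homogeneous"
    return run_battery(
        pool, replicates, families, tests, "causal", weights, null_mode,
        levels, scenario_name=name, seed=seed,
    )


# ---------------------------------------------------------------------------
# marker scans on files
# ---------------------------------------------------------------------------

def scan(
    ped_path,
    dat_path,
    model: str = "onelocus",
    conditioning_marker: str | None = None,
    tested_markers: list[str] | None = None,
    traits: tuple[str, ...] = ("endo", "disease"),
    ibd_path=None,
    weights: str = "eq6",
    null_mode: str = "assoc",
) -> pd.DataFrame:
    """Scan markers in a Merlin/QTDT file set; one row per marker per test.

    For conditional models (full2locus, endo2disease, dichot2locus) the
    conditioning marker provides x1 and each tested marker provides x2; the
    one-locus model ignores the conditioning marker.  A tested marker equal
    to the conditioning marker is flagged degenerate and given no p-value.
    Deterministic given the input files.
    """
    pdata = pedio.read_pedigree(ped_path, dat_path)
    if model not in design.PRESETS:
        raise ValueError(f"unknown model {model!r}")
    needs_x1 = model != "onelocus"
    if needs_x1 and conditioning_marker is None:
        raise ValueError(f"model {model} requires a conditioning marker")
    if tested_markers is None:
        tested_markers = [
            m for m in pdata.marker_names if m != conditioning_marker
        ]
    ibd = None
    if ibd_path is not None:
        peds = pdata.pedigrees()
        ibd = {
            m: pedio.read_ibd(ibd_path, m, peds)
            for m in set(tested_markers) | ({conditioning_marker} if needs_x1 else set())
        }
    K = 2 if len(traits) == 1 else 4
    spec = design.PRESETS[model]() if model != "onelocus" else design.one_locus(K=K)
    if spec.K != K:
        raise ValueError(f"model {model} expects K={spec.K}, traits give K={K}")
    rows = []
    for mk in tested_markers:
        if needs_x1 and mk == conditioning_marker:
            rows.append(
                {
                    "marker": mk, "model": model, "test": "degenerate",
                    "stat": np.nan, "df": 0, "p": np.nan,
                    "null_mode": null_mode, "weight_mode": weights,
                    "kernel": "", "n_informative": 0,
                }
            )
            logger.warning(
                "tested marker %s equals the conditioning marker; skipped", mk
            )
            continue
        samples = pedio.build_family_samples(
            pdata, traits,
            marker_x2=mk,
            marker_x1=conditioning_marker if needs_x1 else None,
            ibd=ibd,
        )
        alpha_fit = None
        use_w = weights
        free = spec.free_labels()
        if free and weights != "equal":
            alpha_fit = nuisance.fit_alpha(samples, spec.restrict(free))
        elif not free:
            use_w = "equal"   # global test: no free coefficients, no weighting model
        joint = scorecore.score_test(
            samples, spec, spec.conditional_null,
            weights=use_w, alpha_fit=alpha_fit, null_mode=null_mode,
        )
        rows.append(joint.row(mk, model, "joint"))
        for lab in spec.conditional_null:
            single = scorecore.score_test(
                samples, spec, (lab,),
                weights=use_w, alpha_fit=alpha_fit, null_mode=null_mode,
            )
            rows.append(single.row(mk, model, lab))
    return pd.DataFrame(rows, columns=TSV_COLUMNS)
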