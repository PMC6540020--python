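"""Metrics, the gender-balanced train/test split, and end-to-end experiment runs.

Model quality is summarized the way the body-composition validation literature
does: the Pearson product-moment correlation r between reference and predicted
values, its square r^2, and the standard error of estimate

    SEE = sqrt( sum (ref_i - pred_i)^2 / (n - 2) ),

in percent-body-fat units.  Cohorts are split into a training set and a test
set with fixed gender counts (default 20 test subjects, 10 of each gender,
leaving 143 for training on the default 163-subject cohort).

:func:`run_experiment` wires the full pipeline — feasibility screen, settling
extrapolation, H^2/R50 estimation, percent-body-fat model — for any subset of
the four regimes (linear/DNN x conventional/proposed features) on one shared
split and one shared set of calibrated impedances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .calibration import CalibrationConfig, check_feasibility, estimate_settled_value
from .errors import SplitError, UndefinedCorrelationError, WristBiaError
from .models import (
    H2RVariant,
    PBFRegime,
    estimate_h2r,
    estimate_pbf,
    fit_h2r_model,
    fit_pbf_model,
)
from .simulate import SubjectRecord

__all__ = [
    "EvaluationReport",
    "SplitSpec",
    "pearson_r",
    "see",
    "split_cohort",
    "run_experiment",
]


@dataclass(frozen=True)
class EvaluationReport:
    """Test-set metrics for one regime."""

    regime: str
    n_train: int
    n_test: int
    pearson_r: float
    r_squared: float
    see: float


@dataclass(frozen=True)
class SplitSpec:
    """Gender-balanced test split: ``balance`` maps gender code to test count."""

    n_test: int = 20
    balance: tuple[tuple[int, int], ...] = ((0, 10), (1, 10))
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(n for _, n in self.balance) != self.n_test:
            raise SplitError("balance counts must sum to n_test")


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise WristBiaError("need equal-length vectors with at least 3 entries")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError("zero variance input")
    return float(stats.pearsonr(x, y).statistic)


def see(ref: np.ndarray, pred: np.ndarray, dof: int | None = None) -> float:
    """Standard error of estimate, sqrt(SS_res / (n - 2)) by convention.

    ``dof`` overrides the residual degrees of freedom (e.g. n - p - 1 for a
    model with p fitted slopes).
    """
    ref = np.asarray(ref, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if len(ref) != len(pred):
        raise WristBiaError("ref and pred must have equal length")
    d = len(ref) - 2 if dof is None else dof
    if d <= 0:
        raise WristBiaError("non-positive residual degrees of freedom")
    return float(np.sqrt(np.sum((ref - pred) ** 2) / d))


def split_cohort(
    cohort: list[SubjectRecord], spec: SplitSpec = SplitSpec()
) -> tuple[list[SubjectRecord], list[SubjectRecord]]:
    """Seeded disjoint train/test split with exact per-gender test counts."""
    if spec.n_test >= len(cohort):
        raise SplitError("n_test must be smaller than the cohort")
    rng = np.random.default_rng(spec.seed)
    test_ids: set[str] = set()
    for gender, count in spec.balance:
        pool = [s.id for s in cohort if s.gender == gender]
        if len(pool) < count:
            raise SplitError(
                f"need {count} subjects of gender {gender}, cohort has {len(pool)}"
            )
        chosen = rng.permutation(len(pool))[:count]
        test_ids.update(pool[i] for i in chosen)
    train = [s for s in cohort if s.id not in test_ids]
    test = [s for s in cohort if s.id in test_ids]
    return train, test


def run_experiment(
    cohort: list[SubjectRecord],
    regimes: list[PBFRegime] | None = None,
    split: SplitSpec = SplitSpec(),
    seed: int = 0,
    calibration: CalibrationConfig = CalibrationConfig(),
    net1_variant: H2RVariant = H2RVariant.MODEL_III,
    net1_hidden_nodes: int = 128,
    net2_hidden_nodes: int = 256,
) -> list[EvaluationReport]:
    """Run the full pipeline and report test-set metrics per regime.

    Every regime consumes the same feasibility-screened subjects, the same
    calibrated impedances and the same train/test split.  Linear regimes use
    the regression H^2/R50 estimate; DNN regimes use the ``net1_variant``
    network estimate.  Subjects flagged by the feasibility screen are dropped
    (the field protocol would re-measure them).
    """
    regimes = list(PBFRegime) if regimes is None else regimes

    usable: list[SubjectRecord] = []
    settled: dict[str, float] = {}
    for s in cohort:
        if not check_feasibility(s.upper_series, calibration).valid:
            continue
        est = estimate_settled_value(s.upper_series, calibration)
        usable.append(s)
        settled[s.id] = est.settled_ohms

    train, test = split_cohort(usable, split)

    h2r_cache: dict[H2RVariant, dict[str, float]] = {}

    def h2r_for(variant: H2RVariant) -> dict[str, float]:
        if variant not in h2r_cache:
            model = fit_h2r_model(
                train, settled, variant, seed=seed, hidden_nodes=net1_hidden_nodes
            )
            values = estimate_h2r(usable, settled, model)
            h2r_cache[variant] = {s.id: float(v) for s, v in zip(usable, values)}
        return h2r_cache[variant]

    reports = []
    for regime in regimes:
        try:
            variant = (
                H2RVariant.REGRESSION
                if regime in (PBFRegime.L_CONV, PBFRegime.L_PROP)
                else net1_variant
            )
            h2r = h2r_for(variant)
            model = fit_pbf_model(
                train, h2r, regime, seed=seed, hidden_nodes=net2_hidden_nodes
            )
            pred = estimate_pbf(test, h2r, model)
        except WristBiaError as exc:
            raise WristBiaError(f"regime {regime.value}: {exc}") from exc
        ref = np.array([s.true_pbf_pct for s in test])
        r = pearson_r(ref, pred)
        reports.append(
            EvaluationReport(
                regime=regime.value,
                n_train=len(train),
                n_test=len(test),
                pearson_r=r,
                r_squared=r * r,
                see=see(ref, pred),
            )
        )
    return reports
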