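"""Reference operating points and predictive-value consistency checks.

The operating points below are published patient-level results (sensitivity,
specificity, PPV, NPV as printed) for the retrospective and prospective
evaluation cohorts. Because PPV and NPV are both determined by sensitivity,
specificity and prevalence, each row can be checked for internal
consistency: back-solve the prevalence from the printed PPV, evaluate the
NPV equation at that prevalence, and compare with the printed NPV.
"""

from __future__ import annotations

from dataclasses import dataclass

from bpfuse.evaluation import ppv_npv, solve_prevalence

__all__ = [
    "OperatingPoint",
    "RETROSPECTIVE_POINTS",
    "PROSPECTIVE_POINTS",
    "npv_from_row",
    "ppv_at_prevalence",
    "consistency_checks",
]


@dataclass(frozen=True)
class OperatingPoint:
    model: str
    sensitivity: float
    specificity: float
    ppv_pct: float  # printed as a percentage
    npv_pct: float


RETROSPECTIVE_POINTS: tuple[OperatingPoint, ...] = (
    OperatingPoint("radiologists", 0.83, 0.71, 81.95, 72.48),
    OperatingPoint("3ch", 0.85, 0.62, 78.01, 72.27),
    OperatingPoint("3ch+clinical", 0.89, 0.62, 78.79, 78.04),
    OperatingPoint("me", 0.81, 0.74, 83.17, 71.06),
    OperatingPoint("me+clinical", 0.86, 0.69, 81.48, 75.65),
    OperatingPoint("meca", 0.86, 0.70, 81.97, 75.92),
    OperatingPoint("meca+clinical", 0.91, 0.72, 83.75, 83.46),
)

PROSPECTIVE_POINTS: tuple[OperatingPoint, ...] = (
    OperatingPoint("radiologists", 0.87, 0.65, 73.15, 82.02),
    OperatingPoint("3ch", 0.71, 0.53, 62.34, 62.51),
    OperatingPoint("3ch+clinical", 0.78, 0.67, 72.15, 73.54),
    OperatingPoint("me", 0.75, 0.71, 73.92, 72.15),
    OperatingPoint("me+clinical", 0.78, 0.77, 78.80, 76.15),
    OperatingPoint("meca", 0.80, 0.73, 76.46, 76.91),
    OperatingPoint("meca+clinical", 0.86, 0.75, 79.04, 83.02),
)

_COHORTS = {"retrospective": RETROSPECTIVE_POINTS, "prospective": PROSPECTIVE_POINTS}


def get_point(cohort: str, model: str) -> OperatingPoint:
    for pt in _COHORTS[cohort]:
        if pt.model == model:
            return pt
    raise KeyError(f"no operating point for {model!r} in {cohort!r}")


def npv_from_row(point: OperatingPoint) -> tuple[float, float]:
    """(implied prevalence, NPV %) obtained by inverting the PPV equation."""
    prev = solve_prevalence(point.sensitivity, point.specificity, point.ppv_pct / 100.0)
    _, npv = ppv_npv(point.sensitivity, point.specificity, prev)
    return prev, 100.0 * npv


def ppv_at_prevalence(point: OperatingPoint, prevalence: float) -> float:
    """PPV % of an operating point transported to a given prevalence."""
    ppv, _ = ppv_npv(point.sensitivity, point.specificity, prevalence)
    return 100.0 * ppv


def consistency_checks(tolerance_pct: float = 0.02) -> list[dict]:
    """Recompute each row's NPV from its own PPV-implied prevalence.

    ``tolerance_pct`` is the allowed absolute deviation in percentage
    points; printed values are rounded to two decimals, so deviations up to
    ~0.01-0.02 points are expected from the rounding of the inputs.
    """
    results = []
    for cohort, points in _COHORTS.items():
        for pt in points:
            prev, npv = npv_from_row(pt)
            results.append(
                {
                    "cohort": cohort,
                    "model": pt.model,
                    "implied_prevalence": prev,
                    "npv_recomputed_pct": npv,
                    "npv_printed_pct": pt.npv_pct,
                    "abs_error_pct": abs(npv - pt.npv_pct),
                    "pass": abs(npv - pt.npv_pct) <= tolerance_pct,
                }
            )
    return results
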