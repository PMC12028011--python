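"""Sub-cohort stratification and per-stratum model comparison.

Strata follow the printed boundary semantics exactly: e.g. the 3-class PSA
scheme is [0, 10), [10, 20], (20, inf); cumulative age schemes are allowed
to overlap and are flagged as non-partitioning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from bpfuse.data_model import BpMriCase
from bpfuse.evaluation import auc, bootstrap_ci, confusion_counts, delong_test

__all__ = [
    "StratificationScheme",
    "BUILTIN_SCHEMES",
    "assign_stratum",
    "per_stratum_report",
    "significance_tier",
]

SIGNIFICANCE_TIERS = (0.0001, 0.001, 0.01, 0.05)


def significance_tier(p: float) -> str:
    """Asterisk markers matching the point-and-range plot captions."""
    for stars, cut in zip(("****", "***", "**", "*"), SIGNIFICANCE_TIERS):
        if p <= cut:
            return stars
    return ""


@dataclass
class StratificationScheme:
    """A named set of strata over one case-level variable.

    ``bins`` maps stratum label -> membership predicate over the variable's
    value. ``partitioning`` is False for deliberately overlapping schemes
    (cumulative age groups) and for schemes that do not cover the range.
    """

    name: str
    variable: str  # PSA | AGE | PROVIDER | FIELD | MANUFACTURER
    bins: Mapping[str, Callable[[float | str], bool]]
    partitioning: bool = True
    min_stratum_n: int = 20

    def value_of(self, case: BpMriCase):
        c = case.clinical
        if self.variable == "PSA":
            return c.psa
        if self.variable == "AGE":
            return c.age
        if self.variable == "PROVIDER":
            return c.site or None
        if self.variable == "FIELD":
            return c.field_strength
        if self.variable == "MANUFACTURER":
            return c.manufacturer or None
        raise ValueError(f"unknown stratification variable {self.variable!r}")


def _interval(lo, hi, lo_closed=True, hi_closed=False):
    def pred(x):
        if x is None:
            return False
        above = True if lo is None else (x >= lo if lo_closed else x > lo)
        below = True if hi is None else (x <= hi if hi_closed else x < hi)
        return above and below

    return pred


def _categorical(label):
    return lambda x: x == label


def psa_three_class() -> StratificationScheme:
    return StratificationScheme(
        name="psa_3class",
        variable="PSA",
        bins={
            "[0-10)": _interval(0, 10),
            "[10-20]": _interval(10, 20, hi_closed=True),
            ">20": _interval(20, None, lo_closed=False),
        },
    )


def psa_four_class() -> StratificationScheme:
    return StratificationScheme(
        name="psa_4class",
        variable="PSA",
        bins={
            "<4": _interval(0, 4),
            "[4-10)": _interval(4, 10),
            "[10-20]": _interval(10, 20, hi_closed=True),
            ">20": _interval(20, None, lo_closed=False),
        },
    )


def age_surgery() -> StratificationScheme:
    return StratificationScheme(
        name="age_surgery",
        variable="AGE",
        bins={"<=75": _interval(None, 75, hi_closed=True), ">75": _interval(75, None, lo_closed=False)},
    )


def age_screening() -> StratificationScheme:
    return StratificationScheme(
        name="age_screening",
        variable="AGE",
        bins={
            "<55": _interval(None, 55),
            "[55-65]": _interval(55, 65, hi_closed=True),
            ">65": _interval(65, None, lo_closed=False),
        },
    )


def age_cumulative() -> StratificationScheme:
    return StratificationScheme(
        name="age_cumulative",
        variable="AGE",
        bins={
            ">45": _interval(45, None, lo_closed=False),
            ">55": _interval(55, None, lo_closed=False),
            ">65": _interval(65, None, lo_closed=False),
            ">75": _interval(75, None, lo_closed=False),
        },
        partitioning=False,  # overlapping by construction
    )


def age_distinct() -> StratificationScheme:
    return StratificationScheme(
        name="age_distinct",
        variable="AGE",
        bins={
            "[45-55)": _interval(45, 55),
            "[55-65]": _interval(55, 65, hi_closed=True),
            "(65-75]": _interval(65, 75, lo_closed=False, hi_closed=True),
        },
        partitioning=False,  # does not cover ages outside [45, 75]
    )


def categorical_scheme(name: str, variable: str, labels: Sequence) -> StratificationScheme:
    return StratificationScheme(
        name=name, variable=variable, bins={str(v): _categorical(v) for v in labels}
    )


def BUILTIN_SCHEMES(cases: Optional[Sequence[BpMriCase]] = None) -> list[StratificationScheme]:
    """The full analysis grid; categorical schemes enumerate observed labels."""
    schemes = [
        psa_three_class(),
        psa_four_class(),
        age_surgery(),
        age_screening(),
        age_cumulative(),
        age_distinct(),
    ]
    if cases:
        sites = sorted({c.clinical.site for c in cases if c.clinical.site})
        fields = sorted({c.clinical.field_strength for c in cases
                         if c.clinical.field_strength is not None})
        vendors = sorted({c.clinical.manufacturer for c in cases if c.clinical.manufacturer})
        if sites:
            schemes.append(categorical_scheme("provider", "PROVIDER", sites))
        if fields:
            schemes.append(categorical_scheme("field_strength", "FIELD", fields))
        if vendors:
            schemes.append(categorical_scheme("manufacturer", "MANUFACTURER", vendors))
    return schemes


def assign_stratum(case: BpMriCase, scheme: StratificationScheme) -> list[str]:
    """All stratum labels the case belongs to under ``scheme``.

    Empty list means the case is excluded (missing variable or value outside
    every bin). Overlapping schemes may return several labels.
    """
    value = scheme.value_of(case)
    if value is None:
        return []
    return [label for label, pred in scheme.bins.items() if pred(value)]


def per_stratum_report(
    scores_by_model: Mapping[str, np.ndarray],
    labels: np.ndarray,
    cases: Sequence[BpMriCase],
    schemes: Sequence[StratificationScheme],
    threshold: float = 0.5,
    n_boot: int = 500,
    seed: int = 0,
) -> dict:
    """AUC + bootstrap CI per stratum per model, with pairwise DeLong tests.

    Strata with fewer than ``scheme.min_stratum_n`` cases, or lacking one of
    the two classes, are suppressed (reported with a reason, no statistics).
    Returns a nested dict; use :func:`report_to_frame` for the CSV long table.
    """
    labels = np.asarray(labels).astype(int)
    model_names = list(scores_by_model)
    for name in model_names:
        if len(scores_by_model[name]) != len(cases):
            raise ValueError(f"scores for {name!r} are not paired with the case list")

    report: dict = {"schemes": {}, "n_total": len(cases)}
    for scheme in schemes:
        memberships = [assign_stratum(c, scheme) for c in cases]
        excluded = sum(1 for m in memberships if not m)
        strata: dict = {}
        for label in scheme.bins:
            idx = np.array([label in m for m in memberships])
            n = int(idx.sum())
            entry: dict = {"n": n}
            sub_labels = labels[idx]
            if n < scheme.min_stratum_n:
                entry["suppressed"] = f"fewer than {scheme.min_stratum_n} cases"
            elif n and (sub_labels.min() == sub_labels.max()):
                entry["suppressed"] = "single-class stratum"
            else:
                entry["n_pos"] = int(sub_labels.sum())
                entry["models"] = {}
                for mi, name in enumerate(model_names):
                    s = np.asarray(scores_by_model[name], dtype=float)[idx]
                    lo, hi = bootstrap_ci(s, sub_labels, n_boot=n_boot,
                                          seed=seed + 7919 * mi)
                    tp, fp, tn, fn = confusion_counts(s, sub_labels, threshold)
                    entry["models"][name] = {
                        "auc": auc(s, sub_labels),
                        "ci": [lo, hi],
                        "confusion": {"tp": tp, "fp": fp, "tn": tn, "fn": fn},
                    }
                entry["delong"] = {}
                for i in range(len(model_names)):
                    for j in range(i + 1, len(model_names)):
                        a, b = model_names[i], model_names[j]
                        _, _, p = delong_test(
                            np.asarray(scores_by_model[a])[idx],
                            np.asarray(scores_by_model[b])[idx],
                            sub_labels,
                        )
                        entry["delong"][f"{a} vs {b}"] = {
                            "p": p,
                            "tier": significance_tier(p),
                        }
            strata[label] = entry
        report["schemes"][scheme.name] = {
            "variable": scheme.variable,
            "partitioning": scheme.partitioning,
            "excluded": excluded,
            "strata": strata,
        }
    return report


def report_to_frame(report: dict) -> pd.DataFrame:
    """Flatten a fairness report to the ``scheme,stratum,model,n,auc,lo,hi`` table."""
    rows = []
    for scheme_name, scheme in report["schemes"].items():
        for stratum, entry in scheme["strata"].items():
            if "models" not in entry:
                rows.append({"scheme": scheme_name, "stratum": stratum, "model": "",
                             "n": entry["n"], "auc": np.nan, "lo": np.nan, "hi": np.nan,
                             "suppressed": entry.get("suppressed", "")})
                continue
            for model, stats_ in entry["models"].items():
                rows.append({
                    "scheme": scheme_name, "stratum": stratum, "model": model,
                    "n": entry["n"], "auc": stats_["auc"],
                    "lo": stats_["ci"][0], "hi": stats_["ci"][1], "suppressed": "",
                })
    return pd.DataFrame(rows)


def save_report(report: dict, json_path, csv_path=None) -> None:
    with open(json_path, "w") as fh:
        json.dump(report, fh, indent=2)
    if csv_path is not None:
        report_to_frame(report).to_csv(csv_path, index=False)


def plot_report(report: dict, scheme_name: str, out_path) -> None:
    """Optional point-and-range rendering (AUC with 95% CI per stratum/model)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scheme = report["schemes"][scheme_name]
    strata = [s for s, e in scheme["strata"].items() if "models" in e]
    if not strata:
        raise ValueError(f"no evaluable strata in scheme {scheme_name!r}")
    models = list(scheme["strata"][strata[0]]["models"])
    fig, ax = plt.subplots(figsize=(1.8 * len(strata) + 2, 4))
    width = 0.8 / max(len(models), 1)
    for mi, model in enumerate(models):
        xs, ys, lo_err, hi_err = [], [], [], []
        for si, stratum in enumerate(strata):
            entry = scheme["strata"][stratum]["models"].get(model)
            if entry is None:
                continue
            xs.append(si + (mi - (len(models) - 1) / 2) * width)
            ys.append(entry["auc"])
            lo_err.append(entry["auc"] - entry["ci"][0])
            hi_err.append(entry["ci"][1] - entry["auc"])
        ax.errorbar(xs, ys, yerr=[lo_err, hi_err], fmt="o", capsize=3, label=model)
    ax.set_xticks(range(len(strata)))
    ax.set_xticklabels(strata, rotation=20, ha="right")
    ax.set_ylabel("AUC")
    ax.set_title(scheme_name)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
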