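"""Cohort comparison statistics.

For each bundle the irregularity of the ROI-based and the streamline-based
segmentation of the same subject form a paired sample. The comparison is a
Shapiro-Wilk normality gate on the paired differences (warn, don't abort, at
p <= 0.05), a two-sided paired t-test, and Cohen's d on the paired
differences, d = mean(x - y) / sd(x - y), which satisfies t = d * sqrt(n)
exactly. Descriptive rows (mean, sd, min, quartiles, max, with linear
interpolation for percentiles) are reported per bundle and method. No
multiple-comparison correction is applied across bundles.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class PairedSample:
    bundle: str
    x: np.ndarray  # per-subject irregularity, ROI-based
    y: np.ndarray  # per-subject irregularity, streamline-based
    subject_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if self.x.size < 2:
            raise ValueError("paired sample needs n >= 2")
        if self.subject_ids is not None:
            self.subject_ids = np.asarray(self.subject_ids)
            if self.subject_ids.shape != self.x.shape:
                raise ValueError("subject_ids must align with x and y")


@dataclass
class TestResult:
    t_statistic: float
    p_value: float
    dof: int
    cohen_d: float
    shapiro_p: float
    n: int


def descriptive_stats(values) -> dict:
    """mean / std (n-1) / min / quartiles (linear interpolation) / max."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("descriptive statistics need at least one value")
    std = float(v.std(ddof=1)) if v.size > 1 else 0.0
    q25, q50, q75 = np.percentile(v, [25, 50, 75])
    return {
        "mean": float(v.mean()),
        "std": std,
        "min": float(v.min()),
        "q25": float(q25),
        "median": float(q50),
        "q75": float(q75),
        "max": float(v.max()),
    }


def normality_gate(values) -> float:
    """Shapiro-Wilk p-value; warns (does not abort) when p <= 0.05."""
    v = np.asarray(values, dtype=float)
    if not 3 <= v.size <= 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got n={v.size}")
    p = float(sps.shapiro(v).pvalue)
    if p <= 0.05:
        warnings.warn(
            f"Shapiro-Wilk p = {p:.4g} <= 0.05: paired differences depart from "
            "normality; the paired t-test is still reported",
            stacklevel=2,
        )
    return p


def paired_t_test(sample: PairedSample) -> TestResult:
    """Two-sided paired t-test with Cohen's d on the paired differences."""
    d = sample.x - sample.y
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        if np.allclose(d, 0):
            # x == y exactly: the null identity, t = 0, p = 1
            shapiro_p = float("nan")
            return TestResult(0.0, 1.0, n - 1, 0.0, shapiro_p, n)
        raise ValueError("degenerate paired sample: all differences identical")
    res = sps.ttest_rel(sample.x, sample.y)
    cohen_d = float(d.mean() / sd)
    shapiro_p = normality_gate(d) if 3 <= n <= 5000 else float("nan")
    return TestResult(
        t_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        dof=n - 1,
        cohen_d=cohen_d,
        shapiro_p=shapiro_p,
        n=n,
    )


# ---------------------------------------------------------------------------
# Cohort-level report
# ---------------------------------------------------------------------------

_METHODS = ("roi", "streamline")


@dataclass
class ComparisonReport:
    table1: pd.DataFrame  # descriptives: bundle x method rows
    table2: pd.DataFrame  # t, p, Cohen's d per bundle
    alpha: float = 0.05
    extra: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "alpha": self.alpha,
            "descriptives": self.table1.to_dict(orient="records"),
            "tests": self.table2.to_dict(orient="records"),
        }
        payload.update(self.extra)
        return json.dumps(payload, indent=2, sort_keys=True)

    def write(self, table1_path, table2_path, json_path) -> None:
        self.table1.to_csv(table1_path, index=False)
        self.table2.to_csv(table2_path, index=False)
        with open(json_path, "w") as fh:
            fh.write(self.to_json())


def plot_irregularity_violins(measures: pd.DataFrame, path) -> None:
    """Optional cosmetic figure: per-bundle irregularity distributions for the
    two methods, with per-subject lines connecting the paired values."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    bundles = list(dict.fromkeys(measures["bundle"]))
    fig, axes = plt.subplots(1, len(bundles), figsize=(3 * len(bundles), 4),
                             sharey=True)
    axes = np.atleast_1d(axes)
    for ax, bundle in zip(axes, bundles):
        sub = measures[measures["bundle"] == bundle]
        piv = sub.pivot_table(index="subject", columns="method",
                              values="irregularity")
        data = [piv["roi"].to_numpy(), piv["streamline"].to_numpy()]
        ax.violinplot(data, positions=[1, 2], showmedians=True)
        for _, row in piv.iterrows():
            ax.plot([1, 2], [row["roi"], row["streamline"]],
                    color="gray", alpha=0.4, lw=0.7)
        ax.set_xticks([1, 2], ["ROI", "streamline"])
        ax.set_title(bundle)
    axes[0].set_ylabel("irregularity")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def compare_cohort(measures: pd.DataFrame, value: str = "irregularity") -> ComparisonReport:
    """Cohort comparison from a per-(subject, bundle, method) measures table.

    ``measures`` needs columns subject, bundle, method and the value column.
    Raises if any (subject, bundle) cell lacks one of the two methods.
    """
    required = {"subject", "bundle", "method", value}
    missing = required - set(measures.columns)
    if missing:
        raise ValueError(f"measures table lacks columns {sorted(missing)}")
    bundles = list(dict.fromkeys(measures["bundle"]))
    rows1, rows2 = [], []
    for bundle in bundles:
        sub = measures[measures["bundle"] == bundle]
        pivot = sub.pivot_table(index="subject", columns="method", values=value,
                                aggfunc="first")
        for method in _METHODS:
            if method not in pivot.columns:
                raise ValueError(f"bundle {bundle!r}: no {method!r} measures at all")
        gaps = pivot[pivot[list(_METHODS)].isna().any(axis=1)]
        if len(gaps):
            raise ValueError(
                f"bundle {bundle!r}: subjects {sorted(gaps.index)} lack one method"
            )
        for method in _METHODS:
            rows1.append({"bundle": bundle, "method": method,
                          **descriptive_stats(pivot[method].to_numpy())})
        sample = PairedSample(bundle, pivot["roi"].to_numpy(),
                              pivot["streamline"].to_numpy(),
                              pivot.index.to_numpy())
        with warnings.catch_warnings():
            warnings.simplefilter("always")
            res = paired_t_test(sample)
        rows2.append({"bundle": bundle, **asdict(res)})
    return ComparisonReport(pd.DataFrame(rows1), pd.DataFrame(rows2))
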