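"""Two-level error propagation and group-comparison tests.

Quantified region means vary for two distinguishable reasons: different
areas (images) of the same sample, and different samples (mice).  The
reported error bar propagates both: a pooled within-mouse (area-to-area)
variance component and a between-mouse component from a method-of-moments
one-way random-effects estimator, combined as

    sd_total = sqrt(sd_within^2 + sd_between^2)

The experimental unit for hypothesis tests is the mouse: one-way ANOVA
and two-sided t-tests run on per-mouse means of per-image values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError


@dataclass
class GroupSummary:
    group: str
    region: str
    channel: str
    grand_mean: float
    sd_within: float         # area-to-area component (NaN if inestimable)
    sd_between: float        # mouse-to-mouse component (NaN if inestimable)
    sd_total: float
    n_images: int
    n_mice: int
    between_floored: bool = False


@dataclass
class TestResult:
    test: str                # "one_way_anova" | "t_test"
    statistic: float
    p_value: float
    df: tuple
    groups: tuple

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise DataError("p-value outside [0, 1]")


# ---------------------------------------------------------------------------
# variance components
# ---------------------------------------------------------------------------

def variance_components(values: Sequence[float],
                        mouse_ids: Sequence) -> dict:
    """Grand mean and within/between-mouse SD components.

    ``values`` are per-image summaries; ``mouse_ids`` assign each to its
    mouse.  The grand mean is the unweighted mean of mouse means.  The
    within component pools the variance of image values around their
    mouse mean; the between component subtracts the within contribution
    from the variance of mouse means (method of moments), floored at 0.
    """
    values = np.asarray(values, dtype=float)
    mouse_ids = np.asarray(mouse_ids)
    if values.size == 0:
        raise DataError("no values supplied")
    if values.shape != mouse_ids.shape:
        raise DataError("values and mouse_ids lengths differ")
    mice = pd.unique(mouse_ids)
    mouse_means = np.array([values[mouse_ids == m].mean() for m in mice])
    counts = np.array([(mouse_ids == m).sum() for m in mice])
    grand = float(mouse_means.mean())

    ss_within = 0.0
    df_within = 0
    for m, mm in zip(mice, mouse_means):
        v = values[mouse_ids == m]
        ss_within += float(((v - mm) ** 2).sum())
        df_within += v.size - 1
    var_within = ss_within / df_within if df_within > 0 else float("nan")

    floored = False
    if mice.size < 2:
        var_between = float("nan")
        if df_within == 0:
            warnings.warn("single mouse with a single image: no variance "
                          "component is estimable")
        else:
            warnings.warn("single mouse: between-mouse component is inestimable")
    else:
        var_mm = float(np.var(mouse_means, ddof=1))
        correction = (var_within * float(np.mean(1.0 / counts))
                      if df_within > 0 else 0.0)
        var_between = var_mm - correction
        if var_between < 0:
            var_between = 0.0
            floored = True
            warnings.warn("between-mouse variance estimate was negative; floored at 0")

    def _sd(v):
        return math.sqrt(v) if np.isfinite(v) else float("nan")

    total_var = np.nansum([v for v in (var_within, var_between) if np.isfinite(v)])
    return {
        "grand_mean": grand,
        "sd_within": _sd(var_within),
        "sd_between": _sd(var_between),
        "sd_total": math.sqrt(total_var) if np.isfinite(total_var) else float("nan"),
        "n_images": int(values.size),
        "n_mice": int(mice.size),
        "between_floored": floored,
        "mouse_means": {m: float(v) for m, v in zip(mice, mouse_means)},
    }


def propagate_group_errors(frame: pd.DataFrame,
                           value_col: str = "mean") -> list[GroupSummary]:
    """Per (group, region, channel) summaries from a tidy record table.

    Expects columns ``group``, ``mouse_id``, ``region``, ``channel`` and
    the value column (normalized region means).
    """
    required = {"group", "mouse_id", "region", "channel", value_col}
    missing = required - set(frame.columns)
    if missing:
        raise DataError(f"record table lacks columns {sorted(missing)}")
    out = []
    for (group, region, channel), sub in frame.groupby(
            ["group", "region", "channel"], sort=True):
        vc = variance_components(sub[value_col].to_numpy(),
                                 sub["mouse_id"].to_numpy())
        out.append(GroupSummary(group, region, channel, vc["grand_mean"],
                                vc["sd_within"], vc["sd_between"],
                                vc["sd_total"], vc["n_images"], vc["n_mice"],
                                vc["between_floored"]))
    return out


def summaries_to_frame(summaries: Sequence[GroupSummary]) -> pd.DataFrame:
    return pd.DataFrame([vars(s).copy() for s in summaries])


def mouse_means(frame: pd.DataFrame, value_col: str = "mean") -> pd.DataFrame:
    """Collapse per-image records to per-mouse means (the experimental unit)."""
    return (frame.groupby(["group", "region", "channel", "mouse_id"],
                          sort=True)[value_col]
            .mean().reset_index())


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

def one_way_anova(groups: Sequence[Sequence[float]],
                  group_names: Optional[Sequence[str]] = None) -> TestResult:
    """Classical one-way ANOVA on per-mouse means."""
    if len(groups) < 2:
        raise DataError("ANOVA needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, a in enumerate(arrays):
        if a.size < 2:
            raise DataError(f"ANOVA group {i} has fewer than 2 units")
    res = sps.f_oneway(*arrays)
    k = len(arrays)
    n = sum(a.size for a in arrays)
    names = tuple(group_names) if group_names is not None \
        else tuple(f"group{i}" for i in range(k))
    return TestResult("one_way_anova", float(res.statistic), float(res.pvalue),
                      (k - 1, n - k), names)


def t_test(a: Sequence[float], b: Sequence[float],
           variant: str = "welch",
           names: tuple = ("a", "b")) -> TestResult:
    """Two-sided two-sample t-test; Welch by default, ``variant="student"``
    for the classical equal-variance form."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DataError("t-test needs at least 2 observations per sample")
    if variant not in ("welch", "student"):
        raise DataError(f"unknown t-test variant {variant!r}")
    res = sps.ttest_ind(a, b, equal_var=(variant == "student"))
    return TestResult("t_test", float(res.statistic), float(res.pvalue),
                      (float(res.df),), tuple(names))


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjustment (optional; no correction is the default)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


# ---------------------------------------------------------------------------
# plotting
# ---------------------------------------------------------------------------

def plot_group_bars(summaries: Sequence[GroupSummary], path,
                    title: Optional[str] = None) -> None:
    """Bar graph of grand means with propagated-error bars, one bar per
    group x region."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = summaries_to_frame(summaries)
    labels = [f"{r.group}\n{r.region}" for r in frame.itertuples()]
    fig, ax = plt.subplots(figsize=(max(4, 0.9 * len(labels)), 4))
    err = np.nan_to_num(frame["sd_total"].to_numpy(), nan=0.0)
    ax.bar(np.arange(len(labels)), frame["grand_mean"], yerr=err,
           capsize=3, color="#888888", edgecolor="black")
    ax.set_xticks(np.arange(len(labels)))
    ax.set_xticklabels(labels, fontsize=8)
    ax.set_ylabel("normalized mean ion counts")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
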