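"""Accuracy and longitudinal test–retest precision statistics.

Two-visit repeated measurements with no expected true change (healthy
reference knees over one year) are summarised by the mean change (MC, with
a two-sided paired t test for longitudinal stability) and by precision
errors: the root-mean-square of the per-knee between-visit standard
deviations (RMS SD) and coefficients of variation (RMS CV%), the standard
error of measurement SEM = SD(differences)/√2 and the smallest detectable
change SDC = 1.96·√2·SEM. For two visits the per-knee SD with the n−1
denominator reduces to |v2 − v1|/√2, which makes RMS SD = SD(diff)/√2 when
the per-knee terms are not rounded.

Method-comparison helpers: Pearson correlation with systematic offset
(automated vs. manual) and Bland–Altman mean difference with 95% limits of
agreement (difference orientation: automated − manual / first − second).
All SDs use the n−1 denominator; tests are two-sided; no multiplicity
correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

_Z95 = 1.96


@dataclass
class PairedSeries:
    """Paired two-visit values of one measure for a set of knees."""

    ids: list[str]
    visit1: np.ndarray
    visit2: np.ndarray
    measure: str = "value"
    units: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        self.visit1 = np.asarray(self.visit1, dtype=float)
        self.visit2 = np.asarray(self.visit2, dtype=float)
        if not (len(self.ids) == len(self.visit1) == len(self.visit2)):
            raise ValueError("ids, visit1 and visit2 must have equal length")


@dataclass
class PrecisionSummary:
    """Longitudinal stability and test–retest precision of one measure."""

    measure: str
    units: str
    source: str
    n: int
    mean_change: float
    sd_change: float
    mc_pct: float
    p_value: float
    rms_sd: float
    rms_cv_pct: float
    sem: float
    sdc: float

    report_kind = "precision"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "measure": self.measure, "units": self.units, "source": self.source,
            "n": self.n, "mean_change": self.mean_change,
            "sd_change": self.sd_change, "mc_pct": self.mc_pct,
            "p_value": self.p_value, "rms_sd": self.rms_sd,
            "rms_cv_pct": self.rms_cv_pct, "sem": self.sem, "sdc": self.sdc,
        }])


def _paired_t(diff: np.ndarray) -> float:
    """Two-sided paired-t p value; degenerate zero-variance cases are
    resolved by the limit (identical visits -> t = 0, p = 1)."""
    if np.std(diff, ddof=1) == 0.0:
        return 1.0 if np.mean(diff) == 0.0 else 0.0
    return float(stats.ttest_1samp(diff, 0.0).pvalue)


def sem_sdc(series: PairedSeries) -> tuple[float, float]:
    """Standard error of measurement and smallest detectable change.

    SEM = SD(v2 − v1)/√2 (n−1 denominator); SDC = 1.96·√2·SEM, the change
    threshold exceeded by chance in only 5% of stable subjects.
    """
    if len(series.ids) < 2:
        raise ValueError("SEM/SDC require at least 2 pairs")
    sd_diff = float(np.std(series.visit2 - series.visit1, ddof=1))
    sem = sd_diff / np.sqrt(2.0)
    return sem, _Z95 * np.sqrt(2.0) * sem


def summarize_pairs(series: PairedSeries) -> PrecisionSummary:
    """Full test–retest summary of a paired two-visit series.

    Per-knee SD uses the n−1 denominator (|d|/√2 for two visits) and the
    per-knee CV is 100·SD/mean of the two visits; RMS aggregation is the
    square root of the mean of squares. MC% is normalised by the mean of
    the visit-1 values. A knee with non-positive visit mean has an
    undefined CV and raises, naming the knee.
    """
    v1, v2 = series.visit1, series.visit2
    if len(series.ids) < 1:
        raise ValueError("need at least one pair")
    diff = v2 - v1
    pair_mean = (v1 + v2) / 2.0
    bad = np.where(pair_mean <= 0)[0]
    if bad.size:
        raise ValueError(f"CV undefined for non-positive pair mean: "
                         f"id {series.ids[bad[0]]!r}")
    per_knee_sd = np.abs(diff) / np.sqrt(2.0)
    per_knee_cv = 100.0 * per_knee_sd / pair_mean
    mc = float(np.mean(diff))
    sd_change = float(np.std(diff, ddof=1)) if len(diff) > 1 else 0.0
    sem = sd_change / np.sqrt(2.0)
    return PrecisionSummary(
        measure=series.measure, units=series.units, source=series.source,
        n=len(diff),
        mean_change=mc, sd_change=sd_change,
        mc_pct=float(100.0 * mc / np.mean(v1)),
        p_value=_paired_t(diff) if len(diff) > 1 else float("nan"),
        rms_sd=float(np.sqrt(np.mean(per_knee_sd ** 2))),
        rms_cv_pct=float(np.sqrt(np.mean(per_knee_cv ** 2))),
        sem=sem, sdc=_Z95 * np.sqrt(2.0) * sem,
    )


def bland_altman(a, b) -> tuple[float, float, float]:
    """Mean difference (a − b) and 95% limits of agreement (mean ± 1.96 SD)."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if len(a) < 2:
        raise ValueError("Bland–Altman needs at least 2 pairs")
    diff = a - b
    md = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    return md, md - _Z95 * sd, md + _Z95 * sd


def bland_altman_plot(a, b, path, label_a: str = "method A",
                      label_b: str = "method B", units: str = "") -> None:
    """Save a Bland–Altman plot (optional artifact; needs matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a, b = np.asarray(a, float), np.asarray(b, float)
    md, lo, hi = bland_altman(a, b)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((a + b) / 2.0, a - b, s=18, color="k")
    for y, style in ((md, "-"), (lo, ":"), (hi, ":")):
        ax.axhline(y, color="r", linestyle=style)
    ax.set_xlabel(f"mean of {label_a} and {label_b} {units}".strip())
    ax.set_ylabel(f"{label_a} − {label_b} {units}".strip())
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def accuracy_compare(auto, manual) -> tuple[float, float, float]:
    """Pearson r, systematic offset (%) and paired-t p, automated vs manual.

    Offset % = 100 x (mean(auto) − mean(manual)) / mean(manual). With zero
    variance in either list, r is undefined and returned as NaN.
    """
    auto, manual = np.asarray(auto, float), np.asarray(manual, float)
    if auto.shape != manual.shape:
        raise ValueError("paired lists must have equal length")
    diff = auto - manual
    offset = float(100.0 * (auto.mean() - manual.mean()) / manual.mean())
    p = _paired_t(diff) if len(diff) > 1 else float("nan")
    if len(auto) < 3 or np.std(auto) == 0 or np.std(manual) == 0:
        r = float("nan")
    else:
        r = float(stats.pearsonr(auto, manual).statistic)
    return r, offset, p
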