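"""Method-agreement statistics: Spearman correlation and Bland–Altman analysis.

Used to compare stricture lengths measured by two methods (e.g. the
automated pipeline against ground truth, or imaging against intraoperative
measurement): Spearman's rank correlation quantifies monotone association,
and Bland–Altman analysis quantifies bias and the 95 % limits of agreement
between paired measurements.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["AgreementReport", "spearman", "bland_altman", "agreement_report"]


@dataclass
class AgreementReport:
    """Agreement summary for paired measurements (mm)."""

    n: int
    spearman_rho: float
    bias_mm: float
    sd_mm: float
    loa_lower_mm: float
    loa_upper_mm: float
    loa_multiplier: float = 1.96

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "spearman_rho": self.spearman_rho,
            "bias_mm": self.bias_mm,
            "sd_mm": self.sd_mm,
            "loa_lower_mm": self.loa_lower_mm,
            "loa_upper_mm": self.loa_upper_mm,
            "loa_multiplier": self.loa_multiplier,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AgreementReport":
        return cls(**d)


def spearman(x, y) -> float:
    """Spearman's rank correlation: Pearson correlation of average ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs for a rank correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation is undefined for a constant vector")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def bland_altman(a, b, multiplier: float = 1.96) -> AgreementReport:
    """Bland–Altman bias and limits of agreement of paired measurements.

    Differences are ``a - b``; the SD uses the sample (n-1) denominator and
    the limits are ``bias ± multiplier × SD`` (1.96 for normal-approximation
    95 % limits).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length 1D vectors")
    if len(a) < 2:
        raise ValueError("need at least 2 pairs for limits of agreement")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    try:
        rho = spearman(a, b)
    except ValueError:
        rho = float("nan")
    return AgreementReport(
        n=len(a),
        spearman_rho=rho,
        bias_mm=bias,
        sd_mm=sd,
        loa_lower_mm=bias - multiplier * sd,
        loa_upper_mm=bias + multiplier * sd,
        loa_multiplier=multiplier,
    )


def agreement_report(
    pairs: pd.DataFrame | str | Path,
    out_json: str | Path | None = None,
    out_plot: str | Path | None = None,
    multiplier: float = 1.96,
) -> AgreementReport:
    """Full agreement analysis of a paired-measurement table.

    ``pairs`` is a DataFrame or CSV path with columns ``length_a_mm`` and
    ``length_b_mm`` (extra columns such as ``id`` are ignored).  Rows with
    missing or unparseable values are dropped, with the dropped count
    reported on stderr.  Optionally writes a JSON report and a Bland–Altman
    scatter (per-pair mean vs difference, with bias and limit lines).
    """
    if not isinstance(pairs, pd.DataFrame):
        pairs = pd.read_csv(pairs)
    for col in ("length_a_mm", "length_b_mm"):
        if col not in pairs.columns:
            raise ValueError(f"pairs table lacks required column {col!r}")
    numeric = pairs[["length_a_mm", "length_b_mm"]].apply(pd.to_numeric, errors="coerce")
    complete = numeric.dropna()
    dropped = len(numeric) - len(complete)
    if dropped:
        import sys

        print(f"agreement_report: dropped {dropped} incomplete pair(s)", file=sys.stderr)
    if len(complete) < 2:
        raise ValueError("insufficient data: need at least 2 complete pairs")
    report = bland_altman(
        complete["length_a_mm"].to_numpy(),
        complete["length_b_mm"].to_numpy(),
        multiplier=multiplier,
    )
    if out_json is not None:
        Path(out_json).write_text(json.dumps(report.to_dict(), indent=2))
    if out_plot is not None:
        _plot_bland_altman(complete, report, out_plot)
    return report


def _plot_bland_altman(complete: pd.DataFrame, report: AgreementReport, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a = complete["length_a_mm"].to_numpy()
    b = complete["length_b_mm"].to_numpy()
    mean = (a + b) / 2
    diff = a - b
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(mean, diff, s=18, alpha=0.8)
    ax.axhline(report.bias_mm, color="k", lw=1, label=f"bias {report.bias_mm:.2f} mm")
    for lim in (report.loa_lower_mm, report.loa_upper_mm):
        ax.axhline(lim, color="r", lw=1, ls="--")
    ax.set_xlabel("mean of methods (mm)")
    ax.set_ylabel("difference A − B (mm)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
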