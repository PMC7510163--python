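"""Cohort-level QC: the n-alpha regression and VSN-based expectations.

Given peak-call summaries for a cohort (peak count n, FRiP, fragment
length, region width w), each sample's signal fraction alpha is
recovered from FRiP, and log10(n) is regressed on log10(alpha) by
ordinary least squares.  For a new sample, its VSN supplies a second
equation alpha^2 / n = VSN; intersecting it with the regression line
yields the expected signal fraction and expected number of callable
peaks before any peak calling is run.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .theory import alpha_from_frip

__all__ = [
    "PeakCallSummary",
    "read_peak_summaries",
    "write_peak_summaries",
    "NAlphaRegression",
    "NAlphaRegressionResult",
    "fit_n_alpha_regression",
    "expected_from_vsn",
]


@dataclass(frozen=True)
class PeakCallSummary:
    """One sample's peak-calling output, as consumed by the regression."""

    sample: str
    n_peaks: int
    frip: float
    fragment_length: float
    w: float
    genome_length: float

    def __post_init__(self) -> None:
        if self.n_peaks < 0:
            raise ValueError("n_peaks must be >= 0")
        if not 0.0 <= self.frip <= 1.0:
            raise ValueError("FRiP must lie in [0, 1]")

    @property
    def d(self) -> float:
        """Region distance implied by fragment length = d + w."""
        return self.fragment_length - self.w

    def alpha_hat(self) -> float:
        """Signal fraction recovered from FRiP via the model relation."""
        return alpha_from_frip(
            self.frip, self.n_peaks, self.w, self.d, self.genome_length
        )


_COLUMNS = ["sample", "n_peaks", "frip", "fragment_length", "w", "genome_length"]


def read_peak_summaries(path: str) -> list[PeakCallSummary]:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in _COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"peak summary TSV lacks columns: {missing}")
    return [
        PeakCallSummary(
            sample=str(row.sample),
            n_peaks=int(row.n_peaks),
            frip=float(row.frip),
            fragment_length=float(row.fragment_length),
            w=float(row.w),
            genome_length=float(row.genome_length),
        )
        for row in table.itertuples(index=False)
    ]


def write_peak_summaries(summaries, path: str) -> None:
    pd.DataFrame([s.__dict__ for s in summaries])[_COLUMNS].to_csv(
        path, sep="\t", index=False
    )


@dataclass(frozen=True)
class NAlphaRegressionResult:
    """log10(n) = intercept + slope * log10(alpha), fitted by OLS."""

    intercept: float
    slope: float
    n_samples: int

    def predict_n(self, alpha: float) -> float:
        return 10.0 ** (self.intercept + self.slope * np.log10(alpha))

    def expected_from_vsn(self, vsn: float):
        return expected_from_vsn(vsn, self)

    def summary(self) -> str:
        return (
            "n-alpha regression (log10-log10 OLS)\n"
            f"  samples:   {self.n_samples}\n"
            f"  intercept: {self.intercept:.6g}\n"
            f"  slope:     {self.slope:.6g}\n"
            f"  model:     log10(n) = {self.intercept:.4g} "
            f"+ {self.slope:.4g} * log10(alpha)"
        )

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "intercept": self.intercept,
                    "slope": self.slope,
                    "n_samples": self.n_samples,
                },
                fh,
                indent=1,
            )
            fh.write("\n")


class NAlphaRegression:
    """OLS model of log10(peak count) on log10(signal fraction).

    Samples with a non-positive recovered alpha or zero peaks are
    excluded (with a warning); at least two usable samples are
    required.
    """

    def __init__(self, summaries: list[PeakCallSummary]):
        self.summaries = list(summaries)

    def fit(self) -> NAlphaRegressionResult:
        alphas, ns = [], []
        skipped = []
        for s in self.summaries:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                a = s.alpha_hat()
            if a <= 0 or s.n_peaks <= 0:
                skipped.append(s.sample)
                continue
            alphas.append(a)
            ns.append(s.n_peaks)
        if skipped:
            warnings.warn(
                f"excluded {len(skipped)} sample(s) with alpha<=0 or no peaks: "
                + ", ".join(skipped),
                stacklevel=2,
            )
        if len(alphas) < 2:
            raise ValueError("need >= 2 usable samples to fit the regression")
        x = np.log10(alphas)
        y = np.log10(ns)
        slope, intercept = np.polyfit(x, y, 1)
        return NAlphaRegressionResult(
            intercept=float(intercept), slope=float(slope), n_samples=len(alphas)
        )


def fit_n_alpha_regression(summaries) -> NAlphaRegressionResult:
    """Functional wrapper around :class:`NAlphaRegression`."""
    return NAlphaRegression(summaries).fit()


def expected_from_vsn(
    vsn: float, model: NAlphaRegressionResult
) -> tuple[float, float, bool]:
    """Expected (alpha, n) for a sample from its VSN and a fitted cohort.

    Solves alpha^2 / 10^(a + b log10 alpha) = VSN, i.e.
    alpha = (VSN * 10^a)^(1 / (2 - b)), n = 10^(a + b log10 alpha).
    Returns (alpha, n, valid) where valid flags alpha in (0, 1].
    """
    if vsn <= 0:
        raise ValueError("VSN must be > 0")
    a, b = model.intercept, model.slope
    if b == 2:
        raise ValueError("slope = 2 makes the system degenerate")
    alpha = (vsn * 10.0**a) ** (1.0 / (2.0 - b))
    n = 10.0 ** (a + b * np.log10(alpha))
    valid = 0.0 < alpha <= 1.0
    if not valid:
        warnings.warn(
            f"expected alpha {alpha:.4g} outside (0, 1]; extrapolation beyond "
            "the fitted cohort",
            stacklevel=2,
        )
    return float(alpha), float(n), bool(valid)
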