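"""QC quantities derived from a cross-correlation profile.

Fragment length (profile argmax outside the read-length "phantom"
window), enriched-region width via the FWHM of the fragment peak, the
virtual signal-to-noise VSN = (2w / M) * max(MSCC), and the legacy
NSC / RSC ratios.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .crosscorr import CCProfile

__all__ = [
    "QCMetrics",
    "estimate_fragment_length",
    "estimate_w_fwhm",
    "adjust_w",
    "fit_w_slope",
    "vsn",
    "nsc_rsc",
    "compute_qc_metrics",
]


@dataclass(frozen=True)
class QCMetrics:
    fragment_length: int
    cc_max: float
    cc_min: float
    cc_at_read_length: float
    w_fwhm: float
    w_adjusted: float
    vsn: float
    nsc: float
    rsc: float

    def as_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str) -> None:
        record = {
            k: (None if isinstance(v, float) and not np.isfinite(v) else v)
            for k, v in self.as_dict().items()
        }
        with open(path, "w") as fh:
            json.dump(record, fh, indent=1, sort_keys=True)
            fh.write("\n")


def _merged(profile: CCProfile) -> tuple[np.ndarray, np.ndarray]:
    merged = profile.merged_or_single()
    if np.count_nonzero(np.isfinite(merged)) < 10:
        raise ValueError("profile defined on fewer than 10 shifts")
    return profile.shifts, merged


def estimate_fragment_length(
    profile: CCProfile,
    read_length: int | None = None,
    exclusion_halfwidth: int = 10,
) -> int:
    """Argmax shift of the merged profile, skipping the phantom window.

    The spurious peak at shift ~R (the "phantom" peak) is excluded by
    masking [R - h, R + h]; MSCC profiles suppress the phantom anyway,
    so exclusion there is harmless.  Ties break toward the smallest
    shift.
    """
    shifts, merged = _merged(profile)
    if read_length is None:
        read_length = profile.read_length
    usable = np.isfinite(merged)
    if exclusion_halfwidth >= 0 and read_length is not None:
        usable &= ~(
            (shifts >= read_length - exclusion_halfwidth)
            & (shifts <= read_length + exclusion_halfwidth)
        )
    if not usable.any():
        raise ValueError("all shifts excluded or undefined")
    masked = np.where(usable, merged, -np.inf)
    return int(shifts[int(np.argmax(masked))])


def estimate_w_fwhm(profile: CCProfile, peak_shift: int) -> float:
    """FWHM of the fragment-length peak, in bp.

    Under the model the peak is triangular with base 2w, so its FWHM
    estimates the enriched-region width w.  The half-maximum level is
    baseline + (peak - baseline) / 2 with baseline the profile minimum
    over the computed range; crossings are located by linear
    interpolation between adjacent evaluated shifts.
    """
    shifts, merged = _merged(profile)
    k = int(np.searchsorted(shifts, peak_shift))
    if k >= shifts.size or shifts[k] != peak_shift:
        raise ValueError(f"peak shift {peak_shift} not in profile")
    peak = merged[k]
    baseline = np.nanmin(merged)
    if not np.isfinite(peak) or peak <= baseline:
        raise ValueError("peak is not above the profile baseline")
    half = baseline + (peak - baseline) / 2.0

    def _crossing(direction: int) -> float:
        j = k
        while True:
            j_next = j + direction
            if j_next < 0 or j_next >= shifts.size:
                raise ValueError(
                    "profile does not descend to half maximum within the "
                    "shift range; widen the range"
                )
            if np.isfinite(merged[j_next]) and merged[j_next] <= half:
                # interpolate between shifts[j] and shifts[j_next]
                x0, x1 = shifts[j], shifts[j_next]
                y0, y1 = merged[j], merged[j_next]
                return float(x0 + (half - y0) * (x1 - x0) / (y1 - y0))
            j = j_next

    left = _crossing(-1)
    right = _crossing(+1)
    return right - left


def adjust_w(w_fwhm: float, slope: float = 1.0) -> float:
    """Rescale an FWHM-based width by a calibration slope.

    The slope comes from regressing profile FWHM on an independent
    width estimate over a cohort (no intercept); the default 1.0 means
    no adjustment.
    """
    if slope <= 0:
        raise ValueError("slope must be > 0")
    return w_fwhm / slope


def fit_w_slope(fwhm_values, w_values) -> float:
    """Least-squares slope through the origin of FWHM on width."""
    x = np.asarray(w_values, dtype=float)
    y = np.asarray(fwhm_values, dtype=float)
    if x.size != y.size or x.size < 1:
        raise ValueError("need matching, non-empty value arrays")
    denom = float(np.dot(x, x))
    if denom == 0:
        raise ValueError("degenerate widths (all zero)")
    return float(np.dot(x, y)) / denom


def vsn(
    profile: CCProfile,
    n_reads: int,
    w: float,
    fragment_length: int | None = None,
    exclusion_halfwidth: int = 10,
) -> float:
    """Virtual signal-to-noise: (2w / M) * max(MSCC).

    M is the total number of mapped reads and w the enriched-region
    width (typically the adjusted FWHM of this same profile).  The
    maximum is the coefficient at the estimated fragment length.
    Under the model VSN approximates alpha^2 / n.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be > 0")
    if w <= 0:
        raise ValueError("w must be > 0")
    if fragment_length is None:
        fragment_length = estimate_fragment_length(
            profile, exclusion_halfwidth=exclusion_halfwidth
        )
    cc = profile.at(fragment_length)
    if not np.isfinite(cc):
        raise ValueError("profile maximum undefined")
    return 2.0 * w / n_reads * cc


def nsc_rsc(
    profile: CCProfile,
    fragment_shift: int,
    read_length: int | None = None,
    min_mode: str = "range_min",
) -> tuple[float, float]:
    """Legacy (NSC, RSC) ratios from a profile.

    NSC = cc(fragment) / cc_min; RSC = (cc(fragment) - cc_min) /
    (cc(R) - cc_min).  ``min_mode`` picks the baseline: "range_min"
    (profile minimum over the computed range, default) or "last_shift".
    Undefined ratios (non-positive baseline for NSC, flat profile for
    RSC) come back as nan with a warning.
    """
    shifts, merged = _merged(profile)
    if read_length is None:
        read_length = profile.read_length
    cc_frag = profile.at(fragment_shift)
    cc_read = profile.at(read_length)
    if min_mode == "range_min":
        cc_min = float(np.nanmin(merged))
    elif min_mode == "last_shift":
        finite = np.flatnonzero(np.isfinite(merged))
        cc_min = float(merged[finite[-1]])
    else:
        raise ValueError(f"unknown min_mode {min_mode!r}")
    if cc_min <= 0:
        warnings.warn("profile minimum <= 0; NSC undefined", stacklevel=2)
        nsc = np.nan
    else:
        nsc = cc_frag / cc_min
    if cc_read == cc_min:
        warnings.warn("cc(R) equals the baseline; RSC undefined", stacklevel=2)
        rsc = np.nan
    else:
        rsc = (cc_frag - cc_min) / (cc_read - cc_min)
    return float(nsc), float(rsc)


def compute_qc_metrics(
    profile: CCProfile,
    read_length: int,
    n_reads: int,
    exclusion_halfwidth: int = 10,
    w_slope: float = 1.0,
) -> QCMetrics:
    """Assemble the full QC record from one profile."""
    shifts, merged = _merged(profile)
    frag = estimate_fragment_length(
        profile, read_length=read_length, exclusion_halfwidth=exclusion_halfwidth
    )
    cc_max = profile.at(frag)
    cc_min = float(np.nanmin(merged))
    try:
        cc_at_r = profile.at(read_length)
    except KeyError:
        cc_at_r = np.nan
    w_fwhm = estimate_w_fwhm(profile, frag)
    w_adj = adjust_w(w_fwhm, w_slope)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if np.isfinite(cc_at_r):
            nsc, rsc = nsc_rsc(profile, frag, read_length)
        else:
            nsc = rsc = np.nan
    return QCMetrics(
        fragment_length=frag,
        cc_max=float(cc_max),
        cc_min=cc_min,
        cc_at_read_length=float(cc_at_r),
        w_fwhm=w_fwhm,
        w_adjusted=w_adj,
        vsn=vsn(profile, n_reads, w_adj, fragment_length=frag),
        nsc=float(nsc),
        rsc=float(rsc),
    )
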