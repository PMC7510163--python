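"""Closed-form expectations of the read-density model.

The model: a genome of length G carries n binding events.  Each event
has a forward-read enriched region of width w and, d bp downstream of
it, a reverse-read enriched region of the same width, so the matching
forward and reverse 5' ends sit exactly d + w apart.  Of M mapped
reads (M/2 per strand), a fraction alpha are signal reads placed
uniformly inside the enriched regions; the rest are noise placed
uniformly over the genome.  Densities are binarised per position.

From the per-position Bernoulli probabilities one obtains the expected
shifted AND count <|D_x|> and hence the expected cross-correlation at
any shift; the shifts with complete overlap (x = d + w) and no overlap
(x0) give the theoretical maximum and minimum coefficients.

The "degree of saturation" M*alpha / (2 n w) separates two regimes: at
values above one the expected signal reads exceed the available
enriched positions and the binarised enriched regions fill up
("saturated"); the closed forms below switch accordingly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ModelParams",
    "TheoreticalBounds",
    "degree_of_saturation",
    "regime",
    "unsaturated_probabilities",
    "expected_dx",
    "expected_ncc_from_dx",
    "expected_profile",
    "theoretical_max",
    "theoretical_min",
    "theoretical_bounds",
    "frip_from_alpha",
    "alpha_from_frip",
]

LEVELS = ("exact", "approx1", "approx2")


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the generative read-density model.

    G: genome length (bp); n: number of binding events; w: enriched
    region width (bp); d: distance between paired enriched regions
    (bp); alpha: signal fraction in [0, 1]; M: total mapped reads;
    M_u: deduplicated mapped reads (defaults to M); R: read length.
    """

    G: int
    n: int
    w: int
    d: int
    alpha: float
    M: int
    M_u: int | None = None
    R: int = 50

    def __post_init__(self) -> None:
        if self.G < 1 or self.w < 1 or self.d < 1 or self.R < 1:
            raise ValueError("lengths G, w, d, R must be >= 1")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if self.n == 0 and self.alpha > 0:
            raise ValueError("n = 0 requires alpha = 0 (signal reads need regions)")
        if self.M < 0:
            raise ValueError("M must be >= 0")
        if self.n * (2 * self.w + self.d) > self.G:
            raise ValueError("enriched regions do not fit in the genome")
        if self.M_u is None:
            object.__setattr__(self, "M_u", self.M)
        elif self.M_u > self.M:
            raise ValueError("M_u cannot exceed M")

    @property
    def fragment_length(self) -> int:
        """The shift maximising the cross-correlation: d + w."""
        return self.d + self.w


def _check_preconditions(p: ModelParams) -> None:
    if p.M >= 2 * p.G:
        raise ValueError("model precondition violated: M must be < 2G")


def degree_of_saturation(params: ModelParams) -> float:
    """M*alpha / (2 n w); > 1 means the enriched regions saturate."""
    if params.alpha == 0.0:
        return 0.0
    if params.n * params.w == 0:
        raise ValueError("signal reads (alpha > 0) require n*w > 0")
    return params.M * params.alpha / (2.0 * params.n * params.w)


def regime(params: ModelParams) -> str:
    """"saturated" iff the degree of saturation exceeds one."""
    return "saturated" if degree_of_saturation(params) > 1.0 else "unsaturated"


def unsaturated_probabilities(params: ModelParams) -> tuple[float, float, float]:
    """(mu, p_S, p_N): per-position Bernoulli rates, unsaturated regime.

    mu = M/2G; p_N = mu(1 - alpha); p_S composes the signal placement
    rate M*alpha/2nw with the noise rate.
    """
    _check_preconditions(params)
    mu = params.M / (2.0 * params.G)
    p_n = mu * (1.0 - params.alpha)
    if params.alpha == 0.0:
        return mu, p_n, p_n
    s = params.M * params.alpha / (2.0 * params.n * params.w)
    p_s = p_n + s * (1.0 - p_n)
    return mu, p_s, p_n


def expected_dx(
    params: ModelParams,
    x: int,
    sizes: tuple[int, int, int, int],
) -> float:
    """Expected shifted AND count <|D_x|> from region-overlap set sizes.

    ``sizes`` = (|X_SS|, |X_SN|, |X_NS|, |X_NN|): counts of window
    positions i by whether i is enriched on the forward strand and
    i + x enriched on the reverse strand.  They must sum to G - x.
    """
    x_ss, x_sn, x_ns, x_nn = (int(v) for v in sizes)
    if min(x_ss, x_sn, x_ns, x_nn) < 0:
        raise ValueError("set sizes must be non-negative")
    if x_ss + x_sn + x_ns + x_nn != params.G - x:
        raise ValueError("set sizes must sum to G - x")
    _, p_s, p_n = unsaturated_probabilities(params)
    return x_ss * p_s**2 + (x_sn + x_ns) * p_s * p_n + x_nn * p_n**2


def expected_ncc_from_dx(params: ModelParams, x: int, dx: float) -> float:
    """Expected coefficient from an expected AND count at shift x."""
    _check_preconditions(params)
    mu = params.M / (2.0 * params.G)
    sigma = mu * (1.0 - mu)
    return (dx / (params.G - x) - mu**2) / sigma


def overlap_sizes(params: ModelParams, x: int) -> tuple[int, int, int, int]:
    """Region-overlap set sizes at an arbitrary shift x.

    Assumes non-interacting sites: each forward region overlaps only
    its own paired reverse region, giving per-pair overlap
    max(0, w - |x - (d + w)|).  At x = x0 (no overlap) and x = d + w
    (full overlap) this reduces to the minimum- and maximum-shift
    configurations.
    """
    n, w = params.n, params.w
    per_pair = max(0, w - abs(x - params.fragment_length))
    x_ss = n * per_pair
    x_sn = n * w - x_ss
    x_ns = n * w - x_ss
    x_nn = params.G - x - x_sn - x_ns - x_ss
    if x_nn < 0:
        raise ValueError("shift too large for the region layout")
    return x_ss, x_sn, x_ns, x_nn


def expected_profile(params: ModelParams, shifts) -> np.ndarray:
    """Expected NCC coefficient at each shift (unsaturated regime)."""
    out = np.empty(len(shifts), dtype=float)
    for k, x in enumerate(shifts):
        dx = expected_dx(params, int(x), overlap_sizes(params, int(x)))
        out[k] = expected_ncc_from_dx(params, int(x), dx)
    return out


def _saturated_max(params: ModelParams) -> float:
    nw = params.n * params.w
    return nw / (params.M_u / 2.0 * (1.0 - params.alpha) + nw)


def theoretical_max(
    params: ModelParams,
    level: str = "exact",
    force_regime: str | None = None,
) -> float:
    """Theoretical maximum coefficient, attained at shift d + w.

    Unsaturated levels: "exact" is the full closed form; "approx1"
    drops the d + w terms (requires d + w << G); "approx2" is
    M*alpha^2 / 2nw (additionally requires M << G).  The saturated
    regime uses nw / (M_u/2 (1 - alpha) + nw) at every level (the only
    closed form carried here).
    """
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}")
    _check_preconditions(params)
    if params.alpha == 0.0:
        return 0.0
    reg = force_regime or regime(params)
    if reg == "saturated":
        return _saturated_max(params)
    G, M, a = params.G, params.M, params.alpha
    nw = params.n * params.w
    if level == "approx2":
        return M * a**2 / (2.0 * nw)
    x = params.fragment_length if level == "exact" else 0
    term1 = (
        M * a**2 * (2.0 * G - (1.0 - a) * M) ** 2
        / (4.0 * nw * (2.0 * G - M) * (G - x))
    )
    term2 = (
        M * a * (M * (1.0 - a) ** 2 + (G + x) * a - 2.0 * x)
        / ((2.0 * G - M) * (G - x))
    )
    return term1 - term2


def theoretical_min(
    params: ModelParams,
    x0: int | None = None,
    level: str = "exact",
    force_regime: str | None = None,
) -> float:
    """Theoretical minimum coefficient, attained at non-overlap shifts x0.

    "exact" is the closed form at the given x0 (default x0 = d, the
    largest shift with zero region overlap); "approx1" drops x0
    (x0 << G); "approx2" is 0 (additionally M << G).  The saturated
    regime returns 0.
    """
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}")
    _check_preconditions(params)
    if params.alpha == 0.0:
        return 0.0
    reg = force_regime or regime(params)
    if reg == "saturated":
        return 0.0
    if level == "approx2":
        return 0.0
    if x0 is None:
        x0 = params.d
    if not 0 <= x0 < params.G:
        raise ValueError("x0 must lie in [0, G)")
    G, M, a = params.G, params.M, params.alpha
    x = x0 if level == "exact" else 0
    return -(
        M * a * (M * (1.0 - a) ** 2 + (G + x) * a - 2.0 * x)
        / ((2.0 * G - M) * (G - x))
    )


@dataclass(frozen=True)
class TheoreticalBounds:
    """Min/max coefficients at all approximation levels, plus regime."""

    regime: str
    degree_of_saturation: float
    maximum: dict
    minimum: dict

    def as_dict(self) -> dict:
        return {
            "regime": self.regime,
            "degree_of_saturation": self.degree_of_saturation,
            "maximum": dict(self.maximum),
            "minimum": dict(self.minimum),
        }


def theoretical_bounds(params: ModelParams, x0: int | None = None) -> TheoreticalBounds:
    """Bundle regime, saturation degree and min/max at every level."""
    return TheoreticalBounds(
        regime=regime(params),
        degree_of_saturation=degree_of_saturation(params),
        maximum={lv: theoretical_max(params, lv) for lv in LEVELS},
        minimum={lv: theoretical_min(params, x0, lv) for lv in LEVELS},
    )


def frip_from_alpha(params: ModelParams) -> float:
    """FRiP implied by the model: alpha + n(2w + d)/G * (1 - alpha)."""
    peak_frac = params.n * (2 * params.w + params.d) / params.G
    if peak_frac >= 1.0:
        raise ValueError("peak territory n(2w + d) must be < G")
    return params.alpha + peak_frac * (1.0 - params.alpha)


def alpha_from_frip(
    frip: float, n: float, w: float, d: float, G: float
) -> float:
    """Invert the FRiP relation to an estimated signal fraction.

    Estimates below 0 (FRiP under the noise floor) are clamped to 0
    with a warning.
    """
    if not 0.0 <= frip <= 1.0:
        raise ValueError("FRiP must lie in [0, 1]")
    peak_frac = n * (2.0 * w + d) / G
    if peak_frac >= 1.0:
        raise ValueError("peak territory n(2w + d) must be < G")
    alpha = (frip - peak_frac) / (1.0 - peak_frac)
    if alpha < 0.0:
        warnings.warn(
            f"FRiP {frip:.4g} below the noise floor {peak_frac:.4g}; "
            "clamping alpha to 0",
            stacklevel=2,
        )
        return 0.0
    return alpha
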