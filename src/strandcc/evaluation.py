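"""Simulation-versus-theory evaluation experiments.

These routines rerun the package's validation studies: simulate read
densities under the generative model at fixed study conditions, fit
cross-correlation profiles, and compare the measured maxima/minima and
QC metrics against the closed-form predictions.  Problem sizes are
scaled so each experiment runs on a single CPU in seconds to a couple
of minutes (see docs/methods.md for the design of each scenario).
"""

from __future__ import annotations

import numpy as np

from .crosscorr import merge_profiles, mscc_profile, ncc_profile
from .genome import GenomeSpec
from .mappability import MappabilityMask
from .metrics import estimate_fragment_length, estimate_w_fwhm, vsn
from .simulate import simulate_experiment, simulate_mappability
from .theory import (
    ModelParams,
    theoretical_max,
    theoretical_min,
)

__all__ = [
    "fig_scenario_run",
    "low_alpha_mscc_run",
    "saturated_run",
    "vsn_large_run",
]

# reduced-scale simulation study: G shrunk 300x against a mammalian
# genome while the saturation degree and region geometry are preserved
REDUCED = dict(G=10_000_000, M=100_000, n=1000, w=100, d=200, R=50)


def fig_scenario_run(
    alpha: float,
    seed: int,
    with_mscc: bool = False,
    shifts=450,
    **overrides,
) -> dict:
    """One simulation at the reduced study scale, measured against theory.

    Returns the NCC coefficient at the predicted peak shift d + w, the
    coefficient at the predicted non-overlap (minimum) shift x0 = d,
    and, optionally, MSCC-based QC metrics (fragment length, FWHM, VSN)
    for parameter-recovery checks.
    """
    cond = dict(REDUCED, **overrides)
    params = ModelParams(
        G=cond["G"], n=cond["n"], w=cond["w"], d=cond["d"],
        alpha=alpha, M=cond["M"], R=cond["R"],
    )
    genome = GenomeSpec(("chrSim",), (cond["G"],))
    _, density = simulate_experiment(genome, params, seed=seed)
    prof = merge_profiles(ncc_profile(density, shifts=shifts))
    peak_shift = params.fragment_length
    out = {
        "alpha": alpha,
        "seed": seed,
        "cc_at_peak": prof.at(peak_shift),
        "cc_at_x0": prof.at(params.d),
        "theory_max_approx2": theoretical_max(params, "approx2"),
        "theory_max_exact": theoretical_max(params, "exact"),
        "theory_min_exact": theoretical_min(params, x0=params.d),
    }
    if with_mscc:
        mask = MappabilityMask.all_mappable(genome, params.R)
        mprof = merge_profiles(mscc_profile(density, mask, shifts=shifts))
        frag = estimate_fragment_length(mprof, params.R)
        out["fragment_length"] = frag
        out["fwhm"] = estimate_w_fwhm(mprof, frag)
        out["vsn"] = vsn(mprof, params.M, cond["w"], fragment_length=frag)
        out["vsn_expected"] = alpha**2 / params.n
    return out


def low_alpha_mscc_run(
    seed: int,
    alpha: float = 1e-3,
    G: int = 100_000_000,
    n: int = 60,
    w: int = 100,
    d: int = 200,
    R: int = 50,
    saturation: float = 0.8,
    unmappable_fraction: float = 0.2,
) -> dict:
    """MSCC detectability of an extremely weak signal.

    A fifth of the genome is unmappable in random blocks; reads whose
    5' placement is unmappable are dropped, as alignment would drop
    them.  The MSCC coefficient at the predicted peak shift d + w is
    compared with the mean + 3 SD of background shifts (outside the
    region-overlap band (d, d + 2w)).
    """
    M = int(round(2 * n * w * saturation / alpha))
    params = ModelParams(G=G, n=n, w=w, d=d, alpha=alpha, M=M, R=R)
    genome = GenomeSpec(("chrSim",), (G,))
    rng = np.random.default_rng(seed)
    mask = simulate_mappability(
        genome, R, unmappable_fraction, seed=int(rng.integers(2**31))
    )
    _, density = simulate_experiment(
        genome, params, seed=int(rng.integers(2**31)), mask=mask
    )
    peak_shift = d + w
    background = np.concatenate(
        [np.arange(0, d + 1, 4), np.arange(d + 2 * w, 601, 4)]
    )
    shifts = np.union1d(background, np.arange(peak_shift - 30, peak_shift + 31))
    prof = merge_profiles(mscc_profile(density, mask, shifts=shifts))
    merged = prof.merged
    is_bg = np.isin(prof.shifts, background)
    bg = merged[is_bg & np.isfinite(merged)]
    peak = prof.at(peak_shift)
    bg_mean, bg_sd = float(bg.mean()), float(bg.std(ddof=1))
    return {
        "alpha": alpha,
        "M": M,
        "cc_at_peak": float(peak),
        "background_mean": bg_mean,
        "background_sd": bg_sd,
        "threshold": bg_mean + 3 * bg_sd,
        "zscore": (float(peak) - bg_mean) / bg_sd,
        "theory_max_approx2": theoretical_max(params, "approx2"),
    }


def saturated_run(
    seed: int,
    G: int = 10_000_000,
    n: int = 100,
    w: int = 100,
    d: int = 200,
    M: int = 100_000,
    R: int = 50,
) -> dict:
    """alpha = 1 deep in the saturated regime: the peak approaches 1."""
    params = ModelParams(G=G, n=n, w=w, d=d, alpha=1.0, M=M, R=R)
    genome = GenomeSpec(("chrSim",), (G,))
    _, density = simulate_experiment(genome, params, seed=seed)
    shifts = [0, 50, 100, 150, 200, 250, 280, 300, 320, 350, 400]
    prof = merge_profiles(ncc_profile(density, shifts=shifts))
    params_obs = ModelParams(
        G=G, n=n, w=w, d=d, alpha=1.0, M=M, M_u=density.n_positions, R=R
    )
    return {
        "cc_at_peak": prof.at(d + w),
        "theory_max_saturated": theoretical_max(params_obs),
        "degree_of_saturation": M / (2.0 * n * w),
    }


def vsn_large_run(
    alpha: float,
    seed: int,
    G: int = 100_000_000,
    n: int = 500,
    w: int = 100,
    d: int = 200,
    R: int = 50,
    saturation: float = 0.5,
) -> dict:
    """VSN accuracy at large scale with the saturation degree held fixed.

    M = 2 n w * saturation / alpha, so lowering alpha raises the read
    depth the way a low-enrichment experiment sequenced deeply would;
    the profile is evaluated densely around the peak and coarsely
    elsewhere.
    """
    M = int(round(2 * n * w * saturation / alpha))
    params = ModelParams(G=G, n=n, w=w, d=d, alpha=alpha, M=M, R=R)
    genome = GenomeSpec(("chrSim",), (G,))
    _, density = simulate_experiment(genome, params, seed=seed)
    shifts = np.union1d(np.arange(0, 451, 5), np.arange(d - 20, d + 2 * w + 21))
    mask = MappabilityMask.all_mappable(genome, R)
    prof = merge_profiles(mscc_profile(density, mask, shifts=shifts))
    frag = estimate_fragment_length(prof, R)
    value = vsn(prof, M, w, fragment_length=frag)
    expected = alpha**2 / n
    return {
        "alpha": alpha,
        "M": M,
        "fragment_length": frag,
        "vsn": value,
        "vsn_expected": expected,
        "rel_err": abs(value - expected) / expected,
    }
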