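import numpy as np
import pytest

from strandcc import BinaryDensity, GenomeSpec


def naive_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook Pearson correlation, position by position (oracle)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm = x - x.mean()
    ym = y - y.mean()
    den = np.sqrt((xm * xm).sum() * (ym * ym).sum())
    if den == 0:
        return np.nan
    return float((xm * ym).sum() / den)


def naive_ncc(f: np.ndarray, g: np.ndarray, shifts) -> np.ndarray:
    """Double-loop NCC oracle: Pearson of f[:L-x] vs g[x:]."""
    L = len(f)
    out = np.full(len(shifts), np.nan)
    for k, x in enumerate(shifts):
        if L - x >= 4:
            out[k] = naive_pearson(f[: L - x], g[x:])
    return out


def naive_mscc(f, g, mf, mr, shifts) -> np.ndarray:
    """Index-set Pearson oracle for the mappability-restricted profile."""
    L = len(f)
    out = np.full(len(shifts), np.nan)
    for k, x in enumerate(shifts):
        idx = np.flatnonzero(mf[: L - x] & mr[x:])
        if idx.size >= 4:
            out[k] = naive_pearson(
                np.asarray(f)[idx], np.asarray(g)[idx + x]
            )
    return out


def density_from_bools(f: np.ndarray, g: np.ndarray, read_length: int = 5,
                       chrom: str = "chr1") -> BinaryDensity:
    genome = GenomeSpec((chrom,), (len(f),))
    return BinaryDensity(
        genome=genome,
        read_length=read_length,
        forward={chrom: np.flatnonzero(f)},
        reverse={chrom: np.flatnonzero(g)},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20)


@pytest.fixture
def toy_genome():
    return GenomeSpec(("chr1", "chr2"), (1000, 600))
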