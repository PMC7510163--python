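"""Independent brute-force oracles used by the acceptance script.

Deliberately naive: plain position-by-position Pearson on the overlap
window (or on an explicit index set), sharing no code with the
package's estimators.
"""

from __future__ import annotations

import numpy as np


def naive_pearson(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm = x - x.mean()
    ym = y - y.mean()
    den = np.sqrt((xm * xm).sum() * (ym * ym).sum())
    if den == 0:
        return np.nan
    return float((xm * ym).sum() / den)


def naive_ncc(f, g, shifts) -> np.ndarray:
    L = len(f)
    out = np.full(len(shifts), np.nan)
    for k, x in enumerate(shifts):
        if L - x >= 4:
            out[k] = naive_pearson(f[: L - x], g[x:])
    return out


def naive_mscc(f, g, mf, mr, shifts) -> np.ndarray:
    L = len(f)
    out = np.full(len(shifts), np.nan)
    for k, x in enumerate(shifts):
        idx = np.flatnonzero(mf[: L - x] & mr[x:])
        if idx.size >= 4:
            out[k] = naive_pearson(np.asarray(f)[idx], np.asarray(g)[idx + x])
    return out
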