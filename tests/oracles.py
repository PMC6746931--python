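"""Independent brute-force oracles used by the test suite.

Everything here is written directly from the defining formulas with
plain Python loops, deliberately sharing no code with the package
(`numpy` is used only as an array container).
"""

from __future__ import annotations

import math

import numpy as np
import pywt


def iav(x) -> float:
    return float(sum(abs(float(v)) for v in x))


def mav(x) -> float:
    return iav(x) / len(x)


def rms(x) -> float:
    return math.sqrt(sum(float(v) ** 2 for v in x) / len(x))


def wl(x) -> float:
    return float(sum(abs(float(x[t]) - float(x[t - 1])) for t in range(1, len(x))))


def ssc(x, deadzone: float) -> int:
    count = 0
    for t in range(1, len(x) - 1):
        prev, cur, nxt = float(x[t - 1]), float(x[t]), float(x[t + 1])
        is_max = cur > prev and cur > nxt
        is_min = cur < prev and cur < nxt
        if (is_max or is_min) and (
            abs(cur - nxt) >= deadzone or abs(cur - prev) >= deadzone
        ):
            count += 1
    return count


def zc(x, deadzone: float) -> int:
    count = 0
    for t in range(len(x) - 1):
        a, b = float(x[t]), float(x[t + 1])
        if ((a > 0 and b < 0) or (a < 0 and b > 0)) and abs(a - b) >= deadzone:
            count += 1
    return count


def mavs(mav_rows):
    """Forward difference of per-window MAV rows; final row 0."""
    rows = [list(map(float, r)) for r in mav_rows]
    out = []
    for w in range(len(rows)):
        if w + 1 < len(rows):
            out.append([rows[w + 1][c] - rows[w][c] for c in range(len(rows[w]))])
        else:
            out.append([0.0] * len(rows[w]))
    return np.array(out)


def hist(x, n_bins: int, range_sigma: float, sigma: float):
    """Direct binning over [-range_sigma*sigma, +range_sigma*sigma] with
    out-of-range samples clipped into the outermost bins."""
    counts = [0] * n_bins
    if sigma == 0:
        counts[n_bins // 2] = len(x)
        return np.array(counts, dtype=float)
    lo = -range_sigma * sigma
    width = 2 * range_sigma * sigma / n_bins
    for v in x:
        b = int(math.floor((float(v) - lo) / width))
        b = min(max(b, 0), n_bins - 1)
        counts[b] += 1
    return np.array(counts, dtype=float)


def mdwt(x, wavelet_name: str, n_levels: int):
    """Marginal DWT by explicit circular convolution and dyadic
    downsampling: at each level, detail[k] = sum_n g[n] * a[(2k + L/2 - n)
    mod N] (g the highpass analysis filter of length L), the approximation
    computed likewise with the lowpass filter and fed to the next level.
    The marginal of level l is the sum of |detail| at that level."""
    w = pywt.Wavelet(wavelet_name)
    lo = [float(v) for v in w.dec_lo]
    hi = [float(v) for v in w.dec_hi]
    L = len(lo)
    a = [float(v) for v in x]
    marginals = []
    for _ in range(n_levels):
        n = len(a)
        half = (n + 1) // 2
        detail = []
        approx = []
        for k in range(half):
            sd = sa = 0.0
            for i in range(L):
                v = a[(2 * k + L // 2 - i) % n]
                sd += hi[i] * v
                sa += lo[i] * v
            detail.append(sd)
            approx.append(sa)
        marginals.append(sum(abs(d) for d in detail))
        a = approx
    return np.array(marginals)


def window_starts(m: int, winsize: int, wininc: int):
    """Exhaustive enumeration of fully contained window starts."""
    starts = []
    s = 0
    while s + winsize <= m:
        starts.append(s)
        s += wininc
    return starts


def pure_windows(stimulus, repetition, winsize: int, wininc: int):
    """Per-window constancy scan: (start, stim, rep, is_pure) tuples."""
    out = []
    for s in window_starts(len(stimulus), winsize, wininc):
        sw = list(stimulus[s : s + winsize])
        rw = list(repetition[s : s + winsize])
        pure = len(set(sw)) == 1 and len(set(rw)) == 1
        out.append((s, sw[0], rw[0], pure))
    return out
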