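"""Per-window sEMG feature functions.

Each feature maps one window (``T`` samples x ``n`` channels) to a fixed
number of values per channel; multi-valued features are laid out
channel-major (all values for channel 0, then channel 1, ...).  The ten
features are the classical time- and wavelet-domain descriptors of the
myoelectric-control literature:

========  ===========================================  ==============
name      definition (per channel ``x``, window ``w``) values/channel
========  ===========================================  ==============
iav       integrated absolute value  sum |x_t|                      1
mav       mean absolute value  (1/T) sum |x_t|                      1
ssc       slope-sign-change count (dead-zone gated)                 1
zc        zero-crossing count (dead-zone gated)                     1
mavs      MAV slope  MAV_{w+1} - MAV_w                              1
rms       root mean square  sqrt((1/T) sum x_t^2)                   1
wl        waveform length  sum |x_t - x_{t-1}|                      1
hist      amplitude histogram over +-3 sigma, B bins           B (20)
mdwt      marginal DWT: per-level sum of |detail coeffs|       levels
td        Hudgins set [MAV, MAVS, ZC, SSC, WL]                      5
========  ===========================================  ==============

The slope-sign-change count increments at a strict local extremum
``x_t`` whose step to at least one neighbour exceeds the dead zone; the
zero-crossing count increments on a strict sign change whose step
exceeds the dead zone.  Zeros and plateaus never count.

Two call surfaces exist: the public ``feat_*`` functions take a single
window, while the ``stack_*`` functions take a ``(W, T, C)`` stack of
windows and are the vectorized kernels the extraction engine dispatches
to its workers.  Both compute identical values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

__all__ = [
    "HistConfig",
    "MdwtConfig",
    "feat_iav",
    "feat_mav",
    "feat_ssc",
    "feat_zc",
    "feat_mavs",
    "feat_rms",
    "feat_wl",
    "feat_hist",
    "feat_mdwt",
    "feat_td",
]


@dataclass(frozen=True)
class HistConfig:
    """Histogram feature parameters: ``n_bins`` equal-width bins spanning
    ``[-range_sigma * sigma_c, +range_sigma * sigma_c]`` per channel."""

    n_bins: int = 20
    range_sigma: float = 3.0

    def __post_init__(self) -> None:
        if int(self.n_bins) != self.n_bins or self.n_bins < 1:
            raise ValueError("n_bins must be a positive integer")
        if self.range_sigma <= 0:
            raise ValueError("range_sigma must be positive")


@dataclass(frozen=True)
class MdwtConfig:
    """Marginal-DWT parameters: wavelet family and decomposition depth."""

    wavelet_name: str = "db7"
    n_levels: int = 3

    def __post_init__(self) -> None:
        if int(self.n_levels) != self.n_levels or self.n_levels < 1:
            raise ValueError("n_levels must be a positive integer")
        pywt.Wavelet(self.wavelet_name)  # raises on unknown name


def _as_stack(win: np.ndarray, min_t: int = 2) -> np.ndarray:
    """Coerce a single (T,) or (T, C) window to a (1, T, C) stack."""
    w = np.asarray(win, dtype=np.float64)
    if w.ndim == 1:
        w = w[:, None]
    if w.ndim != 2:
        raise ValueError("window must be 1-D or 2-D (samples x channels)")
    if w.shape[0] < min_t:
        raise ValueError(f"window needs at least {min_t} samples, got {w.shape[0]}")
    return w[None, :, :]


# ---------------------------------------------------------------------------
# vectorized kernels on (W, T, C) stacks
# ---------------------------------------------------------------------------

def stack_iav(stack: np.ndarray) -> np.ndarray:
    return np.abs(stack).sum(axis=1)


def stack_mav(stack: np.ndarray) -> np.ndarray:
    return np.abs(stack).mean(axis=1)


def stack_rms(stack: np.ndarray) -> np.ndarray:
    return np.sqrt(np.square(stack).mean(axis=1))


def stack_wl(stack: np.ndarray) -> np.ndarray:
    return np.abs(np.diff(stack, axis=1)).sum(axis=1)


def stack_ssc(stack: np.ndarray, deadzone: float = 0.0) -> np.ndarray:
    if stack.shape[1] < 3:
        raise ValueError("slope-sign-change needs windows of >= 3 samples")
    prev = stack[:, :-2, :]
    cur = stack[:, 1:-1, :]
    nxt = stack[:, 2:, :]
    extremum = ((cur > prev) & (cur > nxt)) | ((cur < prev) & (cur < nxt))
    over = (np.abs(cur - nxt) >= deadzone) | (np.abs(cur - prev) >= deadzone)
    return (extremum & over).sum(axis=1).astype(np.float64)


def stack_zc(stack: np.ndarray, deadzone: float = 0.0) -> np.ndarray:
    a = stack[:, :-1, :]
    b = stack[:, 1:, :]
    crossing = ((a > 0) & (b < 0)) | ((a < 0) & (b > 0))
    over = np.abs(a - b) >= deadzone
    return (crossing & over).sum(axis=1).astype(np.float64)


def stack_hist(
    stack: np.ndarray, cfg: HistConfig, sigma: np.ndarray
) -> np.ndarray:
    """Histogram counts, channel-major ``(W, n_bins * C)``.

    ``sigma`` has shape ``(W, C)`` (window-local scale) or ``(C,)``
    (recording-global scale, broadcast over windows).  Samples outside
    the +-range are clipped into the outermost bins, so counts per
    channel always sum to T.  A flat channel (sigma 0) puts all T counts
    in the central bin.
    """
    w_count, t_count, c_count = stack.shape
    b = cfg.n_bins
    sigma = np.broadcast_to(np.asarray(sigma, dtype=np.float64), (w_count, c_count))
    half = cfg.range_sigma * sigma  # (W, C)
    width = 2.0 * half / b
    flat = half == 0
    safe_width = np.where(flat, 1.0, width)
    idx = np.floor((stack + half[:, None, :]) / safe_width[:, None, :])
    idx = np.clip(idx, 0, b - 1).astype(np.int64)
    if flat.any():
        idx = np.where(flat[:, None, :], b // 2, idx)
    group = (
        np.arange(w_count, dtype=np.int64)[:, None, None] * c_count
        + np.arange(c_count, dtype=np.int64)[None, None, :]
    )
    counts = np.bincount(
        (group * b + idx).ravel(), minlength=w_count * c_count * b
    ).reshape(w_count, c_count * b)
    return counts.astype(np.float64)


def stack_mdwt(stack: np.ndarray, cfg: MdwtConfig) -> np.ndarray:
    """Marginal DWT, channel-major ``(W, n_levels * C)``.

    Level ``l`` marginal is the sum of absolute detail coefficients of a
    cascaded filter-bank decomposition with periodic signal extension;
    levels are ordered 1 (finest) to ``n_levels``.  The approximation
    band is excluded.
    """
    t = stack.shape[1]
    wavelet = pywt.Wavelet(cfg.wavelet_name)
    max_level = pywt.dwt_max_level(t, wavelet.dec_len)
    if max_level < cfg.n_levels:
        raise ValueError(
            f"window of {t} samples supports at most {max_level} "
            f"decomposition levels with wavelet {cfg.wavelet_name!r} "
            f"(requested {cfg.n_levels})"
        )
    coeffs = pywt.wavedec(
        stack, wavelet, mode="periodization", level=cfg.n_levels, axis=1
    )
    # coeffs = [cA_L, cD_L, ..., cD_1]; marginal for level l = sum |cD_l|
    w_count, _, c_count = stack.shape
    out = np.empty((w_count, c_count, cfg.n_levels), dtype=np.float64)
    for lev in range(1, cfg.n_levels + 1):
        out[:, :, lev - 1] = np.abs(coeffs[len(coeffs) - lev]).sum(axis=1)
    return out.reshape(w_count, c_count * cfg.n_levels)


def stack_td_local(stack: np.ndarray, deadzone: float = 0.0) -> np.ndarray:
    """The window-local part of the Hudgins set: ``(W, C, 4)`` holding
    [MAV, ZC, SSC, WL]; the MAV-slope column is inserted by the caller,
    which sees the full ordered window sequence."""
    return np.stack(
        [
            stack_mav(stack),
            stack_zc(stack, deadzone),
            stack_ssc(stack, deadzone),
            stack_wl(stack),
        ],
        axis=-1,
    )


def mavs_from_mav(mav: np.ndarray) -> np.ndarray:
    """MAV slope across an ordered window sequence: row ``w`` is
    ``MAV_{w+1} - MAV_w``; the final row (no successor) is 0."""
    mav = np.asarray(mav, dtype=np.float64)
    out = np.zeros_like(mav)
    if mav.shape[0] > 1:
        out[:-1] = np.diff(mav, axis=0)
    return out


def assemble_td(mav: np.ndarray, mavs: np.ndarray, local: np.ndarray) -> np.ndarray:
    """Interleave [MAV, MAVS, ZC, SSC, WL] channel-major -> (W, 5*C)."""
    w_count, c_count, _ = local.shape
    td = np.empty((w_count, c_count, 5), dtype=np.float64)
    td[:, :, 0] = mav
    td[:, :, 1] = mavs
    td[:, :, 2:] = local[:, :, 1:]
    return td.reshape(w_count, c_count * 5)


# ---------------------------------------------------------------------------
# single-window API
# ---------------------------------------------------------------------------

def feat_iav(win: np.ndarray) -> np.ndarray:
    """Integrated absolute value, one value per channel."""
    return stack_iav(_as_stack(win))[0]


def feat_mav(win: np.ndarray) -> np.ndarray:
    """Mean absolute value, one value per channel."""
    return stack_mav(_as_stack(win))[0]


def feat_rms(win: np.ndarray) -> np.ndarray:
    """Root mean square, one value per channel."""
    return stack_rms(_as_stack(win))[0]


def feat_wl(win: np.ndarray) -> np.ndarray:
    """Waveform length (total variation), one value per channel."""
    return stack_wl(_as_stack(win))[0]


def feat_ssc(win: np.ndarray, deadzone: float = 0.0) -> np.ndarray:
    """Slope-sign-change count, one value per channel.

    Counts strict local extrema whose amplitude step to the next or the
    previous sample is at least ``deadzone``.
    """
    return stack_ssc(_as_stack(win, min_t=3), deadzone)[0]


def feat_zc(win: np.ndarray, deadzone: float = 0.0) -> np.ndarray:
    """Zero-crossing count, one value per channel.

    Counts strict sign changes between consecutive samples whose
    amplitude step is at least ``deadzone``; a sample exactly at zero
    breaks both sign conditions and never contributes.
    """
    return stack_zc(_as_stack(win), deadzone)[0]


def feat_mavs(mav_per_window: np.ndarray) -> np.ndarray:
    """MAV slope across windows (not within one window).

    Takes the ordered (windows x channels) MAV table and returns the
    same-shaped forward difference; the last row is 0 so the output
    stays aligned one-row-per-window.
    """
    mav = np.asarray(mav_per_window, dtype=np.float64)
    if mav.ndim == 1:
        mav = mav[:, None]
        return mavs_from_mav(mav)[:, 0]
    return mavs_from_mav(mav)


def feat_hist(
    win: np.ndarray,
    cfg: HistConfig = HistConfig(),
    sigma_per_channel: np.ndarray | None = None,
) -> np.ndarray:
    """Amplitude histogram, ``n_bins`` counts per channel (channel-major).

    Bins are equal-width over ``[-range_sigma * sigma_c, +range_sigma *
    sigma_c]``; out-of-range samples are clipped into the outermost
    bins.  ``sigma_per_channel`` defaults to the window-local population
    standard deviation of each channel.
    """
    stack = _as_stack(win)
    if sigma_per_channel is None:
        sigma = stack.std(axis=1)  # (1, C) window-local
    else:
        sigma = np.asarray(sigma_per_channel, dtype=np.float64)
        if np.any(sigma < 0):
            raise ValueError("sigma_per_channel must be non-negative")
    return stack_hist(stack, cfg, sigma)[0]


def feat_mdwt(win: np.ndarray, cfg: MdwtConfig = MdwtConfig()) -> np.ndarray:
    """Marginal discrete wavelet transform, ``n_levels`` values per
    channel (channel-major), each the sum of absolute detail
    coefficients at that level."""
    return stack_mdwt(_as_stack(win), cfg)[0]


def feat_td(all_windows, deadzone: float = 0.0) -> np.ndarray:
    """Hudgins time-domain set over an ordered window sequence.

    Returns ``(n_windows, 5 * n_channels)``: per channel the block
    [MAV, MAVS, ZC, SSC, WL], with MAVS differenced across the given
    window sequence.
    """
    stacks = [_as_stack(w, min_t=3)[0] for w in all_windows]
    if not stacks:
        raise ValueError("need at least one window")
    stack = np.stack(stacks, axis=0)
    local = stack_td_local(stack, deadzone)
    mav = local[:, :, 0]
    return assemble_td(mav, mavs_from_mav(mav), local)
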