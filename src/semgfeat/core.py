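"""Domain types, sliding-window geometry and label-purity logic.

A recording is an ``m x n`` signal matrix (rows = synchronized time
samples, columns = electrode channels) with two per-sample integer label
vectors: ``stimulus`` (which movement is being performed; 0 means rest)
and ``repetition`` (which repeat of that movement; 0 during rest).

Windowing follows the classical overlapping-window scheme used in
myoelectric control: fixed length ``winsize`` samples, advanced by
``wininc`` samples, anchored at sample 0; a trailing partial window is
dropped.  A window is *pure* when both label vectors are constant across
all of its samples; impure windows (those straddling a movement onset or
offset) are discarded from downstream feature matrices.
"""

from __future__ import annotations

from dataclasses import dataclass


import numpy as np

__all__ = [
    "EMGRecording",
    "ExtractionConfig",
    "WindowPlan",
    "WindowLabels",
    "FEATURE_NAMES",
    "plan_windows",
    "label_windows",
]

#: Canonical short names of the supported per-window features.
FEATURE_NAMES = ("iav", "mav", "ssc", "zc", "mavs", "rms", "wl", "hist", "mdwt", "td")

#: Legacy long names (as used by the original MATLAB-style tooling) -> short names.
FEATURE_ALIASES = {
    "getiavfeat": "iav",
    "getmavfeat": "mav",
    "getsscfeat": "ssc",
    "getzcfeat": "zc",
    "getmavsfeat": "mavs",
    "getrmsfeat": "rms",
    "getwlfeat": "wl",
    "getHISTfeat": "hist",
    "getmDWTfeat": "mdwt",
    "getTDfeat": "td",
}


def canonical_feature_name(name: str) -> str:
    """Resolve a feature name or legacy alias to its canonical short form.

    Raises
    ------
    ValueError
        If the name is not a recognized feature.
    """
    n = FEATURE_ALIASES.get(name, name.lower())
    if n not in FEATURE_NAMES:
        valid = ", ".join(FEATURE_NAMES)
        raise ValueError(f"unknown feature {name!r}; valid names: {valid}")
    return n


@dataclass(frozen=True)
class EMGRecording:
    """Multichannel sEMG signal with synchronized per-sample labels.

    Parameters
    ----------
    signal : ndarray, shape (m, n)
        One column per electrode channel, arbitrary units.
    stimulus : ndarray of int, shape (m,)
        Movement id per sample; 0 = rest.
    repetition : ndarray of int, shape (m,)
        Repetition index per sample; 0 = rest.
    sampling_rate : float
        Samples per second, > 0.
    """

    signal: np.ndarray
    stimulus: np.ndarray
    repetition: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        signal = np.atleast_2d(np.asarray(self.signal, dtype=np.float64))
        if signal.ndim != 2:
            raise ValueError("signal must be a 2-D (samples x channels) array")
        stimulus = np.asarray(self.stimulus)
        repetition = np.asarray(self.repetition)
        for name, vec in (("stimulus", stimulus), ("repetition", repetition)):
            if vec.ndim != 1:
                raise ValueError(f"{name} must be a 1-D vector")
            if vec.size != signal.shape[0]:
                raise ValueError(
                    f"{name} length {vec.size} != signal row count {signal.shape[0]}"
                )
            if not np.issubdtype(vec.dtype, np.integer):
                if not np.all(vec == np.round(vec)):
                    raise ValueError(f"{name} must contain integers")
            if np.any(vec < 0):
                raise ValueError(f"{name} values must be non-negative")
        if signal.shape[0] < 1 or signal.shape[1] < 1:
            raise ValueError("signal needs >= 1 sample and >= 1 channel")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        object.__setattr__(self, "signal", signal)
        object.__setattr__(self, "stimulus", stimulus.astype(np.int64))
        object.__setattr__(self, "repetition", repetition.astype(np.int64))

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def n_channels(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass(frozen=True)
class ExtractionConfig:
    """Parameters of a feature-extraction run.

    ``winsize``/``wininc`` are in samples (convert from milliseconds via
    ``round(ms * sampling_rate / 1000)``).  ``deadzone`` is the symmetric
    amplitude threshold used by the zero-crossing and slope-sign-change
    counts.  ``workers`` is the number of parallel workers; the output is
    identical for every value.
    """

    winsize: int
    wininc: int
    feature_name: str = "rms"
    deadzone: float = 1e-5
    workers: int = 1
    hist_bins: int = 20
    hist_sigma: float = 3.0
    hist_sigma_scope: str = "window"  # or "recording"
    mdwt_wavelet: str = "db7"
    mdwt_levels: int = 3

    def __post_init__(self) -> None:
        name = canonical_feature_name(self.feature_name)
        object.__setattr__(self, "feature_name", name)
        if int(self.winsize) != self.winsize or self.winsize < 2:
            raise ValueError("winsize must be an integer >= 2")
        min_size = 3 if name in ("ssc", "td") else 2
        if self.winsize < min_size:
            raise ValueError(f"winsize must be >= {min_size} for feature {name!r}")
        if int(self.wininc) != self.wininc or self.wininc < 1:
            raise ValueError("wininc must be a positive integer")
        if self.deadzone < 0:
            raise ValueError("deadzone must be non-negative")
        if int(self.workers) != self.workers or self.workers < 1:
            raise ValueError("workers must be a positive integer")
        if self.hist_bins < 1:
            raise ValueError("hist_bins must be >= 1")
        if self.hist_sigma <= 0:
            raise ValueError("hist_sigma must be positive")
        if self.hist_sigma_scope not in ("window", "recording"):
            raise ValueError("hist_sigma_scope must be 'window' or 'recording'")
        if self.mdwt_levels < 1:
            raise ValueError("mdwt_levels must be >= 1")


@dataclass(frozen=True)
class WindowPlan:
    """Ordered window start indices plus the geometry that produced them."""

    starts: np.ndarray
    winsize: int
    wininc: int

    @property
    def n_windows(self) -> int:
        return int(self.starts.size)


@dataclass(frozen=True)
class WindowLabels:
    """Per-window (stimulus, repetition, purity) derived from sample labels.

    ``stim``/``rep`` are only meaningful where ``is_pure`` is True.
    """

    stim: np.ndarray
    rep: np.ndarray
    is_pure: np.ndarray


def plan_windows(m: int, winsize: int, wininc: int) -> WindowPlan:
    """Plan fully contained sliding windows over ``m`` samples.

    Windows are half-open slices ``[s, s + winsize)`` with starts
    ``0, wininc, 2*wininc, ...``; the count is
    ``floor((m - winsize) / wininc) + 1`` when ``m >= winsize``, else 0
    (a signal shorter than one window yields an empty plan, not an error).
    """
    m = int(m)
    winsize = int(winsize)
    wininc = int(wininc)
    if winsize < 1 or wininc < 1:
        raise ValueError("winsize and wininc must be positive integers")
    if m < 1:
        raise ValueError("m must be a positive integer")
    if m < winsize:
        starts = np.empty(0, dtype=np.int64)
    else:
        n = (m - winsize) // wininc + 1
        starts = np.arange(n, dtype=np.int64) * wininc
    return WindowPlan(starts=starts, winsize=winsize, wininc=wininc)


def label_windows(
    stimulus: np.ndarray, repetition: np.ndarray, plan: WindowPlan
) -> WindowLabels:
    """Label each planned window and flag purity.

    A window is pure iff *both* the stimulus and the repetition vector are
    constant across all ``winsize`` samples of the window.  For pure
    windows ``stim``/``rep`` carry that constant value; for impure windows
    they hold the first sample's value but must not be read.
    """
    stimulus = np.asarray(stimulus)
    repetition = np.asarray(repetition)
    if stimulus.shape != repetition.shape or stimulus.ndim != 1:
        raise ValueError("stimulus and repetition must be 1-D vectors of equal length")
    m = stimulus.size
    if plan.n_windows and plan.starts[-1] + plan.winsize > m:
        raise ValueError(
            f"label vectors of length {m} do not cover the window plan "
            f"(needs >= {int(plan.starts[-1]) + plan.winsize} samples)"
        )
    n = plan.n_windows
    stim = np.zeros(n, dtype=np.int64)
    rep = np.zeros(n, dtype=np.int64)
    pure = np.zeros(n, dtype=bool)
    if n == 0:
        return WindowLabels(stim=stim, rep=rep, is_pure=pure)

    # Change-point positions let purity be decided without slicing each
    # window: a window is pure iff no label change falls strictly inside it.
    changes = np.flatnonzero(
        (np.diff(stimulus) != 0) | (np.diff(repetition) != 0)
    )  # change between sample c and c+1
    stim[:] = stimulus[plan.starts]
    rep[:] = repetition[plan.starts]
    pure[:] = True
    for c in changes:
        # window [s, s+winsize) contains both c and c+1 iff c+2-winsize <= s <= c
        lo = max(0, c - plan.winsize + 2)
        first = -(-lo // plan.wininc)  # ceil division
        last = c // plan.wininc
        if first <= last:
            pure[first : min(last, n - 1) + 1] = False
    return WindowLabels(stim=stim, rep=rep, is_pure=pure)
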