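"""Parallel window feature extraction.

The extraction pipeline mirrors the classical windowed myoelectric
workflow: plan overlapping windows, compute the requested feature for
every window (dispatched to parallel workers in contiguous chunks),
derive per-window stimulus/repetition labels, drop windows whose labels
are not constant, and return the aligned triple ``(feat, featStim,
featRep)``.

Determinism contract: the output is element-wise identical for every
worker count, including 1.  Two design points make this hold:

* workers receive contiguous, ordered chunks of windows and results are
  concatenated in chunk order, so row order never depends on scheduling;
* the inter-window MAV-slope terms of the ``mavs`` and ``td`` features
  are differenced over the *full ordered* MAV table after the parallel
  pass, so chunk boundaries cannot alter values.

MAV slope is computed over all planned windows before purity filtering;
this keeps the forward difference well-defined even when a neighbouring
window is later discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from joblib import Parallel, delayed

from .core import (
    EMGRecording,
    ExtractionConfig,
    WindowLabels,
    WindowPlan,
    label_windows,
    plan_windows,
)
from . import features as F
from .features import HistConfig, MdwtConfig

__all__ = [
    "FeatureMatrix",
    "ChunkPlan",
    "partition_windows",
    "extract_features",
    "feature_dimension",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FeatureMatrix:
    """Extraction output: retained (pure) windows x feature columns.

    ``feat`` rows are in window-start order; ``featStim``/``featRep``
    give the constant stimulus and repetition label of each retained
    window.  ``column_layout`` describes the channel-major layout as
    ``(values_per_channel, n_channels)``.
    """

    feat: np.ndarray
    featStim: np.ndarray
    featRep: np.ndarray
    feature_name: str
    column_layout: tuple[int, int]

    def __post_init__(self) -> None:
        if not (self.feat.shape[0] == self.featStim.size == self.featRep.size):
            raise ValueError("feat rows, featStim and featRep must align")

    @property
    def n_windows(self) -> int:
        return int(self.feat.shape[0])


@dataclass(frozen=True)
class ChunkPlan:
    """Balanced partition of window indices into contiguous runs."""

    chunk_boundaries: tuple[tuple[int, int], ...]  # half-open (start, stop)

    @property
    def n_chunks(self) -> int:
        return len(self.chunk_boundaries)

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(stop - start for start, stop in self.chunk_boundaries)


def partition_windows(n_windows: int, workers: int) -> ChunkPlan:
    """Split ``0..n_windows-1`` into at most ``workers`` contiguous,
    ordered chunks whose sizes differ by at most one."""
    if n_windows < 0:
        raise ValueError("n_windows must be >= 0")
    if workers < 1:
        raise ValueError("workers must be >= 1")
    k = min(workers, n_windows)
    if k == 0:
        return ChunkPlan(chunk_boundaries=())
    base, extra = divmod(n_windows, k)
    bounds = []
    start = 0
    for i in range(k):
        size = base + (1 if i < extra else 0)
        bounds.append((start, start + size))
        start += size
    return ChunkPlan(chunk_boundaries=tuple(bounds))


def feature_dimension(
    feature_name: str,
    n_channels: int,
    hist: HistConfig = HistConfig(),
    mdwt: MdwtConfig = MdwtConfig(),
) -> int:
    """Number of feature columns for ``feature_name`` on ``n_channels``."""
    from .core import canonical_feature_name

    name = canonical_feature_name(feature_name)
    per_channel = {
        "iav": 1,
        "mav": 1,
        "ssc": 1,
        "zc": 1,
        "mavs": 1,
        "rms": 1,
        "wl": 1,
        "hist": hist.n_bins,
        "mdwt": mdwt.n_levels,
        "td": 5,
    }[name]
    return per_channel * n_channels


#: windows materialized per batch; bounds peak memory at roughly
#: BATCH * winsize * n_channels * 8 bytes without affecting values
_BATCH = 1024


def _window_stack(signal: np.ndarray, plan: WindowPlan, lo: int, hi: int) -> np.ndarray:
    """Materialize windows lo..hi-1 as a (W, T, C) stack."""
    starts = plan.starts[lo:hi]
    idx = starts[:, None] + np.arange(plan.winsize)[None, :]
    return signal[idx, :]  # (W, T, C)


def _chunk_values(
    signal: np.ndarray,
    plan: WindowPlan,
    lo: int,
    hi: int,
    name: str,
    cfg: ExtractionConfig,
    hist_sigma: np.ndarray | None,
) -> np.ndarray:
    """Compute the window-local feature values for one chunk of windows.

    Large chunks are processed in fixed-size batches; every value is a
    per-window reduction, so batching cannot change the output.
    """
    if hi - lo > _BATCH:
        return np.concatenate(
            [
                _chunk_values(signal, plan, b, min(b + _BATCH, hi), name, cfg, hist_sigma)
                for b in range(lo, hi, _BATCH)
            ],
            axis=0,
        )
    stack = _window_stack(signal, plan, lo, hi)
    if name == "iav":
        return F.stack_iav(stack)
    if name in ("mav", "mavs"):
        # mavs is differenced from the full MAV table after the parallel pass
        return F.stack_mav(stack)
    if name == "rms":
        return F.stack_rms(stack)
    if name == "wl":
        return F.stack_wl(stack)
    if name == "ssc":
        return F.stack_ssc(stack, cfg.deadzone)
    if name == "zc":
        return F.stack_zc(stack, cfg.deadzone)
    if name == "hist":
        hc = HistConfig(n_bins=cfg.hist_bins, range_sigma=cfg.hist_sigma)
        sigma = stack.std(axis=1) if hist_sigma is None else hist_sigma
        return F.stack_hist(stack, hc, sigma)
    if name == "mdwt":
        mc = MdwtConfig(wavelet_name=cfg.mdwt_wavelet, n_levels=cfg.mdwt_levels)
        return F.stack_mdwt(stack, mc)
    if name == "td":
        local = F.stack_td_local(stack, cfg.deadzone)  # (W, C, 4)
        return local.reshape(local.shape[0], -1)
    raise AssertionError(f"unreachable feature {name!r}")


def extract_features(rec: EMGRecording, cfg: ExtractionConfig) -> FeatureMatrix:
    """Run the full extraction pipeline on one recording.

    Returns a :class:`FeatureMatrix` whose rows are the pure windows in
    window-start order.  The result is identical for any ``cfg.workers``
    value.
    """
    plan = plan_windows(rec.n_samples, cfg.winsize, cfg.wininc)
    name = cfg.feature_name
    n_ch = rec.n_channels
    hist = HistConfig(n_bins=cfg.hist_bins, range_sigma=cfg.hist_sigma)
    mdwt = MdwtConfig(wavelet_name=cfg.mdwt_wavelet, n_levels=cfg.mdwt_levels)
    n_cols = feature_dimension(name, n_ch, hist, mdwt)

    if plan.n_windows == 0:
        logger.warning(
            "signal of %d samples is shorter than winsize %d: empty feature matrix",
            rec.n_samples,
            cfg.winsize,
        )
        empty = np.empty((0, n_cols))
        zeros = np.empty(0, dtype=np.int64)
        return FeatureMatrix(
            feat=empty,
            featStim=zeros,
            featRep=zeros,
            feature_name=name,
            column_layout=(n_cols // n_ch, n_ch),
        )

    labels: WindowLabels = label_windows(rec.stimulus, rec.repetition, plan)
    chunks = partition_windows(plan.n_windows, cfg.workers)
    logger.info(
        "extracting %s: %d windows (%d impure), %d workers, chunk sizes %s",
        name,
        plan.n_windows,
        int((~labels.is_pure).sum()),
        cfg.workers,
        chunks.sizes,
    )

    hist_sigma = None
    if name == "hist" and cfg.hist_sigma_scope == "recording":
        hist_sigma = rec.signal.std(axis=0)  # (C,), broadcast over windows

    parts = Parallel(n_jobs=cfg.workers, backend="threading")(
        delayed(_chunk_values)(rec.signal, plan, lo, hi, name, cfg, hist_sigma)
        for lo, hi in chunks.chunk_boundaries
    )
    values = np.concatenate(parts, axis=0)

    # inter-window terms on the full ordered table, before purity filtering
    if name == "mavs":
        values = F.mavs_from_mav(values)
    elif name == "td":
        local = values.reshape(plan.n_windows, n_ch, 4)
        mav = local[:, :, 0]
        values = F.assemble_td(mav, F.mavs_from_mav(mav), local)

    keep = labels.is_pure
    return FeatureMatrix(
        feat=values[keep],
        featStim=labels.stim[keep],
        featRep=labels.rep[keep],
        feature_name=name,
        column_layout=(n_cols // n_ch, n_ch),
    )
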