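"""Autoregressive prediction of keypoints into the future.

How far ahead a keypoint can be linearly predicted measures its intrinsic
timescale: whisking decorrelates within tens of milliseconds while eye
position drifts over seconds.  Each keypoint coordinate is convolved with a
bank of causal exponential-decay basis kernels (unit-sum, decay constants
log-spaced from 40 ms to 5 s); a joint ridge regression from the basis
features at time ``t`` to all coordinates at ``t + lag`` is fit separately
for every lag on training segments; variance explained on held-out test
segments yields a VE-vs-lag curve per keypoint, summarized by the lag at
which VE falls to half its value at a 20 ms lag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .io_core import KeypointSeries, SegmentSplit, make_split


def default_lags() -> np.ndarray:
    """Future-prediction lags: 0.02-10 s step 0.02 s, then 10.5-40 s step 0.5 s."""
    return np.concatenate([np.arange(1, 501) * 0.02, 10.0 + np.arange(1, 61) * 0.5])


@dataclass
class ARConfig:
    basis_taus: np.ndarray = field(
        default_factory=lambda: np.geomspace(0.04, 5.0, 10)
    )  # s, log-spaced decay constants
    lags: np.ndarray = field(default_factory=default_lags)  # s
    ridge_lambda: float = 1e-4  # on standardized features
    include_instantaneous: bool = True  # tau -> 0 basis element (delta kernel)
    n_segments: int = 10
    train_frac: float = 0.75
    gap: float = 2.6  # s excluded between train and test

    def __post_init__(self):
        self.basis_taus = np.asarray(self.basis_taus, dtype=float)
        self.lags = np.asarray(self.lags, dtype=float)
        if not (np.all(self.basis_taus > 0) and np.all(np.diff(self.basis_taus) > 0)):
            raise ValueError("basis_taus must be positive ascending")
        if not (np.all(self.lags > 0) and np.all(np.diff(self.lags) > 0)):
            raise ValueError("lags must be positive ascending")


def basis_features(traces: np.ndarray, taus: np.ndarray, rate: float,
                   include_instantaneous: bool = True) -> np.ndarray:
    """Causal exponential-decay features: (T, D) traces -> (T, D * n_kernels).

    Each kernel is ``exp(-t / tau)`` normalized to unit sum, applied causally
    (feature at time t depends only on samples <= t), implemented as a
    first-order recursive filter.  With ``include_instantaneous`` the tau -> 0
    limit of the family (a delta kernel, i.e. the raw trace) is included as
    the first element: finite-tau kernels alone cannot reconstruct the
    current sample, which caps prediction accuracy at short lags.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    if traces.ndim == 1:
        traces = traces[:, None]
    T, D = traces.shape
    n_extra = 1 if include_instantaneous else 0
    out = np.empty((T, D * (len(taus) + n_extra)))
    if include_instantaneous:
        out[:, :D] = traces
    for i, tau in enumerate(taus, start=n_extra):
        a = np.exp(-1.0 / (tau * rate))
        out[:, i * D : (i + 1) * D] = lfilter([1 - a], [1, -a], traces, axis=0)
    return out


@dataclass
class FutureFit:
    lag: float
    weights: np.ndarray  # (features, outputs)
    ve: np.ndarray  # per coordinate
    ve_keypoint: np.ndarray  # per keypoint (x/y averaged)
    ve_group: dict[str, float]


def _ridge_fit(Xtr, Ytr, lam):
    G = Xtr.T @ Xtr + lam * len(Xtr) * np.eye(Xtr.shape[1])
    return np.linalg.solve(G, Xtr.T @ Ytr)


def fit_future(series: KeypointSeries, config: ARConfig, lag: float,
               split: SegmentSplit | None = None,
               features: np.ndarray | None = None) -> FutureFit:
    """Ridge regression from basis features at t to all coordinates at t + lag.

    A single joint multi-output fit predicts every keypoint coordinate;
    variance explained is reported per coordinate, per keypoint and per
    group on test indices.
    """
    T = series.n_frames
    rate = series.rate
    lag_frames = int(round(lag * rate))
    coords = series.coords.reshape(T, -1)
    if features is None:
        features = basis_features(coords, config.basis_taus, rate,
                                  config.include_instantaneous)
    if split is None:
        split = make_split(T, rate, config.n_segments, config.train_frac, config.gap)
    train = split.train_idx[split.train_idx + lag_frames < T]
    test = split.test_idx[split.test_idx + lag_frames < T]
    if len(test) < 2:
        raise ValueError(f"insufficient test samples at lag {lag} s")
    mu = features[train].mean(axis=0)
    sd = np.maximum(features[train].std(axis=0), 1e-12)
    Xtr = (features[train] - mu) / sd
    Xte = (features[test] - mu) / sd
    Ytr = coords[train + lag_frames]
    ym = Ytr.mean(axis=0)
    W = _ridge_fit(Xtr, Ytr - ym, config.ridge_lambda)
    pred = Xte @ W + ym
    Yte = coords[test + lag_frames]
    sst = ((Yte - Yte.mean(axis=0)) ** 2).sum(axis=0)
    sse = ((Yte - pred) ** 2).sum(axis=0)
    ve = np.where(sst > 0, 1 - sse / np.where(sst > 0, sst, 1.0), np.nan)
    ve_kp = ve.reshape(-1, 2).mean(axis=1)
    groups = {}
    for g in ("eye", "whisker", "nose", "mouth"):
        idx = series.schema.group_indices(g)
        if len(idx):
            groups[g] = float(np.nanmean(ve_kp[idx]))
    return FutureFit(lag=lag, weights=W, ve=ve, ve_keypoint=ve_kp, ve_group=groups)


def ve_vs_lag(series: KeypointSeries, config: ARConfig | None = None) -> dict:
    """VE-vs-lag curves for every keypoint and group.

    Returns a dict with ``lags`` (s), ``ve_keypoint`` (lags x keypoints),
    and ``ve_group`` (group -> array over lags).  The basis features and the
    segment split are computed once and shared across lags.
    """
    config = config or ARConfig()
    coords = series.coords.reshape(series.n_frames, -1)
    features = basis_features(coords, config.basis_taus, series.rate,
                              config.include_instantaneous)
    split = make_split(series.n_frames, series.rate, config.n_segments,
                       config.train_frac, config.gap)
    ve_kp = np.empty((len(config.lags), series.schema.n_keypoints))
    groups: dict[str, list] = {}
    for li, lag in enumerate(config.lags):
        fit = fit_future(series, config, lag, split=split, features=features)
        ve_kp[li] = fit.ve_keypoint
        for g, v in fit.ve_group.items():
            groups.setdefault(g, []).append(v)
    return {
        "lags": config.lags.copy(),
        "ve_keypoint": ve_kp,
        "ve_group": {g: np.array(v) for g, v in groups.items()},
    }


def half_decay_time(lags: np.ndarray, ve: np.ndarray, ref_lag: float = 0.02) -> float:
    """First lag at which VE falls to half its value at the reference lag.

    Linear interpolation between grid points; ``inf`` if the curve never
    reaches half within the lag range; ``nan`` (undefined) if the reference
    VE is not positive.
    """
    lags = np.asarray(lags, dtype=float)
    ve = np.asarray(ve, dtype=float)
    i0 = int(np.argmin(np.abs(lags - ref_lag)))
    v0 = ve[i0]
    if not v0 > 0:
        return float("nan")
    half = 0.5 * v0
    below = np.flatnonzero(ve[i0:] <= half) + i0
    if len(below) == 0:
        return float("inf")
    j = below[0]
    if j == i0:
        return float(lags[i0])
    x0, x1 = lags[j - 1], lags[j]
    y0, y1 = ve[j - 1], ve[j]
    if y0 == y1:
        return float(x1)
    return float(x0 + (y0 - half) / (y0 - y1) * (x1 - x0))
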