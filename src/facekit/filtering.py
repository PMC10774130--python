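"""Post-hoc quality control of keypoint traces.

Three passes, mirroring how occluded or mistracked keypoints show up in
practice (e.g. during grooming): (1) frames where the tracker confidence
drops far below its slow baseline, (2) frames where the keypoint jumps or
deviates from its local median, and (3) imputation of the flagged frames
from the median-filtered trace.

Thresholds follow the defaults used for neural prediction: the likelihood is
baselined with a 4 s Gaussian filter and frames more than 8 standard
deviations below baseline are outliers; a jump or deviation of more than
25 px flags a frame; imputation median-filters with a 300 ms window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d, median_filter

from .io_core import KeypointSeries, logger


@dataclass
class FilterConfig:
    baseline_sigma: float = 4.0  # s, Gaussian baseline of the likelihood trace
    likelihood_threshold_sd: float = -8.0  # multiplier on sd of baselined likelihood
    jump_px: float = 25.0  # Euclidean single-frame step threshold
    deviation_px: float = 25.0  # per-axis deviation from the 1 s median
    deviation_window: float = 1.0  # s
    impute_window: float = 0.3  # s, median window used for imputation

    def __post_init__(self):
        if self.baseline_sigma <= 0 or self.deviation_window <= 0 or self.impute_window <= 0:
            raise ValueError("all windows must be > 0")
        if self.jump_px <= 0 or self.deviation_px <= 0:
            raise ValueError("jump/deviation thresholds must be > 0")


def _odd_window(seconds: float, rate: float) -> int:
    """Window length in frames, rounded to the nearest odd count (>= 1)."""
    w = int(round(seconds * rate))
    if w % 2 == 0:
        w += 1
    return max(w, 1)


def likelihood_outliers(series: KeypointSeries, config: FilterConfig | None = None) -> np.ndarray:
    """Frames whose likelihood drops far below its slow Gaussian baseline.

    Per bodypart: baseline = Gaussian filter of the likelihood trace
    (sigma = ``baseline_sigma`` seconds, reflective edges); residual =
    likelihood - baseline; a frame is an outlier when the residual is below
    ``likelihood_threshold_sd`` times the residual's standard deviation
    (computed per bodypart over all frames).
    """
    config = config or FilterConfig()
    sigma_frames = config.baseline_sigma * series.rate
    if series.n_frames < sigma_frames:
        raise ValueError(
            f"series of {series.n_frames} frames is shorter than one baseline sigma "
            f"({sigma_frames:.0f} frames)"
        )
    like = series.likelihood
    baseline = gaussian_filter1d(like, sigma=sigma_frames, axis=0, mode="reflect")
    resid = like - baseline
    sd = resid.std(axis=0)
    mask = resid < config.likelihood_threshold_sd * sd
    # zero-residual traces (constant likelihood) can never be outliers
    mask[:, sd == 0] = False
    return mask


def trace_outliers(series: KeypointSeries, config: FilterConfig | None = None) -> np.ndarray:
    """Frames where a keypoint jumps or deviates from its local median.

    Jump rule: frame ``t`` is flagged when the Euclidean (x, y) step from
    frame ``t - 1`` exceeds ``jump_px`` *and* the keypoint has not simply
    returned to where it was at ``t - 2`` — the extra condition stops the
    recovery frame after a single-frame glitch from being flagged, while a
    step change that persists still flags its transition frame.

    Deviation rule: frame ``t`` is flagged when either coordinate deviates
    from its ``deviation_window`` running median by more than
    ``deviation_px``.
    """
    config = config or FilterConfig()
    coords = series.coords
    T = series.n_frames
    mask = np.zeros((T, coords.shape[1]), dtype=bool)
    if T < 2:
        return mask
    step = np.linalg.norm(np.diff(coords, axis=0), axis=2)  # (T-1, K): step into frame t
    jump = np.zeros_like(mask)
    jump[1:] = step > config.jump_px
    if T >= 3:
        disp2 = np.linalg.norm(coords[2:] - coords[:-2], axis=2)  # t vs t-2
        jump[2:] &= disp2 > config.jump_px
    win = _odd_window(config.deviation_window, series.rate)
    med = median_filter(coords, size=(win, 1, 1), mode="nearest")
    dev = (np.abs(coords - med) > config.deviation_px).any(axis=2)
    return jump | dev


def impute(
    series: KeypointSeries,
    outlier_mask: np.ndarray,
    config: FilterConfig | None = None,
) -> KeypointSeries:
    """Replace flagged frames by values from the median-filtered trace.

    Flagged values are first bridged by linear interpolation between the
    neighbouring unflagged samples, the bridged trace is median-filtered with
    a ``impute_window`` window, and the flagged frames take the filtered
    values.  Unflagged samples are never modified.

    Raises
    ------
    ValueError
        If every frame of some bodypart is flagged (nothing to interpolate
        from), naming the bodypart.
    """
    config = config or FilterConfig()
    outlier_mask = np.asarray(outlier_mask, dtype=bool)
    out = series.copy()
    T, K, _ = out.coords.shape
    win = _odd_window(config.impute_window, series.rate)
    t = np.arange(T)
    n_flagged = 0
    for k in range(K):
        m = outlier_mask[:, k]
        if not m.any():
            continue
        if m.all():
            raise ValueError(f"all frames flagged for bodypart {series.schema.names[k]!r}")
        n_flagged += int(m.sum())
        for ax in range(2):
            trace = out.coords[:, k, ax]
            bridged = trace.copy()
            bridged[m] = np.interp(t[m], t[~m], trace[~m])
            med = median_filter(bridged, size=win, mode="nearest")
            trace[m] = med[m]
    frac = n_flagged / max(T * K, 1)
    logger.info("impute: replaced %d samples (%.3f%% of timepoints)", n_flagged, 100 * frac)
    out.outlier_mask = series.outlier_mask | outlier_mask
    return out


def filter_series(
    series: KeypointSeries, config: FilterConfig | None = None
) -> tuple[KeypointSeries, dict]:
    """Full QC pass: detect likelihood + trace outliers, impute, report counts."""
    config = config or FilterConfig()
    lmask = likelihood_outliers(series, config)
    tmask = trace_outliers(series, config)
    mask = lmask | tmask
    filtered = impute(series, mask, config)
    report = {
        "likelihood_flags": lmask.sum(axis=0).tolist(),
        "trace_flags": tmask.sum(axis=0).tolist(),
        "total_flagged_fraction": float(mask.mean()),
    }
    logger.info(
        "filter: flagged %.3f%% of timepoints (likelihood %.3f%%, trace %.3f%%)",
        100 * mask.mean(), 100 * lmask.mean(), 100 * tmask.mean(),
    )
    return filtered, report
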