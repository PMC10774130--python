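"""Core data model, file I/O, configuration and the shared train/test split.

Coordinate convention used throughout the package: coordinates are 0-based
pixel centers with ``x`` = column and ``y`` = row, origin at the top-left of
the image.  Keypoint files come in two dialects: a long CSV with columns
``frame,bodypart,x,y,likelihood`` (one row per frame x bodypart) and an HDF5
layout mirroring the in-memory arrays under ``/coords``, ``/likelihood``,
``/names``.  Neural recordings are NPZ or HDF5 with keys ``activity``,
``positions``, ``rate``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("facekit")

_LOG_FORMAT = "%(asctime)s %(levelname)s %(name)s: %(message)s"
_DATE_FORMAT = "%Y-%m-%dT%H:%M:%S"


def setup_logging(level: int = logging.INFO, path: str | None = None) -> None:
    """Configure plain-text logging with ISO-8601 timestamps.

    Parameters
    ----------
    level : int
        Logging level for the package logger.
    path : str, optional
        When given, messages are also appended to this file.
    """
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if path is not None:
        handlers.append(logging.FileHandler(path))
    fmt = logging.Formatter(_LOG_FORMAT, datefmt=_DATE_FORMAT)
    logger.setLevel(level)
    logger.handlers.clear()
    for h in handlers:
        h.setFormatter(fmt)
        logger.addHandler(h)


def load_config(path: str) -> dict:
    """Load a YAML configuration file into a plain dict."""
    with open(path) as f:
        cfg = yaml.safe_load(f)
    return cfg if cfg is not None else {}


def save_config(cfg: dict, path: str) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(cfg, f, sort_keys=False)


# ---------------------------------------------------------------------------
# Keypoint schema
# ---------------------------------------------------------------------------

#: bodyparts of the default 13-point schema, grouped by facial region
_DEFAULT_PARTS: list[tuple[str, str]] = [
    ("eye(bottom)", "eye"),
    ("eye(top)", "eye"),
    ("eye(front)", "eye"),
    ("eye(back)", "eye"),
    ("mouth", "mouth"),
    ("lowerlip", "mouth"),
    ("nose(bottom)", "nose"),
    ("nose(top)", "nose"),
    ("nose(tip)", "nose"),
    ("nose(r)", "nose"),
    ("whisker(I)", "whisker"),
    ("whisker(II)", "whisker"),
    ("whisker(III)", "whisker"),
]

#: extra bodyparts of the extended 15-point schema, excluded by default
_EXTENDED_PARTS: list[tuple[str, str]] = [
    ("paw", "paw"),
    ("nosebridge", "nose"),
]

VALID_GROUPS = frozenset({"eye", "nose", "whisker", "mouth", "paw", "other"})


@dataclass(frozen=True)
class KeypointSchema:
    """Named bodyparts, their facial-region groups, and the neural-prediction subset.

    The neural-prediction subset contains the eye (4), nose (4) and whisker (3)
    bodyparts — mouth keypoints are not visible from the side view used during
    neural recordings, so they are excluded from neural prediction.
    """

    names: tuple[str, ...]
    groups: dict[str, str] = field(hash=False)
    neural_subset: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate bodypart names in schema")
        for name in self.names:
            g = self.groups.get(name)
            if g not in VALID_GROUPS:
                raise ValueError(f"bodypart {name!r} has invalid group {g!r}")
        missing = [n for n in self.neural_subset if n not in self.names]
        if missing:
            raise ValueError(f"neural_subset entries not in schema: {missing}")

    @property
    def n_keypoints(self) -> int:
        return len(self.names)

    @property
    def n_neural_coords(self) -> int:
        """Number of (x, y) coordinates entering neural prediction."""
        return 2 * len(self.neural_subset)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def group_indices(self, group: str) -> np.ndarray:
        return np.array([i for i, n in enumerate(self.names) if self.groups[n] == group], dtype=int)

    def neural_indices(self) -> np.ndarray:
        return np.array([self.names.index(n) for n in self.neural_subset], dtype=int)


def default_schema(extended: bool = False) -> KeypointSchema:
    """The default 13-bodypart orofacial schema (eye 4, mouth 2, nose 4, whisker 3).

    With ``extended=True`` the 15-point schema adds the paw and nose-bridge
    keypoints; both remain excluded from the neural-prediction subset.
    """
    parts = list(_DEFAULT_PARTS) + (list(_EXTENDED_PARTS) if extended else [])
    names = tuple(p for p, _ in parts)
    groups = {p: g for p, g in parts}
    neural = tuple(
        p for p, g in parts if g in ("eye", "nose", "whisker") and p != "nosebridge"
    )
    return KeypointSchema(names=names, groups=groups, neural_subset=neural)


def schema_from_names(names, groups: dict[str, str] | None = None) -> KeypointSchema:
    """Build a schema for an arbitrary bodypart list; unknown parts get group 'other'."""
    default = default_schema(extended=True)
    groups = dict(groups or {})
    for n in names:
        if n not in groups:
            groups[n] = default.groups.get(n, "other")
    neural = tuple(n for n in names if n in default.neural_subset)
    return KeypointSchema(names=tuple(names), groups=groups, neural_subset=neural)


# ---------------------------------------------------------------------------
# Keypoint series
# ---------------------------------------------------------------------------


@dataclass
class KeypointSeries:
    """Per-frame (x, y, likelihood) traces for a keypoint schema.

    Attributes
    ----------
    schema : KeypointSchema
    coords : (T, K, 2) float array, full-image pixels (x, y)
    likelihood : (T, K) float array in [0, 1]
    rate : float
        Frame rate in Hz (constant).
    outlier_mask : (T, K) bool array, True where a sample is flagged.
    """

    schema: KeypointSchema
    coords: np.ndarray
    likelihood: np.ndarray
    rate: float
    outlier_mask: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 2:
            raise ValueError(f"coords must be (T, K, 2), got {self.coords.shape}")
        if self.coords.shape[1] != self.schema.n_keypoints:
            raise ValueError("coords second axis must match schema size")
        if self.likelihood is None:
            self.likelihood = np.ones(self.coords.shape[:2])
        self.likelihood = np.asarray(self.likelihood, dtype=float)
        if self.likelihood.shape != self.coords.shape[:2]:
            raise ValueError("likelihood must be (T, K)")
        finite = self.likelihood[np.isfinite(self.likelihood)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("likelihood values must lie in [0, 1]")
        if not self.rate > 0:
            raise ValueError("sampling rate must be > 0")
        if self.outlier_mask is None:
            self.outlier_mask = np.zeros(self.coords.shape[:2], dtype=bool)
        self.outlier_mask = np.asarray(self.outlier_mask, dtype=bool)
        bad = ~np.isfinite(self.coords).all(axis=2) & ~self.outlier_mask
        if bad.any():
            # non-finite coords are only legal where flagged; auto-flag NaN labels
            self.outlier_mask = self.outlier_mask | bad

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def t(self) -> np.ndarray:
        """Frame times in seconds."""
        return np.arange(self.n_frames) / self.rate

    def neural_coords(self) -> np.ndarray:
        """(T, 2 * n_subset) coordinate matrix for the neural-prediction subset."""
        idx = self.schema.neural_indices()
        return self.coords[:, idx, :].reshape(self.n_frames, -1)

    def copy(self) -> "KeypointSeries":
        return replace(
            self,
            coords=self.coords.copy(),
            likelihood=self.likelihood.copy(),
            outlier_mask=self.outlier_mask.copy(),
        )


def read_keypoints(path: str, dialect: str | None = None, rate: float = 50.0) -> KeypointSeries:
    """Read a keypoint file in the long-CSV or HDF5 dialect.

    The dialect is inferred from the file extension when not given.  The schema
    is inferred from the bodypart column; bodyparts outside the default schema
    are preserved with group ``"other"``.

    Raises
    ------
    ValueError
        On malformed rows (naming the line), duplicate (frame, bodypart) pairs,
        or likelihoods outside [0, 1].
    """
    if dialect is None:
        dialect = "hdf5" if str(path).endswith((".h5", ".hdf5")) else "long-csv"
    if dialect == "long-csv":
        return _read_keypoints_csv(path, rate)
    if dialect == "hdf5":
        return _read_keypoints_h5(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_keypoints_csv(path: str, rate: float) -> KeypointSeries:
    df = pd.read_csv(path)
    required = ["frame", "bodypart", "x", "y", "likelihood"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    for col in ("frame", "x", "y", "likelihood"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            line = int(np.flatnonzero(bad.values)[0]) + 2  # header + 1-based
            raise ValueError(f"{path}: malformed value in column {col!r} at line {line}")
        df[col] = vals
    dup = df.duplicated(subset=["frame", "bodypart"])
    if dup.any():
        line = int(np.flatnonzero(dup.values)[0]) + 2
        raise ValueError(f"{path}: duplicate (frame, bodypart) at line {line}")
    names = list(dict.fromkeys(df["bodypart"]))  # first-appearance order
    frames = np.sort(df["frame"].unique().astype(int))
    n_t, n_k = len(frames), len(names)
    frame_pos = {f: i for i, f in enumerate(frames)}
    name_pos = {n: i for i, n in enumerate(names)}
    coords = np.full((n_t, n_k, 2), np.nan)
    like = np.zeros((n_t, n_k))
    ti = df["frame"].astype(int).map(frame_pos).values
    ki = df["bodypart"].map(name_pos).values
    coords[ti, ki, 0] = df["x"].values
    coords[ti, ki, 1] = df["y"].values
    like[ti, ki] = df["likelihood"].values
    return KeypointSeries(schema=schema_from_names(names), coords=coords, likelihood=like, rate=rate)


def _read_keypoints_h5(path: str) -> KeypointSeries:
    with h5py.File(path, "r") as f:
        coords = f["coords"][()]
        like = f["likelihood"][()]
        names = [n.decode() if isinstance(n, bytes) else str(n) for n in f["names"][()]]
        rate = float(f.attrs.get("rate", 50.0))
        mask = f["outlier_mask"][()] if "outlier_mask" in f else None
    return KeypointSeries(
        schema=schema_from_names(names), coords=coords, likelihood=like, rate=rate, outlier_mask=mask
    )


def write_keypoints(series: KeypointSeries, path: str, dialect: str | None = None) -> None:
    """Write a keypoint series in the long-CSV or HDF5 dialect (round-trip safe)."""
    if dialect is None:
        dialect = "hdf5" if str(path).endswith((".h5", ".hdf5")) else "long-csv"
    if dialect == "long-csv":
        t_idx, k_idx = np.meshgrid(
            np.arange(series.n_frames), np.arange(series.schema.n_keypoints), indexing="ij"
        )
        df = pd.DataFrame(
            {
                "frame": t_idx.ravel(),
                "bodypart": np.array(series.schema.names)[k_idx.ravel()],
                "x": series.coords[..., 0].ravel(),
                "y": series.coords[..., 1].ravel(),
                "likelihood": series.likelihood.ravel(),
            }
        )
        df.to_csv(path, index=False)
    elif dialect == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("coords", data=series.coords)
            f.create_dataset("likelihood", data=series.likelihood)
            f.create_dataset("names", data=np.array(series.schema.names, dtype="S"))
            f.create_dataset("outlier_mask", data=series.outlier_mask)
            f.attrs["rate"] = series.rate
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Neural recordings
# ---------------------------------------------------------------------------


@dataclass
class NeuralRecording:
    """Population activity (neurons x timepoints) with per-neuron 2-D positions.

    ``rate`` is the imaging frame rate in Hz (nominally 3 Hz, ~300 ms bins);
    ``positions`` are micrometres in the imaging plane.
    """

    activity: np.ndarray
    positions: np.ndarray
    rate: float = 3.0

    def __post_init__(self):
        self.activity = np.asarray(self.activity, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.activity.ndim != 2:
            raise ValueError("activity must be (neurons, timepoints)")
        if self.positions.shape != (self.activity.shape[0], 2):
            raise ValueError("positions must be (neurons, 2)")
        if not np.isfinite(self.positions).all():
            raise ValueError("positions must be finite")
        if not self.rate > 0:
            raise ValueError("rate must be > 0")

    @property
    def n_neurons(self) -> int:
        return self.activity.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.activity.shape[1]

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_timepoints) / self.rate

    def zscored(self) -> tuple[np.ndarray, np.ndarray]:
        """Z-score each neuron; returns (activity, keep_mask).

        Zero-variance neurons cannot be z-scored; they are flagged False in the
        mask and returned as zeros (they are excluded from variance-explained
        denominators downstream).
        """
        mu = self.activity.mean(axis=1, keepdims=True)
        sd = self.activity.std(axis=1, keepdims=True)
        keep = sd[:, 0] > 0
        safe = np.where(sd > 0, sd, 1.0)
        z = (self.activity - mu) / safe
        z[~keep] = 0.0
        if (~keep).any():
            logger.info("z-scoring: %d zero-variance neurons flagged", int((~keep).sum()))
        return z, keep


def read_neural(path: str) -> NeuralRecording:
    """Read a neural recording from NPZ or HDF5 (keys activity, positions, rate)."""
    if str(path).endswith(".npz"):
        with np.load(path) as d:
            return NeuralRecording(d["activity"], d["positions"], float(d["rate"]))
    with h5py.File(path, "r") as f:
        return NeuralRecording(f["activity"][()], f["positions"][()], float(f["rate"][()]))


def write_neural(rec: NeuralRecording, path: str) -> None:
    if str(path).endswith(".npz"):
        np.savez(path, activity=rec.activity, positions=rec.positions, rate=rec.rate)
    else:
        with h5py.File(path, "w") as f:
            f.create_dataset("activity", data=rec.activity)
            f.create_dataset("positions", data=rec.positions)
            f.create_dataset("rate", data=rec.rate)


# ---------------------------------------------------------------------------
# Train/test segmentation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SegmentSplit:
    """Contiguous-segment train/test split with a temporal guard gap.

    The recording is cut into ``n_segments`` equal contiguous blocks (remainder
    frames appended to the last block).  Within each block the first
    ``train_frac`` of frames (floor) is training data, the next
    ``ceil(gap * rate)`` frames are discarded to break temporal autocorrelation,
    and the remainder is test data.
    """

    n_segments: int
    train_frac: float
    gap: float
    rate: float
    train_idx: np.ndarray = field(hash=False)
    test_idx: np.ndarray = field(hash=False)
    segments: tuple[tuple[int, int], ...] = ()

    def train_segments(self) -> list[np.ndarray]:
        """Training indices of each segment, as contiguous index arrays."""
        out = []
        for s0, s1 in self.segments:
            seg = self.train_idx[(self.train_idx >= s0) & (self.train_idx < s1)]
            out.append(seg)
        return out


def make_split(
    n_timepoints: int,
    rate: float,
    n_segments: int = 10,
    train_frac: float = 0.75,
    gap: float = 3.0,
) -> SegmentSplit:
    """Segmented train/test split with a gap excluded between train and test.

    Raises
    ------
    ValueError
        If a segment is too short to contain train, gap and at least one test
        frame.
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    gap_frames = int(np.ceil(gap * rate))
    seg_len = n_timepoints // n_segments
    if seg_len < 2:
        raise ValueError(f"{n_timepoints} timepoints cannot form {n_segments} segments")
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    bounds: list[tuple[int, int]] = []
    for s in range(n_segments):
        start = s * seg_len
        end = (s + 1) * seg_len if s < n_segments - 1 else n_timepoints
        length = end - start
        n_train = int(np.floor(train_frac * length))
        n_test = length - n_train - gap_frames
        if n_train < 1 or n_test < 1:
            raise ValueError(
                f"segment {s} of length {length} cannot hold {n_train} train + "
                f"{gap_frames} gap frames and still have test frames"
            )
        train_idx.append(np.arange(start, start + n_train))
        test_idx.append(np.arange(start + n_train + gap_frames, end))
        bounds.append((start, end))
    return SegmentSplit(
        n_segments=n_segments,
        train_frac=train_frac,
        gap=gap,
        rate=rate,
        train_idx=np.concatenate(train_idx),
        test_idx=np.concatenate(test_idx),
        segments=tuple(bounds),
    )
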