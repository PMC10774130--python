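"""Heatmap-based orofacial keypoint tracker.

A U-Net-style convolutional network maps a normalized grayscale frame to,
per keypoint, (1) a downsampled heatmap whose per-cell sigmoid value is the
probability of the keypoint lying in that cell and (2) x/y location
refinement maps holding the full-resolution offset from each cell to the
keypoint, so sub-cell accuracy survives the downsampling.  Decoding takes
the heatmap argmax cell plus its refinement offset; the peak heatmap value
is the prediction likelihood.

Cell convention: heatmap cell (row r, col c) corresponds to full-image
pixel (x, y) = (c * downsample_factor, r * downsample_factor); refinement
offsets are in full-image pixels relative to that point.

Training minimizes binary cross-entropy between the heatmaps and unit-peak
Gaussian targets plus a smooth-L1 penalty on the refinement maps within a
radius of the target cell; keypoints labeled NaN (not visible) are masked
out of both terms.  Augmentations: random crop + resize, horizontal flip
(only when a left/right flip-pair map is provided) and contrast gain.
Fine-tuning reruns the same loop from a trained network with a lower
learning rate and nonzero weight decay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from . import nn
from .io_core import KeypointSchema, KeypointSeries, logger


@dataclass
class TrackerConfig:
    input_size: int = 256
    downsample_factor: int = 4
    n_keypoints: int = 13
    channels: tuple[int, ...] = (16, 32, 64, 128)  # encoder widths, shallowest first
    heatmap_sigma: float = 2.0  # cells
    refine_radius: float = 4.0  # cells within which the refinement loss applies
    # base training
    lr: float = 4e-4
    epochs: int = 36
    batch_size: int = 8
    weight_decay: float = 0.0
    schedule: tuple[int, int, int] = (30, 3, 3)  # epochs at LR, LR/10, LR/25
    # fine-tuning
    finetune_lr: float = 1e-4
    finetune_epochs: int = 36
    finetune_weight_decay: float = 1e-3
    # augmentation
    crop_scale: tuple[float, float] = (0.8, 1.0)
    contrast_gain: tuple[float, float] = (0.7, 1.3)
    flip_prob: float = 0.5

    def __post_init__(self):
        if self.input_size % self.downsample_factor:
            raise ValueError("input_size must be divisible by downsample_factor")
        n_pool = int(np.log2(self.downsample_factor))
        if 2**n_pool != self.downsample_factor:
            raise ValueError("downsample_factor must be a power of 2")
        if sum(self.schedule) != self.epochs:
            raise ValueError("schedule epochs must sum to total epochs")

    @property
    def grid_size(self) -> int:
        return self.input_size // self.downsample_factor


def desk_config(n_keypoints: int = 3, input_size: int = 128) -> TrackerConfig:
    """Reduced-width profile for CPU-scale synthetic experiments."""
    return TrackerConfig(
        input_size=input_size, n_keypoints=n_keypoints, channels=(8, 16, 32, 48)
    )


@dataclass
class HeatmapBundle:
    """Per-keypoint probability heatmaps and x/y refinement maps (downsampled grid)."""

    heatmaps: np.ndarray  # (K, h, w) in [0, 1]
    refine_x: np.ndarray  # (K, h, w), full-image px offsets
    refine_y: np.ndarray
    mask: np.ndarray | None = None  # (K,) False where the keypoint is unlabeled

    def __post_init__(self):
        if self.heatmaps.min() < 0 or self.heatmaps.max() > 1:
            raise ValueError("heatmap values must lie in [0, 1]")
        if self.mask is None:
            self.mask = np.ones(self.heatmaps.shape[0], dtype=bool)


@dataclass
class Prediction:
    coords: np.ndarray  # (K, 2) full-image (x, y)
    likelihood: np.ndarray  # (K,) peak heatmap values
    degenerate: np.ndarray | None = None  # (K,) True where the heatmap was all zero


# ---------------------------------------------------------------------------
# Frame normalization and targets
# ---------------------------------------------------------------------------


def normalize_frame(image: np.ndarray) -> np.ndarray:
    """Map the 1st intensity percentile to 0.0 and the 99th to 1.0 (no clipping)."""
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("empty image")
    p1, p99 = np.percentile(image, [1, 99])
    if p99 <= p1:
        return np.zeros_like(image)
    return (image - p1) / (p99 - p1)


def make_targets(coords: np.ndarray, config: TrackerConfig) -> HeatmapBundle:
    """Training targets for one frame.

    Per keypoint: a unit-peak Gaussian bump (sd ``heatmap_sigma`` cells) at
    the keypoint's cell position ``coords / downsample_factor``, and
    refinement maps holding the full-image offset from each cell's pixel to
    the keypoint.  NaN coords produce an all-masked keypoint.
    """
    df = config.downsample_factor
    g = config.grid_size
    K = len(coords)
    rr, cc = np.mgrid[0:g, 0:g].astype(float)
    heat = np.zeros((K, g, g))
    rx = np.zeros((K, g, g))
    ry = np.zeros((K, g, g))
    mask = np.ones(K, dtype=bool)
    for k in range(K):
        x, y = coords[k]
        if not (np.isfinite(x) and np.isfinite(y)):
            mask[k] = False
            continue
        u, v = x / df, y / df  # cell-space position
        heat[k] = np.exp(-((cc - u) ** 2 + (rr - v) ** 2) / (2 * config.heatmap_sigma**2))
        rx[k] = x - cc * df
        ry[k] = y - rr * df
    return HeatmapBundle(heatmaps=heat, refine_x=rx, refine_y=ry, mask=mask)


def decode(bundle: HeatmapBundle, config: TrackerConfig) -> Prediction:
    """Subpixel decoding: argmax cell plus its refinement offset.

    Ties at the maximum resolve to the first cell in row-major order.  An
    all-zero heatmap yields likelihood 0 with coords at the image center,
    flagged in ``degenerate``.
    """
    df = config.downsample_factor
    K, h, w = bundle.heatmaps.shape
    coords = np.empty((K, 2))
    like = np.empty(K)
    degenerate = np.zeros(K, dtype=bool)
    center = (config.input_size - 1) / 2.0
    for k in range(K):
        hm = bundle.heatmaps[k]
        flat = int(np.argmax(hm))  # first max in row-major order
        r, c = divmod(flat, w)
        like[k] = hm[r, c]
        if like[k] == 0:
            coords[k] = (center, center)
            degenerate[k] = True
            continue
        coords[k, 0] = c * df + bundle.refine_x[k, r, c]
        coords[k, 1] = r * df + bundle.refine_y[k, r, c]
    return Prediction(coords=coords, likelihood=like, degenerate=degenerate)


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------


class TrackerNet:
    """U-Net: downsampling conv blocks with skip connections back up to the
    heatmap grid; two output heads (heatmap logits, refinement maps)."""

    def __init__(self, config: TrackerConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        ch = config.channels
        n_pool = int(np.log2(config.downsample_factor))
        if len(ch) < n_pool + 2:
            raise ValueError("need at least n_pool + 2 channel widths")
        self.n_pool = n_pool
        K = config.n_keypoints

        def conv_p(cin, cout, ksz=3):
            # float32: halves memory traffic in the conv-heavy training loop
            return (
                nn.parameter(rng, (cout, cin, ksz, ksz), dtype=np.float32),
                nn.zeros_parameter((cout,), dtype=np.float32),
            )

        # encoder: stem at full res, then one conv per pooling level (down to
        # grid), then one extra pooled bottleneck level
        self.enc = []
        cin = 1
        for lvl in range(n_pool + 2):
            cout = ch[min(lvl, len(ch) - 1)]
            self.enc.append(conv_p(cin, cout))
            cin = cout
        # decoder: upsample bottleneck back to the grid level with skip
        skip_ch = ch[min(n_pool, len(ch) - 1)]
        self.dec = conv_p(cin + skip_ch, skip_ch)
        self.head_heat = conv_p(skip_ch, K, ksz=1)
        self.head_ref = conv_p(skip_ch, 2 * K, ksz=1)

    @property
    def params(self):
        ps = []
        for w, b in self.enc + [self.dec, self.head_heat, self.head_ref]:
            ps += [w, b]
        return ps

    @property
    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.params))

    def forward(self, x: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor]:
        """(B, 1, H, W) -> heatmap logits (B, K, h, w), refinement (B, 2K, h, w)."""
        h = x
        feats = []
        for lvl, (w, b) in enumerate(self.enc):
            if lvl > 0:
                h = nn.maxpool2(h)
            h = nn.conv2d(h, w, b).relu()
            feats.append(h)
        skip = feats[self.n_pool]  # grid-resolution features
        h = nn.upsample2(h)
        h = nn.concat_channels(h, skip)
        h = nn.conv2d(h, self.dec[0], self.dec[1]).relu()
        heat = nn.conv2d(h, self.head_heat[0], self.head_heat[1])
        ref = nn.conv2d(h, self.head_ref[0], self.head_ref[1])
        return heat, ref

    def predict_bundle(self, frame: np.ndarray) -> HeatmapBundle:
        """Normalized frame -> HeatmapBundle (sigmoid heatmaps)."""
        x = nn.Tensor(np.asarray(frame, dtype=np.float32)[None, None])
        heat, ref = self.forward(x)
        K = self.config.n_keypoints
        hm = 1.0 / (1.0 + np.exp(-heat.data[0]))
        return HeatmapBundle(
            heatmaps=hm, refine_x=ref.data[0, :K], refine_y=ref.data[0, K:]
        )

    def predict(self, frames: np.ndarray, normalized: bool = False) -> list[Prediction]:
        out = []
        for f in frames:
            if not normalized:
                f = normalize_frame(f)
            out.append(decode(self.predict_bundle(f), self.config))
        return out

    def state_dict(self) -> dict:
        return {f"p{i}": p.data for i, p in enumerate(self.params)}

    def load_state_dict(self, d: dict) -> None:
        for i, p in enumerate(self.params):
            p.data = np.array(d[f"p{i}"], dtype=p.data.dtype)

    def copy(self) -> "TrackerNet":
        other = TrackerNet(self.config)
        other.load_state_dict(self.state_dict())
        return other


def build_network(config: TrackerConfig, seed: int = 0) -> TrackerNet:
    """Construct the tracker network; logs the parameter count."""
    net = TrackerNet(config, seed=seed)
    logger.info("tracker network: %d parameters", net.n_parameters)
    return net


def save_checkpoint(net: TrackerNet, path: str, schema: KeypointSchema | None = None) -> None:
    """Single-file checkpoint embedding the weights, config and schema."""
    cfg = net.config
    meta = dict(
        input_size=cfg.input_size, downsample_factor=cfg.downsample_factor,
        n_keypoints=cfg.n_keypoints, channels=np.array(cfg.channels),
        heatmap_sigma=cfg.heatmap_sigma,
    )
    names = np.array(schema.names, dtype="S") if schema is not None else np.array([], dtype="S")
    np.savez(path, **net.state_dict(), __names=names, **{f"__{k}": v for k, v in meta.items()})


def load_checkpoint(path: str) -> TrackerNet:
    with np.load(path) as d:
        cfg = TrackerConfig(
            input_size=int(d["__input_size"]),
            downsample_factor=int(d["__downsample_factor"]),
            n_keypoints=int(d["__n_keypoints"]),
            channels=tuple(int(c) for c in d["__channels"]),
            heatmap_sigma=float(d["__heatmap_sigma"]),
        )
        net = TrackerNet(cfg)
        net.load_state_dict({k: d[k] for k in d.files if not k.startswith("__")})
    return net


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def _augment(frame, coords, config: TrackerConfig, rng, flip_pairs=None):
    """Random crop + resize, optional horizontal flip, contrast gain."""
    H = config.input_size
    s = rng.uniform(*config.crop_scale)
    crop = max(int(round(s * H)), config.downsample_factor)
    ox = rng.integers(0, H - crop + 1)
    oy = rng.integers(0, H - crop + 1)
    frame = frame[oy : oy + crop, ox : ox + crop]
    frame = _sk_resize(frame, (H, H), order=1, anti_aliasing=False, preserve_range=True)
    scale = H / crop
    coords = (coords - np.array([ox, oy])) * scale
    out = np.isfinite(coords).all(axis=1) & (
        (coords < 0).any(axis=1) | (coords > H - 1).any(axis=1)
    )
    coords = coords.copy()
    coords[out] = np.nan  # cropped-out keypoints become unlabeled
    if flip_pairs is not None and rng.random() < config.flip_prob:
        frame = frame[:, ::-1].copy()
        coords = coords.copy()
        coords[:, 0] = H - 1 - coords[:, 0]
        perm = np.arange(len(coords))
        for a, b in flip_pairs:
            perm[a], perm[b] = perm[b], perm[a]
        coords = coords[perm]
    gain = rng.uniform(*config.contrast_gain)
    m = frame.mean()
    frame = (frame - m) * gain + m
    return frame, coords


def _loss_for_batch(net: TrackerNet, frames, coords_list, config: TrackerConfig):
    K = config.n_keypoints
    g = config.grid_size
    x = nn.Tensor(np.stack(frames).astype(np.float32)[:, None])
    heat_logits, ref = net.forward(x)
    theat = np.zeros((len(frames), K, g, g), dtype=np.float32)
    tref = np.zeros((len(frames), 2 * K, g, g), dtype=np.float32)
    hmask = np.zeros((len(frames), K, g, g), dtype=np.float32)
    rmask = np.zeros((len(frames), 2 * K, g, g), dtype=np.float32)
    rr, cc = np.mgrid[0:g, 0:g].astype(float)
    for b, coords in enumerate(coords_list):
        bundle = make_targets(coords, config)
        theat[b] = bundle.heatmaps
        tref[b, :K] = bundle.refine_x
        tref[b, K:] = bundle.refine_y
        hmask[b] = bundle.mask[:, None, None]
        for k in range(K):
            if not bundle.mask[k]:
                continue
            u, v = coords[k, 0] / config.downsample_factor, coords[k, 1] / config.downsample_factor
            near = ((cc - u) ** 2 + (rr - v) ** 2) <= config.refine_radius**2
            rmask[b, k] = near
            rmask[b, K + k] = near
    lh = nn.bce_with_logits(heat_logits, theat, hmask)
    lr_ = nn.smooth_l1(ref, tref, rmask, beta=float(config.downsample_factor))
    return nn.add_scaled(lh, lr_, 0.05)


def train(
    net: TrackerNet,
    frames: np.ndarray,
    coords: np.ndarray,
    config: TrackerConfig | None = None,
    seed: int = 0,
    lr: float | None = None,
    weight_decay: float | None = None,
    epochs: int | None = None,
    flip_pairs: list[tuple[int, int]] | None = None,
    normalized: bool = False,
) -> np.ndarray:
    """Train (in place) on labeled frames; returns the per-epoch loss history.

    The learning-rate schedule holds the base LR for the first block of
    epochs, then LR/10, then LR/25 (block lengths scaled to the actual epoch
    count).  Missing keypoints (NaN) are masked from the loss; horizontal
    flips are applied only when ``flip_pairs`` maps left/right-symmetric
    bodyparts.  Deterministic given ``seed``.
    """
    config = config or net.config
    frames = np.asarray(frames, dtype=float)
    coords = np.asarray(coords, dtype=float)
    if len(frames) < 1:
        raise ValueError("need at least one labeled frame")
    if not np.isfinite(coords).any():
        raise ValueError("no visible keypoints in the training set")
    if not normalized:
        frames = np.stack([normalize_frame(f) for f in frames])
    lr = config.lr if lr is None else lr
    weight_decay = config.weight_decay if weight_decay is None else weight_decay
    epochs = config.epochs if epochs is None else epochs
    rng = np.random.default_rng(seed)
    opt = nn.Adam(net.params, lr=lr, weight_decay=weight_decay)
    # schedule blocks proportional to the configured (30, 3, 3) split
    s = np.array(config.schedule, dtype=float) / sum(config.schedule)
    b1 = int(round(s[0] * epochs))
    b2 = int(round((s[0] + s[1]) * epochs))
    losses = np.empty(epochs)
    n = len(frames)
    for ep in range(epochs):
        if ep == b1:
            opt.lr = lr / 10
        elif ep == b2:
            opt.lr = lr / 25
        order = rng.permutation(n)
        ep_loss, n_batches = 0.0, 0
        for i in range(0, n, config.batch_size):
            idx = order[i : i + config.batch_size]
            fs, cs = [], []
            for j in idx:
                f, c = _augment(frames[j], coords[j], config, rng, flip_pairs)
                fs.append(f)
                cs.append(c)
            loss = _loss_for_batch(net, fs, cs, config)
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_loss += loss.data
            n_batches += 1
        losses[ep] = ep_loss / n_batches
    return losses


def finetune(
    base: TrackerNet,
    frames: np.ndarray,
    coords: np.ndarray,
    config: TrackerConfig | None = None,
    seed: int = 0,
    epochs: int | None = None,
    **kwargs,
) -> TrackerNet:
    """Fine-tune a copy of ``base`` on refined frames (LR 1e-4, decay 1e-3).

    With zero frames the base network is returned unchanged.
    """
    config = config or base.config
    if len(frames) == 0:
        return base
    net = base.copy()
    train(
        net, frames, coords, config, seed=seed,
        lr=config.finetune_lr, weight_decay=config.finetune_weight_decay,
        epochs=config.finetune_epochs if epochs is None else epochs, **kwargs,
    )
    return net


def finetune_curve(
    base: TrackerNet,
    frames: np.ndarray,
    coords: np.ndarray,
    eval_frames: np.ndarray,
    eval_coords: np.ndarray,
    n_frames_list=(0, 1, 5, 10, 25, 50),
    config: TrackerConfig | None = None,
    seed: int = 0,
    epochs: int | None = None,
) -> dict[int, float]:
    """Mean pixel error on an eval set vs number of fine-tuning frames."""
    out = {}
    for nf in n_frames_list:
        if nf > len(frames):
            break
        net = finetune(base, frames[:nf], coords[:nf], config, seed=seed, epochs=epochs)
        preds = np.stack([p.coords for p in net.predict(eval_frames)])
        out[nf] = evaluate(preds, eval_coords)["mean"]
    return out


def evaluate(pred_coords: np.ndarray, gt_coords: np.ndarray,
             schema: KeypointSchema | None = None) -> dict:
    """Euclidean pixel error per keypoint, overall, and per facial group.

    NaN ground-truth labels are skipped; raises if no labels are present.
    """
    pred = np.asarray(pred_coords, dtype=float)
    gt = np.asarray(gt_coords, dtype=float)
    if pred.shape != gt.shape:
        raise ValueError("prediction/ground-truth shape mismatch")
    err = np.linalg.norm(pred - gt, axis=-1)  # (frames, K)
    present = np.isfinite(gt).all(axis=-1)
    if not present.any():
        raise ValueError("no present ground-truth labels")
    err = np.where(present, err, np.nan)
    per_kp = np.nanmean(err, axis=0)
    out = {"per_keypoint": per_kp, "mean": float(np.nanmean(err))}
    if schema is not None:
        out["per_group"] = {
            g: float(np.nanmean(per_kp[schema.group_indices(g)]))
            for g in ("eye", "mouth", "nose", "whisker")
            if len(schema.group_indices(g))
        }
    return out


def track(net: TrackerNet, frames: np.ndarray, rate: float = 50.0,
          schema: KeypointSchema | None = None) -> KeypointSeries:
    """Run the tracker over a frame stack, returning a KeypointSeries."""
    preds = net.predict(frames)
    coords = np.stack([p.coords for p in preds])
    like = np.stack([np.clip(p.likelihood, 0, 1) for p in preds])
    if schema is None:
        from .io_core import schema_from_names

        schema = schema_from_names([f"kp{i}" for i in range(net.config.n_keypoints)])
    return KeypointSeries(schema=schema, coords=coords, likelihood=like, rate=rate)
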