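"""Synthetic fixtures with known ground truth for every analysis module.

Four generators define the study conditions used throughout the test suite:

* blob-rendered grayscale face frames with exactly known keypoint positions,
* multi-timescale keypoint dynamics (fast pseudo-random ~10 Hz whisking,
  fast-OU nose motion with tau ~ 0.5 s, slow-OU eye motion with tau ~ 5 s),
* neural populations driven by a known nonlinear function of the keypoints
  plus shared low-rank non-behavioral structure and independent noise,
* feature sequences sampled from a discrete HMM with known parameters.

All dynamics are Ornstein-Uhlenbeck (OU) processes — mean-reverting with
autocorrelation exp(-lag / tau) — so every fixture has a closed-form
statistic to test against.  Every generator is deterministic per seed and
emits both the data and its ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_core import KeypointSchema, KeypointSeries, NeuralRecording, schema_from_names
from .statehmm import HmmModel, simulate as hmm_simulate

#: default group timescales in seconds, mirroring slow eye drift vs fast nose motion
DEFAULT_TAUS = {"eye": 5.0, "nose": 0.5, "whisker": 0.3, "mouth": 1.0, "paw": 1.0, "other": 1.0}
WHISK_FREQ_HZ = 10.0


def ou_process(T: int, tau: float, rate: float, rng: np.random.Generator,
               sd: float = 1.0) -> np.ndarray:
    """Stationary OU samples: x_{t+1} = a x_t + sd*sqrt(1-a^2) eps, a = exp(-1/(tau*rate))."""
    from scipy.signal import lfilter

    a = np.exp(-1.0 / (tau * rate))
    x0 = rng.normal(0, sd)
    if T == 1:
        return np.array([x0])
    drive = rng.normal(0, sd * np.sqrt(1 - a**2), size=T - 1)
    rest, _ = lfilter([1.0], [1.0, -a], drive, zi=np.array([a * x0]))
    return np.concatenate([[x0], rest])


def whisk_trace(T: int, rate: float, rng: np.random.Generator, amp_sd: float = 1.0,
                freq: float = WHISK_FREQ_HZ, phase_tau: float = 0.5) -> np.ndarray:
    """Pseudo-random ~10 Hz whisking: sinusoid with OU phase noise and OU envelope."""
    phase = 2 * np.pi * freq * np.arange(T) / rate + 1.5 * ou_process(T, phase_tau, rate, rng)
    envelope = 1.0 + 0.4 * ou_process(T, 2.0, rate, rng)
    return amp_sd * envelope * np.sin(phase)


# ---------------------------------------------------------------------------
# Keypoint traces (no video)
# ---------------------------------------------------------------------------


def make_keypoint_traces(
    T: int,
    rate: float = 50.0,
    seed: int = 0,
    schema: KeypointSchema | None = None,
    taus: dict[str, float] | None = None,
    amplitude_px: float = 6.0,
    whisker_oscillation: bool = True,
    center: tuple[float, float] = (128.0, 128.0),
) -> KeypointSeries:
    """OU keypoint traces with group-specific timescales around fixed base positions."""
    if schema is None:
        from .io_core import default_schema

        schema = default_schema()
    taus = {**DEFAULT_TAUS, **(taus or {})}
    rng = np.random.default_rng(seed)
    K = schema.n_keypoints
    base = np.column_stack(
        [
            center[0] + 60 * np.cos(2 * np.pi * np.arange(K) / K),
            center[1] + 60 * np.sin(2 * np.pi * np.arange(K) / K),
        ]
    )
    coords = np.empty((T, K, 2))
    for k, name in enumerate(schema.names):
        g = schema.groups[name]
        tau = taus.get(g, 1.0)
        for ax in range(2):
            if g == "whisker" and whisker_oscillation:
                # whisking spans fewer px per 20 ms frame than drift artifacts
                tr = whisk_trace(T, rate, rng, amp_sd=0.6 * amplitude_px)
            else:
                tr = ou_process(T, tau, rate, rng, sd=amplitude_px)
            coords[:, k, ax] = base[k, ax] + tr
    like = np.clip(0.98 + 0.005 * rng.standard_normal((T, K)), 0, 1)
    return KeypointSeries(schema=schema, coords=coords, likelihood=like, rate=rate)


# ---------------------------------------------------------------------------
# Face videos
# ---------------------------------------------------------------------------


@dataclass
class FaceSceneSpec:
    """Blob-rendered toy face scene.

    Each keypoint is drawn as a Gaussian blob with its own amplitude and
    width so that keypoints are visually distinguishable; group-specific OU /
    oscillatory motion matches the keypoint-trace generator.  Motion that
    would carry a blob within 2 blob-widths of the border is reflected.
    """

    image_size: int = 128
    schema: KeypointSchema = None
    amplitudes: np.ndarray = None  # per keypoint
    widths: np.ndarray = None  # per keypoint, px
    motion_px: float = 6.0
    noise_sd: float = 0.02
    background: float = 0.1
    taus: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.schema is None:
            self.schema = schema_from_names(
                ["eye(top)", "nose(tip)", "whisker(I)"],
            )
        K = self.schema.n_keypoints
        if self.amplitudes is None:
            self.amplitudes = 0.6 + 0.35 * np.arange(K) / max(K - 1, 1)
        if self.widths is None:
            self.widths = 2.5 + 2.0 * np.arange(K) / max(K - 1, 1)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.widths = np.asarray(self.widths, dtype=float)


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect values into [lo, hi] (triangle-wave folding)."""
    rng_ = hi - lo
    y = np.mod(x - lo, 2 * rng_)
    y = np.where(y > rng_, 2 * rng_ - y, y)
    return lo + y


def render_frames(coords: np.ndarray, spec: FaceSceneSpec,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """Render (T, H, W) grayscale frames with Gaussian blobs at ``coords``."""
    T, K, _ = coords.shape
    H = W = spec.image_size
    yy, xx = np.mgrid[0:H, 0:W]
    frames = np.full((T, H, W), spec.background)
    for k in range(K):
        w2 = 2 * spec.widths[k] ** 2
        dx = xx[None] - coords[:, k, 0][:, None, None]
        dy = yy[None] - coords[:, k, 1][:, None, None]
        frames += spec.amplitudes[k] * np.exp(-(dx**2 + dy**2) / w2)
    if rng is not None and spec.noise_sd > 0:
        frames += rng.normal(0, spec.noise_sd, size=frames.shape)
    return frames


def make_face_video(spec: FaceSceneSpec, T: int, rate: float = 50.0,
                    ) -> tuple[np.ndarray, KeypointSeries]:
    """Rendered toy face frames plus the exact ground-truth keypoint series."""
    rng = np.random.default_rng(spec.seed)
    K = spec.schema.n_keypoints
    H = spec.image_size
    margin = 2 * spec.widths.max()
    # base positions on a ring well inside the frame
    cx = cy = H / 2.0
    r = H / 2.0 - margin - spec.motion_px - 4
    ang = 2 * np.pi * np.arange(K) / max(K, 1) + 0.5
    base = np.column_stack([cx + r * np.cos(ang), cy + r * np.sin(ang)])
    coords = np.empty((T, K, 2))
    for k, name in enumerate(spec.schema.names):
        g = spec.schema.groups[name]
        tau = {**DEFAULT_TAUS, **spec.taus}.get(g, 1.0)
        for ax in range(2):
            if g == "whisker":
                tr = whisk_trace(T, rate, rng, amp_sd=spec.motion_px)
            else:
                tr = ou_process(T, tau, rate, rng, sd=spec.motion_px)
            coords[:, k, ax] = base[k, ax] + tr
        lo, hi = margin, H - 1 - margin
        coords[:, k, 0] = _reflect(coords[:, k, 0], lo, hi)
        coords[:, k, 1] = _reflect(coords[:, k, 1], lo, hi)
    frames = render_frames(coords, spec, rng)
    series = KeypointSeries(
        schema=spec.schema, coords=coords,
        likelihood=np.ones((T, K)), rate=rate,
    )
    return frames, series


def shifted_domain_spec(spec: FaceSceneSpec, seed: int | None = None) -> FaceSceneSpec:
    """A shifted-appearance variant of a scene (different blob contrast/size and
    background), emulating a new lab's video for fine-tuning experiments."""
    return FaceSceneSpec(
        image_size=spec.image_size,
        schema=spec.schema,
        amplitudes=spec.amplitudes * np.linspace(0.45, 0.8, len(spec.amplitudes)),
        widths=spec.widths * 1.7,
        motion_px=spec.motion_px,
        noise_sd=spec.noise_sd * 2.0,
        background=spec.background + 0.25,
        taus=spec.taus,
        seed=spec.seed + 1000 if seed is None else seed,
    )


# ---------------------------------------------------------------------------
# Planted-encoder neural populations
# ---------------------------------------------------------------------------


@dataclass
class PlantedEncoderSpec:
    """Neural population driven by a known nonlinear function of the keypoints.

    Latent signals are a fixed random ReLU-family network of the keypoint
    coordinates: ``n_abs`` rectifier-pair units ``relu(w.x) + relu(-w.x)``
    (zero linear component under symmetric inputs, yet representable by a
    single ReLU hidden layer) plus ``n_lin`` purely linear units, temporally
    smoothed.  Each neuron mixes behavior-driven latents, shared
    non-behavioral low-rank latents and independent Gaussian noise with
    variance fractions ``behavior_frac``, ``shared_frac`` and
    ``1 - behavior_frac - shared_frac``.  Peer-predictable (explainable)
    variance is therefore ``behavior_frac + shared_frac``.
    """

    n_neurons: int = 800
    n_abs: int = 4  # rectifier-pair (absolute-value) latent units
    n_lin: int = 2  # purely linear latent units
    n_shared: int = 4
    behavior_frac: float = 0.5
    shared_frac: float = 0.2
    neural_rate: float = 3.0
    fov_um: float = 1000.0
    cluster_spread_um: float | None = None  # None -> uniform (spatially diffuse)
    smooth_tau: float = 0.6  # s, temporal smoothing of the behavioral latents
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.behavior_frac + self.shared_frac <= 1:
            raise ValueError("variance fractions must lie in [0, 1] and sum <= 1")

    @property
    def n_latents(self) -> int:
        return self.n_abs + self.n_lin

    @property
    def noise_frac(self) -> float:
        return 1.0 - self.behavior_frac - self.shared_frac


def _planted_network(x: np.ndarray, spec: PlantedEncoderSpec,
                     rng: np.random.Generator) -> np.ndarray:
    """Fixed random ReLU-family network applied row-wise (see PlantedEncoderSpec)."""
    d = x.shape[1]
    cols = []
    if spec.n_abs:
        W = rng.normal(0, 1.0 / np.sqrt(d), size=(d, spec.n_abs))
        u = x @ W
        a = np.maximum(u, 0.0) + np.maximum(-u, 0.0)  # rectifier pair = |u|
        a = a - a.mean(axis=0)
        cols.append(a / np.maximum(a.std(axis=0), 1e-12))
    if spec.n_lin:
        Wl = rng.normal(0, 1.0 / np.sqrt(d), size=(d, spec.n_lin))
        lin = x @ Wl
        cols.append(lin / np.maximum(lin.std(axis=0), 1e-12))
    return np.concatenate(cols, axis=1)


def _smooth_causal(x: np.ndarray, tau: float, rate: float) -> np.ndarray:
    """Causal exponential smoothing along axis 0 (unit-sum kernel)."""
    from scipy.signal import lfilter

    a = np.exp(-1.0 / (tau * rate))
    return lfilter([1 - a], [1, -a], x, axis=0)


def make_neural_from_behavior(
    keypoints: KeypointSeries, spec: PlantedEncoderSpec
) -> tuple[NeuralRecording, dict]:
    """Simulate a neural population from keypoints; returns (recording, ground truth).

    The ground-truth dict records per-neuron explainable variance
    (``behavior_frac + shared_frac``), the behavior-driven variance fraction,
    the latent time courses at the neural rate, and the latent membership used
    for spatial layout.
    """
    rng = np.random.default_rng(spec.seed)
    X = keypoints.neural_coords()
    X = (X - X.mean(axis=0)) / np.maximum(X.std(axis=0), 1e-12)
    lat = _planted_network(X, spec, rng)
    lat = _smooth_causal(lat, spec.smooth_tau, keypoints.rate)
    # subsample at neural frame times (nearest behavior frame at or before)
    duration = keypoints.n_frames / keypoints.rate
    n_t = int(np.floor(duration * spec.neural_rate))
    beh_idx = np.floor(np.arange(n_t) / spec.neural_rate * keypoints.rate).astype(int)
    beh_idx = np.clip(beh_idx, 0, keypoints.n_frames - 1)
    lat = lat[beh_idx]
    lat = (lat - lat.mean(axis=0)) / np.maximum(lat.std(axis=0), 1e-12)
    shared = rng.standard_normal((n_t, spec.n_shared))
    shared = _smooth_causal(shared, 1.0, spec.neural_rate)
    shared = (shared - shared.mean(axis=0)) / np.maximum(shared.std(axis=0), 1e-12)

    n = spec.n_neurons
    Wb = rng.normal(size=(spec.n_latents, n)) / np.sqrt(spec.n_latents)
    Ws = rng.normal(size=(spec.n_shared, n)) / np.sqrt(spec.n_shared)
    sig_b = lat @ Wb
    sig_s = shared @ Ws
    sig_b /= np.maximum(sig_b.std(axis=0), 1e-12)
    sig_s /= np.maximum(sig_s.std(axis=0), 1e-12)
    noise = rng.standard_normal((n_t, n))
    act = (
        np.sqrt(spec.behavior_frac) * sig_b
        + np.sqrt(spec.shared_frac) * sig_s
        + np.sqrt(spec.noise_frac) * noise
    ).T  # neurons x time

    # spatial layout: each neuron tagged by its dominant latent; compact or diffuse
    membership = rng.integers(0, spec.n_latents + spec.n_shared, size=n)
    if spec.cluster_spread_um is None:
        pos = rng.uniform(0, spec.fov_um, size=(n, 2))
    else:
        centers = rng.uniform(0.2 * spec.fov_um, 0.8 * spec.fov_um,
                              size=(spec.n_latents + spec.n_shared, 2))
        pos = centers[membership] + rng.normal(0, spec.cluster_spread_um, size=(n, 2))
        pos = np.clip(pos, 0, spec.fov_um)
    rec = NeuralRecording(activity=act, positions=pos, rate=spec.neural_rate)
    truth = {
        "explainable_variance": np.full(n, spec.behavior_frac + spec.shared_frac),
        "behavior_variance": np.full(n, spec.behavior_frac),
        "latents": lat,
        "shared": shared,
        "membership": membership,
        "behavior_index": beh_idx,
    }
    return rec, truth


# ---------------------------------------------------------------------------
# HMM sequences
# ---------------------------------------------------------------------------


def make_hmm_transitions(K: int, dwell_p: float, asymmetry: float,
                         rng: np.random.Generator | None = None) -> np.ndarray:
    """Transition matrix with self-transition ``dwell_p`` and forward-cycle bias.

    Off-diagonal mass (1 - dwell_p) interpolates between a symmetric uniform
    kernel (asymmetry 0) and a deterministic next-state cycle (asymmetry 1).
    """
    if not 0 <= asymmetry <= 1:
        raise ValueError("asymmetry must be in [0, 1]")
    if K < 2:
        return np.ones((1, 1))
    A = np.zeros((K, K))
    for j in range(K):
        off = np.full(K, (1.0 - asymmetry) / (K - 1))
        off[j] = 0.0
        off[(j + 1) % K] += asymmetry
        off /= off.sum()
        A[j] = (1 - dwell_p) * off
        A[j, j] += dwell_p
    return A


def make_hmm_sequence(
    K: int = 10,
    dwell_p: float = 0.9,
    asymmetry: float = 0.0,
    n_dims: int = 16,
    T: int = 10000,
    sigma: float = 1.0,
    mean_scale: float = 2.0,
    seed: int = 0,
) -> tuple[np.ndarray, HmmModel, np.ndarray]:
    """Features sampled from a known HMM; returns (features, true model, true path)."""
    rng = np.random.default_rng(seed)
    A = make_hmm_transitions(K, dwell_p, asymmetry, rng)
    C = rng.normal(0, mean_scale, size=(K, n_dims))
    model = HmmModel.from_probabilities(A, C, sigma**2)
    states, feats = hmm_simulate(model, T, seed=seed + 1)
    return feats, model, states
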