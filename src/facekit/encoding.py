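"""Behavior-to-neural prediction.

Population activity is z-scored and reduced to its top 128 principal
components (``Y = V S``).  Two model families predict the neural PCs from
behavioral inputs (keypoint coordinates or movie PCs):

* **Reduced-rank regression (RRR)** — ridge regression followed by a best
  rank-r truncation in the output space (the classical closed-form
  construction): ``Y = X B A^T``.
* **Deep encoder** — a core of [linear n_in -> n_in, temporal convolution
  with 10 filters, ReLU, dense 50 + ReLU, dense 256 + ReLU] producing
  256-dim "deep behavioral features" at the behavior frame rate, subsampled
  at neural frame times, followed by a linear readout onto the 128 neural
  PCs (or onto neurons directly when fewer than 200 are recorded).

Performance is the per-neuron variance explained
``VE_i = 1 - ||s_test - s_pred||^2 / ||s_test - mean||^2``, normalized by
the *explainable variance* — the ceiling estimated by peer prediction,
where the field of view is split into even/odd 200 um strips and each
half-population is predicted from the other's PCs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .io_core import NeuralRecording, SegmentSplit, logger


# ---------------------------------------------------------------------------
# Variance explained
# ---------------------------------------------------------------------------


def variance_explained(test: np.ndarray, pred: np.ndarray) -> float:
    """VE = 1 - SSE / SST with SST the squared deviation of test from its mean.

    Returns NaN (undefined / excluded) for a zero-variance test trace.
    """
    test = np.asarray(test, dtype=float).ravel()
    pred = np.asarray(pred, dtype=float).ravel()
    if test.shape != pred.shape or len(test) < 2:
        raise ValueError("test and pred must have equal length >= 2")
    sst = ((test - test.mean()) ** 2).sum()
    if sst == 0:
        return float("nan")
    return float(1.0 - ((test - pred) ** 2).sum() / sst)


def _ve_rows(test: np.ndarray, pred: np.ndarray) -> np.ndarray:
    """Row-wise VE for (units, time) arrays; NaN rows where test has no variance."""
    sst = ((test - test.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    sse = ((test - pred) ** 2).sum(axis=1)
    return np.where(sst > 0, 1.0 - sse / np.where(sst > 0, sst, 1.0), np.nan)


def cumulative_ve(Y_test: np.ndarray, Y_pred: np.ndarray) -> np.ndarray:
    """Cumulative variance explained across neural PCs.

    ``curve[i]`` = sum over the first i+1 PCs of (SST_k - SSE_k), normalized
    by the total SST over all PCs; estimates the dimensionality of the
    behavioral prediction.
    """
    Y_test = np.asarray(Y_test, dtype=float)
    Y_pred = np.asarray(Y_pred, dtype=float)
    sst = ((Y_test - Y_test.mean(axis=0)) ** 2).sum(axis=0)
    sse = ((Y_test - Y_pred) ** 2).sum(axis=0)
    return np.cumsum(sst - sse) / sst.sum()


# ---------------------------------------------------------------------------
# Neural SVD
# ---------------------------------------------------------------------------


@dataclass
class NeuralPCs:
    U: np.ndarray  # neurons x k loadings (orthonormal columns)
    S: np.ndarray  # k singular values
    Y: np.ndarray  # timepoints x k, Y = V S
    keep: np.ndarray  # neurons kept after z-scoring (zero-variance excluded)

    @property
    def k(self) -> int:
        return len(self.S)

    def project_to_neurons(self, Y_hat: np.ndarray) -> np.ndarray:
        """Neuron-space prediction U @ Y_hat^T: (neurons, timepoints)."""
        return self.U @ Y_hat.T


def neural_svd(recording: NeuralRecording, k: int = 128) -> NeuralPCs:
    """Truncated SVD of z-scored activity; deterministic sign convention.

    Per component, the loading with the largest magnitude is made positive.
    """
    z, keep = recording.zscored()
    if k > min(z.shape):
        raise ValueError(f"k={k} exceeds activity dimensions {z.shape}")
    U, S, Vt = np.linalg.svd(z, full_matrices=False)
    U, S, Vt = U[:, :k], S[:k], Vt[:k]
    for i in range(k):
        j = np.argmax(np.abs(U[:, i]))
        if U[j, i] < 0:
            U[:, i] *= -1
            Vt[i] *= -1
    return NeuralPCs(U=U, S=S, Y=Vt.T * S, keep=keep)


# ---------------------------------------------------------------------------
# Reduced-rank regression
# ---------------------------------------------------------------------------


@dataclass
class RRRModel:
    B: np.ndarray  # inputs x rank
    A: np.ndarray  # outputs x rank
    x_mean: np.ndarray
    y_mean: np.ndarray
    lam: float
    rank: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (X - self.x_mean) @ self.B @ self.A.T + self.y_mean


def fit_rrr(X: np.ndarray, Y: np.ndarray, rank: int, lam: float = 1e-6,
            train_idx: np.ndarray | None = None) -> RRRModel:
    """Closed-form reduced-rank regression ``Y = X B A^T``.

    Ridge solution (``lam`` times the identity added to the input covariance)
    followed by projection of the fitted values onto their top-``rank``
    principal directions in output space; deterministic.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if rank > min(X.shape[1], Y.shape[1]):
        raise ValueError("rank exceeds input/output dimensionality")
    tr = np.arange(len(X)) if train_idx is None else np.asarray(train_idx)
    xm = X[tr].mean(axis=0)
    ym = Y[tr].mean(axis=0)
    Xc, Yc = X[tr] - xm, Y[tr] - ym
    G = Xc.T @ Xc + lam * np.eye(X.shape[1])
    try:
        W = np.linalg.solve(G, Xc.T @ Yc)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            "singular input covariance; use lam > 0 for regularization"
        ) from e
    fitted = Xc @ W
    # top-rank output-space directions of the fitted values
    _, _, Vt = np.linalg.svd(fitted, full_matrices=False)
    A = Vt[:rank].T  # outputs x rank
    B = W @ A
    return RRRModel(B=B, A=A, x_mean=xm, y_mean=ym, lam=lam, rank=rank)


# ---------------------------------------------------------------------------
# Deep encoder
# ---------------------------------------------------------------------------


@dataclass
class EncoderSpec:
    """Architecture and training hyperparameters of the deep encoder."""

    n_deep: int = 256  # deep behavioral feature dimensionality
    n_hidden: int = 50
    n_conv: int = 10  # temporal convolution filters
    conv_len: int = 51  # frames (~1 s at 50 Hz), centered, zero-padded
    init_scale: float = 0.4  # shrink He init toward uniform-fan-in convention
    lr: float = 1e-1
    weight_decay: float = 1e-4
    epochs: int = 300
    anneal_at: tuple[int, ...] = (200, 250)
    anneal_factor: float = 0.1
    small_population: int = 2000  # neurons below which LR and decay are /10
    small_data_hours: float = 1.0  # training hours below which LR, decay /2, epochs -100


class Encoder:
    """The numpy deep encoder (see module docstring for the layer stack)."""

    def __init__(self, n_in: int, n_out: int, spec: EncoderSpec, seed: int = 0):
        self.spec = spec
        self.n_in = n_in
        self.n_out = n_out
        rng = np.random.default_rng(seed)
        s = spec
        self.W0 = nn.parameter(rng, (n_in, n_in))  # pure linear, no bias
        self.Wc = nn.parameter(rng, (s.n_conv, n_in, s.conv_len))
        self.bc = nn.zeros_parameter((s.n_conv,))
        self.W1 = nn.parameter(rng, (s.n_conv, s.n_hidden))
        self.b1 = nn.zeros_parameter((s.n_hidden,))
        self.W2 = nn.parameter(rng, (s.n_hidden, s.n_deep))
        self.b2 = nn.zeros_parameter((s.n_deep,))
        self.Wr = nn.parameter(rng, (s.n_deep, n_out))
        self.br = nn.zeros_parameter((n_out,))
        for p in self.params:
            p.data *= s.init_scale

    @property
    def params(self):
        return [self.W0, self.Wc, self.bc, self.W1, self.b1, self.W2, self.b2,
                self.Wr, self.br]

    def core(self, x: nn.Tensor) -> nn.Tensor:
        """Deep behavioral features (T, n_deep) at the behavior frame rate."""
        h = x.matmul(self.W0)
        h = nn.conv1d_temporal(h, self.Wc, self.bc).relu()
        h = nn.linear(h, self.W1, self.b1).relu()
        h = nn.linear(h, self.W2, self.b2).relu()
        return h

    def forward(self, x: nn.Tensor, neural_rows: np.ndarray) -> nn.Tensor:
        feats = self.core(x)
        return nn.linear(feats.take_rows(neural_rows), self.Wr, self.br)

    def deep_features(self, X: np.ndarray) -> np.ndarray:
        return self.core(nn.Tensor(X)).data


def behavior_to_neural_rows(n_neural: int, neural_rate: float, behavior_rate: float,
                            n_behavior: int) -> np.ndarray:
    """Behavior frame index at (or immediately before) each neural frame time."""
    rows = np.floor(np.arange(n_neural) / neural_rate * behavior_rate).astype(int)
    return np.clip(rows, 0, n_behavior - 1)


@dataclass
class VarianceLedger:
    """Per-neuron variance-explained bookkeeping."""

    ve: np.ndarray  # per neuron (Eq. VE), NaN where undefined
    ev: np.ndarray | None = None  # explainable variance per neuron
    ev_floor: float = 1e-3

    @property
    def normalized_ve(self) -> np.ndarray:
        """Neuron-level VE / EV, reported only where EV exceeds the floor."""
        if self.ev is None:
            raise ValueError("no explainable variance available")
        out = np.full_like(self.ve, np.nan)
        ok = np.isfinite(self.ev) & (self.ev > self.ev_floor)
        out[ok] = self.ve[ok] / self.ev[ok]
        return out

    @property
    def population_normalized_ve(self) -> float:
        """Mean VE across neurons divided by mean EV across neurons."""
        if self.ev is None:
            raise ValueError("no explainable variance available")
        return float(np.nanmean(self.ve) / np.nanmean(self.ev))


@dataclass
class EncodingFit:
    encoder: "Encoder"
    split: SegmentSplit
    ledger: VarianceLedger
    loss_history: np.ndarray
    deep_features: np.ndarray  # (T_behavior, 256) at behavior rate
    Y_pred_test: np.ndarray  # PC-space (or neuron-space) test predictions
    Y_test: np.ndarray
    test_ve_pc: np.ndarray  # VE per predicted output on test segments


def fit_encoder(
    X: np.ndarray,
    behavior_rate: float,
    targets: np.ndarray,
    neural_rate: float,
    split: SegmentSplit,
    spec: EncoderSpec | None = None,
    seed: int = 0,
    ev: np.ndarray | None = None,
    pcs: NeuralPCs | None = None,
    n_neurons: int | None = None,
    verbose: bool = False,
) -> EncodingFit:
    """Train the deep encoder end-to-end.

    Parameters
    ----------
    X : (T_behavior, n_in) behavioral inputs at the behavior frame rate.
    targets : (T_neural, n_out) neural PCs (``Y = VS``) or single-neuron
        activity when predicting fewer than 200 neurons directly.
    split : segment split over the *neural* timepoints; each training batch
        is one training segment.
    ev : optional per-neuron explainable variance for the ledger.
    pcs : when given, test predictions are projected through ``pcs.U`` so
        the ledger holds per-neuron VE.
    n_neurons : population size used for the small-population adjustment
        (defaults to the target dimensionality).

    Notes
    -----
    Small-data adjustments: populations under 2,000 neurons divide the
    learning rate and weight decay by 10; under 1 h of training data the
    learning rate and decay are halved and 100 epochs are dropped.
    Deterministic given ``seed``.
    """
    spec = spec or EncoderSpec()
    X = np.asarray(X, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if np.isnan(X).any():
        raise ValueError("NaNs in inputs; run the trace-filtering module first")
    if np.isnan(targets).any():
        raise ValueError("NaNs in targets")
    lr, wd, epochs = spec.lr, spec.weight_decay, spec.epochs
    n_pop = n_neurons if n_neurons is not None else targets.shape[1]
    if n_pop < spec.small_population:
        lr, wd = lr / 10, wd / 10
    train_hours = sum(len(s) for s in split.train_segments()) / neural_rate / 3600
    if train_hours < spec.small_data_hours:
        lr, wd = lr / 2, wd / 2
        epochs = max(epochs - 100, 1)

    rows = behavior_to_neural_rows(targets.shape[0], neural_rate, behavior_rate, X.shape[0])
    enc = Encoder(X.shape[1], targets.shape[1], spec, seed=seed)
    opt = nn.AdamW(enc.params, lr=lr, weight_decay=wd)
    # per-segment behavior slices with a margin for the conv receptive field
    segments = []
    pad = spec.conv_len // 2
    for seg in split.train_segments():
        b0 = max(int(rows[seg[0]]) - pad, 0)
        b1 = min(int(rows[seg[-1]]) + pad + 1, X.shape[0])
        segments.append((seg, b0, b1))
    losses = np.empty(epochs)
    for ep in range(epochs):
        if ep in spec.anneal_at:
            opt.lr *= spec.anneal_factor
        ep_loss = 0.0
        for seg, b0, b1 in segments:
            x = nn.Tensor(X[b0:b1])
            pred = enc.forward(x, rows[seg] - b0)
            loss = nn.mse_loss(pred, targets[seg])
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_loss += loss.data
        losses[ep] = ep_loss / len(segments)
        if verbose and (ep % 25 == 0 or ep == epochs - 1):
            logger.info("encoder epoch %d/%d loss %.5f", ep, epochs, losses[ep])

    feats = enc.deep_features(X)
    pred_all = feats[rows] @ enc.Wr.data + enc.br.data
    test = split.test_idx
    Y_pred_test, Y_test = pred_all[test], targets[test]
    ve_pc = _ve_rows(Y_test.T, Y_pred_test.T)
    if pcs is not None:
        neuron_pred = pcs.project_to_neurons(Y_pred_test)
        neuron_test = pcs.project_to_neurons(Y_test)
        ve = _ve_rows(neuron_test, neuron_pred)
        ve[~pcs.keep] = np.nan
    else:
        ve = ve_pc
    ledger = VarianceLedger(ve=ve, ev=ev)
    return EncodingFit(
        encoder=enc, split=split, ledger=ledger, loss_history=losses,
        deep_features=feats, Y_pred_test=Y_pred_test, Y_test=Y_test, test_ve_pc=ve_pc,
    )


# ---------------------------------------------------------------------------
# Peer prediction (explainable variance)
# ---------------------------------------------------------------------------


def peer_prediction(
    recording: NeuralRecording,
    split: SegmentSplit,
    strip_um: float = 200.0,
    lam: float = 1e-1,
    rank: int = 127,
    k: int = 128,
) -> np.ndarray:
    """Per-neuron explainable variance from spatially split peer populations.

    The field of view is divided into vertical strips of ``strip_um``
    micrometres by x-position (depth ignored); neurons in even strips form
    one group and odd strips the other.  Each group's top-``k`` PCs are
    predicted from the other group's PCs with RRR (``rank``, ``lam``) fit on
    training segments; predictions are projected back to neurons through the
    group's loadings, and VE on test segments is the explainable variance.
    """
    z, keep = recording.zscored()
    strip = np.floor(recording.positions[:, 0] / strip_um).astype(int)
    even = strip % 2 == 0
    groups = [np.flatnonzero(even), np.flatnonzero(~even)]
    for g in groups:
        if len(g) < k:
            raise ValueError(
                f"a strip-parity group has {len(g)} neurons < k={k}; use a smaller k"
            )
    ev = np.full(recording.n_neurons, np.nan)
    pcs = []
    for g in groups:
        sub = NeuralRecording(recording.activity[g], recording.positions[g], recording.rate)
        pcs.append(neural_svd(sub, k=k))
    for src, dst, gidx in ((0, 1, groups[1]), (1, 0, groups[0])):
        model = fit_rrr(pcs[src].Y, pcs[dst].Y, rank=rank, lam=lam, train_idx=split.train_idx)
        Y_hat = model.predict(pcs[src].Y)
        test = split.test_idx
        pred_neurons = pcs[dst].project_to_neurons(Y_hat[test])
        true_neurons = z[gidx][:, test]
        ev[gidx] = _ve_rows(true_neurons, pred_neurons)
        ev[gidx[~pcs[dst].keep]] = np.nan
    ev[~keep] = np.nan
    return ev


# ---------------------------------------------------------------------------
# Scaling analyses and movie PCs
# ---------------------------------------------------------------------------


def scaling_curves(
    X: np.ndarray,
    recording: NeuralRecording,
    split: SegmentSplit,
    neuron_fractions=(0.25, 0.5, 1.0),
    time_fractions=(0.25, 0.5, 1.0),
    k: int = 128,
    rank: int = 21,
    lam: float = 1e-6,
    seed: int = 0,
) -> dict:
    """Normalized VE as a function of neuron count and training duration.

    Fits the RRR behavioral model on neuron subsets (test timepoints fixed)
    and on truncated training segments; VE is normalized by the explainable
    variance averaged over the same neuron subset.
    """
    if len(X) != recording.n_timepoints:
        raise ValueError("X must be sampled at neural frame times")
    rng = np.random.default_rng(seed)
    k_ev = min(k, recording.n_neurons // 2 - 1)
    ev = peer_prediction(recording, split, k=k_ev, rank=k_ev - 1)
    Xn = X

    def fit_ve(rec_sub: NeuralRecording, ev_sub: np.ndarray, train_idx: np.ndarray):
        k_eff = min(k, rec_sub.n_neurons, rec_sub.n_timepoints)
        pcs = neural_svd(rec_sub, k=k_eff)
        model = fit_rrr(Xn, pcs.Y, rank=min(rank, k_eff), lam=lam, train_idx=train_idx)
        test = split.test_idx
        pred = pcs.project_to_neurons(model.predict(Xn)[test])
        z, _ = rec_sub.zscored()
        ve = _ve_rows(z[:, test], pred)
        return float(np.nanmean(ve) / np.nanmean(ev_sub))

    out = {"neurons": {}, "time": {}}
    for f in neuron_fractions:
        n_sub = max(int(round(f * recording.n_neurons)), 2)
        if n_sub < 4:
            logger.warning("neuron fraction %.2f too small for SVD; skipped", f)
            continue
        idx = np.sort(rng.choice(recording.n_neurons, n_sub, replace=False)) \
            if f < 1.0 else np.arange(recording.n_neurons)
        sub = NeuralRecording(recording.activity[idx], recording.positions[idx], recording.rate)
        out["neurons"][f] = fit_ve(sub, ev[idx], split.train_idx)
    for f in time_fractions:
        tr = np.concatenate([seg[: max(int(round(f * len(seg))), 2)]
                             for seg in split.train_segments()])
        out["time"][f] = fit_ve(recording, ev, tr)
    return out


def movie_pcs(frames: np.ndarray, k: int = 500) -> tuple[np.ndarray, np.ndarray]:
    """Whole-frame SVD of a video: returns (PCs (T, k), singular values).

    A plain truncated SVD of mean-subtracted flattened frames — a simple
    stand-in for blockwise video SVD pipelines.
    """
    T = frames.shape[0]
    flat = frames.reshape(T, -1).astype(float)
    flat -= flat.mean(axis=0)
    k = min(k, *flat.shape)
    U, S, _ = np.linalg.svd(flat, full_matrices=False)
    return U[:, :k] * S[:k], S[:k]
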