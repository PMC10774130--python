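"""Discrete Gaussian-emission hidden Markov model over behavioral features.

The model has ``K`` discrete states with categorical initial distribution
``b``, row-stochastic transition matrix ``A`` and spherical Gaussian
emissions ``z_t ~ N(C_{h_t}, sigma^2 I)``.  Rather than expectation
maximization, fitting ascends the *exact* marginal log-likelihood — computed
by the log-space forward recursion — by gradient steps on unconstrained
parameters: a log-transition matrix ``Q`` (``A`` = row-softmax of ``Q``),
initial-state logits, and the emission means.  The emission scale is never
learned; it is frozen by a policy proportional to the summed feature
variance so that feature sets of different dimensionality weight the
emission term comparably.

The gradient of the log-likelihood is evaluated analytically through the
forward-backward recursions (posterior state marginals and expected
transition counts), which is exactly the quantity reverse-mode
differentiation of the forward recursion produces.

A battery of transition-structure statistics operates on the fitted model:
self-transition lifetimes, the off-diagonal-normalized matrix ``B``,
transition-matrix sorting, n-nearest transition curves, reverse and
two-step transition probabilities, forward-sequence lengths and
state-conditioned neural averages.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .io_core import NeuralRecording, logger
from .nn import Adam

try:  # numba speeds up the sequential forward/backward recursions when present
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]

#: default number of behavioral states
DEFAULT_K = 50
#: reference dimensionality for the emission-scale policy: sigma^2 = n / SIGMA_REF_DIM
#: after per-feature standardization (1.0 for 256-dim deep features)
SIGMA_REF_DIM = 256


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------


def _row_softmax(Q: np.ndarray) -> np.ndarray:
    m = Q.max(axis=1, keepdims=True)
    e = np.exp(Q - m)
    return e / e.sum(axis=1, keepdims=True)


def _softmax(v: np.ndarray) -> np.ndarray:
    e = np.exp(v - v.max())
    return e / e.sum()


@dataclass
class HmmModel:
    """HMM parameters in unconstrained (logit) form plus the fixed emission scale."""

    Q: np.ndarray  # (K, K) log-transition matrix
    C: np.ndarray  # (K, n) emission means
    b_logits: np.ndarray  # (K,) initial-state logits
    sigma2: float  # fixed emission variance (spherical)

    def __post_init__(self):
        self.Q = np.asarray(self.Q, dtype=float)
        self.C = np.atleast_2d(np.asarray(self.C, dtype=float))
        self.b_logits = np.asarray(self.b_logits, dtype=float)
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be > 0")

    @property
    def K(self) -> int:
        return self.Q.shape[0]

    @property
    def n(self) -> int:
        return self.C.shape[1]

    @property
    def A(self) -> np.ndarray:
        """Row-stochastic transition matrix, A[j, i] = Prob(h_{t+1}=i | h_t=j)."""
        return _row_softmax(self.Q)

    @property
    def b(self) -> np.ndarray:
        return _softmax(self.b_logits)

    @classmethod
    def from_probabilities(cls, A: np.ndarray, C: np.ndarray, sigma2: float,
                           b: np.ndarray | None = None) -> "HmmModel":
        A = np.asarray(A, dtype=float)
        K = A.shape[0]
        if b is None:
            b = np.full(K, 1.0 / K)
        with np.errstate(divide="ignore"):
            return cls(Q=np.log(np.maximum(A, 1e-300)), C=C,
                       b_logits=np.log(np.maximum(b, 1e-300)), sigma2=sigma2)


def _emission_loglik(model: HmmModel, z: np.ndarray) -> np.ndarray:
    """(T, K) spherical Gaussian log-densities including all constants."""
    d2 = cdist(z, model.C, metric="sqeuclidean")
    return -0.5 * d2 / model.sigma2 - 0.5 * model.n * np.log(2 * np.pi * model.sigma2)


def _check_features(z: np.ndarray) -> np.ndarray:
    z = np.atleast_2d(np.asarray(z, dtype=float))
    if z.ndim != 2:
        raise ValueError("features must be (T, n)")
    if not np.isfinite(z).all():
        raise ValueError("features contain NaN/inf")
    return z


@_njit(cache=False)
def _forward_core(E: np.ndarray, A: np.ndarray, b: np.ndarray):
    """Scaled forward recursion.

    Equivalent to the log-space recursion alpha_i(t) = e_i(t) +
    logsumexp_j(alpha_j(t-1) + log A_ji): each step keeps a normalized
    alpha-hat vector and a per-step log scale, so sequences of length 1e5
    neither overflow nor underflow.  Returns (alpha_hat (T, K), logc (T,)),
    with log-likelihood = logc.sum().
    """
    T, K = E.shape
    abar = np.empty((T, K))
    logc = np.empty(T)
    for t in range(T):
        m = E[t].max()
        e = np.exp(E[t] - m)
        if t == 0:
            a = b * e
        else:
            a = (abar[t - 1] @ A) * e
        s = a.sum()
        abar[t] = a / s
        logc[t] = m + np.log(s)
    return abar, logc


@_njit(cache=False)
def _backward_core(E: np.ndarray, A: np.ndarray):
    """Scaled backward recursion (per-step normalized beta-hat)."""
    T, K = E.shape
    bbar = np.empty((T, K))
    bbar[T - 1] = 1.0 / K
    for t in range(T - 2, -1, -1):
        m = E[t + 1].max()
        w = np.exp(E[t + 1] - m) * bbar[t + 1]
        v = A @ w
        bbar[t] = v / v.sum()
    return bbar


def log_likelihood(model: HmmModel, z: np.ndarray) -> float:
    """Exact log Prob(z_1..z_T) under the model (all Gaussian constants included)."""
    z = _check_features(z)
    if z.shape[1] != model.n:
        raise ValueError("feature dimension mismatch")
    E = _emission_loglik(model, z)
    _, logc = _forward_core(E, model.A, model.b)
    return float(logc.sum())


def _forward_backward(model: HmmModel, z: np.ndarray):
    """Posterior marginals gamma (T, K), expected transition counts xi (K, K), LL."""
    E = _emission_loglik(model, z)
    A = model.A
    abar, logc = _forward_core(E, A, model.b)
    bbar = _backward_core(E, A)
    g = abar * bbar
    gamma = g / g.sum(axis=1, keepdims=True)
    ll = float(logc.sum())
    if E.shape[0] > 1:
        # xi[j, i] = sum_t P(h_{t-1}=j, h_t=i | z); per-step normalizer d_t is a
        # scalar, so the sum collapses to a single matmul
        U = abar[:-1]
        W = np.exp(E[1:] - E[1:].max(axis=1, keepdims=True)) * bbar[1:]
        d = ((U @ A) * W).sum(axis=1)
        xi = A * ((U / d[:, None]).T @ W)
    else:
        xi = np.zeros_like(A)
    return gamma, xi, ll


@dataclass
class FitResult:
    model: HmmModel
    loglik_trace: np.ndarray
    mean: np.ndarray = field(default=None)
    scale: np.ndarray = field(default=None)


def sigma_policy(z: np.ndarray, policy: str | float = "auto") -> float:
    """Emission variance policy.

    ``"auto"``: after per-feature standardization the summed variance equals
    the feature count ``n``, and sigma^2 = n / 256 — giving 1.0 for 256-dim
    deep behavioral features and n/256 (e.g. 22/256) for keypoint inputs.
    A float is used as-is.
    """
    if isinstance(policy, (int, float)):
        return float(policy)
    if policy == "auto":
        return z.shape[1] / SIGMA_REF_DIM
    raise ValueError(f"unknown sigma policy {policy!r}")


def standardize_features(z: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Z-score each feature column; returns (standardized, mean, scale)."""
    mu = z.mean(axis=0)
    sd = z.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (z - mu) / sd, mu, sd


def downsample_features(z: np.ndarray, factor: int = 10) -> np.ndarray:
    """Temporal striding (e.g. 50 Hz -> 5 Hz with factor 10)."""
    return z[::factor]


def _gradient_ascent(z: np.ndarray, C0: np.ndarray, s2: float, lr: float,
                     n_iter: int) -> tuple[HmmModel, np.ndarray]:
    """Adam ascent of the exact log-likelihood from the standard init."""
    T, _ = z.shape
    K = C0.shape[0]
    Q = np.zeros((K, K))
    np.fill_diagonal(Q, 3.0)
    params = [_P(Q), _P(C0), _P(np.zeros(K))]
    opt = Adam(params, lr=lr)
    trace = np.empty(n_iter)
    s2 = float(s2)
    for it in range(n_iter):
        model = HmmModel(Q=params[0].data, C=params[1].data,
                         b_logits=params[2].data, sigma2=s2)
        gamma, xi, ll = _forward_backward(model, z)
        if not np.isfinite(ll):
            raise RuntimeError(
                f"non-finite log-likelihood at iteration {it}; "
                f"|Q|max={np.abs(params[0].data).max():.3g}, "
                f"|C|max={np.abs(params[1].data).max():.3g}"
            )
        trace[it] = ll / T
        A = model.A
        b = model.b
        # analytic gradients of LL; Adam minimizes, so negate
        gQ = xi - xi.sum(axis=1, keepdims=True) * A
        gC = (gamma.T @ z - gamma.sum(axis=0)[:, None] * params[1].data) / s2
        gb = gamma[0] - b
        params[0].grad = -gQ / T
        params[1].grad = -gC / T
        params[2].grad = -gb / T
        opt.step()
        opt.zero_grad()
    model = HmmModel(Q=params[0].data, C=params[1].data,
                     b_logits=params[2].data, sigma2=s2)
    return model, trace


def fit(
    z: np.ndarray,
    K: int = DEFAULT_K,
    sigma2: str | float = "auto",
    lr: float = 0.05,
    n_iter: int = 400,
    seed: int = 0,
    standardize: bool = True,
    n_restarts: int = 3,
    burn_in: int = 50,
) -> FitResult:
    """Fit the HMM by direct gradient ascent on the exact log-likelihood.

    Initialization: Q_ii = 3, Q_ij = 0 (i != j); initial-state logits 0;
    emission means drawn as random data samples.  Because a random-sample
    draw can place two means in the same mode (duplicating one state and
    losing another), ``n_restarts`` independent draws are burned in for
    ``burn_in`` iterations and the one with the highest training likelihood
    continues for the full ``n_iter``.  sigma^2 is frozen by
    :func:`sigma_policy` and never learned.  Deterministic given ``seed``.

    Returns a :class:`FitResult` whose ``loglik_trace`` holds the training
    log-likelihood per timepoint at every iteration of the winning run.
    """
    z = _check_features(z)
    T, n = z.shape
    if T <= K:
        raise ValueError("need T >> K timepoints")
    mean = scale = None
    if standardize:
        z, mean, scale = standardize_features(z)
    s2 = sigma_policy(z, sigma2)
    inits = []
    for r in range(max(n_restarts, 1)):
        rng = np.random.default_rng([seed, r])
        inits.append(z[rng.choice(T, size=K, replace=False)].copy())
    best_init = inits[0]
    if len(inits) > 1 and burn_in > 0:
        best_ll = -np.inf
        for C0 in inits:
            _, trace = _gradient_ascent(z, C0.copy(), s2, lr, burn_in)
            if trace[-1] > best_ll:
                best_ll, best_init = trace[-1], C0
    model, trace = _gradient_ascent(z, best_init.copy(), s2, lr, n_iter)
    return FitResult(model=model, loglik_trace=trace, mean=mean, scale=scale)


class _P:
    """Bare parameter holder compatible with the Adam optimizer."""

    __slots__ = ("data", "grad")

    def __init__(self, data):
        self.data = np.array(data, dtype=float)
        self.grad = None


def apply_standardization(res: FitResult, z: np.ndarray) -> np.ndarray:
    """Standardize new features with the transform learned during fitting."""
    z = np.atleast_2d(np.asarray(z, dtype=float))
    if res.mean is None:
        return z
    return (z - res.mean) / res.scale


def viterbi(model: HmmModel, z: np.ndarray) -> np.ndarray:
    """Most likely state path (log-space max-product; ties -> lowest state index)."""
    z = _check_features(z)
    E = _emission_loglik(model, z)
    with np.errstate(divide="ignore"):
        logA = np.log(np.maximum(model.A, 1e-300))
        logb = np.log(np.maximum(model.b, 1e-300))
    T, K = E.shape
    delta = logb + E[0]
    psi = np.zeros((T, K), dtype=int)
    for t in range(1, T):
        M = delta[:, None] + logA
        psi[t] = M.argmax(axis=0)  # first max = lowest predecessor index
        delta = E[t] + M[psi[t], np.arange(K)]
    path = np.empty(T, dtype=int)
    path[-1] = int(delta.argmax())
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1][path[t + 1]]
    return path


def simulate(model: HmmModel, T: int, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Sample (states, features) from the model; deterministic per seed."""
    rng = np.random.default_rng(seed)
    A, b = model.A, model.b
    states = np.empty(T, dtype=int)
    states[0] = rng.choice(model.K, p=b)
    for t in range(1, T):
        states[t] = rng.choice(model.K, p=A[states[t - 1]])
    feats = model.C[states] + rng.normal(0, np.sqrt(model.sigma2), size=(T, model.n))
    return states, feats


# ---------------------------------------------------------------------------
# Transition-structure statistics
# ---------------------------------------------------------------------------


@dataclass
class TransitionAnalysis:
    """Derived transition structure: the off-diagonal-normalized matrix and lifetimes."""

    B: np.ndarray  # (K, K), B_ii = 0, rows sum to 1 (absorbing rows all-zero)
    lifetimes: np.ndarray  # (K,), -log(1 - A_ii)
    absorbing: np.ndarray  # (K,) bool, True where A_ii = 1
    order: np.ndarray | None = None  # permutation from sort_states


def normalize_transitions(model: HmmModel) -> TransitionAnalysis:
    """Zero self-transitions and renormalize rows; lifetime_i = -log(1 - A_ii)."""
    A = model.A
    K = A.shape[0]
    diag = np.diag(A)
    with np.errstate(divide="ignore"):
        lifetimes = -np.log(np.maximum(1.0 - diag, 0.0))
    absorbing = diag >= 1.0 - 1e-12
    B = A.copy()
    np.fill_diagonal(B, 0.0)
    rs = B.sum(axis=1, keepdims=True)
    B = np.where(rs > 0, B / np.where(rs > 0, rs, 1.0), 0.0)
    if absorbing.any():
        logger.info("normalize_transitions: %d absorbing states zeroed", int(absorbing.sum()))
        B[absorbing] = 0.0
    return TransitionAnalysis(B=B, lifetimes=lifetimes, absorbing=absorbing)


def _sort_target(K: int) -> np.ndarray:
    """F_ji = -log((i - j)^2) for j < i, else 0: rewards mass just above the diagonal."""
    F = np.zeros((K, K))
    j, i = np.meshgrid(np.arange(K), np.arange(K), indexing="ij")
    above = j < i
    F[above] = -np.log((i[above] - j[above]) ** 2.0)
    return F


def _sort_objective(B: np.ndarray, perm: np.ndarray, F: np.ndarray) -> float:
    return float((B[np.ix_(perm, perm)] * F).sum())


def _above_mass(B: np.ndarray, perm: np.ndarray) -> float:
    Bs = B[np.ix_(perm, perm)]
    return float(np.triu(Bs, k=1).sum())


def sort_states(B: np.ndarray, seed: int = 0, n_restarts: int = 30) -> np.ndarray:
    """Permutation maximizing similarity of the reordered B to the band target F.

    Exact enumeration for K <= 8; otherwise seeded restarts of greedy
    insertion followed by pairwise-swap hill climbing.  The objective is
    degenerate about mass placed below the diagonal (it scores 0 there), so
    ties are broken toward the permutation with the larger above-diagonal
    mass, matching the forward-running intent of the band target.
    """
    B = np.asarray(B, dtype=float)
    K = B.shape[0]
    F = _sort_target(K)
    if K <= 8:
        best, best_key = None, None
        for perm in itertools.permutations(range(K)):
            p = np.array(perm)
            key = (_sort_objective(B, p, F), _above_mass(B, p))
            if best_key is None or key > best_key:
                best, best_key = p, key
        return best

    rng = np.random.default_rng(seed)
    best, best_key = None, None
    for _ in range(n_restarts):
        perm = _greedy_insertion(B, F, rng)
        perm = _swap_hill_climb(B, F, perm)
        key = (_sort_objective(B, perm, F), _above_mass(B, perm))
        if best_key is None or key > best_key:
            best, best_key = perm.copy(), key
    return best


def _greedy_insertion(B: np.ndarray, F: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    K = B.shape[0]
    states = list(rng.permutation(K))
    order = [states.pop(0)]
    for s in states:
        cand_best, cand_val = 0, -np.inf
        for pos in range(len(order) + 1):
            trial = np.array(order[:pos] + [s] + order[pos:])
            m = len(trial)
            val = _sort_objective(B, trial, F[:m, :m])
            if val > cand_val:
                cand_best, cand_val = pos, val
        order.insert(cand_best, s)
    return np.array(order)


def _swap_hill_climb(B: np.ndarray, F: np.ndarray, perm: np.ndarray, max_sweeps: int = 60) -> np.ndarray:
    perm = perm.copy()
    K = len(perm)
    cur = _sort_objective(B, perm, F)
    for _ in range(max_sweeps):
        improved = False
        for a in range(K - 1):
            for bpos in range(a + 1, K):
                perm[a], perm[bpos] = perm[bpos], perm[a]
                val = _sort_objective(B, perm, F)
                if val > cur + 1e-12:
                    cur = val
                    improved = True
                else:
                    perm[a], perm[bpos] = perm[bpos], perm[a]
        if not improved:
            break
    return perm


@dataclass
class TransitionStats:
    """Reverse/two-step transition probabilities and the n-nearest curve."""

    nearest_curve: np.ndarray  # (K, K-1) per-state cumulative prob to n nearest
    mean_nearest_curve: np.ndarray  # (K-1,)
    near_pairs: list[tuple[int, int]]  # (j, i) with i among j's n_near top successors
    reverse_prob: np.ndarray  # B[i, j] per near pair
    forward_two_step: np.ndarray  # max_k B[j,k] B[k,i] per near pair
    backward_two_step: np.ndarray  # max_k B[i,k] B[k,j] per near pair
    baseline: float  # mean off-diagonal transition probability


def transition_stats(analysis: TransitionAnalysis, n_near: int = 5) -> TransitionStats:
    """Transition sparsity and asymmetry statistics of the B matrix."""
    B = analysis.B
    K = B.shape[0]
    sorted_rows = np.sort(B, axis=1)[:, ::-1]  # descending
    curve = np.cumsum(sorted_rows[:, : K - 1], axis=1)
    pairs: list[tuple[int, int]] = []
    rev, fwd2, bwd2 = [], [], []
    for j in range(K):
        if analysis.absorbing[j]:
            continue
        top = np.argsort(-B[j])[:n_near]
        for i in top:
            pairs.append((j, int(i)))
            rev.append(B[i, j])
            fwd2.append(np.max(B[j] * B[:, i]))
            bwd2.append(np.max(B[i] * B[:, j]))
    off = B[~np.eye(K, dtype=bool)]
    return TransitionStats(
        nearest_curve=curve,
        mean_nearest_curve=curve.mean(axis=0),
        near_pairs=pairs,
        reverse_prob=np.array(rev),
        forward_two_step=np.array(fwd2),
        backward_two_step=np.array(bwd2),
        baseline=float(off.mean()),
    )


def forward_sequences(path: np.ndarray, order: np.ndarray) -> dict[int, int]:
    """Histogram of maximal strictly-increasing run lengths in the sorted state order.

    Consecutive duplicate states are collapsed first; ``order`` is the
    permutation from :func:`sort_states` (order[r] = original state at rank r).
    """
    path = np.asarray(path, dtype=int)
    if path.size == 0:
        return {}
    rank = np.empty(len(order), dtype=int)
    rank[np.asarray(order)] = np.arange(len(order))
    collapsed = path[np.insert(np.diff(path) != 0, 0, True)]
    seq = rank[collapsed]
    hist: dict[int, int] = {}
    run = 1
    for a, bv in zip(seq[:-1], seq[1:]):
        if bv > a:
            run += 1
        else:
            hist[run] = hist.get(run, 0) + 1
            run = 1
    hist[run] = hist.get(run, 0) + 1
    return hist


# ---------------------------------------------------------------------------
# State-conditioned neural populations
# ---------------------------------------------------------------------------


@dataclass
class StateTrials:
    """Per-state occupancy trials and state-tuned neural population summaries."""

    trials: dict[int, list[tuple[int, int]]]  # state -> [(start, end)) in neural frames
    selected: dict[int, np.ndarray]  # state -> top_n neuron indices (train-selected)
    train_response: dict[int, np.ndarray]  # state -> mean train-trial response of selected
    test_response: dict[int, np.ndarray]  # state -> mean test-trial response of selected
    n_trials: dict[int, tuple[int, int]]  # state -> (n_train, n_test)


def resample_path(path: np.ndarray, path_rate: float, target_times: np.ndarray) -> np.ndarray:
    """State at the last path frame at or before each target time."""
    idx = np.floor(target_times * path_rate).astype(int)
    idx = np.clip(idx, 0, len(path) - 1)
    return np.asarray(path)[idx]


def state_trials(path: np.ndarray) -> dict[int, list[tuple[int, int]]]:
    """Uninterrupted same-state runs as half-open (start, end) frame intervals."""
    path = np.asarray(path, dtype=int)
    out: dict[int, list[tuple[int, int]]] = {}
    start = 0
    for t in range(1, len(path) + 1):
        if t == len(path) or path[t] != path[start]:
            out.setdefault(int(path[start]), []).append((start, t))
            start = t
    return out


def state_tuned_populations(
    path: np.ndarray,
    neural: NeuralRecording,
    top_n: int = 300,
    train_frac: float = 0.5,
) -> StateTrials:
    """Select state-selective neurons on train trials; report test-trial averages.

    ``path`` must already be at neural frame resolution (see
    :func:`resample_path`).  Trials are uninterrupted same-state runs; a
    neuron's trial response is its mean z-scored activity over the trial.
    Trials are split train/test by alternation, the ``top_n`` neurons with
    the highest mean train-trial response are selected per state, and their
    mean test-trial responses are reported.  States with fewer than 2 trials
    are excluded with a warning.
    """
    z, _ = neural.zscored()
    trials = state_trials(path)
    selected, train_resp, test_resp, counts = {}, {}, {}, {}
    kept: dict[int, list[tuple[int, int]]] = {}
    for s, runs in sorted(trials.items()):
        if len(runs) < 2:
            logger.warning("state %d has %d trial(s); excluded", s, len(runs))
            continue
        responses = np.stack([z[:, a:b].mean(axis=1) for a, b in runs], axis=0)  # trials x neurons
        n_train = max(1, int(round(train_frac * len(runs))))
        train_ids = np.arange(0, len(runs), 2)[: n_train]
        test_ids = np.setdiff1d(np.arange(len(runs)), train_ids)
        if len(test_ids) == 0:
            test_ids = train_ids[-1:]
        train_mean = responses[train_ids].mean(axis=0)
        top = np.argsort(-train_mean)[: min(top_n, neural.n_neurons)]
        kept[s] = runs
        selected[s] = top
        train_resp[s] = train_mean[top]
        test_resp[s] = responses[test_ids].mean(axis=0)[top]
        counts[s] = (len(train_ids), len(test_ids))
    return StateTrials(trials=kept, selected=selected, train_response=train_resp,
                       test_response=test_resp, n_trials=counts)


def control_shuffle(z: np.ndarray, seed: int = 0, mode: str = "time-shuffle") -> np.ndarray:
    """Temporal control: random permutation of timepoints, jointly across features."""
    if mode != "time-shuffle":
        raise ValueError(f"unknown shuffle mode {mode!r}")
    z = np.atleast_2d(np.asarray(z))
    rng = np.random.default_rng(seed)
    return z[rng.permutation(z.shape[0])]
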