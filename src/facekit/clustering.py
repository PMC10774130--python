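"""Scaled k-means clustering of neurons and the spatial locality index.

Scaled k-means models each neuron's z-scored activity as a scalar gain times
its cluster's temporal pattern plus noise, ``x_i = lambda_i mu_{sigma_i} +
noise``, and alternates gain/assignment updates with cluster-mean
re-estimation.  The gain is unconstrained in sign (z-scored activity can
anti-correlate with its cluster); each cluster mean's sign is fixed so the
majority of member gains are positive.

The locality index of a cluster is the KL divergence between the cluster's
discretized spatial distribution in the field of view and that of all
neurons (200 um bins anchored at the data bounding box): low values mean
the cluster is spatially diffuse.  Correlating the locality index with each
cluster's behavior-prediction r links spatial spread to predictability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import kmeans_plusplus

from .io_core import logger


@dataclass
class ClusterModel:
    assignments: np.ndarray  # (neurons,)
    means: np.ndarray  # (k, T) cluster temporal patterns
    scales: np.ndarray  # (neurons,) per-neuron gain lambda_i
    traces: np.ndarray  # (k, T) mean member activity per cluster
    objective: np.ndarray  # per-iteration sum of squared residuals
    k: int


def _objective(X, means, assign, scales):
    return float(((X - scales[:, None] * means[assign]) ** 2).sum())


def scaled_kmeans(
    activity: np.ndarray,
    k: int = 100,
    n_iter: int = 100,
    seed: int = 0,
) -> ClusterModel:
    """Alternating optimization of gains, assignments and cluster means.

    Per iteration: for the current means, each neuron's optimal gain against
    cluster j is ``(x_i . mu_j) / (mu_j . mu_j)`` and it is assigned to the
    cluster minimizing the residual ``||x_i - lambda mu_j||^2``; each mean is
    then the gain-weighted average ``sum lambda_i x_i / sum lambda_i^2`` over
    members.  Emptied clusters are re-seeded from the worst-fit neuron.
    Stops at an assignment fixpoint or ``n_iter``; deterministic given seed.
    """
    X = np.asarray(activity, dtype=float)
    n, T = X.shape
    if k > n:
        raise ValueError(f"k={k} exceeds {n} neurons")
    if not np.isfinite(X).all():
        raise ValueError("activity must be finite")
    norms = np.maximum(np.linalg.norm(X, axis=1, keepdims=True), 1e-12)
    means, _ = kmeans_plusplus(X / norms, n_clusters=k, random_state=seed)
    x2 = (X**2).sum(axis=1)
    assign = np.full(n, -1)
    objective = []
    for it in range(n_iter):
        m2 = np.maximum((means**2).sum(axis=1), 1e-300)
        G = X @ means.T  # (n, k)
        # residual of the gain-optimal fit: ||x||^2 - (x.mu)^2/||mu||^2
        score = G**2 / m2
        new_assign = np.argmax(score, axis=1)
        scales = G[np.arange(n), new_assign] / m2[new_assign]
        # re-seed empty clusters from worst-fit neurons
        empty = np.setdiff1d(np.arange(k), new_assign)
        if len(empty):
            resid = x2 - score[np.arange(n), new_assign]
            worst = np.argsort(-resid)
            for e, w in zip(empty, worst):
                logger.info("scaled_kmeans: re-seeding empty cluster %d from neuron %d", e, w)
                new_assign[w] = e
                scales[w] = 1.0
                means[e] = X[w]
        for j in range(k):
            member = new_assign == j
            lam = scales[member]
            denom = (lam**2).sum()
            if denom > 0:
                means[j] = lam @ X[member] / denom
        # fix sign: majority-positive gains
        for j in range(k):
            member = new_assign == j
            if member.any() and (scales[member] < 0).sum() > (scales[member] > 0).sum():
                means[j] *= -1
                scales[member] *= -1
        objective.append(_objective(X, means, new_assign, scales))
        # stop once assignments are stable AND the means have converged
        # (with stable assignments the mean/gain updates are a power
        # iteration that still needs a few rounds, e.g. at k = 1)
        if np.array_equal(new_assign, assign) and len(objective) >= 2 and (
            objective[-2] - objective[-1] <= 1e-10 * max(abs(objective[-1]), 1.0)
        ):
            assign = new_assign
            break
        assign = new_assign
    traces = np.stack([
        X[assign == j].mean(axis=0) if (assign == j).any() else np.zeros(T)
        for j in range(k)
    ])
    return ClusterModel(assignments=assign, means=means, scales=scales,
                        traces=traces, objective=np.array(objective), k=k)


def cluster_prediction_r(
    model: ClusterModel,
    activity: np.ndarray,
    predictions: np.ndarray,
    test_idx: np.ndarray | None = None,
) -> np.ndarray:
    """Pearson r between each cluster's mean member prediction and activity.

    Both the per-neuron predicted activity and the true activity are
    averaged over cluster members, then correlated on ``test_idx``
    (all timepoints when None).  Constant traces give NaN (flagged).
    """
    activity = np.asarray(activity, dtype=float)
    predictions = np.asarray(predictions, dtype=float)
    if test_idx is None:
        test_idx = np.arange(activity.shape[1])
    r = np.full(model.k, np.nan)
    for j in range(model.k):
        member = model.assignments == j
        if not member.any():
            continue
        a = activity[member][:, test_idx].mean(axis=0)
        p = predictions[member][:, test_idx].mean(axis=0)
        if a.std() == 0 or p.std() == 0:
            logger.warning("cluster %d has a constant trace; r undefined", j)
            continue
        r[j] = np.corrcoef(a, p)[0, 1]
    return r


def locality_index(
    model: ClusterModel | np.ndarray,
    positions: np.ndarray,
    bin_um: float = 200.0,
) -> np.ndarray:
    """KL divergence of each cluster's spatial distribution from the population's.

    Positions are histogrammed in ``bin_um`` square bins over the data
    bounding box.  Q (all neurons) gets a 0.5 pseudocount in each occupied
    bin before normalization so the divergence is defined after
    discretization; P (cluster members) is the raw normalized histogram.
    """
    assignments = np.asarray(getattr(model, "assignments", model))
    k = getattr(model, "k", assignments.max() + 1)
    positions = np.asarray(positions, dtype=float)
    lo = positions.min(axis=0)
    hi = positions.max(axis=0)
    if np.any(hi - lo <= 0):
        raise ValueError("degenerate field of view (zero spatial extent)")
    edges = [np.arange(lo[d], hi[d] + bin_um, bin_um) for d in range(2)]
    for d in range(2):
        if len(edges[d]) < 2 or edges[d][-1] < hi[d]:
            edges[d] = np.append(edges[d], edges[d][-1] + bin_um)
    Qc, _, _ = np.histogram2d(positions[:, 0], positions[:, 1], bins=edges)
    occupied = Qc > 0
    Qc = Qc + 0.5 * occupied
    Q = Qc / Qc.sum()
    kl = np.full(k, np.nan)
    for j in range(k):
        member = assignments == j
        if not member.any():
            continue
        Pc, _, _ = np.histogram2d(positions[member, 0], positions[member, 1], bins=edges)
        P = Pc / Pc.sum()
        nz = P > 0
        kl[j] = float((P[nz] * np.log(P[nz] / Q[nz])).sum())
    return kl
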