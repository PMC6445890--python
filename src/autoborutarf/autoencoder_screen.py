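"""Autoencoder-based feature screening via Gedeon weight contributions.

A single-hidden-layer autoencoder (tanh hidden units, linear reconstruction)
is trained per real-valued feature kind.  Inputs are then ranked by their
Gedeon proportional contribution through the network weights:

    P_ik = |W_ik| / sum_i* |W_i*k|        (input i -> hidden unit k)
    P_kj = |V_kj| / sum_k* |V_k*j|        (hidden unit k -> output j)
    Q_ij = sum_k P_ik * P_kj              (input i -> output j)
    q_i  = sum_j Q_ij / sum_i* Q_i*j      (total contribution of input i)

Columns of P and Q each sum to one, so sum_i q_i = G.  The bottom half of
the ranking is dropped, then features whose mean absolute Pearson
correlation with the other survivors exceeds 0.95 are pruned (lowest
contribution first).  Binary mutation features never pass through here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import FeatureMatrix

logger = logging.getLogger("autoborutarf")


class TrainingDivergenceError(RuntimeError):
    pass


class DegenerateNetworkError(ValueError):
    pass


class DegenerateScreenError(ValueError):
    pass


@dataclass
class AutoencoderModel:
    """Weights of a trained single-hidden-layer tanh autoencoder."""

    W: np.ndarray  # (G, K) encoder weights
    b_enc: np.ndarray  # (K,)
    V: np.ndarray  # (K, G) decoder weights
    b_dec: np.ndarray  # (G,)
    epochs_run: int = 0
    final_loss: float = float("nan")
    seed: int | None = None

    def __post_init__(self) -> None:
        G, K = self.W.shape
        if self.V.shape != (K, G):
            raise ValueError(f"decoder shape {self.V.shape} != ({K}, {G})")
        for arr in (self.W, self.b_enc, self.V, self.b_dec):
            if not np.all(np.isfinite(arr)):
                raise ValueError("non-finite weight")

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        return np.tanh(X @ self.W + self.b_enc) @ self.V + self.b_dec


@dataclass
class ContributionScores:
    feature_ids: list[str]
    P: np.ndarray  # (G, K)
    Q: np.ndarray  # (G, G)
    q: np.ndarray  # (G,)

    def ranked(self) -> pd.Series:
        s = pd.Series(self.q, index=self.feature_ids, name="q")
        return s.sort_values(ascending=False, kind="stable")


def default_hidden_size(n_features: int) -> int:
    """Bottleneck width for the screening autoencoder.

    The hidden layer must be narrow relative to G: with ample capacity the
    network can dedicate units to individual inputs and the contribution
    ranking degenerates to noise, whereas a tight bottleneck forces it to
    encode shared-variance structure (co-expression modules), which is what
    the screen should retain.
    """
    return min(32, max(2, int(np.ceil(n_features / 10))))


def train_autoencoder(matrix: FeatureMatrix, hidden_size: int | None = None,
                      epochs: int = 500, learning_rate: float = 1e-2,
                      seed: int = 0) -> AutoencoderModel:
    """Train by full-batch Adam on the mean squared reconstruction error.

    Inputs are standardised internally (tanh saturates on raw expression
    scales); the model is deterministic for a fixed seed.  Training stops
    early when the relative loss change stays below 1e-6 for 20 epochs.
    """
    if matrix.kind == "snv":
        raise ValueError("mutation features are not screened by autoencoder")
    if matrix.n_missing:
        raise ValueError("matrix must be complete")
    X = matrix.values.to_numpy(dtype=float)
    n, G = X.shape
    K = hidden_size if hidden_size is not None else default_hidden_size(G)
    if K < 1:
        raise ValueError("hidden_size must be >= 1")

    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd

    rng = np.random.default_rng(seed)
    lim_enc = np.sqrt(6.0 / (G + K))
    lim_dec = np.sqrt(6.0 / (K + G))
    params = [rng.uniform(-lim_enc, lim_enc, (G, K)), np.zeros(K),
              rng.uniform(-lim_dec, lim_dec, (K, G)), np.zeros(G)]

    # full-batch Adam
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]

    def loss_and_grads(W, b1, V, b2):
        H = np.tanh(Xs @ W + b1)
        R = H @ V + b2
        err = R - Xs
        loss = float((err ** 2).mean())
        gR = 2.0 * err / err.size
        gV = H.T @ gR
        gb2 = gR.sum(axis=0)
        gH = gR @ V.T
        gZ = gH * (1.0 - H ** 2)
        gW = Xs.T @ gZ
        gb1 = gZ.sum(axis=0)
        return loss, [gW, gb1, gV, gb2]

    loss = loss_and_grads(*params)[0]
    plateau = 0
    epochs_run = 0
    for t in range(1, epochs + 1):
        loss_new, grads = loss_and_grads(*params)
        for i, g in enumerate(grads):
            m[i] = beta1 * m[i] + (1 - beta1) * g
            v[i] = beta2 * v[i] + (1 - beta2) * g ** 2
            mhat = m[i] / (1 - beta1 ** t)
            vhat = v[i] / (1 - beta2 ** t)
            params[i] = params[i] - learning_rate * mhat / (np.sqrt(vhat) + eps)
        epochs_run = t
        if not np.isfinite(loss_new):
            raise TrainingDivergenceError(
                f"non-finite loss at epoch {t} (lr={learning_rate})")
        rel = abs(loss - loss_new) / max(loss, 1e-300)
        plateau = plateau + 1 if rel < 1e-6 else 0
        loss = loss_new
        if plateau >= 20:
            break
    final = loss_and_grads(*params)[0]
    return AutoencoderModel(W=params[0], b_enc=params[1], V=params[2],
                            b_dec=params[3], epochs_run=epochs_run,
                            final_loss=final, seed=seed)


def gedeon_contributions(model: AutoencoderModel,
                         feature_ids=None) -> ContributionScores:
    """Proportional weight-magnitude contribution of every input feature."""
    W = np.abs(model.W)  # (G, K)
    V = np.abs(model.V)  # (K, G)
    G = W.shape[0]
    col_enc = W.sum(axis=0)
    if np.any(col_enc == 0):
        raise DegenerateNetworkError("hidden unit with all-zero incoming weights")
    P = W / col_enc  # (G, K), columns sum to 1
    col_dec = V.sum(axis=0)
    if np.any(col_dec == 0):
        raise DegenerateNetworkError("output with all-zero incoming weights")
    Pd = V / col_dec  # (K, G), columns sum to 1
    Q = P @ Pd  # (G, G)
    q = (Q / Q.sum(axis=0)).sum(axis=1)
    if feature_ids is None:
        feature_ids = [str(i) for i in range(G)]
    return ContributionScores(feature_ids=list(feature_ids), P=P, Q=Q, q=q)


def screen_features(matrix: FeatureMatrix, scores: ContributionScores,
                    keep_fraction: float = 0.5,
                    corr_threshold: float = 0.95) -> FeatureMatrix:
    """Apply the contribution cut and correlation pruning.

    Ranks features by q descending and drops the bottom
    ``floor((1 - keep_fraction) * G)``; then walks the survivors in
    ascending-q order and removes any whose mean absolute Pearson correlation
    with the remaining survivors exceeds ``corr_threshold``, so the
    lower-contribution members of a correlated group go first.
    """
    if list(matrix.feature_ids) != list(scores.feature_ids):
        raise ValueError("scores not aligned with matrix columns")
    G = len(scores.feature_ids)
    n_drop = int(np.floor((1.0 - keep_fraction) * G))
    order = np.argsort(-scores.q, kind="stable")  # descending q, stable
    keep_idx = sorted(order[:G - n_drop])
    survivors = [scores.feature_ids[i] for i in keep_idx]
    q_kept = {scores.feature_ids[i]: scores.q[i] for i in keep_idx}

    df = matrix.values[survivors]
    corr = df.corr().abs().to_numpy()
    np.fill_diagonal(corr, np.nan)
    corr = np.nan_to_num(corr)  # constant columns: treat correlation as 0

    alive = {f: True for f in survivors}
    by_q_asc = sorted(survivors, key=lambda f: (q_kept[f], survivors.index(f)))
    pos = {f: i for i, f in enumerate(survivors)}
    for f in by_q_asc:
        others = [pos[g] for g in survivors if alive[g] and g != f]
        if not others:
            continue
        if corr[pos[f], others].mean() > corr_threshold:
            alive[f] = False
    kept = [f for f in survivors if alive[f]]
    if len(kept) < 2:
        raise DegenerateScreenError(
            f"only {len(kept)} features survive the screen")
    if len(kept) < len(survivors):
        logger.info("correlation pruning removed %d of %d survivors",
                    len(survivors) - len(kept), len(survivors))
    return matrix.subset(features=kept)


def screen_kind(matrix: FeatureMatrix, keep_fraction: float = 0.5,
                corr_threshold: float = 0.95, hidden_size: int | None = None,
                epochs: int = 500, learning_rate: float = 1e-2,
                seed: int = 0):
    """Train + rank + screen one real-valued feature kind.

    Returns ``(reduced_matrix, scores)``.
    """
    model = train_autoencoder(matrix, hidden_size=hidden_size, epochs=epochs,
                              learning_rate=learning_rate, seed=seed)
    scores = gedeon_contributions(model, feature_ids=matrix.feature_ids)
    reduced = screen_features(matrix, scores, keep_fraction=keep_fraction,
                              corr_threshold=corr_threshold)
    return reduced, scores
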