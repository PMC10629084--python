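"""Linear-chain conditional random field for token sequence labeling.

A discriminative sequence model: the score of a tag sequence ``y`` for a
token sequence with binary feature vectors ``x_t`` is

    s(x, y) = b_start[y_1] + sum_t  w[:, y_t] . x_t
                            + sum_t  T[y_{t-1}, y_t]  + b_end[y_T]

and ``p(y|x) = exp(s) / Z(x)``.  Training maximizes the penalized
log-likelihood with an elastic-net penalty (L1 + L2) using L-BFGS; the
non-smooth L1 term is handled exactly by splitting each weight into a
positive and a negative part and bound-constraining both at zero, which
turns the problem into a smooth box-constrained one solvable by L-BFGS-B.
Decoding uses the Viterbi algorithm.  All recursions (forward, backward,
marginals, Viterbi) are vectorized across the whole batch of sequences.

:class:`CrfTagger` wraps the model as a scikit-learn style estimator whose
``X`` is a list of sequences of per-token feature-string lists (as produced
by :func:`labdigitize.features.extract_features`) and whose ``y`` is a list
of tag-string sequences.
"""

from __future__ import annotations

import pickle
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.optimize import minimize
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

__all__ = ["CrfTagger"]

_MODEL_FORMAT_VERSION = 1


def _build_design(
    X: Sequence[Sequence[Sequence[str]]], feat_index: dict[str, int]
) -> tuple[sp.csr_matrix, np.ndarray]:
    """Stack all tokens of all sequences into one sparse indicator matrix."""
    lengths = np.array([len(seq) for seq in X], dtype=np.int64)
    rows, cols = [], []
    r = 0
    for seq in X:
        for feats in seq:
            for f in feats:
                j = feat_index.get(f)
                if j is not None:
                    rows.append(r)
                    cols.append(j)
            r += 1
    data = np.ones(len(rows), dtype=np.float64)
    mat = sp.csr_matrix(
        (data, (rows, cols)), shape=(int(lengths.sum()), len(feat_index))
    )
    return mat, lengths


def _pad_scores(
    flat: np.ndarray, lengths: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Reshape (total_tokens, K) emission scores to (S, Tmax, K) + mask."""
    S = len(lengths)
    Tmax = int(lengths.max())
    K = flat.shape[1]
    E = np.zeros((S, Tmax, K))
    mask = np.zeros((S, Tmax), dtype=bool)
    offs = np.concatenate([[0], np.cumsum(lengths)])
    for s in range(S):
        L = lengths[s]
        E[s, :L] = flat[offs[s] : offs[s] + L]
        mask[s, :L] = True
    return E, mask


class _Batch:
    """Padded emission scores and gold tags for a set of sequences."""

    def __init__(self, flat_scores: np.ndarray, lengths: np.ndarray):
        self.lengths = lengths
        self.offsets = np.concatenate([[0], np.cumsum(lengths)])
        self.E, self.mask = _pad_scores(flat_scores, lengths)
        self.S, self.Tmax, self.K = self.E.shape


def _forward(batch: _Batch, T: np.ndarray, b_start: np.ndarray) -> np.ndarray:
    """All forward (alpha) log-messages, frozen past each sequence's end."""
    alphas = np.empty((batch.S, batch.Tmax, batch.K))
    alpha = b_start[None, :] + batch.E[:, 0]
    alphas[:, 0] = alpha
    for t in range(1, batch.Tmax):
        nxt = logsumexp(alpha[:, :, None] + T[None, :, :], axis=1) + batch.E[:, t]
        alpha = np.where(batch.mask[:, t, None], nxt, alpha)
        alphas[:, t] = alpha
    return alphas


def _backward(batch: _Batch, T: np.ndarray, b_end: np.ndarray) -> np.ndarray:
    betas = np.empty((batch.S, batch.Tmax, batch.K))
    beta = np.broadcast_to(b_end, (batch.S, batch.K)).copy()
    betas[:, batch.Tmax - 1] = beta
    for t in range(batch.Tmax - 2, -1, -1):
        inner = (batch.E[:, t + 1] + beta)[:, None, :] + T[None, :, :]
        nxt = logsumexp(inner, axis=2)
        beta = np.where(batch.mask[:, t + 1, None], nxt, beta)
        betas[:, t] = beta
    return betas


class CrfTagger(BaseEstimator):
    """Linear-chain CRF sequence tagger (L-BFGS, elastic-net penalty).

    Parameters
    ----------
    c1 : float, default 0.1
        L1 penalty coefficient (drives sparse feature weights).
    c2 : float, default 0.1
        L2 penalty coefficient.
    max_iterations : int, default 100
        L-BFGS iteration cap.

    Attributes
    ----------
    classes_ : list of str
        Tag alphabet observed in training data (sorted).
    feature_names_ : list of str
        Feature vocabulary observed in training data (sorted).
    state_weights_ : ndarray (n_features, n_classes)
    transition_weights_ : ndarray (n_classes, n_classes)
    n_iter_ : int
    objective_ : float
        Final penalized negative log-likelihood.
    """

    def __init__(self, c1: float = 0.1, c2: float = 0.1, max_iterations: int = 100):
        self.c1 = c1
        self.c2 = c2
        self.max_iterations = max_iterations

    # -- parameter (un)flattening ------------------------------------------

    def _split(self, theta: np.ndarray):
        F, K = len(self.feature_names_), len(self.classes_)
        W = theta[: F * K].reshape(F, K)
        T = theta[F * K : F * K + K * K].reshape(K, K)
        b_start = theta[F * K + K * K : F * K + K * K + K]
        b_end = theta[F * K + K * K + K :]
        return W, T, b_start, b_end

    def _nll_grad(self, theta, Xmat, batch_template, emp_stats):
        """Unpenalized NLL and gradient over the training batch."""
        W, T, b_start, b_end = self._split(theta)
        flat_scores = Xmat @ W
        batch = _Batch(flat_scores, batch_template.lengths)
        alphas = _forward(batch, T, b_start)
        betas = _backward(batch, T, b_end)
        last = batch.lengths - 1
        logZ = logsumexp(alphas[np.arange(batch.S), last] + b_end[None, :], axis=1)

        # Gold path scores.
        y_flat, y_first, y_last, emp_trans, emp_first, emp_last = emp_stats
        gold_emit = flat_scores[np.arange(flat_scores.shape[0]), y_flat].sum()
        gold = (
            gold_emit
            + b_start[y_first].sum()
            + b_end[y_last].sum()
            + (emp_trans * T).sum()
        )
        nll = logZ.sum() - gold

        # Unary marginals at valid positions, flattened to token order.
        post = np.exp(alphas + betas - logZ[:, None, None])
        P_flat = np.empty_like(flat_scores)
        for s in range(batch.S):
            L = batch.lengths[s]
            P_flat[batch.offsets[s] : batch.offsets[s] + L] = post[s, :L]

        # Expected minus empirical emission feature counts.
        P_flat[np.arange(len(y_flat)), y_flat] -= 1.0
        gW = np.asarray(Xmat.T @ P_flat)

        # Pairwise marginals -> expected transitions.
        exp_trans = np.zeros((batch.K, batch.K))
        for t in range(1, batch.Tmax):
            valid = batch.mask[:, t]
            if not valid.any():
                continue
            M = (
                alphas[valid, t - 1][:, :, None]
                + T[None, :, :]
                + (batch.E[valid, t] + betas[valid, t])[:, None, :]
                - logZ[valid][:, None, None]
            )
            exp_trans += np.exp(M).sum(axis=0)
        gT = exp_trans - emp_trans

        g_start = post[:, 0, :].sum(axis=0) - np.bincount(
            y_first, minlength=batch.K
        )
        g_end = post[np.arange(batch.S), last].sum(axis=0) - np.bincount(
            y_last, minlength=batch.K
        )
        grad = np.concatenate([gW.ravel(), gT.ravel(), g_start, g_end])
        return nll, grad

    # -- estimator API ------------------------------------------------------

    def fit(self, X, y):
        """Fit on sequences of feature lists ``X`` and tag sequences ``y``.

        Training is deterministic given corpus order and hyperparameters.
        """
        if len(X) == 0:
            raise ValueError("training corpus is empty")
        if len(X) != len(y):
            raise ValueError("X and y have different numbers of sequences")
        for i, (xs, ys) in enumerate(zip(X, y)):
            if len(xs) == 0:
                raise ValueError(f"sequence {i} is empty")
            if len(xs) != len(ys):
                raise ValueError(f"sequence {i}: feature/tag length mismatch")
        if not np.isfinite(self.c1) or not np.isfinite(self.c2):
            raise ValueError("penalties must be finite")
        if self.c1 < 0 or self.c2 < 0:
            raise ValueError("penalties must be non-negative")

        self.classes_ = sorted({t for seq in y for t in seq})
        self.feature_names_ = sorted({f for seq in X for fl in seq for f in fl})
        feat_index = {f: j for j, f in enumerate(self.feature_names_)}
        tag_index = {t: k for k, t in enumerate(self.classes_)}
        K = len(self.classes_)

        Xmat, lengths = _build_design(X, feat_index)
        batch_template = _Batch(np.zeros((Xmat.shape[0], K)), lengths)

        y_flat = np.array([tag_index[t] for seq in y for t in seq], dtype=np.int64)
        y_first = np.array([tag_index[seq[0]] for seq in y], dtype=np.int64)
        y_last = np.array([tag_index[seq[-1]] for seq in y], dtype=np.int64)
        emp_trans = np.zeros((K, K))
        for seq in y:
            for a, b in zip(seq, seq[1:]):
                emp_trans[tag_index[a], tag_index[b]] += 1.0
        emp_stats = (y_flat, y_first, y_last, emp_trans, y_first, y_last)

        n_params = len(self.feature_names_) * K + K * K + 2 * K

        if self.c1 > 0:
            # w = p - q with p, q >= 0; L1 becomes a smooth linear term.
            def obj(z):
                p, q = z[:n_params], z[n_params:]
                theta = p - q
                nll, g = self._nll_grad(theta, Xmat, batch_template, emp_stats)
                f = nll + self.c2 * (theta @ theta) + self.c1 * (p.sum() + q.sum())
                g_theta = g + 2.0 * self.c2 * theta
                grad = np.concatenate([g_theta + self.c1, -g_theta + self.c1])
                return f, grad

            z0 = np.zeros(2 * n_params)
            res = minimize(
                obj,
                z0,
                jac=True,
                method="L-BFGS-B",
                bounds=[(0.0, None)] * (2 * n_params),
                options={"maxiter": self.max_iterations, "maxfun": 4 * self.max_iterations},
            )
            theta = res.x[:n_params] - res.x[n_params:]
        else:

            def obj(theta):
                nll, g = self._nll_grad(theta, Xmat, batch_template, emp_stats)
                return nll + self.c2 * (theta @ theta), g + 2.0 * self.c2 * theta

            res = minimize(
                obj,
                np.zeros(n_params),
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": self.max_iterations, "maxfun": 4 * self.max_iterations},
            )
            theta = res.x

        W, T, b_start, b_end = self._split(theta)
        self.state_weights_ = W
        self.transition_weights_ = T
        self.start_weights_ = b_start
        self.end_weights_ = b_end
        self.n_iter_ = int(res.nit)
        self.objective_ = float(res.fun)
        return self

    def predict(self, X) -> list[list[str]]:
        """Viterbi-decode the most likely tag sequence for each input."""
        if not hasattr(self, "state_weights_"):
            raise ValueError("CrfTagger is not fitted")
        nonempty = [i for i, seq in enumerate(X) if len(seq) > 0]
        out: list[list[str]] = [[] for _ in X]
        if not nonempty:
            return out
        feat_index = {f: j for j, f in enumerate(self.feature_names_)}
        Xmat, lengths = _build_design([X[i] for i in nonempty], feat_index)
        flat = Xmat @ self.state_weights_
        batch = _Batch(flat, lengths)
        T = self.transition_weights_
        K = batch.K

        delta = self.start_weights_[None, :] + batch.E[:, 0]
        back = np.zeros((batch.S, batch.Tmax, K), dtype=np.int32)
        deltas = np.empty((batch.S, batch.Tmax, K))
        deltas[:, 0] = delta
        for t in range(1, batch.Tmax):
            cand = delta[:, :, None] + T[None, :, :]
            best = cand.argmax(axis=1)
            nxt = np.take_along_axis(cand, best[:, None, :], axis=1)[:, 0, :]
            nxt = nxt + batch.E[:, t]
            delta = np.where(batch.mask[:, t, None], nxt, delta)
            back[:, t] = best
            deltas[:, t] = delta

        for row, i in enumerate(nonempty):
            L = int(lengths[row])
            final = deltas[row, L - 1] + self.end_weights_
            k = int(final.argmax())
            tags = [k]
            for t in range(L - 1, 0, -1):
                k = int(back[row, t, k])
                tags.append(k)
            tags.reverse()
            out[i] = [self.classes_[k] for k in tags]
        return out

    def score(self, X, y) -> float:
        """Token-level accuracy of Viterbi decoding against gold tags."""
        pred = self.predict(X)
        total = sum(len(s) for s in y)
        if total == 0:
            return 1.0
        hits = sum(
            p == g for ps, gs in zip(pred, y) for p, g in zip(ps, gs)
        )
        return hits / total

    # -- persistence --------------------------------------------------------

    def save(self, path: str) -> None:
        """Persist the fitted model (weights + vocab + hyperparams)."""
        payload = {
            "format_version": _MODEL_FORMAT_VERSION,
            "params": self.get_params(),
            "classes": self.classes_,
            "feature_names": self.feature_names_,
            "state_weights": self.state_weights_,
            "transition_weights": self.transition_weights_,
            "start_weights": self.start_weights_,
            "end_weights": self.end_weights_,
            "n_iter": self.n_iter_,
            "objective": self.objective_,
        }
        with open(path, "wb") as fh:
            pickle.dump(payload, fh)

    @classmethod
    def load(cls, path: str) -> "CrfTagger":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        if payload.get("format_version") != _MODEL_FORMAT_VERSION:
            raise ValueError("unsupported model format version")
        model = cls(**payload["params"])
        model.classes_ = payload["classes"]
        model.feature_names_ = payload["feature_names"]
        model.state_weights_ = payload["state_weights"]
        model.transition_weights_ = payload["transition_weights"]
        model.start_weights_ = payload["start_weights"]
        model.end_weights_ = payload["end_weights"]
        model.n_iter_ = payload["n_iter"]
        model.objective_ = payload["objective"]
        return model
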