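"""Model core: losses, the bias/residual factorization, and estimators.

Two sklearn-style estimators are exposed:

``ProfileCountModel``
    A single sequence-to-profile network (used both for the enzyme-bias
    submodel trained on background regions and for uncorrected models).

``BiasFactorizedModel``
    The factorized model: a frozen, pre-trained bias submodel plus a trainable
    residual (TF) submodel. Predicted profile probabilities are the
    renormalized product of the two submodels' probabilities (realized as
    logit addition + softmax) and predicted log counts combine additively with
    a scaling factor gamma.

The count heads work on the ``log(1 + counts)`` scale throughout.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import gammaln, xlogy
from scipy.stats import pearsonr
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .nn import (Adam, ArchitectureConfig, SeqCNN, receptive_field,
                 seed_kmer_filters, softmax)

__all__ = [
    "ProfilePrediction", "FactorizedPrediction", "ProfileCountModel",
    "BiasFactorizedModel", "mnll_loss", "mse_log_counts", "combined_loss",
    "estimate_gamma", "combine", "corrected_prediction", "receptive_field",
    "ArchitectureConfig",
]


# ---------------------------------------------------------------------------
# prediction containers
# ---------------------------------------------------------------------------

@dataclass
class ProfilePrediction:
    """Profile-head logits plus count-head output (log(1+counts) scale)."""

    logits: np.ndarray
    log_total: np.ndarray

    @property
    def probabilities(self) -> np.ndarray:
        return softmax(np.asarray(self.logits, dtype=np.float64), axis=-1)

    @property
    def total_counts(self) -> np.ndarray:
        return np.expm1(np.asarray(self.log_total, dtype=np.float64))


@dataclass
class FactorizedPrediction:
    tf_part: ProfilePrediction
    bias_part: ProfilePrediction
    gamma: float
    combined: ProfilePrediction = field(init=False)
    count_combine: str = "add"

    def __post_init__(self):
        self.combined = combine_parts(
            self.tf_part, self.bias_part, self.gamma, self.count_combine)


def _combine_log_totals(n_tf, n_bias, gamma: float, count_combine: str):
    if count_combine == "add":
        return n_tf + gamma * n_bias
    if count_combine == "logsumexp":
        return np.logaddexp(n_tf, np.log(gamma) + n_bias)
    raise ValueError(f"unknown count_combine {count_combine!r}")


def combine_parts(tf_part: ProfilePrediction, bias_part: ProfilePrediction,
                  gamma: float, count_combine: str = "add") -> ProfilePrediction:
    """Factorized combination: logits add (probability product after softmax),
    log-count heads combine as ``n_tf + gamma * n_bias`` (default) or through
    a log-sum-exp on the count scale."""
    return ProfilePrediction(
        logits=np.asarray(tf_part.logits) + np.asarray(bias_part.logits),
        log_total=_combine_log_totals(
            np.asarray(tf_part.log_total), np.asarray(bias_part.log_total),
            gamma, count_combine))


def combine(tf_part: ProfilePrediction, bias_part: ProfilePrediction,
            gamma: float, count_combine: str = "add") -> FactorizedPrediction:
    return FactorizedPrediction(tf_part=tf_part, bias_part=bias_part,
                                gamma=gamma, count_combine=count_combine)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def mnll_loss(k_obs: np.ndarray, probabilities: np.ndarray) -> float:
    """Multinomial negative log-likelihood (natural log) of observed counts
    ``k_obs`` under the predicted positional probabilities."""
    k = np.asarray(k_obs, dtype=np.float64)
    p = np.asarray(probabilities, dtype=np.float64)
    if k.shape != p.shape:
        raise ValueError("k_obs and probabilities must have the same shape")
    n = k.sum(axis=-1)
    log_pmf = (gammaln(n + 1) - gammaln(k + 1).sum(axis=-1)
               + xlogy(k, p).sum(axis=-1))
    return float(np.mean(-log_pmf)) if log_pmf.ndim else float(-log_pmf)


def mse_log_counts(n_obs, n_pred) -> float:
    """(log(1+n_obs) - log(1+n_pred))^2, averaged if vectors. Counts scale."""
    d = np.log1p(np.asarray(n_obs, dtype=np.float64)) - np.log1p(
        np.asarray(n_pred, dtype=np.float64))
    return float(np.mean(d * d))


def combined_loss(k_obs: np.ndarray, prediction: ProfilePrediction,
                  lambda_counts: float) -> float:
    """MNLL profile loss plus lambda times the squared log-count error."""
    k = np.asarray(k_obs, dtype=np.float64)
    mnll = mnll_loss(k, prediction.probabilities)
    mse = mse_log_counts(k.sum(axis=-1), prediction.total_counts)
    return mnll + lambda_counts * mse


def default_lambda(validation_totals) -> float:
    """lambda = median of total counts across validation sequences / 10."""
    return float(np.median(np.asarray(validation_totals, dtype=np.float64)) / 10.0)


def estimate_gamma(bias_log_totals, obs_totals) -> float:
    """gamma = exp(mean[log(n_bias + 1) - log(n_obs + 1)]) over regions.

    ``bias_log_totals`` are count-head outputs (already log(1+n) scale);
    ``obs_totals`` are raw observed totals.
    """
    b = np.asarray(bias_log_totals, dtype=np.float64)
    o = np.log1p(np.asarray(obs_totals, dtype=np.float64))
    return float(np.exp(np.mean(b - o)))


# ---------------------------------------------------------------------------
# training helpers
# ---------------------------------------------------------------------------

def _center_crop(arr: np.ndarray, target: int) -> np.ndarray:
    off = (arr.shape[1] - target) // 2
    return arr[:, off: off + target]


def _gather_crops(X, y, idx, offsets, input_len, output_len):
    xb = np.stack([X[i, o: o + input_len] for i, o in zip(idx, offsets)])
    yb = np.stack([y[i, o: o + output_len] for i, o in zip(idx, offsets)])
    return xb, yb


def _batch_losses(logits, log_counts, yb, lam):
    """Per-batch mean combined loss + grads wrt (logits, log_counts)."""
    k = yb.astype(np.float64)
    n = k.sum(axis=1)
    p = softmax(logits.astype(np.float64), axis=1)
    log_pmf = (gammaln(n + 1) - gammaln(k + 1).sum(axis=1)
               + xlogy(k, p).sum(axis=1))
    target = np.log1p(n)
    diff = log_counts.astype(np.float64) - target
    loss = float(np.mean(-log_pmf) + lam * np.mean(diff * diff))
    B = k.shape[0]
    dlogits = (p * n[:, None] - k) / B
    dlogc = 2.0 * lam * diff / B
    return loss, dlogits, dlogc


class _EarlyStopper:
    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.best_state = None
        self.best_epoch = -1
        self.bad = 0

    def update(self, loss: float, epoch: int, net: SeqCNN) -> bool:
        """Returns True when training should stop."""
        if loss < self.best - 1e-12:
            self.best = loss
            self.best_state = net.state_copy()
            self.best_epoch = epoch
            self.bad = 0
            return False
        self.bad += 1
        return self.bad >= self.patience


_ARCH_PARAM_NAMES = ("n_filters", "first_conv_width", "n_dilated_layers",
                     "dilated_width", "dilation_base", "profile_head_width",
                     "input_len", "output_len")


class _SeqModelBase(BaseEstimator):
    """Shared plumbing for the sequence-model estimators."""

    def _arch_config(self) -> ArchitectureConfig:
        return ArchitectureConfig(**{k: getattr(self, k) for k in _ARCH_PARAM_NAMES})

    def _validate_Xy(self, X, y, max_jitter):
        X = np.asarray(X)
        y = np.asarray(y)
        if X.ndim != 3 or X.shape[2] != 4:
            raise ValueError("X must be one-hot of shape (N, L, 4)")
        need_x = self.input_len + 2 * max_jitter
        need_y = self.output_len + 2 * max_jitter
        if X.shape[1] != need_x:
            raise ValueError(f"X window must be {need_x} bp (input_len + 2*max_jitter)")
        if y.shape != (X.shape[0], need_y):
            raise ValueError(f"y must have shape (N, {need_y})")
        if np.any(y < 0):
            raise ValueError("counts must be non-negative")
        return X, y

    def _crop_X(self, X) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim == 2:
            X = X[None]
        if X.shape[1] < self.input_len:
            raise ValueError("input window shorter than model input_len")
        return _center_crop(X, self.input_len)

    def _forward_batched(self, net, X, batch=64):
        logits, counts = [], []
        for i in range(0, X.shape[0], batch):
            lo, lc = net.forward(np.ascontiguousarray(X[i: i + batch]))
            logits.append(lo)
            counts.append(lc)
        return np.concatenate(logits), np.concatenate(counts)

    def score(self, X, y) -> float:
        """Pearson r between observed and predicted log(1+total counts)."""
        obs = np.log1p(np.asarray(y).sum(axis=1))
        pred = self.predict(X)
        return float(pearsonr(obs, pred)[0])


class ProfileCountModel(_SeqModelBase):
    """A single sequence-to-profile CNN with profile and count heads.

    Parameters follow the architecture fields plus training controls. ``X``
    passed to :meth:`fit` may carry a symmetric jitter margin: give
    ``max_jitter`` > 0 and windows of ``input_len + 2*max_jitter`` bp; each
    epoch every jitterable sample is randomly cropped (uniform offset),
    implementing summit jitter, while non-jitterable samples stay centered.
    """

    def __init__(self, n_filters=32, first_conv_width=21, n_dilated_layers=4,
                 dilated_width=3, dilation_base=2, profile_head_width=75,
                 input_len=1114, output_len=500, learning_rate=1e-3,
                 batch_size=32, max_epochs=100, patience=5,
                 lambda_counts=None, val_fraction=0.1, max_jitter=0,
                 count_refit_every=1, count_refit_alpha=1.0,
                 dropout=0.0, seed_patterns=None,
                 random_state=0, dtype="float32"):
        self.n_filters = n_filters
        self.first_conv_width = first_conv_width
        self.n_dilated_layers = n_dilated_layers
        self.dilated_width = dilated_width
        self.dilation_base = dilation_base
        self.profile_head_width = profile_head_width
        self.input_len = input_len
        self.output_len = output_len
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.lambda_counts = lambda_counts
        self.val_fraction = val_fraction
        self.max_jitter = max_jitter
        self.count_refit_every = count_refit_every
        self.count_refit_alpha = count_refit_alpha
        self.dropout = dropout
        self.seed_patterns = seed_patterns
        self.random_state = random_state
        self.dtype = dtype

    # -- fitting ------------------------------------------------------------
    def fit(self, X, y, X_val=None, y_val=None, jitterable=None):
        cfg = self._arch_config()
        X, y = self._validate_Xy(X, y, self.max_jitter)
        rng = np.random.default_rng(self.random_state)
        if X_val is None:
            n_val = max(1, int(round(self.val_fraction * X.shape[0])))
            perm = rng.permutation(X.shape[0])
            val_idx, tr_idx = perm[:n_val], perm[n_val:]
            X_val, y_val = X[val_idx], y[val_idx]
            X, y = X[tr_idx], y[tr_idx]
            if jitterable is not None:
                jitterable = np.asarray(jitterable)[tr_idx]
        Xv = _center_crop(np.asarray(X_val), cfg.input_len)
        yv = _center_crop(np.asarray(y_val), cfg.output_len)
        lam = (self.lambda_counts if self.lambda_counts is not None
               else default_lambda(yv.sum(axis=1)))
        self.lambda_ = lam
        net = SeqCNN(cfg, rng, dtype=np.dtype(self.dtype))
        if self.seed_patterns:
            seed_kmer_filters(net, self.seed_patterns)
        self.net_ = net
        self.config_ = cfg
        self._fit_loop(net, X, y, Xv, yv, jitterable, lam, rng,
                       bias_ctx=None)
        return self

    def _fit_loop(self, net, X, y, Xv, yv, jitterable, lam, rng, bias_ctx):
        """Shared training loop. ``bias_ctx`` (frozen bias net, gamma,
        count_combine) activates factorized training."""
        cfg = net.cfg
        N = X.shape[0]
        if jitterable is None:
            jitterable = np.zeros(N, dtype=bool)
        jitterable = np.asarray(jitterable, dtype=bool)
        # warm-start the count head bias at the mean training log total so
        # early epochs refine variation instead of chasing the global mean
        yc = _center_crop(y, cfg.output_len)
        net.params["count_b"][0] = np.log1p(yc.sum(axis=1)).mean()
        Xc = _center_crop(X, cfg.input_len)
        count_targets = np.log1p(yc.sum(axis=1))
        if bias_ctx is not None and self.count_refit_every:
            _, bias_c = self._forward_batched(bias_ctx["net"], Xc)
            g = bias_ctx["gamma"]
            if bias_ctx["count_combine"] == "add":
                count_targets = count_targets - g * bias_c
            else:
                count_targets = np.log(np.maximum(
                    np.exp(count_targets) - g * np.exp(bias_c), 1e-6))
        opt = Adam(net.params, lr=self.learning_rate)
        stopper = _EarlyStopper(self.patience)
        history = []
        if self.count_refit_every:
            self._refit_count_head(net, Xc, count_targets, opt)
        for epoch in range(self.max_epochs):
            perm = rng.permutation(N)
            offsets = np.full(N, self.max_jitter, dtype=int)
            if self.max_jitter > 0:
                jit = rng.integers(0, 2 * self.max_jitter + 1,
                                   size=int(jitterable.sum()))
                offsets[jitterable] = jit
            ep_loss, nb = 0.0, 0
            for s in range(0, N, self.batch_size):
                idx = perm[s: s + self.batch_size]
                xb, yb = _gather_crops(X, y, idx, offsets[idx],
                                       cfg.input_len, cfg.output_len)
                xb = np.ascontiguousarray(xb, dtype=net.dtype)
                logits, log_counts, cache = net.forward(
                    xb, want_cache=True, drop_p=self.dropout, drop_rng=rng)
                if bias_ctx is not None:
                    blogits, bcounts = bias_ctx["net"].forward(xb)
                    logits = logits + blogits
                    g = bias_ctx["gamma"]
                    if bias_ctx["count_combine"] == "add":
                        comb = log_counts + g * bcounts
                        dcomb_dtf = np.ones_like(log_counts)
                    else:
                        comb = np.logaddexp(log_counts, np.log(g) + bcounts)
                        dcomb_dtf = np.exp(log_counts - comb)
                    loss, dlogits, dlogc = _batch_losses(logits, comb, yb, lam)
                    dlogc = dlogc * dcomb_dtf
                else:
                    loss, dlogits, dlogc = _batch_losses(logits, log_counts,
                                                         yb, lam)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}")
                grads, _ = net.backward(cache, dlogits.astype(net.dtype),
                                        dlogc.astype(net.dtype))
                opt.step(net.params, grads)
                ep_loss += loss
                nb += 1
            if (self.count_refit_every and
                    epoch % self.count_refit_every == 0):
                # keep the count readout at its closed-form optimum so the
                # validation trajectory reflects trunk progress, not readout
                # drift
                self._refit_count_head(net, Xc, count_targets, opt)
            val_loss = self._validation_loss(net, Xv, yv, lam, bias_ctx)
            if not np.isfinite(val_loss):
                raise FloatingPointError(
                    f"non-finite validation loss at epoch {epoch}")
            history.append({"epoch": epoch, "train_loss": ep_loss / max(nb, 1),
                            "val_loss": val_loss})
            if stopper.update(val_loss, epoch, net):
                break
        if stopper.best_state is not None:
            net.load_state(stopper.best_state)
        self.best_epoch_ = stopper.best_epoch
        self.best_val_loss_ = stopper.best
        import pandas as pd
        self.history_ = pd.DataFrame(history)

    def _refit_count_head(self, net, Xc, targets, opt):
        """Closed-form ridge refit of the count readout on pooled features.

        At desk-scale step counts, gradient descent alone cannot bridge the
        scale mismatch between pooled-feature variation and log-count
        variation; periodically solving the final linear layer exactly
        (alternating minimization) lets the trunk receive meaningful count
        gradients from the start. For factorized training ``targets`` must
        already have the scaled bias count-head contribution removed.
        """
        from sklearn.linear_model import Ridge
        pooled = []
        for i in range(0, Xc.shape[0], 64):
            xb = np.ascontiguousarray(Xc[i: i + 64], dtype=net.dtype)
            _, _, cache = net.forward(xb, want_cache=True)
            pooled.append(cache["pooled"])
        P = np.concatenate(pooled).astype(np.float64)
        r = Ridge(alpha=self.count_refit_alpha).fit(P, targets)
        net.params["count_w"] = r.coef_.astype(net.dtype)
        net.params["count_b"] = np.array([r.intercept_], dtype=net.dtype)
        for k in ("count_w", "count_b"):  # moments no longer match
            opt.m[k][:] = 0.0
            opt.v[k][:] = 0.0

    def _validation_loss(self, net, Xv, yv, lam, bias_ctx):
        losses = []
        for i in range(0, Xv.shape[0], 64):
            xb = np.ascontiguousarray(Xv[i: i + 64], dtype=net.dtype)
            yb = yv[i: i + 64]
            logits, log_counts = net.forward(xb)
            if bias_ctx is not None:
                blogits, bcounts = bias_ctx["net"].forward(xb)
                logits = logits + blogits
                g = bias_ctx["gamma"]
                if bias_ctx["count_combine"] == "add":
                    log_counts = log_counts + g * bcounts
                else:
                    log_counts = np.logaddexp(log_counts,
                                              np.log(g) + bcounts)
            loss, _, _ = _batch_losses(logits, log_counts, yb, lam)
            losses.append(loss * xb.shape[0])
        return float(np.sum(losses) / Xv.shape[0])

    # -- prediction ---------------------------------------------------------
    def predict_logits(self, X) -> np.ndarray:
        check_is_fitted(self, "net_")
        return self._forward_batched(self.net_, self._crop_X(X))[0]

    def predict_log_counts(self, X) -> np.ndarray:
        check_is_fitted(self, "net_")
        return self._forward_batched(self.net_, self._crop_X(X))[1]

    def predict_profile(self, X) -> np.ndarray:
        return softmax(self.predict_logits(X).astype(np.float64), axis=1)

    def predict(self, X) -> np.ndarray:
        return self.predict_log_counts(X)

    def predict_prediction(self, X) -> ProfilePrediction:
        logits, counts = self._forward_batched(self.net_, self._crop_X(X))
        return ProfilePrediction(logits=logits, log_total=counts)

    # -- persistence --------------------------------------------------------
    def save(self, path_prefix: str) -> None:
        check_is_fitted(self, "net_")
        _save_net(path_prefix, self.net_, self.get_params())

    @classmethod
    def load(cls, path_prefix: str) -> "ProfileCountModel":
        params, state = _load_net(path_prefix)
        est = cls(**{k: v for k, v in params.items()
                     if k in cls().get_params()})
        cfg = est._arch_config()
        net = SeqCNN(cfg, np.random.default_rng(0), dtype=np.dtype(est.dtype))
        net.load_state(state)
        est.net_ = net
        est.config_ = cfg
        return est


class BiasFactorizedModel(_SeqModelBase):
    """Factorized accessibility model: frozen bias submodel + residual CNN.

    ``bias_model`` must be a fitted :class:`ProfileCountModel` with identical
    input/output lengths. The bias submodel's weights are never touched during
    :meth:`fit`. gamma, the bias count-scale factor, is estimated from the
    training + validation data unless given.
    """

    def __init__(self, bias_model=None, n_filters=32, first_conv_width=21,
                 n_dilated_layers=4, dilated_width=3, dilation_base=2,
                 profile_head_width=75, input_len=1114, output_len=500,
                 count_combine="add", gamma=None, learning_rate=1e-3,
                 batch_size=32, max_epochs=100, patience=5,
                 lambda_counts=None, val_fraction=0.1, max_jitter=0,
                 count_refit_every=1, count_refit_alpha=1.0,
                 dropout=0.25, seed_patterns=None,
                 random_state=0, dtype="float32"):
        self.bias_model = bias_model
        self.n_filters = n_filters
        self.first_conv_width = first_conv_width
        self.n_dilated_layers = n_dilated_layers
        self.dilated_width = dilated_width
        self.dilation_base = dilation_base
        self.profile_head_width = profile_head_width
        self.input_len = input_len
        self.output_len = output_len
        self.count_combine = count_combine
        self.gamma = gamma
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.lambda_counts = lambda_counts
        self.val_fraction = val_fraction
        self.max_jitter = max_jitter
        self.count_refit_every = count_refit_every
        self.count_refit_alpha = count_refit_alpha
        self.dropout = dropout
        self.seed_patterns = seed_patterns
        self.random_state = random_state
        self.dtype = dtype

    def _check_bias(self):
        if self.bias_model is None:
            raise ValueError("bias_model is required")
        check_is_fitted(self.bias_model, "net_")
        bcfg = self.bias_model.config_
        if (bcfg.input_len, bcfg.output_len) != (self.input_len, self.output_len):
            raise ValueError("bias model input/output lengths must match")

    def fit(self, X, y, X_val=None, y_val=None, jitterable=None):
        self._check_bias()
        cfg = self._arch_config()
        X, y = self._validate_Xy(X, y, self.max_jitter)
        rng = np.random.default_rng(self.random_state)
        if X_val is None:
            n_val = max(1, int(round(self.val_fraction * X.shape[0])))
            perm = rng.permutation(X.shape[0])
            val_idx, tr_idx = perm[:n_val], perm[n_val:]
            X_val, y_val = X[val_idx], y[val_idx]
            X, y = X[tr_idx], y[tr_idx]
            if jitterable is not None:
                jitterable = np.asarray(jitterable)[tr_idx]
        Xv = _center_crop(np.asarray(X_val), cfg.input_len)
        yv = _center_crop(np.asarray(y_val), cfg.output_len)
        lam = (self.lambda_counts if self.lambda_counts is not None
               else default_lambda(yv.sum(axis=1)))
        self.lambda_ = lam
        bias_net = self.bias_model.net_
        self._bias_checksum_before_ = _params_checksum(bias_net.params)
        # stage 1: fit the bias scale gamma on train + validation regions
        if self.gamma is not None:
            self.gamma_ = float(self.gamma)
        else:
            Xc = _center_crop(X, cfg.input_len)
            yc = _center_crop(y, cfg.output_len)
            _, b_tr = self._forward_batched(bias_net, Xc)
            _, b_va = self._forward_batched(bias_net, Xv)
            self.gamma_ = estimate_gamma(
                np.concatenate([b_tr, b_va]),
                np.concatenate([yc.sum(axis=1), yv.sum(axis=1)]))
        net = SeqCNN(cfg, rng, dtype=np.dtype(self.dtype))
        if self.seed_patterns:
            seed_kmer_filters(net, self.seed_patterns)
        self.net_ = net
        self.config_ = cfg
        bias_ctx = {"net": bias_net, "gamma": self.gamma_,
                    "count_combine": self.count_combine}
        self._fit_loop(net, X, y, Xv, yv, jitterable, lam, rng, bias_ctx)
        self._bias_checksum_after_ = _params_checksum(bias_net.params)
        assert self._bias_checksum_after_ == self._bias_checksum_before_, \
            "bias submodel weights changed during residual training"
        return self

    _fit_loop = ProfileCountModel._fit_loop
    _validation_loss = ProfileCountModel._validation_loss
    _refit_count_head = ProfileCountModel._refit_count_head

    # -- prediction ---------------------------------------------------------
    def predict_factorized(self, X) -> FactorizedPrediction:
        check_is_fitted(self, "net_")
        Xc = self._crop_X(X)
        t_logits, t_counts = self._forward_batched(self.net_, Xc)
        b_logits, b_counts = self._forward_batched(self.bias_model.net_, Xc)
        return FactorizedPrediction(
            tf_part=ProfilePrediction(t_logits, t_counts),
            bias_part=ProfilePrediction(b_logits, b_counts),
            gamma=self.gamma_, count_combine=self.count_combine)

    def predict_logits(self, X, corrected: bool = False) -> np.ndarray:
        fp = self.predict_factorized(X)
        return fp.tf_part.logits if corrected else fp.combined.logits

    def predict_log_counts(self, X, corrected: bool = False) -> np.ndarray:
        fp = self.predict_factorized(X)
        return fp.tf_part.log_total if corrected else fp.combined.log_total

    def predict_profile(self, X, corrected: bool = False) -> np.ndarray:
        return softmax(self.predict_logits(X, corrected=corrected)
                       .astype(np.float64), axis=1)

    def predict(self, X) -> np.ndarray:
        return self.predict_log_counts(X)

    def save(self, path_prefix: str) -> None:
        check_is_fitted(self, "net_")
        params = {k: v for k, v in self.get_params().items()
                  if k != "bias_model"}
        params["gamma_fitted"] = self.gamma_
        _save_net(path_prefix + ".residual", self.net_, params)
        self.bias_model.save(path_prefix + ".bias")

    @classmethod
    def load(cls, path_prefix: str) -> "BiasFactorizedModel":
        bias = ProfileCountModel.load(path_prefix + ".bias")
        params, state = _load_net(path_prefix + ".residual")
        gamma_fitted = params.pop("gamma_fitted")
        est = cls(bias_model=bias,
                  **{k: v for k, v in params.items()
                     if k in cls().get_params() and k != "bias_model"})
        cfg = est._arch_config()
        net = SeqCNN(cfg, np.random.default_rng(0), dtype=np.dtype(est.dtype))
        net.load_state(state)
        est.net_ = net
        est.config_ = cfg
        est.gamma_ = float(gamma_fitted)
        return est


def corrected_prediction(model: BiasFactorizedModel, X) -> ProfilePrediction:
    """Bias-corrected prediction: the residual submodel alone, with the bias
    submodel disconnected."""
    fp = model.predict_factorized(X)
    return fp.tf_part


# ---------------------------------------------------------------------------
# checkpoint helpers (npz weights + JSON config with hash validation)
# ---------------------------------------------------------------------------

def _config_hash(params: dict) -> str:
    return hashlib.sha256(
        json.dumps(params, sort_keys=True, default=str).encode()).hexdigest()


def _params_checksum(params: dict) -> str:
    h = hashlib.sha256()
    for k in sorted(params):
        h.update(k.encode())
        h.update(np.ascontiguousarray(params[k]).tobytes())
    return h.hexdigest()


def _save_net(path_prefix: str, net: SeqCNN, params: dict) -> None:
    np.savez(path_prefix + ".weights.npz", **net.params)
    meta = {"params": params, "hash": _config_hash(params)}
    with open(path_prefix + ".config.json", "w") as fh:
        json.dump(meta, fh, indent=1, default=str)


def _load_net(path_prefix: str):
    with open(path_prefix + ".config.json") as fh:
        meta = json.load(fh)
    if _config_hash(meta["params"]) != meta["hash"]:
        raise ValueError(f"config hash mismatch for {path_prefix}")
    with np.load(path_prefix + ".weights.npz") as z:
        state = {k: z[k] for k in z.files}
    return meta["params"], state
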