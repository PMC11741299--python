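"""Minimal convolutional network core for sequence-to-profile models.

Implements the BPNet-style trunk used by both the bias submodel and the
residual (TF) submodel: a wide first convolution, a stack of dilated
convolutions with residual skip connections and doubling dilation rates, a
wide convolutional profile head and a global-average-pool count head. All
forward, gradient and DeepLIFT-rescale passes are written against numpy so
the package has no deep-learning-framework dependency; the nets involved are
small enough that BLAS-backed convolutions are fast on a single CPU.

Conventions
-----------
* Input is one-hot encoded DNA of shape ``(batch, input_len, 4)`` with
  ``A=[1,0,0,0], C=[0,1,0,0], G=[0,0,1,0], T=[0,0,0,1]`` and N as an
  all-zero column.
* Convolutions use 'same' zero padding, so the trunk preserves length and the
  profile head is centre-cropped to ``output_len``.
* The count head predicts ``log(1 + total counts)`` over the output window.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Dict, Tuple

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


def one_hot(seq: str, dtype=np.float32) -> np.ndarray:
    """One-hot encode a DNA string; any non-ACGT base becomes a zero column."""
    out = np.zeros((len(seq), 4), dtype=dtype)
    for i, b in enumerate(seq.upper()):
        j = _BASE_INDEX.get(b)
        if j is not None:
            out[i, j] = 1.0
    return out


def decode_one_hot(x: np.ndarray) -> str:
    """Inverse of :func:`one_hot`; zero columns decode to N."""
    idx = x.argmax(axis=1)
    hit = x.max(axis=1) > 0
    return "".join(BASES[j] if h else "N" for j, h in zip(idx, hit))


@dataclass(frozen=True)
class ArchitectureConfig:
    """Hyper-parameters of the sequence-to-profile architecture.

    Defaults are the desk-scale residual model; the full-scale configuration
    (512 filters, 8 dilated layers, 2114 bp in / 1000 bp out) is available by
    constructing it explicitly.
    """

    n_filters: int = 32
    first_conv_width: int = 21
    n_dilated_layers: int = 4
    dilated_width: int = 3
    dilation_base: int = 2
    profile_head_width: int = 75
    input_len: int = 1114
    output_len: int = 500

    def __post_init__(self):
        for name in ("first_conv_width", "dilated_width", "profile_head_width"):
            if getattr(self, name) % 2 == 0:
                raise ValueError(f"{name} must be odd for symmetric 'same' padding")
        if self.n_dilated_layers < 0:
            raise ValueError("n_dilated_layers must be >= 0")
        if self.output_len > self.input_len:
            raise ValueError("output_len cannot exceed input_len")

    @property
    def dilation_rates(self) -> Tuple[int, ...]:
        return tuple(self.dilation_base * 2 ** l for l in range(self.n_dilated_layers))

    def to_dict(self) -> dict:
        return asdict(self)


def receptive_field(cfg: ArchitectureConfig) -> int:
    """Effective receptive field of the trunk, in bp.

    first_conv_width + sum over dilated layers of (width-1) * rate, where the
    rate doubles each layer starting at ``dilation_base``.
    """
    rf = cfg.first_conv_width
    for rate in cfg.dilation_rates:
        rf += (cfg.dilated_width - 1) * rate
    return rf


# ---------------------------------------------------------------------------
# convolution primitives ('same' padding, arbitrary dilation)
# ---------------------------------------------------------------------------

def _im2col(xp: np.ndarray, w: int, dilation: int, L: int) -> np.ndarray:
    """(B, L, w*Cin) tap-gathered view copy of the padded input."""
    return np.concatenate(
        [xp[:, k * dilation: k * dilation + L, :] for k in range(w)], axis=2)


def conv1d_same(x: np.ndarray, W: np.ndarray, b: np.ndarray,
                dilation: int = 1) -> np.ndarray:
    """x: (B, L, Cin); W: (w, Cin, Cout); returns (B, L, Cout).

    One GEMM per layer: taps are gathered on the input side when w*Cin is the
    smaller flattening, otherwise the input is projected once onto all
    (tap, output-channel) pairs and shifted output taps are summed (the
    cheaper route for the wide single-channel profile head).
    """
    w, Cin, Cout = W.shape
    B, L, _ = x.shape
    pad = (w // 2) * dilation
    xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
    if Cin <= Cout:
        xcat = _im2col(xp, w, dilation, L)
        y = xcat @ W.reshape(w * Cin, Cout)
    else:
        P = (xp @ W.transpose(1, 0, 2).reshape(Cin, w * Cout)).reshape(
            B, xp.shape[1], w, Cout)
        y = np.zeros((B, L, Cout), dtype=x.dtype)
        for k in range(w):
            y += P[:, k * dilation: k * dilation + L, k, :]
    if b is not None:
        y += b
    return y


def conv1d_same_backward(x: np.ndarray, W: np.ndarray, dilation: int,
                         dy: np.ndarray, need_dx: bool = True):
    """Gradients of conv1d_same. Returns (dx or None, dW, db)."""
    w, Cin, Cout = W.shape
    B, L, _ = x.shape
    pad = (w // 2) * dilation
    xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
    Lp = xp.shape[1]
    dx = None
    if Cin <= Cout:
        xcat = _im2col(xp, w, dilation, L)
        dW = (xcat.reshape(-1, w * Cin).T
              @ dy.reshape(-1, Cout)).reshape(w, Cin, Cout)
        if need_dx:
            dxcat = dy @ W.reshape(w * Cin, Cout).T
            dxp = np.zeros_like(xp)
            for k in range(w):
                dxp[:, k * dilation: k * dilation + L, :] += \
                    dxcat[:, :, k * Cin: (k + 1) * Cin]
            dx = dxp[:, pad: pad + L, :]
    else:
        dP = np.zeros((B, Lp, w, Cout), dtype=dy.dtype)
        for k in range(w):
            dP[:, k * dilation: k * dilation + L, k, :] = dy[:, :, None] \
                if dy.ndim == 2 else dy
        dPf = dP.reshape(B * Lp, w * Cout)
        dW = (xp.reshape(B * Lp, Cin).T @ dPf).reshape(
            Cin, w, Cout).transpose(1, 0, 2)
        if need_dx:
            dxp = (dPf @ W.transpose(1, 0, 2).reshape(Cin, w * Cout).T
                   ).reshape(B, Lp, Cin)
            dx = dxp[:, pad: pad + L, :]
    db = dy.sum(axis=(0, 1))
    return dx, dW, db


def _relu(z):
    return np.maximum(z, 0.0)


def _rescale_multiplier(z, z_ref, eps=1e-7):
    """DeepLIFT rescale multiplier for a ReLU given pre-activations."""
    dz = z - z_ref
    m = np.where(np.abs(dz) > eps,
                 (_relu(z) - _relu(z_ref)) / np.where(np.abs(dz) > eps, dz, 1.0),
                 (z > 0).astype(z.dtype))
    return m


class SeqCNN:
    """The sequence-to-profile network with explicit forward/backward passes."""

    def __init__(self, cfg: ArchitectureConfig, rng: np.random.Generator,
                 dtype=np.float32):
        self.cfg = cfg
        self.dtype = np.dtype(dtype)
        F = cfg.n_filters
        p: Dict[str, np.ndarray] = {}

        def he(shape, fan_in):
            return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)

        p["conv0_W"] = he((cfg.first_conv_width, 4, F), cfg.first_conv_width * 4)
        p["conv0_b"] = np.zeros(F, dtype=dtype)
        for l, rate in enumerate(cfg.dilation_rates):
            p[f"dil{l}_W"] = he((cfg.dilated_width, F, F), cfg.dilated_width * F)
            p[f"dil{l}_b"] = np.zeros(F, dtype=dtype)
        p["prof_W"] = (rng.standard_normal((cfg.profile_head_width, F, 1))
                       * 0.01).astype(dtype)
        p["prof_b"] = np.zeros(1, dtype=dtype)
        p["count_w"] = (rng.standard_normal(F) * 0.01).astype(dtype)
        p["count_b"] = np.zeros(1, dtype=dtype)
        self.params = p

    # -- serialization ------------------------------------------------------
    def state_copy(self) -> Dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state(self, state: Dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = state[k].copy().astype(self.dtype)

    # -- forward ------------------------------------------------------------
    def _crop_slice(self):
        off = (self.cfg.input_len - self.cfg.output_len) // 2
        return slice(off, off + self.cfg.output_len)

    def forward(self, x: np.ndarray, want_cache: bool = False,
                drop_p: float = 0.0, drop_rng: np.random.Generator = None):
        """Returns (logits (B, output_len), log_counts (B,)[, cache]).

        ``drop_p`` > 0 applies inverted dropout to each ReLU output during
        training (never at inference); masks are cached for the backward pass.
        """
        cfg = self.cfg
        if x.ndim != 3 or x.shape[1] != cfg.input_len or x.shape[2] != 4:
            raise ValueError(
                f"expected input of shape (B, {cfg.input_len}, 4), got {x.shape}")
        x = np.ascontiguousarray(x, dtype=self.dtype)
        p = self.params
        cache = {"x": x, "pre": [], "h_in": [], "masks": []}

        def dropped(a):
            if drop_p <= 0.0:
                cache["masks"].append(None)
                return a
            m = ((drop_rng.random(a.shape) > drop_p) / (1.0 - drop_p)) \
                .astype(self.dtype)
            cache["masks"].append(m)
            return a * m

        z0 = conv1d_same(x, p["conv0_W"], p["conv0_b"], 1)
        h = dropped(_relu(z0))
        cache["pre"].append(z0)
        for l, rate in enumerate(cfg.dilation_rates):
            cache["h_in"].append(h)
            z = conv1d_same(h, p[f"dil{l}_W"], p[f"dil{l}_b"], rate)
            cache["pre"].append(z)
            h = dropped(_relu(z)) + h  # residual skip
        cache["trunk"] = h
        prof_full = conv1d_same(h, p["prof_W"], p["prof_b"], 1)[:, :, 0]
        logits = prof_full[:, self._crop_slice()]
        pooled = h.mean(axis=1)
        cache["pooled"] = pooled
        log_counts = pooled @ p["count_w"] + p["count_b"][0]
        if want_cache:
            return logits, log_counts, cache
        return logits, log_counts

    # -- gradient backward --------------------------------------------------
    def backward(self, cache, dlogits: np.ndarray, dlog_counts: np.ndarray,
                 need_dx: bool = False):
        """Backprop from output grads. Returns (grads dict, dx or None)."""
        cfg = self.cfg
        p = self.params
        grads: Dict[str, np.ndarray] = {}
        h = cache["trunk"]
        B, L, F = h.shape
        # profile head
        dprof_full = np.zeros((B, L, 1), dtype=self.dtype)
        dprof_full[:, self._crop_slice(), 0] = dlogits
        dh, grads["prof_W"], grads["prof_b"] = conv1d_same_backward(
            h, p["prof_W"], 1, dprof_full)
        # count head
        grads["count_w"] = cache["pooled"].T @ dlog_counts
        grads["count_b"] = np.array([dlog_counts.sum()], dtype=self.dtype)
        dh += (dlog_counts[:, None, None] / L) * p["count_w"][None, None, :]
        # dilated stack (reverse)
        masks = cache.get("masks") or [None] * (cfg.n_dilated_layers + 1)
        for l in reversed(range(cfg.n_dilated_layers)):
            rate = cfg.dilation_rates[l]
            z = cache["pre"][l + 1]
            dhh = dh if masks[l + 1] is None else dh * masks[l + 1]
            dz = dhh * (z > 0)
            dh_conv, grads[f"dil{l}_W"], grads[f"dil{l}_b"] = conv1d_same_backward(
                cache["h_in"][l], p[f"dil{l}_W"], rate, dz)
            dh = dh + dh_conv  # residual: grad flows through skip and conv
        dh0 = dh if masks[0] is None else dh * masks[0]
        dz0 = dh0 * (cache["pre"][0] > 0)
        dx, grads["conv0_W"], grads["conv0_b"] = conv1d_same_backward(
            cache["x"], p["conv0_W"], 1, dz0, need_dx=need_dx)
        return grads, dx

    # -- DeepLIFT rescale ---------------------------------------------------
    def deeplift(self, x: np.ndarray, ref: np.ndarray,
                 dlogits: np.ndarray, dlog_counts: np.ndarray) -> np.ndarray:
        """Per-base contributions of ``x`` relative to ``ref``.

        ``dlogits``/``dlog_counts`` seed the output linear functional being
        explained (e.g. all-zero logits and ones for the count head, or fixed
        probability weights for the profile head). Satisfies
        summation-to-delta exactly for this ReLU/linear architecture:
        ``contributions.sum() == f(x) - f(ref)`` for each batch row.
        """
        cfg = self.cfg
        p = self.params
        _, _, cx = self.forward(x, want_cache=True)
        _, _, cr = self.forward(ref, want_cache=True)
        B, L = x.shape[0], cfg.input_len
        F = cfg.n_filters
        dprof_full = np.zeros((B, L, 1), dtype=self.dtype)
        dprof_full[:, self._crop_slice(), 0] = dlogits
        h = cx["trunk"]
        dh, _, _ = conv1d_same_backward(h, p["prof_W"], 1, dprof_full,
                                        need_dx=True)
        dh += (np.asarray(dlog_counts)[:, None, None] / L) * p["count_w"][None, None, :]
        for l in reversed(range(cfg.n_dilated_layers)):
            rate = cfg.dilation_rates[l]
            m = _rescale_multiplier(cx["pre"][l + 1], cr["pre"][l + 1])
            dz = dh * m
            dh_conv, _, _ = conv1d_same_backward(
                cx["h_in"][l], p[f"dil{l}_W"], rate, dz, need_dx=True)
            dh = dh + dh_conv
        m0 = _rescale_multiplier(cx["pre"][0], cr["pre"][0])
        dz0 = dh * m0
        dx, _, _ = conv1d_same_backward(cx["x"], p["conv0_W"], 1, dz0,
                                        need_dx=True)
        return dx * (x - ref)


def seed_kmer_filters(net: "SeqCNN", patterns, scale: float = 1.0,
                      threshold_fraction: float = 0.75) -> int:
    """Initialize first-layer filters as thresholded k-mer match detectors.

    Each pattern (and its reverse complement) is written into one first-conv
    filter as a centred position weight (+scale at the pattern base,
    -scale/4 elsewhere) with a negative bias so the ReLU fires only on
    near-perfect matches — a clean, context-free sequence indicator that the
    heads can exploit immediately. Data-driven patterns (e.g. summit-enriched
    k-mers) keep this free of any ground-truth knowledge. Returns the number
    of filters seeded.
    """
    comp = str.maketrans("ACGT", "TGCA")
    W = net.params["conv0_W"]
    b = net.params["conv0_b"]
    width, _, n_filters = W.shape
    expanded = []
    for pat in patterns:
        pat = pat.upper()
        expanded += [pat, pat.translate(comp)[::-1]]
    n = 0
    for j, pat in enumerate(expanded):
        if j >= n_filters or len(pat) > width:
            break
        off = (width - len(pat)) // 2
        W[:, :, j] *= 0.02  # keep a whisper of the random init
        for i, base in enumerate(pat):
            k = _BASE_INDEX.get(base)
            W[off + i, :, j] += -0.25 * scale
            if k is not None:
                W[off + i, k, j] += scale
        # consensus activation is 0.75*scale*len; fire only above threshold
        b[j] = -threshold_fraction * 0.75 * scale * len(pat)
        n += 1
    return n


class Adam:
    """Adam optimizer over a SeqCNN parameter dict."""

    def __init__(self, params: Dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: Dict[str, np.ndarray], grads: Dict[str, np.ndarray]):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= (self.lr * (self.m[k] / b1t)
                          / (np.sqrt(self.v[k] / b2t) + self.eps)).astype(params[k].dtype)


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)
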