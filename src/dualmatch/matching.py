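"""Adaptive selection machinery for dual-source feature matching.

For each source network k and each candidate layer pair (m, n) between
source layer m and target layer n, transfer is governed by three small
learnable pieces:

* an adapter r_v: a pointwise (1x1) convolution mapping the target tap to
  the source layer's channel count;
* a channel-weight head f: one linear layer + softmax over the source
  map's per-channel global means, yielding simplex weights w_c (which
  feature maps of the source layer deserve attention);
* a pair-weight head g: one linear layer + ReLU6 on the same global
  means, yielding lambda in [0, 6] (how transferable the layer pair is).

The weighted matching loss for one pair is

    (1/HW) sum_c w_c sum_ij (r(T^n(x)) - S^m(x))^2_cij,

averaged over the batch; the total matching loss sums lambda-weighted
pair losses over both sources, and the training loss is
L_total = L_org + tradeoff * L_wfm.

Source networks are frozen: their taps enter as plain arrays, so no
gradient can reach source parameters by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor


@dataclass
class FeatureMap:
    """A tapped 4-D activation [batch, channels, H, W] with its origin."""

    values: np.ndarray
    layer: int
    network: str = "target"  # "source1" | "source2" | "target"

    def __post_init__(self):
        if self.values.ndim != 4:
            raise ValueError("feature maps are 4-D [N, C, H, W]")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature map contains non-finite values")


class PointwiseAdapter(nn.Module):
    """1x1 convolution C_target -> C_source; identity-initialized on the
    overlapping channels for reproducibility."""

    def __init__(self, c_target: int, c_source: int):
        w = np.eye(c_source, c_target, dtype=np.float32).reshape(
            c_source, c_target, 1, 1)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(c_source), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return nn.conv2d(x, self.weight, self.bias, stride=1)


def adapt(target_map: Tensor, adapter: PointwiseAdapter) -> Tensor:
    """Project a target tap to the paired source layer's channel count;
    spatial dimensions are unchanged."""
    return adapter(target_map)


def _gap(source_values: np.ndarray) -> Tensor:
    return Tensor(source_values.mean(axis=(2, 3)))


def channel_weights(source_map: np.ndarray, head: nn.Linear) -> Tensor:
    """Per-channel simplex weights w_c = softmax(linear(GAP(S))); shape
    (N, C).  A zero-initialized head yields uniform weights 1/C."""
    return nn.softmax(head(_gap(source_map)), axis=1)


def pair_weight(source_map: np.ndarray, head: nn.Linear) -> Tensor:
    """Layer-pair transferability lambda = ReLU6(linear(GAP(S))); shape
    (N, 1), clipped to [0, 6]."""
    return nn.relu6(head(_gap(source_map)))


def weighted_matching_loss(source_map: np.ndarray, adapted: Tensor,
                           w: Tensor) -> Tensor:
    """Batch-mean of (1/HW) sum_c w_c sum_ij (adapted - source)^2."""
    if adapted.shape != source_map.shape:
        raise ValueError(
            f"shape mismatch after adaptation: {adapted.shape} vs {source_map.shape}")
    h, wd = source_map.shape[2], source_map.shape[3]
    diff = nn.sub(adapted, Tensor(source_map))
    per_chan = nn.tsum(nn.mul(diff, diff), axis=(2, 3))        # (N, C)
    per_sample = nn.tsum(nn.mul(w, per_chan), axis=1)          # (N,)
    return nn.scale(nn.tmean(per_sample), 1.0 / (h * wd))


def _per_sample_pair_loss(source_map: np.ndarray, adapted: Tensor,
                          w: Tensor) -> Tensor:
    h, wd = source_map.shape[2], source_map.shape[3]
    diff = nn.sub(adapted, Tensor(source_map))
    per_chan = nn.tsum(nn.mul(diff, diff), axis=(2, 3))
    return nn.scale(nn.tsum(nn.mul(w, per_chan), axis=1), 1.0 / (h * wd))


@dataclass
class LossBreakdown:
    """Scalar losses of one step: L_total = L_org + tradeoff * L_wfm."""

    l_org: float
    l_wfm: float
    l_total: float
    per_pair: dict = field(default_factory=dict)  # (k, m, n) -> (lambda, pair loss)


class MatchState(nn.Module):
    """All matching parameters for two frozen sources and one target.

    ``pairs[k]`` lists candidate (m, n) layer pairs for source k (both
    0-based stage indices); by default every stage combination is a
    candidate and the pair weights learn to silence useless ones.
    """

    def __init__(self, source_channels: dict, target_channels: list,
                 pairs: dict | None = None, tradeoff: float = 0.5):
        if tradeoff < 0:
            raise ValueError("tradeoff must be nonnegative")
        self.tradeoff = tradeoff
        self.source_channels = source_channels
        self.target_channels = list(target_channels)
        if pairs is None:
            pairs = {
                k: [(m, n) for m in range(len(chs))
                    for n in range(len(target_channels))]
                for k, chs in source_channels.items()
            }
        for k, plist in pairs.items():
            if not plist:
                raise ValueError(f"empty candidate pair set for source {k}")
        self.pairs = pairs
        self.adapters, self.f_heads, self.g_heads = {}, {}, {}
        for k, plist in pairs.items():
            for (m, n) in plist:
                cs = source_channels[k][m]
                ct = target_channels[n]
                self.adapters[(k, m, n)] = PointwiseAdapter(ct, cs)
                self.f_heads[(k, m, n)] = nn.Linear(cs, cs, zero_init=True)
                g = nn.Linear(cs, 1, zero_init=True)
                g.bias.data[:] = 1.0  # lambda starts at 1, inside ReLU6's linear region
                self.g_heads[(k, m, n)] = g

    # parameter groups -------------------------------------------------
    def adapter_params(self):
        out = []
        for a in self.adapters.values():
            out.extend(a.params())
        return out

    def meta_params(self):
        out = []
        for h in list(self.f_heads.values()) + list(self.g_heads.values()):
            out.extend(h.params())
        return out

    def params(self):
        return self.adapter_params() + self.meta_params()

    # losses -----------------------------------------------------------
    def pair_terms(self, source_taps: dict, target_taps: list):
        """Yield (key, source map aligned to target geometry, adapted tap,
        channel weights, per-sample lambda) for every candidate pair."""
        for k, plist in self.pairs.items():
            for (m, n) in plist:
                s_map = source_taps[k][m]
                t_tap = target_taps[n]
                if s_map.shape[2:] != t_tap.shape[2:]:
                    s_map = nn.resize_bilinear(s_map, t_tap.shape[2],
                                               t_tap.shape[3])
                key = (k, m, n)
                adapted = adapt(t_tap, self.adapters[key])
                w = channel_weights(s_map, self.f_heads[key])
                lam = pair_weight(s_map, self.g_heads[key])
                yield key, s_map, adapted, w, lam

    def total_matching_loss(self, source_taps: dict, target_taps: list):
        """L_wfm = sum_k sum_(m,n) lambda * weighted pair loss (batch
        mean, per-sample lambda).  Returns (loss Tensor, per-pair log)."""
        total = None
        per_pair = {}
        for key, s_map, adapted, w, lam in self.pair_terms(source_taps, target_taps):
            per_sample = _per_sample_pair_loss(s_map, adapted, w)   # (N,)
            contrib = nn.tmean(nn.mul(nn.reshape(lam, (-1,)), per_sample))
            per_pair[key] = {
                "lam_mean": float(lam.data.mean()),
                "lam_min": float(lam.data.min()),
                "lam_max": float(lam.data.max()),
                "loss": float(per_sample.data.mean()),
                "w_sum_dev": float(np.abs(w.data.sum(axis=1) - 1.0).max()),
                "w_min": float(w.data.min()),
            }
            total = contrib if total is None else nn.add(total, contrib)
        return total, per_pair


def total_loss(logits: Tensor, labels: np.ndarray, l_wfm: Tensor,
               per_pair: dict, tradeoff: float):
    """L_total = cross-entropy + tradeoff * L_wfm; returns the Tensor to
    backpropagate plus a LossBreakdown of floats."""
    l_org = nn.softmax_cross_entropy(logits, labels)
    total = nn.add(l_org, nn.scale(l_wfm, tradeoff))
    breakdown = LossBreakdown(
        l_org=float(l_org.data), l_wfm=float(l_wfm.data),
        l_total=float(total.data), per_pair=dict(per_pair))
    return total, l_org, breakdown
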