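"""Diverse branch block (DBB) and its exact collapse into one convolution.

A DBB is a train-time block of four batch-normalized branches that sum to
one output:

    (1) a 1x1 convolution,
    (2) a 1x1 convolution -> BN -> KxK convolution,
    (3) a 1x1 convolution -> BN -> KxK average pool,
    (4) a KxK convolution,

all sharing output width D and spatial geometry ("same" padding, common
stride).  By homogeneity and additivity of convolution the whole block is
algebraically equivalent to a single D x C x K x K kernel plus bias, which
is what deployment uses: rich multi-branch expressiveness during training,
plain-convolution cost at inference.

Exactness at image borders requires one care: inside the sequential
branches the intermediate map is padded with the batch-norm's bias-at-zero
value (beta - mu*gamma/sigma), not zero, because the merged kernel pads the
*original* input with zeros and a zero input patch emerges from the 1x1+BN
stage carrying exactly that bias.

Evaluation-mode (running-statistics) outputs of the block and of its
reparameterized convolution agree to float32 roundoff; the test suite
checks < 1e-4 across randomized configurations.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import Tensor

_F32 = np.float32


# ------------------------------------------------------------ primitives

def fuse_bn(weight: np.ndarray, gamma: np.ndarray, sigma: np.ndarray,
            mu: np.ndarray, beta: np.ndarray):
    """Fold a batch-norm (scale gamma/sigma, shift beta - mu*gamma/sigma)
    into the convolution kernel it follows.

    Returns (fused_kernel, fused_bias) with
    ``F'[d] = (gamma[d]/sigma[d]) * F[d]`` and
    ``b'[d] = beta[d] - mu[d]*gamma[d]/sigma[d]``.
    """
    sigma = np.asarray(sigma, dtype=np.float64)
    if np.any(sigma <= 0):
        raise ValueError("batch-norm sigma must be positive")
    s = (np.asarray(gamma, np.float64) / sigma).astype(_F32)
    fused = weight * s[:, None, None, None]
    bias = (np.asarray(beta, np.float64)
            - np.asarray(mu, np.float64) * np.asarray(gamma, np.float64) / sigma).astype(_F32)
    return fused, bias


def merge_sequential(f_point: np.ndarray, f_spatial: np.ndarray) -> np.ndarray:
    """Collapse a 1x1 (D_mid x C x 1 x 1) followed by a KxK
    (D x D_mid x K x K) convolution into one D x C x K x K kernel."""
    if f_point.shape[2:] != (1, 1) or f_spatial.shape[1] != f_point.shape[0]:
        raise ValueError("incompatible kernel chain for sequential merge")
    return np.einsum("deij,ec->dcij", f_spatial, f_point[:, :, 0, 0]).astype(_F32)


def avgpool_as_conv(d: int, k: int) -> np.ndarray:
    """KxK average pooling over D channels expressed as a D x D x K x K
    kernel: 1/K^2 on the matching channel, zero elsewhere."""
    if k % 2 == 0:
        raise ValueError("kernel size must be odd")
    kern = np.zeros((d, d, k, k), dtype=_F32)
    for i in range(d):
        kern[i, i] = 1.0 / (k * k)
    return kern


# ------------------------------------------------------------- the block

class DBBBlock(nn.Module):
    """Four-branch train-time block, output width ``cout``, odd kernel ``k``."""

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1, rng=None):
        if k % 2 == 0:
            raise ValueError("DBBBlock supports odd kernel sizes only")
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        self.pad = (k - 1) // 2

        def kern(shape, fan_in):
            return Tensor(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape),
                          requires_grad=True)

        self.f1 = kern((cout, cin, 1, 1), cin)
        self.f2 = kern((cout, cin, 1, 1), cin)
        self.f3 = kern((cout, cout, k, k), cout * k * k)
        self.f4 = kern((cout, cin, 1, 1), cin)
        self.f6 = kern((cout, cin, k, k), cin * k * k)
        self.bn1 = nn.BatchNorm2d(cout)
        self.bn2 = nn.BatchNorm2d(cout)
        self.bn3 = nn.BatchNorm2d(cout)
        self.bn4 = nn.BatchNorm2d(cout)
        self.bn5 = nn.BatchNorm2d(cout)
        self.bn6 = nn.BatchNorm2d(cout)
        self._avg = Tensor(avgpool_as_conv(cout, k))  # constant, not trained

    def _pad_value(self, bn: nn.BatchNorm2d, training: bool) -> Tensor:
        if training:
            mean, var = bn._last_mean, bn._last_var
            inv = 1.0 / np.sqrt(var + bn.eps)
            return nn.add(nn.mul(bn.gamma, Tensor(-mean * inv)), bn.beta)
        return bn.bias_at_zero()

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        if x.shape[1] != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {x.shape[1]}")
        s, p = self.stride, self.pad
        # branch 1: 1x1
        b1 = self.bn1(nn.conv2d(x, self.f1, stride=s), training)
        # branch 2: 1x1 -> BN -> pad(bias) -> KxK
        mid2 = self.bn2(nn.conv2d(x, self.f2, stride=1), training)
        mid2 = nn.pad2d(mid2, p, self._pad_value(self.bn2, training))
        b2 = self.bn3(nn.conv2d(mid2, self.f3, stride=s), training)
        # branch 3: 1x1 -> BN -> pad(bias) -> KxK average pool
        mid4 = self.bn4(nn.conv2d(x, self.f4, stride=1), training)
        mid4 = nn.pad2d(mid4, p, self._pad_value(self.bn4, training))
        b3 = self.bn5(nn.conv2d(mid4, self._avg, stride=s), training)
        # branch 4: KxK
        b4 = self.bn6(nn.conv2d(nn.pad2d(x, p), self.f6, stride=s), training)
        return nn.add(nn.add(b1, b2), nn.add(b3, b4))

    __call__ = forward


class ReparamConv(nn.Module):
    """The single convolution a :class:`DBBBlock` collapses into."""

    def __init__(self, weight: np.ndarray, bias: np.ndarray, stride: int, pad: int):
        self.weight = Tensor(weight)
        self.bias = Tensor(bias)
        self.stride, self.pad = stride, pad

    def forward(self, x: Tensor) -> Tensor:
        return nn.conv2d(nn.pad2d(x, self.pad), self.weight, self.bias,
                         stride=self.stride)

    __call__ = forward


def _bn_terms(bn: nn.BatchNorm2d):
    sigma = np.sqrt(bn.running_var.astype(np.float64) + bn.eps)
    return bn.gamma.data, sigma, bn.running_mean, bn.beta.data


def reparameterize(block: DBBBlock) -> ReparamConv:
    """Collapse the four branches into one kernel + bias (running stats)."""
    if block.k % 2 == 0:
        raise ValueError("even kernel sizes are unsupported")
    k, d, c = block.k, block.cout, block.cin
    ctr = (k - 1) // 2

    # branch 1: 1x1, embedded at the kernel center
    k1, b1 = fuse_bn(block.f1.data, *_bn_terms(block.bn1))
    k1_full = np.zeros((d, c, k, k), dtype=_F32)
    k1_full[:, :, ctr, ctr] = k1[:, :, 0, 0]

    # branch 2: 1x1 -> KxK
    k2, b2 = fuse_bn(block.f2.data, *_bn_terms(block.bn2))
    k3, b3 = fuse_bn(block.f3.data, *_bn_terms(block.bn3))
    k2_full = merge_sequential(k2, k3)
    b2_full = k3.sum(axis=(2, 3)) @ b2 + b3

    # branch 3: 1x1 -> avg pool (pool scaled by BN5)
    k4, b4 = fuse_bn(block.f4.data, *_bn_terms(block.bn4))
    gamma5, sigma5, mu5, beta5 = _bn_terms(block.bn5)
    scale5 = (gamma5 / sigma5).astype(_F32)
    a_fused = block._avg.data * scale5[:, None, None, None]
    b5 = (beta5 - mu5 * gamma5 / sigma5).astype(_F32)
    k3_full = merge_sequential(k4, a_fused)
    b3_full = a_fused.sum(axis=(2, 3)) @ b4 + b5

    # branch 4: KxK
    k6, b6 = fuse_bn(block.f6.data, *_bn_terms(block.bn6))

    weight = k1_full + k2_full + k3_full + k6
    bias = b1 + b2_full + b3_full + b6
    return ReparamConv(weight, bias, block.stride, block.pad)


# ------------------------------------------------------------- networks

class _DBBStage(nn.Module):
    def __init__(self, cin, cout, k, rng, n_blocks=2):
        self.blocks = [DBBBlock(cin, cout, k, stride=2, rng=rng)]
        for _ in range(n_blocks - 1):
            self.blocks.append(DBBBlock(cout, cout, k, stride=1, rng=rng))

    def forward(self, x, training=False):
        for b in self.blocks:
            x = nn.relu(b(x, training))
        return x


class ToyDBBNet(nn.Module):
    """Stage-wise DBB CNN (``blocks_per_stage`` blocks per stage, the
    first one downsampling), the desk-scale target backbone.  Taps T^n
    are the post-activation stage outputs, n = 1..len(widths)."""

    def __init__(self, widths=(8, 16, 32, 64), in_channels=3, n_classes=2,
                 k=3, seed=0, blocks_per_stage=2):
        rng = np.random.default_rng(seed)
        self.widths = tuple(widths)
        self.stages = []
        cin = in_channels
        for w in widths:
            self.stages.append(_DBBStage(cin, w, k, rng, blocks_per_stage))
            cin = w
        self.head = nn.Linear(cin, n_classes, rng=rng)

    def dbb_blocks(self):
        out = []
        for st in self.stages:
            out.extend(st.blocks)
        return out

    def forward(self, x: Tensor, training: bool = False, return_taps: bool = False):
        taps = []
        for st in self.stages:
            x = st.forward(x, training)
            taps.append(x)
        logits = self.head(nn.global_mean_pool(x))
        return (logits, taps) if return_taps else logits

    __call__ = forward

    def reparameterize(self) -> "ToyReparamNet":
        return ToyReparamNet(self)


class ToyReparamNet(nn.Module):
    """Deployment form of :class:`ToyDBBNet`: every DBB replaced by its
    collapsed convolution.  Also serves as the per-patient feature
    extractor: :meth:`feature_maps` yields the pre-activation output of
    every reparameterized convolution."""

    def __init__(self, net: ToyDBBNet):
        self.widths = net.widths
        self.stage_ends = np.cumsum([len(st.blocks) for st in net.stages]) - 1
        self.convs = [reparameterize(b) for b in net.dbb_blocks()]
        self.head = nn.Linear(net.head.weight.shape[0], net.head.weight.shape[1])
        self.head.weight = Tensor(net.head.weight.data.copy())
        self.head.bias = Tensor(net.head.bias.data.copy())

    def feature_maps(self, x: Tensor):
        """Pre-activation output of each collapsed convolution, in order."""
        maps = []
        for conv in self.convs:
            pre = conv(x)
            maps.append(pre)
            x = nn.relu(pre)
        return maps

    def forward(self, x: Tensor, training: bool = False, return_taps: bool = False):
        del training  # deployment form has no train-time behavior
        taps = []
        for i, conv in enumerate(self.convs):
            x = nn.relu(conv(x))
            if i in self.stage_ends:
                taps.append(x)
        logits = self.head(nn.global_mean_pool(x))
        return (logits, taps) if return_taps else logits

    __call__ = forward


class _BasicBlockDBB(nn.Module):
    def __init__(self, cin, cout, stride, rng):
        self.conv1 = DBBBlock(cin, cout, 3, stride=stride, rng=rng)
        self.conv2 = DBBBlock(cout, cout, 3, stride=1, rng=rng)
        self.downsample = None
        if stride != 1 or cin != cout:
            self.downsample = nn.Conv2d(cin, cout, 1, stride=stride, rng=rng)
            self.down_bn = nn.BatchNorm2d(cout)

    def forward(self, x, training=False):
        idn = x
        if self.downsample is not None:
            idn = self.down_bn(self.downsample(x), training)
        out = nn.relu(self.conv1(x, training))
        out = self.conv2(out, training)
        return nn.relu(nn.add(out, idn))


class ResNet18DBB(nn.Module):
    """ResNet18-style target network with every main-path convolution
    replaced by a DBB; 1x1 shortcut projections stay plain convolutions.
    Its reparameterized feature-kernel count is 3904
    (64 + 4*64 + 4*128 + 4*256 + 4*512)."""

    def __init__(self, n_classes=2, seed=0):
        rng = np.random.default_rng(seed)
        self.stem = DBBBlock(3, 64, 7, stride=2, rng=rng)
        self.layers = []
        cin = 64
        for cout, stride in [(64, 1), (64, 1), (128, 2), (128, 1),
                             (256, 2), (256, 1), (512, 2), (512, 1)]:
            self.layers.append(_BasicBlockDBB(cin, cout, stride, rng))
            cin = cout
        self.head = nn.Linear(512, n_classes, rng=rng)

    def dbb_blocks(self):
        out = [self.stem]
        for layer in self.layers:
            out.extend([layer.conv1, layer.conv2])
        return out

    def forward(self, x: Tensor, training: bool = False):
        x = nn.relu(self.stem(x, training))
        x = nn.maxpool2d(nn.pad2d(x, 1), 3, 2)
        for layer in self.layers:
            x = layer.forward(x, training)
        return self.head(nn.global_mean_pool(x))

    __call__ = forward


def count_feature_channels(net) -> int:
    """Number of reparameterized convolution kernels (= output channels
    summed over all DBB-derived convolutions); shortcut projections are
    excluded.  This is the per-patient deep-feature dimension L."""
    if isinstance(net, ToyReparamNet):
        return int(sum(c.weight.shape[0] for c in net.convs))
    return int(sum(b.cout for b in net.dbb_blocks()))


def build_target_network(config: dict):
    """Build the DBB target network named by ``config['backbone']``
    ('toy' or 'resnet18'), with ``config['n_classes']`` outputs."""
    backbone = config.get("backbone", "toy")
    n_classes = int(config.get("n_classes", 2))
    seed = int(config.get("seed", 0))
    if backbone == "toy":
        widths = tuple(config.get("widths", (8, 16, 32, 64)))
        return ToyDBBNet(widths=widths, n_classes=n_classes, seed=seed)
    if backbone == "resnet18":
        return ResNet18DBB(n_classes=n_classes, seed=seed)
    raise ValueError(f"unknown backbone {backbone!r}")
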