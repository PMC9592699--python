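"""Source pretraining and the four-stage alternating transfer training.

Each outer step runs, on one mini-batch:

  stage 1  one SGD step on (theta, v) minimizing L_total = L_org + tradeoff*L_wfm
  stage 2  T SGD steps on (theta, v) minimizing L_wfm alone
  stage 3  one SGD step on (theta, v) minimizing L_org alone
  stage 4  one Adam step on the matching-head parameters (f, g) driven by
           how the stage-1..3 updates changed L_org

so the target network parameters theta and adapters v receive exactly
T + 2 updates per step and the matching heads exactly one.  Stage 4 uses
a first-order, feature-space meta-gradient: for every candidate pair the
alignment g_p between dL_org/d(tap) and the pair loss's gradient at the
same tap scores whether pulling the target toward that source layer also
lowers the task loss; one Adam step then moves lambda (and the channel
weights) up for aligned pairs and down for misaligned ones.

Source networks are pretrained once, then frozen; their taps enter the
matching loss as plain arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .matching import MatchState, total_loss
from .nn import Tensor


@dataclass
class TrainingConfig:
    """Hyperparameters of target training.  Defaults follow the full-scale
    settings (momentum SGD 1e-4/0.9/1e-5 for the target and adapters,
    Adam 1e-4 with weight decay 1e-4 for the matching heads, tradeoff 0.5,
    batch 200); :func:`desk_config` scales them to toy problems."""

    tradeoff: float = 0.5
    inner_steps: int = 2            # T of stage 2
    lr_theta: float = 1e-4
    momentum: float = 0.9
    weight_decay_theta: float = 1e-5
    lr_meta: float = 1e-4
    weight_decay_meta: float = 1e-4
    batch_size: int = 200
    epochs: int = 200
    patience: int = 10
    seed: int = 0
    widths: tuple = (8, 16, 32, 64)
    n_classes: int = 2

    def __post_init__(self):
        if self.inner_steps < 1:
            raise ValueError("inner_steps T must be >= 1")
        if self.lr_theta <= 0 or self.lr_meta < 0:
            raise ValueError("learning rates must be positive (lr_meta may be 0 to freeze the heads)")


def desk_config(**overrides) -> TrainingConfig:
    """Toy-scale study conditions: small batches, few epochs, learning
    rates sized so toy networks move within a handful of steps."""
    base = TrainingConfig(lr_theta=0.02, lr_meta=0.02, batch_size=8,
                          epochs=4, inner_steps=2)
    return replace(base, **overrides)


# ----------------------------------------------------------- source nets

class _PlainStage(nn.Module):
    def __init__(self, cin, cout, rng):
        self.conv_a = nn.Conv2d(cin, cout, 3, stride=2, rng=rng)
        self.bn_a = nn.BatchNorm2d(cout)
        self.conv_b = nn.Conv2d(cout, cout, 3, stride=1, rng=rng)
        self.bn_b = nn.BatchNorm2d(cout)

    def forward(self, x, training=False):
        x = nn.relu(self.bn_a(self.conv_a(x), training))
        return nn.relu(self.bn_b(self.conv_b(x), training))


class PlainCNN(nn.Module):
    """Four-stage plain CNN used as the desk-scale source backbone; taps
    S^m are the post-activation stage outputs, m = 1..4."""

    def __init__(self, widths=(8, 16, 32, 64), in_channels=3, n_classes=2, seed=0):
        rng = np.random.default_rng(seed)
        self.widths = tuple(widths)
        self.stages = []
        cin = in_channels
        for w in widths:
            self.stages.append(_PlainStage(cin, w, rng))
            cin = w
        self.head = nn.Linear(cin, n_classes, rng=rng)

    def forward(self, x: Tensor, training=False, return_taps=False):
        taps = []
        for st in self.stages:
            x = st.forward(x, training)
            taps.append(x)
        logits = self.head(nn.global_mean_pool(x))
        return (logits, taps) if return_taps else logits

    __call__ = forward


class SourceNetwork:
    """A frozen, pretrained source: exposes tap maps as plain arrays so no
    gradient can reach its parameters."""

    def __init__(self, net: PlainCNN, task_id: str = "source"):
        self.net = net
        self.task_id = task_id
        self.channels = list(net.widths)

    def forward_taps(self, x: np.ndarray) -> list:
        _, taps = self.net.forward(Tensor(x), training=False, return_taps=True)
        return [t.data for t in taps]

    def predict_logits(self, x: np.ndarray) -> np.ndarray:
        return self.net.forward(Tensor(x), training=False).data

    def parameter_snapshot(self):
        return [p.data.copy() for p in self.net.params()]


@dataclass
class PretrainConfig:
    lr: float = 0.05
    momentum: float = 0.9
    weight_decay: float = 1e-5
    batch_size: int = 16
    epochs: int = 30
    seed: int = 0
    widths: tuple = (8, 16, 32, 64)


def pretrain_source(task, config: PretrainConfig | None = None) -> SourceNetwork:
    """Train a plain CNN on a labeled image batch with momentum SGD and
    cross-entropy, then freeze it.  Aborts on non-finite loss."""
    config = config or PretrainConfig()
    n_classes = int(task.labels.max()) + 1
    net = PlainCNN(widths=config.widths, in_channels=task.images.shape[1],
                   n_classes=n_classes, seed=config.seed)
    opt = nn.SGD(net.params(), lr=config.lr, momentum=config.momentum,
                 weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed)
    n = task.images.shape[0]
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            logits = net.forward(Tensor(task.images[idx]), training=True)
            loss = nn.softmax_cross_entropy(logits, task.labels[idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError("source pretraining diverged")
            opt.zero_grad()
            loss.backward()
            opt.step()
    return SourceNetwork(net, task_id=task.task_id)


def training_accuracy(net, images: np.ndarray, labels: np.ndarray) -> float:
    logits = net.forward(Tensor(images), training=False)
    if isinstance(logits, tuple):
        logits = logits[0]
    return float((logits.data.argmax(axis=1) == labels).mean())


# --------------------------------------------------------- four-stage loop

@dataclass
class StepTrace:
    """Loss trace of one four-stage step."""

    l_org: float
    l_wfm: float
    l_total: float
    l_org_post: float
    theta_updates: int
    meta_updates: int
    per_pair: dict = field(default_factory=dict)


class TransferTrainer:
    """Holds the target network, matching state, and both optimizers, and
    runs four-stage steps; the same mini-batch is reused across all four
    stages of a step."""

    def __init__(self, target, sources: list, state: MatchState,
                 config: TrainingConfig):
        self.target = target
        self.sources = {i + 1: s for i, s in enumerate(sources)}
        self.state = state
        self.config = config
        self.opt_theta = nn.SGD(target.params() + state.adapter_params(),
                                lr=config.lr_theta, momentum=config.momentum,
                                weight_decay=config.weight_decay_theta)
        self.opt_meta = nn.Adam(state.meta_params(), lr=config.lr_meta,
                                weight_decay=config.weight_decay_meta)

    # ------------------------------------------------------------------
    def _source_taps(self, x: np.ndarray) -> dict:
        return {k: s.forward_taps(x) for k, s in self.sources.items()}

    def _forward(self, x: np.ndarray):
        return self.target.forward(Tensor(x), training=True, return_taps=True)

    def four_stage_step(self, x: np.ndarray, y: np.ndarray) -> StepTrace:
        cfg = self.config
        staps = self._source_taps(x)

        # stage 1: one step on (theta, v) with L_total
        logits, taps = self._forward(x)
        l_wfm, per_pair = self.state.total_matching_loss(staps, taps)
        total, _, breakdown = total_loss(logits, y, l_wfm, per_pair, cfg.tradeoff)
        if not np.isfinite(total.data):
            raise FloatingPointError("non-finite training loss")
        self.opt_theta.zero_grad()
        total.backward()
        self.opt_theta.step()
        theta_updates = 1

        # stage 2: T steps on (theta, v) with L_wfm alone
        for _ in range(cfg.inner_steps):
            _, taps = self._forward(x)
            l_wfm2, _ = self.state.total_matching_loss(staps, taps)
            self.opt_theta.zero_grad()
            l_wfm2.backward()
            self.opt_theta.step()
            theta_updates += 1

        # stage 3: one step on (theta, v) with L_org alone
        logits, _ = self._forward(x)
        l_org3 = nn.softmax_cross_entropy(logits, y)
        self.opt_theta.zero_grad()
        l_org3.backward()
        self.opt_theta.step()
        theta_updates += 1

        # stage 4: one step on the matching heads (f, g)
        l_org_post = self._meta_step(x, y, staps)

        return StepTrace(l_org=breakdown.l_org, l_wfm=breakdown.l_wfm,
                         l_total=breakdown.l_total, l_org_post=l_org_post,
                         theta_updates=theta_updates, meta_updates=1,
                         per_pair=breakdown.per_pair)

    def _meta_step(self, x, y, staps) -> float:
        logits, taps = self._forward(x)
        l_org = nn.softmax_cross_entropy(logits, y)
        for p in self.target.params():
            p.zero_grad()
        l_org.backward()

        n = x.shape[0]
        meta_loss = None
        for key, s_map, adapted, w, lam in self.state.pair_terms(staps, taps):
            tap = taps[key[2]]
            if tap.grad is None:
                continue
            h, wd = s_map.shape[2], s_map.shape[3]
            diff = adapted.data - s_map
            # gradient of the (unit-lambda) pair loss at the adapted map
            dl_dadapted = 2.0 * w.data[:, :, None, None] * diff / (h * wd * n)
            w1x1 = self.state.adapters[key].weight.data[:, :, 0, 0]
            dl_dtap = np.einsum("st,nshw->nthw", w1x1, dl_dadapted)
            g_p = float((tap.grad * dl_dtap).sum())
            # surrogate: minimizing -g_p * lambda * l_hat moves the heads so
            # that aligned pairs (g_p > 0) gain weight
            e_chan = (diff ** 2).sum(axis=(2, 3)).mean(axis=0) / (h * wd)
            l_hat = nn.tmean(nn.tsum(nn.mul(w, Tensor(e_chan)), axis=1))
            lam_bar = nn.tmean(lam)
            prod = nn.mul(lam_bar, l_hat)
            denom = abs(float(prod.data)) + 1e-12
            term = nn.scale(prod, -g_p / denom)
            meta_loss = term if meta_loss is None else nn.add(meta_loss, term)

        if meta_loss is not None:
            self.opt_meta.zero_grad()
            meta_loss.backward()
            self.opt_meta.step()
        return float(l_org.data)

    def lambda_grid(self, x: np.ndarray) -> dict:
        """Mean lambda per (source layer m, target layer n) on a batch."""
        staps = self._source_taps(x)
        grids = {}
        for k, plist in self.state.pairs.items():
            grid = np.zeros((len(self.state.source_channels[k]),
                             len(self.state.target_channels)))
            for (m, n_) in plist:
                lam = pair_weight_value(self.state, k, m, n_, staps[k][m])
                grid[m, n_] = lam
            grids[k] = grid
        return grids


def pair_weight_value(state: MatchState, k, m, n, source_map: np.ndarray) -> float:
    from .matching import pair_weight
    return float(pair_weight(source_map, state.g_heads[(k, m, n)]).data.mean())


# --------------------------------------------------------------- training

def cohort_to_arrays(cohort):
    """Flatten patient slice stacks into (images, labels, patient index)."""
    xs, ys, pid = [], [], []
    for i, rec in enumerate(cohort):
        for sl in rec.slices:
            xs.append(sl)
            ys.append(rec.label)
            pid.append(i)
    return (np.stack(xs).astype(np.float32), np.array(ys, dtype=np.int64),
            np.array(pid))


def train_target(train_data, sources: list, config: TrainingConfig,
                 val_data=None, pairs: dict | None = None):
    """Train the DBB target network with four-stage feature-matching
    transfer.  ``train_data`` is (images, labels); returns
    (target network, match state, history, trainer)."""
    x_all, y_all = train_data
    from .dbb import ToyDBBNet

    target = ToyDBBNet(widths=config.widths, in_channels=x_all.shape[1],
                       n_classes=config.n_classes, seed=config.seed)
    source_channels = {i + 1: s.channels for i, s in enumerate(sources)}
    state = MatchState(source_channels, list(config.widths), pairs=pairs,
                       tradeoff=config.tradeoff)
    trainer = TransferTrainer(target, sources, state, config)
    rng = np.random.default_rng(config.seed)
    history = []
    best_val, best_epoch = np.inf, -1
    n = x_all.shape[0]
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        traces = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            if len(idx) < 2:
                continue  # batch-norm needs more than one sample
            traces.append(trainer.four_stage_step(x_all[idx], y_all[idx]))
        row = {
            "epoch": epoch,
            "l_org": float(np.mean([t.l_org for t in traces])),
            "l_wfm": float(np.mean([t.l_wfm for t in traces])),
            "l_total": float(np.mean([t.l_total for t in traces])),
        }
        if val_data is not None:
            xv, yv = val_data
            logits = target.forward(Tensor(xv), training=False)
            row["val_loss"] = float(nn.softmax_cross_entropy(logits, yv).data)
            if row["val_loss"] < best_val - 1e-6:
                best_val, best_epoch = row["val_loss"], epoch
            elif epoch - best_epoch >= config.patience:
                history.append(row)
                break
        history.append(row)
    return target, state, history, trainer


def patient_scores_from_arrays(net, x: np.ndarray, patient_idx: np.ndarray,
                               n_patients: int) -> np.ndarray:
    """Per-patient class-1 probability from pre-flattened slice arrays."""
    logits = net.forward(Tensor(x), training=False)
    if isinstance(logits, tuple):
        logits = logits[0]
    scores = np.empty(n_patients)
    for i in range(n_patients):
        mean_logit = logits.data[patient_idx == i].mean(axis=0)
        z = mean_logit - mean_logit.max()
        p = np.exp(z) / np.exp(z).sum()
        scores[i] = p[1]
    return scores


def patient_scores(net, cohort) -> np.ndarray:
    """Per-patient class-1 probability: softmax of the mean slice logits."""
    scores = []
    for rec in cohort:
        x = np.stack(rec.slices).astype(np.float32)
        logits = net.forward(Tensor(x), training=False)
        if isinstance(logits, tuple):
            logits = logits[0]
        mean_logit = logits.data.mean(axis=0)
        z = mean_logit - mean_logit.max()
        p = np.exp(z) / np.exp(z).sum()
        scores.append(p[1])
    return np.array(scores)
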