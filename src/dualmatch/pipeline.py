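"""End-to-end desk-scale pipeline: simulate -> pretrain two sources ->
four-stage transfer training -> reparameterize -> per-patient features ->
Mann-Whitney screening -> sparse Bayes ELM ensemble -> evaluation.

Every stage is driven by one config dictionary (see DEFAULT_CONFIG) and a
master seed; all artifacts (CSV tables, metrics report, reproducibility
manifest, optional PNGs) land in the output directory.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, features, sbelm, synthetic, training
from .nn import Tensor
from .synthetic import SyntheticSpec, TextureParams

DEFAULT_CONFIG = {
    "seed": 0,
    "source": {
        "n_per_class": 16,
        "image_size": 48,
        "noise_sd": 0.08,
        "widths": [8, 16, 32, 64],
        "epochs": 25,
        "batch_size": 16,
        "lr": 0.05,
    },
    "cohort": {
        "n_train": 20,
        "n_test": 16,
        "slices_range": [3, 5],
        "image_size": 224,
        "noise_sd": 0.12,
    },
    "target": {
        "widths": [8, 16, 32, 64],
        "tradeoff": 0.5,
        "inner_steps": 2,
        "lr_theta": 0.02,
        "lr_meta": 0.02,
        "batch_size": 6,
        "epochs": 2,
        # desk-scale study conditions: train at reduced resolution and on
        # same-stage candidate pairs; records stay 224x224 and feature
        # extraction runs at full resolution
        "train_image_size": 96,
        "pairs": "diagonal",
    },
    "classifier": {
        "m_bases": 10,
        "bag_fraction": 1.0,
        "hidden_width": 40,
        "alpha": 0.05,
    },
    "threshold": 0.5,
    "n_boot": 500,
}


def _merge(base: dict, override: dict | None) -> dict:
    out = {k: (dict(v) if isinstance(v, dict) else v) for k, v in base.items()}
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _source_specs(cfg: dict, seed: int):
    """Two source tasks: a coarse 'natural texture' task and a finer
    'microscopy tile' task, both 2-class texture discriminations."""
    s = cfg["source"]
    natural = SyntheticSpec(
        n_per_class=s["n_per_class"], n_classes=2, image_size=s["image_size"],
        noise_sd=s["noise_sd"], seed=seed + 11, task_id="source1")
    micro = SyntheticSpec(
        n_per_class=s["n_per_class"], n_classes=2, image_size=s["image_size"],
        texture_params=(TextureParams(0.18, 0.3, n_blobs=2),
                        TextureParams(0.25, 1.2, n_blobs=4)),
        noise_sd=s["noise_sd"], seed=seed + 12, task_id="source2")
    return natural, micro


def pretrain_sources(cfg: dict, seed: int):
    natural, micro = _source_specs(cfg, seed)
    s = cfg["source"]
    out = []
    for i, spec in enumerate((natural, micro)):
        task = synthetic.gen_task(spec)
        pc = training.PretrainConfig(
            lr=s["lr"], batch_size=s["batch_size"], epochs=s["epochs"],
            seed=seed + 21 + i, widths=tuple(s["widths"]))
        net = training.pretrain_source(task, pc)
        acc = training.training_accuracy(net.net, task.images, task.labels)
        out.append((net, acc))
    return out


def make_cohorts(cfg: dict, seed: int):
    c = cfg["cohort"]
    train = synthetic.gen_patient_cohort(
        c["n_train"], tuple(c["slices_range"]), 0.5, seed=seed + 31,
        image_size=c["image_size"], noise_sd=c["noise_sd"])
    test = synthetic.gen_patient_cohort(
        c["n_test"], tuple(c["slices_range"]), 0.5, seed=seed + 32,
        image_size=c["image_size"], noise_sd=c["noise_sd"])
    return train, test


def target_config(cfg: dict, seed: int, tradeoff=None) -> training.TrainingConfig:
    t = cfg["target"]
    return training.TrainingConfig(
        tradeoff=t["tradeoff"] if tradeoff is None else tradeoff,
        inner_steps=t["inner_steps"], lr_theta=t["lr_theta"],
        lr_meta=t["lr_meta"], batch_size=t["batch_size"], epochs=t["epochs"],
        seed=seed + 41, widths=tuple(t["widths"]))


def _candidate_pairs(cfg: dict, n_stages: int):
    """'diagonal' pairs each source stage with the same target stage;
    'all' (the MatchState default) crosses every stage combination."""
    mode = cfg["target"].get("pairs", "all")
    if mode == "all":
        return None
    if mode == "diagonal":
        diag = [(m, m) for m in range(n_stages)]
        return {1: list(diag), 2: list(diag)}
    raise ValueError(f"unknown pair mode {mode!r}")


def _train_resolution(cfg: dict, x: np.ndarray) -> np.ndarray:
    size = int(cfg["target"].get("train_image_size", x.shape[-1]))
    if size == x.shape[-1]:
        return x
    from .nn import resize_bilinear
    return resize_bilinear(x, size, size)


def run_pipeline(config: dict | None = None, out_dir=None) -> dict:
    """Execute the full pipeline; returns a result dict and, when
    ``out_dir`` is given, writes every artifact there."""
    cfg = _merge(DEFAULT_CONFIG, config)
    seed = int(cfg["seed"])
    t0 = time.time()

    (src1, acc1), (src2, acc2) = pretrain_sources(cfg, seed)
    train_cohort, test_cohort = make_cohorts(cfg, seed)
    x_tr_full, y_tr, _ = training.cohort_to_arrays(train_cohort)
    x_tr = _train_resolution(cfg, x_tr_full)

    tc = target_config(cfg, seed)
    pairs = _candidate_pairs(cfg, len(tc.widths))
    target, state, history, trainer = training.train_target(
        (x_tr, y_tr), [src1, src2], tc, pairs=pairs)

    reparam = target.reparameterize()
    # reparameterization consistency on a training batch
    probe = x_tr[: min(4, len(x_tr))]
    dev = float(np.abs(target.forward(Tensor(probe), training=False).data
                       - reparam.forward(Tensor(probe)).data).max())

    feats_tr = features.extract_cohort_features(reparam, train_cohort)
    feats_te = features.extract_cohort_features(reparam, test_cohort)
    labels_tr = np.array([r.label for r in train_cohort])
    labels_te = np.array([r.label for r in test_cohort])

    screen = features.mann_whitney_screen(feats_tr, labels_tr,
                                          alpha=cfg["classifier"]["alpha"])
    selected = list(screen.selected)
    if not selected:  # degenerate screen on tiny cohorts: keep the 10 best
        selected = list(screen.table["p"].nsmallest(10).index)
    mu, sd = features.zscore_fit(feats_tr[selected])
    z_tr = features.zscore_apply(feats_tr[selected], mu, sd)
    z_te = features.zscore_apply(feats_te[selected], mu, sd)

    clf_cfg = sbelm.SBELMConfig(hidden_width=cfg["classifier"]["hidden_width"],
                                seed=seed + 51)
    ensemble = sbelm.fit_ensemble(z_tr.to_numpy(), labels_tr.astype(float),
                                  m_bases=cfg["classifier"]["m_bases"],
                                  bag_fraction=cfg["classifier"]["bag_fraction"],
                                  config=clf_cfg)
    scores_tr = sbelm.predict_ensemble(ensemble, z_tr.to_numpy())
    scores_te = sbelm.predict_ensemble(ensemble, z_te.to_numpy())

    thr = cfg["threshold"]
    metrics = {
        "train": evaluation.threshold_metrics(scores_tr, labels_tr, thr,
                                              n_boot=cfg["n_boot"], seed=seed).as_dict(),
        "test": evaluation.threshold_metrics(scores_te, labels_te, thr,
                                             n_boot=cfg["n_boot"], seed=seed).as_dict(),
    }

    lam_grids = trainer.lambda_grid(x_tr[: min(8, len(x_tr))])
    result = {
        "config": cfg,
        "source_train_acc": [acc1, acc2],
        "history": history,
        "reparam_max_dev": dev,
        "n_features_total": feats_tr.shape[1],
        "n_features_selected": len(selected),
        "metrics": metrics,
        "lambda_grids": {str(k): v.tolist() for k, v in lam_grids.items()},
        "runtime_s": time.time() - t0,
    }

    if out_dir is not None:
        _write_artifacts(Path(out_dir), cfg, result, history, screen,
                         feats_tr, feats_te, scores_te, labels_te, lam_grids)
    return result


def _write_artifacts(out, cfg, result, history, screen, feats_tr, feats_te,
                     scores_te, labels_te, lam_grids):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out.mkdir(parents=True, exist_ok=True)
    cfg_text = json.dumps(cfg, sort_keys=True, indent=2)
    (out / "config.json").write_text(cfg_text)
    pd.DataFrame(history).to_csv(out / "history.csv", index=False)
    screen.table.to_csv(out / "screening.csv")
    feats_tr.to_csv(out / "features_train.csv")
    feats_te.to_csv(out / "features_test.csv")
    for k, grid in lam_grids.items():
        pd.DataFrame(grid).to_csv(out / f"lambda_grid_source{k}.csv")
    (out / "metrics.json").write_text(json.dumps(result["metrics"], indent=2))
    manifest = {
        "seed": cfg["seed"],
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "runtime_s": result["runtime_s"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    fpr, tpr, _ = evaluation.roc_points(scores_te, labels_te)
    pd.DataFrame({"fpr": fpr, "tpr": tpr}).to_csv(out / "roc_test.csv", index=False)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(fpr, tpr, marker="o", ms=3)
    ax.plot([0, 1], [0, 1], "--", color="grey")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    fig.savefig(out / "roc_test.png", dpi=120, bbox_inches="tight")
    plt.close(fig)


def transfer_benefit(config: dict | None = None, seeds=(0, 1, 2)) -> list:
    """Paired comparison: held-out patient accuracy of the transfer-trained
    target network vs an identically trained tradeoff=0 baseline, on the
    same data, over several seeds.  Returns (seed, acc_transfer, acc_base)
    rows; the patient score is the softmax of the mean slice logits."""
    cfg = _merge(DEFAULT_CONFIG, config)
    base_seed = int(cfg["seed"])
    (src1, _), (src2, _) = pretrain_sources(cfg, base_seed)
    train_cohort, test_cohort = make_cohorts(cfg, base_seed)
    x_tr, y_tr, _ = training.cohort_to_arrays(train_cohort)
    x_tr = _train_resolution(cfg, x_tr)
    x_te, _, pid_te = training.cohort_to_arrays(test_cohort)
    x_te = _train_resolution(cfg, x_te)
    labels_te = np.array([r.label for r in test_cohort])
    pairs = _candidate_pairs(cfg, len(cfg["target"]["widths"]))
    rows = []
    for s in seeds:
        accs = []
        for tradeoff in (None, 0.0):
            tc = target_config(cfg, base_seed, tradeoff=tradeoff)
            tc = training.replace(tc, seed=base_seed + 41 + 1000 * s)
            net, _, _, _ = training.train_target((x_tr, y_tr), [src1, src2],
                                                 tc, pairs=pairs)
            scores = training.patient_scores_from_arrays(net, x_te, pid_te,
                                                         len(test_cohort))
            accs.append(float(((scores >= 0.5).astype(int) == labels_te).mean()))
        rows.append((s, accs[0], accs[1]))
    return rows
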