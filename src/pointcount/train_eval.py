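"""Training protocol and evaluation statistics.

Training follows the point-proposal recipe: Adam over three parameter groups
(decayed weights / undecayed normalization / biases) with a reduced learning
rate for the fusion (FPN) parameters, linear warm-up followed by cosine decay,
global gradient-norm clipping, train-time-only augmentation, periodic
validation and early stopping on validation MAE.

Evaluation reports per-image count agreement: MAE, RMSE, the coefficient of
determination R^2, t-based 95% confidence intervals of the error means, a
paired t-test between two models' predictions, and density-stratified /
per-cultivar breakdowns with scatter-fit data.
"""

from __future__ import annotations

import json
import math
import os
import time
from dataclasses import dataclass, field, asdict

import numpy as np
from PIL import Image
from scipy import stats
from skimage import transform as sktransform

from . import autodiff as ad
from .autodiff import Adam, Tensor, clip_grad_norm
from .annotations_io import AugmentationSpec, DatasetManifest, augment_sample
from .losses import LossConfig, total_loss
from .network import CountingNetwork, NetworkConfig, decode_points, normalize_image, predict_points
from .point_core import PointSet, density_stratum, pairwise_distances


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class TrainConfig:
    input_size: int = 256
    batch_size: int = 4
    base_lr: float = 1e-4
    fpn_lr: float = 1e-5
    epochs: int = 200
    warmup_epochs: int = 3
    weight_decay: float = 1e-4
    clip_norm: float = 0.1
    eval_every: int = 2
    patience: int = 10  # evaluations without MAE improvement
    min_improvement: float = 1e-3
    seed: int = 0
    max_steps: int | None = None  # optional hard cap on optimizer steps

    def __post_init__(self):
        for name in ("input_size", "batch_size", "epochs", "eval_every"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass
class EvalRecord:
    image_id: str
    y: int  # ground-truth count
    y_hat: int  # predicted count
    cultivar: str = ""
    stratum: str = ""

    def __post_init__(self):
        if self.y < 0 or self.y_hat < 0:
            raise ValueError("counts must be nonnegative")
        if not self.stratum:
            self.stratum = density_stratum(self.y)


@dataclass
class MetricReport:
    mae: float
    rmse: float
    r2: float | None  # None when ground-truth variance is zero (undefined)
    ci95: dict = field(default_factory=dict)  # metric -> (low, high)
    n: int = 0

    @property
    def r2_defined(self) -> bool:
        return self.r2 is not None


@dataclass
class PairedComparison:
    d: np.ndarray
    d_bar: float
    s_d: float
    t: float
    dof: int
    p_value: float
    degenerate: bool = False


# ---------------------------------------------------------------------------
# Schedule and parameter groups
# ---------------------------------------------------------------------------

LR_FLOOR = 0.01  # warm-up start and cosine floor, as a fraction of the base rate


def lr_schedule(step: int, total_steps: int, cfg: TrainConfig) -> dict:
    """Per-group learning rates at an optimizer step.

    Linear warm-up from base/100 to base over the warm-up epochs, then a
    half-cosine decay back to base/100; the FPN group follows the same
    factor applied to its own base rate."""
    if not (0 <= step <= total_steps):
        raise ValueError("step out of range")
    warmup_steps = int(round(total_steps * cfg.warmup_epochs / max(cfg.epochs, 1)))
    warmup_steps = min(warmup_steps, total_steps)
    if warmup_steps > 0 and step <= warmup_steps:
        f = LR_FLOOR + (1.0 - LR_FLOOR) * step / warmup_steps
    else:
        denom = max(total_steps - warmup_steps, 1)
        t = (step - warmup_steps) / denom
        f = LR_FLOOR + (1.0 - LR_FLOOR) * 0.5 * (1.0 + math.cos(math.pi * t))
    return {"base": cfg.base_lr * f, "fpn": cfg.fpn_lr * f}


def make_param_groups(model: CountingNetwork, cfg: TrainConfig) -> list:
    """Three groups: decayed weights, undecayed normalization scales, biases."""
    decay, no_decay, bias = [], [], []
    for name, p in model.named_parameters():
        if name.endswith("bias"):
            bias.append((name, p))
        elif p.data.ndim >= 2:
            decay.append((name, p))
        else:  # batch-norm gamma/beta, 1-D attention kernels
            no_decay.append((name, p))
    return [
        {"name": "decay", "params": [p for _, p in decay],
         "param_names": [n for n, _ in decay], "weight_decay": cfg.weight_decay},
        {"name": "no_decay", "params": [p for _, p in no_decay],
         "param_names": [n for n, _ in no_decay], "weight_decay": 0.0},
        {"name": "bias", "params": [p for _, p in bias],
         "param_names": [n for n, _ in bias], "weight_decay": 0.0},
    ]


def _optimizer_groups(model: CountingNetwork, cfg: TrainConfig) -> list:
    """Split the three groups by FPN membership so the fusion layer trains
    at its reduced rate (lr_scale = fpn_lr / base_lr)."""
    scale = cfg.fpn_lr / cfg.base_lr
    groups = []
    for g in make_param_groups(model, cfg):
        main, fpn = [], []
        for name, p in zip(g["param_names"], g["params"]):
            (fpn if name.startswith("fpn.") else main).append(p)
        if main:
            groups.append({"params": main, "weight_decay": g["weight_decay"], "lr_scale": 1.0})
        if fpn:
            groups.append({"params": fpn, "weight_decay": g["weight_decay"], "lr_scale": scale})
    return groups


# ---------------------------------------------------------------------------
# Data plumbing
# ---------------------------------------------------------------------------

def load_sample(record, root: str, input_size: int):
    """Load an image and rescale it (and its points) to input_size square."""
    img = np.asarray(Image.open(os.path.join(root, record.image_path)).convert("RGB"))
    pts = record.points.points
    H, W = img.shape[:2]
    if (H, W) != (input_size, input_size):
        img = sktransform.resize(img.astype(float), (input_size, input_size),
                                 order=1, preserve_range=True, anti_aliasing=True).astype(np.uint8)
        if len(pts):
            pts = np.stack([
                (pts[:, 0] + 0.5) * input_size / W - 0.5,
                (pts[:, 1] + 0.5) * input_size / H - 0.5,
            ], axis=1)
    return img, pts


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def train(manifest: DatasetManifest, net_cfg: NetworkConfig | None = None,
          loss_cfg: LossConfig | None = None, train_cfg: TrainConfig | None = None,
          aug_spec: AugmentationSpec | None = None, log_path: str | None = None,
          verbose: bool = False):
    """Train a counting network on the manifest's train split.

    Returns (model, history); the model carries the best-validation-MAE
    parameters seen.  History entries are dicts (epoch losses and periodic
    validation metrics); the same records go to ``log_path`` as JSON lines.
    """
    net_cfg = net_cfg or NetworkConfig()
    loss_cfg = loss_cfg or LossConfig()
    cfg = train_cfg or TrainConfig()
    aug_spec = aug_spec or AugmentationSpec()

    train_recs = manifest.subset("train")
    val_recs = manifest.subset("val")
    if not train_recs:
        raise ValueError("manifest has an empty train split")
    rng = np.random.default_rng(cfg.seed)

    samples = [load_sample(r, manifest.root, cfg.input_size) for r in train_recs]
    val_samples = [load_sample(r, manifest.root, cfg.input_size) for r in val_recs]

    model = CountingNetwork(net_cfg)
    opt = Adam(_optimizer_groups(model, cfg))
    all_params = model.parameters()
    refs = model.fused_grid(cfg.input_size, cfg.input_size)
    refs_t = Tensor(refs.astype(np.float32))

    steps_per_epoch = math.ceil(len(samples) / cfg.batch_size)
    total_steps = steps_per_epoch * cfg.epochs
    if cfg.max_steps is not None:
        total_steps = min(total_steps, cfg.max_steps)

    history = []
    log_fh = open(log_path, "w") if log_path else None

    def emit(rec: dict):
        history.append(rec)
        if log_fh:
            log_fh.write(json.dumps(rec) + "\n")
            log_fh.flush()
        if verbose:
            print(rec)

    best = {"mae": float("inf"), "state": model.state_dict(), "epoch": 0}
    evals_since_improve = 0
    step = 0
    stop = False

    for epoch in range(1, cfg.epochs + 1):
        model.train()
        order = rng.permutation(len(samples))
        sums = {"L_cls": 0.0, "L_reg": 0.0, "L_near": 0.0, "L_overlap": 0.0, "L_total": 0.0}
        nb = 0
        for b0 in range(0, len(order), cfg.batch_size):
            if step >= total_steps:
                stop = True
                break
            idxs = order[b0 : b0 + cfg.batch_size]
            imgs, gts = [], []
            for i in idxs:
                img, pts = samples[i]
                if aug_spec.enabled:
                    partners = None
                    if len(samples) >= 4:
                        js = rng.choice(len(samples), size=3, replace=False)
                        partners = [samples[j] for j in js]
                    img, pts = augment_sample(img, pts, aug_spec, rng, partners)
                imgs.append(normalize_image(img))
                gts.append(np.asarray(pts, dtype=float).reshape(-1, 2))
            x = Tensor(np.stack(imgs))
            offsets, logits = model(x)
            batch_loss = None
            for bi in range(len(idxs)):
                pred_pts = refs_t + offsets[bi]
                s = ad.sigmoid(logits[bi])
                bd = total_loss(s, pred_pts, gts[bi], loss_cfg, logits=logits[bi])
                for k, v in bd.as_dict().items():
                    sums[k] += v
                batch_loss = bd.tensor if batch_loss is None else batch_loss + bd.tensor
            nb += len(idxs)
            model.zero_grad()
            (batch_loss * (1.0 / len(idxs))).backward()
            clip_grad_norm(all_params, cfg.clip_norm)
            step += 1
            lrs = lr_schedule(step, total_steps, cfg)
            opt.step(lrs["base"])
        if nb:
            emit({"epoch": epoch, "step": step,
                  **{k: v / nb for k, v in sums.items()},
                  "lr": lr_schedule(step, total_steps, cfg)["base"]})

        if epoch % cfg.eval_every == 0 and val_samples:
            rep = _evaluate_samples(model, val_samples)
            emit({"epoch": epoch, "val_mae": rep.mae, "val_rmse": rep.rmse,
                  "val_r2": rep.r2, "n_val": rep.n})
            if rep.mae < best["mae"] - cfg.min_improvement:
                best = {"mae": rep.mae, "state": model.state_dict(), "epoch": epoch}
                evals_since_improve = 0
            else:
                evals_since_improve += 1
                if evals_since_improve >= cfg.patience:
                    emit({"epoch": epoch, "early_stop": True, "best_epoch": best["epoch"]})
                    stop = True
        if stop:
            break

    if best["mae"] < float("inf"):
        model.load_state_dict(best["state"])
    model.eval()
    if log_fh:
        log_fh.close()
    return model, history


def _evaluate_samples(model: CountingNetwork, samples) -> MetricReport:
    recs = []
    for i, (img, pts) in enumerate(samples):
        pred = predict_points(img, model)
        recs.append(EvalRecord(str(i), len(pts), len(pred)))
    return evaluate(recs)


def predict_records(model: CountingNetwork, manifest: DatasetManifest, split: str = "test",
                    input_size: int | None = None) -> list:
    """Predicted vs true counts for every record of a split."""
    out = []
    size = input_size or 256
    for r in manifest.subset(split):
        img, pts = load_sample(r, manifest.root, size)
        pred = predict_points(img, model)
        out.append(EvalRecord(r.image_path, len(pts), len(pred), cultivar=r.cultivar))
    return out


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def evaluate(records) -> MetricReport:
    """MAE / RMSE / R^2 over per-image counts, with t-based 95% CIs.

    R^2 is reported as None (undefined) when the ground-truth counts have
    zero variance, rather than being clamped."""
    if not records:
        raise ValueError("no records to evaluate")
    y = np.array([r.y for r in records], dtype=float)
    yhat = np.array([r.y_hat for r in records], dtype=float)
    err = y - yhat
    mae = float(np.abs(err).mean())
    rmse = float(np.sqrt((err**2).mean()))
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = None if ss_tot == 0.0 else float(1.0 - (err**2).sum() / ss_tot)
    ci = {}
    if len(records) >= 2:
        ci["MAE"] = ci95(np.abs(err))
        lo, hi = ci95(err**2)
        ci["RMSE"] = (float(np.sqrt(max(lo, 0.0))), float(np.sqrt(max(hi, 0.0))))
    return MetricReport(mae, rmse, r2, ci, n=len(records))


def ci95(values) -> tuple:
    """Mean +/- t_{0.975, N-1} * s / sqrt(N), s the sample std (ddof=1)."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError("ci95 needs at least two values")
    m = values.mean()
    s = values.std(ddof=1)
    half = stats.t.ppf(0.975, n - 1) * s / math.sqrt(n)
    return (float(m - half), float(m + half))


def paired_t_test(a, b) -> PairedComparison:
    """Two-sided paired t-test on per-sample prediction differences a - b."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("need two equal-length 1-D prediction vectors")
    n = len(a)
    if n < 2:
        raise ValueError("paired t-test needs N >= 2")
    d = a - b
    d_bar = float(d.mean())
    s_d = float(d.std(ddof=1))
    dof = n - 1
    if s_d == 0.0:
        if d_bar == 0.0:
            return PairedComparison(d, 0.0, 0.0, 0.0, dof, 1.0, degenerate=False)
        t = math.inf if d_bar > 0 else -math.inf
        return PairedComparison(d, d_bar, 0.0, t, dof, 0.0, degenerate=True)
    t = d_bar / (s_d / math.sqrt(n))
    p = float(2.0 * stats.t.sf(abs(t), dof))
    return PairedComparison(d, d_bar, s_d, t, dof, p)


def stratified_report(records) -> dict:
    """Per-stratum and per-cultivar metric reports plus scatter/fit data."""
    out = {"overall": evaluate(records), "strata": {}, "cultivars": {}}
    for label in ("Sparse", "Medium", "Dense"):
        grp = [r for r in records if r.stratum == label]
        if grp:
            out["strata"][label] = evaluate(grp)
    for cul in sorted({r.cultivar for r in records if r.cultivar}):
        grp = [r for r in records if r.cultivar == cul]
        if grp:
            out["cultivars"][cul] = evaluate(grp)
    y = np.array([r.y for r in records], dtype=float)
    yhat = np.array([r.y_hat for r in records], dtype=float)
    out["scatter"] = np.stack([y, yhat], axis=1)
    if len(records) >= 2 and y.var() > 0:
        slope, intercept = np.polyfit(y, yhat, 1)
        out["fit"] = {"slope": float(slope), "intercept": float(intercept)}
    else:
        out["fit"] = None
    return out


# ---------------------------------------------------------------------------
# Spatial-duplication diagnostics (penalty efficacy)
# ---------------------------------------------------------------------------

def count_close_pairs(points, d_min: float) -> int:
    """Unordered prediction pairs closer than d_min in one image."""
    pts = points.points if isinstance(points, PointSet) else np.asarray(points, dtype=float)
    n = len(pts)
    if n < 2:
        return 0
    d = pairwise_distances(pts, pts)
    iu = np.triu_indices(n, k=1)
    return int((d[iu] < d_min).sum())


def mean_close_pairs(model: CountingNetwork, samples, d_min: float) -> float:
    """Mean close-pair count of the decoded predictions over images."""
    total = 0
    for img, _ in samples:
        pred = predict_points(img, model)
        total += count_close_pairs(pred, d_min)
    return total / max(len(samples), 1)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: CountingNetwork, path: str) -> str:
    state = model.state_dict()
    cfg = asdict(model.cfg)
    np.savez(path if str(path).endswith(".npz") else str(path) + ".npz",
             __config__=json.dumps(cfg), **state)
    return str(path)


def load_checkpoint(path: str) -> CountingNetwork:
    data = np.load(path, allow_pickle=False)
    cfg_d = json.loads(str(data["__config__"]))
    from .network import EcaConfig, SvitConfig
    cfg_d["svit"] = SvitConfig(**{**cfg_d["svit"], "grid": tuple(cfg_d["svit"]["grid"])})
    cfg_d["eca"] = EcaConfig(**cfg_d["eca"])
    model = CountingNetwork(NetworkConfig(**cfg_d))
    model.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
    model.eval()
    return model
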