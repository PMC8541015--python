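"""Two-stage training and inference for the coarse-to-fine cascade.

Stage 1 (U-Net) is trained first with the adaptive weighted cross-entropy;
its frozen probability maps are fused with the inputs and the fused maps,
presented at the configured resolutions, train stage 2 (the dense-ASPP /
attention network).  An optional joint fine-tuning phase optimises
alpha * L_coarse + (1 - alpha) * L_fine with the stage-2 input detached from
the stage-1 graph, so alpha mixes the two losses without backpropagating
through the fusion.  Class weights are computed once from the training
split's pixel proportions before training.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .coarse_net import UNet, UNetConfig, build_unet
from .fine_net import (ADenseConfig, ADenseNet, build_adensenet,
                       build_multires_inputs, fuse_coarse)
from .loss_metrics import (CaseMetrics, ClassWeights, adaptive_weights,
                           aggregate_metrics, case_metrics, class_proportions,
                           metrics_frame)
from .nn import Tensor


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 300
    learning_rate: float = 1e-4
    alpha: float = 0.33
    batch_size: int = 8
    seed: int = 0
    val_fraction: float = 0.2
    joint_epochs: int = 0
    fine_epochs: int | None = None

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")


#: reduced profile for CPU-scale experiments and tests; the fine stage gets a
#: longer schedule because its loss is still falling when stage 1 has settled
CPU_TEST_TRAIN = TrainConfig(epochs=16, fine_epochs=24,
                             learning_rate=3e-3, batch_size=8)


@dataclass
class CascadeModel:
    coarse: UNet
    fine: ADenseNet | None
    coarse_config: UNetConfig
    fine_config: ADenseConfig | None
    weights: ClassWeights | None = None


def split_dataset(images: list[np.ndarray], masks: list[np.ndarray],
                  val_fraction: float, seed: int,
                  extras: list | None = None):
    """Deterministic random train/validation split (by case)."""
    n = len(images)
    idx = np.random.default_rng(seed).permutation(n)
    n_val = int(round(val_fraction * n))
    val_idx, tr_idx = idx[:n_val], idx[n_val:]

    def take(sel):
        parts = ([images[i] for i in sel], [masks[i] for i in sel])
        if extras is not None:
            parts += ([extras[i] for i in sel],)
        return parts

    return take(tr_idx), take(val_idx)


def _batches(n: int, batch_size: int, rng: np.random.Generator | None):
    order = np.arange(n) if rng is None else rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def _stack_images(images: list[np.ndarray], sel) -> np.ndarray:
    return np.stack([images[i] for i in sel]).astype(np.float32)[:, None]


def _stack_masks(masks: list[np.ndarray], sel) -> np.ndarray:
    return np.stack([masks[i] for i in sel]).astype(np.int64)


def _check_loss(value: float) -> float:
    if not np.isfinite(value):
        raise FloatingPointError(f"non-finite training loss: {value}")
    return float(value)


def _train_epochs(forward_loss, params, n_items: int, epochs: int,
                  cfg: TrainConfig, rng: np.random.Generator) -> list[float]:
    opt = nn.Adam(params, lr=cfg.learning_rate)
    history = []
    for _ in range(epochs):
        losses = []
        for sel in _batches(n_items, cfg.batch_size, rng):
            opt.zero_grad()
            loss = forward_loss(sel)
            loss.backward()
            opt.step()
            losses.append(_check_loss(float(loss.data)))
        history.append(float(np.mean(losses)))
    return history


def coarse_probs(net: UNet, images: list[np.ndarray],
                 batch_size: int = 8) -> list[np.ndarray]:
    """Frozen stage-1 probability maps for a list of (H, W) images."""
    out: list[np.ndarray] = []
    for start in range(0, len(images), batch_size):
        sel = range(start, min(start + batch_size, len(images)))
        x = _stack_images(images, sel)
        probs = nn.softmax_np(net(Tensor(x)).data, axis=1)
        out.extend(probs)
    return out


def _fine_inputs(prior: np.ndarray, image: np.ndarray,
                 factors: tuple[int, ...]) -> list[np.ndarray]:
    return build_multires_inputs(fuse_coarse(prior, image), factors)


def train_cascade(images: list[np.ndarray], masks: list[np.ndarray],
                  cfg: TrainConfig,
                  coarse_cfg: UNetConfig = UNetConfig(),
                  fine_cfg: ADenseConfig | None = ADenseConfig(),
                  ) -> tuple[CascadeModel, dict[str, list[float]]]:
    """Train stage 1, then stage 2 on fused priors; optional joint phase.

    Returns the trained cascade and a history of per-epoch mean losses
    (keys ``stage1``, ``stage2``, ``joint``).
    """
    if len(images) == 0 or len(images) != len(masks):
        raise ValueError("dataset must be non-empty, images paired with masks")
    if not any(np.any(np.asarray(m) > 0) for m in masks):
        raise ValueError("dataset contains no foreground pixels")

    ss = np.random.SeedSequence(cfg.seed)
    init_coarse, init_fine, shuffle_ss = ss.spawn(3)
    rng = np.random.default_rng(shuffle_ss)

    weights = adaptive_weights(class_proportions(masks))
    coarse = build_unet(coarse_cfg, np.random.default_rng(init_coarse))
    n = len(images)

    def stage1_loss(sel):
        logits = coarse(Tensor(_stack_images(images, sel)))
        return nn.softmax_cross_entropy(logits, _stack_masks(masks, sel), weights.w)

    history = {"stage1": _train_epochs(stage1_loss, coarse.parameters(),
                                       n, cfg.epochs, cfg, rng),
               "stage2": [], "joint": []}

    model = CascadeModel(coarse, None, coarse_cfg, fine_cfg, weights)
    if fine_cfg is None:
        return model, history

    fine = build_adensenet(fine_cfg, np.random.default_rng(init_fine))
    model.fine = fine
    priors = coarse_probs(coarse, images, cfg.batch_size)
    fused_branches = [_fine_inputs(p, img, fine_cfg.resolutions)
                      for p, img in zip(priors, images)]

    def stage2_loss(sel):
        branch_t = [Tensor(np.stack([fused_branches[i][b] for i in sel])[:, None])
                    for b in range(len(fine_cfg.resolutions))]
        logits = fine(branch_t)
        return nn.softmax_cross_entropy(logits, _stack_masks(masks, sel), weights.w)

    fine_epochs = cfg.fine_epochs if cfg.fine_epochs is not None else cfg.epochs
    history["stage2"] = _train_epochs(stage2_loss, fine.parameters(),
                                      n, fine_epochs, cfg, rng)

    if cfg.joint_epochs > 0:
        params = coarse.parameters() + fine.parameters()

        def joint_loss(sel):
            x = _stack_images(images, sel)
            y = _stack_masks(masks, sel)
            logits1 = coarse(Tensor(x))
            l1 = nn.softmax_cross_entropy(logits1, y, weights.w)
            probs = nn.softmax_np(logits1.data, axis=1)  # detached prior
            branches = [[] for _ in fine_cfg.resolutions]
            for p, img in zip(probs, x[:, 0]):
                for b, arr in enumerate(_fine_inputs(p, img, fine_cfg.resolutions)):
                    branches[b].append(arr)
            branch_t = [Tensor(np.stack(b)[:, None]) for b in branches]
            l2 = nn.softmax_cross_entropy(fine(branch_t), y, weights.w)
            return nn.add(nn.mul(l1, np.float32(cfg.alpha)),
                          nn.mul(l2, np.float32(1.0 - cfg.alpha)))

        history["joint"] = _train_epochs(joint_loss, params, n,
                                         cfg.joint_epochs, cfg, rng)
    return model, history


def predict(model: CascadeModel, images: list[np.ndarray],
            batch_size: int = 8) -> list[np.ndarray]:
    """Cascade inference: coarse -> fuse -> multi-res -> fine -> argmax.

    Argmax ties resolve to the lowest class index.  With no fine stage the
    coarse probabilities are decoded directly.
    """
    priors = coarse_probs(model.coarse, images, batch_size)
    if model.fine is None:
        return [p.argmax(axis=0).astype(np.uint8) for p in priors]
    out = []
    factors = model.fine_config.resolutions
    for start in range(0, len(images), batch_size):
        sel = range(start, min(start + batch_size, len(images)))
        branches = [[] for _ in factors]
        for i in sel:
            for b, arr in enumerate(_fine_inputs(priors[i], images[i], factors)):
                branches[b].append(arr)
        branch_t = [Tensor(np.stack(b)[:, None]) for b in branches]
        logits = model.fine(branch_t).data
        out.extend(logits.argmax(axis=1).astype(np.uint8))
    return out


def predict_coarse(model: CascadeModel, images: list[np.ndarray],
                   batch_size: int = 8) -> list[np.ndarray]:
    """Stage-1-only decoding (the coarse baseline)."""
    priors = coarse_probs(model.coarse, images, batch_size)
    return [p.argmax(axis=0).astype(np.uint8) for p in priors]


def evaluate_run(predictions: list[np.ndarray], truths: list[np.ndarray],
                 patterns: list[str] | None = None,
                 case_ids: list[str] | None = None
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-case and aggregate Dice/VOE/RVD tables (liver and tumor)."""
    if len(predictions) != len(truths):
        raise ValueError("predictions and truths must pair one-to-one")
    from .phantom import classify_pattern
    cases: list[CaseMetrics] = []
    for i, (p, t) in enumerate(zip(predictions, truths)):
        pat = patterns[i] if patterns is not None else classify_pattern(t)
        cid = case_ids[i] if case_ids is not None else f"case{i:04d}"
        cases.append(case_metrics(p, t, cid, pat))
    return metrics_frame(cases), aggregate_metrics(cases)


ABLATION_VARIANTS = ("coarse-only", "dense-aspp-no-attention",
                     "attention-single-resolution", "full-cascade")


def _variant_fine_cfg(variant: str, fine_cfg: ADenseConfig) -> ADenseConfig | None:
    from dataclasses import replace
    if variant == "coarse-only":
        return None
    if variant == "dense-aspp-no-attention":
        return replace(fine_cfg, use_attention=False)
    if variant == "attention-single-resolution":
        return replace(fine_cfg, resolutions=(1,))
    if variant == "full-cascade":
        return fine_cfg
    raise ValueError(f"unknown variant {variant!r}")


def ablation_suite(train_images, train_masks, eval_images, eval_masks,
                   cfg: TrainConfig,
                   coarse_cfg: UNetConfig = UNetConfig(),
                   fine_cfg: ADenseConfig = ADenseConfig()) -> pd.DataFrame:
    """Train the four cascade variants with a shared stage 1 and compare.

    All variants share the seed, and hence the identical stage-1 network;
    only stage 2 differs.  Emits one row per variant with Dice/VOE/RVD for
    liver and tumor on the evaluation set.
    """
    rows = []
    base_model = None
    for variant in ABLATION_VARIANTS:
        vcfg = _variant_fine_cfg(variant, fine_cfg)
        model, _ = train_cascade(train_images, train_masks, cfg,
                                 coarse_cfg, vcfg)
        if base_model is None:
            base_model = model
        preds = predict(model, eval_images, cfg.batch_size)
        _, agg = evaluate_run(preds, eval_masks)
        overall = agg[agg["pattern"] == "overall"].iloc[0]
        rows.append({"model": variant,
                     "dice_liver": overall["dice_liver"],
                     "voe_liver": overall["voe_liver"],
                     "rvd_liver": overall["rvd_liver"],
                     "dice_tumor": overall["dice_tumor"],
                     "voe_tumor": overall["voe_tumor"],
                     "rvd_tumor": overall["rvd_tumor"]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(model: CascadeModel, path: str | Path) -> Path:
    """Write weights (.npz) with the configs embedded as JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"coarse/{k}": v for k, v in model.coarse.state_dict().items()}
    if model.fine is not None:
        arrays.update({f"fine/{k}": v for k, v in model.fine.state_dict().items()})
    meta = {"coarse_config": asdict(model.coarse_config),
            "fine_config": asdict(model.fine_config) if model.fine_config else None,
            "has_fine": model.fine is not None,
            "weights": model.weights.w.tolist() if model.weights else None,
            "weights_t": model.weights.t if model.weights else None,
            "proportions": model.weights.proportions.tolist() if model.weights else None}
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)
    return path


def load_checkpoint(path: str | Path) -> CascadeModel:
    data = np.load(Path(path), allow_pickle=False)
    meta = json.loads(bytes(data["meta_json"]).decode())
    coarse_cfg = UNetConfig(**meta["coarse_config"])
    coarse = build_unet(coarse_cfg, 0)
    coarse.load_state_dict({k[len("coarse/"):]: data[k]
                            for k in data.files if k.startswith("coarse/")})
    fine = None
    fine_cfg = None
    if meta["has_fine"]:
        fc = dict(meta["fine_config"])
        for key in ("dilation_rates", "branch_kernels", "resolutions"):
            fc[key] = tuple(fc[key])
        fine_cfg = ADenseConfig(**fc)
        fine = build_adensenet(fine_cfg, 0)
        fine.load_state_dict({k[len("fine/"):]: data[k]
                              for k in data.files if k.startswith("fine/")})
    weights = None
    if meta["weights"] is not None:
        weights = ClassWeights(np.asarray(meta["weights"]), meta["weights_t"],
                               np.asarray(meta["proportions"]))
    return CascadeModel(coarse, fine, coarse_cfg, fine_cfg, weights)
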