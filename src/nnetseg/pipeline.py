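"""Training, k-fold evaluation, checkpointing and the ablation harness.

Training follows the protocol used for the network on ultrasound data:
Adam at learning rate 1e-4, pixel-wise binary cross-entropy on the
sigmoid output, online geometric augmentation (one of six dihedral
transforms per sample per epoch), validation Dice monitored every epoch
with the best-validation weights kept.  Evaluation binarises at 0.5,
optionally after six-view TTA, and reports per-image metrics aggregated
as mean +/- SD.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .arch import ArchitectureConfig, NNet, ablation_configs, build_model
from .augment import augment_pair, tta_predict
from .data import ImagePair, stack_pairs
from .metrics import MetricReport, image_metrics, report_from_masks
from .nn import functional as F
from .nn.tensor import Tensor


@dataclass
class TrainConfig:
    """Optimisation hyperparameters.  Defaults are the desk-scale test
    settings; at full 512-px scale the reference protocol uses batch 16
    and 300 epochs."""

    lr: float = 1e-4
    batch_size: int = 4
    max_epochs: int = 30
    seed: int = 0
    augment: bool = True
    patience: int | None = None  # early stop on stagnant val Dice; None = off
    checkpoint_path: str | None = None

    def __post_init__(self):
        if self.lr < 0:
            raise ValueError("lr must be >= 0")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")


@dataclass
class FoldPlan:
    """Index sets for k-fold cross-validation with 6:2:2 ratios.

    The k test sets are pairwise disjoint and cover every index; within a
    fold the non-test indices are split 3:1 into train:val, yielding
    train:val:test = 6:2:2 of the whole set (up to rounding)."""

    k: int
    folds: list[dict[str, np.ndarray]]

    def validate(self, n_items: int) -> None:
        all_test = np.concatenate([f["test"] for f in self.folds])
        if len(all_test) != n_items or len(np.unique(all_test)) != n_items:
            raise AssertionError("test sets do not partition the index set")
        for f in self.folds:
            combined = np.concatenate([f["train"], f["val"], f["test"]])
            if len(np.unique(combined)) != n_items:
                raise AssertionError("fold roles overlap or miss indices")


def kfold_split(n_items: int, k: int = 5, seed: int = 0,
                strata=None) -> FoldPlan:
    """Deterministic k-fold plan with 6:2:2 train:val:test per fold.

    ``strata``, if given, is a per-item label sequence; shuffling happens
    within each stratum so every fold sees proportional label mix.
    """
    if n_items < 2 * k:
        raise ValueError(f"need at least {2 * k} items for k={k}, got {n_items}")
    rng = np.random.default_rng(seed)
    if strata is None:
        order = rng.permutation(n_items)
    else:
        strata = np.asarray(strata)
        if len(strata) != n_items:
            raise ValueError("strata length must equal n_items")
        order = np.concatenate([
            rng.permutation(np.nonzero(strata == s)[0])
            for s in pd.unique(strata)
        ])
        # interleave strata across folds by round-robin position
        order = order[np.argsort(np.arange(n_items) % k, kind="stable")]
    test_chunks = np.array_split(order, k)
    folds = []
    for i in range(k):
        test = np.sort(test_chunks[i])
        rest = np.concatenate([test_chunks[j] for j in range(k) if j != i])
        rest = rng.permutation(rest)
        n_val = round(len(rest) / 4)  # 3:1 of the 80% -> 6:2:2 overall
        folds.append({
            "train": np.sort(rest[n_val:]),
            "val": np.sort(rest[:n_val]),
            "test": test,
        })
    plan = FoldPlan(k=k, folds=folds)
    plan.validate(n_items)
    return plan


def _val_dice(model: NNet, x_val: np.ndarray, y_val: np.ndarray,
              batch_size: int) -> float:
    dices = []
    for i in range(0, len(x_val), batch_size):
        probs = model.predict(x_val[i:i + batch_size])
        for p, g in zip(probs, y_val[i:i + batch_size]):
            dices.append(image_metrics((p[0] >= 0.5).astype(np.uint8),
                                       g[0].astype(np.uint8))["dice"])
    return float(np.mean(dices))


@dataclass
class TrainResult:
    history: pd.DataFrame          # columns: epoch, train_loss, val_dice
    best_state: dict
    best_epoch: int
    best_val_dice: float
    checkpoint_path: str | None = None


def train(model: NNet, train_set: list[ImagePair], val_set: list[ImagePair],
          config: TrainConfig) -> TrainResult:
    """Optimise ``model`` in place; returns history and best-val weights.

    The best-validation-Dice state is restored into the model before
    returning.  Reproducible for a fixed ``config.seed`` (all randomness
    — batch order and augmentation draws — flows from one generator).
    """
    if not train_set:
        raise ValueError("train_set is empty")
    if not val_set:
        raise ValueError("val_set is empty: validation supervises checkpointing")
    rng = np.random.default_rng(config.seed)
    optimizer = nn.Adam(model.parameters(), lr=config.lr)
    x_val, y_val = stack_pairs(val_set)

    history_rows = []
    best_state, best_dice, best_epoch = model.state_dict(), -1.0, 0
    stale = 0
    for epoch in range(1, config.max_epochs + 1):
        model.train()
        order = rng.permutation(len(train_set))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            ims, msks = [], []
            for j in idx:
                pair = train_set[j]
                if config.augment:
                    im, mk = augment_pair(pair.image, pair.mask, rng)
                else:
                    im, mk = pair.image, pair.mask
                ims.append(im)
                msks.append(mk)
            x = np.stack(ims).astype(np.float32)[:, None]
            y = np.stack(msks).astype(np.float32)[:, None]
            optimizer.zero_grad()
            pred = model(Tensor(x))
            loss = F.binary_cross_entropy(pred, y)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}")
            loss.backward()
            optimizer.step()
            losses.append(loss.item())

        vd = _val_dice(model, x_val, y_val, config.batch_size)
        history_rows.append({"epoch": epoch,
                             "train_loss": float(np.mean(losses)),
                             "val_dice": vd})
        if vd > best_dice:
            best_dice, best_epoch, best_state = vd, epoch, model.state_dict()
            stale = 0
        else:
            stale += 1
            if config.patience is not None and stale >= config.patience:
                break

    model.load_state_dict(best_state)
    result = TrainResult(pd.DataFrame(history_rows), best_state, best_epoch,
                         best_dice)
    if config.checkpoint_path:
        result.checkpoint_path = str(
            save_checkpoint(model, config.checkpoint_path))
    return result


def save_checkpoint(model: NNet, path) -> Path:
    """Weights + architecture config in one ``.npz`` archive."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.state_dict()
    np.savez(path, __config__=json.dumps(model.config.to_dict()), **state)
    return path


def load_checkpoint(path) -> NNet:
    with np.load(Path(path), allow_pickle=False) as archive:
        config = ArchitectureConfig.from_dict(
            json.loads(str(archive["__config__"])))
        state = {k: archive[k] for k in archive.files if k != "__config__"}
    model = build_model(config)
    model.load_state_dict(state)
    model.eval()
    return model


def evaluate(model: NNet, test_set: list[ImagePair], use_tta: bool = False,
             fold: int | None = None, batch_size: int = 4) -> MetricReport:
    """Per-image metrics on a held-out set at threshold 0.5."""
    if not test_set:
        raise ValueError("test_set is empty")
    preds, gts = [], []
    x, y = stack_pairs(test_set)
    for i in range(0, len(x), batch_size):
        batch = x[i:i + batch_size]
        probs = tta_predict(model, batch) if use_tta else model.predict(batch)
        for p, g in zip(probs, y[i:i + batch_size]):
            preds.append((p[0] >= 0.5).astype(np.uint8))
            gts.append(g[0].astype(np.uint8))
    return report_from_masks(preds, gts, fold=fold)


def run_fold(dataset: list[ImagePair], fold_indices: dict, arch: ArchitectureConfig,
             train_config: TrainConfig, use_tta: bool = False,
             fold: int | None = None, model_seed: int = 0) -> tuple[MetricReport, TrainResult]:
    """Train on one fold's split and evaluate on its test set."""
    model = build_model(arch, seed=model_seed)
    result = train(model,
                   [dataset[i] for i in fold_indices["train"]],
                   [dataset[i] for i in fold_indices["val"]],
                   train_config)
    report = evaluate(model, [dataset[i] for i in fold_indices["test"]],
                      use_tta=use_tta, fold=fold,
                      batch_size=train_config.batch_size)
    return report, result


def run_ablation(dataset: list[ImagePair],
                 configs: list[tuple[str, ArchitectureConfig]] | None = None,
                 train_config: TrainConfig | None = None,
                 k: int = 5, split_seed: int = 0, use_tta: bool = False,
                 out_path=None, **arch_common) -> pd.DataFrame:
    """Train and evaluate each configuration under identical folds/seeds.

    Returns one row per configuration with ``mean +/- SD`` across folds
    for the five metrics; optionally written as CSV.
    """
    if configs is None:
        configs = ablation_configs(**arch_common)
    if len(configs) < 2:
        raise ValueError("an ablation needs at least two configurations")
    train_config = train_config or TrainConfig()
    plan = kfold_split(len(dataset), k=k, seed=split_seed)

    rows = []
    failures = []
    for name, arch in configs:
        per_fold = []
        for fi, fold_idx in enumerate(plan.folds):
            try:
                report, _ = run_fold(dataset, fold_idx, arch, train_config,
                                     use_tta=use_tta, fold=fi,
                                     model_seed=train_config.seed)
                per_fold.append(report.mean())
            except Exception as exc:  # noqa: BLE001 - annotate and continue
                failures.append(f"{name}/fold{fi}: {exc}")
        row = {"config": name, "n_folds": len(per_fold)}
        if per_fold:
            df = pd.DataFrame(per_fold)
            for m in df.columns:
                row[f"{m}_mean"] = float(df[m].mean())
                row[f"{m}_sd"] = float(df[m].std(ddof=1)) if len(df) > 1 else 0.0
        rows.append(row)
    table = pd.DataFrame(rows)
    if failures:
        table.attrs["failures"] = failures
    if out_path is not None:
        Path(out_path).parent.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_path, index=False)
    if failures:
        raise RuntimeError(
            "ablation finished with failures: " + "; ".join(failures))
    return table
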