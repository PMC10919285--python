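"""Preprocessing, training schedule, slice-wise inference and the
three-part experimental design.

Training follows the fixed recipe: axial slices cropped to a fixed input
width, random-crop augmentation to a narrower width during training only,
SGD with momentum under the learning-rate schedule lr(e) = 0.01 * 0.9^e,
100 epochs by default, and the checkpoint with the best validation DSC
retained.  Batch size defaults to 16 for U-Net/UNet++ and 10 for
FFU/AFFU.

``run_experiment`` reproduces the three designs: leave-one-out
cross-validation on one cohort; training on one cohort and testing across
cohorts; and retraining with the augmented cohort (warm-started from the
cross-cohort weights by default), with augmented subjects barred from
every test set.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core import LabelMap, Subject, Volume
from .metrics import evaluate_subject
from .networks import NetworkConfig, _SegNet, build_network
from .nn import autograd as ag
from .nn.optim import SGD, segmentation_loss

__all__ = [
    "TrainConfig",
    "SliceDataset",
    "preprocess",
    "train",
    "predict",
    "run_experiment",
    "default_batch_size",
]


def default_batch_size(arch: str) -> int:
    """16 for the plain U-Nets, 10 for the feature-fusion variants."""
    return 10 if arch in ("ffu", "affu") else 16


@dataclass(frozen=True)
class TrainConfig:
    """Training schedule and preprocessing geometry.

    ``crop_width_input`` is the fixed slice width fed to the network;
    ``crop_width_random`` the narrower random crop applied during training
    only.  For phantom grids smaller than the clinical 256-pixel width use
    :meth:`scaled_for`, which preserves the 125/256 crop ratio.
    """

    batch_size: int | None = None  # None: architecture default
    lr0: float = 0.01
    lr_decay: float = 0.9
    epochs: int = 100
    crop_width_input: int = 256
    crop_width_random: int = 125
    loss: str = "ce+dice"
    momentum: float = 0.9
    seed: int = 0
    val_subjects: int = 1
    early_stop_dsc: float | None = None  # stop once best val DSC reaches this

    def __post_init__(self) -> None:
        if not (0 < self.lr_decay <= 1):
            raise ValueError("lr_decay must be in (0, 1]")
        if self.crop_width_random > self.crop_width_input:
            raise ValueError("crop_width_random must be <= crop_width_input")

    def lr_at(self, epoch: int) -> float:
        return self.lr0 * self.lr_decay**epoch

    def scaled_for(self, grid_shape: Sequence[int]) -> "TrainConfig":
        """Proportionally scale crop widths for small (phantom) grids."""
        w = int(grid_shape[1])
        if w >= self.crop_width_input:
            return self
        ratio = self.crop_width_random / self.crop_width_input
        return replace(
            self,
            crop_width_input=w,
            crop_width_random=max(8, int(round(w * ratio))),
        )


def _crop_or_pad_width(arr: np.ndarray, width: int) -> tuple[np.ndarray, int]:
    """Center-crop or symmetrically zero-pad axis 1 to ``width``.

    Returns the result and the offset of the output window in the input
    (negative when padding was added)."""
    w = arr.shape[1]
    if w == width:
        return arr, 0
    if w > width:
        lo = (w - width) // 2
        return arr[:, lo : lo + width], lo
    pad = width - w
    lo = pad // 2
    out = np.zeros((arr.shape[0], width), dtype=arr.dtype)
    out[:, lo : lo + w] = arr
    return out, -lo


def preprocess(subject: Subject, config: TrainConfig) -> list[tuple[np.ndarray, np.ndarray]]:
    """Axial (limb-axis) slices, intensity-normalised and width-adjusted.

    Intensities are z-scored per volume; slices are center-cropped or
    zero-padded to ``config.crop_width_input``.  Subjects with an empty
    label volume are skipped with a warning (empty list returned).
    """
    if not subject.labels.data.any():
        warnings.warn(f"subject {subject.id!r} has an empty label volume; skipped")
        return []
    img = np.asarray(subject.volume.data, dtype=np.float64)
    sd = img.std()
    img = (img - img.mean()) / (sd if sd > 0 else 1.0)
    out = []
    for z in range(img.shape[2]):
        sl_img, _ = _crop_or_pad_width(img[:, :, z].astype(np.float32), config.crop_width_input)
        sl_lab, _ = _crop_or_pad_width(subject.labels.data[:, :, z], config.crop_width_input)
        out.append((sl_img, sl_lab))
    return out


@dataclass
class SliceDataset:
    """2D training samples with per-slice subject ids.

    The train/validation split is by subject, never by slice.
    """

    images: np.ndarray  # (N, 1, H, W) float32
    labels: np.ndarray  # (N, H, W) int32
    subject_ids: list[str]

    @classmethod
    def from_subjects(cls, subjects: Sequence[Subject], config: TrainConfig) -> "SliceDataset":
        imgs, labs, sids = [], [], []
        for s in subjects:
            for im, lb in preprocess(s, config):
                imgs.append(im[None])
                labs.append(lb)
                sids.append(s.id)
        if not imgs:
            raise ValueError("no usable slices in the given subjects")
        return cls(
            np.stack(imgs).astype(np.float32),
            np.stack(labs).astype(np.int32),
            sids,
        )

    def __len__(self) -> int:
        return len(self.subject_ids)

    def subjects(self) -> list[str]:
        seen = dict.fromkeys(self.subject_ids)
        return list(seen)

    def split_by_subject(self, val_ids: Sequence[str]) -> tuple["SliceDataset", "SliceDataset"]:
        val_set = set(val_ids)
        mask = np.array([sid in val_set for sid in self.subject_ids])
        if mask.all() or not mask.any():
            raise ValueError("split leaves train or validation empty")
        tr = SliceDataset(
            self.images[~mask], self.labels[~mask],
            [s for s, m in zip(self.subject_ids, mask) if not m],
        )
        va = SliceDataset(
            self.images[mask], self.labels[mask],
            [s for s, m in zip(self.subject_ids, mask) if m],
        )
        return tr, va


def _random_crops(imgs, labs, width, rng):
    """Independent random width-crops per sample (positions cover the full
    valid range uniformly)."""
    W = imgs.shape[3]
    if width >= W:
        return imgs, labs
    outs_i = np.empty(imgs.shape[:3] + (width,), dtype=imgs.dtype)
    outs_l = np.empty(labs.shape[:2] + (width,), dtype=labs.dtype)
    for i in range(imgs.shape[0]):
        x0 = int(rng.integers(0, W - width + 1))
        outs_i[i] = imgs[i, :, :, x0 : x0 + width]
        outs_l[i] = labs[i, :, x0 : x0 + width]
    return outs_i, outs_l


def _val_dsc(net: _SegNet, val: SliceDataset, n_classes: int, batch: int = 16) -> float:
    """Mean per-class foreground DSC pooled over all validation slices."""
    preds = []
    for i in range(0, len(val), batch):
        preds.append(net.predict_classes(val.images[i : i + batch]))
    pred = np.concatenate(preds)
    ref = val.labels
    scores = []
    for c in range(1, n_classes):
        r = ref == c
        p = pred == c
        denom = int(r.sum()) + int(p.sum())
        if denom == 0:
            continue
        scores.append(2.0 * int(np.logical_and(r, p).sum()) / denom)
    return float(np.mean(scores)) if scores else 0.0


@dataclass
class TrainResult:
    best_state: dict
    best_epoch: int
    best_val_dsc: float
    log: pd.DataFrame


def train(
    net: _SegNet,
    dataset: SliceDataset,
    config: TrainConfig,
    val_ids: Sequence[str] | None = None,
) -> TrainResult:
    """Optimise the network; retain the best-validation-DSC weights.

    Validation defaults to the last ``config.val_subjects`` subjects of
    the dataset (held out whole, never by slice).  The returned log has
    one row per epoch: (epoch, lr, train_loss, val_dsc).  The network is
    left loaded with the best weights.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(config.seed)
    if val_ids is None:
        subs = dataset.subjects()
        if len(subs) < 2:
            raise ValueError("need >= 2 subjects to split train/validation")
        val_ids = subs[-config.val_subjects :]
    tr, va = dataset.split_by_subject(val_ids)
    batch = config.batch_size or default_batch_size(net.config.arch)
    opt = SGD(net.parameters(), lr=config.lr0, momentum=config.momentum)

    rows = []
    best = (-1.0, -1, None)
    for epoch in range(config.epochs):
        lr = config.lr_at(epoch)
        opt.lr = lr
        net.train()
        order = rng.permutation(len(tr))
        losses = []
        for i in range(0, len(order), batch):
            idx = order[i : i + batch]
            imgs, labs = _random_crops(
                tr.images[idx], tr.labels[idx], config.crop_width_random, rng
            )
            logits = net(imgs)
            loss_t, loss_v = segmentation_loss(logits, labs, config.loss)
            if not np.isfinite(loss_v):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={loss_v}"
                )
            opt.zero_grad()
            loss_t.backward()
            opt.step()
            losses.append(loss_v)
        net.eval()
        vd = _val_dsc(net, va, net.config.n_classes)
        rows.append(
            {"epoch": epoch, "lr": lr, "train_loss": float(np.mean(losses)), "val_dsc": vd}
        )
        if vd > best[0]:
            best = (vd, epoch, copy.deepcopy(net.state_dict()))
        if config.early_stop_dsc is not None and best[0] >= config.early_stop_dsc:
            break
    log = pd.DataFrame(rows)
    if best[2] is not None:
        net.load_state_dict(best[2])
    return TrainResult(best_state=best[2], best_epoch=best[1], best_val_dsc=best[0], log=log)


def predict(net: _SegNet, volume: Volume, config: TrainConfig, batch: int = 16) -> LabelMap:
    """Slice-wise argmax segmentation reassembled on the subject grid.

    The width crop/pad applied by preprocessing is inverted; regions
    outside the crop window are background.
    """
    img = np.asarray(volume.data, dtype=np.float64)
    sd = img.std()
    img = (img - img.mean()) / (sd if sd > 0 else 1.0)
    nx, ny, nz = img.shape
    slices = []
    offsets = []
    for z in range(nz):
        sl, off = _crop_or_pad_width(img[:, :, z].astype(np.float32), config.crop_width_input)
        slices.append(sl[None])
        offsets.append(off)
    X = np.stack(slices)
    preds = []
    for i in range(0, nz, batch):
        preds.append(net.predict_classes(X[i : i + batch]))
    pred = np.concatenate(preds)  # (nz, H, W')
    out = np.zeros((nx, ny, nz), dtype=np.int32)
    for z in range(nz):
        off = offsets[z]
        if off >= 0:  # input was cropped: embed back
            out[:, off : off + config.crop_width_input, z] = pred[z]
        else:  # input was padded: cut the pad away
            out[:, :, z] = pred[z][:, -off : -off + ny]
    return LabelMap(out, volume.spacing, volume.origin)


# ---------------------------------------------------------------------------
# experiment designs


DESIGNS = ("cross_validation", "cross_cohort", "augmented")


def _check_no_overlap(train_subjects, test_subjects):
    tr = {s.id for s in train_subjects}
    te = {s.id for s in test_subjects}
    inter = tr & te
    if inter:
        raise ValueError(f"test/train overlap detected: {sorted(inter)}")


def _check_no_leakage(train_subjects, test_subjects):
    """Augmented subjects must never be tested, and their references must
    come from the training originals only."""
    test_ids = {s.id for s in test_subjects}
    train_original_ids = {s.id for s in train_subjects if not s.is_augmented}
    for s in test_subjects:
        if s.is_augmented:
            raise ValueError(f"augmented subject {s.id!r} in a test set")
    for s in train_subjects:
        if s.is_augmented:
            ref = s.provenance_info.get("reference_id")
            if ref in test_ids:
                raise ValueError(
                    f"augmented subject {s.id!r} derives from test subject {ref!r}"
                )
            if ref not in train_original_ids:
                raise ValueError(
                    f"augmented subject {s.id!r} references {ref!r}, which is "
                    "not among the training originals"
                )


def run_experiment(
    design: str,
    cohorts: dict[str, list[Subject]],
    config: TrainConfig,
    net_config: NetworkConfig | None = None,
    predictor: Callable[[Subject], LabelMap] | None = None,
    trainer: Callable[[list[Subject]], Callable[[Subject], LabelMap]] | None = None,
    label_ids: Sequence[int] | None = None,
    init_state: dict | None = None,
    warm_start: bool = True,
) -> pd.DataFrame:
    """Run one experimental design and return the per-label metrics table.

    ``cohorts`` maps cohort names to subject lists; ``"train"`` is the
    training cohort, every other key is a test cohort (for
    ``cross_validation`` only ``"train"`` is used).  Supply ``predictor``
    to evaluate a fixed model (or a stub) without training, or ``trainer``
    to customise how a model is fit to a subject list; otherwise a network
    is built from ``net_config`` and trained with :func:`train`.

    The returned DataFrame has one row per (fold, test subject, muscle):
    columns design/fold/cohort/subject_id/label_id/dsc/rve/one_minus_rve/
    hd_mm.
    """
    if design not in DESIGNS:
        raise ValueError(f"design must be one of {DESIGNS}")
    if "train" not in cohorts:
        raise ValueError('cohorts must contain a "train" entry')

    def fit(subjects: list[Subject]) -> Callable[[Subject], LabelMap]:
        if predictor is not None:
            return predictor
        if trainer is not None:
            return trainer(subjects)
        if net_config is None:
            raise ValueError("need net_config (or predictor/trainer)")
        net = build_network(net_config)
        if init_state is not None and warm_start:
            net.load_state_dict(init_state)
        ds = SliceDataset.from_subjects(subjects, config)
        train(net, ds, config)
        return lambda subj: predict(net, subj.volume, config)

    rows: list[dict] = []

    def evaluate(pred_fn, subj: Subject, fold: str, cohort: str):
        pred = pred_fn(subj)
        for m in evaluate_subject(subj.labels, pred, label_ids, subject_id=subj.id):
            r = m.as_dict()
            r.update({"design": design, "fold": fold, "cohort": cohort})
            rows.append(r)

    if design == "cross_validation":
        subjects = [s for s in cohorts["train"] if not s.is_augmented]
        for held_out in subjects:
            rest = [s for s in subjects if s.id != held_out.id]
            _check_no_overlap(rest, [held_out])
            pred_fn = fit(rest)
            evaluate(pred_fn, held_out, fold=f"loo_{held_out.id}", cohort="train")
    else:
        train_subjects = list(cohorts["train"])
        test_items = [
            (name, s) for name, subs in cohorts.items() if name != "train" for s in subs
        ]
        if not test_items:
            raise ValueError("no test cohorts provided")
        _check_no_overlap(train_subjects, [s for _, s in test_items])
        if design == "augmented":
            _check_no_leakage(train_subjects, [s for _, s in test_items])
        else:
            train_subjects = [s for s in train_subjects if not s.is_augmented]
        pred_fn = fit(train_subjects)
        for name, subj in test_items:
            evaluate(pred_fn, subj, fold=design, cohort=name)

    return pd.DataFrame(rows)
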