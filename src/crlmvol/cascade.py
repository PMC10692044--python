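"""Cascaded two-stage liver → tumor segmentation.

Stage one segments the liver from the normalized CT; stage two segments
tumors, but only inside the liver volume of interest (the predicted liver
mask dilated by a safety margin).  Restricting the second model to the
liver removes almost all of the background the tumor model would otherwise
have to reject, which is what makes the small model workable.  The final
tumor mask is intersected with the liver mask, so ``tumor ⊆ liver`` holds
by construction.

The trainable core follows the Model/Results convention: build a
:class:`CascadeModel` from a cohort manifest plus in-memory phantoms (or
file paths), call :meth:`~CascadeModel.fit`, and get a
:class:`CascadeResults` carrying the two trained networks, their training
histories, and ``segment`` / ``evaluate`` / ``summary`` methods.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .ct_io import CTVolume, MaskVolume, read_mask, read_volume
from .metrics import global_metrics
from .preprocess import (
    DEFAULT_BINS,
    DEFAULT_CLIP_HI,
    DEFAULT_CLIP_LO,
    NormalizedVolume,
    normalize,
)
from .unet import Adam, UNet, dice_bce_loss
from .volumetry import total_tumor_volume

__all__ = [
    "ModelConfig",
    "DEFAULT_LIVER_CONFIG",
    "DEFAULT_TUMOR_CONFIG",
    "SegmentationResult",
    "LiverROI",
    "EmptyLiverError",
    "TrainedSegmenter",
    "build_unet",
    "train_model",
    "restrict_to_liver",
    "predict_volume",
    "postprocess_liver",
    "segment_cascade",
    "CascadeModel",
    "CascadeResults",
]


class EmptyLiverError(RuntimeError):
    """The liver stage produced no volume of interest; the tumor stage cannot run."""


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters for one U-Net stage.

    Defaults are sized for CPU training on phantom cohorts in minutes.
    """

    depth: int = 3
    base_filters: int = 8
    loss: str = "dice+bce"
    learning_rate: float = 1e-3
    epochs: int = 12
    batch_size: int = 16
    prob_threshold: float = 0.5
    seed: int = 0
    early_stop_patience: int = 3

    def __post_init__(self) -> None:
        if not (0.0 < self.prob_threshold < 1.0):
            raise ValueError(f"prob_threshold must be in (0, 1), got {self.prob_threshold}")
        if self.depth < 1:
            raise ValueError(f"depth must be >= 1, got {self.depth}")
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")
        if self.loss != "dice+bce":
            raise ValueError(f"unknown loss {self.loss!r}; available: 'dice+bce'")


# stage defaults: the liver is a large high-contrast structure and saturates
# with a narrow net at a fast rate; the tumor stage needs the wider net and a
# gentler rate to stay stable under heavy class imbalance
DEFAULT_LIVER_CONFIG = ModelConfig(
    seed=1, base_filters=4, epochs=6, early_stop_patience=2, learning_rate=3e-3
)
DEFAULT_TUMOR_CONFIG = ModelConfig(
    seed=2, base_filters=8, epochs=12, early_stop_patience=3, learning_rate=1e-3
)


@dataclass
class SegmentationResult:
    """Cascade output for one scan: masks plus the probability grids behind them."""

    scan_id: str
    liver_mask: MaskVolume
    tumor_mask: MaskVolume
    liver_prob: np.ndarray
    tumor_prob: np.ndarray


def build_unet(config: ModelConfig) -> UNet:
    """Instantiate the 2-D U-Net for a stage; parameter count is reported."""
    return UNet(depth=config.depth, base_filters=config.base_filters, seed=config.seed)


def train_model(
    train_x: np.ndarray,
    train_y: np.ndarray,
    val_cases: list[tuple[np.ndarray, np.ndarray, str]],
    config: ModelConfig,
) -> tuple[UNet, dict]:
    """Train one U-Net stage on 2-D slices with early stopping.

    `train_x`/`train_y` are (N, 1, H, W) slice stacks; `val_cases` holds
    per-scan slice stacks used for the validation per-case DSC that drives
    early stopping.  The weights from the best validation epoch are
    restored before returning.  History records per-epoch training loss
    and validation DSC.
    """
    if len(train_x) == 0:
        raise ValueError("empty training set")
    if train_y.sum() == 0:
        warnings.warn("all training targets are background; the model can only learn to predict empty masks", stacklevel=2)
    net = build_unet(config)
    opt = Adam(net.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    history: dict = {"train_loss": [], "val_dsc": []}
    best_dsc, best_epoch, best_params = -1.0, -1, None
    for epoch in range(config.epochs):
        order = rng.permutation(len(train_x))
        losses = []
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            try:
                loss, dz = dice_bce_loss(net.forward(train_x[idx]), train_y[idx])
            except FloatingPointError as e:
                raise FloatingPointError(
                    f"epoch {epoch}, batch {i // config.batch_size}: {e}"
                ) from e
            net.backward(dz)
            opt.step(net.parameters(), net.gradients())
            losses.append(loss)
        val_dscs = []
        for vx, vy, _sid in val_cases:
            prob = net.predict_proba(vx)
            pred = prob >= config.prob_threshold
            inter = float((pred * vy).sum())
            denom = float(pred.sum() + vy.sum())
            val_dscs.append(1.0 if denom == 0 else 2 * inter / denom)
        val_dsc = float(np.mean(val_dscs)) if val_dscs else float("nan")
        history["train_loss"].append(float(np.mean(losses)))
        history["val_dsc"].append(val_dsc)
        if not val_cases or val_dsc > best_dsc + 1e-6:
            best_dsc, best_epoch = val_dsc, epoch
            best_params = [p.copy() for p in net.parameters()]
        elif epoch - best_epoch > config.early_stop_patience:
            break
    if best_params is not None:
        net.set_parameters(best_params)
    history["best_epoch"] = best_epoch
    history["n_params"] = net.n_params
    return net, history


@dataclass
class LiverROI:
    """Liver-restricted, cropped sub-volume with exact map-back metadata."""

    values: np.ndarray  # cropped, voxels outside dilated liver zeroed
    offset: tuple[int, int, int]  # crop origin in the original grid
    original_shape: tuple[int, int, int]
    dilated_mask: np.ndarray  # full-grid dilated liver (bool)

    def paste(self, grid: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Place a cropped-shaped grid back at the original coordinates."""
        if grid.shape != self.values.shape:
            raise ValueError(f"grid shape {grid.shape} != ROI shape {self.values.shape}")
        out = np.full(self.original_shape, fill, dtype=grid.dtype)
        i, j, k = self.offset
        si, sj, sk = grid.shape
        out[i : i + si, j : j + sj, k : k + sk] = grid
        return out


def restrict_to_liver(
    volume: NormalizedVolume,
    liver_mask: MaskVolume,
    margin_mm: float = 5.0,
) -> LiverROI:
    """Mask the volume to the liver dilated by `margin_mm` and crop to it.

    Voxels outside the dilated liver are set to 0 (the background value of
    the normalized intensity scale); the crop offset and original shape
    are recorded so stage-two output maps back to the original grid
    exactly.  An empty liver mask is an error — there is no volume of
    interest for the tumor stage.
    """
    m = liver_mask.labels.astype(bool)
    if m.shape != volume.values.shape:
        raise ValueError(
            f"liver mask shape {m.shape} does not match volume shape {volume.values.shape}"
        )
    if not m.any():
        raise EmptyLiverError(f"scan {volume.scan_id}: no liver volume of interest")
    if margin_mm > 0:
        dist = ndimage.distance_transform_edt(~m, sampling=volume.spacing_mm)
        dilated = dist <= margin_mm
    else:
        dilated = m
    idx = np.nonzero(dilated)
    lo = [int(a.min()) for a in idx]
    hi = [int(a.max()) + 1 for a in idx]
    masked = np.where(dilated, volume.values, 0.0).astype(np.float32)
    crop = masked[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    return LiverROI(
        values=crop,
        offset=(lo[0], lo[1], lo[2]),
        original_shape=volume.values.shape,
        dilated_mask=dilated,
    )


def predict_volume(
    model: UNet,
    volume: "NormalizedVolume | np.ndarray",
    config: ModelConfig,
    axis: int = 2,
) -> tuple[np.ndarray, "MaskVolume | np.ndarray"]:
    """Per-slice inference restacked to 3-D: (probability grid, mask).

    Accepts a :class:`NormalizedVolume` (returns a :class:`MaskVolume`) or
    a bare intensity array (returns a boolean array).  Slice height/width
    must be divisible by 2^depth; otherwise the model raises an error
    naming the required padding.
    """
    if isinstance(volume, NormalizedVolume):
        values = volume.values
    else:
        values = np.asarray(volume, dtype=np.float32)
    vals = np.moveaxis(values.astype(np.float32), axis, 0)
    stack = vals[:, None, :, :]  # (n_slices, 1, H, W)
    model.check_input(stack.shape[2], stack.shape[3])
    prob = model.predict_proba(stack)[:, 0]
    prob = np.moveaxis(prob, 0, axis)
    binary = prob >= config.prob_threshold
    if isinstance(volume, NormalizedVolume):
        return prob, MaskVolume(volume.scan_id, binary.astype(np.uint8), volume.spacing_mm)
    return prob, binary


def postprocess_liver(mask: np.ndarray, spacing_mm) -> np.ndarray:
    """Keep the largest 3-D connected component and fill internal holes.

    Prevents spurious islands in the liver prediction from widening the
    tumor volume of interest.
    """
    labeled, n = ndimage.label(mask)
    if n == 0:
        return mask.astype(bool)
    counts = np.bincount(labeled.ravel())
    counts[0] = 0
    largest = labeled == counts.argmax()
    return ndimage.binary_fill_holes(largest)


def _pad_to_multiple(values: np.ndarray, div: int) -> tuple[np.ndarray, tuple[int, int]]:
    """Zero-pad the two in-plane axes up to a multiple of `div`."""
    h, w, _ = values.shape
    ph = (div - h % div) % div
    pw = (div - w % div) % div
    if ph or pw:
        values = np.pad(values, ((0, ph), (0, pw), (0, 0)))
    return values, (ph, pw)


@dataclass
class TrainedSegmenter:
    """A trained stage: network + config + preprocessing provenance."""

    net: UNet
    config: ModelConfig
    provenance: dict
    target: str  # "liver" or "tumor"
    history: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        self.net.save(
            path,
            extra={
                "config": asdict(self.config),
                "provenance": self.provenance,
                "target": self.target,
                "history": self.history,
            },
        )

    @classmethod
    def load(cls, path: str | Path) -> "TrainedSegmenter":
        net, extra = UNet.load(path)
        return cls(
            net=net,
            config=ModelConfig(**extra["config"]),
            provenance=extra["provenance"],
            target=extra["target"],
            history=extra.get("history", {}),
        )


def segment_cascade(
    ct: CTVolume,
    liver_model: TrainedSegmenter,
    tumor_model: TrainedSegmenter,
    margin_mm: float = 5.0,
) -> SegmentationResult:
    """Run the full cascade on one CT scan.

    preprocess → liver prediction → largest-component/hole-fill
    post-processing → liver-restricted crop → tumor prediction → map back
    → intersect with the liver mask.
    """
    if liver_model.provenance != tumor_model.provenance:
        raise ValueError(
            "liver and tumor models were trained with different preprocessing: "
            f"{liver_model.provenance} vs {tumor_model.provenance}"
        )
    prov = liver_model.provenance
    norm = normalize(
        ct,
        lo=prov.get("clip_lo", DEFAULT_CLIP_LO),
        hi=prov.get("clip_hi", DEFAULT_CLIP_HI),
        bins=prov.get("bins", DEFAULT_BINS),
    )
    liver_prob, liver_raw = predict_volume(liver_model.net, norm.values, liver_model.config)
    liver = postprocess_liver(liver_raw, ct.spacing_mm)
    liver_mask = MaskVolume(ct.scan_id, liver.astype(np.uint8), ct.spacing_mm)
    try:
        roi = restrict_to_liver(norm, liver_mask, margin_mm=margin_mm)
    except EmptyLiverError:
        raise EmptyLiverError(
            f"scan {ct.scan_id}: liver stage produced an empty mask; cannot run tumor stage"
        ) from None
    div = 2 ** tumor_model.config.depth
    padded, (ph, pw) = _pad_to_multiple(roi.values, div)
    tumor_prob_roi, _ = predict_volume(tumor_model.net, padded, tumor_model.config)
    if ph or pw:
        tumor_prob_roi = tumor_prob_roi[: roi.values.shape[0], : roi.values.shape[1], :]
    tumor_prob = roi.paste(tumor_prob_roi.astype(np.float32))
    tumor = (tumor_prob >= tumor_model.config.prob_threshold) & liver
    tumor_mask = MaskVolume(ct.scan_id, tumor.astype(np.uint8), ct.spacing_mm)
    return SegmentationResult(
        scan_id=ct.scan_id,
        liver_mask=liver_mask,
        tumor_mask=tumor_mask,
        liver_prob=liver_prob,
        tumor_prob=tumor_prob,
    )


# ---------------------------------------------------------------------------
# Model / Results interface
# ---------------------------------------------------------------------------


class CascadeModel:
    """The cascade as a fittable model over a patient-split cohort.

    Parameters
    ----------
    manifest : CohortManifest
        Patient-level train/validation/test assignment (leakage control).
    data : dict
        scan_id → (CTVolume, liver MaskVolume, tumor MaskVolume, truth) —
        e.g. the output of :func:`crlmvol.phantoms.generate_cohort` — or
        scan_id → (ct_path, liver_path, tumor_path) to load lazily.
    liver_config, tumor_config : ModelConfig
    margin_mm : float
        Dilation of the liver volume of interest for the tumor stage.
    """

    def __init__(
        self,
        manifest,
        data: dict,
        liver_config: ModelConfig | None = None,
        tumor_config: ModelConfig | None = None,
        margin_mm: float = 5.0,
        clip_lo: float = DEFAULT_CLIP_LO,
        clip_hi: float = DEFAULT_CLIP_HI,
        bins: int = DEFAULT_BINS,
    ):
        self.manifest = manifest
        self.data = data
        self.liver_config = liver_config or DEFAULT_LIVER_CONFIG
        self.tumor_config = tumor_config or DEFAULT_TUMOR_CONFIG
        self.margin_mm = margin_mm
        self.provenance = {"clip_lo": clip_lo, "clip_hi": clip_hi, "bins": bins}

    # -- data access ------------------------------------------------------

    def _load(self, scan_id: str):
        entry = self.data[scan_id]
        if isinstance(entry[0], (str, Path)):
            ct = read_volume(entry[0], scan_id=scan_id)
            liver = read_mask(entry[1], reference=ct, scan_id=scan_id)
            tumor = read_mask(entry[2], reference=ct, scan_id=scan_id)
            return ct, liver, tumor
        return entry[0], entry[1], entry[2]

    def _normalized(self, ct: CTVolume) -> NormalizedVolume:
        p = self.provenance
        return normalize(ct, lo=p["clip_lo"], hi=p["clip_hi"], bins=p["bins"])

    #: training-time repetition factor for lesion-bearing slices; tumor
    #: voxels are <1% of the volume and the batch-level Dice term needs
    #: foreground in most batches to produce a useful gradient
    FG_OVERSAMPLE = 4

    def _stage_slices(self, scan_ids, target: str, oversample: bool = False):
        """Slice stacks (X, Y) for one stage over the given scans.

        Liver stage: full normalized slices vs liver masks.  Tumor stage:
        liver-restricted input (ground-truth liver dilated by the margin,
        background zeroed) vs tumor masks, keeping only slices that
        intersect the volume of interest.  With ``oversample`` the
        lesion-bearing slices are repeated ``FG_OVERSAMPLE`` times.
        """
        xs, ys = [], []
        for sid in scan_ids:
            ct, liver, tumor = self._load(sid)
            norm = self._normalized(ct)
            if target == "liver":
                vals, mask = norm.values, liver.labels
                keep = np.ones(vals.shape[2], dtype=bool)
            else:
                roi_full = restrict_to_liver(norm, liver, margin_mm=self.margin_mm)
                vals = np.where(roi_full.dilated_mask, norm.values, 0.0).astype(np.float32)
                mask = tumor.labels
                keep = roi_full.dilated_mask.any(axis=(0, 1))
            for k in range(vals.shape[2]):
                if keep[k]:
                    xs.append(vals[:, :, k])
                    ys.append(mask[:, :, k])
        x = np.asarray(xs, dtype=np.float32)[:, None]
        y = np.asarray(ys, dtype=np.float32)[:, None]
        if oversample:
            reps = np.where(y.sum(axis=(1, 2, 3)) > 0, self.FG_OVERSAMPLE, 1)
            x, y = np.repeat(x, reps, axis=0), np.repeat(y, reps, axis=0)
        return x, y

    def _val_cases(self, scan_ids, target: str):
        cases = []
        for sid in scan_ids:
            x, y = self._stage_slices([sid], target)
            cases.append((x, y, sid))
        return cases

    # -- fitting ----------------------------------------------------------

    def fit(self) -> "CascadeResults":
        train_ids = list(self.manifest.scans("train")["scan_id"])
        val_ids = list(self.manifest.scans("validation")["scan_id"])
        if not train_ids:
            raise ValueError("manifest has no training scans")

        lx, ly = self._stage_slices(train_ids, "liver")
        liver_net, liver_hist = train_model(
            lx, ly, self._val_cases(val_ids, "liver"), self.liver_config
        )
        tx, ty = self._stage_slices(train_ids, "tumor", oversample=True)
        tumor_net, tumor_hist = train_model(
            tx, ty, self._val_cases(val_ids, "tumor"), self.tumor_config
        )
        return CascadeResults(
            model=self,
            liver=TrainedSegmenter(liver_net, self.liver_config, self.provenance, "liver", liver_hist),
            tumor=TrainedSegmenter(tumor_net, self.tumor_config, self.provenance, "tumor", tumor_hist),
        )


@dataclass
class CascadeResults:
    """Fitted cascade: trained stages plus evaluation helpers."""

    model: CascadeModel
    liver: TrainedSegmenter
    tumor: TrainedSegmenter

    def segment(self, ct: CTVolume) -> SegmentationResult:
        return segment_cascade(ct, self.liver, self.tumor, margin_mm=self.model.margin_mm)

    def evaluate(self, partition: str = "test") -> dict:
        """Segment every scan of a partition and score against ground truth.

        Returns per-structure :class:`MetricReport`s plus reference and
        automatic total tumor volumes per scan.
        """
        scan_ids = list(self.model.manifest.scans(partition)["scan_id"])
        if not scan_ids:
            raise ValueError(f"no scans in partition {partition!r}")
        liver_pairs, tumor_pairs, rows = [], [], []
        for sid in scan_ids:
            ct, liver_ref, tumor_ref = self.model._load(sid)
            res = self.segment(ct)
            liver_pairs.append((res.liver_mask, liver_ref))
            tumor_pairs.append((res.tumor_mask, tumor_ref))
            rows.append(
                {
                    "scan_id": sid,
                    "reference_ttv_cm3": total_tumor_volume(tumor_ref).ttv_cm3,
                    "automatic_ttv_cm3": total_tumor_volume(res.tumor_mask).ttv_cm3,
                }
            )
        return {
            "liver": global_metrics(liver_pairs),
            "tumor": global_metrics(tumor_pairs),
            "ttv": pd.DataFrame(rows),
            "n_scans": len(scan_ids),
        }

    def summary(self, evaluation: dict | None = None) -> str:
        lines = [
            "Cascaded liver/tumor segmentation — fit summary",
            "=" * 48,
            f"liver stage : depth={self.liver.config.depth}, base_filters={self.liver.config.base_filters}, "
            f"params={self.liver.net.n_params}, best epoch={self.liver.history.get('best_epoch')}, "
            f"val DSC={max(self.liver.history.get('val_dsc') or [float('nan')]):.3f}",
            f"tumor stage : depth={self.tumor.config.depth}, base_filters={self.tumor.config.base_filters}, "
            f"params={self.tumor.net.n_params}, best epoch={self.tumor.history.get('best_epoch')}, "
            f"val DSC={max(self.tumor.history.get('val_dsc') or [float('nan')]):.3f}",
            f"preprocess  : clip [{self.model.provenance['clip_lo']}, {self.model.provenance['clip_hi']}] HU, "
            f"{self.model.provenance['bins']} bins; VOI margin {self.model.margin_mm} mm",
        ]
        if evaluation is not None:
            lv, tm = evaluation["liver"], evaluation["tumor"]
            lines += [
                "-" * 48,
                f"test scans  : {evaluation['n_scans']}",
                f"liver  global DSC {lv.global_dsc:.3f}, per-case median {lv.per_case_dsc_median:.3f} "
                f"(IQR {lv.per_case_dsc_iqr[0]:.3f}-{lv.per_case_dsc_iqr[1]:.3f})",
                f"tumor  global DSC {tm.global_dsc:.3f}, per-case median {tm.per_case_dsc_median:.3f} "
                f"(IQR {tm.per_case_dsc_iqr[0]:.3f}-{tm.per_case_dsc_iqr[1]:.3f}), "
                f"IoU {tm.iou:.3f}, precision {tm.precision:.3f}, recall {tm.recall:.3f}",
            ]
        return "\n".join(lines)
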