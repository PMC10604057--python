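"""Decentralized coarse-to-fine landmark detection.

Landmarks are located by a cascade of three orders of trainable
coordinate regressors, each order narrowing the region of interest for
the next: order 1 roughly locates the cervical, lumbosacral and hip
regions on the full image; order 2 locates individual vertebrae inside
each region crop; order 3 precisely localizes the named landmarks inside
each vertebra crop.  Cropping per order removes unrelated image features
and effectively diversifies the training set.

Training minimizes the mean absolute error between predicted and labelled
coordinates (the cascade's loss function), with each weight updated along
the negative loss gradient scaled by the learning rate.  The cascade is
agnostic to the regressor: anything with the small ``fit``/``predict``
contract of :class:`MLPCoordinateRegressor` plugs in.  The default
regressor is a compact fully-connected network sized for CPU training on
phantom images, optimized with Adam directly on the MAE objective.

During training, order-2 and order-3 crops are taken around ground-truth
targets with random jitter; at inference the crops come from the previous
order's predictions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from skimage.transform import resize

from .geometry import (
    LANDMARK_NAMES,
    TEST_PARAMETER_NAMES,
    FrameConvention,
    LandmarkSet,
    full_report,
)
from .phantom import AnnotatedImage

__all__ = [
    "RoiBox",
    "CropTransform",
    "CascadeConfig",
    "TrainingConfig",
    "CascadeModel",
    "PredictionResult",
    "MLPCoordinateRegressor",
    "mae_loss",
    "crop_roi",
    "train_cascade",
    "predict_landmarks",
    "evaluate_detector",
]


def mae_loss(predicted: Sequence[float], labels: Sequence[float]) -> float:
    """Mean absolute error between predicted and labelled positions.

    The loss is the mean over all labels of |prediction - label|;
    non-negative, and zero exactly when the two coincide.
    """
    a = np.asarray(predicted, dtype=float)
    y = np.asarray(labels, dtype=float)
    if a.shape != y.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {y.shape}")
    if a.size == 0:
        raise ValueError("need at least one label")
    return float(np.mean(np.abs(a - y)))


# -- ROI cropping -------------------------------------------------------------


@dataclass(frozen=True)
class RoiBox:
    """An axis-aligned region of interest in parent-image pixels."""

    x: float
    y: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError(f"RoiBox extent must be positive, got {self}")

    @classmethod
    def centered(cls, cx: float, cy: float, width: float, height: float) -> "RoiBox":
        return cls(x=cx - width / 2.0, y=cy - height / 2.0, width=width, height=height)


@dataclass(frozen=True)
class CropTransform:
    """Exact affine map between a resized crop and its parent image.

    Local coordinates are pixels of the resized crop (``out_w`` x
    ``out_h``); parent coordinates are pixels of the image the crop was
    taken from.
    """

    x0: float
    y0: float
    sx: float  # parent px per local px
    sy: float
    out_w: int
    out_h: int

    def to_parent(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return np.stack(
            [self.x0 + pts[..., 0] * self.sx, self.y0 + pts[..., 1] * self.sy], axis=-1
        )

    def to_local(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return np.stack(
            [(pts[..., 0] - self.x0) / self.sx, (pts[..., 1] - self.y0) / self.sy],
            axis=-1,
        )


def crop_roi(
    image: np.ndarray,
    box: RoiBox,
    margin: float = 0.0,
    out_size: Optional[Tuple[int, int]] = None,
) -> Tuple[np.ndarray, CropTransform]:
    """Crop a (possibly margin-expanded) ROI and resize it for a regressor.

    ``margin`` expands the box symmetrically by that fraction of its
    extent before clipping at the image borders.  ``out_size`` is the
    resized (height, width); when omitted the clipped crop is returned at
    native resolution.  The returned transform maps resized-crop
    coordinates back to the parent image exactly.
    """
    h, w = image.shape
    bx = box.x - margin * box.width
    by = box.y - margin * box.height
    bw = box.width * (1 + 2 * margin)
    bh = box.height * (1 + 2 * margin)
    x0 = int(math.floor(max(bx, 0.0)))
    y0 = int(math.floor(max(by, 0.0)))
    x1 = int(math.ceil(min(bx + bw, w)))
    y1 = int(math.ceil(min(by + bh, h)))
    if x1 <= x0 or y1 <= y0:
        raise ValueError(f"ROI {box} (margin {margin}) does not intersect the image")
    sub = image[y0:y1, x0:x1]
    if out_size is None:
        out_h, out_w = sub.shape
        resized = sub
    else:
        out_h, out_w = out_size
        resized = resize(sub, (out_h, out_w), anti_aliasing=True, preserve_range=True)
    transform = CropTransform(
        x0=float(x0),
        y0=float(y0),
        sx=(x1 - x0) / out_w,
        sy=(y1 - y0) / out_h,
        out_w=out_w,
        out_h=out_h,
    )
    return resized, transform


# -- default coordinate regressor --------------------------------------------


class MLPCoordinateRegressor:
    """A small fully-connected coordinate regressor trained on the MAE loss.

    One hidden ReLU layer on the flattened, resized crop; outputs are
    coordinates normalized to [0, 1] of the crop and clipped there at
    prediction time.  Adam updates follow the negative MAE-loss gradient
    scaled by the learning rate.  Fully deterministic under a fixed seed.
    """

    def __init__(
        self,
        input_size: Tuple[int, int],
        n_outputs: int,
        hidden: int = 64,
        learning_rate: float = 3e-3,
        seed: int = 0,
    ) -> None:
        self.input_size = tuple(input_size)
        self.n_outputs = int(n_outputs)
        self.hidden = int(hidden)
        self.learning_rate = float(learning_rate)
        self.seed = int(seed)
        d = input_size[0] * input_size[1]
        rng = np.random.default_rng(seed)
        self.w1 = rng.normal(0.0, math.sqrt(2.0 / d), size=(d, hidden))
        self.b1 = np.zeros(hidden)
        self.w2 = rng.normal(0.0, 1e-3, size=(hidden, n_outputs))
        self.b2 = np.full(n_outputs, 0.5)
        self._adam_state = None

    # forward ---------------------------------------------------------------

    def _forward(self, x: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        z1 = x @ self.w1 + self.b1
        a1 = np.maximum(z1, 0.0)
        out = a1 @ self.w2 + self.b2
        return a1, out

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Normalized [0, 1] coordinates for a batch of crops (n, h, w)."""
        x = np.asarray(images, dtype=float).reshape(len(images), -1) - 0.5
        _, out = self._forward(x)
        return np.clip(out, 0.0, 1.0)

    # training --------------------------------------------------------------

    def fit(
        self,
        images: np.ndarray,
        targets: np.ndarray,
        epochs: int = 30,
        batch_size: int = 16,
        seed: Optional[int] = None,
    ) -> List[float]:
        """Minimize the MAE loss with Adam; returns the per-epoch training loss."""
        x_all = np.asarray(images, dtype=float).reshape(len(images), -1) - 0.5
        y_all = np.asarray(targets, dtype=float)
        if len(x_all) != len(y_all):
            raise ValueError("images/targets length mismatch")
        n = len(x_all)
        rng = np.random.default_rng(self.seed if seed is None else seed)
        params = [self.w1, self.b1, self.w2, self.b2]
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        history: List[float] = []
        for _ in range(epochs):
            order = rng.permutation(n)
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                x, y = x_all[idx], y_all[idx]
                a1, out = self._forward(x)
                # MAE gradient: sign of the residual, averaged over labels
                g_out = np.sign(out - y) / out.size
                grads = [
                    x.T @ (g_out @ self.w2.T * (a1 > 0)),
                    np.sum(g_out @ self.w2.T * (a1 > 0), axis=0),
                    a1.T @ g_out,
                    np.sum(g_out, axis=0),
                ]
                step += 1
                for p, g, mi, vi in zip(params, grads, m, v):
                    mi *= beta1
                    mi += (1 - beta1) * g
                    vi *= beta2
                    vi += (1 - beta2) * g * g
                    m_hat = mi / (1 - beta1**step)
                    v_hat = vi / (1 - beta2**step)
                    p -= self.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
                if not np.isfinite(out).all():
                    raise FloatingPointError("non-finite predictions during training")
            _, out_all = self._forward(x_all)
            loss = mae_loss(out_all, y_all)
            if not math.isfinite(loss):
                raise FloatingPointError("non-finite training loss")
            history.append(loss)
        return history

    # serialization ---------------------------------------------------------

    def get_state(self) -> Dict[str, np.ndarray]:
        return {"w1": self.w1, "b1": self.b1, "w2": self.w2, "b2": self.b2}

    def set_state(self, state: Dict[str, np.ndarray]) -> None:
        self.w1 = np.array(state["w1"], dtype=float)
        self.b1 = np.array(state["b1"], dtype=float)
        self.w2 = np.array(state["w2"], dtype=float)
        self.b2 = np.array(state["b2"], dtype=float)


# -- cascade configuration ----------------------------------------------------

#: Order-1 regions and their landmarks; T1 belongs to the cervical region.
REGION_LANDMARKS: Dict[str, Tuple[str, ...]] = {
    "hip": ("femoral_head_1", "femoral_head_2"),
    "lumbosacral": (
        "sacrum_center",
        "s1_sup_ant",
        "s1_sup_post",
        "l1_sup_ant",
        "l1_sup_post",
    ),
    "cervical": ("t1_sup_ant", "t1_sup_post", "c2_inf_ant", "c2_inf_post"),
}

#: Order-2 vertebra groups inside each region, each carrying its order-3 landmarks.
VERTEBRA_LANDMARKS: Dict[str, Dict[str, Tuple[str, ...]]] = {
    "hip": {"femoral": ("femoral_head_1", "femoral_head_2")},
    "lumbosacral": {
        "s1": ("sacrum_center", "s1_sup_ant", "s1_sup_post"),
        "l1": ("l1_sup_ant", "l1_sup_post"),
    },
    "cervical": {
        "t1": ("t1_sup_ant", "t1_sup_post"),
        "c2": ("c2_inf_ant", "c2_inf_post"),
    },
}


@dataclass(frozen=True)
class CascadeConfig:
    """Region decomposition, crop sizes and input resolutions of the cascade."""

    region_extent: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {
            "hip": (0.95, 0.30),
            "lumbosacral": (0.95, 0.45),
            "cervical": (0.95, 0.35),
        }
    )  # (width, height) fractions of the full image
    vertebra_extent: Tuple[float, float] = (0.60, 0.22)
    crop_margin: float = 0.10
    input_order1: Tuple[int, int] = (64, 24)  # (height, width)
    input_order2: Tuple[int, int] = (32, 32)
    input_order3: Tuple[int, int] = (32, 32)
    hidden: int = 64

    def __post_init__(self) -> None:
        assigned = [
            lm for groups in VERTEBRA_LANDMARKS.values() for lms in groups.values() for lm in lms
        ]
        if sorted(assigned) != sorted(LANDMARK_NAMES):
            raise ValueError("every landmark must belong to exactly one order-3 head")


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization settings for the cascade."""

    learning_rate: float = 3e-3
    epochs: int = 30
    batch_size: int = 16
    seed: int = 0
    validation_split: float = 0.1  # held-out fraction; default 9:1 train:validation
    jitter: float = 0.08  # training-crop center jitter, fraction of box extent

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if not (0.0 < self.validation_split < 1.0):
            raise ValueError("validation split must be in (0, 1)")


@dataclass
class CascadeModel:
    """The trained 3-order detector with its crop geometry and history."""

    config: CascadeConfig
    image_size: Tuple[int, int]  # (width, height) the cascade was trained at
    regressors: Dict[str, MLPCoordinateRegressor]
    history: List[float] = field(default_factory=list)
    per_model_history: Dict[str, List[float]] = field(default_factory=dict)
    train_indices: List[int] = field(default_factory=list)
    val_indices: List[int] = field(default_factory=list)

    # -- persistence ---------------------------------------------------------

    def save(self, path: str) -> None:
        """Serialize to a single .npz archive (exact float64 weights)."""
        meta = {
            "image_size": list(self.image_size),
            "history": self.history,
            "per_model_history": self.per_model_history,
            "train_indices": self.train_indices,
            "val_indices": self.val_indices,
            "config": {
                "region_extent": {k: list(v) for k, v in self.config.region_extent.items()},
                "vertebra_extent": list(self.config.vertebra_extent),
                "crop_margin": self.config.crop_margin,
                "input_order1": list(self.config.input_order1),
                "input_order2": list(self.config.input_order2),
                "input_order3": list(self.config.input_order3),
                "hidden": self.config.hidden,
            },
            "regressors": {
                key: {
                    "input_size": list(reg.input_size),
                    "n_outputs": reg.n_outputs,
                    "hidden": reg.hidden,
                    "learning_rate": reg.learning_rate,
                    "seed": reg.seed,
                }
                for key, reg in self.regressors.items()
            },
        }
        arrays = {"_meta": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)}
        for key, reg in self.regressors.items():
            for name, arr in reg.get_state().items():
                arrays[f"{key}//{name}"] = arr
        with open(path, "wb") as fh:
            np.savez(fh, **arrays)

    @classmethod
    def load(cls, path: str) -> "CascadeModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["_meta"]).decode())
            cfg = meta["config"]
            config = CascadeConfig(
                region_extent={k: tuple(v) for k, v in cfg["region_extent"].items()},
                vertebra_extent=tuple(cfg["vertebra_extent"]),
                crop_margin=cfg["crop_margin"],
                input_order1=tuple(cfg["input_order1"]),
                input_order2=tuple(cfg["input_order2"]),
                input_order3=tuple(cfg["input_order3"]),
                hidden=cfg["hidden"],
            )
            regressors = {}
            for key, rmeta in meta["regressors"].items():
                reg = MLPCoordinateRegressor(
                    input_size=tuple(rmeta["input_size"]),
                    n_outputs=rmeta["n_outputs"],
                    hidden=rmeta["hidden"],
                    learning_rate=rmeta["learning_rate"],
                    seed=rmeta["seed"],
                )
                reg.set_state(
                    {name: data[f"{key}//{name}"] for name in ("w1", "b1", "w2", "b2")}
                )
                regressors[key] = reg
            return cls(
                config=config,
                image_size=tuple(meta["image_size"]),
                regressors=regressors,
                history=list(meta["history"]),
                per_model_history={k: list(v) for k, v in meta["per_model_history"].items()},
                train_indices=list(meta["train_indices"]),
                val_indices=list(meta["val_indices"]),
            )


@dataclass(frozen=True)
class PredictionResult:
    """Predicted landmarks in full-image coordinates, with per-landmark flags.

    ``flags`` names landmarks whose ROI collapsed (a predicted region fell
    outside the image and was clipped) rather than silently filling them.
    """

    landmarks: LandmarkSet
    flags: Dict[str, str] = field(default_factory=dict)


# -- training -----------------------------------------------------------------


def _region_center(landmarks: LandmarkSet, names: Sequence[str]) -> np.ndarray:
    return np.mean([landmarks[n].as_array() for n in names], axis=0)


def _jittered_box(
    center: np.ndarray,
    extent: Tuple[float, float],
    image_size: Tuple[int, int],
    jitter: float,
    rng: Optional[np.random.Generator],
) -> RoiBox:
    w, h = image_size
    bw, bh = extent[0] * w, extent[1] * h
    cx, cy = center
    if rng is not None and jitter > 0:
        cx += rng.uniform(-jitter, jitter) * bw
        cy += rng.uniform(-jitter, jitter) * bh
    return RoiBox.centered(cx, cy, bw, bh)


def train_cascade(
    cohort: Sequence[AnnotatedImage],
    cascade: Optional[CascadeConfig] = None,
    training: Optional[TrainingConfig] = None,
) -> CascadeModel:
    """Train the 3-order cascade on annotated phantom images.

    Order 1 trains on the full (downscaled) images; orders 2 and 3 train
    on crops taken around ground-truth region/vertebra centers with
    random jitter.  Returns the model with its per-epoch MAE loss history
    (mean over all sub-models, in normalized crop coordinates); the same
    seed and cohort reproduce the history and weights exactly.
    """
    if len(cohort) == 0:
        raise ValueError("cohort must be non-empty")
    cascade = cascade or CascadeConfig()
    training = training or TrainingConfig()
    h, w = cohort[0].image.shape
    image_size = (w, h)
    rng = np.random.default_rng(training.seed)

    n = len(cohort)
    order = rng.permutation(n)
    n_val = max(1, int(round(training.validation_split * n))) if n > 1 else 0
    val_idx = sorted(int(i) for i in order[:n_val])
    train_idx = sorted(int(i) for i in order[n_val:])
    train_set = [cohort[i] for i in train_idx]

    regressors: Dict[str, MLPCoordinateRegressor] = {}
    per_model_history: Dict[str, List[float]] = {}

    def fit_model(key, inputs, targets, input_size):
        reg = MLPCoordinateRegressor(
            input_size=input_size,
            n_outputs=targets.shape[1],
            hidden=cascade.hidden,
            learning_rate=training.learning_rate,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        losses = reg.fit(
            np.asarray(inputs),
            targets,
            epochs=training.epochs,
            batch_size=training.batch_size,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        regressors[key] = reg
        per_model_history[key] = losses

    # order 1: full image -> region centers, normalized to the image
    imgs1, t1 = [], []
    for item in train_set:
        img, tr = crop_roi(
            item.image, RoiBox(0, 0, w, h), margin=0.0, out_size=cascade.input_order1
        )
        centers = [
            tr.to_local(_region_center(item.landmarks, REGION_LANDMARKS[r]))
            for r in REGION_LANDMARKS
        ]
        imgs1.append(img)
        t1.append(
            np.concatenate(
                [c / [cascade.input_order1[1], cascade.input_order1[0]] for c in centers]
            )
        )
    fit_model("order1", imgs1, np.asarray(t1), cascade.input_order1)

    # order 2: region crop -> vertebra centers within it
    for region, groups in VERTEBRA_LANDMARKS.items():
        imgs2, t2 = [], []
        for item in train_set:
            center = _region_center(item.landmarks, REGION_LANDMARKS[region])
            box = _jittered_box(
                center, cascade.region_extent[region], image_size, training.jitter, rng
            )
            img, tr = crop_roi(
                item.image, box, margin=cascade.crop_margin, out_size=cascade.input_order2
            )
            locals_ = [
                tr.to_local(_region_center(item.landmarks, lms)) for lms in groups.values()
            ]
            imgs2.append(img)
            t2.append(
                np.concatenate(
                    [c / [cascade.input_order2[1], cascade.input_order2[0]] for c in locals_]
                )
            )
        fit_model(f"order2:{region}", imgs2, np.asarray(t2), cascade.input_order2)

    # order 3: vertebra crop -> landmark positions within it
    for region, groups in VERTEBRA_LANDMARKS.items():
        for vertebra, lms in groups.items():
            imgs3, t3 = [], []
            for item in train_set:
                center = _region_center(item.landmarks, lms)
                box = _jittered_box(
                    center, cascade.vertebra_extent, image_size, training.jitter, rng
                )
                img, tr = crop_roi(
                    item.image, box, margin=cascade.crop_margin, out_size=cascade.input_order3
                )
                pts = [tr.to_local(item.landmarks[name].as_array()) for name in lms]
                imgs3.append(img)
                t3.append(
                    np.concatenate(
                        [p / [cascade.input_order3[1], cascade.input_order3[0]] for p in pts]
                    )
                )
            fit_model(f"order3:{vertebra}", imgs3, np.asarray(t3), cascade.input_order3)

    history = [
        float(np.mean([per_model_history[k][e] for k in per_model_history]))
        for e in range(training.epochs)
    ]
    return CascadeModel(
        config=cascade,
        image_size=image_size,
        regressors=regressors,
        history=history,
        per_model_history=per_model_history,
        train_indices=train_idx,
        val_indices=val_idx,
    )


# -- inference ----------------------------------------------------------------


def _predict_points(
    reg: MLPCoordinateRegressor,
    image: np.ndarray,
    box: RoiBox,
    margin: float,
    input_size: Tuple[int, int],
) -> np.ndarray:
    crop, tr = crop_roi(image, box, margin=margin, out_size=input_size)
    out = reg.predict(crop[None, :, :])[0]
    pts_local = out.reshape(-1, 2) * [input_size[1], input_size[0]]
    return tr.to_parent(pts_local)


def predict_landmarks(image: np.ndarray, model: CascadeModel) -> PredictionResult:
    """Run the cascade coarse-to-fine and return all 11 landmarks.

    Predictions are mapped back to full-image pixel coordinates at every
    order.  If an intermediate prediction falls outside the image its ROI
    is clipped to the borders and the affected landmarks are flagged.
    """
    h, w = image.shape
    cfg = model.config
    flags: Dict[str, str] = {}

    full_box = RoiBox(0, 0, w, h)
    region_centers = _predict_points(
        model.regressors["order1"], image, full_box, 0.0, cfg.input_order1
    )

    coords: Dict[str, Tuple[float, float]] = {}
    for r_i, (region, groups) in enumerate(VERTEBRA_LANDMARKS.items()):
        center = region_centers[r_i]
        if not (0 <= center[0] < w and 0 <= center[1] < h):
            for lms in groups.values():
                for name in lms:
                    flags[name] = f"order-1 ROI center off-image for region '{region}'"
            center = np.clip(center, [0, 0], [w - 1, h - 1])
        box = RoiBox.centered(
            center[0],
            center[1],
            cfg.region_extent[region][0] * w,
            cfg.region_extent[region][1] * h,
        )
        vert_centers = _predict_points(
            model.regressors[f"order2:{region}"], image, box, cfg.crop_margin, cfg.input_order2
        )
        for v_i, (vertebra, lms) in enumerate(groups.items()):
            vc = vert_centers[v_i]
            if not (0 <= vc[0] < w and 0 <= vc[1] < h):
                for name in lms:
                    flags.setdefault(
                        name, f"order-2 ROI center off-image for vertebra '{vertebra}'"
                    )
                vc = np.clip(vc, [0, 0], [w - 1, h - 1])
            vbox = RoiBox.centered(
                vc[0], vc[1], cfg.vertebra_extent[0] * w, cfg.vertebra_extent[1] * h
            )
            pts = _predict_points(
                model.regressors[f"order3:{vertebra}"],
                image,
                vbox,
                cfg.crop_margin,
                cfg.input_order3,
            )
            for name, pt in zip(lms, pts):
                coords[name] = (float(pt[0]), float(pt[1]))

    return PredictionResult(landmarks=LandmarkSet.from_dict(coords), flags=flags)


# -- evaluation ---------------------------------------------------------------


def evaluate_detector(
    predictions: Sequence[LandmarkSet],
    truths: Sequence[LandmarkSet],
    frame: FrameConvention = FrameConvention(),
) -> Dict[str, pd.DataFrame]:
    """Per-landmark pixel errors and per-parameter angular errors.

    Angular errors come from running the full geometric measurement on
    predicted and true landmark sets and comparing all 12 parameters.
    Returns ``{"landmarks": ..., "parameters": ...}`` tables with MAE and
    SD columns, plus per-case error matrices under ``"landmark_errors"``
    and ``"parameter_errors"``.
    """
    if len(predictions) != len(truths):
        raise ValueError("predictions/truths pairing mismatch")
    if len(predictions) == 0:
        raise ValueError("nothing to evaluate")

    px = {name: [] for name in LANDMARK_NAMES}
    for pred, truth in zip(predictions, truths):
        for name in LANDMARK_NAMES:
            d = pred[name].as_array() - truth[name].as_array()
            px[name].append(float(np.hypot(*d)))

    param_names = ["PI", "PT", "SS", "L1I", "T1I", "C2I", *TEST_PARAMETER_NAMES]

    def params_of(lm: LandmarkSet) -> Dict[str, float]:
        rep = full_report(lm, frame)
        return {
            "PI": rep.pelvic.PI,
            "PT": rep.pelvic.PT,
            "SS": rep.pelvic.SS,
            "L1I": rep.incidences.L1I,
            "T1I": rep.incidences.T1I,
            "C2I": rep.incidences.C2I,
            **rep.direct.as_dict(),
        }

    ang = {name: [] for name in param_names}
    for pred, truth in zip(predictions, truths):
        pp, tp = params_of(pred), params_of(truth)
        for name in param_names:
            ang[name].append(abs(pp[name] - tp[name]))

    def summarize(errors: Dict[str, List[float]]) -> pd.DataFrame:
        rows = [
            {
                "name": name,
                "mae": float(np.mean(v)),
                "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
            }
            for name, v in errors.items()
        ]
        return pd.DataFrame(rows).set_index("name")

    return {
        "landmarks": summarize(px),
        "parameters": summarize(ang),
        "landmark_errors": pd.DataFrame(px),
        "parameter_errors": pd.DataFrame(ang),
    }
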