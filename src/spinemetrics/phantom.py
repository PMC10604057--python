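"""Synthetic spine phantoms: landmark forward model and radiograph rendering.

The phantom is the forward model of the measurement geometry: given target
values of the five independent angles the method measures (PI, PT, and the
three incidence angles L1I, T1I, C2I), it constructs an 11-landmark set
from which :mod:`spinemetrics.geometry` recovers every target exactly.
Sacral slope and the six test parameters follow from the targets by the
signed identities and are never free.

A cohort sampler draws the five independent angles from truncated normals
whose defaults match the descriptive statistics of a published 63-subject
standing-radiograph validation cohort (means, SDs, observed min/max), and
a renderer paints femoral-head discs and vertebral-body quadrilaterals
along a smooth interpolating curve, with Gaussian blur and additive noise,
to give radiograph-like training images with exact ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.ndimage import gaussian_filter
from scipy.stats import truncnorm
from skimage.draw import disk, polygon

from .geometry import (
    FrameConvention,
    LandmarkSet,
    SagittalReport,
    full_report,
)

__all__ = [
    "PhantomSpec",
    "CohortConfig",
    "AnnotatedImage",
    "InfeasibleSpecError",
    "DEFAULT_COHORT_DISTRIBUTIONS",
    "generate_landmark_set",
    "sample_cohort",
    "render_radiograph",
]


class InfeasibleSpecError(ValueError):
    """Raised when a phantom spec cannot be realized inside the image bounds."""


#: Default sampling distributions for the five independent angles:
#: (mean, SD, min, max) in degrees, from the standard-reference column of
#: the 63-subject validation cohort.
DEFAULT_COHORT_DISTRIBUTIONS: Dict[str, Tuple[float, float, float, float]] = {
    "PI": (51.76, 12.47, 27.94, 80.18),
    "PT": (14.21, 8.94, -5.36, 46.55),
    "L1I": (-0.56, 13.30, -23.69, 54.78),
    "T1I": (39.07, 11.74, 12.50, 64.85),
    "C2I": (26.21, 11.26, 2.76, 53.06),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Target angles plus rendering controls for one synthetic subject.

    The default image is a 4x downscale of a 1080 x 3240 px full-length
    lateral film (width x height); resolution is a rendering detail with
    no effect on the measured angles.
    """

    pi: float = 52.16
    pt: float = 14.99
    l1i: float = 2.46
    t1i: float = 39.77
    c2i: float = 26.87
    image_size: Tuple[int, int] = (270, 810)  # (width, height) px
    spine_length: float = 600.0  # femoral midpoint to C2, px
    endplate_half_widths: Dict[str, float] = field(
        default_factory=lambda: {"s1": 26.0, "l1": 24.0, "t1": 18.0, "c2": 11.0}
    )
    femoral_head_radius: float = 22.0
    femoral_head_separation: float = 10.0  # px between the two head centers
    frame: FrameConvention = FrameConvention("+x")
    noise: float = 0.05  # additive Gaussian noise SD, fraction of intensity range
    blur: float = 1.0  # Gaussian blur sigma, px
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pi", "pt", "l1i", "t1i", "c2i"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"target {name} is not finite")
        w, h = self.image_size
        if w <= 0 or h <= 0:
            raise ValueError(f"image size must be positive, got {self.image_size}")
        if self.spine_length <= 0:
            raise ValueError("spine length must be positive")


@dataclass(frozen=True)
class CohortConfig:
    """Sampling plan for a synthetic cohort.

    Only the five independent angles are sampled (independent truncated
    normals); SS = PI - PT and the six test parameters are derived inside
    each subject, preserving the deterministic identities.
    """

    distributions: Dict[str, Tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COHORT_DISTRIBUTIONS)
    )
    n: int = 63
    seed: int = 0
    base_spec: PhantomSpec = PhantomSpec()
    max_retries: int = 50

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("cohort size must be non-negative")
        expected = set(DEFAULT_COHORT_DISTRIBUTIONS)
        if set(self.distributions) != expected:
            raise ValueError(f"distributions must have keys {sorted(expected)}")
        for key, (_, sd, lo, hi) in self.distributions.items():
            if sd < 0:
                raise ValueError(f"negative SD for {key}")
            if hi < lo:
                raise ValueError(f"empty truncation interval for {key}")


@dataclass(frozen=True)
class AnnotatedImage:
    """A rendered phantom radiograph with its exact ground truth."""

    image: np.ndarray  # float grayscale in [0, 1], shape (height, width)
    landmarks: LandmarkSet
    truth: SagittalReport


# -- landmark forward model ---------------------------------------------------


def _endplate_dir(slope_deg: float) -> np.ndarray:
    """Posterior-to-anterior unit vector of an endplate with the given slope.

    Anatomical frame (X anterior, Y up); positive slope means the anterior
    end is inferior.
    """
    r = math.radians(slope_deg)
    return np.array([math.cos(r), -math.sin(r)])


def generate_landmark_set(
    spec: PhantomSpec,
) -> Tuple[LandmarkSet, SagittalReport]:
    """Construct an 11-landmark set realizing the spec's target angles.

    Landmarks are laid out in the anatomical frame anchored at the
    femoral-head midpoint, then mapped into image coordinates and centered
    within the image.  Vertebral midpoints between the inflection points
    lie on a smooth (PCHIP) curve; only endplate orientations and the
    pelvic-tilt line enter any measured angle, so the curve is purely a
    rendering choice.

    Returns the landmark set and the full geometric report computed from
    it, whose PI, PT, L1I, T1I and C2I equal the targets to floating-point
    precision.

    Raises :class:`InfeasibleSpecError` if the construction does not fit
    inside the image bounds.
    """
    ss = spec.pi - spec.pt
    slopes = {
        "s1": ss,
        "l1": spec.l1i - spec.pt,
        "t1": spec.t1i - spec.pt,
        "c2": spec.c2i - spec.pt,
    }
    L = spec.spine_length
    hw = spec.endplate_half_widths

    # anatomical frame, origin = femoral-head midpoint
    pt_rad = math.radians(spec.pt)
    pt_dir = np.array([-math.sin(pt_rad), math.cos(pt_rad)])  # up, tilted posterior
    pt_len = 0.22 * L
    m_s1 = pt_len * pt_dir

    # endplate midpoints along the spine; anterior offsets give a gentle,
    # slope-consistent curve (rendering only — no measured angle depends on them)
    heights = {"l1": 0.42, "t1": 0.78, "c2": 1.00}
    mids = {"s1": m_s1}
    for level, frac in heights.items():
        dx = (
            m_s1[0]
            - 0.10 * L * math.sin(0.5 * math.radians(slopes[level]))
            - 0.3 * (frac - 0.22) * L * math.sin(pt_rad)
        )
        mids[level] = np.array([dx, frac * L])

    pts_anat: Dict[str, np.ndarray] = {}
    sep = spec.femoral_head_separation / 2.0
    pts_anat["femoral_head_1"] = np.array([-sep, 0.0])
    pts_anat["femoral_head_2"] = np.array([+sep, 0.0])
    for level in ("s1", "l1", "t1", "c2"):
        e = _endplate_dir(slopes[level])
        suffix = "inf" if level == "c2" else "sup"
        pts_anat[f"{level}_{suffix}_ant"] = mids[level] + hw[level] * e
        pts_anat[f"{level}_{suffix}_post"] = mids[level] - hw[level] * e
    # sacrum center sits below the S1 plate along its inward normal
    n_s1 = np.array([math.sin(math.radians(ss)), math.cos(math.radians(ss))])
    pts_anat["sacrum_center"] = m_s1 - 0.8 * hw["s1"] * n_s1

    # anatomical -> image: x = +/-X, y = -Y, then translate into bounds
    sign = spec.frame.anterior_sign
    raw = {k: np.array([sign * v[0], -v[1]]) for k, v in pts_anat.items()}
    xs = np.array([v[0] for v in raw.values()])
    ys = np.array([v[1] for v in raw.values()])
    w, h = spec.image_size
    margin = max(spec.femoral_head_radius + 2.0, 8.0)
    extent_x, extent_y = xs.max() - xs.min(), ys.max() - ys.min()
    if extent_x + 2 * margin > w or extent_y + 2 * margin > h:
        raise InfeasibleSpecError(
            f"landmark extent ({extent_x:.0f} x {extent_y:.0f} px plus margin) "
            f"exceeds image size {w} x {h}"
        )
    offset = np.array(
        [
            (w - extent_x) / 2.0 - xs.min(),
            (h - extent_y) / 2.0 - ys.min(),
        ]
    )
    coords = {k: tuple(v + offset) for k, v in raw.items()}
    landmarks = LandmarkSet.from_dict(coords)
    truth = full_report(landmarks, spec.frame)
    return landmarks, truth


# -- cohort sampling ----------------------------------------------------------


def _draw_truncated(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    if sd == 0.0:
        return float(min(max(mean, lo), hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def sample_cohort(
    config: CohortConfig,
) -> List[Tuple[LandmarkSet, SagittalReport]]:
    """Draw ``config.n`` independent synthetic subjects.

    Each subject's PI, PT, L1I, T1I, C2I come from the configured
    truncated normals; geometrically infeasible draws are resampled up to
    ``config.max_retries`` times before erroring.  Fixed seed gives
    bit-identical landmark coordinates.
    """
    rng = np.random.default_rng(config.seed)
    cohort: List[Tuple[LandmarkSet, SagittalReport]] = []
    for i in range(config.n):
        for attempt in range(config.max_retries + 1):
            draws = {
                key: _draw_truncated(rng, *config.distributions[key])
                for key in ("PI", "PT", "L1I", "T1I", "C2I")
            }
            spec = replace(
                config.base_spec,
                pi=draws["PI"],
                pt=draws["PT"],
                l1i=draws["L1I"],
                t1i=draws["T1I"],
                c2i=draws["C2I"],
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            try:
                cohort.append(generate_landmark_set(spec))
                break
            except InfeasibleSpecError:
                if attempt == config.max_retries:
                    raise InfeasibleSpecError(
                        f"subject {i}: no feasible draw in {config.max_retries} retries"
                    )
    return cohort


# -- rendering ----------------------------------------------------------------


def _vertebra_quad(
    center: np.ndarray, angle_deg: float, half_w: float, half_h: float
) -> np.ndarray:
    """Corner coordinates (4, 2) of a rotated vertebral-body rectangle, image frame."""
    r = math.radians(angle_deg)
    u = np.array([math.cos(r), math.sin(r)])  # along the endplate, image frame
    v = np.array([-math.sin(r), math.cos(r)])
    return np.array(
        [
            center + half_w * u + half_h * v,
            center + half_w * u - half_h * v,
            center - half_w * u - half_h * v,
            center - half_w * u + half_h * v,
        ]
    )


def render_radiograph(landmarks: LandmarkSet, spec: PhantomSpec) -> AnnotatedImage:
    """Paint a radiograph-like image of the landmark configuration.

    Femoral heads become discs; S1, L1, T1, C2 and interpolated
    intermediate vertebrae become bright quadrilaterals along a PCHIP
    curve through the endplate midpoints.  Gaussian blur and additive
    noise follow the spec; the annotation coordinates are exactly the
    input landmarks.  Same seed, same bytes.
    """
    from .geometry import LANDMARK_NAMES

    w, h = spec.image_size
    arr = landmarks.as_array()
    oob = [
        name
        for name, (x, y) in zip(LANDMARK_NAMES, arr)
        if not (0 <= x < w and 0 <= y < h)
    ]
    if oob:
        raise ValueError(f"landmarks outside image bounds: {', '.join(oob)}")

    img = np.full((h, w), 0.08, dtype=np.float64)

    def paint_poly(corners: np.ndarray, value: float) -> None:
        rr, cc = polygon(corners[:, 1], corners[:, 0], shape=img.shape)
        img[rr, cc] = value

    # femoral heads
    for head in (landmarks.femoral_head_1, landmarks.femoral_head_2):
        rr, cc = disk((head.y, head.x), spec.femoral_head_radius, shape=img.shape)
        img[rr, cc] = 0.55

    # named vertebral bodies: one quad edge lies exactly on the endplate
    # segment, the body extending away from the endplate's outward normal
    mids, angles, widths = [], [], []
    for level in ("s1", "l1", "t1", "c2"):
        suffix = "inf" if level == "c2" else "sup"
        ant = landmarks[f"{level}_{suffix}_ant"].as_array()
        post = landmarks[f"{level}_{suffix}_post"].as_array()
        e = ant - post
        half_w = 0.5 * float(np.linalg.norm(e))
        mids.append(0.5 * (ant + post))
        angles.append(math.degrees(math.atan2(e[1], e[0])))
        widths.append(half_w)
        # outward normal in image frame: rotate the anatomical endplate
        # vector 90 deg toward "up", then map back to image coordinates
        e_anat = spec.frame.to_anatomical(e)
        n_img = spec.frame.to_image(
            np.array([-e_anat[1], e_anat[0]]) / (2.0 * half_w)
        )
        depth = 1.2 * half_w
        d = -depth * n_img if suffix == "sup" else depth * n_img
        paint_poly(np.array([ant, post, post + d, ant + d]), 0.80)
    mids_arr = np.array(mids)

    # intermediate bodies along a smooth curve through the endplate midpoints
    t_known = np.array([0.0, 1.0, 2.0, 3.0])
    fx = PchipInterpolator(t_known, mids_arr[:, 0])
    fy = PchipInterpolator(t_known, mids_arr[:, 1])
    fa = PchipInterpolator(t_known, np.unwrap(np.radians(angles)))
    fw = PchipInterpolator(t_known, widths)
    t_render = np.concatenate(
        [np.linspace(0.35, 0.78, 3), np.linspace(1.2, 1.85, 4), [2.35, 2.6]]
    )
    for t in t_render:
        c = np.array([float(fx(t)), float(fy(t))])
        half_w = 0.85 * float(fw(t))
        quad = _vertebra_quad(c, math.degrees(float(fa(t))), half_w, 0.45 * half_w)
        paint_poly(quad, 0.80)

    if spec.blur > 0:
        img = gaussian_filter(img, sigma=spec.blur)
    if spec.noise > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    truth = full_report(landmarks, spec.frame)
    return AnnotatedImage(image=img, landmarks=landmarks, truth=truth)
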