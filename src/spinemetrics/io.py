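"""File formats: landmark annotations, measurement reports, cohort manifests, config.

Landmark files use the canonical 11-name schema, one file per image:
CSV with a ``name,x,y`` header, or JSON with a ``landmarks`` mapping plus
an ``anterior_direction`` field.  Reports are written as CSV (human
facing, angles rounded to 2 decimals) or JSON (machine facing, full
precision).  Run configuration round-trips through YAML with unknown
keys rejected.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .geometry import (
    LANDMARK_NAMES,
    TEST_PARAMETER_NAMES,
    FrameConvention,
    LandmarkSet,
    SagittalReport,
)

__all__ = [
    "read_landmarks",
    "write_landmarks",
    "read_image",
    "write_image",
    "write_report",
    "read_report",
    "report_frame",
    "write_cohort_manifest",
    "RunConfig",
    "load_config",
    "save_config",
]

PathLike = Union[str, Path]


def read_landmarks(path: PathLike) -> Tuple[LandmarkSet, FrameConvention]:
    """Read an annotation file (CSV or JSON by extension).

    All 11 canonical landmark names must appear exactly once; errors name
    the missing, duplicated or unknown landmark.  CSV carries no
    orientation and defaults to anterior ``+x``; JSON may carry an
    ``anterior_direction`` field.
    """
    path = Path(path)
    frame = FrameConvention("+x")
    coords: Dict[str, Tuple[float, float]] = {}
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        if "anterior_direction" in payload:
            frame = FrameConvention(payload["anterior_direction"])
        entries = payload["landmarks"].items()
    else:
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not {"name", "x", "y"} <= set(reader.fieldnames):
                raise ValueError(f"{path}: expected header 'name,x,y'")
            entries = [(row["name"], (row["x"], row["y"])) for row in reader]
    for name, xy in entries:
        if name not in LANDMARK_NAMES:
            raise ValueError(f"{path}: unknown landmark name {name!r}")
        if name in coords:
            raise ValueError(f"{path}: duplicate landmark {name!r}")
        try:
            coords[name] = (float(xy[0]), float(xy[1]))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed coordinates for {name!r}: {xy}") from exc
    missing = [n for n in LANDMARK_NAMES if n not in coords]
    if missing:
        raise ValueError(f"{path}: missing landmark(s): {', '.join(missing)}")
    return LandmarkSet.from_dict(coords), frame


def write_landmarks(
    landmarks: LandmarkSet,
    path: PathLike,
    frame: FrameConvention = FrameConvention(),
) -> None:
    """Write an annotation file (format by extension, CSV or JSON)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "anterior_direction": frame.anterior_direction,
            "landmarks": {name: [pt.x, pt.y] for name, pt in landmarks},
        }
        path.write_text(json.dumps(payload, indent=2))
    else:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["name", "x", "y"])
            for name, pt in landmarks:
                writer.writerow([name, repr(pt.x), repr(pt.y)])


def read_image(path: PathLike) -> np.ndarray:
    """Load a grayscale PNG/TIFF as float in [0, 1] (16-bit aware)."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    arr = arr.astype(float)
    if arr.max() > 1.0:
        arr /= 65535.0 if arr.max() > 255 else 255.0
    return arr


def write_image(image: np.ndarray, path: PathLike) -> None:
    """Write a float [0, 1] grayscale image as 8-bit PNG/TIFF."""
    iio.imwrite(Path(path), (np.clip(image, 0, 1) * 255).astype(np.uint8))


# -- reports ------------------------------------------------------------------


def report_frame(report: SagittalReport, round_to: Optional[int] = None) -> pd.DataFrame:
    """Tabulate a report: one row per parameter, direct/derived/discrepancy columns."""
    rows = []
    for name, value in (
        ("PI", report.pelvic.PI),
        ("PT", report.pelvic.PT),
        ("SS", report.pelvic.SS),
        ("L1I", report.incidences.L1I),
        ("T1I", report.incidences.T1I),
        ("C2I", report.incidences.C2I),
    ):
        rows.append({"parameter": name, "direct": value, "derived": np.nan, "discrepancy": np.nan})
    for name in TEST_PARAMETER_NAMES:
        rows.append(
            {
                "parameter": name,
                "direct": getattr(report.direct, name),
                "derived": getattr(report.derived, name),
                "discrepancy": report.discrepancy[name],
            }
        )
    df = pd.DataFrame(rows).set_index("parameter")
    if round_to is not None:
        df = df.round(round_to)
    return df


def write_report(report: SagittalReport, path: PathLike) -> None:
    """Write a report as JSON (full precision) or CSV (rounded to 2 decimals)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(report.as_dict(), indent=2))
    else:
        report_frame(report, round_to=2).to_csv(path)


def read_report(path: PathLike) -> SagittalReport:
    """Read a JSON report back (lossless round trip)."""
    return SagittalReport.from_dict(json.loads(Path(path).read_text()))


def write_cohort_manifest(
    rows: List[Dict[str, object]], path: PathLike
) -> None:
    """Cohort manifest CSV: one row per subject (file paths, truth parameters, seed)."""
    pd.DataFrame(rows).to_csv(Path(path), index=False)


# -- run configuration --------------------------------------------------------


@dataclass
class RunConfig:
    """End-to-end pipeline configuration; YAML round trip is lossless."""

    anterior_direction: str = "+x"
    output_dir: str = "out"
    seed: int = 0
    log_level: str = "INFO"
    cohort_n: int = 63
    image_size: Tuple[int, int] = (270, 810)
    noise: float = 0.05
    blur: float = 1.0
    epochs: int = 30
    learning_rate: float = 3e-3
    batch_size: int = 16
    validation_split: float = 0.1
    threshold_grid_max: float = 10.0
    threshold_grid_step: float = 0.5

    def to_dict(self) -> Dict[str, object]:
        d = asdict(self)
        d["image_size"] = list(self.image_size)
        return d


def load_config(path: PathLike) -> RunConfig:
    """Load a YAML config, rejecting unknown keys."""
    payload = yaml.safe_load(Path(path).read_text()) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(payload) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    if "image_size" in payload:
        payload["image_size"] = tuple(payload["image_size"])
    return RunConfig(**payload)


def save_config(config: RunConfig, path: PathLike) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
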