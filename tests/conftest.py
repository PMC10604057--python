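import numpy as np
import pytest

from spinemetrics.geometry import FrameConvention, LandmarkSet
from spinemetrics.phantom import CohortConfig, PhantomSpec, generate_landmark_set


@pytest.fixture(scope="session")
def frame() -> FrameConvention:
    return FrameConvention("+x")


@pytest.fixture(scope="session")
def reference_means() -> dict:
    """Published CNN-column cohort means of the five independent angles (degrees)."""
    return {"PI": 52.16, "PT": 14.99, "L1I": 2.46, "T1I": 39.77, "C2I": 26.87}


@pytest.fixture(scope="session")
def mean_phantom(reference_means):
    """Landmark set realizing the reference cohort means exactly."""
    spec = PhantomSpec(
        pi=reference_means["PI"],
        pt=reference_means["PT"],
        l1i=reference_means["L1I"],
        t1i=reference_means["T1I"],
        c2i=reference_means["C2I"],
    )
    return generate_landmark_set(spec)


def random_feasible_specs(n: int, seed: int):
    """Uniform draws over a broad feasible window of the five target angles."""
    rng = np.random.default_rng(seed)
    specs = []
    for _ in range(n):
        specs.append(
            PhantomSpec(
                pi=rng.uniform(30.0, 80.0),
                pt=rng.uniform(-5.0, 40.0),
                l1i=rng.uniform(-20.0, 50.0),
                t1i=rng.uniform(15.0, 60.0),
                c2i=rng.uniform(5.0, 50.0),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return specs


def rotate_about(landmarks: LandmarkSet, pivot, theta_deg: float, frame: FrameConvention):
    """Rotate all landmarks about ``pivot`` by ``theta_deg`` in the PT-positive sense."""
    t = np.radians(theta_deg)
    rot = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])

    def fn(arr):
        out = []
        for xy in arr:
            v = frame.to_anatomical(xy - pivot)
            out.append(frame.to_image(rot @ v) + pivot)
        return np.array(out)

    return landmarks.transformed(fn)
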