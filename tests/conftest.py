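import numpy as np
import pytest

from gazekit import (
    CameraModel,
    HeadPose,
    LandmarkSet,
    SyntheticEyeSpec,
    eye_roi_from_image,
    render_eye_roi,
    render_face_landmarks,
)


@pytest.fixture
def camera() -> CameraModel:
    return CameraModel.default(640, 480)


@pytest.fixture
def frontal_landmarks(camera) -> LandmarkSet:
    """68 landmarks of the generic face template, frontal pose, 600 mm away."""
    return render_face_landmarks(HeadPose(0.0, 0.0, 0.0, (0.0, 0.0, 600.0)), camera)


@pytest.fixture
def clean_eye_roi():
    """Default hard-edge synthetic eye ROI plus its true center."""
    img, tc = render_eye_roi(SyntheticEyeSpec())
    return eye_roi_from_image(img), tc


def naive_snakuscule_energy(image: np.ndarray, x: int, y: int, r: int, beta: float) -> float:
    """Independent gray-difference oracle: fresh distance masks per call."""
    img = np.asarray(image, dtype=float)
    yy, xx = np.ogrid[0 : img.shape[0], 0 : img.shape[1]]
    d2 = (xx - x) ** 2 + (yy - y) ** 2
    disk = d2 <= r * r
    annulus = (d2 > r * r) & (d2 <= (beta * r) ** 2)
    return float(img[annulus].mean() - img[disk].mean())
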