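"""Shared fixtures: expensive calibration artifacts built once per session."""

import numpy as np
import pytest

from osteodose.kernel import generate_voxel_kernel
from osteodose.nuclide import RE186
from osteodose.quantify import build_recovery_curve
from osteodose.synthetic import ImagingModel, generate_phantom_set, scan_phantoms


@pytest.fixture(scope="session")
def small_kernel():
    """Dose kernel at modest statistics for convolution tests."""
    return generate_voxel_kernel(RE186, n_histories=60_000, seed=42)


@pytest.fixture(scope="session")
def phantom_bundle():
    """The 11-cylinder set, its noiseless scans and the derived recovery curve."""
    phantoms = generate_phantom_set()
    imaging = ImagingModel(noise=False)
    images = scan_phantoms(phantoms, imaging)
    curve = build_recovery_curve(images, [o.true_volume_ml for o, _ in phantoms])
    return phantoms, images, curve
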