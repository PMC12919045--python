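import numpy as np
import pytest

from memkymo.boundary import Boundary


def fourier_shape(
    n_points: int,
    seed: int,
    radius: float = 50.0,
    center=(64.0, 64.0),
    amplitude: float = 0.1,
    n_modes: int = 4,
) -> Boundary:
    """A smooth random closed star-shaped test boundary (CCW on screen)."""
    rng = np.random.default_rng(seed)
    phi = 2 * np.pi * np.arange(n_points) / n_points
    r = np.ones(n_points)
    amps = rng.uniform(0.3, 1.0, n_modes)
    amps *= amplitude / amps.sum()
    phases = rng.uniform(0, 2 * np.pi, n_modes)
    for m, (a, p) in enumerate(zip(amps, phases), start=2):
        r += a * np.cos(m * phi + p)
    r *= radius
    cy, cx = center
    return Boundary(np.column_stack([cy - r * np.sin(phi), cx + r * np.cos(phi)]))


def circle_boundary(n_points: int = 360, radius: float = 40.0, center=(64.0, 64.0)):
    phi = 2 * np.pi * np.arange(n_points) / n_points
    cy, cx = center
    return Boundary(
        np.column_stack([cy - radius * np.sin(phi), cx + radius * np.cos(phi)])
    )


def square_mask(size: int = 64, lo: int = 20, hi: int = 40) -> np.ndarray:
    m = np.zeros((size, size), dtype=np.uint8)
    m[lo:hi, lo:hi] = 1
    return m


@pytest.fixture(scope="session")
def tiny_movie(tmp_path_factory):
    """A small uniform-pattern synthetic movie written as a TIFF pair."""
    from memkymo.synthetic import SynthSpec, write_movie

    root = tmp_path_factory.mktemp("tiny_movie")
    spec = SynthSpec(
        n_frames=6,
        height=128,
        width=128,
        base_radius=30.0,
        drift=0.5,
        noise_sigma=1.0,
        seed=11,
    )
    image_path = root / "movie.tif"
    mask_path = root / "mask.tif"
    truth = write_movie(spec, image_path, mask_path)
    return {"image": image_path, "mask": mask_path, "spec": spec, "truth": truth}
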