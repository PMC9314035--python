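"""Synthetic vessel phantoms, coil sensitivities, and simulated k-space.

The phantoms emulate the image statistics that make time-of-flight MR
angiography amenable to compressed sensing: a handful of bright, roughly
tubular vessels (large smooth arteries plus thin tortuous perforators,
lenticulostriate-style) on a dim, smoothly varying background. Multi-coil
k-space is simulated with smooth complex receive sensitivities and iid
complex Gaussian thermal noise.

Volume axis convention: ``(anteroposterior, left-right, head-foot)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray
from scipy import ndimage

from csmra.fourier import cfftn, dc_index

#: Edge taper half-widths (voxels).  The cosine edge runs from
#: radius - _EDGE_IN to radius + edge_out, with edge_out scaled to the
#: vessel radius so thin vessels stay near voxel caliber (their k-space
#: energy then extends far from the center, as for high-resolution
#: angiograms); support always stays strictly inside radius + 2.
_EDGE_IN = 0.5


@dataclass
class VesselPhantom:
    """Ground-truth vessel image with its generating geometry.

    Attributes
    ----------
    image : ndarray
        Nonnegative real 3D array; vessel peak ≈ 1.0 above a dim
        background (before any k-space noise).
    centerlines : list of (n_i, 3) float arrays
        Vessel centerline point sequences in voxel coordinates.
    radii : list of float
        Per-vessel tube radius in voxels.
    background_level : float
        Upper bound of the background intensity, in [0, 0.3].
    """

    image: NDArray[np.float64]
    centerlines: list[NDArray[np.float64]] = field(default_factory=list)
    radii: list[float] = field(default_factory=list)
    background_level: float = 0.1

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.image.shape  # type: ignore[return-value]


@dataclass
class SensitivityMaps:
    """Complex per-coil receive sensitivity volumes.

    ``maps`` has shape ``(ncoils, *volume_shape)``. Maps are smooth in
    space; the root-sum-of-squares over coils is positive everywhere
    inside the support.
    """

    maps: NDArray[np.complex128]

    @property
    def ncoils(self) -> int:
        return self.maps.shape[0]

    @property
    def volume_shape(self) -> tuple[int, int, int]:
        return self.maps.shape[1:]  # type: ignore[return-value]

    def rss(self) -> NDArray[np.float64]:
        """Root-sum-of-squares magnitude over coils."""
        return np.sqrt(np.sum(np.abs(self.maps) ** 2, axis=0))

    def normalized(self, floor_frac: float = 1e-3) -> "SensitivityMaps":
        """RSS-normalized copy (RSS = 1 wherever RSS exceeds the floor)."""
        rss = self.rss()
        floor = floor_frac * rss.max()
        return SensitivityMaps(self.maps / np.maximum(rss, floor))


@dataclass
class KSpaceData:
    """DC-centered complex multi-coil 3D k-space.

    ``data`` has shape ``(ncoils, kx, ky, kz)`` with DC at index
    ``N // 2`` along each spatial axis (centered orthonormal FFT
    convention, see :mod:`csmra.fourier`). The readout axis ``kx`` is
    always fully sampled; undersampling acts on the ``(ky, kz)``
    phase-encode plane.
    """

    data: NDArray[np.complex128]
    noise_sigma: float = 0.0
    seed: int | None = None

    @property
    def ncoils(self) -> int:
        return self.data.shape[0]

    @property
    def volume_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]  # type: ignore[return-value]

    @property
    def dc_index(self) -> tuple[int, int, int]:
        return dc_index(self.volume_shape)  # type: ignore[return-value]


def _smooth_path(points: NDArray, sigma: float) -> NDArray:
    return ndimage.gaussian_filter1d(points, sigma=sigma, axis=0, mode="nearest")


def _large_vessel_centerline(
    shape: tuple[int, int, int], rng: np.random.Generator
) -> NDArray[np.float64]:
    """A smooth tube spanning the volume along a random principal axis."""
    axis = int(rng.integers(3))
    other = [a for a in range(3) if a != axis]
    n = shape[axis]
    t = np.arange(0, n - 1 + 1e-9, 0.5)
    pts = np.empty((t.size, 3))
    pts[:, axis] = t
    for a in other:
        c0 = shape[a] * rng.uniform(0.3, 0.7)
        amp = shape[a] * rng.uniform(0.04, 0.10)
        freq = rng.uniform(0.5, 2.0)
        phase = rng.uniform(0, 2 * np.pi)
        pts[:, a] = c0 + amp * np.sin(2 * np.pi * freq * t / n + phase)
    for a in range(3):
        pts[:, a] = np.clip(pts[:, a], 0, shape[a] - 1)
    return pts


def _small_vessel_centerline(
    shape: tuple[int, int, int], tortuosity: float, rng: np.random.Generator
) -> NDArray[np.float64]:
    """A thin tortuous tube: a direction-perturbed walk, then smoothed."""
    start = np.array([rng.uniform(0.2 * s, 0.8 * s) for s in shape])
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    step = 0.5
    n_steps = int(0.55 * min(shape) / step)
    pts = [start.copy()]
    p = start.copy()
    for _ in range(n_steps):
        direction = direction + 0.35 * tortuosity * rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        p = p + step * direction
        if np.any(p < 0) or np.any(p > np.array(shape) - 1):
            break
        pts.append(p.copy())
    path = np.asarray(pts)
    if len(path) > 4:
        path = _smooth_path(path, sigma=2.0)
    for a in range(3):
        path[:, a] = np.clip(path[:, a], 0, shape[a] - 1)
    return path


def _render_tube(
    shape: tuple[int, int, int], centerline: NDArray, radius: float
) -> NDArray[np.float64]:
    """Tube intensity from the distance to the rasterized centerline.

    Cosine-tapered edge: 1 inside ``radius - 0.5``, 0 beyond
    ``radius + edge_out`` where ``edge_out = clip(radius / 2, 0.5, 1.5)``.
    """
    marks = np.zeros(shape, dtype=bool)
    idx = np.round(centerline).astype(int)
    for a in range(3):
        idx[:, a] = np.clip(idx[:, a], 0, shape[a] - 1)
    marks[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    dist = ndimage.distance_transform_edt(~marks)
    inner = radius - _EDGE_IN
    outer = radius + float(np.clip(radius / 2, 0.5, 1.5))
    profile = np.zeros(shape)
    profile[dist <= inner] = 1.0
    ramp = (dist > inner) & (dist < outer)
    profile[ramp] = 0.5 * (1 + np.cos(np.pi * (dist[ramp] - inner) / (outer - inner)))
    return profile


def make_vessel_phantom(
    shape: tuple[int, int, int],
    n_large: int = 2,
    n_small: int = 6,
    tortuosity: float = 1.0,
    seed: int = 0,
    background_level: float = 0.1,
) -> VesselPhantom:
    """Generate a sparse bright-vessel phantom on a dim smooth background.

    Parameters
    ----------
    shape : tuple of int
        Grid size per axis; each dimension must be ≥ 16.
    n_large : int
        Number of large smooth vessels (radius 2–4 voxels).
    n_small : int
        Number of thin tortuous vessels (radius ≤ 1.5 voxels).
    tortuosity : float
        Scale of the random direction perturbations of the small
        vessels; 0 gives straight thin tubes.
    seed : int
        Seed for the generator; the output is a pure function of the
        arguments.
    background_level : float
        Maximum background intensity in [0, 0.3]; vessels peak at
        ~1.0 above it.

    Returns
    -------
    VesselPhantom
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < 16 for s in shape):
        raise ValueError(
            f"shape {shape} too small to host the requested vessel radii; "
            "every dimension must be >= 16"
        )
    if n_large < 0 or n_small < 0:
        raise ValueError("vessel counts must be nonnegative")
    if not 0.0 <= background_level <= 0.3:
        raise ValueError("background_level must lie in [0, 0.3]")
    if tortuosity < 0:
        raise ValueError("tortuosity must be nonnegative")

    rng = np.random.default_rng(seed)

    centerlines: list[NDArray[np.float64]] = []
    radii: list[float] = []
    vessel = np.zeros(shape)
    for _ in range(n_large):
        cl = _large_vessel_centerline(shape, rng)
        r = float(rng.uniform(2.0, 3.0))
        vessel = np.maximum(vessel, _render_tube(shape, cl, r))
        centerlines.append(cl)
        radii.append(r)
    for _ in range(n_small):
        cl = _small_vessel_centerline(shape, tortuosity, rng)
        r = float(rng.uniform(0.6, 1.2))
        vessel = np.maximum(vessel, _render_tube(shape, cl, r))
        centerlines.append(cl)
        radii.append(r)

    # Smooth low-frequency background modulation bounded by background_level.
    field_ = rng.normal(size=shape)
    field_ = ndimage.gaussian_filter(field_, sigma=min(shape) / 6)
    span = field_.max() - field_.min()
    if span > 0:
        field_ = (field_ - field_.min()) / span
    background = background_level * (0.7 + 0.3 * field_)

    return VesselPhantom(
        image=vessel + background,
        centerlines=centerlines,
        radii=radii,
        background_level=background_level,
    )


def make_coil_sensitivities(
    shape: tuple[int, int, int],
    ncoils: int = 8,
    seed: int = 0,
    uniform: bool = False,
) -> SensitivityMaps:
    """Smooth complex coil sensitivity maps for a receive array.

    Coil magnitudes are broad Gaussian lobes (plus a small constant
    offset so the root-sum-of-squares never vanishes) centered on an
    ellipse around the volume perimeter; phases are gentle linear
    ramps. With ``uniform=True`` every map is identically 1, which is
    the single-body-coil idealization used in oracle tests.
    """
    shape = tuple(int(s) for s in shape)
    if ncoils < 1:
        raise ValueError("ncoils must be >= 1")
    if uniform:
        return SensitivityMaps(np.ones((ncoils, *shape), dtype=complex))

    rng = np.random.default_rng(seed)
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    sigma = float(np.mean(shape))
    maps = np.empty((ncoils, *shape), dtype=complex)
    angles = 2 * np.pi * np.arange(ncoils) / ncoils
    for c in range(ncoils):
        center = np.array(
            [
                shape[0] / 2 + 0.75 * shape[0] * np.cos(angles[c]),
                shape[1] / 2 + 0.75 * shape[1] * np.sin(angles[c]),
                shape[2] * rng.uniform(0.3, 0.7),
            ]
        )
        d2 = sum((g - center[a]) ** 2 for a, g in enumerate(grids))
        mag = 0.1 + np.exp(-d2 / (2 * sigma**2))
        ramp = sum(
            rng.uniform(-0.03, 0.03) * g / max(shape) * 2 * np.pi for g in grids
        )
        maps[c] = mag * np.exp(1j * (ramp + rng.uniform(0, 2 * np.pi)))
    return SensitivityMaps(maps)


def simulate_kspace(
    phantom: VesselPhantom,
    sens: SensitivityMaps,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> KSpaceData:
    """Forward-simulate fully sampled multi-coil k-space.

    Per coil ``c``: ``F(sens_c * image)`` under the centered orthonormal
    FFT, plus iid complex Gaussian noise with standard deviation
    ``noise_sigma`` per real/imaginary component, equal across coils.
    """
    if sens.volume_shape != phantom.shape:
        raise ValueError(
            f"sensitivity shape {sens.volume_shape} does not match "
            f"phantom shape {phantom.shape}"
        )
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be nonnegative")
    coil_images = sens.maps * phantom.image[None]
    data = cfftn(coil_images, axes=(-3, -2, -1))
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        data = data + noise_sigma * (
            rng.standard_normal(data.shape) + 1j * rng.standard_normal(data.shape)
        )
    return KSpaceData(data=data, noise_sigma=float(noise_sigma), seed=seed)
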