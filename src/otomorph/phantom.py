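"""Synthetic osmium-stained inner-ear phantom with voxel-level ground truth.

Osmium tetroxide binds unsaturated lipids, so myelinated neural tissue is
the brightest class in a contrast-enhanced micro-CT of a decalcified
temporal bone; membranes are fainter, bone fainter still.  The phantom
emulates exactly the image features the processing pipelines act on:

* a solid spiral-ganglion-like *trunk* (bright, label ``nerve``) with thin
  curved *fibers* fanning out of it — one connected bright network;
* a helical *membrane* wall (cochlear-duct-like) at intermediate intensity;
* a spherical *bone* shell (otic-capsule-like) at low intensity;
* many small, bright, mutually unconnected *speckle* blobs — the noise
  objects the geodesic opening must delete;
* partial-volume Gaussian blur, a linear slice-to-slice intensity drift
  along the stack axis, and additive Gaussian sensor noise.

Truth labels are recorded before blur and noise (the "ideal" anatomy), so
evaluation tolerates a one-to-two voxel boundary band.  Generation is pure:
a fixed spec (including its seed, drawn through numpy's PCG64 generator)
reproduces the volume bit-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage as ndi

from .exceptions import ParameterError, PhantomSpecificationError
from .volume_io import IntensityVolume

__all__ = [
    "LABELS",
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
    "generate_flat_noise_block",
]

#: label ids of the truth grid
LABELS = {"background": 0, "bone": 1, "membrane": 2, "nerve": 3, "speckle": 4}

_DEFAULT_INTENSITIES = {
    "background": 0.02,
    "bone": 0.15,
    "membrane": 0.25,
    "nerve": 0.55,
    "speckle": 0.55,
}

# geometry ratios relative to the 160-voxel reference edge
_BASE = 160.0
_TRUNK_R = 34.0 / _BASE
_FIBER_LEN = 12.0 / _BASE
_HELIX_R_INNER = 56.0 / _BASE
_HELIX_R_OUTER = 62.0 / _BASE
_FIBER_BEND = 0.15  # max perpendicular deflection, fraction of fiber length
_BONE_R_INNER = 70.0 / _BASE
_BONE_R_OUTER = 78.0 / _BASE
_HELIX_Z_MARGIN = 14.0 / _BASE


@dataclass
class PhantomSpec:
    """Everything needed to generate one phantom deterministically.

    Geometry defaults scale with the smallest volume edge so smaller test
    phantoms stay valid; intensities encode the contrast ordering
    nerve > membrane > bone > background of an OsO4-stained scan.
    """

    shape: tuple[int, int, int] = (160, 160, 160)
    seed: int = 0
    intensities: dict = field(default_factory=lambda: dict(_DEFAULT_INTENSITIES))
    trunk_radius: float | None = None
    fiber_count: int = 20
    fiber_radius: float = 2.0
    fiber_length: float | None = None
    helix_turns: float = 3.0
    helix_radius: tuple[float, float] | None = None  # (base, apex); decreasing toward apex
    membrane_thickness: float = 2.0
    speckle_count: int | None = None  # None -> 60 scaled by (n/160)^3, min 12
    speckle_radius: tuple[int, int] = (1, 3)
    speckle_margin: float = 6.0
    noise_sigma: float = 0.02
    z_drift: float = 0.05
    blur_sigma: float = 0.7

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) != 3 or any(s < 16 for s in self.shape):
            raise PhantomSpecificationError(f"shape must be 3 axes of >= 16 voxels, got {self.shape}")
        n = min(self.shape)
        if self.trunk_radius is None:
            self.trunk_radius = _TRUNK_R * n
        if self.helix_radius is None:
            self.helix_radius = (_HELIX_R_OUTER * n, _HELIX_R_INNER * n)
        # clearance between the nerve's outermost reach and the membrane's
        # inner surface, so the two classes stay unconnected under blur
        allowed = (min(self.helix_radius) - self.membrane_thickness - 2.0
                   - self.trunk_radius - self.fiber_radius)
        if self.fiber_length is None:
            self.fiber_length = max(0.0, min(_FIBER_LEN * n,
                                             allowed / (1.0 + _FIBER_BEND)))
        if self.speckle_count is None:
            self.speckle_count = max(12, round(60 * (n / _BASE) ** 3))
        for k, v in self.intensities.items():
            if not (0.0 <= v <= 1.0):
                raise PhantomSpecificationError(f"intensity for '{k}' outside [0, 1]: {v}")
        if self.fiber_radius >= self.trunk_radius:
            raise PhantomSpecificationError("fiber radius must be smaller than trunk radius")
        if self.noise_sigma < 0 or self.blur_sigma < 0:
            raise PhantomSpecificationError("noise_sigma and blur_sigma must be >= 0")
        if _BONE_R_OUTER * n >= n / 2.0:
            raise PhantomSpecificationError("bone shell does not fit inside the volume")
        reach = (self.trunk_radius + self.fiber_length * (1.0 + _FIBER_BEND)
                 + self.fiber_radius)
        if reach > min(self.helix_radius) - self.membrane_thickness - 2.0:
            raise PhantomSpecificationError(
                "nerve (trunk + fibers) reaches into the membrane shell; "
                "shrink trunk_radius or fiber_length"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["shape"] = list(self.shape)
        return d


@dataclass
class PhantomTruth:
    """Voxel labels (see :data:`LABELS`) plus the generating spec echo."""

    labels: np.ndarray
    spec: PhantomSpec
    rng_algorithm: str = "numpy.random.Generator(PCG64)"

    def mask(self, label: str | int) -> np.ndarray:
        lab = LABELS[label] if isinstance(label, str) else int(label)
        return self.labels == lab


def _paint_ball(labels, center, radius, value):
    """Set ``value`` inside the Euclidean ball; clipped at volume faces."""
    nz, ny, nx = labels.shape
    cz, cy, cx = center
    r = int(math.ceil(radius))
    z0, z1 = max(0, int(cz) - r), min(nz, int(cz) + r + 2)
    y0, y1 = max(0, int(cy) - r), min(ny, int(cy) + r + 2)
    x0, x1 = max(0, int(cx) - r), min(nx, int(cx) + r + 2)
    if z0 >= z1 or y0 >= y1 or x0 >= x1:
        return
    zz, yy, xx = np.mgrid[z0:z1, y0:y1, x0:x1]
    inside = ((zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2) <= radius ** 2
    sub = labels[z0:z1, y0:y1, x0:x1]
    sub[inside] = value


def _paint_curve(labels, points, radius, value):
    for p in points:
        _paint_ball(labels, p, radius, value)


def generate_phantom(spec: PhantomSpec) -> tuple[IntensityVolume, PhantomTruth]:
    """Rasterise the phantom and return (volume, truth).

    Construction order: bone shell and membrane helix; nerve trunk + fibers
    (overwriting, so the nerve is never split by another class); speckle
    blobs in free space; then partial-volume blur, z-drift, sensor noise,
    clip to [0, 1].  Labels are recorded before blur/noise.
    """
    nz, ny, nx = spec.shape
    n = min(spec.shape)
    center = np.array([(nz - 1) / 2.0, (ny - 1) / 2.0, (nx - 1) / 2.0])
    rng = np.random.default_rng(spec.seed)
    labels = np.zeros(spec.shape, dtype=np.int8)

    # --- bone: spherical shell (otic capsule) -----------------------------
    zz, yy, xx = np.ogrid[0:nz, 0:ny, 0:nx]
    d2 = ((zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2)
    r_in, r_out = _BONE_R_INNER * n, _BONE_R_OUTER * n
    labels[(d2 >= r_in ** 2) & (d2 <= r_out ** 2)] = LABELS["bone"]

    # --- membrane: helical tube wall --------------------------------------
    r_base, r_apex = spec.helix_radius
    z0 = _HELIX_Z_MARGIN * nz
    z1 = nz - z0
    arc = 2 * math.pi * spec.helix_turns * max(r_base, r_apex) + (z1 - z0)
    n_samples = max(64, int(arc / 0.4))
    t = np.linspace(0.0, 1.0, n_samples)
    theta = 2 * math.pi * spec.helix_turns * t
    rho = r_base + (r_apex - r_base) * t  # decreasing toward apex
    pts = np.stack([
        z0 + (z1 - z0) * t,
        center[1] + rho * np.sin(theta),
        center[2] + rho * np.cos(theta),
    ], axis=1)
    _paint_curve(labels, pts, spec.membrane_thickness, LABELS["membrane"])

    # --- nerve: trunk ball + curved fibers (one connected component) ------
    _paint_ball(labels, center, spec.trunk_radius, LABELS["nerve"])
    for _ in range(spec.fiber_count):
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        perp = np.cross(v, rng.normal(size=3))
        perp /= np.linalg.norm(perp)
        bend = rng.uniform(-0.15, 0.15)
        s = np.linspace(0.0, 1.0, max(8, int(spec.fiber_length / 0.4)))
        start = spec.trunk_radius - 2.0 * spec.fiber_radius
        radial = start + (spec.fiber_length + 2.0 * spec.fiber_radius) * s
        curve = center[None, :] + radial[:, None] * v[None, :] \
            + (bend * spec.fiber_length) * (s ** 2)[:, None] * perp[None, :]
        _paint_curve(labels, curve, spec.fiber_radius, LABELS["nerve"])

    # --- speckle: small unconnected bright blobs in free space ------------
    free_dist = ndi.distance_transform_edt(labels == 0)
    placed = []
    attempts = 0
    max_attempts = 400 * max(spec.speckle_count, 1)
    r_lo, r_hi = spec.speckle_radius
    while len(placed) < spec.speckle_count:
        attempts += 1
        if attempts > max_attempts:
            raise PhantomSpecificationError(
                f"could not place {spec.speckle_count} speckles with margin "
                f"{spec.speckle_margin}; placed {len(placed)}"
            )
        r = int(rng.integers(r_lo, r_hi + 1))
        pos = np.array([
            rng.integers(r + 1, nz - r - 1),
            rng.integers(r + 1, ny - r - 1),
            rng.integers(r + 1, nx - r - 1),
        ], dtype=float)
        if free_dist[tuple(pos.astype(int))] < spec.speckle_margin + r:
            continue
        if any(np.linalg.norm(pos - q) < r + qr + 3.0 for q, qr in placed):
            continue
        _paint_ball(labels, pos, r, LABELS["speckle"])
        placed.append((pos, r))

    # --- intensities, blur, drift, noise -----------------------------------
    lut = np.array([
        spec.intensities["background"],
        spec.intensities["bone"],
        spec.intensities["membrane"],
        spec.intensities["nerve"],
        spec.intensities["speckle"],
    ])
    img = lut[labels]
    if spec.blur_sigma > 0:
        img = ndi.gaussian_filter(img, sigma=spec.blur_sigma, mode="nearest")
    if spec.z_drift != 0 and nz > 1:
        ramp = spec.z_drift * (np.arange(nz) / (nz - 1) - 0.5)
        img = img + ramp[:, None, None]
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=spec.shape)
    img = np.clip(img, 0.0, 1.0)

    vol = IntensityVolume(img, name=f"phantom(seed={spec.seed})")
    return vol, PhantomTruth(labels=labels, spec=spec)


def generate_flat_noise_block(shape, mean: float, noise_sigma: float, seed: int
                              ) -> IntensityVolume:
    """Homogeneous block with i.i.d. Gaussian noise — the substrate for
    measuring noise reduction in a flat region."""
    shape = tuple(int(s) for s in shape)
    if not (0.0 <= mean - 4 * noise_sigma and mean + 4 * noise_sigma <= 1.0):
        raise ParameterError(
            f"mean +/- 4*sigma must stay within [0, 1]; got mean={mean}, sigma={noise_sigma}"
        )
    rng = np.random.default_rng(seed)
    data = np.full(shape, mean, dtype=np.float64)
    if noise_sigma > 0:
        data = data + rng.normal(0.0, noise_sigma, size=shape)
    return IntensityVolume(np.clip(data, 0.0, 1.0), name=f"flat(seed={seed})")
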