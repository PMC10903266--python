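"""Synthetic 3D epithelium generator with exact ground truth.

Generates z-stacks that emulate the regime of a densely packed
pseudostratified epithelium imaged with a confocal nuclear stain:
ellipsoidal nuclei (elongated along z, so they overlap in projection)
packed by random sequential adsorption inside a folded slab, spatially
contiguous clones grown from single founder nuclei, and a twin-spot
intensity structure — heterozygous nuclei at one gene dose, homozygous
clone nuclei at twice that dose, unmarked twin clones dark — modulated by
a smooth regional intensity field that defeats global thresholding.

Rendering paints each nucleus as a flat-top ellipsoid (real stained
nuclei image as filled blobs whose basins are defined by the optics, not
by an intensity peak), convolves with a Gaussian point-spread function,
and applies Poisson photon noise plus Gaussian read noise before
quantizing to the configured bit depth.

Everything is deterministic given the scene spec and seed, and the exact
per-nucleus ground truth (centers, radii, clone membership, zygosity) is
returned alongside the images.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from typing import Dict, Iterable, Optional, Tuple, Union

import numpy as np
from scipy import ndimage as ndi

from .volumes import VolumeImage

__all__ = [
    "SlabSpec",
    "IntensitySpec",
    "NoiseSpec",
    "CloneSpec",
    "ZygositySpec",
    "SceneSpec",
    "GroundTruth",
    "place_nuclei",
    "assign_clones",
    "render",
    "preset_scenes",
    "simulate_scene",
    "CHANNELS",
]

logger = logging.getLogger(__name__)

CHANNELS = ("dapi", "marker", "twin")
_CHANNEL_STREAM = {"dapi": 2, "marker": 3, "twin": 4}

ZYG_HET = "heterozygous"
ZYG_HOM = "homozygous"
ZYG_UNMARKED = "unmarked"


@dataclasses.dataclass
class SlabSpec:
    """Folded-slab geometry: a sinusoidal midplane of the given amplitude
    and wavelength (voxels along x), with the stated thickness in z."""

    thickness: float = 34.0
    fold_amplitude: float = 8.0
    fold_wavelength: float = 200.0


@dataclasses.dataclass
class IntensitySpec:
    """Base in-nucleus intensity and background offset, in intensity units."""

    base: float = 180.0
    background: float = 1.0


@dataclasses.dataclass
class NoiseSpec:
    """Poisson photon noise (``photons_per_unit`` photons per intensity
    unit) plus additive Gaussian read noise.  The defaults give a moderate
    signal-to-noise ratio (~10 at the nominal nuclear intensity)."""

    enabled: bool = True
    photons_per_unit: float = 0.55
    read_noise_sd: float = 2.0


@dataclasses.dataclass
class CloneSpec:
    """Clone induction: number of founder cells, cells per clone (an int
    or an inclusive ``(lo, hi)`` range sampled per clone), and the
    fraction of clones carrying the fluorescent marker (the rest are the
    unmarked recombinant twins)."""

    n_founders: int = 0
    cells_per_clone: Union[int, Tuple[int, int]] = 8
    marked_fraction: float = 1.0
    #: minimum in-plane distance between founder nuclei, in voxels; 0 means
    #: fully random founders (clones may then touch and fuse, as real
    #: neighboring clones do)
    founder_min_separation: float = 0.0
    #: largest surface gap (voxels, normalized metric) allowed between a
    #: newly added member and the clone; None grows unconditionally.  Real
    #: clones are contiguous cell patches, so presets bound this; a clone
    #: that cannot grow contiguously stays smaller than its target (the
    #: achieved membership is ground truth either way).
    max_link_gap: Optional[float] = None
    #: grow clones as recombination twins: consecutive clones form a pair,
    #: the second founded next to the first, and exactly one clone of each
    #: pair carries the marker (marked_fraction is ignored).  This mirrors
    #: mitotic recombination, where every marked clone has an unmarked
    #: sister clone beside it — so marked clones never clump.
    twin_pairs: bool = False


@dataclasses.dataclass
class ZygositySpec:
    """Two-dose intensity structure of the twin channel."""

    het_level: float = 70.0
    hom_multiplier: float = 2.0
    field_amplitude: Tuple[float, float] = (1.0, 1.0)
    field_correlation_px: float = 80.0

    def __post_init__(self) -> None:
        if self.hom_multiplier <= 1:
            raise ValueError("hom_multiplier must be > 1")
        lo, hi = self.field_amplitude
        if lo <= 0 or hi < lo:
            raise ValueError("field_amplitude must be positive with lo <= hi")


@dataclasses.dataclass
class SceneSpec:
    """Full description of a synthetic scene."""

    shape: Tuple[int, int, int] = (60, 300, 300)
    n_nuclei: int = 800
    nucleus_radii: Tuple[float, float, float] = (4.5, 3.0, 3.0)
    radius_jitter: float = 0.15
    min_gap: float = 2.0
    slab: SlabSpec = dataclasses.field(default_factory=SlabSpec)
    intensity: IntensitySpec = dataclasses.field(default_factory=IntensitySpec)
    noise: NoiseSpec = dataclasses.field(default_factory=NoiseSpec)
    psf_sigma: float = 1.0
    clone_spec: CloneSpec = dataclasses.field(default_factory=CloneSpec)
    zygosity_spec: ZygositySpec = dataclasses.field(default_factory=ZygositySpec)
    bit_depth: int = 8
    spacing: Tuple[float, float, float] = (0.3, 0.3, 0.3)
    seed: int = 0
    attempt_factor: int = 50

    def __post_init__(self) -> None:
        if min(self.nucleus_radii) < 1:
            raise ValueError("all nucleus radii must be >= 1 voxel")
        if self.min_gap < 0:
            raise ValueError("min_gap must be >= 0")
        if not 0 <= self.radius_jitter < 1:
            raise ValueError("radius_jitter must be in [0, 1)")
        if self.n_nuclei < 1:
            raise ValueError("n_nuclei must be >= 1")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


@dataclasses.dataclass
class GroundTruth:
    """Exact per-nucleus ground truth of a generated scene."""

    centers: np.ndarray  # (n, 3) voxel coordinates (z, y, x)
    radii: np.ndarray  # (n, 3) semi-axes in voxels
    clone_id: np.ndarray  # (n,) marked-clone membership, 0 = unmarked
    zygosity: np.ndarray  # (n,) of {heterozygous, homozygous, unmarked}
    clone_sizes: Dict[int, int] = dataclasses.field(default_factory=dict)
    clones_assigned: bool = False

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.radii = np.atleast_2d(np.asarray(self.radii, dtype=float))
        self.clone_id = np.asarray(self.clone_id, dtype=int)
        self.zygosity = np.asarray(self.zygosity)
        if (self.zygosity == ZYG_HOM).any() and (
            self.clone_id[self.zygosity == ZYG_HOM] <= 0
        ).any():
            raise ValueError("every homozygous nucleus must have clone_id > 0")
        marked = int((self.clone_id > 0).sum())
        if self.clone_sizes and sum(self.clone_sizes.values()) != marked:
            raise ValueError("clone_sizes must sum to the number of marked nuclei")

    @property
    def n_nuclei(self) -> int:
        return int(self.centers.shape[0])

    def channel_indices(self, channel: str) -> np.ndarray:
        """Ground-truth nucleus indices visible in a rendered channel."""
        if channel == "dapi":
            return np.arange(self.n_nuclei)
        if channel == "marker":
            return np.nonzero(self.clone_id > 0)[0]
        if channel == "twin":
            return np.nonzero(self.zygosity != ZYG_UNMARKED)[0]
        raise ValueError(f"unknown channel {channel!r}")

    def to_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "nucleus": np.arange(1, self.n_nuclei + 1),
                "center_z": self.centers[:, 0],
                "center_y": self.centers[:, 1],
                "center_x": self.centers[:, 2],
                "radius_z": self.radii[:, 0],
                "radius_y": self.radii[:, 1],
                "radius_x": self.radii[:, 2],
                "clone_id": self.clone_id,
                "zygosity": self.zygosity,
            }
        )


def _midplane(spec: SceneSpec, x: np.ndarray) -> np.ndarray:
    nz = spec.shape[0]
    return (nz - 1) / 2.0 + spec.slab.fold_amplitude * np.sin(
        2.0 * np.pi * x / spec.slab.fold_wavelength
    )


def surface_separation(
    center_a, radii_a, center_b, radii_b, base_radii
) -> float:
    """Separation between two nuclei in the anisotropy-normalized metric.

    Coordinates are divided by the scene's base semi-axes, which maps every
    (isotropically jittered) nucleus to a sphere; the returned value is the
    center distance minus both sphere radii, in units of the in-plane base
    radius — i.e. approximately voxels of surface clearance in-plane, and
    at least that along z for z-elongated nuclei.
    """
    base = np.asarray(base_radii, dtype=float)
    d = np.linalg.norm((np.asarray(center_a) - np.asarray(center_b)) / base)
    sa = float(np.asarray(radii_a)[1] / base[1])
    sb = float(np.asarray(radii_b)[1] / base[1])
    return float((d - sa - sb) * base[1])


def place_nuclei(spec: SceneSpec, rng: Optional[np.random.Generator] = None) -> GroundTruth:
    """Place nuclei by random sequential adsorption inside the folded slab.

    Every accepted nucleus keeps a surface clearance of at least
    ``min_gap`` (in the normalized metric of :func:`surface_separation`)
    from all others.  Placement stops at ``n_nuclei`` or after
    ``attempt_factor * n_nuclei`` attempts; the achieved count is exact
    ground truth either way.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape
    rz, ry, rx = spec.nucleus_radii
    jit = spec.radius_jitter
    smax = 1.0 + jit
    half = spec.slab.thickness / 2.0
    if spec.slab.thickness < 2 * rz * smax or ny <= 2 * ry * smax or nx <= 2 * rx * smax:
        raise ValueError("slab too small to hold a single nucleus")

    base = np.array([rz, ry, rx], dtype=float)
    gap_n = spec.min_gap / ry  # normalized-metric gap
    centers = np.empty((spec.n_nuclei, 3), dtype=float)
    scales = np.empty(spec.n_nuclei, dtype=float)
    placed = 0
    budget = spec.attempt_factor * spec.n_nuclei
    for _ in range(budget):
        if placed >= spec.n_nuclei:
            break
        s = 1.0 + (rng.uniform(-jit, jit) if jit > 0 else 0.0)
        y = rng.uniform(ry * s, ny - 1 - ry * s)
        x = rng.uniform(rx * s, nx - 1 - rx * s)
        zmid = float(_midplane(spec, np.asarray(x)))
        zlo = max(rz * s, zmid - half + rz * s)
        zhi = min(nz - 1 - rz * s, zmid + half - rz * s)
        if zhi <= zlo:
            continue
        z = rng.uniform(zlo, zhi)
        cand = np.array([z, y, x]) / base
        if placed:
            d = np.linalg.norm(centers[:placed] / base - cand, axis=1)
            if np.any(d < scales[:placed] + s + gap_n):
                continue
        centers[placed] = (z, y, x)
        scales[placed] = s
        placed += 1
    if placed < spec.n_nuclei:
        logger.warning(
            "placed %d of %d nuclei within the attempt budget", placed, spec.n_nuclei
        )
    if placed == 0:
        raise ValueError("could not place any nucleus in the slab")
    centers = centers[:placed]
    radii = scales[:placed, None] * base[None, :]
    return GroundTruth(
        centers=centers,
        radii=radii,
        clone_id=np.zeros(placed, dtype=int),
        zygosity=np.full(placed, ZYG_HET, dtype="<U12"),
    )


def assign_clones(
    gt: GroundTruth, spec: SceneSpec, rng: Optional[np.random.Generator] = None
) -> GroundTruth:
    """Grow clones from random founder nuclei.

    Each clone starts at a founder drawn from the unassigned pool and adds
    the nearest unassigned nucleus to its current member set until the
    target size (so clones are spatially contiguous).  A ``marked_fraction``
    of clones carries the marker (homozygous, clone_id > 0); the remaining
    clones are the unmarked recombinant twins; everything else stays
    heterozygous background.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed + 1)
    cs = spec.clone_spec
    n = gt.n_nuclei
    zygosity = np.full(n, ZYG_HET, dtype="<U12")
    clone_id = np.zeros(n, dtype=int)
    if cs.n_founders == 0:
        return GroundTruth(
            centers=gt.centers,
            radii=gt.radii,
            clone_id=clone_id,
            zygosity=zygosity,
            clone_sizes={},
            clones_assigned=True,
        )
    if isinstance(cs.cells_per_clone, (tuple, list)):
        lo, hi = cs.cells_per_clone
        sizes = rng.integers(int(lo), int(hi) + 1, size=cs.n_founders)
    else:
        sizes = np.full(cs.n_founders, int(cs.cells_per_clone))
    if int(sizes.sum()) > n:
        raise ValueError(
            f"requested {int(sizes.sum())} clone cells but only {n} nuclei available"
        )

    assigned = np.full(n, -1, dtype=int)  # clone index per nucleus, -1 = free
    founder_yx: list = []
    prev_founder = -1
    for k in range(cs.n_founders):
        free = np.nonzero(assigned == -1)[0]
        if free.size == 0:
            break
        if cs.twin_pairs and k % 2 == 1:
            # the sister clone of a recombination event starts beside its twin
            d = np.linalg.norm(gt.centers[free] - gt.centers[prev_founder], axis=1)
            founder = int(free[int(np.argmin(d))])
        elif cs.founder_min_separation > 0 and founder_yx:
            prev = np.asarray(founder_yx)
            d = np.linalg.norm(
                gt.centers[free][:, None, 1:] - prev[None, :, :], axis=2
            ).min(axis=1)
            far = free[d >= cs.founder_min_separation]
            # fall back to the farthest available nucleus if none qualifies
            founder = int(rng.choice(far)) if far.size else int(free[int(np.argmax(d))])
        else:
            founder = int(rng.choice(free))
        founder_yx.append(gt.centers[founder, 1:])
        prev_founder = founder
        members = [founder]
        assigned[founder] = k
        base = np.asarray(spec.nucleus_radii, dtype=float)
        scale = gt.radii[:, 1] / base[1]
        while len(members) < sizes[k]:
            free = np.nonzero(assigned == -1)[0]
            if free.size == 0:
                break
            dists = np.linalg.norm(
                gt.centers[free][:, None, :] - gt.centers[members][None, :, :], axis=2
            ).min(axis=1)
            pick = int(np.argmin(dists))
            nxt = int(free[pick])
            if cs.max_link_gap is not None:
                dn = np.linalg.norm(
                    gt.centers[nxt] / base - gt.centers[members] / base, axis=1
                )
                gaps = (dn - scale[nxt] - scale[members]) * base[1]
                if gaps.min() > cs.max_link_gap:
                    break
            assigned[nxt] = k
            members.append(nxt)

    if cs.twin_pairs:
        # exactly one clone of each recombination pair carries the marker
        marked_clones = np.array(
            [2 * e + int(rng.integers(0, 2)) for e in range(cs.n_founders // 2)]
        )
    else:
        n_marked_clones = int(round(cs.marked_fraction * cs.n_founders))
        marked_clones = rng.choice(cs.n_founders, size=n_marked_clones, replace=False)
    clone_sizes: Dict[int, int] = {}
    for new_id, k in enumerate(np.sort(marked_clones), start=1):
        sel = assigned == k
        clone_id[sel] = new_id
        zygosity[sel] = ZYG_HOM
        clone_sizes[new_id] = int(sel.sum())
    unmarked_clones = set(range(cs.n_founders)) - set(int(k) for k in marked_clones)
    for k in unmarked_clones:
        zygosity[assigned == k] = ZYG_UNMARKED
    return GroundTruth(
        centers=gt.centers,
        radii=gt.radii,
        clone_id=clone_id,
        zygosity=zygosity,
        clone_sizes=clone_sizes,
        clones_assigned=True,
    )


def _paint_ellipsoids(
    canvas: np.ndarray, centers: np.ndarray, radii: np.ndarray, levels: np.ndarray
) -> None:
    nz, ny, nx = canvas.shape
    for (cz, cy, cx), (az, ay, ax_), level in zip(centers, radii, levels):
        z0, z1 = max(0, int(np.floor(cz - az))), min(nz, int(np.ceil(cz + az)) + 1)
        y0, y1 = max(0, int(np.floor(cy - ay))), min(ny, int(np.ceil(cy + ay)) + 1)
        x0, x1 = max(0, int(np.floor(cx - ax_))), min(nx, int(np.ceil(cx + ax_)) + 1)
        zz = (np.arange(z0, z1) - cz) / az
        yy = (np.arange(y0, y1) - cy) / ay
        xx = (np.arange(x0, x1) - cx) / ax_
        inside = (
            zz[:, None, None] ** 2 + yy[None, :, None] ** 2 + xx[None, None, :] ** 2
            <= 1.0
        )
        region = canvas[z0:z1, y0:y1, x0:x1]
        region[inside] = level


def regional_field(
    shape_yx: Tuple[int, int],
    amplitude: Tuple[float, float],
    correlation_px: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Smooth multiplicative intensity field over the (y, x) plane.

    Uniform noise is Gaussian-smoothed at half the correlation length and
    then histogram-equalized onto the amplitude interval, so the field is
    smooth in space yet covers the full stated range (a min/max rescale
    would concentrate values mid-range and leave global thresholds nearly
    sufficient)."""
    lo, hi = amplitude
    if hi == lo:
        return np.full(shape_yx, float(lo))
    noise = rng.random(shape_yx)
    smooth = ndi.gaussian_filter(noise, sigma=correlation_px / 2.0, mode="reflect")
    ranks = np.argsort(np.argsort(smooth.ravel())).reshape(shape_yx)
    u = ranks / max(ranks.size - 1, 1)
    return lo + (hi - lo) * u


def render(
    gt: GroundTruth,
    spec: SceneSpec,
    channel: str = "dapi",
    rng: Optional[np.random.Generator] = None,
) -> VolumeImage:
    """Render one channel of the scene to a quantized intensity stack."""
    if channel not in CHANNELS:
        raise ValueError(f"unknown channel {channel!r}; expected one of {CHANNELS}")
    if channel != "dapi" and not gt.clones_assigned:
        raise ValueError("assign_clones must run before rendering marker/twin channels")
    rng = rng if rng is not None else np.random.default_rng([spec.seed, _CHANNEL_STREAM[channel]])

    idx = gt.channel_indices(channel)
    if channel == "dapi":
        levels = np.full(idx.size, spec.intensity.base)
    elif channel == "marker":
        levels = np.full(idx.size, spec.intensity.base)
    else:
        zs = spec.zygosity_spec
        levels = np.where(
            gt.zygosity[idx] == ZYG_HOM,
            zs.het_level * zs.hom_multiplier,
            zs.het_level,
        )
    canvas = np.zeros(spec.shape, dtype=np.float64)
    _paint_ellipsoids(canvas, gt.centers[idx], gt.radii[idx], levels)
    canvas += spec.intensity.background
    if channel == "twin":
        # regional variation in staining/illumination scales every photon
        # collected from the tissue, background autofluorescence included
        zs = spec.zygosity_spec
        field = regional_field(
            spec.shape[1:], zs.field_amplitude, zs.field_correlation_px, rng
        )
        canvas *= field[None, :, :]
    if spec.psf_sigma > 0:
        canvas = ndi.gaussian_filter(canvas, sigma=spec.psf_sigma)
    if spec.noise.enabled:
        alpha = spec.noise.photons_per_unit
        canvas = rng.poisson(canvas * alpha).astype(np.float64) / alpha
        canvas += rng.normal(0.0, spec.noise.read_noise_sd, size=canvas.shape)
    max_value = (1 << spec.bit_depth) - 1
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
    data = np.clip(np.rint(canvas), 0, max_value).astype(dtype)
    return VolumeImage(
        data=data,
        spacing=spec.spacing,
        bit_depth=spec.bit_depth,
        name=f"synthetic:{channel}",
    )


def preset_scenes() -> Dict[str, SceneSpec]:
    """Documented scene presets.

    ``dense_disc``
        ~800 nuclei in a 60x300x300 stack (0.3 µm voxels), the density of
        a 100x100 µm epithelial patch holding ~800 cells; the counting
        validation workhorse.
    ``sparse_clones``
        A smaller stack with six marked clones of 3-12 cells in an
        unmarked background, for clone segmentation and per-clone counts
        (including sub-5-cell clones that must be flagged discarded).
    ``twin_spot_hard``
        Heavy twin-spot induction (36 recombinant clones of 10-16 cells,
        half marked) under a strong regional field spanning 0.5-1.5x, the
        condition where bright heterozygous nuclei outshine dim homozygous
        ones and global thresholding fails.
    """
    return {
        "dense_disc": SceneSpec(
            shape=(60, 300, 300),
            n_nuclei=800,
            clone_spec=CloneSpec(n_founders=0),
        ),
        "sparse_clones": SceneSpec(
            shape=(48, 256, 256),
            n_nuclei=580,
            clone_spec=CloneSpec(
                n_founders=6,
                cells_per_clone=(3, 12),
                marked_fraction=1.0,
                founder_min_separation=85.0,
                max_link_gap=6.0,
            ),
        ),
        "twin_spot_hard": SceneSpec(
            shape=(60, 300, 300),
            n_nuclei=800,
            clone_spec=CloneSpec(
                n_founders=50,
                cells_per_clone=(5, 9),
                twin_pairs=True,
                founder_min_separation=55.0,
            ),
            zygosity_spec=ZygositySpec(
                het_level=70.0,
                hom_multiplier=2.0,
                field_amplitude=(0.5, 1.5),
                field_correlation_px=80.0,
            ),
        ),
    }


def simulate_scene(
    spec: Union[SceneSpec, str],
    seed: Optional[int] = None,
    channels: Iterable[str] = CHANNELS,
) -> Tuple[GroundTruth, Dict[str, VolumeImage]]:
    """Place, assign and render a full scene deterministically.

    Independent random streams are derived from the seed for placement,
    clone assignment and each channel, so rendering a subset of channels
    does not change the others."""
    if isinstance(spec, str):
        presets = preset_scenes()
        if spec not in presets:
            raise KeyError(f"unknown preset {spec!r}; options: {sorted(presets)}")
        spec = presets[spec]
    if seed is not None:
        spec = dataclasses.replace(spec, seed=int(seed))
    gt = place_nuclei(spec, np.random.default_rng([spec.seed, 0]))
    gt = assign_clones(gt, spec, np.random.default_rng([spec.seed, 1]))
    images = {
        ch: render(gt, spec, ch, np.random.default_rng([spec.seed, _CHANNEL_STREAM[ch]]))
        for ch in channels
    }
    return gt, images
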