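"""Synthetic layered-retina A-scan phantoms, M-scans, and hand-tremor trajectories.

The generator emulates what a common-path OCT distal sensor sees looking into
a retina from the vitreous: a stack of retinal layers with distinct mean
backscatter, fully developed speckle (unit-mean exponential intensity noise),
exponential depth attenuation, Gaussian axial blur from the coherence
gate/PSF, and an additive detector noise floor.  Depth pixel 0 is the fiber
end (top of the image); depth increases with index; the axial pixel size is
2.7 um by default.

Eight classes are used, in fixed anatomical order along depth:
vitreous humor (VH), ganglion cell layer (GCL), inner plexiform layer (IPL),
merged inner nuclear/outer plexiform (INL-OPL), merged outer nuclear/external
limiting membrane (ONL-ELM), photoreceptor layers (PR), choroid (CH), and the
region below the retina.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "LAYER_NAMES",
    "BOUNDARY_NAMES",
    "N_CLASSES",
    "PhantomSpec",
    "AScan",
    "LabelMask",
    "MScan",
    "TremorTrajectory",
    "make_ascan",
    "make_mscan",
    "make_tremor",
    "sample_thicknesses",
    "boundaries_from_thicknesses",
    "render_ascan",
]

LAYER_NAMES = ("VH", "GCL", "IPL", "INL-OPL", "ONL-ELM", "PR", "CH", "below-retina")
N_CLASSES = len(LAYER_NAMES)

#: The seven class transitions, top to bottom.  Index b separates class b
#: from class b+1; boundary 0 is VH/GCL (the retinal surface), boundary 5 is
#: PR/CH (the subretinal-injection guidance target).
BOUNDARY_NAMES = tuple(
    f"{LAYER_NAMES[i]}/{LAYER_NAMES[i + 1]}" for i in range(N_CLASSES - 1)
)

# Interior layers that have a finite thickness (VH and below-retina extend to
# the window edges).
_THICK_LAYERS = LAYER_NAMES[1:7]


@dataclass
class PhantomSpec:
    """Geometry, optics and noise parameters of the synthetic retina.

    Layer thicknesses and reflectivity contrasts are configurable defaults
    chosen to look like a healthy large-mammal retina; they are not
    calibrated against any particular dataset.
    """

    pixel_size_um: float = 2.7
    raw_length_px: int = 1024
    #: mean geometric thickness per interior layer, um (GCL..CH order)
    layer_thickness_um: dict = field(
        default_factory=lambda: {
            "GCL": 60.0,
            "IPL": 70.0,
            "INL-OPL": 80.0,
            "ONL-ELM": 120.0,
            "PR": 80.0,
            "CH": 250.0,
        }
    )
    #: per-layer thickness jitter SD, um (one value applied to all layers)
    thickness_jitter_um: float = 5.0
    #: relative mean backscatter per class (VH..below-retina order); bright
    #: plexiform/photoreceptor bands alternating with dark nuclear bands
    layer_reflectivity: dict = field(
        default_factory=lambda: {
            "VH": 0.02,
            "GCL": 0.60,
            "IPL": 0.25,
            "INL-OPL": 0.55,
            "ONL-ELM": 0.10,
            "PR": 1.00,
            "CH": 0.45,
            "below-retina": 0.04,
        }
    )
    #: mild single-pass attenuation so deep layers stay distinguishable from
    #: mid-retina bands of similar intrinsic backscatter
    attenuation_per_um: float = 0.0005
    #: axial PSF sigma; ~1.9 px FWHM matches a ~5 um axial resolution at
    #: 2.7 um/px (1060 nm center, 100 nm sweep bandwidth)
    psf_sigma_px: float = 0.8
    speckle: bool = True
    detector_noise_sd: float = 0.01
    #: distance from the fiber end (pixel 0) to the VH/GCL boundary, um
    surface_depth_um: float = 750.0

    def validate(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.raw_length_px <= 0:
            raise ValueError("raw_length_px must be positive")
        for name in _THICK_LAYERS:
            if self.layer_thickness_um[name] <= 0:
                raise ValueError(f"thickness of {name} must be strictly positive")
        for name in LAYER_NAMES:
            if self.layer_reflectivity[name] < 0:
                raise ValueError(f"reflectivity of {name} must be non-negative")
        total = self.surface_depth_um + sum(
            self.layer_thickness_um[n] for n in _THICK_LAYERS
        )
        if total >= self.raw_length_px * self.pixel_size_um:
            raise ValueError(
                "surface_depth_um + total retina thickness must fit in the scan window"
            )

    @property
    def mean_thicknesses(self) -> np.ndarray:
        return np.array([self.layer_thickness_um[n] for n in _THICK_LAYERS])

    @property
    def reflectivities(self) -> np.ndarray:
        return np.array([self.layer_reflectivity[n] for n in LAYER_NAMES])

    def to_dict(self) -> dict:
        return {
            "pixel_size_um": self.pixel_size_um,
            "raw_length_px": self.raw_length_px,
            "layer_thickness_um": dict(self.layer_thickness_um),
            "thickness_jitter_um": self.thickness_jitter_um,
            "layer_reflectivity": dict(self.layer_reflectivity),
            "attenuation_per_um": self.attenuation_per_um,
            "psf_sigma_px": self.psf_sigma_px,
            "speckle": self.speckle,
            "detector_noise_sd": self.detector_noise_sd,
            "surface_depth_um": self.surface_depth_um,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        return cls(**d)


@dataclass
class AScan:
    """One axial intensity profile.  ``depth0_px`` is the offset of sample 0
    in uncropped coordinates, so raw index = depth0_px + local index."""

    intensity: np.ndarray
    pixel_size_um: float = 2.7
    depth0_px: int = 0

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity must be finite")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be non-negative")

    def __len__(self) -> int:
        return len(self.intensity)


@dataclass
class LabelMask:
    """Per-pixel class labels over an A-scan.

    For generator ground truth, ``boundaries_px`` carries the exact
    fractional boundary positions (7 values, BOUNDARY_NAMES order, raw
    coordinates); predicted masks have ``boundaries_px=None``.
    """

    labels: np.ndarray
    boundaries_px: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= N_CLASSES):
            raise ValueError(f"labels must lie in 0..{N_CLASSES - 1}")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class TremorTrajectory:
    """Axial hand position vs. time: slow drift + physiological tremor + jitter."""

    t: np.ndarray
    z_um: np.ndarray
    components: dict
    seed: int

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.float64)
        self.z_um = np.asarray(self.z_um, dtype=np.float64)
        if len(self.t) != len(self.z_um):
            raise ValueError("t and z_um must have the same length")

    @property
    def dt_s(self) -> float:
        return float(self.t[1] - self.t[0]) if len(self.t) > 1 else 0.0

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class MScan:
    """Time-ordered stack of A-scans: ``intensity[depth, column]``."""

    intensity: np.ndarray  # (raw_length_px, n_columns)
    labels: np.ndarray  # (raw_length_px, n_columns)
    boundaries_px: np.ndarray  # (7, n_columns), fractional raw coordinates
    pixel_size_um: float
    trajectory: TremorTrajectory | None = None

    @property
    def n_columns(self) -> int:
        return self.intensity.shape[1]

    def column(self, j: int) -> tuple[AScan, LabelMask]:
        return (
            AScan(self.intensity[:, j], self.pixel_size_um),
            LabelMask(self.labels[:, j], self.boundaries_px[:, j]),
        )


def sample_thicknesses(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Draw per-layer thicknesses (um) around the spec means, clipped to stay
    strictly positive."""
    mean = spec.mean_thicknesses
    jitter = rng.normal(0.0, spec.thickness_jitter_um, size=mean.shape)
    return np.maximum(mean + jitter, 1.0)


def boundaries_from_thicknesses(
    spec: PhantomSpec, thicknesses_um: np.ndarray, shift_um: float
) -> np.ndarray:
    """Fractional boundary positions in pixels (raw coordinates)."""
    depths_um = spec.surface_depth_um + shift_um + np.concatenate(
        [[0.0], np.cumsum(thicknesses_um)]
    )
    return depths_um / spec.pixel_size_um


def _labels_from_boundaries(boundaries_px: np.ndarray, length: int) -> np.ndarray:
    # pixel i belongs to the class whose span contains index i
    return np.searchsorted(boundaries_px, np.arange(length), side="right")


def render_ascan(
    spec: PhantomSpec, boundaries_px: np.ndarray, rng: np.random.Generator
) -> tuple[AScan, LabelMask]:
    """Render one A-scan for a fixed retina geometry.

    The signal chain is: piecewise-constant reflectivity profile ->
    multiplicative unit-mean exponential speckle -> exponential depth
    attenuation -> Gaussian axial PSF blur -> additive detector noise
    (clipped at zero).  The label mask is the noise-free class of every pixel.
    """
    n = spec.raw_length_px
    if boundaries_px[0] < 0 or boundaries_px[-1] > n:
        raise ValueError(
            f"retina outside the scan window: boundaries span "
            f"[{boundaries_px[0]:.1f}, {boundaries_px[-1]:.1f}] px of {n}"
        )
    labels = _labels_from_boundaries(boundaries_px, n)
    profile = spec.reflectivities[labels]
    if spec.speckle:
        profile = profile * rng.exponential(1.0, size=n)
    if spec.attenuation_per_um > 0:
        depth_um = np.arange(n) * spec.pixel_size_um
        profile = profile * np.exp(-spec.attenuation_per_um * depth_um)
    if spec.psf_sigma_px > 0:
        profile = gaussian_filter1d(profile, spec.psf_sigma_px, mode="nearest")
    if spec.detector_noise_sd > 0:
        profile = profile + rng.normal(0.0, spec.detector_noise_sd, size=n)
    profile = np.maximum(profile, 0.0)
    return (
        AScan(profile, spec.pixel_size_um),
        LabelMask(labels, np.asarray(boundaries_px, dtype=np.float64)),
    )


def render_averaged_ascan(
    spec: PhantomSpec,
    boundaries_px: np.ndarray,
    rng: np.random.Generator,
    n_average: int = 8,
) -> tuple[AScan, LabelMask]:
    """Mean of ``n_average`` independent-speckle renders of one geometry,
    emulating the block averaging a swept-source acquisition chain performs
    to raise SNR before segmentation (speckle CV drops by ~1/sqrt(n))."""
    first, mask = render_ascan(spec, boundaries_px, rng)
    if n_average <= 1:
        return first, mask
    acc = first.intensity.copy()
    for _ in range(n_average - 1):
        a, _ = render_ascan(spec, boundaries_px, rng)
        acc += a.intensity
    return AScan(acc / n_average, spec.pixel_size_um), mask


def make_ascan(
    spec: PhantomSpec, shift_um: float = 0.0, seed: int = 0, n_average: int = 1
) -> tuple[AScan, LabelMask]:
    """Generate one synthetic A-scan plus its ground-truth mask.

    ``shift_um > 0`` moves the whole retina deeper into the scan (away from
    the fiber end).  ``n_average`` renders that many independent-speckle
    realizations of the same geometry and averages them, as the acquisition
    chain does with blocks of sequential A-scans.  Identical
    ``(spec, shift_um, seed, n_average)`` give bit-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    thicknesses = sample_thicknesses(spec, rng)
    boundaries = boundaries_from_thicknesses(spec, thicknesses, shift_um)
    try:
        return render_averaged_ascan(spec, boundaries, rng, n_average)
    except ValueError as e:
        raise ValueError(f"shift_um={shift_um}: {e}") from e


def make_mscan(
    spec: PhantomSpec,
    trajectory: TremorTrajectory,
    n_columns: int,
    seed: int = 0,
    n_average: int = 1,
) -> MScan:
    """Generate an M-scan: one retina geometry, column j shifted by
    ``trajectory.z_um[j]``, with independent speckle per column.
    ``n_average > 1`` makes each column a block-averaged scan."""
    spec.validate()
    if n_columns > len(trajectory):
        raise ValueError(
            f"n_columns={n_columns} exceeds trajectory length {len(trajectory)}"
        )
    n = spec.raw_length_px
    intensity = np.empty((n, n_columns))
    labels = np.empty((n, n_columns), dtype=np.int64)
    bounds = np.empty((N_CLASSES - 1, n_columns))
    ss = np.random.SeedSequence(seed)
    rng0 = np.random.default_rng(ss)
    thicknesses = sample_thicknesses(spec, rng0)
    col_rngs = [np.random.default_rng(s) for s in ss.spawn(n_columns)]
    for j in range(n_columns):
        b = boundaries_from_thicknesses(spec, thicknesses, trajectory.z_um[j])
        try:
            ascan, mask = render_averaged_ascan(spec, b, col_rngs[j], n_average)
        except ValueError as e:
            raise ValueError(f"column {j}: {e}") from e
        intensity[:, j] = ascan.intensity
        labels[:, j] = mask.labels
        bounds[:, j] = b
    return MScan(intensity, labels, bounds, spec.pixel_size_um, trajectory)


def make_tremor(
    components: dict | None = None,
    duration_s: float = 5.0,
    dt_s: float = 0.003,
    seed: int = 0,
) -> TremorTrajectory:
    """Synthetic axial hand motion.

    ``components`` keys (all optional, defaults below): ``drift_amplitude_um``
    (peak-to-peak, default 300), ``drift_freq_hz`` (0.2),
    ``tremor_pp_um`` (peak-to-peak physiological tremor, 50),
    ``tremor_freq_hz`` (10), ``jitter_sd_um`` (white jitter SD, 0).

    The defaults follow the motion regime of handheld ophthalmic tools:
    slow drift of hundreds of micrometers plus ~10 Hz tremor of tens of
    micrometers, whose mean axial speed is about 1 um/ms.  The mean is
    removed so z_um oscillates around zero.
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    defaults = {
        "drift_amplitude_um": 300.0,
        "drift_freq_hz": 0.2,
        "tremor_pp_um": 50.0,
        "tremor_freq_hz": 10.0,
        "jitter_sd_um": 0.0,
    }
    comp = dict(defaults)
    if components:
        unknown = set(components) - set(defaults)
        if unknown:
            raise ValueError(f"unknown tremor components: {sorted(unknown)}")
        comp.update(components)
    rng = np.random.default_rng(seed)
    n = int(round(duration_s / dt_s))
    t = np.arange(n) * dt_s
    phase_d, phase_t = rng.uniform(0, 2 * np.pi, size=2)
    z = np.zeros(n)
    if comp["drift_amplitude_um"] > 0:
        z += (comp["drift_amplitude_um"] / 2.0) * np.sin(
            2 * np.pi * comp["drift_freq_hz"] * t + phase_d
        )
    if comp["tremor_pp_um"] > 0:
        z += (comp["tremor_pp_um"] / 2.0) * np.sin(
            2 * np.pi * comp["tremor_freq_hz"] * t + phase_t
        )
    if comp["jitter_sd_um"] > 0:
        z += rng.normal(0.0, comp["jitter_sd_um"], size=n)
    if n:
        z -= z.mean()
    return TremorTrajectory(t, z, comp, seed)
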