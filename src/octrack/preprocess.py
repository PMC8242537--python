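"""Signal conditioning between the raw A-scan and the segmentation network.

The pipeline mirrors a swept-source OCT signal chain after the FFT stage:
background subtraction, averaging of 8 sequential A-scans to raise SNR, and a
crop from the raw 1024-pixel depth range to the 320 pixels around the retina.
The crop location is found by cross-correlating each A-scan against a
surface-aligned mean template, so the displacement maximizing the correlation
marks the retinal surface.  Training data are augmented by random axial
translations of up to +/-15 pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import AScan, LabelMask, PhantomSpec, make_ascan

__all__ = [
    "CropTemplate",
    "average_block",
    "subtract_background",
    "build_template",
    "crop_ascan",
    "augment",
    "make_dataset",
    "save_dataset",
    "load_dataset",
    "CROP_LENGTH",
]

CROP_LENGTH = 320


@dataclass
class CropTemplate:
    """Mean A-scan with the retinal surface aligned to index 0, background
    thresholded to zero."""

    template: np.ndarray
    surface_px: int = 0
    crop_length_px: int = CROP_LENGTH

    def __post_init__(self) -> None:
        self.template = np.asarray(self.template, dtype=np.float64)


def average_block(ascans: list[AScan], n: int = 8) -> AScan:
    """Elementwise mean of ``n`` sequential A-scans (SNR improvement)."""
    if len(ascans) != n:
        raise ValueError(f"expected {n} A-scans, got {len(ascans)}")
    lengths = {len(a) for a in ascans}
    if len(lengths) != 1:
        raise ValueError(f"A-scans have mismatched lengths: {sorted(lengths)}")
    mean = np.mean([a.intensity for a in ascans], axis=0)
    first = ascans[0]
    return AScan(mean, first.pixel_size_um, first.depth0_px)


def subtract_background(ascan: AScan, background: AScan) -> AScan:
    """Background-subtract, clamping negative residuals to zero."""
    if len(ascan) != len(background):
        raise ValueError(
            f"length mismatch: ascan {len(ascan)} vs background {len(background)}"
        )
    out = np.maximum(ascan.intensity - background.intensity, 0.0)
    return AScan(out, ascan.pixel_size_um, ascan.depth0_px)


def build_template(
    ascans: list[AScan],
    surface_px: list[int] | np.ndarray,
    threshold_fraction: float = 0.05,
) -> CropTemplate:
    """Average surface-aligned A-scans into a crop template.

    Each scan is rolled so its known surface index lands on position 0, the
    rolled scans are averaged, and values below ``threshold_fraction`` of the
    template maximum are zeroed to suppress background noise.
    """
    if len(ascans) == 0:
        raise ValueError("cannot build a template from an empty dataset")
    if len(surface_px) != len(ascans):
        raise ValueError("need one surface index per A-scan")
    aligned = np.stack(
        [np.roll(a.intensity, -int(s)) for a, s in zip(ascans, surface_px)]
    )
    template = aligned.mean(axis=0)
    if threshold_fraction > 0:
        template = np.where(
            template >= threshold_fraction * template.max(), template, 0.0
        )
    return CropTemplate(template, surface_px=0)


def _xcorr_best_lag(signal: np.ndarray, template: np.ndarray) -> int:
    """Integer lag maximizing the circular cross-correlation of ``signal``
    against ``template``; ties broken toward the smallest lag."""
    n = len(signal)
    corr = np.fft.irfft(np.fft.rfft(signal) * np.conj(np.fft.rfft(template)), n=n)
    # ties -> smallest displacement: argmax returns the first index, which is
    # the smallest non-negative lag
    return int(np.argmax(np.round(corr, 9)))


def crop_ascan(
    ascan: AScan, template: CropTemplate, margin_px: int = 40
) -> tuple[AScan, int, bool]:
    """Crop the 320-pixel retinal window out of a raw A-scan.

    The displacement ``d*`` maximizing the cross-correlation with the
    surface-aligned template estimates the retinal surface position; the crop
    window starts ``margin_px`` above it, clamped into the valid range.
    Returns ``(cropped, d_star, clamped)``.
    """
    L = template.crop_length_px
    if len(ascan) < L:
        raise ValueError(f"raw A-scan shorter than crop length {L}")
    if not np.any(ascan.intensity > 0):
        raise ValueError("no retinal signal: A-scan is identically zero")
    d_star = _xcorr_best_lag(ascan.intensity, template.template)
    start = d_star - margin_px
    clamped = False
    hi = len(ascan) - L
    if start < 0 or start > hi:
        start = min(max(start, 0), hi)
        clamped = True
    out = AScan(
        ascan.intensity[start : start + L],
        ascan.pixel_size_um,
        ascan.depth0_px + start,
    )
    return out, d_star, clamped


def crop_mask(mask: LabelMask, start: int, length: int = CROP_LENGTH) -> LabelMask:
    """Crop a label mask to the same window as its A-scan, shifting the
    ground-truth boundary coordinates into raw coordinates unchanged."""
    return LabelMask(mask.labels[start : start + length], mask.boundaries_px)


def augment(
    ascan: AScan,
    mask: LabelMask,
    n_extra: int = 5,
    max_shift_px: int = 15,
    seed: int = 0,
) -> list[tuple[AScan, LabelMask]]:
    """Translation augmentation: the original plus ``n_extra`` copies rolled
    by uniform integer shifts in [-max_shift_px, max_shift_px].

    Vacated pixels are filled by edge replication (intensity) and edge class
    (labels), avoiding spurious class transitions at the window edges.
    Ground-truth boundary positions are shifted along with the data.
    """
    rng = np.random.default_rng(seed)
    out = [(ascan, mask)]
    for _ in range(n_extra):
        s = int(rng.integers(-max_shift_px, max_shift_px + 1))
        out.append(_shift_pair(ascan, mask, s))
    return out


def _shift_pair(ascan: AScan, mask: LabelMask, s: int) -> tuple[AScan, LabelMask]:
    inten = _shift_edge(ascan.intensity, s)
    labels = _shift_edge(mask.labels, s)
    bounds = None if mask.boundaries_px is None else mask.boundaries_px + s
    return (
        AScan(inten, ascan.pixel_size_um, ascan.depth0_px - s),
        LabelMask(labels, bounds),
    )


def _shift_edge(x: np.ndarray, s: int) -> np.ndarray:
    """Roll by ``s`` (positive = toward larger depth) with edge replication."""
    if s == 0:
        return x.copy()
    out = np.roll(x, s)
    if s > 0:
        out[:s] = x[0]
    else:
        out[s:] = x[-1]
    return out


# ---------------------------------------------------------------------------
# dataset assembly


def make_dataset(
    spec: PhantomSpec,
    n_eyes: int = 11,
    n_per_eye: int = 100,
    n_train_eyes: int = 9,
    shift_range_um: float = 150.0,
    eye_thickness_sd_um: float = 15.0,
    n_extra_augment: int = 5,
    margin_px: int = 40,
    n_average: int = 8,
    seed: int = 0,
):
    """Generate a cropped, augmented segmentation dataset from phantoms.

    Each "eye" is a retina with its own per-layer mean thicknesses (drawn
    around the spec means with SD ``eye_thickness_sd_um``); each A-scan of an
    eye adds per-scan thickness jitter and a random axial offset up to
    ``shift_range_um`` either way, emulating the probe standing at varying
    distances from the retina.  Every sample is a block average of
    ``n_average`` speckle realizations, as the acquisition chain produces.
    The split is by eye identity so no retina geometry leaks from train to
    test.  Only the train split is augmented (``n_extra_augment`` translated
    copies per scan).

    Returns ``(train, test, template)`` where train/test are
    :class:`~octrack.train_eval.ArrayDataset` and ``template`` is the
    cross-correlation crop template built from the raw training scans.
    """
    from .train_eval import ArrayDataset  # avoid a module cycle

    spec.validate()
    if not (0 < n_train_eyes < n_eyes):
        raise ValueError("need at least one train eye and one test eye")
    rng = np.random.default_rng(seed)
    raw, masks, eye_of = [], [], []
    for e in range(n_eyes):
        eye_spec = _perturbed_spec(spec, rng, eye_thickness_sd_um)
        for _ in range(n_per_eye):
            shift = rng.uniform(-shift_range_um, shift_range_um)
            a, m = make_ascan(eye_spec, shift, int(rng.integers(2**31)), n_average)
            raw.append(a)
            masks.append(m)
            eye_of.append(e)
    eye_of = np.array(eye_of)
    train_sel = eye_of < n_train_eyes
    surfaces = [int(round(m.boundaries_px[0])) for m in masks]
    template = build_template(
        [a for a, s in zip(raw, train_sel) if s],
        [s for s, t in zip(surfaces, train_sel) if t],
    )

    def _crop_split(sel: np.ndarray, augment_n: int, aug_seed: int):
        arng = np.random.default_rng(aug_seed)
        X, Y, Bb, E = [], [], [], []
        for i in np.flatnonzero(sel):
            cropped, _, _ = crop_ascan(raw[i], template, margin_px)
            start = cropped.depth0_px
            local_mask = LabelMask(
                masks[i].labels[start : start + CROP_LENGTH],
                masks[i].boundaries_px - start,
            )
            pairs = [(cropped, local_mask)]
            if augment_n:
                pairs = augment(
                    cropped, local_mask, augment_n,
                    seed=int(arng.integers(2**31)),
                )
            for a2, m2 in pairs:
                X.append(a2.intensity)
                Y.append(m2.labels)
                Bb.append(m2.boundaries_px)
                E.append(eye_of[i])
        return ArrayDataset(
            np.array(X, dtype=np.float32),
            np.array(Y, dtype=np.int64),
            np.array(Bb),
            np.array(E),
            spec.pixel_size_um,
        )

    train = _crop_split(train_sel, n_extra_augment, seed + 1)
    test = _crop_split(~train_sel, 0, seed + 2)
    return train, test, template


def _perturbed_spec(
    spec: PhantomSpec, rng: np.random.Generator, sd_um: float
) -> PhantomSpec:
    d = spec.to_dict()
    d["layer_thickness_um"] = {
        k: max(v + rng.normal(0.0, sd_um), 5.0)
        for k, v in d["layer_thickness_um"].items()
    }
    return PhantomSpec.from_dict(d)


def save_dataset(dataset, path) -> None:
    """Write an ArrayDataset as one NPZ shard (intensity float32, labels
    uint8, boundaries, eye ids, pixel size)."""
    np.savez_compressed(
        path,
        intensity=dataset.intensity.astype(np.float32),
        labels=dataset.labels.astype(np.uint8),
        boundaries_px=(
            np.zeros((len(dataset), 0)) if dataset.boundaries_px is None
            else dataset.boundaries_px
        ),
        eye=(np.zeros(len(dataset), dtype=np.int64) if dataset.eye is None
             else dataset.eye),
        pixel_size_um=dataset.pixel_size_um,
    )


def load_dataset(path):
    from .train_eval import ArrayDataset

    with np.load(path) as d:
        b = d["boundaries_px"]
        return ArrayDataset(
            d["intensity"],
            d["labels"].astype(np.int64),
            None if b.size == 0 else b,
            d["eye"],
            float(d["pixel_size_um"]),
        )
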