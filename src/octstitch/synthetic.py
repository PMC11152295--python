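"""Synthetic OCT-like B-scan generator for the three AMD staging classes.

Real retinal B-scans show a stack of bright, gently curved horizontal
bands (the retinal layers) over a dark vitreous/choroid background,
corrupted by multiplicative speckle.  The three phenotypes differ in the
morphology of the outer retina:

* **normal** — smooth bands, no deformation;
* **drusen** — several localized dome-shaped elevations of the lowest
  bright band (the RPE), the dry-AMD hallmark;
* **CNV** — one large irregular hyperreflective lesion beneath the bands
  with an adjacent dark fluid pocket, the wet-AMD hallmark.

The generator renders these features geometrically and applies
gamma-distributed multiplicative speckle last.  It deliberately does not
model A-scan optics, shadowing or vendor post-processing; its purpose is
to provide label-faithful, strongly separable images so that training and
stitching machinery can be exercised end-to-end without any download.
"""
from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

CLASS_NAMES = ("normal", "drusen", "cnv")
NORMAL, DRUSEN, CNV = 0, 1, 2


@dataclass
class SyntheticOCTParams:
    """Rendering parameters; lengths are fractions of the image side."""
    side: int = 224
    n_bands: int = 4
    band_thickness: tuple[float, float] = (0.02, 0.05)
    band_gap: tuple[float, float] = (0.01, 0.03)
    band_intensity: tuple[float, float] = (0.55, 0.9)
    curvature_amplitude: float = 0.06       # vertical bow of the band stack
    center_band: tuple[float, float] = (0.35, 0.55)  # top of stack
    drusen_count: tuple[int, int] = (4, 7)
    drusen_height: tuple[float, float] = (0.10, 0.16)
    drusen_width: tuple[float, float] = (0.02, 0.045)
    drusen_fill: tuple[float, float] = (0.30, 0.44)  # sub-RPE deposit level
    cnv_diameter: tuple[float, float] = (0.22, 0.32)
    cnv_intensity: float = 0.85
    fluid_darkness: float = 0.05
    speckle_variance: float = 0.02
    background: float = 0.06
    samples_per_patient: int = 8

    def validate(self) -> None:
        if self.speckle_variance < 0:
            raise ValueError("speckle variance must be >= 0")
        for name in ("band_thickness", "band_gap", "band_intensity",
                     "drusen_height", "drusen_width", "cnv_diameter"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} range must be non-degenerate")


@dataclass
class LabeledImage:
    pixels: np.ndarray          # (side, side) float in [0, 1]
    label: int
    sample_id: str
    patient_id: str

    @property
    def label_name(self) -> str:
        return CLASS_NAMES[self.label]


def _band_baseline(side: int, params: SyntheticOCTParams,
                   rng: np.random.Generator) -> np.ndarray:
    """Smooth curved vertical position of the band-stack top, per column."""
    x = np.linspace(-1.0, 1.0, side)
    center = rng.uniform(*params.center_band)
    amp = params.curvature_amplitude * rng.uniform(0.5, 1.0)
    phase = rng.uniform(-0.3, 0.3)
    return side * (center + amp * (x + phase) ** 2)


def generate_image(label: int, params: SyntheticOCTParams | None = None,
                   rng: np.random.Generator | int | None = None,
                   sample_id: str = "s0", patient_id: str = "p0"
                   ) -> LabeledImage:
    """Render one labelled B-scan. Deterministic given the rng state."""
    if label not in (NORMAL, DRUSEN, CNV):
        raise ValueError(f"invalid label {label}")
    params = params or SyntheticOCTParams()
    params.validate()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    side = params.side
    img = np.full((side, side), params.background, dtype=np.float64)
    cols = np.arange(side)
    rows = np.arange(side)[:, None]

    top = _band_baseline(side, params, rng)
    # stack bands downward from `top`
    y = top.copy()
    boundaries = []
    for b in range(params.n_bands):
        thick = side * rng.uniform(*params.band_thickness)
        gap = side * rng.uniform(*params.band_gap)
        intensity = rng.uniform(*params.band_intensity)
        lower = y + thick
        boundaries.append((y.copy(), lower.copy(), intensity))
        y = lower + gap
    bottom_edge = boundaries[-1][1].copy()

    drusen_deposit = None
    if label == DRUSEN:
        # dome-shaped elevations of the lowest band
        n_bumps = int(rng.integers(params.drusen_count[0],
                                   params.drusen_count[1] + 1))
        # one bump per horizontal slot so domes stay distinct
        slots = np.linspace(0.1, 0.9, n_bumps + 1)
        for k in range(n_bumps):
            cx = rng.uniform(slots[k] + 0.02, slots[k + 1] - 0.02) * side
            # floors keep domes resolvable at small renderings
            h = max(side * rng.uniform(*params.drusen_height), 2.5)
            w = max(side * rng.uniform(*params.drusen_width), 1.2)
            bump = h * np.exp(-0.5 * ((cols - cx) / w) ** 2)
            lo, hi, inten = boundaries[-1]
            # the whole band domes upward, leaving dark space beneath
            boundaries[-1] = (lo - bump, hi - bump, inten)
        # vacated space under the domes holds medium-reflective deposit
        drusen_deposit = (boundaries[-1][1], bottom_edge,
                          rng.uniform(*params.drusen_fill))

    if drusen_deposit is not None:
        lo, hi, inten = drusen_deposit
        mask = (rows >= lo[None, :]) & (rows < hi[None, :])
        img[mask] = inten
    for lo, hi, inten in boundaries:
        mask = (rows >= lo[None, :]) & (rows < hi[None, :])
        img[mask] = inten

    if label == CNV:
        # one large irregular bright lesion + adjacent dark fluid pocket
        d = side * rng.uniform(*params.cnv_diameter)
        cx = rng.uniform(0.25, 0.75) * side
        cy = float(np.interp(cx, cols, bottom_edge)) + 0.35 * d
        ry, rx = d * 0.5 * rng.uniform(0.7, 1.0), d * 0.5
        wobble = 1.0 + 0.15 * np.sin(
            np.arctan2(rows - cy, cols[None, :] - cx) * 3
            + rng.uniform(0, 2 * np.pi))
        dist = (((cols[None, :] - cx) / rx) ** 2
                + ((rows - cy) / ry) ** 2) * wobble
        img[dist <= 1.0] = params.cnv_intensity
        # dark fluid pocket nested against the lesion (dark-in-bright)
        fx = cx + rng.choice([-1.0, 1.0]) * rx * 0.35
        fy = cy + ry * 0.15
        fdist = (((cols[None, :] - fx) / (rx * 0.45)) ** 2
                 + ((rows - fy) / (ry * 0.4)) ** 2)
        img[fdist <= 1.0] = params.fluid_darkness

    if params.speckle_variance > 0:
        # multiplicative gamma speckle, mean 1, variance as configured
        shape = 1.0 / params.speckle_variance
        noise = rng.gamma(shape, 1.0 / shape, size=img.shape)
        img = img * noise
    img = np.clip(img, 0.0, 1.0)
    return LabeledImage(img.astype(np.float32), int(label), sample_id,
                        patient_id)


def class_counts(n: int, proportions: tuple[float, ...]) -> list[int]:
    """Largest-remainder apportionment of n samples to class proportions."""
    props = np.asarray(proportions, dtype=float)
    if props.min() < 0 or abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must be non-negative and sum to 1")
    if n < len(props):
        raise ValueError("need at least one sample per class")
    raw = props * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts))
    for i in range(remainder):
        counts[order[i]] += 1
    return counts.tolist()


# Normal-majority imbalance of the kind seen in clinical OCT archives.
DEFAULT_PROPORTIONS = (0.55, 0.25, 0.20)


def generate_samples(n: int,
                     proportions: tuple[float, ...] = DEFAULT_PROPORTIONS,
                     params: SyntheticOCTParams | None = None,
                     seed: int = 0) -> list[LabeledImage]:
    """Generate n labelled images in memory (no files)."""
    params = params or SyntheticOCTParams()
    rng = np.random.default_rng(seed)
    counts = class_counts(n, proportions)
    samples: list[LabeledImage] = []
    sid = 0
    for label, count in enumerate(counts):
        for i in range(count):
            patient = f"p{label}_{i // params.samples_per_patient:04d}"
            samples.append(generate_image(
                label, params, rng, sample_id=f"s{sid:05d}",
                patient_id=patient))
            sid += 1
    order = np.random.default_rng(seed + 1).permutation(len(samples))
    return [samples[i] for i in order]


def generate_dataset(n: int,
                     proportions: tuple[float, ...] = DEFAULT_PROPORTIONS,
                     params: SyntheticOCTParams | None = None,
                     seed: int = 0,
                     out_dir: str | os.PathLike | None = None
                     ) -> pd.DataFrame:
    """Generate a class-per-subdirectory image dataset plus manifest CSV.

    Returns the manifest (sample_id, patient_id, label, label_name, path).
    When out_dir is None nothing is written and `path` is empty.
    """
    from PIL import Image

    samples = generate_samples(n, proportions, params, seed)
    rows = []
    for s in samples:
        path = ""
        if out_dir is not None:
            cls_dir = os.path.join(out_dir, s.label_name)
            os.makedirs(cls_dir, exist_ok=True)
            path = os.path.join(cls_dir, f"{s.sample_id}.png")
            Image.fromarray(
                (s.pixels * 255).round().astype(np.uint8), mode="L"
            ).save(path)
        rows.append({"sample_id": s.sample_id, "patient_id": s.patient_id,
                     "label": s.label, "label_name": s.label_name,
                     "path": path})
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest


def to_arrays(samples: list[LabeledImage]
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack samples into (images (n,H,W), labels (n,), patient_ids (n,))."""
    X = np.stack([s.pixels for s in samples])
    y = np.array([s.label for s in samples], dtype=np.int64)
    groups = np.array([s.patient_id for s in samples])
    return X, y, groups
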