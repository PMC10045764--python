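"""Synthetic multi-NEX rectal DWI phantom.

Generates 2-D slice volumes with the statistical structure a guided DWI
denoiser is trained on: mono-exponential signal decay across b-values,
per-excitation Rician magnitude noise, and repetition (NEX) averaging.  The
default geometry is a pelvis-like ellipse containing a rectum-like annulus
with two concentric wall layers of distinct signal, so that wall delineation
after denoising is measurable.

The forward signal model per pixel is

    S(b) = S0 * exp(-b * ADC)

with S0 in arbitrary units and ADC in mm^2/s.  Each excitation observes the
magnitude of the clean signal plus complex Gaussian noise (Rician noise;
Rayleigh where the signal is zero); averaging N excitations lowers the noise
standard deviation by 1/sqrt(N) in the high-SNR regime.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from .containers import DWISeries, RepetitionStack

__all__ = [
    "Tissue",
    "PhantomSpec",
    "GroundTruth",
    "make_phantom",
    "simulate_clean",
    "simulate_repetitions",
    "gas_warp",
    "make_dataset",
]


@dataclass
class Tissue:
    """One tissue compartment: a geometric primitive with uniform S0 and ADC.

    ``geometry`` kinds:

    - ``{"kind": "full"}`` — covers the whole matrix
    - ``{"kind": "ellipse", "center": (r, c), "radii": (a, b)}``
    - ``{"kind": "disk", "center": (r, c), "radius": r}``
    - ``{"kind": "annulus", "center": (r, c), "r_in": a, "r_out": b}``

    Tissues are painted in list order; later tissues overwrite earlier ones.
    """

    label: int
    s0: float
    adc: float
    geometry: dict
    name: str = ""

    def __post_init__(self) -> None:
        # normalize coordinate tuples to lists so YAML round trips are stable
        self.geometry = {
            k: list(v) if isinstance(v, tuple) else v for k, v in self.geometry.items()
        }


def _default_tissues(m: int) -> list[Tissue]:
    c = (m / 2.0, m / 2.0)
    return [
        Tissue(1, 0.75, 1.4e-3, {"kind": "ellipse", "center": c, "radii": (0.42 * m, 0.46 * m)}, "pelvis"),
        Tissue(2, 0.15, 2.5e-3, {"kind": "disk", "center": c, "radius": 8.0}, "lumen"),
        Tissue(3, 1.00, 1.0e-3, {"kind": "annulus", "center": c, "r_in": 8.0, "r_out": 14.0}, "inner_wall"),
        Tissue(4, 0.80, 1.3e-3, {"kind": "annulus", "center": c, "r_in": 14.0, "r_out": 20.0}, "outer_wall"),
    ]


@dataclass
class PhantomSpec:
    """Full description of one simulated acquisition.

    noise_sigma is the per-excitation standard deviation of each complex
    channel, in the same arbitrary units as S0.  The default (0.06) puts the
    NEX=1 rectal-wall SNR at roughly 5-7 for the default geometry, i.e. a
    visibly noisy single excitation.
    """

    matrix_size: int = 140
    n_slices: int = 4
    tissues: list[Tissue] = field(default_factory=list)
    rectum_roi: tuple[int, ...] = (3, 4)
    noise_sigma: float = 0.06
    b_low: float = 50.0
    b_high: float = 800.0
    nex_low: int = 4
    nex_high_reference: int = 16
    # amplitude (pixels) of the optional per-excitation gas-distortion warp
    # of the rectal region; 0 disables it
    gas_warp_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.tissues:
            self.tissues = _default_tissues(self.matrix_size)
        self.rectum_roi = tuple(self.rectum_roi)
        self.validate()

    def validate(self) -> None:
        if self.matrix_size < 64:
            raise ValueError(f"matrix_size must be >= 64, got {self.matrix_size}")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if self.b_high <= self.b_low:
            raise ValueError(f"b_high ({self.b_high}) must exceed b_low ({self.b_low})")
        labels = [t.label for t in self.tissues]
        if len(labels) != len(set(labels)):
            raise ValueError(f"tissue labels must be distinct, got {labels}")
        for t in self.tissues:
            if t.adc < 0:
                raise ValueError(f"tissue {t.label}: adc must be >= 0, got {t.adc}")
        if self.nex_low < 1 or self.nex_high_reference < 1:
            raise ValueError("nex counts must be >= 1")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tissues"] = [dataclasses.asdict(t) for t in self.tissues]
        d["rectum_roi"] = list(self.rectum_roi)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        tissues = [t if isinstance(t, Tissue) else Tissue(**t) for t in d.pop("tissues", [])]
        return cls(tissues=tissues, **d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class GroundTruth:
    """Simulation truth: per-pixel S0, ADC, tissue label, and the rectum mask.

    All maps are ``(n_slices, H, W)``; ``roi_mask`` flags the rectal-wall
    annulus (the labels listed in ``PhantomSpec.rectum_roi``).
    """

    s0_map: np.ndarray
    adc_map: np.ndarray
    roi_mask: np.ndarray
    label_map: np.ndarray

    def __post_init__(self) -> None:
        shapes = {self.s0_map.shape, self.adc_map.shape, self.roi_mask.shape, self.label_map.shape}
        if len(shapes) != 1:
            raise ValueError("all ground-truth maps must share shape")
        if np.any(self.adc_map < 0):
            raise ValueError("adc_map must be nonnegative everywhere")
        if not self.roi_mask.any():
            raise ValueError("roi_mask is empty")


def _paint(mask_shape: tuple[int, int], geometry: dict, offset=(0.0, 0.0), scale=1.0) -> np.ndarray:
    """Rasterise one geometric primitive to a boolean mask.

    ``offset`` shifts the primitive's center, ``scale`` multiplies its radii —
    used for subject jitter and per-slice size variation.
    """
    h, w = mask_shape
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    kind = geometry["kind"]
    if kind == "full":
        return np.ones(mask_shape, bool)
    cy, cx = geometry["center"]
    cy, cx = cy + offset[0], cx + offset[1]
    if kind == "ellipse":
        a, b = geometry["radii"]
        return ((rr - cy) / (a * scale)) ** 2 + ((cc - cx) / (b * scale)) ** 2 <= 1.0
    r2 = (rr - cy) ** 2 + (cc - cx) ** 2
    if kind == "disk":
        return r2 <= (geometry["radius"] * scale) ** 2
    if kind == "annulus":
        return ((geometry["r_in"] * scale) ** 2 < r2) & (r2 <= (geometry["r_out"] * scale) ** 2)
    raise ValueError(f"unknown geometry kind {kind!r}")


# labels whose geometry follows the rectum (jittered together across subjects)
_RECTUM_GROUP_NAMES = {"lumen", "inner_wall", "outer_wall"}

# per-slice radius scaling of the rectum group: mild, deterministic taper
def _slice_scale(z: int, n_slices: int) -> float:
    if n_slices == 1:
        return 1.0
    return 1.0 + 0.06 * (z - (n_slices - 1) / 2.0) / max(n_slices - 1, 1)


def make_phantom(spec: PhantomSpec, jitter: tuple[float, float] = (0.0, 0.0)) -> GroundTruth:
    """Rasterise a :class:`PhantomSpec` to per-pixel S0 / ADC / label maps.

    ``jitter`` shifts the rectum-group tissues (lumen and wall layers) by the
    given (row, col) offset; :func:`make_dataset` uses it for per-subject
    geometry variation.  Deterministic given (spec, jitter).
    """
    spec.validate()
    m, ns = spec.matrix_size, spec.n_slices
    s0 = np.zeros((ns, m, m))
    adc = np.zeros((ns, m, m))
    labels = np.zeros((ns, m, m), dtype=np.int32)
    for z in range(ns):
        sc = _slice_scale(z, ns)
        for t in spec.tissues:
            in_rectum = t.name in _RECTUM_GROUP_NAMES or t.label in spec.rectum_roi or (
                t.geometry["kind"] in ("disk", "annulus")
            )
            off = jitter if in_rectum else (0.0, 0.0)
            scale = sc if in_rectum else 1.0
            mask = _paint((m, m), t.geometry, offset=off, scale=scale)
            s0[z][mask] = t.s0
            adc[z][mask] = t.adc
            labels[z][mask] = t.label
    roi = np.isin(labels, spec.rectum_roi)
    if not roi.any():
        raise ValueError(f"rectum_roi labels {spec.rectum_roi} produced an empty mask")
    return GroundTruth(s0_map=s0, adc_map=adc, roi_mask=roi, label_map=labels)


def simulate_clean(gt: GroundTruth, b: float) -> np.ndarray:
    """Noise-free signal volume at diffusion weighting ``b`` (s/mm^2).

    Pixel-wise ``S0 * exp(-b * ADC)``, float64.
    """
    if b < 0:
        raise ValueError(f"b must be >= 0, got {b}")
    return gt.s0_map * np.exp(-b * gt.adc_map)


def simulate_repetitions(
    clean: np.ndarray,
    sigma: float,
    nex: int,
    seed: int,
    noise_model: str = "rician",
) -> RepetitionStack:
    """Draw ``nex`` independent noisy excitations of a clean volume.

    Rician model (default): each repetition is ``|clean + g1 + i*g2|`` with g1,
    g2 independent N(0, sigma^2) fields — the standard magnitude-MRI noise
    model.  The ``gaussian`` model returns ``clean + g1`` (no magnitude
    operation), kept for analytic tests where unbiased additive noise is
    needed.  Fully reproducible from ``seed``.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if nex < 1:
        raise ValueError("nex must be >= 1")
    clean = np.asarray(clean, dtype=np.float64)
    rng = np.random.default_rng(seed)
    shape = (nex,) + clean.shape
    if sigma == 0:
        reps = np.broadcast_to(clean, shape).copy()
    elif noise_model == "rician":
        g1 = rng.normal(0.0, sigma, size=shape)
        g2 = rng.normal(0.0, sigma, size=shape)
        reps = np.hypot(clean + g1, g2)
    elif noise_model == "gaussian":
        reps = clean + rng.normal(0.0, sigma, size=shape)
    else:
        raise ValueError(f"unknown noise_model {noise_model!r}")
    # b_value unknown at this level; callers wrap with the right b — store NaN-free 0
    return RepetitionStack(b_value=0.0, repetitions=reps, seed_used=seed)


def gas_warp(image: np.ndarray, amplitude: float, seed: int, center=None, radius: float = 30.0) -> np.ndarray:
    """Smooth random geometric warp of the region around ``center``.

    Emulates the per-excitation distortions produced by gas in the rectum:
    a Gaussian-windowed random displacement field (peak ``amplitude`` pixels)
    remaps the image by bilinear interpolation.  amplitude = 0 returns the
    input unchanged.
    """
    if amplitude == 0:
        return image
    from scipy import ndimage

    img2d = image.ndim == 2
    vol = image[None] if img2d else image
    rng = np.random.default_rng(seed)
    s, h, w = vol.shape
    cy, cx = center if center is not None else (h / 2.0, w / 2.0)
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    window = np.exp(-((rr - cy) ** 2 + (cc - cx) ** 2) / (2 * radius**2))
    out = np.empty_like(vol, dtype=np.float64)
    for z in range(s):
        disp = [ndimage.gaussian_filter(rng.normal(size=(h, w)), sigma=8.0) for _ in range(2)]
        disp = [d / max(np.abs(d).max(), 1e-12) * amplitude * window for d in disp]
        out[z] = ndimage.map_coordinates(vol[z], [rr + disp[0], cc + disp[1]], order=1, mode="nearest")
    return out[0] if img2d else out


def _subject_seeds(seed: int, n_subjects: int) -> list[dict]:
    """Derive independent integer seeds for each subject's jitter and noise."""
    ss = np.random.SeedSequence(seed)
    out = []
    for child in ss.spawn(n_subjects):
        jit, high, low = child.spawn(3)
        out.append(
            {
                "jitter": int(jit.generate_state(1)[0] % (2**31)),
                "high": int(high.generate_state(1)[0] % (2**31)),
                "low": int(low.generate_state(1)[0] % (2**31)),
            }
        )
    return out


def make_dataset(
    spec: PhantomSpec,
    n_subjects: int,
    seed: int,
    noise_model: str = "rician",
    nex_levels: tuple[int, ...] = (1, 2, 4),
) -> list[tuple[DWISeries, GroundTruth]]:
    """Simulate ``n_subjects`` complete multi-NEX acquisitions.

    Per subject: the guide is the average of ``spec.nex_low`` low-b
    excitations; one stack of ``spec.nex_high_reference`` high-b excitations
    is drawn, the noisy NEX=1/2/4 volumes are prefix averages of that stack,
    and the reference is the full average — so comparisons across NEX isolate
    the effect of averaging, exactly as when all NEX images come from a single
    acquisition.  Subject geometry (rectum position) is jittered per subject.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    max_nex = max(nex_levels)
    if max_nex > spec.nex_high_reference:
        raise ValueError("nex_levels exceed the reference repetition count")
    out = []
    for subj, seeds in enumerate(_subject_seeds(seed, n_subjects)):
        jr = np.random.default_rng(seeds["jitter"])
        jitter = tuple(jr.uniform(-4.0, 4.0, size=2))
        gt = make_phantom(spec, jitter=jitter)
        clean_low = simulate_clean(gt, spec.b_low)
        clean_high = simulate_clean(gt, spec.b_high)

        if spec.gas_warp_amplitude > 0:
            # each excitation sees its own distortion of the rectal region
            m = spec.matrix_size
            center = (m / 2.0 + jitter[0], m / 2.0 + jitter[1])
            reps = []
            for k in range(spec.nex_high_reference):
                warped = gas_warp(clean_high, spec.gas_warp_amplitude, seeds["high"] + 7 * k + 1, center=center)
                reps.append(
                    simulate_repetitions(warped, spec.noise_sigma, 1, seeds["high"] + 7 * k, noise_model).repetitions[0]
                )
            high = RepetitionStack(b_value=spec.b_high, repetitions=np.stack(reps), seed_used=seeds["high"])
        else:
            high = simulate_repetitions(
                clean_high, spec.noise_sigma, spec.nex_high_reference, seeds["high"], noise_model
            )
        high.b_value = spec.b_high
        low = simulate_repetitions(clean_low, spec.noise_sigma, spec.nex_low, seeds["low"], noise_model)
        low.b_value = spec.b_low

        guide = low.repetitions.mean(axis=0)
        noisy = {int(n): high.repetitions[:n].mean(axis=0) for n in nex_levels}
        reference = high.repetitions.mean(axis=0)
        series = DWISeries(
            guide=guide.astype(np.float32),
            noisy={n: v.astype(np.float32) for n, v in noisy.items()},
            reference=reference.astype(np.float32),
            subject_id=f"sub-{subj:03d}",
            b_low=spec.b_low,
            b_high=spec.b_high,
        )
        out.append((series, gt))
    return out
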