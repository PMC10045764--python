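"""Image-quality and diffusion quantification metrics.

PSNR and SSIM follow the literal conventions of the guided-denoising study:

- PSNR = 10 * log10(d_max / MSE) with d_max the peak intensity of the image
  under test (note: d_max, not d_max**2 — on unit-normalized images the two
  coincide at d_max = 1).  A standards-conformant variant (d_max**2) is
  available via ``variant="standard"``.
- SSIM is the single *global* product I*C*S of the luminance, contrast and
  structure comparison functions, computed over the whole image (or mask)
  without local windows or the conventional C1/C2/C3 stabilizers; tiny
  ``eps`` terms stabilize the denominators.  The windowed scikit-image SSIM
  is available via ``variant="windowed"`` for cross-checks.

ADC maps use the two-point mono-exponential inversion
``ADC = -(1/db) * ln(s_high / s_low)`` in mm^2/s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.metrics import structural_similarity as _skimage_ssim

__all__ = [
    "psnr",
    "ssim",
    "roi_metrics",
    "ADCMap",
    "adc_map",
    "roi_mean_adc",
    "QualityReport",
    "evaluate_series",
    "dilate_mask",
]


def _flatten(d: np.ndarray, r: np.ndarray, mask: np.ndarray | None):
    d = np.asarray(d, dtype=np.float64)
    r = np.asarray(r, dtype=np.float64)
    if d.shape != r.shape:
        raise ValueError(f"shape mismatch: {d.shape} vs {r.shape}")
    if mask is not None:
        mask = np.asarray(mask, bool)
        if mask.shape != d.shape:
            raise ValueError("mask shape must match the images")
        if not mask.any():
            raise ValueError("mask is empty")
        return d[mask], r[mask]
    return d.ravel(), r.ravel()


def psnr(d: np.ndarray, r: np.ndarray, mask: np.ndarray | None = None, variant: str = "literal") -> float:
    """Peak signal-to-noise ratio of image ``d`` against reference ``r`` (dB).

    Returns ``inf`` when the images are identical over the evaluated region
    (zero MSE).  ``variant="literal"`` uses 10*log10(d_max/MSE);
    ``variant="standard"`` uses d_max**2.
    """
    dv, rv = _flatten(d, r, mask)
    mse = np.mean((dv - rv) ** 2)
    if mse == 0:
        return float("inf")
    dmax = float(np.max(dv))
    if variant == "literal":
        return float(10.0 * np.log10(dmax / mse))
    if variant == "standard":
        return float(10.0 * np.log10(dmax**2 / mse))
    raise ValueError(f"unknown PSNR variant {variant!r}")


def ssim(
    d: np.ndarray,
    r: np.ndarray,
    mask: np.ndarray | None = None,
    eps: float = 1e-12,
    variant: str = "global",
) -> float:
    """Structural similarity of ``d`` against ``r``.

    Global variant: SSIM = I * C * S with

        I = 2*mu_d*mu_r / (mu_d^2 + mu_r^2)
        C = 2*sd_d*sd_r / (sd_d^2 + sd_r^2)
        S = cov(d, r) / (sd_d * sd_r)

    over all evaluated pixels, each denominator stabilized by ``eps``.
    Degenerate inputs (zero variance with eps=0) raise.  The windowed variant
    delegates to scikit-image's standard implementation.
    """
    if variant == "windowed":
        dv = np.asarray(d, np.float64)
        rv = np.asarray(r, np.float64)
        rng = max(dv.max() - dv.min(), rv.max() - rv.min(), 1e-12)
        return float(_skimage_ssim(dv, rv, data_range=rng))
    if variant != "global":
        raise ValueError(f"unknown SSIM variant {variant!r}")
    dv, rv = _flatten(d, r, mask)
    mu_d, mu_r = dv.mean(), rv.mean()
    sd_d, sd_r = dv.std(), rv.std()
    cov = np.mean((dv - mu_d) * (rv - mu_r))
    if eps == 0 and (sd_d == 0 or sd_r == 0 or (mu_d == 0 and mu_r == 0)):
        raise ValueError("degenerate input (zero variance or zero means) with eps=0")
    lum = 2 * mu_d * mu_r / (mu_d**2 + mu_r**2 + eps)
    con = 2 * sd_d * sd_r / (sd_d**2 + sd_r**2 + eps)
    struct = cov / (sd_d * sd_r + eps)
    return float(lum * con * struct)


def roi_metrics(d: np.ndarray, r: np.ndarray, mask: np.ndarray) -> dict:
    """PSNR and SSIM restricted to masked pixels (d_max taken over the mask)."""
    return {"psnr": psnr(d, r, mask=mask), "ssim": ssim(d, r, mask=mask)}


def dilate_mask(mask: np.ndarray, radius: int = 3) -> np.ndarray:
    """Dilate a boolean mask by ``radius`` pixels (per slice for 3-D masks)."""
    if radius <= 0:
        return mask.astype(bool)
    if mask.ndim == 3:
        return np.stack([dilate_mask(m, radius) for m in mask])
    st = np.hypot(*np.mgrid[-radius : radius + 1, -radius : radius + 1]) <= radius
    return ndimage.binary_dilation(mask, structure=st)


# -- ADC -------------------------------------------------------------------


@dataclass
class ADCMap:
    """Pixel-wise apparent diffusion coefficient (mm^2/s).

    ``validity_mask`` flags pixels where both signals were safely positive;
    negative ADC values (noise pushing s_high above s_low) are retained and
    flagged in ``negative_mask``, never clamped.
    """

    adc: np.ndarray
    delta_b: float
    validity_mask: np.ndarray

    @property
    def negative_mask(self) -> np.ndarray:
        return self.validity_mask & (self.adc < 0)


def adc_map(s_low: np.ndarray, s_high: np.ndarray, b_low: float, b_high: float) -> ADCMap:
    """Two-point mono-exponential ADC: ``-(1/db) * ln(s_high/s_low)``.

    Pixels with s_low or s_high at or below 1e-6 of max(s_low) are excluded
    via the validity mask (log of a non-positive ratio is ill-posed).
    """
    s_low = np.asarray(s_low, dtype=np.float64)
    s_high = np.asarray(s_high, dtype=np.float64)
    if s_low.shape != s_high.shape:
        raise ValueError(f"shape mismatch: {s_low.shape} vs {s_high.shape}")
    db = b_high - b_low
    if db <= 0:
        raise ValueError(f"b_high ({b_high}) must exceed b_low ({b_low})")
    eps = 1e-6 * float(np.max(s_low))
    valid = (s_low > eps) & (s_high > eps)
    adc = np.zeros_like(s_low)
    np.divide(s_high, s_low, out=adc, where=valid)
    np.log(adc, out=adc, where=valid)
    adc[valid] *= -1.0 / db
    adc[~valid] = np.nan
    return ADCMap(adc=adc, delta_b=db, validity_mask=valid)


def roi_mean_adc(adc: ADCMap, mask: np.ndarray) -> float:
    """Mean ADC over valid masked pixels (mm^2/s)."""
    sel = np.asarray(mask, bool) & adc.validity_mask
    if not sel.any():
        raise ValueError("mask has no valid ADC pixels")
    return float(adc.adc[sel].mean())


# -- series-level evaluation ----------------------------------------------


@dataclass
class QualityReport:
    """Per-slice and aggregate quality table for one evaluated series.

    ``table`` has one row per (image kind, NEX, slice) with global and ROI
    PSNR/SSIM; ``summary`` aggregates mean and std across slices.
    """

    table: pd.DataFrame
    summary: pd.DataFrame
    adc: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def __str__(self) -> str:
        return f"QualityReport\n{self.summary.to_string()}\n\nROI-mean ADC (1e-3 mm^2/s)\n{self.adc.to_string()}"


def evaluate_series(
    series,
    denoised: dict[int, np.ndarray],
    roi_mask: np.ndarray,
    nex_levels: tuple[int, ...] | None = None,
    variant: str = "literal",
) -> QualityReport:
    """Score noisy and denoised volumes against the NEX=16 reference.

    Computes per-slice global and ROI-restricted PSNR/SSIM for each NEX
    level, aggregates mean +- std across slices, and reports ROI-mean ADC per
    volume (using the guide as the low-b signal).  ``denoised`` maps NEX ->
    denoised volume in the same units as the series.
    """
    nex_levels = tuple(nex_levels or series.nex_levels)
    ref = series.reference
    rows = []
    adc_rows = []
    roi3 = np.broadcast_to(roi_mask, ref.shape) if roi_mask.ndim == ref.ndim else None
    if roi3 is None:
        roi3 = roi_mask
    delta = (series.b_low, series.b_high)

    def _adc_entry(kind, n, vol):
        amap = adc_map(series.guide * series.norm_scale_guide, vol * series.norm_scale_highb, *delta)
        adc_rows.append(
            {"image": kind, "nex": n, "roi_mean_adc_1e-3": 1e3 * roi_mean_adc(amap, roi3)}
        )

    for n in nex_levels:
        for kind, vol in (("noisy", series.noisy[n]), ("denoised", denoised.get(n))):
            if vol is None:
                continue
            for z in range(ref.shape[0]):
                rows.append(
                    {
                        "image": kind,
                        "nex": n,
                        "slice": z,
                        "psnr_global": psnr(vol[z], ref[z], variant=variant),
                        "ssim_global": ssim(vol[z], ref[z]),
                        "psnr_roi": psnr(vol[z], ref[z], mask=roi3[z]),
                        "ssim_roi": ssim(vol[z], ref[z], mask=roi3[z]),
                    }
                )
            _adc_entry(kind, n, vol)
    ref_amap = adc_map(series.guide * series.norm_scale_guide, ref * series.norm_scale_highb, *delta)
    adc_rows.append({"image": "reference", "nex": 16, "roi_mean_adc_1e-3": 1e3 * roi_mean_adc(ref_amap, roi3)})

    table = pd.DataFrame(rows)
    summary = (
        table.groupby(["image", "nex"])[["psnr_global", "ssim_global", "psnr_roi", "ssim_roi"]]
        .agg(["mean", "std"])
        .reset_index()
    )
    return QualityReport(table=table, summary=summary, adc=pd.DataFrame(adc_rows))
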