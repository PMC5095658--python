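"""Xenon-based sensitivity normalization.

The 134Xe+ ion is always present as an impurity of the argon plasma and
its signal is spatially uniform, so its per-image mean tracks the
instrument's sensitivity state.  The procedure: build the 134Xe intensity
histogram of each image, fit a Gaussian (ion counts follow counting
statistics, approximately Gaussian at the means involved), take the
fitted mean as the image's *normalization value*, and define the
*normalization factor* of an image as the ratio of its normalization
value to that of an arbitrarily chosen reference image (whose factor is
therefore exactly 1).

Normalization is applied to region-level mean values after segmentation
— never to pixels — by dividing by the factor, so higher-sensitivity
images are scaled down.  Uncertainty is propagated to first order in the
ratio: relative variances of the measured mean, the image's Xe mean and
the reference's Xe mean add.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import DataError, FitError
from .raw_io import MultichannelImage
from .region_quant import QuantRecord

MIN_PIXELS = 100
MIN_OCCUPIED_BINS = 5


@dataclass
class Histogram:
    bin_edges: np.ndarray      # (n_bins + 1,)
    frequencies: np.ndarray    # (n_bins,) pixel counts

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def n_pixels(self) -> int:
        return int(self.frequencies.sum())

    def sample_mean_sd(self) -> tuple[float, float]:
        w = self.frequencies.astype(float)
        if w.sum() == 0:
            raise FitError("empty histogram")
        c = self.centers
        mean = float(np.average(c, weights=w))
        var = float(np.average((c - mean) ** 2, weights=w))
        return mean, math.sqrt(var)


@dataclass
class XeFit:
    """Gaussian fit of a per-image Xe histogram.

    ``mean`` is the normalization value.  ``mean_stderr`` is the standard
    error of the normalization value, taken as ``sigma / sqrt(n_pixels)``
    (the uncertainty of a mean estimated from n independent pixels).
    ``fallback_used`` marks fits that fell back to the sample mean/SD.
    """

    histogram: Histogram
    mean: float
    sigma: float
    amplitude: float
    fit_converged: bool
    fallback_used: bool
    mean_stderr: float
    n_pixels: int
    image_id: Optional[str] = None


@dataclass
class NormalizationFactor:
    image_id: Optional[str]
    factor: float
    reference_id: Optional[str]
    xe_mean: float
    xe_mean_sd: float


# ---------------------------------------------------------------------------

def xe_histogram(image: Union[MultichannelImage, np.ndarray],
                 channel: str = "134Xe",
                 bin_width: Optional[float] = None) -> Histogram:
    """Intensity histogram of the Xe channel over all acquired pixels.

    Integer-valued data get unit bins centred on the integers; otherwise
    the given ``bin_width`` or the Freedman-Diaconis rule is used.
    """
    if isinstance(image, MultichannelImage):
        vals = np.asarray(image.channel(channel), dtype=float).ravel()
    else:
        vals = np.asarray(image, dtype=float).ravel()
    vals = vals[np.isfinite(vals)]
    if vals.size < MIN_PIXELS:
        raise DataError(f"need >= {MIN_PIXELS} pixels for a Xe histogram, "
                        f"got {vals.size}")
    integer_like = np.allclose(vals, np.round(vals))
    if bin_width is not None:
        lo = math.floor(vals.min() / bin_width) * bin_width
        hi = math.ceil(vals.max() / bin_width) * bin_width + bin_width
        edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    elif integer_like:
        lo, hi = int(round(vals.min())), int(round(vals.max()))
        edges = np.arange(lo - 0.5, hi + 1.5, 1.0)
    else:
        edges = np.histogram_bin_edges(vals, bins="fd")
    freqs, edges = np.histogram(vals, bins=edges)
    return Histogram(np.asarray(edges, float), np.asarray(freqs, np.int64))


def _gauss(x, amplitude, mu, sigma):
    return amplitude * np.exp(-((x - mu) ** 2) / (2.0 * sigma ** 2))


def fit_gaussian(histogram: Histogram, image_id: Optional[str] = None) -> XeFit:
    """Least-squares Gaussian fit to histogram bin centers and frequencies.

    Initialized at the sample mean/SD and the peak frequency.  With fewer
    than five occupied bins, or on non-convergence or a non-positive
    fitted mean, the sample mean/SD are used instead and the fit is
    flagged ``fallback_used``.
    """
    n = histogram.n_pixels
    if n == 0:
        raise FitError("cannot fit an empty histogram")
    s_mean, s_sd = histogram.sample_mean_sd()
    occupied = int(np.count_nonzero(histogram.frequencies))
    converged = False
    fallback = True
    mean, sigma, amp = s_mean, s_sd, float(histogram.frequencies.max())
    if occupied >= MIN_OCCUPIED_BINS:
        x = histogram.centers
        y = histogram.frequencies.astype(float)
        p0 = (float(y.max()), s_mean, max(s_sd, 1e-6))
        try:
            popt, _ = curve_fit(_gauss, x, y, p0=p0, maxfev=10000)
            if popt[1] > 0 and abs(popt[2]) > 0 and np.all(np.isfinite(popt)):
                amp, mean, sigma = float(popt[0]), float(popt[1]), abs(float(popt[2]))
                converged = True
                fallback = False
        except RuntimeError:
            pass
    if sigma <= 0:
        sigma = max(s_sd, 1e-12)
    stderr = sigma / math.sqrt(n)
    return XeFit(histogram, mean, sigma, amp, converged, fallback, stderr, n,
                 image_id=image_id)


def fit_xe(image: MultichannelImage, channel: str = "134Xe",
           bin_width: Optional[float] = None,
           image_id: Optional[str] = None) -> XeFit:
    """Histogram + Gaussian fit of an image's Xe channel in one call."""
    if image_id is None:
        image_id = image.provenance.get("image_id")
    return fit_gaussian(xe_histogram(image, channel, bin_width), image_id=image_id)


def normalization_factor(fit: XeFit, reference: XeFit) -> NormalizationFactor:
    """Factor = (image Xe mean) / (reference Xe mean); 1 for the reference itself."""
    if fit.mean <= 0 or reference.mean <= 0:
        raise DataError("normalization requires positive Xe means")
    return NormalizationFactor(
        image_id=fit.image_id,
        factor=fit.mean / reference.mean,
        reference_id=reference.image_id,
        xe_mean=fit.mean,
        xe_mean_sd=fit.mean_stderr,
    )


def normalize_quant(record: QuantRecord, nf: NormalizationFactor,
                    reference: XeFit) -> QuantRecord:
    """Divide a region mean by the image's normalization factor.

    The normalized spread carries three first-order relative-variance
    terms: the measured values, the image's Xe normalization value and
    the reference's.  The same rule propagates both the pixel-level SD
    and the standard error of the mean.
    """
    if record.normalized:
        raise DataError(f"record {record.image_id}/{record.region}/{record.channel} "
                        "is already normalized")
    if record.mean == 0 and record.sd > 0:
        raise DataError("cannot propagate a relative error on a zero mean")
    m = record.mean / nf.factor
    rel_xe2 = ((nf.xe_mean_sd / nf.xe_mean) ** 2
               + (reference.mean_stderr / reference.mean) ** 2)
    if record.mean != 0:
        sd = abs(m) * math.sqrt((record.sd / record.mean) ** 2 + rel_xe2)
        se = abs(m) * math.sqrt((record.mean_se / record.mean) ** 2 + rel_xe2)
    else:
        sd = se = 0.0
    out = replace(record, mean=m, sd=sd, normalized=True)
    out.mean_se = se
    return out


# ---------------------------------------------------------------------------
# batch helpers
# ---------------------------------------------------------------------------

def fit_batch(images: Sequence[MultichannelImage],
              image_ids: Optional[Sequence[str]] = None,
              channel: str = "134Xe",
              bin_width: Optional[float] = None) -> list[XeFit]:
    fits = []
    for i, img in enumerate(images):
        iid = image_ids[i] if image_ids is not None else \
            img.provenance.get("image_id", f"image{i}")
        fits.append(fit_xe(img, channel, bin_width, image_id=iid))
    return fits


def factors_for_batch(fits: Sequence[XeFit],
                      reference_id: Optional[str] = None) -> list[NormalizationFactor]:
    """Factors for a batch against one reference (default: first image)."""
    if not fits:
        raise DataError("no Xe fits supplied")
    if reference_id is None:
        ref = fits[0]
    else:
        matches = [f for f in fits if f.image_id == reference_id]
        if not matches:
            raise DataError(f"reference image {reference_id!r} not in batch")
        ref = matches[0]
    return [normalization_factor(f, ref) for f in fits]


def factors_to_frame(factors: Sequence[NormalizationFactor]) -> pd.DataFrame:
    return pd.DataFrame([{
        "image_id": f.image_id, "xe_mean": f.xe_mean, "xe_sd": f.xe_mean_sd,
        "factor": f.factor, "reference_id": f.reference_id,
    } for f in factors])
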