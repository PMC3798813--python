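"""Region-of-interest intensity statistics and distribution comparison.

Mean pixel intensity per frame and the average 256-bin intensity histogram
(mean number of pixels at each intensity over frames) summarise a trial;
two trials are compared with a test on the per-frame means (paired when
frame counts match) and a Kolmogorov-Smirnov test on the mean histograms
treated as empirical distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats as sps
from scipy.special import kolmogorov

from .containers import ImageSequence
from .errors import ValidationError

__all__ = ["IntensityReport", "roi_intensity", "compare_intensity", "histogram_ks"]


@dataclass
class IntensityReport:
    """Intensity summary of one rectangular ROI over a trial."""

    roi: tuple[int, int, int, int]  # top, left, height, width (px)
    per_frame_mean: np.ndarray
    trial_mean: float
    mean_histogram: np.ndarray  # (256,) mean pixel counts per intensity

    @property
    def roi_area_px(self) -> int:
        return self.roi[2] * self.roi[3]


def roi_intensity(seq: ImageSequence, roi: tuple[int, int, int, int]) -> IntensityReport:
    """Per-frame ROI mean intensity and the trial-average histogram.

    The histogram counts of every frame sum to the ROI pixel count, as does
    their average.
    """
    top, left, h, w = roi
    T, H, W = seq.frames.shape
    if top < 0 or left < 0 or top + h > H or left + w > W or h < 1 or w < 1:
        raise ValidationError("ROI must lie fully inside the frames")
    patch = seq.frames[:, top : top + h, left : left + w]
    means = patch.reshape(T, -1).mean(axis=1)
    hist = np.zeros(256)
    for f in range(T):
        hist += np.bincount(patch[f].ravel(), minlength=256)
    hist /= T
    return IntensityReport(
        roi=(top, left, h, w),
        per_frame_mean=means,
        trial_mean=float(means.mean()),
        mean_histogram=hist,
    )


def histogram_ks(hist_a: np.ndarray, hist_b: np.ndarray) -> tuple[float, float]:
    """Two-sample KS on binned data: (statistic, asymptotic p).

    Histograms are normalised to unit mass and compared through their
    discrete empirical CDFs; the statistic is the maximum CDF gap. The
    p-value uses the Kolmogorov asymptotic with effective sample size
    ``sqrt(na nb / (na + nb))`` from the raw counts; with heavy binning the
    statistic lattice makes this mildly conservative.
    """
    a = np.asarray(hist_a, dtype=float)
    b = np.asarray(hist_b, dtype=float)
    if a.shape != b.shape or a.size == 0:
        raise ValidationError("histograms must be non-empty and equal length")
    na, nb = a.sum(), b.sum()
    if na <= 0 or nb <= 0:
        raise ValidationError("histograms must have positive mass")
    cdf_a = np.cumsum(a) / na
    cdf_b = np.cumsum(b) / nb
    d = float(np.max(np.abs(cdf_a - cdf_b)))
    en = np.sqrt(na * nb / (na + nb))
    p = float(kolmogorov(en * d)) if d > 0 else 1.0
    return d, min(max(p, 0.0), 1.0)


def compare_intensity(report_a: IntensityReport, report_b: IntensityReport) -> dict:
    """Compare two intensity reports.

    Returns mean difference of trial means, a t-test (paired when frame
    counts match, Welch otherwise) plus Wilcoxon signed-rank when paired,
    and the KS statistic/p on the mean histograms.
    """
    if report_a.mean_histogram.shape != report_b.mean_histogram.shape:
        raise ValidationError("reports use different histogram bin counts")
    out: dict = {
        "mean_difference": report_a.trial_mean - report_b.trial_mean,
    }
    a, b = report_a.per_frame_mean, report_b.per_frame_mean
    if a.size == b.size and a.size >= 3:
        d = a - b
        if np.all(d == d[0]):
            out["t"], out["t_p"] = (0.0, 1.0) if d[0] == 0 else (np.nan, np.nan)
        else:
            t, p = sps.ttest_rel(a, b)
            out["t"], out["t_p"] = float(t), float(p)
            if np.any(d != 0):
                w, wp = sps.wilcoxon(a, b)
                out["wilcoxon"], out["wilcoxon_p"] = float(w), float(wp)
    elif a.size >= 3 and b.size >= 3:
        t, p = sps.ttest_ind(a, b, equal_var=False)
        out["t"], out["t_p"] = float(t), float(p)
    ks, ks_p = histogram_ks(report_a.mean_histogram, report_b.mean_histogram)
    out["ks_statistic"], out["ks_p"] = ks, ks_p
    return out
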