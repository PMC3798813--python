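"""Sparse feature tracking with probe-grid interpolation for twitch kinematics.

The muscle-motion chain follows the classic Kanade-Lucas-Tomasi recipe:

1. detect corners (minimum eigenvalue of the local gradient structure
   tensor), greedily selected best-first with a spacing constraint;
2. track each corner frame-to-frame by iterative local brightness-constancy
   least squares, coarse-to-fine over an image pyramid, dropping features
   that fail to converge or leave the frame and replenishing the pool;
3. carry an 8 x 10 grid of measurement probes through the sequence: the
   outer probe rows ride the aponeuroses, the inner six span the fascicle
   region, and each probe advects by the Delaunay/barycentric interpolation
   of the displacements of same-region features (inverse-distance weighting
   of the three nearest features outside the hull);
4. reduce probe trajectories to muscle length (deep-to-superficial fascicle
   probe distance) and thickness (inter-aponeurosis distance) series.

Series from two recordings are aligned by cross-correlation and compared
with Pearson correlation and model II (reduced major axis) regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from scipy.spatial import Delaunay, QhullError, cKDTree
from skimage.feature import corner_shi_tomasi, peak_local_max

from .containers import ImageSequence, Segmentation
from .errors import AnalysisError, ValidationError
from . import stats as _stats

__all__ = [
    "FeatureSet",
    "ProbeGrid",
    "TwitchSeries",
    "AlignResult",
    "detect_features",
    "track_features",
    "interpolate_probe_displacement",
    "track_probes",
    "twitch_series",
    "align_and_compare",
    "track_twitch",
]

REGION_LABELS = ("superficial_apo", "deep_apo", "fascicle")


@dataclass
class FeatureSet:
    """Features alive in one frame.

    ``displacement`` is each feature's motion from the previous frame
    (NaN for features detected in this frame); ``age`` counts frames the
    feature has persisted.
    """

    positions: np.ndarray  # (N, 2) (row, col), sub-pixel
    scores: np.ndarray  # (N,)
    ages: np.ndarray  # (N,) int
    labels: np.ndarray  # (N,) str
    displacement: np.ndarray  # (N, 2), NaN for fresh features

    @property
    def n(self) -> int:
        return int(self.positions.shape[0])


def _label_points(points: np.ndarray, seg: Optional[Segmentation], band_px: float = 4.0) -> np.ndarray:
    labels = np.full(points.shape[0], "other", dtype=object)
    if seg is None or points.size == 0:
        return labels
    sup = seg.depth_at(points[:, 1], "superficial")
    deep = seg.depth_at(points[:, 1], "deep")
    lo, hi = seg.lateral_extent
    in_lat = (points[:, 1] >= lo) & (points[:, 1] <= hi)
    labels[in_lat & (np.abs(points[:, 0] - sup) <= band_px)] = "superficial_apo"
    labels[in_lat & (np.abs(points[:, 0] - deep) <= band_px)] = "deep_apo"
    fasc = (
        in_lat
        & (points[:, 0] > sup + band_px)
        & (points[:, 0] < deep - band_px)
    )
    labels[fasc] = "fascicle"
    return labels


def detect_features(
    frame: np.ndarray,
    segmentation: Optional[Segmentation] = None,
    max_n: int = 300,
    min_score: Optional[float] = None,
    min_spacing_px: int = 6,
    exclude: Optional[np.ndarray] = None,
    apo_min_features: int = 12,
) -> FeatureSet:
    """Corner detection: local maxima of the minimum-eigenvalue measure.

    Peaks are selected best-first; ``min_spacing_px`` enforces pairwise
    separation. ``exclude`` (existing feature positions) suppresses peaks
    within the spacing radius so replenishment avoids duplicates. When a
    segmentation is given, each aponeurosis band is topped up to
    ``apo_min_features`` corners from within the band (the dense fascicle
    speckle would otherwise monopolise the best-first selection, leaving the
    boundary regions untrackable). A constant frame yields an empty set.
    """
    img = np.asarray(frame, dtype=float)
    if img.std() == 0:
        return _empty_featureset()
    response = corner_shi_tomasi(img, sigma=1.5)
    if exclude is not None and len(exclude):
        rr, cc = np.mgrid[: img.shape[0], : img.shape[1]]
        for p in np.atleast_2d(exclude):
            mask = (rr - p[0]) ** 2 + (cc - p[1]) ** 2 < min_spacing_px**2
            response[mask] = 0.0
    thresh = min_score if min_score is not None else 0.02 * float(response.max())
    if thresh <= 0:
        return _empty_featureset()
    peaks = peak_local_max(
        response,
        min_distance=min_spacing_px,
        threshold_abs=thresh,
        num_peaks=max_n,
        exclude_border=min_spacing_px,
    )
    if peaks.size == 0:
        return _empty_featureset()
    pos = peaks.astype(float)
    labels = _label_points(pos, segmentation)

    if segmentation is not None and apo_min_features > 0:
        rr, cc = np.mgrid[: img.shape[0], : img.shape[1]]
        ex_labels = (
            _label_points(np.atleast_2d(exclude), segmentation)
            if exclude is not None and len(exclude)
            else np.empty(0, dtype=object)
        )
        for region in ("superficial_apo", "deep_apo"):
            present = int(np.sum(labels == region)) + int(np.sum(ex_labels == region))
            deficit = apo_min_features - present
            if deficit <= 0:
                continue
            depth = segmentation.depth_at(cc[0], region.split("_")[0])
            band = np.abs(rr - depth[None, :]) <= 4.0
            masked = np.where(band, response, 0.0)
            for p in pos:
                masked[
                    (rr - p[0]) ** 2 + (cc - p[1]) ** 2 < min_spacing_px**2
                ] = 0.0
            extra = peak_local_max(
                masked,
                min_distance=min_spacing_px,
                threshold_abs=1e-12 * float(response.max()),
                num_peaks=deficit,
                exclude_border=min_spacing_px,
            )
            if extra.size:
                pos = np.vstack([pos, extra.astype(float)])
                labels = np.concatenate(
                    [labels, np.full(len(extra), region, dtype=object)]
                )

    scores = response[pos[:, 0].astype(int), pos[:, 1].astype(int)]
    order = np.argsort(scores)[::-1]
    pos, scores, labels = pos[order], scores[order], labels[order]
    return FeatureSet(
        positions=pos,
        scores=scores,
        ages=np.zeros(len(pos), dtype=int),
        labels=labels,
        displacement=np.full((len(pos), 2), np.nan),
    )


def _empty_featureset() -> FeatureSet:
    return FeatureSet(
        positions=np.empty((0, 2)),
        scores=np.empty(0),
        ages=np.empty(0, dtype=int),
        labels=np.empty(0, dtype=object),
        displacement=np.empty((0, 2)),
    )


def _build_pyramid(img: np.ndarray, levels: int) -> list[np.ndarray]:
    pyr = [np.asarray(img, dtype=float)]
    for _ in range(1, levels):
        sm = gaussian_filter(pyr[-1], 1.0)
        pyr.append(sm[::2, ::2])
    return pyr


def _lk_pair(
    prev_pyr: list[np.ndarray],
    cur_pyr: list[np.ndarray],
    pts: np.ndarray,
    window_px: int,
    max_iters: int,
    residual_max: float = 20.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Pyramidal Lucas-Kanade displacement for all points at once.

    Returns (displacement (N, 2), ok (N,) bool). The spatial gradient matrix
    is evaluated once per level on the previous frame (constant-Hessian
    Lucas-Kanade); the residual is re-sampled from the current frame each
    iteration.
    """
    n = pts.shape[0]
    if n == 0:
        return np.empty((0, 2)), np.empty(0, dtype=bool)
    half = window_px // 2
    offs = np.stack(
        np.meshgrid(np.arange(-half, half + 1), np.arange(-half, half + 1), indexing="ij"),
        axis=-1,
    ).reshape(-1, 2)  # (K, 2)
    levels = len(prev_pyr)
    d = np.zeros((n, 2))
    ok = np.ones(n, dtype=bool)
    for lv in range(levels - 1, -1, -1):
        scale = 2.0**lv
        prev = prev_pyr[lv]
        cur = cur_pyr[lv]
        gy, gx = np.gradient(prev)
        p = pts / scale
        coords = p[:, None, :] + offs[None, :, :]  # (n, K, 2)
        flat = coords.reshape(-1, 2).T
        tmpl = map_coordinates(prev, flat, order=1, mode="nearest").reshape(n, -1)
        jy = map_coordinates(gy, flat, order=1, mode="nearest").reshape(n, -1)
        jx = map_coordinates(gx, flat, order=1, mode="nearest").reshape(n, -1)
        a11 = np.sum(jy * jy, axis=1)
        a12 = np.sum(jy * jx, axis=1)
        a22 = np.sum(jx * jx, axis=1)
        det = a11 * a22 - a12 * a12
        ok &= det > 1e-6
        det = np.where(det > 1e-6, det, 1.0)
        d *= 1.0  # d is kept in full-resolution px; convert to level units
        d_lv = d / scale
        for _ in range(max_iters):
            cc = (p + d_lv)[:, None, :] + offs[None, :, :]
            cur_w = map_coordinates(
                cur, cc.reshape(-1, 2).T, order=1, mode="nearest"
            ).reshape(n, -1)
            e = cur_w - tmpl
            b1 = np.sum(e * jy, axis=1)
            b2 = np.sum(e * jx, axis=1)
            dd1 = -(a22 * b1 - a12 * b2) / det
            dd2 = -(a11 * b2 - a12 * b1) / det
            d_lv[:, 0] += np.where(ok, dd1, 0.0)
            d_lv[:, 1] += np.where(ok, dd2, 0.0)
            if np.all(np.hypot(dd1, dd2)[ok] < 0.01) if ok.any() else True:
                break
        d = d_lv * scale
    def _residual(dd: np.ndarray) -> np.ndarray:
        cc = (pts + dd)[:, None, :] + offs[None, :, :]
        cur_w = map_coordinates(
            cur_pyr[0], cc.reshape(-1, 2).T, order=1, mode="nearest"
        ).reshape(n, -1)
        return np.sqrt(np.mean((cur_w - tmpl0) ** 2, axis=1))

    flat = (pts[:, None, :] + offs[None, :, :]).reshape(-1, 2).T
    tmpl0 = map_coordinates(prev_pyr[0], flat, order=1, mode="nearest").reshape(n, -1)
    res = _residual(d)

    # rescue pass: features whose residual is anomalously high (fast local
    # motion outside the pyramid's convergence basin) are re-localised by an
    # exhaustive normalized cross-correlation search, then LK-refined
    med = float(np.median(res[ok])) if ok.any() else 0.0
    rescue = np.where(ok & (res > max(2.5 * med, 6.0)))[0]
    if rescue.size:
        d = _zncc_rescue(prev_pyr[0], cur_pyr[0], pts, d, rescue, half)
        gy0, gx0 = np.gradient(prev_pyr[0])
        jy = map_coordinates(gy0, flat, order=1, mode="nearest").reshape(n, -1)
        jx = map_coordinates(gx0, flat, order=1, mode="nearest").reshape(n, -1)
        a11 = np.sum(jy * jy, axis=1)
        a12 = np.sum(jy * jx, axis=1)
        a22 = np.sum(jx * jx, axis=1)
        det = np.where(a11 * a22 - a12 * a12 > 1e-6, a11 * a22 - a12 * a12, np.inf)
        for _ in range(5):
            cc = (pts + d)[:, None, :] + offs[None, :, :]
            cur_w = map_coordinates(
                cur_pyr[0], cc.reshape(-1, 2).T, order=1, mode="nearest"
            ).reshape(n, -1)
            e = cur_w - tmpl0
            b1 = np.sum(e * jy, axis=1)
            b2 = np.sum(e * jx, axis=1)
            dd1 = -(a22 * b1 - a12 * b2) / det
            dd2 = -(a11 * b2 - a12 * b1) / det
            d[rescue, 0] += dd1[rescue]
            d[rescue, 1] += dd2[rescue]
        res = _residual(d)

    ok &= res < residual_max
    ok &= np.all(np.isfinite(d), axis=1)
    ok &= np.hypot(d[:, 0], d[:, 1]) < half * (2 ** (levels - 1)) * 4.0
    return d, ok


def _zncc_rescue(
    prev: np.ndarray,
    cur: np.ndarray,
    pts: np.ndarray,
    d: np.ndarray,
    idx: np.ndarray,
    half: int,
    search_px: int = 12,
) -> np.ndarray:
    """Integer re-localisation of selected features by exhaustive ZNCC."""
    from skimage.feature import match_template

    H, W = prev.shape
    d = d.copy()
    for i in idx:
        r0 = int(round(pts[i, 0]))
        c0 = int(round(pts[i, 1]))
        if not (half <= r0 < H - half and half <= c0 < W - half):
            continue
        tmpl = prev[r0 - half : r0 + half + 1, c0 - half : c0 + half + 1]
        if tmpl.std() == 0:
            continue
        sr = max(r0 - half - search_px, 0)
        sc = max(c0 - half - search_px, 0)
        search = cur[sr : r0 + half + search_px + 1, sc : c0 + half + search_px + 1]
        if search.shape[0] < tmpl.shape[0] or search.shape[1] < tmpl.shape[1]:
            continue
        corr = match_template(search, tmpl, pad_input=False)
        ij = np.unravel_index(np.argmax(corr), corr.shape)
        d[i, 0] = sr + ij[0] + half - pts[i, 0] + (pts[i, 0] - r0)
        d[i, 1] = sc + ij[1] + half - pts[i, 1] + (pts[i, 1] - c0)
    return d


def track_features(
    seq: ImageSequence,
    segmentation: Optional[Segmentation] = None,
    window_px: int = 11,
    pyramid_levels: int = 3,
    max_n: int = 300,
    min_spacing_px: int = 6,
    max_iters: int = 12,
    min_score: Optional[float] = None,
    replenish: bool = True,
) -> list[FeatureSet]:
    """Detect on frame 0 then track through the sequence, dropping failed
    features and replenishing the pool each frame.

    Raises :class:`AnalysisError` naming the frame if every feature is lost.
    """
    frames = seq.frames.astype(float)
    T, H, W = frames.shape
    fs0 = detect_features(
        frames[0], segmentation, max_n=max_n, min_score=min_score,
        min_spacing_px=min_spacing_px,
    )
    if fs0.n == 0:
        raise AnalysisError("no features detected on the initialization frame")
    sets = [fs0]
    prev_pyr = _build_pyramid(frames[0], pyramid_levels)
    half = window_px // 2
    for f in range(1, T):
        cur_pyr = _build_pyramid(frames[f], pyramid_levels)
        prev_fs = sets[-1]
        d, ok = _lk_pair(prev_pyr, cur_pyr, prev_fs.positions, window_px, max_iters)
        new_pos = prev_fs.positions + d
        inside = (
            (new_pos[:, 0] >= half)
            & (new_pos[:, 0] < H - half)
            & (new_pos[:, 1] >= half)
            & (new_pos[:, 1] < W - half)
        )
        keep = ok & inside
        if not keep.any() and not replenish:
            raise AnalysisError(f"all features lost at frame {f}")
        fs = FeatureSet(
            positions=new_pos[keep],
            scores=prev_fs.scores[keep],
            ages=prev_fs.ages[keep] + 1,
            labels=prev_fs.labels[keep],
            displacement=d[keep],
        )
        if replenish and fs.n < max_n:
            fresh = detect_features(
                frames[f],
                segmentation,
                max_n=max_n - fs.n,
                min_score=min_score,
                min_spacing_px=min_spacing_px,
                exclude=fs.positions,
            )
            fs = FeatureSet(
                positions=np.vstack([fs.positions, fresh.positions]),
                scores=np.concatenate([fs.scores, fresh.scores]),
                ages=np.concatenate([fs.ages, fresh.ages]),
                labels=np.concatenate([fs.labels, fresh.labels]),
                displacement=np.vstack([fs.displacement, fresh.displacement]),
            )
        if fs.n == 0:
            raise AnalysisError(f"all features lost at frame {f}")
        sets.append(fs)
        prev_pyr = cur_pyr
    return sets


# ---------------------------------------------------------------------------
# Probe grid
# ---------------------------------------------------------------------------


@dataclass
class ProbeGrid:
    """8 x 10 measurement probes: outer rows on the aponeuroses, inner six
    equally spaced across the fascicle region."""

    positions: np.ndarray  # (rows, cols, 2) px
    labels: np.ndarray  # (rows, cols) str

    @classmethod
    def from_segmentation(
        cls, seg: Segmentation, n_rows: int = 8, n_cols: int = 10, inset: float = 0.05
    ) -> "ProbeGrid":
        lo, hi = seg.lateral_extent
        span = hi - lo
        xs = np.linspace(lo + inset * span, hi - inset * span, n_cols)
        sup = seg.depth_at(xs, "superficial")
        deep = seg.depth_at(xs, "deep")
        fracs = np.linspace(0.0, 1.0, n_rows)
        pos = np.empty((n_rows, n_cols, 2))
        labels = np.full((n_rows, n_cols), "fascicle", dtype=object)
        for i, fr in enumerate(fracs):
            pos[i, :, 0] = sup + fr * (deep - sup)
            pos[i, :, 1] = xs
        labels[0, :] = "superficial_apo"
        labels[-1, :] = "deep_apo"
        return cls(positions=pos, labels=labels)

    @property
    def shape(self) -> tuple[int, int]:
        return self.positions.shape[0], self.positions.shape[1]


def interpolate_probe_displacement(
    feature_positions: np.ndarray,
    feature_displacements: np.ndarray,
    feature_labels: np.ndarray,
    probe_positions: np.ndarray,
    probe_labels: np.ndarray,
) -> np.ndarray:
    """Per-probe displacement from same-region feature displacements.

    Features of each region are Delaunay-triangulated; a probe inside the
    hull takes the barycentric combination of its enclosing triangle's vertex
    displacements (exact for affine fields); outside the hull it takes
    inverse-distance weights of its three nearest same-region features.
    Probes whose region has fewer than three non-collinear features get NaN.
    """
    probes_flat = probe_positions.reshape(-1, 2)
    labels_flat = np.asarray(probe_labels).reshape(-1)
    out = np.full_like(probes_flat, np.nan, dtype=float)
    for region in np.unique(labels_flat):
        pmask = labels_flat == region
        fmask = (np.asarray(feature_labels) == region) & np.all(
            np.isfinite(feature_displacements), axis=1
        )
        fp = feature_positions[fmask]
        fd = feature_displacements[fmask]
        if fp.shape[0] < 3:
            continue
        targets = probes_flat[pmask]
        try:
            tri = Delaunay(fp)
        except QhullError:
            continue  # collinear feature cloud: displacement undefined
        simplex = tri.find_simplex(targets)
        vals = np.full((targets.shape[0], 2), np.nan)
        inside = simplex >= 0
        if inside.any():
            trans = tri.transform[simplex[inside]]
            delta = targets[inside] - trans[:, 2]
            bary2 = np.einsum("nij,nj->ni", trans[:, :2], delta)
            bary = np.concatenate([bary2, 1 - bary2.sum(axis=1, keepdims=True)], axis=1)
            verts = tri.simplices[simplex[inside]]
            vals[inside] = np.einsum("ni,nij->nj", bary, fd[verts])
        if (~inside).any():
            k = min(3, fp.shape[0])
            dist, idx = cKDTree(fp).query(targets[~inside], k=k)
            dist = np.atleast_2d(dist)
            idx = np.atleast_2d(idx)
            w = 1.0 / np.maximum(dist, 1e-9)
            w /= w.sum(axis=1, keepdims=True)
            vals[~inside] = np.einsum("nk,nkj->nj", w, fd[idx])
        out[pmask] = vals
    return out.reshape(probe_positions.shape)


def track_probes(
    feature_sets: Sequence[FeatureSet], probes: ProbeGrid
) -> np.ndarray:
    """Advect the probe grid through the sequence (Lagrangian update).

    Each frame, probes move by the interpolated displacement of same-region
    features; probes with no usable interpolation hold their position.
    Returns ``(T, rows, cols, 2)`` probe positions.
    """
    T = len(feature_sets)
    rows, cols = probes.shape
    out = np.empty((T, rows, cols, 2))
    out[0] = probes.positions
    for f in range(1, T):
        fs = feature_sets[f]
        moved = np.all(np.isfinite(fs.displacement), axis=1)
        # interpolation nodes: feature positions *before* this frame's motion
        nodes = fs.positions - np.where(moved[:, None], fs.displacement, 0.0)
        disp = interpolate_probe_displacement(
            nodes, fs.displacement, fs.labels, out[f - 1], probes.labels
        )
        disp = np.where(np.isfinite(disp), disp, 0.0)
        out[f] = out[f - 1] + disp
    return out


@dataclass
class TwitchSeries:
    """Muscle length and thickness series derived from probe trajectories."""

    time_s: np.ndarray
    length_mm: np.ndarray
    thickness_mm: np.ndarray


def twitch_series(
    probe_positions: np.ndarray,
    calib_mm_per_px: tuple[float, float],
    frame_rate_hz: float,
) -> TwitchSeries:
    """Reduce probe trajectories to twitch kinematics.

    Muscle (fascicle-span) length: mean over probe columns of the distance
    between the most superficial and the deepest fascicle-region probes
    (rows 1 and -2). Thickness: mean over columns of the distance between the
    two aponeurosis rows (0 and -1). Distances are Euclidean in mm with
    per-axis calibration.
    """
    ax, lat = calib_mm_per_px
    T = probe_positions.shape[0]

    def pair_dist(row_a: int, row_b: int) -> np.ndarray:
        d = probe_positions[:, row_a, :, :] - probe_positions[:, row_b, :, :]
        dist = np.hypot(d[..., 0] * ax, d[..., 1] * lat)  # (T, cols)
        return np.nanmean(np.where(np.isfinite(dist), dist, np.nan), axis=1)

    return TwitchSeries(
        time_s=np.arange(T) / frame_rate_hz,
        length_mm=pair_dist(1, -2),
        thickness_mm=pair_dist(0, -1),
    )


@dataclass
class AlignResult:
    lag: int
    r: float
    r2: float
    slope: float
    intercept: float
    n: int


def align_and_compare(
    series_a: np.ndarray, series_b: np.ndarray, max_lag: int
) -> AlignResult:
    """Align ``series_b`` to ``series_a`` by cross-correlation, then compare.

    The lag maximising the normalized cross-correlation of the mean-removed
    series within ``+/- max_lag`` is applied to ``b`` (positive lag: ``b``
    trails ``a``); Pearson correlation and a model II (reduced major axis)
    regression are computed on the overlapping samples.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.ndim != 1 or b.ndim != 1:
        raise ValidationError("series must be one-dimensional")
    if max_lag >= min(a.size, b.size) / 2:
        raise ValidationError("max_lag must be below half the series length")
    if a.std() == 0 or b.std() == 0:
        raise AnalysisError("constant series: correlation undefined")
    am = a - a.mean()
    bm = b - b.mean()
    best_lag, best_c = 0, -np.inf
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            x, y = am[: am.size - lag], bm[lag:]
        else:
            x, y = am[-lag:], bm[: bm.size + lag]
        ns = min(x.size, y.size)
        x, y = x[:ns], y[:ns]
        denom = math.sqrt(float(np.sum(x**2)) * float(np.sum(y**2)))
        c = float(np.sum(x * y)) / denom if denom > 0 else -np.inf
        if c > best_c:
            best_c, best_lag = c, lag
    lag = best_lag
    if lag >= 0:
        x, y = a[: a.size - lag], b[lag:]
    else:
        x, y = a[-lag:], b[: b.size + lag]
    ns = min(x.size, y.size)
    x, y = x[:ns], y[:ns]
    reg = _stats.model2_regression(x, y)
    r, _ = _stats.pearson(x, y)
    return AlignResult(
        lag=lag, r=float(r), r2=reg.r2, slope=reg.slope,
        intercept=reg.intercept, n=ns,
    )


def track_twitch(
    seq: ImageSequence,
    segmentation: Segmentation,
    **track_kwargs,
) -> TwitchSeries:
    """End-to-end twitch pipeline: KLT tracking, probe advection, series."""
    sets = track_features(seq, segmentation, **track_kwargs)
    probes = ProbeGrid.from_segmentation(segmentation)
    traj = track_probes(sets, probes)
    return twitch_series(traj, seq.calib_mm_per_px, seq.frame_rate_hz)
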