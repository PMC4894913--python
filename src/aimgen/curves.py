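"""Within-subject generalization curves and tuning fits.

A subject's generalization curve is the mean calculated implicit at every
aiming location they reported during the rotation block, re-expressed as an
offset from their *modal aim* (most frequently reported landmark).  Curves
are pooled across subjects at offsets where enough subjects contribute, a
cosine tuning function is fitted by separable least squares (linear in
amplitude and vertical offset, nonlinear search over center and period), and
the folded-angle correlation quantifies the decay of implicit learning with
absolute distance from the modal aim.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy import stats as sps

from .preprocess import SubjectSeries
from .protocol import LANDMARK_SPACING_DEG, landmark_angle, wrap_angle
from .stats import StatResult

DEFAULT_MIN_SUBJECTS = 11  # strict "more than 10 subjects"
DEFAULT_WINDOW = (-35.0, 40.0)  # 35 deg CW to 40 deg CCW of the modal aim
PERIOD_BOUNDS = (90.0, 720.0)


@dataclass(frozen=True)
class GeneralizationCurve:
    """Mean implicit magnitude per angular offset from a reference direction."""

    offsets: np.ndarray  # degrees, strictly increasing, landmark-spaced
    means: np.ndarray
    n_subjects: np.ndarray
    reference: str = "modal_aim"

    def __post_init__(self) -> None:
        if not (len(self.offsets) == len(self.means) == len(self.n_subjects)):
            raise ValueError("offsets, means, n_subjects must be equal length")
        if len(self.offsets) > 1 and not np.all(np.diff(self.offsets) > 0):
            raise ValueError("offsets must be strictly increasing")


@dataclass(frozen=True)
class FitResult:
    """Parameters and goodness of fit for a tuning/distribution fit."""

    center: float
    amplitude: float
    offset_term: float = math.nan
    period: float = math.nan
    width: float = math.nan  # Gaussian SD, where applicable
    r_squared: float = math.nan


def modal_aim(reports) -> int:
    """Most frequently reported aiming landmark.

    Ties are broken toward the landmark whose angle is closest to the mean
    reported aim angle, then toward the more CCW landmark.
    """
    r = np.asarray(reports, dtype=float)
    r = r[~np.isnan(r)]
    if len(r) == 0:
        raise ValueError("no aim reports")
    landmarks, counts = np.unique(r.astype(int), return_counts=True)
    top = landmarks[counts == counts.max()]
    if len(top) == 1:
        return int(top[0])
    mean_aim = float(np.mean(r * -LANDMARK_SPACING_DEG))
    dist = np.abs(top * -LANDMARK_SPACING_DEG - mean_aim)
    nearest = top[dist == dist.min()]
    # remaining tie: more CCW = greater angle = more negative landmark
    return int(nearest.min())


def subject_curve(series: SubjectSeries) -> GeneralizationCurve:
    """Generalization curve of one subject, centered on their modal aim."""
    lm = series.reported_landmark
    good = ~np.isnan(lm)
    if not good.any():
        raise ValueError(f"subject {series.subject_id}: no aim reports")
    modal = modal_aim(lm[good])
    modal_angle = landmark_angle(modal)
    offsets, means = [], []
    for landmark in np.unique(lm[good].astype(int)):
        sel = good & (lm == landmark)
        vals = series.calculated_implicit[sel]
        vals = vals[~np.isnan(vals)]
        if len(vals) == 0:
            continue
        offsets.append(landmark_angle(int(landmark)) - modal_angle)
        means.append(float(vals.mean()))
    order = np.argsort(offsets)
    return GeneralizationCurve(
        offsets=np.asarray(offsets)[order],
        means=np.asarray(means)[order],
        n_subjects=np.ones(len(offsets), dtype=int)[order],
    )


def pool_curves(
    curves: list[GeneralizationCurve],
    min_subjects: int = DEFAULT_MIN_SUBJECTS,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> GeneralizationCurve:
    """Across-subject mean curve at offsets meeting the inclusion rules.

    An offset survives only if at least ``min_subjects`` subjects contribute
    a mean there *and* it lies within ``window`` (degrees, CW negative).
    An empty result is returned (not an error) when nothing survives.
    """
    lo, hi = window
    bucket: dict[float, list[float]] = {}
    for curve in curves:
        for off, mean in zip(curve.offsets, curve.means):
            bucket.setdefault(round(float(off), 6), []).append(float(mean))
    offsets, means, counts = [], [], []
    for off in sorted(bucket):
        vals = bucket[off]
        if len(vals) >= min_subjects and lo <= off <= hi:
            offsets.append(off)
            means.append(float(np.mean(vals)))
            counts.append(len(vals))
    return GeneralizationCurve(
        offsets=np.asarray(offsets),
        means=np.asarray(means),
        n_subjects=np.asarray(counts, dtype=int),
    )


def _cosine_sse(c: float, period: float, theta: np.ndarray, y: np.ndarray):
    """Separable step: solve amplitude and offset linearly for fixed (c, T).

    Closed-form 2x2 normal equations for ``y ~ A cos(...) + d``; falls back
    to the mean-only model when the cosine column is (near-)constant.
    """
    x = np.cos(2.0 * np.pi * (theta - c) / period)
    n = len(y)
    sx, sy = x.sum(), y.sum()
    sxx, sxy = float(x @ x), float(x @ y)
    det = n * sxx - sx * sx
    if abs(det) < 1e-12 * n * max(sxx, 1.0):
        d = sy / n
        resid = y - d
        return float(resid @ resid), 0.0, float(d)
    a = (n * sxy - sx * sy) / det
    d = (sxx * sy - sx * sxy) / det
    resid = y - a * x - d
    return float(resid @ resid), float(a), float(d)


def fit_cosine(
    curve: GeneralizationCurve,
    period: float | None = None,
    period_bounds: tuple[float, float] = PERIOD_BOUNDS,
) -> FitResult:
    """Fit ``y = A cos(2 pi (theta - c) / T) + d`` to a generalization curve.

    Amplitude and vertical offset enter linearly and are solved exactly for
    each candidate ``(c, T)`` (separable least squares); the center and
    period are found by Nelder-Mead polishing from multiple starts of ``c``
    on the landmark grid.  Pass ``period`` to fix ``T`` (e.g. 360) instead
    of fitting it within ``period_bounds``.  The returned amplitude is
    sign-normalized (A >= 0) and the center wrapped into (-180, 180].
    """
    theta = np.asarray(curve.offsets, dtype=float)
    y = np.asarray(curve.means, dtype=float)
    n_params = 3 if period is not None else 4
    if len(theta) < max(4, n_params):
        raise ValueError(f"need at least {max(4, n_params)} points, got {len(theta)}")

    t_lo, t_hi = period_bounds
    centers = np.arange(theta.min() - 2 * LANDMARK_SPACING_DEG,
                        theta.max() + 2 * LANDMARK_SPACING_DEG, LANDMARK_SPACING_DEG)
    periods = [period] if period is not None else list(np.linspace(t_lo, t_hi, 22))

    # coarse separable grid, then Nelder-Mead polish from the best starts
    grid = sorted(
        ((_cosine_sse(c0, t0, theta, y)[0], c0, t0) for c0 in centers for t0 in periods),
    )[:4]

    best = None
    for _, c0, t0 in grid:
        if period is not None:
            res = optimize.minimize(
                lambda x: _cosine_sse(x[0], period, theta, y)[0],
                x0=[c0], method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 2000},
            )
            c, t = float(res.x[0]), period
        else:
            def sse_of(x):
                t_clip = min(max(x[1], t_lo), t_hi)
                return _cosine_sse(x[0], t_clip, theta, y)[0]
            res = optimize.minimize(
                sse_of, x0=[c0, t0], method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 4000},
            )
            c = float(res.x[0])
            t = min(max(float(res.x[1]), t_lo), t_hi)
        sse, amp, off = _cosine_sse(c, t, theta, y)
        if best is None or sse < best[0]:
            best = (sse, c, t, amp, off)

    sse, c, t, amp, off = best
    if amp < 0:  # sign normalization: flip the phase by half a period
        amp, c = -amp, c + t / 2.0
    c = wrap_angle(c)
    # with T = 360 the model is periodic; report the center nearest zero
    if abs(c) > t / 2.0:
        c = c - math.copysign(t, c)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else math.nan
    return FitResult(center=c, amplitude=amp, offset_term=off, period=t,
                     r_squared=min(max(r2, 0.0), 1.0) if not math.isnan(r2) else r2)


def fold_and_correlate(curve: GeneralizationCurve) -> tuple[StatResult, dict]:
    """Correlate implicit magnitude with absolute offset from the modal aim.

    Offsets are folded to |offset| (means sharing an |offset| are averaged,
    weighted by subject counts), then Pearson r of |offset| vs magnitude is
    computed with a two-sided p from the t transform.  Also returns the
    least-squares line and its R^2.
    """
    folded: dict[float, list[tuple[float, float]]] = {}
    for off, mean, n in zip(curve.offsets, curve.means, curve.n_subjects):
        folded.setdefault(round(abs(float(off)), 6), []).append((float(mean), float(n)))
    if len(folded) < 3:
        raise ValueError("need at least 3 distinct absolute offsets")
    x, y = [], []
    for off in sorted(folded):
        vals, weights = zip(*folded[off])
        x.append(off)
        y.append(float(np.average(vals, weights=weights)))
    x = np.asarray(x)
    y = np.asarray(y)
    if np.ptp(y) == 0.0:
        return (
            StatResult("folded_correlation", math.nan, (len(x) - 2,),
                       math.nan, note="degenerate: constant magnitudes"),
            {"slope": math.nan, "intercept": math.nan, "r_squared": math.nan,
             "abs_offsets": x, "means": y},
        )
    r, p = sps.pearsonr(x, y)
    line = sps.linregress(x, y)
    detail = {
        "slope": float(line.slope),
        "intercept": float(line.intercept),
        "r_squared": float(line.rvalue**2),
        "abs_offsets": x,
        "means": y,
    }
    return StatResult("folded_correlation", float(r), (len(x) - 2,), float(p)), detail


def fit_angle_gaussian(angles, bin_width: float = LANDMARK_SPACING_DEG) -> FitResult:
    """Least-squares Gaussian fit to the histogram of a pooled angle series.

    Angles are binned into landmark-aligned bins (bin centers at multiples
    of the landmark spacing); a three-parameter Gaussian
    ``h = amp * exp(-(x - mu)^2 / (2 sd^2))`` is fitted to the occupied bin
    heights.  Normalizing heights to the fitted peak is a display choice and
    does not change ``mu``, ``sd`` or R^2.
    """
    a = np.asarray(angles, dtype=float)
    a = a[~np.isnan(a)]
    if len(a) == 0:
        raise ValueError("no angles to fit")
    lo = math.floor(a.min() / bin_width) - 1
    hi = math.ceil(a.max() / bin_width) + 1
    edges = (np.arange(lo, hi + 1) - 0.5) * bin_width
    heights, _ = np.histogram(a, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    occupied = heights > 0
    if occupied.sum() < 3:
        raise ValueError(
            f"only {int(occupied.sum())} occupied bins; need at least 3 to fit a Gaussian"
        )
    x = centers[occupied]
    h = heights[occupied].astype(float)

    def gauss(x, amp, mu, sd):
        return amp * np.exp(-((x - mu) ** 2) / (2.0 * sd**2))

    mu0 = float(np.average(x, weights=h))
    sd0 = float(math.sqrt(np.average((x - mu0) ** 2, weights=h))) or bin_width
    try:
        popt, _ = optimize.curve_fit(
            gauss, x, h, p0=[h.max(), mu0, sd0], maxfev=20000
        )
    except RuntimeError as exc:
        raise ValueError(f"Gaussian fit did not converge: {exc}") from None
    amp, mu, sd = float(popt[0]), float(popt[1]), abs(float(popt[2]))
    resid = h - gauss(x, *popt)
    sst = float(((h - h.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / sst if sst > 0 else math.nan
    return FitResult(center=mu, amplitude=amp, width=sd,
                     r_squared=min(max(r2, 0.0), 1.0) if not math.isnan(r2) else r2)
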