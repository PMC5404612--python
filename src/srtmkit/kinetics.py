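"""Simplified reference tissue model (SRTM) fitting by basis functions.

The SRTM expresses a target-region TAC in terms of a reference-region TAC
(here, cerebellum — assumed devoid of specific binding)::

    C_T(t) = R1 * C_R(t) + (k2 - R1 * k2a) * (C_R (*) exp(-k2a * t))

with ``k2a = k2 / (1 + BP_ND)`` the apparent target efflux rate and
``BP_ND = k2 / k2a - 1`` the non-displaceable binding potential.  The
basis-function method grids over ``k2a``: for each candidate the model is
linear in ``(R1, theta2 = k2 - R1*k2a)``, so a weighted linear solve per
basis followed by an RSS minimum over the grid yields the fit.  This is
convex per basis and robust enough to run per voxel.

All curves are frame averages on a :class:`~srtmkit.schedule.FrameSchedule`;
the convolution is carried out on a fine regular grid (default 0.05 min).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.interpolate import PchipInterpolator
from scipy.signal import lfilter

from .schedule import FrameSchedule

__all__ = [
    "TimeActivityCurve",
    "SRTMFit",
    "BPMap",
    "SRTMFitter",
    "C11_DECAY_LAMBDA",
    "default_k2a_grid",
    "frame_average",
    "fine_from_frames",
    "exp_convolve",
    "compute_weights",
    "fit_srtm",
    "fit_voxelwise",
]

#: Physical decay constant of carbon-11, 1/min (half-life 20.4 min).
C11_DECAY_LAMBDA: float = float(np.log(2.0) / 20.4)

#: Fine-grid spacing for convolutions, minutes.
FINE_DT: float = 0.05

#: Voxel-level plausibility clamp on BP_ND; outside -> fit marked invalid.
BP_CLAMP: tuple[float, float] = (-0.9, 10.0)


def default_k2a_grid(n: int = 128, lo: float = 0.006, hi: float = 0.6) -> np.ndarray:
    """Log-spaced k2a search grid in 1/min."""
    return np.geomspace(lo, hi, n)


@dataclass(frozen=True)
class TimeActivityCurve:
    """Frame-averaged activity concentration (kBq/ml) for a region or voxel."""

    schedule: FrameSchedule
    activity: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        act = np.asarray(self.activity, dtype=float)
        object.__setattr__(self, "activity", act)
        if act.shape != (self.schedule.n_frames,):
            raise ValueError(
                f"activity length {act.shape} does not match "
                f"{self.schedule.n_frames} frames"
            )
        if not np.all(np.isfinite(act)):
            raise ValueError("activity must be finite")


@dataclass(frozen=True)
class SRTMFit:
    """SRTM parameter estimates with fit diagnostics.

    ``bp_nd == k2 / k2a - 1`` holds exactly for every returned fit.
    ``boundary_flag`` is set when the winning k2a sits on the search-grid
    edge, which usually signals an unreliable fit.
    """

    r1: float
    k2: float
    k2a: float
    bp_nd: float
    rss: float
    weights: np.ndarray
    boundary_flag: bool

    def __post_init__(self) -> None:
        if not self.k2a > 0:
            raise ValueError("k2a must be positive")


@dataclass(frozen=True)
class BPMap:
    """Voxelwise BP_ND parametric map plus a quality mask of valid fits."""

    bp: np.ndarray        # 3-D float map; entries outside `valid` are meaningless
    valid: np.ndarray     # 3-D bool: fit succeeded, off grid-edge, inside clamp
    r1: np.ndarray
    k2a: np.ndarray


# ---------------------------------------------------------------------------
# fine-grid <-> frame-average plumbing

def frame_average(t_fine: np.ndarray, y_fine: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
    """Average a fine-grid curve over each frame ``[start, end)``.

    Uses the cumulative trapezoidal integral, so frame boundaries need not
    coincide with grid points.
    """
    t_fine = np.asarray(t_fine, dtype=float)
    if schedule.frame_end[-1] > t_fine[-1] + 1e-9:
        raise ValueError("schedule extends past the support of the fine-grid curve")
    cum = cumulative_trapezoid(y_fine, t_fine, initial=0.0)
    hi = np.interp(schedule.frame_end, t_fine, cum)
    lo = np.interp(schedule.frame_start, t_fine, cum)
    return (hi - lo) / schedule.duration


def fine_from_frames(
    tac: TimeActivityCurve,
    dt: float = FINE_DT,
    n_iter: int = 6,
) -> tuple[np.ndarray, np.ndarray]:
    """Reconstruct a smooth fine-grid curve from a frame-averaged TAC.

    Shape-preserving (PCHIP) interpolation through ``(0, 0)`` and the frame
    midpoints, followed by a few multiplicative corrections so the frame
    averages of the reconstruction match the measured values.  Used to
    recover a usable reference input from a measured cerebellum TAC.
    """
    sched = tac.schedule
    t = np.arange(0.0, sched.total_minutes + dt / 2, dt)
    knots = np.concatenate([[0.0], sched.midpoint])
    vals = np.concatenate([[0.0], tac.activity])
    y = PchipInterpolator(knots, vals, extrapolate=True)(t)
    for _ in range(n_iter):
        avg = frame_average(t, y, sched)
        ratio = np.where(np.abs(avg) > 1e-12, tac.activity / np.where(avg == 0, 1, avg), 1.0)
        corr = PchipInterpolator(sched.midpoint, ratio, extrapolate=True)(
            np.clip(t, sched.midpoint[0], sched.midpoint[-1])
        )
        y = y * corr
    return t, y


def _exp_conv_fine(ref: np.ndarray, dt: float, k2a: float) -> np.ndarray:
    """Trapezoidal ``ref (*) exp(-k2a t)`` on a regular grid, recursive form.

    ``b[i] = b[i-1]*E + dt/2*(ref[i] + ref[i-1]*E)`` with ``b[0] = 0``,
    realized as a first-order IIR filter.
    """
    e = float(np.exp(-k2a * dt))
    out = lfilter([0.5 * dt, 0.5 * dt * e], [1.0, -e], ref)
    # lfilter starts from b[0] = dt/2 * ref[0]; remove that transient
    if ref[0] != 0.0:
        out = out - 0.5 * dt * ref[0] * e ** np.arange(ref.size)
    return out


def exp_convolve(
    ref_fine: tuple[np.ndarray, np.ndarray],
    k2a: float,
    schedule: FrameSchedule | None = None,
) -> np.ndarray:
    """Convolve a fine-grid curve with ``exp(-k2a * t)``.

    Returns the frame-averaged basis TAC when ``schedule`` is given, else
    the fine-grid convolution itself.
    """
    if not k2a > 0:
        raise ValueError("k2a must be positive")
    t, ref = ref_fine
    t = np.asarray(t, dtype=float)
    ref = np.asarray(ref, dtype=float)
    dt = float(t[1] - t[0])
    if schedule is not None and dt > schedule.duration.min() + 1e-12:
        raise ValueError("fine grid is coarser than the shortest frame")
    b = _exp_conv_fine(ref, dt, float(k2a))
    if schedule is None:
        return b
    return frame_average(t, b, schedule)


def compute_weights(
    schedule: FrameSchedule,
    tac: TimeActivityCurve | None = None,
    decay_lambda: float = C11_DECAY_LAMBDA,
    uniform: bool = False,
) -> np.ndarray:
    """Per-frame fitting weights, normalized to sum to 1.

    Default: proportional to ``duration * exp(-decay_lambda * midpoint)`` —
    long, early frames carry more counts and hence more weight.  ``tac`` is
    accepted for interface symmetry; the default weighting depends only on
    the schedule.  ``uniform=True`` gives equal weights.
    """
    if uniform:
        w = np.ones(schedule.n_frames)
    else:
        w = schedule.duration * np.exp(-decay_lambda * schedule.midpoint)
    return w / w.sum()


# ---------------------------------------------------------------------------
# basis-function solver

class SRTMFitter:
    """Reusable SRTM basis-function solver for one reference curve.

    Precomputes the frame-averaged reference and the convolution bases for
    a k2a grid, then fits any number of target TACs (ROI curves or voxel
    matrices) against them.
    """

    def __init__(
        self,
        ref_fine: tuple[np.ndarray, np.ndarray],
        schedule: FrameSchedule,
        k2a_grid: np.ndarray | None = None,
        weights: np.ndarray | None = None,
    ) -> None:
        if k2a_grid is None:
            k2a_grid = default_k2a_grid()
        self.k2a_grid = np.asarray(k2a_grid, dtype=float)
        if self.k2a_grid.size == 0:
            raise ValueError("k2a grid must be non-empty")
        self.schedule = schedule
        self._ref_fine = ref_fine
        self.weights = (
            compute_weights(schedule) if weights is None
            else np.asarray(weights, dtype=float)
        )
        self.ref_frames = frame_average(ref_fine[0], ref_fine[1], schedule)
        if float(np.sum(self.weights * self.ref_frames**2)) <= 0:
            raise ValueError("degenerate reference curve: all-zero frame averages")
        self.bases = np.stack(
            [exp_convolve(ref_fine, k, schedule) for k in self.k2a_grid]
        )
        w, r = self.weights, self.ref_frames
        self._a11 = float(np.sum(w * r * r))
        self._a12 = self.bases @ (w * r)
        self._a22 = np.sum(self.bases * self.bases * w, axis=1)
        self._det = self._a11 * self._a22 - self._a12**2
        if np.any(self._det <= 0):
            raise ValueError("degenerate reference curve: design matrix is singular")

    def solve_matrix(
        self, y: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Weighted linear solve for many TACs at once.

        Parameters
        ----------
        y : (n_curves, n_frames)

        Returns
        -------
        (r1, theta2, rss, best_idx), each of shape (n_curves,).
        """
        w, r = self.weights, self.ref_frames
        c1 = y @ (w * r)                                  # (n,)
        c2 = (y * w) @ self.bases.T                       # (n, n_grid)
        sum_wy2 = np.sum(y * y * w, axis=1)
        r1_all = (self._a22 * c1[:, None] - self._a12 * c2) / self._det
        th_all = (self._a11 * c2 - self._a12 * c1[:, None]) / self._det
        # weighted RSS at the per-basis LS optimum
        rss_all = sum_wy2[:, None] - (r1_all * c1[:, None] + th_all * c2)
        best = np.argmin(rss_all, axis=1)
        rows = np.arange(y.shape[0])
        return (
            r1_all[rows, best],
            th_all[rows, best],
            np.maximum(rss_all[rows, best], 0.0),
            best,
        )

    def _solve_at(self, y: np.ndarray, k2a: float) -> tuple[float, float, float]:
        """Weighted 2-parameter solve for a single continuous k2a value."""
        w, r = self.weights, self.ref_frames
        b = exp_convolve(self._ref_fine, k2a, self.schedule)
        a12 = float(np.sum(w * r * b))
        a22 = float(np.sum(w * b * b))
        det = self._a11 * a22 - a12 * a12
        c1 = float(np.sum(w * r * y))
        c2 = float(np.sum(w * b * y))
        r1 = (a22 * c1 - a12 * c2) / det
        th = (self._a11 * c2 - a12 * c1) / det
        rss = float(np.sum(w * (y - r1 * r - th * b) ** 2))
        return r1, th, rss

    def fit(self, tac: TimeActivityCurve, refine: bool = True) -> SRTMFit:
        """Fit one TAC; see :func:`fit_srtm` for the contract.

        ``refine=True`` (default) polishes k2a by a bounded 1-D minimization
        of the weighted RSS between the grid neighbours of the winning basis,
        removing the grid-discretization error.
        """
        y = tac.activity
        w, r = self.weights, self.ref_frames
        # collinearity guard: target explained exactly by the reference alone
        r1_only = float(np.sum(w * r * y) / self._a11)
        rss_only = float(np.sum(w * (y - r1_only * r) ** 2))
        scale = float(np.sum(w * y * y))
        if rss_only <= 1e-16 * max(scale, 1e-300):
            k2a_mid = float(np.sqrt(self.k2a_grid[0] * self.k2a_grid[-1]))
            return SRTMFit(
                r1=r1_only, k2=r1_only * k2a_mid, k2a=k2a_mid, bp_nd=0.0,
                rss=rss_only, weights=w, boundary_flag=False,
            )
        r1, theta2, rss, idx = self.solve_matrix(y[None, :])
        r1_v, th_v, rss_v, i = float(r1[0]), float(theta2[0]), float(rss[0]), int(idx[0])
        k2a = float(self.k2a_grid[i])
        on_edge = i == 0 or i == self.k2a_grid.size - 1
        if refine and not on_edge:
            from scipy.optimize import minimize_scalar

            lo, hi = float(self.k2a_grid[i - 1]), float(self.k2a_grid[i + 1])
            res = minimize_scalar(
                lambda k: self._solve_at(y, k)[2],
                bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-7},
            )
            if np.isfinite(res.fun) and res.fun <= rss_v + 1e-15:
                k2a = float(res.x)
                r1_v, th_v, rss_v = self._solve_at(y, k2a)
        if abs(th_v) < 1e-10 * w.max():
            th_v = 0.0
        k2 = th_v + r1_v * k2a
        return SRTMFit(
            r1=r1_v, k2=k2, k2a=k2a, bp_nd=k2 / k2a - 1.0, rss=rss_v, weights=w,
            boundary_flag=on_edge,
        )


def fit_srtm(
    tac: TimeActivityCurve,
    ref_fine: tuple[np.ndarray, np.ndarray],
    schedule: FrameSchedule | None = None,
    k2a_grid: np.ndarray | None = None,
    weights: np.ndarray | None = None,
    refine: bool = True,
) -> SRTMFit:
    """Fit the SRTM to one TAC by the basis-function method.

    Parameters
    ----------
    tac
        Target time-activity curve.
    ref_fine
        ``(t, y)`` reference-region curve on a regular fine grid covering
        the schedule span.
    schedule
        Defaults to ``tac.schedule``.
    k2a_grid
        Candidate apparent efflux rates (1/min); default 128 log-spaced
        points in [0.006, 0.6].
    weights
        Per-frame weights; default duration x decay weighting.

    Notes
    -----
    When the target is (numerically) proportional to the reference, every
    k2a gives an equally perfect fit; the fit is then reported with
    ``bp_nd = 0`` and R1 from the single-regressor solve.
    """
    schedule = schedule or tac.schedule
    return SRTMFitter(ref_fine, schedule, k2a_grid, weights).fit(tac, refine=refine)


def fit_voxelwise(
    dynamic: np.ndarray,
    schedule: FrameSchedule,
    ref_fine: tuple[np.ndarray, np.ndarray],
    mask: np.ndarray,
    k2a_grid: np.ndarray | None = None,
    weights: np.ndarray | None = None,
    bp_clamp: tuple[float, float] = BP_CLAMP,
) -> BPMap:
    """Fit the SRTM in every voxel of a 4-D dynamic image.

    Parameters
    ----------
    dynamic
        ``(x, y, z, frame)`` activity array, kBq/ml.
    mask
        Boolean or integer label volume on the same grid; voxels where
        ``mask > 0`` are fitted.
    bp_clamp
        Plausibility interval for BP_ND; fits outside it, on the grid
        boundary, non-finite, or from all-zero voxels are marked invalid in
        the quality mask (they do not propagate into region summaries).
    """
    dynamic = np.asarray(dynamic, dtype=float)
    mask = np.asarray(mask)
    if dynamic.ndim != 4 or dynamic.shape[:3] != mask.shape:
        raise ValueError("dynamic image and mask must share the 3-D grid")
    if dynamic.shape[3] != schedule.n_frames:
        raise ValueError("frame axis length must match the schedule")

    fitter = SRTMFitter(ref_fine, schedule, k2a_grid, weights)
    grid = fitter.k2a_grid

    sel = mask > 0
    y = dynamic[sel]                                   # (n_vox, n_frames)
    usable = np.any(y != 0.0, axis=1) & np.all(np.isfinite(y), axis=1)

    r1 = np.zeros(y.shape[0])
    theta2 = np.zeros(y.shape[0])
    idx = np.zeros(y.shape[0], dtype=int)
    if np.any(usable):
        r1_u, th_u, _, idx_u = fitter.solve_matrix(y[usable])
        r1[usable], theta2[usable], idx[usable] = r1_u, th_u, idx_u
    k2a = grid[idx]
    bp = (theta2 + r1 * k2a) / k2a - 1.0
    on_edge = (idx == 0) | (idx == grid.size - 1)
    ok = (
        usable
        & np.isfinite(bp)
        & ~on_edge
        & (bp > bp_clamp[0])
        & (bp < bp_clamp[1])
    )

    shape = mask.shape
    bp_map = np.full(shape, np.nan)
    r1_map = np.full(shape, np.nan)
    k2a_map = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)
    bp_map[sel] = bp
    r1_map[sel] = r1
    k2a_map[sel] = k2a
    valid[sel] = ok
    return BPMap(bp=bp_map, valid=valid, r1=r1_map, k2a=k2a_map)
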