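"""FRAP quantification: region intensities, trace normalization, recovery fits.

Centrosomal signal per frame is measured from two concentric rectangular
regions: the integrated intensity is (mean inner - mean ring) * inner area,
where the ring between the boxes estimates local cytoplasmic background.
Post-bleach points, normalized to the pre-bleach mean, are fitted to the
single-exponential recovery model

    Y = A * (1 - exp(-k * X)) + B

with X the time since the first post-bleach frame, A the mobile fraction,
B the background remaining after the bleach, and half-time of recovery
t_1/2 = ln(2) / k.  Goodness of fit is reported as R^2 = 1 - SS_res/SS_tot
over the fitted (post-bleach) points.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import curve_fit


class FrapError(ValueError):
    pass


class FitError(RuntimeError):
    """Recovery fit failed; carries the best residual seen across restarts."""

    def __init__(self, message: str, best_residual: float | None = None):
        super().__init__(message)
        self.best_residual = best_residual


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle, 0-based half-open pixel coordinates."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise FrapError(f"degenerate rectangle {self}")

    @property
    def area(self) -> int:
        return (self.x1 - self.x0) * (self.y1 - self.y0)

    def contains(self, other: "Rect") -> bool:
        return (
            self.x0 <= other.x0
            and self.y0 <= other.y0
            and self.x1 >= other.x1
            and self.y1 >= other.y1
        )


@dataclass(frozen=True)
class RegionPair:
    """Two concentric regions: inner encompassing the spot, outer adding
    surrounding background; the ring outer\\inner must be non-empty."""

    inner: Rect
    outer: Rect

    def __post_init__(self) -> None:
        if not self.outer.contains(self.inner):
            raise FrapError("outer region must contain inner region")
        if self.outer.area <= self.inner.area:
            raise FrapError("ring between regions is empty")


@dataclass(frozen=True)
class FrapTrace:
    times: np.ndarray
    raw: np.ndarray
    bleach_index: int
    normalized: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "raw", np.asarray(self.raw, dtype=float))
        if self.normalized is not None:
            object.__setattr__(
                self, "normalized", np.asarray(self.normalized, dtype=float)
            )
        if self.times.shape != self.raw.shape or self.times.ndim != 1:
            raise FrapError("times and raw must be 1-D arrays of equal length")
        if np.any(np.diff(self.times) <= 0):
            raise FrapError("times must be strictly increasing")
        if not (1 <= self.bleach_index < len(self.times)):
            raise FrapError(
                f"bleach_index {self.bleach_index} out of range "
                f"[1, {len(self.times) - 1}]"
            )

    @property
    def pre_bleach(self) -> np.ndarray:
        return self.raw[: self.bleach_index]

    @property
    def post_times(self) -> np.ndarray:
        return self.times[self.bleach_index :]


@dataclass(frozen=True)
class RecoveryFit:
    A: float
    k: float
    B: float
    t_half: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise FitError("no recovery detected (k <= 0)")
        if abs(self.t_half * self.k - np.log(2)) > 1e-9:
            raise FrapError("t_half inconsistent with k")


def recovery_model(x: np.ndarray, A: float, k: float, B: float) -> np.ndarray:
    return A * (1.0 - np.exp(-k * np.asarray(x, dtype=float))) + B


def integrated_intensity(frame: np.ndarray, regions: RegionPair) -> float:
    """Background-subtracted integrated intensity over the inner region.

    (mean over inner - mean over ring) * area(inner), with the ring being
    outer minus inner.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise FrapError("frame must be a 2-D image")
    h, w = frame.shape
    o = regions.outer
    if o.x0 < 0 or o.y0 < 0 or o.x1 > w or o.y1 > h:
        raise FrapError(f"outer region {o} exceeds frame bounds {w}x{h}")
    i = regions.inner
    inner_px = frame[i.y0 : i.y1, i.x0 : i.x1]
    outer_sum = frame[o.y0 : o.y1, o.x0 : o.x1].sum()
    ring_sum = outer_sum - inner_px.sum()
    ring_area = o.area - i.area
    return float((inner_px.mean() - ring_sum / ring_area) * i.area)


def extract_trace(
    stack: np.ndarray,
    regions: RegionPair | list[RegionPair],
    times: np.ndarray,
    bleach_index: int,
) -> FrapTrace:
    """Measure one integrated intensity per frame of a time series."""
    stack = np.asarray(stack, dtype=float)
    times = np.asarray(times, dtype=float)
    if stack.ndim != 3:
        raise FrapError("stack must be a 3-D (time, y, x) array")
    if len(times) != stack.shape[0]:
        raise FrapError(
            f"length mismatch: {stack.shape[0]} frames vs {len(times)} time points"
        )
    if isinstance(regions, RegionPair):
        regions = [regions] * stack.shape[0]
    if len(regions) != stack.shape[0]:
        raise FrapError("need one region pair per frame")
    raw = np.array(
        [integrated_intensity(f, r) for f, r in zip(stack, regions)]
    )
    return FrapTrace(times=times, raw=raw, bleach_index=bleach_index)


def normalize_trace(trace: FrapTrace, n_pre: int | None = None) -> FrapTrace:
    """Divide the trace by the mean of its pre-bleach points.

    ``n_pre`` restricts the normalization to the last ``n_pre`` frames before
    the bleach ("shortly before"); default uses all pre-bleach frames.
    """
    pre = trace.pre_bleach
    if n_pre is not None:
        if n_pre < 1:
            raise FrapError("n_pre must be >= 1")
        pre = pre[-n_pre:]
    baseline = pre.mean()
    if baseline <= 0:
        raise FrapError(f"pre-bleach mean {baseline} is not positive")
    return replace(trace, normalized=trace.raw / baseline)


def _initial_guess(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    b0 = float(y[0])
    a0 = float(max(y.max() - y.min(), 1e-3))
    plateau = b0 + a0
    half_level = b0 + 0.5 * a0
    above = np.nonzero(y >= half_level)[0]
    t_half_guess = x[above[0]] if above.size and x[above[0]] > 0 else (x[-1] / 4 or 1.0)
    k0 = float(np.log(2) / t_half_guess)
    return a0, k0, b0


def fit_recovery(
    trace: FrapTrace, max_restarts: int = 5, seed: int = 0
) -> RecoveryFit:
    """Nonlinear least-squares fit of the recovery model to post-bleach points.

    X is measured from the first post-bleach frame.  On convergence failure
    the initial guesses are jittered for up to ``max_restarts`` retries.
    """
    if trace.normalized is None:
        raise FrapError("normalize the trace before fitting")
    y = trace.normalized[trace.bleach_index :]
    x = trace.post_times - trace.post_times[0]
    if len(y) < 4:
        raise FrapError(f"need >= 4 post-bleach points, have {len(y)}")

    a0, k0, b0 = _initial_guess(x, y)
    rng = np.random.default_rng(seed)
    best_residual = None
    last_err: Exception | None = None
    for attempt in range(max_restarts + 1):
        if attempt == 0:
            p0 = (a0, k0, b0)
        else:
            p0 = (
                a0 * rng.uniform(0.5, 2.0),
                k0 * rng.uniform(0.25, 4.0),
                b0 + rng.normal(0, 0.1),
            )
        try:
            popt, _ = curve_fit(recovery_model, x, y, p0=p0, maxfev=10000)
        except RuntimeError as err:
            last_err = err
            continue
        A, k, B = (float(v) for v in popt)
        residuals = y - recovery_model(x, A, k, B)
        ss_res = float(residuals @ residuals)
        if best_residual is None or ss_res < best_residual:
            best_residual = ss_res
        if k <= 0 or A <= 0:
            # a non-positive rate or mobile fraction means the signal never
            # recovers toward a plateau above the post-bleach level
            last_err = FitError("no recovery detected", ss_res)
            continue
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        return RecoveryFit(
            A=A, k=k, B=B, t_half=float(np.log(2) / k), r_squared=r2
        )
    if isinstance(last_err, FitError):
        raise last_err
    raise FitError(
        f"fit did not converge after {max_restarts} restarts: {last_err}",
        best_residual,
    )
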