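"""Analytic cell-shape model for germinating spores.

A germinating spore is modelled as a mirror-symmetric planar shape built
from a circular spore body and zero, one, or two cylindrical germ tubes
(capsules) growing along the symmetry axis.  Because every shape is
symmetric about its major axis, all of its area moments reduce to 1-D
integrals of the half-width profile ``h(x)``:

    A    = integral 2 h(x) dx
    Ixx  = integral 2 h(x) (x - xbar)^2 dx      (along the axis)
    Iyy  = integral (2/3) h(x)^3 dx             (across the axis)

and the moments-matching ellipse has aspect ratio ``sqrt(Ixx / Iyy)``.
These integrals are evaluated by dense Simpson quadrature on the exact
piecewise-algebraic profile, independently of any pixel renderer, so the
generator's ground-truth kinematics (e.g. the frame at which AR crosses
the division threshold) come from closed-form geometry rather than from
rasterized masks.

Units are micrometres throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SporeShape",
    "shape_moments",
    "shape_aspect_ratio",
    "solve_outgrowth_for_ar",
    "solve_tube_radius_for_ar",
]

_QUAD_STEP_UM = 0.002  # quadrature resolution; profiles are smooth at this scale


@dataclass(frozen=True)
class SporeShape:
    """Spore body of radius ``body_radius`` at the axis origin, with a germ
    tube of radius ``tube_radius`` protruding ``tube_plus`` beyond the body
    boundary in the +x direction and ``tube_minus`` in the -x direction
    (either may be zero).  ``tube_radius <= body_radius`` is required so the
    tube emerges from inside the body outline."""

    body_radius: float
    tube_radius: float = 0.0
    tube_plus: float = 0.0
    tube_minus: float = 0.0

    def __post_init__(self) -> None:
        if self.body_radius <= 0:
            raise ValueError("body_radius must be positive")
        if self.tube_plus > 0 or self.tube_minus > 0:
            if not 0 < self.tube_radius <= self.body_radius:
                raise ValueError("tube_radius must be in (0, body_radius]")

    @property
    def x_min(self) -> float:
        return -(self.body_radius + self.tube_minus)

    @property
    def x_max(self) -> float:
        return self.body_radius + self.tube_plus

    def half_width(self, x: np.ndarray) -> np.ndarray:
        """Half-width profile h(x) of the union body ∪ tubes."""
        x = np.asarray(x, dtype=float)
        rb, rt = self.body_radius, self.tube_radius
        h = np.sqrt(np.clip(rb * rb - x * x, 0.0, None))
        for sign, length in ((1.0, self.tube_plus), (-1.0, self.tube_minus)):
            if length <= 0:
                continue
            tip = rb + length
            # capsule axis runs from 0 to sign*(tip - rt); radius rt
            seg_end = tip - rt
            xs = sign * x
            cap = np.where(
                xs <= seg_end,
                np.where(xs >= 0.0, rt, np.sqrt(np.clip(rt * rt - xs * xs, 0.0, None))),
                np.sqrt(np.clip(rt * rt - (xs - seg_end) ** 2, 0.0, None)),
            )
            h = np.maximum(h, cap)
        return h

    def signed_distance(self, px: np.ndarray, py: np.ndarray) -> np.ndarray:
        """Signed distance (negative inside) from points given in the shape's
        own axis frame (x along the major axis, origin at the body centre)."""
        rb, rt = self.body_radius, self.tube_radius
        d = np.hypot(px, py) - rb
        for sign, length in ((1.0, self.tube_plus), (-1.0, self.tube_minus)):
            if length <= 0:
                continue
            seg_end = rb + length - rt
            t = np.clip(sign * px, 0.0, seg_end)
            d = np.minimum(d, np.hypot(sign * px - t, py) - rt)
        return d


def shape_moments(shape: SporeShape) -> tuple[float, float, float, float]:
    """Return (area, centroid_x, Ixx, Iyy) of the shape by 1-D quadrature.

    Ixx is the second moment about the centroid along the axis; Iyy across it.
    """
    n = max(int(np.ceil((shape.x_max - shape.x_min) / _QUAD_STEP_UM)), 64)
    if n % 2 == 1:
        n += 1
    x = np.linspace(shape.x_min, shape.x_max, n + 1)
    h = shape.half_width(x)
    w = 2.0 * h
    from scipy.integrate import simpson

    area = float(simpson(w, x=x))
    cx = float(simpson(w * x, x=x)) / area
    ixx = float(simpson(w * (x - cx) ** 2, x=x))
    iyy = float(simpson((2.0 / 3.0) * h**3, x=x))
    return area, cx, ixx, iyy


def shape_aspect_ratio(shape: SporeShape) -> float:
    """Aspect ratio of the moments-matching ellipse (>= 1)."""
    _, _, ixx, iyy = shape_moments(shape)
    big, small = max(ixx, iyy), min(ixx, iyy)
    return float(np.sqrt(big / small))


def _bisect(f, lo: float, hi: float, tol: float = 1e-6, maxit: int = 80) -> float:
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise ValueError("bisection bracket does not straddle a root")
    for _ in range(maxit):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if abs(hi - lo) < tol:
            return mid
        if flo * fm <= 0:
            hi, fhi = mid, fm
        else:
            lo, flo = mid, fm
    return 0.5 * (lo + hi)


def solve_outgrowth_for_ar(
    body_radius: float,
    tube_radius: float,
    ar_target: float,
    bipolar: bool = False,
    l_max: float = 60.0,
) -> float:
    """Outgrowth length L at which the analytic AR reaches ``ar_target``.

    For ``bipolar`` both tubes carry length L.  Raises if the target is not
    reached by ``l_max``.
    """

    def f(length: float) -> float:
        s = SporeShape(
            body_radius,
            tube_radius,
            tube_plus=length,
            tube_minus=length if bipolar else 0.0,
        )
        return shape_aspect_ratio(s) - ar_target

    return _bisect(f, 1e-3, l_max, tol=1e-5)


def solve_tube_radius_for_ar(
    body_radius: float, outgrowth_um: float, ar_target: float
) -> float:
    """Tube radius such that a mono-tube cell reaches ``ar_target`` exactly at
    outgrowth length ``outgrowth_um``.

    AR is not monotone in the tube radius (very thin tubes carry too little
    mass to elongate the ellipse), so the solver locates the AR peak and
    returns the root on the wide-tube branch, the physically sensible one.
    """

    def f(rt: float) -> float:
        s = SporeShape(body_radius, rt, tube_plus=outgrowth_um)
        return shape_aspect_ratio(s) - ar_target

    grid = np.linspace(0.15, body_radius * 0.999, 40)
    vals = [f(rt) for rt in grid]
    peak = int(np.argmax(vals))
    if vals[peak] < 0:
        raise ValueError(
            f"AR {ar_target} is unattainable at outgrowth {outgrowth_um} um "
            f"for body radius {body_radius} um"
        )
    return _bisect(f, grid[peak], body_radius * 0.999, tol=1e-6)
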