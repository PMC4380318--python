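"""Elliptic Fourier analysis of closed contours.

A closed contour traced at constant speed has periodic coordinate
functions x(t), y(t) which are expanded in a truncated Fourier series of
N harmonics.  The coefficients (a_n, b_n) of x and (c_n, d_n) of y are
computed with the piecewise-linear arc-length closed forms (exact for
polygonal contours), standardized to be invariant to contour size,
rotation and trace starting point, and assembled into a shape descriptor
vector of length 4N - 3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ContourSequence",
    "EFDSet",
    "ShapeVector",
    "compute_efd",
    "approximation_error",
    "standardize",
    "average_shape",
    "reconstruct_contour",
]


@dataclass
class ContourSequence:
    """Ordered loop of (x, y) boundary coordinates of one object.

    The loop is implicitly closed: the last point connects back to the
    first.  Consecutive duplicate points are rejected because they make
    the arc-length parameterization degenerate.
    """

    points: np.ndarray
    closed: bool = True

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("contour points must be an (P, 2) array")
        if pts.shape[0] >= 2 and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]  # drop explicit closing point
        if pts.shape[0] < 3:
            raise ValueError("a closed contour needs at least 3 distinct points")
        seg = np.diff(np.vstack([pts, pts[:1]]), axis=0)
        if np.any(np.hypot(seg[:, 0], seg[:, 1]) == 0.0):
            raise ValueError("contour contains identical consecutive points")
        self.points = pts

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def signed_area(self) -> float:
        """Shoelace area; positive for counterclockwise traversal."""
        x, y = self.points[:, 0], self.points[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    @property
    def is_counterclockwise(self) -> bool:
        return self.signed_area > 0.0

    def canonicalized(self) -> "ContourSequence":
        """Return the contour traversed counterclockwise."""
        if self.is_counterclockwise:
            return self
        return ContourSequence(self.points[::-1].copy())

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)


@dataclass
class EFDSet:
    """Raw elliptic Fourier coefficients of one contour.

    ``coeffs`` is an (N, 4) array with columns (a_n, b_n, c_n, d_n).
    ``a0``/``c0`` are the position offsets, ignored downstream because
    they carry no shape information.  The period ``T`` is the total
    perimeter used during fitting; reconstruction rescales it freely.
    """

    N: int
    a0: float
    c0: float
    coeffs: np.ndarray
    T: float = 1.0

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.N < 1 or self.coeffs.shape != (self.N, 4):
            raise ValueError("coeffs must have shape (N, 4) with N >= 1")
        if not np.all(np.isfinite(self.coeffs)):
            raise ValueError("non-finite Fourier coefficients")


@dataclass
class ShapeVector:
    """Standardized shape descriptor of length 4N - 3.

    Layout: (a_2..a_N, b_2..b_N, c_2..c_N, d_1..d_N).  The constant
    first-harmonic coefficients a_1 = 1, b_1 = 0, c_1 = 0 are implied
    and not stored.
    """

    values: np.ndarray
    N: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (4 * self.N - 3,):
            raise ValueError(
                f"shape vector for N={self.N} must have length {4 * self.N - 3}, "
                f"got {self.values.shape}"
            )

    def to_efd(self, T: float = 1.0) -> EFDSet:
        """Expand back to a full coefficient set with a_1=1, b_1=c_1=0."""
        n = self.N
        coeffs = np.zeros((n, 4))
        coeffs[0, 0] = 1.0
        m = n - 1
        coeffs[1:, 0] = self.values[:m]
        coeffs[1:, 1] = self.values[m : 2 * m]
        coeffs[1:, 2] = self.values[2 * m : 3 * m]
        coeffs[:, 3] = self.values[3 * m :]
        return EFDSet(N=n, a0=0.0, c0=0.0, coeffs=coeffs, T=T)

    @staticmethod
    def from_coeffs(coeffs: np.ndarray) -> "ShapeVector":
        """Pack an (N, 4) standardized coefficient array (row 0 = harmonic 1)."""
        coeffs = np.asarray(coeffs, dtype=float)
        n = coeffs.shape[0]
        values = np.concatenate(
            [coeffs[1:, 0], coeffs[1:, 1], coeffs[1:, 2], coeffs[:, 3]]
        )
        return ShapeVector(values=values, N=n)


def _arc_length_params(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Segment vectors, segment lengths and cumulative arc length of a loop."""
    closed = np.vstack([points, points[:1]])
    d = np.diff(closed, axis=0)
    dt = np.hypot(d[:, 0], d[:, 1])
    t = np.concatenate([[0.0], np.cumsum(dt)])
    return d, dt, t


def compute_efd(contour: ContourSequence, N: int) -> EFDSet:
    """Fit N Fourier harmonics to a closed contour.

    Uses the closed-form integrals of the piecewise-linear (polygonal)
    arc-length parameterization, so the result is exact for the polygon
    through the contour points, independent of point spacing.
    """
    if N < 1:
        raise ValueError("harmonic count N must be >= 1")
    pts = contour.points
    d, dt, t = _arc_length_params(pts)
    T = t[-1]
    if T <= 0.0:
        raise ValueError("degenerate contour with zero perimeter")

    n = np.arange(1, N + 1)[:, None]  # (N, 1)
    phi = 2.0 * np.pi * t[None, :] / T  # (1, P+1)
    cos_np, sin_np = np.cos(n * phi), np.sin(n * phi)
    dcos = cos_np[:, 1:] - cos_np[:, :-1]
    dsin = sin_np[:, 1:] - sin_np[:, :-1]
    scale = T / (2.0 * (n.ravel() ** 2) * np.pi**2)

    dx_dt = d[:, 0] / dt
    dy_dt = d[:, 1] / dt
    a = scale * (dcos @ dx_dt)
    b = scale * (dsin @ dx_dt)
    c = scale * (dcos @ dy_dt)
    dd = scale * (dsin @ dy_dt)

    # DC terms: exact integral of the piecewise-linear coordinate functions.
    dt2 = t[1:] ** 2 - t[:-1] ** 2
    xi = np.concatenate([[0.0], np.cumsum(d[:-1, 0])]) - dx_dt * t[:-1]
    delta = np.concatenate([[0.0], np.cumsum(d[:-1, 1])]) - dy_dt * t[:-1]
    a0 = pts[0, 0] + np.sum(d[:, 0] / (2.0 * dt) * dt2 + xi * dt) / T
    c0 = pts[0, 1] + np.sum(d[:, 1] / (2.0 * dt) * dt2 + delta * dt) / T

    coeffs = np.column_stack([a, b, c, dd])
    return EFDSet(N=N, a0=float(a0), c0=float(c0), coeffs=coeffs, T=float(T))


def _evaluate_series(
    efd: EFDSet, t: np.ndarray, N_used: int | None = None, with_offset: bool = True
) -> np.ndarray:
    """Evaluate the truncated Fourier series at parameters ``t`` (same period as fit)."""
    N_used = efd.N if N_used is None else N_used
    n = np.arange(1, N_used + 1)[:, None]
    phi = 2.0 * np.pi * n * t[None, :] / efd.T
    cos_np, sin_np = np.cos(phi), np.sin(phi)
    a, b, c, d = (efd.coeffs[:N_used, k] for k in range(4))
    x = a @ cos_np + b @ sin_np
    y = c @ cos_np + d @ sin_np
    if with_offset:
        x = x + efd.a0
        y = y + efd.c0
    return np.column_stack([x, y])


def approximation_error(contour: ContourSequence, efd: EFDSet, N_used: int) -> float:
    """Proportion of contour variation not captured by the first N harmonics.

    E^2_N = sum_p [(x_p - x_Np)^2 + (y_p - y_Np)^2]
          / sum_p [(x_p - xbar)^2 + (y_p - ybar)^2]

    where (x_Np, y_Np) is the series truncated at N_used evaluated at
    pixel p's arc-length parameter and (xbar, ybar) is the centroid.
    """
    if N_used < 1 or N_used > efd.N:
        raise ValueError("N_used must be in 1..efd.N")
    pts = contour.points
    _, _, t = _arc_length_params(pts)
    approx = _evaluate_series(efd, t[:-1], N_used=N_used, with_offset=True)
    centered = pts - pts.mean(axis=0)
    denom = float(np.sum(centered**2))
    if denom <= 0.0:
        raise ValueError("contour has zero coordinate variance")
    return float(np.sum((pts - approx) ** 2) / denom)


def _phase_shift(coeffs: np.ndarray, theta: float) -> np.ndarray:
    """Shift the trace starting point by phase theta (per-harmonic rotation n*theta)."""
    N = coeffs.shape[0]
    out = np.empty_like(coeffs)
    for i in range(N):
        nt = (i + 1) * theta
        rot = np.array([[np.cos(nt), -np.sin(nt)], [np.sin(nt), np.cos(nt)]])
        m = coeffs[i].reshape(2, 2) @ rot
        out[i] = m.ravel()
    return out


def _spatial_rotate(coeffs: np.ndarray, psi: float) -> np.ndarray:
    """Rotate the contour in the plane by -psi (align major axis with x)."""
    rot = np.array([[np.cos(psi), np.sin(psi)], [-np.sin(psi), np.cos(psi)]])
    out = np.empty_like(coeffs)
    for i in range(coeffs.shape[0]):
        out[i] = (rot @ coeffs[i].reshape(2, 2)).ravel()
    return out


def standardize(efd: EFDSet, return_full: bool = False):
    """Standardize EFDs against size, rotation and starting point.

    The transform (i) shifts the starting-point phase so the trace
    starts at an end of the first-harmonic ellipse's major axis,
    (ii) rotates the plane so that axis lies along x, and (iii) divides
    by the semi-major axis length.  Afterwards a_1 = 1, b_1 = 0, c_1 = 0
    and the free coefficients form the 4N-3 shape vector.

    Both the phase and the rotation admit a joint half-period / 180-degree
    ambiguity (two valid candidates); it is resolved deterministically by
    taking the candidate with the larger a_2 (ties: smaller phase shift).
    Reflection (chirality) is not normalized, so the sign of d_1 records
    the traversal handedness.
    """
    co = efd.coeffs
    a1, b1, c1, d1 = co[0]
    theta0 = 0.5 * np.arctan2(
        2.0 * (a1 * b1 + c1 * d1), a1**2 + c1**2 - b1**2 - d1**2
    )

    candidates = []
    for theta in (theta0, theta0 + np.pi):
        shifted = _phase_shift(co, theta)
        psi = np.arctan2(shifted[0, 2], shifted[0, 0])
        rotated = _spatial_rotate(shifted, psi)
        scale = rotated[0, 0]  # semi-major axis length after alignment
        if scale <= 1e-12 * max(1.0, np.abs(co[0]).max()):
            raise ValueError("degenerate first-harmonic ellipse; cannot standardize")
        candidates.append((rotated / scale, theta % (2.0 * np.pi)))

    a2_key = [cand[0][1, 0] if efd.N >= 2 else 0.0 for cand in candidates]
    if a2_key[0] == a2_key[1]:
        best = candidates[0] if candidates[0][1] <= candidates[1][1] else candidates[1]
    else:
        best = candidates[int(np.argmax(a2_key))]

    raw = best[0]
    std = raw.copy()
    # exact by construction; remove residual floating-point dust
    std[0, 0], std[0, 1], std[0, 2] = 1.0, 0.0, 0.0
    vec = ShapeVector.from_coeffs(std)
    if return_full:
        # raw first-harmonic row kept as computed, for inspection
        return vec, EFDSet(N=efd.N, a0=0.0, c0=0.0, coeffs=raw, T=efd.T)
    return vec


def average_shape(vectors: list[ShapeVector]) -> ShapeVector:
    """Element-wise arithmetic mean of shape vectors (same harmonic count)."""
    if not vectors:
        raise ValueError("cannot average an empty list of shape vectors")
    N = vectors[0].N
    if any(v.N != N for v in vectors):
        raise ValueError("all shape vectors must share the same harmonic count N")
    stacked = np.stack([v.values for v in vectors])
    return ShapeVector(values=stacked.mean(axis=0), N=N)


def reconstruct_contour(
    shape: ShapeVector | EFDSet, num_points: int = 100, T: float = 1.0
) -> ContourSequence:
    """Evaluate the Fourier series at num_points equally spaced parameters.

    Offsets a_0, c_0 are ignored (set to zero): the reconstruction is a
    pure shape, centred at the origin.  A ShapeVector input implies the
    standardized first harmonic a_1 = 1, b_1 = 0, c_1 = 0.
    """
    if num_points < 3:
        raise ValueError("num_points must be >= 3")
    efd = shape.to_efd(T=T) if isinstance(shape, ShapeVector) else shape
    efd = EFDSet(N=efd.N, a0=0.0, c0=0.0, coeffs=efd.coeffs, T=T)
    t = np.arange(num_points) * (T / num_points)
    pts = _evaluate_series(efd, t, with_offset=False)
    return ContourSequence(points=pts)
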