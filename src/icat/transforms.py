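"""Planar affine transforms — the universal currency of the pipeline.

Every tile carries one :class:`AffineTransform2D` mapping its local pixel
coordinates into the section world frame (the high-magnification EM pixel
grid, 5 nm px⁻¹). Conventions: coordinates are 0-based with pixel centers at
integer positions, x to the right and y down; points are applied as columns,
``p' = A @ p + t``; the serialized order is row-major
``[a11, a12, tx, a21, a22, ty]``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import SingularTransformError

__all__ = [
    "AffineTransform2D",
    "compose",
    "invert",
    "apply_transform",
]

_DET_EPS = 1e-12


@dataclass(frozen=True)
class AffineTransform2D:
    """Invertible 6-parameter planar affine transform.

    ``a11..a22`` form the dimensionless linear part, ``tx, ty`` the
    translation in world pixels.
    """

    a11: float = 1.0
    a12: float = 0.0
    a21: float = 0.0
    a22: float = 1.0
    tx: float = 0.0
    ty: float = 0.0

    def __post_init__(self) -> None:
        if not all(
            math.isfinite(v)
            for v in (self.a11, self.a12, self.a21, self.a22, self.tx, self.ty)
        ):
            raise SingularTransformError("non-finite transform coefficients")
        if abs(self.det) < _DET_EPS:
            raise SingularTransformError(
                f"singular transform (det={self.det:.3e})"
            )

    # ---------------------------------------------------------------- views
    @property
    def det(self) -> float:
        return self.a11 * self.a22 - self.a12 * self.a21

    @property
    def linear(self) -> np.ndarray:
        """2×2 linear part."""
        return np.array([[self.a11, self.a12], [self.a21, self.a22]], dtype=float)

    @property
    def translation(self) -> np.ndarray:
        return np.array([self.tx, self.ty], dtype=float)

    @property
    def matrix(self) -> np.ndarray:
        """Homogeneous 3×3 matrix."""
        return np.array(
            [
                [self.a11, self.a12, self.tx],
                [self.a21, self.a22, self.ty],
                [0.0, 0.0, 1.0],
            ],
            dtype=float,
        )

    def to_params(self) -> list[float]:
        """Row-major ``[a11, a12, tx, a21, a22, ty]`` (the on-disk order)."""
        return [self.a11, self.a12, self.tx, self.a21, self.a22, self.ty]

    # --------------------------------------------------------- constructors
    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls()

    @classmethod
    def from_params(cls, params) -> "AffineTransform2D":
        a11, a12, tx, a21, a22, ty = (float(v) for v in params)
        return cls(a11, a12, a21, a22, tx, ty)

    @classmethod
    def from_matrix(cls, m) -> "AffineTransform2D":
        m = np.asarray(m, dtype=float)
        return cls(m[0, 0], m[0, 1], m[1, 0], m[1, 1], m[0, 2], m[1, 2])

    @classmethod
    def from_translation(cls, tx: float, ty: float) -> "AffineTransform2D":
        return cls(tx=float(tx), ty=float(ty))

    @classmethod
    def from_rotation(cls, degrees: float) -> "AffineTransform2D":
        c, s = math.cos(math.radians(degrees)), math.sin(math.radians(degrees))
        return cls(c, -s, s, c, 0.0, 0.0)

    @classmethod
    def from_scale(cls, sx: float, sy: float | None = None) -> "AffineTransform2D":
        sy = sx if sy is None else sy
        return cls(float(sx), 0.0, 0.0, float(sy), 0.0, 0.0)

    @classmethod
    def from_similarity(
        cls, scale: float, degrees: float, tx: float = 0.0, ty: float = 0.0
    ) -> "AffineTransform2D":
        c = scale * math.cos(math.radians(degrees))
        s = scale * math.sin(math.radians(degrees))
        return cls(c, -s, s, c, float(tx), float(ty))

    # ----------------------------------------------------------- operations
    def apply(self, points) -> np.ndarray:
        """Map an (N, 2) array of (x, y) points; a single point is accepted."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.linear.T + self.translation
        return out if np.asarray(points).ndim > 1 else out[0]

    def compose(self, inner: "AffineTransform2D") -> "AffineTransform2D":
        """Return self ∘ inner (``inner`` applied first)."""
        return AffineTransform2D.from_matrix(self.matrix @ inner.matrix)

    def invert(self) -> "AffineTransform2D":
        a = self.linear
        try:
            ainv = np.linalg.inv(a)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
            raise SingularTransformError(str(exc)) from exc
        t = -ainv @ self.translation
        return AffineTransform2D(
            ainv[0, 0], ainv[0, 1], ainv[1, 0], ainv[1, 1], t[0], t[1]
        )

    def almost_equals(self, other: "AffineTransform2D", tol: float = 1e-9) -> bool:
        return bool(np.allclose(self.matrix, other.matrix, atol=tol, rtol=0.0))

    def __matmul__(self, inner: "AffineTransform2D") -> "AffineTransform2D":
        return self.compose(inner)


def compose(outer: AffineTransform2D, inner: AffineTransform2D) -> AffineTransform2D:
    """``apply(compose(outer, inner), p) == apply(outer, apply(inner, p))``."""
    return outer.compose(inner)


def invert(transform: AffineTransform2D) -> AffineTransform2D:
    return transform.invert()


def apply_transform(transform: AffineTransform2D, points) -> np.ndarray:
    return transform.apply(points)
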