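"""Spherocylindrical (rod) cell geometry.

A rod-shaped bacterium of total length ``L`` and width ``w`` is modelled as a
spherocylinder: a cylinder of radius ``R = w/2`` and length ``L - w`` capped by
two hemispheres, with the long axis along x and the centre at the origin.  The
focal-plane silhouette of this body is a stadium shape: all 2-D points within
``R`` of the centreline segment from ``(-a, 0)`` to ``(+a, 0)`` where
``a = (L - w) / 2``.

All lengths are in μm.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Spherocylinder"]


class Spherocylinder:
    """Rod cell body used both as a 2-D silhouette and a 3-D surface."""

    def __init__(self, length_um: float, width_um: float):
        if not np.isfinite(length_um) or not np.isfinite(width_um):
            raise ValueError("cell dimensions must be finite")
        if not (length_um >= width_um > 0):
            raise ValueError(
                f"require length >= width > 0, got {length_um} x {width_um}"
            )
        self.length = float(length_um)
        self.width = float(width_um)
        self.radius = self.width / 2.0
        #: half-length of the cylindrical part of the centreline
        self.half_axis = (self.length - self.width) / 2.0

    # ------------------------------------------------------------------ 2-D

    def _axis_foot(self, pts: np.ndarray) -> np.ndarray:
        """Nearest centreline point for each 2-D point, shape (..., 2)."""
        x = np.clip(pts[..., 0], -self.half_axis, self.half_axis)
        out = np.zeros_like(pts)
        out[..., 0] = x
        return out

    def dist_to_axis(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        foot = self._axis_foot(pts)
        return np.hypot(pts[..., 0] - foot[..., 0], pts[..., 1] - foot[..., 1])

    def contains_2d(self, pts: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        """Boolean mask: which points lie inside the silhouette."""
        return self.dist_to_axis(pts) <= self.radius + tol

    def reflect_into_2d(self, pts: np.ndarray, max_iter: int = 8) -> np.ndarray:
        """Fold points outside the silhouette back across the boundary.

        For a point at distance ``d > R`` from the centreline the excess
        ``d - R`` is mirrored inward along the local outward normal.  Steps
        much larger than the cell may need several folds; any residue is
        finally clamped onto the boundary.
        """
        pts = np.array(pts, dtype=float)
        flat = pts.reshape(-1, 2)
        for _ in range(max_iter):
            foot = self._axis_foot(flat)
            delta = flat - foot
            d = np.hypot(delta[:, 0], delta[:, 1])
            outside = d > self.radius + 1e-12
            if not outside.any():
                break
            # outward normal; points exactly on the axis have no direction,
            # push them along +y (measure-zero event)
            n = np.zeros_like(delta)
            nz = d > 0
            n[nz] = delta[nz] / d[nz, None]
            n[~nz] = [0.0, 1.0]
            flat[outside] -= 2.0 * (d[outside] - self.radius)[:, None] * n[outside]
        else:  # still outside after max_iter folds: clamp to boundary
            flat = self.clamp_to_silhouette(flat)
        return flat.reshape(pts.shape)

    def clamp_to_silhouette(self, pts: np.ndarray) -> np.ndarray:
        """Project outside points onto the boundary; inside points unchanged."""
        pts = np.array(pts, dtype=float)
        flat = pts.reshape(-1, 2)
        foot = self._axis_foot(flat)
        delta = flat - foot
        d = np.hypot(delta[:, 0], delta[:, 1])
        outside = d > self.radius
        scale = np.ones_like(d)
        scale[outside] = self.radius / d[outside]
        flat = foot + delta * scale[:, None]
        return flat.reshape(pts.shape)

    def sample_uniform_2d(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Uniform points in the silhouette by rejection from the bounding box."""
        out = np.empty((n, 2))
        filled = 0
        half_l = self.length / 2.0
        while filled < n:
            m = max(2 * (n - filled), 16)
            cand = np.column_stack(
                [
                    rng.uniform(-half_l, half_l, m),
                    rng.uniform(-self.radius, self.radius, m),
                ]
            )
            good = cand[self.contains_2d(cand)]
            take = min(len(good), n - filled)
            out[filled : filled + take] = good[:take]
            filled += take
        return out

    def boundary_perimeter(self) -> float:
        return 2.0 * (self.length - self.width) + np.pi * self.width

    def boundary_points_2d(
        self, n: int, rng: np.random.Generator
    ) -> tuple[np.ndarray, np.ndarray]:
        """Uniform points on the silhouette boundary with outward unit normals."""
        a, r = self.half_axis, self.radius
        s = rng.uniform(0.0, self.boundary_perimeter(), n)
        pts = np.empty((n, 2))
        nrm = np.empty((n, 2))
        flat = 2.0 * a  # length of each straight edge
        for i, si in enumerate(s):
            if si < flat:  # top edge
                pts[i] = (-a + si, r)
                nrm[i] = (0.0, 1.0)
            elif si < 2 * flat:  # bottom edge
                pts[i] = (-a + (si - flat), -r)
                nrm[i] = (0.0, -1.0)
            else:  # two semicircular caps, right then left
                t = si - 2 * flat
                if t < np.pi * r:
                    ang = -np.pi / 2 + t / r
                    centre = np.array([a, 0.0])
                else:
                    ang = np.pi / 2 + (t - np.pi * r) / r
                    centre = np.array([-a, 0.0])
                nrm[i] = (np.cos(ang), np.sin(ang))
                pts[i] = centre + r * nrm[i]
        return pts, nrm

    # ------------------------------------------------------------------ 3-D

    def project_to_surface(self, pts: np.ndarray) -> np.ndarray:
        """Radially re-project 3-D points onto the spherocylinder surface.

        Cylinder part: rescale (y, z) to radius R at fixed x.  Cap part:
        rescale the vector from the cap centre.  The axis itself is a
        measure-zero degenerate set; such points are pushed along +z.
        """
        pts = np.array(pts, dtype=float)
        flat = pts.reshape(-1, 3)
        a, r = self.half_axis, self.radius
        on_cyl = np.abs(flat[:, 0]) <= a
        # cylinder
        yz = flat[on_cyl, 1:]
        d = np.hypot(yz[:, 0], yz[:, 1])
        deg = d < 1e-300
        yz[deg] = [0.0, 1e-300]
        d[deg] = 1e-300
        flat[on_cyl, 1:] = yz * (r / d)[:, None]
        # caps
        cap = ~on_cyl
        centres = np.zeros((cap.sum(), 3))
        centres[:, 0] = np.sign(flat[cap, 0]) * a
        v = flat[cap] - centres
        dv = np.linalg.norm(v, axis=1)
        degc = dv < 1e-300
        v[degc] = [0.0, 0.0, 1e-300]
        dv[degc] = 1e-300
        flat[cap] = centres + v * (r / dv)[:, None]
        return flat.reshape(pts.shape)

    def surface_normal(self, pts: np.ndarray) -> np.ndarray:
        """Outward unit normals for points assumed on the surface."""
        pts = np.asarray(pts, dtype=float)
        flat = pts.reshape(-1, 3)
        a = self.half_axis
        n = np.empty_like(flat)
        on_cyl = np.abs(flat[:, 0]) <= a
        n[on_cyl, 0] = 0.0
        n[on_cyl, 1:] = flat[on_cyl, 1:]
        cap = ~on_cyl
        n[cap] = flat[cap]
        n[cap, 0] -= np.sign(flat[cap, 0]) * a
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return (n / norm).reshape(pts.shape)

    def sample_uniform_surface(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Uniform points on the 3-D surface (area-weighted cylinder vs caps)."""
        a, r = self.half_axis, self.radius
        area_cyl = 2 * np.pi * r * (2 * a)
        area_caps = 4 * np.pi * r * r  # two hemispheres = one full sphere
        on_cyl = rng.random(n) < area_cyl / (area_cyl + area_caps)
        pts = np.empty((n, 3))
        m = int(on_cyl.sum())
        phi = rng.uniform(0, 2 * np.pi, m)
        pts[on_cyl, 0] = rng.uniform(-a, a, m)
        pts[on_cyl, 1] = r * np.cos(phi)
        pts[on_cyl, 2] = r * np.sin(phi)
        k = n - m
        v = rng.normal(size=(k, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        v[:, 0] = np.abs(v[:, 0]) * np.sign(rng.random(k) - 0.5)
        pts[~on_cyl] = v * r
        pts[~on_cyl, 0] += np.sign(v[:, 0]) * a
        return pts
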