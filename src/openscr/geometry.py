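"""State-space grid and line-transect geometry.

The region of inference S is discretized into a regular grid of square pixels
(row-major, optionally masked), and detection is driven by ``mindist``: the
Euclidean distance from an individual's location to the closest point on the
closest surveyed transect segment.

Distances use the clamped-projection form

    u = clip(((p - a) . (b - a)) / |b - a|^2, 0, 1),   d = |p - (a + u (b - a))|

which equals the perpendicular distance when the foot of the perpendicular
falls inside the segment and the nearer-endpoint distance otherwise.  Unlike
a slope/intercept formulation it is well defined for north-south (vertical)
segments and is invariant to endpoint order.

All coordinates are in scaled planar units (one unit is typically 10 km);
no geodesic handling is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class GeometryError(ValueError):
    """Invalid geometric input (zero-length segment, bad grid spec...)."""


class OutOfStateSpaceError(GeometryError):
    """A point falls outside the state-space grid (or in a masked pixel)."""


@dataclass(frozen=True)
class Segment:
    """A straight transect segment surveyed on one secondary occasion.

    Parameters
    ----------
    x1, y1, x2, y2
        Endpoint coordinates (scaled units).  Endpoints must be distinct.
    platform
        Index of the survey platform that flew this segment (selects the
        detection-function family).
    t, k
        Primary period and secondary occasion indices (0-based internally).
    """

    x1: float
    y1: float
    x2: float
    y2: float
    platform: int = 0
    t: int = 0
    k: int = 0

    def __post_init__(self) -> None:
        if self.x1 == self.x2 and self.y1 == self.y2:
            raise GeometryError(
                f"zero-length segment at ({self.x1}, {self.y1})"
            )

    @property
    def coords(self) -> np.ndarray:
        return np.array([self.x1, self.y1, self.x2, self.y2], dtype=float)

    @property
    def length(self) -> float:
        return float(np.hypot(self.x2 - self.x1, self.y2 - self.y1))


def _as_segment_array(segments) -> tuple[np.ndarray, np.ndarray]:
    """Coerce a list of Segment (or (L,4) array) to coords and platforms."""
    if isinstance(segments, np.ndarray):
        coords = np.atleast_2d(np.asarray(segments, dtype=float))
        platforms = np.zeros(coords.shape[0], dtype=int)
    else:
        segments = list(segments)
        if not segments:
            return np.empty((0, 4)), np.empty(0, dtype=int)
        coords = np.array([s.coords for s in segments], dtype=float)
        platforms = np.array([s.platform for s in segments], dtype=int)
    if coords.ndim != 2 or coords.shape[1] != 4:
        raise GeometryError("segment coordinates must have shape (L, 4)")
    return coords, platforms


def segment_point_distances(points: np.ndarray, seg_coords: np.ndarray) -> np.ndarray:
    """Distances from N points to L segments.

    Parameters
    ----------
    points : (N, 2) array
    seg_coords : (L, 4) array of ``x1, y1, x2, y2``

    Returns
    -------
    (N, L) array of Euclidean point-to-segment distances.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    seg_coords = np.atleast_2d(np.asarray(seg_coords, dtype=float))
    a = seg_coords[:, 0:2]  # (L, 2)
    b = seg_coords[:, 2:4]
    ab = b - a
    denom = np.einsum("ld,ld->l", ab, ab)  # |b-a|^2, (L,)
    if np.any(denom == 0.0):
        raise GeometryError("zero-length segment")
    ap = points[:, None, :] - a[None, :, :]  # (N, L, 2)
    u = np.einsum("nld,ld->nl", ap, ab) / denom
    u = np.clip(u, 0.0, 1.0)
    closest = a[None, :, :] + u[..., None] * ab[None, :, :]
    diff = points[:, None, :] - closest
    return np.sqrt(np.einsum("nld,nld->nl", diff, diff))


def point_segment_distance(px: float, py: float, seg) -> float:
    """Distance from point ``(px, py)`` to the closed segment ``seg``.

    ``seg`` may be a :class:`Segment` or a length-4 coordinate sequence.
    """
    if isinstance(seg, Segment):
        coords = seg.coords[None, :]
    else:
        coords = np.asarray(seg, dtype=float).reshape(1, 4)
        if coords[0, 0] == coords[0, 2] and coords[0, 1] == coords[0, 3]:
            raise GeometryError("zero-length segment")
    return float(segment_point_distances(np.array([[px, py]]), coords)[0, 0])


def min_distance_to_transects(px: float, py: float, segments) -> tuple[float, int]:
    """``mindist`` and the index of the nearest segment.

    The nearest segment's platform selects the detection function.  Ties
    (a probability-zero event for continuous locations) go to the lowest
    segment index via ``argmin``.

    Raises
    ------
    GeometryError
        If ``segments`` is empty (a no-effort occasion).
    """
    coords, _ = _as_segment_array(segments)
    if coords.shape[0] == 0:
        raise GeometryError("no transect segments surveyed on this occasion")
    d = segment_point_distances(np.array([[px, py]]), coords)[0]
    idx = int(np.argmin(d))
    return float(d[idx]), idx


# ---------------------------------------------------------------------------
# State-space grid
# ---------------------------------------------------------------------------

@dataclass
class StateSpaceGrid:
    """Regular-grid discretization of the state space S.

    Pixels are squares of width ``side`` laid out row-major from
    ``(origin_x, origin_y)`` (south-west corner).  ``valid_mask`` marks which
    of the ``n_x * n_y`` cells belong to S; the G valid pixels are indexed
    ``0..G-1`` in row-major order of the underlying full grid.
    """

    origin_x: float
    origin_y: float
    side: float
    n_x: int
    n_y: int
    valid_mask: np.ndarray = field(default=None)  # (n_x*n_y,) bool

    def __post_init__(self) -> None:
        if self.side <= 0 or self.n_x <= 0 or self.n_y <= 0:
            raise GeometryError("grid dimensions and pixel side must be positive")
        n_cells = self.n_x * self.n_y
        if self.valid_mask is None:
            self.valid_mask = np.ones(n_cells, dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool).ravel()
            if self.valid_mask.size != n_cells:
                raise GeometryError("valid_mask size does not match grid")
        if not self.valid_mask.any():
            raise GeometryError("grid has no valid pixels (G must be >= 1)")
        cols = np.arange(self.n_x)
        rows = np.arange(self.n_y)
        cx = self.origin_x + (cols + 0.5) * self.side
        cy = self.origin_y + (rows + 0.5) * self.side
        xx, yy = np.meshgrid(cx, cy)  # row-major: row = y index
        self._centers_full = np.column_stack([xx.ravel(), yy.ravel()])
        self.valid_to_full = np.flatnonzero(self.valid_mask)
        self.full_to_valid = np.full(n_cells, -1, dtype=int)
        self.full_to_valid[self.valid_to_full] = np.arange(self.valid_to_full.size)
        self.pixel_centers = self._centers_full[self.valid_to_full]

    @property
    def G(self) -> int:
        """Number of valid pixels."""
        return int(self.valid_to_full.size)

    @property
    def pixel_area(self) -> float:
        return self.side ** 2

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(x_min, y_min, x_max, y_max) of the full bounding box."""
        return (
            self.origin_x,
            self.origin_y,
            self.origin_x + self.n_x * self.side,
            self.origin_y + self.n_y * self.side,
        )

    @property
    def diameter(self) -> float:
        """Diagonal of the bounding box — used as a default prior upper bound
        for spatial scale parameters."""
        return float(np.hypot(self.n_x * self.side, self.n_y * self.side))

    def pixel_of_point(self, px, py) -> np.ndarray | int:
        """Valid-pixel index containing point(s); half-open convention.

        Each pixel owns ``[x_lo, x_lo + side) x [y_lo, y_lo + side)``, so a
        point exactly on a shared edge belongs to the higher-index pixel.

        Raises
        ------
        OutOfStateSpaceError
            For points outside the bounding box or in masked pixels.
        """
        px = np.asarray(px, dtype=float)
        py = np.asarray(py, dtype=float)
        scalar = px.ndim == 0
        px, py = np.atleast_1d(px), np.atleast_1d(py)
        col = np.floor((px - self.origin_x) / self.side).astype(int)
        row = np.floor((py - self.origin_y) / self.side).astype(int)
        bad = (col < 0) | (col >= self.n_x) | (row < 0) | (row >= self.n_y)
        if np.any(bad):
            i = int(np.flatnonzero(bad)[0])
            raise OutOfStateSpaceError(
                f"point ({px[i]}, {py[i]}) outside the state-space bounding box"
            )
        full = row * self.n_x + col
        g = self.full_to_valid[full]
        if np.any(g < 0):
            i = int(np.flatnonzero(g < 0)[0])
            raise OutOfStateSpaceError(
                f"point ({px[i]}, {py[i]}) falls in a masked pixel"
            )
        return int(g[0]) if scalar else g

    def pixel_lower_corner(self, g) -> np.ndarray:
        """South-west corner(s) of valid pixel(s) g, shape (..., 2)."""
        centers = self.pixel_centers[np.asarray(g)]
        return centers - self.side / 2.0


def build_grid(
    origin_x: float,
    origin_y: float,
    side: float,
    n_x: int,
    n_y: int,
    valid_mask: np.ndarray | None = None,
) -> StateSpaceGrid:
    """Construct a :class:`StateSpaceGrid` (thin convenience wrapper)."""
    return StateSpaceGrid(origin_x, origin_y, side, n_x, n_y, valid_mask)


def pairwise_center_distances(grid: StateSpaceGrid) -> np.ndarray:
    """(G, G) matrix of Euclidean distances between valid-pixel centers."""
    c = grid.pixel_centers
    diff = c[:, None, :] - c[None, :, :]
    return np.sqrt(np.einsum("abd,abd->ab", diff, diff))
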