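"""Coupled hexagonal/triangular lattice geometry.

Cell agents live on a hexagonal grid addressed by cube coordinates
``(u, v, w, z)`` with ``u + v + w = 0``; ``z`` indexes the 2D layer for 3D
simulations.  Molecules diffuse on triangular lattices addressed by
rectangular coordinates ``(x, y, z)``: the triangle at column ``x``, row
``y`` points *up* when ``x + y`` is even and *down* otherwise.

Each hexagon owns six triangles.  The mapping used here anchors hexagon
``(u, v, w)`` at rectangular position::

    x0 = 3 * (u + w) + x_offset      (= -3 v + x_offset)
    y0 = u - w + y_offset

and the hexagon covers the 2 x 3 block ``{x0..x0+2} x {y0..y0+1}``::

            p5  p0  p1          (x0,y0) (x0+1,y0) (x0+2,y0)
            p4  p3  p2          (x0,y0+1) (x0+1,y0+1) (x0+2,y0+1)

with position ``p`` indexed clockwise from the upper center triangle.
Any consistent partition of the triangular lattice into hexagons
reproduces the same physics; this one keeps the arithmetic integral and
the block contiguous for fast array access.

The grid has radius ``R`` (hexes with radius index ``r <= R - 1`` may hold
agents) plus a margin of ``M`` hexes that carries lattice sites, and
vasculature sources, but no agents.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# six in-layer neighbor offsets (Δu, Δv, Δw)
IN_LAYER_NEIGHBORS = (
    (0, +1, -1), (0, -1, +1), (-1, +1, 0),
    (+1, -1, 0), (-1, 0, +1), (+1, 0, -1),
)

# vertical neighbor offsets, selected by the offset class of the *target*
# layer: class 0 = aligned, class 1 = offset a, class 2 = offset b.  The
# directly-stacked location is always a neighbor; offset layers add the
# printed triplet.
_OFFSET_A_UP = ((+1, 0, -1), (-1, +1, 0), (0, -1, +1))
_OFFSET_B_UP = ((0, +1, -1), (-1, 0, +1), (+1, -1, 0))
_OFFSET_A_DOWN = ((-1, +1, 0), (0, -1, +1), (+1, 0, -1))
_OFFSET_B_DOWN = ((0, +1, -1), (-1, 0, +1), (+1, -1, 0))


def layer_offset_class(z: int) -> int:
    """Offset class of layer ``z``: 0 = none, 1 = offset a, 2 = offset b.

    Layer 0 has no offset, offset a always has offset b above, offset b
    has no offset above, which forces the period-3 pattern.
    """
    return z % 3


def hex_radius(u: int, v: int, w: int) -> int:
    """Ring index of a hexagon: 0 at the center, r on the r-th ring."""
    if u + v + w != 0:
        raise ValueError(f"invalid hex coordinate ({u}, {v}, {w}): u+v+w != 0")
    return (abs(u) + abs(v) + abs(w)) // 2


def max_locations(r: int) -> int:
    """Number of hexagonal locations on the ring at radius ``r``."""
    if r < 0:
        raise ValueError("radius must be non-negative")
    return 1 if r == 0 else 6 * r


def hex_ring(r: int) -> list[tuple[int, int, int]]:
    """All (u, v, w) on the ring of radius ``r``, in a fixed order."""
    if r == 0:
        return [(0, 0, 0)]
    out = []
    # walk the ring starting from (r, -r, 0) using the six directions
    u, v, w = r, -r, 0
    for du, dv, dw in ((-1, 0, +1), (-1, +1, 0), (0, +1, -1),
                       (+1, 0, -1), (+1, -1, 0), (0, -1, +1)):
        for _ in range(r):
            out.append((u, v, w))
            u, v, w = u + du, v + dv, w + dw
    return out


def hex_disk(r: int) -> list[tuple[int, int, int]]:
    """All (u, v, w) with radius <= r."""
    out = []
    for rr in range(r + 1):
        out.extend(hex_ring(rr))
    return out


# the five 60-degree rotation images of (u, v, w), used by the symmetry metric
SYMMETRY_MAPS = (
    lambda u, v, w: (-w, -u, -v),
    lambda u, v, w: (v, w, u),
    lambda u, v, w: (-u, -v, -w),
    lambda u, v, w: (w, u, v),
    lambda u, v, w: (-v, -w, -u),
)


@dataclass(frozen=True)
class HexGeometry:
    """Geometry of one simulation environment.

    Parameters
    ----------
    R : int
        Grid radius in hexes; agents occupy radii ``0..R-1``.
    M : int
        Margin in hexes between the agent region and the lattice edge;
        margin hexes carry lattice sites and act as vasculature sources.
    H : int
        Height parameter; layers are ``z = -(H-1) .. H-1``.
    hex_size : float
        Side-to-side width of a hexagon in μm.
    max_height : float
        Height of one layer (Δz) in μm.
    slab_height : float
        Absolute packing ceiling of a location in μm (volume cap).
    """

    R: int
    M: int = 0
    H: int = 1
    hex_size: float = 30.0
    max_height: float = 8.7
    slab_height: float = 17.4

    def __post_init__(self):
        if self.R < 1 or self.M < 0 or self.H < 1:
            raise ValueError("require R >= 1, M >= 0, H >= 1")

    # -- scalar geometry ---------------------------------------------------

    @property
    def hex_area(self) -> float:
        """Area of one hexagon, μm² (side-to-side width w: A = √3/2 w²)."""
        return np.sqrt(3.0) / 2.0 * self.hex_size ** 2

    @property
    def hex_volume(self) -> float:
        """Nutrient-exchange volume of one location, μm³ (area x Δz)."""
        return self.hex_area * self.max_height

    @property
    def location_capacity(self) -> float:
        """Hard cap on summed agent volume in a location, μm³."""
        return self.hex_area * self.slab_height

    @property
    def ds(self) -> float:
        """Triangular lattice spacing Δs = half of the hexagon width."""
        return self.hex_size / 2.0

    @property
    def dz(self) -> float:
        return self.max_height

    @property
    def lattice_radius(self) -> int:
        """Largest hex radius index covered by the molecule lattices."""
        return self.R + self.M - 1

    @property
    def n_layers(self) -> int:
        return 2 * self.H - 1

    @property
    def lattice_shape(self) -> tuple[int, int, int]:
        rm = self.lattice_radius
        return (self.n_layers, 4 * rm + 2, 6 * rm + 3)

    # -- membership --------------------------------------------------------

    def _check(self, u, v, w, z):
        if u + v + w != 0:
            raise ValueError(f"invalid hex coordinate ({u},{v},{w}): u+v+w != 0")
        if abs(z) > self.H - 1:
            raise ValueError(f"layer {z} outside |z| <= {self.H - 1}")

    def in_lattice(self, u, v, w, z=0) -> bool:
        return (u + v + w == 0 and abs(z) <= self.H - 1
                and hex_radius(u, v, w) <= self.lattice_radius)

    def in_agent_region(self, u, v, w, z=0) -> bool:
        return (u + v + w == 0 and abs(z) <= self.H - 1
                and hex_radius(u, v, w) <= self.R - 1)

    def is_margin(self, u, v, w, z=0) -> bool:
        r = hex_radius(u, v, w)
        return self.R - 1 < r <= self.lattice_radius

    # -- neighborhoods -----------------------------------------------------

    def neighbors(self, u, v, w, z=0) -> list[tuple[int, int, int, int]]:
        """In-grid neighbors of an agent location (agent region only)."""
        self._check(u, v, w, z)
        if not self.in_agent_region(u, v, w, z):
            raise ValueError(f"({u},{v},{w},{z}) outside the agent grid")
        out = []
        for du, dv, dw in IN_LAYER_NEIGHBORS:
            c = (u + du, v + dv, w + dw, z)
            if self.in_agent_region(*c):
                out.append(c)
        if self.H > 1:
            for dz, a_set, b_set in ((+1, _OFFSET_A_UP, _OFFSET_B_UP),
                                     (-1, _OFFSET_A_DOWN, _OFFSET_B_DOWN)):
                zt = z + dz
                if abs(zt) > self.H - 1:
                    continue
                cls = layer_offset_class(zt)
                cands = [(u, v, w, zt)]
                if cls == 1:
                    cands += [(u + d[0], v + d[1], w + d[2], zt) for d in a_set]
                elif cls == 2:
                    cands += [(u + d[0], v + d[1], w + d[2], zt) for d in b_set]
                out.extend(c for c in cands if self.in_agent_region(*c))
        return out

    # -- hex <-> triangle coupling -----------------------------------------

    def hex_anchor(self, u, v, w) -> tuple[int, int]:
        """(x0, y0) of the upper-left triangle of the hexagon's block."""
        rm = self.lattice_radius
        return (3 * (u + w) + 3 * rm, (u - w) + 2 * rm)

    def hex_to_triangles(self, u, v, w, z=0) -> list[tuple[int, int, int]]:
        """Six (x, y, z) triangles of a hexagon, clockwise from upper center."""
        self._check(u, v, w, z)
        if not self.in_lattice(u, v, w, z):
            raise ValueError(f"({u},{v},{w},{z}) outside the lattice region")
        x0, y0 = self.hex_anchor(u, v, w)
        return [
            (x0 + 1, y0, z),      # p0 upper center
            (x0 + 2, y0, z),      # p1
            (x0 + 2, y0 + 1, z),  # p2
            (x0 + 1, y0 + 1, z),  # p3 lower center
            (x0, y0 + 1, z),      # p4
            (x0, y0, z),          # p5
        ]

    def triangle_index_arrays(self, u, v, w, z=0):
        """(zi, yi, xi) integer arrays indexing the hexagon's six triangles."""
        tris = self.hex_to_triangles(u, v, w, z)
        x = np.array([t[0] for t in tris])
        y = np.array([t[1] for t in tris])
        zi = np.full(6, z + self.H - 1)
        return zi, y, x

    # -- lattice masks -----------------------------------------------------

    def lattice_masks(self):
        """Boolean masks over the lattice array: (valid, source).

        ``valid`` marks triangles belonging to any in-lattice hexagon;
        ``source`` marks triangles of margin hexes (vasculature sites).
        """
        nz, ny, nx = self.lattice_shape
        valid = np.zeros((nz, ny, nx), dtype=bool)
        source = np.zeros((nz, ny, nx), dtype=bool)
        for (u, v, w) in hex_disk(self.lattice_radius):
            x0, y0 = self.hex_anchor(u, v, w)
            margin = self.is_margin(u, v, w)
            for zi in range(nz):
                valid[zi, y0:y0 + 2, x0:x0 + 3] = True
                if margin:
                    source[zi, y0:y0 + 2, x0:x0 + 3] = True
        return valid, source

    def agent_hexes(self, z=0) -> list[tuple[int, int, int, int]]:
        """All agent-region locations in one layer."""
        return [(u, v, w, z) for (u, v, w) in hex_disk(self.R - 1)]


def local_concentration(field, geom: HexGeometry, u, v, w, z=0) -> float:
    """Mean concentration of a molecule field over a hexagon's triangles."""
    zi, y, x = geom.triangle_index_arrays(u, v, w, z)
    return float(field.C[zi, y, x].mean())
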