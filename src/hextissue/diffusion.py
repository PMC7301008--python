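"""Reaction-diffusion of glucose, oxygen and TGFα on triangular lattices.

Transport is solved with an explicit finite-difference stencil on the
triangular lattice (three in-plane neighbors, plus the two vertical
neighbors for 3D runs) with a 1 s sub-step, 60 sub-steps per 1-min tick.
A von Neumann stability analysis selects the scheme per molecule::

    λ = 4 D Δt (1/Δs² + δ/Δz²)

If ``0 <= λ < 1`` the explicit update is used; otherwise the field is
relaxed with a pseudo-steady-state approximation (each site replaced by
a weighted average of its neighbors).  Consumption/production by cell
agents and the vasculature sources are handled separately: agents scale
their local triangles once per tick, and all margin-region lattice sites
are clamped to the source concentration after every sub-step.

Out-of-lattice neighbors are treated as zero-flux (mirror) boundaries,
so a closed lattice conserves mass exactly under the explicit scheme.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .geometry import HexGeometry


def stability_lambda(D: float, dt: float, ds: float, dz: float, delta: int) -> float:
    """Von Neumann stability number of the explicit triangular stencil."""
    if ds <= 0 or dz <= 0:
        raise ValueError("lattice spacings must be positive")
    if D < 0 or dt <= 0:
        raise ValueError("require D >= 0 and dt > 0")
    return 4.0 * D * dt * (1.0 / ds ** 2 + delta / dz ** 2)


@njit(cache=True)
def _fd_kernel(C, out, valid, k_s, k_z, use_z):  # pragma: no cover - jit
    nz, ny, nx = C.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                c = C[z, y, x]
                if not valid[z, y, x]:
                    out[z, y, x] = c
                    continue
                # three in-plane neighbors; missing neighbors mirror c
                n = 0.0
                if x > 0 and valid[z, y, x - 1]:
                    n += C[z, y, x - 1]
                else:
                    n += c
                if x < nx - 1 and valid[z, y, x + 1]:
                    n += C[z, y, x + 1]
                else:
                    n += c
                yv = y + 1 if (x + y) % 2 == 0 else y - 1
                if 0 <= yv < ny and valid[z, yv, x]:
                    n += C[z, yv, x]
                else:
                    n += c
                val = c + k_s * (n - 3.0 * c)
                if use_z:
                    m = 0.0
                    if z > 0 and valid[z - 1, y, x]:
                        m += C[z - 1, y, x]
                    else:
                        m += c
                    if z < nz - 1 and valid[z + 1, y, x]:
                        m += C[z + 1, y, x]
                    else:
                        m += c
                    val += k_z * (m - 2.0 * c)
                out[z, y, x] = val


@njit(cache=True)
def _pseudo_kernel(C, out, valid, beta, use_z):  # pragma: no cover - jit
    # beta = 3 Δs² / (2 Δz²); site -> weighted neighbor average
    denom = 3.0 + (2.0 * beta if use_z else 0.0)
    nz, ny, nx = C.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                c = C[z, y, x]
                if not valid[z, y, x]:
                    out[z, y, x] = c
                    continue
                n = 0.0
                if x > 0 and valid[z, y, x - 1]:
                    n += C[z, y, x - 1]
                else:
                    n += c
                if x < nx - 1 and valid[z, y, x + 1]:
                    n += C[z, y, x + 1]
                else:
                    n += c
                yv = y + 1 if (x + y) % 2 == 0 else y - 1
                if 0 <= yv < ny and valid[z, yv, x]:
                    n += C[z, yv, x]
                else:
                    n += c
                if use_z:
                    m = 0.0
                    if z > 0 and valid[z - 1, y, x]:
                        m += C[z - 1, y, x]
                    else:
                        m += c
                    if z < nz - 1 and valid[z + 1, y, x]:
                        m += C[z + 1, y, x]
                    else:
                        m += c
                    n += beta * m
                out[z, y, x] = n / denom


@njit(cache=True)
def _tick_flat(c, buf, n1, n2, n3, n4, n5, src, src_conc, has_src,
               scheme_fd, k_s, k_z, beta, use_z, nsteps):  # pragma: no cover
    """Full tick on the compact valid-site vector; neighbor indices point
    at the site itself where a neighbor is missing (zero-flux)."""
    n = c.shape[0]
    denom = 3.0 + (2.0 * beta if use_z else 0.0)
    a, b = c, buf
    for _ in range(nsteps):
        if scheme_fd:
            for i in range(n):
                ci = a[i]
                s = a[n1[i]] + a[n2[i]] + a[n3[i]]
                val = ci + k_s * (s - 3.0 * ci)
                if use_z:
                    m = a[n4[i]] + a[n5[i]]
                    val += k_z * (m - 2.0 * ci)
                b[i] = val
        else:
            for i in range(n):
                ci = a[i]
                s = a[n1[i]] + a[n2[i]] + a[n3[i]]
                if use_z:
                    s += beta * (a[n4[i]] + a[n5[i]])
                b[i] = s / denom
        if has_src:
            for i in range(src.shape[0]):
                b[src[i]] = src_conc
        a, b = b, a
    return nsteps % 2 == 1


class MoleculeField:
    """One diffusing molecule on the triangular lattice of an environment.

    Parameters
    ----------
    name : str
        Molecule label (``glucose``, ``oxygen`` or ``tgfa``).
    geom : HexGeometry
        Environment geometry providing lattice shape, masks and spacings.
    diffusivity : float
        D in μm²/s.
    source_conc : float or None
        Concentration clamped at margin (vasculature) sites after each
        sub-step; ``None`` disables sources for this molecule.
    initial_conc : float
        Uniform initial concentration over the valid lattice region.
    dt : float
        Diffusion sub-step in seconds.
    """

    def __init__(self, name, geom: HexGeometry, diffusivity, source_conc,
                 initial_conc=0.0, dt=1.0):
        self.name = name
        self.geom = geom
        self.D = float(diffusivity)
        self.source_conc = source_conc
        self.dt = float(dt)
        self.delta = 0 if geom.H == 1 else 1
        self.valid, self.source_mask = geom.lattice_masks()
        self.C = np.zeros(geom.lattice_shape, dtype=np.float64)
        self.C[self.valid] = initial_conc
        self._buf = np.empty_like(self.C)
        self.lambda_ = stability_lambda(self.D, self.dt, geom.ds, geom.dz,
                                        self.delta)
        self.scheme = "fd" if self.lambda_ < 1.0 else "pseudo"
        # stencil coefficients
        self._k_s = 4.0 * self.D * self.dt / (3.0 * geom.ds ** 2)
        self._k_z = 2.0 * self.D * self.dt / geom.dz ** 2
        self._beta = 3.0 * geom.ds ** 2 / (2.0 * geom.dz ** 2)
        self._compact = None

    def _build_compact(self):
        """Compact valid-site vector plus neighbor index tables."""
        nz, ny, nx = self.valid.shape
        zz, yy, xx = np.nonzero(self.valid)
        n = zz.size
        idx = -np.ones(self.valid.shape, dtype=np.int64)
        idx[zz, yy, xx] = np.arange(n)
        self_ids = np.arange(n)

        def lookup(z2, y2, x2):
            out = self_ids.copy()
            inb = ((z2 >= 0) & (z2 < nz) & (y2 >= 0) & (y2 < ny)
                   & (x2 >= 0) & (x2 < nx))
            found = idx[z2[inb], y2[inb], x2[inb]]
            sub = out[inb]
            sub[found >= 0] = found[found >= 0]
            out[inb] = sub
            return out

        yv = np.where((xx + yy) % 2 == 0, yy + 1, yy - 1)
        n1 = lookup(zz, yy, xx - 1)
        n2 = lookup(zz, yy, xx + 1)
        n3 = lookup(zz, yv, xx)
        n4 = lookup(zz - 1, yy, xx)
        n5 = lookup(zz + 1, yy, xx)
        src = idx[self.source_mask & self.valid]
        self._compact = ((zz, yy, xx), n1, n2, n3, n4, n5,
                         np.ascontiguousarray(src),
                         np.empty(n), np.empty(n))

    # -- sub-step updates --------------------------------------------------

    def step_fd(self):
        """One explicit finite-difference sub-step (requires λ < 1)."""
        _fd_kernel(self.C, self._buf, self.valid, self._k_s, self._k_z,
                   self.delta == 1)
        self.C, self._buf = self._buf, self.C

    def step_pseudo_steady(self):
        """One pseudo-steady relaxation sub-step (used when λ >= 1)."""
        _pseudo_kernel(self.C, self._buf, self.valid, self._beta,
                       self.delta == 1)
        self.C, self._buf = self._buf, self.C

    def apply_sources(self):
        """Clamp vasculature (margin) sites to the source concentration."""
        if self.source_conc is not None:
            self.C[self.source_mask] = self.source_conc

    def step_tick(self, substeps: int = 60):
        """Advance one simulation tick (default 60 x 1 s sub-steps)."""
        if self._compact is None:
            self._build_compact()
        (zz, yy, xx), n1, n2, n3, n4, n5, src, vec, buf = self._compact
        has_src = self.source_conc is not None and src.size > 0
        vec[:] = self.C[zz, yy, xx]
        swapped = _tick_flat(
            vec, buf, n1, n2, n3, n4, n5, src,
            self.source_conc if has_src else 0.0, has_src,
            self.scheme == "fd", self._k_s, self._k_z, self._beta,
            self.delta == 1, substeps)
        self.C[zz, yy, xx] = buf if swapped else vec
        if not np.isfinite(self.C).all():
            raise FloatingPointError(f"non-finite concentration in {self.name}")
        if self.C.min() < 0.0:
            raise FloatingPointError(f"negative concentration in {self.name}")

    # -- agent coupling ----------------------------------------------------

    def mean_at_hex(self, u, v, w, z=0) -> float:
        """Local concentration: mean over the hexagon's six triangles."""
        zi, y, x = self.geom.triangle_index_arrays(u, v, w, z)
        return float(self.C[zi, y, x].mean())

    def scale_at_hex(self, factor: float, u, v, w, z=0):
        """Multiply the hexagon's six triangles by ``factor`` (uptake)."""
        zi, y, x = self.geom.triangle_index_arrays(u, v, w, z)
        self.C[zi, y, x] *= factor

    def set_at_hex(self, value: float, u, v, w, z=0):
        """Overwrite the hexagon's six triangles (TGFα write-back)."""
        zi, y, x = self.geom.triangle_index_arrays(u, v, w, z)
        self.C[zi, y, x] = value

    def total_amount(self, triangle_volume: float = 1.0) -> float:
        """Total Σ C · vol over the valid region (for conservation checks)."""
        return float(self.C[self.valid].sum() * triangle_volume)
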