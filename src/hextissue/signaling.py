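"""TGFα/EGFR/PLCγ signaling and the migrate-vs-proliferate decision.

Undecided cells commit to migration or proliferation based on the
relative fold change Δ of active PLCγ between consecutive ticks::

    Δ = max(PLCγ_t, PLCγ_{t-1}) / min(PLCγ_t, PLCγ_{t-1})

Cells with Δ greater than the migratory threshold θ become migratory,
otherwise proliferative (the boundary Δ = θ is proliferative).

Three mechanistic network reductions of an EGFR gene-protein interaction
network are provided (species in nM; forward Euler, 1 s steps, 60 steps
per tick), plus a ``random`` variant that migrates with probability
MIGRA_PROB and ignores the environment:

* ``simple`` — 4 species: extracellular TGFα, cytoplasmic TGFα-EGFR
  complex, inactive/active PLCγ.
* ``medium`` — 7 species: adds the membrane compartment (EGFR, surface
  complex, phosphorylated complex).
* ``complex`` — 12 species: adds the nuclear compartment (EGFR/TGFα
  RNA transcribed from a shared nucleotide pool) and five regulatory
  edges.

Regulatory interactions enter as saturating weights
``w = 1 ± X/(W + X)``: neutral (1) when the regulator is absent,
approaching 2 (activating) or 0 (inhibitory) at saturation.  Regulator
wiring per complexity: internal glucose drives w_G; active PLCγ (the
negative feedback, applied to the receptor dephosphorylation / uptake
reverse path) drives w_C; the phosphorylated receptor complex drives
w_P (PLCγ activation) and, for the complex network, the transcription
weights w_E and w_T.

Exchange with the environment: the extracellular species X₁ is loaded
from the cell's six lattice triangles before integration and written
back afterwards.
"""

from __future__ import annotations

import numpy as np
from numba import njit

PLC_INDEX = {"simple": 3, "medium": 6, "complex": 10}
N_SPECIES = {"simple": 4, "medium": 7, "complex": 12}

_RATE_ORDER = {
    "simple": ("k1", "k2", "k3", "k4", "k5", "k6"),
    "medium": ("k1", "k-1", "k2", "k-2", "k3", "k4", "k5", "k6", "k7",
               "k8", "k9", "k10", "k11"),
    "complex": ("k1", "k-1", "k2", "k-2", "k3", "k4", "k5", "k-5", "k6",
                "k7", "k8", "k-8", "k9", "k10", "k11", "k12", "k13",
                "k14", "k15", "k16", "k17", "k18", "k19"),
}

_CODE = {"simple": 0, "medium": 1, "complex": 2}


def regulatory_weight(x: float, W: float, sign: int) -> float:
    """Saturating regulatory weight w = 1 + sign * X/(W + X)."""
    if x < 0:
        raise ValueError("regulator concentration must be non-negative")
    if x == 0.0:
        return 1.0
    return 1.0 + sign * x / (W + x)


def initial_state(complexity: str, conc_tgfa: float) -> np.ndarray:
    """Printed initial concentrations (nM) for a network complexity."""
    if complexity == "simple":
        x = np.zeros(4)
        x[0] = conc_tgfa
        x[2], x[3] = 0.333, 0.667          # PLCγ pair
    elif complexity == "medium":
        x = np.zeros(7)
        x[0] = conc_tgfa
        x[1] = 25.0                        # membrane EGFR
        x[5], x[6] = 0.333, 0.667
    elif complexity == "complex":
        x = np.zeros(12)
        x[0] = conc_tgfa
        x[1] = 25.0
        x[5] = x[6] = 5.0                  # cytoplasmic EGFR / TGFα
        x[7] = x[8] = 2.5                  # EGFR / TGFα RNA
        x[9], x[10] = 0.333, 0.667         # PLCγ pair
        x[11] = 5.0                        # nucleotide pool
    else:
        raise ValueError(f"unknown signaling complexity {complexity!r}")
    return x


def pack_rates(complexity: str, params: dict) -> np.ndarray:
    return np.array([params[complexity][k] for k in _RATE_ORDER[complexity]],
                    dtype=np.float64)


def pack_weights(params: dict) -> np.ndarray:
    """(W_G, W_C, W_P, W_E, W_T) half-saturation constants."""
    return np.array([params["W_G"], params["W_C"], params["W_P"],
                     params["W_E"], params["W_T"]], dtype=np.float64)


@njit(cache=True)
def _w(x, W, sign):  # pragma: no cover - jit
    if x <= 0.0:
        return 1.0
    return 1.0 + sign * x / (W + x)


@njit(cache=True)
def _deriv(code, X, k, Wc, g_conc, out):  # pragma: no cover - jit
    """dX/dt for one network; g_conc is the internal-glucose regulator."""
    wg = _w(g_conc, Wc[0], 1.0)
    if code == 0:  # simple: X1 Tα_ext, X2 Tα-EGFR_cyt, X3/X4 PLCγ
        wc = _w(X[3], Wc[1], -1.0)         # active PLCγ damps uptake
        wp = _w(X[1], Wc[2], 1.0)          # complex activates PLCγ
        k1, k2, k3, k4, k5, k6 = k[0], k[1], k[2], k[3], k[4], k[5]
        out[0] = k6 - k1 * X[0] * wg * wc - k3 * X[0]
        out[1] = k1 * X[0] * wg * wc - k2 * X[1]
        out[2] = k5 * X[3] - k4 * (1.0 - X[3]) * wp
        out[3] = k4 * (1.0 - X[3]) * wp - k5 * X[3]
    elif code == 1:  # medium
        wc = _w(X[6], Wc[1], 1.0)          # active PLCγ promotes reverse
        wp = _w(X[3], Wc[2], 1.0)          # p-complex activates PLCγ
        k1, km1, k2, km2 = k[0], k[1], k[2], k[3]
        k3, k4, k5, k6, k7 = k[4], k[5], k[6], k[7], k[8]
        k8, k9, k10, k11 = k[9], k[10], k[11], k[12]
        out[0] = km1 * X[2] - k1 * X[0] * X[1] - k7 * X[0] + k11
        out[1] = km1 * X[2] - k1 * X[0] * X[1] - k6 * X[1] + k10
        out[2] = (2.0 * k1 * X[0] * X[1] - 2.0 * km1 * X[2]
                  - k2 * X[2] * wg + km2 * X[3] * wc - k3 * X[2])
        out[3] = k2 * X[2] * wg - km2 * X[3] * wc - k4 * X[3]
        out[4] = k3 * X[2] + k4 * X[3] - k5 * X[4]
        out[5] = k9 * X[6] - k8 * (1.0 - X[6]) * wp
        out[6] = k8 * (1.0 - X[6]) * wp - k9 * X[6]
    else:  # complex
        wc = _w(X[10], Wc[1], 1.0)
        wp = _w(X[3], Wc[2], 1.0)
        we = _w(X[3], Wc[3], 1.0)
        wt = _w(X[3], Wc[4], 1.0)
        k1, km1, k2, km2, k3, k4 = k[0], k[1], k[2], k[3], k[4], k[5]
        k5, km5, k6, k7, k8, km8 = k[6], k[7], k[8], k[9], k[10], k[11]
        k9, k10, k11, k12, k13 = k[12], k[13], k[14], k[15], k[16]
        k14, k15, k16, k17, k18, k19 = (k[17], k[18], k[19], k[20],
                                        k[21], k[22])
        out[0] = km1 * X[2] - k1 * X[0] * X[1] + k9 * X[6] - k11 * X[0]
        out[1] = (km1 * X[2] - k1 * X[0] * X[1] + k8 * X[5]
                  - km8 * X[1] - k10 * X[1])
        out[2] = (2.0 * k1 * X[0] * X[1] - 2.0 * km1 * X[2]
                  - k2 * X[2] * wg + km2 * X[3] * wc - k3 * X[2])
        out[3] = k2 * X[2] * wg - km2 * X[3] * wc - k4 * X[3]
        out[4] = (k3 * X[2] + k4 * X[3] + 2.0 * km5 * X[5] * X[6]
                  - 2.0 * k5 * X[4])
        out[5] = (k5 * X[4] - km5 * X[5] * X[6] + k14 * X[7]
                  - k6 * X[5] - k8 * X[5] + km8 * X[1])
        out[6] = (k5 * X[4] - km5 * X[5] * X[6] + k15 * X[8]
                  - k7 * X[6] - k9 * X[6])
        out[7] = k16 * X[11] * we - k18 * X[7]
        out[8] = k17 * X[11] * wt - k19 * X[8]
        out[9] = k13 * X[10] - k12 * (1.0 - X[10]) * wp
        out[10] = k12 * (1.0 - X[10]) * wp - k13 * X[10]
        out[11] = (-k16 * X[11] * we - k17 * X[11] * wt
                   + k18 * X[7] + k19 * X[8])


@njit(cache=True)
def _euler(code, X, k, Wc, g_conc, dt, nsteps):  # pragma: no cover - jit
    """Forward-Euler integration in place; returns number of 0-clamps."""
    out = np.empty_like(X)
    clamps = 0
    for _ in range(nsteps):
        _deriv(code, X, k, Wc, g_conc, out)
        for i in range(X.shape[0]):
            X[i] += dt * out[i]
            if X[i] < 0.0:
                X[i] = 0.0
                clamps += 1
    return clamps


def derivatives(complexity, X, rates, weights, g_conc):
    """dX/dt of the chosen network (thin wrapper over the jit kernel)."""
    out = np.empty_like(np.asarray(X, dtype=np.float64))
    _deriv(_CODE[complexity], np.asarray(X, dtype=np.float64), rates,
           weights, g_conc, out)
    return out


class SignalingState:
    """Per-cell signaling bookkeeping for the mechanistic variants."""

    __slots__ = ("complexity", "X", "plc_prev", "_rates", "_weights")

    def __init__(self, complexity, params, conc_tgfa):
        self.complexity = complexity
        self.X = initial_state(complexity, conc_tgfa)
        self.plc_prev = self.X[PLC_INDEX[complexity]]
        self._rates = pack_rates(complexity, params)
        self._weights = pack_weights(params)

    @property
    def plc_active(self) -> float:
        return float(self.X[PLC_INDEX[self.complexity]])

    def integrate_tick(self, tgfa_local, g_conc, dt=1.0, substeps=60):
        """Integrate one tick; returns (new external TGFα, Δ fold change).

        ``tgfa_local`` is the mean TGFα over the cell's triangles (nM)
        and ``g_conc`` the internal glucose concentration (fmol/μm³)
        driving the w_G weight.
        """
        self.plc_prev = self.plc_active
        self.X[0] = tgfa_local
        _euler(_CODE[self.complexity], self.X, self._rates, self._weights,
               g_conc, dt, substeps)
        if not np.isfinite(self.X).all():
            bad = int(np.flatnonzero(~np.isfinite(self.X))[0])
            raise FloatingPointError(f"non-finite signaling species X{bad + 1}")
        return float(self.X[0]), plc_fold_change(self.plc_active,
                                                 self.plc_prev)

    def copy_for_daughter(self) -> "SignalingState":
        """Concentrations are intensive: the daughter inherits them."""
        d = SignalingState.__new__(SignalingState)
        d.complexity = self.complexity
        d.X = self.X.copy()
        d.plc_prev = self.plc_prev
        d._rates = self._rates
        d._weights = self._weights
        return d


def plc_fold_change(plc_now: float, plc_prev: float) -> float:
    """Relative fold change Δ >= 1; Δ = +inf when either value is zero."""
    lo, hi = min(plc_now, plc_prev), max(plc_now, plc_prev)
    if lo <= 0.0:
        return float("inf")
    return hi / lo


def decide_state(delta: float, theta: float) -> tuple[int, int]:
    """(x_mi, x_pr) flags: migratory iff Δ > θ (boundary proliferative)."""
    return (1, 0) if delta > theta else (0, 1)


def decide_random(migra_prob: float, rng) -> tuple[int, int]:
    """Random-signaling decision: migratory with probability MIGRA_PROB."""
    return (1, 0) if rng.uniform() < migra_prob else (0, 1)
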