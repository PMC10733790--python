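"""Molecular level: cytokine diffusion–decay, cell secretion, debris engulfment.

Four cytokine fields (TNFα, IL-10, TGFβ, IFNγ) diffuse by Fick's law with
no-flux boundaries at the healing-region border and the bone cortex, and
decay exponentially.  The fracture-debris field neither diffuses nor decays;
it is removed only by phagocyte engulfment.  All concentrations are in
opaque model units per voxel of the 10 µm grid.

The functions here are the reference NumPy implementations of each
operation; :mod:`callusim.kernels` fuses them into one numba loop for the
60:1 molecular block of the scheduler, and the two paths are cross-checked
by the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np

from callusim.geometry import DomainMasks

CYTOKINES = ("tnfa", "il10", "tgfb", "ifng")


class StabilityError(RuntimeError):
    """Raised when a molecular step produces a negative concentration."""


class ConsistencyError(RuntimeError):
    """Raised when a cell lies outside the healing region."""


@dataclass
class TransportParams:
    """Diffusion/decay constants (µm² s⁻¹ and s⁻¹) and the molecular step."""

    D_tnfa: float = 20.0
    D_il10: float = 20.0
    D_tgfb: float = 20.0
    D_ifng: float = 20.0
    d_tnfa: float = 2.0e-4
    d_il10: float = 1.0e-4
    d_tgfb: float = 1.0e-4
    d_ifng: float = 2.0e-4
    dt_mol: float = 1.0

    def D(self, cyt: str) -> float:
        return getattr(self, f"D_{cyt}")

    def d(self, cyt: str) -> float:
        return getattr(self, f"d_{cyt}")

    @classmethod
    def from_parameters(cls, params) -> "TransportParams":
        return cls(**{k: params[k] for k in
                      ("D_tnfa", "D_il10", "D_tgfb", "D_ifng",
                       "d_tnfa", "d_il10", "d_tgfb", "d_ifng", "dt_mol")})

    def n_substeps(self, h: float) -> int:
        """Substeps needed for the explicit stability bound dt <= h²/(4 D)."""
        dmax = max(self.D_tnfa, self.D_il10, self.D_tgfb, self.D_ifng)
        if dmax == 0:
            return 1
        return max(1, math.ceil(self.dt_mol / (h * h / (4.0 * dmax))))


@dataclass
class SecretionParams:
    """Constants of the cell-specific cytokine source terms (per minute)."""

    k_TNF: float = 5.0e-2
    k_TNI: float = 1.0
    a_TNI: float = 1.0
    k_TNIL: float = 0.8
    a_TNIL: float = 2.0
    b_TNIL: float = 0.2
    k_TNTG: float = 0.8
    a_TNTG: float = 2.0
    b_TNTG: float = 0.2
    k_IL10: float = 2.0e-2
    k_TGF: float = 2.0e-2
    k_IFN: float = 1.0e-2
    a_ITN: float = 1.0

    @classmethod
    def from_parameters(cls, params) -> "SecretionParams":
        names = ("k_TNF", "k_TNI", "a_TNI", "k_TNIL", "a_TNIL", "b_TNIL",
                 "k_TNTG", "a_TNTG", "b_TNTG", "k_IL10", "k_TGF", "k_IFN", "a_ITN")
        return cls(**{k: params[k] for k in names})


@dataclass
class MolecularState:
    """Five scalar concentration fields on the molecular grid plus the clock."""

    tnfa: np.ndarray
    il10: np.ndarray
    tgfb: np.ndarray
    ifng: np.ndarray
    debris: np.ndarray
    time: float = 0.0  # s
    masks: DomainMasks = dc_field(default=None, repr=False)

    @classmethod
    def zeros(cls, masks: DomainMasks, db0: float = 0.0) -> "MolecularState":
        shape = masks.shape
        debris = np.where(masks.healing_region, float(db0), 0.0)
        return cls(*(np.zeros(shape) for _ in range(4)), debris=debris, masks=masks)

    def field(self, cyt: str) -> np.ndarray:
        return getattr(self, cyt)

    def copy(self) -> "MolecularState":
        return MolecularState(self.tnfa.copy(), self.il10.copy(), self.tgfb.copy(),
                              self.ifng.copy(), self.debris.copy(), self.time, self.masks)

    def totals(self) -> dict[str, float]:
        m = self.masks.healing_region
        out = {c: float(self.field(c)[m].sum()) for c in CYTOKINES}
        out["debris"] = float(self.debris[m].sum())
        return out


def neighbor_count(mask: np.ndarray) -> np.ndarray:
    """In-region 4-neighbour count for each voxel (no-flux stencil weight)."""
    m = mask.astype(np.int8)
    n = np.zeros(mask.shape, dtype=np.int8)
    n[1:, :] += m[:-1, :]
    n[:-1, :] += m[1:, :]
    n[:, 1:] += m[:, :-1]
    n[:, :-1] += m[:, 1:]
    return n


def _laplacian_noflux(c: np.ndarray, mask: np.ndarray, nbr: np.ndarray) -> np.ndarray:
    """Masked 5-point Laplacian with no-flux walls, in units of voxel^-2."""
    cm = np.where(mask, c, 0.0)
    s = np.zeros_like(c)
    s[1:, :] += cm[:-1, :]
    s[:-1, :] += cm[1:, :]
    s[:, 1:] += cm[:, :-1]
    s[:, :-1] += cm[:, 1:]
    return np.where(mask, s - nbr * c, 0.0)


def step_diffuse_decay(state: MolecularState, tp: TransportParams,
                       masks: DomainMasks | None = None) -> MolecularState:
    """Advance the cytokines one molecular step (diffusion then decay).

    The explicit step is internally substepped to respect the stability
    bound ``dt <= h²/(4 D)``.  Debris is untouched.  Returns a new state.
    """
    masks = masks or state.masks
    mask = masks.healing_region
    h = masks.resolution
    nbr = neighbor_count(mask)
    nsub = tp.n_substeps(h)
    dt = tp.dt_mol / nsub
    out = state.copy()
    for cyt in CYTOKINES:
        c = out.field(cyt)
        lam = tp.D(cyt) * dt / (h * h)
        for _ in range(nsub):
            c = c + lam * _laplacian_noflux(c, mask, nbr)
        c *= math.exp(-tp.d(cyt) * tp.dt_mol)
        if np.any(c[mask] < 0):
            raise StabilityError(f"negative {cyt} concentration after diffusion step")
        setattr(out, cyt, c)
    out.time = state.time + tp.dt_mol
    return out


_TNFA_LABELS = {"tnfa", "TNFa", "TNFα", "TNF"}
_IL10_LABELS = {"il10", "IL10"}
_TGFB_LABELS = {"tgfb", "TGFb", "TGFβ"}
_IFNG_LABELS = {"ifng", "IFNg", "IFNγ", "IFN"}


def _canon(cytokine: str) -> str:
    for canon, labels in (("tnfa", _TNFA_LABELS), ("il10", _IL10_LABELS),
                          ("tgfb", _TGFB_LABELS), ("ifng", _IFNG_LABELS)):
        if cytokine in labels or cytokine.lower() == canon:
            return canon
    raise KeyError(f"unknown cytokine: {cytokine!r}")


def _ifng_amplification(ifng: float, sp: SecretionParams) -> float:
    return 1.0 + sp.k_TNI / (1.0 + math.exp(sp.a_TNI - ifng))


def secretion_rate(phenotype: str, cytokine: str, local: dict[str, float],
                   sp: SecretionParams) -> float:
    """Secretion rate (model units per minute) for a (phenotype, cytokine) pair.

    ``local`` maps cytokine names to the concentrations sampled at the
    cell's voxel.  Pairs without a source term (e.g. M2/TNFα, PMN/IL10)
    return 0 rather than raising.
    """
    cyt = _canon(cytokine)
    tnfa = local.get("tnfa", 0.0)
    il10 = local.get("il10", 0.0)
    tgfb = local.get("tgfb", 0.0)
    ifng = local.get("ifng", 0.0)

    if phenotype == "M0":
        if cyt == "tnfa":
            return sp.k_TNF * _ifng_amplification(ifng, sp)
        if cyt == "il10":
            return sp.k_IL10
        if cyt == "tgfb":
            return sp.k_TGF
        if cyt == "ifng":
            return sp.k_IFN * math.exp(-sp.a_ITN * tnfa)
    elif phenotype == "M1":
        if cyt == "tnfa":
            il10_inhib = sp.k_TNIL * math.exp(-sp.a_TNIL * il10) + sp.b_TNIL
            tgfb_inhib = sp.k_TNTG * math.exp(-sp.a_TNTG * tgfb) + sp.b_TNTG
            return sp.k_TNF * il10_inhib * tgfb_inhib * _ifng_amplification(ifng, sp)
        if cyt == "tgfb":
            return sp.k_TGF
        if cyt == "ifng":
            return sp.k_IFN * math.exp(-sp.a_ITN * tnfa)
    elif phenotype == "M2":
        if cyt == "il10":
            return sp.k_IL10
        if cyt == "tgfb":
            return sp.k_TGF
    elif phenotype == "PMN":
        if cyt == "tnfa":
            return sp.k_TNF
        if cyt == "ifng":
            return sp.k_IFN
    return 0.0


def _cell_voxels(cells, masks: DomainMasks) -> tuple[np.ndarray, np.ndarray, list[str]]:
    xs = np.array([c.position[0] for c in cells], dtype=float)
    ys = np.array([c.position[1] for c in cells], dtype=float)
    rows, cols = masks.voxel_of(xs, ys)
    if len(cells) and not masks.healing_region[rows, cols].all():
        raise ConsistencyError("cell outside the healing region")
    return rows, cols, [c.phenotype for c in cells]


def apply_secretion(state: MolecularState, cells, sp: SecretionParams,
                    dt: float) -> MolecularState:
    """Deposit each cell's secretion into its containing voxel over ``dt`` seconds.

    Point sources, additive over cells and order-independent.  Returns a
    new state.
    """
    out = state.copy()
    if not len(cells):
        return out
    masks = state.masks
    rows, cols, phens = _cell_voxels(cells, masks)
    dt_min = dt / 60.0  # secretion constants are per minute
    for cyt in CYTOKINES:
        f = out.field(cyt)
        for r, c, ph in zip(rows, cols, phens):
            local = {k: float(state.field(k)[r, c]) for k in CYTOKINES}
            f[r, c] += secretion_rate(ph, cyt, local, sp) * dt_min
    return out


def engulf_debris(state: MolecularState, cells, k_e: dict[str, float],
                  dt: float) -> tuple[MolecularState, np.ndarray]:
    """Phagocytose debris around each cell over ``dt`` seconds.

    Each phagocyte removes debris from its voxel and 4-neighbourhood at
    fractional rate ``k_e`` (per minute).  With several cells covering one
    voxel the voxel loses ``debris * (1 - exp(-Σ k_e dt))`` — the
    order-independent limit of sequential engulfment — and the removed mass
    is shared between the cells proportionally to their ``k_e``.  Returns
    the new state and the per-cell debris-load increments.
    """
    out = state.copy()
    gains = np.zeros(len(cells))
    if not len(cells):
        return out, gains
    masks = state.masks
    mask = masks.healing_region
    rows, cols, phens = _cell_voxels(cells, masks)
    rates = np.array([k_e.get(ph, 0.0) for ph in phens]) * dt / 60.0

    demand = np.zeros(mask.shape)
    stencil = ((0, 0), (1, 0), (-1, 0), (0, 1), (0, -1))
    ny, nx = mask.shape
    cover: list[list[tuple[int, int, int]]] = [[] for _ in range(len(cells))]
    for i, (r, c) in enumerate(zip(rows, cols)):
        for dr, dc in stencil:
            rr, cc = r + dr, c + dc
            if 0 <= rr < ny and 0 <= cc < nx and mask[rr, cc]:
                demand[rr, cc] += rates[i]
                cover[i].append((rr, cc, i))
    with np.errstate(divide="ignore", invalid="ignore"):
        removed = out.debris * -np.expm1(-demand)
        per_unit = np.where(demand > 0, removed / demand, 0.0)
    out.debris -= removed
    np.maximum(out.debris, 0.0, out=out.debris)
    for i in range(len(cells)):
        gains[i] = sum(per_unit[rr, cc] * rates[i] for rr, cc, _ in cover[i])
    return out, gains


def local_gradient(field: np.ndarray, position: tuple[float, float],
                   masks: DomainMasks) -> np.ndarray:
    """Central-difference gradient (per µm) of a field at a µm position.

    Out-of-region neighbours mirror the centre value (no-flux), so the
    gradient is zero across region walls and on flat fields.
    """
    r, c = (int(v) for v in masks.voxel_of(position[0], position[1]))
    mask = masks.healing_region
    h = masks.resolution
    ny, nx = mask.shape

    def val(rr: int, cc: int) -> float:
        if 0 <= rr < ny and 0 <= cc < nx and mask[rr, cc]:
            return float(field[rr, cc])
        return float(field[r, c])

    gx = (val(r, c + 1) - val(r, c - 1)) / (2.0 * h)
    gy = (val(r + 1, c) - val(r - 1, c)) / (2.0 * h)
    return np.array([gx, gy])
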