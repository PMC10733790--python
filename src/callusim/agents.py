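"""Cellular level: discrete immune-cell agents and their stochastic rules.

Cells live on a 1 µm lattice inside the healing region with a hard
exclusion radius ``r_ex`` between centres (≈ half a macrophage diameter),
so "occupied position" means "within r_ex of another cell's centre".  Per
1 min iteration each cell runs an event lottery — apoptosis, proliferation,
polarization, in that order, apoptosis preempting the rest — and then
migrates as a sequence of 1 µm jumps, uniformly random or debris-gradient
biased (chemotaxis).

The functions here are the per-cell reference implementations; the
scheduler uses the fused numba kernels of :mod:`callusim.kernels`, which
the tests check against these.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from callusim.geometry import DomainMasks

PHENOTYPE_CODES = {"M0": 0, "M1": 1, "M2": 2, "PMN": 3}
PHENOTYPE_NAMES = {v: k for k, v in PHENOTYPE_CODES.items()}
MACROPHAGE_CODES = (0, 1, 2)

#: allowed phenotype switches: M0→M1, M0→M2, M1→M2, M2→M1
ALLOWED_TRANSITIONS = {(0, 1), (0, 2), (1, 2), (2, 1)}

_LOTTERY_QUANTUM = 1e-6


@dataclass
class CellAgent:
    """One immune cell: phenotype, lattice position (µm), phagocytosed load."""

    id: int
    phenotype: str
    position: tuple[float, float]
    debris_load: float = 0.0
    age: float = 0.0  # min


@dataclass
class PhenotypeParams:
    """Per-phenotype kinetic constants (dict keyed by phenotype name)."""

    k_v: dict[str, float]
    k_p: dict[str, float]
    k_a0: dict[str, float]
    k_e: dict[str, float]
    alpha_d: float = 1.0e-4
    alpha_n: float = 1.0e-1

    def __post_init__(self) -> None:
        if self.k_p.get("PMN", 0.0) != 0.0:
            raise ValueError("PMN proliferation is not part of the model (k_p(PMN)=0)")

    @classmethod
    def from_parameters(cls, params) -> "PhenotypeParams":
        return cls(
            k_v=params.per_phenotype("k_v"),
            k_p=params.per_phenotype("k_p"),
            k_a0=params.per_phenotype("k_a0"),
            k_e=params.per_phenotype("k_e"),
            alpha_d=params.alpha_d,
            alpha_n=params.alpha_n,
        )


@dataclass
class RecruitmentParams:
    """Constants of the debris-driven boundary recruitment law."""

    k_R_M0: float           # h^-1
    k_R_PMN: float          # h^-1
    MPhi_max: float         # mm^-2
    PMN_0: float            # mm^-2 (model units)
    Db_0: float             # model units

    @classmethod
    def from_parameters(cls, params) -> "RecruitmentParams":
        return cls(
            k_R_M0=params.k_R_M0,
            k_R_PMN=params.k_R_M0 * params.k_R_PMN_factor,
            MPhi_max=params.MPhi_max,
            PMN_0=params.PMN_0,
            Db_0=params.Db_0,
        )


@dataclass
class PolarizationParams:
    """Polarization ratios (min^-1) and cytokine half-saturations."""

    k01: float
    k02: float
    k12: float
    k21: float
    a01: float
    a02: float
    a12: float
    a21: float

    @classmethod
    def from_parameters(cls, params) -> "PolarizationParams":
        return cls(**{k: params[k] for k in
                      ("k01", "k02", "k12", "k21", "a01", "a02", "a12", "a21")})


# ---------------------------------------------------------------------------
# probability laws
# ---------------------------------------------------------------------------

def polarization_probabilities(local_tnfa: float, local_il10: float,
                               pp: PolarizationParams, dt: float) -> dict[str, float]:
    """Per-iteration phenotype-switch probabilities from local cytokines.

    Michaelis–Menten saturation in the driving cytokine: TNFα pushes toward
    M1 (M0→M1, M2→M1), IL-10 toward M2 (M0→M2, M1→M2).  ``dt`` in minutes.
    """
    T, I = max(local_tnfa, 0.0), max(local_il10, 0.0)

    def mm(k: float, a: float, c: float) -> float:
        p = k * (c / (a + c)) * dt if c > 0 else 0.0
        return min(max(p, 0.0), 1.0)

    return {
        "M0->M1": mm(pp.k01, pp.a01, T),
        "M0->M2": mm(pp.k02, pp.a02, I),
        "M1->M2": mm(pp.k12, pp.a12, I),
        "M2->M1": mm(pp.k21, pp.a21, T),
    }


def apoptosis_probability(cell: CellAgent, n_neighbors: int,
                          pp: PhenotypeParams, dt: float) -> float:
    """Apoptosis probability per iteration.

    Baseline ``k_a0`` scaled up linearly by accumulated phagocytosed debris
    and by crowding (cells within the neighbour radius), clamped to [0, 1];
    monotone non-decreasing in both.
    """
    k_a0 = pp.k_a0[cell.phenotype]
    p = k_a0 * (1.0 + pp.alpha_d * max(cell.debris_load, 0.0)
                + pp.alpha_n * max(n_neighbors, 0)) * dt
    return min(max(p, 0.0), 1.0)


def _quantized_uniform(rng: np.random.Generator) -> float:
    """Uniform draw quantized to 1e-6, mirroring the per-event lottery."""
    return np.floor(rng.random() * 1e6) * _LOTTERY_QUANTUM


def event_lottery(cell: CellAgent, probabilities: dict, rng: np.random.Generator):
    """Draw the cell's fate for one iteration.

    ``probabilities`` holds 'apoptosis', 'proliferation' and a
    'polarization' mapping of target phenotype → probability.  Independent
    quantized uniform draws per event, evaluated apoptosis → proliferation
    → polarization; apoptosis preempts everything else, and the remaining
    events are independent of each other.  Returns ``('apoptosis',)``,
    ``('proliferation',)``, ``('polarization', target)``, combinations
    excluded by preemption, or ``('none',)``.
    """
    if _quantized_uniform(rng) < probabilities.get("apoptosis", 0.0):
        return ("apoptosis",)
    events = []
    if _quantized_uniform(rng) < probabilities.get("proliferation", 0.0):
        events.append(("proliferation",))
    for target, p in probabilities.get("polarization", {}).items():
        if _quantized_uniform(rng) < p:
            events.append(("polarization", target))
            break
    if not events:
        return ("none",)
    return events[0] if len(events) == 1 else events[0]


# ---------------------------------------------------------------------------
# occupancy index
# ---------------------------------------------------------------------------

class Occupancy:
    """Uniform-bin spatial index answering exclusion and crowding queries."""

    MAX_PER_BIN = 8

    def __init__(self, extent_x: float, extent_y: float, origin: tuple[float, float],
                 r_ex: float) -> None:
        self.r_ex = float(r_ex)
        self.bin = float(r_ex)
        self.origin = origin
        self.nbx = int(np.ceil(extent_x / self.bin)) + 2
        self.nby = int(np.ceil(extent_y / self.bin)) + 2
        self.count = np.zeros((self.nby, self.nbx), dtype=np.int32)
        self.slots = np.full((self.nby, self.nbx, self.MAX_PER_BIN), -1, dtype=np.int32)

    def _bin_of(self, x: float, y: float) -> tuple[int, int]:
        bx = int((x - self.origin[0]) / self.bin) + 1
        by = int((y - self.origin[1]) / self.bin) + 1
        return (min(max(by, 0), self.nby - 1), min(max(bx, 0), self.nbx - 1))

    def rebuild(self, xs: np.ndarray, ys: np.ndarray) -> None:
        self.count[:] = 0
        self.slots[:] = -1
        for i in range(len(xs)):
            self.insert(i, xs[i], ys[i])
        self._xs, self._ys = xs, ys

    def insert(self, idx: int, x: float, y: float) -> None:
        by, bx = self._bin_of(x, y)
        k = self.count[by, bx]
        if k >= self.MAX_PER_BIN:
            raise RuntimeError("occupancy bin overflow")
        self.slots[by, bx, k] = idx
        self.count[by, bx] = k + 1

    def remove(self, idx: int, x: float, y: float) -> None:
        by, bx = self._bin_of(x, y)
        k = self.count[by, bx]
        row = self.slots[by, bx]
        for j in range(k):
            if row[j] == idx:
                row[j] = row[k - 1]
                row[k - 1] = -1
                self.count[by, bx] = k - 1
                return
        raise RuntimeError("cell not found in occupancy bin")

    def _iter_near(self, x: float, y: float, radius: float):
        reach = int(np.ceil(radius / self.bin))
        by, bx = self._bin_of(x, y)
        for dy in range(-reach, reach + 1):
            for dx in range(-reach, reach + 1):
                yy, xx = by + dy, bx + dx
                if 0 <= yy < self.nby and 0 <= xx < self.nbx:
                    for j in range(self.count[yy, xx]):
                        yield self.slots[yy, xx, j]

    def is_free(self, x: float, y: float, xs: np.ndarray, ys: np.ndarray,
                exclude: int = -1) -> bool:
        """True if no cell other than ``exclude`` is within r_ex of (x, y)."""
        r2 = self.r_ex**2
        for i in self._iter_near(x, y, self.r_ex):
            if i == exclude:
                continue
            if (xs[i] - x) ** 2 + (ys[i] - y) ** 2 < r2:
                return False
        return True

    def neighbors_within(self, x: float, y: float, radius: float,
                         xs: np.ndarray, ys: np.ndarray, exclude: int = -1) -> int:
        r2 = radius**2
        n = 0
        for i in self._iter_near(x, y, radius):
            if i == exclude:
                continue
            if (xs[i] - x) ** 2 + (ys[i] - y) ** 2 <= r2:
                n += 1
        return n


# ---------------------------------------------------------------------------
# population container
# ---------------------------------------------------------------------------

@dataclass
class CellPopulation:
    """Array-backed cell population (structure-of-arrays for the kernels)."""

    x: np.ndarray = field(default_factory=lambda: np.empty(0))
    y: np.ndarray = field(default_factory=lambda: np.empty(0))
    phen: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int8))
    load: np.ndarray = field(default_factory=lambda: np.empty(0))
    age: np.ndarray = field(default_factory=lambda: np.empty(0))
    ids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    next_id: int = 0

    def __len__(self) -> int:
        return len(self.x)

    def add(self, x, y, phen_code, load=0.0, age=0.0) -> None:
        n = np.size(x)
        self.x = np.append(self.x, x)
        self.y = np.append(self.y, y)
        self.phen = np.append(self.phen, np.full(n, phen_code, dtype=np.int8))
        self.load = np.append(self.load, np.full(n, float(load)))
        self.age = np.append(self.age, np.full(n, float(age)))
        self.ids = np.append(self.ids, np.arange(self.next_id, self.next_id + n))
        self.next_id += n

    def keep(self, keep_mask: np.ndarray) -> None:
        for name in ("x", "y", "phen", "load", "age", "ids"):
            setattr(self, name, getattr(self, name)[keep_mask])

    def counts(self) -> dict[str, int]:
        return {name: int((self.phen == code).sum())
                for name, code in PHENOTYPE_CODES.items()}

    def macrophage_count(self) -> int:
        return int(np.isin(self.phen, MACROPHAGE_CODES).sum())

    def agents(self) -> list[CellAgent]:
        return [CellAgent(int(self.ids[i]), PHENOTYPE_NAMES[int(self.phen[i])],
                          (float(self.x[i]), float(self.y[i])),
                          float(self.load[i]), float(self.age[i]))
                for i in range(len(self))]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "id": self.ids,
            "phenotype": [PHENOTYPE_NAMES[int(p)] for p in self.phen],
            "x": self.x, "y": self.y,
            "debris_load": self.load, "age": self.age,
        })

    def copy(self) -> "CellPopulation":
        return CellPopulation(self.x.copy(), self.y.copy(), self.phen.copy(),
                              self.load.copy(), self.age.copy(), self.ids.copy(),
                              self.next_id)


# ---------------------------------------------------------------------------
# recruitment
# ---------------------------------------------------------------------------

def expected_recruits(k_R: float, conc: float, conc_max: float,
                      debris_mean: float, dt_min: float, area_mm2: float) -> float:
    """Closed-form mean of the recruitment draw over one iteration.

    Debris-driven influx with saturation:
    ``k_R (1 - conc/conc_max) * debris_mean * dt * area``, clamped at 0
    when the compartment is full.  ``k_R`` per hour, ``dt`` in minutes.
    """
    crowding = max(0.0, 1.0 - conc / conc_max)
    return max(0.0, k_R / 60.0 * crowding * max(debris_mean, 0.0) * dt_min * area_mm2)


def recruit(pop: CellPopulation, masks: DomainMasks, debris: np.ndarray,
            rp: RecruitmentParams, dt_min: float, rng: np.random.Generator,
            occupancy: Occupancy, r_snap: float = 1.0) -> int:
    """Poisson influx of new M0 and PMN at free recruitment-boundary sites.

    The expected count follows :func:`expected_recruits` with the
    region-mean debris and compartment concentration (count / region area);
    realized counts are Poisson draws, placed at uniformly random unoccupied
    boundary voxels (fewer are placed if the boundary is saturated).
    Returns the number of cells added.
    """
    from callusim.geometry import area_of

    region = masks.healing_region
    area = area_of(region, masks.resolution)
    debris_mean = float(debris[region].mean()) if region.any() else 0.0
    added = 0

    rows, cols = np.nonzero(masks.recruitment_boundary)
    if len(rows) == 0:
        return 0
    h = masks.resolution

    for phen_code, k_R, conc_now in (
        (0, rp.k_R_M0, pop.macrophage_count() / area),
        (3, rp.k_R_PMN, pop.counts()["PMN"] / area),
    ):
        mean = expected_recruits(k_R, conc_now, rp.MPhi_max, debris_mean, dt_min, area)
        n = int(rng.poisson(mean)) if mean > 0 else 0
        for _ in range(n):
            placed = False
            for _attempt in range(20):
                j = int(rng.integers(len(rows)))
                x = masks.origin[0] + (cols[j] + 0.5) * h
                y = masks.origin[1] + (rows[j] + 0.5) * h
                x = round(x / r_snap) * r_snap
                y = round(y / r_snap) * r_snap
                if occupancy.is_free(x, y, pop.x, pop.y):
                    pop.add(x, y, phen_code)
                    occupancy.insert(len(pop) - 1, x, y)
                    added += 1
                    placed = True
                    break
            if not placed:
                break  # boundary saturated; recruit fewer this iteration
    return added


# ---------------------------------------------------------------------------
# migration (per-cell reference path)
# ---------------------------------------------------------------------------

def bilinear_sample(field: np.ndarray, x: float, y: float,
                    origin: tuple[float, float], h: float) -> float:
    """Bilinear sample of a voxel-centred field at a continuous µm position."""
    ny, nx = field.shape
    gx = (x - origin[0]) / h - 0.5
    gy = (y - origin[1]) / h - 0.5
    c0, r0 = int(np.floor(gx)), int(np.floor(gy))
    tx, ty = gx - c0, gy - r0
    if c0 < 0:
        c0, tx = 0, 0.0
    if r0 < 0:
        r0, ty = 0, 0.0
    c1 = c0 + 1 if c0 + 1 < nx else c0
    r1 = r0 + 1 if r0 + 1 < ny else r0
    if c0 >= nx:
        c0 = c1 = nx - 1
        tx = 0.0
    if r0 >= ny:
        r0 = r1 = ny - 1
        ty = 0.0
    v00, v01 = field[r0, c0], field[r0, c1]
    v10, v11 = field[r1, c0], field[r1, c1]
    return float((v00 * (1 - tx) + v01 * tx) * (1 - ty)
                 + (v10 * (1 - tx) + v11 * tx) * ty)

def migrate(cell_idx: int, pop: CellPopulation, debris: np.ndarray,
            masks: DomainMasks, k_v: float, occupancy: Occupancy,
            rng: np.random.Generator, dt_min: float = 1.0,
            chemotaxis: bool = True, r_snap: float = 1.0) -> tuple[float, float]:
    """Move one cell by ``round(k_v dt / lattice)`` unit jumps.

    Each jump considers the four lattice neighbours that are inside the
    healing region and unoccupied; with chemotaxis the candidate with the
    highest debris concentration is taken (uniform tie-break), otherwise a
    uniform choice.  A fully blocked cell stays put.  Returns the new
    position (the population and occupancy index are updated in place).
    """
    n_jumps = int(round(k_v * dt_min / r_snap))
    x, y = float(pop.x[cell_idx]), float(pop.y[cell_idx])
    for _ in range(n_jumps):
        cands = []
        for dx, dy in ((r_snap, 0.0), (-r_snap, 0.0), (0.0, r_snap), (0.0, -r_snap)):
            nx_, ny_ = x + dx, y + dy
            r, c = masks.voxel_of(nx_, ny_)
            if not masks.healing_region[r, c]:
                continue
            if not occupancy.is_free(nx_, ny_, pop.x, pop.y, exclude=cell_idx):
                continue
            cands.append((nx_, ny_, bilinear_sample(debris, nx_, ny_, masks.origin,
                                                    masks.resolution)))
        if not cands:
            continue
        if chemotaxis:
            best = max(v for _, _, v in cands)
            cands = [c for c in cands if c[2] == best]
        nx_, ny_, _ = cands[int(rng.integers(len(cands)))]
        occupancy.remove(cell_idx, x, y)
        x, y = nx_, ny_
        pop.x[cell_idx], pop.y[cell_idx] = x, y
        occupancy.insert(cell_idx, x, y)
    return x, y
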