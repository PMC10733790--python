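"""Two-clock multiscale loop: 1 s molecular steps, 1 min cellular steps.

Each cellular iteration advances the molecular level 60 steps (secretion,
diffusion, decay, engulfment) with cell positions frozen, then performs one
cellular update (recruitment, event lottery, migration).  Hourly summaries
are recorded: per-phenotype concentrations (cells per mm² of healing
region), region totals of each cytokine and of debris.

Runs are bitwise reproducible per seed: a single numpy Generator drives
every stochastic choice, and the numba kernels consume pre-drawn arrays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from callusim import kernels
from callusim.agents import (
    CellPopulation,
    Occupancy,
    PhenotypeParams,
    PolarizationParams,
    RecruitmentParams,
    recruit,
)
from callusim.config import ParameterSet, RunOptions
from callusim.fields import MolecularState, SecretionParams, TransportParams
from callusim.geometry import ConfigurationError, DomainMasks, DomainSpec, area_of, build_domain

_PHEN_NAMES = ("M0", "M1", "M2", "PMN")


@dataclass
class SimulationState:
    """Full mutable simulation state: agents, molecular fields, clock, RNG."""

    pop: CellPopulation
    molecular: MolecularState
    t: float  # min
    rng: np.random.Generator
    domain: DomainMasks
    occupancy: Occupancy = field(repr=False, default=None)

    @property
    def area_mm2(self) -> float:
        return area_of(self.domain.healing_region, self.domain.resolution)


@dataclass
class TrajectoryRecord:
    """Hourly time series of population and molecular summaries."""

    data: pd.DataFrame
    area_mm2: float
    seed: int

    def at_day(self, day: float) -> pd.Series:
        """Row closest to the requested day."""
        idx = (self.data["time_h"] - day * 24.0).abs().idxmin()
        return self.data.loc[idx]

    def peak_time_h(self, column: str) -> float:
        return float(self.data.loc[self.data[column].idxmax(), "time_h"])


def initialize(spec: DomainSpec, params: ParameterSet, seed: int,
               masks: DomainMasks | None = None) -> SimulationState:
    """Initial condition: uniform PMNs, homogeneous debris, zero cytokines.

    No macrophages are present at t=0; they are recruited from the first
    iterations onward.  The PMN count is ``round(PMN_0 * area)`` placed
    uniformly at random on the cell lattice, respecting exclusion.
    """
    masks = masks if masks is not None else build_domain(spec)
    rng = np.random.default_rng(seed)
    mol = MolecularState.zeros(masks, db0=params.Db_0)
    pop = CellPopulation()
    occ = Occupancy(spec.extent, spec.extent, masks.origin, params.r_ex)

    area = area_of(masks.healing_region, masks.resolution)
    n_pmn = int(round(params.PMN_0 * area))
    rows, cols = np.nonzero(masks.healing_region)
    h = masks.resolution
    snap = spec.cell_resolution
    placed = 0
    attempts = 0
    max_attempts = 200 * max(n_pmn, 1)
    xs = pop.x
    ys = pop.y
    while placed < n_pmn:
        if attempts >= max_attempts:
            raise ConfigurationError(
                f"cannot place {n_pmn} PMNs at exclusion radius {params.r_ex} um")
        attempts += 1
        j = int(rng.integers(len(rows)))
        x = masks.origin[0] + cols[j] * h + float(rng.integers(int(h / snap))) * snap
        y = masks.origin[1] + rows[j] * h + float(rng.integers(int(h / snap))) * snap
        if occ.is_free(x, y, pop.x, pop.y):
            pop.add(x, y, 3)  # PMN
            occ.insert(len(pop) - 1, x, y)
            placed += 1
    return SimulationState(pop=pop, molecular=mol, t=0.0, rng=rng,
                           domain=masks, occupancy=occ)


def sensed_debris(debris: np.ndarray, mask: np.ndarray, sigma_vox: float) -> np.ndarray:
    """Chemoattractant signal: mask-normalized Gaussian blur of the debris.

    Phagocytes sense debris through diffusible damage signals rather than
    by contact, so migration ascends this smoothed view (sensing range
    ``sigma``); engulfment and every debris invariant act on the raw,
    non-diffusing field.
    """
    if sigma_vox <= 0:
        return debris
    from scipy.ndimage import gaussian_filter

    num = gaussian_filter(np.where(mask, debris, 0.0), sigma_vox)
    den = gaussian_filter(mask.astype(float), sigma_vox)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 1e-12, num / den, 0.0)
    return np.where(mask, out, 0.0)


def _crop_box(mask: np.ndarray) -> tuple[slice, slice]:
    rows = np.nonzero(mask.any(axis=1))[0]
    cols = np.nonzero(mask.any(axis=0))[0]
    return slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1)


def _record_row(state: SimulationState, area: float) -> dict[str, float]:
    counts = state.pop.counts()
    totals = state.molecular.totals()
    region = state.domain.healing_region
    row = {"time_h": state.t / 60.0}
    for name in _PHEN_NAMES:
        row[f"n_{name}"] = counts[name]
        row[f"conc_{name}"] = counts[name] / area
    mphi = counts["M0"] + counts["M1"] + counts["M2"]
    row["n_MPhi"] = mphi
    row["conc_MPhi"] = mphi / area
    for cyt in ("tnfa", "il10", "tgfb", "ifng", "debris"):
        row[f"total_{cyt}"] = totals[cyt]
    row["debris_max"] = float(state.molecular.debris[region].max()) if region.any() else 0.0
    return row


def run(state: SimulationState, params: ParameterSet, t_end_days: float,
        opts: RunOptions | None = None) -> TrajectoryRecord:
    """Advance the coupled simulation to ``t_end_days`` and record hourly.

    Mutates ``state`` in place and returns the trajectory.  The horizon is
    capped at 5 days (the scope of the inflammatory-stage model).
    """
    if t_end_days <= 0 or t_end_days > 5:
        raise ConfigurationError("simulated horizon must be in (0, 5] days")
    opts = opts or RunOptions(days=min(t_end_days, 5.0))

    masks = state.domain
    spec = masks.spec
    mask = masks.healing_region
    h = masks.resolution
    area = state.area_mm2
    snap = spec.cell_resolution if spec is not None else 1.0

    tp = TransportParams.from_parameters(params)
    sp = SecretionParams.from_parameters(params)
    pp = PhenotypeParams.from_parameters(params)
    rp = RecruitmentParams.from_parameters(params)
    pol = PolarizationParams.from_parameters(params)

    dt_cell = params.dt_cell                       # min
    dt_mol = tp.dt_mol                             # s
    n_mol = int(round(dt_cell * 60.0 / dt_mol))
    if abs(n_mol * dt_mol - dt_cell * 60.0) > 1e-9:
        raise ConfigurationError("dt_mol must divide the cellular step")
    nsub = tp.n_substeps(h)
    lam = np.array([tp.D(c) * (dt_mol / nsub) / (h * h)
                    for c in ("tnfa", "il10", "tgfb", "ifng")])
    dexp = np.array([math.exp(-tp.d(c) * dt_mol)
                     for c in ("tnfa", "il10", "tgfb", "ifng")])

    # cropped working arrays around the healing region
    rsl, csl = _crop_box(mask)
    mask_c = np.ascontiguousarray(mask[rsl, csl])
    from callusim.fields import neighbor_count

    nbr_c = np.ascontiguousarray(neighbor_count(mask)[rsl, csl])
    mol = state.molecular
    F = np.stack([mol.tnfa[rsl, csl], mol.il10[rsl, csl],
                  mol.tgfb[rsl, csl], mol.ifng[rsl, csl]])
    debris_c = np.ascontiguousarray(mol.debris[rsl, csl])
    mox = masks.origin[0] + csl.start * h
    moy = masks.origin[1] + rsl.start * h

    k_e = np.array([pp.k_e[n] for n in _PHEN_NAMES])
    k_v = np.array([pp.k_v[n] for n in _PHEN_NAMES])
    k_p = np.array([pp.k_p[n] for n in _PHEN_NAMES])
    k_a0 = np.array([pp.k_a0[n] for n in _PHEN_NAMES])
    njump_by_phen = np.round(k_v * dt_cell / snap).astype(np.int64)
    stencil_radius = int(params.engulf_radius)
    daughter_step = math.ceil(params.r_ex / snap) * snap
    rng = state.rng
    occ = state.occupancy

    def sync_full() -> None:
        mol.tnfa[rsl, csl] = F[0]
        mol.il10[rsl, csl] = F[1]
        mol.tgfb[rsl, csl] = F[2]
        mol.ifng[rsl, csl] = F[3]
        mol.debris[rsl, csl] = debris_c

    records = [_record_row(state, area)]
    next_record = opts.record_every_min
    n_steps = int(round(t_end_days * 24.0 * 60.0 / dt_cell))

    for _step in range(n_steps):
        pop = state.pop
        n = len(pop)
        # ---- molecular block: 60 x (secretion, diffusion, decay), engulf --
        if n:
            crow = ((pop.y - moy) / h).astype(np.int64)
            ccol = ((pop.x - mox) / h).astype(np.int64)
        else:
            crow = np.empty(0, dtype=np.int64)
            ccol = np.empty(0, dtype=np.int64)
        kernels.mol_block(F, mask_c, nbr_c, lam, dexp, nsub, crow, ccol,
                          pop.phen, n_mol, dt_mol / 60.0,
                          sp.k_TNF, sp.k_TNI, sp.a_TNI, sp.k_TNIL, sp.a_TNIL,
                          sp.b_TNIL, sp.k_TNTG, sp.a_TNTG, sp.b_TNTG,
                          sp.k_IL10, sp.k_TGF, sp.k_IFN, sp.a_ITN)
        if n:
            # engulfment composes exactly over the block (debris only decays
            # by removal), so one call with dt = dt_cell is the 60-step limit
            ke_dt = k_e[pop.phen] * dt_cell
            kernels.engulf_block(debris_c, mask_c, crow, ccol, ke_dt,
                                 stencil_radius, pop.load)
        mol.time += dt_cell * 60.0

        # ---- cellular step: recruitment, lottery, migration ---------------
        sync_full()
        recruit(pop, masks, mol.debris, rp, dt_cell, rng, occ, snap)
        n = len(pop)
        if n:
            crow = ((pop.y - moy) / h).astype(np.int64)
            ccol = ((pop.x - mox) / h).astype(np.int64)
            local_t = F[0][crow, ccol]
            local_i = F[1][crow, ccol]
            nnbr = np.zeros(n, dtype=np.int64)
            kernels.count_neighbors(pop.x, pop.y, params.r_neighbor, occ.count,
                                    occ.slots, occ.origin[0], occ.origin[1],
                                    occ.bin, nnbr)

            p_apop = np.clip(k_a0[pop.phen] * (1.0 + pp.alpha_d * pop.load
                                               + pp.alpha_n * nnbr) * dt_cell, 0.0, 1.0)
            p_prol = np.clip(k_p[pop.phen] * dt_cell, 0.0, 1.0)
            with np.errstate(invalid="ignore"):
                sat_t = np.where(local_t > 0, local_t / (pol.a01 + local_t), 0.0)
                sat_t21 = np.where(local_t > 0, local_t / (pol.a21 + local_t), 0.0)
                sat_i02 = np.where(local_i > 0, local_i / (pol.a02 + local_i), 0.0)
                sat_i12 = np.where(local_i > 0, local_i / (pol.a12 + local_i), 0.0)

            def q(u: np.ndarray) -> np.ndarray:
                return np.floor(u * 1e6) * 1e-6

            u_apop = q(rng.random(n))
            u_prol = q(rng.random(n))
            u_pol1 = q(rng.random(n))
            u_pol2 = q(rng.random(n))

            apop = u_apop < p_apop
            prol = ~apop & (u_prol < p_prol)
            # polarization: first matching transition wins (M0: M1 then M2)
            pol_target = np.full(n, -1, dtype=np.int8)
            is_m0 = pop.phen == 0
            is_m1 = pop.phen == 1
            is_m2 = pop.phen == 2
            p01 = np.clip(pol.k01 * sat_t * dt_cell, 0.0, 1.0)
            p02 = np.clip(pol.k02 * sat_i02 * dt_cell, 0.0, 1.0)
            p12 = np.clip(pol.k12 * sat_i12 * dt_cell, 0.0, 1.0)
            p21 = np.clip(pol.k21 * sat_t21 * dt_cell, 0.0, 1.0)
            pol_target[is_m0 & (u_pol1 < p01)] = 1
            pol_target[is_m0 & ~(u_pol1 < p01) & (u_pol2 < p02)] = 2
            pol_target[is_m1 & (u_pol1 < p12)] = 2
            pol_target[is_m2 & (u_pol1 < p21)] = 1
            polarize = ~apop & ~prol & (pol_target >= 0)

            # proliferation: daughters one exclusion radius away, random
            # unoccupied cardinal direction, skipped if all four blocked
            daughters: list[tuple[float, float, int]] = []
            for i in np.nonzero(prol)[0]:
                dirs = rng.permutation(4)
                for dcode in dirs:
                    dx, dy = ((daughter_step, 0.0), (-daughter_step, 0.0),
                              (0.0, daughter_step), (0.0, -daughter_step))[dcode]
                    xd, yd = pop.x[i] + dx, pop.y[i] + dy
                    r, c = masks.voxel_of(xd, yd)
                    if not masks.healing_region[r, c]:
                        continue
                    if not occ.is_free(xd, yd, pop.x, pop.y):
                        continue
                    daughters.append((xd, yd, int(pop.phen[i])))
                    break

            pop.phen[polarize] = pol_target[polarize]
            pop.age += dt_cell
            if apop.any():
                pop.keep(~apop)
            for xd, yd, ph in daughters:
                pop.add(xd, yd, ph)
            kernels.rebuild_bins(pop.x, pop.y, occ.count, occ.slots,
                                 occ.origin[0], occ.origin[1], occ.bin)

            # migration
            n = len(pop)
            if n:
                njumps = njump_by_phen[pop.phen]
                maxj = int(njumps.max()) if n else 0
                if maxj > 0:
                    if opts.chemotaxis:
                        chemo_field = sensed_debris(debris_c, mask_c,
                                                    params.chemotaxis_range / h)
                    else:
                        chemo_field = debris_c
                    order = rng.permutation(n).astype(np.int64)
                    u_choice = rng.random((n, maxj))
                    kernels.migrate_all(pop.x, pop.y, order, njumps, mask_c,
                                        mox, moy, h, chemo_field,
                                        occ.count, occ.slots, occ.origin[0],
                                        occ.origin[1], occ.bin, params.r_ex**2,
                                        u_choice, opts.chemotaxis, snap)

        state.t += dt_cell
        if state.t + 1e-9 >= next_record:
            sync_full()
            records.append(_record_row(state, area))
            next_record += opts.record_every_min

    sync_full()
    if abs(records[-1]["time_h"] - state.t / 60.0) > 1e-9:
        records.append(_record_row(state, area))
    seed_val = -1
    return TrajectoryRecord(pd.DataFrame.from_records(records), area, seed_val)


def simulate(spec: DomainSpec, params: ParameterSet, seed: int, days: float,
             opts: RunOptions | None = None,
             masks: DomainMasks | None = None) -> TrajectoryRecord:
    """Convenience wrapper: initialize and run one replicate."""
    state = initialize(spec, params, seed, masks=masks)
    traj = run(state, params, days, opts)
    traj.seed = seed
    return traj


def run_replicates(spec: DomainSpec, params: ParameterSet, seeds,
                   days: float, opts: RunOptions | None = None) -> list[TrajectoryRecord]:
    """Independent replicates under identical conditions, one per seed."""
    masks = build_domain(spec)
    return [simulate(spec, params, int(s), days, opts, masks=masks) for s in seeds]


def summarize_replicates(trajectories: list[TrajectoryRecord]) -> pd.DataFrame:
    """Mean and SD (ddof=1) per recorded output across replicates.

    Returns a frame indexed like the trajectories with ``<col>_mean`` /
    ``<col>_sd`` columns.  Requires at least two replicates.
    """
    if len(trajectories) < 2:
        raise ValueError("replicate statistics need n >= 2")
    frames = [t.data for t in trajectories]
    nrows = min(len(f) for f in frames)
    stack = np.stack([f.iloc[:nrows].to_numpy(dtype=float) for f in frames])
    cols = frames[0].columns
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    # identical replicates have exactly zero spread (no rounding residue)
    sd[np.ptp(stack, axis=0) == 0] = 0.0
    out = {}
    for j, col in enumerate(cols):
        if col == "time_h":
            out[col] = mean[:, j]
        else:
            out[f"{col}_mean"] = mean[:, j]
            out[f"{col}_sd"] = sd[:, j]
    return pd.DataFrame(out)


def one_tailed_t(a, b, alternative: str = "greater") -> float:
    """One-tailed Welch t-test p-value for mean(a) vs mean(b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("t-test needs n >= 2 per sample")
    res = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return float(res.pvalue)
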