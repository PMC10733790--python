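"""Numba kernels fusing the hot loops of the two-clock scheduler.

The reference semantics live in :mod:`callusim.fields` and
:mod:`callusim.agents`; these kernels reproduce them exactly (same update
order, same no-flux stencil, same occupancy rule) and are cross-checked by
the test suite.  All randomness is pre-drawn from the single simulation
generator and passed in as arrays, so the fused path stays bitwise
deterministic per seed.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# phenotype codes (must match agents.PHENOTYPE_CODES)
_M0, _M1, _M2, _PMN = 0, 1, 2, 3


@njit(cache=True)
def mol_block(F, mask, nbr, lam, dexp, nsub, crow, ccol, phen, n_steps, dt_min,
              kTNF, kTNI, aTNI, kTNIL, aTNIL, bTNIL, kTNTG, aTNTG, bTNTG,
              kIL10, kTGF, kIFN, aITN):  # pragma: no cover - exercised via wrapper
    """Advance the four cytokine fields ``n_steps`` molecular steps.

    ``F`` is the (4, ny, nx) stack [tnfa, il10, tgfb, ifng]; per step:
    secretion from the frozen cell positions (rates read from the pre-step
    concentrations), then ``nsub`` explicit diffusion substeps with no-flux
    walls, then exponential decay.  ``lam`` = D * dt_sub / h² per field,
    ``dexp`` = exp(-d * dt_mol) per field, ``dt_min`` the molecular step in
    minutes (secretion constants are per minute).
    """
    ny, nx = mask.shape
    ncell = crow.shape[0]
    inc = np.empty((ncell, 4))
    buf = np.empty((ny, nx))
    for _step in range(n_steps):
        # --- secretion: gather rates from pre-step state, then deposit ----
        for i in range(ncell):
            r, c = crow[i], ccol[i]
            T = F[0, r, c]
            I = F[1, r, c]
            G = F[2, r, c]
            N = F[3, r, c]
            amp = 1.0 + kTNI / (1.0 + math.exp(aTNI - N))
            i_tnfa = 0.0
            i_il10 = 0.0
            i_tgfb = 0.0
            i_ifng = 0.0
            p = phen[i]
            if p == _M0:
                i_tnfa = kTNF * amp
                i_il10 = kIL10
                i_tgfb = kTGF
                i_ifng = kIFN * math.exp(-aITN * T)
            elif p == _M1:
                inh = (kTNIL * math.exp(-aTNIL * I) + bTNIL) * \
                      (kTNTG * math.exp(-aTNTG * G) + bTNTG)
                i_tnfa = kTNF * inh * amp
                i_tgfb = kTGF
                i_ifng = kIFN * math.exp(-aITN * T)
            elif p == _M2:
                i_il10 = kIL10
                i_tgfb = kTGF
            else:  # PMN
                i_tnfa = kTNF
                i_ifng = kIFN
            inc[i, 0] = i_tnfa * dt_min
            inc[i, 1] = i_il10 * dt_min
            inc[i, 2] = i_tgfb * dt_min
            inc[i, 3] = i_ifng * dt_min
        for i in range(ncell):
            r, c = crow[i], ccol[i]
            for f in range(4):
                F[f, r, c] += inc[i, f]
        # --- diffusion (explicit, substepped) + decay ---------------------
        for f in range(4):
            for _s in range(nsub):
                for r in range(ny):
                    for c in range(nx):
                        if not mask[r, c]:
                            buf[r, c] = F[f, r, c]
                            continue
                        s = 0.0
                        if r > 0 and mask[r - 1, c]:
                            s += F[f, r - 1, c]
                        if r < ny - 1 and mask[r + 1, c]:
                            s += F[f, r + 1, c]
                        if c > 0 and mask[r, c - 1]:
                            s += F[f, r, c - 1]
                        if c < nx - 1 and mask[r, c + 1]:
                            s += F[f, r, c + 1]
                        buf[r, c] = F[f, r, c] + lam[f] * (s - nbr[r, c] * F[f, r, c])
                for r in range(ny):
                    for c in range(nx):
                        F[f, r, c] = buf[r, c]
            for r in range(ny):
                for c in range(nx):
                    if mask[r, c]:
                        F[f, r, c] *= dexp[f]


@njit(cache=True)
def engulf_block(debris, mask, crow, ccol, ke_dt, stencil_radius,
                 loads):  # pragma: no cover - exercised via wrapper
    """Engulf debris around each phagocyte over one (possibly long) interval.

    ``ke_dt`` is the per-cell fractional engulfment ``k_e * dt``.  Per
    voxel the removed mass is ``debris * (1 - exp(-Σ ke_dt))`` (the
    order-independent limit of sequential engulfment) shared among covering
    cells proportionally to their rate.  ``loads`` accumulates per-cell
    gains in place.
    """
    ny, nx = mask.shape
    ncell = crow.shape[0]
    demand = np.zeros((ny, nx))
    for i in range(ncell):
        r0, c0 = crow[i], ccol[i]
        for dr in range(-stencil_radius, stencil_radius + 1):
            for dc in range(-stencil_radius, stencil_radius + 1):
                if abs(dr) + abs(dc) > stencil_radius:
                    continue
                r, c = r0 + dr, c0 + dc
                if 0 <= r < ny and 0 <= c < nx and mask[r, c]:
                    demand[r, c] += ke_dt[i]
    per_unit = np.zeros((ny, nx))
    for r in range(ny):
        for c in range(nx):
            if demand[r, c] > 0.0:
                removed = debris[r, c] * -math.expm1(-demand[r, c])
                per_unit[r, c] = removed / demand[r, c]
                debris[r, c] -= removed
                if debris[r, c] < 0.0:
                    debris[r, c] = 0.0
    for i in range(ncell):
        r0, c0 = crow[i], ccol[i]
        for dr in range(-stencil_radius, stencil_radius + 1):
            for dc in range(-stencil_radius, stencil_radius + 1):
                if abs(dr) + abs(dc) > stencil_radius:
                    continue
                r, c = r0 + dr, c0 + dc
                if 0 <= r < ny and 0 <= c < nx and mask[r, c]:
                    loads[i] += per_unit[r, c] * ke_dt[i]


# ---------------------------------------------------------------------------
# occupancy bins (must mirror agents.Occupancy exactly)
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _bin_of(x, y, ox, oy, binsize, nby, nbx):
    bx = int((x - ox) / binsize) + 1
    by = int((y - oy) / binsize) + 1
    if by < 0:
        by = 0
    elif by > nby - 1:
        by = nby - 1
    if bx < 0:
        bx = 0
    elif bx > nbx - 1:
        bx = nbx - 1
    return by, bx


@njit(cache=True)
def rebuild_bins(xs, ys, bin_count, bin_slots, ox, oy, binsize):
    bin_count[:] = 0
    bin_slots[:] = -1
    nby, nbx = bin_count.shape
    for i in range(xs.shape[0]):
        by, bx = _bin_of(xs[i], ys[i], ox, oy, binsize, nby, nbx)
        k = bin_count[by, bx]
        bin_slots[by, bx, k] = i
        bin_count[by, bx] = k + 1


@njit(cache=True, inline="always")
def _is_free(x, y, exclude, xs, ys, bin_count, bin_slots, ox, oy, binsize, r_ex2):
    nby, nbx = bin_count.shape
    by, bx = _bin_of(x, y, ox, oy, binsize, nby, nbx)
    for dy in range(-1, 2):
        for dx in range(-1, 2):
            yy, xx = by + dy, bx + dx
            if yy < 0 or yy >= nby or xx < 0 or xx >= nbx:
                continue
            for j in range(bin_count[yy, xx]):
                i = bin_slots[yy, xx, j]
                if i == exclude:
                    continue
                d2 = (xs[i] - x) ** 2 + (ys[i] - y) ** 2
                if d2 < r_ex2:
                    return False
    return True


@njit(cache=True)
def count_neighbors(xs, ys, radius, bin_count, bin_slots, ox, oy, binsize, out):
    """Cells within ``radius`` of each cell (self excluded), via the bins."""
    nby, nbx = bin_count.shape
    reach = int(math.ceil(radius / binsize))
    r2 = radius * radius
    for i in range(xs.shape[0]):
        by, bx = _bin_of(xs[i], ys[i], ox, oy, binsize, nby, nbx)
        n = 0
        for dy in range(-reach, reach + 1):
            for dx in range(-reach, reach + 1):
                yy, xx = by + dy, bx + dx
                if yy < 0 or yy >= nby or xx < 0 or xx >= nbx:
                    continue
                for j in range(bin_count[yy, xx]):
                    k = bin_slots[yy, xx, j]
                    if k == i:
                        continue
                    if (xs[k] - xs[i]) ** 2 + (ys[k] - ys[i]) ** 2 <= r2:
                        n += 1
        out[i] = n


@njit(cache=True, inline="always")
def _bilinear(field, x, y, mox, moy, h):
    """Bilinear sample of a voxel-centred field at a continuous position."""
    ny, nx = field.shape
    gx = (x - mox) / h - 0.5
    gy = (y - moy) / h - 0.5
    c0 = int(math.floor(gx))
    r0 = int(math.floor(gy))
    tx = gx - c0
    ty = gy - r0
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
    v00 = field[r0, c0]
    v01 = field[r0, c1]
    v10 = field[r1, c0]
    v11 = field[r1, c1]
    return (v00 * (1 - tx) + v01 * tx) * (1 - ty) + (v10 * (1 - tx) + v11 * tx) * ty


@njit(cache=True)
def migrate_all(xs, ys, order, njumps, mask, mox, moy, h, debris,
                bin_count, bin_slots, ox, oy, binsize, r_ex2,
                u_choice, chemotaxis, snap):  # pragma: no cover - via wrapper
    """Jump-migrate every cell (sequentially, in ``order``), updating bins.

    Per jump the four lattice neighbours are screened for being inside the
    healing region and unoccupied; with chemotaxis the free candidate with
    the highest debris concentration wins (uniform tie-break via
    ``u_choice``), otherwise a uniform choice.  Blocked cells stay.
    """
    ny, nx = mask.shape
    nby, nbx = bin_count.shape
    cand_x = np.empty(4)
    cand_y = np.empty(4)
    cand_v = np.empty(4)
    for oi in range(order.shape[0]):
        i = order[oi]
        x = xs[i]
        y = ys[i]
        for j in range(njumps[i]):
            ncand = 0
            for k in range(4):
                if k == 0:
                    nx_, ny_ = x + snap, y
                elif k == 1:
                    nx_, ny_ = x - snap, y
                elif k == 2:
                    nx_, ny_ = x, y + snap
                else:
                    nx_, ny_ = x, y - snap
                r = int((ny_ - moy) / h)
                c = int((nx_ - mox) / h)
                if r < 0 or r >= ny or c < 0 or c >= nx or not mask[r, c]:
                    continue
                if not _is_free(nx_, ny_, i, xs, ys, bin_count, bin_slots,
                                ox, oy, binsize, r_ex2):
                    continue
                cand_x[ncand] = nx_
                cand_y[ncand] = ny_
                cand_v[ncand] = _bilinear(debris, nx_, ny_, mox, moy, h)
                ncand += 1
            if ncand == 0:
                continue
            lo = 0
            n_tie = ncand
            if chemotaxis:
                best = cand_v[0]
                for k in range(1, ncand):
                    if cand_v[k] > best:
                        best = cand_v[k]
                # stable compaction of the ties to the front
                n_tie = 0
                for k in range(ncand):
                    if cand_v[k] == best:
                        cand_x[n_tie] = cand_x[k]
                        cand_y[n_tie] = cand_y[k]
                        n_tie += 1
            pick = lo + int(u_choice[i, j] * n_tie)
            if pick >= n_tie:
                pick = n_tie - 1
            # move: update bins
            by, bx = _bin_of(x, y, ox, oy, binsize, nby, nbx)
            kcnt = bin_count[by, bx]
            for s in range(kcnt):
                if bin_slots[by, bx, s] == i:
                    bin_slots[by, bx, s] = bin_slots[by, bx, kcnt - 1]
                    bin_slots[by, bx, kcnt - 1] = -1
                    bin_count[by, bx] = kcnt - 1
                    break
            x = cand_x[pick]
            y = cand_y[pick]
            xs[i] = x
            ys[i] = y
            by, bx = _bin_of(x, y, ox, oy, binsize, nby, nbx)
            kcnt = bin_count[by, bx]
            bin_slots[by, bx, kcnt] = i
            bin_count[by, bx] = kcnt + 1
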