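"""Numba-compiled inner loop of the motion sweep.

Cells are updated one by one in id order; each later cell sees the already
updated positions of earlier cells.  Per cell the kernel gathers, from a
uniform grid built on the pre-sweep positions, (a) the attraction drift from
all cells within the force cutoff and (b) the list of admissibility
candidates (cells currently within 3 cell diameters, enough to cover any
realistic proposal displacement).  The proposal ``drift*dt + sqrt(2*D*dt)*eta``
is then tested against the overlap floor; on rejection only the Gaussian
noise is redrawn, up to ``max_retries`` times, after which the cell stays
put.

The pair force ``(Delta/sigma) * K1(r/sigma)`` is evaluated through a
linear-interpolation table built from scipy's K1 (pair separations are
bounded below by the overlap floor, so the table domain is safe); numba's
own RNG is seeded per sweep from the caller's generator, which keeps runs
bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Proposals displacing a cell by more than this fall back to a brute-force
# admissibility check over all cells (the candidate list only covers
# displacements up to ~2 diameters; Gaussian steps are ~0.05).
_CAND_RADIUS2 = 9.0
_SAFE_DISP2 = 1.0


@njit(cache=True)
def move_sweep_kernel(
    pos,            # (N, 2) float64, updated in place
    use_force,      # bool: skip force gather when Delta == 0
    ftab,           # force table: (Delta/sigma) * K1(r/sigma) / r
    ftab_r0,        # first tabulated r
    ftab_dr,        # table spacing
    rc2,            # cutoff_radius ** 2
    dt,
    noise_scale,    # sqrt(2 * D * dt)
    floor2,         # overlap_floor ** 2
    max_retries,
    seed,
    ox, oy,         # grid origin
    inv_bin,        # 1 / bin_size
    nbx, nby,       # grid shape
    bin_start,      # CSR offsets into bin_cells, length nbx*nby + 1
    bin_cells,      # cell indices sorted by flat bin id
    scan,           # bin scan radius (covers the force cutoff)
):
    np.random.seed(seed)
    n = pos.shape[0]
    cand = np.empty(n, np.int64)
    last = ftab.shape[0] - 1
    n_frozen = 0
    for i in range(n):
        xi = pos[i, 0]
        yi = pos[i, 1]
        bx = int((xi - ox) * inv_bin)
        by = int((yi - oy) * inv_bin)
        fx = 0.0
        fy = 0.0
        nc = 0
        x0 = bx - scan
        if x0 < 0:
            x0 = 0
        x1 = bx + scan + 1
        if x1 > nbx:
            x1 = nbx
        y0 = by - scan
        if y0 < 0:
            y0 = 0
        y1 = by + scan + 1
        if y1 > nby:
            y1 = nby
        for gx in range(x0, x1):
            base = gx * nby
            for gy in range(y0, y1):
                b = base + gy
                for m in range(bin_start[b], bin_start[b + 1]):
                    j = bin_cells[m]
                    if j == i:
                        continue
                    dx = pos[j, 0] - xi
                    dy = pos[j, 1] - yi
                    r2 = dx * dx + dy * dy
                    if r2 < _CAND_RADIUS2:
                        cand[nc] = j
                        nc += 1
                    if use_force and r2 < rc2:
                        r = np.sqrt(r2)
                        u = (r - ftab_r0) / ftab_dr
                        if u < 0.0:
                            u = 0.0
                        k = int(u)
                        if k >= last:
                            s = 0.0
                        else:
                            w = u - k
                            s = ftab[k] * (1.0 - w) + ftab[k + 1] * w
                        fx += s * dx
                        fy += s * dy
        drift_x = fx * dt
        drift_y = fy * dt
        moved = False
        for _ in range(max_retries):
            nxp = xi + drift_x + noise_scale * np.random.normal()
            nyp = yi + drift_y + noise_scale * np.random.normal()
            ddx = nxp - xi
            ddy = nyp - yi
            ok = True
            if ddx * ddx + ddy * ddy > _SAFE_DISP2:
                for j in range(n):
                    if j == i:
                        continue
                    ex = pos[j, 0] - nxp
                    ey = pos[j, 1] - nyp
                    if ex * ex + ey * ey < floor2:
                        ok = False
                        break
            else:
                for m in range(nc):
                    j = cand[m]
                    ex = pos[j, 0] - nxp
                    ey = pos[j, 1] - nyp
                    if ex * ex + ey * ey < floor2:
                        ok = False
                        break
            if ok:
                pos[i, 0] = nxp
                pos[i, 1] = nyp
                moved = True
                break
        if not moved:
            n_frozen += 1
    return n_frozen
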