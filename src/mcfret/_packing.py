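"""Hard-disk placement kernels (numba-compiled).

Nanodomains are modelled as non-overlapping disks of radius R in a periodic
square box.  Low coverage uses random sequential adsorption (RSA); above the
regime where RSA becomes impractically slow (it jams near 54.7% coverage) the
disks are seeded on a randomly vacated square lattice and randomised with
Metropolis displacement sweeps.  Both paths keep every pair of centres at
least 2R apart under the minimum-image convention.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# coverage above which the lattice-seeded path is used
LATTICE_THRESHOLD = 0.42


@njit(cache=False)
def _min_image_1d(d: float, box: float) -> float:
    if d > 0.5 * box:
        return d - box
    if d < -0.5 * box:
        return d + box
    return d


@njit(cache=False)
def _conflicts(x, y, pos, n_placed, skip, box, dmin2):
    for j in range(n_placed):
        if j == skip:
            continue
        dx = _min_image_1d(x - pos[j, 0], box)
        dy = _min_image_1d(y - pos[j, 1], box)
        if dx * dx + dy * dy < dmin2:
            return True
    return False


@njit(cache=False)
def _rsa_fill(pos, start, n, radius, box, max_fails):
    """Insert disks pos[start:n] by RSA; returns new placed count."""
    dmin2 = 4.0 * radius * radius
    placed = start
    fails = 0
    while placed < n and fails < max_fails:
        x = np.random.random() * box
        y = np.random.random() * box
        if _conflicts(x, y, pos, placed, -1, box, dmin2):
            fails += 1
        else:
            pos[placed, 0] = x
            pos[placed, 1] = y
            placed += 1
            fails = 0
    return placed


@njit(cache=False)
def _metropolis_sweeps(pos, n, radius, box, n_sweeps, delta):
    dmin2 = 4.0 * radius * radius
    for _ in range(n_sweeps):
        for i in range(n):
            xn = (pos[i, 0] + (2.0 * np.random.random() - 1.0) * delta) % box
            yn = (pos[i, 1] + (2.0 * np.random.random() - 1.0) * delta) % box
            if not _conflicts(xn, yn, pos, n, i, box, dmin2):
                pos[i, 0] = xn
                pos[i, 1] = yn


@njit(cache=False)
def _lattice_start(pos, n, box):
    """Place n disks on randomly chosen sites of an m x m square lattice."""
    m = int(np.ceil(np.sqrt(n)))
    n_sites = m * m
    order = np.arange(n_sites)
    # Fisher-Yates shuffle so the vacancies are randomly distributed
    for i in range(n_sites - 1, 0, -1):
        j = int(np.random.random() * (i + 1))
        tmp = order[i]
        order[i] = order[j]
        order[j] = tmp
    for k in range(n):
        site = order[k]
        pos[k, 0] = (site // m + 0.5) * box / m
        pos[k, 1] = (site % m + 0.5) * box / m


@njit(cache=False)
def pack_disks(n, radius, box, seed, n_sweeps=60, rsa_fail_cap=100000):
    """Return (positions, success) for n hard disks in a periodic box."""
    np.random.seed(seed)
    pos = np.empty((n, 2))
    if n == 0:
        return pos, True
    coverage = n * np.pi * radius * radius / (box * box)
    if coverage <= LATTICE_THRESHOLD:
        placed = _rsa_fill(pos, 0, n, radius, box, rsa_fail_cap)
        # bounded relaxation: shake what is placed, retry insertion
        tries = 0
        while placed < n and tries < 20:
            _metropolis_sweeps(pos, placed, radius, box, 5, 0.3 * radius)
            placed = _rsa_fill(pos, placed, n, radius, box, rsa_fail_cap)
            tries += 1
        if placed < n:
            return pos, False
    else:
        m = int(np.ceil(np.sqrt(n)))
        if box / m < 2.0 * radius:
            return pos, False
        _lattice_start(pos, n, box)
        _metropolis_sweeps(pos, n, radius, box, n_sweeps, 0.3 * radius)
    return pos, True
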