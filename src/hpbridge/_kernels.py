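"""Numba kernels for lattice enumeration and bit-parallel sequence sweeps.

All heavy loops of the exhaustive genotype-phenotype map live here: the
depth-first enumeration of symmetry-canonical self-avoiding walks, and the
per-sequence scan over contact-map equivalence classes that yields native
contact counts, degeneracies and densities of states.

Direction encoding is 2 bits per step with U=0, D=1, L=2, R=3, so that
integer order on packed direction words equals lexicographic order on
direction strings under U<D<L<R.
"""

import numpy as np
from numba import njit

U, D, L_, R = 0, 1, 2, 3
_DX = np.array([0, 0, -1, 1], dtype=np.int64)
_DY = np.array([1, -1, 0, 0], dtype=np.int64)

_M1 = np.uint64(0x5555555555555555)
_M2 = np.uint64(0x3333333333333333)
_M4 = np.uint64(0x0F0F0F0F0F0F0F0F)
_H01 = np.uint64(0x0101010101010101)


@njit(cache=True, inline="always")
def popcount64(x):
    x = x - ((x >> np.uint64(1)) & _M1)
    x = (x & _M2) + ((x >> np.uint64(2)) & _M2)
    x = (x + (x >> np.uint64(4))) & _M4
    return np.int64((x * _H01) >> np.uint64(56))


@njit(cache=True)
def enumerate_canonical(L, pair_bit, out_dirs, out_masks, fill):
    """Enumerate canonical self-avoiding walks of L monomers.

    Iterative backtracking over walks whose first step is R, pruning any
    direction prefix that is lexicographically larger than its up/down
    reflection (cmp: 0 = prefix equal to its reflection so far, -1 = already
    smaller).  Exactly one representative per symmetry orbit is emitted.
    Returns the number of walks; fills out_dirs/out_masks when fill is true.
    """
    G = 2 * L + 3
    grid = np.zeros((G, G), dtype=np.int16)
    # per-depth state; index j = number of residues already placed
    xs = np.zeros(L + 1, dtype=np.int64)
    ys = np.zeros(L + 1, dtype=np.int64)
    cmps = np.zeros(L + 1, dtype=np.int8)
    masks = np.zeros(L + 1, dtype=np.uint64)
    trial = np.zeros(L + 1, dtype=np.int8)  # next direction to try at depth j
    dirs = np.zeros(L, dtype=np.int8)
    count = np.int64(0)
    cx = L + 1
    grid[cx, cx] = 1
    cy = cx
    xs[1] = cx
    ys[1] = cy
    cmps[1] = 0
    masks[1] = np.uint64(0)
    trial[1] = R  # first step fixed to R
    j = 1
    while j >= 1:
        if j == L:
            if fill:
                packed = np.uint64(0)
                for k in range(L - 1):
                    packed = (packed << np.uint64(2)) | np.uint64(dirs[k])
                out_dirs[count] = packed
                out_masks[count] = masks[j]
            count += 1
            grid[xs[j], ys[j]] = 0
            j -= 1
            continue
        d = trial[j]
        if d > 3:
            grid[xs[j], ys[j]] = 0
            j -= 1
            continue
        trial[j] = d + 1
        cmp = cmps[j]
        if cmp == 0 and d == D:
            continue  # the reflected image (U here) is smaller
        nx = xs[j] + _DX[d]
        ny = ys[j] + _DY[d]
        if grid[nx, ny] != 0:
            continue
        add = np.uint64(0)
        for e in range(4):
            occ = grid[nx + _DX[e], ny + _DY[e]]
            if occ > 0 and (j + 1) - occ >= 3:
                b = pair_bit[occ - 1, j]
                add |= np.uint64(1) << np.uint64(b)
        dirs[j - 1] = d
        grid[nx, ny] = j + 1
        j += 1
        xs[j] = nx
        ys[j] = ny
        masks[j] = masks[j - 1] | add
        cmps[j] = -1 if (cmp == 0 and d == U) else cmp
        trial[j] = 0
    grid[cx, cy] = 0
    return count


@njit(cache=True)
def sweep_native(L, n_pairs, pair_i, pair_j, class_masks, class_mult,
                 class_pop, g_cap, out_n, out_g, out_hits, out_nhits):
    """Native-state summary for every HP sequence of length L.

    class_* arrays must be sorted by descending contact count (class_pop);
    the scan for a sequence stops once remaining classes cannot reach its
    current maximum.  out_hits receives the indices of the classes attaining
    the maximum (meaningful only when the final degeneracy is <= g_cap).
    """
    n_seq = 1 << L
    K = class_masks.size
    max_rec = out_hits.shape[1]
    for s in range(n_seq):
        smask = np.uint64(0)
        for p in range(n_pairs):
            if ((s >> pair_i[p]) & 1) == 1 and ((s >> pair_j[p]) & 1) == 1:
                smask |= np.uint64(1) << np.uint64(p)
        m = -1
        g = 0
        nh = 0
        for k in range(K):
            if class_pop[k] < m:
                break
            v = popcount64(class_masks[k] & smask)
            if v > m:
                m = v
                g = class_mult[k]
                out_hits[s, 0] = k
                nh = 1
            elif v == m:
                g += class_mult[k]
                if nh < max_rec:
                    out_hits[s, nh] = k
                nh += 1
        out_n[s] = m
        out_g[s] = g
        out_nhits[s] = nh if nh <= max_rec else max_rec


@njit(cache=True)
def dos_batch(seqs, L, n_pairs, pair_i, pair_j, class_masks, class_mult,
              n_max):
    """Exact density of states h[n] for each sequence in `seqs`."""
    out = np.zeros((seqs.size, n_max + 1), dtype=np.int64)
    K = class_masks.size
    for t in range(seqs.size):
        s = seqs[t]
        smask = np.uint64(0)
        for p in range(n_pairs):
            if ((s >> pair_i[p]) & 1) == 1 and ((s >> pair_j[p]) & 1) == 1:
                smask |= np.uint64(1) << np.uint64(p)
        for k in range(K):
            v = popcount64(class_masks[k] & smask)
            out[t, v] += class_mult[k]
    return out


@njit(cache=True)
def contacts_for_sequences(seqs, struct_mask, n_pairs, pair_i, pair_j):
    """HH-contact count of each sequence when threaded onto one structure."""
    out = np.zeros(seqs.size, dtype=np.int64)
    for t in range(seqs.size):
        s = seqs[t]
        c = 0
        for p in range(n_pairs):
            if (struct_mask >> np.uint64(p)) & np.uint64(1):
                if ((s >> pair_i[p]) & 1) == 1 and ((s >> pair_j[p]) & 1) == 1:
                    c += 1
        out[t] = c
    return out
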