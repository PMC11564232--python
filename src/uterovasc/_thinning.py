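"""Topology-preserving 3D curve thinning.

The skeletonization used for the utero-placental vascular skeleton peels off
the outermost layer of foreground voxels round after round until only a
one-voxel-wide centerline network remains.  A naive erosion would disconnect
or erase thin vessels, so deletion is restricted to *simple points*: border
voxels whose removal provably changes neither the number of 26-connected
foreground components nor the number of 6-connected background components in
their 3x3x3 neighbourhood (Malandain & Bertrand characterization).  Voxels
with at most one foreground neighbour are line ends and are never deleted,
which keeps branch lengths intact.

Each peel round consists of six directional sub-iterations (+z, -z, +y, -y,
+x, -x).  Within a sub-iteration, candidate voxels (foreground with the
sub-iteration's face neighbour in the background) are visited in fixed
lexicographic order and deleted *sequentially*, re-checking simplicity on the
current image, so topology preservation holds exactly and the output is
deterministic.

Peel depth: after a round r completes, every surviving foreground voxel that
is 26-adjacent to a voxel deleted during round r is stamped with depth r.
Voxels never exposed to a deletion keep depth 0, so an already-thin line has
depth 0 everywhere, while the centerline of a tube of radius R voxels ends up
with depth ~R.  Mean depth times the voxel edge length is the thickness
marker.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["thin", "neighbor_counts"]


@njit(cache=True)
def _is_simple(img, x, y, z):
    """Simple-point test for foreground voxel (x,y,z) of a padded uint8 image.

    Condition A: the foreground voxels of the 26-neighbourhood (centre
    removed) form exactly one 26-connected component.
    Condition B: the background voxels of the 18-neighbourhood form exactly
    one 6-connected component that is 6-adjacent to the centre.
    """
    nb = np.zeros(27, np.uint8)
    p = 0
    for i in range(3):
        for j in range(3):
            for k in range(3):
                nb[p] = img[x - 1 + i, y - 1 + j, z - 1 + k]
                p += 1
    nb[13] = 0  # remove centre

    # --- condition A: 26-components of foreground in N26 ---
    lab = np.zeros(27, np.int8)
    stack = np.zeros(27, np.int8)
    ncomp_fg = 0
    for s in range(27):
        if nb[s] == 1 and lab[s] == 0:
            ncomp_fg += 1
            if ncomp_fg > 1:
                return False
            lab[s] = 1
            top = 0
            stack[top] = s
            top += 1
            while top > 0:
                top -= 1
                c = stack[top]
                ci = c // 9
                cj = (c // 3) % 3
                ck = c % 3
                for t in range(27):
                    if nb[t] == 1 and lab[t] == 0:
                        ti = t // 9
                        tj = (t // 3) % 3
                        tk = t % 3
                        di = ti - ci
                        dj = tj - cj
                        dk = tk - ck
                        if di >= -1 and di <= 1 and dj >= -1 and dj <= 1 and dk >= -1 and dk <= 1:
                            lab[t] = 1
                            stack[top] = t
                            top += 1
    if ncomp_fg != 1:
        return False

    # --- condition B: 6-components of background in N18, 6-adjacent to centre ---
    # N18 membership: |di|+|dj|+|dk| <= 2 with (di,dj,dk) offsets in {-1,0,1}
    lab2 = np.zeros(27, np.int8)
    ncomp_bg = 0
    for s in range(27):
        si = s // 9
        sj = (s // 3) % 3
        sk = s % 3
        man = abs(si - 1) + abs(sj - 1) + abs(sk - 1)
        if man == 0 or man > 2:
            continue
        if nb[s] != 0 or lab2[s] != 0:
            continue
        # flood this background component within N18 via 6-adjacency,
        # checking whether it touches a face neighbour of the centre
        touches_centre = False
        lab2[s] = 1
        top = 0
        stack[top] = s
        top += 1
        while top > 0:
            top -= 1
            c = stack[top]
            ci = c // 9
            cj = (c // 3) % 3
            ck = c % 3
            if abs(ci - 1) + abs(cj - 1) + abs(ck - 1) == 1:
                touches_centre = True
            for t in range(27):
                ti = t // 9
                tj = (t // 3) % 3
                tk = t % 3
                if abs(ti - 1) + abs(tj - 1) + abs(tk - 1) > 2:
                    continue
                if ti == 1 and tj == 1 and tk == 1:
                    continue
                if nb[t] == 0 and lab2[t] == 0:
                    if abs(ti - ci) + abs(tj - cj) + abs(tk - ck) == 1:
                        lab2[t] = 1
                        stack[top] = t
                        top += 1
        if touches_centre:
            ncomp_bg += 1
            if ncomp_bg > 1:
                return False
    return ncomp_bg == 1


@njit(cache=True)
def _count_fg_neighbors(img, x, y, z):
    n = 0
    for i in range(-1, 2):
        for j in range(-1, 2):
            for k in range(-1, 2):
                if i == 0 and j == 0 and k == 0:
                    continue
                if img[x + i, y + j, z + k] == 1:
                    n += 1
    return n


@njit(cache=True)
def _thin_padded(img):
    """Thin a zero-padded uint8 volume in place; return the peel-depth array."""
    nx, ny, nz = img.shape
    depth = np.zeros(img.shape, np.int32)
    deleted = np.zeros(img.shape, np.uint8)
    dxs = np.array([0, 0, 0, 0, 1, -1], np.int64)
    dys = np.array([0, 0, 1, -1, 0, 0], np.int64)
    dzs = np.array([1, -1, 0, 0, 0, 0], np.int64)
    snapshot = np.zeros(img.shape, np.uint8)
    rnd = 0
    while True:
        rnd += 1
        any_deleted = False
        deleted[:, :, :] = 0
        # Snapshot the image at round start: only voxels that are border
        # voxels *now* may be deleted this round, so each round peels exactly
        # one shell of the current object (the peel-depth semantics) no matter
        # how the sub-iterations cascade within the round.
        snapshot[:, :, :] = img
        for d in range(6):
            dx = dxs[d]
            dy = dys[d]
            dz = dzs[d]
            # Pass 1: collect this direction's border voxels from the snapshot.
            ncand = 0
            for x in range(1, nx - 1):
                for y in range(1, ny - 1):
                    for z in range(1, nz - 1):
                        if snapshot[x, y, z] == 1 and snapshot[x + dx, y + dy, z + dz] == 0:
                            ncand += 1
            if ncand == 0:
                continue
            cand = np.empty((ncand, 3), np.int64)
            c = 0
            for x in range(1, nx - 1):
                for y in range(1, ny - 1):
                    for z in range(1, nz - 1):
                        if snapshot[x, y, z] == 1 and snapshot[x + dx, y + dy, z + dz] == 0:
                            cand[c, 0] = x
                            cand[c, 1] = y
                            cand[c, 2] = z
                            c += 1
            # Pass 2: sequential deletion in lexicographic order with the
            # simple-point and line-end conditions re-checked on the current
            # image, so topology preservation is exact.
            for c in range(ncand):
                x = cand[c, 0]
                y = cand[c, 1]
                z = cand[c, 2]
                if img[x, y, z] != 1:
                    continue
                if _count_fg_neighbors(img, x, y, z) <= 1:
                    continue  # line end or isolated voxel
                if _is_simple(img, x, y, z):
                    img[x, y, z] = 0
                    deleted[x, y, z] = 1
                    any_deleted = True
        if not any_deleted:
            break
        for x in range(1, nx - 1):
            for y in range(1, ny - 1):
                for z in range(1, nz - 1):
                    if img[x, y, z] != 1:
                        continue
                    stamped = False
                    for i in range(-1, 2):
                        if stamped:
                            break
                        for j in range(-1, 2):
                            if stamped:
                                break
                            for k in range(-1, 2):
                                if deleted[x + i, y + j, z + k] == 1:
                                    depth[x, y, z] = rnd
                                    stamped = True
                                    break
    return depth


def thin(volume: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Skeletonize a 3D binary volume.

    Parameters
    ----------
    volume : 3D array interpretable as binary foreground.

    Returns
    -------
    skeleton : 3D bool array, the one-voxel-wide centerline set.
    peel_depth : 3D int32 array, peel round at which each surviving voxel was
        last exposed to a deletion (0 for voxels of already-thin structures).
    """
    vol = np.ascontiguousarray(volume.astype(np.uint8))
    if vol.ndim != 3:
        raise ValueError("thin expects a 3D volume")
    padded = np.pad(vol, 1)
    depth = _thin_padded(padded)
    core = slice(1, -1)
    return padded[core, core, core].astype(bool), depth[core, core, core]


def neighbor_counts(skeleton: np.ndarray) -> np.ndarray:
    """Number of 26-adjacent skeleton voxels for every voxel (0 off-skeleton)."""
    from scipy import ndimage

    sk = skeleton.astype(np.uint8)
    kernel = np.ones((3, 3, 3), np.uint8)
    counts = ndimage.convolve(sk, kernel, mode="constant", cval=0) - sk
    counts[sk == 0] = 0
    return counts
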