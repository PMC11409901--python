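"""Independent reference implementations used only as test oracles.

Everything here is deliberately written in the most literal, slowest style
possible — plain Python loops over explicit data structures — and shares no
code with the package implementation it checks.
"""

import itertools
import math

import numpy as np


def focal_transcription(coords, photon_count, voxel_size, minL, minC, maPC=0.0):
    """Literal transcription of the voxel-grid clustering steps.

    (1) bin each point into the voxel floor((coord - min) / voxel_size);
    (2) score each occupied voxel with the number of points in the voxel
        and its 26 neighbours;
    (3) core voxels: score >= minL;
    (4) candidate clusters: 26-connected components of core voxels;
    (5) gate (when maPC > 0): keep only voxels whose mean photon count is
        strictly above maPC; within each candidate, re-group survivors by
        26-connectivity and keep sub-groups that have >= minC voxels and a
        voxel whose score, recomputed over surviving voxels only, is
        >= minL.  When maPC == 0 this reduces to the plain minC check;
    (6) every point inside a kept voxel gets the cluster id, others -1.

    Returns per-point labels (cluster numbering arbitrary).
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n == 0:
        return np.empty(0, dtype=int)
    origin = coords.min(axis=0)

    voxel_of = {}
    for i in range(n):
        v = tuple(int(math.floor((coords[i][d] - origin[d]) / voxel_size))
                  for d in range(3))
        voxel_of.setdefault(v, []).append(i)

    neighbours = [d for d in itertools.product((-1, 0, 1), repeat=3)]

    def scores_over(vox_set):
        out = {}
        for v in vox_set:
            total = 0
            for d in neighbours:
                w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                if w in vox_set:
                    total += len(voxel_of[w])
            out[v] = total
        return out

    def components(vox_set):
        comps, todo = [], set(vox_set)
        while todo:
            seed = next(iter(todo))
            comp, stack = set(), [seed]
            while stack:
                v = stack.pop()
                if v in comp:
                    continue
                comp.add(v)
                for d in neighbours:
                    if d == (0, 0, 0):
                        continue
                    w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                    if w in todo and w not in comp:
                        stack.append(w)
            todo -= comp
            comps.append(comp)
        return comps

    all_scores = scores_over(set(voxel_of))
    core = {v for v in voxel_of if all_scores[v] >= minL}
    candidates = components(core)

    survivors_grid = set()
    for v, members in voxel_of.items():
        mean_pc = sum(photon_count[i] for i in members) / len(members)
        if mean_pc > maPC:
            survivors_grid.add(v)
    survivor_scores = scores_over(survivors_grid)

    kept = []
    for cand in candidates:
        surv = cand & survivors_grid
        for sub in components(surv):
            if len(sub) < minC:
                continue
            if max(survivor_scores[v] for v in sub) >= minL:
                kept.append(sub)

    labels = np.full(n, -1, dtype=int)
    for cid, comp in enumerate(kept):
        for v in comp:
            for i in voxel_of[v]:
                labels[i] = cid
    return labels


def mwu_pair_enumeration(a, b):
    """Exact two-sided Mann-Whitney p by enumerating group assignments.

    The U statistic is computed by direct pair counting (no ranks):
    U = sum over (x in A, y in B) of 1[x > y] + 0.5 * 1[x == y].
    """
    def u_stat(xs, ys):
        u = 0.0
        for x in xs:
            for y in ys:
                if x > y:
                    u += 1.0
                elif x == y:
                    u += 0.5
        return u

    pooled = list(a) + list(b)
    n_a = len(a)
    u_obs = u_stat(list(a), list(b))
    us = []
    for idx in itertools.combinations(range(len(pooled)), n_a):
        grp_a = [pooled[i] for i in idx]
        grp_b = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(u_stat(grp_a, grp_b))
    eps = 1e-9
    p_le = sum(u <= u_obs + eps for u in us) / len(us)
    p_ge = sum(u >= u_obs - eps for u in us) / len(us)
    return u_obs, min(1.0, 2.0 * min(p_le, p_ge))


def same_partition(labels_a, labels_b):
    """True when two labelings induce the same partition (up to renaming)."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        return False
    if not np.array_equal(labels_a == -1, labels_b == -1):
        return False
    fwd, bwd = {}, {}
    for la, lb in zip(labels_a, labels_b):
        if la == -1:
            continue
        if fwd.setdefault(la, lb) != lb or bwd.setdefault(lb, la) != la:
            return False
    return True
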