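"""Independent brute-force oracles for texture matrices and statistics.

Everything here is written as plain per-voxel / per-pair Python loops,
directly transcribing the defining formulas, so that the vectorized
implementations in the package can be checked against exhaustive
enumeration on small ROIs.
"""

import math

import numpy as np

NEIGHBORS_26 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]
OFFSETS_13 = [o for o in NEIGHBORS_26 if o > (0, 0, 0)]


def _in(shape, v):
    return all(0 <= c < s for c, s in zip(v, shape))


def oracle_glcm(levels, mask, n_levels):
    """Symmetric co-occurrence counts pooled over 13 offsets, normalized."""
    shape = mask.shape
    P = np.zeros((n_levels, n_levels))
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                if not mask[z, y, x]:
                    continue
                for off in OFFSETS_13:
                    w = (z + off[0], y + off[1], x + off[2])
                    if _in(shape, w) and mask[w]:
                        i = levels[z, y, x] - 1
                        j = levels[w] - 1
                        P[i, j] += 1
                        P[j, i] += 1
    t = P.sum()
    return P / t if t > 0 else P


def oracle_glrlm(levels, mask, n_levels):
    """Run-length counts pooled over the 13 directions."""
    shape = mask.shape
    runs = {}
    for off in OFFSETS_13:
        for z in range(shape[0]):
            for y in range(shape[1]):
                for x in range(shape[2]):
                    v = (z, y, x)
                    if not mask[v]:
                        continue
                    prev = (z - off[0], y - off[1], x - off[2])
                    if _in(shape, prev) and mask[prev] and levels[prev] == levels[v]:
                        continue  # not a run start
                    length = 1
                    cur = v
                    while True:
                        nxt = (cur[0] + off[0], cur[1] + off[1], cur[2] + off[2])
                        if _in(shape, nxt) and mask[nxt] and levels[nxt] == levels[v]:
                            length += 1
                            cur = nxt
                        else:
                            break
                    key = (levels[v], length)
                    runs[key] = runs.get(key, 0) + 1
    max_len = max((k[1] for k in runs), default=1)
    P = np.zeros((n_levels, max_len))
    for (g, r), c in runs.items():
        P[g - 1, r - 1] = c
    return P


def oracle_glszm(levels, mask, n_levels):
    """Zone counts via flood fill over 26-connected equal-level components."""
    shape = mask.shape
    seen = np.zeros(shape, dtype=bool)
    zones = {}
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                if not mask[z, y, x] or seen[z, y, x]:
                    continue
                g = levels[z, y, x]
                stack = [(z, y, x)]
                seen[z, y, x] = True
                size = 0
                while stack:
                    v = stack.pop()
                    size += 1
                    for off in NEIGHBORS_26:
                        w = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
                        if (_in(shape, w) and mask[w] and not seen[w]
                                and levels[w] == g):
                            seen[w] = True
                            stack.append(w)
                zones[(g, size)] = zones.get((g, size), 0) + 1
    max_size = max((k[1] for k in zones), default=1)
    P = np.zeros((n_levels, max_size))
    for (g, s), c in zones.items():
        P[g - 1, s - 1] = c
    return P


def oracle_gldm(levels, mask, n_levels):
    """Dependence counts: equal-level in-mask 26-neighbors per voxel."""
    shape = mask.shape
    deps = {}
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                if not mask[z, y, x]:
                    continue
                g = levels[z, y, x]
                d = 0
                for off in NEIGHBORS_26:
                    w = (z + off[0], y + off[1], x + off[2])
                    if _in(shape, w) and mask[w] and levels[w] == g:
                        d += 1
                deps[(g, d)] = deps.get((g, d), 0) + 1
    max_d = max((k[1] for k in deps), default=0)
    P = np.zeros((n_levels, max_d + 1))
    for (g, d), c in deps.items():
        P[g - 1, d] = c
    return P


def oracle_ngtdm(levels, mask, n_levels):
    """(n_i, p_i, s_i) per gray level via per-voxel neighbor enumeration."""
    shape = mask.shape
    n_i = np.zeros(n_levels)
    s_i = np.zeros(n_levels)
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                if not mask[z, y, x]:
                    continue
                g = levels[z, y, x]
                nb = []
                for off in NEIGHBORS_26:
                    w = (z + off[0], y + off[1], x + off[2])
                    if _in(shape, w) and mask[w]:
                        nb.append(levels[w])
                n_i[g - 1] += 1
                if nb:
                    s_i[g - 1] += abs(g - sum(nb) / len(nb))
    return n_i, n_i / n_i.sum(), s_i


def oracle_cooc_descriptors(P):
    """Loop transcription of the 13 co-occurrence descriptors + AVD."""
    n = P.shape[0]
    asm = contrast = idm = avd = entropy = 0.0
    mu_x = mu_y = 0.0
    px = [sum(P[i][j] for j in range(n)) for i in range(n)]
    py = [sum(P[i][j] for i in range(n)) for j in range(n)]
    for i in range(n):
        mu_x += (i + 1) * px[i]
        mu_y += (i + 1) * py[i]
    var_x = sum(px[i] * ((i + 1) - mu_x) ** 2 for i in range(n))
    var_y = sum(py[j] * ((j + 1) - mu_y) ** 2 for j in range(n))
    p_sum = {}
    p_diff = {}
    cross = 0.0
    for i in range(n):
        for j in range(n):
            p = P[i][j]
            asm += p * p
            contrast += p * (i - j) ** 2
            idm += p / (1.0 + (i - j) ** 2)
            avd += p * abs(i - j)
            cross += p * (i + 1) * (j + 1)
            if p > 0:
                entropy -= p * math.log2(p)
            p_sum[i + j + 2] = p_sum.get(i + j + 2, 0.0) + p
            p_diff[abs(i - j)] = p_diff.get(abs(i - j), 0.0) + p
    corr = (cross - mu_x * mu_y) / math.sqrt(var_x * var_y) if var_x * var_y > 0 else 0.0
    sum_avg = sum(k * v for k, v in p_sum.items())
    sum_var = sum(v * (k - sum_avg) ** 2 for k, v in p_sum.items())
    sum_ent = -sum(v * math.log2(v) for v in p_sum.values() if v > 0)
    diff_avg = sum(k * v for k, v in p_diff.items())
    diff_var = sum(v * (k - diff_avg) ** 2 for k, v in p_diff.items())
    diff_ent = -sum(v * math.log2(v) for v in p_diff.values() if v > 0)
    hx = -sum(v * math.log2(v) for v in px if v > 0)
    hy = -sum(v * math.log2(v) for v in py if v > 0)
    hxy1 = 0.0
    hxy2 = 0.0
    for i in range(n):
        for j in range(n):
            q = px[i] * py[j]
            if q > 0:
                hxy2 -= q * math.log2(q)
                if P[i][j] > 0:
                    hxy1 -= P[i][j] * math.log2(q)
    imc1 = (entropy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - entropy))))
    variance = sum(
        P[i][j] * ((i + 1) - mu_x) ** 2 for i in range(n) for j in range(n))
    return {
        "asm": asm, "contrast": contrast, "correlation": corr,
        "variance": variance, "idm": idm, "sum_average": sum_avg,
        "sum_variance": sum_var, "sum_entropy": sum_ent, "entropy": entropy,
        "difference_variance": diff_var, "difference_entropy": diff_ent,
        "imc1": imc1, "imc2": imc2, "avd": avd,
    }


def oracle_bh(pvals):
    """Step-up FDR adjustment straight from the definition."""
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        q = min(1.0, m * p[i] / rank)
        running_min = min(running_min, q)
        adj[i] = running_min
    return adj


def oracle_auc(scores, labels):
    """Mann-Whitney pair-count AUC with half credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def oracle_hotspot(pe_map, mask):
    """Exhaustive 3x3x3 neighborhood-mean scan."""
    shape = mask.shape
    best = -math.inf
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                if not mask[z, y, x]:
                    continue
                vals = []
                for dz in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            w = (z + dz, y + dy, x + dx)
                            if _in(shape, w) and mask[w]:
                                vals.append(pe_map[w])
                best = max(best, sum(vals) / len(vals))
    return best


def random_roi(rng, max_side=6, n_levels=5):
    """Random small level volume + mask for oracle comparisons."""
    shape = tuple(rng.integers(3, max_side + 1, size=3))
    mask = rng.random(shape) < 0.7
    if not mask.any():
        mask[tuple(s // 2 for s in shape)] = True
    levels = np.zeros(shape, dtype=np.int64)
    levels[mask] = rng.integers(1, n_levels + 1, size=int(mask.sum()))
    return levels, mask
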