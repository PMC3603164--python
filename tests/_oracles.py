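"""Independent nested-loop reference implementations used as test oracles.

Everything here is deliberately written with plain Python loops (and a
little math) so it shares no code path with the package.  Intended only for
tiny images.
"""

import math


def similarity_map_bf(ch, n, eps):
    """Brute-force similarity index with replicate padding."""
    h, w = len(ch), len(ch[0])
    r = n // 2
    out = [[0] * w for _ in range(h)]
    for x in range(h):
        for y in range(w):
            center = int(ch[x][y])
            count = 0
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    i = min(max(x + di, 0), h - 1)
                    j = min(max(y + dj, 0), w - 1)
                    if abs(int(ch[i][j]) - center) <= eps:
                        count += 1
            out[x][y] = count
    return out


def cclsc_table_bf(ch, g, n):
    """Product-of-marginals normalized table as a 256 x N^2 list of lists."""
    h, w = len(ch), len(ch[0])
    total = h * w
    pk = [0] * 256
    qm = [0] * (n * n)
    for x in range(h):
        for y in range(w):
            pk[int(ch[x][y])] += 1
            qm[int(g[x][y]) - 1] += 1
    return [[(pk[k] / total) * (qm[m] / total) for m in range(n * n)] for k in range(256)]


def probs_bf(table, t):
    p_o = sum(sum(row) for row in table[: t + 1])
    p_b = sum(sum(row) for row in table[t + 1 :])
    return p_o, p_b


def weight_bf(m, n):
    return 5.0 * math.exp(-((m - (n * n) / 2.0) ** 2) / 32.0)


def entropy_bf(table, t, region, n):
    """Weighted region entropy; returns None if the region is empty."""
    rows = range(0, t + 1) if region == "object" else range(t + 1, 256)
    p = sum(table[k][m] for k in rows for m in range(n * n))
    if p <= 0.0:
        return None
    total = 0.0
    for k in rows:
        for m in range(n * n):
            v = table[k][m]
            if v > 0.0:
                q = v / p
                total -= q * math.log(q) * weight_bf(m + 1, n)
    return total


def phi_scan_bf(ch, n, eps):
    """Full independent threshold scan; returns (T, phi dict over admissible t)."""
    g = similarity_map_bf(ch, n, eps)
    table = cclsc_table_bf(ch, g, n)
    # Pixel counts decide admissibility (both partitions non-empty).
    counts = [0] * 256
    for row in ch:
        for v in row:
            counts[int(v)] += 1
    nonzero = [k for k in range(256) if counts[k] > 0]
    phi = {}
    best_t, best_phi = None, None
    for t in range(255):
        below = sum(counts[k] for k in nonzero if k <= t)
        if below == 0 or below == sum(counts):
            continue
        h_o = entropy_bf(table, t, "object", n)
        h_b = entropy_bf(table, t, "background", n)
        phi[t] = h_o + h_b
        if best_phi is None or phi[t] > best_phi:
            best_phi, best_t = phi[t], t
    return best_t, phi, g, table


def flood_fill_holes_bf(mask, connectivity=4):
    """Fill-holes via breadth-first flood fill of background from the border."""
    h, w = len(mask), len(mask[0])
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
    outside = [[False] * w for _ in range(h)]
    queue = []
    for x in range(h):
        for y in range(w):
            if (x in (0, h - 1) or y in (0, w - 1)) and mask[x][y] == 0:
                outside[x][y] = True
                queue.append((x, y))
    while queue:
        x, y = queue.pop()
        for di, dj in steps:
            i, j = x + di, y + dj
            if 0 <= i < h and 0 <= j < w and mask[i][j] == 0 and not outside[i][j]:
                outside[i][j] = True
                queue.append((i, j))
    return [[0 if (mask[x][y] == 0 and outside[x][y]) else 1 for y in range(w)] for x in range(h)]


def count_components_bf(mask, connectivity=8):
    """Flood-fill connected-component count."""
    h, w = len(mask), len(mask[0])
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
    seen = [[False] * w for _ in range(h)]
    count = 0
    for x in range(h):
        for y in range(w):
            if mask[x][y] and not seen[x][y]:
                count += 1
                stack = [(x, y)]
                seen[x][y] = True
                while stack:
                    cx, cy = stack.pop()
                    for di, dj in steps:
                        i, j = cx + di, cy + dj
                        if 0 <= i < h and 0 <= j < w and mask[i][j] and not seen[i][j]:
                            seen[i][j] = True
                            stack.append((i, j))
    return count


def otsu_bf(values):
    """Brute-force Otsu scan over the 256-bin histogram, smallest argmax."""
    counts = [0] * 256
    for v in values:
        counts[int(v)] += 1
    total = sum(counts)
    best_t, best_var = None, -1.0
    for t in range(255):
        w0 = sum(counts[: t + 1])
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = sum(k * counts[k] for k in range(t + 1)) / w0
        mu1 = sum(k * counts[k] for k in range(t + 1, 256)) / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var + 1e-12:
            best_var, best_t = var, t
    return best_t
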