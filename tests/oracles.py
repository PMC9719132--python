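"""Naive, loop-based reference implementations used as independent oracles.

Everything here is deliberately written with explicit Python loops and
first-principles formulas, separate from the vectorized production code path,
so that agreement on small rasters is meaningful evidence of correctness.
"""

from __future__ import annotations

import math

import numpy as np

# ---------------------------------------------------------------- GLCM

OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def glcm_matrix_naive(gray, mask, levels, angle):
    """Symmetric normalized co-occurrence matrix by exhaustive pair enumeration."""
    dr, dc = OFFSETS[angle]
    h, w = gray.shape
    counts = np.zeros((levels, levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                counts[gray[r, c], gray[r2, c2]] += 1
                counts[gray[r2, c2], gray[r, c]] += 1
    total = counts.sum()
    return counts / total if total > 0 else counts


def haralick_naive(p):
    """The 14 Haralick statistics by explicit loops (natural log)."""
    levels = p.shape[0]
    px = [sum(p[i][j] for j in range(levels)) for i in range(levels)]
    py = [sum(p[i][j] for i in range(levels)) for j in range(levels)]
    mu_x = sum(i * px[i] for i in range(levels))
    mu_y = sum(j * py[j] for j in range(levels))
    sd_x = math.sqrt(sum((i - mu_x) ** 2 * px[i] for i in range(levels)))
    sd_y = math.sqrt(sum((j - mu_y) ** 2 * py[j] for j in range(levels)))
    p_sum = [0.0] * (2 * levels - 1)
    p_diff = [0.0] * levels
    for i in range(levels):
        for j in range(levels):
            p_sum[i + j] += p[i][j]
            p_diff[abs(i - j)] += p[i][j]

    def ent(seq):
        return -sum(v * math.log(v) for v in seq if v > 0)

    out = {}
    out["asm"] = sum(p[i][j] ** 2 for i in range(levels) for j in range(levels))
    out["contrast"] = sum(
        (i - j) ** 2 * p[i][j] for i in range(levels) for j in range(levels)
    )
    if sd_x * sd_y > 1e-12:
        out["correlation"] = (
            sum(i * j * p[i][j] for i in range(levels) for j in range(levels)) - mu_x * mu_y
        ) / (sd_x * sd_y)
    else:
        out["correlation"] = 1.0
    out["variance"] = sum(
        (i - mu_x) ** 2 * p[i][j] for i in range(levels) for j in range(levels)
    )
    out["idm"] = sum(
        p[i][j] / (1 + (i - j) ** 2) for i in range(levels) for j in range(levels)
    )
    sum_avg = sum(k * p_sum[k] for k in range(len(p_sum)))
    out["sum_average"] = sum_avg
    out["sum_variance"] = sum((k - sum_avg) ** 2 * p_sum[k] for k in range(len(p_sum)))
    out["sum_entropy"] = ent(p_sum)
    hxy = ent([p[i][j] for i in range(levels) for j in range(levels)])
    out["entropy"] = hxy
    diff_avg = sum(k * p_diff[k] for k in range(levels))
    out["difference_variance"] = sum((k - diff_avg) ** 2 * p_diff[k] for k in range(levels))
    out["difference_entropy"] = ent(p_diff)
    hxy1 = -sum(
        p[i][j] * math.log(px[i] * py[j])
        for i in range(levels)
        for j in range(levels)
        if px[i] * py[j] > 0 and p[i][j] > 0
    )
    # include p==0 terms where the product is positive (0 * log -> 0 either way)
    hxy2 = -sum(
        px[i] * py[j] * math.log(px[i] * py[j])
        for i in range(levels)
        for j in range(levels)
        if px[i] * py[j] > 0
    )
    hx, hy = ent(px), ent(py)
    denom = max(hx, hy)
    out["imc1"] = (hxy - hxy1) / denom if denom > 1e-12 else 0.0
    out["imc2"] = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))
    active = [i for i in range(levels) if px[i] > 0]
    if len(active) < 2:
        out["mcc"] = 1.0
    else:
        q = np.zeros((len(active), len(active)))
        for a, i in enumerate(active):
            for b, j in enumerate(active):
                q[a, b] = sum(
                    p[i][k] * p[j][k] / (px[i] * py[k]) for k in active if py[k] > 0
                )
        eig = sorted(np.real(np.linalg.eigvals(q)))
        out["mcc"] = math.sqrt(max(0.0, eig[-2]))
    return out


# ---------------------------------------------------------------- NGTDM


def ngtdm_naive(gray, mask, levels):
    """(s, p, n) of the neighbourhood gray-tone difference matrix, by loops."""
    h, w = gray.shape
    s = [0.0] * levels
    counts = [0] * levels
    n_valid = 0
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            neigh = []
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    r2, c2 = r + dr, c + dc
                    if 0 <= r2 < h and 0 <= c2 < w and mask[r2, c2]:
                        neigh.append(float(gray[r2, c2]))
            if not neigh:
                continue
            n_valid += 1
            lv = int(gray[r, c])
            s[lv] += abs(float(gray[r, c]) - sum(neigh) / len(neigh))
            counts[lv] += 1
    p = [cnt / n_valid for cnt in counts]
    return s, p, n_valid


def ngtdm_features_naive(gray, mask, levels, cap=1e6):
    s, p, n = ngtdm_naive(gray, mask, levels)
    present = [i for i in range(levels) if p[i] > 0]
    ngp = len(present)
    intens = [i + 1 for i in range(levels)]  # 1-based
    psum = sum(p[i] * s[i] for i in range(levels))
    coarseness = min(1.0 / psum, cap) if psum > 1e-12 else cap
    if ngp < 2:
        contrast = 0.0
    else:
        acc = sum(
            p[i] * p[j] * (intens[i] - intens[j]) ** 2
            for i in range(levels)
            for j in range(levels)
        )
        contrast = acc / (ngp * (ngp - 1)) * (sum(s) / n)
    busy_den = sum(
        abs(intens[i] * p[i] - intens[j] * p[j]) for i in present for j in present
    )
    busyness = psum / busy_den if busy_den > 1e-12 else 0.0
    complexity = sum(
        abs(intens[i] - intens[j]) * (p[i] * s[i] + p[j] * s[j]) / (n * (p[i] + p[j]))
        for i in present
        for j in present
    )
    s_total = sum(s)
    strength = (
        sum((p[i] + p[j]) * (intens[i] - intens[j]) ** 2 for i in present for j in present)
        / s_total
        if s_total > 1e-12
        else 0.0
    )
    return {
        "ngtdm_coarseness": coarseness,
        "ngtdm_contrast": contrast,
        "ngtdm_busyness": busyness,
        "ngtdm_complexity": complexity,
        "ngtdm_strength": strength,
    }


# ---------------------------------------------------------------- GLSZM


def glszm_zones_naive(gray, mask, levels):
    """List of (level, zone size) by explicit 8-connected flood fill."""
    h, w = gray.shape
    seen = np.zeros((h, w), dtype=bool)
    zones = []
    for r in range(h):
        for c in range(w):
            if not mask[r, c] or seen[r, c]:
                continue
            level = int(gray[r, c])
            stack = [(r, c)]
            seen[r, c] = True
            size = 0
            while stack:
                cr, cc = stack.pop()
                size += 1
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        r2, c2 = cr + dr, cc + dc
                        if (
                            0 <= r2 < h
                            and 0 <= c2 < w
                            and mask[r2, c2]
                            and not seen[r2, c2]
                            and int(gray[r2, c2]) == level
                        ):
                            seen[r2, c2] = True
                            stack.append((r2, c2))
            zones.append((level, size))
    return zones


def glszm_matrix_naive(gray, mask, levels):
    n_px = int(np.asarray(mask, dtype=bool).sum())
    p = np.zeros((levels, n_px))
    for level, size in glszm_zones_naive(gray, mask, levels):
        p[level, size - 1] += 1
    return p


# ------------------------------------------------------------------ LBP


def lbp_uniform_code_naive(gray, r, c):
    """Uniform LBP code (P=8, R=1) of one interior pixel, with the circular
    bilinear sampling used by the standard operator."""
    g = np.asarray(gray, dtype=float)
    center = g[r, c]
    bits = []
    for k in range(8):
        theta = 2 * math.pi * k / 8
        rr, cc = r - math.sin(theta), c + math.cos(theta)
        r0, c0 = int(math.floor(rr)), int(math.floor(cc))
        fr, fc = rr - r0, cc - c0
        r1 = min(r0 + 1, g.shape[0] - 1)  # zero-weight corner when fr or fc is 0
        c1 = min(c0 + 1, g.shape[1] - 1)
        val = (
            g[r0, c0] * (1 - fr) * (1 - fc)
            + g[r0, c1] * (1 - fr) * fc
            + g[r1, c0] * fr * (1 - fc)
            + g[r1, c1] * fr * fc
        )
        # the standard operator thresholds tiny interpolation noise away
        if abs(val - center) < 1e-9:
            val = center
        bits.append(1 if val >= center else 0)
    transitions = sum(bits[k] != bits[(k + 1) % 8] for k in range(8))
    return sum(bits) if transitions <= 2 else 9


# ----------------------------------------------------- model-level oracles


def precision_at_recall_naive(scores, labels, min_recall):
    """Exhaustive sweep over every distinct-score threshold plus -inf."""
    scores = list(map(float, scores))
    labels = list(map(int, labels))
    n_pos = sum(labels)
    best = None
    for t in sorted(set(scores)) + [-math.inf]:
        tp = sum(1 for s, y in zip(scores, labels) if s >= t and y == 1)
        np_pred = sum(1 for s in scores if s >= t)
        if np_pred == 0 or tp / n_pos < min_recall:
            continue
        prec = tp / np_pred
        if best is None or prec > best:
            best = prec
    return 0.0 if best is None else best


def auc_mann_whitney(scores, labels):
    """AUC as the normalized Mann-Whitney U statistic (ties count 1/2)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def pearson_naive(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den
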