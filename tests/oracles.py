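"""Independent brute-force oracles for the texture features.

Deliberately naive: explicit Python loops over pixels, pairs, runs and
matrix cells, sharing no code with the implementation under test.
"""

from __future__ import annotations

import math

import numpy as np


def glcm_brute(img: np.ndarray, distance: int, angle_deg: int, levels: int) -> np.ndarray:
    """Normalised non-symmetric co-occurrence matrix by pair enumeration."""
    rad = math.radians(angle_deg)
    dr = int(round(math.sin(rad) * distance))
    dc = int(round(math.cos(rad) * distance))
    rows, cols = img.shape
    p = np.zeros((levels, levels), dtype=np.float64)
    for r in range(rows):
        for c in range(cols):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < rows and 0 <= c2 < cols:
                p[img[r, c], img[r2, c2]] += 1.0
    total = p.sum()
    return p / total if total else p


def glcm_features_brute(p: np.ndarray) -> dict[str, float]:
    """All ten GLCM statistics by explicit double loops."""
    n = p.shape[0]
    mu_i = sum(i * p[i, j] for i in range(n) for j in range(n))
    mu_j = sum(j * p[i, j] for i in range(n) for j in range(n))
    var_i = sum((i - mu_i) ** 2 * p[i, j] for i in range(n) for j in range(n))
    var_j = sum((j - mu_j) ** 2 * p[i, j] for i in range(n) for j in range(n))
    si, sj = math.sqrt(var_i), math.sqrt(var_j)

    contrast = sum((i - j) ** 2 * p[i, j] for i in range(n) for j in range(n))
    dissimilarity = sum(abs(i - j) * p[i, j] for i in range(n) for j in range(n))
    homogeneity = sum(p[i, j] / (1 + (i - j) ** 2) for i in range(n) for j in range(n))
    asm = sum(p[i, j] ** 2 for i in range(n) for j in range(n))
    entropy = -sum(
        p[i, j] * math.log(p[i, j])
        for i in range(n)
        for j in range(n)
        if p[i, j] > 0
    )
    if si * sj == 0:
        correlation = 1.0
    else:
        correlation = sum(
            (i - mu_i) * (j - mu_j) * p[i, j] for i in range(n) for j in range(n)
        ) / (si * sj)
    shade = sum(
        (i + j - mu_i - mu_j) ** 3 * p[i, j] for i in range(n) for j in range(n)
    )
    prominence = sum(
        (i + j - mu_i - mu_j) ** 4 * p[i, j] for i in range(n) for j in range(n)
    )
    return {
        "correlation": correlation,
        "dissimilarity": dissimilarity,
        "contrast": contrast,
        "homogeneity": homogeneity,
        "asm": asm,
        "energy": math.sqrt(asm),
        "max_probability": float(p.max()),
        "entropy": entropy,
        "cluster_shade": shade,
        "cluster_prominence": prominence,
    }


def _runs(seq: list[int]) -> list[tuple[int, int]]:
    """Maximal (value, length) runs of a sequence, by walking it."""
    out: list[tuple[int, int]] = []
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        out.append((seq[i], j - i))
        i = j
    return out


def glrlm_brute(img: np.ndarray, angle_deg: int, levels: int) -> np.ndarray:
    """Run-length matrix by naive line traversal and run walking."""
    rows, cols = img.shape
    q = [[(int(img[r, c]) * levels) // 256 for c in range(cols)] for r in range(rows)]
    lines: list[list[int]] = []
    if angle_deg == 0:
        lines = [list(row) for row in q]
    elif angle_deg == 180:
        lines = [list(reversed(row)) for row in q]
    elif angle_deg == 90:
        lines = [[q[r][c] for r in range(rows)] for c in range(cols)]
    elif angle_deg == 45:  # up-right: start on left column and bottom row
        starts = [(r, 0) for r in range(rows)] + [(rows - 1, c) for c in range(1, cols)]
        for r0, c0 in starts:
            line, r, c = [], r0, c0
            while r >= 0 and c < cols:
                line.append(q[r][c])
                r, c = r - 1, c + 1
            lines.append(line)
    elif angle_deg == 135:  # up-left: start on right column and bottom row
        starts = [(r, cols - 1) for r in range(rows)] + [
            (rows - 1, c) for c in range(cols - 1)
        ]
        for r0, c0 in starts:
            line, r, c = [], r0, c0
            while r >= 0 and c >= 0:
                line.append(q[r][c])
                r, c = r - 1, c - 1
            lines.append(line)
    else:
        raise ValueError(angle_deg)

    max_len = max(rows, cols)
    m = np.zeros((levels, max_len), dtype=np.int64)
    for line in lines:
        for value, length in _runs(line):
            m[value, length - 1] += 1
    return m


def glrlm_stats_brute(m: np.ndarray, n_pixels: int) -> dict[str, float]:
    n_runs = int(m.sum())
    sre = lre = 0.0
    for g in range(m.shape[0]):
        for l1, count in enumerate(m[g], start=1):
            sre += count / l1**2
            lre += count * l1**2
    glu = sum(int(m[g].sum()) ** 2 for g in range(m.shape[0])) / n_runs
    rlu = sum(int(m[:, l].sum()) ** 2 for l in range(m.shape[1])) / n_runs
    return {
        "sre": sre / n_runs,
        "lre": lre / n_runs,
        "glu": glu,
        "rlu": rlu,
        "rpc": n_runs / n_pixels,
    }
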