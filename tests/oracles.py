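"""Independent brute-force oracles used to validate the vectorized statistics.

Everything here is deliberately naive — per-haplotype Python loops, explicit
set arithmetic — and shares no code with the package implementations.
"""

import math


def safe_oracle(X):
    """Per-site (f, k, phi, safe) by direct enumeration of the definitions."""
    n = len(X)
    m = len(X[0]) if n else 0
    counts = [sum(int(X[h][j]) for h in range(n)) for j in range(m)]
    haf = [sum(counts[j] for j in range(m) if X[h][j]) for h in range(n)]
    total_haf = sum(haf)
    n_distinct = len(set(haf))
    out = []
    for e in range(m):
        carriers = [h for h in range(n) if X[h][e]]
        f = counts[e] / n
        k = len({haf[h] for h in carriers}) / n_distinct
        phi = sum(haf[h] for h in carriers) / total_haf
        safe = (phi - k) / math.sqrt(f * (1.0 - f))
        out.append((f, k, phi, safe))
    return out


def ehh_oracle(X, positions, core, allele, direction, cutoff=0.05, max_gap=200_000):
    """EHH curve by explicit pairwise haplotype-identity counting.

    Returns (marker_indices, ehh_values) including the core point, mirroring
    the truncation rules: keep the first sub-cutoff point, stop at gaps larger
    than ``max_gap``, never extrapolate.
    """
    n = len(X)
    m = len(X[0])
    carriers = [h for h in range(n) if X[h][core] == allele]
    nc = len(carriers)
    if nc < 2:
        raise ValueError("fewer than 2 carriers")
    npairs = nc * (nc - 1) // 2
    idx, vals = [core], [1.0]
    scan = range(core + 1, m) if direction == "up" else range(core - 1, -1, -1)
    prev = core
    for j in scan:
        if abs(positions[j] - positions[prev]) > max_gap:
            break
        lo, hi = min(core, j), max(core, j)
        identical = 0
        for a in range(nc):
            for b in range(a + 1, nc):
                ha, hb = carriers[a], carriers[b]
                if all(X[ha][t] == X[hb][t] for t in range(lo, hi + 1)):
                    identical += 1
        e = identical / npairs
        idx.append(j)
        vals.append(e)
        if e < cutoff:
            break
        prev = j
    return idx, vals


def ihh_oracle(X, positions, core, allele, map_rate=1.0, cutoff=0.05, max_gap=200_000):
    """Trapezoidal integral of both directional EHH curves, in cM."""
    total = 0.0
    for direction in ("down", "up"):
        idx, vals = ehh_oracle(X, positions, core, allele, direction, cutoff, max_gap)
        for t in range(1, len(idx)):
            gap_cm = abs(positions[idx[t]] - positions[idx[t - 1]]) / 1e6 * map_rate
            total += 0.5 * (vals[t] + vals[t - 1]) * gap_cm
    return total
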