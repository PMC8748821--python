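"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written the slow, obvious way and shares no
code with the package.
"""

from __future__ import annotations

import numpy as np


def dfs_walk_counts(adjacency: np.ndarray, seeds, max_step: int) -> np.ndarray:
    """Count walks from any seed by exhaustive depth-first enumeration."""
    a = np.asarray(adjacency)
    r = a.shape[0]
    counts = np.zeros((max_step, r), dtype=object)
    neighbours = [np.flatnonzero(a[i]).tolist() for i in range(r)]

    def walk(node: int, depth: int) -> None:
        if depth == max_step:
            return
        for nxt in neighbours[node]:
            counts[depth, nxt] += 1
            walk(nxt, depth + 1)

    for s in seeds:
        walk(int(s), 0)
    return counts


def naive_partial_correlation(timeseries: np.ndarray) -> np.ndarray:
    """Textbook precision-based partial correlation, no regularisation."""
    x = np.asarray(timeseries, dtype=float)
    z = (x - x.mean(0)) / x.std(0)
    s = z.T @ z / z.shape[0]
    p = np.linalg.inv(s)
    r = x.shape[1]
    out = np.zeros((r, r))
    for i in range(r):
        for j in range(r):
            if i != j:
                out[i, j] = -p[i, j] / np.sqrt(p[i, i] * p[j, j])
    return out


def welch_t(a: np.ndarray, b: np.ndarray) -> float:
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    return float((a.mean() - b.mean()) / np.sqrt(va + vb))


def pooled_t(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    return float((a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb)))


def groupby_mean(values: np.ndarray, labels: list[str]) -> dict[str, float]:
    out: dict[str, list[float]] = {}
    for v, lab in zip(values, labels):
        out.setdefault(lab, []).append(float(v))
    return {k: float(np.mean(v)) for k, v in out.items()}
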