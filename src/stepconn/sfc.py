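"""Stepwise functional connectivity on the thresholded, binarised graph.

The connectivity matrix is thresholded at a retention percentile (95 by
default, keeping the top 5% strongest edges) and binarised. Seeding from a
region set, the step-k connectivity of a target region is the number of
length-k walks from any seed to that region,

    counts_k[j] = sum_{s in seeds} (A^k)_{s j},

computed by iterated integer matrix multiplication (revisits are allowed;
this is the standard walk-count definition of stepwise connectivity --
counting simple paths is NP-hard and deliberately not attempted). Each step's
count vector is z-normalised across regions, and regions whose degree exceeds
1.5x the mean are reported as hubs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectivity import ConnectivityMatrix
from .errors import DegenerateGraphError, InputError

#: int64 walk counts above this bound trigger a switch to arbitrary precision
_OVERFLOW_GUARD = np.int64(2) ** 53


@dataclass(frozen=True)
class BinaryGraph:
    adjacency: np.ndarray
    threshold_percentile: float
    cutoff: float = float("nan")

    @property
    def n_regions(self) -> int:
        return self.adjacency.shape[0]

    @property
    def density(self) -> float:
        r = self.n_regions
        return float(self.adjacency.sum()) / (r * (r - 1))


def threshold_binarize(
    fc: ConnectivityMatrix | np.ndarray,
    percentile: float = 95.0,
    edge_rank: str = "signed",
) -> BinaryGraph:
    """Binarise a connectivity matrix, keeping edges above a weight percentile.

    The cutoff is the given percentile of the upper-triangle edge weights.
    ``edge_rank="signed"`` (default) ranks raw weights so only the most
    positive edges survive; ``"absolute"`` ranks |w|, letting strong negative
    edges count as connections.
    """
    if not 0 <= percentile < 100:
        raise InputError(f"percentile must lie in [0, 100), got {percentile}")
    w = fc.values if isinstance(fc, ConnectivityMatrix) else np.asarray(fc, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise InputError("connectivity must be a square matrix")
    if edge_rank == "absolute":
        w = np.abs(w)
    elif edge_rank != "signed":
        raise InputError(f"unknown edge_rank {edge_rank!r}")
    iu = np.triu_indices(w.shape[0], k=1)
    edges = w[iu]
    if edges.size == 0 or np.ptp(edges) == 0:
        raise DegenerateGraphError("all edge weights are equal; the top fraction is undefined")
    cutoff = float(np.percentile(edges, percentile))
    adj = (w > cutoff).astype(np.int64)
    adj = adj | adj.T
    np.fill_diagonal(adj, 0)
    return BinaryGraph(adjacency=adj, threshold_percentile=float(percentile), cutoff=cutoff)


def _seed_indicator(graph_size: int, seeds) -> np.ndarray:
    idx = getattr(seeds, "indices", None)
    idx = np.asarray(idx if idx is not None else seeds, dtype=int)
    if idx.size == 0:
        raise InputError("seed set is empty")
    if idx.min() < 0 or idx.max() >= graph_size:
        raise InputError(f"seed indices out of range for {graph_size} regions")
    ind = np.zeros(graph_size, dtype=np.int64)
    ind[idx] = 1
    return ind


def sfc_walk_counts(graph: BinaryGraph | np.ndarray, seeds, max_step: int = 5) -> np.ndarray:
    """Walk counts from the seed set to every region at steps 1..max_step.

    Returns a (max_step, R) integer array; row k-1 holds the number of
    length-k walks from any seed. Uses the recursion counts_{k+1} = A counts_k
    starting from the seed indicator; switches to Python integers if counts
    approach the int64 range.
    """
    if max_step < 1:
        raise InputError("max_step must be >= 1")
    a = graph.adjacency if isinstance(graph, BinaryGraph) else np.asarray(graph)
    a = a.astype(np.int64)
    r = a.shape[0]
    counts: np.ndarray = np.zeros((max_step, r), dtype=np.int64)
    # float64 matmul is exact below 2**53 and BLAS-fast; beyond the guard we
    # switch to Python integers for exactness
    a_f = a.astype(np.float64)
    max_deg = max(int(a.sum(axis=1).max(initial=0)), 1)
    v: np.ndarray = _seed_indicator(r, seeds).astype(np.float64)
    exact = False
    for k in range(max_step):
        if not exact and float(v.max()) * max_deg > float(_OVERFLOW_GUARD):
            a = a.astype(object)
            v = v.astype(np.int64).astype(object)
            counts = counts.astype(object)
            exact = True
        if exact:
            v = a @ v
            counts[k] = v
        else:
            v = a_f @ v
            counts[k] = v.astype(np.int64)
    return counts


def z_normalize_steps(raw_counts: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Z-score each step's counts across regions (population sd convention).

    Steps with zero variance cannot be normalised; they are returned as
    all-zero rows and their (1-based) step numbers are flagged.
    """
    raw = np.asarray(raw_counts, dtype=float)
    if raw.ndim != 2:
        raise InputError("raw_counts must be steps x R")
    mu = raw.mean(axis=1, keepdims=True)
    sd = raw.std(axis=1, keepdims=True)  # population (1/N) convention
    degenerate = [k + 1 for k in range(raw.shape[0]) if sd[k, 0] == 0]
    sd_safe = np.where(sd == 0, 1.0, sd)
    z = (raw - mu) / sd_safe
    for k in degenerate:
        z[k - 1] = 0.0
    return z, degenerate


def detect_hubs(step_degrees: np.ndarray, multiplier: float = 1.5) -> np.ndarray:
    """Regions whose degree exceeds ``multiplier`` times the mean degree.

    Degrees must be non-negative (raw walk counts, or z-scores shifted by
    their minimum): the rule is degenerate on signed zero-mean values.
    """
    d = np.asarray(step_degrees, dtype=float)
    if d.ndim != 1:
        raise InputError("step_degrees must be a 1-d vector")
    if np.any(d < 0):
        raise InputError("hub detection requires non-negative degrees; min-shift z-scores first")
    return np.flatnonzero(d > multiplier * d.mean())


@dataclass(frozen=True)
class SFCResult:
    """Per-subject stepwise connectivity profile."""

    raw_counts: np.ndarray
    z_counts: np.ndarray
    degenerate_steps: tuple[int, ...]
    subject_id: str = ""

    @property
    def max_step(self) -> int:
        return self.raw_counts.shape[0]

    @property
    def step_degrees(self) -> np.ndarray:
        """Alias: the z-normalised counts are the per-step degree profile."""
        return self.z_counts

    def hubs(self, step: int, multiplier: float = 1.5, basis: str = "shifted_z") -> np.ndarray:
        """Hub regions at a (1-based) step.

        ``basis="shifted_z"`` applies the rule to min-shifted z-degrees (the
        1.5x-mean rule is ill-posed on zero-mean values); ``"raw"`` uses the
        raw walk counts.
        """
        if not 1 <= step <= self.max_step:
            raise InputError(f"step must lie in 1..{self.max_step}")
        if basis == "shifted_z":
            d = self.z_counts[step - 1]
            d = d - d.min()
        elif basis == "raw":
            d = self.raw_counts[step - 1].astype(float)
        else:
            raise InputError(f"unknown hub basis {basis!r}")
        return detect_hubs(d, multiplier)


def run_sfc_subject(
    fc: ConnectivityMatrix | np.ndarray,
    seeds,
    percentile: float = 95.0,
    max_step: int = 5,
    edge_rank: str = "signed",
    subject_id: str = "",
) -> SFCResult:
    graph = threshold_binarize(fc, percentile=percentile, edge_rank=edge_rank)
    raw = sfc_walk_counts(graph, seeds, max_step=max_step)
    z, degenerate = z_normalize_steps(raw)
    return SFCResult(
        raw_counts=raw, z_counts=z, degenerate_steps=tuple(degenerate), subject_id=subject_id
    )


def run_sfc_cohort(
    matrices: dict[str, ConnectivityMatrix | np.ndarray],
    seeds,
    percentile: float = 95.0,
    max_step: int = 5,
    edge_rank: str = "signed",
) -> tuple[dict[str, SFCResult], dict[str, str]]:
    """Apply threshold -> walk counts -> z-normalisation per subject.

    Per-subject failures are collected (keyed by subject id) instead of
    aborting the cohort; the caller decides whether a partial result is
    acceptable.
    """
    results: dict[str, SFCResult] = {}
    failures: dict[str, str] = {}
    for sid, fc in matrices.items():
        try:
            results[sid] = run_sfc_subject(
                fc, seeds, percentile=percentile, max_step=max_step,
                edge_rank=edge_rank, subject_id=sid,
            )
        except Exception as exc:  # noqa: BLE001 - summarised for the caller
            failures[sid] = f"{type(exc).__name__}: {exc}"
    return results, failures
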