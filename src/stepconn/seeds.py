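"""Phenotype-driven seed selection.

Regional degree centrality is correlated with a continuous obesity phenotype
(WHR by default) across subjects; two-sided p-values come from the exact t
transform of Pearson's r with n-2 degrees of freedom, multiplicity is handled
by Benjamini-Hochberg FDR, and regions with q below the level (0.05) form the
seed set for the stepwise connectivity analysis. Robustness is quantified by
bootstrap resampling (90% of subjects with replacement, 1000 iterations):
each iteration's whole-brain r-map is correlated with the full-sample map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import EstimationError, InputError
from .parcellation import stratify_by_network  # noqa: F401  (module surface)


@dataclass(frozen=True)
class EffectMap:
    """Per-region association of degree with a phenotype."""

    r: np.ndarray
    p: np.ndarray
    q: np.ndarray
    phenotype_name: str = "WHR"
    constant_regions: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))


@dataclass(frozen=True)
class SeedSet:
    """Regions with q below ``alpha``; ids are 1-based, signs follow r."""

    region_ids: np.ndarray
    alpha: float
    signs: np.ndarray

    @property
    def indices(self) -> np.ndarray:
        """0-based region indices, for matrix slicing."""
        return np.asarray(self.region_ids, dtype=int) - 1

    def __len__(self) -> int:
        return int(np.asarray(self.region_ids).size)


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j, clipped at 1, mapped back to the
    original order; ties share the same q through the suffix minimum.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise InputError("p must be a 1-d vector")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise InputError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def pearson_map(values: np.ndarray, phenotype: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Columnwise Pearson r of ``values`` (n x R) against a phenotype vector.

    Returns (r, two-sided p, indices of constant columns). Constant columns are
    reported with r = 0, p = 1 rather than raising, so a flat region does not
    abort a whole-brain map.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    if x.ndim != 2 or y.ndim != 1 or x.shape[0] != y.size:
        raise InputError("values must be n x R and phenotype length n")
    n = y.size
    if n < 4:
        raise InputError(f"need at least 4 subjects, got {n}")
    if y.std() == 0:
        raise InputError("phenotype is constant")
    yc = y - y.mean()
    xc = x - x.mean(axis=0)
    sx = np.sqrt((xc**2).sum(axis=0))
    const = np.flatnonzero(sx == 0)
    sx_safe = np.where(sx == 0, 1.0, sx)
    r = (xc.T @ yc) / (sx_safe * np.sqrt((yc**2).sum()))
    r = np.clip(r, -1.0, 1.0)
    r[const] = 0.0
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.clip(1.0 - r**2, 1e-300, None))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.clip(p, 0.0, 1.0)
    p[const] = 1.0
    return r, p, const


def phenotype_association(
    degrees: np.ndarray,
    phenotype: np.ndarray,
    alpha: float = 0.05,
    phenotype_name: str = "WHR",
) -> tuple[EffectMap, SeedSet]:
    """Region-wise degree-phenotype correlation with BH-FDR seed selection."""
    r, p, const = pearson_map(degrees, phenotype)
    q = bh_fdr(p)
    selected = np.flatnonzero(q < alpha)
    effect = EffectMap(r=r, p=p, q=q, phenotype_name=phenotype_name, constant_regions=const)
    seed = SeedSet(region_ids=selected + 1, alpha=alpha, signs=np.sign(r[selected]).astype(int))
    return effect, seed


@dataclass(frozen=True)
class BootstrapStability:
    correlations: np.ndarray
    mean: float
    sd: float
    n_boot: int
    frac: float


def bootstrap_stability(
    degrees: np.ndarray,
    phenotype: np.ndarray,
    n_boot: int = 1000,
    frac: float = 0.9,
    rng: np.random.Generator | int | None = None,
    with_replacement: bool = True,
    max_retries: int = 100,
) -> BootstrapStability:
    """Stability of the whole-brain effect map under subject resampling.

    Each iteration draws ``ceil(frac * n)`` subjects (with replacement by
    default), recomputes the degree-phenotype r-map, and reports its Pearson
    correlation with the full-sample map. ``frac=1.0`` with
    ``with_replacement=False`` is the identity resample, useful for testing.
    Degenerate draws (constant phenotype) are retried up to ``max_retries``
    times before raising.
    """
    if n_boot < 1:
        raise InputError("n_boot must be >= 1")
    if not 0 < frac <= 1:
        raise InputError("frac must lie in (0, 1]")
    rng = np.random.default_rng(rng)
    degrees = np.asarray(degrees, dtype=float)
    phenotype = np.asarray(phenotype, dtype=float)
    n = phenotype.size
    k = int(np.ceil(frac * n))
    full_r, _, _ = pearson_map(degrees, phenotype)
    out = np.empty(n_boot)
    for b in range(n_boot):
        for attempt in range(max_retries + 1):
            if with_replacement:
                idx = rng.integers(0, n, size=k)
            else:
                idx = rng.permutation(n)[:k]
            sub = phenotype[idx]
            if sub.std() > 0:
                break
        else:
            raise EstimationError(
                f"bootstrap iteration {b}: phenotype constant in {max_retries} consecutive resamples"
            )
        boot_r, _, _ = pearson_map(degrees[idx], sub)
        denom = full_r.std() * boot_r.std()
        if denom == 0:
            out[b] = 0.0
        else:
            out[b] = float(np.corrcoef(full_r, boot_r)[0, 1])
    return BootstrapStability(
        correlations=out,
        mean=float(out.mean()),
        sd=float(out.std(ddof=1)) if n_boot > 1 else 0.0,
        n_boot=n_boot,
        frac=frac,
    )
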