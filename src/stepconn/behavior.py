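"""Association of network step degrees with eating-behavior (TFEQ) scores.

Five score combinations are tested: dietary restraint (1), disinhibition (2),
hunger (3), restraint+disinhibition (1+2) and the total (1+2+3); composites
are always recomputed from the subscales. For each (network, score) pair the
observed Pearson r is compared against a permutation null built by shuffling
subjects (5000 permutations by default) with a two-sided count; q-values come
from BH-FDR applied jointly across all tested pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .seeds import bh_fdr

SUBSCALES: tuple[str, ...] = ("dietary_restraint", "disinhibition", "hunger")
SCORE_NAMES: tuple[str, ...] = SUBSCALES + ("restraint_plus_disinhibition", "total")


def compute_scores(tfeq: pd.DataFrame) -> pd.DataFrame:
    """Expand the three TFEQ subscales into the five tested score columns."""
    missing = [c for c in SUBSCALES if c not in tfeq.columns]
    if missing:
        raise InputError(f"tfeq table lacks subscale column(s) {missing}")
    out = tfeq[list(SUBSCALES)].astype(float).copy()
    out["restraint_plus_disinhibition"] = out["dietary_restraint"] + out["disinhibition"]
    out["total"] = out["dietary_restraint"] + out["disinhibition"] + out["hunger"]
    return out


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))


@dataclass(frozen=True)
class PermutationResult:
    r: float
    p_perm: float
    n_perm: int
    convention: str


def permutation_correlation(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 5000,
    rng: np.random.Generator | int | None = None,
    convention: str = "add_one",
) -> PermutationResult:
    """Two-sided permutation test of Pearson's r.

    The null shuffles ``y`` over subjects ``n_perm`` times. With the default
    add-one convention p = (1 + #{|r_null| >= |r|}) / (n_perm + 1), which is a
    valid p-value and never 0; ``convention="plug_in"`` uses the raw
    proportion #{|r_null| >= |r|} / n_perm.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.shape != x.shape:
        raise InputError("x and y must be equal-length vectors")
    if x.size < 5:
        raise InputError(f"need at least 5 subjects, got {x.size}")
    if x.std() == 0 or y.std() == 0:
        raise InputError("constant input vector")
    if convention not in ("add_one", "plug_in"):
        raise InputError(f"unknown convention {convention!r}")
    rng = np.random.default_rng(rng)
    r = _pearson(x, y)
    perms = _permutation_matrix(rng, n_perm, x.size)
    null = _null_correlations(x, y, perms)
    exceed = int(np.count_nonzero(np.abs(null) >= abs(r) - 1e-12))
    if convention == "add_one":
        p = (1 + exceed) / (n_perm + 1)
    else:
        p = exceed / n_perm
    return PermutationResult(r=r, p_perm=float(p), n_perm=n_perm, convention=convention)


def _permutation_matrix(rng: np.random.Generator, n_perm: int, n: int) -> np.ndarray:
    perms = np.empty((n_perm, n), dtype=np.intp)
    for i in range(n_perm):
        perms[i] = rng.permutation(n)
    return perms


def _null_correlations(x: np.ndarray, y: np.ndarray, perms: np.ndarray) -> np.ndarray:
    """Pearson r of x against every row-permutation of y, vectorised."""
    xc = (x - x.mean()) / (x.std() * np.sqrt(x.size))
    yc = (y - y.mean()) / (y.std() * np.sqrt(y.size))
    return yc[perms] @ xc


@dataclass(frozen=True)
class BehaviorAssoc:
    """Permutation correlations for every tested (network, score) pair."""

    table: pd.DataFrame  # columns: network, score, r, p_perm, q
    n_perm: int
    family_size: int
    convention: str

    def wide(self, value: str = "r") -> pd.DataFrame:
        """Networks x score-combinations table (one value per cell)."""
        return self.table.pivot(index="network", columns="score", values=value).reindex(
            columns=list(SCORE_NAMES)
        )


def associate_behavior(
    network_degrees: pd.DataFrame,
    tfeq: pd.DataFrame,
    n_perm: int = 5000,
    rng: np.random.Generator | int | None = None,
    networks: list[str] | None = None,
    convention: str = "add_one",
) -> BehaviorAssoc:
    """Permutation correlation of each network's degree with each TFEQ score.

    ``network_degrees`` holds one column per network (typically the step-5
    degrees of the networks flagged by the group contrast, plus subcortex).
    Scores are shuffled; the same permutations are reused across networks for
    a given score so the family shares one null ensemble. BH-FDR runs jointly
    over all (network, score) pairs.
    """
    if networks is None:
        networks = list(network_degrees.columns)
    if not networks:
        raise InputError("no networks to test")
    missing = [n for n in networks if n not in network_degrees.columns]
    if missing:
        raise InputError(f"network column(s) {missing} not present")
    rng = np.random.default_rng(rng)
    scores = compute_scores(tfeq)
    n = len(scores)
    if len(network_degrees) != n:
        raise InputError("network_degrees and tfeq must describe the same subjects")
    deg = network_degrees[networks].to_numpy(dtype=float)
    rows: list[dict] = []
    for score_name in SCORE_NAMES:
        y = scores[score_name].to_numpy(dtype=float)
        if y.std() == 0:
            raise InputError(f"score {score_name!r} is constant")
        perms = _permutation_matrix(rng, n_perm, n)
        for j, net in enumerate(networks):
            x = deg[:, j]
            if x.std() == 0:
                raise InputError(f"network degree {net!r} is constant")
            r = _pearson(x, y)
            null = _null_correlations(x, y, perms)
            exceed = int(np.count_nonzero(np.abs(null) >= abs(r) - 1e-12))
            p = (1 + exceed) / (n_perm + 1) if convention == "add_one" else exceed / n_perm
            rows.append({"network": net, "score": score_name, "r": r, "p_perm": p})
    table = pd.DataFrame(rows)
    table["q"] = bh_fdr(table["p_perm"].to_numpy())
    return BehaviorAssoc(
        table=table, n_perm=n_perm, family_size=len(table), convention=convention
    )
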