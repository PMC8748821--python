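"""Synthetic cohorts with recoverable ground truth.

The generator emulates the statistical structure the analysis assumes, at the
level of parcellated time series:

* Subject time series are drawn from a zero-mean multivariate normal whose
  covariance is built from cliques of up to five regions nested inside each
  community/subcortical label (within-clique covariance
  ``within_community_covariance``), plus a constant-covariance gateway ring
  linking consecutive cliques so the thresholded graph is connected and walk
  counts can propagate. Fixed-size cliques keep per-edge partial correlations
  comparable across parcellation sizes; a single equicorrelated block per
  community would drive them to ~1/(block size) and starve the estimator.
* A continuous obesity phenotype (WHR, sex-specific distributions) is planted
  into regional degree: true seed regions are whole cliques whose internal
  covariance is scaled per subject by a factor linear in a latent that
  correlates with WHR. The latent-WHR correlation is inflated by a calibrated
  attenuation model so that the *measured* degree-WHR correlation approximates
  ``planted_effect_r`` despite estimation noise at finite T.
* Overweight subjects (group membership realised exactly through zone-wise
  phenotype sampling) receive additional signed covariance shifts in the
  ``group_effect_networks``, calibrated so the network-level step-degree
  Cohen's d approximates ``group_effect_magnitude``.
* TFEQ subscales are correlated integer scores; for each planted
  (network, subscale) pair the subscale mixes in the subject's latent network
  strength so the measured degree-score correlation approximates
  ``behavior_effect_r``.

BMI is a noisy monotone transform of the same latent adiposity that drives
WHR; ``bmi_whr_coupling`` sets the strength of that coupling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .parcellation import (
    ALL_LABELS,
    Parcellation,
    default_parcellation,
    parcellation_from_community_sizes,
)

# --- internal calibration constants -----------------------------------------
# Calibrated once for the generator's reference regime (cliques of 4-5
# regions, within-clique covariance 0.3, ridge rho = 0.5, 95% threshold,
# 5 steps), most accurately near the operating scales R ~ 60 and R ~ 246 at
# T ~ 300-400; see docs/methods.md for the calibration protocol.
_KAPPA_WHR = 0.55          # clique-scale amplitude per unit of the WHR latent
_ALPHA_SIGNAL = 7.2686     # direct signal slope, in per-edge noise units
_ALPHA_DRIFT = 0.070923    # noise-floor drift per edge, same units
_GROUP_SCALE_PER_D = 0.2275  # covariance shift per unit of target Cohen's d
_BEHAV_KAPPA = 0.50        # clique-scale amplitude per unit behaviour latent
_BEHAV_ATTEN = 0.67        # corr(latent, measured step-5 network degree)

_CLIQUE_MAX = 5
_BACKBONE_COV = 0.30
_SCALE_LIMITS = (0.05, 1.95)
_TOTAL_SCALE_LIMITS = (0.05, 2.0)

_TFEQ_PARAMS = {  # mean, sd of the integer subscale scores
    "dietary_restraint": (7.6, 4.8),
    "disinhibition": (4.5, 3.0),
    "hunger": (4.3, 3.2),
}
_TFEQ_CORR = np.array([
    [1.00, 0.30, 0.20],
    [0.30, 1.00, 0.45],
    [0.20, 0.45, 1.00],
])
_SUBSCALES = tuple(_TFEQ_PARAMS)

_WHR_BASE = {"female": 0.78, "male": 0.88}
_WHR_SLOPE = 0.08
_WHR_NOISE = 0.03
_BMI_WHR_CUT = {"female": 0.85, "male": 0.90}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort."""

    n_subjects: int = 301
    n_regions: int = 246
    n_timepoints: int = 400
    community_sizes: tuple[int, ...] | None = None
    within_community_covariance: float = 0.3
    planted_effect_r: float = 0.0
    n_true_seeds: int = 0
    group_fraction: float = 0.25
    healthy_fraction: float = 0.35
    group_effect_magnitude: float = 0.0
    group_effect_networks: tuple[tuple[str, float], ...] = (("somatomotor", -1.0), ("visual", 1.0))
    behavior_effect_r: float = 0.0
    behavior_effects: tuple[tuple[str, str], ...] = (("somatomotor", "disinhibition"),)
    bmi_whr_coupling: float = 0.7
    noise_sd: float = 0.0
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_regions < 20:
            raise ConfigurationError(f"n_regions must be >= 20, got {self.n_regions}")
        if not 0 <= self.planted_effect_r < 1:
            raise ConfigurationError(
                f"planted_effect_r must lie in [0, 1), got {self.planted_effect_r}"
            )
        if not -1 < self.behavior_effect_r < 1:
            raise ConfigurationError(
                f"behavior_effect_r must lie in (-1, 1), got {self.behavior_effect_r}"
            )
        if self.group_fraction < 0 or self.healthy_fraction < 0 or \
                self.group_fraction + self.healthy_fraction > 1:
            raise ConfigurationError("group_fraction + healthy_fraction must not exceed 1")
        if not 0 < self.within_community_covariance < 0.5:
            raise ConfigurationError("within_community_covariance must lie in (0, 0.5)")
        if self.n_true_seeds < 0 or self.n_true_seeds > self.n_regions:
            raise ConfigurationError("n_true_seeds must lie in [0, n_regions]")
        for name, _ in self.group_effect_networks:
            if name not in ALL_LABELS:
                raise ConfigurationError(f"unknown group effect network {name!r}")
        for name, score in self.behavior_effects:
            if name not in ALL_LABELS:
                raise ConfigurationError(f"unknown behavior effect network {name!r}")
            if score not in _SUBSCALES:
                raise ConfigurationError(
                    f"behavior effects plant into a TFEQ subscale, got {score!r}"
                )
        if self.community_sizes is not None:
            cortical = sum(self.community_sizes)
            if cortical + 7 > self.n_regions:
                raise ConfigurationError(
                    "community_sizes leave no room for the 7 subcortical structures"
                )


@dataclass(frozen=True)
class GroundTruth:
    """What was planted, for parameter-recovery tests."""

    seed_region_ids: np.ndarray        # 1-based ids with nonzero phenotype effect
    effect_sizes: np.ndarray           # per-region signed planted correlation
    group_effect_networks: tuple[tuple[str, float], ...]  # (network, signed d)
    behavior_effects: tuple[tuple[str, str, float], ...]  # (network, subscale, r)
    group_labels: tuple[str, ...]      # realised per-subject group label


@dataclass(frozen=True)
class Cohort:
    """The pipeline's single input bundle."""

    subject_ids: tuple[str, ...]
    phenotypes: pd.DataFrame
    timeseries: np.ndarray             # subjects x T x R
    parcellation: Parcellation
    ground_truth: GroundTruth | None = None

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def tfeq(self) -> pd.DataFrame:
        """TFEQ subscales under their canonical names."""
        return self.phenotypes.rename(columns={
            "tfeq_restraint": "dietary_restraint",
            "tfeq_disinhibition": "disinhibition",
            "tfeq_hunger": "hunger",
        })[["dietary_restraint", "disinhibition", "hunger"]]


def degree_attenuation(n_regions: int, n_timepoints: int) -> float:
    """Signed expected corr(latent, measured absolute degree) at planted regions.

    Two opposing channels link a subject's clique-strength latent to the
    absolute-value degree of a seed region: the direct one (stronger clique
    edges -> larger within-clique partial correlations, roughly constant sd
    because the number of within-clique edges per region is fixed) and an
    indirect noise-floor drift (a stronger clique raises the region's
    precision diagonal, shrinking *all* its spurious partial correlations;
    this accumulates over R-1 edges and scales with the per-edge estimation
    noise ~ 1/sqrt(T)). At small R the direct channel wins; beyond the
    crossover (around R ~ 150 at T = 400) the net coupling is negative and
    the generator flips its internal sign so the realised correlation keeps
    the requested sign.
    """
    scale = np.sqrt(200.0 / n_timepoints)
    signal = _ALPHA_SIGNAL - _ALPHA_DRIFT * (n_regions - 1) * scale
    noise = np.sqrt((n_regions - 1) * 200.0 / n_timepoints)
    return float(signal / np.hypot(signal, noise))


def _build_cliques(parcellation: Parcellation) -> list[tuple[str, np.ndarray]]:
    """Split every label's regions into cliques of at most _CLIQUE_MAX."""
    cliques: list[tuple[str, np.ndarray]] = []
    for label in ALL_LABELS:
        idx = parcellation.members(label)
        if idx.size == 0:
            continue
        n_cliques = int(np.ceil(idx.size / _CLIQUE_MAX))
        for part in np.array_split(idx, n_cliques):
            cliques.append((label, part))
    return cliques


def _backbone_edges(cliques: list[tuple[str, np.ndarray]]) -> list[tuple[int, int]]:
    """Gateway ring plus long-range chords between cliques.

    The ring (last region of each clique to the first region of the next)
    makes the graph connected; chords between cliques a third of the ring
    apart keep the diameter small, so walk counts at moderate steps cover the
    whole graph instead of depending sharply on where the seed cliques sit.
    Every region carries at most one backbone edge, so the backbone is a
    matching and the covariance perturbation it adds has spectral norm
    exactly _BACKBONE_COV regardless of clique scaling.
    """
    edges: list[tuple[int, int]] = []
    n_cliques = len(cliques)
    for i, (_, part) in enumerate(cliques):
        nxt = cliques[(i + 1) % n_cliques][1]
        a, b = int(part[-1]), int(nxt[0])
        if a != b:
            edges.append((a, b))
    offset = max(2, n_cliques // 3)
    for i, (_, part) in enumerate(cliques):
        tgt = cliques[(i + offset) % n_cliques][1]
        # chords use interior regions so the matching property is preserved
        if part.size >= 4 and tgt.size >= 4:
            edges.append((int(part[1]), int(tgt[-2])))
    return edges


def _select_seed_cliques(
    cliques: list[tuple[str, np.ndarray]],
    n_true_seeds: int,
    rng: np.random.Generator,
    exclude_labels: frozenset[str] = frozenset(),
) -> list[int]:
    """Indices of cliques whose sizes sum exactly to ``n_true_seeds``.

    Cliques in ``exclude_labels`` (networks carrying other planted effects)
    are never chosen, so the planted channels stay identifiable.
    """
    eligible = [i for i, (lab, _) in enumerate(cliques) if lab not in exclude_labels]
    order = np.asarray(eligible)[rng.permutation(len(eligible))]
    sizes = [cliques[i][1].size for i in order]
    # subset-sum DP with parent pointers, exact hit required
    parent: dict[int, tuple[int, int] | None] = {0: None}
    for pos, size in enumerate(sizes):
        for total in sorted(parent, reverse=True):
            new = total + size
            if new <= n_true_seeds and new not in parent:
                parent[new] = (total, pos)
    if n_true_seeds not in parent:
        raise ConfigurationError(
            f"cannot realise exactly {n_true_seeds} true seed regions from clique sizes "
            f"{sorted(set(sizes))}; choose a reachable count"
        )
    chosen: list[int] = []
    node = n_true_seeds
    while parent[node] is not None:
        prev, pos = parent[node]  # type: ignore[misc]
        chosen.append(int(order[pos]))
        node = prev
    return chosen


def _zone_whr(rng, sex: str, a: float, zone: str) -> float:
    """WHR draw constrained to the healthy/overweight/neither zone."""
    cut = _BMI_WHR_CUT[sex]
    base = _WHR_BASE[sex] + _WHR_SLOPE * a
    for _ in range(200):
        w = base + _WHR_NOISE * rng.standard_normal()
        if zone == "healthy" and w <= cut:
            return float(np.clip(w, 0.45, cut))
        if zone == "overweight" and w > cut:
            return float(np.clip(w, cut + 1e-3, 1.4))
        if zone == "free":
            return float(np.clip(w, 0.45, 1.4))
    return cut - 0.01 if zone == "healthy" else cut + 0.01


def _zone_bmi(rng, a_b: float, zone: str) -> float:
    base = 24.0 + 4.5 * a_b
    for _ in range(200):
        b = base + 1.5 * rng.standard_normal()
        if zone == "healthy" and 18.5 <= b < 25:
            return float(b)
        if zone == "overweight" and b >= 25:
            return float(min(b, 50.0))
        if zone == "free":
            return float(np.clip(b, 15.0, 50.0))
    return 22.0 if zone == "healthy" else 27.0


def _simulate_phenotypes(config: SimulationConfig, rng: np.random.Generator):
    n = config.n_subjects
    sex = np.where(rng.random(n) < 0.6, "female", "male")
    n_ow = int(round(config.group_fraction * n))
    n_hw = int(round(config.healthy_fraction * n))
    intent = np.array(["unassigned"] * n, dtype=object)
    order = rng.permutation(n)
    intent[order[:n_ow]] = "overweight"
    intent[order[n_ow:n_ow + n_hw]] = "healthy_weight"

    mean_a = {"overweight": 1.2, "healthy_weight": -0.8, "unassigned": 0.2}
    sd_a = {"overweight": 0.5, "healthy_weight": 0.5, "unassigned": 0.8}
    a = np.array([rng.normal(mean_a[g], sd_a[g]) for g in intent])

    zone = {"overweight": "overweight", "healthy_weight": "healthy", "unassigned": "free"}
    whr = np.array([_zone_whr(rng, s, ai, zone[g]) for s, ai, g in zip(sex, a, intent)])
    cpl = float(np.clip(config.bmi_whr_coupling, 0.0, 1.0))
    a_b = cpl * a + np.sqrt(1.0 - cpl**2) * rng.standard_normal(n)
    bmi = np.array([_zone_bmi(rng, ab, zone[g]) for ab, g in zip(a_b, intent)])

    # force 'unassigned' intents out of both group zones so realised counts
    # equal the configured fractions exactly
    cut = np.array([_BMI_WHR_CUT[s] for s in sex])
    for i in np.flatnonzero(intent == "unassigned"):
        if 18.5 <= bmi[i] < 25 and whr[i] <= cut[i]:
            whr[i] = cut[i] + 0.005 + abs(rng.normal(0, 0.02))
        elif bmi[i] >= 25 and whr[i] > cut[i]:
            whr[i] = cut[i] - abs(rng.normal(0, 0.02))

    age = np.clip(40.0 + 6.0 * a + 14.0 * rng.standard_normal(n), 18.0, 85.0)
    return sex, intent, a, whr, bmi, age


def _simulate_tfeq(
    rng: np.random.Generator,
    n: int,
    planted: dict[str, list[tuple[float, np.ndarray]]],
) -> dict[str, np.ndarray]:
    """Correlated integer subscales, optionally mixed with network latents."""
    chol = np.linalg.cholesky(_TFEQ_CORR)
    latent = rng.standard_normal((n, 3)) @ chol.T
    out: dict[str, np.ndarray] = {}
    for j, name in enumerate(_SUBSCALES):
        x = latent[:, j]
        for weight, z in planted.get(name, []):
            x = weight * z + np.sqrt(max(0.0, 1.0 - weight**2)) * x
        mu, sd = _TFEQ_PARAMS[name]
        out[name] = np.clip(np.round(mu + sd * x), 0, None).astype(int)
    return out


def generate_cohort(config: SimulationConfig) -> Cohort:
    """Draw one cohort under the configured study conditions.

    Identical config and seed produce byte-identical cohorts: all randomness
    flows through one generator in a fixed call order.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    if config.community_sizes is None:
        parcellation = default_parcellation(config.n_regions)
    else:
        parcellation = parcellation_from_community_sizes(
            tuple(config.community_sizes), config.n_regions
        )
    n, t, r = config.n_subjects, config.n_timepoints, config.n_regions
    cliques = _build_cliques(parcellation)
    backbone = _backbone_edges(cliques)

    sex, intent, a, whr, bmi, age = _simulate_phenotypes(config, rng)

    # --- planted WHR-degree association ------------------------------------
    effect_sizes = np.zeros(r)
    seed_clique_sign: dict[int, float] = {}
    h = np.zeros(n)
    if config.n_true_seeds > 0 and config.planted_effect_r > 0:
        alpha = degree_attenuation(r, t)
        c1 = config.planted_effect_r / abs(alpha)
        if c1 > 0.995:
            raise ConfigurationError(
                f"planted_effect_r={config.planted_effect_r} is not realisable at "
                f"R={r}, T={t} (attenuation {alpha:.2f}); lower the target, raise "
                f"n_timepoints, or move away from the coupling crossover in R"
            )
        exclude = frozenset(
            name for name, _ in config.group_effect_networks
            if config.group_effect_magnitude > 0
        ) | frozenset(
            name for name, _ in config.behavior_effects
            if config.behavior_effect_r != 0
        )
        chosen = _select_seed_cliques(cliques, config.n_true_seeds, rng, exclude)
        # balance signed region counts so the opposing planted directions
        # cancel at the whole-brain level, as in real effect maps
        chosen = sorted(chosen, key=lambda ci: -cliques[ci][1].size)
        running = 0.0
        for pos, ci in enumerate(chosen):
            sign = -1.0 if running > 0 else 1.0
            running += sign * cliques[ci][1].size
            # np.sign(alpha): the covariance coupling is flipped where the
            # noise-floor drift dominates, so the realised correlation keeps
            # the intended sign (see degree_attenuation)
            seed_clique_sign[ci] = sign * float(np.sign(alpha))
            effect_sizes[cliques[ci][1]] = sign * config.planted_effect_r
        z_whr = (whr - whr.mean()) / whr.std()
        h = c1 * z_whr + np.sqrt(1.0 - c1**2) * rng.standard_normal(n)
    elif config.n_true_seeds > 0:
        chosen = _select_seed_cliques(cliques, config.n_true_seeds, rng)
        for ci in chosen:
            seed_clique_sign[ci] = 0.0

    # --- group and behaviour latents ---------------------------------------
    gamma = _GROUP_SCALE_PER_D * config.group_effect_magnitude
    group_nets = {name: s for name, s in config.group_effect_networks}
    behav_nets = sorted({name for name, _ in config.behavior_effects})
    v = {name: rng.standard_normal(n) for name in behav_nets}

    planted_tfeq: dict[str, list[tuple[float, np.ndarray]]] = {}
    truth_behavior: list[tuple[str, str, float]] = []
    if config.behavior_effect_r != 0:
        c_b = config.behavior_effect_r / _BEHAV_ATTEN  # signed mixing weight
        if abs(c_b) > 0.995:
            raise ConfigurationError(
                f"behavior_effect_r={config.behavior_effect_r} exceeds the realisable "
                f"range (attenuation {_BEHAV_ATTEN})"
            )
        for net, score in config.behavior_effects:
            planted_tfeq.setdefault(score, []).append((c_b, v[net]))
            truth_behavior.append((net, score, config.behavior_effect_r))
    tfeq = _simulate_tfeq(rng, n, planted_tfeq)

    is_ow = intent == "overweight"

    # --- per-subject covariance scales and time series ----------------------
    rho_w = config.within_community_covariance
    lo, hi = _SCALE_LIMITS
    tlo, thi = _TOTAL_SCALE_LIMITS
    scales = np.ones((n, len(cliques)))
    for ci, (label, _) in enumerate(cliques):
        s = np.ones(n)
        if ci in seed_clique_sign and config.planted_effect_r > 0:
            s = s * np.clip(1.0 + _KAPPA_WHR * seed_clique_sign[ci] * h, lo, hi)
        if label in group_nets and gamma > 0:
            s = s * np.where(is_ow, 1.0 + group_nets[label] * gamma, 1.0)
        if label in v and config.behavior_effect_r != 0:
            s = s * np.clip(1.0 + _BEHAV_KAPPA * v[label], lo, hi)
        scales[:, ci] = np.clip(s, tlo, thi)

    timeseries = np.empty((n, t, r))
    chol_cache: dict[bytes, np.ndarray] = {}
    clique_of = np.empty(r, dtype=int)
    for ci, (_, part) in enumerate(cliques):
        clique_of[part] = ci
    clique_size = np.array([part.size for _, part in cliques])

    def _cond_var(ci: int, scale: float) -> float:
        # residual variance of a clique member given its mates (equicorrelated)
        m = clique_size[ci]
        if m < 2:
            return 1.0
        c = rho_w * scale
        return 1.0 - (m - 1) * c * c / (1.0 + (m - 2) * c)

    for s_i in range(n):
        key = scales[s_i].tobytes()
        chol = chol_cache.get(key)
        if chol is None:
            sigma = np.eye(r)
            for ci, (_, part) in enumerate(cliques):
                cov = rho_w * scales[s_i, ci]
                block = np.full((part.size, part.size), cov)
                np.fill_diagonal(block, 0.0)
                sigma[np.ix_(part, part)] += block
            for e0, e1 in backbone:
                # compensate each endpoint's conditional-variance change so a
                # scaled clique does not modulate its neighbours' partial
                # correlations (which would leak planted effects off-target)
                w = _BACKBONE_COV
                for node in (e0, e1):
                    ci = clique_of[node]
                    w *= np.sqrt(
                        max(_cond_var(ci, scales[s_i, ci]), 1e-3)
                        / _cond_var(ci, 1.0)
                    )
                sigma[e0, e1] = sigma[e1, e0] = w
            chol = np.linalg.cholesky(sigma)
            chol_cache[key] = chol
        x = rng.standard_normal((t, r)) @ chol.T
        if config.noise_sd > 0:
            x = x + config.noise_sd * rng.standard_normal((t, r))
        timeseries[s_i] = x

    subject_ids = tuple(f"sub-{i + 1:04d}" for i in range(n))
    phenotypes = pd.DataFrame({
        "subject_id": subject_ids,
        "age": np.round(age, 2),
        "sex": sex,
        "bmi": np.round(bmi, 2),
        "whr": np.round(whr, 4),
        "tfeq_restraint": tfeq["dietary_restraint"],
        "tfeq_disinhibition": tfeq["disinhibition"],
        "tfeq_hunger": tfeq["hunger"],
    })
    seed_ids = np.flatnonzero(effect_sizes != 0) + 1
    if config.n_true_seeds > 0 and config.planted_effect_r == 0:
        seed_ids = np.sort(np.concatenate(
            [cliques[ci][1] for ci in seed_clique_sign] or [np.empty(0, dtype=int)]
        )) + 1
    truth = GroundTruth(
        seed_region_ids=seed_ids,
        effect_sizes=effect_sizes,
        group_effect_networks=tuple(
            (name, s * config.group_effect_magnitude) for name, s in config.group_effect_networks
        ) if config.group_effect_magnitude > 0 else (),
        behavior_effects=tuple(truth_behavior),
        group_labels=tuple(intent.tolist()),
    )
    return Cohort(
        subject_ids=subject_ids,
        phenotypes=phenotypes,
        timeseries=timeseries,
        parcellation=parcellation,
        ground_truth=truth,
    )
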