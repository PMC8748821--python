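"""Group assignment and group comparison of step degrees.

Subjects are assigned to weight groups from BMI and sex-specific WHR cutoffs
(healthy weight: 18.5 <= BMI < 25 and WHR <= 0.85 female / 0.90 male;
overweight: BMI >= 25 and WHR > the same cutoffs; everyone else is
unassigned), or to WHO waist-to-hip risk groups (low: WHR < 0.80/0.95
female/male; high: WHR > 0.86/1.00). Step degrees are compared with
two-sample t-tests per region and per network at each step; positive t means
a higher degree in the overweight (or high-risk) group. BH-FDR is applied
within each step, separately for the regional family (R tests) and the
network family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .parcellation import Parcellation
from .seeds import bh_fdr

BMI_WHR_CUTOFFS = {"female": 0.85, "male": 0.90}
WHO_LOW_CUTOFFS = {"female": 0.80, "male": 0.95}
WHO_HIGH_CUTOFFS = {"female": 0.86, "male": 1.00}

_GROUP_NAMES = {
    "bmi_whr": ("healthy_weight", "overweight"),
    "who_whr": ("low_risk", "high_risk"),
}


@dataclass(frozen=True)
class GroupAssignment:
    labels: pd.Series  # subject_id -> group label (or "unassigned")
    criteria_name: str
    errors: tuple[str, ...] = ()

    @property
    def reference_group(self) -> str:
        return _GROUP_NAMES[self.criteria_name][0]

    @property
    def positive_group(self) -> str:
        """The group whose excess degree yields a positive t-statistic."""
        return _GROUP_NAMES[self.criteria_name][1]

    def counts(self) -> dict[str, int]:
        return self.labels.value_counts().to_dict()

    def members(self, group: str) -> np.ndarray:
        return np.flatnonzero((self.labels == group).to_numpy())


def assign_groups(phenotypes: pd.DataFrame, criteria: str = "bmi_whr") -> GroupAssignment:
    """Label each subject from its BMI, WHR and sex.

    ``phenotypes`` needs columns ``subject_id``, ``bmi``, ``whr``, ``sex``
    (values ``"female"``/``"male"``). Subjects with missing fields receive an
    ``unassigned`` label and an error record rather than aborting the cohort.
    """
    if criteria not in _GROUP_NAMES:
        raise InputError(f"criteria must be one of {sorted(_GROUP_NAMES)}, got {criteria!r}")
    labels: list[str] = []
    errors: list[str] = []
    for _, row in phenotypes.iterrows():
        sid = str(row.get("subject_id", "?"))
        bmi, whr, sex = row.get("bmi"), row.get("whr"), row.get("sex")
        if pd.isna(bmi) or pd.isna(whr) or sex not in BMI_WHR_CUTOFFS:
            errors.append(f"{sid}: missing or invalid bmi/whr/sex")
            labels.append("unassigned")
            continue
        if criteria == "bmi_whr":
            cut = BMI_WHR_CUTOFFS[sex]
            if 18.5 <= bmi < 25 and whr <= cut:
                labels.append("healthy_weight")
            elif bmi >= 25 and whr > cut:
                labels.append("overweight")
            else:
                labels.append("unassigned")
        else:
            if whr < WHO_LOW_CUTOFFS[sex]:
                labels.append("low_risk")
            elif whr > WHO_HIGH_CUTOFFS[sex]:
                labels.append("high_risk")
            else:
                labels.append("unassigned")
    series = pd.Series(labels, index=phenotypes["subject_id"].astype(str).to_numpy(), name="group")
    return GroupAssignment(labels=series, criteria_name=criteria, errors=tuple(errors))


def network_degree(
    step_degrees: np.ndarray,
    parcellation: Parcellation,
    subcortical: str = "split",
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Mean step degree within each network, per subject and step.

    ``step_degrees`` is (subjects, steps, R); returns (subjects, steps, N)
    and the network names.
    """
    d = np.asarray(step_degrees, dtype=float)
    if d.ndim != 3 or d.shape[2] != parcellation.n_regions:
        raise InputError("step_degrees must be subjects x steps x R")
    names = parcellation.network_names(subcortical)
    out = np.empty(d.shape[:2] + (len(names),))
    for j, name in enumerate(names):
        out[:, :, j] = d[:, :, parcellation.members(name)].mean(axis=2)
    return out, names


def _two_sample_t(a: np.ndarray, b: np.ndarray, variant: str) -> tuple[np.ndarray, np.ndarray]:
    """t and two-sided p for positive-group a minus reference b, columnwise."""
    equal_var = variant == "pooled"
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a, b, axis=0, equal_var=equal_var)
    t = np.nan_to_num(np.asarray(res.statistic), nan=0.0)
    p = np.asarray(res.pvalue)
    p = np.where(np.isfinite(p), p, 1.0)
    return t, p


@dataclass(frozen=True)
class GroupContrast:
    """Regional and network step-degree contrasts (positive group minus reference)."""

    t_regional: np.ndarray  # steps x R
    p_regional: np.ndarray
    q_regional: np.ndarray
    t_network: np.ndarray | None  # steps x N
    p_network: np.ndarray | None
    q_network: np.ndarray | None
    network_names: tuple[str, ...]
    group_means: dict[str, np.ndarray]  # group -> steps x R mean degree
    group_sizes: dict[str, int]
    positive_group: str
    variant: str
    fdr_families: dict[str, int] = field(default_factory=dict)

    def flagged_networks(self, step: int, alpha: float = 0.05) -> tuple[str, ...]:
        """Networks with a significant contrast at a 1-based step."""
        if self.q_network is None:
            return ()
        sig = np.flatnonzero(self.q_network[step - 1] < alpha)
        return tuple(self.network_names[i] for i in sig)


def compare_groups(
    step_degrees: np.ndarray,
    assignment: GroupAssignment,
    parcellation: Parcellation | None = None,
    variant: str = "welch",
    subcortical: str = "split",
) -> GroupContrast:
    """Two-sample t-tests of step degrees between the assigned groups.

    ``step_degrees`` is (subjects, steps, R) ordered like ``assignment.labels``.
    Welch's t is the default (the groups differ in size and variance); the
    pooled-variance variant is available as ``variant="pooled"``. Regional and
    network q-values are BH-corrected within each step over their respective
    families.
    """
    if variant not in ("welch", "pooled"):
        raise InputError(f"variant must be 'welch' or 'pooled', got {variant!r}")
    d = np.asarray(step_degrees, dtype=float)
    if d.ndim != 3 or d.shape[0] != len(assignment.labels):
        raise InputError("step_degrees must be subjects x steps x R, matching the assignment")
    pos = assignment.members(assignment.positive_group)
    ref = assignment.members(assignment.reference_group)
    if min(pos.size, ref.size) < 3:
        raise InputError(
            f"need >= 3 subjects per group, got {assignment.positive_group}={pos.size}, "
            f"{assignment.reference_group}={ref.size}"
        )
    n_steps = d.shape[1]
    t_reg = np.empty((n_steps, d.shape[2]))
    p_reg = np.empty_like(t_reg)
    q_reg = np.empty_like(t_reg)
    for k in range(n_steps):
        t_reg[k], p_reg[k] = _two_sample_t(d[pos, k, :], d[ref, k, :], variant)
        q_reg[k] = bh_fdr(p_reg[k])
    families = {"regional_per_step": d.shape[2]}
    t_net = p_net = q_net = None
    names: tuple[str, ...] = ()
    if parcellation is not None:
        nd, names = network_degree(d, parcellation, subcortical=subcortical)
        t_net = np.empty((n_steps, nd.shape[2]))
        p_net = np.empty_like(t_net)
        q_net = np.empty_like(t_net)
        for k in range(n_steps):
            t_net[k], p_net[k] = _two_sample_t(nd[pos, k, :], nd[ref, k, :], variant)
            q_net[k] = bh_fdr(p_net[k])
        families["network_per_step"] = nd.shape[2]
    means = {
        assignment.positive_group: d[pos].mean(axis=0),
        assignment.reference_group: d[ref].mean(axis=0),
    }
    return GroupContrast(
        t_regional=t_reg, p_regional=p_reg, q_regional=q_reg,
        t_network=t_net, p_network=p_net, q_network=q_net,
        network_names=names, group_means=means,
        group_sizes={assignment.positive_group: int(pos.size),
                     assignment.reference_group: int(ref.size)},
        positive_group=assignment.positive_group, variant=variant,
        fdr_families=families,
    )


@dataclass(frozen=True)
class BalancedBootstrap:
    t_network: np.ndarray  # n_iter x steps x N
    network_names: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray
    subsample_size: int


def balanced_bootstrap_compare(
    step_degrees: np.ndarray,
    assignment: GroupAssignment,
    n_iter: int = 1000,
    subsample_size: int | None = None,
    rng: np.random.Generator | int | None = None,
    parcellation: Parcellation | None = None,
    variant: str = "welch",
    subcortical: str = "split",
) -> BalancedBootstrap:
    """Size-balanced comparison for unequal groups (WHO risk analysis).

    Each iteration draws ``subsample_size`` reference-group subjects without
    replacement (default: the size of the smaller, positive group), compares
    them against the full positive group, and records the network-level
    t-statistics.
    """
    if parcellation is None:
        raise InputError("balanced_bootstrap_compare needs a parcellation for network stats")
    rng = np.random.default_rng(rng)
    d = np.asarray(step_degrees, dtype=float)
    pos = assignment.members(assignment.positive_group)
    ref = assignment.members(assignment.reference_group)
    if subsample_size is None:
        subsample_size = int(pos.size)
    if subsample_size > ref.size:
        raise InputError(
            f"subsample_size {subsample_size} exceeds the {assignment.reference_group} "
            f"group size {ref.size}"
        )
    nd, names = network_degree(d, parcellation, subcortical=subcortical)
    out = np.empty((n_iter, d.shape[1], len(names)))
    for i in range(n_iter):
        take = ref[rng.permutation(ref.size)[:subsample_size]]
        for k in range(d.shape[1]):
            out[i, k], _ = _two_sample_t(nd[pos, k, :], nd[take, k, :], variant)
    return BalancedBootstrap(
        t_network=out, network_names=names,
        mean=out.mean(axis=0), sd=out.std(axis=0, ddof=1) if n_iter > 1 else np.zeros(out.shape[1:]),
        subsample_size=int(subsample_size),
    )
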