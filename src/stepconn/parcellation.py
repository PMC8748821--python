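"""Region labelling: seven cortical communities plus seven subcortical structures.

A :class:`Parcellation` maps 1-based region ids onto exactly one label each,
either a canonical functional community (visual ... default-mode) or a
subcortical structure (amygdala ... thalamus). Network-level aggregation
throughout the package is driven by these labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InputError

COMMUNITIES: tuple[str, ...] = (
    "visual",
    "somatomotor",
    "dorsal_attention",
    "ventral_attention",
    "limbic",
    "frontoparietal",
    "default_mode",
)

SUBCORTICAL_STRUCTURES: tuple[str, ...] = (
    "amygdala",
    "hippocampus",
    "globus_pallidus",
    "nucleus_accumbens",
    "putamen",
    "caudate",
    "thalamus",
)

ALL_LABELS: tuple[str, ...] = COMMUNITIES + SUBCORTICAL_STRUCTURES


@dataclass(frozen=True)
class Parcellation:
    """Assignment of every region to one community or subcortical structure.

    Attributes
    ----------
    region_ids:
        1-based contiguous integer labels, length R.
    region_names:
        Human-readable region names, length R.
    labels:
        Per-region label, each an element of :data:`ALL_LABELS`.
    """

    region_ids: np.ndarray
    region_names: tuple[str, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        ids = np.asarray(self.region_ids, dtype=int)
        object.__setattr__(self, "region_ids", ids)
        if ids.ndim != 1 or len(self.region_names) != ids.size or len(self.labels) != ids.size:
            raise ConfigurationError("region_ids, region_names and labels must have equal length")
        if not np.array_equal(ids, np.arange(1, ids.size + 1)):
            raise ConfigurationError("region_ids must be unique and contiguous from 1")
        bad = sorted({lab for lab in self.labels if lab not in ALL_LABELS})
        if bad:
            raise ConfigurationError(f"unknown labels: {bad}")

    @property
    def n_regions(self) -> int:
        return int(self.region_ids.size)

    @property
    def label_array(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=object)

    def members(self, label: str) -> np.ndarray:
        """0-based indices of the regions carrying ``label``."""
        if label == "subcortical":
            return np.flatnonzero(np.isin(self.label_array, SUBCORTICAL_STRUCTURES))
        return np.flatnonzero(self.label_array == label)

    @property
    def is_subcortical(self) -> np.ndarray:
        return np.isin(self.label_array, SUBCORTICAL_STRUCTURES)

    def network_names(self, subcortical: str = "split") -> tuple[str, ...]:
        """Names of the aggregation networks.

        ``subcortical="split"`` keeps the seven structures separate (14 groups);
        ``"pooled"`` collapses them into one ``subcortical`` group (8 groups),
        the grouping used for behavior tables.
        """
        if subcortical == "split":
            return ALL_LABELS
        if subcortical == "pooled":
            return COMMUNITIES + ("subcortical",)
        raise ConfigurationError(f"subcortical must be 'split' or 'pooled', got {subcortical!r}")

    def network_members(self, subcortical: str = "split") -> dict[str, np.ndarray]:
        return {name: self.members(name) for name in self.network_names(subcortical)}


def default_parcellation(n_regions: int) -> Parcellation:
    """Deterministic stand-in parcellation with all 14 labels populated.

    Regions are split as evenly as possible over the 7 communities followed by
    the 7 subcortical structures; when ``n_regions`` is not a multiple of 14
    the first ``n_regions % 14`` labels receive one extra region.
    """
    if n_regions < 14:
        raise ConfigurationError(f"need at least 14 regions to populate every label, got {n_regions}")
    base, extra = divmod(n_regions, 14)
    sizes = [base + 1 if i < extra else base for i in range(14)]
    labels: list[str] = []
    names: list[str] = []
    for label, size in zip(ALL_LABELS, sizes):
        for k in range(size):
            labels.append(label)
            names.append(f"{label}_{k + 1}")
    return Parcellation(
        region_ids=np.arange(1, n_regions + 1),
        region_names=tuple(names),
        labels=tuple(labels),
    )


def parcellation_from_community_sizes(community_sizes: tuple[int, ...], n_regions: int) -> Parcellation:
    """Build a parcellation from explicit cortical community sizes.

    The remaining ``n_regions - sum(community_sizes)`` regions are distributed
    as evenly as possible over the 7 subcortical structures.
    """
    if len(community_sizes) != len(COMMUNITIES):
        raise ConfigurationError("community_sizes must list one size per cortical community")
    cortical = int(sum(community_sizes))
    sub_total = n_regions - cortical
    if sub_total < 7 or any(s < 1 for s in community_sizes):
        raise ConfigurationError(
            f"community_sizes {community_sizes} incompatible with n_regions={n_regions}: "
            "every community and subcortical structure needs at least one region"
        )
    base, extra = divmod(sub_total, 7)
    sub_sizes = [base + 1 if i < extra else base for i in range(7)]
    labels: list[str] = []
    names: list[str] = []
    for label, size in zip(ALL_LABELS, list(community_sizes) + sub_sizes):
        for k in range(size):
            labels.append(label)
            names.append(f"{label}_{k + 1}")
    return Parcellation(
        region_ids=np.arange(1, n_regions + 1),
        region_names=tuple(names),
        labels=tuple(labels),
    )


def stratify_by_network(
    values: np.ndarray,
    parcellation: Parcellation,
    restrict: np.ndarray | None = None,
    subcortical: str = "split",
) -> dict[str, float]:
    """Mean of a per-region vector within each network.

    Parameters
    ----------
    values:
        Length-R vector of regional values.
    restrict:
        Optional 0-based indices; only regions in this subset enter the means
        (e.g. significant regions only). A network with no retained region is
        reported as ``nan`` rather than 0.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (parcellation.n_regions,):
        raise InputError(
            f"values has shape {values.shape}, expected ({parcellation.n_regions},)"
        )
    keep = np.zeros(parcellation.n_regions, dtype=bool)
    if restrict is None:
        keep[:] = True
    else:
        keep[np.asarray(restrict, dtype=int)] = True
    out: dict[str, float] = {}
    for name, idx in parcellation.network_members(subcortical).items():
        idx = idx[keep[idx]]
        out[name] = float(values[idx].mean()) if idx.size else float("nan")
    return out
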