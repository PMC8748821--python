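"""Readers and writers: TSV tables everywhere, JSON for metadata.

Cohorts are stored as one time-series TSV per subject (T rows x R columns,
header = region names), a phenotype TSV, a parcellation TSV and, for
synthetic cohorts, a ground-truth JSON. Region identity is checked by name,
not column order. Floats are written with repr-precision so that
write -> read round-trips are numerically exact and re-runs are
byte-identical.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .parcellation import Parcellation
from .synthetic import Cohort, GroundTruth

_PHENOTYPE_COLUMNS = (
    "subject_id", "age", "sex", "bmi", "whr",
    "tfeq_restraint", "tfeq_disinhibition", "tfeq_hunger",
)
_FLOAT_FMT = "%.17g"


def _ts_path(directory: Path, subject_id: str) -> Path:
    return directory / f"{subject_id}_timeseries.tsv"


def write_cohort(cohort: Cohort, directory: str | Path) -> dict[str, str]:
    """Write a cohort bundle; returns a name -> path map of what was written."""
    directory = Path(directory)
    ts_dir = directory / "timeseries"
    ts_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}
    names = list(cohort.parcellation.region_names)
    for i, sid in enumerate(cohort.subject_ids):
        path = _ts_path(ts_dir, sid)
        pd.DataFrame(cohort.timeseries[i], columns=names).to_csv(
            path, sep="\t", index=False, float_format=_FLOAT_FMT
        )
        written[f"timeseries/{sid}"] = str(path)

    pheno_path = directory / "phenotypes.tsv"
    cohort.phenotypes.to_csv(pheno_path, sep="\t", index=False, float_format=_FLOAT_FMT)
    written["phenotypes"] = str(pheno_path)

    parc_path = directory / "parcellation.tsv"
    write_parcellation(cohort.parcellation, parc_path)
    written["parcellation"] = str(parc_path)

    if cohort.ground_truth is not None:
        gt_path = directory / "ground_truth.json"
        write_ground_truth(cohort.ground_truth, gt_path)
        written["ground_truth"] = str(gt_path)
    return written


def write_parcellation(parcellation: Parcellation, path: str | Path) -> None:
    pd.DataFrame({
        "region_id": parcellation.region_ids,
        "name": list(parcellation.region_names),
        "community_or_subcortical": list(parcellation.labels),
    }).to_csv(path, sep="\t", index=False)


def read_parcellation(path: str | Path) -> Parcellation:
    df = pd.read_csv(path, sep="\t")
    required = {"region_id", "name", "community_or_subcortical"}
    if not required.issubset(df.columns):
        raise InputError(f"parcellation file {path} lacks columns {sorted(required - set(df.columns))}")
    df = df.sort_values("region_id")
    return Parcellation(
        region_ids=df["region_id"].to_numpy(),
        region_names=tuple(df["name"].astype(str)),
        labels=tuple(df["community_or_subcortical"].astype(str)),
    )


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "seed_region_ids": [int(i) for i in truth.seed_region_ids],
        "effect_sizes": [float(e) for e in truth.effect_sizes],
        "group_effect_networks": [[n, float(d)] for n, d in truth.group_effect_networks],
        "behavior_effects": [[n, s, float(r)] for n, s, r in truth.behavior_effects],
        "group_labels": list(truth.group_labels),
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        seed_region_ids=np.asarray(payload["seed_region_ids"], dtype=int),
        effect_sizes=np.asarray(payload["effect_sizes"], dtype=float),
        group_effect_networks=tuple((n, d) for n, d in payload["group_effect_networks"]),
        behavior_effects=tuple((n, s, r) for n, s, r in payload["behavior_effects"]),
        group_labels=tuple(payload["group_labels"]),
    )


def read_cohort(
    timeseries_dir: str | Path,
    phenotype_file: str | Path,
    parcellation_file: str | Path,
    ground_truth_file: str | Path | None = None,
) -> Cohort:
    """Load and validate a cohort bundle.

    Subject ids in the phenotype table must match the time-series files
    one-to-one and region columns must match the parcellation by name; both
    mismatches fail hard with a listing. Extra phenotype columns are accepted
    with a warning.
    """
    parcellation = read_parcellation(parcellation_file)
    pheno = pd.read_csv(phenotype_file, sep="\t", float_precision="round_trip")
    missing_cols = [c for c in _PHENOTYPE_COLUMNS if c not in pheno.columns]
    if missing_cols:
        raise InputError(f"phenotype table lacks column(s) {missing_cols}")
    extra = [c for c in pheno.columns if c not in _PHENOTYPE_COLUMNS]
    if extra:
        warnings.warn(f"ignoring extra phenotype column(s) {extra}", stacklevel=2)
    ids = pheno["subject_id"].astype(str)
    if ids.duplicated().any():
        raise InputError(f"duplicate subject ids: {sorted(ids[ids.duplicated()])}")

    ts_dir = Path(timeseries_dir)
    available = {p.name.removesuffix("_timeseries.tsv"): p
                 for p in sorted(ts_dir.glob("*_timeseries.tsv"))}
    missing = [s for s in ids if s not in available]
    extra_files = [s for s in available if s not in set(ids)]
    if missing:
        raise InputError(f"no time-series file for subject(s): {missing}")
    if extra_files:
        warnings.warn(f"time-series files without phenotype rows ignored: {extra_files}",
                      stacklevel=2)

    expected = list(parcellation.region_names)
    series = []
    t_len: int | None = None
    for sid in ids:
        df = pd.read_csv(available[sid], sep="\t", float_precision="round_trip")
        if list(df.columns) != expected:
            raise InputError(
                f"{sid}: region columns do not match the parcellation "
                f"(got {len(df.columns)} columns, expected {len(expected)})"
            )
        if t_len is None:
            t_len = len(df)
        elif len(df) != t_len:
            raise InputError(f"{sid}: {len(df)} timepoints, expected {t_len}")
        series.append(df.to_numpy(dtype=float))

    truth = read_ground_truth(ground_truth_file) if ground_truth_file else None
    return Cohort(
        subject_ids=tuple(ids),
        phenotypes=pheno[list(_PHENOTYPE_COLUMNS)].copy(),
        timeseries=np.stack(series),
        parcellation=parcellation,
        ground_truth=truth,
    )


def write_matrix_tsv(values: np.ndarray, path: str | Path, columns: list[str],
                     index: list | None = None, index_label: str | None = None) -> None:
    df = pd.DataFrame(np.asarray(values), columns=columns)
    if index is not None:
        df.insert(0, index_label or "row", index)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
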