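"""End-to-end orchestration: connectivity -> seeds -> SFC -> groups -> behavior.

Two entry points:

* :func:`analyze_cohort` runs the full analysis in memory on a
  :class:`~stepconn.synthetic.Cohort` and returns a :class:`StudyResult`.
* :func:`run_pipeline` is the file-level driver used by the CLI: it reads a
  cohort bundle, runs the stages, writes every table as TSV/JSON under the
  configured output directory and returns a manifest with content hashes.
  Given the same config and seed the manifest is byte-identical across runs.

Each randomised stage draws its own child seed from the master seed; the
derived seeds are logged in the manifest so any stage can be reproduced in
isolation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as behavior_mod
from . import connectivity as conn_mod
from . import groups as groups_mod
from . import seeds as seeds_mod
from . import sfc as sfc_mod
from .config import PipelineConfig
from .errors import InputError
from .io import read_cohort, write_matrix_tsv
from .parcellation import Parcellation
from .synthetic import Cohort

_STAGES = ("connect", "seeds", "sfc", "compare", "behavior")


def derive_stage_seeds(master: int) -> dict[str, int]:
    """One independent child seed per randomised stage, all below 2**31."""
    children = np.random.SeedSequence(master).spawn(len(_STAGES))
    return {
        stage: int(child.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)
        for stage, child in zip(_STAGES, children)
    }


@dataclass
class StudyResult:
    effect_map: seeds_mod.EffectMap
    seed_set: seeds_mod.SeedSet
    bootstrap: seeds_mod.BootstrapStability | None
    step_degrees: np.ndarray                 # subjects x steps x R (z-degrees)
    degenerate_steps: dict[str, tuple[int, ...]]
    assignment: groups_mod.GroupAssignment
    contrast: groups_mod.GroupContrast
    balanced_bootstrap: groups_mod.BalancedBootstrap | None
    behavior: behavior_mod.BehaviorAssoc | None
    tested_networks: tuple[str, ...]
    stage_seeds: dict[str, int]


def subject_degrees(
    cohort: Cohort,
    rho: float = 0.5,
    degree_mode: str = "absolute",
    ridge_dialect: str = "identity",
) -> tuple[dict[str, conn_mod.ConnectivityMatrix], np.ndarray]:
    """Per-subject connectivity matrices and the subjects x R degree table."""
    matrices: dict[str, conn_mod.ConnectivityMatrix] = {}
    degrees = np.empty((cohort.n_subjects, cohort.parcellation.n_regions))
    for i, sid in enumerate(cohort.subject_ids):
        fc = conn_mod.partial_correlation(
            cohort.timeseries[i], rho=rho, subject_id=sid, ridge_dialect=ridge_dialect
        )
        matrices[sid] = fc
        degrees[i] = conn_mod.degree_centrality(fc, mode=degree_mode).values
    return matrices, degrees


def _covariate_matrix(cohort: Cohort, which: str) -> np.ndarray:
    pheno = cohort.phenotypes
    sex01 = (pheno["sex"] == "male").astype(float).to_numpy()
    if which == "age_sex":
        return np.column_stack([pheno["age"].to_numpy(dtype=float), sex01])
    if which == "tfeq":
        return pheno[["tfeq_restraint", "tfeq_disinhibition", "tfeq_hunger"]].to_numpy(dtype=float)
    raise InputError(f"unknown sensitivity covariate set {which!r}")


def residualize_matrices(
    matrices: dict[str, conn_mod.ConnectivityMatrix],
    covariates: np.ndarray,
) -> dict[str, conn_mod.ConnectivityMatrix]:
    """Regress covariates out of every edge across subjects (upper triangle)."""
    sids = list(matrices)
    r = next(iter(matrices.values())).n_regions
    iu = np.triu_indices(r, k=1)
    stacked = np.stack([matrices[s].values[iu] for s in sids])
    resid = conn_mod.regress_out(stacked, covariates, keep_mean=True)
    out: dict[str, conn_mod.ConnectivityMatrix] = {}
    for i, sid in enumerate(sids):
        w = np.zeros((r, r))
        w[iu] = resid[i]
        w = w + w.T
        out[sid] = conn_mod.ConnectivityMatrix(
            values=w, subject_id=sid, regularization=matrices[sid].regularization
        )
    return out


def analyze_cohort(
    cohort: Cohort,
    config: PipelineConfig | None = None,
    sensitivity: str | None = None,
    tested_networks: list[str] | None = None,
) -> StudyResult:
    """Run the full analysis on an in-memory cohort.

    ``sensitivity`` may be ``"age_sex"`` or ``"tfeq"`` (residualise the
    connectivity edges before seed selection and SFC) or ``"who"`` (use WHO
    waist-to-hip risk groups for the comparison). ``tested_networks``
    overrides the behavior stage's default (networks flagged at the largest
    step, plus pooled subcortex).
    """
    config = config or PipelineConfig()
    stage_seeds = derive_stage_seeds(config.rng_seed)
    matrices, degrees = subject_degrees(
        cohort, rho=config.connectivity.rho,
        degree_mode=config.connectivity.degree_mode,
        ridge_dialect=config.connectivity.ridge_dialect,
    )
    if sensitivity in ("age_sex", "tfeq"):
        matrices = residualize_matrices(matrices, _covariate_matrix(cohort, sensitivity))
        degrees = np.stack([
            conn_mod.degree_centrality(matrices[s], mode=config.connectivity.degree_mode).values
            for s in cohort.subject_ids
        ])

    phenotype = cohort.phenotypes[config.seeds.phenotype].to_numpy(dtype=float)
    effect_map, seed_set = seeds_mod.phenotype_association(
        degrees, phenotype, alpha=config.seeds.alpha,
        phenotype_name=config.seeds.phenotype.upper(),
    )
    bootstrap = None
    if config.seeds.n_boot > 0:
        bootstrap = seeds_mod.bootstrap_stability(
            degrees, phenotype, n_boot=config.seeds.n_boot,
            frac=config.seeds.boot_frac, rng=stage_seeds["seeds"],
        )
    if len(seed_set) == 0:
        raise InputError("no seed regions survive FDR; stepwise analysis is undefined")

    results, failures = sfc_mod.run_sfc_cohort(
        {sid: matrices[sid] for sid in cohort.subject_ids}, seed_set,
        percentile=config.sfc.percentile, max_step=config.sfc.max_step,
        edge_rank=config.sfc.edge_rank,
    )
    if failures:
        raise InputError(f"stepwise analysis failed for {len(failures)} subject(s): {failures}")
    step_degrees = np.stack([results[sid].z_counts for sid in cohort.subject_ids])
    degenerate = {sid: results[sid].degenerate_steps for sid in cohort.subject_ids
                  if results[sid].degenerate_steps}

    criteria = "who_whr" if sensitivity == "who" else config.stats.criteria
    assignment = groups_mod.assign_groups(cohort.phenotypes, criteria=criteria)
    contrast = groups_mod.compare_groups(
        step_degrees, assignment, parcellation=cohort.parcellation,
        variant=config.stats.t_variant,
    )
    balanced = None
    if sensitivity == "who" and config.stats.n_boot_balanced > 0:
        balanced = groups_mod.balanced_bootstrap_compare(
            step_degrees, assignment, n_iter=config.stats.n_boot_balanced,
            rng=stage_seeds["compare"], parcellation=cohort.parcellation,
            variant=config.stats.t_variant,
        )

    behavior_step = config.behavior.step or config.sfc.max_step
    if tested_networks is None:
        flagged = contrast.flagged_networks(behavior_step, alpha=config.seeds.alpha)
        tested = sorted({n for n in flagged if n in cohort.parcellation.network_names("pooled")}
                        | {"subcortical"})
    else:
        tested = list(tested_networks)
    nd, names = groups_mod.network_degree(step_degrees, cohort.parcellation, subcortical="pooled")
    nd_frame = pd.DataFrame(nd[:, behavior_step - 1, :], columns=list(names))
    assoc = behavior_mod.associate_behavior(
        nd_frame, cohort.tfeq, n_perm=config.behavior.n_perm,
        rng=stage_seeds["behavior"], networks=tested,
        convention=config.behavior.convention,
    )
    return StudyResult(
        effect_map=effect_map, seed_set=seed_set, bootstrap=bootstrap,
        step_degrees=step_degrees, degenerate_steps=degenerate,
        assignment=assignment, contrast=contrast, balanced_bootstrap=balanced,
        behavior=assoc,
        tested_networks=tuple(tested), stage_seeds=stage_seeds,
    )


# --- file-level driver -------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_effect_map(result: StudyResult, parcellation: Parcellation, path: Path) -> None:
    selected = np.zeros(parcellation.n_regions, dtype=int)
    selected[result.seed_set.indices] = 1
    pd.DataFrame({
        "region_id": parcellation.region_ids,
        "r": result.effect_map.r,
        "p": result.effect_map.p,
        "q": result.effect_map.q,
        "selected_flag": selected,
    }).to_csv(path, sep="\t", index=False, float_format="%.17g")


def run_pipeline(
    config: PipelineConfig,
    cohort: Cohort | None = None,
    sensitivity: str | None = None,
) -> dict:
    """Execute every stage and write a manifest of all outputs.

    The cohort is read from ``config.paths`` unless given directly. A stage
    failure aborts with the stage name; files written by completed stages
    remain on disk and are listed in the partial manifest attached to the
    raised exception.
    """
    out_dir = Path(config.paths.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "stage_seeds": derive_stage_seeds(config.rng_seed),
        "sensitivity": sensitivity,
        "files": {},
        "stages_completed": [],
    }

    def record(name: str, path: Path) -> None:
        manifest["files"][name] = {"path": str(path), "sha256": _sha256(path)}

    stage = "read"
    try:
        if cohort is None:
            cohort = read_cohort(
                config.paths.timeseries_dir, config.paths.phenotype_file,
                config.paths.parcellation_file,
            )
        stage = "analyze"
        result = analyze_cohort(cohort, config, sensitivity=sensitivity)

        stage = "write"
        parc = cohort.parcellation
        region_cols = list(parc.region_names)

        _, degrees = subject_degrees(
            cohort, rho=config.connectivity.rho,
            degree_mode=config.connectivity.degree_mode,
            ridge_dialect=config.connectivity.ridge_dialect,
        )
        path = out_dir / "degrees.tsv"
        write_matrix_tsv(degrees, path, region_cols, list(cohort.subject_ids), "subject_id")
        record("degrees", path)

        path = out_dir / "effect_map.tsv"
        _write_effect_map(result, parc, path)
        record("effect_map", path)

        summary = {
            "n_seeds": int(len(result.seed_set)),
            "alpha": config.seeds.alpha,
            "seed_region_ids": [int(i) for i in result.seed_set.region_ids],
        }
        if result.bootstrap is not None:
            summary["bootstrap_mean"] = result.bootstrap.mean
            summary["bootstrap_sd"] = result.bootstrap.sd
        path = out_dir / "seed_summary.json"
        path.write_text(json.dumps(summary, indent=1, sort_keys=True) + "\n")
        record("seed_summary", path)

        n, steps, r = result.step_degrees.shape
        flat = result.step_degrees.reshape(n * steps, r)
        idx = [f"{sid}:step{k + 1}" for sid in cohort.subject_ids for k in range(steps)]
        path = out_dir / "step_degrees.tsv"
        write_matrix_tsv(flat, path, region_cols, idx, "subject_step")
        record("step_degrees", path)

        hub_rows = []
        for group, mean_deg in result.contrast.group_means.items():
            for k in range(steps):
                z = mean_deg[k]
                hubs = sfc_mod.detect_hubs(z - z.min(), config.sfc.hub_multiplier)
                hub_rows.append({
                    "group": group, "step": k + 1,
                    "hub_region_ids": ",".join(str(i + 1) for i in hubs),
                })
        path = out_dir / "hubs.tsv"
        pd.DataFrame(hub_rows).to_csv(path, sep="\t", index=False)
        record("hubs", path)

        path = out_dir / "group_assignment.tsv"
        result.assignment.labels.rename_axis("subject_id").reset_index().to_csv(
            path, sep="\t", index=False
        )
        record("group_assignment", path)

        rows = []
        for k in range(steps):
            for j in range(r):
                rows.append({
                    "region_id": j + 1, "step": k + 1,
                    "t": result.contrast.t_regional[k, j],
                    "p": result.contrast.p_regional[k, j],
                    "q": result.contrast.q_regional[k, j],
                })
        path = out_dir / "contrast_regional.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")
        record("contrast_regional", path)

        if result.contrast.t_network is not None:
            rows = []
            for k in range(steps):
                for j, name in enumerate(result.contrast.network_names):
                    rows.append({
                        "network": name, "step": k + 1,
                        "t": result.contrast.t_network[k, j],
                        "p": result.contrast.p_network[k, j],
                        "q": result.contrast.q_network[k, j],
                    })
            path = out_dir / "contrast_network.tsv"
            pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")
            record("contrast_network", path)

        if result.behavior is not None:
            path = out_dir / "behavior_assoc.tsv"
            result.behavior.table.to_csv(path, sep="\t", index=False, float_format="%.17g")
            record("behavior_assoc", path)
            path = out_dir / "behavior_table.tsv"
            wide_r = result.behavior.wide("r")
            wide_q = result.behavior.wide("q")
            wide = pd.concat({"r": wide_r, "q": wide_q}, axis=1)
            wide.to_csv(path, sep="\t", float_format="%.17g")
            record("behavior_table", path)

        for name in _STAGES:
            manifest["stages_completed"].append(name)
    except Exception as exc:
        exc.add_note(f"pipeline aborted in stage '{stage}'")
        exc.add_note(f"partial manifest: {json.dumps(manifest['files'], sort_keys=True)}")
        raise

    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
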