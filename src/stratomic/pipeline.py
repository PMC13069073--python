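"""End-to-end orchestration: simulate/load -> preprocess -> select ->
evaluate -> filter -> re-stratify, per data modality, with a machine-readable
manifest so any finished run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bench import build_classifiers, evaluate_models, permutation_test
from .clinical import knn_impute
from .datatypes import (
    ClinicalTable,
    CohortBundle,
    ConfigError,
    CVScheme,
    DataError,
    GROUPS,
    ProteinMatrix,
    read_labels,
)
from .proteomics import (
    filter_valid_fraction,
    impute_downshifted_normal,
    log2_transform,
    quantile_normalize,
    run_differential_suite,
)
from .selection import select_consensus_features
from .stratify import compare_modalities, consensus_reassign, misclassification_probability
from .synthetic import generate_cohort, preset

log = logging.getLogger("stratomic")

MODALITIES = ("clinical", "proteomic", "combined")

REPORT_FILES = (
    "differential.csv",
    "feature_panel.csv",
    "metrics.csv",
    "roc_results.csv",
    "misclass_matrix.csv",
    "stratification.csv",
    "modality_comparison.csv",
)


@dataclass
class RunConfig:
    """Everything a run needs; exactly one of ``preset`` / file paths."""

    preset: str | None = None
    protein_tsv: str | None = None
    clinical_csv: str | None = None
    labels_csv: str | None = None
    out_dir: str = "run"
    seed: int = 0

    # proteomic preprocessing
    min_valid_fraction: float = 0.70
    impute_shift_sd: float = 1.8
    impute_width_sd: float = 0.3
    n_permutations: int = 250
    alpha: float = 0.05

    # clinical preparation
    knn_k: int = 5

    # consensus selection
    select_repeats: int = 3
    select_folds: int = 5
    n_bootstrap: int = 50
    retain_fraction: float = 0.60
    fold_threshold: float = 0.20
    target_fraction: float = 0.25
    rfe_step: float = 0.1
    rho_threshold: float = 0.85

    # evaluation
    eval_repeats: int = 20
    eval_folds: int = 3
    perm_shuffles: int = 0  # 0 skips the permutation stage

    # panel filter / correlation screen
    auc_threshold: float = 0.7
    spearman_threshold: float = 0.6

    # re-stratification
    misclass_threshold: float = 0.5
    min_models: int = 3

    model_config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        has_paths = any([self.protein_tsv, self.clinical_csv, self.labels_csv])
        if (self.preset is None) == (not has_paths):
            raise ConfigError("supply exactly one of a preset name or the three input paths")
        if has_paths and not all([self.protein_tsv, self.clinical_csv, self.labels_csv]):
            raise ConfigError("all three input paths are required together")
        for name, value, lo, hi in (
            ("min_valid_fraction", self.min_valid_fraction, 0.0, 1.0),
            ("retain_fraction", self.retain_fraction, 0.0, 1.0),
            ("fold_threshold", self.fold_threshold, 0.0, 1.0),
            ("target_fraction", self.target_fraction, 0.0, 1.0),
            ("rho_threshold", self.rho_threshold, 0.0, 1.0),
            ("auc_threshold", self.auc_threshold, 0.0, 1.0),
            ("spearman_threshold", self.spearman_threshold, 0.0, 1.0),
            ("misclass_threshold", self.misclass_threshold, 0.0, 1.0),
        ):
            if not lo <= value <= hi:
                raise ConfigError(f"{name}={value} outside [{lo}, {hi}]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)

    def to_manifest(self) -> dict:
        return {"stratomic_version": __version__, "config": asdict(self)}

    def select_scheme(self) -> CVScheme:
        return CVScheme(self.select_repeats, self.select_folds, seed=self.seed + 11)

    def eval_scheme(self) -> CVScheme:
        return CVScheme(self.eval_repeats, self.eval_folds, seed=self.seed + 23)


def validate_inputs(protein_tsv: str | Path, clinical_csv: str | Path, labels_csv: str | Path) -> dict:
    """Non-mutating dialect and alignment checks on the three input files."""
    problems: list[str] = []
    try:
        proteins = pd.read_csv(protein_tsv, sep="\t", index_col="sample_id")
    except Exception as exc:  # noqa: BLE001 - report, don't crash
        return {"ok": False, "problems": [f"protein TSV unreadable: {exc}"]}
    try:
        clinical = pd.read_csv(clinical_csv, index_col="sample_id")
    except Exception as exc:  # noqa: BLE001
        return {"ok": False, "problems": [f"clinical CSV unreadable: {exc}"]}
    try:
        labels = pd.read_csv(labels_csv, index_col="sample_id")
    except Exception as exc:  # noqa: BLE001
        return {"ok": False, "problems": [f"labels CSV unreadable: {exc}"]}

    sets = {"proteins": set(proteins.index), "clinical": set(clinical.index), "labels": set(labels.index)}
    universe = set.union(*sets.values())
    for name, ids in sets.items():
        extra = sorted(universe - ids)
        if extra:
            problems.append(f"{name} is missing samples {extra}")
    bad_groups = sorted(set(labels.get("group", pd.Series(dtype=str))) - set(GROUPS))
    if bad_groups:
        problems.append(f"unknown group labels {bad_groups}")
    nonpos = proteins.le(0)
    if nonpos.any().any():
        s, p = next(zip(*np.where(nonpos.to_numpy())))
        problems.append(
            f"non-positive raw intensity at sample={proteins.index[s]!r} protein={proteins.columns[p]!r}"
        )
    return {"ok": not problems, "problems": problems}


def _load_bundle(config: RunConfig) -> CohortBundle:
    if config.preset is not None:
        return generate_cohort(preset(config.preset, seed=config.seed + 7))
    report = validate_inputs(config.protein_tsv, config.clinical_csv, config.labels_csv)
    if not report["ok"]:
        raise DataError("input validation failed: " + "; ".join(report["problems"]))
    return CohortBundle(
        ProteinMatrix.from_tsv(config.protein_tsv),
        ClinicalTable.from_csv(config.clinical_csv),
        read_labels(config.labels_csv),
    )


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise DataError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s finished in %.1fs", name, time.perf_counter() - t0)
            return out

        return inner

    return wrap


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage per modality and emit the full report set."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = _stage("load")(_load_bundle)(config)
    groups = bundle.groups

    # -- proteomic preprocessing ----------------------------------------
    def prep_proteins() -> tuple[ProteinMatrix, pd.DataFrame]:
        m = log2_transform(bundle.proteins)
        m, report = filter_valid_fraction(m, config.min_valid_fraction)
        m = impute_downshifted_normal(
            m, config.impute_shift_sd, config.impute_width_sd, seed=config.seed + 101
        )
        m = quantile_normalize(m)
        diffs = run_differential_suite(
            m, groups, n_permutations=config.n_permutations, alpha=config.alpha,
            seed=config.seed + 211,
        )
        tables = []
        for comparison, res in diffs.items():
            t = res.table.copy()
            t.insert(0, "comparison", f"{comparison[0]}_vs_{comparison[1]}")
            t.index.name = "protein"
            tables.append(t.reset_index())
        diff_table = pd.concat(tables, ignore_index=True)
        log.info("filter kept %d / dropped %d proteins", report.n_retained, report.n_dropped)
        return m, diff_table

    normalized, diff_table = _stage("proteomics_prep")(prep_proteins)()
    diff_table.to_csv(out / "differential.csv", index=False)

    # -- clinical preparation -------------------------------------------
    def prep_clinical() -> pd.DataFrame:
        modeling = ClinicalTable(bundle.clinical.modeling_view(),
                                 bundle.clinical.meta.loc[~bundle.clinical.meta["excluded"]])
        imputed = knn_impute(modeling, k=config.knn_k)
        return imputed.data

    clinical_df = _stage("clinical_prep")(prep_clinical)()

    modal_X = {
        "clinical": clinical_df,
        "proteomic": normalized.data,
        "combined": pd.concat([clinical_df, normalized.data], axis=1),
    }

    specs = build_classifiers(config.model_config)
    panels, metric_tables, strat_results, misclass_tables, panel_tables = {}, [], {}, [], []
    for modality in MODALITIES:
        X = modal_X[modality]

        def select():
            return select_consensus_features(
                X,
                groups,
                config.select_scheme(),
                fold_threshold=config.fold_threshold,
                n_bootstrap=config.n_bootstrap,
                target_fraction=config.target_fraction,
                rfe_step=config.rfe_step,
                rho_threshold=config.rho_threshold,
                seed=config.seed + 307,
            )

        panel = _stage(f"select[{modality}]")(select)()
        panels[modality] = panel
        features = panel.features if len(panel) else list(X.columns)
        pt = panel.table.copy()
        pt.insert(0, "modality", modality)
        pt.index.name = "feature"
        panel_tables.append(pt.reset_index())

        def bench():
            return evaluate_models(
                X, groups, features, config.eval_scheme(), specs=specs, seed=config.seed + 401
            )

        report = _stage(f"bench[{modality}]")(bench)()
        t = report.table.copy()
        t.insert(0, "modality", modality)
        metric_tables.append(t)

        def strat():
            m = misclassification_probability(
                X.loc[:, features], groups, config.eval_scheme(), specs=specs,
                modality=modality, seed=config.seed + 503,
            )
            return m, consensus_reassign(m, config.misclass_threshold, config.min_models)

        misclass, result = _stage(f"restratify[{modality}]")(strat)()
        strat_results[modality] = result
        mt = misclass.probabilities.copy()
        mt.insert(0, "modality", modality)
        mt.insert(1, "pre_label", misclass.pre_labels)
        mt.index.name = "sample_id"
        misclass_tables.append(mt.reset_index())

    pd.concat(panel_tables, ignore_index=True).to_csv(out / "feature_panel.csv", index=False)
    pd.concat(metric_tables, ignore_index=True).to_csv(out / "metrics.csv", index=False)
    pd.concat(misclass_tables, ignore_index=True).to_csv(out / "misclass_matrix.csv", index=False)

    strat_table = pd.concat(
        [r.table.assign(modality=m).rename_axis("sample_id").reset_index() for m, r in strat_results.items()],
        ignore_index=True,
    )
    strat_table.to_csv(out / "stratification.csv", index=False)

    comparison = compare_modalities(strat_results)
    comparison["rates"].to_csv(out / "modality_comparison.csv", index=False)

    # -- AUC panel filter on the combined panel's proteomic members ------
    def panel_filter():
        from .stats import filter_panel_by_auc

        candidates = [f for f in panels["combined"].features if f in normalized.data.columns]
        rows = []
        retained: list[str] = []
        if candidates:
            retained, results = filter_panel_by_auc(
                normalized.data, groups, candidates, threshold=config.auc_threshold
            )
            for feat, rocs in results.items():
                for r in rocs:
                    rows.append(
                        {
                            "feature": feat,
                            "comparison": f"{r.comparison[0]}_vs_{r.comparison[1]}",
                            "auc": r.auc,
                            "cutoff": r.cutoff,
                            "sensitivity": r.sensitivity,
                            "specificity": r.specificity,
                            "retained": feat in retained,
                        }
                    )
        pd.DataFrame(
            rows, columns=["feature", "comparison", "auc", "cutoff", "sensitivity", "specificity", "retained"]
        ).to_csv(out / "roc_results.csv", index=False)
        return retained

    retained_panel = _stage("panel_filter")(panel_filter)()

    perm_lines = []
    if config.perm_shuffles > 0:
        def perms():
            X = modal_X["combined"]
            features = panels["combined"].features or list(X.columns)
            rows = []
            for spec in specs:
                r = permutation_test(
                    X.loc[:, features], groups, spec,
                    CVScheme(1, config.eval_folds, seed=config.seed + 601),
                    n_shuffles=config.perm_shuffles, seed=config.seed + 601,
                )
                rows.append(
                    {"model": spec.name, "observed_auc": r.observed_auc,
                     "mean_null_auc": r.mean_null_auc, "p_value": r.p_value}
                )
            return pd.DataFrame(rows)

        perm_table = _stage("permutation")(perms)()
        perm_table.to_csv(out / "permutation.csv", index=False)
        perm_lines = [
            f"  {row.model}: observed AUC {row.observed_auc:.3f}, "
            f"mean null {row.mean_null_auc:.3f}, p {row.p_value:.4g}"
            for row in perm_table.itertuples()
        ]

    manifest = config.to_manifest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    lines = [
        f"stratomic {__version__} run summary",
        f"samples: {len(groups)}  groups: " + ", ".join(
            f"{g}={int((groups == g).sum())}" for g in GROUPS if (groups == g).any()
        ),
        f"proteins after filtering: {normalized.n_proteins}",
        "",
        "panel sizes: " + ", ".join(f"{m}={len(panels[m])}" for m in MODALITIES),
        "AUC-filtered proteomic panel: " + (", ".join(retained_panel) if retained_panel else "(none)"),
        "",
        "misclassification rates (% reassigned):",
    ]
    for m in MODALITIES:
        lines.append(f"  {m}: {strat_results[m].misclassification_rate:.2f}%")
    if perm_lines:
        lines += ["", "permutation tests (combined modality):"] + perm_lines
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    return out


def run_from_manifest(manifest_path: str | Path, out_dir: str | Path) -> Path:
    """Reproduce a finished run from its manifest alone."""
    payload = json.loads(Path(manifest_path).read_text())
    config = RunConfig(**{**payload["config"], "out_dir": str(out_dir)})
    return run_pipeline(config)
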