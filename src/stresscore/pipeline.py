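"""End-to-end orchestration: simulate -> preprocess -> set operations ->
random forest -> coexpression -> enrichment -> regulatory network.

Every stochastic stage is seeded from the single master seed via fixed
spawn keys, so one (config, seed) pair reproduces the whole analysis
byte-for-byte.  The final product is a core-gene report in the three-row
layout (set operations / random forest / combined, each split into
up / down / no-differential-expression counts) plus per-stage tables and
a checksum manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import coexpression as coex
from . import enrichment as enr
from . import grn as grn_mod
from . import prep, rf, setops
from .datatypes import (
    ExpressionMatrix,
    GeneSetCollection,
    SampleMetadata,
    ValidationError,
)
from .simulate import (
    SimulationConfig,
    TruthSet,
    config_from_dict,
    simulate_annotations,
    simulate_dataset,
)


def _derive_seed(master: int, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=master, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Master configuration: nested per-stage configs plus stage toggles."""

    out_dir: str = "stresscore_out"
    seed: int = 7
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    setops: setops.SetOpsConfig = field(default_factory=setops.SetOpsConfig)
    rf: rf.RFConfig | None = None
    coexpression: coex.CoexpressionConfig = field(
        default_factory=coex.CoexpressionConfig
    )
    grn: grn_mod.GRNConfig | None = None
    run_rf: bool = True
    run_coexpression: bool = True
    run_enrichment: bool = True
    run_grn: bool = True
    run_feature_curve: bool = False
    rf_top_n: int = 500  # desk-scale top-N for the per-model importance lists
    grn_background_targets: int = 300
    grn_dunnett_reps: int = 2000
    de_alpha: float = 0.05
    annotation_kwargs: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "simulation" in kwargs:
            kwargs["simulation"] = config_from_dict(kwargs["simulation"])
        if "setops" in kwargs:
            kwargs["setops"] = setops.SetOpsConfig(**kwargs["setops"])
        if "rf" in kwargs and kwargs["rf"] is not None:
            kwargs["rf"] = rf.RFConfig(**kwargs["rf"])
        if "coexpression" in kwargs:
            kwargs["coexpression"] = coex.CoexpressionConfig(**kwargs["coexpression"])
        if "grn" in kwargs and kwargs["grn"] is not None:
            kwargs["grn"] = grn_mod.GRNConfig(**kwargs["grn"])
        return cls(**kwargs)


@dataclass
class PipelineResult:
    """In-memory handles on every stage output plus the JSON-ready report."""

    matrix_tpm: ExpressionMatrix
    matrix_corrected: ExpressionMatrix
    metadata: SampleMetadata
    truth: TruthSet
    calls: setops.ResponseCalls
    setops_sets: GeneSetCollection
    de_flags: pd.Series
    rf_reports: list[rf.ModelReport]
    rf_core: frozenset[str]
    coexpression: dict | None
    enrichment_tables: dict[str, pd.DataFrame]
    grn_tables: dict[str, pd.DataFrame]
    report: dict
    out_dir: Path


def combine_core_sets(
    setops_sets: GeneSetCollection,
    rf_core: frozenset[str],
    de_flags: pd.Series,
    calls: setops.ResponseCalls,
) -> dict:
    """Merge set-operations and random-forest core sets with direction labels.

    Directions for RF-only genes follow the majority of their
    per-experiment TN-ratio calls (ties put the gene in both lists);
    RF genes never flagged as differentially expressed go to the
    no-differential-expression column.  The combined set is the plain
    union of the two methods' core sets.
    """
    universe = set(calls.ratios.index)
    so_core = set(setops_sets.core_up) | set(setops_sets.core_down)
    outside = (so_core | set(rf_core)) - universe
    if outside:
        raise ValidationError(
            f"core genes outside the calls' gene universe: {sorted(outside)[:10]}"
        )
    call_df = calls.calls()
    n_up = (call_df == "up").sum(axis=1)
    n_down = (call_df == "down").sum(axis=1)

    def classify_rf(genes: set[str]) -> tuple[set[str], set[str], set[str]]:
        up, down, node = set(), set(), set()
        for g in genes:
            if not bool(de_flags.get(g, False)):
                node.add(g)
            elif n_up[g] > n_down[g]:
                up.add(g)
            elif n_down[g] > n_up[g]:
                down.add(g)
            else:  # tie: differentially expressed in both directions
                up.add(g)
                down.add(g)
        return up, down, node

    rf_up, rf_down, rf_node = classify_rf(set(rf_core))
    rf_only = set(rf_core) - so_core
    rfo_up, rfo_down, rfo_node = classify_rf(rf_only)

    combined_up = set(setops_sets.core_up) | rfo_up
    combined_down = set(setops_sets.core_down) | rfo_down
    combined_node = rfo_node
    combined_total = so_core | set(rf_core)

    def entry(up, down, node, total):
        return {
            "up": sorted(up),
            "down": sorted(down),
            "no_de": sorted(node),
            "n_up": len(up),
            "n_down": len(down),
            "n_no_de": len(node),
            "n_total": len(total),
        }

    return {
        "set_operations": entry(
            setops_sets.core_up, setops_sets.core_down, set(), so_core
        ),
        "random_forest": entry(rf_up, rf_down, rf_node, set(rf_core)),
        "combined": entry(combined_up, combined_down, combined_node, combined_total),
    }


def _truth_recovery(setops_sets: GeneSetCollection, truth: TruthSet) -> dict:
    found = set(setops_sets.core_up) | set(setops_sets.core_down)
    planted = set(truth.core)
    correct_direction = len(set(setops_sets.core_up) & truth.core_up) + len(
        set(setops_sets.core_down) & truth.core_down
    )
    recall = correct_direction / len(planted) if planted else float("nan")
    fp = len(found - planted) / len(found) if found else 0.0
    return {
        "n_planted_core": len(planted),
        "n_reported_core": len(found),
        "recall": recall,
        "false_positive_fraction": fp,
    }


def _write_tsv(path: Path, df: pd.DataFrame, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute all enabled stages in dependency order and write outputs."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed, "stages": []}
    files: dict[str, Path] = {}

    # --- simulate -----------------------------------------------------
    matrix_tpm, metadata, truth = simulate_dataset(cfg.simulation)
    report["stages"].append("simulate")
    report["n_genes"] = matrix_tpm.n_genes
    report["n_samples"] = matrix_tpm.n_samples

    # --- preprocess ---------------------------------------------------
    filtered = prep.filter_zero_variance(matrix_tpm)
    logged = prep.log2p1_transform(filtered)
    corrected = prep.combat_correct(logged, metadata)
    scores, var_exp = prep.pca_overview(corrected, n_components=2)
    report["stages"].append("preprocess")
    report["pca_variance_explained"] = [float(v) for v in var_exp]
    files["pca_scores.tsv"] = out_dir / "pca_scores.tsv"
    _write_tsv(files["pca_scores.tsv"], scores.rename_axis("sample"), index=True)

    # --- set operations (raw TPM, per batch) --------------------------
    contrasts = setops.contrasts_from_metadata(metadata)
    calls = setops.call_experiment_responses(filtered, contrasts, cfg.setops)
    union_up, union_down = setops.stressor_unions(calls, metadata)
    so_sets = setops.derive_core_and_specific(union_up, union_down)
    de_flags = setops.simple_de_flag(filtered, contrasts, alpha=cfg.de_alpha)
    report["stages"].append("setops")
    report["setops"] = {
        "core_up": sorted(so_sets.core_up),
        "core_down": sorted(so_sets.core_down),
        "n_specific": {
            s: {
                "up": len(so_sets.specific_up[s]),
                "down": len(so_sets.specific_down[s]),
            }
            for s in sorted(so_sets.specific_up)
        },
    }
    report["truth_recovery"] = _truth_recovery(so_sets, truth)
    files["gene_sets.tsv"] = out_dir / "gene_sets.tsv"
    set_rows = [("core_up", g) for g in sorted(so_sets.core_up)]
    set_rows += [("core_down", g) for g in sorted(so_sets.core_down)]
    for s in sorted(so_sets.specific_up):
        set_rows += [(f"specific_up:{s}", g) for g in sorted(so_sets.specific_up[s])]
        set_rows += [
            (f"specific_down:{s}", g) for g in sorted(so_sets.specific_down[s])
        ]
    _write_tsv(files["gene_sets.tsv"], pd.DataFrame(set_rows, columns=["set", "gene"]))

    # --- random forest ------------------------------------------------
    rf_reports: list[rf.ModelReport] = []
    rf_core: frozenset[str] = frozenset()
    if cfg.run_rf:
        rf_cfg = cfg.rf or rf.RFConfig(
            top_n=min(cfg.rf_top_n, corrected.n_genes),
            seed=_derive_seed(cfg.seed, 1),
        )
        splits = rf.make_holdout_splits(metadata)
        for i, split in enumerate(splits):
            rep = rf.train_and_tune(split, corrected, metadata, rf_cfg, split_index=i)
            if cfg.run_feature_curve:
                rep.curve = rf.feature_selection_curve(
                    split,
                    corrected,
                    metadata,
                    rf_cfg,
                    rep.importances,
                    best_params=rep.best_params,
                    split_index=i,
                )
            rf_reports.append(rep)
        rf_core = rf.rf_core_genes(rf_reports, rf_cfg.top_n)
        report["stages"].append("rf")
        report["rf"] = {
            "top_n": rf_cfg.top_n,
            "models": [
                {
                    "held_out": r.split,
                    "accuracy": r.accuracy,
                    "auc": r.auc,
                    "f1": r.f1,
                    "best_params": {k: str(v) for k, v in sorted(r.best_params.items())},
                }
                for r in rf_reports
            ],
            "n_core": len(rf_core),
        }
        imp_rows = []
        for r in rf_reports:
            ranked = r.importances.sort_values(ascending=False)
            imp_rows.append(
                pd.DataFrame(
                    {
                        "split": r.split,
                        "gene": ranked.index[: rf_cfg.top_n],
                        "importance": ranked.to_numpy()[: rf_cfg.top_n],
                        "rank": np.arange(1, min(rf_cfg.top_n, len(ranked)) + 1),
                    }
                )
            )
        files["rf_importances.tsv"] = out_dir / "rf_importances.tsv"
        _write_tsv(files["rf_importances.tsv"], pd.concat(imp_rows, ignore_index=True))

    # --- combined core report -----------------------------------------
    if cfg.run_rf:
        report["core_genes"] = combine_core_sets(so_sets, rf_core, de_flags, calls)

    # --- coexpression -------------------------------------------------
    coex_result: dict | None = None
    if cfg.run_coexpression:
        sd = corrected.values.to_numpy().std(axis=1)
        net_input = ExpressionMatrix(
            corrected.values.loc[sd > 0], scale_tag="batch_corrected"
        )
        coex_result = coex.build_network(net_input, cfg.coexpression)
        assignment = coex_result["assignment"]
        report["stages"].append("coexpression")
        sizes = assignment.value_counts().to_dict()
        report["coexpression"] = {
            "n_modules": len(set(assignment) - {coex.UNASSIGNED}),
            "module_sizes": {str(k): int(v) for k, v in sorted(sizes.items())},
            "n_hubs": len(coex_result["hubs"]),
            "hub_threshold": float(coex_result["hub_threshold"]),
        }
        files["modules.tsv"] = out_dir / "modules.tsv"
        _write_tsv(
            files["modules.tsv"],
            assignment.rename("module").rename_axis("gene").reset_index(),
        )

    # --- enrichment ---------------------------------------------------
    enrichment_tables: dict[str, pd.DataFrame] = {}
    annotation = None
    if cfg.run_enrichment:
        universe = list(filtered.gene_ids)
        ann_seed = _derive_seed(cfg.seed, 2)
        annotation = simulate_annotations(
            truth, universe, seed=ann_seed, **cfg.annotation_kwargs
        )
        universe_set = set(universe)
        tf_genes = set(annotation.tf_genes())
        core_sets = {
            "setops_up": set(so_sets.core_up),
            "setops_down": set(so_sets.core_down),
        }
        if cfg.run_rf:
            cc = report["core_genes"]
            core_sets.update(
                {
                    "rf_up": set(cc["random_forest"]["up"]),
                    "rf_down": set(cc["random_forest"]["down"]),
                    "combined_up": set(cc["combined"]["up"]),
                    "combined_down": set(cc["combined"]["down"]),
                }
            )
        core_sets = {k: v for k, v in core_sets.items() if v}
        if core_sets:
            enrichment_tables["tf_overall"] = enr.enrichment_table(
                core_sets, {"TF": tf_genes}, universe_set
            )
            fam_sets = {
                f: set(g) for f, g in annotation.family_to_genes().items()
            }
            fam_queries = {
                k: core_sets[k]
                for k in ("combined_up", "combined_down")
                if k in core_sets
            } or core_sets
            enrichment_tables["tf_families"] = enr.enrichment_table(
                fam_queries, fam_sets, universe_set
            )
            enrichment_tables["terms"] = enr.enrichment_table(
                core_sets, {t: set(g) for t, g in annotation.term_to_genes.items()},
                universe_set,
            )
        if coex_result is not None and coex_result["kme"] is not None:
            assignment = coex_result["assignment"]
            module_sets = {
                str(mod): set(assignment.index[assignment == mod])
                for mod in sorted(set(assignment) - {coex.UNASSIGNED})
            }
            query_sets = dict(core_sets)
            for s in sorted(so_sets.specific_up):
                if so_sets.specific_up[s]:
                    query_sets[f"specific_up:{s}"] = set(so_sets.specific_up[s])
                if so_sets.specific_down[s]:
                    query_sets[f"specific_down:{s}"] = set(so_sets.specific_down[s])
            if module_sets and query_sets:
                enrichment_tables["modules"] = enr.enrichment_table(
                    query_sets, module_sets, universe_set
                )
            core_all = set(so_sets.core_up) | set(so_sets.core_down) | set(rf_core)
            if core_all and coex_result["hubs"]:
                res = enr.hub_core_overlap_test(
                    set(coex_result["hubs"]), core_all, universe_set
                )
                report["hub_core_overlap"] = {
                    "overlap": res.a,
                    "p_value": res.p_value,
                }
        report["stages"].append("enrichment")
        for name, table in enrichment_tables.items():
            files[f"enrichment_{name}.tsv"] = out_dir / f"enrichment_{name}.tsv"
            _write_tsv(files[f"enrichment_{name}.tsv"], table)

    # --- regulatory network -------------------------------------------
    grn_tables: dict[str, pd.DataFrame] = {}
    if cfg.run_grn and cfg.run_enrichment and annotation is not None:
        grn_seed = _derive_seed(cfg.seed, 3)
        tf_genes = sorted(set(annotation.tf_genes()) & set(corrected.gene_ids))
        # core TFs from enriched / near-enriched families, orphan-style
        # blocklists excluded upstream by the annotation simulation
        interest = set()
        if "tf_families" in enrichment_tables:
            tab = enrichment_tables["tf_families"]
            fams = set(
                tab.loc[tab["tier"].isin([enr.TIER_ENRICHED, enr.TIER_NEAR]), "annotation"]
            )
            combined_core = set()
            if cfg.run_rf:
                combined_core = set(report["core_genes"]["combined"]["up"]) | set(
                    report["core_genes"]["combined"]["down"]
                )
            else:
                combined_core = set(so_sets.core_up) | set(so_sets.core_down)
            fam_map = annotation.family_to_genes()
            for fam in fams:
                interest |= set(fam_map.get(fam, frozenset())) & combined_core
        if not interest:
            warnings.warn(
                "no core TFs from enriched families; falling back to all core TFs"
            )
            core_all = set(so_sets.core_up) | set(so_sets.core_down) | set(rf_core)
            interest = core_all & set(tf_genes)
        interest &= set(tf_genes)
        if len(interest) == 0 or len(tf_genes) < 2:
            warnings.warn("regulatory-network stage skipped: no usable regulators")
        else:
            core_all = set(so_sets.core_up) | set(so_sets.core_down) | set(rf_core)
            groups = pd.Series(dtype=object)
            target_list: list[str] = []
            labels: dict[str, str] = {}
            for g in sorted(core_all):
                labels[g] = "core"
            for s in sorted(so_sets.specific_up):
                for g in sorted(
                    set(so_sets.specific_up[s]) | set(so_sets.specific_down[s])
                ):
                    labels.setdefault(g, f"specific:{s}")
            rng = np.random.default_rng(_derive_seed(cfg.seed, 4))
            background = sorted(
                set(corrected.gene_ids) - set(labels) - set(tf_genes)
            )
            n_bg = min(cfg.grn_background_targets, len(background))
            for g in rng.choice(background, size=n_bg, replace=False):
                labels[str(g)] = "other"
            target_list = sorted(set(labels) & set(corrected.gene_ids))
            groups = pd.Series({g: labels[g] for g in target_list})

            grn_cfg = cfg.grn or grn_mod.GRNConfig(
                seed=grn_seed, dunnett_reps=cfg.grn_dunnett_reps
            )
            edges = grn_mod.genie3_weights(
                corrected,
                regulators=tf_genes,
                targets=target_list,
                n_trees=grn_cfg.n_trees,
                max_features=grn_cfg.max_features,
                seed=grn_seed,
            )
            mean_w = grn_mod.mean_regulator_weight(edges, interest)
            comparison = grn_mod.compare_target_groups(
                mean_w, groups, control_label="other", cfg=grn_cfg
            )
            grn_tables["dunnett"] = comparison
            mean_table = pd.DataFrame(
                {
                    "target": mean_w.index,
                    "group": groups.reindex(mean_w.index).to_numpy(),
                    "mean_weight": mean_w.to_numpy(),
                }
            )
            grn_tables["mean_weights"] = mean_table
            report["stages"].append("grn")
            report["grn"] = {
                "n_regulators": len(tf_genes),
                "n_regulators_of_interest": len(interest),
                "n_targets": len(target_list),
                "comparisons": json.loads(
                    comparison.round(10).to_json(orient="records")
                ),
            }
            files["grn_dunnett.tsv"] = out_dir / "grn_dunnett.tsv"
            _write_tsv(files["grn_dunnett.tsv"], comparison)
            files["grn_mean_weights.tsv"] = out_dir / "grn_mean_weights.tsv"
            _write_tsv(files["grn_mean_weights.tsv"], mean_table)

    # --- report + manifest --------------------------------------------
    report_path = out_dir / "report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")
    files["report.json"] = report_path
    manifest = {
        name: hashlib.sha256(path.read_bytes()).hexdigest()
        for name, path in sorted(files.items())
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(
            {"seed": cfg.seed, "files": manifest}, fh, indent=2, sort_keys=True
        )
        fh.write("\n")

    return PipelineResult(
        matrix_tpm=filtered,
        matrix_corrected=corrected,
        metadata=metadata,
        truth=truth,
        calls=calls,
        setops_sets=so_sets,
        de_flags=de_flags,
        rf_reports=rf_reports,
        rf_core=rf_core,
        coexpression=coex_result,
        enrichment_tables=enrichment_tables,
        grn_tables=grn_tables,
        report=report,
        out_dir=out_dir,
    )
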