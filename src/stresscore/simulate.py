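"""Synthetic multi-stressor, multi-batch expression data with planted truth.

The generator emulates the statistical structure of a meta-analysis corpus
of stress/control RNA-seq experiments: six abiotic stressors, several
independent batches (BioProject analogues) per stressor, each batch
carrying its own control group, per-batch location/scale effects on the
log scale, and three planted gene classes — *core* genes responsive (in a
consistent direction) under every stressor, *stress-specific* genes
responsive under exactly one, and *null* genes.

Expression is log-normal: a gene's log2 abundance is its baseline plus
treatment effect plus batch offset plus scaled noise, exponentiated to a
TPM-like non-negative scale.  A log-normal model (rather than counts) is
used because every downstream consumer works on log2(x+1) values and the
batch model is location/scale — exactly what empirical-Bayes batch
correction removes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    ConfigurationError,
    ExpressionMatrix,
    GeneAnnotation,
    SampleMetadata,
    ValidationError,
)

DEFAULT_STRESSORS = ("cold", "drought", "flooding", "heat", "low_nitrogen", "salt")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study design.

    Defaults describe the package's standard desk-scale conditions:
    2,000 genes, six stressors with two batches each, four replicates per
    group, 30/20 planted core up/down genes with an 8-fold effect and
    15/15 stress-specific genes per stressor.
    """

    n_genes: int = 2000
    n_stressors: int = 6
    stressor_names: tuple[str, ...] = DEFAULT_STRESSORS
    batches_per_stressor: int = 2
    replicates_per_group: int = 4
    n_core_up: int = 30
    n_core_down: int = 20
    n_specific_up: int = 15
    n_specific_down: int = 15
    core_effect: float = 8.0
    specific_effect: float = 8.0
    batch_location_sd: float = 1.0
    batch_scale_sd: float = 0.15
    baseline_log_mean_range: tuple[float, float] = (2.0, 8.0)
    noise_sd: float = 0.25
    n_mixed_direction: int = 0
    seed: int = 7

    def __post_init__(self) -> None:
        self.stressor_names = tuple(self.stressor_names)
        if self.n_stressors != len(self.stressor_names):
            raise ConfigurationError(
                f"n_stressors={self.n_stressors} but {len(self.stressor_names)} "
                "stressor names given"
            )
        counts = {
            "n_genes": self.n_genes,
            "batches_per_stressor": self.batches_per_stressor,
            "replicates_per_group": self.replicates_per_group,
        }
        for name, v in counts.items():
            if v < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {v}")
        for name in (
            "n_core_up",
            "n_core_down",
            "n_specific_up",
            "n_specific_down",
            "n_mixed_direction",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        planted = (
            self.n_core_up
            + self.n_core_down
            + self.n_mixed_direction
            + self.n_stressors * (self.n_specific_up + self.n_specific_down)
        )
        if planted > self.n_genes:
            raise ConfigurationError(
                f"planted genes ({planted}) exceed n_genes ({self.n_genes})"
            )
        if self.core_effect <= 1 or self.specific_effect <= 1:
            raise ConfigurationError("core_effect and specific_effect must be > 1")
        if self.noise_sd < 0 or self.batch_location_sd < 0 or self.batch_scale_sd < 0:
            raise ConfigurationError("noise/batch effect magnitudes must be >= 0")
        lo, hi = self.baseline_log_mean_range
        if not lo <= hi:
            raise ConfigurationError("baseline_log_mean_range must be (lo, hi) with lo <= hi")

    @property
    def n_samples(self) -> int:
        return (
            self.n_stressors
            * self.batches_per_stressor
            * 2
            * self.replicates_per_group
        )


@dataclass
class TruthSet:
    """Ground-truth planted gene classes for downstream recovery checks."""

    core_up: frozenset[str]
    core_down: frozenset[str]
    specific_up: dict[str, frozenset[str]]
    specific_down: dict[str, frozenset[str]]
    null_genes: frozenset[str]
    mixed_direction: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        groups = [self.core_up, self.core_down, self.mixed_direction, self.null_genes]
        groups += list(self.specific_up.values()) + list(self.specific_down.values())
        total = sum(len(g) for g in groups)
        union: set[str] = set()
        for g in groups:
            union |= g
        if len(union) != total:
            raise ValidationError("truth-set categories must be pairwise disjoint")

    @property
    def core(self) -> frozenset[str]:
        return self.core_up | self.core_down

    @property
    def all_specific(self) -> frozenset[str]:
        out: set[str] = set()
        for d in (self.specific_up, self.specific_down):
            for s in d.values():
                out |= s
        return frozenset(out)


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"g{i:0{width}d}" for i in range(n)]


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, SampleMetadata, TruthSet]:
    """Draw a full synthetic expression study from ``config``.

    Returns a TPM-scale :class:`ExpressionMatrix` of shape
    ``n_genes x n_samples``, the matching :class:`SampleMetadata` and the
    planted :class:`TruthSet`.  Bitwise reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    order = rng.permutation(config.n_genes)

    # assign planted classes from a random permutation of gene indices
    cursor = 0

    def take(n: int) -> list[int]:
        nonlocal cursor
        idx = order[cursor : cursor + n]
        cursor += n
        return list(idx)

    core_up_idx = take(config.n_core_up)
    core_down_idx = take(config.n_core_down)
    mixed_idx = take(config.n_mixed_direction)
    spec_up_idx = {s: take(config.n_specific_up) for s in config.stressor_names}
    spec_down_idx = {s: take(config.n_specific_down) for s in config.stressor_names}

    lo, hi = config.baseline_log_mean_range
    baseline = rng.uniform(lo, hi, size=config.n_genes)

    # per-gene, per-stressor log2 treatment effect
    effect = np.zeros((config.n_genes, config.n_stressors))
    log_core = np.log2(config.core_effect)
    log_spec = np.log2(config.specific_effect)
    effect[core_up_idx, :] = log_core
    effect[core_down_idx, :] = -log_core
    for j, s in enumerate(config.stressor_names):
        effect[spec_up_idx[s], j] = log_spec
        effect[spec_down_idx[s], j] = -log_spec
    if mixed_idx:
        signs = rng.choice([-1.0, 1.0], size=(len(mixed_idx), config.n_stressors))
        effect[mixed_idx, :] = signs * log_core

    columns: list[str] = []
    meta_rows: list[dict[str, str]] = []
    blocks: list[np.ndarray] = []
    for s_idx, stressor in enumerate(config.stressor_names):
        for b in range(config.batches_per_stressor):
            batch_id = f"BP_{stressor}_{b + 1}"
            loc = rng.normal(0.0, config.batch_location_sd, size=config.n_genes)
            scale = rng.lognormal(0.0, config.batch_scale_sd, size=config.n_genes)
            for treatment in ("control", "stress"):
                shift = effect[:, s_idx] if treatment == "stress" else 0.0
                for r in range(config.replicates_per_group):
                    eps = rng.normal(0.0, config.noise_sd, size=config.n_genes)
                    logx = baseline + shift + loc + scale * eps
                    blocks.append(np.exp2(logx))
                    sample = f"{stressor}_b{b + 1}_{treatment}_{r + 1}"
                    columns.append(sample)
                    meta_rows.append(
                        {
                            "sample": sample,
                            "batch": batch_id,
                            "stressor": stressor,
                            "treatment": treatment,
                            "tissue": "leaf",
                            "genotype": "B73",
                        }
                    )

    values = pd.DataFrame(
        np.column_stack(blocks), index=genes, columns=columns
    )
    matrix = ExpressionMatrix(values, scale_tag="tpm")
    meta = pd.DataFrame(meta_rows).set_index("sample")
    metadata = SampleMetadata(meta)

    planted = set(core_up_idx) | set(core_down_idx) | set(mixed_idx)
    for s in config.stressor_names:
        planted |= set(spec_up_idx[s]) | set(spec_down_idx[s])
    null_idx = [i for i in range(config.n_genes) if i not in planted]
    truth = TruthSet(
        core_up=frozenset(genes[i] for i in core_up_idx),
        core_down=frozenset(genes[i] for i in core_down_idx),
        specific_up={
            s: frozenset(genes[i] for i in spec_up_idx[s]) for s in config.stressor_names
        },
        specific_down={
            s: frozenset(genes[i] for i in spec_down_idx[s])
            for s in config.stressor_names
        },
        null_genes=frozenset(genes[i] for i in null_idx),
        mixed_direction=frozenset(genes[i] for i in mixed_idx),
    )
    return matrix, metadata, truth


def simulate_annotations(
    truth: TruthSet,
    universe: list[str],
    n_families: int = 8,
    n_terms: int = 40,
    enrichment_factor: float = 8.0,
    seed: int = 0,
    family_base_rate: float = 0.008,
    term_base_rate: float = 0.04,
    n_enriched_families: int = 2,
    n_enriched_terms: int = 2,
) -> GeneAnnotation:
    """Generate TF-family and term annotations with planted core-gene enrichment.

    The first ``n_enriched_families`` families (``FAM_00`` ...) and the
    first ``n_enriched_terms`` terms are over-represented among core genes
    by ``enrichment_factor`` relative to null genes; all other assignments
    are uniform.  Each gene belongs to at most one TF family; terms may
    overlap freely.
    """
    if enrichment_factor < 1:
        raise ConfigurationError("enrichment_factor must be >= 1")
    universe_set = set(universe)
    declared = truth.core | truth.all_specific | truth.null_genes | truth.mixed_direction
    missing = sorted(declared - universe_set)
    if missing:
        raise ValidationError(f"truth genes absent from universe: {missing[:10]}")

    rng = np.random.default_rng(seed)
    core = truth.core
    families = [f"FAM_{i:02d}" for i in range(n_families)]
    enriched_families = set(families[:n_enriched_families])

    tf_family: dict[str, str] = {}
    for gene in universe:
        rates = np.full(n_families, family_base_rate)
        if gene in core:
            for i, fam in enumerate(families):
                if fam in enriched_families:
                    rates[i] *= enrichment_factor
        total = rates.sum()
        if total > 0.95:  # keep a residual "no family" mass
            rates = rates * (0.95 / total)
            total = 0.95
        u = rng.uniform()
        acc = 0.0
        for i, fam in enumerate(families):
            acc += rates[i]
            if u < acc:
                tf_family[gene] = fam
                break

    terms = [f"TERM_{i:03d}" for i in range(n_terms)]
    enriched_terms = set(terms[:n_enriched_terms])
    term_to_genes: dict[str, frozenset[str]] = {}
    core_arr = np.fromiter((g in core for g in universe), bool, count=len(universe))
    for term in terms:
        rate = np.full(len(universe), term_base_rate)
        if term in enriched_terms:
            rate[core_arr] = np.minimum(1.0, term_base_rate * enrichment_factor)
        mask = rng.uniform(size=len(universe)) < rate
        term_to_genes[term] = frozenset(g for g, m in zip(universe, mask) if m)

    return GeneAnnotation(tf_family=tf_family, term_to_genes=term_to_genes)


def write_dataset(
    outdir: str | Path,
    matrix: ExpressionMatrix,
    metadata: SampleMetadata,
    truth: TruthSet | None = None,
    annotation: GeneAnnotation | None = None,
) -> dict[str, Path]:
    """Write expression/metadata (and optionally truth/annotation) TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    expr_path = outdir / "expression.tsv"
    matrix.values.rename_axis("gene").to_csv(expr_path, sep="\t")
    written["expression"] = expr_path

    meta_path = outdir / "metadata.tsv"
    metadata.table.rename_axis("sample").to_csv(meta_path, sep="\t")
    written["metadata"] = meta_path

    if truth is not None:
        rows = []
        for g in sorted(truth.core_up):
            rows.append((g, "core_up", ""))
        for g in sorted(truth.core_down):
            rows.append((g, "core_down", ""))
        for s in sorted(truth.specific_up):
            rows.extend((g, "specific_up", s) for g in sorted(truth.specific_up[s]))
        for s in sorted(truth.specific_down):
            rows.extend((g, "specific_down", s) for g in sorted(truth.specific_down[s]))
        for g in sorted(truth.mixed_direction):
            rows.append((g, "mixed_direction", ""))
        for g in sorted(truth.null_genes):
            rows.append((g, "null", ""))
        truth_path = outdir / "truth.tsv"
        pd.DataFrame(rows, columns=["gene", "category", "stressor"]).to_csv(
            truth_path, sep="\t", index=False
        )
        written["truth"] = truth_path

    if annotation is not None:
        fam_path = outdir / "tf_families.tsv"
        pd.DataFrame(
            sorted(annotation.tf_family.items()), columns=["gene", "family"]
        ).to_csv(fam_path, sep="\t", index=False)
        written["tf_families"] = fam_path
        term_rows = [
            (term, g)
            for term in sorted(annotation.term_to_genes)
            for g in sorted(annotation.term_to_genes[term])
        ]
        term_path = outdir / "term_to_gene.tsv"
        pd.DataFrame(term_rows, columns=["term", "gene"]).to_csv(
            term_path, sep="\t", index=False
        )
        written["terms"] = term_path
        if annotation.term_parents:
            par_rows = [
                (t, p)
                for t in sorted(annotation.term_parents)
                for p in annotation.term_parents[t]
            ]
            par_path = outdir / "term_parents.tsv"
            pd.DataFrame(par_rows, columns=["term", "parent"]).to_csv(
                par_path, sep="\t", index=False
            )
            written["term_parents"] = par_path
    return written


def config_from_dict(d: dict) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a plain (e.g. YAML) mapping."""
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(d) - known
    if unknown:
        raise ConfigurationError(f"unknown simulation keys: {sorted(unknown)}")
    d = dict(d)
    if "stressor_names" in d:
        d["stressor_names"] = tuple(d["stressor_names"])
        d.setdefault("n_stressors", len(d["stressor_names"]))
    if "baseline_log_mean_range" in d:
        d["baseline_log_mean_range"] = tuple(d["baseline_log_mean_range"])
    return SimulationConfig(**d)
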