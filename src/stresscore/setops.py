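"""TN-ratio response calls and core / stress-specific gene set operations.

The TN-ratio of a gene in one experiment (batch) is the pseudocounted
ratio of mean stress-treated to mean control expression,
``(T + 1) / (N + 1)`` by default, computed on raw TPM *within* each batch
so that cross-batch effects cancel.  Genes with a TN-ratio strictly above
2 are called up, strictly below 0.5 down.  Per-stressor unions of the
per-experiment calls are intersected across all stressors to give the
core sets; genes responsive in exactly one stressor (across both
directions' unions) form that stressor's specific sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    ConfigurationError,
    ExperimentContrast,
    ExpressionMatrix,
    GeneSetCollection,
    SampleMetadata,
    ValidationError,
)


@dataclass(frozen=True)
class SetOpsConfig:
    up_threshold: float = 2.0
    down_threshold: float = 0.5
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if not (self.up_threshold > 1 > self.down_threshold > 0):
            raise ConfigurationError(
                "thresholds must satisfy up_threshold > 1 > down_threshold > 0"
            )
        if self.pseudocount <= 0:
            raise ConfigurationError("pseudocount must be > 0")


def tn_ratio(mean_stress_tpm, mean_control_tpm, pseudocount: float = 1.0):
    """(T + c) / (N + c) for non-negative mean expression values.

    Accepts scalars or arrays; strictly positive for finite inputs.
    """
    t = np.asarray(mean_stress_tpm, dtype=float)
    n = np.asarray(mean_control_tpm, dtype=float)
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(n))):
        raise ValueError("TN-ratio inputs must be finite")
    if np.any(t < 0) or np.any(n < 0):
        raise ValueError("TN-ratio inputs must be non-negative")
    out = (t + pseudocount) / (n + pseudocount)
    return out.item() if out.ndim == 0 else out


@dataclass
class ResponseCalls:
    """Per-(experiment, gene) TN-ratios and up/down/none calls."""

    ratios: pd.DataFrame  # genes x experiment keys
    contrasts: dict[str, ExperimentContrast]
    config: SetOpsConfig = field(default_factory=SetOpsConfig)

    def calls(self) -> pd.DataFrame:
        out = pd.DataFrame("none", index=self.ratios.index, columns=self.ratios.columns)
        out = out.mask(self.ratios > self.config.up_threshold, "up")
        out = out.mask(self.ratios < self.config.down_threshold, "down")
        return out

    def up_genes(self, experiment: str) -> frozenset[str]:
        col = self.ratios[experiment]
        return frozenset(col.index[col > self.config.up_threshold])

    def down_genes(self, experiment: str) -> frozenset[str]:
        col = self.ratios[experiment]
        return frozenset(col.index[col < self.config.down_threshold])

    def to_long(self) -> pd.DataFrame:
        calls = self.calls()
        rows = []
        for exp in self.ratios.columns:
            rows.append(
                pd.DataFrame(
                    {
                        "experiment": exp,
                        "gene": self.ratios.index,
                        "tn_ratio": self.ratios[exp].to_numpy(),
                        "call": calls[exp].to_numpy(),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def contrasts_from_metadata(meta: SampleMetadata) -> list[ExperimentContrast]:
    """One stress-vs-control contrast per (batch, stressor) pair."""
    out = []
    table = meta.table
    for batch in pd.unique(table["batch"]):
        sub = table[table["batch"] == batch]
        controls = tuple(sub.index[sub["treatment"] == "control"])
        for stressor in pd.unique(
            sub.loc[sub["treatment"] == "stress", "stressor"]
        ):
            stressed = tuple(
                sub.index[(sub["treatment"] == "stress") & (sub["stressor"] == stressor)]
            )
            if controls and stressed:
                out.append(
                    ExperimentContrast(
                        batch=str(batch),
                        stressor=str(stressor),
                        control_samples=controls,
                        stress_samples=stressed,
                    )
                )
    return out


def call_experiment_responses(
    m: ExpressionMatrix,
    contrasts: list[ExperimentContrast],
    cfg: SetOpsConfig | None = None,
) -> ResponseCalls:
    """Compute per-experiment TN-ratios on raw TPM and call responses."""
    cfg = cfg or SetOpsConfig()
    if m.scale_tag != "tpm":
        raise ValidationError(
            "TN-ratios are computed on raw TPM within each batch; got scale "
            f"{m.scale_tag!r}"
        )
    known = set(m.sample_ids)
    cols = {}
    registry: dict[str, ExperimentContrast] = {}
    for c in contrasts:
        missing = sorted((set(c.control_samples) | set(c.stress_samples)) - known)
        if missing:
            raise ValidationError(
                f"contrast {c.key} references unknown samples: {missing}"
            )
        t = m.values[list(c.stress_samples)].mean(axis=1).to_numpy()
        n = m.values[list(c.control_samples)].mean(axis=1).to_numpy()
        cols[c.key] = tn_ratio(t, n, cfg.pseudocount)
        registry[c.key] = c
    ratios = pd.DataFrame(cols, index=m.values.index)
    return ResponseCalls(ratios=ratios, contrasts=registry, config=cfg)


def stressor_unions(
    calls: ResponseCalls, meta: SampleMetadata | None = None
) -> tuple[dict[str, frozenset[str]], dict[str, frozenset[str]]]:
    """Union the per-experiment up/down calls over each stressor's experiments."""
    by_stressor: dict[str, list[str]] = {}
    for key, contrast in calls.contrasts.items():
        by_stressor.setdefault(contrast.stressor, []).append(key)
    if meta is not None:
        empty = sorted(set(meta.stressors()) - set(by_stressor))
        if empty:
            raise ValidationError(f"stressors with no experiments: {empty}")
    union_up = {}
    union_down = {}
    for stressor, keys in by_stressor.items():
        union_up[stressor] = frozenset().union(*(calls.up_genes(k) for k in keys))
        union_down[stressor] = frozenset().union(*(calls.down_genes(k) for k in keys))
    return union_up, union_down


def derive_core_and_specific(
    union_up: dict[str, frozenset[str]],
    union_down: dict[str, frozenset[str]],
) -> GeneSetCollection:
    """Intersect unions into core sets; isolate single-stressor specific sets.

    A gene is specific to stressor ``s`` only if it appears in one of
    ``s``'s unions and in *no* union (either direction) of any other
    stressor.
    """
    stressors = sorted(union_up)
    if sorted(union_down) != stressors:
        raise ValidationError("union_up and union_down must cover the same stressors")
    if len(stressors) < 2:
        raise ValidationError("need at least two stressors to derive core sets")
    core_up = frozenset.intersection(*(union_up[s] for s in stressors))
    core_down = frozenset.intersection(*(union_down[s] for s in stressors))
    any_union = {s: union_up[s] | union_down[s] for s in stressors}
    specific_up = {}
    specific_down = {}
    for s in stressors:
        others: set[str] = set()
        for t in stressors:
            if t != s:
                others |= any_union[t]
        specific_up[s] = frozenset(union_up[s] - others)
        specific_down[s] = frozenset(union_down[s] - others)
    return GeneSetCollection(
        union_up=dict(union_up),
        union_down=dict(union_down),
        core_up=core_up,
        core_down=core_down,
        specific_up=specific_up,
        specific_down=specific_down,
        provenance="setops",
    )


def simple_de_flag(
    m: ExpressionMatrix,
    contrasts: list[ExperimentContrast],
    alpha: float = 0.05,
) -> pd.Series:
    """Welch-test differential-expression flag on log2(x+1) values.

    Per contrast, a two-sample Welch t-test is run for every gene on
    log2(TPM+1) and BH-adjusted within the contrast; a gene is flagged if
    it is significant at ``alpha`` in at least one contrast.  Contrasts
    with fewer than three replicates in either group are skipped with a
    warning.  This is deliberately lightweight plumbing used only to
    annotate genes as differentially expressed or not.
    """
    from .enrichment import fdr_adjust

    if m.scale_tag != "tpm":
        raise ValidationError("simple_de_flag expects raw TPM input")
    log_values = np.log2(m.values + 1.0)
    flag = pd.Series(False, index=m.values.index)
    for c in contrasts:
        if len(c.control_samples) < 3 or len(c.stress_samples) < 3:
            warnings.warn(
                f"contrast {c.key} skipped: fewer than 3 replicates per group"
            )
            continue
        a = log_values[list(c.stress_samples)].to_numpy()
        b = log_values[list(c.control_samples)].to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.ttest_ind(a, b, axis=1, equal_var=False)
        p = np.where(np.isfinite(res.pvalue), res.pvalue, 1.0)
        adj = np.asarray(fdr_adjust(list(p)))
        flag |= pd.Series(adj < alpha, index=m.values.index)
    return flag
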