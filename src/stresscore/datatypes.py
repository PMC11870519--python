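"""Shared containers and validation for expression data and derived gene sets.

The in-memory convention throughout the package is a pandas DataFrame of
genes (rows) by samples (columns), wrapped in :class:`ExpressionMatrix`
together with a ``scale_tag`` recording which transform has been applied.
Preprocessing steps check and update the tag so that, e.g., batch
correction cannot silently be run on raw TPM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

SCALE_TAGS = ("tpm", "log2p1", "batch_corrected", "zscore")

REQUIRED_METADATA_COLUMNS = ("batch", "stressor", "treatment", "tissue", "genotype")


class ValidationError(ValueError):
    """Input table violates a structural contract."""


class AlignmentError(ValidationError):
    """Expression matrix and metadata do not describe the same samples."""


class ConfigurationError(ValueError):
    """A configuration object violates one of its invariants."""


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression values on a declared scale.

    Parameters
    ----------
    values:
        DataFrame with gene ids as the index and sample ids as columns.
    scale_tag:
        One of ``tpm`` (non-negative TPM-like values), ``log2p1``,
        ``batch_corrected`` or ``zscore``.
    """

    values: pd.DataFrame
    scale_tag: str = "tpm"

    def __post_init__(self) -> None:
        if self.scale_tag not in SCALE_TAGS:
            raise ValidationError(
                f"unknown scale_tag {self.scale_tag!r}; expected one of {SCALE_TAGS}"
            )
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dupes}")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dupes}")
        if self.scale_tag == "tpm":
            arr = self.values.to_numpy()
            if arr.size and np.nanmin(arr) < 0:
                raise ValidationError("negative values are not valid on the tpm scale")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class SampleMetadata:
    """Per-sample experimental annotation (batch, stressor, treatment, ...).

    ``table`` is indexed by sample id and must carry the columns
    ``batch``, ``stressor``, ``treatment``, ``tissue`` and ``genotype``.
    ``treatment`` is binary (``control`` / ``stress``); every stress
    sample must name its stressor.  ``batch`` plays the role of an
    independent experiment (the BioProject analogue) and is the unit of
    both batch correction and per-experiment contrasts.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"metadata missing required columns: {missing}")
        if self.table.index.duplicated().any():
            dupes = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids in metadata: {dupes}")
        bad = set(self.table["treatment"]) - {"control", "stress"}
        if bad:
            raise ValidationError(f"treatment must be control/stress; got {sorted(bad)}")
        stress = self.table[self.table["treatment"] == "stress"]
        unlabeled = stress[stress["stressor"].isna() | (stress["stressor"] == "")]
        if len(unlabeled):
            raise ValidationError(
                f"stress samples without a stressor label: {list(unlabeled.index)}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        """Check that metadata and matrix describe exactly the same samples."""
        meta = set(self.table.index)
        expr = set(matrix.sample_ids)
        only_expr = sorted(expr - meta)
        only_meta = sorted(meta - expr)
        if only_expr or only_meta:
            raise AlignmentError(
                "sample mismatch between expression and metadata; "
                f"missing from metadata: {only_expr}; missing from matrix: {only_meta}"
            )

    def aligned_to(self, matrix: ExpressionMatrix) -> "SampleMetadata":
        """Return metadata row-ordered to the matrix's columns."""
        self.validate_against(matrix)
        return SampleMetadata(self.table.loc[matrix.sample_ids].copy())

    def stressors(self) -> list[str]:
        labels = self.table.loc[self.table["treatment"] == "stress", "stressor"]
        return sorted(set(labels))


@dataclass(frozen=True)
class ExperimentContrast:
    """One stress-vs-control comparison inside a single batch."""

    batch: str
    stressor: str
    control_samples: tuple[str, ...]
    stress_samples: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.control_samples or not self.stress_samples:
            raise ValidationError(
                f"contrast {self.batch}/{self.stressor}: both groups must be non-empty"
            )
        if set(self.control_samples) & set(self.stress_samples):
            raise ValidationError(
                f"contrast {self.batch}/{self.stressor}: control and stress overlap"
            )

    @property
    def key(self) -> str:
        return f"{self.batch}|{self.stressor}"


@dataclass
class GeneSetCollection:
    """Per-stressor unions plus derived core and stress-specific sets."""

    union_up: dict[str, frozenset[str]]
    union_down: dict[str, frozenset[str]]
    core_up: frozenset[str]
    core_down: frozenset[str]
    specific_up: dict[str, frozenset[str]]
    specific_down: dict[str, frozenset[str]]
    provenance: str = "setops"

    def validate(self) -> None:
        stressors = list(self.union_up)
        core_up = frozenset.intersection(*(self.union_up[s] for s in stressors))
        core_down = frozenset.intersection(*(self.union_down[s] for s in stressors))
        if core_up != self.core_up or core_down != self.core_down:
            raise ValidationError("core sets are not the intersection of the unions")
        per_stressor = {
            s: self.specific_up.get(s, frozenset()) | self.specific_down.get(s, frozenset())
            for s in set(self.specific_up) | set(self.specific_down)
        }
        core = self.core_up | self.core_down
        labels = sorted(per_stressor)
        for i, s in enumerate(labels):
            if per_stressor[s] & core:
                raise ValidationError(f"specific set for {s} overlaps a core set")
            for t in labels[i + 1 :]:
                if per_stressor[s] & per_stressor[t]:
                    raise ValidationError(
                        f"specific sets for {s} and {t} are not disjoint"
                    )


@dataclass
class GeneAnnotation:
    """TF family membership and term-to-gene mappings for enrichment tests."""

    tf_family: Mapping[str, str]
    term_to_genes: Mapping[str, frozenset[str]]
    term_parents: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def tf_genes(self) -> frozenset[str]:
        return frozenset(self.tf_family)

    def family_to_genes(self) -> dict[str, frozenset[str]]:
        out: dict[str, set[str]] = {}
        for gene, fam in self.tf_family.items():
            out.setdefault(fam, set()).add(gene)
        return {fam: frozenset(genes) for fam, genes in out.items()}
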