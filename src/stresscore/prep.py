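"""Loading, validation and preprocessing of expression tables.

Preprocessing follows the standard meta-analysis recipe: drop
zero-variance genes from raw TPM, transform to log2(x+1), remove
batch (BioProject) location/scale effects with parametric empirical-Bayes
ComBat, then summarize with PCA and treatment-level hierarchical
clustering.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from sklearn.decomposition import PCA

from . import combat as _combat
from .datatypes import (
    ExpressionMatrix,
    SampleMetadata,
    ValidationError,
)

LINKAGE_METHODS = ("single", "complete", "average", "ward")


def load_dataset(
    expression_path: str, metadata_path: str
) -> tuple[ExpressionMatrix, SampleMetadata]:
    """Read an expression TSV/CSV (genes x samples) and its metadata table.

    The expression table's first column is the gene id; the metadata table
    must have a ``sample`` column (or first column) plus batch, stressor,
    treatment, tissue and genotype.  Metadata rows are aligned to the
    matrix's column order.
    """
    sep_expr = "\t" if str(expression_path).endswith((".tsv", ".txt")) else None
    expr = pd.read_csv(expression_path, sep=sep_expr, engine="python", index_col=0)
    sep_meta = "\t" if str(metadata_path).endswith((".tsv", ".txt")) else None
    meta = pd.read_csv(metadata_path, sep=sep_meta, engine="python")
    if "sample" in meta.columns:
        meta = meta.set_index("sample")
    else:
        meta = meta.set_index(meta.columns[0])
    matrix = ExpressionMatrix(expr, scale_tag="tpm")
    metadata = SampleMetadata(meta).aligned_to(matrix)
    return matrix, metadata


def filter_zero_variance(m: ExpressionMatrix) -> ExpressionMatrix:
    """Remove genes whose value is identical across all samples."""
    _require_scale(m, "tpm")
    arr = m.values.to_numpy()
    keep = ~(arr == arr[:, [0]]).all(axis=1) if arr.shape[1] else np.ones(0, bool)
    return ExpressionMatrix(m.values.loc[keep], scale_tag=m.scale_tag)


def log2p1_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Replace every TPM value v with log2(v + 1)."""
    _require_scale(m, "tpm")
    if m.values.size and m.values.to_numpy().min() < 0:
        raise ValidationError("negative values cannot be log2(x+1)-transformed")
    return ExpressionMatrix(np.log2(m.values + 1.0), scale_tag="log2p1")


def combat_correct(m: ExpressionMatrix, meta: SampleMetadata) -> ExpressionMatrix:
    """Batch-correct log2(x+1) values with parametric EB ComBat.

    Batch is the only model term (no covariates).  A single batch is a
    pass-through with a warning; a batch with fewer than two samples is an
    error because its scale parameter cannot be estimated.
    """
    _require_scale(m, "log2p1")
    meta = meta.aligned_to(m)
    batch = meta.table["batch"]
    if batch.nunique() < 2:
        warnings.warn("only one batch present; returning data unchanged")
        return ExpressionMatrix(m.values.copy(), scale_tag="batch_corrected")
    corrected = _combat.combat(m.values, batch)
    return ExpressionMatrix(corrected, scale_tag="batch_corrected")


def pca_overview(
    m: ExpressionMatrix, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Centered PCA of samples; returns (scores, variance_explained)."""
    n_max = min(m.n_genes, m.n_samples)
    if not 1 <= n_components <= n_max:
        raise ValueError(
            f"n_components must be in [1, {n_max}] for a "
            f"{m.n_genes}x{m.n_samples} matrix; got {n_components}"
        )
    if m.n_samples < 2:
        raise ValueError("PCA requires at least two samples")
    X = m.values.to_numpy().T  # samples x genes
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return (
        pd.DataFrame(scores, index=m.sample_ids, columns=cols),
        pca.explained_variance_ratio_,
    )


def zscore_genes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Standardize each gene across samples, dropping zero-variance genes."""
    arr = m.values.to_numpy()
    sd = arr.std(axis=1)
    keep = sd > 0
    z = (arr[keep] - arr[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    return ExpressionMatrix(
        pd.DataFrame(z, index=m.values.index[keep], columns=m.values.columns),
        scale_tag="zscore",
    )


def cluster_treatments(
    m: ExpressionMatrix,
    meta: SampleMetadata,
    method: str = "average",
) -> tuple[np.ndarray, list[str]]:
    """Hierarchically cluster mean z-scored profiles of the treatments.

    Treatments are the stressors plus a pooled ``control`` built from all
    control samples.  Returns the scipy linkage matrix and the treatment
    labels in leaf order of the profile matrix.
    """
    _require_scale(m, "batch_corrected")
    if method not in LINKAGE_METHODS:
        raise ValueError(f"linkage method must be one of {LINKAGE_METHODS}")
    meta = meta.aligned_to(m)
    z = zscore_genes(m)
    table = meta.table
    labels = ["control"] + meta.stressors()
    profiles = []
    for label in labels:
        if label == "control":
            cols = table.index[table["treatment"] == "control"]
        else:
            cols = table.index[
                (table["treatment"] == "stress") & (table["stressor"] == label)
            ]
        if len(cols) == 0:
            raise ValueError(f"treatment {label!r} has no samples")
        profiles.append(z.values[cols].mean(axis=1).to_numpy())
    Z = linkage(np.vstack(profiles), method=method, metric="euclidean")
    return Z, labels


def _require_scale(m: ExpressionMatrix, expected: str) -> None:
    if m.scale_tag != expected:
        raise ValidationError(
            f"expected a matrix on the {expected!r} scale, got {m.scale_tag!r}"
        )
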