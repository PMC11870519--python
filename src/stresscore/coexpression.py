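"""Soft-threshold coexpression network, modules, eigengenes, kME and hubs.

The network follows the weighted-coexpression recipe: correlations are
raised to a soft-threshold power (beta, default 9) to form the adjacency,
converted to the topological overlap measure (TOM), and 1 - TOM is
clustered by average-linkage hierarchy with a static height cut (a
deliberately simpler, fully reproducible stand-in for dynamic tree
cutting).  Module eigengenes are first principal components of the
standardized module submatrices; kME is the signed correlation of each
gene with each eigengene; hub genes sit strictly above the 95th
percentile of own-module |kME| (or an explicit override threshold).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .datatypes import ConfigurationError, ExpressionMatrix, ValidationError

UNASSIGNED = "unassigned"


@dataclass
class CoexpressionConfig:
    beta: float = 9.0
    network_type: str = "unsigned"
    min_module_size: int = 20
    cut_height: float = 0.95
    hub_percentile: float = 0.95
    hub_threshold_override: float | None = None
    linkage_method: str = "average"

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ConfigurationError("beta must be >= 1")
        if self.network_type not in ("unsigned", "signed"):
            raise ConfigurationError("network_type must be 'unsigned' or 'signed'")
        if not 0 < self.hub_percentile < 1:
            raise ConfigurationError("hub_percentile must be in (0, 1)")
        if self.min_module_size < 1:
            raise ConfigurationError("min_module_size must be >= 1")


def soft_adjacency(m: ExpressionMatrix, cfg: CoexpressionConfig) -> pd.DataFrame:
    """|cor|^beta (unsigned) or ((1+cor)/2)^beta (signed) adjacency."""
    if m.n_samples < 3:
        raise ValidationError("need at least 3 samples to estimate correlations")
    arr = m.values.to_numpy()
    sd = arr.std(axis=1)
    zero = [g for g, s in zip(m.gene_ids, sd) if s == 0]
    if zero:
        raise ValidationError(f"zero-variance genes present: {zero[:10]}")
    cor = np.corrcoef(arr)
    cor = np.clip(cor, -1.0, 1.0)
    if cfg.network_type == "unsigned":
        adj = np.abs(cor) ** cfg.beta
    else:
        adj = ((1.0 + cor) / 2.0) ** cfg.beta
    np.fill_diagonal(adj, 1.0)
    return pd.DataFrame(adj, index=m.gene_ids, columns=m.gene_ids)


def tom_similarity(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap: TOM_ij = (sum_k a_ik a_kj + a_ij) / (min(k_i,k_j) + 1 - a_ij)."""
    A = adj.to_numpy(dtype=float)
    if A.shape[0] != A.shape[1] or not np.allclose(A, A.T, atol=1e-12):
        raise ValidationError("adjacency must be square and symmetric")
    if A.min() < 0 or A.max() > 1 or not np.allclose(np.diag(A), 1.0):
        raise ValidationError("adjacency values must lie in [0,1] with unit diagonal")
    A0 = A.copy()
    np.fill_diagonal(A0, 0.0)
    k = A0.sum(axis=1)
    shared = A0 @ A0
    denom = np.minimum.outer(k, k) + 1.0 - A0
    tom = (shared + A0) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


def detect_modules(tom: pd.DataFrame, cfg: CoexpressionConfig) -> pd.Series:
    """Average-linkage clustering of 1 - TOM with a static height cut.

    Clusters smaller than ``min_module_size`` become ``unassigned``;
    surviving modules are labelled M1, M2, ... by decreasing size (ties
    broken by the smallest member gene id) so the labelling is invariant
    to gene order.
    """
    genes = list(tom.index)
    dist = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(dist, 0.0)
    # symmetrize tiny float asymmetries before condensing
    condensed = squareform((dist + dist.T) / 2.0, checks=False)
    Z = linkage(condensed, method=cfg.linkage_method)
    raw = fcluster(Z, t=cfg.cut_height, criterion="distance")
    labels = pd.Series(raw, index=genes)
    sizes = labels.value_counts()
    keep = sizes[sizes >= cfg.min_module_size].index
    ordering = sorted(
        keep,
        key=lambda c: (-sizes[c], min(g for g, l in labels.items() if l == c)),
    )
    rename = {c: f"M{i + 1}" for i, c in enumerate(ordering)}
    out = labels.map(lambda c: rename.get(c, UNASSIGNED))
    if (out == UNASSIGNED).all():
        warnings.warn("no module reached min_module_size; all genes unassigned")
    return out


def eigengenes_and_kme(
    m: ExpressionMatrix, assignment: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Module eigengenes (unit variance, mean-profile oriented) and signed kME.

    The eigengene of a module is the first principal component across
    samples of its standardized gene submatrix; kME(g, M) is the Pearson
    correlation of gene g with module M's eigengene, computed for *all*
    gene-module pairs.
    """
    arr = m.values.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    if np.any(sd == 0):
        raise ValidationError("zero-variance genes cannot enter the network")
    if m.n_samples < 2:
        raise ValidationError("eigengenes need at least two samples")
    z = (arr - arr.mean(axis=1, keepdims=True)) / sd[:, None]
    modules = sorted(set(assignment) - {UNASSIGNED})
    if not modules:
        raise ValidationError("no assigned modules")
    gene_index = {g: i for i, g in enumerate(m.gene_ids)}
    eig = {}
    for mod in modules:
        members = [gene_index[g] for g in assignment.index[assignment == mod]]
        sub = z[members]
        # first right singular vector = PC1 over samples
        _, _, vt = np.linalg.svd(sub - sub.mean(axis=1, keepdims=True), full_matrices=False)
        e = vt[0]
        if np.corrcoef(e, sub.mean(axis=0))[0, 1] < 0:
            e = -e
        e = (e - e.mean()) / e.std()
        eig[mod] = e
    eigengenes = pd.DataFrame(eig, index=m.sample_ids).T  # module x sample
    ez = eigengenes.to_numpy()
    # kME: correlation of standardized genes with standardized eigengenes
    kme = (z @ ez.T) / m.n_samples
    kme = np.clip(kme, -1.0, 1.0)
    return eigengenes, pd.DataFrame(kme, index=m.gene_ids, columns=modules)


def hub_genes(
    kme: pd.DataFrame, assignment: pd.Series, cfg: CoexpressionConfig
) -> tuple[frozenset[str], float]:
    """Genes with own-module |kME| strictly above the hub threshold.

    The threshold is ``hub_threshold_override`` when set, otherwise the
    ``hub_percentile`` linear-interpolation quantile of own-module |kME|
    over assigned genes.  Returns (hub set, realized threshold).
    """
    assigned = assignment.index[assignment != UNASSIGNED]
    if len(assigned) == 0:
        raise ValidationError("no assigned genes; cannot call hubs")
    missing = [g for g in assigned if g not in kme.index]
    if missing:
        raise ValidationError(f"assigned genes without kME values: {missing[:10]}")
    scores = pd.Series(
        [abs(kme.at[g, assignment[g]]) for g in assigned], index=assigned
    )
    if cfg.hub_threshold_override is not None:
        threshold = float(cfg.hub_threshold_override)
    else:
        threshold = float(np.quantile(scores.to_numpy(), cfg.hub_percentile))
    hubs = frozenset(scores.index[scores > threshold])
    return hubs, threshold


def build_network(
    m: ExpressionMatrix, cfg: CoexpressionConfig | None = None
) -> dict:
    """Convenience: adjacency -> TOM -> modules -> eigengenes/kME -> hubs."""
    cfg = cfg or CoexpressionConfig()
    adj = soft_adjacency(m, cfg)
    tom = tom_similarity(adj)
    assignment = detect_modules(tom, cfg)
    if (assignment == UNASSIGNED).all():
        return {
            "assignment": assignment,
            "eigengenes": None,
            "kme": None,
            "hubs": frozenset(),
            "hub_threshold": float("nan"),
        }
    eigengenes, kme = eigengenes_and_kme(m, assignment)
    hubs, threshold = hub_genes(kme, assignment, cfg)
    return {
        "assignment": assignment,
        "eigengenes": eigengenes,
        "kme": kme,
        "hubs": hubs,
        "hub_threshold": threshold,
    }
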