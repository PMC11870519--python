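"""Tree-ensemble regulatory-network inference and repeated-Dunnett analysis.

Link weights follow the GENIE3 recipe: for every target gene a
random-forest regression of its standardized profile on all candidate
regulators (excluding itself) is fit, and each regulator's share of the
forest's impurity importance — normalized to sum to one per target — is
the regulator-to-target weight.  Per-target mean weights over a chosen
regulator subset (e.g. core TFs from enriched families) are then compared
between target groups (core, per-stressor specific, other) with
many-to-one Dunnett tests against the "other" control group.  Because the
Dunnett max-|t| tail is evaluated by Monte Carlo, the test is repeated
many times and a central confidence interval of the p-value sample is
used: a comparison is significant when the interval's upper bound is
below alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .datatypes import ConfigurationError, ExpressionMatrix, ValidationError


@dataclass
class GRNConfig:
    regulators: tuple[str, ...] = ()
    n_trees: int = 200
    max_features: float | str = "sqrt"
    seed: int = 0
    dunnett_reps: int = 5000
    dunnett_mc_samples: int = 1000
    ci_mass: float = 0.975
    alpha: float = 0.05
    ci_mode: str = "central"  # or "upper"
    resample: str = "mc"  # or "bootstrap" (resample group values per repetition)

    def __post_init__(self) -> None:
        if self.dunnett_reps < 1:
            raise ConfigurationError("dunnett_reps must be >= 1")
        if not 0 < self.ci_mass < 1:
            raise ConfigurationError("ci_mass must be in (0, 1)")
        if self.ci_mode not in ("central", "upper"):
            raise ConfigurationError("ci_mode must be 'central' or 'upper'")
        if self.resample not in ("mc", "bootstrap"):
            raise ConfigurationError("resample must be 'mc' or 'bootstrap'")


def genie3_weights(
    m: ExpressionMatrix,
    regulators: list[str],
    targets: list[str] | None = None,
    n_trees: int = 200,
    max_features: float | str = "sqrt",
    seed: int = 0,
) -> pd.DataFrame:
    """Per-target normalized random-forest importances of each regulator.

    Returns a dense targets-by-regulators frame; a regulator's weight on
    itself is NaN (no self-edges).  Zero-variance targets are skipped with
    a warning.
    """
    if not regulators:
        raise ValueError("regulator list must be non-empty")
    missing = sorted(set(regulators) - set(m.gene_ids))
    if missing:
        raise ValidationError(f"regulators absent from matrix: {missing[:10]}")
    if m.n_samples < 10:
        raise ValidationError("GENIE3 needs at least 10 samples")
    targets = list(targets) if targets is not None else list(m.gene_ids)
    missing = sorted(set(targets) - set(m.gene_ids))
    if missing:
        raise ValidationError(f"targets absent from matrix: {missing[:10]}")

    arr = m.values
    reg_mat = arr.loc[regulators].to_numpy(dtype=float)
    reg_sd = reg_mat.std(axis=1)
    reg_sd[reg_sd == 0] = 1.0
    reg_z = ((reg_mat - reg_mat.mean(axis=1, keepdims=True)) / reg_sd[:, None]).T

    rows = {}
    reg_index = {r: i for i, r in enumerate(regulators)}
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(targets)) % (2**31)
    for t_i, target in enumerate(targets):
        y = arr.loc[target].to_numpy(dtype=float)
        if y.std() == 0:
            warnings.warn(f"target {target} has zero variance; skipped")
            continue
        y = (y - y.mean()) / y.std()
        cand = [r for r in regulators if r != target]
        if not cand:
            continue
        cols = [reg_index[r] for r in cand]
        X = reg_z[:, cols]
        model = RandomForestRegressor(
            n_estimators=n_trees,
            max_features=max_features,
            random_state=int(child_seeds[t_i]),
            n_jobs=1,
        )
        model.fit(X, y)
        imp = np.asarray(model.feature_importances_, dtype=float)
        total = imp.sum()
        if total > 0:
            imp = imp / total
        row = pd.Series(np.nan, index=regulators)
        row[cand] = imp
        rows[target] = row
    return pd.DataFrame(rows).T.reindex(columns=regulators)


def mean_regulator_weight(
    edges: pd.DataFrame, regulators_of_interest: set[str]
) -> pd.Series:
    """Per-target arithmetic mean of weights from the listed regulators.

    ``edges`` is the dense targets-by-regulators weight frame; self-edge
    NaNs are excluded from the mean.
    """
    regs = sorted(regulators_of_interest)
    if not regs:
        raise ValueError("regulators_of_interest must be non-empty")
    missing = sorted(set(regs) - set(edges.columns))
    if missing:
        raise ValueError(f"regulators not in edge table: {missing[:10]}")
    return edges[regs].mean(axis=1, skipna=True)


def _dunnett_stats(
    groups: dict[str, np.ndarray], control_label: str
) -> tuple[list[str], np.ndarray, np.ndarray, float, int]:
    if control_label not in groups:
        raise ValueError(f"control group {control_label!r} missing")
    if len(groups) < 2:
        raise ValueError("need at least one treatment group besides control")
    labels = [g for g in groups if g != control_label]
    for name, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"group {name!r} has n < 2")
    n_c = len(groups[control_label])
    n_i = np.array([len(groups[g]) for g in labels], dtype=float)
    N = n_c + n_i.sum()
    k = len(labels)
    df = N - (k + 1)
    ss = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    if ss <= 0:
        raise ValueError("pooled within-group variance is zero")
    s2 = ss / df
    mean_c = groups[control_label].mean()
    diffs = np.array([groups[g].mean() - mean_c for g in labels])
    t = diffs / np.sqrt(s2 * (1.0 / n_i + 1.0 / n_c))
    lam = np.sqrt(n_i / (n_i + n_c))
    return labels, t, lam, df, int(k)


def dunnett_pvalues(
    groups: dict[str, list[float] | np.ndarray],
    control_label: str = "other",
    mc_samples: int = 1000,
    seed: int = 0,
) -> pd.Series:
    """Two-sided Dunnett many-to-one p-values by Monte Carlo.

    t_i = (mean_i - mean_control) / (s_pooled * sqrt(1/n_i + 1/n_c));
    p_i = P(max_j |T_j| >= |t_i|) under the equicorrelated multivariate-t
    null with rho_ij = sqrt(n_i n_j / ((n_i + n_c)(n_j + n_c))), evaluated
    with ``mc_samples`` draws.  p-values are floored at 1/(mc_samples+1).
    """
    arrs = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    labels, t, lam, df, k = _dunnett_stats(arrs, control_label)
    rng = np.random.default_rng(seed)
    z0 = rng.standard_normal(mc_samples)
    zi = rng.standard_normal((mc_samples, k))
    chi = rng.chisquare(df, size=mc_samples)
    T = (lam[None, :] * z0[:, None] + np.sqrt(1.0 - lam**2)[None, :] * zi)
    T /= np.sqrt(chi / df)[:, None]
    max_abs = np.abs(T).max(axis=1)
    p = (np.sum(max_abs[:, None] >= np.abs(t)[None, :], axis=0) + 1.0) / (
        mc_samples + 1.0
    )
    return pd.Series(np.minimum(p, 1.0), index=labels)


@dataclass
class DunnettComparison:
    label: str
    mean_difference: float
    p_sample: np.ndarray
    ci_lower: float
    ci_upper: float
    significant: bool


def repeated_dunnett_ci(
    groups: dict[str, list[float] | np.ndarray],
    control_label: str = "other",
    cfg: GRNConfig | None = None,
) -> list[DunnettComparison]:
    """Repeat the Monte-Carlo Dunnett test and summarize each p distribution.

    With ``resample='mc'`` (default) the data are fixed and only the
    Monte-Carlo evaluation of the max-|t| tail varies between
    repetitions; ``resample='bootstrap'`` additionally resamples each
    group's values with replacement per repetition.  A comparison is
    significant when the upper bound of the central ``ci_mass`` interval
    (or the ``ci_mass`` upper quantile in ``ci_mode='upper'``) of its
    p-value sample is below ``alpha``.
    """
    cfg = cfg or GRNConfig()
    arrs = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    labels, t, lam, df, k = _dunnett_stats(arrs, control_label)
    ss = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(7,))
    rep_seeds = ss.generate_state(cfg.dunnett_reps) % (2**31)
    samples = np.empty((cfg.dunnett_reps, k))
    for r in range(cfg.dunnett_reps):
        if cfg.resample == "bootstrap":
            rng = np.random.default_rng(int(rep_seeds[r]))
            boot = {
                g: rng.choice(v, size=len(v), replace=True) for g, v in arrs.items()
            }
            p = dunnett_pvalues(
                boot, control_label, cfg.dunnett_mc_samples, int(rep_seeds[r]) + 1
            )
        else:
            p = dunnett_pvalues(
                arrs, control_label, cfg.dunnett_mc_samples, int(rep_seeds[r])
            )
        samples[r] = p.loc[labels].to_numpy()

    out = []
    mean_c = arrs[control_label].mean()
    for j, label in enumerate(labels):
        p_sample = samples[:, j]
        if cfg.ci_mode == "central":
            lo = float(np.quantile(p_sample, (1.0 - cfg.ci_mass) / 2.0))
            hi = float(np.quantile(p_sample, 1.0 - (1.0 - cfg.ci_mass) / 2.0))
        else:
            lo = float(p_sample.min())
            hi = float(np.quantile(p_sample, cfg.ci_mass))
        out.append(
            DunnettComparison(
                label=label,
                mean_difference=float(arrs[label].mean() - mean_c),
                p_sample=p_sample,
                ci_lower=lo,
                ci_upper=hi,
                significant=bool(hi < cfg.alpha),
            )
        )
    return out


def compare_target_groups(
    mean_weights: pd.Series,
    target_groups: pd.Series,
    control_label: str = "other",
    cfg: GRNConfig | None = None,
) -> pd.DataFrame:
    """Group per-target mean weights and run the repeated-Dunnett procedure.

    ``target_groups`` maps target gene -> group label ('core',
    'specific:<stressor>' or 'other').  Groups with fewer than two targets
    are dropped with a warning.  Returns one row per comparison.
    """
    cfg = cfg or GRNConfig()
    common = mean_weights.index.intersection(target_groups.index)
    groups: dict[str, np.ndarray] = {}
    for label in sorted(set(target_groups.loc[common])):
        vals = mean_weights.loc[common][target_groups.loc[common] == label]
        vals = vals.dropna()
        if len(vals) < 2:
            warnings.warn(f"group {label!r} has fewer than 2 targets; dropped")
            continue
        groups[label] = vals.to_numpy()
    comparisons = repeated_dunnett_ci(groups, control_label, cfg)
    return pd.DataFrame(
        {
            "comparison": [c.label for c in comparisons],
            "n": [len(groups[c.label]) for c in comparisons],
            "n_control": len(groups[control_label]),
            "mean_difference": [c.mean_difference for c in comparisons],
            "p_median": [float(np.median(c.p_sample)) for c in comparisons],
            "ci_lower": [c.ci_lower for c in comparisons],
            "ci_upper": [c.ci_upper for c in comparisons],
            "significant": [c.significant for c in comparisons],
        }
    )
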