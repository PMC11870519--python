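"""Coexpression network: adjacency, TOM, modules, eigengenes, kME, hubs."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from stresscore import coexpression as coex
from stresscore.datatypes import (
    ConfigurationError,
    ExpressionMatrix,
    ValidationError,
)


def _matrix(values, genes=None, prefix="s"):
    arr = np.asarray(values, dtype=float)
    genes = genes or [f"g{i:03d}" for i in range(arr.shape[0])]
    cols = [f"{prefix}{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(arr, index=genes, columns=cols), "batch_corrected"
    )


def planted_block_matrix(
    n_blocks=3, block_size=30, n_background=200, n_samples=40, seed=0
):
    """Blocks of genes sharing a latent sample profile plus small noise."""
    rng = np.random.default_rng(seed)
    rows, truth = [], []
    for b in range(n_blocks):
        profile = rng.normal(0, 2.0, size=n_samples)
        for _ in range(block_size):
            rows.append(profile + rng.normal(0, 0.3, size=n_samples))
            truth.append(b)
    for _ in range(n_background):
        rows.append(rng.normal(0, 1.0, size=n_samples))
        truth.append(-1)
    return _matrix(np.array(rows)), np.array(truth)


# ---- adjacency -------------------------------------------------------


def test_adjacency_matches_brute_force_correlation_power():
    rng = np.random.default_rng(1)
    m = _matrix(rng.normal(size=(8, 12)))
    cfg = coex.CoexpressionConfig(beta=9.0)
    adj = coex.soft_adjacency(m, cfg)
    arr = m.values.to_numpy()
    for i in range(8):
        for j in range(8):
            r = np.corrcoef(arr[i], arr[j])[0, 1]
            expected = 1.0 if i == j else abs(r) ** 9
            assert adj.iat[i, j] == pytest.approx(expected, abs=1e-12)


def test_signed_adjacency_discriminates_anticorrelation():
    t = np.linspace(0, 1, 10)
    m = _matrix(np.vstack([t, -t + 1.0]))
    cfg = coex.CoexpressionConfig(beta=2.0, network_type="signed")
    adj = coex.soft_adjacency(m, cfg)
    assert adj.iat[0, 1] == pytest.approx(0.0, abs=1e-12)
    unsigned = coex.soft_adjacency(m, coex.CoexpressionConfig(beta=2.0))
    assert unsigned.iat[0, 1] == pytest.approx(1.0, abs=1e-12)


def test_adjacency_rejects_zero_variance_gene():
    m = _matrix([[1.0, 1.0, 1.0, 1.0], [0.0, 1.0, 2.0, 1.0]])
    with pytest.raises(ValidationError, match="zero-variance"):
        coex.soft_adjacency(m, coex.CoexpressionConfig())


def test_config_invariants():
    with pytest.raises(ConfigurationError):
        coex.CoexpressionConfig(beta=0.5)
    with pytest.raises(ConfigurationError):
        coex.CoexpressionConfig(network_type="other")
    with pytest.raises(ConfigurationError):
        coex.CoexpressionConfig(hub_percentile=1.0)


# ---- TOM -------------------------------------------------------------


def test_tom_closed_form_full_clique():
    """For an all-ones adjacency on n genes, TOM is exactly 1 everywhere:
    shared = n-2, a_ij = 1, min(k) = n-1, so (n-2+1)/(n-1+1-1) = 1."""
    n = 5
    adj = pd.DataFrame(
        np.ones((n, n)), index=[f"g{i}" for i in range(n)],
        columns=[f"g{i}" for i in range(n)],
    )
    tom = coex.tom_similarity(adj)
    np.testing.assert_allclose(tom.to_numpy(), 1.0)


def test_tom_closed_form_isolated_pair():
    """Two genes connected only to each other with weight 1 and no third
    neighbour: shared = 0, min(k) = 1, TOM = (0 + 1)/(1 + 1 - 1) = 1;
    against a detached third gene TOM = 0."""
    adj = pd.DataFrame(
        np.array([[1.0, 1.0, 0.0], [1.0, 1.0, 0.0], [0.0, 0.0, 1.0]]),
        index=list("abc"), columns=list("abc"),
    )
    tom = coex.tom_similarity(adj)
    assert tom.at["a", "b"] == pytest.approx(1.0)
    assert tom.at["a", "c"] == pytest.approx(0.0)


def test_tom_hand_computed_three_node_chain():
    """Chain a-b-c with weights 0.5: for (a,b) shared = a_ac*a_cb = 0,
    k_a = 0.5, k_b = 1.0, TOM_ab = 0.5 / (0.5 + 1 - 0.5) = 0.5; for (a,c)
    shared = 0.25, a_ac = 0, TOM_ac = 0.25 / (0.5 + 1) = 1/6."""
    adj = pd.DataFrame(
        np.array([[1.0, 0.5, 0.0], [0.5, 1.0, 0.5], [0.0, 0.5, 1.0]]),
        index=list("abc"), columns=list("abc"),
    )
    tom = coex.tom_similarity(adj)
    assert tom.at["a", "b"] == pytest.approx(0.5)
    assert tom.at["a", "c"] == pytest.approx(1.0 / 6.0)


def test_tom_validates_input():
    bad = pd.DataFrame(np.array([[1.0, 2.0], [2.0, 1.0]]), index=list("ab"), columns=list("ab"))
    with pytest.raises(ValidationError):
        coex.tom_similarity(bad)
    asym = pd.DataFrame(np.array([[1.0, 0.2], [0.4, 1.0]]), index=list("ab"), columns=list("ab"))
    with pytest.raises(ValidationError):
        coex.tom_similarity(asym)


def test_tom_bounded_and_symmetric_on_random_adjacency():
    rng = np.random.default_rng(7)
    raw = rng.uniform(0, 1, size=(20, 20))
    A = (raw + raw.T) / 2
    np.fill_diagonal(A, 1.0)
    adj = pd.DataFrame(A, index=[f"g{i}" for i in range(20)], columns=[f"g{i}" for i in range(20)])
    tom = coex.tom_similarity(adj)
    arr = tom.to_numpy()
    assert np.allclose(arr, arr.T)
    assert arr.min() >= 0 and arr.max() <= 1


# ---- module detection ------------------------------------------------


def test_planted_blocks_are_recovered():
    m, truth = planted_block_matrix(seed=0)
    cfg = coex.CoexpressionConfig(min_module_size=20)
    result = coex.build_network(m, cfg)
    assignment = result["assignment"]
    modules = sorted(set(assignment) - {coex.UNASSIGNED})
    assert len(modules) == 3
    in_blocks = truth >= 0
    pred = assignment.to_numpy()[in_blocks]
    ari = adjusted_rand_score(truth[in_blocks], pred)
    assert ari >= 0.9
    # background genes overwhelmingly stay unassigned
    bg = assignment.to_numpy()[~in_blocks]
    assert (bg == coex.UNASSIGNED).mean() > 0.9


def test_module_labels_ordered_by_size():
    m, _ = planted_block_matrix(n_blocks=2, block_size=25, n_background=0, seed=1)
    # enlarge first block by 15 genes to force a strict size ordering
    extra, _ = planted_block_matrix(n_blocks=1, block_size=15, n_background=0, seed=1)
    values = pd.concat(
        [m.values, extra.values.set_axis([f"x{i}" for i in range(15)])]
    )
    # x genes copy block 0's latent profile; correlate them with block 0
    rng = np.random.default_rng(2)
    values.iloc[50:] = m.values.iloc[:15].to_numpy() + rng.normal(0, 0.1, (15, 40))
    big = ExpressionMatrix(values, "batch_corrected")
    assignment = coex.detect_modules(
        coex.tom_similarity(
            coex.soft_adjacency(big, coex.CoexpressionConfig())
        ),
        coex.CoexpressionConfig(min_module_size=20),
    )
    sizes = assignment.value_counts()
    labels = [l for l in sizes.index if l != coex.UNASSIGNED]
    assert sizes["M1"] == max(sizes[l] for l in labels)


def test_detection_invariant_to_gene_order():
    m, _ = planted_block_matrix(n_blocks=2, block_size=25, n_background=30, seed=3)
    cfg = coex.CoexpressionConfig(min_module_size=20)
    a1 = coex.build_network(m, cfg)["assignment"]
    perm = np.random.default_rng(0).permutation(m.n_genes)
    shuffled = ExpressionMatrix(m.values.iloc[perm], "batch_corrected")
    a2 = coex.build_network(shuffled, cfg)["assignment"]
    pd.testing.assert_series_equal(a1.sort_index(), a2.sort_index())


def test_all_unassigned_warns():
    rng = np.random.default_rng(5)
    m = _matrix(rng.normal(size=(30, 20)))
    cfg = coex.CoexpressionConfig(min_module_size=25, cut_height=0.05)
    with pytest.warns(UserWarning, match="unassigned"):
        out = coex.detect_modules(
            coex.tom_similarity(coex.soft_adjacency(m, cfg)), cfg
        )
    assert (out == coex.UNASSIGNED).all()


# ---- eigengenes, kME, hubs -------------------------------------------


def test_eigengene_recovers_latent_profile_and_kme_is_correlation():
    m, truth = planted_block_matrix(n_blocks=1, block_size=30, n_background=0, seed=6)
    assignment = pd.Series("M1", index=m.gene_ids)
    eigengenes, kme = coex.eigengenes_and_kme(m, assignment)
    e = eigengenes.loc["M1"].to_numpy()
    assert e.std() == pytest.approx(1.0)
    # eigengene tracks the mean standardized profile almost perfectly
    arr = m.values.to_numpy()
    z = (arr - arr.mean(axis=1, keepdims=True)) / arr.std(axis=1, keepdims=True)
    mean_profile = z.mean(axis=0)
    assert np.corrcoef(e, mean_profile)[0, 1] > 0.99
    # kME equals the plain Pearson correlation with the eigengene
    for i, g in enumerate(m.gene_ids[:5]):
        r = np.corrcoef(arr[i], e)[0, 1]
        assert kme.at[g, "M1"] == pytest.approx(r, abs=1e-10)
    assert (kme["M1"] > 0.9).all()


def test_kme_is_signed():
    rng = np.random.default_rng(8)
    profile = rng.normal(size=20)
    rows = [profile + rng.normal(0, 0.05, 20) for _ in range(10)]
    rows.append(-profile + rng.normal(0, 0.05, 20))  # anti-correlated outsider
    m = _matrix(np.array(rows))
    assignment = pd.Series(
        ["M1"] * 10 + [coex.UNASSIGNED], index=m.gene_ids
    )
    _, kme = coex.eigengenes_and_kme(m, assignment)
    assert kme.iloc[-1]["M1"] < -0.9


def test_hub_quantile_and_override():
    kme = pd.DataFrame(
        {"M1": [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 0.95]},
        index=[f"g{i}" for i in range(10)],
    )
    assignment = pd.Series("M1", index=kme.index)
    cfg = coex.CoexpressionConfig(hub_percentile=0.95)
    hubs, threshold = coex.hub_genes(kme, assignment, cfg)
    assert threshold == pytest.approx(np.quantile(kme["M1"], 0.95))
    assert hubs == frozenset({"g9"})
    cfg2 = coex.CoexpressionConfig(hub_threshold_override=0.86)
    hubs2, threshold2 = coex.hub_genes(kme, assignment, cfg2)
    assert threshold2 == 0.86
    assert hubs2 == frozenset({"g8", "g9"})


def test_hub_all_equal_scores_yields_no_hubs():
    kme = pd.DataFrame({"M1": [0.5] * 8}, index=[f"g{i}" for i in range(8)])
    assignment = pd.Series("M1", index=kme.index)
    hubs, threshold = coex.hub_genes(kme, assignment, coex.CoexpressionConfig())
    assert threshold == pytest.approx(0.5)
    assert hubs == frozenset()


def test_hub_uses_own_module_kme_only():
    kme = pd.DataFrame(
        {
            "M1": [0.99, 0.2, 0.1, 0.15],
            "M2": [0.1, 0.98, 0.97, 0.2],
        },
        index=["a", "b", "c", "d"],
    )
    assignment = pd.Series(["M1", "M2", "M2", "M2"], index=kme.index)
    cfg = coex.CoexpressionConfig(hub_threshold_override=0.9)
    hubs, _ = coex.hub_genes(kme, assignment, cfg)
    # d has own-module kME 0.2 despite nothing; a qualifies via M1
    assert hubs == frozenset({"a", "b", "c"})


def test_hub_errors():
    kme = pd.DataFrame({"M1": [0.5]}, index=["a"])
    with pytest.raises(ValidationError):
        coex.hub_genes(
            kme,
            pd.Series(coex.UNASSIGNED, index=["a"]),
            coex.CoexpressionConfig(),
        )
    with pytest.raises(ValidationError, match="without kME"):
        coex.hub_genes(
            kme, pd.Series("M1", index=["b"]), coex.CoexpressionConfig()
        )
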