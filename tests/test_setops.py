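"""TN-ratio calls and core / stress-specific set derivation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stresscore.datatypes import ConfigurationError, ExpressionMatrix, ValidationError
from stresscore.setops import (
    SetOpsConfig,
    call_experiment_responses,
    contrasts_from_metadata,
    derive_core_and_specific,
    simple_de_flag,
    stressor_unions,
    tn_ratio,
)
from stresscore.simulate import SimulationConfig, simulate_dataset

# ---- tn_ratio --------------------------------------------------------


def test_tn_ratio_hand_examples():
    assert tn_ratio(9.0, 4.0) == pytest.approx(2.0)
    assert tn_ratio(0.0, 0.0) == pytest.approx(1.0)
    assert tn_ratio(7.0, 1.0) == pytest.approx(4.0)
    assert tn_ratio(1.0, 7.0) == pytest.approx(0.25)
    # pseudocount matters at low expression
    assert tn_ratio(1.0, 0.0, pseudocount=0.5) == pytest.approx(3.0)


def test_tn_ratio_vectorized_matches_scalar():
    t = np.array([0.0, 1.0, 100.0, 3.5])
    n = np.array([0.0, 2.0, 10.0, 3.5])
    vec = tn_ratio(t, n)
    for i in range(4):
        assert vec[i] == pytest.approx(tn_ratio(float(t[i]), float(n[i])))


@pytest.mark.parametrize("t,n", [(-1.0, 1.0), (1.0, -1.0), (np.inf, 1.0), (np.nan, 1.0)])
def test_tn_ratio_rejects_invalid_inputs(t, n):
    with pytest.raises(ValueError):
        tn_ratio(t, n)


@settings(max_examples=200, derandomize=True)
@given(
    t=st.floats(min_value=0.0, max_value=1e6),
    n=st.floats(min_value=0.0, max_value=1e6),
)
def test_tn_ratio_reciprocity_property(t, n):
    """Swapping stress and control inverts the ratio exactly."""
    r = tn_ratio(t, n)
    assert r > 0
    assert r * tn_ratio(n, t) == pytest.approx(1.0, rel=1e-12)


@settings(max_examples=200, derandomize=True)
@given(
    t1=st.floats(min_value=0.0, max_value=1e6),
    t2=st.floats(min_value=0.0, max_value=1e6),
    n=st.floats(min_value=0.0, max_value=1e6),
)
def test_tn_ratio_monotone_in_stress_mean(t1, t2, n):
    lo, hi = sorted((t1, t2))
    assert tn_ratio(lo, n) <= tn_ratio(hi, n)


def test_config_invariants():
    with pytest.raises(ConfigurationError):
        SetOpsConfig(up_threshold=0.9)
    with pytest.raises(ConfigurationError):
        SetOpsConfig(down_threshold=1.5)
    with pytest.raises(ConfigurationError):
        SetOpsConfig(pseudocount=0.0)


# ---- per-experiment calls --------------------------------------------


def _tpm_matrix(values, genes, samples):
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), "tpm"
    )


def _meta_frame(rows):
    from stresscore.datatypes import SampleMetadata

    return SampleMetadata(pd.DataFrame(rows).set_index("sample"))


def two_experiment_toy():
    """Two batches of one stressor; hand-computable means."""
    samples = []
    rows = []
    for b in (1, 2):
        for treatment in ("control", "stress"):
            for r in range(2):
                name = f"heat_b{b}_{treatment}_{r}"
                samples.append(name)
                rows.append(
                    {
                        "sample": name,
                        "batch": f"B{b}",
                        "stressor": "heat",
                        "treatment": treatment,
                        "tissue": "leaf",
                        "genotype": "B73",
                    }
                )
    # gene g0: up in batch 1 only; g1: down everywhere; g2: flat
    values = np.array(
        [
            [1.0, 1.0, 9.0, 9.0, 4.0, 4.0, 5.0, 5.0],
            [9.0, 9.0, 1.0, 1.0, 7.0, 7.0, 1.0, 1.0],
            [3.0, 3.0, 3.0, 3.0, 3.0, 3.0, 3.0, 3.0],
        ]
    )
    m = _tpm_matrix(values, ["g0", "g1", "g2"], samples)
    return m, _meta_frame(rows)


def test_call_experiment_responses_hand_values():
    m, meta = two_experiment_toy()
    contrasts = contrasts_from_metadata(meta)
    assert sorted(c.key for c in contrasts) == ["B1|heat", "B2|heat"]
    calls = call_experiment_responses(m, contrasts)
    assert calls.ratios.at["g0", "B1|heat"] == pytest.approx(5.0)
    assert calls.ratios.at["g0", "B2|heat"] == pytest.approx(1.2)
    assert calls.ratios.at["g1", "B1|heat"] == pytest.approx(0.2)
    assert calls.ratios.at["g2", "B1|heat"] == pytest.approx(1.0)
    assert calls.up_genes("B1|heat") == frozenset({"g0"})
    assert calls.down_genes("B1|heat") == frozenset({"g1"})
    assert calls.down_genes("B2|heat") == frozenset({"g1"})
    table = calls.calls()
    assert table.at["g2", "B1|heat"] == "none"


def test_thresholds_are_strict():
    """A ratio exactly at a threshold must not be called."""
    samples = ["c0", "c1", "s0", "s1"]
    rows = [
        {"sample": n, "batch": "B1", "stressor": "heat",
         "treatment": "control" if n.startswith("c") else "stress",
         "tissue": "leaf", "genotype": "B73"}
        for n in samples
    ]
    # ratios: (9+1)/(4+1)=2 exactly; (4+1)/(9+1)=0.5 exactly
    values = np.array([[4.0, 4.0, 9.0, 9.0], [9.0, 9.0, 4.0, 4.0]])
    m = _tpm_matrix(values, ["g0", "g1"], samples)
    calls = call_experiment_responses(m, contrasts_from_metadata(_meta_frame(rows)))
    assert calls.up_genes("B1|heat") == frozenset()
    assert calls.down_genes("B1|heat") == frozenset()


def test_calls_require_raw_tpm_scale():
    m, meta = two_experiment_toy()
    logged = ExpressionMatrix(np.log2(m.values + 1.0), "log2p1")
    with pytest.raises(ValidationError, match="raw TPM"):
        call_experiment_responses(logged, contrasts_from_metadata(meta))


def test_unknown_contrast_samples_raise():
    m, meta = two_experiment_toy()
    contrasts = contrasts_from_metadata(meta)
    m2 = ExpressionMatrix(m.values.iloc[:, :-1], "tpm")
    with pytest.raises(ValidationError, match="unknown samples"):
        call_experiment_responses(m2, contrasts)


# ---- unions, core, specific ------------------------------------------


def test_stressor_unions_hand_example():
    m, meta = two_experiment_toy()
    calls = call_experiment_responses(m, contrasts_from_metadata(meta))
    union_up, union_down = stressor_unions(calls, meta)
    assert union_up["heat"] == frozenset({"g0"})
    assert union_down["heat"] == frozenset({"g1"})


def test_derive_core_and_specific_hand_example():
    union_up = {
        "heat": frozenset({"a", "b", "x"}),
        "cold": frozenset({"a", "b"}),
        "salt": frozenset({"a", "b", "q"}),
    }
    union_down = {
        "heat": frozenset({"d", "y"}),
        "cold": frozenset({"d", "q"}),
        "salt": frozenset({"d"}),
    }
    sets = derive_core_and_specific(union_up, union_down)
    assert sets.core_up == frozenset({"a", "b"})
    assert sets.core_down == frozenset({"d"})
    # x only in heat's up union; y only in heat's down union
    assert sets.specific_up["heat"] == frozenset({"x"})
    assert sets.specific_down["heat"] == frozenset({"y"})
    # q appears under both cold (down) and salt (up): specific to neither
    assert "q" not in sets.specific_up["salt"]
    assert "q" not in sets.specific_down["cold"]


def test_derive_core_requires_two_stressors():
    with pytest.raises(ValidationError):
        derive_core_and_specific({"heat": frozenset()}, {"heat": frozenset()})
    with pytest.raises(ValidationError):
        derive_core_and_specific(
            {"heat": frozenset(), "cold": frozenset()}, {"heat": frozenset()}
        )


def brute_force_sets(union_up, union_down):
    """Literal re-derivation by gene-wise membership enumeration."""
    stressors = sorted(union_up)
    genes = set().union(*union_up.values(), *union_down.values())
    core_up = {
        g for g in genes if all(g in union_up[s] for s in stressors)
    }
    core_down = {
        g for g in genes if all(g in union_down[s] for s in stressors)
    }
    specific_up = {s: set() for s in stressors}
    specific_down = {s: set() for s in stressors}
    for g in genes:
        hit = [
            s
            for s in stressors
            if g in union_up[s] or g in union_down[s]
        ]
        if len(hit) == 1:
            s = hit[0]
            if g in union_up[s]:
                specific_up[s].add(g)
            if g in union_down[s]:
                specific_down[s].add(g)
    return core_up, core_down, specific_up, specific_down


@settings(max_examples=100, derandomize=True)
@given(data=st.data())
def test_derive_matches_brute_force_enumeration(data):
    stressors = ["heat", "cold", "salt"]
    genes = [f"g{i}" for i in range(12)]
    union_up = {
        s: frozenset(data.draw(st.sets(st.sampled_from(genes)), label=f"up_{s}"))
        for s in stressors
    }
    union_down = {
        s: frozenset(data.draw(st.sets(st.sampled_from(genes)), label=f"down_{s}"))
        for s in stressors
    }
    sets = derive_core_and_specific(union_up, union_down)
    core_up, core_down, spec_up, spec_down = brute_force_sets(union_up, union_down)
    assert sets.core_up == core_up and sets.core_down == core_down
    for s in stressors:
        assert sets.specific_up[s] == spec_up[s]
        assert sets.specific_down[s] == spec_down[s]


def test_specific_sets_are_cross_stressor_disjoint_on_simulated_data():
    cfg = SimulationConfig(
        n_genes=400, batches_per_stressor=2, replicates_per_group=3, seed=5
    )
    matrix, meta, _ = simulate_dataset(cfg)
    calls = call_experiment_responses(matrix, contrasts_from_metadata(meta))
    sets = derive_core_and_specific(*stressor_unions(calls, meta))
    pooled = {
        s: sets.specific_up[s] | sets.specific_down[s] for s in sets.specific_up
    }
    for a, b in itertools.combinations(sorted(pooled), 2):
        assert not (pooled[a] & pooled[b])
        assert not (pooled[a] & (sets.core_up | sets.core_down))


# ---- simple DE flag --------------------------------------------------


def test_simple_de_flag_detects_planted_effect():
    rng = np.random.default_rng(0)
    samples = [f"c{r}" for r in range(6)] + [f"s{r}" for r in range(6)]
    rows = [
        {"sample": n, "batch": "B1", "stressor": "heat",
         "treatment": "control" if n.startswith("c") else "stress",
         "tissue": "leaf", "genotype": "B73"}
        for n in samples
    ]
    values = rng.uniform(4, 6, size=(50, 12))
    values[0, 6:] += 40.0  # strong planted shift
    m = _tpm_matrix(values, [f"g{i}" for i in range(50)], samples)
    flag = simple_de_flag(m, contrasts_from_metadata(_meta_frame(rows)))
    assert bool(flag["g0"])
    assert flag.sum() <= 3  # background essentially unflagged


def test_simple_de_flag_skips_underpowered_contrast():
    m, meta = two_experiment_toy()  # 2 replicates per group
    with pytest.warns(UserWarning, match="fewer than 3"):
        flag = simple_de_flag(m, contrasts_from_metadata(meta))
    assert not flag.any()
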