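"""Expression integration: directional significance, EPOD contrast, and
regulon coherence."""
import numpy as np
import pandas as pd
import pytest

from methylpod.expression import (RegulonEdge, directional_log10q,
                                  epod_expression_contrast, regulon_coherence,
                                  regulon_coherence_table)
from methylpod.intervals import IntervalSet
from methylpod.simulate import SimSpec, simulate_expression


def _expr(genes, log2fc, q=None, start=None, end=None):
    n = len(genes)
    return pd.DataFrame({
        "gene": genes,
        "start": start if start is not None else np.arange(n) * 1000,
        "end": end if end is not None else np.arange(n) * 1000 + 900,
        "log2fc": log2fc,
        "q": q if q is not None else np.full(n, 0.5),
    })


class TestDirectionalLog10Q:
    def test_q_one_gives_zero(self):
        out = directional_log10q(_expr(["a"], [2.0], [1.0]))
        assert out["a"] == 0.0

    def test_signed_arithmetic(self):
        out = directional_log10q(
            _expr(["up", "down"], [1.5, -0.5], [0.01, 0.001]))
        assert np.isclose(out["up"], 2.0)
        assert np.isclose(out["down"], -3.0)

    def test_antisymmetric_under_direction_flip(self, rng):
        q = rng.uniform(1e-6, 1, 50)
        fc = rng.normal(size=50)
        genes = [f"g{i}" for i in range(50)]
        a = directional_log10q(_expr(genes, fc, q))
        b = directional_log10q(_expr(genes, -fc, q))
        assert np.allclose(a.to_numpy(), -b.to_numpy())

    def test_missing_q_skipped_with_warning(self):
        df = _expr(["a", "b"], [1.0, 1.0], [0.1, np.nan])
        with pytest.warns(UserWarning, match="skipped"):
            out = directional_log10q(df)
        assert list(out.index) == ["a"]

    def test_zero_q_floored_finite(self):
        out = directional_log10q(_expr(["a"], [1.0], [0.0]))
        assert np.isfinite(out["a"]) and out["a"] >= 300


class TestEpodExpressionContrast:
    def test_planted_shift_recovered(self, rng):
        n = 2200
        starts = np.arange(n) * 1000
        inside = np.zeros(n, bool)
        inside[:200] = True
        fc = rng.normal(0, 0.3, n) + np.where(inside, -0.5, 0.0)
        epods = IntervalSet(starts[inside], starts[inside] + 900)
        df = _expr([f"g{i}" for i in range(n)], fc, start=starts,
                   end=starts + 900)
        delta, p = epod_expression_contrast(df, epods)
        assert abs(delta - (-0.5)) < 0.1
        assert p < 1e-6

    def test_null_delta_small(self, rng):
        n = 1000
        starts = np.arange(n) * 1000
        fc = rng.normal(0, 0.3, n)
        epods = IntervalSet(starts[:100], starts[:100] + 900)
        df = _expr([f"g{i}" for i in range(n)], fc, start=starts,
                   end=starts + 900)
        delta, p = epod_expression_contrast(df, epods)
        assert abs(delta) < 0.15

    def test_delta_invariant_to_constant_offset(self, rng):
        n = 500
        starts = np.arange(n) * 1000
        fc = rng.normal(size=n)
        epods = IntervalSet(starts[:50], starts[:50] + 900)
        df1 = _expr([f"g{i}" for i in range(n)], fc, start=starts,
                    end=starts + 900)
        df2 = df1.copy()
        df2["log2fc"] += 3.7
        d1, _ = epod_expression_contrast(df1, epods)
        d2, _ = epod_expression_contrast(df2, epods)
        assert np.isclose(d1, d2)

    def test_all_inside_rejected(self):
        df = _expr(["a", "b"], [1.0, 2.0])
        epods = IntervalSet(np.array([0]), np.array([5000]))
        with pytest.raises(ValueError):
            epod_expression_contrast(df, epods)


class TestRegulonCoherence:
    def test_activator_all_up_gives_plus_one(self):
        df = _expr(["t1", "t2"], [1.0, 1.0])
        edges = [RegulonEdge("reg", "t1", "activator"),
                 RegulonEdge("reg", "t2", "activator")]
        assert regulon_coherence(df, edges, "reg") == 1.0

    def test_repressor_all_up_gives_minus_one(self):
        df = _expr(["t1", "t2"], [1.0, 1.0])
        edges = [RegulonEdge("reg", "t1", "repressor"),
                 RegulonEdge("reg", "t2", "repressor")]
        assert regulon_coherence(df, edges, "reg") == -1.0

    def test_mixed_regulon_with_dual_excluded(self):
        df = _expr(["a", "r", "d"], [0.6, -0.4, 9.0])
        edges = [RegulonEdge("reg", "a", "activator"),
                 RegulonEdge("reg", "r", "repressor"),
                 RegulonEdge("reg", "d", "dual")]
        assert np.isclose(regulon_coherence(df, edges, "reg"), 0.5)

    def test_negating_fold_changes_negates_statistic(self, rng):
        genes = [f"t{i}" for i in range(20)]
        fc = rng.normal(size=20)
        modes = ["activator" if i % 2 else "repressor" for i in range(20)]
        edges = [RegulonEdge("reg", g, m) for g, m in zip(genes, modes)]
        a = regulon_coherence(_expr(genes, fc), edges, "reg")
        b = regulon_coherence(_expr(genes, -fc), edges, "reg")
        assert np.isclose(a, -b)

    def test_no_usable_targets_rejected(self):
        df = _expr(["t1"], [1.0])
        edges = [RegulonEdge("reg", "t1", "dual")]
        with pytest.raises(ValueError):
            regulon_coherence(df, edges, "reg")
        with pytest.raises(ValueError, match="unknown regulatory mode"):
            RegulonEdge("reg", "t1", "enhancer")

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError):
            RegulonEdge("reg", "t", "silencer-ish")


class TestSimulatedExpressionRecovery:
    def test_planted_activator_effect_recovered(self):
        edges = [RegulonEdge("lrhA", f"g{i:04d}", "activator")
                 for i in range(30)]
        spec = SimSpec(expression_effects=[("lrhA", "activator", 0.8, 0.05)],
                       seed=2)
        df, truth = simulate_expression(spec, edges)
        coh = regulon_coherence(df, edges, "lrhA")
        assert abs(coh - 0.8) < 0.1

    def test_null_effect_coherence_near_zero(self):
        edges = [RegulonEdge("fur", f"g{i:04d}", "repressor")
                 for i in range(30)]
        spec = SimSpec(expression_effects=[("fur", "repressor", 0.0, 0.05)],
                       seed=3)
        df, _ = simulate_expression(spec, edges)
        coh = regulon_coherence(df, edges, "fur")
        # null sd of the mean over 30 targets at noise 0.05
        assert abs(coh) < 3 * 0.05 / np.sqrt(30)

    def test_coherence_table_lists_regulators(self):
        edges = ([RegulonEdge("lrhA", f"g{i:04d}", "repressor")
                  for i in range(10)]
                 + [RegulonEdge("flhDC", f"g{i:04d}", "activator")
                    for i in range(10, 25)])
        spec = SimSpec(expression_effects=[("lrhA", "repressor", 0.5, 0.1)],
                       seed=4)
        df, _ = simulate_expression(spec, edges)
        tab = regulon_coherence_table(df, edges)
        assert set(tab["regulator"]) == {"lrhA", "flhDC"}
        assert (tab["n_targets"] > 0).all()
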