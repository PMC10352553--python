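"""Panel construction, beta/M conversion, and weighted-sum scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from episcore import (
    CpGPanel,
    MethylationMatrix,
    beta_to_m,
    compute_score,
    m_to_beta,
    random_subpanels,
    refine_panel,
    standardize,
)
from episcore.exceptions import (
    CoverageError,
    EmptyPanelError,
    ParameterError,
    ScaleError,
    SchemaError,
    ZeroVarianceError,
)
from episcore.panels import MVALUE


def _matrix(values, cpgs, scale=MVALUE, samples=None):
    samples = samples or [f"s{i}" for i in range(len(values))]
    return MethylationMatrix(
        values=pd.DataFrame(values, index=samples, columns=cpgs), scale=scale
    )


class TestCpGPanel:
    def test_rejects_duplicate_ids(self):
        with pytest.raises(SchemaError, match="unique"):
            CpGPanel(cpg_ids=("a", "a"), weights=np.array([1.0, 2.0]))

    def test_rejects_all_zero_weights(self):
        with pytest.raises(SchemaError, match="zero"):
            CpGPanel(cpg_ids=("a", "b"), weights=np.zeros(2))

    def test_rejects_nonfinite_weights(self):
        with pytest.raises(SchemaError, match="finite"):
            CpGPanel(cpg_ids=("a",), weights=np.array([np.inf]))

    def test_tsv_round_trip(self, tmp_path, panel):
        path = tmp_path / "panel.tsv"
        panel.to_tsv(path)
        back = CpGPanel.from_tsv(path, name=panel.name)
        assert back.cpg_ids == panel.cpg_ids
        np.testing.assert_allclose(back.weights, panel.weights)


class TestBetaToM:
    @pytest.mark.parametrize(
        "beta,expected", [(0.5, 0.0), (0.8, 2.0), (0.2, -2.0), (0.25, np.log2(1 / 3))]
    )
    def test_known_values(self, beta, expected):
        m = beta_to_m(_matrix([[beta]], ["cg1"], scale="beta"))
        assert m.scale == MVALUE
        assert m.values.iloc[0, 0] == pytest.approx(expected, abs=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(min_value=1e-5, max_value=1 - 1e-5))
    def test_antisymmetry(self, beta):
        m1 = beta_to_m(_matrix([[beta]], ["cg1"], scale="beta")).values.iloc[0, 0]
        m2 = beta_to_m(_matrix([[1 - beta]], ["cg1"], scale="beta")).values.iloc[0, 0]
        assert m1 == pytest.approx(-m2, abs=1e-9)

    def test_round_trip_through_m(self):
        rngv = np.random.default_rng(0).uniform(0.01, 0.99, size=(5, 4))
        mat = _matrix(rngv, [f"cg{i}" for i in range(4)], scale="beta")
        back = m_to_beta(beta_to_m(mat))
        np.testing.assert_allclose(back.values.to_numpy(), rngv, atol=1e-12)

    def test_scale_and_epsilon_errors(self):
        mvals = _matrix([[0.0]], ["cg1"])
        with pytest.raises(ScaleError):
            beta_to_m(mvals)
        betas = _matrix([[0.5]], ["cg1"], scale="beta")
        with pytest.raises(ParameterError):
            beta_to_m(betas, epsilon=0.7)

    def test_beta_domain_enforced(self):
        with pytest.raises(ScaleError, match="strictly"):
            _matrix([[0.0]], ["cg1"], scale="beta")


class TestStandardize:
    def test_simple_example(self):
        np.testing.assert_allclose(standardize([1, 2, 3]), [-1, 0, 1], atol=1e-12)

    def test_idempotent_and_contract(self, rng):
        x = rng.normal(3.0, 7.0, size=200)
        z = standardize(x)
        assert abs(z.mean()) < 1e-12
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(standardize(z), z, atol=1e-10)

    def test_constant_vector_refused(self):
        with pytest.raises(ZeroVarianceError):
            standardize(np.full(10, 2.5))


class TestComputeScore:
    def test_two_cpg_example(self):
        panel = CpGPanel(("cgA", "cgB"), np.array([0.5, -1.0]))
        mat = _matrix([[2.0, 1.0], [0.0, 1.0]], ["cgA", "cgB"])
        sv = compute_score(mat, panel)
        assert sv.raw[0] == pytest.approx(0.0)
        assert sv.raw[1] == pytest.approx(-1.0)
        assert sv.coverage == 1.0

    def test_matches_naive_loop(self, rng):
        """Vectorized score equals a per-sample brute-force (cpg, weight) loop."""
        for _ in range(10):
            n_s, n_c = rng.integers(5, 30), rng.integers(10, 60)
            cpgs = [f"cg{i}" for i in range(n_c)]
            panel = CpGPanel(tuple(cpgs), rng.normal(0, 0.5, n_c))
            mat = _matrix(rng.normal(0, 2, (n_s, n_c)), cpgs)
            sv = compute_score(mat, panel)
            for t, sid in enumerate(mat.sample_ids):
                naive = sum(
                    w * mat.values.at[sid, c]
                    for c, w in zip(panel.cpg_ids, panel.weights)
                )
                assert sv.raw[t] == pytest.approx(naive, abs=1e-10)

    def test_missing_cpgs_contribute_zero(self, rng):
        cpgs = [f"cg{i}" for i in range(10)]
        panel = CpGPanel(tuple(cpgs), rng.normal(0, 1, 10))
        mat = _matrix(rng.normal(0, 1, (6, 6)), cpgs[:6])
        sv = compute_score(mat, panel, min_coverage=0.5)
        assert sv.coverage == pytest.approx(0.6)
        assert sv.used_cpgs == 6
        sub = panel.subset(cpgs[:6])
        np.testing.assert_allclose(sv.raw, compute_score(mat, sub).raw, atol=1e-12)

    def test_low_coverage_refused(self, rng):
        cpgs = [f"cg{i}" for i in range(10)]
        panel = CpGPanel(tuple(cpgs), rng.normal(0, 1, 10))
        mat = _matrix(rng.normal(0, 1, (4, 2)), cpgs[:2])
        with pytest.raises(CoverageError, match="coverage 0.200"):
            compute_score(mat, panel, min_coverage=0.5)

    def test_constant_scores_refuse_standardization(self):
        panel = CpGPanel(("cgA",), np.array([1.0]))
        mat = _matrix([[1.0], [1.0], [1.0]], ["cgA"])
        with pytest.raises(ZeroVarianceError):
            compute_score(mat, panel)

    def test_linearity_and_additivity(self, rng):
        cpgs = [f"cg{i}" for i in range(20)]
        w = rng.normal(0, 1, 20)
        mat = _matrix(rng.normal(0, 2, (8, 20)), cpgs)
        full = compute_score(mat, CpGPanel(tuple(cpgs), w))
        lam = 3.7
        scaled = compute_score(mat, CpGPanel(tuple(cpgs), lam * w))
        np.testing.assert_allclose(scaled.raw, lam * full.raw, rtol=1e-12)
        a = compute_score(mat, CpGPanel(tuple(cpgs[:9]), w[:9]), min_coverage=0.0)
        b = compute_score(mat, CpGPanel(tuple(cpgs[9:]), w[9:]), min_coverage=0.0)
        np.testing.assert_allclose(a.raw + b.raw, full.raw, atol=1e-10)


class TestRandomSubpanels:
    def test_draws_are_subsets_with_weights(self, panel):
        subs = random_subpanels(panel, subset_size=68, count=10, seed=11)
        parent = dict(zip(panel.cpg_ids, panel.weights))
        assert len(subs) == 10
        for sp in subs:
            assert len(sp) == 68
            assert len(set(sp.cpg_ids)) == 68
            for c, w in zip(sp.cpg_ids, sp.weights):
                assert parent[c] == w

    def test_full_size_draw_is_permutation(self, panel):
        (sp,) = random_subpanels(panel, subset_size=len(panel), count=1, seed=3)
        assert set(sp.cpg_ids) == set(panel.cpg_ids)

    def test_seed_determinism(self, panel):
        a = random_subpanels(panel, 68, 5, seed=42)
        b = random_subpanels(panel, 68, 5, seed=42)
        c = random_subpanels(panel, 68, 5, seed=43)
        assert [s.cpg_ids for s in a] == [s.cpg_ids for s in b]
        assert any(x.cpg_ids != y.cpg_ids for x, y in zip(a, c))

    def test_oversized_subset_rejected(self, panel):
        with pytest.raises(ParameterError):
            random_subpanels(panel, subset_size=len(panel) + 1, count=1, seed=0)

    def test_partition_scores_sum_to_full(self, panel, rng):
        mat = _matrix(rng.normal(0, 1, (6, len(panel))), list(panel.cpg_ids))
        full = compute_score(mat, panel)
        half = len(panel) // 2
        a = panel.subset(panel.cpg_ids[:half])
        b = panel.subset(panel.cpg_ids[half:])
        total = compute_score(mat, a).raw + compute_score(mat, b).raw
        np.testing.assert_allclose(total, full.raw, atol=1e-10)


class _FakeDiff:
    def __init__(self, q):
        self._q = q

    def q_by_cpg(self):
        return self._q


class TestRefinePanel:
    def test_exact_intersection(self):
        panel = CpGPanel(("a", "b", "c"), np.array([0.1, 0.2, 0.3]))
        diff = _FakeDiff({"a": 0.001, "b": 0.9, "c": 0.01, "z": 0.0001})
        refined = refine_panel(panel, diff, q_threshold=0.05)
        assert refined.cpg_ids == ("a", "c")
        np.testing.assert_allclose(refined.weights, [0.1, 0.3])
        assert refined.name.endswith("_refined")

    def test_all_nonsignificant_is_error(self):
        panel = CpGPanel(("a", "b"), np.array([0.1, 0.2]))
        with pytest.raises(EmptyPanelError, match="intersection 0"):
            refine_panel(panel, _FakeDiff({"a": 1.0, "b": 1.0}))
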