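"""Differential expression: filter semantics, OLS Wald oracle, BH step-up."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from convergex import (
    ExperimentMatrix,
    bh_adjust,
    filter_low_expression,
    fit_gene_model,
    run_de,
)
from convergex.diffexpr import (
    DesignError,
    MissingArmError,
    NoGenesRetainedError,
)

from conftest import gene_ids


def _matrix(values, meta):
    ab = pd.DataFrame(
        np.asarray(values, float), index=gene_ids(len(values)), columns=meta.index
    )
    return ExperimentMatrix(abundance=ab, sample_meta=meta)


def _meta(n, treatment, plate=None, buffer=None, cell_type="daoy"):
    return pd.DataFrame(
        {
            "cell_type": [cell_type] * n,
            "treatment": treatment,
            "buffer": buffer or ["H2O"] * n,
            "plate": plate or ["P1"] * n,
        },
        index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"),
    )


class TestFilterLowExpression:
    def test_gene_passing_in_all_samples_retained(self, toy_matrix):
        m = _matrix([[12.0] * 10], toy_matrix.sample_meta)
        out = filter_low_expression(m, 10, 0.9)
        assert list(out.abundance.index) == ["G00000"]

    def test_gene_passing_in_8_of_10_removed(self, toy_matrix):
        # ceil(0.9 * 10) = 9 required; 8 passing samples is not enough
        vals = [[12.0] * 8 + [1.0, 1.0], [12.0] * 10]
        m = _matrix(vals, toy_matrix.sample_meta)
        out = filter_low_expression(m, 10, 0.9)
        assert list(out.abundance.index) == ["G00001"]

    def test_min_fraction_one_zero_sample_removed(self, toy_matrix):
        vals = [[12.0] * 9 + [0.0], [12.0] * 10]
        m = _matrix(vals, toy_matrix.sample_meta)
        out = filter_low_expression(m, 10, 1.0)
        assert list(out.abundance.index) == ["G00001"]

    def test_all_removed_raises(self, toy_matrix):
        m = _matrix([[1.0] * 10], toy_matrix.sample_meta)
        with pytest.raises(NoGenesRetainedError):
            filter_low_expression(m, 10, 0.9)


class TestFitGeneModel:
    def test_constant_response(self):
        meta = _meta(6, ["H2O"] * 3 + ["propranolol"] * 3)
        fit = fit_gene_model(np.full(6, 5.0), meta, treatment_control="H2O")
        assert fit.log2fc == 0 and fit.z == 0 and fit.p == 1

    def test_exact_fit_sentinel(self):
        # y fits the treatment dummy perfectly: se = 0, infinite z, p = 0
        meta = _meta(4, ["H2O", "H2O", "propranolol", "propranolol"])
        fit = fit_gene_model([1.0, 1.0, 2.0, 2.0], meta, treatment_control="H2O")
        assert fit.log2fc == pytest.approx(1.0)
        assert fit.se == 0 and np.isinf(fit.z) and fit.z > 0 and fit.p == 0

    def test_six_sample_normal_equation_oracle(self):
        # independent oracle: explicit (X'X)^-1 X'y with X written out by hand
        meta = _meta(
            6,
            ["H2O", "H2O", "H2O", "propranolol", "propranolol", "propranolol"],
            plate=["P1", "P2", "P1", "P2", "P1", "P2"],
        )
        y = np.array([5.1, 4.8, 5.3, 6.2, 6.6, 6.0])
        X = np.array(
            [
                [1, 0, 0],
                [1, 1, 0],
                [1, 0, 0],
                [1, 1, 1],
                [1, 0, 1],
                [1, 1, 1],
            ],
            dtype=float,
        )
        xtx_inv = np.linalg.inv(X.T @ X)
        beta = xtx_inv @ X.T @ y
        resid = y - X @ beta
        sigma2 = resid @ resid / (6 - 3)
        se = np.sqrt(sigma2 * xtx_inv[2, 2])
        fit = fit_gene_model(y, meta, treatment_control="H2O", reference="normal")
        assert fit.log2fc == pytest.approx(beta[2], abs=1e-10)
        assert fit.se == pytest.approx(se, abs=1e-10)
        assert fit.z == pytest.approx(beta[2] / se, abs=1e-10)

    def test_t_reference_z_matches_p_quantile(self):
        from scipy import stats

        meta = _meta(6, ["H2O"] * 3 + ["propranolol"] * 3, plate=["P1", "P2"] * 3)
        y = np.array([5.1, 4.8, 5.3, 6.2, 6.6, 6.0])
        fit = fit_gene_model(y, meta, treatment_control="H2O", reference="t")
        assert fit.z == pytest.approx(
            np.sign(fit.log2fc) * stats.norm.isf(fit.p / 2)
        )
        # z sign always matches the effect sign
        assert np.sign(fit.z) == np.sign(fit.log2fc)

    def test_rank_deficient_design_errors(self):
        # plate aliased with treatment
        meta = _meta(
            4, ["H2O", "H2O", "propranolol", "propranolol"], plate=["P1", "P1", "P2", "P2"]
        )
        with pytest.raises(DesignError):
            fit_gene_model([1.0, 2.0, 3.0, 4.0], meta, treatment_control="H2O")


class TestRunDe:
    def test_single_gene_q_equals_p(self, toy_matrix):
        m = _matrix([[50, 60, 55, 52, 58, 80, 85, 90, 82, 88]], toy_matrix.sample_meta)
        de = run_de(m, "daoy", "propranolol")
        assert de.q.iloc[0] == pytest.approx(de.p.iloc[0])

    def test_permuting_samples_leaves_statistics_unchanged(self, small_experiment):
        m, _ = small_experiment
        de1 = run_de(m, "daoy", "propranolol")
        rng = np.random.default_rng(0)
        perm = rng.permutation(m.abundance.columns)
        m2 = ExperimentMatrix(m.abundance[perm], m.sample_meta.loc[perm])
        de2 = run_de(m2, "daoy", "propranolol")
        merged = de1.merge(de2, on="gene_id", suffixes=("_a", "_b"))
        np.testing.assert_allclose(merged.z_a, merged.z_b, atol=1e-9)
        np.testing.assert_allclose(merged.q_a, merged.q_b, atol=1e-9)

    def test_missing_arm_named(self, small_experiment):
        m, _ = small_experiment
        with pytest.raises(MissingArmError, match="lamotrigine"):
            run_de(m, "daoy", "lamotrigine", control="H2O")
        with pytest.raises(MissingArmError, match="cortex"):
            run_de(m, "cortex", "propranolol")

    def test_excludes_other_drug_arm(self, small_experiment):
        # propranolol is contrasted against H2O only; DMSO/primidone samples
        # must not influence the fit
        m, _ = small_experiment
        keep = m.sample_meta.treatment.isin(["propranolol", "H2O"])
        m2 = ExperimentMatrix(
            m.abundance.loc[:, keep.to_numpy()], m.sample_meta.loc[keep]
        )
        de_full = run_de(m, "daoy", "propranolol")
        de_sub = run_de(m2, "daoy", "propranolol")
        pd.testing.assert_frame_equal(de_full, de_sub)

    def test_sorted_by_q_with_stable_gene_tiebreak(self, small_experiment):
        m, _ = small_experiment
        de = run_de(m, "npc", "primidone")
        assert de.q.is_monotonic_increasing
        for _, grp in de.groupby("q"):
            assert list(grp.gene_id) == sorted(grp.gene_id)


def _bh_brute_force(p):
    """Step-up definition: q_i = min over p_(j) >= p_i of min(1, m p_(j) / j)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for i in range(m):
        cands = [
            min(1.0, m * p[order[j]] / (j + 1))
            for j in range(m)
            if p[order[j]] >= p[i] - 1e-15
        ]
        q[i] = min(cands)
    return q


class TestBhAdjust:
    def test_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_singleton(self):
        np.testing.assert_allclose(bh_adjust([0.5]), [0.5])

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.2])

    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=12,
        )
    )
    @settings(max_examples=300, derandomize=True)
    def test_matches_brute_force_step_up(self, p):
        np.testing.assert_allclose(bh_adjust(p), _bh_brute_force(p), atol=1e-12)

    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=30,
        )
    )
    @settings(max_examples=100, derandomize=True)
    def test_dominates_input_and_bounded(self, p):
        q = bh_adjust(p)
        assert (q >= np.asarray(p) - 1e-15).all() and (q <= 1.0).all()
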