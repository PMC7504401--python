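"""Differential-expression engine: logFC, moderated t, BH FDR, selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from beconcord.diffexpr import (
    EBayesPrior,
    ExpressionDataset,
    ModeratedT,
    SelectionCriteria,
    bh_adjust,
    estimate_prior,
    log2_fold_change,
    select_genes,
)
from beconcord.exceptions import DomainError, GroupingError
from beconcord.simulate import ExpressionSimSpec, simulate_expression


def bh_bruteforce(p):
    """Direct min-over-suffix definition of the BH step-up adjustment."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    sorted_p = p[order]
    adj_sorted = [
        min(min(sorted_p[j] * n / (j + 1) for j in range(i, n)), 1.0)
        for i in range(n)
    ]
    out = np.empty(n)
    out[order] = adj_sorted
    return out


class TestLog2FoldChange:
    def test_forced_arithmetic(self, tiny_dataset):
        lfc = log2_fold_change(tiny_dataset)
        assert lfc["pA"] == pytest.approx(2.0)  # {5,5,5} vs {3,3,3}
        assert lfc["pB"] == pytest.approx(0.5)
        assert lfc["pC"] == pytest.approx(0.0)  # identical group means

    def test_requires_both_groups(self, tiny_dataset):
        with pytest.raises(GroupingError):
            ExpressionDataset(
                values=tiny_dataset.values,
                gene_symbols=tiny_dataset.gene_symbols,
                groups=pd.Series("BE", index=tiny_dataset.values.columns),
            )


class TestBHAdjust:
    def test_single_p_identity(self):
        assert bh_adjust(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_hand_computed_example(self):
        got = bh_adjust(np.array([0.01, 0.04, 0.03, 0.005]))
        assert got == pytest.approx([0.02, 0.04, 0.04, 0.02])

    def test_against_bruteforce_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 51))
            np.testing.assert_allclose(bh_adjust(p), bh_bruteforce(p), atol=1e-12)

    def test_against_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(7)
        p = rng.uniform(size=200)
        np.testing.assert_allclose(
            bh_adjust(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
        )

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40)
    )
    @settings(deadline=None, max_examples=200)
    def test_definition_properties(self, p):
        p = np.array(p)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)
        perm = np.random.default_rng(0).permutation(len(p))
        np.testing.assert_allclose(bh_adjust(p[perm]), adj[perm], atol=1e-12)

    def test_domain_error(self):
        with pytest.raises(DomainError):
            bh_adjust(np.array([0.5, 1.5]))


class TestModeratedT:
    def test_d0_zero_equals_classical_pooled_t(self, sim_expression):
        ds, _ = sim_expression
        res = ModeratedT(ds).fit(prior=EBayesPrior(0.0, 1.0))
        be = ds.group_matrix("BE").to_numpy()
        nm = ds.group_matrix("normal").to_numpy()
        classic = stats.ttest_ind(be, nm, axis=1)
        np.testing.assert_allclose(
            res.frame["t_mod"].to_numpy(), classic.statistic, atol=1e-10
        )
        np.testing.assert_allclose(res.frame["p"].to_numpy(), classic.pvalue, atol=1e-10)

    def test_d0_inf_pools_to_prior_variance(self, sim_expression):
        ds, _ = sim_expression
        s0 = 0.05
        res = ModeratedT(ds).fit(prior=EBayesPrior(np.inf, s0))
        n = (ds.groups == "BE").sum()
        expected = res.frame["logFC"] / (np.sqrt(s0) * np.sqrt(2.0 / n))
        np.testing.assert_allclose(res.frame["t_mod"], expected, atol=1e-12)

    def test_adj_p_dominates_p(self, sim_expression):
        ds, _ = sim_expression
        frame = ModeratedT(ds).fit().frame
        assert (frame["adj_p"] >= frame["p"] - 1e-15).all()
        assert (frame["adj_p"] <= 1.0).all()

    def test_null_pvalues_uniform(self):
        """With no true effects, moderated-t p-values are U(0,1) to KS 0.05."""
        spec = ExpressionSimSpec(
            n_genes=2000, n_per_group=7, true_logfc=[0.0] * 2000, d0=4, s0_sq=0.05, seed=17
        )
        ds, _ = simulate_expression(spec)
        frame = ModeratedT(ds).fit().frame
        ks = stats.kstest(frame["p"], "uniform").statistic
        assert ks < 0.05

    def test_prior_recovery_envelope(self):
        """Moment-matching recovers (d0, s0_sq) from data simulated under the
        scaled inverse-chi-square variance model."""
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            spec = ExpressionSimSpec(
                n_genes=2000,
                n_per_group=7,
                true_logfc=[0.0] * 2000,
                d0=4.0,
                s0_sq=0.05,
                seed=seed,
            )
            ds, _ = simulate_expression(spec)
            prior = ModeratedT(ds).fit().prior
            if 2.5 <= prior.d0 <= 6.5 and 0.035 <= prior.s0_sq <= 0.07:
                hits += 1
        assert hits >= 0.9 * n_seeds

    def test_estimate_prior_pooled_limit(self):
        # equal variances -> no excess spread -> d0 = inf
        s2 = np.full(100, 0.05)
        prior = estimate_prior(s2, np.full(100, 12.0))
        assert np.isinf(prior.d0)


KRT10_EVIDENCE = [
    ("KRT10", "D1", -1.9265443, 4.80e-03, True),
    ("KRT10", "D2", -1.9039765, 1.43e-02, True),
    ("KRT10", "D3", 0.0731168, 0.925, True),
]
KRT23_EVIDENCE = [
    ("KRT23", "D1", -2.0889186, 3.74e-02, True),
    ("KRT23", "D2", -1.2800192, 7.70e-02, True),
    ("KRT23", "D3", 0.0060589, 0.997, True),
]
MUC5AC_EVIDENCE = [
    ("MUC5AC", "D1", 8.1766871, 8.25e-07, True),
    ("MUC5AC", "D2", np.nan, np.nan, False),
    ("MUC5AC", "D3", 7.1466461, 0.005318, True),
]


def evidence_frame(rows):
    return pd.DataFrame(
        rows, columns=["gene", "dataset", "logFC", "adj_p", "present"]
    )


class TestSelectGenes:
    def test_no_dataset_passes_both_thresholds(self):
        out = select_genes(evidence_frame(KRT10_EVIDENCE))
        assert out.loc["KRT10", "decision"] == "excluded"

    def test_one_qualifying_dataset_suffices(self):
        out = select_genes(evidence_frame(KRT23_EVIDENCE))
        assert out.loc["KRT23", "decision"] == "selected_down"

    def test_absent_from_one_dataset_excluded(self):
        out = select_genes(evidence_frame(MUC5AC_EVIDENCE))
        assert out.loc["MUC5AC", "decision"] == "excluded"

    def test_absence_tolerated_when_not_required(self):
        crit = SelectionCriteria(require_all_datasets=False)
        out = select_genes(evidence_frame(MUC5AC_EVIDENCE), crit)
        assert out.loc["MUC5AC", "decision"] == "selected_up"

    def test_opposite_significant_signs_conflict(self):
        rows = [
            ("G", "D1", 3.0, 0.001, True),
            ("G", "D2", -3.0, 0.001, True),
        ]
        out = select_genes(evidence_frame(rows))
        assert out.loc["G", "decision"] == "conflict"

    def test_empty_evidence_empty_result(self):
        out = select_genes(evidence_frame([]))
        assert out.empty

    def test_monotonicity_in_thresholds(self, evidence):
        """Raising the fold threshold or lowering alpha never grows the panel."""
        base = select_genes(evidence, SelectionCriteria())
        selected = lambda t: set(
            t.index[t["decision"].isin(["selected_up", "selected_down"])]
        )
        for crit in [
            SelectionCriteria(lfc_threshold=3.0),
            SelectionCriteria(alpha=0.01),
            SelectionCriteria(lfc_threshold=4.0, alpha=0.001),
        ]:
            assert selected(select_genes(evidence, crit)) <= selected(base)

    def test_alpha_zero_selects_nothing(self, evidence):
        out = select_genes(evidence, SelectionCriteria(alpha=0.0))
        assert not out["decision"].isin(["selected_up", "selected_down"]).any()
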