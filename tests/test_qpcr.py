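"""2^-ddCt quantification: replicate aggregation, normalization, Dunnett,
direction calling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from beconcord.exceptions import (
    ConfigurationError,
    InsufficientReplicationError,
    ReferenceIntegrityError,
)
from beconcord.qpcr import (
    RelativeQuantifier,
    aggregate_replicates,
    call_direction,
    compare_groups,
    direction_calls,
    dunnett_pvalue,
)
from beconcord.simulate import CtSimSpec, simulate_ct


def ct_frame(rows):
    return pd.DataFrame(
        rows, columns=["sample_id", "condition", "gene", "replicate", "ct"]
    )


class TestAggregateReplicates:
    @pytest.mark.parametrize(
        "cts, expected_ct, expected_detected",
        [
            ([24.1, 24.3], 24.2, True),  # arithmetic mean
            ([np.nan, np.nan, np.nan], np.nan, False),  # all missing
            ([30.0, np.nan], 30.0, True),  # half missing is not a majority
            ([30.0, np.nan, np.nan], np.nan, False),  # 2/3 missing is
            ([29.0, 30.0, np.nan], 29.5, True),
        ],
    )
    def test_majority_rule(self, cts, expected_ct, expected_detected):
        rows = [("s1", "c", "G", i + 1, ct) for i, ct in enumerate(cts)]
        out = aggregate_replicates(ct_frame(rows))
        assert bool(out["detected"].iloc[0]) is expected_detected
        if expected_detected:
            assert out["ct"].iloc[0] == pytest.approx(expected_ct)
        else:
            assert np.isnan(out["ct"].iloc[0])


def two_condition_table():
    """Hand example: control dCt 4, treated dCt 2 -> ddCt -2, RQ 4."""
    rows = []
    for cond, tct in [("control", 25.0), ("treated", 23.0)]:
        for s in (1, 2):
            sid = f"{cond}{s}"
            rows += [
                (sid, cond, "T", 1, tct),
                (sid, cond, "ACTB", 1, 20.0),
                (sid, cond, "GAPDH", 1, 22.0),
            ]
    return ct_frame(rows)


class TestDeltaDeltaCt:
    def test_hand_computed_example(self):
        res = RelativeQuantifier(
            two_condition_table(), reference_condition="control"
        ).fit()
        t = res.frame.set_index(["gene", "condition"])
        assert t.loc[("T", "control"), "delta_ct"] == pytest.approx(4.0)
        assert t.loc[("T", "treated"), "delta_ct"] == pytest.approx(2.0)
        assert t.loc[("T", "treated"), "delta_delta_ct"] == pytest.approx(-2.0)
        assert t.loc[("T", "treated"), "rq"] == pytest.approx(4.0)
        assert t.loc[("T", "control"), "rq"] == pytest.approx(1.0)

    def test_shift_invariance(self):
        """Adding a constant to every Ct of one sample changes no RQ."""
        base = two_condition_table()
        shifted = base.copy()
        shifted.loc[shifted["sample_id"] == "treated1", "ct"] += 3.0
        rq_a = RelativeQuantifier(base, reference_condition="control").fit().frame["rq"]
        rq_b = (
            RelativeQuantifier(shifted, reference_condition="control").fit().frame["rq"]
        )
        np.testing.assert_allclose(rq_a, rq_b)

    def test_reference_gene_undetected_raises(self):
        bad = two_condition_table()
        bad.loc[
            (bad["sample_id"] == "control1") & (bad["gene"] == "ACTB"), "ct"
        ] = np.nan
        with pytest.raises(ReferenceIntegrityError, match="ACTB"):
            RelativeQuantifier(bad, reference_condition="control").fit()

    def test_missing_reference_condition_raises(self):
        with pytest.raises(ConfigurationError):
            RelativeQuantifier(two_condition_table(), reference_condition="nope")


class TestCompareGroups:
    def test_identical_groups_p_one(self):
        p = compare_groups({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]}, "a")
        assert p["b"] == pytest.approx(1.0)

    def test_matches_scipy_ttest(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(0, 1, 6), rng.normal(1, 1, 6)
        p = compare_groups({"ref": x, "trt": y}, "ref")["trt"]
        assert p == pytest.approx(stats.ttest_ind(y, x).pvalue, abs=1e-12)

    def test_insufficient_replication(self):
        with pytest.raises(InsufficientReplicationError):
            compare_groups({"a": [1.0, 2.0], "b": [1.0]}, "a")

    def test_dunnett_cross_checked_against_scipy(self):
        rng = np.random.default_rng(11)
        ctrl = rng.normal(0, 1, 5)
        g1, g2, g3 = rng.normal(0.8, 1, 5), rng.normal(0, 1, 5), rng.normal(-0.5, 1, 7)
        mine = compare_groups({"c": ctrl, "x": g1, "y": g2, "z": g3}, "c")
        ref = stats.dunnett(
            g1, g2, g3, control=ctrl, random_state=np.random.default_rng(0)
        ).pvalue
        for got, want in zip([mine["x"], mine["y"], mine["z"]], ref):
            assert got == pytest.approx(want, abs=2e-3)


class TestDunnettPvalue:
    @pytest.mark.parametrize("t", [0.5, 1.5, 2.7])
    @pytest.mark.parametrize("nu", [4, 10, 30])
    def test_k1_reduces_to_two_sided_t(self, t, nu):
        p = dunnett_pvalue(t, nu, [np.sqrt(0.5)])
        assert p == pytest.approx(2 * stats.t.sf(t, nu), abs=1e-6)

    def test_monotone_in_t(self):
        lam = [np.sqrt(0.5)] * 3
        ps = [dunnett_pvalue(t, 16, lam) for t in (0.5, 1.0, 2.0, 3.0)]
        assert ps == sorted(ps, reverse=True)

    def test_adjusted_exceeds_unadjusted(self):
        # familywise correction can only raise the single-comparison p
        for t in (1.0, 2.0, 3.0):
            p1 = dunnett_pvalue(t, 16, [np.sqrt(0.5)])
            p3 = dunnett_pvalue(t, 16, [np.sqrt(0.5)] * 3)
            assert p3 >= p1 - 1e-12

    def test_t_zero_is_one(self):
        assert dunnett_pvalue(0.0, 10, [np.sqrt(0.5)] * 3) == 1.0


class TestCallDirection:
    @pytest.mark.parametrize(
        "rq, p, detected, expected",
        [
            (0.25, 0.001, True, "down"),
            (1.9, 0.0001, True, "no_change"),  # fold below threshold
            (3.0, 0.2, True, "no_change"),  # not significant
            (4.0, 0.01, False, "na"),
            (2.0, 0.01, True, "up"),  # boundary inclusive
            (0.5, 0.01, True, "down"),  # boundary inclusive
            (np.nan, np.nan, True, "nd"),
        ],
    )
    def test_threshold_rule(self, rq, p, detected, expected):
        assert call_direction(rq, p, detected) == expected


class TestNoiselessRecovery:
    def test_rq_equals_true_fold_and_calls_exact(self, noiseless_ct):
        table, truth = noiseless_ct
        res = RelativeQuantifier(table, reference_condition="control").fit()
        t = res.frame.set_index(["gene", "condition"])
        for gene, fold in [("G_UP", 4.0), ("G_NC", 1.0), ("G_DOWN", 0.25)]:
            assert t.loc[(gene, "treated"), "rq"] == pytest.approx(fold)
            assert t.loc[(gene, "treated"), "delta_delta_ct"] == pytest.approx(
                -np.log2(fold)
            )
        calls = direction_calls(res, "treated").set_index("gene")["status"]
        assert calls.to_dict() == {
            "G_UP": "up",
            "G_NC": "no_change",
            "G_DOWN": "down",
            "G_NA": "na",
        }

    def test_stochastic_rq_recovery_short(self):
        """Mean recovered RQ over 30 seeds within 10% of truth (quick check;
        the 200-seed version runs in the acceptance suite)."""
        rqs = []
        for seed in range(30):
            spec = CtSimSpec(
                genes=["ACTB", "GAPDH", "G"],
                conditions=["control", "treated"],
                true_fold={"G": {"treated": 0.25}},
                noise_sd=0.15,
                n_replicates=3,
                n_samples=5,
                seed=seed,
            )
            table, _ = simulate_ct(spec)
            res = RelativeQuantifier(table, reference_condition="control").fit()
            t = res.frame.set_index(["gene", "condition"])
            rqs.append(t.loc[("G", "treated"), "rq"])
        assert np.mean(rqs) == pytest.approx(0.25, rel=0.10)
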