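"""Per-gene Welch tests and ddCt relative quantification."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from allelerx.expression_stats import (
    StatsError,
    compare_candidate_genes,
    ddct,
    results_to_frame,
)
from allelerx.synthetic_data import simulate_ct_table

SAMPLES_A = ["a1", "a2", "a3"]
SAMPLES_B = ["b1", "b2", "b3"]
GROUPS = {**{s: "treated" for s in SAMPLES_A}, **{s: "control" for s in SAMPLES_B}}


def welch_oracle(a, b):
    """Closed-form Welch t, Satterthwaite df, and p from the t CDF."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p


class TestCompareCandidateGenes:
    def test_identical_group_distributions_give_t0_p1(self):
        expr = pd.DataFrame(
            [[3.0, 5.0, 7.0, 3.0, 5.0, 7.0]], index=["g1"],
            columns=SAMPLES_A + SAMPLES_B,
        )
        (r,) = compare_candidate_genes(expr, GROUPS, "treated", "control", ["g1"])
        assert r.t_stat == pytest.approx(0.0, abs=1e-12)
        assert r.p_raw == pytest.approx(1.0)

    def test_all_zero_gene_flagged_not_detected(self):
        expr = pd.DataFrame(
            [[0.0] * 6, [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]],
            index=["Gm_zero", "g2"], columns=SAMPLES_A + SAMPLES_B,
        )
        results = compare_candidate_genes(
            expr, GROUPS, "treated", "control", ["Gm_zero", "g2"]
        )
        zero = results[0]
        assert not zero.detected
        assert zero.p_raw is None and zero.p_adj is None
        assert results[1].detected and results[1].p_raw is not None

    def test_welch_matches_independent_computation(self, rng):
        genes = {}
        for i in range(20):
            genes[f"g{i}"] = np.concatenate(
                [rng.normal(10 + i, 1 + 0.2 * i, 3), rng.normal(10, 2, 3)]
            )
        expr = pd.DataFrame(genes).T
        expr.columns = SAMPLES_A + SAMPLES_B
        results = compare_candidate_genes(
            expr, GROUPS, "treated", "control", list(genes)
        )
        for r in results:
            a = expr.loc[r.gene, SAMPLES_A]
            b = expr.loc[r.gene, SAMPLES_B]
            t, df, p = welch_oracle(a, b)
            assert r.t_stat == pytest.approx(t, abs=1e-10)
            assert r.df == pytest.approx(df, abs=1e-10)
            assert r.p_raw == pytest.approx(p, abs=1e-10)

    def test_group_swap_flips_t_and_preserves_p(self, rng):
        expr = pd.DataFrame(
            [rng.normal(5, 1, 6)], index=["g1"], columns=SAMPLES_A + SAMPLES_B
        )
        (fwd,) = compare_candidate_genes(expr, GROUPS, "treated", "control", ["g1"])
        (rev,) = compare_candidate_genes(expr, GROUPS, "control", "treated", ["g1"])
        assert fwd.t_stat == pytest.approx(-rev.t_stat, rel=1e-12)
        assert fwd.p_raw == pytest.approx(rev.p_raw, rel=1e-12)

    def test_bh_adjustment_order_invariant_and_bounded(self, rng):
        genes = {f"g{i}": rng.normal(5 + (i % 4), 1, 6) for i in range(12)}
        expr = pd.DataFrame(genes).T
        expr.columns = SAMPLES_A + SAMPLES_B
        order1 = list(genes)
        order2 = list(reversed(order1))
        r1 = {r.gene: r.p_adj for r in compare_candidate_genes(
            expr, GROUPS, "treated", "control", order1)}
        r2 = {r.gene: r.p_adj for r in compare_candidate_genes(
            expr, GROUPS, "treated", "control", order2)}
        for g in order1:
            assert r1[g] == pytest.approx(r2[g], rel=1e-12)
        for r in compare_candidate_genes(expr, GROUPS, "treated", "control", order1):
            assert r.p_raw <= r.p_adj <= 1.0

    def test_missing_gene_listed_in_error(self):
        expr = pd.DataFrame(
            [[1.0] * 6], index=["g1"], columns=SAMPLES_A + SAMPLES_B
        )
        with pytest.raises(StatsError, match="ghost"):
            compare_candidate_genes(expr, GROUPS, "treated", "control", ["ghost"])

    def test_degenerate_gene_skipped_with_reason(self):
        expr = pd.DataFrame(
            [[2.0] * 6], index=["g1"], columns=SAMPLES_A + SAMPLES_B
        )
        (r,) = compare_candidate_genes(expr, GROUPS, "treated", "control", ["g1"])
        assert r.note == "degenerate"
        assert r.p_raw is None and r.detected

    def test_small_group_rejected(self):
        expr = pd.DataFrame(
            [[1.0, 2.0, 3.0]], index=["g1"], columns=["a1", "a2", "b1"]
        )
        groups = {"a1": "treated", "a2": "treated", "b1": "control"}
        with pytest.raises(StatsError, match=">= 2 samples"):
            compare_candidate_genes(expr, groups, "treated", "control", ["g1"])

    def test_results_frame_has_all_genes(self, rng):
        expr = pd.DataFrame(
            [[0.0] * 6, list(rng.normal(4, 1, 6))],
            index=["gz", "g1"], columns=SAMPLES_A + SAMPLES_B,
        )
        frame = results_to_frame(
            compare_candidate_genes(expr, GROUPS, "treated", "control", ["gz", "g1"])
        )
        assert list(frame["gene"]) == ["gz", "g1"]
        assert frame["detected"].tolist() == [False, True]


class TestDdct:
    def _table(self, rows):
        return pd.DataFrame(
            rows, columns=["sample", "condition", "ct_target", "ct_reference"]
        )

    def test_flat_table_gives_unity(self):
        ct = self._table(
            [["t1", "treated", 24.0, 24.0], ["c1", "control", 24.0, 24.0],
             ["c2", "control", 24.0, 24.0]]
        )
        per_sample, summary = ddct(ct)
        assert (per_sample["rel_expr"] == 1.0).all()
        ctrl = summary[summary["condition"] == "control"].iloc[0]
        assert ctrl["geometric_mean"] == pytest.approx(1.0)

    def test_one_cycle_earlier_doubles_expression(self):
        ct = self._table(
            [["t1", "treated", 23.0, 24.0], ["c1", "control", 24.0, 24.0],
             ["c2", "control", 24.0, 24.0]]
        )
        per_sample, _ = ddct(ct)
        assert per_sample.loc[per_sample["sample"] == "t1", "rel_expr"].iloc[
            0
        ] == pytest.approx(2.0)

    def test_matches_closed_form_on_random_table(self, rng):
        rows = []
        for i in range(4):
            rows.append([f"t{i}", "treated", rng.uniform(20, 30), rng.uniform(18, 22)])
        for i in range(4):
            rows.append([f"c{i}", "control", rng.uniform(20, 30), rng.uniform(18, 22)])
        ct = self._table(rows)
        per_sample, _ = ddct(ct)
        dct = ct["ct_target"] - ct["ct_reference"]
        control_mean = dct[ct["condition"] == "control"].mean()
        expected = 2.0 ** (-(dct - control_mean))
        assert np.allclose(per_sample["rel_expr"], expected, atol=1e-10)

    def test_invariant_to_sample_wide_ct_shift(self, rng):
        rows = [
            ["t1", "treated", 25.0, 22.0],
            ["c1", "control", 24.0, 21.5],
            ["c2", "control", 23.0, 22.5],
        ]
        ct = self._table(rows)
        shifted = ct.copy()
        shifted.loc[0, ["ct_target", "ct_reference"]] += 3.7  # one sample's offset
        base, _ = ddct(ct)
        moved, _ = ddct(shifted)
        assert np.allclose(base["rel_expr"], moved["rel_expr"], atol=1e-12)

    def test_missing_reference_names_sample(self):
        ct = self._table(
            [["t1", "treated", 24.0, np.nan], ["c1", "control", 24.0, 24.0]]
        )
        with pytest.raises(StatsError, match="t1"):
            ddct(ct)

    def test_recovers_simulated_truth_noise_free(self):
        truth_rel = {"t1": 0.3, "t2": 0.3, "c1": 1.0, "c2": 1.0}
        conditions = {"t1": "treated", "t2": "treated", "c1": "control", "c2": "control"}
        ct, _ = simulate_ct_table(truth_rel, conditions, noise_sd=0.0, seed=4)
        per_sample, _ = ddct(ct)
        by_sample = dict(zip(per_sample["sample"], per_sample["rel_expr"]))
        for sample, rel in truth_rel.items():
            assert by_sample[sample] == pytest.approx(rel, abs=1e-10)

    def test_noisy_recovery_within_lognormal_tolerance(self):
        noise_sd, truth = 0.1, 0.3
        rels = {f"t{i}": truth for i in range(6)} | {f"c{i}": 1.0 for i in range(6)}
        conds = {f"t{i}": "treated" for i in range(6)} | {
            f"c{i}": "control" for i in range(6)
        }
        estimates = []
        for seed in range(10):
            ct, _ = simulate_ct_table(rels, conds, noise_sd=noise_sd, seed=seed)
            per_sample, summary = ddct(ct)
            estimates.append(
                float(
                    summary.loc[
                        summary["condition"] == "treated", "geometric_mean"
                    ].iloc[0]
                )
            )
        # log2(rel) has SD sqrt(2)*noise_sd per sample; the geometric mean
        # over 6 treated samples (plus control-mean noise) stays within 3 SE
        log_est = np.log2(estimates)
        se = math.sqrt(2) * noise_sd * math.sqrt(1 / 6 + 1 / 6) / math.sqrt(10)
        assert abs(log_est.mean() - math.log2(truth)) < 3 * se
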