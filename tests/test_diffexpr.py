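"""Normalization and differential-test contracts with hand-worked oracles."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fibroscore import synthdata
from fibroscore.diffexpr import (
    bh_adjust, de_test, signed_fold_change, size_factors, total_area_normalize,
)

from conftest import make_design


def brute_force_bh(p):
    """Textbook step-up: p_(i) * m / i with running minimum from the top."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    out = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        out[i] = running
    return out


class TestSizeFactors:
    def test_two_sample_doubling(self):
        counts = pd.DataFrame({"s1": [10, 20, 30], "s2": [20, 40, 60]})
        sf = size_factors(counts)
        assert sf.to_numpy() == pytest.approx([1 / math.sqrt(2), math.sqrt(2)])

    def test_identical_samples_give_unit_factors(self, rng):
        col = rng.integers(1, 500, 50)
        counts = pd.DataFrame({f"s{j}": col for j in range(4)})
        assert size_factors(counts).to_numpy() == pytest.approx(np.ones(4))

    def test_scaling_property_matches_brute_force(self, rng):
        counts = pd.DataFrame(rng.integers(1, 1000, (100, 6)).astype(np.int64),
                              columns=[f"s{j}" for j in range(6)])
        c = 3.7
        scaled = counts.copy()
        scaled["s2"] = (scaled["s2"] * c).round().astype(np.int64)
        # brute-force definition on the scaled matrix
        x = scaled.to_numpy(dtype=float)
        geo = np.exp(np.log(x).mean(axis=1))
        expected = np.median(x / geo[:, None], axis=0)
        assert size_factors(scaled).to_numpy() == pytest.approx(expected)
        # the scaled sample's factor grows ~c, up to the geometric-mean shift
        n = counts.shape[1]
        base = size_factors(counts)
        exact_scaled = counts.copy().astype(float)
        exact_scaled["s2"] *= c
        sf2 = size_factors(exact_scaled)
        assert sf2["s2"] / base["s2"] == pytest.approx(c ** ((n - 1) / n))
        others = [s for s in counts.columns if s != "s2"]
        assert (sf2[others] / base[others]).to_numpy() == pytest.approx(
            np.full(n - 1, c ** (-1 / n))
        )

    def test_no_universally_positive_gene_is_error(self):
        counts = pd.DataFrame({"s1": [0, 5], "s2": [5, 0]})
        with pytest.raises(ValueError, match="positive in all samples"):
            size_factors(counts)


class TestTotalArea:
    def test_equal_sums_unchanged(self):
        m = pd.DataFrame({"a": [1.0, 3.0], "b": [2.0, 2.0]})
        assert total_area_normalize(m).to_numpy() == pytest.approx(m.to_numpy())

    def test_sums_10_and_30_become_20(self):
        m = pd.DataFrame({"a": [4.0, 6.0], "b": [10.0, 20.0]})
        out = total_area_normalize(m)
        assert out.sum().to_numpy() == pytest.approx([20.0, 20.0])

    def test_column_sums_equal_on_random_input(self, rng):
        m = pd.DataFrame(rng.uniform(1, 100, (30, 5)))
        out = total_area_normalize(m)
        sums = out.sum().to_numpy()
        assert sums == pytest.approx(np.full(5, sums[0]), abs=1e-9)

    def test_zero_sum_column_is_error(self):
        m = pd.DataFrame({"a": [1.0, 2.0], "b": [0.0, 0.0]})
        with pytest.raises(ValueError, match="zero-sum"):
            total_area_normalize(m)


class TestBHAdjust:
    def test_hand_worked_example(self):
        out = bh_adjust([0.01, 0.04, 0.03, 0.05])
        assert out == pytest.approx([0.04, 0.05, 0.05, 0.05])

    def test_all_ones_and_singleton(self):
        assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1, 1, 1])
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_equals_brute_force_step_up(self, p):
        assert bh_adjust(p) == pytest.approx(brute_force_bh(p), abs=1e-12)

    def test_cross_checks_against_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.uniform(0, 1, 200)
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        assert bh_adjust(p) == pytest.approx(ref, abs=1e-12)

    @pytest.mark.parametrize("bad", [[-0.1], [1.3], [float("nan")]])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            bh_adjust(bad)


class TestSignedFoldChange:
    def test_negative_reciprocal_convention(self):
        assert signed_fold_change([1.0, 0.0, -1.0]) == pytest.approx([2.0, 1.0, -2.0])


def null_counts(rng, n_genes=300, n=6):
    design = make_design(sources=("A",), n_rep=n // 2)
    counts = pd.DataFrame(rng.poisson(200, (n_genes, n)),
                          index=[f"g{i}" for i in range(n_genes)],
                          columns=design["sample_id"].tolist())
    return counts, design


class TestDETest:
    def test_transcript_rule_planted_recovery(self):
        cfg = synthdata.SimulationConfig(
            n_genes=500, n_proteins=1, sources=("aHCF",), frac_deg=0.1,
            nb_mean_log_mu=6.0, nb_mean_log_sd=0.5, panel_response_lfc=0.0,
            panel_offset=0.0, preactivated_sources=(), seed=8,
        )
        counts, design, truth = synthdata.simulate_counts(cfg)
        de = de_test(counts, design, "aHCF", "transcript")
        assert list(de.columns) == [
            "feature_id", "mean_control", "mean_treated", "log2fc",
            "signed_fc", "p_value", "fdr", "call",
        ]
        planted = truth.deg_sets["aHCF"]
        called = set(de.loc[de["call"] != "ns", "feature_id"])
        recovered = len(called & set(planted)) / len(planted)
        assert recovered > 0.9
        # directions match the planted signs
        sub = de.set_index("feature_id")
        for g, lfc in planted.items():
            if g in called:
                assert sub.loc[g, "call"] == ("up" if lfc > 0 else "down")

    def test_protein_fc_gate_blocks_small_folds(self, rng):
        # strongly consistent but small shift: significant FDR, FC below 1.5
        design = make_design(sources=("A",), n_rep=3)
        base = rng.uniform(1e4, 1e6, 200)
        m = pd.DataFrame(
            np.outer(base, np.ones(6)) * rng.lognormal(0, 0.05, (200, 6)),
            index=[f"p{i}" for i in range(200)], columns=design["sample_id"].tolist(),
        )
        treated = design.loc[design["condition"] == "treated", "sample_id"]
        m.loc["p0", treated] *= 2 ** 0.4      # FC 1.32 < 1.5
        m.loc["p1", treated] *= 2 ** 1.0      # FC 2.0 > 1.5
        de = de_test(m, design, "A", "protein").set_index("feature_id")
        assert de.loc["p0", "fdr"] < 0.1
        assert de.loc["p0", "call"] == "ns"
        assert de.loc["p1", "call"] == "up"

    def test_label_swap_negates_lfc_preserves_p(self, rng):
        counts, design = null_counts(rng)
        swapped = design.copy()
        swapped["condition"] = swapped["condition"].map(
            {"control": "treated", "treated": "control"}
        )
        a = de_test(counts, design, "A", "transcript")
        b = de_test(counts, swapped, "A", "transcript")
        assert a["log2fc"].to_numpy() == pytest.approx(-b["log2fc"].to_numpy(), abs=1e-9)
        assert a["p_value"].to_numpy() == pytest.approx(b["p_value"].to_numpy(), abs=1e-9)

    def test_explicit_size_factors_absorb_sample_scaling_exactly(self, rng):
        counts, design = null_counts(rng)
        sf = size_factors(counts)
        a = de_test(counts, design, "A", "transcript", sample_size_factors=sf)
        scaled = counts.copy()
        target = counts.columns[1]
        scaled[target] *= 8
        sf2 = sf.copy()
        sf2[target] *= 8.0
        b = de_test(scaled, design, "A", "transcript", sample_size_factors=sf2)
        assert a["p_value"].to_numpy() == pytest.approx(b["p_value"].to_numpy(), abs=1e-9)
        assert a["log2fc"].to_numpy() == pytest.approx(b["log2fc"].to_numpy(), abs=1e-9)

    def test_reestimated_factors_leave_only_pseudocount_residue(self, rng):
        # re-estimation leaves a global 8^(1/n) rescaling that interacts with
        # the +1 pseudocount; at count scale ~200 the p shift stays small
        counts, design = null_counts(rng)
        a = de_test(counts, design, "A", "transcript")
        scaled = counts.copy()
        scaled[counts.columns[1]] *= 8
        b = de_test(scaled, design, "A", "transcript")
        assert np.abs(a["p_value"].to_numpy() - b["p_value"].to_numpy()).max() < 0.02

    def test_single_replicate_group_rejected(self, rng):
        design = make_design(sources=("A",), n_rep=2)
        keep = design["sample_id"] != "A_treated_2"
        counts = pd.DataFrame(rng.poisson(100, (20, keep.sum())),
                              columns=design.loc[keep, "sample_id"].tolist())
        with pytest.raises(ValueError, match=">= 2 replicates"):
            de_test(counts, design[keep].reset_index(drop=True), "A", "transcript")

    def test_zero_variance_everywhere_rejected(self):
        design = make_design(sources=("A",), n_rep=3)
        m = pd.DataFrame(np.full((5, 6), 7.0), columns=design["sample_id"].tolist())
        with pytest.raises(ValueError, match="variance"):
            de_test(m, design, "A", "protein")
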