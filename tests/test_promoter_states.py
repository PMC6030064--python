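"""Four-state promoter classification and transition/retention tables."""

import numpy as np
import pandas as pd
import pytest

from chromfate.core_io import FragmentSet, TssAnnotation, make_binned_track
from chromfate.promoter_states import (
    STATES,
    classify_promoter,
    classify_states,
    quantify_promoters,
    signal_by_class,
    transition_table,
)


class TestClassifyPromoter:
    @pytest.mark.parametrize(
        "k4,k27,expected",
        [
            (True, False, "active"),
            (True, True, "bivalent"),
            (False, True, "repressive"),
            (False, False, "no_mark"),
        ],
    )
    def test_mapping(self, k4, k27, expected):
        assert classify_promoter(k4, k27) == expected

    def test_total_function_distinct_outputs(self):
        outputs = {classify_promoter(a, b) for a in (True, False) for b in (True, False)}
        assert outputs == set(STATES)


class TestQuantifyPromoters:
    def test_window_coordinates(self, tiny_tss, make_fragset):
        chip = make_fragset("c", [("chr1", 9_000, 9_200)])
        inp = make_fragset("i", [("chr1", 9_000, 9_200)])
        k4 = quantify_promoters(chip, inp, tiny_tss, "H3K4me3")
        k27 = quantify_promoters(chip, inp, tiny_tss, "H3K27me3")
        a4 = k4[k4["gene_id"] == "geneA"].iloc[0]
        a27 = k27[k27["gene_id"] == "geneA"].iloc[0]
        assert (a4["start"], a4["end"]) == (8_000, 12_000)
        assert (a27["start"], a27["end"]) == (5_000, 15_000)

    def test_enrichment_arithmetic(self, make_fragset):
        # one promoter: chip 40 fragments vs input 10, equal library sizes
        tss = TssAnnotation(
            pd.DataFrame(
                {"gene_id": ["g1"], "chrom": ["chr1"], "strand": ["+"], "tss": [50_000]}
            )
        )
        chip_frags = [("chr1", 49_000 + i, 49_200 + i) for i in range(40)]
        inp_frags = [("chr1", 49_000 + i, 49_200 + i) for i in range(10)]
        # pad both libraries with distant fragments to a common depth
        pad = [("chr1", 500_000 + 10 * i, 500_200 + 10 * i) for i in range(990)]
        chip = make_fragset("c", chip_frags + pad[: 1000 - 40])
        inp = make_fragset("i", inp_frags + pad[: 1000 - 10])
        q = quantify_promoters(chip, inp, tss, "H3K4me3")
        row = q.iloc[0]
        assert row["chip_count"] == 40 and row["input_count"] == 10
        # cpm pseudocount 0.5: log2((40000+0.5)/(10000+0.5)) ~ 2
        assert row["log2_ratio"] == pytest.approx(2.0, abs=1e-3)
        assert row["present"] == (row["log2_ratio"] > 1 and row["q_value"] < 0.05)

    def test_empty_tss_errors(self, make_fragset):
        tss = TssAnnotation(
            pd.DataFrame(columns=["gene_id", "chrom", "strand", "tss"]).astype(
                {"tss": np.int64}
            )
        )
        chip = make_fragset("c", [("chr1", 0, 200)])
        with pytest.raises(ValueError, match="empty"):
            quantify_promoters(chip, chip, tss, "H3K4me3")


class TestClassifyStates:
    def test_universe_mismatch(self):
        k4 = pd.DataFrame({"gene_id": ["a", "b"], "present": [True, False]})
        k27 = pd.DataFrame({"gene_id": ["a", "c"], "present": [True, False]})
        with pytest.raises(ValueError, match="universe"):
            classify_states(k4, k27)


class TestTransitionTable:
    def test_identity(self):
        states = pd.Series(
            ["active", "bivalent", "repressive", "no_mark"] * 5,
            index=[f"g{i}" for i in range(20)],
        )
        table = transition_table(states, states)
        assert np.all(np.diag(table.counts) == 5)
        assert int(table.counts.to_numpy().sum()) == 20
        assert (table.retention == 1.0).all()

    def test_hand_counted_bivalent_row(self):
        genes = [f"g{i}" for i in range(10)]
        wt = pd.Series(["bivalent"] * 10, index=genes)
        ko = pd.Series(
            ["active"] * 4 + ["repressive"] * 2 + ["bivalent"] * 4, index=genes
        )
        table = transition_table(wt, ko)
        row = table.row_percent.loc["bivalent"]
        assert row.to_dict() == pytest.approx(
            {"active": 40.0, "bivalent": 40.0, "repressive": 20.0, "no_mark": 0.0}
        )
        assert table.retention["bivalent"] == pytest.approx(0.4)

    def test_empty_class_retention_missing(self):
        wt = pd.Series(["active", "active"], index=["g1", "g2"])
        ko = pd.Series(["active", "no_mark"], index=["g1", "g2"])
        table = transition_table(wt, ko)
        assert np.isnan(table.retention["bivalent"])

    def test_mismatched_universe_errors(self):
        wt = pd.Series(["active"], index=["g1"])
        ko = pd.Series(["active"], index=["g2"])
        with pytest.raises(ValueError, match="g2"):
            transition_table(wt, ko)

    def test_relabeling_invariance(self):
        genes = [f"g{i}" for i in range(12)]
        rng = np.random.default_rng(0)
        wt = pd.Series(rng.choice(STATES, 12), index=genes)
        ko = pd.Series(rng.choice(STATES, 12), index=genes)
        t1 = transition_table(wt, ko)
        renamed = {g: f"x{g}" for g in genes}
        t2 = transition_table(wt.rename(index=renamed), ko.rename(index=renamed))
        pd.testing.assert_frame_equal(t1.counts, t2.counts)


class TestSignalByClass:
    def test_planted_bivalent_signal(self, rng):
        n_per_class = 200
        rows, values = [], {}
        pos = 10_000
        for ci, state in enumerate(STATES):
            for i in range(n_per_class):
                g = f"{state}_{i}"
                rows.append((g, "chr1", "+", pos))
                values[g] = state
                pos += 5_000
        tss = TssAnnotation(
            pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss"])
        )
        states = pd.Series(values)
        # 3x signal at bivalent promoters on a binned track
        frags = FragmentSet.from_intervals("x", [])
        track = make_binned_track(frags, {"chr1": pos + 10_000}, 1_000)
        base = rng.normal(10, 1, size=len(track.values["chr1"]))
        track.values["chr1"] = np.abs(base)
        for g, state in states.items():
            t = tss.df.set_index("gene_id").loc[g, "tss"]
            if state == "bivalent":
                track.values["chr1"][t // 1_000] *= 3
        means, tests = signal_by_class(track, states, tss, halfwidth=2_000)
        assert means["bivalent"] > means["active"]
        row = tests[
            (tests["class_a"] == "active") & (tests["class_b"] == "bivalent")
        ].iloc[0]
        assert row["p_value"] < 0.01

    def test_single_class_means_only(self, make_fragset):
        tss = TssAnnotation(
            pd.DataFrame(
                {
                    "gene_id": ["g1", "g2"],
                    "chrom": ["chr1", "chr1"],
                    "strand": ["+", "+"],
                    "tss": [5_000, 15_000],
                }
            )
        )
        states = pd.Series({"g1": "active", "g2": "active"})
        frags = make_fragset("x", [("chr1", 4_000, 4_200), ("chr1", 14_000, 14_200)])
        track = make_binned_track(frags, {"chr1": 30_000}, 1_000)
        with pytest.warns(UserWarning):
            means, tests = signal_by_class(track, states, tss, halfwidth=2_000)
        assert not np.isnan(means["active"])
        assert tests["p_value"].isna().all()
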