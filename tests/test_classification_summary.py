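"""Growth-habit classification, top-fraction selection, clade summaries,
augmented-design adjustment, and candidate-gene retrieval."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import envmeta as em
from envmeta.classification_summary import (
    AugmentedLayout,
    VernClassConfig,
    _round_half_up,
    adjust_augmented,
    parse_vrn_h2_label,
)


class TestClassifyVernalization:
    @pytest.mark.parametrize(
        "dtf,expected",
        [
            (1, "insensitive"),
            (73, "insensitive"),
            (74, "intermediate"),
            (89, "intermediate"),
            (129, "intermediate"),
            (130, "sensitive"),
            (154, "sensitive"),
        ],
    )
    def test_thresholds(self, dtf, expected):
        assert em.classify_vernalization(dtf) == expected

    def test_missing_is_unclassified(self):
        assert em.classify_vernalization(None) == "unclassified"
        assert em.classify_vernalization(float("nan")) == "unclassified"

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            em.classify_vernalization(0)

    @given(st.integers(min_value=1, max_value=154))
    def test_partition_exactly_one_class(self, dtf):
        cls = em.classify_vernalization(dtf)
        assert cls in {"insensitive", "intermediate", "sensitive"}
        assert (cls == "insensitive") == (dtf <= 73)
        assert (cls == "sensitive") == (dtf >= 130)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            VernClassConfig(insensitive_max=130, sensitive_min=73)


class TestCallVrnH2:
    def test_exhaustive_truth_table(self):
        for flags in itertools.product([True, False], repeat=3):
            status = em.call_vrn_h2(*flags)
            if all(flags):
                assert status == "intact"
            elif not any(flags):
                assert status == "complete_deletion"
            else:
                assert status == "partial_deletion"

    def test_any_missing_flag_gives_missing(self):
        assert em.call_vrn_h2(None, True, True) == "missing"
        assert em.call_vrn_h2(True, None, False) == "missing"
        assert em.call_vrn_h2(None, None, None) == "missing"


class TestParseVrnH2Label:
    def test_intact(self):
        status, flags = parse_vrn_h2_label("Intact ZCCT_Ha ZCCT_Hb ZCCT_Hc")
        assert status == "intact" and flags == (True, True, True)

    def test_complete_deletion(self):
        status, flags = parse_vrn_h2_label("Deletion ZCCT_Ha ZCCT_Hb ZCCT_Hc")
        assert status == "complete_deletion"
        assert flags == (False, False, False)

    def test_partial_deletion_named_genes(self):
        status, flags = parse_vrn_h2_label("Deletion ZCCT_Ha ZCCT_Hb")
        assert status == "partial_deletion"
        assert flags == (False, False, True)

    def test_partial_deletion_unresolved(self):
        status, flags = parse_vrn_h2_label("Partial deletion")
        assert status == "partial_deletion" and flags == (None, None, None)

    def test_missing_and_garbage(self):
        assert parse_vrn_h2_label(None) == (None, (None, None, None))
        assert parse_vrn_h2_label(float("nan"))[0] is None
        with pytest.raises(ValueError):
            parse_vrn_h2_label("who knows")


class TestClassifyFacultative:
    @staticmethod
    def _calls(**kw):
        base = dict(
            accession="x",
            ppd_h2="truncated_HvFT3",
            ppd_h1="dominant_PPD-H1",
            vrn_h1="intact_intron1",
            vrn_h2_status="complete_deletion",
        )
        base.update(kw)
        return em.LocusCallSet(**base)

    def test_full_key_is_facultative(self):
        assert em.classify_facultative(self._calls(), "insensitive") == "facultative"

    def test_intact_vrn_h2_and_sensitive_is_winter(self):
        calls = self._calls(vrn_h2_status="intact", ppd_h2="intact_HvFT3")
        assert em.classify_facultative(calls, "sensitive") == "winter"

    def test_insensitive_without_full_key_is_spring_like(self):
        for broken in (
            self._calls(vrn_h2_status="intact"),
            self._calls(vrn_h2_status="partial_deletion"),
            self._calls(ppd_h2="intact_HvFT3"),
            self._calls(vrn_h1="other"),
        ):
            assert em.classify_facultative(broken, "insensitive") == "spring_like"

    def test_missing_fields_unclassified(self):
        assert (
            em.classify_facultative(self._calls(vrn_h2_status=None), "insensitive")
            == "unclassified"
        )
        assert em.classify_facultative(self._calls(), "unclassified") == "unclassified"
        assert em.classify_facultative(self._calls(), "intermediate") == "unclassified"

    def test_fixture_examples(self):
        df = em.load_locus_call_table()
        by_acc = {c.accession: c for c in em.locus_calls_from_table(df)}
        dtf = df.set_index("accession")["dtf"]
        # full facultative key, DTF 73 -> facultative
        assert (
            em.classify_facultative(
                by_acc["06OR-20"], em.classify_vernalization(dtf["06OR-20"])
            )
            == "facultative"
        )
        # intact VRN-H2, DTF 135 -> winter
        assert (
            em.classify_facultative(
                by_acc["NB09433"], em.classify_vernalization(dtf["NB09433"])
            )
            == "winter"
        )

    def test_all_missing_calls_unclassified(self):
        calls = em.LocusCallSet("x", None, None, None, None)
        assert em.classify_facultative(calls, "insensitive") == "unclassified"


class TestLocusCallTableCounts:
    def test_ppd_h2_split_among_non_insensitive(self):
        """Among re-genotyped accessions that are NOT vernalization
        insensitive and have a resolved PPD-H2 call, 11 carry the
        truncated HvFT3 allele and 7 the intact allele."""
        df = em.load_locus_call_table()
        vern = df["dtf"].map(em.classify_vernalization)
        sub = df[(vern != "insensitive") & df["ppd_h2"].notna()]
        counts = sub["ppd_h2"].value_counts()
        assert counts["truncated_HvFT3"] == 11
        assert counts["intact_HvFT3"] == 7

    def test_one_unresolved_ppd_h2(self):
        df = em.load_locus_call_table()
        assert df["ppd_h2"].isna().sum() == 1
        assert df.loc[df["ppd_h2"].isna(), "accession"].item() == "LENINAKANSKIJ"


class TestSelectTopFraction:
    def test_882_accessions_gives_44(self):
        rng = np.random.default_rng(0)
        s = pd.Series(rng.normal(50, 10, 882), index=[f"a{i:04d}" for i in range(882)])
        top = em.select_top_fraction(s, 0.05)
        assert len(top) == 44
        cutoff = top.min()
        assert (s.drop(top.index) <= cutoff).all()

    def test_sorted_descending_with_deterministic_ties(self):
        s = pd.Series(
            [90.0, 90.0, 90.0, 10.0] * 10,
            index=[f"x{i:02d}" for i in range(40)],
        )
        top = em.select_top_fraction(s, 0.1)  # floor(4) = 4
        assert len(top) == 4
        assert list(top.index) == ["x00", "x01", "x02", "x04"]
        assert (top.to_numpy()[:-1] >= top.to_numpy()[1:]).all()

    def test_zero_selection_warns(self):
        s = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.warns(UserWarning, match="zero"):
            top = em.select_top_fraction(s, 0.05)
        assert len(top) == 0

    def test_invalid_fraction(self):
        s = pd.Series([1.0], index=["a"])
        with pytest.raises(ValueError):
            em.select_top_fraction(s, 0.0)
        with pytest.raises(ValueError):
            em.select_top_fraction(s, 1.5)

    def test_nan_means_excluded_before_counting(self):
        s = pd.Series([np.nan] * 60 + list(range(40)), dtype=float)
        s.index = [f"a{i:03d}" for i in range(100)]
        top = em.select_top_fraction(s, 0.5)  # floor(0.5 * 40) = 20
        assert len(top) == 20
        assert top.notna().all()


class TestRoundHalfUp:
    @pytest.mark.parametrize(
        "x,expected", [(64.5, 65), (64.4999, 64), (0.5, 1), (2.5, 3), (-0.4, 0)]
    )
    def test_values(self, x, expected):
        assert _round_half_up(x) == expected

    def test_differs_from_bankers_rounding(self):
        assert _round_half_up(2.5) == 3
        assert round(2.5) == 2  # banker's rounding would disagree


class TestCladeSummary:
    def test_fixture_clade_means(self):
        """Per-clade mean WS of the 44 top accessions, rounded half-up."""
        df = em.load_top5_table()
        means, grand = em.clade_summary(
            df.set_index("accession")["clade"],
            df.set_index("accession")["avg_ws"].astype(float),
        )
        assert means.to_dict() == {1: 61, 2: 59, 3: 58, 4: 60, 5: 62, 6: 65, 7: 59}
        assert grand == 60

    def test_empty_clades_omitted_and_nan_dropped(self):
        membership = pd.Series({"a": 1, "b": 1, "c": 2, "d": 3})
        ws = pd.Series({"a": 10.0, "b": 11.0, "c": np.nan, "d": 20.0})
        means, grand = em.clade_summary(membership, ws)
        assert set(means.index) == {1, 3}
        assert means[1] == 11  # (10 + 11)/2 = 10.5 rounds up
        assert grand == _round_half_up((10 + 11 + 20) / 3)


class TestAdjustAugmented:
    @staticmethod
    def _layout(shift_by_block, entries_noise=None):
        """Three blocks: primary check P, secondary check S, two entries."""
        base = {"P": 50.0, "S": 40.0, "e1": 55.0, "e2": 45.0}
        blocks = {}
        for b, shift in shift_by_block.items():
            blocks[b] = {k: v + shift for k, v in base.items()}
        return AugmentedLayout(
            blocks=blocks, primary_check="P", secondary_checks=("S",)
        )

    def test_none_is_identity_with_re_one(self):
        layout = self._layout({"b1": 0.0, "b2": 5.0})
        res = adjust_augmented(layout, method="none")
        assert res.relative_efficiency == 1.0
        assert res.adjusted["P"] in (50.0, 55.0)  # raw values pass through

    def test_primary_recovers_additive_block_shifts_exactly(self):
        layout = self._layout({"b1": 0.0, "b2": 7.0, "b3": -3.0})
        res = adjust_augmented(layout, method="primary")
        # entry values dropped back to a common scale: e1 identical everywhere
        mean_shift = (0 + 7 - 3) / 3
        assert res.adjusted["e1"] == pytest.approx(55.0 + mean_shift)
        assert res.adjusted["S"] == pytest.approx(40.0 + mean_shift)
        assert res.relative_efficiency == np.inf  # secondary variance -> 0

    def test_secondary_method_evaluated_on_primary_check(self):
        layout = self._layout({"b1": 0.0, "b2": 10.0, "b3": -10.0})
        res = adjust_augmented(layout, method="secondary")
        vals = {res.adjusted["P"]}
        assert len(vals) == 1  # primary check fully homogenized
        assert res.relative_efficiency == np.inf

    def test_no_block_effect_gives_re_one(self):
        layout = self._layout({"b1": 0.0, "b2": 0.0})
        res = adjust_augmented(layout, method="primary")
        assert res.relative_efficiency == 1.0
        assert res.adjusted["e1"] == pytest.approx(55.0)

    def test_missing_primary_check_rejected(self):
        with pytest.raises(ValueError, match="primary check"):
            AugmentedLayout(blocks={"b": {"e": 1.0}}, primary_check="P")

    def test_unknown_method_rejected(self):
        layout = self._layout({"b1": 0.0})
        with pytest.raises(ValueError, match="method"):
            adjust_augmented(layout, method="tertiary")

    def test_harmful_adjustment_flagged_by_low_re(self):
        """Primary-check noise uncorrelated with true block effects: the
        correction injects variance and RE on the secondary check < 1."""
        rng = np.random.default_rng(5)
        blocks = {}
        for b in range(8):
            blocks[f"b{b}"] = {
                "P": 50.0 + rng.normal(0, 5),  # noisy primary, no block shift
                "S": 40.0,
                "e": 55.0,
            }
        layout = AugmentedLayout(blocks, primary_check="P", secondary_checks=("S",))
        res = adjust_augmented(layout, method="primary")
        assert res.relative_efficiency < 1.0


class TestCandidateGenes:
    @staticmethod
    def _genes():
        return [
            em.GeneAnnotation("g_inside", "2H", 31_600_000, 31_700_000),
            em.GeneAnnotation("g_near", "2H", 31_900_000, 32_000_000),
            em.GeneAnnotation("g_far", "2H", 40_000_000, 40_100_000),
            em.GeneAnnotation("g_other_chrom", "5H", 31_600_000, 31_700_000),
        ]

    def test_inside_gene_distance_zero(self):
        hits = em.candidate_genes(
            [("q1", "2H", 31_685_164)], self._genes(), window_bp=300_000
        )["q1"]
        assert hits[0].gene.gene_id == "g_inside" and hits[0].distance == 0

    def test_window_boundary_inclusive_and_sorted(self):
        genes = [
            em.GeneAnnotation("a", "1H", 1, 1),
            em.GeneAnnotation("b", "1H", 100_000, 100_001),
            em.GeneAnnotation("c", "1H", 259_000, 259_100),
            em.GeneAnnotation("d", "1H", 400_000, 400_100),
        ]
        hits = em.candidate_genes([("s", "1H", 1)], genes, window_bp=300_000)["s"]
        assert [h.gene.gene_id for h in hits] == ["a", "b", "c"]
        assert [h.distance for h in hits] == [0, 99_999, 258_999]

    def test_chromosome_mismatch_excluded(self):
        hits = em.candidate_genes(
            [("q", "5H", 31_650_000)], self._genes(), window_bp=10_000_000
        )["q"]
        assert [h.gene.gene_id for h in hits] == ["g_other_chrom"]

    def test_unplaced_marker_skipped(self):
        out = em.candidate_genes(
            [("placed", "2H", 31_650_000), ("unplaced", "UN", None)],
            self._genes(),
            window_bp=1_000,
        )
        assert "unplaced" not in out and "placed" in out

    def test_negative_window_rejected(self):
        with pytest.raises(ValueError):
            em.candidate_genes([], [], window_bp=-1)
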