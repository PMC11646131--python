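import math

import numpy as np
import pandas as pd
import pytest

from paleosieve.filter_eval import (
    ConfusionCounts,
    FilterPolicy,
    apply_filter,
    categorize,
    fit_exponential_decay,
    metrics,
    misincorporation_profile,
    stratify_by_length,
)
from paleosieve.simulate import DamageModel, FragmentLengthModel, simulate_damaged_alignments
from paleosieve.taxonomy import UnknownTaxonError, taxonomy_from_records

TREE = taxonomy_from_records(
    [
        (1, 1, "root"),
        (2, 1, "order"),
        (4, 2, "species"),  # endogenous, inside clade 2
        (6, 1, "order"),
        (7, 6, "species"),  # contaminant, outside clade 2
    ]
)


class TestApplyFilter:
    @pytest.mark.parametrize("strategy", ["positive", "negative"])
    @pytest.mark.parametrize(
        "status,taxid,in_clade",
        [("C", 4, True), ("C", 7, False), ("U", 0, False), ("U", 0, True)],
    )
    def test_all_status_clade_strategy_combinations(self, strategy, status, taxid, in_clade):
        rows = [(status, "r0", taxid)]
        policy = FilterPolicy(strategy, clade_root=2)
        retained, removed = apply_filter(rows, policy, TREE)
        if status == "U":
            expect_keep = strategy == "negative"
        else:
            expect_keep = in_clade
        assert ("r0" in retained) == expect_keep
        assert retained | removed == {"r0"} and not (retained & removed)

    def test_in_clade_species_kept_by_both_strategies(self):
        for strategy in ("positive", "negative"):
            retained, _ = apply_filter([("C", "r", 4)], FilterPolicy(strategy, 2), TREE)
            assert retained == {"r"}

    def test_clade_root_itself_retained(self):
        retained, _ = apply_filter([("C", "r", 2)], FilterPolicy("positive", 2), TREE)
        assert retained == {"r"}

    def test_random_tables_match_set_comprehension_oracle(self):
        rng = np.random.default_rng(0)
        taxa = [1, 2, 4, 6, 7]
        in_clade = {4: True, 2: True, 1: False, 6: False, 7: False}
        for trial in range(200):
            n = int(rng.integers(1, 40))
            rows = []
            for i in range(n):
                if rng.random() < 0.3:
                    rows.append(("U", f"r{i}", 0))
                else:
                    rows.append(("C", f"r{i}", int(rng.choice(taxa))))
            for strategy in ("positive", "negative"):
                retained, removed = apply_filter(rows, FilterPolicy(strategy, 2), TREE)
                expected = {
                    rid
                    for status, rid, t in rows
                    if (status == "C" and in_clade[t])
                    or (status == "U" and strategy == "negative")
                }
                assert retained == expected
                assert removed == {rid for _s, rid, _t in rows} - expected

    def test_unknown_taxon_listed_in_error(self):
        with pytest.raises(UnknownTaxonError, match="99"):
            apply_filter([("C", "r", 99)], FilterPolicy("positive", 2), TREE)

    def test_invalid_strategy_rejected(self):
        with pytest.raises(ValueError):
            FilterPolicy("both", 2)


def truth_frame(rows):
    return pd.DataFrame(rows, columns=["read_id", "taxon_id", "frag_len"])


class TestCategorize:
    def test_all_endogenous_all_mapped_nothing_filtered(self):
        truth = truth_frame([(f"r{i}", 4, 50) for i in range(5)])
        sam = {f"r{i}": (60, "c", 50) for i in range(5)}
        c = categorize(truth, set(sam), sam, TREE, endogenous_clade=2)
        assert (c.tp, c.fp, c.tn, c.fn) == (5, 0, 0, 0)

    def test_retained_mapped_contaminant_is_fp(self):
        truth = truth_frame([("r0", 7, 50)])
        c = categorize(truth, {"r0"}, {"r0": (37, "c", 50)}, TREE, 2)
        assert (c.tp, c.fp, c.tn, c.fn) == (0, 1, 0, 0)

    def test_filtered_endogenous_is_fn(self):
        truth = truth_frame([("r0", 4, 50)])
        c = categorize(truth, set(), {"r0": (60, "c", 50)}, TREE, 2)
        assert c.fn == 1 and c.total == 1

    def test_mapq_threshold_is_strict(self):
        truth = truth_frame([("r0", 4, 50), ("r1", 4, 50)])
        sam = {"r0": (20, "c", 50), "r1": (21, "c", 50)}
        c = categorize(truth, {"r0", "r1"}, sam, TREE, 2, mapq_threshold=20)
        assert (c.tp, c.fn) == (1, 1)

    def test_competitive_nontarget_hit_counts_as_unmapped(self):
        truth = truth_frame([("r0", 7, 50)])
        sam = {"r0": (60, "humanchr", 50)}
        labels = {"humanchr": "human", "dogchr": "target"}
        c = categorize(truth, {"r0"}, sam, TREE, 2, contig_labels=labels, target_label="target")
        assert (c.fp, c.tn) == (0, 1)

    def test_sam_read_missing_from_truth_is_error(self):
        truth = truth_frame([("r0", 4, 50)])
        with pytest.raises(ValueError, match="missing from truth"):
            categorize(truth, {"r0"}, {"zzz": (60, "c", 50)}, TREE, 2)

    def test_counts_always_partition_total(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(1, 60))
            truth = truth_frame(
                [(f"r{i}", int(rng.choice([4, 7])), 50) for i in range(n)]
            )
            sam = {
                f"r{i}": (int(rng.integers(0, 61)), "c", 50)
                for i in range(n)
                if rng.random() < 0.7
            }
            retained = {f"r{i}" for i in range(n) if rng.random() < 0.6}
            c = categorize(truth, retained, sam, TREE, 2)
            assert c.total == n


class TestMetrics:
    def test_direct_formula_example(self):
        m = metrics(ConfusionCounts(tp=9, fp=1, tn=0, fn=0))
        assert m.precision == 0.9 and m.recall == 1.0
        assert math.isclose(m.f1, 2 * 0.9 / 1.9)

    def test_undefined_marker_on_zero_denominators(self):
        m = metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=0))
        assert m.precision is None and m.recall is None and m.f1 is None

    def test_f1_equals_p_when_p_equals_r(self):
        m = metrics(ConfusionCounts(tp=30, fp=10, tn=0, fn=10))
        assert math.isclose(m.precision, m.recall) and math.isclose(m.f1, m.precision)

    def test_random_tables_match_hand_formulas(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            tp, fp, tn, fn = (int(x) for x in rng.integers(0, 100, size=4))
            m = metrics(ConfusionCounts(tp, fp, tn, fn))
            p = tp / (tp + fp) if tp + fp else None
            r = tp / (tp + fn) if tp + fn else None
            assert m.precision == p and m.recall == r
            if p is not None and r is not None and p + r > 0:
                assert math.isclose(m.f1, 2 * p * r / (p + r))
            else:
                assert m.f1 is None


class TestStratifyByLength:
    def test_single_length_populates_one_bin(self):
        truth = truth_frame([(f"r{i}", 4, 35) for i in range(4)])
        sam = {f"r{i}": (60, "c", 35) for i in range(4)}
        out = stratify_by_length(truth, set(sam), sam, TREE, 2)
        assert out[(30, 40)][0].total == 4
        assert all(out[b][0].total == 0 for b in out if b != (30, 40))

    def test_bin_counts_sum_to_global(self):
        rng = np.random.default_rng(3)
        n = 200
        truth = truth_frame(
            [(f"r{i}", int(rng.choice([4, 7])), int(rng.integers(30, 120))) for i in range(n)]
        )
        sam = {
            f"r{i}": (int(rng.integers(0, 61)), "c", int(truth["frag_len"][i]))
            for i in range(n)
            if rng.random() < 0.8
        }
        retained = {f"r{i}" for i in range(n) if rng.random() < 0.5}
        out = stratify_by_length(truth, retained, sam, TREE, 2)
        total = categorize(truth, retained, sam, TREE, 2)
        assert sum(c.total for c, _m in out.values()) == total.total == n
        assert sum(c.tp for c, _m in out.values()) == total.tp
        assert sum(c.fp for c, _m in out.values()) == total.fp

    def test_overlapping_bins_rejected(self):
        truth = truth_frame([("r0", 4, 35)])
        with pytest.raises(ValueError, match="overlap"):
            stratify_by_length(truth, set(), {}, TREE, 2, bins=[(30, 45), (40, 60)])

    def test_short_contaminant_enrichment_lowers_short_bin_precision(self):
        # short reads 80% contaminant, long reads 80% endogenous, all mapped
        rows, sam = [], {}
        for i in range(100):
            short = i < 50
            endog = (i % 10 < 2) if short else (i % 10 >= 2)
            L = 35 if short else 70
            rows.append((f"r{i}", 4 if endog else 7, L))
            sam[f"r{i}"] = (60, "c", L)
        truth = truth_frame(rows)
        out = stratify_by_length(truth, set(sam), sam, TREE, 2)
        p_short = out[(30, 40)][1].precision
        p_long = out[(61, None)][1].precision
        assert p_short < p_long


class TestMisincorporationProfile:
    def test_empty_sam_gives_empty_depths(self, tmp_path):
        sam = tmp_path / "empty.sam"
        sam.write_text("@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:c1\tLN:100\n")
        from paleosieve.seqio import write_fasta

        ref = tmp_path / "ref.fasta"
        write_fasta(ref, [("c1", "ACGT" * 25)])
        prof = misincorporation_profile(sam, ref)
        assert (prof["depth"] == 0).all() and prof["rate"].isna().all()

    def test_flat_background_rate_recovered(self, tmp_path):
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACGT"), 20_000))
        from paleosieve.seqio import write_fasta

        ref = tmp_path / "ref.fasta"
        write_fasta(ref, [("c1", seq)])
        model = DamageModel(p5_max=0.0, p3_max=0.0, decay=0.0, background=0.05)
        sam = simulate_damaged_alignments(
            [("c1", seq)], 5000, model, FragmentLengthModel(), seed=5, out_sam=tmp_path / "d.sam"
        )
        prof = misincorporation_profile(sam, ref)
        ct5 = prof[(prof.end == "5p") & (prof.substitution == "CT")]
        rates, depths = ct5["rate"].to_numpy(), ct5["depth"].to_numpy()
        se = np.sqrt(0.05 * 0.95 / depths)
        assert (np.abs(rates - 0.05) < 4 * se).all()

    def test_no_damage_means_no_mismatches(self, tmp_path):
        rng = np.random.default_rng(6)
        seq = "".join(rng.choice(list("ACGT"), 10_000))
        from paleosieve.seqio import write_fasta

        ref = tmp_path / "ref.fasta"
        write_fasta(ref, [("c1", seq)])
        model = DamageModel(p5_max=0.0, p3_max=0.0, background=0.0)
        sam = simulate_damaged_alignments(
            [("c1", seq)], 500, model, FragmentLengthModel(), seed=7, out_sam=tmp_path / "d.sam"
        )
        prof = misincorporation_profile(sam, ref)
        assert (prof["rate"].fillna(0) == 0).all()

    def test_unknown_contig_rejected(self, tmp_path):
        sam = tmp_path / "bad.sam"
        sam.write_text(
            "@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:cX\tLN:100\n"
            "r0\t0\tcX\t1\t60\t4M\t*\t0\t0\tACGT\tIIII\n"
        )
        from paleosieve.seqio import write_fasta

        ref = tmp_path / "ref.fasta"
        write_fasta(ref, [("c1", "ACGT" * 25)])
        with pytest.raises(ValueError, match="absent"):
            misincorporation_profile(sam, ref)


class TestDecayFit:
    def test_exact_exponential_recovered(self):
        x = np.arange(25)
        y = 0.3 * np.exp(-0.5 * x) + 0.01
        a, b, c = fit_exponential_decay(x, y)
        assert math.isclose(a, 0.3, rel_tol=1e-6)
        assert math.isclose(b, 0.5, rel_tol=1e-6)
        assert math.isclose(c, 0.01, abs_tol=1e-8)
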