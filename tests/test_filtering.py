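"""Background subtraction, Venn partitioning and three-criteria selection."""

import itertools
import random

import pandas as pd
import pytest

from segbioid.core import ContaminantPolicy, DetectionTable, TABLE_COLUMNS
from segbioid.filtering import (
    FilterTrace,
    carboxylase_qc,
    mark_control_background,
    presence_set,
    remove_contaminants,
    select_segment_candidates,
    venn_partition,
)
from segbioid.simulate import generate_interactome, simulate_detection_tables

from conftest import ALL_LINES, DVWA, FULL, NLS, PARENTAL, VWA, make_table


def random_table(rng: random.Random, n_genes: int = 30, keratins: int = 2) -> DetectionTable:
    """Random sparse detection table over the five study lines."""
    rows = []
    for i in range(n_genes):
        gene = f"KRT{i:03d}" if i < keratins else f"G{i:03d}"
        for line in ALL_LINES:
            for rep in (1, 2, 3):
                if rng.random() < 0.35:
                    rows.append((f"A{i:03d}", gene, line, rep, 1 + rng.randrange(3),
                                 1 + rng.randrange(20)))
    return DetectionTable(pd.DataFrame(rows, columns=TABLE_COLUMNS))


class TestControlBackground:
    def test_one_parental_plus_three_nls_is_background(self, design):
        # a true interactor can still be dismissed when the ligase-only control
        # tags it in >= 2 replicates on its own
        t = make_table({"MRE11A": {PARENTAL: [1], NLS: [1, 2, 3], FULL: [1, 2, 3]}})
        assert mark_control_background(t, design) == {"MRE11A"}

    def test_one_replicate_in_each_control_is_not_background(self, design):
        t = make_table({"G1": {PARENTAL: [1], NLS: [2]}})
        assert mark_control_background(t, design) == set()
        # ... but the pooled-across-lines mode does subtract it
        assert mark_control_background(t, design, pooled=True) == {"G1"}

    def test_empty_table(self, design):
        t = make_table({})
        assert mark_control_background(t, design) == set()

    def test_missing_control_line_errors(self, design):
        t = make_table({"G1": {FULL: [1, 2]}})
        with pytest.raises(ValueError, match="absent"):
            mark_control_background(t, design)

    def test_trace_records_every_gene(self, design):
        t = make_table({"G1": {PARENTAL: [1, 2], FULL: [1]}, "G2": {NLS: [1], FULL: [1]}})
        trace = FilterTrace()
        mark_control_background(t, design, trace=trace)
        stage = trace.frame[trace.frame["stage"] == "control_subtraction"]
        assert sorted(stage["gene"]) == ["G1", "G2"]
        assert set(stage["outcome"]) == {"background", "kept"}


class TestContaminants:
    def test_keratin_removed_by_prefix(self):
        t = make_table({
            "KRT18": {FULL: [1]}, "KRT9": {VWA: [2]}, "XRCC6": {FULL: [1]},
            "G1": {VWA: [1]}, "G2": {DVWA: [3]},
        })
        out, removed = remove_contaminants(t)
        assert removed == {"KRT18", "KRT9"}
        assert sorted(out.genes) == ["G1", "G2", "XRCC6"]


class TestPresenceAndVenn:
    def test_presence_thresholds(self, design):
        t = make_table({"G1": {VWA: [2]}, "G2": {VWA: [1, 3]}})
        assert presence_set(t, VWA, 1) == {"G1", "G2"}
        assert presence_set(t, VWA, 2) == {"G2"}
        assert presence_set(t, VWA, 3) == set()

    def test_unknown_line_errors(self):
        t = make_table({"G1": {VWA: [1]}})
        with pytest.raises(ValueError, match="unknown cell line"):
            presence_set(t, "nope", 1)

    def test_presence_monotone_over_random_tables(self):
        rng = random.Random(0)
        for _ in range(20):
            t = random_table(rng)
            for line in ALL_LINES:
                s1 = presence_set(t, line, 1)
                s2 = presence_set(t, line, 2)
                s3 = presence_set(t, line, 3)
                assert s3 <= s2 <= s1

    @pytest.mark.parametrize(
        "a,b,c,expected",
        [
            ({"a", "b"}, {"b", "c"}, {"c"},
             {"A_only": 1, "AB": 1, "BC": 1, "B_only": 0, "C_only": 0, "AC": 0, "ABC": 0}),
            ({"x"}, {"x"}, {"x"}, {"ABC": 1}),
            ({"a"}, {"b"}, {"c"}, {"A_only": 1, "B_only": 1, "C_only": 1}),
        ],
    )
    def test_venn_examples(self, a, b, c, expected):
        part = venn_partition(a, b, c)
        counts = part.counts()
        for region, n in expected.items():
            assert counts[region] == n
        assert sum(counts.values()) == len(a | b | c)

    def test_venn_matches_brute_force_membership(self):
        rng = random.Random(1)
        universe = [f"p{i}" for i in range(40)]
        for _ in range(25):
            a, b, c = (frozenset(x for x in universe if rng.random() < 0.4) for _ in range(3))
            part = venn_partition(a, b, c)
            # brute force: classify each element by its membership triple
            for x in a | b | c:
                key = "".join(lbl for lbl, s in zip("ABC", (a, b, c)) if x in s)
                region = key if len(key) > 1 else f"{key}_only"
                assert x in part.regions[region]
            # disjoint regions summing to the union
            regions = list(part.regions.values())
            for r1, r2 in itertools.combinations(regions, 2):
                assert not (r1 & r2)
            assert part.union_size == len(a | b | c)

    def test_percentages_sum_to_100(self):
        part = venn_partition({"a", "b"}, {"b"}, {"c"})
        assert sum(part.percentages().values()) == pytest.approx(100.0)


def brute_force_candidates(table, design, target_line, partner_line):
    """Literal three-criteria enumeration, independent of the pipeline code."""
    out = []
    pos = design.positive_control_line
    for gene in table.genes:
        in_partner = table.n_replicates_detected(gene, partner_line) > 0
        in_pos = table.n_replicates_detected(gene, pos) >= 1
        all_target = table.n_replicates_detected(gene, target_line) >= design.final_required_reps
        if (not in_partner) and in_pos and all_target:
            out.append(gene)
    return sorted(out)


class TestSegmentCandidates:
    def segs(self, design):
        vwa = design.segment_of(VWA)
        dvwa = design.segment_of(DVWA)
        return vwa, dvwa

    def test_absent_from_positive_control_is_excluded(self, design):
        vwa, dvwa = self.segs(design)
        t = make_table({"TERF2IP": {VWA: [1]}})
        assert select_segment_candidates(t, design, vwa, dvwa).genes == []

    def test_all_criteria_met_is_included(self, design):
        vwa, dvwa = self.segs(design)
        t = make_table({"G1": {VWA: [1, 2, 3], FULL: [1, 2]}})
        cl = select_segment_candidates(t, design, vwa, dvwa)
        assert cl.genes == ["G1"]
        row = cl.frame.iloc[0]
        assert row["target_replicates"] == "111"
        assert row["positive_replicates"] == "110"
        assert row["partner_replicates"] == "000"

    def test_single_partner_replicate_disqualifies(self, design):
        vwa, dvwa = self.segs(design)
        t = make_table({"G1": {VWA: [1, 2, 3], FULL: [1, 2, 3], DVWA: [2]}})
        assert select_segment_candidates(t, design, vwa, dvwa).genes == []

    def test_overlapping_segments_rejected(self, design):
        vwa, _ = self.segs(design)
        full = design.segment_of(FULL)
        t = make_table({"G1": {VWA: [1, 2, 3]}})
        with pytest.raises(ValueError, match="overlap"):
            select_segment_candidates(t, design, vwa, full)

    def test_matches_brute_force_on_random_tables(self, design):
        vwa, dvwa = self.segs(design)
        rng = random.Random(7)
        for _ in range(30):
            t = random_table(rng)
            got = select_segment_candidates(t, design, vwa, dvwa).genes
            assert got == brute_force_candidates(t, design, VWA, DVWA)
            got_d = select_segment_candidates(t, design, dvwa, vwa).genes
            assert got_d == brute_force_candidates(t, design, DVWA, VWA)
            # structural mutual exclusivity of the two lists
            assert not (set(got) & set(got_d))

    def test_noiseless_recovery_of_planted_classes(self, design):
        probs = {c: 1.0 for c in ("vwa_specific", "non_vwa_specific",
                                  "heterodimer_mediated", "shared_background", "keratin")}
        truth = generate_interactome(detection_probs=probs, seed=2)
        table = simulate_detection_tables(truth, design, seed=2)
        background = mark_control_background(table, design)
        filtered, _ = remove_contaminants(table.drop_genes(background))
        vwa, dvwa = self.segs(design)
        got_vwa = select_segment_candidates(filtered, design, vwa, dvwa).genes
        got_dvwa = select_segment_candidates(filtered, design, dvwa, vwa).genes
        assert got_vwa == truth.members("vwa_specific")
        assert got_dvwa == sorted(
            truth.members("non_vwa_specific") + truth.members("heterodimer_mediated")
        )
        # partner-surface-mediated interactors land only in the deletion list
        assert set(truth.members("heterodimer_mediated")) <= set(got_dvwa)
        assert not (set(truth.members("heterodimer_mediated")) & set(got_vwa))


class TestCarboxylaseQC:
    def test_all_samples_pass_with_default_simulation(self, design):
        truth = generate_interactome(seed=1)
        table = simulate_detection_tables(truth, design, seed=1)
        qc = carboxylase_qc(table, design)
        assert qc.passed and qc.failures().empty

    def test_missing_sample_flagged(self, design):
        t = make_table({"PC": {FULL: [1, 2]}})  # nothing in FULL rep 3 or other lines
        qc = carboxylase_qc(t, design)
        assert not qc.passed
        fails = qc.failures()
        assert {(r.cell_line, r.replicate) for r in fails.itertuples()} >= {(FULL, 3)}

    def test_alias_counts_as_carboxylase(self, design):
        t = make_table({"MCCCA": {FULL: [1]}})
        qc = carboxylase_qc(t, design)
        row = qc.frame[(qc.frame.cell_line == FULL) & (qc.frame.replicate == 1)]
        assert row.iloc[0]["carboxylases"] == "MCCC1"

    def test_empty_table_fails_everywhere(self, design):
        qc = carboxylase_qc(make_table({}), design)
        assert not qc.passed
        assert (~qc.frame["sample_pass"]).all()
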