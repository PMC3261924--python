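"""Data model, I/O, deduplication and constraint-driven reconstruction."""

import dataclasses

import pandas as pd
import pytest

from swapmeta.dataset import (
    ALIKE, DIFFERENT, UNKNOWN,
    DatasetError, InfeasibleConstraintsError, SwapExperiment,
    TallyConstraint, build_fixture, deduplicate, read_experiments, to_frame,
    validate_dataset, write_experiments,
)


def make_exp(**kw):
    base = dict(id="E1", gene="eve", donor_taxon="D. simulans",
                host_taxon="D. melanogaster", controlled=True,
                rel_donor_host=ALIKE, rel_swap_donor=ALIKE,
                rel_swap_host=ALIKE)
    base.update(kw)
    return SwapExperiment(**base)


class TestInvariants:
    def test_valid_controlled_record(self):
        assert make_exp().violations() == []

    def test_host_must_be_anchor_species(self):
        v = make_exp(host_taxon="D. simulans").violations()
        assert any("anchor" in msg for msg in v)

    def test_controlled_forbids_unknown_relations(self):
        v = make_exp(rel_swap_host=UNKNOWN).violations()
        assert any("unknown relation" in msg for msg in v)

    def test_alike_endogenous_forces_matching_swap_relations(self):
        v = make_exp(rel_donor_host=ALIKE, rel_swap_donor=DIFFERENT,
                     rel_swap_host=ALIKE).violations()
        assert v

    def test_noncontrolled_knows_exactly_one_swap_relation(self):
        ok = make_exp(controlled=False, rel_donor_host=UNKNOWN,
                      rel_swap_donor=ALIKE, rel_swap_host=UNKNOWN)
        assert ok.violations() == []
        bad = make_exp(controlled=False, rel_donor_host=UNKNOWN,
                       rel_swap_donor=ALIKE, rel_swap_host=DIFFERENT)
        assert bad.violations()

    def test_sex_flags_require_sex_specific(self):
        v = make_exp(sex_specific=False, swap_sex_proper=True).violations()
        assert any("fidelity" in msg for msg in v)


class TestIO:
    def test_round_trip_preserves_content_and_order(self, tmp_path):
        rows = [make_exp(id=f"E{i}", enhancer=f"eve.{i}") for i in range(3)]
        path = tmp_path / "t.tsv"
        write_experiments(path, rows)
        back = read_experiments(path)
        assert [e.id for e in back] == ["E0", "E1", "E2"]
        assert back == rows
        # a second write/read cycle is byte-stable
        path2 = tmp_path / "t2.tsv"
        write_experiments(path2, back)
        assert path.read_text() == path2.read_text()

    def test_csv_round_trip(self, tmp_path):
        rows = [make_exp(id="E1", citation="a, b (2001)")]
        path = tmp_path / "t.csv"
        write_experiments(path, rows)
        assert read_experiments(path) == rows

    def test_missing_column_names_the_column(self, tmp_path):
        path = tmp_path / "t.tsv"
        frame = to_frame([make_exp()]).drop(columns=["rel_swap_host"])
        frame.to_csv(path, sep="\t", index=False)
        with pytest.raises(DatasetError, match="rel_swap_host"):
            read_experiments(path)

    def test_invariant_violation_reported_with_row_number(self, tmp_path):
        bad = to_frame([make_exp()])
        bad.loc[0, "rel_swap_host"] = "unknown"
        path = tmp_path / "t.tsv"
        bad.to_csv(path, sep="\t", index=False)
        with pytest.raises(DatasetError, match="row 1.*unknown relation"):
            read_experiments(path)

    def test_empty_relation_cell_is_an_error_not_a_default(self, tmp_path):
        bad = to_frame([make_exp()])
        bad.loc[0, "rel_donor_host"] = ""
        path = tmp_path / "t.tsv"
        bad.to_csv(path, sep="\t", index=False)
        with pytest.raises(DatasetError, match="empty relation"):
            read_experiments(path)

    def test_vocabulary_violation_reported_with_row_number(self, tmp_path):
        bad = to_frame([make_exp()])
        bad.loc[0, "rel_donor_host"] = "similar"
        path = tmp_path / "t.tsv"
        bad.to_csv(path, sep="\t", index=False)
        with pytest.raises(DatasetError, match="row 1"):
            read_experiments(path)

    def test_packaged_fixture_shape(self, fixture_rows):
        assert len(fixture_rows) == 230
        assert sum(e.controlled for e in fixture_rows) == 146


class TestDeduplicate:
    def test_same_enhancer_donor_host_collapses(self):
        a = make_exp(id="A", enhancer="eve.stripe2")
        b = make_exp(id="B", enhancer="eve.stripe2")
        assert deduplicate([a, b]) == [a]

    def test_longest_fragment_preferred(self):
        short = make_exp(id="A", enhancer="eve.stripe2",
                         fragment_longest=False)
        long_ = make_exp(id="B", enhancer="eve.stripe2")
        assert deduplicate([short, long_]) == [long_]

    def test_empty_and_distinct_inputs_pass_through(self):
        assert deduplicate([]) == []
        rows = [make_exp(id=f"E{i}", enhancer=f"eve.{i}") for i in range(5)]
        assert deduplicate(rows) == rows

    def test_idempotent(self, fixture_rows):
        once = deduplicate(fixture_rows)
        assert deduplicate(once) == once


class TestBuildFixture:
    def test_same_seed_identical_table(self, constraints):
        a = build_fixture(constraints, seed=7)
        b = build_fixture(constraints, seed=7)
        assert a == b

    def test_packaged_file_matches_seed_1_rebuild(self, fixture_rows,
                                                  rebuilt_rows):
        assert fixture_rows == rebuilt_rows

    def test_different_seeds_identical_tallies(self, constraints):
        a = build_fixture(constraints, seed=1)
        b = build_fixture(constraints, seed=2)
        assert a != b  # presentational randomness differs
        ra = validate_dataset(a, constraints)
        rb = validate_dataset(b, constraints)
        assert ra.passed and rb.passed
        assert [l[:3] for l in ra.constraint_lines] == \
               [l[:3] for l in rb.constraint_lines]

    def test_minimal_constraint_set(self):
        cons = [
            TallyConstraint("total", {}, 230),
            TallyConstraint("controlled", {"controlled": True}, 146),
            TallyConstraint("controlled_diverged",
                            {"controlled": True, "group": "diverged"}, 105),
            TallyConstraint("nc_diverged",
                            {"controlled": False, "group": "diverged"}, 40),
        ]
        rows = build_fixture(cons, seed=3)
        report = validate_dataset(rows, cons)
        assert report.passed

    def test_infeasible_contradiction_names_conflict(self):
        cons = [TallyConstraint("total", {}, 4),
                TallyConstraint("controlled", {"controlled": True}, 5)]
        with pytest.raises(InfeasibleConstraintsError) as err:
            build_fixture(cons, seed=0)
        assert set(err.value.conflict) == {"total", "controlled"}

    def test_all_rows_reconstructed_and_valid(self, rebuilt_rows):
        assert all(e.provenance == "reconstructed" for e in rebuilt_rows)
        assert all(e.violations() == [] for e in rebuilt_rows)
        # unique ids and no dedup casualties
        assert len({e.id for e in rebuilt_rows}) == 230
        assert deduplicate(rebuilt_rows) == rebuilt_rows


class TestValidateDataset:
    def test_fixture_passes_packaged_constraints(self, fixture_rows,
                                                 constraints):
        report = validate_dataset(fixture_rows, constraints)
        assert report.passed
        assert len(report.constraint_lines) == len(constraints)

    def test_flipping_one_controlled_flag_fails_constraints(
            self, fixture_rows, constraints):
        rows = list(fixture_rows)
        victim = next(e for e in rows if e.controlled)
        # turn a controlled row into a valid non-controlled one
        flipped = dataclasses.replace(
            victim, controlled=False, rel_donor_host="unknown",
            rel_swap_host="unknown",
            rel_swap_donor=victim.rel_swap_donor if
            victim.rel_swap_donor != "unknown" else "alike")
        rows[rows.index(victim)] = flipped
        report = validate_dataset(rows, constraints)
        assert not report.passed
        assert any(not ok for *_, ok in report.constraint_lines)

    def test_empty_constraint_list_still_checks_invariants(self):
        bad = make_exp(host_taxon="H. sapiens")
        report = validate_dataset([bad], [])
        assert report.constraint_lines == []
        assert report.invariant_violations


class TestTallyConstraint:
    def test_unknown_subset_key_rejected(self):
        with pytest.raises(DatasetError, match="unknown subset"):
            TallyConstraint("x", {"flavour": "salty"}, 1)

    def test_negative_count_rejected(self):
        with pytest.raises(DatasetError):
            TallyConstraint("x", {}, -1)

    def test_group_and_category_intersect(self):
        c = TallyConstraint("x", {"category": ["C2", "C4"],
                                  "group": "misregulation"}, 0)
        e = make_exp(rel_donor_host=DIFFERENT, rel_swap_donor=DIFFERENT,
                     rel_swap_host=DIFFERENT)  # C4
        assert c.matches(e)
        e2 = make_exp(rel_donor_host=DIFFERENT, rel_swap_donor=DIFFERENT,
                      rel_swap_host=ALIKE)  # C2, excluded by the group
        assert not c.matches(e2)
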