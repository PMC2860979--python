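"""Diagnostic-site filtering, classification and specimen assignment."""

import numpy as np
import pytest

from neodiag.alignment_io import AlignmentError
from neodiag.diagnostics import (
    SiteStatus,
    ambiguity_filter,
    assign_specimen,
    classify_sites,
    count_pure_differences,
    render_site_alignment,
    table_to_frame,
    variable_site_filter,
)

from conftest import make_locus, make_specimens, random_alignment
from oracles import oracle_classify


def columns(locus_rows: list[str]) -> object:
    """Transpose row strings into a locus (each input string = one column)."""
    n_seqs = len(locus_rows[0])
    return make_locus(["".join(col[i] for col in locus_rows) for i in range(n_seqs)])


class TestAmbiguityFilter:
    def test_ambiguity_column_excluded(self):
        locus = columns(["AAR"])  # one column, states A,A,R
        assert ambiguity_filter(locus) == {1}

    def test_clean_variable_column_retained(self):
        assert ambiguity_filter(columns(["AGT"])) == set()

    def test_gap_is_not_a_double_peak(self):
        assert ambiguity_filter(columns(["A-A"])) == set()


class TestVariableSiteFilter:
    def test_singleton_variation_excluded(self):
        locus = columns(["AAAAG"])
        assert variable_site_filter(locus) == set()

    def test_two_variant_carriers_retained(self):
        locus = columns(["AAAGG"])
        assert variable_site_filter(locus) == {1}

    def test_modal_tie_needs_enough_carriers(self):
        assert variable_site_filter(columns(["AAGG"])) == {1}
        assert variable_site_filter(columns(["AG--"])) == set()

    def test_gaps_ignored_in_carrier_count(self):
        assert variable_site_filter(columns(["AAG-G"])) == {1}

    def test_threshold_parameter(self):
        locus = columns(["AAAGG"])
        assert variable_site_filter(locus, min_variant_carriers=3) == set()


class TestClassifySites:
    def test_reciprocal_fixation_is_pure_for_both(self):
        locus = make_locus({"a1": "AA", "a2": "AA", "b1": "GG", "b2": "GG"})
        specimens = make_specimens({"A": ["a1", "a2"], "B": ["b1", "b2"]})
        table = classify_sites(locus, specimens)
        site = table.retained_columns[0]
        assert site.per_group["A"].status is SiteStatus.PURE
        assert site.per_group["B"].status is SiteStatus.PURE
        assert site.informative

    def test_shared_state_gives_private_not_pure(self):
        # group A = {A,A,G}, group B = {G,G,G}: A is private to A, nothing pure
        locus = make_locus(
            {"a1": "AA", "a2": "AA", "a3": "GG", "b1": "GG", "b2": "GG", "b3": "GG"}
        )
        specimens = make_specimens(
            {"A": ["a1", "a2", "a3"], "B": ["b1", "b2", "b3"]}
        )
        table = classify_sites(locus, specimens)
        site = table.retained_columns[0]
        assert site.per_group["A"].status is SiteStatus.PRIVATE
        assert site.per_group["B"].status is SiteStatus.NONE

    def test_single_group_rejected(self):
        locus = make_locus({"a1": "AA", "a2": "AA"})
        with pytest.raises(ValueError):
            classify_sites(locus, make_specimens({"A": ["a1", "a2"]}))

    def test_all_gap_group_gets_none_status(self):
        locus = make_locus({"a1": "AA", "a2": "GG", "b1": "--", "b2": "--",
                            "c1": "AA", "c2": "GG"})
        specimens = make_specimens(
            {"A": ["a1", "a2"], "B": ["b1", "b2"], "C": ["c1", "c2"]}
        )
        table = classify_sites(locus, specimens)
        for site in table.retained_columns:
            assert site.per_group["B"].state_set == frozenset()
            assert site.per_group["B"].status is SiteStatus.NONE

    def test_exclusion_counts_recorded(self):
        # col1 ambiguous, col2 singleton variation, col3 retained
        locus = make_locus({"a1": "RAA", "a2": "AAA", "b1": "AGG", "b2": "AAG"})
        specimens = make_specimens({"A": ["a1", "a2"], "B": ["b1", "b2"]})
        table = classify_sites(locus, specimens)
        assert table.n_excluded_ambiguous == 1
        assert table.n_excluded_rare == 1
        assert table.columns == [3]

    def test_matches_bruteforce_oracle_on_random_alignments(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            locus, specimens = random_alignment(
                rng,
                n_seqs=int(rng.integers(4, 13)),
                n_cols=int(rng.integers(5, 31)),
                n_groups=int(rng.integers(2, 5)),
            )
            table = classify_sites(locus, specimens)
            expected = oracle_classify(
                locus.sequences, {s.specimen_id: s.group for s in specimens}
            )
            got = {
                site.column: {
                    g: (st.state_set, st.status.value)
                    for g, st in site.per_group.items()
                }
                for site in table.retained_columns
            }
            assert got == expected


class TestMonotonicity:
    def test_added_disagreeing_member_breaks_purity(self):
        locus = make_locus({"a1": "A", "a2": "A", "b1": "G", "b2": "G"})
        specimens = make_specimens({"A": ["a1", "a2"], "B": ["b1", "b2"]})
        before = classify_sites(locus, specimens)
        assert before.retained_columns[0].per_group["A"].status is SiteStatus.PURE

        locus2 = make_locus({"a1": "A", "a2": "A", "a3": "C", "b1": "G", "b2": "G"})
        specimens2 = make_specimens({"A": ["a1", "a2", "a3"], "B": ["b1", "b2"]})
        after = classify_sites(locus2, specimens2)
        assert after.retained_columns[0].per_group["A"].status is not SiteStatus.PURE

    def test_removing_a_group_never_demotes_pure(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            locus, specimens = random_alignment(rng, 9, 20, 3)
            groups = sorted({s.group for s in specimens})
            if len(groups) < 3:
                continue
            table = classify_sites(locus, specimens)
            drop = groups[-1]
            kept = [s for s in specimens if s.group != drop]
            sub = make_locus(
                {s.specimen_id: locus.sequences[s.specimen_id] for s in kept}
            )
            sub_table = classify_sites(sub, kept)
            sub_by_col = {c.column: c for c in sub_table.retained_columns}
            for site in table.retained_columns:
                for g, st in site.per_group.items():
                    if g == drop or st.status is not SiteStatus.PURE:
                        continue
                    if site.column in sub_by_col:
                        assert (
                            sub_by_col[site.column].per_group[g].status
                            is SiteStatus.PURE
                        )


class TestPureDifferences:
    def _table(self):
        locus = make_locus(
            {"a1": "AAAAA", "a2": "AAAAA", "b1": "GGGGG", "b2": "GGGGG"}
        )
        specimens = make_specimens({"A": ["a1", "a2"], "B": ["b1", "b2"]})
        return classify_sites(locus, specimens)

    def test_reciprocally_fixed_columns_counted(self):
        assert count_pure_differences(self._table(), "A", "B") == 5

    def test_identical_groups_give_zero(self):
        locus = make_locus({"a1": "AG", "a2": "AG", "b1": "AG", "b2": "AG",
                            "c1": "GA", "c2": "GA"})
        specimens = make_specimens(
            {"A": ["a1", "a2"], "B": ["b1", "b2"], "C": ["c1", "c2"]}
        )
        table = classify_sites(locus, specimens)
        assert count_pure_differences(table, "A", "B") == 0
        assert count_pure_differences(table, "A", "C") == 2

    def test_unknown_group_raises(self):
        with pytest.raises(KeyError):
            count_pure_differences(self._table(), "A", "Z")


class TestAssignment:
    def _table(self):
        locus = make_locus(
            {
                "a1": "AAAAAAAAAA",
                "a2": "AAAAAAAAAA",
                "b1": "GGGGGGGGGG",
                "b2": "GGGGGGGGGG",
            }
        )
        specimens = make_specimens({"A": ["a1", "a2"], "B": ["b1", "b2"]})
        return classify_sites(locus, specimens)

    def test_member_query_assigned_with_full_tally(self):
        res = assign_specimen("AAAAAAAAAA", self._table())
        assert res.group == "A"
        assert res.tally == {"A": 10}

    def test_tie_is_unassigned(self):
        res = assign_specimen("AAAAAGGGGG", self._table())
        assert res.group is None
        assert res.tally == {"A": 5, "B": 5}

    def test_all_n_query_unassigned_empty_tally(self):
        # N can represent anything, so it votes for every pure state
        res = assign_specimen("NNNNNNNNNN", self._table())
        assert res.group is None

    def test_gap_query_has_empty_tally(self):
        res = assign_specimen("-" * 10, self._table())
        assert res.group is None
        assert res.tally == {}

    def test_ambiguity_code_votes_when_compatible(self):
        # R = A/G votes for both; M = A/C votes only for A
        res = assign_specimen("MAAAAAAAAA", self._table())
        assert res.group == "A"
        assert res.tally["A"] == 10

    def test_length_mismatch_raises(self):
        with pytest.raises(AlignmentError):
            assign_specimen("AAA", self._table())

    def test_noiseless_simulated_queries_recover_their_group(self):
        from neodiag.synthetic_data import (
            default_paper_config,
            simulate_dataset,
        )

        config = default_paper_config(seed=11)
        for spec in config.locus_specs.values():
            spec.ambiguity_rate = 0.0
        sim = simulate_dataset(config)
        ds = sim.dataset
        coi = ds.loci["COI"]
        table = classify_sites(coi, ds.specimens)
        for s in ds.specimens:
            res = assign_specimen(coi.sequences[s.specimen_id], table)
            assert res.group == s.group


class TestWriters:
    def test_frame_and_render(self, default_sim):
        ds = default_sim.dataset
        table = classify_sites(ds.loci["28S"], ds.specimens)
        df = table_to_frame(table)
        assert set(df.columns) == {
            "locus", "column", "group", "states", "status", "informative"
        }
        text = render_site_alignment(table, ds.loci["28S"], ds.specimens)
        assert "PURE" in text or "=" in text
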