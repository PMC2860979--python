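"""The Jukes–Cantor simulator: closed form, determinism, recovery."""

import math

import numpy as np
import pytest

from neodiag.alignment_io import TWOFOLD_CODES, iupac_states
from neodiag.distance import distance_matrix, group_summary
from neodiag.synthetic_data import (
    CRISTATUS,
    FLEM_LARGE,
    FLEM_SMALL,
    GROUPS,
    PLUMCHRUS,
    LocusSpec,
    SimulationConfig,
    TARGET_MEAN_P,
    default_paper_config,
    evolve_jc,
    jc_divergence,
    jc_expected_p,
    simulate_dataset,
    solve_branch_lengths,
    write_simulated,
)


class TestClosedForm:
    def test_inverse_pair(self):
        for p in (0.005, 0.15):
            assert jc_expected_p(jc_divergence(p)) == pytest.approx(p)

    def test_rejects_saturated_p(self):
        with pytest.raises(ValueError):
            jc_divergence(0.75)

    def test_negative_divergence_rejected(self):
        with pytest.raises(ValueError):
            jc_expected_p(-0.1)


class TestEvolveJC:
    def test_zero_divergence_is_identity(self):
        rng = np.random.default_rng(0)
        seq = "ACGT" * 25
        assert evolve_jc(seq, 0.0, rng) == seq

    def test_expected_difference_matches_closed_form(self):
        # d = 0.1 -> p_diff = (3/4)(1 - e^(-0.4/3)) ~= 0.09365
        rng = np.random.default_rng(1)
        L, reps, d = 2000, 30, 0.1
        seq = "".join(rng.choice(list("ACGT"), L))
        diffs = [
            np.mean([a != b for a, b in zip(seq, evolve_jc(seq, d, rng))])
            for _ in range(reps)
        ]
        p = jc_expected_p(d)
        assert p == pytest.approx(0.0936, abs=0.0005)
        se = math.sqrt(p * (1 - p) / (L * reps))
        assert np.mean(diffs) == pytest.approx(p, abs=4 * se)

    def test_saturation_approaches_three_quarters(self):
        rng = np.random.default_rng(2)
        seq = "A" * 4000
        evolved = evolve_jc(seq, 50.0, rng)
        frac_diff = np.mean([a != b for a, b in zip(seq, evolved)])
        assert frac_diff == pytest.approx(0.75, abs=0.03)

    def test_same_seed_same_output(self):
        seq = "ACGT" * 10
        a = evolve_jc(seq, 0.3, np.random.default_rng(5))
        b = evolve_jc(seq, 0.3, np.random.default_rng(5))
        assert a == b


class TestDefaultConfig:
    def test_targets_match_published_means(self):
        config = default_paper_config(0)
        coi = config.locus_specs["COI"]
        assert jc_expected_p(
            coi.divergence(FLEM_LARGE, FLEM_SMALL)
        ) == pytest.approx(0.03586)
        s28 = config.locus_specs["28S"]
        assert s28.divergence(FLEM_LARGE, FLEM_SMALL) == 0.0

    def test_group_sizes_are_study_design(self):
        config = default_paper_config(0)
        assert config.group_sizes == {
            CRISTATUS: 8, PLUMCHRUS: 8, FLEM_SMALL: 16, FLEM_LARGE: 5
        }

    def test_json_round_trip(self, tmp_path):
        config = default_paper_config(3)
        config.to_json(tmp_path / "c.json")
        back = SimulationConfig.from_json(tmp_path / "c.json")
        assert back.to_dict() == config.to_dict()


class TestBranchSolver:
    def test_budgets_nonnegative_for_default(self):
        for spec in default_paper_config(0).locus_specs.values():
            assert all(v >= 0 for v in solve_branch_lengths(spec).values())

    def test_unrealizable_hierarchy_rejected(self):
        spec = default_paper_config(0).locus_specs["COI"]
        # forms further apart than flemingeri is from plumchrus
        pair = frozenset((FLEM_LARGE, FLEM_SMALL))
        spec.pairwise_divergence[pair] = 0.5
        with pytest.raises(ValueError, match="unrealizable"):
            solve_branch_lengths(spec)

    def test_additivity_of_solved_budgets(self):
        spec = default_paper_config(0).locus_specs["COI"]
        b = solve_branch_lengths(spec)
        intra = jc_expected_p(spec.intra_diversity)
        path = b["node2->large"] + b["node1->node2"] + b["node1->plumchrus"]
        assert path + intra == pytest.approx(
            jc_expected_p(spec.divergence(FLEM_LARGE, PLUMCHRUS))
        )


class TestSimulateDataset:
    def test_same_seed_byte_identical(self, tmp_path):
        a = simulate_dataset(default_paper_config(9))
        b = simulate_dataset(default_paper_config(9))
        for name in a.dataset.loci:
            assert a.dataset.loci[name].sequences == b.dataset.loci[name].sequences
        da, db = tmp_path / "a", tmp_path / "b"
        write_simulated(a, da)
        write_simulated(b, db)
        for f in da.iterdir():
            assert f.read_bytes() == (db / f.name).read_bytes()

    def test_zero_ambiguity_rate_gives_no_codes(self):
        config = default_paper_config(4)
        for spec in config.locus_specs.values():
            spec.ambiguity_rate = 0.0
        sim = simulate_dataset(config)
        for locus in sim.dataset.loci.values():
            for seq in locus.sequences.values():
                assert set(seq) <= set("ACGT")

    def test_ambiguity_injection_rate_and_codes(self):
        config = default_paper_config(4)
        rate = 0.01
        for spec in config.locus_specs.values():
            spec.ambiguity_rate = rate
        sim = simulate_dataset(config)
        n_cells = n_amb = 0
        for locus in sim.dataset.loci.values():
            for seq in locus.sequences.values():
                n_cells += len(seq)
                for ch in seq:
                    if ch not in "ACGT":
                        assert ch in TWOFOLD_CODES
                        assert len(iupac_states(ch)) == 2
                        n_amb += 1
        expected = rate * n_cells
        sd = math.sqrt(n_cells * rate * (1 - rate))
        assert abs(n_amb - expected) < 4 * sd

    def test_group_sizes_and_validity(self, default_sim):
        ds = default_sim.dataset
        sizes = {g: sum(1 for s in ds.specimens if s.group == g) for g in ds.groups}
        assert sizes == {CRISTATUS: 8, PLUMCHRUS: 8, FLEM_SMALL: 16, FLEM_LARGE: 5}
        for name, locus in ds.loci.items():
            assert len(locus) == 37
            assert all(len(s) == locus.length for s in locus.sequences.values())

    def test_branch_substitution_counts_recorded(self, default_sim):
        counts = default_sim.branch_substitutions["COI"]
        assert counts["node2->large"] > 0
        assert sum(v for k, v in counts.items() if k.startswith("tip:")) > 0

    def test_invalid_group_sizes_rejected(self):
        config = default_paper_config(0)
        config.group_sizes = {CRISTATUS: 8}
        with pytest.raises(ValueError):
            simulate_dataset(config)

    def test_divergence_exceeding_length_budget_rejected(self):
        spec = LocusSpec(
            length=10,
            pairwise_divergence={
                frozenset(p): 0.5
                for p in [(a, b) for i, a in enumerate(GROUPS) for b in GROUPS[i + 1:]]
            },
            intra_diversity=0.1,
            ambiguity_rate=0.0,
        )
        config = SimulationConfig(seed=0, locus_specs={"x": spec})
        with pytest.raises(ValueError, match="length|columns"):
            simulate_dataset(config)


class TestRecovery:
    def test_between_group_means_near_targets(self):
        """The pipeline recovers the configured divergence hierarchy."""
        sim = simulate_dataset(default_paper_config(17))
        ds = sim.dataset
        for name, locus in ds.loci.items():
            m = distance_matrix(locus)
            for pair, target in TARGET_MEAN_P[name].items():
                a, b = sorted(pair)
                s = group_summary(m, ds.specimens, a, b)
                # binomial-scale Monte-Carlo envelope per pair
                se = math.sqrt(max(target * (1 - target), 1e-6) / locus.length)
                assert s.mean_p == pytest.approx(target, abs=max(3 * se, 0.004))

    def test_within_group_diversity_scale(self, default_sim):
        ds = default_sim.dataset
        coi = distance_matrix(ds.loci["COI"])
        for g in ds.groups:
            s = group_summary(coi, ds.specimens, g, g)
            assert s.mean_p < 0.010
        s28 = distance_matrix(ds.loci["28S"])
        for g in ds.groups:
            assert group_summary(s28, ds.specimens, g, g).mean_p == 0.0
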