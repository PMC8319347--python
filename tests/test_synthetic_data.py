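"""Generator calibration: determinism, margins, planted structure."""

import numpy as np
import pytest
from scipy import stats

from syntrophevo.sc_lineage import MISSING
from syntrophevo.synthetic_data import (
    CallerProfile,
    SimConfig,
    SweepSpec,
    make_gene_catalog,
    random_mutation_tree,
    simulate_caller_outputs,
    simulate_growth_plate,
    simulate_lines,
    simulate_single_cells,
    true_variants_from_hits,
)
from syntrophevo.trajectory_stats import detect_fixation, detect_sweep, lines_to_frame
from syntrophevo.variant_filtering import MutationCall


class TestSimConfigValidation:
    def test_defaults_valid(self):
        SimConfig()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"generations": (300, 100)},
            {"generations": ()},
            {"fd": 1.5},
            {"parallel_genes": {"G0001": 0.5}},
            {"dilution_fold": 1.0},
            {"n_genes": 0},
            {"mutation_rate": -1},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)


class TestSimulateLines:
    def test_same_seed_identical_output(self):
        config = SimConfig(seed=42, parallel_genes={"G0003": 5.0})
        a, _ = simulate_lines(config)
        b, _ = simulate_lines(config)
        assert lines_to_frame(a).equals(lines_to_frame(b))

    def test_different_seed_differs(self):
        a, _ = simulate_lines(SimConfig(seed=1))
        b, _ = simulate_lines(SimConfig(seed=2))
        assert not lines_to_frame(a).equals(lines_to_frame(b))

    def test_zero_mutation_rate_empty_trajectories(self):
        lines, truth = simulate_lines(SimConfig(seed=3, mutation_rate=0.0))
        assert all(not s.frequencies for ln in lines for s in ln.samples)
        assert truth.hits.empty

    def test_each_line_sampled_at_configured_generations(self):
        config = SimConfig(seed=4, n_lines=5)
        lines, _ = simulate_lines(config)
        assert len(lines) == 5
        for ln in lines:
            assert tuple(ln.generations) == config.generations

    def test_enrichment_one_is_length_proportional(self):
        """Pooled hit counts match a length-proportional multinomial
        (chi-square goodness of fit over pooled seeds)."""
        pvals = []
        for seed in range(20):
            config = SimConfig(seed=seed, n_lines=20, n_genes=12,
                               gene_length_range=(500, 5000), mutation_rate=30.0)
            catalog = make_gene_catalog(config)
            lines, truth = simulate_lines(config, catalog=catalog)
            counts = truth.hits["gene"].value_counts().reindex(
                catalog.gene_ids, fill_value=0
            )
            expected = counts.sum() * catalog.lengths / catalog.lengths.sum()
            p = stats.chisquare(counts.to_numpy(), expected).pvalue
            pvals.append(p)
        assert min(pvals) > 0.001

    def test_planted_parallel_genes_hit_more_often(self):
        config = SimConfig(seed=5, n_lines=13, mutation_rate=12.0,
                           parallel_genes={"G0007": 8.0})
        _, truth = simulate_lines(config)
        counts = truth.hits["gene"].value_counts()
        catalog = truth.catalog
        rel = counts.get("G0007", 0) / catalog.lengths[catalog.index_of("G0007")]
        others = [
            counts.get(g, 0) / catalog.lengths[i]
            for i, g in enumerate(catalog.gene_ids)
            if g != "G0007"
        ]
        assert rel > np.median(others)

    def test_selected_mutations_reach_fixation(self):
        config = SimConfig(seed=6, mutation_rate=15.0, selected_fraction=1.0)
        lines, truth = simulate_lines(config)
        early = truth.hits[truth.hits["appear_generation"] <= 300]
        fixed = 0
        for rec in early.itertuples():
            ln = next(l for l in lines if l.line == rec.line)
            gens, freqs = ln.series(rec.gene)
            if detect_fixation(gens, freqs) is not None:
                fixed += 1
        assert fixed >= 0.8 * len(early)

    def test_sweep_spec_planted_and_detected(self):
        sweep_dv = SweepSpec("L02", (500, 780), frozenset({"Ga", "Gb"}),
                             frozenset({"Gc"}))
        sweep_mm = SweepSpec("L02", (500, 780), frozenset({"Gx"}),
                             frozenset({"Gy", "IG_184033"}))
        dv, _ = simulate_lines(SimConfig(seed=7, sweep_spec=sweep_dv), organism="Dv")
        mm, _ = simulate_lines(SimConfig(seed=8, sweep_spec=sweep_mm), organism="Mm")
        line_dv = next(l for l in dv if l.line == "L02")
        line_mm = next(l for l in mm if l.line == "L02")
        record = detect_sweep(line_dv, line_mm)
        assert record is not None
        assert record.interval == (500, 780)
        assert record.replaced["Dv"] >= {"Ga", "Gb"}
        assert record.novel["Mm"] >= {"Gy", "IG_184033"}

    def test_sweep_spec_validation(self):
        with pytest.raises(ValueError):
            SweepSpec("L1", (780, 500), frozenset("a"), frozenset("b"))
        with pytest.raises(ValueError):
            SweepSpec("L1", (500, 780), frozenset("a"), frozenset("a"))


class TestCallerOutputs:
    def truth_calls(self, n=100):
        return [
            MutationCall(locus=f"g{i}", position=i + 1, ref="A", alt="T",
                         frequency=0.5, callers=frozenset({"truth"}))
            for i in range(n)
        ]

    def test_zero_error_identical_to_truth(self):
        profiles = {c: CallerProfile() for c in ("a", "b", "c")}
        sets = simulate_caller_outputs(self.truth_calls(), profiles, seed=0)
        for calls in sets.values():
            assert [(c.position, c.frequency) for c in calls] == [
                (t.position, t.frequency) for t in self.truth_calls()
            ]

    def test_full_false_negative_empties_caller(self):
        profiles = {"a": CallerProfile(fn_rate=1.0), "b": CallerProfile()}
        sets = simulate_caller_outputs(self.truth_calls(), profiles, seed=0)
        assert sets["a"] == []
        assert len(sets["b"]) == 100

    def test_false_positive_count_binomial(self):
        """FP rate 0.05 over 1000 decoy sites: mean spurious count near 50."""
        counts = []
        for seed in range(30):
            profiles = {"a": CallerProfile(fp_rate=0.05), "b": CallerProfile()}
            sets = simulate_caller_outputs(
                self.truth_calls(), profiles, seed=seed, n_decoy_sites=1000
            )
            counts.append(sum(c.locus.startswith("DECOY") for c in sets["a"]))
        mean = np.mean(counts)
        # 3 sigma band for the mean of 30 binomial(1000, 0.05) draws
        assert abs(mean - 50) < 3 * np.sqrt(1000 * 0.05 * 0.95 / 30)

    def test_requires_two_profiles(self):
        with pytest.raises(ValueError):
            simulate_caller_outputs(self.truth_calls(), {"a": CallerProfile()})

    def test_profile_validation(self):
        with pytest.raises(ValueError):
            CallerProfile(fp_rate=1.5)


class TestSingleCells:
    def test_no_error_rows_are_path_genotypes(self):
        tree = random_mutation_tree(5, seed=0)
        matrix, truth = simulate_single_cells(tree, 50, fd=0.0, ad=0.0, seed=0)
        A = tree.ancestor_matrix()
        for i, cell in enumerate(matrix.cells):
            node = truth.attachments[cell]
            np.testing.assert_array_equal(matrix.states[i], A[node].astype(np.int8))

    def test_perfect_phylogeny_no_conflicting_columns(self):
        tree = random_mutation_tree(5, seed=1)
        matrix, _ = simulate_single_cells(tree, 200, fd=0.0, ad=0.0, seed=1)
        S = matrix.states
        for a in range(S.shape[1]):
            for b in range(a + 1, S.shape[1]):
                pa, pb = S[:, a] == 1, S[:, b] == 1
                both, only_a, only_b = (pa & pb).any(), (pa & ~pb).any(), (~pa & pb).any()
                assert not (both and only_a and only_b)

    def test_all_missing_when_rate_one(self):
        tree = random_mutation_tree(3, seed=2)
        matrix, _ = simulate_single_cells(tree, 10, missing_rate=1.0, seed=2)
        assert (matrix.states == MISSING).all()

    def test_dropout_rate_calibrated(self):
        """Fraction of 0-states among truly mutated entries approximates ad."""
        ad = 0.2
        tree = random_mutation_tree(1, seed=3)  # single mutation under root
        matrix, truth = simulate_single_cells(tree, 2000, fd=0.0, ad=ad, seed=3)
        carriers = [i for i, c in enumerate(matrix.cells)
                    if truth.attachments[c] == 0]
        observed = matrix.states[carriers, 0]
        rate = float((observed == 0).mean())
        n = len(carriers)
        assert abs(rate - ad) < 3 * np.sqrt(ad * (1 - ad) / n)

    def test_determinism(self):
        tree = random_mutation_tree(4, seed=4)
        a, _ = simulate_single_cells(tree, 30, seed=77)
        b, _ = simulate_single_cells(tree, 30, seed=77)
        np.testing.assert_array_equal(a.states, b.states)

    def test_invalid_probability_errors(self):
        tree = random_mutation_tree(2, seed=5)
        with pytest.raises(ValueError):
            simulate_single_cells(tree, 5, fd=-0.1)


class TestGrowthPlate:
    def test_noiseless_plateau_matches_capacity(self):
        config = SimConfig(seed=0, growth_params=(0.05, 8.0, 0.6), noise_sd=0.0)
        plate, _ = simulate_growth_plate(
            config, n_dilutions=3, n_replicates=2,
            min_permissive_density=0.0, top_density=0.02, t_max=400.0,
        )
        curve = plate.wells_at(0)[0]
        # late plateau = blank baseline (0.04) + configured capacity
        assert curve.od[-1] == pytest.approx(0.04 + 0.6, abs=1e-6)

    def test_all_grow_below_min_density(self):
        config = SimConfig(seed=1, growth_params=(0.05, 8.0, 0.6))
        plate, truth = simulate_growth_plate(config, 5, 2, min_permissive_density=0.0)
        assert all(truth.growth_grew.values())

    def test_none_grow_above_max_density(self):
        config = SimConfig(seed=2, growth_params=(0.05, 8.0, 0.6))
        plate, truth = simulate_growth_plate(config, 5, 2, min_permissive_density=1.0)
        assert not any(truth.growth_grew.values())

    def test_dilution_series_fold(self):
        config = SimConfig(seed=3)
        plate, _ = simulate_growth_plate(config, 6, 2, min_permissive_density=0.004)
        ratios = np.array(plate.densities[:-1]) / np.array(plate.densities[1:])
        np.testing.assert_allclose(ratios, 1.5, rtol=1e-12)

    def test_needs_two_dilutions(self):
        with pytest.raises(ValueError):
            simulate_growth_plate(SimConfig(), n_dilutions=1, n_replicates=2,
                                  min_permissive_density=0.004)


def test_true_variants_positions_lie_within_genome():
    config = SimConfig(seed=9, mutation_rate=8.0)
    catalog = make_gene_catalog(config)
    _, truth = simulate_lines(config, catalog=catalog)
    variants = true_variants_from_hits(truth.hits, catalog)
    assert len(variants) == len(truth.hits)
    assert all(1 <= v.position for v in variants)
    gene_set = set(catalog.gene_ids)
    assert all(v.locus in gene_set for v in variants)
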