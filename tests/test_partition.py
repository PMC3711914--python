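import itertools
import math

import numpy as np
import pandas as pd
import pytest

from phylopart import test_bc_vs_wc as bc_vs_wc_test
from phylopart import (
    Alignment,
    amova_phist,
    bc_wc_statistics,
    classify_origin,
    default_structured_config,
    distance_matrix,
    fst_permutation_test,
    northern_origin_test,
    run_origin_battery,
    scheme_from_tables,
    simulate_dataset,
)
from phylopart.errors import ConfigError, DataError
from phylopart.partition import PartitionScheme, _permute_unit_labels


def fixed_difference_matrix():
    """Two groups of two: all between-pairs at distance 1, none within."""
    return distance_matrix(
        Alignment.from_records(
            {"a1": "AAAA", "a2": "AAAA", "b1": "TTTT", "b2": "TTTT"}
        )
    )


def amova_oracle(d: np.ndarray, labels: list[int]) -> float:
    """Literal loop transcription of the two-level AMOVA variance components."""
    n = len(labels)
    groups = sorted(set(labels))
    g = len(groups)
    ss_total = sum(
        d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)
    ) / n
    ss_within = 0.0
    for grp in groups:
        rows = [i for i in range(n) if labels[i] == grp]
        ss_within += sum(
            d[i, j] ** 2
            for i in rows
            for j in rows
            if i < j
        ) / len(rows)
    ss_among = ss_total - ss_within
    sizes = [labels.count(grp) for grp in groups]
    sigma_w = ss_within / (n - g)
    n_bar = (n - sum(s**2 for s in sizes) / n) / (g - 1)
    sigma_a = (ss_among / (g - 1) - sigma_w) / n_bar
    return sigma_a / (sigma_a + sigma_w)


class TestAmova:
    def test_fixed_differences_give_phi_one(self):
        D = fixed_difference_matrix()
        res = amova_phist(D, {"a1": 1, "a2": 1, "b1": 2, "b2": 2})
        assert res.phi_st == pytest.approx(1.0)

    def test_matches_loop_oracle_on_random_data(self):
        rng = np.random.default_rng(21)
        seqs = {f"s{i}": "".join(rng.choice(list("ACGT"), 80)) for i in range(9)}
        D = distance_matrix(Alignment.from_records(seqs))
        labels = [0, 0, 0, 1, 1, 1, 2, 2, 2]
        res = amova_phist(D, dict(zip(seqs, labels)))
        assert res.phi_st == pytest.approx(amova_oracle(D.d, labels))

    def test_small_groups_dropped_with_warning(self):
        # three groups, one a singleton: the singleton is dropped
        D5 = distance_matrix(
            Alignment.from_records(
                {"a1": "AAAA", "a2": "AAAA", "b1": "TTTT", "b2": "TTTT",
                 "c1": "AATT"}
            )
        )
        with pytest.warns(UserWarning, match="<2 members"):
            res = amova_phist(D5, {"a1": 1, "a2": 1, "b1": 2, "b2": 2, "c1": 3})
        assert res.phi_st == pytest.approx(1.0)

    def test_needs_two_groups(self):
        D = fixed_difference_matrix()
        with pytest.raises(DataError):
            amova_phist(D, {"a1": 1, "a2": 1})

    def test_null_phi_near_zero_on_panmictic_data(self):
        from phylopart.simulate import CladeSpec, SimulationConfig

        phis = []
        for rep in range(40):
            cfg = SimulationConfig(
                seed=500 + rep,
                locus_lengths={"x": 800},
                clades=[CladeSpec(c, [c + 1], [5]) for c in range(4)],
                divergence=0.0,
                theta=0.01,
                scenario="panmixia",
            )
            alns, _, truth = simulate_dataset(cfg)
            D = distance_matrix(alns["x"])
            phis.append(amova_phist(D, truth.clade_of).phi_st)
        assert abs(np.mean(phis)) < 0.05


class TestFstPermutation:
    def test_tied_partitions_count_as_exceedances(self):
        # 2+2 fixed differences: any permutation reproducing the observed
        # split (or its label swap) ties at Phi=1 and counts, so the exact
        # p is 1/3, not the floor.
        D = fixed_difference_matrix()
        res = fst_permutation_test(
            D, {"a1": 1, "a2": 1, "b1": 2, "b2": 2}, n_perm=3000, seed=0,
            p_mode="raw",
        )
        assert res.p_value == pytest.approx(1 / 3, abs=0.04)

    def test_strong_structure_reaches_p_floor(self, structured_dataset):
        alns, _, truth = structured_dataset
        D = distance_matrix(alns["sim"])
        res = fst_permutation_test(D, truth.clade_of, n_perm=999, seed=0)
        assert res.p_value == pytest.approx(1 / 1000)
        assert res.phi_st > 0.5

    def test_reproducible_under_seed(self, structured_dataset):
        alns, _, truth = structured_dataset
        D = distance_matrix(alns["sim"])
        a = fst_permutation_test(D, truth.clade_of, n_perm=200, seed=3)
        b = fst_permutation_test(D, truth.clade_of, n_perm=200, seed=3)
        assert a.p_value == b.p_value and a.phi_st == b.phi_st

    def test_invalid_n_perm(self):
        D = fixed_difference_matrix()
        with pytest.raises(ConfigError):
            fst_permutation_test(D, {"a1": 1, "a2": 1, "b1": 2, "b2": 2},
                                 n_perm=0)


class TestBcWc:
    def test_fixed_difference_toy(self):
        D = fixed_difference_matrix()
        d_bc, d_wc = bc_wc_statistics(D, {"a1": 1, "a2": 1, "b1": 2, "b2": 2})
        assert (d_bc, d_wc) == (1.0, 0.0)

    def test_single_clade_bc_undefined(self):
        D = fixed_difference_matrix()
        d_bc, d_wc = bc_wc_statistics(D, {"a1": 1, "a2": 1})
        assert math.isnan(d_bc) and d_wc == 0.0

    def test_pair_means_mode_weights_clades_equally(self):
        # clades of sizes 2,2,1: pooled and pair-mean D_bc differ in weights
        aln = Alignment.from_records(
            {"a1": "AAAAAAAA", "a2": "AAAAAAAA",
             "b1": "TTTTTTTT", "b2": "TTTTTTTT", "c1": "AAAATTTT"}
        )
        D = distance_matrix(aln)
        clades = {"a1": 1, "a2": 1, "b1": 2, "b2": 2, "c1": 3}
        pooled, _ = bc_wc_statistics(D, clades, bc_mode="pooled")
        pair_means, _ = bc_wc_statistics(D, clades, bc_mode="pair_means")
        # pooled: (4*1 + 2*0.5 + 2*0.5)/8; pair means: (1 + .5 + .5)/3
        assert pooled == pytest.approx(6 / 8)
        assert pair_means == pytest.approx(2 / 3)

    def test_strong_structure_reaches_p_floor(self, structured_dataset):
        alns, _, truth = structured_dataset
        D = distance_matrix(alns["sim"])
        res = bc_vs_wc_test(D, truth.clade_of, n_perm=1000, seed=1)
        assert res.p_values["p"] == pytest.approx(1 / 1001)

    def test_monte_carlo_matches_exhaustive_enumeration(self):
        """5 individuals in clades (3,2): MC p vs all C(5,3)=10 assignments."""
        rng = np.random.default_rng(13)
        seqs = {f"s{i}": "".join(rng.choice(list("ACGT"), 60)) for i in range(5)}
        D = distance_matrix(Alignment.from_records(seqs))
        ids = list(seqs)
        clades = {i: (1 if k < 3 else 2) for k, i in enumerate(ids)}

        def statistic(assign):
            d_bc, d_wc = bc_wc_statistics(D, dict(zip(ids, assign)))
            return d_bc - d_wc

        t_obs = statistic([clades[i] for i in ids])
        exact_ts = []
        for rows in itertools.combinations(range(5), 3):
            assign = [1 if k in rows else 2 for k in range(5)]
            exact_ts.append(statistic(assign))
        exact_p = np.mean([t >= t_obs - 1e-12 for t in exact_ts])
        res = bc_vs_wc_test(D, clades, n_perm=4000, seed=2, p_mode="raw")
        se = math.sqrt(exact_p * (1 - exact_p) / 4000) + 1e-9
        assert abs(res.p_values["p"] - exact_p) <= 4 * se + 1e-3

    def test_reproducible_under_seed(self, structured_dataset):
        alns, _, truth = structured_dataset
        D = distance_matrix(alns["sim"])
        a = bc_vs_wc_test(D, truth.clade_of, n_perm=150, seed=8)
        b = bc_vs_wc_test(D, truth.clade_of, n_perm=150, seed=8)
        assert a.p_values == b.p_values
        assert a.observed == b.observed

    def test_observed_independent_of_permutations(self, structured_dataset):
        alns, _, truth = structured_dataset
        D = distance_matrix(alns["sim"])
        a = bc_vs_wc_test(D, truth.clade_of, n_perm=50, seed=1)
        direct = bc_wc_statistics(D, truth.clade_of)
        assert (a.observed["D_bc"], a.observed["D_wc"]) == direct


class TestUnits:
    def test_unit_rows_stay_together(self):
        labels = np.array([0, 0, 1, 1, 2, 2])
        units = [np.array([0, 1]), np.array([2, 3]), np.array([4, 5])]
        rng = np.random.default_rng(0)
        for _ in range(20):
            out = _permute_unit_labels(labels, units, rng)
            for u in units:
                assert len({out[i] for i in u}) == 1

    def test_diploid_pairing_respected_in_test(self):
        rng = np.random.default_rng(33)
        seqs = {f"h{i}": "".join(rng.choice(list("ACGT"), 40)) for i in range(8)}
        D = distance_matrix(Alignment.from_records(seqs))
        clades = {f"h{i}": (1 if i < 4 else 2) for i in range(8)}
        individual_of = {f"h{i}": f"ind{i // 2}" for i in range(8)}
        res = bc_vs_wc_test(D, clades, n_perm=100, seed=5,
                            individual_of=individual_of)
        assert 0 < res.p_values["p"] <= 1


class TestNorthernOrigin:
    def _scheme(self, table):
        northern = sorted(
            table.loc[table["region"] == "northern", "locality_code"].unique()
        )
        southern = sorted(
            table.loc[table["region"] == "southern", "locality_code"].unique()
        )
        return scheme_from_tables(
            table, {"northern": northern, "southern": southern}
        )

    @pytest.mark.parametrize(
        "scenario,expected",
        [
            ("northern_in_situ", "in_situ"),
            ("northern_recent_expansion", "southern_origin"),
        ],
    )
    def test_scenarios_classified_by_battery(self, scenario, expected):
        from phylopart import classify_battery

        region_config = {
            "northern": [100],
            "southern": [1, 2, 3, 4],
            "contiguous_blocks": [
                {"northern": [100], "southern_sets": {"adjacent": [1]}}
            ],
        }
        hits = 0
        for rep in range(10):
            cfg = default_structured_config(seed=900 + rep, scenario=scenario)
            alns, table, _ = simulate_dataset(cfg)
            D = distance_matrix(alns["sim"])
            scheme = scheme_from_tables(table, region_config)
            battery = run_origin_battery(D, scheme, n_perm=500, seed=rep,
                                         region_config=region_config)
            hits += classify_battery(battery)[100] == expected
        assert hits >= 8

    def test_recent_expansion_within_level_against_source(self):
        """Against its source pool, a colonist locality's D_i sits at the
        within-clade level (p_wc non-significant)."""
        cfg = default_structured_config(
            seed=901, scenario="northern_recent_expansion"
        )
        alns, table, _ = simulate_dataset(cfg)
        D = distance_matrix(alns["sim"])
        scheme = self._scheme(table)
        res = northern_origin_test(D, scheme, 100, [1], n_perm=500, seed=0)
        assert res.p_values["p_wc"] > 0.05
        assert classify_origin(res) == "southern_origin"

    def test_contiguous_set_must_nest_in_all_southern(self):
        with pytest.raises(ConfigError):
            PartitionScheme(
                locality_of={"a": 1},
                clade_of_locality={1: 1},
                northern=frozenset({1}),
                southern_sets={
                    "all_southern": frozenset({2}),
                    "contig_x": frozenset({3}),
                },
            )

    def test_battery_row_structure(self):
        cfg = default_structured_config(seed=42, scenario="northern_in_situ")
        alns, table, _ = simulate_dataset(cfg)
        D = distance_matrix(alns["sim"])
        scheme = self._scheme(table)
        out = run_origin_battery(D, scheme, n_perm=99, seed=0)
        assert len(out) == 1  # one northern locality x all_southern
        assert set(out.columns) >= {"locality", "reference_set", "D_i",
                                    "p_bc", "p_wc", "classification"}

    def test_battery_covers_study_comparisons(self):
        """With the study's region config, every northern locality gets an
        all-southern row plus its contiguous row(s); 35-36 get two."""
        from phylopart import default_region_config, default_sample_table

        table = default_sample_table()
        cfg_regions = default_region_config()
        scheme = scheme_from_tables(table, cfg_regions)
        rng = np.random.default_rng(77)
        ids = list(table["specimen_id"])
        seqs = {i: "".join(rng.choice(list("ACGT"), 30)) for i in ids}
        D = distance_matrix(Alignment.from_records(seqs))
        out = run_origin_battery(D, scheme, n_perm=9, seed=0,
                                 region_config=cfg_regions)
        counts = out.groupby("locality").size().to_dict()
        assert counts[35] == 3 and counts[36] == 3  # all + Italy + Balkans
        for loc in (1, 20, 21, 22, 23, 25, 26, 37, 38, 39):
            assert counts[loc] == 2
        assert len(out) == 10 * 2 + 2 * 3
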