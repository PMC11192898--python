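import numpy as np
import pandas as pd
import pytest

from lpicalc import (
    AdjustmentConfig,
    LambdaSet,
    MERGED_5REALM,
    ProcessedSeries,
    WeightTable,
    aggregate,
    build_hierarchy,
    chain_index,
    compute_lambdas,
    compute_lpi,
    prepare_population_lambdas,
)

from conftest import make_series


def lam_set(entity, mapping, level="population"):
    return LambdaSet(
        level=level,
        entity_id=entity,
        lambdas=pd.Series(mapping, dtype=float),
        counts=pd.Series(1, index=list(mapping)),
    )


def proc(values, start=1970, pid="p"):
    years = np.arange(start, start + len(values))
    return ProcessedSeries(pid, "chain", years, np.asarray(values, dtype=float))


class TestComputeLambdas:
    def test_log10_ratio_assigned_to_later_year(self):
        lam = compute_lambdas(proc([3, 5]))
        assert lam.lambdas.to_dict() == {1971: pytest.approx(np.log10(5 / 3))}
        assert lam.lambdas[1971] == pytest.approx(0.2218, abs=5e-5)

    def test_equal_values_give_zero(self):
        lam = compute_lambdas(proc([4, 4, 4]))
        assert (lam.lambdas == 0).all()

    def test_cap_clamps_not_discards(self):
        lam = compute_lambdas(proc([3, 1]), cap=0.3)
        assert lam.lambdas[1971] == pytest.approx(-0.3)
        lam_uncapped = compute_lambdas(proc([3, 1]))
        assert lam_uncapped.lambdas[1971] == pytest.approx(-0.4771, abs=5e-5)


class TestAggregate:
    def test_unweighted_mean(self):
        parent = aggregate(
            [lam_set("a", {1971: np.log10(5 / 3)}), lam_set("b", {1971: np.log10(1 / 3)})]
        )
        assert parent.lambdas[1971] == pytest.approx(-0.12765, abs=5e-5)
        assert parent.counts[1971] == 2

    def test_symmetric_weights_cancel(self):
        parent = aggregate(
            [lam_set("a", {1971: 0.1}), lam_set("b", {1971: -0.1})],
            weights={"a": 0.5, "b": 0.5},
        )
        assert parent.lambdas[1971] == pytest.approx(0.0)

    def test_absent_child_weight_renormalized(self):
        """A 0.7/0.3 weighting where the 0.3 child is absent in a year gives
        the present child full weight that year."""
        parent = aggregate(
            [lam_set("a", {1971: 0.2, 1972: 0.1}), lam_set("b", {1971: -0.2})],
            weights={"a": 0.7, "b": 0.3},
        )
        assert parent.lambdas[1971] == pytest.approx(0.7 * 0.2 + 0.3 * -0.2)
        assert parent.lambdas[1972] == pytest.approx(0.1)
        assert parent.counts[1972] == 1

    def test_duplicate_child_ids_count_twice(self):
        parent = aggregate([lam_set("a", {1971: 0.3}), lam_set("a", {1971: 0.0})])
        assert parent.lambdas[1971] == pytest.approx(0.15)


class TestChainIndex:
    def test_multiplicative_chaining(self):
        top = lam_set("g", {1971: np.log10(5 / 3), 1972: np.log10(1 / 3)}, level="global")
        idx = chain_index(top, 1970)
        np.testing.assert_allclose(
            idx.values.to_numpy(), [1.0, 1.6667, 0.5556], atol=5e-5
        )

    def test_all_zero_lambda_gives_flat_index(self):
        top = lam_set("g", {y: 0.0 for y in range(1971, 1980)}, level="global")
        idx = chain_index(top, 1970)
        assert (idx.values == 1.0).all()

    def test_gap_years_carry_forward_and_are_flagged(self):
        top = lam_set("g", {1971: 0.1, 1974: -0.1}, level="global")
        idx = chain_index(top, 1970)
        assert idx.carried_forward == (1972, 1973)
        assert idx.values[1972] == idx.values[1971]
        assert idx.values[1974] == pytest.approx(1.0)

    def test_index_satisfies_recurrence(self):
        rng = np.random.default_rng(1)
        lam = {y: rng.normal(0, 0.1) for y in range(1971, 1990)}
        idx = chain_index(lam_set("g", lam, level="global"), 1970)
        for y in range(1971, 1990):
            assert idx.values[y] == pytest.approx(idx.values[y - 1] * 10 ** lam[y])


def nested_geometric_mean_oracle(pop_lambdas, year):
    """Brute-force nested geometric means: populations of a species, species
    of a taxon, taxa of a realm, realms of an ecosystem, ecosystems —
    products and roots, no logs."""

    def geomean(values):
        prod = 1.0
        for v in values:
            prod *= v
        return prod ** (1.0 / len(values))

    species = {}
    for meta, lam in pop_lambdas:
        if year in lam.lambdas.index:
            key = (meta.ecosystem, meta.realm, meta.taxon, meta.species)
            species.setdefault(key, []).append(10.0 ** lam.lambdas[year])
    s = {key: geomean(ratios) for key, ratios in species.items()}
    taxa = {}
    for key, val in s.items():
        taxa.setdefault(key[:3], []).append(val)
    t = {key: geomean(vals) for key, vals in taxa.items()}
    realms = {}
    for key, val in t.items():
        realms.setdefault(key[:2], []).append(val)
    r = {key: geomean(vals) for key, vals in realms.items()}
    ecos = {}
    for key, val in r.items():
        ecos.setdefault(key[0], []).append(val)
    e = {key: geomean(vals) for key, vals in ecos.items()}
    return geomean(list(e.values()))


def random_small_dataset(rng):
    n = rng.integers(1, 6)
    pops = []
    ecosystems = ["terrestrial", "freshwater", "marine"]
    for i in range(n):
        eco = ecosystems[rng.integers(0, 3)]
        realm = MERGED_5REALM.realms[eco][rng.integers(0, len(MERGED_5REALM.realms[eco]))]
        taxon = MERGED_5REALM.taxa[eco][rng.integers(0, len(MERGED_5REALM.taxa[eco]))]
        length = rng.integers(2, 7)
        start = 1970 + rng.integers(0, 4)
        values = np.exp(rng.uniform(0, 5, size=length))
        pops.append(
            make_series(
                f"p{i}",
                values,
                start=start,
                species=f"sp{rng.integers(0, 3)}",
                taxon=taxon,
                realm=realm,
                ecosystem=eco,
            )
        )
    return pops


class TestHierarchy:
    def test_single_population_passes_through(self):
        cfg = AdjustmentConfig(bootstrap_reps=0)
        pops = [make_series("p", [3, 5, 4])]
        pl = prepare_population_lambdas(pops, cfg, MERGED_5REALM)
        top = build_hierarchy(pl, MERGED_5REALM, weighted=False)
        pd.testing.assert_series_equal(top.lambdas, pl[0][1].lambdas)

    def test_single_declining_taxon_contributes_third_of_realm_lambda(self):
        """One declining population alone in its taxon among 3 equally
        weighted taxa pulls the realm mean by a third of its rate."""
        cfg = AdjustmentConfig(bootstrap_reps=0)
        decline = make_series("viper", 30 * 10 ** (-0.3 * np.arange(4)), taxon="herptiles")
        flat1 = make_series("bird", [50.0] * 4, taxon="birds")
        flat2 = make_series("mouse", [80.0] * 4, taxon="mammals")
        pl = prepare_population_lambdas([decline, flat1, flat2], cfg, MERGED_5REALM)
        top = build_hierarchy(pl, MERGED_5REALM, weighted=True, scope="terrestrial")
        np.testing.assert_allclose(top.lambdas.to_numpy(), -0.1, atol=1e-12)

    def test_weighted_equals_direct_weighted_mean(self):
        cfg = AdjustmentConfig(bootstrap_reps=0)
        a = make_series("a", [10, 20], taxon="birds")
        b = make_series("b", [10, 5], taxon="mammals")
        weights = WeightTable(
            {("Palearctic", "birds"): 0.8, ("Palearctic", "mammals"): 0.2},
            {("terrestrial", "Palearctic"): 1.0},
        )
        pl = prepare_population_lambdas([a, b], cfg, MERGED_5REALM)
        top = build_hierarchy(
            pl, MERGED_5REALM, weights=weights, weighted=True, scope="terrestrial"
        )
        expected = 0.8 * np.log10(2) + 0.2 * np.log10(0.5)
        assert top.lambdas[1971] == pytest.approx(expected, abs=1e-14)
        unweighted = build_hierarchy(pl, MERGED_5REALM, weighted=False, scope="terrestrial")
        assert unweighted.lambdas[1971] == pytest.approx(0.5 * np.log10(2) + 0.5 * np.log10(0.5))

    def test_matches_nested_geometric_mean_oracle(self):
        """Mean-of-logs pipeline equals brute-force nested geometric means."""
        cfg = AdjustmentConfig(bootstrap_reps=0)
        rng = np.random.default_rng(42)
        for _ in range(25):
            pops = random_small_dataset(rng)
            pl = prepare_population_lambdas(pops, cfg, MERGED_5REALM)
            top = build_hierarchy(pl, MERGED_5REALM, weighted=False)
            for year in top.lambdas.index:
                oracle = nested_geometric_mean_oracle(pl, year)
                assert 10 ** top.lambdas[year] == pytest.approx(oracle, abs=1e-12)

    def test_permutation_invariance(self):
        cfg = AdjustmentConfig(bootstrap_reps=0)
        rng = np.random.default_rng(7)
        pops = random_small_dataset(rng)
        pl = list(prepare_population_lambdas(pops, cfg, MERGED_5REALM))
        top1 = build_hierarchy(pl, MERGED_5REALM, weighted=False)
        top2 = build_hierarchy(pl[::-1], MERGED_5REALM, weighted=False)
        pd.testing.assert_series_equal(top1.lambdas, top2.lambdas)


class TestFullPipelineInvariances:
    def test_paired_reciprocal_ratios_give_flat_index(self):
        """Populations with yearly ratios r and 1/r cancel exactly: doubling
        populations are compensated by halving ones."""
        r = 1.7
        up = make_series("up", 10 * r ** np.arange(5), species="sa")
        down = make_series("down", 10 * (1 / r) ** np.arange(5), species="sb")
        idx = compute_lpi([up, down], AdjustmentConfig(bootstrap_reps=0))
        np.testing.assert_allclose(idx.values.to_numpy(), 1.0, atol=1e-12)

    @pytest.mark.parametrize("policy", ["replace_one_percent", "remove_and_split"])
    def test_rescaling_one_population_leaves_index_unchanged(self, policy):
        values_a = [3.0, 0.0, 6.0, 7.0, 5.0]
        values_b = [10.0, 12.0, 9.0, 14.0, 11.0]
        cfg = AdjustmentConfig(zero_policy=policy, bootstrap_reps=0)
        base = compute_lpi(
            [make_series("a", values_a, species="sa"), make_series("b", values_b, species="sb")],
            cfg,
        )
        scaled = compute_lpi(
            [
                make_series("a", [v * 137.5 for v in values_a], species="sa"),
                make_series("b", values_b, species="sb"),
            ],
            cfg,
        )
        np.testing.assert_allclose(
            scaled.values.to_numpy(), base.values.to_numpy(), rtol=1e-12
        )

    def test_universal_two_percent_decline_recovered(self):
        """Every population declining 2%/year for 48 years: final index
        0.98**48 to 1e-10, through the spline path included."""
        t = np.arange(49)
        pops = [
            make_series("a", 100 * 0.98 ** t, species="sa", taxon="birds"),
            make_series("b", 55 * 0.98 ** t, species="sb", taxon="mammals"),
            make_series("c", 700 * 0.98 ** t, species="sc", taxon="herptiles", realm="Nearctic"),
        ]
        idx = compute_lpi(pops, AdjustmentConfig(bootstrap_reps=0))
        assert idx.final_year == 1970 + 48
        assert idx.final_value == pytest.approx(0.98 ** 48, abs=1e-10)


class TestBootstrap:
    def test_one_species_per_taxon_gives_zero_width_ci(self):
        pops = [
            make_series("a", [3, 5, 4], species="sa", taxon="birds"),
            make_series("b", [8, 6, 9], species="sb", taxon="mammals"),
        ]
        idx = compute_lpi(pops, AdjustmentConfig(bootstrap_reps=100, seed=1))
        np.testing.assert_allclose(idx.ci_low.to_numpy(), idx.values.to_numpy(), atol=1e-14)
        np.testing.assert_allclose(idx.ci_high.to_numpy(), idx.values.to_numpy(), atol=1e-14)

    def test_fixed_seed_reproduces_cis_bit_identically(self):
        rng = np.random.default_rng(3)
        pops = [
            make_series(f"p{i}", np.exp(rng.uniform(0, 3, 4)), species=f"s{i % 5}")
            for i in range(10)
        ]
        cfg = AdjustmentConfig(bootstrap_reps=100, seed=11)
        a = compute_lpi(pops, cfg)
        b = compute_lpi(pops, cfg)
        assert a.ci_low.equals(b.ci_low) and a.ci_high.equals(b.ci_high)

    def test_central_index_inside_its_own_ci(self):
        rng = np.random.default_rng(5)
        pops = [
            make_series(
                f"p{i}",
                np.exp(rng.normal(2, 0.3, 6)),
                species=f"s{i}",
                taxon=["birds", "mammals", "herptiles"][i % 3],
            )
            for i in range(50)
        ]
        idx = compute_lpi(pops, AdjustmentConfig(bootstrap_reps=100, seed=2))
        assert ((idx.ci_low <= idx.values + 1e-9) & (idx.values <= idx.ci_high + 1e-9)).all()
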