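import numpy as np
import pandas as pd
import pytest

from mescore.flux_attribution import (
    balance_cohorts,
    compare_totals,
    confounder_model,
    exchange_graph,
    key_species,
    log2_with_offset,
    sample_totals,
    weighted_flux_sums,
)


def records_from_tuples(rows):
    return pd.DataFrame(
        rows, columns=["sample_id", "taxon_id", "metabolite_id", "direction", "flux"]
    )


@pytest.fixture
def two_taxon_records():
    return records_from_tuples(
        [("s1", "A", "h2s", "export", 2.0), ("s1", "B", "h2s", "import", 1.0)]
    )


class TestSampleTotals:
    def test_weighted_totals_and_flux_ratio(self, two_taxon_records):
        abundance = pd.DataFrame({"A": [0.5], "B": [0.25]}, index=["s1"])
        totals = sample_totals(two_taxon_records, abundance, "h2s").iloc[0]
        assert totals["production"] == pytest.approx(1.0)
        assert totals["consumption"] == pytest.approx(0.25)
        assert totals["ratio_flux"] == pytest.approx(4.0)
        assert totals["excess"] == pytest.approx(0.75)

    def test_no_consumers_flags_ratio_undefined(self):
        records = records_from_tuples([("s1", "A", "h2s", "export", 2.0)])
        abundance = pd.DataFrame({"A": [1.0]}, index=["s1"])
        with pytest.warns(UserWarning, match="undefined"):
            totals = sample_totals(records, abundance, "h2s").iloc[0]
        assert np.isnan(totals["ratio_flux"])
        assert np.isnan(totals["ratio_counts"])

    def test_abundance_scaling_cancels_in_ratio(self, two_taxon_records):
        base = pd.DataFrame({"A": [0.5], "B": [0.25]}, index=["s1"])
        doubled = base * 2  # renormalization deliberately bypassed
        a = sample_totals(two_taxon_records, base, "h2s").iloc[0]
        b = sample_totals(two_taxon_records, doubled, "h2s").iloc[0]
        assert b["production"] == pytest.approx(2 * a["production"])
        assert b["consumption"] == pytest.approx(2 * a["consumption"])
        assert b["ratio_flux"] == pytest.approx(a["ratio_flux"])

    def test_unknown_metabolite_rejected(self, two_taxon_records):
        abundance = pd.DataFrame({"A": [1.0]}, index=["s1"])
        with pytest.raises(ValueError):
            sample_totals(two_taxon_records, abundance, "urea")

    def test_log2_offset_defaults_to_half_smallest_nonzero(self):
        out = log2_with_offset(np.array([0.0, 4.0, 8.0]))
        assert out[1] == pytest.approx(2.0)
        assert out[0] == pytest.approx(np.log2(2.0))  # half of 4.0


class TestCompareTotals:
    def test_identical_cohorts_all_h_zero(self, small_dataset):
        met = small_dataset.records["metabolite_id"].iloc[0]
        totals = sample_totals(small_dataset.records, small_dataset.abundance, met)
        # mirror the same per-sample totals into a second cohort: identical data
        doubled = pd.concat([totals, totals.assign(sample_id=totals["sample_id"] + "_b")])
        meta2 = pd.DataFrame(
            {"cohort": ["a"] * len(totals) + ["b"] * len(totals)},
            index=pd.Index(list(totals["sample_id"]) + [s + "_b" for s in totals["sample_id"]],
                           name="sample_id"),
        )
        res = compare_totals(doubled, meta2, ("a", "b"))
        assert (res["H"].abs() < 1e-9).all()  # zero up to rank-tie rounding


class TestBalanceCohorts:
    @pytest.fixture
    def meta_46_38(self):
        labels = ["healthy"] * 46 + ["cd"] * 38
        return pd.DataFrame(
            {"cohort": labels},
            index=pd.Index([f"s{i:03d}" for i in range(84)], name="sample_id"),
        )

    def test_downsamples_to_smaller_cohort(self, meta_46_38):
        balanced = balance_cohorts(meta_46_38, ("healthy", "cd"), seed=3)
        counts = balanced["cohort"].value_counts()
        assert counts["healthy"] == 38 and counts["cd"] == 38
        assert len(meta_46_38) - len(balanced) == 8

    def test_equal_sizes_unchanged(self, meta_46_38):
        equal = meta_46_38.iloc[:76]  # 46 healthy + 30 cd -> trim to equal by hand
        equal = pd.concat(
            [
                meta_46_38[meta_46_38["cohort"] == "healthy"].iloc[:38],
                meta_46_38[meta_46_38["cohort"] == "cd"],
            ]
        )
        balanced = balance_cohorts(equal, ("healthy", "cd"), seed=3)
        assert sorted(balanced.index) == sorted(equal.index)

    def test_seed_reproducible_and_subset(self, meta_46_38):
        a = balance_cohorts(meta_46_38, ("healthy", "cd"), seed=11)
        b = balance_cohorts(meta_46_38, ("healthy", "cd"), seed=11)
        assert list(a.index) == list(b.index)
        assert set(a.index) <= set(meta_46_38.index)
        c = balance_cohorts(meta_46_38, ("healthy", "cd"), seed=12)
        assert list(a.index) != list(c.index)


class TestKeySpecies:
    @pytest.fixture
    def cohort_records(self):
        rows = []
        for i, cohort in enumerate(["h", "h", "d", "d"]):
            sample = f"{cohort}{i}"
            rows.append((sample, "A", "h2s", "export", 1.0))
            rows.append((sample, "B", "h2s", "import", 1.0))
        # taxon X only in the disease cohort
        rows.append(("d2", "X", "h2s", "export", 3.0))
        return records_from_tuples(rows)

    @pytest.fixture
    def cohort_meta(self):
        return pd.DataFrame(
            {"cohort": ["healthy", "healthy", "cd", "cd"]},
            index=pd.Index(["h0", "h1", "d2", "d3"], name="sample_id"),
        )

    @pytest.fixture
    def flat_abundance(self, cohort_meta):
        return pd.DataFrame(
            0.25, index=cohort_meta.index, columns=["A", "B", "X"]
        )

    def test_cohort_exclusive_taxon_has_zero_sum_elsewhere(
        self, cohort_records, cohort_meta, flat_abundance
    ):
        key = key_species(
            cohort_records, flat_abundance, cohort_meta, "h2s",
            ("healthy", "cd"), top_n=None, seed=0,
        )
        row = key[(key["taxon_id"] == "X") & (key["role"] == "producer")].iloc[0]
        assert row["weighted_sum_a"] == 0.0
        assert row["weighted_sum_b"] > 0.0

    def test_identical_cohorts_all_deltas_zero(
        self, cohort_records, cohort_meta, flat_abundance
    ):
        sans_x = cohort_records[cohort_records["taxon_id"] != "X"]
        key = key_species(
            sans_x, flat_abundance, cohort_meta, "h2s", ("healthy", "cd"),
            top_n=None, seed=0,
        )
        assert (key["delta"] == 0.0).all()

    def test_delta_antisymmetry_under_cohort_swap(self, planted_dataset):
        met = "m004"
        args = (planted_dataset.records, planted_dataset.abundance, planted_dataset.metadata, met)
        ab = key_species(*args, ("healthy", "disease"), top_n=None, seed=5)
        ba = key_species(*args, ("disease", "healthy"), top_n=None, seed=5)
        merged = ab.merge(ba, on=["taxon_id", "role"], suffixes=("_ab", "_ba"))
        assert len(merged) == len(ab)
        assert (merged["delta_ab"] == -merged["delta_ba"]).all()

    def test_ranking_invariant_to_taxon_relabeling(
        self, cohort_records, cohort_meta, flat_abundance
    ):
        rename = {"A": "Q1", "B": "Q2", "X": "Q3"}
        relabeled = cohort_records.assign(
            taxon_id=cohort_records["taxon_id"].map(rename)
        )
        ab2 = flat_abundance.rename(columns=rename)
        base = key_species(cohort_records, flat_abundance, cohort_meta, "h2s",
                           ("healthy", "cd"), top_n=None, seed=0)
        perm = key_species(relabeled, ab2, cohort_meta, "h2s",
                           ("healthy", "cd"), top_n=None, seed=0)
        assert list(base["delta"]) == list(perm["delta"])

    def test_weighted_sum_linear_in_abundance(self, cohort_records, flat_abundance):
        samples = ["h0", "h1"]
        base = weighted_flux_sums(cohort_records, flat_abundance, samples, "h2s")
        scaled_ab = flat_abundance.copy()
        scaled_ab["A"] *= 3.0
        scaled = weighted_flux_sums(cohort_records, scaled_ab, samples, "h2s")
        merged = base.merge(scaled, on=["taxon_id", "role"], suffixes=("_1", "_3"))
        a_row = merged[merged["taxon_id"] == "A"].iloc[0]
        b_row = merged[merged["taxon_id"] == "B"].iloc[0]
        assert a_row["weighted_sum_3"] == pytest.approx(3 * a_row["weighted_sum_1"])
        assert b_row["weighted_sum_3"] == pytest.approx(b_row["weighted_sum_1"])

    def test_missing_taxon_abundance_is_referential_error(self, cohort_records, cohort_meta):
        from mescore.errors import ReferentialError

        partial = pd.DataFrame(0.5, index=cohort_meta.index, columns=["A", "B"])
        with pytest.raises(ReferentialError):
            key_species(cohort_records, partial, cohort_meta, "h2s",
                        ("healthy", "cd"), seed=0)

    def test_edge_list_orientation(self, cohort_records, cohort_meta, flat_abundance):
        key = key_species(cohort_records, flat_abundance, cohort_meta, "h2s",
                          ("healthy", "cd"), top_n=None, seed=0)
        edges = exchange_graph(key, "h2s")
        producers = edges[edges["role"] == "producer"]
        consumers = edges[edges["role"] == "consumer"]
        assert (producers["target"] == "h2s").all()
        assert (consumers["source"] == "h2s").all()


class TestConfounderModel:
    def simulate(self, seed, disease_effect, n=30, noise_sd=0.5):
        rng = np.random.default_rng(seed)
        idx = pd.Index([f"s{i}" for i in range(2 * n)], name="sample_id")
        cohort = ["healthy"] * n + ["cd"] * n
        richness = rng.integers(99, 200, size=2 * n)
        response = (
            0.05 * richness
            + disease_effect * (np.array(cohort) == "cd")
            + rng.normal(0, noise_sd, size=2 * n)
        )
        meta = pd.DataFrame({"cohort": cohort}, index=idx)
        adiv = pd.DataFrame({"richness": richness, "shannon": 1.0}, index=idx)
        return pd.Series(response, index=idx), meta, adiv

    def test_low_richness_samples_excluded(self):
        response, meta, adiv = self.simulate(0, disease_effect=0.0)
        adiv.iloc[0, adiv.columns.get_loc("richness")] = 98
        fit = confounder_model(response, meta, adiv, disease="cd", min_species=99)
        assert fit["n_samples"] == len(meta) - 1

    def test_pure_richness_effect_not_attributed_to_disease(self):
        hits = 0
        n_seeds = 20
        for s in range(n_seeds):
            response, meta, adiv = self.simulate(s, disease_effect=0.0)
            fit = confounder_model(response, meta, adiv, disease="cd")
            hits += fit["disease_p"] > 0.05
        assert hits / n_seeds >= 0.9

    def test_planted_disease_effect_recovered(self):
        hits = 0
        n_seeds = 20
        for s in range(n_seeds):
            response, meta, adiv = self.simulate(s, disease_effect=1.0)
            fit = confounder_model(response, meta, adiv, disease="cd")
            hits += (0.5 <= fit["disease_coef"] <= 1.5) and fit["disease_p"] < 0.05
        assert hits / n_seeds >= 0.9

    def test_everything_filtered_is_explicit_error(self):
        response, meta, adiv = self.simulate(0, disease_effect=0.0)
        with pytest.raises(ValueError, match="filter"):
            confounder_model(response, meta, adiv, disease="cd", min_species=10_000)
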