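"""Delta-Tm matrix assembly, hit calling and screen summaries."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import kinscreen as ks
from kinscreen.errors import MalformedInputError, MissingReferenceError, UndefinedRateError


def random_matrix(seed, n_kinases=8, n_compounds=30):
    """Random clamped delta-Tm matrix with random per-kinase DMSO SDs."""
    rng = np.random.default_rng(seed)
    kinases = [f"K{i}" for i in range(n_kinases)]
    compounds = [f"C{j}" for j in range(n_compounds)]
    dtm = pd.DataFrame(
        np.round(np.maximum(0.0, rng.normal(0.3, 1.0, (n_compounds, n_kinases))), 3),
        index=compounds,
        columns=kinases,
    )
    sd = pd.Series(rng.uniform(0.1, 0.5, n_kinases), index=kinases)
    return ks.matrix_from_dtm(dtm, sd)


class TestBuildReference:
    def test_zero_variance(self):
        ref = ks.build_reference("k1", [50.0, 50.0, 50.0])
        assert ref.tm_mean == 50.0
        assert ref.dtm_sd == 0.0

    def test_matches_two_pass_sample_sd(self):
        tms = [49.8, 50.0, 50.2]
        ref = ks.build_reference("k1", tms)
        mean = sum(tms) / 3
        sd = math.sqrt(sum((x - mean) ** 2 for x in tms) / 2)
        assert ref.dtm_sd == pytest.approx(sd, rel=1e-12)
        assert ref.n_wells == 3

    def test_single_control_raises(self):
        with pytest.raises(MissingReferenceError, match="k9"):
            ks.build_reference("k9", [50.0])


class TestDeltaTm:
    def setup_method(self):
        self.ref = ks.build_reference("k1", [50.0, 50.0, 50.0])

    def test_replicate_mean(self):
        shift = ks.delta_tm("c1", [52.1, 52.3, 52.2], self.ref)
        assert shift.dtm_mean == pytest.approx(2.2)
        assert shift.n_replicates == 3
        assert not shift.clamped

    def test_negative_mean_clamped_to_zero(self):
        shift = ks.delta_tm("c1", [49.2, 49.2, 49.2], self.ref, clamp=True)
        assert shift.dtm_mean == pytest.approx(-0.8)
        assert shift.dtm_reported == 0.0
        assert shift.clamped

    def test_identical_to_reference_not_clamped(self):
        shift = ks.delta_tm("c1", [50.0, 50.0, 50.0], self.ref)
        assert shift.dtm_reported == 0.0
        assert not shift.clamped

    def test_no_passing_fits_absent(self):
        shift = ks.delta_tm("c1", [], self.ref)
        assert shift.absent and shift.n_replicates == 0


class TestCallHits:
    def test_boundary_equality_is_hit(self):
        dtm = pd.DataFrame({"K0": [0.70, 0.0]}, index=["c1", "c2"])
        m = ks.matrix_from_dtm(dtm, {"K0": 0.35})
        assert bool(m.hits.loc["c1", "K0"]) is True  # 0.70 == 2 * 0.35
        assert bool(m.hits.loc["c2", "K0"]) is False

    def test_zero_sd_kinase_hits_on_strictly_positive(self):
        dtm = pd.DataFrame({"K0": [0.0, 0.01]}, index=["c1", "c2"])
        m = ks.matrix_from_dtm(dtm, {"K0": 0.0})
        assert bool(m.hits.loc["c1", "K0"]) is False
        assert bool(m.hits.loc["c2", "K0"]) is True

    def test_matches_elementwise_oracle_on_simulated_screen(self):
        """Seeded 40 x 627 matrix: flags equal a brute-force comparison."""
        sim = ks.simulate_screen(dataclasses.replace(ks.ScreenScenario(), seed=21))
        m = ks.matrix_from_fit_table(sim.to_fit_table())
        for kinase in m.kinases[:5] + m.kinases[-2:]:
            thr = 2.0 * m.dmso_sd[kinase]
            for compound in m.compounds[::97]:
                val = m.dtm_reported.loc[compound, kinase]
                expected = (val >= thr) if thr > 0 else (val > 0)
                assert bool(m.hits.loc[compound, kinase]) == bool(expected)

    def test_absent_cells_are_never_hits(self):
        dtm = pd.DataFrame({"K0": [np.nan, 5.0]}, index=["c1", "c2"])
        m = ks.matrix_from_dtm(dtm, {"K0": 0.1})
        assert bool(m.hits.loc["c1", "K0"]) is False
        assert bool(m.hits.loc["c2", "K0"]) is True


class TestCounts:
    def test_all_zero_matrix(self):
        dtm = pd.DataFrame(0.0, index=[f"c{i}" for i in range(627)], columns=["K0", "K1"])
        m = ks.matrix_from_dtm(dtm, {"K0": 0.3, "K1": 0.4})
        assert ks.kinase_hit_count(m).sum() == 0
        counts, summary = ks.compound_promiscuity(m)
        assert summary["n_zero_hit"] == 627
        assert summary["n_at_least_cutoff"] == 0

    def test_counts_equal_brute_force_sums(self):
        m = random_matrix(2)
        hits = m.hits
        by_kinase = ks.kinase_hit_count(m)
        by_compound, _ = ks.compound_promiscuity(m)
        for k in m.kinases:
            assert by_kinase[k] == sum(bool(hits.loc[c, k]) for c in m.compounds)
        for c in m.compounds:
            assert by_compound[c] == sum(bool(hits.loc[c, k]) for k in m.kinases)

    def test_single_hit(self):
        dtm = pd.DataFrame(0.0, index=["c1", "c2"], columns=["K0", "K1"])
        dtm.loc["c1", "K0"] = 3.0
        m = ks.matrix_from_dtm(dtm, {"K0": 0.3, "K1": 0.3})
        counts = ks.kinase_hit_count(m)
        assert counts["K0"] == 1 and counts["K1"] == 0

    def test_conservation_by_kinase_and_compound(self):
        for seed in range(4):
            m = random_matrix(seed)
            assert ks.kinase_hit_count(m).sum() == ks.compound_promiscuity(m)[0].sum()

    def test_constructed_promiscuity_tail(self):
        """Exactly 20 compounds hitting >= 10 kinases are counted as such."""
        kinases = [f"K{i}" for i in range(12)]
        compounds = [f"c{j}" for j in range(50)]
        dtm = pd.DataFrame(0.0, index=compounds, columns=kinases)
        dtm.iloc[:20, :10] = 5.0  # 20 promiscuous compounds hit 10 kinases
        m = ks.matrix_from_dtm(dtm, {k: 0.3 for k in kinases})
        _, summary = ks.compound_promiscuity(m)
        assert summary["n_at_least_cutoff"] == 20
        assert summary["n_zero_hit"] == 30


class TestHitRatePercent:
    @pytest.mark.parametrize(
        "n_hits,n_compounds,expected",
        [
            (5, 627, 0.8),
            (0, 627, 0.0),
            (43, 627, 6.9),  # 6.858...% rounds half-up to one decimal
            (1, 16, 6.3),  # 6.25% -> half-up
        ],
    )
    def test_examples(self, n_hits, n_compounds, expected):
        assert ks.hit_rate_percent(n_hits, n_compounds) == expected

    def test_zero_compounds_undefined(self):
        with pytest.raises(UndefinedRateError):
            ks.hit_rate_percent(0, 0)


class TestScreenReport:
    def test_empty_hit_matrix(self):
        dtm = pd.DataFrame(0.0, index=["c1", "c2"], columns=["K0"])
        report = ks.screen_report(ks.matrix_from_dtm(dtm, {"K0": 0.3}))
        assert report["total_hits"] == 0
        assert report["n_zero_hit"] == 2

    def test_totals_cross_check(self):
        m = random_matrix(7)
        report = ks.screen_report(m)
        assert report["total_hits"] == sum(r["n_hits"] for r in report["kinase_hit_counts"])
        assert report["total_hits"] == sum(
            r["n_kinases_stabilized"] for r in report["compound_promiscuity"]
        )

    def test_fda_subset(self):
        kinases = [f"K{i}" for i in range(6)]
        dtm = pd.DataFrame(0.0, index=["c1", "c2", "c3", "c4"], columns=kinases)
        dtm.loc["c1"] = 5.0  # 6 hits
        dtm.loc["c2", kinases[:5]] = 5.0  # 5 hits
        dtm.loc["c3", "K0"] = 5.0  # 1 hit
        m = ks.matrix_from_dtm(dtm, {k: 0.3 for k in kinases})
        annotations = [
            ks.CompoundRecord("c1", "drug-a", fda_approved=True),
            ks.CompoundRecord("c2", "drug-b", fda_approved=True),
            ks.CompoundRecord("c3", "drug-c", fda_approved=True),
            ks.CompoundRecord("c4", "tool", fda_approved=False),
        ]
        report = ks.screen_report(m, annotations)
        fda = report["fda_approved"]["compounds"]
        with_5plus = [r["compound_id"] for r in fda if r["n_kinases_stabilized"] >= 5]
        assert with_5plus == ["c1", "c2"]

    def test_unknown_compound_flagged(self):
        dtm = pd.DataFrame({"K0": [1.0]}, index=["mystery"])
        report = ks.screen_report(
            ks.matrix_from_dtm(dtm, {"K0": 0.3}), [ks.CompoundRecord("c1", "x")]
        )
        assert report["unknown_compounds"] == ["mystery"]


class TestClampProperties:
    @given(st.lists(st.floats(-5, 10, allow_nan=False), min_size=1, max_size=6))
    def test_clamp_idempotent_and_order_preserving(self, tms):
        ref = ks.build_reference("k", [50.0, 50.0])
        shift = ks.delta_tm("c", tms, ref, clamp=True)
        assert shift.dtm_reported == max(0.0, shift.dtm_mean)
        assert shift.dtm_reported >= 0.0
        # raw mean retained unmodified
        assert shift.dtm_mean == pytest.approx(np.mean(tms) - 50.0, abs=1e-9)

    @given(st.integers(0, 2**31 - 1))
    def test_multiplier_monotonicity(self, seed):
        m2 = random_matrix(seed % 100)
        m3 = ks.call_hits(m2, multiplier=3.0)
        assert (m3.hits.values.sum(axis=None)) <= (m2.hits.values.sum(axis=None))
        # elementwise: no hit appears when the threshold is raised
        assert not (m3.hits & ~m2.hits).values.any()


class TestMatrixFromFitTable:
    def test_missing_reference_raises(self):
        table = pd.DataFrame(
            {
                "kinase_id": ["K0"] * 4,
                "compound_id": ["DMSO", "c1", "c1", "c1"],
                "replicate": [1, 1, 2, 3],
                "tm_c": [50.0, 52.0, 52.1, 51.9],
            }
        )
        with pytest.raises(MissingReferenceError, match="K0"):
            ks.matrix_from_fit_table(table)

    def test_qc_failed_wells_drop_replicates(self):
        table = pd.DataFrame(
            {
                "kinase_id": ["K0"] * 6,
                "compound_id": ["DMSO", "DMSO", "DMSO", "c1", "c1", "c1"],
                "replicate": [1, 2, 3, 1, 2, 3],
                "tm_c": [50.0, 50.1, 49.9, 53.0, 53.2, 80.0],
                "qc": ["pass"] * 5 + ["fail"],
            }
        )
        m = ks.matrix_from_fit_table(table)
        assert m.n_replicates.loc["c1", "K0"] == 2
        assert m.dtm_raw.loc["c1", "K0"] == pytest.approx(53.1 - 50.0)

    def test_pair_with_no_passing_wells_reported_absent(self):
        table = pd.DataFrame(
            {
                "kinase_id": ["K0"] * 5,
                "compound_id": ["DMSO", "DMSO", "DMSO", "c1", "c1"],
                "replicate": [1, 2, 3, 1, 2],
                "tm_c": [50.0, 50.1, 49.9, 53.0, 53.2],
                "qc": ["pass"] * 3 + ["fail", "fail"],
            }
        )
        m = ks.matrix_from_fit_table(table)
        assert np.isnan(m.dtm_reported.loc["c1", "K0"])
        assert not bool(m.hits.loc["c1", "K0"])

    def test_multiplier_must_be_positive(self):
        m = random_matrix(1)
        with pytest.raises(MalformedInputError):
            ks.call_hits(m, multiplier=0.0)
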