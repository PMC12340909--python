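"""HDX engine: masses, filters, uptake, consolidation, differential maps."""

import numpy as np
import pandas as pd
import pytest

from phosdyn import hdx, simulate
from phosdyn.errors import DataFormatError


class TestMassesAndPpm:
    @pytest.mark.parametrize(
        "seq, expected",
        [("G", 75.0320), ("GG", 132.0535)],  # residue-mass table + one water
    )
    def test_monoisotopic_mass(self, seq, expected):
        assert hdx.peptide_monoisotopic_mass(seq) == pytest.approx(expected, abs=5e-4)

    def test_empty_sequence_rejected(self):
        with pytest.raises(DataFormatError):
            hdx.peptide_monoisotopic_mass("")

    def test_unknown_letter_rejected(self):
        with pytest.raises(DataFormatError):
            hdx.peptide_monoisotopic_mass("AXZ1")

    @pytest.mark.parametrize(
        "obs, theo, ppm",
        [(1000.007, 1000.0, 7.0), (500.0, 500.0, 0.0), (500.0005, 500.0, 1.0)],
    )
    def test_ppm_error(self, obs, theo, ppm):
        assert hdx.ppm_error(obs, theo) == pytest.approx(ppm, abs=1e-6)

    def test_mz_conversion(self):
        mass = 1500.0
        mz = (mass + 2 * hdx.PROTON_MASS) / 2
        assert hdx.mz_to_neutral_mass(mz, 2) == pytest.approx(mass, abs=1e-9)


class TestExchangeableAmides:
    @pytest.mark.parametrize(
        "seq, count", [("AAAA", 3), ("APAA", 2), ("PAAA", 3), ("AA", 1)]
    )
    def test_convention(self, seq, count):
        assert hdx.exchangeable_amides(seq) == count

    def test_exclude_second_option(self):
        assert hdx.exchangeable_amides("AAAA", exclude_second=True) == 2
        # position 2 proline is already excluded; option removes nothing extra
        assert hdx.exchangeable_amides("APAA", exclude_second=True) == 2

    def test_positions_are_absolute(self):
        assert hdx.exchangeable_positions("APAA", start=10) == [12, 13]


class TestPoolFilter:
    def pool(self, rows):
        return pd.DataFrame(rows, columns=hdx.POOL_COLUMNS)

    def test_length_charge_and_mass_filters(self):
        pool = self.pool(
            [
                ("short", "AG", 1, 2, 1),
                ("long", "A" * 16, 1, 16, 1),
                ("charged", "AGAGA", 1, 5, 4),
                ("massy", "AGAGA", 1, 5, 2),
                ("good", "AGAGA", 6, 10, 2),
            ]
        )
        theo = hdx.peptide_monoisotopic_mass("AGAGA")
        observed = {"massy": theo * (1 + 8e-6), "good": theo * (1 + 3e-6)}
        kept, log = hdx.filter_peptide_pool(pool, observed)
        assert list(kept.id) == ["good"]
        reasons = dict(zip(log.id, log.reason))
        assert "length" in reasons["short"] and "length" in reasons["long"]
        assert "charge" in reasons["charged"]
        assert "ppm" in reasons["massy"]

    def test_no_observed_mass_skips_ppm_check(self):
        pool = self.pool([("p1", "AGAGA", 1, 5, 2)])
        kept, log = hdx.filter_peptide_pool(pool, observed_masses=None)
        assert len(kept) == 1 and log.empty


class TestUptake:
    def centroids(self, rows):
        return pd.DataFrame(rows, columns=hdx.CENTROID_COLUMNS)

    def test_replicate_mean_uptake(self):
        cents = self.centroids(
            [
                ("p1", hdx.UNDEUTERATED, np.nan, 1, 1000.0),
                ("p1", "WT", 30.0, 1, 1002.2),
                ("p1", "WT", 30.0, 2, 1002.3),
            ]
        )
        assert hdx.compute_uptake(cents, "p1", "WT", 30.0) == pytest.approx(2.25)

    def test_zero_uptake(self):
        cents = self.centroids(
            [
                ("p1", hdx.UNDEUTERATED, np.nan, 1, 1000.0),
                ("p1", "WT", 0.0, 1, 1000.0),
            ]
        )
        assert hdx.compute_uptake(cents, "p1", "WT", 0.0) == 0.0

    def test_missing_reference_raises(self):
        cents = self.centroids([("p1", "WT", 30.0, 1, 1002.0)])
        with pytest.raises(DataFormatError, match="undeuterated"):
            hdx.compute_uptake(cents, "p1", "WT", 30.0)

    def test_normalize_with_fulld(self):
        pct, max_d, source = hdx.normalize_uptake(2.25, "AGAGAG", np.array([4.4, 4.6]))
        assert (pct, max_d, source) == (pytest.approx(50.0), pytest.approx(4.5), "full-D")

    def test_normalize_theoretical_fallback(self):
        # 6-mer with no prolines: 5 exchangeable amides x 0.9 D2O
        pct, max_d, source = hdx.normalize_uptake(2.25, "AGAGAG", None, d2o_fraction=0.9)
        assert max_d == pytest.approx(4.5) and source == "theoretical"
        assert pct == pytest.approx(50.0)

    def test_uptake_equal_to_max_is_100(self):
        pct, _, _ = hdx.normalize_uptake(4.5, "AGAGAG", np.array([4.5]))
        assert pct == pytest.approx(100.0)

    def test_out_of_range_flagged_not_clipped(self):
        pool = pd.DataFrame([("p1", "AGAGAG", 1, 6, 1)], columns=hdx.POOL_COLUMNS)
        cents = self.centroids(
            [
                ("p1", hdx.UNDEUTERATED, np.nan, 1, 1000.0),
                ("p1", hdx.FULL_D, np.nan, 1, 1004.0),
                ("p1", "WT", 30.0, 1, 1004.4),
            ]
        )
        up = hdx.analyze_uptake(pool, cents)
        assert up.pct_max.iloc[0] == pytest.approx(110.0)
        assert bool(up.out_of_range.iloc[0])


class TestConsolidation:
    def test_mean_of_covering_peptides(self):
        pool = pd.DataFrame(
            [("a", "AAAAA", 1, 5, 1), ("b", "AAAAA", 4, 8, 1)], columns=hdx.POOL_COLUMNS
        )
        uptake = pd.DataFrame(
            {
                "peptide_id": ["a", "b"],
                "state": ["WT", "WT"],
                "timepoint_s": [30.0, 30.0],
                "pct_max": [40.0, 60.0],
            }
        )
        levels = hdx.consolidate_residue_levels(uptake, pool, 10)
        lv = levels.set_index("residue")
        assert lv.loc[4, "level"] == pytest.approx(50.0)  # covered by both
        assert lv.loc[2, "level"] == pytest.approx(40.0)  # single peptide
        assert 9 not in lv.index  # uncovered residue missing
        assert lv.loc[4, "n_covering"] == 2

    def test_idempotent_for_single_coverage(self):
        pool = pd.DataFrame(
            [("a", "AAAAA", 1, 5, 1), ("b", "AAAAA", 6, 10, 1)], columns=hdx.POOL_COLUMNS
        )
        uptake = pd.DataFrame(
            {
                "peptide_id": ["a", "b"],
                "state": ["WT", "WT"],
                "timepoint_s": [30.0, 30.0],
                "pct_max": [33.0, 77.0],
            }
        )
        levels = hdx.consolidate_residue_levels(uptake, pool, 10)
        assert set(levels[levels.residue <= 5].level) == {33.0}
        assert set(levels[levels.residue > 5].level) == {77.0}


class TestDifferentialExchange:
    def levels(self, entries):
        return pd.DataFrame(
            entries, columns=["state", "residue", "timepoint_s", "level", "n_covering"]
        )

    def test_identity_gives_zero(self):
        lv = self.levels(
            [("WT", 1, 0.0, 10, 1), ("WT", 1, 30.0, 20, 1),
             ("V", 1, 0.0, 10, 1), ("V", 1, 30.0, 20, 1)]
        )
        emap = hdx.differential_exchange(lv, "V", "WT")
        assert emap.dDbar.loc[1] == 0.0

    def test_mean_over_timepoints(self):
        rows = []
        for t, wt, v in [(30.0, 0, 10), (120.0, 0, 20), (480.0, 0, 30), (0.0, 0, 99)]:
            rows += [("WT", 5, t, wt, 1), ("V", 5, t, v, 1)]
        emap = hdx.differential_exchange(self.levels(rows), "V", "WT")
        assert emap.dDbar.loc[5] == pytest.approx(20.0)  # t=0 excluded by default
        emap0 = hdx.differential_exchange(self.levels(rows), "V", "WT", include_t0=True)
        assert emap0.dDbar.loc[5] == pytest.approx((10 + 20 + 30 + 99) / 4)

    def test_antisymmetry(self):
        rows = []
        rng = np.random.default_rng(0)
        for r in range(1, 6):
            for t in (30.0, 120.0):
                rows += [("A", r, t, rng.uniform(0, 100), 1), ("B", r, t, rng.uniform(0, 100), 1)]
        lv = self.levels(rows)
        ab = hdx.differential_exchange(lv, "A", "B")
        ba = hdx.differential_exchange(lv, "B", "A")
        pd.testing.assert_series_equal(ab.dDbar, -ba.dDbar)

    def test_mismatched_grids_error(self):
        lv = self.levels([("WT", 1, 30.0, 10, 1), ("V", 1, 60.0, 12, 1)])
        with pytest.raises(DataFormatError, match="grid"):
            hdx.differential_exchange(lv, "V", "WT")

    def test_residue_in_one_state_missing(self):
        lv = self.levels(
            [("WT", 1, 30.0, 10, 1), ("V", 1, 30.0, 12, 1), ("V", 2, 30.0, 50, 1)]
        )
        emap = hdx.differential_exchange(lv, "V", "WT")
        assert np.isnan(emap.dDbar.loc[2])


class TestCoverage:
    def pool(self, windows):
        return pd.DataFrame(
            [(f"p{i}", "A" * (e - s + 1), s, e, 1) for i, (s, e) in enumerate(windows)],
            columns=hdx.POOL_COLUMNS,
        )

    def test_hand_computed_example(self):
        summ = hdx.summarize_coverage(self.pool([(1, 5), (4, 8)]), 10)
        assert summ.coverage == pytest.approx(80.0)
        assert summ.redundancy == pytest.approx(1.25)
        assert summ.average_peptide_length == pytest.approx(5.0)
        assert summ.peptide_count == 2

    def test_empty_pool(self):
        summ = hdx.summarize_coverage(self.pool([]), 10)
        assert summ.coverage == 0.0 and np.isnan(summ.redundancy)

    def test_full_single_tiling(self):
        summ = hdx.summarize_coverage(self.pool([(i, i) for i in range(1, 11)]), 10)
        assert summ.coverage == 100.0 and summ.redundancy == 1.0

    def test_redundant_peptide_never_decreases_redundancy(self):
        base = self.pool([(1, 5), (6, 10)])
        summ0 = hdx.summarize_coverage(base, 10)
        extra = pd.concat(
            [base, self.pool([(2, 4)]).assign(id="pX")], ignore_index=True
        )
        summ1 = hdx.summarize_coverage(extra, 10)
        assert summ1.coverage == summ0.coverage
        assert summ1.redundancy >= summ0.redundancy


class TestSegments:
    def series(self, mapping):
        return pd.Series(mapping, dtype=float).sort_index()

    def test_single_deprotected_segment(self):
        d = {r: 10.0 if 20 <= r <= 30 else 0.0 for r in range(1, 41)}
        segs = hdx.classify_exchange_regions(self.series(d), threshold=5, min_run=3)
        assert len(segs) == 1
        assert tuple(segs.iloc[0][["start", "end", "label"]]) == (20, 30, "deprotected")

    def test_all_zero_no_segments(self):
        d = {r: 0.0 for r in range(1, 21)}
        assert hdx.classify_exchange_regions(self.series(d), 5, 3).empty

    def test_short_run_dropped(self):
        d = {r: -8.0 if r in (5, 6) else 0.0 for r in range(1, 11)}
        assert hdx.classify_exchange_regions(self.series(d), 5, 3).empty

    def test_missing_residue_breaks_run(self):
        d = {r: 10.0 for r in range(1, 11) if r != 5}
        segs = hdx.classify_exchange_regions(self.series(d), 5, 3)
        assert [(s, e) for s, e in zip(segs.start, segs.end)] == [(1, 4), (6, 10)]


class TestEndToEndOracle:
    """Noiseless synthetic data must round-trip exactly through the engine."""

    def test_pct_max_matches_forward_model(self, planted_hdx_config):
        cfg = planted_hdx_config
        pool, cents = simulate.simulate_hdx_dataset(cfg)
        uptake = hdx.analyze_uptake(pool, cents, d2o_fraction=cfg.d2o_fraction)
        pf = {st: cfg.protection_array(st) for st in cfg.states}
        for rec in uptake.itertuples(index=False):
            pep = pool[pool.id == rec.peptide_id].iloc[0]
            pos = np.array(hdx.exchangeable_positions(pep.sequence, pep.start))
            occ = simulate.simulate_residue_exchange(
                pf[rec.state][pos], 0.0, cfg.k_intrinsic, rec.timepoint_s, cfg.d2o_fraction
            )
            expected = 100.0 * occ.sum() / (len(pos) * cfg.d2o_fraction)
            assert rec.pct_max == pytest.approx(expected, abs=1e-9)

    def test_fulld_rows_normalize_to_100(self, planted_hdx_config):
        pool, cents = simulate.simulate_hdx_dataset(planted_hdx_config)
        pep = pool.iloc[0]
        sub = cents[cents.peptide_id == pep.id]
        m0 = sub[sub.state == hdx.UNDEUTERATED].centroid_mass_da.mean()
        fulld = sub[sub.state == hdx.FULL_D].centroid_mass_da.to_numpy() - m0
        pct, _, _ = hdx.normalize_uptake(float(fulld.mean()), pep.sequence, fulld)
        assert pct == pytest.approx(100.0, abs=1e-9)

    def test_planted_regions_recovered_exactly(self, planted_hdx_config):
        cfg = planted_hdx_config
        pool, cents = simulate.simulate_hdx_dataset(cfg)
        uptake = hdx.analyze_uptake(pool, cents, d2o_fraction=cfg.d2o_fraction)
        levels = hdx.consolidate_residue_levels(uptake, pool, cfg.protein_length)
        emap = hdx.differential_exchange(levels, "Y62D_like", "WT")
        segs = hdx.classify_exchange_regions(emap.dDbar, threshold=5.0, min_run=3)
        assert sorted(zip(segs.start, segs.end)) == [(3, 104), (496, 510)]
        assert set(segs.label) == {"deprotected"}
        # everywhere else the noiseless difference is identically ~0
        outside = emap.dDbar.drop(
            index=[r for r in emap.dDbar.index if 3 <= r <= 104 or 496 <= r <= 510]
        ).dropna()
        assert np.abs(outside).max() < 1e-9
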