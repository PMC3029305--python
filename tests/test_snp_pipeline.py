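"""Intensity-table IO, difference-of-differences traces, region calls, fixtures."""

import numpy as np
import pandas as pd
import pytest

from snpbsa.bsa_engine import ChromosomeTrace, SmoothedTrace
from snpbsa.genetic_models import model_preset
from snpbsa.snp_pipeline import (
    IntensityTable,
    bsa_trace,
    call_region,
    generate_fixture,
    read_intensity_table,
    read_marker_list,
    subsample_markers,
    write_intensity_table,
)
from snpbsa.xam_simulator import ScenarioConfig, ThresholdSet


def _frame(n=10, chrom="1", strand="sense", start=1, step=100, ref=None, alt=None):
    return pd.DataFrame(
        {
            "snp_id": [f"{chrom}_{strand[0]}{i}" for i in range(n)],
            "chrom": chrom,
            "pos": np.arange(start, start + n * step, step)[:n],
            "strand": strand,
            "ref_intensity": np.full(n, 5.0) if ref is None else ref,
            "alt_intensity": np.full(n, 5.0) if alt is None else alt,
        }
    )


class TestIntensityIO:
    def test_well_formed_table_round_trips_bit_exactly(self, tmp_path):
        rng = np.random.default_rng(0)
        frame = _frame(3, ref=rng.uniform(1, 9, 3), alt=rng.uniform(1, 9, 3))
        path = tmp_path / "t.tsv"
        write_intensity_table(IntensityTable(frame), path)
        loaded = read_intensity_table(path)
        assert len(loaded) == 3
        np.testing.assert_array_equal(
            loaded.data["ref_intensity"].to_numpy(), frame["ref_intensity"].to_numpy()
        )

    def test_duplicate_snp_strand_rejected_naming_the_snp(self, tmp_path):
        frame = pd.concat([_frame(2), _frame(2)], ignore_index=True)
        path = tmp_path / "dup.tsv"
        frame.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="1_s0"):
            read_intensity_table(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        _frame(2).drop(columns=["strand"]).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="strand"):
            read_intensity_table(path)

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            IntensityTable(_frame(2, ref=np.array([1.0, -0.5])))

    def test_malformed_rows_dropped_and_logged(self, tmp_path, caplog):
        frame = _frame(3).astype({"ref_intensity": object})
        frame.loc[1, "ref_intensity"] = "oops"
        path = tmp_path / "mal.tsv"
        frame.to_csv(path, sep="\t", index=False)
        with caplog.at_level("WARNING", logger="snpbsa.snp_pipeline"):
            table = read_intensity_table(path)
        assert len(table) == 2
        assert any("line" in rec.message or "rows" in rec.message for rec in caplog.records)


class TestAlleleDifference:
    def test_sign_convention(self):
        from snpbsa.snp_pipeline import allele_difference

        table = IntensityTable(_frame(2, ref=np.array([5.0, 5.0]), alt=np.array([5.0, 2.0])))
        np.testing.assert_array_equal(allele_difference(table)["diff"].to_numpy(), [0.0, 3.0])

    def test_vectorized_matches_row_by_row(self):
        from snpbsa.snp_pipeline import allele_difference

        rng = np.random.default_rng(1)
        frame = _frame(1000, ref=rng.uniform(0, 10, 1000), alt=rng.uniform(0, 10, 1000))
        out = allele_difference(IntensityTable(frame))["diff"].to_numpy()
        oracle = np.array(
            [row.ref_intensity - row.alt_intensity for row in frame.itertuples()]
        )
        np.testing.assert_allclose(out, oracle)


def _bulk_pair(tmp_path, seed=0, skew=1.0, n_snps=600):
    cfg = ScenarioConfig(
        population_type="F2",
        population_size=200,
        selection_fraction=0.10,
        model=model_preset(1),
        seed=seed,
    )
    region = ("1", 8_000_000, 18_000_000)
    paths = generate_fixture(cfg, region, tmp_path / f"fx{seed}", n_snps=n_snps, skew=skew)
    return paths, region


class TestBsaTrace:
    def test_identical_bulks_give_zero_trace(self, tmp_path):
        paths, _ = _bulk_pair(tmp_path)
        bulk = read_intensity_table(paths["bulkA"])
        markers = read_marker_list(paths["markers"])
        traces = bsa_trace(bulk, bulk, markers)
        for trace in traces.values():
            for tr in trace.chromosomes.values():
                np.testing.assert_allclose(tr.raw, 0.0, atol=1e-12)
                np.testing.assert_allclose(tr.smoothed, 0.0, atol=1e-9)

    def test_non_marker_snps_never_enter_the_trace(self, tmp_path):
        paths, _ = _bulk_pair(tmp_path)
        bulkA = read_intensity_table(paths["bulkA"])
        bulkB = read_intensity_table(paths["bulkB"])
        markers = read_marker_list(paths["markers"])
        traces = bsa_trace(bulkA, bulkB, markers)
        n_markers_sense = (
            bulkA.data[bulkA.data["strand"] == "sense"]["snp_id"].isin(markers).sum()
        )
        total = sum(tr.positions.size for tr in traces["sense"].chromosomes.values())
        assert total == n_markers_sense

    def test_swapping_bulks_negates_trace(self, tmp_path):
        paths, _ = _bulk_pair(tmp_path)
        bulkA = read_intensity_table(paths["bulkA"])
        bulkB = read_intensity_table(paths["bulkB"])
        markers = read_marker_list(paths["markers"])
        ab = bsa_trace(bulkA, bulkB, markers)["combined"]
        ba = bsa_trace(bulkB, bulkA, markers)["combined"]
        for chrom in ab.chromosomes:
            np.testing.assert_allclose(
                ab.chromosomes[chrom].smoothed, -ba.chromosomes[chrom].smoothed, atol=1e-9
            )

    def test_empty_marker_intersection_rejected(self, tmp_path):
        paths, _ = _bulk_pair(tmp_path)
        bulkA = read_intensity_table(paths["bulkA"])
        bulkB = read_intensity_table(paths["bulkB"])
        with pytest.raises(ValueError):
            bsa_trace(bulkA, bulkB, {"absent_snp"})


def _manual_trace(values, positions=None):
    values = np.asarray(values, float)
    positions = np.arange(values.size, dtype=float) if positions is None else positions
    return SmoothedTrace(
        chromosomes={"1": ChromosomeTrace(positions, values, values)}, span=0.25, units="bp"
    )


class TestCallRegion:
    thresholds = ThresholdSet(1.0, 1.5)

    def test_zero_trace_yields_no_calls(self):
        assert call_region(_manual_trace(np.zeros(20)), self.thresholds) == []

    def test_single_bump_yields_one_call_containing_apex(self):
        values = np.concatenate([np.zeros(5), [1.2, 2.0, 1.1], np.zeros(5)])
        calls = call_region(_manual_trace(values), self.thresholds)
        assert len(calls) == 1
        call = calls[0]
        assert call.start <= call.peak_pos <= call.end
        assert call.peak_pos == 6.0 and call.peak_value == 2.0

    def test_two_disjoint_bumps_yield_two_calls(self):
        values = np.concatenate(
            [np.zeros(3), [1.5, 1.5], np.zeros(4), [-2.0, -2.5], np.zeros(3)]
        )
        calls = call_region(_manual_trace(values), self.thresholds)
        assert len(calls) == 2
        # interval-extraction oracle: runs of |v| >= 1.0
        assert (calls[0].start, calls[0].end) == (3.0, 4.0)
        assert (calls[1].start, calls[1].end) == (9.0, 10.0)
        assert calls[1].peak_value == -2.5


class TestSubsample:
    def test_full_fraction_is_identity(self):
        markers = {f"s{i}" for i in range(100)}
        assert subsample_markers(markers, 1.0, seed=0) == markers

    def test_quarter_of_1000_gives_250(self):
        markers = {f"s{i}" for i in range(1000)}
        assert len(subsample_markers(markers, 0.25, seed=1)) == 250

    def test_seed_reproducibility(self):
        markers = {f"s{i}" for i in range(500)}
        assert subsample_markers(markers, 0.3, seed=9) == subsample_markers(markers, 0.3, seed=9)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            subsample_markers(set(), 0.5, seed=0)


class TestFixtureAndRecovery:
    def test_fixture_parses_cleanly(self, tmp_path):
        paths, _ = _bulk_pair(tmp_path, n_snps=300)
        for key in ("bulkA", "bulkB"):
            table = read_intensity_table(paths[key])
            assert len(table) == len(pd.read_csv(paths[key], sep="\t"))

    def test_zero_skew_region_produces_no_call(self, tmp_path):
        paths, _ = _bulk_pair(tmp_path, skew=0.0)
        traces = bsa_trace(
            read_intensity_table(paths["bulkA"]),
            read_intensity_table(paths["bulkB"]),
            read_marker_list(paths["markers"]),
        )
        # threshold above the loess edge-noise of a balanced fixture
        assert call_region(traces["combined"], ThresholdSet(0.8, 0.9)) == []

    def test_full_skew_region_is_recovered(self, tmp_path):
        hits = 0
        for seed in range(5):
            paths, region = _bulk_pair(tmp_path, seed=seed)
            traces = bsa_trace(
                read_intensity_table(paths["bulkA"]),
                read_intensity_table(paths["bulkB"]),
                read_marker_list(paths["markers"]),
            )
            calls = call_region(traces["combined"], ThresholdSet(0.5, 0.6))
            for call in calls:
                if call.chrom == region[0] and call.end >= region[1] and call.start <= region[2]:
                    hits += 1
                    break
        assert hits == 5

    def test_sense_and_antisense_agree_on_peak_chromosome(self, tmp_path):
        paths, region = _bulk_pair(tmp_path, seed=42)
        traces = bsa_trace(
            read_intensity_table(paths["bulkA"]),
            read_intensity_table(paths["bulkB"]),
            read_marker_list(paths["markers"]),
        )
        peaks = {}
        for strand in ("sense", "antisense"):
            best = max(
                traces[strand].chromosomes.items(),
                key=lambda kv: np.max(np.abs(kv[1].smoothed)),
            )
            peaks[strand] = best[0]
        assert peaks["sense"] == peaks["antisense"] == region[0]

    def test_invalid_region_rejected(self, tmp_path):
        cfg = ScenarioConfig(
            population_type="F2",
            population_size=100,
            selection_fraction=0.1,
            model=model_preset(1),
            seed=0,
        )
        with pytest.raises(ValueError):
            generate_fixture(cfg, ("9", 0, 100), tmp_path)
        with pytest.raises(ValueError):
            generate_fixture(cfg, ("1", 500, 100), tmp_path)
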