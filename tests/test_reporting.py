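"""Aggregation into study-level summary tables and the two pipelines."""

import json
import math

import numpy as np
import pandas as pd
import pytest

import ihmtquant as iq
from ihmtquant.errors import ManifestError
from ihmtquant.reporting import StudyTable, round_half_away
from ihmtquant.studydata import HISTOLOGY_PER_SAMPLE, IHMTR_PER_SAMPLE


class TestRounding:
    @pytest.mark.parametrize("x,want", [
        (0.25, 0.3), (-0.25, -0.3), (0.24, 0.2), (11.56, 11.6),
        (2.0, 2.0), (15.95, 16.0), (-1.15, -1.2),
    ])
    def test_half_away_from_zero(self, x, want):
        assert round_half_away(x, 1) == pytest.approx(want)


class TestSummaries:
    def test_identical_protocol_means(self):
        row = iq.average_over_protocols([10.0, 10.0, 10.0])
        assert row.mean == 10.0 and row.sd == 0.0 and row.n_units == 3

    def test_two_values_hand_arithmetic(self):
        row = iq.average_over_protocols([9.0, 11.0])
        assert row.mean == 10.0
        assert row.sd == pytest.approx(math.sqrt(2.0))

    def test_seeded_values_match_direct_formula(self, rng):
        vals = rng.normal(10, 2, 7)
        row = iq.average_over_protocols(list(vals))
        assert row.mean == pytest.approx(vals.mean())
        assert row.sd == pytest.approx(vals.std(ddof=1))

    def test_single_value_passthrough_with_undefined_sd(self):
        row = iq.average_over_protocols([8.5])
        assert row.mean == 8.5 and not row.sd_defined

    def test_identical_samples_zero_sd(self):
        row = iq.across_sample_summary([4.0, 4.0, 4.0])
        assert row.sd == 0.0

    def test_order_invariance(self, rng):
        vals = list(rng.normal(10, 3, 6))
        a = iq.across_sample_summary(vals)
        b = iq.across_sample_summary(vals[::-1])
        assert a.mean == pytest.approx(b.mean) and a.sd == pytest.approx(b.sd)

    def test_reproduces_published_collagen_summary_row(self):
        # across-sample means of the per-sample histology table, printed style
        want = {"total_collagen": {"free_running": 72.4, "pmj": 31.1},
                "adipocyte": {"free_running": 3.8, "pmj": 12.3},
                "type1": {"free_running": 93.2, "pmj": 85.7},
                "type3": {"free_running": 3.0, "pmj": 8.8}}
        for measure, regions in want.items():
            for region, printed in regions.items():
                row = iq.across_sample_summary(
                    HISTOLOGY_PER_SAMPLE[measure][region])
                assert round_half_away(row.mean, 1) == pytest.approx(printed)

    def test_reproduces_published_ihmtr_summary(self):
        fr = iq.across_sample_summary(IHMTR_PER_SAMPLE["free_running"])
        pmj = iq.across_sample_summary(IHMTR_PER_SAMPLE["pmj"])
        assert fr.mean == pytest.approx(11.5, abs=0.1)
        assert fr.sd == pytest.approx(1.5, abs=0.1)
        assert pmj.mean == pytest.approx(9.0, abs=0.1)
        assert pmj.sd == pytest.approx(2.9, abs=0.1)


class TestStudyTable:
    def make_table(self, rng):
        rows = pd.DataFrame({
            "sample": ["S1", "S1", "S2"],
            "protocol": ["Pr1", "Pr2", "Pr1"],
            "region": ["free_running"] * 3,
            "mean": rng.normal(10, 1, 3),
            "sd": rng.random(3),
            "n_voxels": [100, 100, 90]})
        return StudyTable(rows=rows, provenance={"version": "x", "config": {}})

    def test_csv_roundtrip_is_bit_exact(self, tmp_path, rng):
        table = self.make_table(rng)
        table.to_csv(tmp_path / "rows.csv")
        back = StudyTable.from_csv(tmp_path / "rows.csv")
        for col in ("mean", "sd"):
            assert (back.rows[col].to_numpy() == table.rows[col].to_numpy()).all()
        assert back.provenance == table.provenance

    def test_duplicate_keys_rejected(self):
        rows = pd.DataFrame({"sample": ["S1", "S1"], "protocol": ["Pr1", "Pr1"],
                             "region": ["pmj", "pmj"], "mean": [1.0, 2.0]})
        with pytest.raises(ValueError, match="duplicate"):
            StudyTable(rows=rows)


@pytest.fixture(scope="module")
def mri_study(tmp_path_factory):
    out = tmp_path_factory.mktemp("mri")
    manifest = iq.simulate_mri_study(out, n_samples=3, noise_sigma=0.02,
                                     n_mt_reps=8, n_m0_reps=4,
                                     matrix_size=96, seed=17)
    return manifest, out


class TestMRIPipeline:
    def test_summary_recovers_prescribed_region_means(self, mri_study, tmp_path):
        manifest, _ = mri_study
        res = iq.run_mri_pipeline(manifest, out_dir=tmp_path / "out")
        want = {"free_running": 11.5, "pmj": 9.0, "myocardium": 8.0}
        for _, row in res.across_samples.iterrows():
            assert row["mean"] == pytest.approx(want[row["region"]], abs=0.3)
        # row-level table covers samples x protocols x regions
        assert len(res.table.rows) == 3 * 3 * 3
        assert (tmp_path / "out" / "rows.csv").exists()
        assert (tmp_path / "out" / "report.json").exists()

    def test_summary_recomputable_from_emitted_rows(self, mri_study, tmp_path):
        manifest, _ = mri_study
        res = iq.run_mri_pipeline(manifest, out_dir=tmp_path / "out")
        rows = pd.read_csv(tmp_path / "out" / "rows.csv")
        for _, srow in res.per_sample.iterrows():
            grp = rows[(rows["sample"] == srow["sample"])
                       & (rows["region"] == srow["region"])]["mean"]
            assert srow["mean"] == pytest.approx(grp.mean(), abs=1e-12)

    def test_rerun_is_deterministic(self, mri_study, tmp_path):
        manifest, _ = mri_study
        iq.run_mri_pipeline(manifest, out_dir=tmp_path / "a")
        iq.run_mri_pipeline(manifest, out_dir=tmp_path / "b")
        for name in ("rows.csv", "summary.csv", "across_samples.csv"):
            assert ((tmp_path / "a" / name).read_bytes()
                    == (tmp_path / "b" / name).read_bytes())
        ra = json.loads((tmp_path / "a" / "report.json").read_text())
        rb = json.loads((tmp_path / "b" / "report.json").read_text())
        ra["provenance"].pop("timestamp"), rb["provenance"].pop("timestamp")
        assert ra == rb

    def test_missing_manifest_entry_fails_fast(self, tmp_path):
        bad = tmp_path / "study.yaml"
        bad.write_text("samples:\n  S1:\n    mask: nowhere.nii.gz\n"
                       "    protocols: {Pr1: nowhere.yaml}\n")
        with pytest.raises(ManifestError, match="missing"):
            iq.run_mri_pipeline(bad)

    def test_empty_manifest_rejected(self, tmp_path):
        bad = tmp_path / "study.yaml"
        bad.write_text("samples: {}\n")
        with pytest.raises(ManifestError, match="no samples"):
            iq.run_mri_pipeline(bad)


@pytest.fixture(scope="module")
def histo_study(tmp_path_factory):
    out = tmp_path_factory.mktemp("histo")
    return iq.simulate_histology_study(out, images_per_region=2,
                                       size=(128, 128), seed=23)


class TestHistologyPipeline:
    def test_summary_close_to_prescribed_compositions(self, histo_study):
        res = iq.run_histology_pipeline(histo_study)
        byrow = {(r["region"], r["measure"]): r["mean"]
                 for _, r in res.across_samples.iterrows()}
        for measure, regions in HISTOLOGY_PER_SAMPLE.items():
            for region, values in regions.items():
                want = float(np.mean(values))
                # sampling error only: generators draw pixel classes i.i.d.
                assert byrow[(region, measure)] == pytest.approx(want, abs=1.5)

    def test_paired_test_reported_per_measure(self, histo_study):
        res = iq.run_histology_pipeline(histo_study)
        assert set(res.paired_tests) == {"total_collagen", "adipocyte",
                                         "type1", "type3"}
        t = res.paired_tests["total_collagen"]
        assert t.mean_diff > 0           # more collagen in free-running
        assert t.p < 0.01

    def test_published_per_sample_block_regenerates_summary_and_test(self):
        # re-entering the printed per-sample values as row-level input
        rows = []
        for measure, regions in HISTOLOGY_PER_SAMPLE.items():
            for region, values in regions.items():
                for s, v in enumerate(values, start=1):
                    rows.append({"sample": f"S{s}", "region": region,
                                 "measure": measure, "mean": v})
        df = pd.DataFrame(rows)
        piv = df[df["measure"] == "total_collagen"].pivot(
            index="sample", columns="region", values="mean")
        test = iq.paired_t_test(list(zip(piv["free_running"], piv["pmj"])))
        assert test.p < 0.01
        summary = iq.across_sample_summary(
            HISTOLOGY_PER_SAMPLE["total_collagen"]["free_running"])
        assert round_half_away(summary.mean, 1) == 72.4

    def test_single_sample_flags_undefined_sd(self, tmp_path):
        manifest = iq.simulate_histology_study(
            tmp_path, truths=[{
                "free_running": iq.HistologyTruth(region="free_running", seed=1),
                "pmj": iq.HistologyTruth(region="pmj", seed=2)}],
            images_per_region=1, size=(96, 96), seed=3)
        with pytest.warns(UserWarning, match="SD undefined"):
            res = iq.run_histology_pipeline(manifest)
        assert res.across_samples["sd"].isna().all()
        assert not res.paired_tests

    def test_pixel_weighting_option(self, histo_study):
        res_img = iq.run_histology_pipeline(histo_study, weighting="image")
        res_px = iq.run_histology_pipeline(histo_study, weighting="pixel")
        # both reproduce the prescription; weighting only reshuffles slightly
        a = res_img.per_sample.set_index(["sample", "region", "measure"])["mean"]
        b = res_px.per_sample.set_index(["sample", "region", "measure"])["mean"]
        assert np.allclose(a.sort_index(), b.sort_index(), atol=2.0)
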