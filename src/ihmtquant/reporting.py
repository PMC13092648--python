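"""Study-level aggregation: summary tables, pipelines and serialization.

The study design aggregates in two stages.  For MRI, per-(sample, protocol,
region) ROI means are first averaged over the selected protocols (mean ±
interprotocol sample SD per sample and region), then summarised across
samples (mean ± intersample SD per region) with a paired t-test comparing
the free-running fiber against the PMJ.  For histology, per-image measures
are averaged per sample and region (equal weight per image by default), then
across samples, again with a paired t-test on total collagen.

Machine-readable outputs keep full precision; printed-style values are
rounded half-away-from-zero to one decimal.  Every report carries a
provenance block (configuration snapshot, input digests, package version) so
each aggregate is traceable to its row-level inputs.
"""

from __future__ import annotations

import hashlib
import json
import math
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import __version__
from .core import compute_ihmtr, load_mtset_manifest, load_volume
from .errors import ManifestError
from .histology import (BrightfieldBandConfig, HueBandConfig,
                        classify_collagen_pixels, collagen_type_fractions,
                        rgb_to_hls, segment_brightfield)
from .roi import (FREE_RUNNING, MYOCARDIUM, PMJ, REGION_NAMES,
                  PairedTTestResult, RegionMask, paired_t_test, region_stats)

__all__ = [
    "round_half_away",
    "SummaryRow",
    "average_over_protocols",
    "across_sample_summary",
    "StudyTable",
    "MRIStudyResult",
    "run_mri_pipeline",
    "HistologyStudyResult",
    "run_histology_pipeline",
]


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (printed-table convention), e.g.
    0.25 -> 0.3 and -0.25 -> -0.3 at one decimal."""
    factor = 10 ** decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


@dataclass
class SummaryRow:
    """Mean ± sample SD across aggregation units (protocols or samples).

    With a single unit the value passes through and the SD is undefined
    (``sd_defined`` False, ``sd`` None).
    """

    grouping: str
    mean: float
    sd: float | None
    n_units: int

    @property
    def sd_defined(self) -> bool:
        return self.sd is not None

    def printed(self, decimals: int = 1) -> str:
        if not self.sd_defined:
            return f"{round_half_away(self.mean, decimals)}"
        return (f"{round_half_away(self.mean, decimals)} "
                f"± {round_half_away(self.sd, decimals)}")


def _summarize(values: Sequence[float], grouping: str) -> SummaryRow:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("no values to summarise")
    if arr.size == 1:
        return SummaryRow(grouping=grouping, mean=float(arr[0]), sd=None, n_units=1)
    return SummaryRow(grouping=grouping, mean=float(arr.mean()),
                      sd=float(arr.std(ddof=1)), n_units=int(arr.size))


def average_over_protocols(per_protocol_means: Sequence[float],
                           grouping: str = "") -> SummaryRow:
    """Mean ± interprotocol sample SD of one sample/region across protocols."""
    return _summarize(per_protocol_means, grouping)


def across_sample_summary(per_sample_values: Sequence[float],
                          grouping: str = "") -> SummaryRow:
    """Mean ± intersample sample SD of a per-sample measure."""
    return _summarize(per_sample_values, grouping)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class StudyTable:
    """Row-level results keyed by (sample, protocol/image, region) plus a
    provenance block; every aggregate must be recomputable from ``rows``."""

    rows: pd.DataFrame
    provenance: dict = field(default_factory=dict)
    key_columns: tuple[str, ...] = ("sample", "protocol", "region")

    def __post_init__(self) -> None:
        keys = [c for c in self.key_columns if c in self.rows.columns]
        if keys and self.rows.duplicated(subset=keys).any():
            raise ValueError(f"duplicate keys in StudyTable on {keys}")

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        # 17 significant digits: float64 values round-trip exactly
        self.rows.to_csv(path, index=False, float_format="%.17g")
        with open(path.with_suffix(".provenance.json"), "w") as fh:
            json.dump(self.provenance, fh, indent=2, sort_keys=True)
        return path

    @classmethod
    def from_csv(cls, path: str | Path,
                 key_columns: tuple[str, ...] = ("sample", "protocol", "region")
                 ) -> "StudyTable":
        path = Path(path)
        # round_trip parser: values written at full precision re-read bit-exactly
        rows = pd.read_csv(path, float_precision="round_trip")
        prov_path = path.with_suffix(".provenance.json")
        provenance = {}
        if prov_path.exists():
            with open(prov_path) as fh:
                provenance = json.load(fh)
        return cls(rows=rows, provenance=provenance, key_columns=key_columns)


def _provenance(config: dict, inputs: Sequence[Path]) -> dict:
    return {"version": __version__,
            "config": config,
            "inputs": {str(p): _sha256(p) for p in sorted(set(inputs))},
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S")}


def _paired_report(result: PairedTTestResult, label: str) -> dict:
    return {"comparison": label, "t": result.t, "df": result.df, "p": result.p,
            "mean_diff": result.mean_diff, "degenerate": result.degenerate}


# ---------------------------------------------------------------------------
# MRI pipeline


@dataclass
class MRIStudyResult:
    """Outputs of the samples x protocols ihMTR pipeline."""

    table: StudyTable                  # per (sample, protocol, region)
    per_sample: pd.DataFrame           # per (sample, region): mean over protocols
    across_samples: pd.DataFrame       # per region: mean over samples
    paired_test: PairedTTestResult     # free-running vs PMJ per-sample means
    report: dict


def _load_study_manifest(path: str | Path) -> tuple[dict, Path]:
    path = Path(path)
    if not path.exists():
        raise ManifestError(f"study manifest not found: {path}")
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    if not isinstance(spec, dict) or not spec.get("samples"):
        raise ManifestError(f"study manifest {path} lists no samples")
    return spec, path.parent


def run_mri_pipeline(manifest: str | Path,
                     out_dir: str | Path | None = None,
                     m0_threshold_frac: float = 0.1) -> MRIStudyResult:
    """Run ihMTR mapping + ROI statistics over a samples x protocols study.

    The study manifest lists, per sample, a region-label NIfTI and one
    acquisition manifest (five image roles + protocol metadata) per protocol::

        samples:
          S1:
            mask: S1/mask.nii.gz
            protocols: {Pr1: S1/Pr1/manifest.yaml, ...}

    Emits the row-level table, the per-sample summary (mean ± interprotocol
    SD), the across-sample summary per region and a paired t-test of the
    free-running vs PMJ per-sample means.  With ``out_dir``, writes
    ``rows.csv``, ``summary.csv``, ``across_samples.csv`` and ``report.json``.
    """
    spec, base = _load_study_manifest(manifest)
    rows = []
    inputs: list[Path] = [Path(manifest)]
    for sample, entry in spec["samples"].items():
        if "mask" not in entry or "protocols" not in entry:
            raise ManifestError(f"sample {sample} needs 'mask' and 'protocols'")
        mask_path = base / entry["mask"]
        if not mask_path.exists():
            raise ManifestError(f"sample {sample}: missing mask {entry['mask']}")
        mask = RegionMask(load_volume(mask_path).astype(int))
        inputs.append(mask_path)
        for prot_name, acq in entry["protocols"].items():
            acq_path = base / acq
            if not acq_path.exists():
                raise ManifestError(
                    f"sample {sample}, protocol {prot_name}: missing {acq}")
            inputs.append(acq_path)
            mtset = load_mtset_manifest(acq_path)
            ihmtr = compute_ihmtr(mtset, m0_threshold_frac=m0_threshold_frac)
            for label in (FREE_RUNNING, PMJ, MYOCARDIUM):
                st = region_stats(ihmtr, mask, label)
                rows.append({"sample": sample, "protocol": prot_name,
                             "region": REGION_NAMES[label],
                             "mean": st.mean_ihmtr, "sd": st.sd_ihmtr,
                             "n_voxels": st.n_voxels})
    rows_df = pd.DataFrame(rows)
    config = {"m0_threshold_frac": m0_threshold_frac}
    table = StudyTable(rows=rows_df, provenance=_provenance(config, inputs))

    per_sample = []
    for (sample, region), grp in rows_df.groupby(["sample", "region"], sort=True):
        s = average_over_protocols(grp["mean"].tolist(), f"{sample}/{region}")
        per_sample.append({"sample": sample, "region": region, "mean": s.mean,
                           "sd": s.sd if s.sd_defined else np.nan,
                           "n_protocols": s.n_units})
    per_sample_df = pd.DataFrame(per_sample)

    across = []
    for region, grp in per_sample_df.groupby("region", sort=True):
        s = across_sample_summary(grp["mean"].tolist(), region)
        across.append({"region": region, "mean": s.mean,
                       "sd": s.sd if s.sd_defined else np.nan,
                       "n_samples": s.n_units})
    across_df = pd.DataFrame(across)

    piv = per_sample_df.pivot(index="sample", columns="region", values="mean")
    test = paired_t_test(list(zip(piv["free_running"], piv["pmj"])))

    report = {"provenance": table.provenance,
              "across_samples": {
                  r["region"]: {"mean": r["mean"], "sd": r["sd"],
                                "n_samples": r["n_samples"],
                                "printed": SummaryRow(r["region"], r["mean"],
                                                      None if np.isnan(r["sd"]) else r["sd"],
                                                      r["n_samples"]).printed()}
                  for r in across},
              "paired_t_test": _paired_report(test, "free_running vs pmj")}

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "rows.csv")
        per_sample_df.to_csv(out_dir / "summary.csv", index=False)
        across_df.to_csv(out_dir / "across_samples.csv", index=False)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return MRIStudyResult(table=table, per_sample=per_sample_df,
                          across_samples=across_df, paired_test=test,
                          report=report)


# ---------------------------------------------------------------------------
# Histology pipeline

#: Measures of the histology summary table.
HISTO_MEASURES = ("total_collagen", "adipocyte", "type1", "type3")


@dataclass
class HistologyStudyResult:
    """Outputs of the samples x regions histology pipeline."""

    table: StudyTable                  # per (sample, region, image, measure)
    per_sample: pd.DataFrame           # per (sample, region, measure)
    across_samples: pd.DataFrame       # per (region, measure)
    paired_tests: dict[str, PairedTTestResult]
    report: dict


def run_histology_pipeline(manifest: str | Path,
                           out_dir: str | Path | None = None,
                           hue_config: HueBandConfig | None = None,
                           brightfield_config: BrightfieldBandConfig | None = None,
                           weighting: str = "image") -> HistologyStudyResult:
    """Quantify collagen composition over a samples x regions image study.

    Per region the manifest lists polarized-light images (collagen typing:
    Type I/III percentages of total collagen) and brightfield images (total
    collagen and adipocyte area percentages)::

        samples:
          S1:
            free_running: {polarized: [...], brightfield: [...]}
            pmj: {polarized: [...], brightfield: [...]}

    Per-sample values average the per-image measures with equal weight
    (``weighting="pixel"`` weights polarized images by collagen pixel count
    and brightfield images by ROI pixel count instead); across-sample rows
    and paired free-running-vs-PMJ t-tests per measure follow.
    """
    if weighting not in ("image", "pixel"):
        raise ValueError("weighting must be 'image' or 'pixel'")
    hue_config = hue_config or HueBandConfig()
    brightfield_config = brightfield_config or BrightfieldBandConfig()
    spec, base = _load_study_manifest(manifest)

    rows = []
    inputs: list[Path] = [Path(manifest)]

    def _img(path_str: str) -> np.ndarray:
        p = base / path_str
        if not p.exists():
            raise ManifestError(f"missing histology image: {path_str}")
        inputs.append(p)
        return np.asarray(Image.open(p).convert("RGB"))

    for sample, regions in spec["samples"].items():
        for region, modalities in regions.items():
            for i, path_str in enumerate(modalities.get("polarized", ())):
                arr = _img(path_str)
                classes = classify_collagen_pixels(rgb_to_hls(arr), config=hue_config)
                frac = collagen_type_fractions(classes)
                for measure, value in (("type1", frac.type1_pct),
                                       ("type3", frac.type3_pct)):
                    rows.append({"sample": sample, "region": region,
                                 "image": f"polarized_{i}", "measure": measure,
                                 "value": value, "weight_px": frac.n_collagen_px})
            for i, path_str in enumerate(modalities.get("brightfield", ())):
                arr = _img(path_str)
                seg = segment_brightfield(arr, config=brightfield_config)
                for measure, value in (("total_collagen", seg.frac_total_collagen),
                                       ("adipocyte", seg.frac_adipocyte)):
                    rows.append({"sample": sample, "region": region,
                                 "image": f"brightfield_{i}", "measure": measure,
                                 "value": value, "weight_px": seg.n_roi_px})
    rows_df = pd.DataFrame(rows)
    config = {"hue_bands": {c.name.lower(): list(map(list, iv))
                            for c, iv in hue_config.bands.items()},
              "lightness_gate": list(hue_config.lightness_gate),
              "saturation_min": hue_config.saturation_min,
              "weighting": weighting}
    table = StudyTable(rows=rows_df, provenance=_provenance(config, inputs),
                       key_columns=("sample", "region", "image", "measure"))

    per_sample = []
    for (sample, region, measure), grp in rows_df.groupby(
            ["sample", "region", "measure"], sort=True):
        if weighting == "pixel":
            w = grp["weight_px"].to_numpy(dtype=float)
            mean = float(np.average(grp["value"], weights=w)) if w.sum() else np.nan
        else:
            mean = float(grp["value"].mean())
        per_sample.append({"sample": sample, "region": region,
                           "measure": measure, "mean": mean,
                           "n_images": len(grp)})
    per_sample_df = pd.DataFrame(per_sample)

    across = []
    for (region, measure), grp in per_sample_df.groupby(["region", "measure"],
                                                        sort=True):
        vals = grp["mean"].tolist()
        if len(vals) >= 2:
            s = across_sample_summary(vals, f"{region}/{measure}")
        else:
            s = SummaryRow(f"{region}/{measure}", vals[0], None, 1)
            warnings.warn("single sample: across-sample SD undefined",
                          stacklevel=2)
        across.append({"region": region, "measure": measure, "mean": s.mean,
                       "sd": s.sd if s.sd_defined else np.nan,
                       "n_samples": s.n_units})
    across_df = pd.DataFrame(across)

    paired: dict[str, PairedTTestResult] = {}
    regions_present = set(per_sample_df["region"])
    if {"free_running", "pmj"} <= regions_present:
        for measure in sorted(set(per_sample_df["measure"])):
            sub = per_sample_df[per_sample_df["measure"] == measure]
            piv = sub.pivot(index="sample", columns="region", values="mean")
            if len(piv) >= 2:
                paired[measure] = paired_t_test(
                    list(zip(piv["free_running"], piv["pmj"])))

    report = {"provenance": table.provenance,
              "across_samples": [
                  {**r, "printed": SummaryRow("", r["mean"],
                                              None if np.isnan(r["sd"]) else r["sd"],
                                              r["n_samples"]).printed()}
                  for r in across],
              "paired_t_tests": {m: _paired_report(t, f"free_running vs pmj ({m})")
                                 for m, t in paired.items()}}

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "rows.csv")
        per_sample_df.to_csv(out_dir / "summary.csv", index=False)
        across_df.to_csv(out_dir / "across_samples.csv", index=False)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return HistologyStudyResult(table=table, per_sample=per_sample_df,
                                across_samples=across_df, paired_tests=paired,
                                report=report)
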