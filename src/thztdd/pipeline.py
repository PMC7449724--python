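"""End-to-end orchestration: simulate (or load) -> extract -> normalize ->
summarize -> compare -> report.

A run produces, under ``output_dir``:

- ``images/<group>_<replicate>.csv``  normalized |M| image per replicate
  (optional, ``write_images``),
- ``summary.csv``                     one row per (group, replicate) with the
  central-ROI mean |M|_norm,
- ``report.json``                     the statistical battery,
- ``manifest.json``                   config (with hash), seed, artifact list.

The manifest is config- and seed-complete: re-running with the same manifest
reproduces every table byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time

import numpy as np
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
import yaml

from . import __version__
from .geometry import Geometry
from .imaging import (
    DEFAULT_EVAL_FREQUENCY_THZ,
    normalize,
    pixel_amplitude,
    roi_mean,
)
from .io import (
    geometry_from_dict,
    geometry_to_dict,
    read_raster_h5,
    write_normalized_image,
)
from .spectroscopy import DEFAULT_BAND
from .stats import GroupSummary, run_group_comparison
from .synthetic import (
    ExperimentDesign,
    ExperimentRecord,
    simulate_experiment,
)

__all__ = [
    "RunConfig",
    "FigshareLayoutError",
    "run",
    "summarize_experiment",
    "load_figshare_export",
]


class FigshareLayoutError(ValueError):
    """Raised when a deposited-data directory has no recognizable layout."""


@dataclass(frozen=True)
class RunConfig:
    """Complete configuration of one analysis run."""

    mode: str = "synthetic"  # "synthetic" | "from_files"
    design: ExperimentDesign = field(default_factory=ExperimentDesign)
    geometry: Geometry = field(default_factory=Geometry)
    f_eval: float = DEFAULT_EVAL_FREQUENCY_THZ
    band: tuple[float, float] = DEFAULT_BAND
    alpha: float = 0.05
    output_dir: str = "thztdd_run"
    input_dir: str | None = None  # from_files mode
    write_images: bool = True
    seed: int | None = None  # overrides design.seed when given

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "from_files"):
            raise ValueError("mode must be 'synthetic' or 'from_files'")
        if self.mode == "from_files" and not self.input_dir:
            raise ValueError("from_files mode requires input_dir")
        if not self.band[0] <= self.f_eval <= self.band[1]:
            raise ValueError("f_eval must lie inside the valid band")

    @property
    def effective_design(self) -> ExperimentDesign:
        if self.seed is None:
            return self.design
        return dataclasses.replace(self.design, seed=self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["geometry"] = geometry_to_dict(self.geometry)
        d["design"]["peak_fractions"] = dict(self.design.peak_fractions)
        d["design"]["spot_shapes"] = dict(self.design.spot_shapes)
        d["band"] = list(self.band)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "design" in d:
            d["design"] = ExperimentDesign(**d["design"])
        if "geometry" in d:
            d["geometry"] = geometry_from_dict(d["geometry"])
        if "band" in d:
            d["band"] = tuple(d["band"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _config_hash(config: RunConfig) -> str:
    canonical = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


def _load_records(input_dir: Path) -> Iterator[ExperimentRecord]:
    """from_files mode: paired ``<group>_<replicate>_{before,after}.h5``."""
    befores = sorted(input_dir.glob("*_before.h5"))
    missing = []
    records = []
    for bpath in befores:
        apath = bpath.with_name(bpath.name.replace("_before", "_after"))
        if not apath.exists():
            missing.append(str(apath))
            continue
        before = read_raster_h5(bpath)
        after = read_raster_h5(apath)
        stem = bpath.name[: -len("_before.h5")]
        group, _, rep = stem.rpartition("_")
        records.append(
            ExperimentRecord(
                group=before.group or group,
                replicate=(
                    before.replicate if before.replicate is not None
                    else int(rep)
                ),
                before=before,
                after=after,
            )
        )
    if missing:
        raise FileNotFoundError(
            "missing after-treatment rasters: " + ", ".join(missing)
        )
    if not records:
        raise FileNotFoundError(
            f"no '*_before.h5' rasters found in {input_dir}"
        )
    return iter(records)


def summarize_experiment(
    design: ExperimentDesign,
    geometry: Geometry | None = None,
    f_eval: float = DEFAULT_EVAL_FREQUENCY_THZ,
    band: tuple[float, float] = DEFAULT_BAND,
) -> list[GroupSummary]:
    """Simulate the experiment and reduce it to per-group ROI summaries
    (the in-memory equivalent of a run's summary table)."""
    geometry = geometry or Geometry()
    values: dict[str, list[float]] = {g: [] for g in design.groups}
    for rec in simulate_experiment(design, geometry=geometry):
        img = normalize(
            pixel_amplitude(rec.before, f_eval=f_eval, band=band),
            pixel_amplitude(rec.after, f_eval=f_eval, band=band),
            f_eval=f_eval,
        )
        values[rec.group].append(roi_mean(img))
    return [GroupSummary(g, np.asarray(v)) for g, v in values.items()]


def run(config: RunConfig, log=None) -> dict:
    """Execute the full pipeline and return the run manifest."""

    def _log(msg: str) -> None:
        if log is not None:
            log(msg)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = config.effective_design
    if config.mode == "synthetic":
        records: Iterable[ExperimentRecord] = simulate_experiment(
            design, geometry=config.geometry
        )
    else:
        records = _load_records(Path(config.input_dir))

    artifacts: list[str] = []
    rows = []
    t0 = time.perf_counter()
    if config.write_images:
        (out / "images").mkdir(exist_ok=True)
    for rec in records:
        before_field = pixel_amplitude(
            rec.before, f_eval=config.f_eval, band=config.band
        )
        after_field = pixel_amplitude(
            rec.after, f_eval=config.f_eval, band=config.band
        )
        img = normalize(before_field, after_field, f_eval=config.f_eval)
        rows.append(
            {
                "group": rec.group,
                "replicate": rec.replicate,
                "m_norm_bar": roi_mean(img),
                "m_before_bar": img.m_before_bar,
            }
        )
        if config.write_images:
            p = write_normalized_image(
                img, out / "images" / f"{rec.group}_{rec.replicate}.csv"
            )
            artifacts.append(str(p.relative_to(out)))
    _log(
        f"extracted {len(rows)} replicate images in "
        f"{time.perf_counter() - t0:.1f} s"
    )

    summary = pd.DataFrame(rows).sort_values(["group", "replicate"])
    summary_path = out / "summary.csv"
    summary.to_csv(summary_path, index=False, float_format="%.17g")
    artifacts.append("summary.csv")

    order = [g for g in design.groups if g in set(summary["group"])]
    groups = [
        GroupSummary(g, summary.loc[summary.group == g, "m_norm_bar"].to_numpy())
        for g in order
    ]
    report = run_group_comparison(groups, alpha=config.alpha)
    report_path = out / "report.json"
    report_path.write_text(json.dumps(report.to_dict(), indent=2))
    artifacts.append("report.json")
    _log(
        f"ANOVA F={report.anova.F:.2f} "
        f"(df {report.anova.df_between},{report.anova.df_within}), "
        f"p={report.anova.p_value:.3g}"
    )

    manifest = {
        "package": "thztdd",
        "version": __version__,
        "seed": design.seed,
        "config": config.to_dict(),
        "config_sha256": _config_hash(config),
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def load_figshare_export(path) -> dict:
    """Best-effort adapter for a manually downloaded data deposit.

    Expects a directory of raster containers (``*_before.h5`` /
    ``*_after.h5`` pairs, as written by :func:`thztdd.io.write_raster_h5`).
    Returns the record list plus group/replicate counts for user
    verification.  Unrecognized layouts raise :class:`FigshareLayoutError`
    naming what was sought; the archive's internal format is not documented,
    so anything else must be converted to this layout first.
    """
    path = Path(path)
    if not path.is_dir():
        raise FileNotFoundError(
            f"{path} is not a directory; download and unpack the deposited "
            "archive manually, then point here"
        )
    try:
        records = list(_load_records(path))
    except FileNotFoundError as exc:
        contents = sorted(p.name for p in path.iterdir())[:20]
        raise FigshareLayoutError(
            "unrecognized deposit layout: expected paired "
            "'<group>_<replicate>_before.h5' / '..._after.h5' raster "
            f"containers ({exc}); directory holds: {contents}"
        ) from exc
    counts: dict[str, int] = {}
    for rec in records:
        counts[rec.group] = counts.get(rec.group, 0) + 1
    return {"records": records, "group_counts": counts}
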