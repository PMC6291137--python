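"""End-to-end pipeline: simulate -> preprocess -> metrics -> image -> annotate.

A :class:`PipelineConfig` (loadable from YAML, unknown keys rejected)
drives a deterministic run that writes every intermediate product —
imzML, ground truth, peak matrix TSV, metrics TSV/JSON, PNG ion images,
annotation TSV — plus the resolved config and a machine-readable run
log with the calibration residuals, into one output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import annotate as _annotate
from . import imaging, io, metrics, preprocess, synth
from .chem import default_reference_set, read_reference_table

__all__ = ["PipelineConfig", "PipelineError", "run"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure: carries the stage name and a short error code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}/{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineConfig:
    """Validated pipeline parameters (one YAML document)."""

    # simulate
    scene_kind: str = "two_region"
    seed: int = 0
    grid_shape: tuple[int, int] | None = None
    instrument: dict = field(default_factory=dict)
    input_imzml: str | None = None          # skip simulation when given
    # preprocess
    references: str | None = None           # TSV path; None -> gold + salt set
    snr_min: float = 5.0
    bin_ppm: float = 20.0
    search_window: float = 0.3
    calibration_degree: int = 2
    # metrics
    top_k: int = 250
    exclude_gold: bool = True
    # imaging
    image_mz: list[float] = field(default_factory=list)
    image_tolerance: float = 0.1
    normalization: str = "none"
    rgb: list[float] | None = None
    # annotation
    db: str | None = None                   # TSV path; None -> bundled table
    adducts: list[str] = field(default_factory=lambda: ["+H", "+Na", "+K", "+NH4"])
    tol_ppm: float = 20.0
    tissue: str | None = None

    _INSTRUMENT_KEYS = {f.name for f in dataclasses.fields(synth.InstrumentModel)}

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise PipelineError("config", "unknown_key", f"unknown config keys: {sorted(unknown)}")
        inst = d.get("instrument") or {}
        bad = set(inst) - cls._INSTRUMENT_KEYS
        if bad:
            raise PipelineError("config", "unknown_key", f"unknown instrument keys: {sorted(bad)}")
        cfg = cls(**d)
        if cfg.grid_shape is not None:
            cfg.grid_shape = tuple(int(v) for v in cfg.grid_shape)  # type: ignore[assignment]
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise PipelineError("config", "not_a_mapping", f"config root must be a mapping: {path}")
        return cls.from_dict(doc)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape) if self.grid_shape else None
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def _stage(name: str, code: str):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except PipelineError:
                raise
            except Exception as e:  # noqa: BLE001 - map to stage error
                raise PipelineError(name, code, str(e)) from e
        return wrapped
    return deco


@_stage("simulate", "render_failed")
def _simulate(cfg: PipelineConfig, outdir: Path):
    scene = synth.default_scene(cfg.scene_kind, cfg.seed, cfg.grid_shape)
    instrument = synth.InstrumentModel(**cfg.instrument)
    ds, truth = synth.render_dataset(scene, instrument, cfg.seed)
    io.write_imzml(ds, outdir / "data.imzML")
    truth.to_frame().to_csv(outdir / "ground_truth.tsv", sep="\t", index=False, float_format="%.6g")
    return ds


@_stage("preprocess", "calibration_failed")
def _preprocess(cfg: PipelineConfig, ds, outdir: Path, run_log: dict):
    refs = read_reference_table(cfg.references) if cfg.references else default_reference_set()
    aligned = preprocess.align_dataset(ds)
    mz, mean = preprocess.mean_spectrum(aligned)
    model = preprocess.calibrate(
        mz, mean, refs, search_window=cfg.search_window, degree=cfg.calibration_degree,
        snr_min=cfg.snr_min,
    )
    run_log["calibration"] = {
        "degree": model.degree,
        "residuals_ppm": {k: round(v, 4) for k, v in model.residuals_ppm.items()},
        "unmatched": model.unmatched,
    }
    calibrated = preprocess.apply_calibration(aligned, model)
    peak_lists = preprocess.pick_peaks_dataset(calibrated, snr_min=cfg.snr_min)
    matrix = preprocess.build_peak_matrix(peak_lists, calibrated.coordinates, cfg.bin_ppm)
    io.write_peak_matrix(matrix, outdir / "peak_matrix.tsv")
    run_log["preprocess"] = {
        "snr_min": cfg.snr_min,
        "bin_ppm": cfg.bin_ppm,
        "n_bins": matrix.n_bins,
        "n_pixels": int(matrix.heights.shape[0]),
    }
    return calibrated, matrix, model


@_stage("metrics", "metrics_failed")
def _metrics(cfg: PipelineConfig, matrix, outdir: Path, run_log: dict):
    per_pixel, summary = metrics.compare_conditions(
        [(cfg.scene_kind, matrix)], k=cfg.top_k, exclude_gold=cfg.exclude_gold
    )
    per_pixel.to_csv(outdir / "metrics.tsv", sep="\t", index=False, float_format="%.6g")
    summary_records = summary.to_dict(orient="records")
    (outdir / "metrics_summary.json").write_text(json.dumps(summary_records, indent=2))
    run_log["metrics"] = {"top_k": cfg.top_k, "exclude_gold": cfg.exclude_gold}
    return per_pixel, summary


@_stage("image", "imaging_failed")
def _images(cfg: PipelineConfig, calibrated, outdir: Path):
    for target in cfg.image_mz:
        img = imaging.ion_image(calibrated, target, cfg.image_tolerance,
                                normalization=cfg.normalization)
        imaging.save_image(img, outdir / f"ion_{target:.4f}.png")
    if cfg.rgb:
        if len(cfg.rgb) != 3:
            raise PipelineError("image", "bad_rgb", "rgb needs exactly three m/z values")
        chans = [
            imaging.scale_image(
                imaging.ion_image(calibrated, t, cfg.image_tolerance,
                                  normalization=cfg.normalization)
            )
            for t in cfg.rgb
        ]
        imaging.save_image(imaging.rgb_composite(*chans), outdir / "rgb_composite.png")


@_stage("annotate", "annotation_failed")
def _annotation(cfg: PipelineConfig, calibrated, outdir: Path, run_log: dict):
    if cfg.db:
        records, rejects = io.read_metabolite_db(cfg.db)
        if rejects:
            run_log["annotate_rejected_rows"] = rejects
    else:
        from .data import load_brain_db

        records = load_brain_db()
    mz, mean = preprocess.mean_spectrum(calibrated)
    peaks = preprocess.pick_peaks(mz, mean, snr_min=cfg.snr_min)
    hits = _annotate.annotate(peaks, records, cfg.adducts, cfg.tol_ppm, cfg.tissue)
    io.write_annotations(hits, outdir / "annotations.tsv")
    run_log["annotate"] = {"n_peaks": len(peaks), "n_hits": len(hits), "tol_ppm": cfg.tol_ppm}
    return hits


def run(config: PipelineConfig, outdir) -> dict:
    """Execute the full pipeline; returns the run log (also written as JSON).

    Deterministic given the config (including its seed): rerunning with
    the same config yields byte-identical peak-matrix TSV output.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run_log: dict = {"config_seed": config.seed}
    if config.input_imzml:
        ds = io.read_imzml(config.input_imzml)
    else:
        ds = _simulate(config, outdir)
    calibrated, matrix, _model = _preprocess(config, ds, outdir, run_log)
    _metrics(config, matrix, outdir, run_log)
    if not config.image_mz and not config.rgb:
        # default: image the three strongest non-background bins
        order = np.argsort(matrix.heights.sum(axis=0))[::-1]
        config.image_mz = [float(matrix.bin_mz[i]) for i in order[:3]]
    _images(config, calibrated, outdir)
    _annotation(config, calibrated, outdir, run_log)
    config.to_yaml(outdir / "config.yaml")
    (outdir / "run_log.json").write_text(json.dumps(run_log, indent=2, sort_keys=True))
    return run_log
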