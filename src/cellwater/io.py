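"""Readers/writers, run configuration, and the end-to-end pipeline.

Formats are deliberately plain: two-column CSV for decay curves (with
``# key: value`` comment-header metadata), CSV for series tables, JSON for
fits/events/reports, TIFF or PNG for images.  Every structured output
carries the seed and a hash of the configuration for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .compartments import (
    CompartmentSeries,
    build_series,
    detect_rupture_events,
)
from .errors import ParseError
from .fitting import FitConfig, compute_snr, fit_multiexponential, gate_by_snr
from .model import CurveMeta, DecayCurve, FitResult
from .segmentation import GrayImage, entropy_threshold, segment, wall_fraction_profile
from .simulate import (
    DryingSimSpec,
    generate_decay,
    generate_drying_series,
    generate_noise_roi,
    generate_signal_roi,
)

__all__ = [
    "read_decay_csv",
    "write_decay_csv",
    "read_series_csv",
    "write_series_csv",
    "read_gray_image",
    "write_mask_image",
    "fit_result_to_dict",
    "RunConfig",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

_META_FIELDS = {"temperature_c": float, "drying_time_min": float, "sample_id": str}


def read_decay_csv(path: Union[str, Path]) -> DecayCurve:
    """Read a decay curve from a two-column CSV (time_ms, signal).

    Leading ``# key: value`` comment lines become curve metadata.  Raises
    :class:`ParseError` naming the offending line on malformed input.
    """
    path = Path(path)
    meta_kwargs: dict = {}
    times, signal = [], []
    with open(path) as fh:
        header_seen = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    key = key.strip()
                    if key in _META_FIELDS:
                        try:
                            meta_kwargs[key] = _META_FIELDS[key](value.strip())
                        except ValueError:
                            raise ParseError(
                                f"{path}:{lineno}: bad metadata value for '{key}'"
                            ) from None
                continue
            fields = [f.strip() for f in line.split(",")]
            if not header_seen:
                header_seen = True
                if len(fields) < 2:
                    raise ParseError(f"{path}:{lineno}: expected a two-column header")
                continue
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            try:
                times.append(float(fields[0]))
                signal.append(float(fields[1]))
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric row: {line!r}") from None
    if len(times) < 4:
        raise ParseError(f"{path}: need >= 4 data rows, found {len(times)}")
    t = np.asarray(times)
    if np.any(np.diff(t) <= 0):
        bad = int(np.argmax(np.diff(t) <= 0)) + 2  # +1 header, +1 next row
        raise ParseError(f"{path}: echo times not strictly increasing near data row {bad}")
    try:
        return DecayCurve(times=t, signal=np.asarray(signal), meta=CurveMeta(**meta_kwargs))
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_decay_csv(curve: DecayCurve, path: Union[str, Path]) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for key in _META_FIELDS:
            value = getattr(curve.meta, key)
            if value is not None:
                fh.write(f"# {key}: {value}\n")
        fh.write("time_ms,signal\n")
        for t, s in zip(curve.times, curve.signal):
            fh.write(f"{t:.6g},{s:.10g}\n")


def read_series_csv(path: Union[str, Path], temperature_c: Optional[float] = None) -> CompartmentSeries:
    """Read a (time_min, icw_pct) CSV into a series; fw is 100 - icw."""
    df = pd.read_csv(path, comment="#")
    for col in ("time_min", "icw_pct"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column '{col}'")
    icw = df["icw_pct"].to_numpy(dtype=float)
    return CompartmentSeries(
        times=df["time_min"].to_numpy(dtype=float),
        icw_pct=icw,
        fw_pct=100.0 - icw,
        temperature_c=temperature_c,
    )


def write_series_csv(series: CompartmentSeries, path: Union[str, Path]) -> None:
    series.to_frame().to_csv(path, index=False)


def read_gray_image(path: Union[str, Path], resolution_um: float = 6.0) -> GrayImage:
    import imageio.v3 as iio

    px = np.asarray(iio.imread(path))
    if px.ndim == 3:  # collapse RGB(A) to luminance
        px = px[..., :3].mean(axis=-1)
    if px.dtype != np.uint8:
        px = np.clip(np.round(px), 0, 255).astype(np.uint8)
    return GrayImage(pixels=px, resolution_um=resolution_um)


def write_mask_image(mask: np.ndarray, path: Union[str, Path]) -> None:
    import imageio.v3 as iio

    iio.imwrite(Path(path), (np.asarray(mask, dtype=np.uint8) * 255))


def fit_result_to_dict(fit: FitResult) -> dict:
    return {
        "components": [
            {"amplitude": c.amplitude, "t2_ms": c.t2} for c in fit.model.components
        ],
        "r_squared": fit.r_squared,
        "residual_norm": fit.residual_norm,
        "snr": None if fit.snr is None else (None if math.isinf(fit.snr) else fit.snr),
        "accepted": fit.accepted,
        "flags": list(fit.flags),
    }


# ---------------------------------------------------------------------------
# Run configuration


class FitSection(BaseModel):
    n_components: Union[int, str] = 2
    max_components: int = 3
    n_starts: int = 8
    snr_gate: float = 5.17

    @field_validator("n_components")
    @classmethod
    def _check_k(cls, v):
        if v != "auto" and v not in (1, 2, 3):
            raise ValueError("n_components must be 1, 2, 3 or 'auto'")
        return v


class SimulateSection(BaseModel):
    temperature_c: float = 60.0
    sample_times: list[float] = Field(
        default_factory=lambda: [float(t) for t in range(30, 421, 30)]
    )
    baseline_icw_pct: float = 88.0
    rupture_times: list[float] = Field(default_factory=list)
    drop_pp: Union[float, list[float]] = 30.0
    recovery_rate: float = 0.6
    fluctuation_sd: float = 1.0
    snr: Optional[float] = None  # None = noiseless
    n_echoes: int = 1000
    echo_spacing_ms: float = 10.0
    noise_model: str = "gaussian"


class RunConfig(BaseModel):
    """Validated configuration of an end-to-end run.

    Exactly one decay source must be given: ``simulate`` (a drying
    protocol generated on the fly) or ``decay_csvs`` (paths to measured
    curves whose metadata carries the drying time).
    """

    seed: int = 0
    min_drop_pp: float = 15.0
    fit: FitSection = Field(default_factory=FitSection)
    simulate: Optional[SimulateSection] = None
    decay_csvs: list[str] = Field(default_factory=list)
    images: list[str] = Field(default_factory=list)
    output_dir: Optional[str] = None
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "RunConfig":
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls.model_validate(payload or {})

    def config_hash(self) -> str:
        canonical = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Pipeline


def _fit_stage(config: RunConfig) -> list[tuple[float, FitResult]]:
    fit_cfg = FitConfig(
        max_components=config.fit.max_components,
        n_starts=config.fit.n_starts,
        snr_gate=config.fit.snr_gate,
    )
    pairs: list[tuple[float, FitResult]] = []
    if config.simulate is not None:
        sim = config.simulate
        spec = DryingSimSpec(
            temperature_c=sim.temperature_c,
            sample_times=tuple(sim.sample_times),
            baseline_icw_pct=sim.baseline_icw_pct,
            rupture_times=tuple(sim.rupture_times),
            drop_pp=sim.drop_pp if np.isscalar(sim.drop_pp) else tuple(sim.drop_pp),
            recovery_rate=sim.recovery_rate,
            fluctuation_sd=sim.fluctuation_sd,
            seed=config.seed,
            snr=math.inf if sim.snr is None else sim.snr,
            n_echoes=sim.n_echoes,
            echo_spacing_ms=sim.echo_spacing_ms,
            noise_model=sim.noise_model,
        )
        _, decay_specs = generate_drying_series(spec)
        for dspec in decay_specs:
            curve = generate_decay(dspec)
            fit = fit_multiexponential(curve, config.fit.n_components, fit_cfg)
            if not math.isinf(dspec.snr):
                # per-voxel image SNR, as measured from in-sample vs
                # outside-sample ROIs
                snr = compute_snr(generate_signal_roi(dspec), generate_noise_roi(dspec))
                fit = gate_by_snr(fit, snr, fit_cfg)
            pairs.append((curve.meta.drying_time_min, fit))
    else:
        for path in config.decay_csvs:
            curve = read_decay_csv(path)
            if curve.meta.drying_time_min is None:
                raise ParseError(f"{path}: metadata lacks 'drying_time_min'")
            fit = fit_multiexponential(curve, config.fit.n_components, fit_cfg)
            pairs.append((curve.meta.drying_time_min, fit))
    return pairs


def run_pipeline(config: RunConfig) -> dict:
    """Run fit -> series -> rupture events (and optional segmentation).

    Returns the report dict; when ``output_dir`` is set, also writes
    ``report.json``, ``series.csv`` and ``events.json`` there.  A stage
    failure is recorded in the report and later stages are skipped, but
    earlier outputs are preserved.  Deterministic given the seed.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    report: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }
    series = None
    try:
        pairs = _fit_stage(config)
        n_rej = sum(1 for _, f in pairs if not f.accepted)
        report["fits"] = [
            {"time_min": t, **fit_result_to_dict(f)} for t, f in sorted(pairs)
        ]
        report["stages"]["fit"] = {"status": "ok", "n_fits": len(pairs), "n_rejected": n_rej}
        logger.info("fit stage: %d curves, %d rejected by SNR gate", len(pairs), n_rej)
    except Exception as exc:
        report["stages"]["fit"] = {"status": "failed", "error": str(exc)}
        pairs = []

    if pairs:
        try:
            temperature = (
                config.simulate.temperature_c if config.simulate is not None else None
            )
            series = build_series(pairs, temperature_c=temperature)
            report["series"] = series.to_frame().to_dict(orient="list")
            report["stages"]["series"] = {"status": "ok", "n_points": len(series)}
        except Exception as exc:
            report["stages"]["series"] = {"status": "failed", "error": str(exc)}

    if series is not None:
        try:
            events = detect_rupture_events(series, min_drop_pp=config.min_drop_pp)
            report["events"] = [
                {"time_min": e.time, "drop_pp": e.drop_pp} for e in events
            ]
            report["stages"]["events"] = {"status": "ok", "n_events": len(events)}
            logger.info("detected %d rupture events", len(events))
        except Exception as exc:
            report["stages"]["events"] = {"status": "failed", "error": str(exc)}

    if config.images:
        seg_reports = []
        try:
            for path in config.images:
                image = read_gray_image(path)
                thr = entropy_threshold(image)
                result = segment(image, thr)
                seg_reports.append(
                    {
                        "path": str(path),
                        "threshold": result.threshold,
                        "wall_fraction": result.wall_fraction,
                        "depth_profile": wall_fraction_profile(result, axis=0).tolist(),
                    }
                )
            report["segmentation"] = seg_reports
            report["stages"]["segmentation"] = {"status": "ok", "n_images": len(seg_reports)}
        except Exception as exc:
            report["segmentation"] = seg_reports
            report["stages"]["segmentation"] = {"status": "failed", "error": str(exc)}

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        if series is not None:
            write_series_csv(series, out / "series.csv")
        if "events" in report:
            with open(out / "events.json", "w") as fh:
                json.dump(
                    {
                        "seed": config.seed,
                        "config_hash": report["config_hash"],
                        "events": report["events"],
                    },
                    fh,
                    indent=2,
                )
    return report
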