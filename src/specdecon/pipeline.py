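"""End-to-end pipeline: interpolate -> denoise -> baseline -> peaks -> fit.

The stage order is fixed because each stage consumes the previous one's
output: the peak detector needs a uniform grid and a flat baseline, and
the decomposition needs detected peaks to seed its components.  Stages
can be disabled (``n_interp=0``, ``denoise_window=0``,
``baseline='none'``, ``decompose=False``) but never reordered.

:func:`run_pipeline` returns all intermediate results and, when given an
output directory, writes them as text artifacts plus a JSON manifest
echoing every parameter, so a run can be reproduced exactly from the
manifest alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from . import __version__
from .baseline import BaselineResult, detrend
from .decompose import Decomposition, fit
from .peaks import PeakSet, detect_peaks
from .preprocess import denoise, interpolate_uniform
from .spectrum import Spectrum, write_peak_table, write_spectrum

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Every knob of the pipeline, with the GUI-style defaults.

    ``denoise_window`` may be a single size or a list applied
    sequentially (multi-pass smoothing with decreasing windows).
    """

    n_interp: int = 10000
    denoise_window: int | list[int] = 0
    denoise_repeats: int = 1
    baseline: str = "arpls"
    lam: float = 200.0
    ratio: float = 1e-6
    baseline_max_iter: int = 50
    window_size: int = 10
    threshold: float = 0.0
    min_amplitude: float = 0.0
    decompose: bool = True
    family: str = "lorentzian"
    loss: str = "soft_l1"
    max_iter: int = 100
    free_centers: bool = False
    crop_min: float | None = None
    crop_max: float | None = None

    def to_manifest(self) -> dict:
        d = asdict(self)
        d["version"] = __version__
        return d

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown pipeline parameters: {sorted(unknown)}")
        return cls(**mapping)


@dataclass
class PipelineResult:
    """All intermediate products of one pipeline run."""

    config: PipelineConfig
    input: Spectrum
    preprocessed: Spectrum
    detrended: Spectrum
    baseline: BaselineResult
    peaks: PeakSet
    decomposition: Decomposition | None


def run_pipeline(
    s: Spectrum,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full analysis on a spectrum.

    When ``out_dir`` is given, writes ``preprocessed.txt``,
    ``baseline.txt``, ``detrended.txt``, ``peaks.tsv``,
    ``decomposition.json``, ``reconstruction.txt``, and
    ``manifest.json`` into it.
    """
    cfg = config or PipelineConfig()

    stage = "crop"
    try:
        if cfg.crop_min is not None or cfg.crop_max is not None:
            from .spectrum import crop
            lo = cfg.crop_min if cfg.crop_min is not None else s.x[0]
            hi = cfg.crop_max if cfg.crop_max is not None else s.x[-1]
            s = crop(s, lo, hi)

        stage = "interpolate"
        work = s
        if cfg.n_interp:
            work = interpolate_uniform(work, cfg.n_interp)

        stage = "denoise"
        windows = (cfg.denoise_window
                   if isinstance(cfg.denoise_window, (list, tuple))
                   else [cfg.denoise_window])
        for w in windows:
            if w and w > 1:
                work = denoise(work, int(w), repeats=cfg.denoise_repeats)
        preprocessed = work

        stage = "baseline"
        detrended, base = detrend(
            work, method=cfg.baseline, lam=cfg.lam, ratio=cfg.ratio,
            max_iter=cfg.baseline_max_iter,
        )

        stage = "peak detection"
        peaks = detect_peaks(
            detrended, window_size=cfg.window_size,
            threshold=cfg.threshold, min_amplitude=cfg.min_amplitude,
        )

        stage = "decomposition"
        decomposition = None
        if cfg.decompose and len(peaks) > 0:
            decomposition = fit(
                detrended, peaks, family=cfg.family, loss=cfg.loss,
                max_iter=cfg.max_iter, free_centers=cfg.free_centers,
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    result = PipelineResult(
        config=cfg, input=s, preprocessed=preprocessed,
        detrended=detrended, baseline=base, peaks=peaks,
        decomposition=decomposition,
    )
    if out_dir is not None:
        _write_artifacts(result, Path(out_dir))
    return result


def _write_artifacts(res: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_spectrum(res.preprocessed, out_dir / "preprocessed.txt")
    write_spectrum(res.preprocessed.with_y(res.baseline.z),
                   out_dir / "baseline.txt")
    write_spectrum(res.detrended, out_dir / "detrended.txt")
    with open(out_dir / "peaks.tsv", "w", encoding="utf-8") as fh:
        fh.write("index\tx\tamplitude\tcurvature\n")
        for p in res.peaks:
            fh.write(f"{p.index}\t{p.x:.9g}\t{p.amplitude:.9g}\t"
                     f"{p.curvature:.9g}\n")
    if res.decomposition is not None:
        res.decomposition.save_json(out_dir / "decomposition.json")
        write_peak_table(res.decomposition, out_dir / "peak_table.tsv")
        write_spectrum(
            res.detrended.with_y(res.decomposition.reconstruction),
            out_dir / "reconstruction.txt",
        )
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(res.config.to_manifest(), fh, indent=2)
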