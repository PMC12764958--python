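"""End-to-end orchestration of the PORH simulation/analysis pipeline.

A run mirrors the study design: synthetic cohorts are generated per group
(profile level, or image level through the acoustic forward model and
reconstruction), biomarkers are extracted per subject and layer, and group
statistics are computed.  All outputs are plain CSV/JSON (plus TIFF frames
in image mode) under one output directory together with a manifest of
versions, seeds and parameters; identical configuration and seeds yield
byte-identical CSV outputs.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .biomarkers import biomarker_table, layer_profile
from .recon import AcquisitionGeometry, ReconGrid, beamform, bandpass, \
    make_beamform_operator, save_tiff
from .segment import detect_surface, flatten, segment_layers
from .stats import compare_groups
from .synthetic import COHORT_PRESETS, CohortPreset, LONG_PROTOCOL, \
    PORHProtocol, SHORT_PROTOCOL, generate_cohort, simulate_frame_sinograms, \
    two_layer_phantom, HemodynamicParams

__all__ = ["RunConfig", "run_porh_pipeline"]

log = logging.getLogger("frsom")

PROTOCOLS = {"long": LONG_PROTOCOL, "short": SHORT_PROTOCOL}
CSV_FLOAT_FORMAT = "%.10g"
BIOMARKER_COLS = ("MVC", "HR_pct", "TP_min")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``groups`` names presets from :data:`frsom.synthetic.COHORT_PRESETS`
    (custom presets may be passed via ``custom_presets``).  Seeds are
    explicit; per-group seeds are derived deterministically from ``seed``.
    """

    protocol: str = "long"  # "long" (2/5/3 min) or "short" (1/3/2 min)
    mode: str = "profile"  # "profile" or "image"
    groups: tuple[str, ...] = ("smoker", "non_smoker")
    n_subjects: Optional[int] = None
    noise_sd: float = 0.02
    seed: int = 0
    out_dir: str = "frsom_run"
    layers: tuple[str, ...] = ("DV", "SD", "RD")
    frame_interval_s: Optional[float] = None
    peak_smooth_s: float = 15.0
    alpha: float = 0.05
    # image-mode knobs (kept small: a thin cross-sectional frame series)
    image_frame_interval_s: float = 60.0
    image_noise_sd: float = 0.002
    save_frames: bool = True
    custom_presets: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as f:
            cfg = yaml.safe_load(f) or {}
        if "groups" in cfg:
            cfg["groups"] = tuple(cfg["groups"])
        if "layers" in cfg:
            cfg["layers"] = tuple(cfg["layers"])
        return cls(**cfg)

    def resolve_protocol(self) -> PORHProtocol:
        proto = PROTOCOLS[self.protocol]
        interval = self.frame_interval_s
        if self.mode == "image" and interval is None:
            interval = self.image_frame_interval_s
        if interval is not None:
            proto = dataclasses.replace(proto, frame_interval_s=interval)
        return proto

    def resolve_preset(self, name: str) -> CohortPreset:
        if name in self.custom_presets:
            preset = self.custom_presets[name]
        elif name in COHORT_PRESETS:
            preset = COHORT_PRESETS[name]
        else:
            raise ValueError(f"unknown cohort preset {name!r}")
        if self.n_subjects is not None:
            preset = dataclasses.replace(preset, n_subjects=self.n_subjects)
        return preset


def _group_seed(base: int, index: int) -> int:
    return int((base * 1009 + 7919 * (index + 1)) % (2 ** 31))


def _stage(manifest: dict, name: str):
    """Context manager recording per-stage wall time in the manifest."""
    class _Ctx:
        def __enter__(self):
            log.info("stage %s: start", name)
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            manifest["stages"].append(
                {"name": name, "seconds": round(dt, 3),
                 "status": "failed" if exc_type else "ok"})
            if exc_type:
                log.error("stage %s failed after %.2fs: %s", name, dt, exc)
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
            log.info("stage %s: done in %.2fs", name, dt)
            return False

    return _Ctx()


def _image_mode_biomarkers(config: RunConfig, preset: CohortPreset,
                           protocol: PORHProtocol, seed: int,
                           out: Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full-physics path: phantom -> raw frames -> reconstruction ->
    segmentation -> layer profiles -> biomarkers, one subject at a time."""
    geometry = AcquisitionGeometry(step_fast_um=24.0)
    phantom = two_layer_phantom(seed=seed)
    ex, ey, ez = phantom.extent_mm()
    grid = ReconGrid(voxel_um=phantom.voxel_um, extent_mm=(ex, ey, ez))
    rng = np.random.default_rng(seed)
    cohort = generate_cohort(preset, protocol, noise_sd=0.0,
                             seed=seed, mode="profile",
                             layers=["SD", "RD"])  # draws the truths
    truths = cohort.truths
    operator = None
    rows = []
    for s_idx, sid in enumerate(truths["subject_id"].unique()):
        sub = truths[truths["subject_id"] == sid].set_index("layer")
        layer_params = {
            layer: HemodynamicParams(mvc_true=sub.loc[layer, "mvc_true"],
                                     hr_true=sub.loc[layer, "hr_true"],
                                     tp_true=sub.loc[layer, "tp_true"])
            for layer in ("SD", "RD")}
        times, frames = simulate_frame_sinograms(
            phantom, layer_params, protocol, geometry,
            noise_sd=config.image_noise_sd,
            seed=int(rng.integers(2 ** 31)))
        recon_frames = []
        for raw in frames:
            raw = bandpass(raw, raw.geometry.band_mhz)
            if operator is None:
                operator = make_beamform_operator(geometry, raw.positions_mm,
                                                  grid, raw.n_samples)
            recon_frames.append(beamform(raw, grid, operator=operator))
        surface = detect_surface(recon_frames[0])
        flat = [flatten(f, surface) for f in recon_frames]
        bounds = segment_layers(flat[0])
        profiles = layer_profile(flat, bounds, protocol, times_min=times,
                                 layers=config.layers, normalize=True)
        if config.save_frames and s_idx == 0:
            stack = np.stack([f.data[:, 0, :] for f in flat])
            save_tiff(out / f"{preset.name}_{sid}_frames.tif", stack,
                      params={"times_min": list(map(float, times)),
                              "bounds": bounds.to_dict()})
        for layer, prof in profiles.items():
            from .biomarkers import compute_biomarkers
            bm = compute_biomarkers(prof, peak_smooth_s=config.peak_smooth_s)
            rows.append({"subject_id": sid, "group": preset.name,
                         "layer": layer, "MVB": bm.mvb, "MVIC": bm.mvic,
                         "PIV": bm.piv, "MVC": bm.mvc, "HR_pct": bm.hr_pct,
                         "TP_min": bm.tp_min})
    return pd.DataFrame(rows), truths


def depth_lag_experiment(seed: int = 0, lag_s: float = 15.0,
                         frame_interval_s: float = 1.0,
                         noise_sd: float = 0.002,
                         n_depth_bins: int = 2) -> dict:
    """Image-level depth-resolved time-to-peak experiment.

    A two-layer phantom (vessels in the subpapillary and reticular dermal
    bands) is driven through the long PORH protocol with the deep layer's
    peak advanced by ``lag_s`` seconds (deeper vessels reach peak hyperemia
    earlier).  Every frame is simulated through the acoustic forward model,
    band-filtered and beamformed; the surface is detected and flattened,
    layers segmented, and time-to-peak computed per depth bin.  Returns the
    per-bin table and the superficial-minus-deep TP difference in seconds.
    """
    protocol = dataclasses.replace(LONG_PROTOCOL,
                                   frame_interval_s=frame_interval_s)
    geometry = AcquisitionGeometry(step_fast_um=24.0)
    phantom = two_layer_phantom(seed=seed)
    ex, ey, ez = phantom.extent_mm()
    grid = ReconGrid(voxel_um=phantom.voxel_um, extent_mm=(ex, ey, ez))
    base = dict(mvc_true=0.40, hr_true=0.18, tp_true=1.5)
    layer_params = {
        "SD": HemodynamicParams(**base),
        "RD": HemodynamicParams(**base, depth_tp_offset_s=-lag_s),
    }
    times, frames = simulate_frame_sinograms(phantom, layer_params, protocol,
                                             geometry, noise_sd=noise_sd,
                                             seed=seed)
    operator = None
    recon_frames = []
    for raw in frames:
        raw = bandpass(raw, raw.geometry.band_mhz)
        if operator is None:
            operator = make_beamform_operator(geometry, raw.positions_mm,
                                              grid, raw.n_samples)
        recon_frames.append(beamform(raw, grid, operator=operator))
    surface = detect_surface(recon_frames[0])
    flat = [flatten(f, surface) for f in recon_frames]
    bounds = segment_layers(flat[0])
    from .biomarkers import depth_resolved_tp
    extent = bounds.interval_um("DV")
    bin_um = (extent[1] - extent[0]) / n_depth_bins
    table = depth_resolved_tp(flat, bounds, bin_um, protocol, times_min=times)
    diff_s = float((table["tp_min"].iloc[0] - table["tp_min"].iloc[-1]) * 60.0)
    return {"table": table, "bounds": bounds, "lag_s": lag_s,
            "superficial_minus_deep_s": diff_s, "n_frames": len(times)}


def run_porh_pipeline(config: RunConfig) -> dict:
    """Run the configured pipeline end to end; returns the manifest.

    Writes per-group truths and biomarker tables, a group x layer x
    biomarker summary, pairwise group comparisons, and a manifest of stages,
    seeds and parameters to ``config.out_dir``.  Any stage failure aborts
    with a stage-named diagnostic; partial outputs are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    protocol = config.resolve_protocol()
    manifest: dict = {
        "version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()
                   if k != "custom_presets"},
        "protocol": dataclasses.asdict(protocol),
        "group_seeds": {},
        "stages": [],
    }

    tables, truth_tables = [], []
    for gi, name in enumerate(config.groups):
        gseed = _group_seed(config.seed, gi)
        manifest["group_seeds"][name] = gseed
        with _stage(manifest, f"cohort:{name}"):
            preset = config.resolve_preset(name)
            if config.mode == "profile":
                cohort = generate_cohort(preset, protocol,
                                         noise_sd=config.noise_sd, seed=gseed,
                                         mode="profile",
                                         layers=list(config.layers))
                table = biomarker_table(cohort.profiles, protocol,
                                        peak_smooth_s=config.peak_smooth_s,
                                        group=name)
                truths = cohort.truths
            elif config.mode == "image":
                table, truths = _image_mode_biomarkers(config, preset, protocol,
                                                       gseed, out)
            else:
                raise ValueError(f"unknown mode {config.mode!r}")
        truths = truths.assign(group=name)
        tables.append(table)
        truth_tables.append(truths)

    with _stage(manifest, "biomarker-tables"):
        biomarkers = pd.concat(tables, ignore_index=True)
        truths = pd.concat(truth_tables, ignore_index=True)
        biomarkers.to_csv(out / "biomarkers.csv", index=False,
                          float_format=CSV_FLOAT_FORMAT)
        truths.to_csv(out / "truths.csv", index=False,
                      float_format=CSV_FLOAT_FORMAT)
        summary = (biomarkers.groupby(["group", "layer"])[list(BIOMARKER_COLS)]
                   .agg(["mean", "std"]))
        summary.columns = ["_".join(c) for c in summary.columns]
        summary.reset_index().to_csv(out / "summary.csv", index=False,
                                     float_format=CSV_FLOAT_FORMAT)

    with _stage(manifest, "group-statistics"):
        comparisons = []
        for (ga, gb) in itertools.combinations(config.groups, 2):
            for layer in biomarkers["layer"].unique():
                for col in BIOMARKER_COLS:
                    a = biomarkers.query("group == @ga and layer == @layer")[col]
                    b = biomarkers.query("group == @gb and layer == @layer")[col]
                    if len(a) < 3 or len(b) < 3:
                        continue
                    cmp_ = compare_groups(a, b, alpha=config.alpha,
                                          labels=(ga, gb))
                    comparisons.append({"layer": layer, "biomarker": col,
                                        **cmp_.to_dict()})
        with open(out / "comparisons.json", "w") as f:
            json.dump(comparisons, f, indent=2, sort_keys=True)

    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, sort_keys=True)
    return manifest
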