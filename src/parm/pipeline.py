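"""End-to-end orchestration: simulate/load -> motion screen -> SVD filter ->
trail velocimetry -> pattern clustering -> per-pattern super-resolved
reconstruction -> vascular metrics.

Every run is driven by a :class:`RunConfig` (YAML round-trippable); the
resolved configuration, a structured log and all intermediate products are
written into the run directory, so any stage can be re-examined and the
whole run is reproducible bit-for-bit from the config alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, metrics, preprocess, reconstruction, synthetic, trail

logger = logging.getLogger("parm")
if not logger.handlers:
    _h = logging.StreamHandler()
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "report",
           "demo_config"]


@dataclass
class RunConfig:
    """Resolved parameters for one full pipeline run."""

    out_dir: str = "parm_run"
    input_path: str | None = None          # HDF5 sequence; None -> simulate
    rng_seed: int = 7
    # --- simulation (used when input_path is None)
    acquisition: dict = field(default_factory=dict)     # AcquisitionSpec kwargs
    streamlines: list = field(default_factory=list)     # StreamlineSpec kwargs
    # --- preprocessing
    motion_threshold: float = 0.8
    min_segment_len: int = 50
    svd_cutoff: int | str = "adaptive"
    svd_cutoff_high: int | None = None
    # --- trail velocimetry
    detect_threshold: float = 0.99
    gradient_sigma: float = 1.0
    window_sigma: float = 2.0
    time_scale: float = 1.0
    min_coherence: float = 0.5
    v_max: float | None = None
    # --- clustering
    k_max: int = 10
    # --- reconstruction
    srrf_ring_radius: float = 8.0
    srrf_magnification: int = 3
    srrf_ring_axes: int = 8
    srrf_temporal_mode: str = "mean"
    # --- metrics
    speed_bins: int = 32
    pv_ddof: int = 1
    vessel_threshold: float | str = "otsu"
    min_object_size: int = 10
    acquisition_id: str = "run"
    day: int | None = None

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls(**yaml.safe_load(text))

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    def srrf_params(self) -> reconstruction.SrrfParams:
        return reconstruction.SrrfParams(
            ring_radius=self.srrf_ring_radius,
            magnification=self.srrf_magnification,
            ring_axes=self.srrf_ring_axes,
            temporal_mode=self.srrf_temporal_mode)


def demo_config(out_dir: str = "parm_run", seed: int = 7) -> RunConfig:
    """Bundled three-streamline phantom: slow rightward, fast leftward and
    intermediate downward flow on the nominal 128x128 / 50 um / 500 Hz /
    1,500-frame acquisition with rank-2 tissue clutter."""
    return RunConfig(
        out_dir=out_dir,
        rng_seed=seed,
        acquisition=dict(frame_rate=500.0, n_frames=1500, pixel_size=0.05,
                         shape=(128, 128), psf_sigma=0.1, noise_sigma=0.01,
                         clutter_rank=2, clutter_amplitude=0.5, rng_seed=seed),
        streamlines=[
            dict(control_points=((0.5, 2.0), (5.9, 2.0)), speed=2.0,
                 mb_rate=20.0),
            dict(control_points=((5.9, 4.0), (0.5, 4.0)), speed=8.0,
                 mb_rate=20.0),
            dict(control_points=((3.2, 0.5), (3.2, 5.9)), speed=5.0,
                 mb_rate=20.0),
        ],
        svd_cutoff=2,
    )


@dataclass
class PipelineResult:
    config: RunConfig
    sequence: synthetic.CeusSequence
    motion: preprocess.MotionReport
    filtered: synthetic.CeusSequence
    points: trail.FeaturePointSet
    feature_space: clustering.FeatureSpace
    model: clustering.PatternModel
    per_pattern_maps: list
    composite_map: reconstruction.SuperResolvedMap
    sentinel: metrics.SentinelSplit
    metric_rows: pd.DataFrame
    ground_truth: synthetic.GroundTruth | None = None


def _stage(name, log):
    t0 = time.perf_counter()

    def done():
        dt = time.perf_counter() - t0
        log[name] = round(dt, 3)
        logger.info("stage %-12s %.2fs", name, dt)
    return done


def run_pipeline(config: RunConfig, write_outputs: bool = True
                 ) -> PipelineResult:
    """Execute every stage in order and write the run directory.

    Outputs: ``config.yaml`` (resolved), ``model.json``, ``points.csv``,
    ``metrics.csv``, per-pattern and composite/sentinel maps as 32-bit
    TIFF, ``motion.json`` and ``log.json`` (versions, seed, timings,
    config hash).  Fully deterministic for a fixed config.
    """
    out = Path(config.out_dir)
    if config.input_path is not None and not Path(config.input_path).exists():
        raise FileNotFoundError(f"input not found: {config.input_path}")
    if write_outputs:
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.yaml").write_text(config.to_yaml())
    timings: dict = {}

    done = _stage("input", timings)
    ground_truth = None
    if config.input_path is None:
        acq = synthetic.AcquisitionSpec(**{
            **config.acquisition,
            "shape": tuple(config.acquisition.get("shape", (128, 128)))})
        specs = [synthetic.StreamlineSpec(**{
            **s, "control_points": tuple(tuple(p) for p in s["control_points"])})
            for s in config.streamlines]
        sim = synthetic.simulate(specs, acq)
        seq, ground_truth = sim.sequence, sim.ground_truth
    else:
        seq = synthetic.load_sequence_h5(config.input_path)
    done()

    done = _stage("motion", timings)
    motion = preprocess.screen_motion(seq, threshold=config.motion_threshold,
                                      min_segment_len=config.min_segment_len)
    if not motion.segments:
        raise RuntimeError("no usable segment after motion screening")
    done()

    # each retained segment is filtered and analyzed independently, then the
    # feature points are merged (velocimetry must not span a temporal gap)
    done = _stage("filter", timings)
    filtered_frames = np.zeros_like(seq.frames, dtype=np.float32)
    segment_sets = []
    for (a, b) in motion.segments:
        sub = seq.copy_with(seq.frames[a:b])
        filt, _ = preprocess.svd_filter(sub, cutoff=config.svd_cutoff,
                                        cutoff_high=config.svd_cutoff_high)
        filtered_frames[a:b] = filt.frames
    filtered = seq.copy_with(filtered_frames)
    done()

    done = _stage("features", timings)
    for (a, b) in motion.segments:
        stack = trail.build_stack(filtered, segment=(a, b),
                                  detect_threshold=config.detect_threshold)
        orient = trail.tensor_orientation(stack,
                                          gradient_sigma=config.gradient_sigma,
                                          window_sigma=config.window_sigma,
                                          time_scale=config.time_scale)
        try:
            pts = trail.extract_feature_points(
                stack, orient, v_max=config.v_max,
                min_coherence=config.min_coherence,
                time_scale=config.time_scale)
        except trail.EmptyFeatureSetError:
            continue
        segment_sets.append(pts)
    if not segment_sets:
        raise trail.EmptyFeatureSetError("no MB signal in any segment")
    points = trail.FeaturePointSet.concat(segment_sets) \
        if len(segment_sets) > 1 else segment_sets[0]
    n_clipped = int(points.clipped.sum())
    if n_clipped < len(points):
        points = points.without_clipped()   # distorted-sample rejection
    logger.info("dropped %d clipped samples, %d feature points remain",
                n_clipped, len(points))
    done()

    done = _stage("cluster", timings)
    space = clustering.build_feature_space(points)
    model = clustering.adaptive_kmeans(space, k_max=config.k_max,
                                       seed=config.rng_seed)
    done()

    done = _stage("reconstruct", timings)
    subseqs = clustering.split_sequence(filtered, points, model)
    params = config.srrf_params()
    per_maps = [reconstruction.srrf_reconstruct(sub, params, pattern_index=k + 1)
                for k, sub in enumerate(subseqs)]
    composite = reconstruction.SuperResolvedMap(
        grid=np.maximum.reduce([m.grid for m in per_maps]),
        pattern_index="composite", pixel_size=per_maps[0].pixel_size,
        provenance={"composite_of": list(range(1, model.K + 1))})
    sentinel = metrics.sentinel_split(model, per_maps, points)
    done()

    done = _stage("metrics", timings)
    het = metrics.heterogeneity(model, ddof=config.pv_ddof)
    rows = []

    def add_row(srmap, compartment, fps):
        graph = metrics.build_vessel_graph(
            srmap, threshold=config.vessel_threshold,
            min_object_size=config.min_object_size)
        struct = metrics.structural_metrics(graph)
        func = metrics.functional_metrics(fps, speed_bins=config.speed_bins) \
            if fps is not None and len(fps) else None
        rows.append(metrics.MetricSet(
            heterogeneity=het if compartment == "whole" else None,
            structural=struct, functional=func, compartment=compartment,
            acquisition_id=config.acquisition_id, day=config.day).to_row())

    add_row(composite, "whole", points)
    for k in range(1, model.K + 1):
        sel = model.labels == k
        sub_pts = _subset_points(points, sel)
        add_row(per_maps[k - 1], f"pattern-{k}", sub_pts)
    add_row(sentinel.sentinel_map, "sentinel",
            _subset_points(points, model.labels == sentinel.sentinel_index))
    add_row(sentinel.non_sentinel_map, "non-sentinel",
            _subset_points(points, model.labels != sentinel.sentinel_index))
    table = pd.DataFrame(rows)
    done()

    if write_outputs:
        (out / "motion.json").write_text(motion.to_json())
        model.save(out / "model.json")
        points.to_csv(out / "points.csv")
        table.to_csv(out / "metrics.csv", index=False, float_format="%.10g")
        for m in per_maps:
            m.save(out / f"map_pattern_{m.pattern_index}.tif")
        composite.save(out / "map_composite.tif")
        sentinel.sentinel_map.save(out / "map_sentinel.tif")
        sentinel.non_sentinel_map.save(out / "map_non_sentinel.tif")
        log = {"seed": config.rng_seed, "config_hash": config.config_hash(),
               "numpy": np.__version__, "timings_s": timings,
               "n_feature_points": int(len(points)), "K": int(model.K),
               "sentinel_pattern": int(sentinel.sentinel_index)}
        (out / "log.json").write_text(json.dumps(log, indent=2))

    return PipelineResult(config=config, sequence=seq, motion=motion,
                          filtered=filtered, points=points,
                          feature_space=space, model=model,
                          per_pattern_maps=per_maps, composite_map=composite,
                          sentinel=sentinel, metric_rows=table,
                          ground_truth=ground_truth)


def _subset_points(points: trail.FeaturePointSet, sel: np.ndarray
                   ) -> trail.FeaturePointSet | None:
    return points.select(sel) if np.any(sel) else None


# --------------------------------------------------------------------------
# report
# --------------------------------------------------------------------------

def report(run_dir: str) -> Path:
    """Render a human-readable summary of a completed run.

    Writes ``report.md`` plus PNG panels: per-pattern maps, the composite
    and sentinel maps, and the feature-space scatter colored by pattern.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import tifffile

    run = Path(run_dir)
    table = pd.read_csv(run / "metrics.csv")
    model = json.loads((run / "model.json").read_text())
    pts = pd.read_csv(run / "points.csv")

    k = model["K"]
    maps = []
    for i in range(1, k + 1):
        maps.append(("pattern %d" % i,
                     tifffile.imread(run / f"map_pattern_{i}.tif")))
    maps.append(("composite", tifffile.imread(run / "map_composite.tif")))
    sent = tifffile.imread(run / "map_sentinel.tif")
    if sent.max() > 0:
        maps.append(("sentinel", sent))

    ncol = min(len(maps), 3)
    nrow = int(np.ceil(len(maps) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 4 * nrow),
                             squeeze=False)
    for ax, (title, grid) in zip(axes.ravel(), maps):
        ax.imshow(grid, cmap="inferno")
        ax.set_title(title)
        ax.axis("off")
    for ax in axes.ravel()[len(maps):]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(run / "maps.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    sc = ax.scatter(pts["speed"], np.degrees(pts["direction"]),
                    c=pts["speed"], s=2, cmap="viridis")
    ax.set_xlabel("speed (mm/s)")
    ax.set_ylabel("direction (deg)")
    fig.colorbar(sc, ax=ax, label="speed (mm/s)")
    fig.tight_layout()
    fig.savefig(run / "feature_space.png", dpi=120)
    plt.close(fig)

    md = ["# PARM run report", "",
          f"Patterns (PC): {k}", "",
          "![maps](maps.png)", "",
          "![feature space](feature_space.png)", "",
          "## Metrics", "", "```", table.to_string(index=False), "```"]
    path = run / "report.md"
    path.write_text("\n".join(md))
    return path
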