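"""End-to-end synthetic pipeline: simulate → pick → classify → measure.

``run_pipeline`` exercises every stage of the package on a synthetic
scene derived deterministically from the config seed, and writes CSV
summaries (each stamped with the seed and config hash) plus MRC/STAR
intermediates into the output directory.  It is the one-command smoke
test of the whole package and the engine behind ``kerafil report``.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import backmap, helix, persistence, profiles, segments, simulate, xsection
from .core import Image2D, ParticleTable, PipelineConfig, Volume
from .mrc import write_mrc
from .star import write_particles

__all__ = ["run_pipeline", "load_config", "build_synthetic_scene",
           "read_contours_csv", "write_contours_csv"]


def load_config(path: str | Path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig(**data)


def read_contours_csv(path: str | Path) -> dict[int, persistence.Contour]:
    """Read traced contours from CSV columns (contour_id, x_nm, y_nm)."""
    df = pd.read_csv(path, comment="#")
    out = {}
    for cid, grp in df.groupby("contour_id"):
        out[int(cid)] = persistence.Contour.from_points(
            grp[["x_nm", "y_nm"]].to_numpy())
    return out


def write_contours_csv(contours: dict[int, persistence.Contour],
                       path: str | Path) -> None:
    frames = [
        pd.DataFrame({"contour_id": cid, "x_nm": c.points[:, 0],
                      "y_nm": c.points[:, 1]})
        for cid, c in contours.items()
    ]
    pd.concat(frames).to_csv(path, index=False, float_format="%.6f")


def _write_csv(df: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    buf = io.StringIO()
    buf.write(f"# seed={config.seed} config={config.config_hash()}\n")
    df.to_csv(buf, index=False, float_format="%.6f")
    path.write_text(buf.getvalue())


def build_synthetic_scene(config: PipelineConfig):
    """Deterministic three-filament scene: a flat 163 Å-pitch filament of
    typical diameter, a gently bent 150 Å filament, and a wide (13.2 nm)
    filament whose weaker modulation classifies as straight."""
    size = max(2 * config.box_px, 480)
    margin = 30
    specs = [
        simulate.FilamentSpec(
            pitch_A=163.0, diameter_nm=10.1, seed=config.seed,
            contour=simulate.line_contour((size / 2 - 80, margin),
                                          (size / 2 - 80, size - margin))),
        simulate.FilamentSpec(
            pitch_A=150.0, diameter_nm=10.1, seed=config.seed + 1,
            contour=persistence.Contour.from_points(np.column_stack([
                size / 2 + 40 + 25 * np.sin(np.linspace(0, np.pi,
                                                        40)),
                np.linspace(margin, size - margin, 40)]))),
        simulate.FilamentSpec(
            pitch_A=163.0, diameter_nm=13.2, modulation=0.0,
            seed=config.seed + 2,
            contour=simulate.line_contour((margin, size / 2 + 150),
                                          (size - margin, size / 2 + 150))),
    ]
    micrograph, table = simulate.generate_micrograph(
        specs, size, config.pixel_size_A, noise_sigma=0.2, seed=config.seed,
        interbox_A=config.interbox_A)
    classes, class_map = simulate.generate_class_library(
        specs, config.box_px, config.pixel_size_A)
    for rec in table:
        rec.class_id = class_map[rec.tube_id]   # generating class is known
    library = {class_map[i]: classes[i] for i in range(len(specs))}
    return specs, micrograph, table, classes, library


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on the synthetic scene; returns result objects and
    writes summaries under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"config_hash": config.config_hash(), "seed": config.seed}

    specs, micrograph, table, classes, library = build_synthetic_scene(config)
    write_mrc(out / "micrograph.mrc", micrograph.pixels, config.pixel_size_A)
    write_particles(table, out / "particles.star")
    write_mrc(out / "classes.mrc",
              np.stack([c.pixels for c in classes]), config.pixel_size_A)
    with open(out / "specs.yaml", "w") as fh:
        yaml.safe_dump([{
            "pitch_A": s.pitch_A, "diameter_nm": s.diameter_nm,
            "modulation": s.modulation, "seed": s.seed} for s in specs], fh)

    # --- segments: extract every picked box ------------------------------
    stack = np.stack([
        segments.extract_segment(micrograph, rec, config.box_px).pixels
        for rec in table])
    write_mrc(out / "segments.mrc", stack, config.pixel_size_A)

    # --- profiles: per-class diameters, particle-weighted distribution ---
    counts = [sum(1 for r in table if r.class_id == cid)
              for cid in sorted(library)]
    rows = []
    for cid in sorted(library):
        prof = profiles.lateral_profile(library[cid])
        rows.append({"class_id": cid,
                     "diameter_nm": profiles.measure_diameter(prof),
                     "n_particles": counts[cid - 1]})
    diam_df = pd.DataFrame(rows)
    _write_csv(diam_df, out / "diameters.csv", config)
    dist = profiles.diameter_distribution(
        diam_df["diameter_nm"], diam_df["n_particles"], diam_df["class_id"])
    results["diameter_distribution"] = dist

    # --- helix: pitch, labels, tilt curve --------------------------------
    labels: dict[int, helix.PatternLabel] = {}
    rows = []
    for cid in sorted(library):
        lab = helix.classify_pattern(library[cid], config, class_id=cid)
        labels[cid] = lab
        rows.append({"class_id": cid,
                     "pitch_A": lab.pitch_A if lab.pitch_A is not None
                     else np.nan,
                     "prominence": lab.prominence, "label": lab.label})
    _write_csv(pd.DataFrame(rows), out / "pitch.csv", config)
    sequences = helix.order_patterns(table, labels)
    _write_csv(pd.DataFrame([
        {"tube_id": s.tube_id, "segment_index": i, "label": lab}
        for s in sequences for i, lab in s.entries]),
        out / "pattern_order.csv", config)
    curve = helix.apparent_pitch_curve(
        163.0, np.arange(0, 51, 10), box_px=config.box_px,
        pixel_size_A=config.pixel_size_A,
        min_lag_A=config.acf_min_lag_A,
        prominence_threshold=config.acf_prominence)
    _write_csv(pd.DataFrame(curve, columns=["theta_deg", "apparent_pitch_A"]),
               out / "apparent_pitch_curve.csv", config)
    results["labels"] = labels
    results["pattern_sequences"] = sequences

    # --- backmap: reconstitute and straighten tube 0 ---------------------
    # per-segment classes (phase-faithful, as 2D classification separates
    # segments of different helical phase); the clean micrograph stands in
    # for the class-averaging denoising
    clean_mic, clean_table = simulate.generate_micrograph(
        specs, micrograph.shape[0], config.pixel_size_A, noise_sigma=0.0,
        interbox_A=config.interbox_A)
    seg_library = simulate.generate_segment_class_library(
        clean_mic, clean_table, config.box_px)
    recon = backmap.compose_reconstitution(
        clean_table, seg_library, micrograph.shape[0],
        mask_width_A=config.mask_width_A, interbox_A=config.interbox_A)
    write_mrc(out / "reconstituted.mrc", recon.image.pixels,
              config.pixel_size_A)
    write_mrc(out / "coverage.mrc", recon.coverage.astype(np.float32),
              config.pixel_size_A)
    contour0 = backmap.fit_contour(clean_table.by_tube(0))
    straightened = backmap.straighten(recon.image, contour0,
                                     width_A=config.mask_width_A)
    write_mrc(out / "straightened_tube0.mrc", straightened.image.pixels,
              config.pixel_size_A)
    results["reconstitution"] = recon

    # --- persistence: worm-like-chain ensemble ---------------------------
    contours = {
        i: simulate.generate_wlc_contour(300.0, 600.0, 5.0,
                                         seed=config.seed * 1000 + i)
        for i in range(80)
    }
    l90s = {i: persistence.min_apparent_persistence_length(c)
            for i, c in contours.items()}
    stats = persistence.population_stats(list(l90s.values()))
    _write_csv(pd.DataFrame([
        {"contour_id": i, "length_nm": contours[i].length,
         "L90_nm": l90s[i] if l90s[i] is not None else np.nan}
        for i in contours]), out / "persistence.csv", config)
    _write_csv(pd.DataFrame([{
        "mean_nm": stats.mean_nm, "sd_nm": stats.sd_nm, "n": stats.n}]),
        out / "persistence_summary.csv", config)
    results["persistence"] = stats

    # --- cross-sections: slab series, counts, core positions -------------
    rng = np.random.default_rng(config.seed + 99)
    n_z = int(round(420.0 / config.pixel_size_A))     # 42 nm of filament
    xs_box = 64
    vol = np.empty((n_z, xs_box, xs_box))
    offsets = rng.uniform(-1.0, 1.0, size=(10, 2)) * np.array([1.0, 0.0])
    for z in range(n_z):
        k = min(int(z / (n_z / 10)), 9)
        spec = simulate.CrossSectionSpec(
            core_offset_nm=tuple(offsets[k]), noise_sigma=0.1,
            seed=config.seed * 100 + z)
        vol[z] = simulate.generate_cross_section(
            spec, xs_box, config.pixel_size_A).pixels
    series = xsection.slab_project(Volume(vol, config.pixel_size_A),
                                   config.slab_thickness_nm)
    rows = []
    for i, sl in enumerate(series.slices):
        cnt = xsection.count_protofilaments(sl)
        off = xsection.core_offset(sl)
        rows.append({
            "slice_index": i,
            "n_protofilaments": cnt.n_detected if cnt.n_detected else np.nan,
            "offset_x_nm": off.offset_nm[0] if off.offset_nm else np.nan,
            "offset_y_nm": off.offset_nm[1] if off.offset_nm else np.nan,
        })
    _write_csv(pd.DataFrame(rows), out / "xsection.csv", config)
    results["xsection_series"] = series
    return results
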