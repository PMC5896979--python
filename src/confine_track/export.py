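"""Result export (CSV/JSON) and verification-overlay rendering."""

from __future__ import annotations

from pathlib import Path

from .pipeline import ResultsBundle
from .rupture import mitoses_to_frame, ruptures_to_frame
from .tracking import tracks_to_frame
from .transit import transits_to_frame


def export_results(bundle: ResultsBundle, out_dir) -> dict[str, Path]:
    """Write tracks.csv, transits.csv, ruptures.csv, mitoses.csv, drift.csv
    and geometry.json with stable column order (UTF-8, deterministic)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "tracks": out / "tracks.csv",
        "transits": out / "transits.csv",
        "ruptures": out / "ruptures.csv",
        "mitoses": out / "mitoses.csv",
        "drift": out / "drift.csv",
        "geometry": out / "geometry.json",
    }
    tracks_to_frame(bundle.tracks).to_csv(paths["tracks"], index=False)
    transits_to_frame(bundle.transits).to_csv(paths["transits"], index=False)
    ruptures_to_frame(bundle.ruptures).to_csv(paths["ruptures"], index=False)
    mitoses_to_frame(bundle.mitoses).to_csv(paths["mitoses"], index=False)
    bundle.drift.to_frame().to_csv(paths["drift"], index=False)
    bundle.geometry.to_json(paths["geometry"])
    return paths


def render_overlay(
    bundle: ResultsBundle,
    out_dir,
    trail_window_min: float = 360.0,
    dpi: int = 100,
) -> list[Path]:
    """Write one annotated PNG per frame for manual verification.

    Each frame shows the chromatin channel with row boundary lines, track
    ids, centroid trails (capped to the last ``trail_window_min`` minutes),
    an R marker at rupture starts and a D marker at divisions. Purely
    presentational; no analysis reads these files.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seq = bundle.sequence
    marker = seq.channel("nuclear_marker")
    trail_frames = max(int(trail_window_min / seq.frame_interval_min), 1)
    rupture_starts = {(e.track_id, e.start_frame) for e in bundle.ruptures}
    divisions = {(m.parent_track_id, m.division_frame) for m in bundle.mitoses}
    vmin, vmax = float(marker.min()), float(marker.max())
    paths = []
    for t in range(seq.n_frames):
        fig, ax = plt.subplots(figsize=(seq.shape[3] / dpi, seq.shape[2] / dpi), dpi=dpi)
        ax.imshow(marker[t], cmap="gray", vmin=vmin, vmax=vmax)
        for row in bundle.geometry.rows:
            ax.axhline(row.upper_boundary_y, color="deepskyblue", lw=0.8, ls="--")
            ax.axhline(row.lower_boundary_y, color="deepskyblue", lw=0.8, ls="--")
        for tr in bundle.tracks:
            if t not in tr.observations:
                continue
            obs = tr.observations[t]
            xs = [
                tr.observations[f].centroid_x
                for f in tr.frames
                if t - trail_frames <= f <= t
            ]
            ys = [
                tr.observations[f].centroid_y
                for f in tr.frames
                if t - trail_frames <= f <= t
            ]
            ax.plot(xs, ys, color="yellow", lw=0.8)
            ax.text(obs.centroid_x + 3, obs.centroid_y - 3, str(tr.track_id),
                    color="orange", fontsize=6)
            if (tr.track_id, t) in rupture_starts:
                ax.text(obs.centroid_x, obs.centroid_y, "R", color="red",
                        fontsize=9, fontweight="bold")
            if (tr.track_id, t) in divisions:
                ax.text(obs.centroid_x, obs.centroid_y, "D", color="cyan",
                        fontsize=9, fontweight="bold")
        ax.set_axis_off()
        ax.set_xlim(0, seq.shape[3])
        ax.set_ylim(seq.shape[2], 0)
        path = out / f"overlay_{t:04d}.png"
        fig.savefig(path, bbox_inches="tight", pad_inches=0)
        plt.close(fig)
        paths.append(path)
    return paths
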