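"""Batch and watch-mode orchestration of the monitoring loop.

Ingests per-time-point image sets from a directory (either through the
generator's ``manifest.json`` or by scanning a
``<dish>/<fov>/frame_<k>`` layout), segments every field of view,
averages the per-FOV confluencies, updates the sliding-window fit and
4-h forecast, tracks forecast-error variance, feeds the notifier and
writes ``confluency.csv``, ``predictions.csv``, ``events.log``,
``state.json``, final-frame overlay PNGs and a static ``report.png``.

All timestamps derive from frame_index x frame_interval_min (the
nominal acquisition clock), never from file mtimes.  Missing or
unreadable FOVs are logged and skipped; the average is taken over the
FOVs actually present.
"""
from __future__ import annotations

import json
import logging
import re
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from .frames import load_frame, save_rgb
from .notification import (Dispatcher, LogFileChannel, MonitorConfig,
                           NotificationMonitor, event_to_dict)
from .prediction import (PredictionState, fit_growth_model, forecast,
                         time_to_threshold, ConfluencySeries)
from .segmentation import SegmentationParams, render_overlay, segment_frame

log = logging.getLogger("cellwatch.pipeline")

_FRAME_RE = re.compile(r"frame_(\d+)\.(png|tif|tiff)$")


@dataclass
class RunManifest:
    """Resolved inputs and configuration of one monitoring run."""

    run_id: str
    frames: dict  # frame index -> list of {"file","fov_id","dish_id"}
    root: Path
    out_dir: Path
    monitor: MonitorConfig = field(default_factory=MonitorConfig)
    seg: SegmentationParams = field(default_factory=SegmentationParams)
    min_fit_points: int = 10

    @classmethod
    def from_manifest_json(cls, manifest_path: str | Path, out_dir: str | Path,
                           monitor: MonitorConfig | None = None,
                           seg: SegmentationParams | None = None) -> "RunManifest":
        manifest_path = Path(manifest_path)
        data = json.loads(manifest_path.read_text())
        interval = float(data.get("frame_interval_min", 5.0))
        monitor = monitor or MonitorConfig(frame_interval_min=interval)
        frames = {int(k): v for k, v in data["frames"].items()}
        return cls(run_id=data.get("run_id", manifest_path.parent.name),
                   frames=frames, root=manifest_path.parent, out_dir=Path(out_dir),
                   monitor=monitor, seg=seg or SegmentationParams())

    @classmethod
    def from_directory(cls, root: str | Path, out_dir: str | Path,
                       monitor: MonitorConfig | None = None,
                       seg: SegmentationParams | None = None) -> "RunManifest":
        """Scan a ``<root>/<dish>/<fov>/frame_<k>.(png|tif)`` tree."""
        root = Path(root)
        frames: dict[int, list[dict]] = {}
        for path in sorted(root.glob("*/*/frame_*")):
            m = _FRAME_RE.search(path.name)
            if not m:
                continue
            k = int(m.group(1))
            frames.setdefault(k, []).append({
                "file": str(path.relative_to(root)),
                "fov_id": path.parent.name,
                "dish_id": path.parent.parent.name,
            })
        return cls(run_id=root.name, frames=frames, root=root, out_dir=Path(out_dir),
                   monitor=monitor or MonitorConfig(), seg=seg or SegmentationParams())


class _RunProcessor:
    """Incremental per-time-point processing shared by batch and watch modes."""

    def __init__(self, manifest: RunManifest) -> None:
        self.m = manifest
        self.out = manifest.out_dir
        self.out.mkdir(parents=True, exist_ok=True)
        cfg = manifest.monitor
        self.h = int(round(cfg.horizon_min / cfg.frame_interval_min))
        self.monitor = NotificationMonitor(cfg)
        self.dispatcher = Dispatcher(manifest.run_id,
                                     [LogFileChannel(self.out / "events.log")])
        self.pred_state = PredictionState()
        self.pending: dict[int, float] = {}
        self.conf_rows: list[dict] = []
        self.pred_rows: list[dict] = []
        self.events: list = []
        self.values: list[float] = []
        self.frame_ids: list[int] = []
        self.fov_ids = sorted({e["fov_id"] for entries in manifest.frames.values()
                               for e in entries})
        self.last_frames: dict[str, object] = {}  # fov_id -> (FrameImage, mask)

    def process_frame(self, k: int, entries: list[dict]) -> None:
        cfg = self.m.monitor
        now = k * cfg.frame_interval_min
        per_fov: dict[str, float] = {}
        for e in entries:
            path = self.m.root / e["file"]
            try:
                frame = load_frame(path, frame_index=k, fov_id=e["fov_id"],
                                   dish_id=e.get("dish_id", ""), timestamp_min=now)
            except Exception as exc:  # noqa: BLE001 - skip-and-continue contract
                log.warning("skipping unreadable FOV %s at frame %d: %s",
                            e["fov_id"], k, exc)
                continue
            mask, conf = segment_frame(frame, self.m.seg)
            per_fov[e["fov_id"]] = conf
            self.last_frames[e["fov_id"]] = (frame, mask)
        if not per_fov:
            log.warning("frame %d had no readable FOVs; skipped", k)
            return
        if len(per_fov) < cfg.fovs_per_timepoint:
            log.warning("frame %d: only %d of %d FOVs present; averaging those",
                        k, len(per_fov), cfg.fovs_per_timepoint)
        avg = float(np.mean(list(per_fov.values())))
        self.frame_ids.append(k)
        self.values.append(avg)
        pos = len(self.values) - 1

        if pos in self.pending:
            self.pred_state.update(avg, self.pending.pop(pos))

        fc = crossing = None
        if len(self.values) >= max(self.m.min_fit_points, 3):
            series = ConfluencySeries(np.asarray(self.frame_ids),
                                      np.asarray(self.frame_ids, dtype=float)
                                      * cfg.frame_interval_min,
                                      np.asarray(self.values),
                                      cfg.frame_interval_min)
            fit = fit_growth_model(series, window_frames=cfg.window_frames)
            fc = forecast(fit, now + cfg.horizon_min)
            self.pending[pos + self.h] = fc
            crossing = time_to_threshold(fit, cfg.threshold, now, cfg.horizon_min)

        row = {"frame": k, "time_min": now}
        row.update({f: per_fov.get(f, np.nan) for f in self.fov_ids})
        row["average"] = avg
        self.conf_rows.append(row)
        self.pred_rows.append({
            "frame": k, "time_min": now, "forecast_4h": fc,
            "predicted_crossing_min": crossing,
            "variance": self.pred_state.variance,
        })
        for event in self.monitor.update(k, now, avg, crossing):
            self.events.append(event)
            self.dispatcher.dispatch(event)

    def finalize(self) -> dict:
        if not self.conf_rows:
            raise RuntimeError("zero complete time points; nothing processed")
        conf_csv = self.out / "confluency.csv"
        pred_csv = self.out / "predictions.csv"
        pd.DataFrame(self.conf_rows).to_csv(conf_csv, index=False)
        pd.DataFrame(self.pred_rows).to_csv(pred_csv, index=False)
        (self.out / "events.log").touch()
        state = {"run_id": self.m.run_id, "monitor": self.monitor.to_dict(),
                 "dispatcher": self.dispatcher.to_dict(),
                 "frames_processed": len(self.conf_rows),
                 "events": [event_to_dict(e) for e in self.events]}
        (self.out / "state.json").write_text(json.dumps(state, indent=1, sort_keys=True))
        overlay_dir = self.out / "overlays"
        overlay_dir.mkdir(exist_ok=True)
        for fov_id, (frame, mask) in sorted(self.last_frames.items()):
            save_rgb(overlay_dir / f"{fov_id}.png", render_overlay(frame, mask))
        return {"confluency_csv": conf_csv, "predictions_csv": pred_csv,
                "events_log": self.out / "events.log",
                "state_json": self.out / "state.json",
                "overlay_dir": overlay_dir, "events": list(self.events),
                "n_frames": len(self.conf_rows)}


def run_batch(manifest: RunManifest) -> dict:
    """Process every time point of the manifest in frame order."""
    proc = _RunProcessor(manifest)
    for k in sorted(manifest.frames):
        proc.process_frame(k, manifest.frames[k])
    return proc.finalize()


def run_watch(root: str | Path, out_dir: str | Path,
              monitor: MonitorConfig | None = None,
              seg: SegmentationParams | None = None,
              poll_seconds: float = 1.0, idle_polls: int = 3) -> dict:
    """Streaming mode: process time points as files appear under ``root``.

    A frame is considered complete once a later frame exists on disk
    (new data keeps arriving) or once the directory has been idle for
    ``idle_polls`` consecutive polls, at which point all remaining
    frames — complete or partial — are flushed.  Produces outputs
    identical to :func:`run_batch` on the same final file set.
    """
    root = Path(root)
    if not root.exists():
        raise FileNotFoundError(root)
    manifest = RunManifest.from_directory(root, out_dir, monitor, seg)
    proc = _RunProcessor(manifest)
    processed: set[int] = set()
    idle = 0
    while idle < idle_polls:
        current = RunManifest.from_directory(root, out_dir, monitor, seg)
        proc.m.frames = current.frames
        known = sorted(current.frames)
        new = [k for k in known[:-1] if k not in processed] if len(known) > 1 else []
        if new:
            idle = 0
            for k in new:
                proc.process_frame(k, current.frames[k])
                processed.add(k)
        else:
            idle += 1
            if idle < idle_polls:
                _time.sleep(poll_seconds)
    # flush the trailing frames once the stream has gone quiet
    current = RunManifest.from_directory(root, out_dir, monitor, seg)
    for k in sorted(current.frames):
        if k not in processed:
            proc.process_frame(k, current.frames[k])
            processed.add(k)
    return proc.finalize()


def report(out_dir: str | Path) -> dict:
    """Static report: confluency + forecasts + threshold + event markers,
    with a thumbnail strip of the latest per-FOV overlays below."""
    out_dir = Path(out_dir)
    conf_csv = out_dir / "confluency.csv"
    if not conf_csv.exists():
        raise FileNotFoundError(conf_csv)
    conf = pd.read_csv(conf_csv)
    preds = pd.read_csv(out_dir / "predictions.csv")
    events = []
    state_path = out_dir / "state.json"
    if state_path.exists():
        events = json.loads(state_path.read_text()).get("events", [])
    overlay_paths = sorted((out_dir / "overlays").glob("*.png")) \
        if (out_dir / "overlays").exists() else []

    n_thumbs = min(len(overlay_paths), 6)
    fig = plt.figure(figsize=(9, 6 if n_thumbs else 4.5))
    gs = fig.add_gridspec(2 if n_thumbs else 1, max(n_thumbs, 1),
                          height_ratios=[3, 1] if n_thumbs else [1])
    ax = fig.add_subplot(gs[0, :])
    ax.plot(conf["time_min"], conf["average"], color="crimson", lw=1.5,
            label="measured confluency")
    valid = preds.dropna(subset=["forecast_4h"])
    if len(valid):
        ax.plot(valid["time_min"] + 240.0, valid["forecast_4h"], color="steelblue",
                lw=1.0, ls="--", label="4-h forecast")
    ax.axhline(0.5, color="gray", lw=0.8, label="threshold")
    for ev in events:
        ax.axvline(ev["time_min"], color="black", ls=":", lw=1.0)
        ax.annotate(ev["kind"], (ev["time_min"], 0.95), rotation=90,
                    fontsize=7, ha="right", va="top")
    ax.set_xlabel("time (min)")
    ax.set_ylabel("confluency")
    ax.set_ylim(0, 1)
    ax.legend(loc="upper left", fontsize=8)
    for i in range(n_thumbs):
        axt = fig.add_subplot(gs[1, i])
        axt.imshow(plt.imread(overlay_paths[i]))
        axt.set_title(overlay_paths[i].stem, fontsize=7)
        axt.axis("off")
    fig.tight_layout()
    out_png = out_dir / "report.png"
    fig.savefig(out_png, dpi=110)
    plt.close(fig)
    return {"report_png": out_png, "n_points": len(conf),
            "n_events": len(events), "n_thumbnails": n_thumbs}


def load_run_config(path: str | Path) -> dict:
    """Parse the YAML run config into typed parameter objects.

    Recognized sections: ``segmentation`` (SegmentationParams fields),
    ``notify``/``prediction`` (MonitorConfig fields, merged), ``io``
    (free-form, returned as-is) and ``expansion`` (free-form).
    """
    data = yaml.safe_load(Path(path).read_text()) or {}
    seg = SegmentationParams(**data.get("segmentation", {}))
    mon_kwargs = {}
    mon_kwargs.update(data.get("prediction", {}))
    mon_kwargs.update(data.get("notify", {}))
    monitor = MonitorConfig(**mon_kwargs)
    return {"segmentation": seg, "monitor": monitor,
            "io": data.get("io", {}), "expansion": data.get("expansion", {})}
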