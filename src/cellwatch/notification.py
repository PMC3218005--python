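"""Advance and threshold-reached alerting for a monitored culture run.

Two one-shot events per run: a PRE_ALERT when the predicted
threshold-crossing time first falls within the notice horizon (default
4 h) after the warm-up gate, and a THRESHOLD_REACHED reminder the first
time the measured average confluency itself meets the threshold.  Both
are at-most-once, survive process restarts through a JSON state file,
and are delivered through pluggable channels (an append-only log file
by default; an SMTP channel exists but is configuration-gated).
"""
from __future__ import annotations

import datetime as _dt
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

PRE_ALERT = "PRE_ALERT"
THRESHOLD_REACHED = "THRESHOLD_REACHED"


@dataclass(frozen=True)
class MonitorConfig:
    """Thresholds and cadence of the monitoring loop.

    ``min_frames`` is the warm-up gate: sliding-window forecasts are
    unreliable for roughly the first 200 frames of a run, so advance
    alerts are suppressed until then.
    """

    threshold: float = 0.5
    horizon_min: float = 240.0
    frame_interval_min: float = 5.0
    window_frames: int = 300
    min_frames: int = 200
    fovs_per_timepoint: int = 12

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold <= 1.0):
            raise ValueError("threshold must lie in (0, 1]")
        if self.horizon_min <= 0 or self.frame_interval_min <= 0:
            raise ValueError("horizon and frame interval must be positive")
        if abs(self.horizon_min / self.frame_interval_min
               - round(self.horizon_min / self.frame_interval_min)) > 1e-9:
            raise ValueError("horizon_min must be a multiple of frame_interval_min")


@dataclass(frozen=True)
class NotificationEvent:
    kind: str
    frame_index: int
    time_min: float
    average_confluency: float
    predicted_crossing_time_min: float | None
    message: str


def _render_message(kind: str, frame_index: int, time_min: float,
                    avg: float, crossing: float | None) -> str:
    if kind == PRE_ALERT:
        return (f"Confluency threshold predicted in "
                f"{crossing - time_min:.0f} min (frame {frame_index}, "
                f"confluency {avg:.3f}); prepare for subculture.")
    return (f"Confluency threshold reached at frame {frame_index} "
            f"(t = {time_min:.0f} min, confluency {avg:.3f}).")


class NotificationMonitor:
    """One-shot event state machine for a single culture run."""

    def __init__(self, config: MonitorConfig | None = None) -> None:
        self.config = config or MonitorConfig()
        self._pre_sent = False
        self._threshold_sent = False
        self._last_frame: int | None = None

    def update(self, frame_index: int, now_min: float, avg_confluency: float,
               predicted_crossing_min: float | None = None) -> list[NotificationEvent]:
        """Feed one time point; returns newly emitted events (possibly empty)."""
        if self._last_frame is not None and frame_index <= self._last_frame:
            raise ValueError(f"out-of-order frame {frame_index} after {self._last_frame}")
        self._last_frame = frame_index
        if not (0.0 <= avg_confluency <= 1.0):
            raise ValueError("avg_confluency must lie in [0, 1]")
        cfg = self.config
        events: list[NotificationEvent] = []
        if (not self._pre_sent and not self._threshold_sent
                and frame_index >= cfg.min_frames
                and predicted_crossing_min is not None
                and predicted_crossing_min - now_min <= cfg.horizon_min):
            self._pre_sent = True
            events.append(NotificationEvent(
                PRE_ALERT, frame_index, now_min, avg_confluency,
                predicted_crossing_min,
                _render_message(PRE_ALERT, frame_index, now_min, avg_confluency,
                                predicted_crossing_min)))
        if not self._threshold_sent and avg_confluency >= cfg.threshold:
            self._threshold_sent = True
            # a reached threshold makes any later advance alert moot
            self._pre_sent = True
            events.append(NotificationEvent(
                THRESHOLD_REACHED, frame_index, now_min, avg_confluency,
                predicted_crossing_min,
                _render_message(THRESHOLD_REACHED, frame_index, now_min,
                                avg_confluency, predicted_crossing_min)))
        return events

    # -- persistence -----------------------------------------------------
    def to_dict(self) -> dict:
        return {"pre_sent": self._pre_sent, "threshold_sent": self._threshold_sent,
                "last_frame": self._last_frame}

    @classmethod
    def from_dict(cls, state: dict, config: MonitorConfig | None = None
                  ) -> "NotificationMonitor":
        mon = cls(config)
        mon._pre_sent = bool(state.get("pre_sent", False))
        mon._threshold_sent = bool(state.get("threshold_sent", False))
        mon._last_frame = state.get("last_frame")
        return mon

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path, config: MonitorConfig | None = None
             ) -> "NotificationMonitor":
        return cls.from_dict(json.loads(Path(path).read_text()), config)


# -- delivery channels ---------------------------------------------------

@dataclass
class DeliveryResult:
    channel: str
    ok: bool
    error: str = ""


@dataclass
class DeliveryReport:
    refused: bool
    results: list = field(default_factory=list)


class LogFileChannel:
    """Always-available channel appending one ISO-timestamped line per event."""

    name = "log"

    def __init__(self, path: str | Path) -> None:
        self.path = Path(path)

    def send(self, event: NotificationEvent) -> None:
        stamp = _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds")
        line = (f"{stamp}\t{event.kind}\tframe={event.frame_index}\t"
                f"t={event.time_min:.0f}min\tconfluency={event.average_confluency:.4f}\t"
                f"{event.message}\n")
        with open(self.path, "a") as fh:
            fh.write(line)


class SmtpChannel:
    """Email delivery stub; inert unless a host is configured.

    Deliberately not exercised anywhere in the test suite: it exists so
    a deployment can point it at a real SMTP relay via the YAML config.
    """

    name = "smtp"

    def __init__(self, host: str = "", port: int = 587, sender: str = "",
                 recipients: tuple[str, ...] = ()) -> None:
        self.host, self.port, self.sender, self.recipients = host, port, sender, recipients

    def send(self, event: NotificationEvent) -> None:
        if not self.host:
            raise RuntimeError("SMTP channel not configured (no host)")
        import smtplib
        from email.message import EmailMessage
        msg = EmailMessage()
        msg["Subject"] = f"[cellwatch] {event.kind}"
        msg["From"] = self.sender
        msg["To"] = ", ".join(self.recipients)
        msg.set_content(event.message)
        with smtplib.SMTP(self.host, self.port) as smtp:
            smtp.send_message(msg)


class Dispatcher:
    """Fans an event out to all channels, at most once per (run, kind).

    Per-channel failures are reported, never raised, so one broken
    channel cannot stall a long-running monitor.
    """

    def __init__(self, run_id: str, channels: list) -> None:
        if not channels:
            raise ValueError("at least one delivery channel is required")
        self.run_id = run_id
        self.channels = channels
        self.sent_keys: set[str] = set()

    def dispatch(self, event: NotificationEvent) -> DeliveryReport:
        key = f"{self.run_id}:{event.kind}"
        if key in self.sent_keys:
            return DeliveryReport(refused=True)
        self.sent_keys.add(key)
        report = DeliveryReport(refused=False)
        for ch in self.channels:
            try:
                ch.send(event)
                report.results.append(DeliveryResult(ch.name, True))
            except Exception as exc:  # noqa: BLE001 - error isolation is the contract
                report.results.append(DeliveryResult(ch.name, False, str(exc)))
        return report

    def to_dict(self) -> dict:
        return {"run_id": self.run_id, "sent_keys": sorted(self.sent_keys)}

    def restore_keys(self, state: dict) -> None:
        if state.get("run_id") == self.run_id:
            self.sent_keys |= set(state.get("sent_keys", []))


def event_to_dict(event: NotificationEvent) -> dict:
    return asdict(event)
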