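"""Experiment protocol annotations: ordered, labelled time epochs.

A protocol describes the perfusion/stimulation timeline of an optic-nerve
experiment: a baseline period, optionally a stimulation ramp (stepwise
increasing frequency), glucose deprivation (GD), reperfusion, and the
terminal mitochondrial-blockade + glucose-deprivation (MB+GD) period that
defines the zero anchor of the ATP signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterator

import numpy as np

__all__ = [
    "Epoch",
    "ProtocolSpec",
    "EPOCH_LABELS",
    "standard_gd_protocol",
    "ramp_protocol",
]

EPOCH_LABELS = ("baseline", "GD", "reperfusion", "MBGD", "stim_step")


@dataclass(frozen=True)
class Epoch:
    """One protocol epoch: label, [start, end) in seconds, optional payload
    (e.g. stimulation frequency in Hz for ``stim_step`` epochs)."""

    label: str
    start: float
    end: float
    payload: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in EPOCH_LABELS:
            raise ValueError(f"unknown epoch label {self.label!r}")
        if not self.end > self.start:
            raise ValueError("epoch end must be after start")

    @property
    def duration(self) -> float:
        return self.end - self.start

    def contains(self, time: np.ndarray) -> np.ndarray:
        """Boolean mask of samples inside [start, end)."""
        time = np.asarray(time, dtype=float)
        return (time >= self.start) & (time < self.end)


@dataclass
class ProtocolSpec:
    """Ordered, non-overlapping epochs; exactly one baseline, first."""

    epochs: list[Epoch]

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("protocol must contain at least one epoch")
        baselines = [e for e in self.epochs if e.label == "baseline"]
        if len(baselines) != 1:
            raise ValueError("protocol must contain exactly one baseline epoch")
        ordered = sorted(self.epochs, key=lambda e: e.start)
        for a, b in zip(ordered, ordered[1:]):
            if b.start < a.end - 1e-9:
                raise ValueError(f"epochs {a.label} and {b.label} overlap")
        if ordered[0].label != "baseline":
            raise ValueError("the baseline epoch must precede all others")
        self.epochs = ordered

    def __iter__(self) -> Iterator[Epoch]:
        return iter(self.epochs)

    @property
    def baseline(self) -> Epoch:
        return next(e for e in self.epochs if e.label == "baseline")

    def by_label(self, label: str) -> list[Epoch]:
        return [e for e in self.epochs if e.label == label]

    def single(self, label: str) -> Epoch:
        matches = self.by_label(label)
        if len(matches) != 1:
            raise ValueError(f"expected exactly one {label!r} epoch, found {len(matches)}")
        return matches[0]

    @property
    def end(self) -> float:
        return max(e.end for e in self.epochs)

    def to_dict(self) -> list[dict[str, Any]]:
        return [
            {"label": e.label, "start": e.start, "end": e.end, "payload": dict(e.payload)}
            for e in self.epochs
        ]

    @classmethod
    def from_dict(cls, items: list[dict[str, Any]]) -> "ProtocolSpec":
        return cls([
            Epoch(d["label"], float(d["start"]), float(d["end"]), dict(d.get("payload", {})))
            for d in items
        ])


def standard_gd_protocol(
    baseline_min: float = 15.0,
    gd_min: float = 30.0,
    reperfusion_min: float = 45.0,
    mbgd_min: float = 15.0,
) -> ProtocolSpec:
    """Canonical GD/reperfusion timeline: baseline, 30 min GD, 45 min
    glucose reperfusion, terminal MB+GD anchor period."""
    t0 = 0.0
    t1 = baseline_min * 60
    t2 = t1 + gd_min * 60
    t3 = t2 + reperfusion_min * 60
    t4 = t3 + mbgd_min * 60
    return ProtocolSpec([
        Epoch("baseline", t0, t1),
        Epoch("GD", t1, t2),
        Epoch("reperfusion", t2, t3),
        Epoch("MBGD", t3, t4),
    ])


def ramp_protocol(
    baseline_min: float = 15.0,
    frequencies_hz: tuple[float, ...] = (1, 4, 7, 15, 25, 50, 75, 100),
    step_s: float = 30.0,
    recovery_min: float = 15.0,
    mbgd_min: float = 15.0,
) -> ProtocolSpec:
    """Stimulation ramp timeline: 30 s steps of increasing frequency."""
    epochs = [Epoch("baseline", 0.0, baseline_min * 60)]
    t = baseline_min * 60
    for f in frequencies_hz:
        epochs.append(Epoch("stim_step", t, t + step_s, {"frequency_hz": float(f)}))
        t += step_s
    epochs.append(Epoch("reperfusion", t, t + recovery_min * 60))
    t += recovery_min * 60
    epochs.append(Epoch("MBGD", t, t + mbgd_min * 60))
    return ProtocolSpec(epochs)
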