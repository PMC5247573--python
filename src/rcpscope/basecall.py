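"""Single-cycle sequencing-by-ligation base calling from channel intensities.

Each sequencing cycle stains every RCP in the colour coding the interrogated
base: A by Cy5, T by FITC, G by Cy3 and C by Texas red (or, in chemistry
variants without a fourth dye, by the absence of signal).  A common anchor
stain (Alexa750) marks all genuine RCPs regardless of base, so objects
without anchor signal are discarded.  Auto-fluorescent debris glows in
several channels at once; an object whose second-brightest base channel
exceeds 0.3 of its brightest (after local background subtraction) is
rejected as such rather than called.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

from .detect import DetectedObject

STATUS_ACCEPTED = "accepted"
STATUS_REJECTED_DOUBLE_STAIN = "rejected_double_stain"
STATUS_REJECTED_NO_ANCHOR = "rejected_no_anchor"
STATUS_NO_CALL = "no_call"

#: default double-stain rejection threshold (strictly above rejects)
DEFAULT_RATIO_THRESHOLD = 0.3


@dataclass(frozen=True)
class BaseCodingMap:
    """Channel-to-base coding for one sequencing cycle.

    ``blank_base`` (if set) is the base reported when no base channel shows
    signal — used by two-dye chemistries where one base is coded by absence
    of stain.  Disabled by default: most runs here are two-channel (Cy3/Cy5)
    and a dark object is more safely reported as ``no_call``.
    """

    base_channels: dict = field(
        default_factory=lambda: {"cy5": "A", "fitc": "T",
                                 "cy3": "G", "txred": "C"})
    anchor_channel: str = "anchor"
    blank_base: str | None = None

    def __post_init__(self) -> None:
        bases = list(self.base_channels.values())
        if len(bases) != len(set(bases)):
            raise ValueError("each base may be coded by at most one channel")
        if self.anchor_channel in self.base_channels:
            raise ValueError("anchor channel cannot also code a base")

    def channels_present(self, obj: DetectedObject) -> list[str]:
        return [ch for ch in self.base_channels if ch in obj.channel_stats]


@dataclass
class BaseCall:
    """Outcome of base calling for one object."""

    object_id: int
    called_base: str              # A/T/G/C or "no_call"
    status: str
    dominant_channel: str | None
    double_stain_ratio: float


def _background_subtracted_means(obj: DetectedObject,
                                 coding: BaseCodingMap) -> dict[str, float]:
    """Per base channel: object mean minus local annulus mean, floored at 0."""
    out = {}
    for ch in coding.channels_present(obj):
        st = obj.channel_stats[ch]
        out[ch] = max(st["mean"] - st["background"], 0.0)
    return out


def anchor_gate(objects: Iterable[DetectedObject],
                anchor_channel: str = "anchor",
                anchor_min_intensity: float = 0.0
                ) -> tuple[list[DetectedObject], list[DetectedObject]]:
    """Split objects by whether they carry anchor stain.

    Objects whose background-subtracted anchor mean falls below
    ``anchor_min_intensity`` are rejected as non-RCPs.  When the anchor
    channel was never measured (two-laser devices image Cy3/Cy5 only) the
    gate is skipped with a warning and everything is kept.
    """
    objects = list(objects)
    if not all(anchor_channel in o.channel_stats for o in objects):
        if objects:
            warnings.warn(
                f"anchor channel {anchor_channel!r} not measured; "
                "anchor gate skipped", stacklevel=2)
        return objects, []
    kept, rejected = [], []
    for obj in objects:
        st = obj.channel_stats[anchor_channel]
        signal = st["mean"] - st["background"]
        (kept if signal >= anchor_min_intensity else rejected).append(obj)
    return kept, rejected


def double_stain_ratio(obj: DetectedObject, coding: BaseCodingMap) -> float:
    """Second-brightest over brightest base-channel mean (background-subtracted).

    Genuine single-stained RCPs score near 0; auto-fluorescent objects that
    glow in several channels score high.  Defined as 0 when the brightest
    channel carries no signal at all.
    """
    signals = sorted(_background_subtracted_means(obj, coding).values(),
                     reverse=True)
    if len(signals) < 2 or signals[0] == 0.0:
        return 0.0
    return signals[1] / signals[0]


def call_base(obj: DetectedObject, coding: BaseCodingMap,
              min_signal: float,
              ratio_threshold: float = DEFAULT_RATIO_THRESHOLD) -> BaseCall:
    """Call one object's base, or reject it.

    Order of rules: (1) no channel above ``min_signal`` → the blank-coded
    base when the coding declares one, else no_call; (2) double-stain ratio
    strictly above ``ratio_threshold`` → rejected as auto-fluorescence
    (a ratio of exactly the threshold is kept); (3) otherwise the base coded
    by the dominant channel.
    """
    if not 0.0 < ratio_threshold < 1.0:
        raise ValueError("ratio_threshold must lie in (0, 1)")
    signals = _background_subtracted_means(obj, coding)
    if not signals:
        raise ValueError("no base channel measured on object "
                         f"{obj.object_id}; coding expects "
                         f"{sorted(coding.base_channels)}")
    ratio = double_stain_ratio(obj, coding)
    dominant = max(sorted(signals), key=lambda ch: signals[ch])
    if all(v < min_signal for v in signals.values()):
        if coding.blank_base is not None:
            return BaseCall(obj.object_id, coding.blank_base, STATUS_ACCEPTED,
                            None, ratio)
        return BaseCall(obj.object_id, "no_call", STATUS_NO_CALL, None, ratio)
    if ratio > ratio_threshold:
        return BaseCall(obj.object_id, "no_call",
                        STATUS_REJECTED_DOUBLE_STAIN, dominant, ratio)
    return BaseCall(obj.object_id, coding.base_channels[dominant],
                    STATUS_ACCEPTED, dominant, ratio)


def call_objects(objects: Iterable[DetectedObject], coding: BaseCodingMap,
                 min_signal: float,
                 ratio_threshold: float = DEFAULT_RATIO_THRESHOLD,
                 anchor_min_intensity: float | None = None
                 ) -> list[BaseCall]:
    """Anchor-gate then base-call a whole object list.

    ``anchor_min_intensity=None`` disables the anchor gate explicitly (the
    gate also self-disables, with a warning, when the anchor channel was
    never measured).
    """
    objects = list(objects)
    calls: list[BaseCall] = []
    if anchor_min_intensity is not None:
        kept, rejected = anchor_gate(objects, coding.anchor_channel,
                                     anchor_min_intensity)
        for obj in rejected:
            calls.append(BaseCall(obj.object_id, "no_call",
                                  STATUS_REJECTED_NO_ANCHOR, None,
                                  double_stain_ratio(obj, coding)))
    else:
        kept = objects
    for obj in kept:
        calls.append(call_base(obj, coding, min_signal, ratio_threshold))
    calls.sort(key=lambda c: c.object_id)
    return calls


def tally_calls(calls: Iterable[BaseCall]) -> dict:
    """Count calls by base and by status; totals are conserved."""
    calls = list(calls)
    base_counts = {b: 0 for b in "ATGC"}
    status_counts = {STATUS_ACCEPTED: 0, STATUS_REJECTED_DOUBLE_STAIN: 0,
                     STATUS_REJECTED_NO_ANCHOR: 0, STATUS_NO_CALL: 0}
    for c in calls:
        status_counts[c.status] += 1
        if c.status == STATUS_ACCEPTED:
            base_counts[c.called_base] += 1
    return {"base_counts": base_counts, "status_counts": status_counts,
            "total": len(calls)}


__all__ = [
    "BaseCodingMap", "BaseCall", "anchor_gate", "double_stain_ratio",
    "call_base", "call_objects", "tally_calls",
    "STATUS_ACCEPTED", "STATUS_REJECTED_DOUBLE_STAIN",
    "STATUS_REJECTED_NO_ANCHOR", "STATUS_NO_CALL",
    "DEFAULT_RATIO_THRESHOLD",
]
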