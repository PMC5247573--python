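"""Stage chaining: frame stacks in, counted and base-called objects out.

``count_scene`` runs the full path used by the command-line tool and the
benchmark experiments: average + denoise each channel, co-register to a
reference, detect candidate spots on a max-projection of the signal
channels, measure every object on every registered channel, optionally
filter with a trained forest, then anchor-gate and base-call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import basecall, classify, detect, preprocess

#: preferred reference channel order for registration
_REFERENCE_PREFERENCE = ("cy3", "cy5", "fitc", "txred", "anchor")


def robust_background(data: np.ndarray) -> tuple[float, float]:
    """(median, MAD-based s.d.) of an image — robust to sparse bright spots."""
    med = float(np.median(data))
    sd = float(1.4826 * np.median(np.abs(data - med)))
    return med, sd


@dataclass
class SceneResult:
    """Everything ``count_scene`` produced for one field of view."""

    registered: preprocess.RegisteredImageSet
    detection_image: preprocess.ChannelImage
    objects: list
    calls: list
    tally: dict
    provenance: dict = field(default_factory=dict)

    @property
    def n_accepted(self) -> int:
        return self.tally["status_counts"][basecall.STATUS_ACCEPTED]


def preprocess_stacks(stacks: dict, gaussian_sigma: float = 1.0,
                      max_shift_px: float = 10.0
                      ) -> preprocess.RegisteredImageSet:
    """Average, denoise and co-register all channels of one acquisition."""
    imgs = {ch: preprocess.gaussian_denoise(preprocess.average_frames(st),
                                            gaussian_sigma)
            for ch, st in stacks.items()}
    ref_label = next((ch for ch in _REFERENCE_PREFERENCE if ch in imgs),
                     next(iter(imgs)))
    moving = [im for ch, im in imgs.items() if ch != ref_label]
    return preprocess.register_channels(imgs[ref_label], moving, max_shift_px)


def count_scene(stacks: dict,
                detection: detect.DetectionConfig | None = None,
                coding: basecall.BaseCodingMap | None = None,
                model: classify.ForestModel | None = None,
                gaussian_sigma: float = 1.0,
                max_shift_px: float = 10.0,
                ratio_threshold: float = basecall.DEFAULT_RATIO_THRESHOLD,
                use_anchor_gate: bool = True) -> SceneResult:
    """Digital counting of one multi-channel scene.

    Detection runs on the pixel-wise maximum over the registered signal
    channels so single-stained spots of either colour are found once.  The
    no-signal floor for base calling and the anchor gate level are both set
    to 3 robust standard deviations above the local image background, a
    level a blank pixel crosses only exceptionally.
    """
    detection = detection or detect.DetectionConfig()
    coding = coding or basecall.BaseCodingMap()
    regset = preprocess_stacks(stacks, gaussian_sigma, max_shift_px)

    signal_channels = [ch for ch in regset.channels
                       if ch in coding.base_channels]
    if not signal_channels:
        raise ValueError(
            f"no base-coding channel found; have {sorted(regset.channels)}, "
            f"coding expects {sorted(coding.base_channels)}")
    proj = np.max([regset.images[ch].data for ch in signal_channels], axis=0)
    proj_img = preprocess.ChannelImage(
        "signal_max", proj, {"source_channels": signal_channels})

    enhanced = detect.enhance_spots(proj_img, detection.enhance_radius_px)
    objects = detect.identify_objects(enhanced, detection)
    detect.measure_across_channels(objects, regset)

    classifier_votes = None
    if model is not None and objects:
        X = np.array([classify.extract_features(o, proj_img) for o in objects])
        labels, classifier_votes = classify.predict_batch(model, X)
        objects = [o for o, lab in zip(objects, labels)
                   if lab == classify.LABEL_RCP]

    # no-signal floor: 3 robust sigma of the brightest channel's background
    noise_sds = [robust_background(regset.images[ch].data)[1]
                 for ch in signal_channels]
    min_signal = 3.0 * max(noise_sds)

    anchor_min = None
    if use_anchor_gate and coding.anchor_channel in regset.channels:
        _, anchor_sd = robust_background(
            regset.images[coding.anchor_channel].data)
        anchor_min = 3.0 * anchor_sd

    calls = basecall.call_objects(objects, coding, min_signal,
                                  ratio_threshold=ratio_threshold,
                                  anchor_min_intensity=anchor_min)
    tally = basecall.tally_calls(calls)
    return SceneResult(
        registered=regset,
        detection_image=proj_img,
        objects=objects,
        calls=calls,
        tally=tally,
        provenance={
            "detection": detection.__dict__,
            "min_signal": min_signal,
            "anchor_min_intensity": anchor_min,
            "ratio_threshold": ratio_threshold,
            "gaussian_sigma": gaussian_sigma,
            "classifier": model.feature_hash if model is not None else None,
            "n_classifier_votes": (None if classifier_votes is None
                                   else len(classifier_votes)),
            "shifts": regset.shifts,
        },
    )


__all__ = ["SceneResult", "preprocess_stacks", "count_scene",
           "robust_background"]
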