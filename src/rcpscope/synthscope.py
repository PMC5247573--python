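"""Synthetic multi-channel micrograph generator with ground truth.

Emulates what a phone-camera fluorescence microscope sees when imaging
rolling-circle amplification products (RCPs): diffraction-limited ~1 µm
spots sampled at ~0.42 µm/px (so 2–8 px objects), auto-fluorescent tissue
artifacts that stain in several channels at once, Poisson photon noise plus
Gaussian read noise that is independent frame to frame, and small rigid
translations between sequentially acquired channels.

Every rendered object is recorded in a ground-truth table, so detection,
classification, base calling and counting can all be scored against a known
answer without any external data.

The emitted intensity model, per channel::

    expected(x, y) = background + sum_objects amp_ch * G(x, y; centre, shape)
    frame          = Poisson(expected) + Normal(0, sigma_read)

where ``G`` is a unit-peak 2-D Gaussian.  True RCPs are isotropic with
sigma = spot_diameter / (2.355 * pixel_size) (FWHM = physical spot size) and
emit in exactly one base-coding channel plus, optionally, the common anchor
channel.  Artifacts are larger, elongated (eccentricity >= 0.6), emit in at
least two base channels with a secondary/primary amplitude ratio above 0.3,
and carry no anchor stain — mirroring the criteria the pipeline uses to
reject them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
import tifffile
import yaml

from .preprocess import FULL_SCALE, FrameStack

#: fraction of full scale used as the flat background level
BACKGROUND_FRACTION = 0.02
BACKGROUND_DN = BACKGROUND_FRACTION * FULL_SCALE

#: mean peak amplitude of a true RCP, in DN above background (~0.45 of range;
#: keeps even dim-tail spots inside the 2-8 px window after the ~2x peak
#: reduction of a 1-px Gaussian denoise at the 0.1 intensity gate)
RCP_PEAK_DN = 0.45 * FULL_SCALE
#: lognormal sigma of the per-spot amplitude scatter
RCP_PEAK_LOGNORM_SIGMA = 0.10

#: channels a ground-truth record carries an amplitude column for
TRUTH_AMP_CHANNELS = ("cy3", "cy5", "fitc", "txred", "anchor")
TRUTH_COLUMNS = ("object_id", "row", "col", "class", "base",
                 "amp_cy3", "amp_cy5", "amp_fitc", "amp_txred", "amp_anchor")

#: base -> emitting channel for true RCPs (C is coded by absence of signal)
BASE_TO_CHANNEL = {"A": "cy5", "T": "fitc", "G": "cy3", "C": "txred"}


@dataclass(frozen=True)
class SceneConfig:
    """Acquisition and sample parameters for one synthetic field of view.

    Densities are expected object counts per rendered tile (Poisson means).
    ``mutant_fraction`` is the fraction of true RCPs assigned the mutant
    base A (Cy5); the remainder carry the wild-type base G (Cy3).
    ``peak_snr`` is the mean RCP peak amplitude divided by the single-frame
    background noise standard deviation; the Gaussian read-noise sigma is
    derived from it after accounting for background shot noise.
    """

    image_height_px: int = 1024
    image_width_px: int = 1024
    pixel_size_um: float = 0.42
    spot_density: float = 200.0
    artifact_density: float = 0.0
    spot_diameter_um: float = 1.0
    psf_sigma_px: float | None = None  # derived from spot size when None
    peak_snr: float = 8.0
    n_frames: int = 5
    channel_shift_px: tuple[float, float] = (0.0, 0.0)
    mutant_fraction: float = 0.0
    channels: tuple[str, ...] = ("cy3", "cy5")
    include_anchor: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "channels", tuple(self.channels))
        object.__setattr__(self, "channel_shift_px",
                           tuple(float(v) for v in self.channel_shift_px))
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.spot_density < 0 or self.artifact_density < 0:
            raise ValueError("densities must be non-negative")
        if not 0.0 <= self.mutant_fraction <= 1.0:
            raise ValueError("mutant_fraction must lie in [0, 1]")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.peak_snr <= 0:
            raise ValueError("peak_snr must be positive")
        if self.psf_sigma_px is not None and self.psf_sigma_px <= 0:
            raise ValueError("psf_sigma_px must be positive")
        if len(self.channels) < 1:
            raise ValueError("at least one signal channel is required")
        unknown = set(self.channels) - set(BASE_TO_CHANNEL.values())
        if unknown:
            raise ValueError(f"unknown signal channels: {sorted(unknown)}")

    @property
    def sigma_px(self) -> float:
        """PSF sigma: spot FWHM equals the physical spot diameter."""
        if self.psf_sigma_px is not None:
            return self.psf_sigma_px
        return self.spot_diameter_um / (2.355 * self.pixel_size_um)

    @property
    def read_noise_dn(self) -> float:
        """Gaussian read-noise sigma implied by ``peak_snr`` (in DN)."""
        total_var = (RCP_PEAK_DN / self.peak_snr) ** 2
        return float(np.sqrt(max(total_var - BACKGROUND_DN, 1.0)))


def _clipped_background_moments(config: SceneConfig) -> tuple[float, float]:
    """(mean, variance) of a blank pixel after truncation at the sensor floor."""
    from scipy.stats import norm

    mu = BACKGROUND_DN
    sigma = float(np.sqrt(BACKGROUND_DN + config.read_noise_dn ** 2))
    a = mu / sigma
    ey = mu * norm.cdf(a) + sigma * norm.pdf(a)
    ey2 = (mu ** 2 + sigma ** 2) * norm.cdf(a) + mu * sigma * norm.pdf(a)
    return float(ey), float(ey2 - ey ** 2)


def expected_background_mean(config: SceneConfig) -> float:
    """Mean recorded value (DN) of a blank pixel.

    Exceeds the nominal background level because truncation at the sensor
    floor lifts the mean of noisy dim pixels; bright pixels are unaffected.
    """
    return _clipped_background_moments(config)[0]


def expected_background_variance(config: SceneConfig) -> float:
    """Single-frame variance of a blank pixel under the rendered noise model.

    Shot noise on the background plus Gaussian read noise, truncated at the
    sensor floor: recorded values are ``max(X, 0)`` with X approximately
    normal, and at low peak_snr the read noise is broad enough for the
    truncation to matter, so the clipped-normal moments are used.
    """
    return _clipped_background_moments(config)[1]


# ---------------------------------------------------------------------------
# optics helpers (acquisition geometry the defaults derive from)

def effective_magnification(camera_focal_mm: float = 6.86,
                            external_lens_focal_mm: float = 2.6) -> float:
    """Magnification of the phone camera + external lens relay.

    The external lens images the sample at its focal plane and the phone
    camera re-images it, so the magnification is the ratio of the two focal
    lengths (~2.6x for a 6.86 mm camera behind a 2.6 mm lens).
    """
    if camera_focal_mm <= 0 or external_lens_focal_mm <= 0:
        raise ValueError("focal lengths must be positive")
    return camera_focal_mm / external_lens_focal_mm


def object_pixel_pitch_um(sensor_pixel_um: float = 1.1,
                          magnification: float | None = None) -> float:
    """Object-plane pixel pitch: sensor pitch / magnification (~0.42 µm/px)."""
    if magnification is None:
        magnification = effective_magnification()
    return sensor_pixel_um / magnification


# ---------------------------------------------------------------------------
# rendering

def _stamp_gaussian(canvas: np.ndarray, row: float, col: float, amp: float,
                    cov_inv: np.ndarray, extent_px: float) -> None:
    """Add an elliptical Gaussian of unit-peak ``amp`` onto ``canvas``."""
    h, w = canvas.shape
    r0 = max(int(np.floor(row - extent_px)), 0)
    r1 = min(int(np.ceil(row + extent_px)) + 1, h)
    c0 = max(int(np.floor(col - extent_px)), 0)
    c1 = min(int(np.ceil(col + extent_px)) + 1, w)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dy = rr - row
    dx = cc - col
    q = (cov_inv[0, 0] * dy * dy + 2 * cov_inv[0, 1] * dy * dx
         + cov_inv[1, 1] * dx * dx)
    canvas[r0:r1, c0:c1] += amp * np.exp(-0.5 * q)


def _isotropic_cov_inv(sigma: float) -> np.ndarray:
    return np.eye(2) / sigma ** 2


def _elliptical_cov_inv(sigma_major: float, sigma_minor: float,
                        theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    cov = rot @ np.diag([sigma_major ** 2, sigma_minor ** 2]) @ rot.T
    return np.linalg.inv(cov)


def render_scene(config: SceneConfig
                 ) -> tuple[dict[str, FrameStack], pd.DataFrame]:
    """Render one synthetic field of view.

    Returns a dict of per-channel :class:`FrameStack` (signal channels in
    ``config.channels``, plus ``"anchor"`` when ``config.include_anchor``)
    and the ground-truth table (columns ``object_id, row, col, class, base,
    amp_<channel>...``).  Identical config (including seed) gives
    bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.image_height_px, config.image_width_px
    sigma = config.sigma_px

    n_spots = int(rng.poisson(config.spot_density))
    n_artifacts = int(rng.poisson(config.artifact_density))

    channel_list = list(config.channels)
    if config.include_anchor:
        channel_list.append("anchor")
    expected = {ch: np.full((h, w), BACKGROUND_DN) for ch in channel_list}

    records: list[dict] = []
    oid = 0

    # --- true RCPs: isotropic spots, one base channel (+ anchor) ----------
    mutant_channel = BASE_TO_CHANNEL["A"]
    wildtype_channel = BASE_TO_CHANNEL["G"]
    cov_inv = _isotropic_cov_inv(sigma)
    for _ in range(n_spots):
        row = rng.uniform(0, h)
        col = rng.uniform(0, w)
        amp = RCP_PEAK_DN * rng.lognormal(0.0, RCP_PEAK_LOGNORM_SIGMA)
        if rng.uniform() < config.mutant_fraction:
            base, ch = "A", mutant_channel
        else:
            base, ch = "G", wildtype_channel
        amps = dict.fromkeys(TRUTH_AMP_CHANNELS, 0.0)
        if ch in expected:
            _stamp_gaussian(expected[ch], row, col, amp, cov_inv, 4 * sigma)
            amps[ch] = amp
        if config.include_anchor:
            anchor_amp = 0.7 * amp
            _stamp_gaussian(expected["anchor"], row, col, anchor_amp,
                            cov_inv, 4 * sigma)
            amps["anchor"] = anchor_amp
        records.append({"object_id": oid, "row": row, "col": col,
                        "class": "rcp", "base": base,
                        **{f"amp_{c}": amps[c] for c in TRUTH_AMP_CHANNELS}})
        oid += 1

    # --- auto-fluorescent artifacts: large, eccentric, multi-channel ------
    for _ in range(n_artifacts):
        row = rng.uniform(0, h)
        col = rng.uniform(0, w)
        sigma_major = rng.uniform(2.0, 4.0)
        ecc = rng.uniform(0.6, 0.95)
        sigma_minor = sigma_major * np.sqrt(1.0 - ecc ** 2)
        theta = rng.uniform(0, np.pi)
        art_cov_inv = _elliptical_cov_inv(sigma_major, sigma_minor, theta)
        major_amp = RCP_PEAK_DN * rng.uniform(0.7, 1.3)
        amps = dict.fromkeys(TRUTH_AMP_CHANNELS, 0.0)
        sig_channels = [c for c in config.channels]
        rng.shuffle(sig_channels)
        primary = sig_channels[0]
        amps[primary] = major_amp
        # secondary stains above the 0.3 double-stain rejection ratio
        for other in sig_channels[1:]:
            amps[other] = major_amp * rng.uniform(0.35, 1.0)
        for ch in config.channels:
            if amps[ch] > 0 and ch in expected:
                _stamp_gaussian(expected[ch], row, col, amps[ch],
                                art_cov_inv, 4 * sigma_major)
        records.append({"object_id": oid, "row": row, "col": col,
                        "class": "artifact", "base": "none",
                        **{f"amp_{c}": amps[c] for c in TRUTH_AMP_CHANNELS}})
        oid += 1

    truth = pd.DataFrame(records, columns=list(TRUTH_COLUMNS))

    # --- rigid inter-channel shift, then per-frame noise -------------------
    reference = channel_list[0]
    dy, dx = config.channel_shift_px
    stacks: dict[str, FrameStack] = {}
    read_sigma = config.read_noise_dn
    for ch in channel_list:
        exp_img = expected[ch]
        if ch != reference and (dy or dx):
            exp_img = ndi.shift(exp_img, (dy, dx), order=1,
                                mode="constant", cval=BACKGROUND_DN)
        frames = np.empty((config.n_frames, h, w), dtype=np.uint16)
        for i in range(config.n_frames):
            noisy = rng.poisson(exp_img).astype(np.float64)
            noisy += rng.normal(0.0, read_sigma, size=(h, w))
            frames[i] = np.clip(noisy, 0, FULL_SCALE).astype(np.uint16)
        stacks[ch] = FrameStack(ch, frames.astype(np.float64),
                                config.pixel_size_um)
    return stacks, truth


def empty_ground_truth() -> pd.DataFrame:
    return pd.DataFrame(columns=list(TRUTH_COLUMNS))


# ---------------------------------------------------------------------------
# dilution series

def proportional_densities(concentrations: Sequence[float],
                           density_at_max: float) -> dict[float, float]:
    """Spot densities proportional to concentration, anchored at the top."""
    cmax = max(concentrations)
    return {c: density_at_max * c / cmax for c in concentrations}


def render_dilution_series(
    base_config: SceneConfig,
    concentrations: Sequence[float],
    density_per_concentration: Mapping[float, float],
) -> list[tuple[float, dict[str, FrameStack], pd.DataFrame]]:
    """One scene per concentration with density following the dilution.

    Scene seeds are derived deterministically from ``base_config.seed`` and
    the point index, so replicate series differ only through the base seed.
    """
    if len(concentrations) == 0:
        raise ValueError("concentration list must not be empty")
    if any(c <= 0 for c in concentrations):
        raise ValueError("concentrations must be strictly positive")
    order = np.argsort(concentrations)
    sorted_conc = [concentrations[i] for i in order]
    densities = [density_per_concentration[c] for c in sorted_conc]
    if any(b < a for a, b in zip(densities, densities[1:])):
        raise ValueError("density mapping must be monotone in concentration")
    out = []
    for i, conc in enumerate(sorted_conc):
        child_seed = int(
            np.random.SeedSequence([base_config.seed, i]).generate_state(1)[0]
            % (2 ** 31)
        )
        cfg = dataclasses.replace(base_config,
                                  spot_density=float(density_per_concentration[conc]),
                                  seed=child_seed)
        stacks, truth = render_scene(cfg)
        out.append((conc, stacks, truth))
    return out


# ---------------------------------------------------------------------------
# file output

def write_scene(out_dir: str | Path, scene_name: str,
                stacks: dict[str, FrameStack], truth: pd.DataFrame,
                config: SceneConfig | None = None) -> dict[str, Path]:
    """Write per-channel multi-page TIFFs, the truth CSV and the config YAML.

    Files: ``<scene>_<channel>.tif`` (one page per frame, uint16),
    ``<scene>_truth.csv`` and ``<scene>_config.yaml``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for ch, stack in stacks.items():
        p = out_dir / f"{scene_name}_{ch}.tif"
        tifffile.imwrite(str(p), stack.frames.astype(np.uint16))
        paths[ch] = p
    truth_path = out_dir / f"{scene_name}_truth.csv"
    truth.to_csv(truth_path, index=False)
    paths["truth"] = truth_path
    if config is not None:
        cfg_path = out_dir / f"{scene_name}_config.yaml"
        cfg_path.write_text(yaml.safe_dump(dataclasses.asdict(config)))
        paths["config"] = cfg_path
    return paths


__all__ = [
    "SceneConfig", "render_scene", "render_dilution_series",
    "proportional_densities", "write_scene", "empty_ground_truth",
    "expected_background_variance", "expected_background_mean",
    "effective_magnification",
    "object_pixel_pitch_um", "BACKGROUND_DN", "RCP_PEAK_DN",
    "BASE_TO_CHANNEL", "TRUTH_COLUMNS",
]
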