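"""Synthetic two-channel movies, bleach controls, tile grids and profiles.

The generator emulates the statistical structure of presynaptic calcium
imaging in acute slices expressing a green calcium sensor and a red,
calcium-independent reference:

* boutons are diffraction-limited spots, rendered as pixel-integrated
  2-D Gaussians at sub-pixel centers on a smooth autofluorescent
  background;
* a stimulus train drives, in responding boutons only, a green transient
  that gains ``amp_per_stim`` (F/F0 units) per stimulus, decays with a
  single exponential and saturates at a hard cap — mirroring the plateau
  of responses above ~20 stimuli;
* the red channel carries no stimulus-locked component;
* both channels bleach multiplicatively with channel-specific
  double-exponential curves (red weaker by default);
* noise is Poisson (via a photon gain) followed by additive Gaussian
  read noise.

Every generator is a pure function of (parameters, seed): identical
inputs give bit-identical outputs.

Default acquisition regime: 64 x 512 pixel frames at 98 ms intervals,
trains of 10 stimuli at 20 Hz — the single-bouton imaging regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import ndtr

from .core import ParameterError, StimulusProtocol, TwoChannelStack
from .flatfield import MosaicLayout, radial_vignette, tile_positions
from .preprocess import BleachModel

__all__ = [
    "BoutonSpec",
    "NoiseModel",
    "GroundTruth",
    "DEFAULT_FRAME_INTERVAL_S",
    "DEFAULT_FRAME_SHAPE",
    "default_stimulus",
    "default_red_bleach",
    "transient_f_over_f0",
    "render_spots",
    "spot_integral",
    "random_bouton_field",
    "simulate_movie",
    "simulate_bleach_control",
    "simulate_tile_grid",
    "simulate_line_profiles",
]

DEFAULT_FRAME_INTERVAL_S = 0.098
DEFAULT_FRAME_SHAPE = (64, 512)  # lines x pixels


def default_stimulus(onset_time_s: float = 1.0) -> StimulusProtocol:
    """Train of 10 stimuli at 20 Hz, the default acquisition protocol."""
    return StimulusProtocol(onset_time_s=onset_time_s, n_stimuli=10,
                            frequency_hz=20.0, intensity_v=20.0)


@dataclass(frozen=True)
class BoutonSpec:
    """Ground-truth description of one synthetic bouton.

    ``amp_per_stim`` is the F/F0 increment contributed by each stimulus;
    the summed transient is clipped at ``saturation_cap`` (F/F0 units
    above baseline). Non-responders keep their resting brightness.
    """

    center: Tuple[float, float]          # (row, col), sub-pixel
    psf_sigma_px: float = 1.5
    green_rest: float = 100.0
    red_level: float = 100.0
    responder: bool = True
    amp_per_stim: float = 0.1
    tau_decay_s: float = 0.5
    saturation_cap: float = 2.0

    def __post_init__(self) -> None:
        if self.psf_sigma_px <= 0:
            raise ParameterError("psf_sigma_px must be > 0")
        if self.green_rest <= 0 or self.red_level <= 0:
            raise ParameterError("resting brightness must be > 0")
        if self.amp_per_stim < 0:
            raise ParameterError("amp_per_stim must be >= 0")
        if self.tau_decay_s <= 0:
            raise ParameterError("tau_decay_s must be > 0")
        if self.saturation_cap < self.amp_per_stim:
            raise ParameterError("saturation_cap must be >= amp_per_stim")


@dataclass(frozen=True)
class NoiseModel:
    """Camera/shot-noise model: Poisson via gain, then Gaussian read noise.

    ``photon_gain`` converts intensity units to expected photon counts;
    0 disables the Poisson stage. ``read_sigma`` is the SD of additive
    Gaussian noise in intensity units; 0 disables it.
    ``background_level`` is the mean autofluorescence and
    ``background_smoothness_px`` the spatial correlation length of its
    mild (10% RMS) static structure; 0 gives a perfectly flat background.
    """

    photon_gain: float = 1.0
    read_sigma: float = 2.0
    background_level: float = 20.0
    background_smoothness_px: float = 8.0

    def __post_init__(self) -> None:
        if self.photon_gain < 0 or self.read_sigma < 0:
            raise ParameterError("noise parameters must be >= 0")
        if self.background_level < 0:
            raise ParameterError("background_level must be >= 0")

    @classmethod
    def noiseless(cls) -> "NoiseModel":
        return cls(photon_gain=0.0, read_sigma=0.0, background_level=0.0,
                   background_smoothness_px=0.0)


@dataclass
class GroundTruth:
    """Record of everything a generator drew, for later scoring."""

    seed: int
    boutons: List[BoutonSpec] = field(default_factory=list)
    bleach_green: Optional[BleachModel] = None
    bleach_red: Optional[BleachModel] = None
    flatfield: Optional[np.ndarray] = None
    truth_image: Optional[np.ndarray] = None
    stim: Optional[StimulusProtocol] = None

    @property
    def responder_labels(self) -> np.ndarray:
        return np.array([b.responder for b in self.boutons], dtype=bool)

    @property
    def centers(self) -> np.ndarray:
        return np.array([b.center for b in self.boutons], dtype=float
                        ).reshape(-1, 2)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "boutons": [vars(b) | {"center": list(b.center)}
                        for b in self.boutons],
            "bleach_green": (self.bleach_green.to_dict()
                             if self.bleach_green else None),
            "bleach_red": (self.bleach_red.to_dict()
                           if self.bleach_red else None),
        }


def default_red_bleach(green: BleachModel) -> BleachModel:
    """Red-channel bleach curve: same time constants, 30% of the depth."""
    shrink = 0.3
    a1, a2 = shrink * green.a1, shrink * green.a2
    return BleachModel(a1=a1, tau1_s=green.tau1_s, a2=a2,
                       tau2_s=green.tau2_s, c=1.0 - a1 - a2)


# ---------------------------------------------------------------------------
# Transient model
# ---------------------------------------------------------------------------

def transient_f_over_f0(t, stim: StimulusProtocol, amp_per_stim: float,
                        tau_decay_s: float, saturation_cap: float
                        ) -> np.ndarray:
    """Fractional response c(t): per-stimulus increments with exponential
    decay, hard-clipped at ``saturation_cap``.

    c(t) = min(cap, sum_{s_j <= t} amp * exp(-(t - s_j)/tau)).
    """
    t = np.asarray(t, dtype=float)
    c = np.zeros_like(t)
    for s in stim.stimulus_times_s():
        dt = t - s
        active = dt >= 0
        c[active] += amp_per_stim * np.exp(-dt[active] / tau_decay_s)
    return np.minimum(c, saturation_cap)


# ---------------------------------------------------------------------------
# Spot rendering (analytic pixel integration)
# ---------------------------------------------------------------------------

def _pixel_profile(coords: np.ndarray, center: float, sigma: float
                   ) -> np.ndarray:
    """Integral of a unit-peak-normalized 1-D Gaussian over unit pixels."""
    upper = ndtr((coords + 0.5 - center) / sigma)
    lower = ndtr((coords - 0.5 - center) / sigma)
    norm = ndtr(0.5 / sigma) - ndtr(-0.5 / sigma)
    return (upper - lower) / norm


def render_spots(shape: Tuple[int, int],
                 boutons: Sequence[BoutonSpec],
                 channel: str = "green",
                 amplitudes: Optional[np.ndarray] = None) -> np.ndarray:
    """Render boutons as pixel-integrated 2-D Gaussians.

    Amplitude convention: a spot centered exactly on a pixel has that
    pixel equal to its amplitude (``green_rest`` or ``red_level`` unless
    ``amplitudes`` overrides). Sub-pixel centers spread the same mass.
    """
    H, W = shape
    img = np.zeros((H, W), dtype=float)
    for i, b in enumerate(boutons):
        cr, cc = b.center
        if not (0 <= cr <= H - 1 and 0 <= cc <= W - 1):
            raise ParameterError(f"bouton center {b.center} outside frame")
        if amplitudes is not None:
            amp = float(amplitudes[i])
        else:
            amp = b.green_rest if channel == "green" else b.red_level
        half = int(np.ceil(6 * b.psf_sigma_px)) + 1
        r0, r1 = max(0, int(cr) - half), min(H, int(cr) + half + 1)
        c0, c1 = max(0, int(cc) - half), min(W, int(cc) + half + 1)
        pr = _pixel_profile(np.arange(r0, r1), cr, b.psf_sigma_px)
        pc = _pixel_profile(np.arange(c0, c1), cc, b.psf_sigma_px)
        img[r0:r1, c0:c1] += amp * np.outer(pr, pc)
    return img


def spot_integral(b: BoutonSpec, channel: str = "green") -> float:
    """Total intensity a bouton contributes to an (unclipped) frame."""
    amp = b.green_rest if channel == "green" else b.red_level
    norm = ndtr(0.5 / b.psf_sigma_px) - ndtr(-0.5 / b.psf_sigma_px)
    # full-plane integral of the pixel-integrated profile = 1/norm per axis
    return amp / norm ** 2


# ---------------------------------------------------------------------------
# Background and noise
# ---------------------------------------------------------------------------

_BACKGROUND_RMS = 0.10  # relative RMS of static background structure


def _background_field(shape: Tuple[int, int], noise: NoiseModel,
                      rng: np.random.Generator) -> np.ndarray:
    """Static autofluorescent background with smooth spatial structure."""
    if noise.background_level == 0:
        return np.zeros(shape)
    base = np.full(shape, noise.background_level, dtype=float)
    if noise.background_smoothness_px > 0:
        raw = rng.standard_normal(shape)
        smooth = gaussian_filter(raw, noise.background_smoothness_px,
                                 mode="reflect")
        sd = smooth.std()
        if sd > 0:
            base *= np.clip(1.0 + _BACKGROUND_RMS * smooth / sd, 0.1, None)
    return base


def _apply_noise(frames: np.ndarray, noise: NoiseModel,
                 rng: np.random.Generator) -> np.ndarray:
    out = frames
    if noise.photon_gain > 0:
        out = rng.poisson(np.clip(out, 0, None) * noise.photon_gain
                          ).astype(float) / noise.photon_gain
    if noise.read_sigma > 0:
        out = out + rng.normal(0.0, noise.read_sigma, size=out.shape)
    return np.clip(out, 0.0, None)


# ---------------------------------------------------------------------------
# Movie generators
# ---------------------------------------------------------------------------

def _check_movie_args(boutons, shape, frame_interval_s, stim):
    T, H, W = shape
    if T < 1 or H < 1 or W < 1:
        raise ParameterError("shape must be positive (T, H, W)")
    if frame_interval_s <= 0:
        raise ParameterError("frame_interval_s must be > 0")
    for b in boutons:
        if not (0 <= b.center[0] <= H - 1 and 0 <= b.center[1] <= W - 1):
            raise ParameterError(f"bouton center {b.center} outside frame")
    if stim is not None and stim.n_stimuli > 0:
        if stim.end_time_s() >= (T - 1) * frame_interval_s:
            raise ParameterError("stack too short for the stimulus protocol")


def simulate_movie(boutons: Sequence[BoutonSpec],
                   stim: StimulusProtocol,
                   noise: NoiseModel,
                   bleach: BleachModel,
                   shape: Tuple[int, int, int] = (100,) + DEFAULT_FRAME_SHAPE,
                   frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S,
                   seed: int = 0,
                   bleach_red: Optional[BleachModel] = None,
                   ) -> Tuple[TwoChannelStack, GroundTruth]:
    """Simulate a stimulated two-channel acquisition with known truth.

    Green signal of a responding bouton follows
    ``green_rest * (1 + c(t))`` with ``c`` from
    :func:`transient_f_over_f0`; non-responders and the red channel are
    flat. Both channels are multiplied by their bleach curve
    (normalized to 1 at t = 0; red defaults to a 30%-depth version of
    the green curve) and noise is applied last.
    """
    boutons = list(boutons)
    _check_movie_args(boutons, shape, frame_interval_s, stim)
    T, H, W = shape
    if bleach_red is None:
        bleach_red = default_red_bleach(bleach)
    rng = np.random.default_rng(seed)

    background = _background_field((H, W), noise, rng)
    red_rest = render_spots((H, W), boutons, channel="red")
    green_rest = render_spots((H, W), boutons, channel="green")

    t = np.arange(T) * frame_interval_s
    bg_t, br_t = bleach(t), bleach_red(t)

    # per-bouton fractional responses at frame times
    resp = np.zeros((len(boutons), T))
    for i, b in enumerate(boutons):
        if b.responder and b.amp_per_stim > 0 and stim.n_stimuli > 0:
            resp[i] = transient_f_over_f0(t, stim, b.amp_per_stim,
                                          b.tau_decay_s, b.saturation_cap)

    green = np.empty((T, H, W))
    red = np.empty((T, H, W))
    static_green = background + green_rest
    static_red = background + red_rest
    for k in range(T):
        frame = static_green
        if resp[:, k].any():
            extra = render_spots(
                (H, W), boutons,
                amplitudes=np.array([b.green_rest for b in boutons])
                * resp[:, k])
            frame = frame + extra
        green[k] = frame * bg_t[k]
        red[k] = static_red * br_t[k]

    green = _apply_noise(green, noise, rng)
    red = _apply_noise(red, noise, rng)

    stack = TwoChannelStack(green=green, red=red,
                            frame_interval_s=frame_interval_s, stim=stim)
    truth = GroundTruth(seed=seed, boutons=boutons, bleach_green=bleach,
                        bleach_red=bleach_red, stim=stim)
    return stack, truth


def simulate_bleach_control(noise: NoiseModel,
                            bleach: BleachModel,
                            shape: Tuple[int, int, int] = (100,)
                            + DEFAULT_FRAME_SHAPE,
                            frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S,
                            seed: int = 0,
                            boutons: Sequence[BoutonSpec] = (),
                            bleach_red: Optional[BleachModel] = None,
                            ) -> TwoChannelStack:
    """Zero-intensity (no-stimulation) control: pure bleach + noise.

    Expected frame-mean green is ``mean(background + spots) * B(t)``;
    with a flat background and no boutons this is
    ``background_level * B(t)``.
    """
    stim = StimulusProtocol(onset_time_s=0.0, n_stimuli=0)
    stack, _ = simulate_movie(boutons, stim, noise, bleach, shape,
                              frame_interval_s, seed, bleach_red=bleach_red)
    stack.stim = None
    return stack


# ---------------------------------------------------------------------------
# Random bouton fields
# ---------------------------------------------------------------------------

def random_bouton_field(n: int,
                        frame_shape: Tuple[int, int] = DEFAULT_FRAME_SHAPE,
                        responder_fraction: float = 0.3,
                        min_spacing_px: float = 6.0,
                        margin_px: int = 4,
                        seed: int = 0,
                        **spec_kw) -> List[BoutonSpec]:
    """Draw ``n`` bouton positions with a minimum pairwise spacing.

    Responder labels are assigned to exactly
    ``round(responder_fraction * n)`` boutons, shuffled by the seed.
    Extra keyword arguments override :class:`BoutonSpec` defaults.
    """
    if not 0 <= responder_fraction <= 1:
        raise ParameterError("responder_fraction must be in [0, 1]")
    H, W = frame_shape
    rng = np.random.default_rng(seed)
    centers: List[Tuple[float, float]] = []
    attempts = 0
    while len(centers) < n:
        attempts += 1
        if attempts > 10000 * max(n, 1):
            raise ParameterError(
                f"could not place {n} boutons with spacing {min_spacing_px}"
                f" in a {H}x{W} frame")
        cand = (rng.uniform(margin_px, H - 1 - margin_px),
                rng.uniform(margin_px, W - 1 - margin_px))
        if all((cand[0] - r) ** 2 + (cand[1] - c) ** 2
               >= min_spacing_px ** 2 for r, c in centers):
            centers.append(cand)
    n_resp = int(round(responder_fraction * n))
    labels = np.zeros(n, dtype=bool)
    labels[:n_resp] = True
    rng.shuffle(labels)
    return [BoutonSpec(center=c, responder=bool(lab), **spec_kw)
            for c, lab in zip(centers, labels)]


# ---------------------------------------------------------------------------
# Tile grids (mosaics)
# ---------------------------------------------------------------------------

def simulate_tile_grid(truth_image: np.ndarray,
                       layout: MosaicLayout,
                       vignette_strength: float,
                       noise: NoiseModel,
                       seed: int = 0,
                       ) -> Tuple[List[np.ndarray], GroundTruth]:
    """Crop a truth image into vignetted, noisy overlapping tiles.

    The vignette is a radial Gaussian falloff, identical across tiles,
    equal to ``1 - vignette_strength`` at the tile corners. The ground
    truth records the vignette and the exactly covered crop of the
    truth image (the region the nominal grid spans).
    """
    if not 0 <= layout.overlap_frac < 1:
        raise ParameterError("overlap_frac must be in [0, 1)")
    if not 0 <= vignette_strength < 1:
        raise ParameterError("vignette_strength must be in [0, 1)")
    truth_image = np.asarray(truth_image, dtype=float)
    Hm, Wm = layout.mosaic_shape()
    if truth_image.shape[0] < Hm or truth_image.shape[1] < Wm:
        raise ParameterError(
            f"truth image {truth_image.shape} smaller than mosaic"
            f" {Hm}x{Wm} implied by the layout")
    covered = truth_image[:Hm, :Wm]
    th, tw = layout.tile_shape
    vignette = radial_vignette((th, tw), vignette_strength)
    rng = np.random.default_rng(seed)
    tiles = []
    for r0, c0 in tile_positions(layout):
        tile = covered[r0:r0 + th, c0:c0 + tw] * vignette
        tiles.append(_apply_noise(tile, noise, rng))
    truth = GroundTruth(seed=seed, flatfield=vignette, truth_image=covered)
    return tiles, truth


# ---------------------------------------------------------------------------
# Correlated line profiles
# ---------------------------------------------------------------------------

def simulate_line_profiles(n: int, rho: float, seed: int = 0,
                           mean: float = 100.0, sd: float = 20.0
                           ) -> Tuple[np.ndarray, np.ndarray]:
    """Two intensity profiles with population correlation ``rho``.

    Bivariate Gaussian pairs shifted/scaled to positive intensities
    (mean 100, SD 20 by default, clipped at 0).
    """
    if n < 3:
        raise ParameterError("need at least 3 samples")
    if not -1 <= rho <= 1:
        raise ParameterError("rho must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    za = z1
    zb = rho * z1 + np.sqrt(max(0.0, 1 - rho ** 2)) * z2
    a = np.clip(mean + sd * za, 0, None)
    b = np.clip(mean + sd * zb, 0, None)
    return a, b
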