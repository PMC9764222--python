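"""Synthetic BOLD runs for the oddball paradigm.

Voxel time series are generated as a hemodynamic convolution of per-sound
neural amplitudes plus structured noise.  Each region of interest (ROI)
of a labelled voxel grid is assigned a generative profile: the neural
amplitude of every sound is an affine function of an amplitude model
(``h1`` habituation, ``h2`` prediction error) or zero (``null``).  Noise
is the sum of an AR(1) process, a slow sinusoidal drift, and white
noise, jointly scaled so the temporal signal-to-noise ratio
(mean / temporal sd) of a baseline voxel hits a target (about 50 for a
7-T acquisition, about 30 at 3 T).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from .design import SOA, RunSchedule, amplitude_model

__all__ = [
    "VoxelGrid",
    "GenerativeProfile",
    "NoiseSpec",
    "BOLDRun",
    "hrf",
    "make_roi_grid",
    "default_roi_spec",
    "simulate_run",
]

MICROTIME = 0.05            # convolution grid, s (sound duration << TR)
HRF_LENGTH = 32.0           # kernel support, s

# Double-gamma HRF shape: response gamma peaking at 5 s, undershoot
# gamma peaking at 15 s with 1/6 relative weight; peak normalised to 1.
_PEAK_SHAPE, _UNDER_SHAPE, _UNDER_RATIO = 6.0, 16.0, 1.0 / 6.0


def hrf(t: np.ndarray | float) -> np.ndarray | float:
    """Canonical double-gamma hemodynamic impulse response.

    Difference of two gamma densities (peak ~5 s, undershoot ~15 s),
    zero at t = 0, normalised to unit peak.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("hrf is defined for t >= 0 only")
    resp = sp_stats.gamma.pdf(t, _PEAK_SHAPE) - \
        _UNDER_RATIO * sp_stats.gamma.pdf(t, _UNDER_SHAPE)
    peak = sp_stats.gamma.pdf(_PEAK_SHAPE - 1.0, _PEAK_SHAPE) - \
        _UNDER_RATIO * sp_stats.gamma.pdf(_PEAK_SHAPE - 1.0, _UNDER_SHAPE)
    out = resp / peak
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class VoxelGrid:
    """3D grid with integer ROI labels (0 = unlabelled)."""

    labels: np.ndarray                  # int array, 3D
    roi_names: dict[int, str]
    voxel_size: float = 1.5             # mm, isotropic

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    @property
    def voxel_indices(self) -> np.ndarray:
        """Flat indices (C order) of labelled voxels, ascending."""
        return np.flatnonzero(self.labels.ravel())

    @property
    def voxel_labels(self) -> np.ndarray:
        """ROI label per labelled voxel, aligned with ``voxel_indices``."""
        return self.labels.ravel()[self.voxel_indices]

    @property
    def voxel_coords(self) -> np.ndarray:
        """(n, 3) integer coordinates of labelled voxels."""
        return np.stack(np.unravel_index(self.voxel_indices, self.shape), axis=1)

    @property
    def n_labeled(self) -> int:
        return int(self.voxel_indices.size)

    def label_of(self, name: str) -> int:
        for lab, nm in self.roi_names.items():
            if nm == name:
                return lab
        raise KeyError(f"unknown ROI {name!r}")

    def to_nifti(self):
        import nibabel as nib
        affine = np.diag([self.voxel_size] * 3 + [1.0])
        return nib.Nifti1Image(self.labels.astype(np.int16), affine)


#: Eight synthetic auditory-cortex fields: bilateral Te1.0, Te1.1, Te1.2, Te3.
DEFAULT_ROI_NAMES = ("Te1.0L", "Te1.0R", "Te1.1L", "Te1.1R",
                     "Te1.2L", "Te1.2R", "Te3L", "Te3R")


def default_roi_spec(shape=(20, 20, 10), block=(5, 5, 4),
                     names=DEFAULT_ROI_NAMES) -> dict:
    """Eight non-overlapping ROI blocks tiled over the grid."""
    blocks, i = {}, 0
    for x in range(0, shape[0] - block[0] + 1, block[0] + 1):
        for y in range(0, shape[1] - block[1] + 1, block[1] + 1):
            for z in range(0, shape[2] - block[2] + 1, block[2] + 1):
                if i < len(names):
                    blocks[names[i]] = (
                        (x, x + block[0]), (y, y + block[1]), (z, z + block[2]))
                    i += 1
    if i < len(names):
        raise ValueError("grid too small for requested ROI blocks")
    return {"shape": shape, "rois": blocks}


def make_roi_grid(spec: dict, voxel_size: float = 1.5) -> VoxelGrid:
    """Build a labelled grid from ``{"shape": ..., "rois": {name: extents}}``.

    Extents are per-axis half-open index ranges.  Overlapping blocks are
    an error; an empty spec yields an all-unlabelled grid.
    """
    shape = tuple(spec["shape"])
    labels = np.zeros(shape, dtype=np.int32)
    roi_names: dict[int, str] = {}
    for lab, (name, ext) in enumerate(spec.get("rois", {}).items(), start=1):
        sl = tuple(slice(a, b) for a, b in ext)
        if np.any(labels[sl] != 0):
            raise ValueError(f"ROI block {name!r} overlaps an earlier block")
        labels[sl] = lab
        roi_names[lab] = name
    return VoxelGrid(labels=labels, roi_names=roi_names, voxel_size=voxel_size)


@dataclass(frozen=True)
class GenerativeProfile:
    """Affine mapping from model amplitudes to neural event amplitudes.

    response = baseline + slope_sign * gain * amplitude.  The default
    prediction-error profile uses slope_sign = −1 with baseline 1, i.e.
    response = gain * (1 − P): BOLD increases with surprise.  Model
    comparison is invariant to this affine choice.
    """

    model: str                  # "h1" | "h2" | "null"
    gain: float = 2.0
    slope_sign: int = -1
    baseline: float = 1.0

    def __post_init__(self) -> None:
        if self.model not in ("h1", "h2", "null"):
            raise ValueError(f"unknown generative model {self.model!r}")
        if self.model == "null" and (self.gain != 0 or self.baseline != 0):
            object.__setattr__(self, "gain", 0.0)
            object.__setattr__(self, "baseline", 0.0)

    def event_amplitudes(self, trial_amps: np.ndarray) -> np.ndarray:
        if self.model == "null":
            return np.zeros_like(trial_amps)
        return self.baseline + self.slope_sign * self.gain * trial_amps


NULL_PROFILE = GenerativeProfile("null", gain=0.0, baseline=0.0)


#: Default peak evoked amplitude, % of the mean signal: a 2% response to
#: suprathreshold auditory stimulation, typical of high-field measurements.
DEFAULT_GAIN = 2.0


def h1_profile(gain: float = DEFAULT_GAIN) -> GenerativeProfile:
    """Habituation responder: response proportional to the h1 amplitude."""
    return GenerativeProfile("h1", gain=gain, slope_sign=+1, baseline=0.0)


def h2_profile(gain: float = DEFAULT_GAIN) -> GenerativeProfile:
    """Prediction-error responder: response = gain * (1 − predictability)."""
    return GenerativeProfile("h2", gain=gain, slope_sign=-1, baseline=1.0)


@dataclass(frozen=True)
class NoiseSpec:
    """Structured noise: AR(1) + sinusoidal drift + white, scaled to tSNR.

    ``tsnr = None`` disables noise entirely (pure signal + mean).  The
    variance budget splits the target noise variance between the three
    components; drift phase is randomised per voxel.
    """

    tsnr: float | None = 50.0
    signal_mean: float = 100.0
    ar1: float = 0.3
    drift_period: float = 60.0         # s
    drift_frac: float = 0.10           # fraction of noise variance
    white_frac: float = 0.30

    def __post_init__(self) -> None:
        if not 0 <= self.ar1 < 1:
            raise ValueError("AR(1) coefficient must be in [0, 1)")
        if self.drift_frac + self.white_frac > 1:
            raise ValueError("variance fractions exceed 1")


NOISELESS = NoiseSpec(tsnr=None)


@dataclass(frozen=True)
class BOLDRun:
    """Simulated volumes for the labelled voxels of a grid."""

    data: np.ndarray            # (n_volumes, n_voxels)
    tr: float
    grid: VoxelGrid
    noise_spec: NoiseSpec
    seed: int

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    def to_nifti(self):
        import nibabel as nib
        vol = np.zeros(self.grid.shape + (self.n_volumes,), dtype=np.float32)
        flat = vol.reshape(-1, self.n_volumes)
        flat[self.grid.voxel_indices] = self.data.T
        affine = np.diag([self.grid.voxel_size] * 3 + [1.0])
        img = nib.Nifti1Image(vol, affine)
        img.header.set_zooms((self.grid.voxel_size,) * 3 + (self.tr,))
        return img


def n_volumes_for(schedule: RunSchedule, tr: float, tail: float = 20.0) -> int:
    """Volumes needed to cover a schedule plus hemodynamic tail."""
    return int(np.ceil((schedule.duration + tail) / tr))


def evoked_signal(schedule: RunSchedule, profile: GenerativeProfile,
                  tr: float, n_volumes: int) -> np.ndarray:
    """Noise-free evoked BOLD time course for one generative profile.

    Neural impulses (one per sound, amplitude from the profile) are laid
    on a 50 ms grid, convolved with the canonical HRF, and sampled at
    volume acquisition times.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    if profile.model == "null":
        return np.zeros(n_volumes)
    model = amplitude_model(profile.model)
    duration = max(schedule.duration, n_volumes * tr) + HRF_LENGTH
    n_micro = int(np.ceil(duration / MICROTIME)) + 1
    impulses = np.zeros(n_micro)
    for trial, t0 in zip(schedule.trials, schedule.trial_onsets):
        amps = profile.event_amplitudes(
            model.trial_amplitudes(trial.deviant_position))
        for pos, a in enumerate(amps):
            impulses[int(round((t0 + pos * SOA) / MICROTIME))] += a
    kernel = hrf(np.arange(0, HRF_LENGTH, MICROTIME))
    convolved = sp_signal.fftconvolve(impulses, kernel)[:n_micro]
    vol_idx = np.round(np.arange(n_volumes) * tr / MICROTIME).astype(int)
    return convolved[vol_idx]


def _noise(rng: np.random.Generator, spec: NoiseSpec, tr: float,
           n_volumes: int, n_voxels: int) -> np.ndarray:
    """AR(1) + drift + white noise with total sd = signal_mean / tsnr."""
    sd_total = spec.signal_mean / spec.tsnr
    var_total = sd_total ** 2
    var_drift = spec.drift_frac * var_total
    var_white = spec.white_frac * var_total
    var_ar = var_total - var_drift - var_white

    # AR(1) with stationary variance var_ar, started from stationarity
    innov_sd = np.sqrt(var_ar * (1.0 - spec.ar1 ** 2))
    eps = rng.normal(0.0, innov_sd, size=(n_volumes, n_voxels))
    x_init = rng.normal(0.0, np.sqrt(var_ar), size=n_voxels)
    ar, _ = sp_signal.lfilter([1.0], [1.0, -spec.ar1], eps, axis=0,
                              zi=(spec.ar1 * x_init)[None, :])

    t = np.arange(n_volumes) * tr
    phase = rng.uniform(0, 2 * np.pi, size=n_voxels)
    drift = np.sqrt(2 * var_drift) * np.sin(
        2 * np.pi * t[:, None] / spec.drift_period + phase[None, :])

    white = rng.normal(0.0, np.sqrt(var_white), size=(n_volumes, n_voxels))
    return ar + drift + white


def simulate_run(schedule: RunSchedule, grid: VoxelGrid,
                 profiles: dict[str, GenerativeProfile],
                 noise_spec: NoiseSpec = NoiseSpec(),
                 tr: float = 1.6, seed: int = 0,
                 n_volumes: int | None = None) -> BOLDRun:
    """Simulate one run over the labelled voxels of ``grid``.

    ``profiles`` maps ROI names to generative profiles; ROIs not listed
    respond as null.  Unknown ROI names are an error.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    known = set(grid.roi_names.values())
    unknown = set(profiles) - known
    if unknown:
        raise ValueError(f"profiles reference unknown ROIs: {sorted(unknown)}")
    if n_volumes is None:
        n_volumes = n_volumes_for(schedule, tr)

    voxel_labels = grid.voxel_labels
    data = np.full((n_volumes, grid.n_labeled), noise_spec.signal_mean)
    for lab, name in grid.roi_names.items():
        profile = profiles.get(name, NULL_PROFILE)
        cols = voxel_labels == lab
        if not cols.any() or profile.model == "null":
            continue
        data[:, cols] += evoked_signal(schedule, profile, tr, n_volumes)[:, None]

    if noise_spec.tsnr is not None:
        rng = np.random.default_rng(seed)
        data += _noise(rng, noise_spec, tr, n_volumes, grid.n_labeled)
    return BOLDRun(data=data, tr=tr, grid=grid, noise_spec=noise_spec, seed=seed)
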