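"""MEG filtering, resampling and ICA decomposition.

The decomposition is run in two modes: "triggered" on 0.6 s epochs centred
on the SEEG spike markers and concatenated in marker order, and
"continuous" on the whole recording with no marker information. Each mode
is combined with two zero-phase analysis bands, 2-60 Hz and 12-60 Hz.

The unmixing is a negentropy-based fixed-point ICA (FastICA) preceded by
PCA whitening to exactly ``n_components`` dimensions. ICA's amplitude and
sign indeterminacies are absorbed by convention: topographies are unit
norm with the maximal-|weight| sensor positive, all variance is carried by
the time course, and components are ordered by decreasing time-course
power. For a fixed seed the decomposition is fully deterministic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal
from sklearn.decomposition import FastICA

from .io import Epochs, Recording

logger = logging.getLogger("deepmeg")

ANALYSIS_BANDS = {"2-60": (2.0, 60.0), "12-60": (12.0, 60.0)}
TARGET_FS = 512.0
EPOCH_WINDOW = 0.6  # s


@dataclass
class IcaComponent:
    """One independent component: unit-norm sensor topography x time course.

    For ``mode="triggered"`` the time course is the concatenation of
    ``n_trials`` epochs of ``n_epoch_samples`` each, in marker order.
    """

    topography: np.ndarray  # (n_channels,), unit L2 norm
    timecourse: np.ndarray  # (n_samples,), carries the variance
    mode: str  # "triggered" | "continuous"
    band: str  # "2-60" | "12-60"
    seed: int
    index: int
    fs: float
    channel_ids: list[str]
    n_trials: int | None = None
    n_epoch_samples: int | None = None

    def epoched(self) -> np.ndarray:
        """Trials x samples view of a triggered-mode time course."""
        if self.n_trials is None or self.n_epoch_samples is None:
            raise ValueError("component has no epoch structure")
        return self.timecourse.reshape(self.n_trials, self.n_epoch_samples)


def _fir_taps(fs: float, low: float, high: float, transition: float) -> np.ndarray:
    numtaps = int(np.ceil(3.3 * fs / transition)) | 1
    taps = signal.firwin(numtaps, [low, high], pass_zero=False, fs=fs)
    # enforce an exact spectral null at DC (band-pass must kill offsets)
    taps = taps - taps.mean()
    return taps


def _zero_phase_filter(data: np.ndarray, taps: np.ndarray) -> np.ndarray:
    if data.shape[-1] <= len(taps):
        raise ValueError(
            f"recording of {data.shape[-1]} samples is shorter than the "
            f"{len(taps)}-tap filter"
        )
    # symmetric (linear-phase) taps + centred 'same' convolution = zero phase
    return signal.fftconvolve(data, taps[None, :], mode="same", axes=-1)


def _resample(data: np.ndarray, fs: float, target: float) -> np.ndarray:
    if abs(fs - round(fs)) < 1e-6 and abs(target - round(target)) < 1e-6:
        frac = Fraction(int(round(target)), int(round(fs)))
        return signal.resample_poly(data, frac.numerator, frac.denominator, axis=-1)
    n_out = int(round(data.shape[-1] * target / fs))
    return signal.resample(data, n_out, axis=-1)


def preprocess(rec: Recording) -> Recording:
    """Wide-band conditioning: zero-phase FIR 1-170 Hz, then resample to 512 Hz."""
    if rec.fs < 1024:
        raise ValueError("preprocess expects a raw sampling rate of at least 1024 Hz")
    taps = _fir_taps(rec.fs, 1.0, 170.0, transition=1.0)
    filtered = _zero_phase_filter(rec.data, taps)
    resampled = _resample(filtered, rec.fs, TARGET_FS)
    return Recording(resampled, TARGET_FS, rec.channel_ids, rec.channel_kinds, rec.t0)


def band_filter(rec: Recording, band: str | tuple[float, float]) -> Recording:
    """Zero-phase band-pass into one of the analysis bands."""
    if isinstance(band, str):
        if band not in ANALYSIS_BANDS:
            raise ValueError(f"unknown band {band!r}; use one of {list(ANALYSIS_BANDS)}")
        low, high = ANALYSIS_BANDS[band]
    else:
        low, high = band
    if high >= rec.fs / 2:
        raise ValueError("band edge above Nyquist")
    taps = _fir_taps(rec.fs, low, high, transition=max(1.0, low / 2.0))
    return Recording(
        _zero_phase_filter(rec.data, taps),
        rec.fs,
        rec.channel_ids,
        rec.channel_kinds,
        rec.t0,
    )


def qc_channels(
    data: np.ndarray, channel_ids: list[str], k_mad: float = 20.0
) -> tuple[np.ndarray, list[str], list[str]]:
    """Drop flat channels and channels with gross amplitude artifacts.

    A channel is flat when its variance is negligible relative to the
    median channel variance, and artifactual when its peak deviation
    exceeds ``k_mad`` times its own robust scale (1.4826 * MAD).
    """
    variances = data.var(axis=1)
    med_var = np.median(variances)
    keep, dropped = [], []
    for i, cid in enumerate(channel_ids):
        flat = variances[i] < max(1e-30, 1e-12 * med_var)
        x = data[i]
        mad = np.median(np.abs(x - np.median(x)))
        robust_sd = 1.4826 * mad
        artifact = robust_sd > 0 and np.max(np.abs(x - np.median(x))) > k_mad * robust_sd
        if flat or artifact:
            dropped.append(cid)
        else:
            keep.append(i)
    if dropped:
        logger.info("QC dropped channels: %s", dropped)
    return data[keep], [channel_ids[i] for i in keep], dropped


def run_ica(
    rec_or_epochs: Recording | Epochs,
    n_components: int = 20,
    seed: int = 0,
    band: str = "2-60",
    qc: bool = True,
    max_iter: int = 500,
) -> list[IcaComponent]:
    """FastICA decomposition into ``n_components`` components.

    Accepts a continuous recording (``mode="continuous"``) or epochs cut
    around spike markers, concatenated in marker order
    (``mode="triggered"``). Data are PCA-whitened to exactly
    ``n_components`` dimensions before the fixed-point iteration.
    """
    if isinstance(rec_or_epochs, Epochs):
        mode = "triggered"
        epochs = rec_or_epochs
        data = epochs.concatenate()
        channel_ids = list(epochs.channel_ids or [])
        fs = epochs.fs
        n_trials, n_epoch_samples = epochs.n_trials, epochs.n_samples
    else:
        mode = "continuous"
        data = rec_or_epochs.data
        channel_ids = list(rec_or_epochs.channel_ids)
        fs = rec_or_epochs.fs
        n_trials = n_epoch_samples = None

    dropped: list[str] = []
    if qc:
        data, channel_ids, dropped = qc_channels(data, channel_ids)
    n_channels, n_samples = data.shape
    if n_channels < n_components:
        raise ValueError(
            f"{n_channels} channels cannot support {n_components} components"
        )
    if n_samples <= n_components:
        raise ValueError("need more samples than components")
    sv = np.linalg.svd(data - data.mean(axis=1, keepdims=True), compute_uv=False)
    rank = int(np.sum(sv > sv[0] * 1e-10))
    if rank < n_components:
        raise ValueError(
            f"data rank {rank} is below the requested {n_components} components"
        )

    ica = FastICA(
        n_components=n_components,
        algorithm="parallel",
        fun="logcosh",
        whiten="unit-variance",
        max_iter=max_iter,
        tol=2e-5,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*did not converge.*")
        sources = ica.fit_transform(data.T)  # (samples, n_components)
    mixing = ica.mixing_  # (channels, n_components)

    comps: list[IcaComponent] = []
    for i in range(n_components):
        topo = mixing[:, i].copy()
        norm = np.linalg.norm(topo)
        if norm == 0:
            continue
        tc = sources[:, i] * norm
        topo = topo / norm
        jmax = int(np.argmax(np.abs(topo)))
        if topo[jmax] < 0:
            topo, tc = -topo, -tc
        comps.append(
            IcaComponent(
                topography=topo,
                timecourse=tc,
                mode=mode,
                band=band,
                seed=seed,
                index=i,
                fs=fs,
                channel_ids=channel_ids,
                n_trials=n_trials,
                n_epoch_samples=n_epoch_samples,
            )
        )
    # deterministic ordering: decreasing time-course power, original index ties
    comps.sort(key=lambda c: (-float(np.var(c.timecourse)), c.index))
    for new_index, c in enumerate(comps):
        c.index = new_index
    return comps


def back_project(component: IcaComponent) -> Recording:
    """Rank-1 sensor-space signal of one component (original sensor units)."""
    data = np.outer(component.topography, component.timecourse)
    return Recording(
        data,
        component.fs,
        component.channel_ids,
        "meg_mag",
    )


def backproject_sensor(component: IcaComponent, sensor: int | None = None) -> np.ndarray:
    """Back-projection on a single sensor (default: max |topography| weight)."""
    if sensor is None:
        sensor = int(np.argmax(np.abs(component.topography)))
    return component.topography[sensor] * component.timecourse
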