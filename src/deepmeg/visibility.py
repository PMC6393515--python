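"""SNR of back-projected components and the bootstrap visibility curve.

Two decibel ratios quantify whether a network found by ICA would be seen
at the helmet. Against background: the peak of the trial-averaged
back-projection in a +-50 ms window around the spike, over the standard
deviation of the same averaged trace in the flanking baseline
([-0.3, -0.05] U [0.05, 0.3] s). Against concurrent activity: the same
peak over the peak of the averaged residual (the sum of all other
components) on the same sensor and window. A signal is "visible" at
>= 10 dB, i.e. roughly a 3x amplitude ratio.

The visibility curve repeats the background SNR on growing random subsets
of events (5, 10, 15, ... without replacement, 50 draws per count) and
reports the smallest count at which at least 75% of draws are visible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

VISIBILITY_DB = 10.0
SIGNAL_WINDOW = (-0.05, 0.05)
NOISE_WINDOWS = ((-0.3, -0.05), (0.05, 0.3))

#: Sentinel minimum-count value when no tested count reaches visibility.
NOT_VISIBLE = -1


def amplitude_ratio(db: float) -> float:
    """Amplitude ratio corresponding to a dB value under 20*log10."""
    return 10.0 ** (db / 20.0)


def percent_visible(n_visible: int, n_total: int) -> int:
    """Whole-percent summary of a visible-component count (45/115 -> 39)."""
    if not 0 <= n_visible <= n_total or n_total <= 0:
        raise ValueError("need 0 <= n_visible <= n_total, n_total > 0")
    return int(np.floor(100.0 * n_visible / n_total))


@dataclass
class SnrResult:
    component: int
    sensor: int
    snr_background_db: float
    snr_concurrent_db: float

    @property
    def visible_background(self) -> bool:
        return self.snr_background_db >= VISIBILITY_DB

    @property
    def visible_concurrent(self) -> bool:
        return self.snr_concurrent_db >= VISIBILITY_DB


@dataclass
class VisibilityCurve:
    counts: np.ndarray
    fractions: np.ndarray  # fraction of draws with SNR >= 10 dB, per count
    n_draws: int
    min_visible_count: int  # NOT_VISIBLE when no count qualifies

    @property
    def visible(self) -> bool:
        return self.min_visible_count != NOT_VISIBLE


def _window_mask(n_samples: int, fs: float, window: tuple[float, float]) -> np.ndarray:
    half = (n_samples - 1) // 2
    rel = (np.arange(n_samples) - half) / fs
    # endpoints inclusive at sample resolution
    eps = 0.5 / fs
    return (rel >= window[0] - eps) & (rel <= window[1] + eps)


def snr_background(
    component_epochs: np.ndarray,
    fs: float,
    signal_window: tuple[float, float] = SIGNAL_WINDOW,
    noise_windows=NOISE_WINDOWS,
) -> float:
    """Background SNR (dB) of single-sensor epochs of a back-projection.

    SNR = 20 log10( max|s_bar| / sigma ), with s_bar the trial average in
    the signal window and sigma the standard deviation of the averaged
    trace over the concatenated baseline segments — so averaging more
    events raises the SNR by ~10 log10(n) for event-locked signals in
    stationary noise.
    """
    ep = np.atleast_2d(np.asarray(component_epochs, dtype=float))
    n_samples = ep.shape[1]
    avg = ep.mean(axis=0)
    sig_mask = _window_mask(n_samples, fs, signal_window)
    noise_mask = np.zeros(n_samples, dtype=bool)
    for w in noise_windows:
        noise_mask |= _window_mask(n_samples, fs, w)
    peak = float(np.max(np.abs(avg[sig_mask])))
    sigma = float(np.std(avg[noise_mask]))
    if sigma == 0:
        import warnings

        warnings.warn("zero background SD; SNR is infinite")
        return np.inf
    return 20.0 * np.log10(peak / sigma)


def snr_concurrent(
    component_epochs: np.ndarray,
    residual_epochs: np.ndarray,
    fs: float,
    signal_window: tuple[float, float] = SIGNAL_WINDOW,
) -> float:
    """Concurrent-activity SNR (dB): component peak over residual peak.

    Both inputs are single-sensor epochs (same sensor: the component's
    maximal-|topography| channel); the residual is the sum of all other
    components' back-projections. Both are averaged over the same trials
    and compared in the same +-50 ms window around the spike.
    """
    comp = np.atleast_2d(np.asarray(component_epochs, dtype=float))
    resid = np.atleast_2d(np.asarray(residual_epochs, dtype=float))
    if comp.shape != resid.shape:
        raise ValueError("component and residual epochs must share trials/samples")
    mask = _window_mask(comp.shape[1], fs, signal_window)
    peak = float(np.max(np.abs(comp.mean(axis=0)[mask])))
    peak_resid = float(np.max(np.abs(resid.mean(axis=0)[mask])))
    if peak_resid == 0:
        import warnings

        warnings.warn("zero residual peak; SNR is infinite")
        return np.inf
    return 20.0 * np.log10(peak / peak_resid)


def visibility_curve(
    component_epochs: np.ndarray,
    fs: float,
    counts: np.ndarray | None = None,
    n_draws: int = 50,
    threshold_db: float = VISIBILITY_DB,
    required_fraction: float = 0.75,
    seed: int = 0,
) -> VisibilityCurve:
    """Bootstrap visibility over an increasing number of averaged events.

    For each tested count, ``n_draws`` random subsets are drawn without
    replacement and the background SNR computed on each; the fraction of
    draws at or above ``threshold_db`` is recorded. Counts exceeding the
    number of available events are skipped with a warning.
    """
    ep = np.atleast_2d(np.asarray(component_epochs, dtype=float))
    n_events = ep.shape[0]
    if counts is None:
        counts = np.arange(5, n_events + 1, 5)
        if len(counts) == 0 or counts[-1] != n_events:
            counts = np.append(counts, n_events)
    counts = np.asarray(sorted(set(int(c) for c in counts)))
    usable = counts[counts <= n_events]
    if len(usable) < len(counts):
        import warnings

        warnings.warn(
            f"counts above the {n_events} available events were skipped"
        )
    rng = np.random.default_rng(seed)
    fractions = np.empty(len(usable))
    for k, count in enumerate(usable):
        ok = 0
        for _ in range(n_draws):
            idx = rng.choice(n_events, size=count, replace=False)
            if snr_background(ep[idx], fs) >= threshold_db:
                ok += 1
        fractions[k] = ok / n_draws
    qualifying = np.nonzero(fractions >= required_fraction)[0]
    min_count = int(usable[qualifying[0]]) if qualifying.size else NOT_VISIBLE
    return VisibilityCurve(
        counts=usable,
        fractions=fractions,
        n_draws=n_draws,
        min_visible_count=min_count,
    )
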