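"""Synthetic simultaneous SEEG-MEG sessions with known ground truth.

The generator emulates the statistical structure of resting-state
recordings in temporal lobe epilepsy: interictal spikes produced by a deep
source (hippocampus, amygdala, thalamus) either alone or co-activated at
zero lag with neocortical sources; ongoing background activity (a
distributed 10 Hz rhythm from superficial dipoles plus 1/f and white sensor
noise); SEEG bipolar channels that read their structure's source almost
directly; and two acquisition clocks related by an affine offset/drift,
co-registrable through shared jittered triggers (inter-trigger 3.0-3.5 s).

Amplitudes follow the regime in which deep activity is small at the helmet
relative to ongoing superficial activity — separable by ICA but hidden in
the raw sensor traces. Deep spiking sources default to 20 nA·m; the
superficial background is scaled so that, at the sensor where the deep
source is largest, the ongoing-activity RMS is ``background_factor`` (3x by
default) the deep source's peak deflection.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import numpy as np
from scipy import fft

from .forward import (
    SensorArray,
    Sphere,
    _sarvas_matrix,
    make_helmet,
    tangential_unit,
)
from .io import (
    Contact,
    ContactMontage,
    EventMarkers,
    Recording,
    build_bipolar_montage,
)

DEEP_STRUCTURES = ("hippocampus", "amygdala", "thalamus", "putamen", "insula")

#: Canonical source positions (m, sphere-centred) used by the presets.
STRUCTURE_POSITIONS = {
    "hippocampus": (0.025, 0.020, 0.000),
    "amygdala": (0.028, 0.012, -0.008),
    "thalamus": (0.008, 0.010, 0.020),
    "lateral temporal neocortex": (0.062, 0.022, 0.010),
}


@dataclass(frozen=True)
class SourceSpec:
    """One simulated generator: where it is, what it is, how strong."""

    structure: str
    position: tuple[float, float, float]
    amplitude: float = 20e-9  # A·m at the spike peak
    orientation: tuple[float, float, float] | None = None  # default: tangential


@dataclass
class NetworkScenario:
    """Full specification of a synthetic session.

    ``co_activation`` lists the candidate active-source subsets (structure
    names); each spike event draws one subset uniformly and all its members
    fire at zero lag. ``marked_structure`` is the structure whose SEEG
    channel carries the visual spike marks.
    """

    name: str
    sources: list[SourceSpec]
    co_activation: list[tuple[str, ...]]
    marked_structure: str | None
    spike_rate: float = 30.0  # events / min
    amplitude_jitter: float = 0.3  # lognormal sigma of per-event amplitude
    duration: float = 120.0  # s
    background_factor: float = 3.0  # background RMS / deep peak, at best sensor
    background_rms_ft: float | None = None  # absolute override (used when no sources)
    sensor_noise_ft: float = 15.0  # white sensor noise RMS
    pink_noise_ft: float = 15.0  # 1/f sensor noise RMS
    seeg_spike_uv: float = 300.0  # SEEG spike peak on the source's channel
    seeg_noise_uv: float = 10.0  # white noise RMS on SEEG channels
    seeg_pink_uv: float = 30.0  # 1/f background RMS on SEEG channels
    seeg_leakage: float = 0.0  # cross-structure leakage factor
    n_background_dipoles: int = 20
    alpha_freq: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(len(s) == 0 for s in self.co_activation):
            raise ValueError("co-activation subsets must be non-empty")
        names = {s.structure for s in self.sources}
        for subset in self.co_activation:
            missing = set(subset) - names
            if missing:
                raise ValueError(f"co-activation names unknown sources: {missing}")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    source_structures: list[str]
    source_positions: np.ndarray  # (n_sources, 3) m
    source_timecourses: np.ndarray  # (n_sources, n_samples) at meg fs, MEG clock
    fs: float
    event_times: np.ndarray  # physical (MEG-clock) anchor times, s
    event_active_sets: list[tuple[str, ...]]
    clock_offset: float
    clock_drift: float


@dataclass
class SimulatedSession:
    meg: Recording
    seeg: Recording
    markers: EventMarkers  # in the SEEG clock (where spikes are marked)
    meg_triggers: np.ndarray
    seeg_triggers: np.ndarray
    ground_truth: GroundTruth
    scenario: NetworkScenario
    montage: ContactMontage


# ---------------------------------------------------------------------------
# Waveform
# ---------------------------------------------------------------------------


def spike_waveform(
    fs: float,
    duration_ms: float = 400.0,
    sharp_ms: float = 60.0,
    wave_ms: float = 200.0,
    wave_amp: float = 0.4,
) -> tuple[np.ndarray, int]:
    """Template interictal spike: biphasic sharp transient + slow wave.

    Returns ``(waveform, anchor)`` where ``anchor`` is the sample index of
    the global absolute extremum, normalised to +1 — the sample on which a
    reviewer would place the instantaneous mark (peak of the maximal
    deflection). Energy is concentrated well below 60 Hz so the analysis
    bands retain the transient.
    """
    if duration_ms <= 0 or sharp_ms <= 0:
        raise ValueError("durations must be positive")
    if sharp_ms >= duration_ms:
        raise ValueError("sharp_ms must be smaller than duration_ms")
    if wave_ms < 0:
        raise ValueError("wave_ms must be >= 0")
    n = int(round(duration_ms / 1000.0 * fs))
    t = np.arange(n) / fs * 1000.0  # ms
    t_peak = duration_ms * 0.3
    sigma = sharp_ms / 4.0
    # biphasic sharp transient: dominant positive lobe + earlier negative lobe
    sharp = np.exp(-((t - t_peak) ** 2) / (2 * sigma**2)) - 0.5 * np.exp(
        -((t - (t_peak - 1.2 * sigma)) ** 2) / (2 * (0.8 * sigma) ** 2)
    )
    w = sharp
    if wave_ms > 0:
        wave_start = t_peak + 1.5 * sigma
        in_wave = (t >= wave_start) & (t <= wave_start + wave_ms)
        wave = np.zeros_like(t)
        wave[in_wave] = -wave_amp * np.sin(
            np.pi * (t[in_wave] - wave_start) / wave_ms
        )
        w = w + wave
    anchor = int(np.argmax(np.abs(w)))
    w = w / w[anchor]  # global extremum +1 at the anchor
    return w, anchor


# ---------------------------------------------------------------------------
# Noise helpers
# ---------------------------------------------------------------------------


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """1/f-amplitude noise with unit RMS per row."""
    n = shape[1]
    nfft = fft.next_fast_len(n)  # arbitrary lengths can hit slow FFT sizes
    white = rng.standard_normal((shape[0], nfft))
    spec = fft.rfft(white, axis=1)
    freqs = fft.rfftfreq(nfft)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz] / freqs[nz][0])
    pink = fft.irfft(spec * scale[None, :], n=nfft, axis=1)[:, :n]
    rms = np.sqrt(np.mean(pink**2, axis=1, keepdims=True))
    return pink / rms


def _slow_envelopes(
    rng: np.random.Generator, n_rows: int, n: int, fs: float
) -> np.ndarray:
    """Positive slowly varying amplitude envelopes (waxing/waning rhythms)."""
    nfft = fft.next_fast_len(n)
    slow = rng.standard_normal((n_rows, nfft))
    spec = fft.rfft(slow, axis=1)
    freqs = fft.rfftfreq(nfft, d=1.0 / fs)
    spec[:, freqs > 0.5] = 0.0
    slow = fft.irfft(spec, n=nfft, axis=1)[:, :n]
    slow = slow / (np.std(slow, axis=1, keepdims=True) + 1e-30)
    return 1.0 + 0.5 * np.tanh(slow)


# ---------------------------------------------------------------------------
# Session synthesis
# ---------------------------------------------------------------------------


def _source_orientation(spec: SourceSpec, sphere: Sphere) -> np.ndarray:
    if spec.orientation is not None:
        v = np.asarray(spec.orientation, dtype=float)
        return v / np.linalg.norm(v)
    return tangential_unit(np.asarray(spec.position), sphere)


def _event_times(rng: np.random.Generator, scenario: NetworkScenario) -> np.ndarray:
    """Spike anchor times: Poisson-like with a refractory gap, inside buffers."""
    rate_hz = scenario.spike_rate / 60.0
    if rate_hz <= 0:
        return np.array([])
    t, times = 4.0, []
    while True:
        t += max(0.8, rng.exponential(1.0 / rate_hz))
        if t > scenario.duration - 2.0:
            break
        times.append(t)
    return np.asarray(times)


def simulate_session(
    scenario: NetworkScenario,
    sensors: SensorArray,
    sphere: Sphere,
    montage: ContactMontage,
    fs_meg: float = 1024.0,
    fs_seeg: float = 2048.0,
) -> SimulatedSession:
    """Generate one simultaneous session (MEG + SEEG + markers + truth).

    MEG rows are ``gain x source time courses`` plus projected background
    dipoles and sensor noise. Each SEEG bipolar channel whose anatomical
    label matches a source structure reads that source's time course at
    full amplitude plus local noise; all channels carry 1/f background.
    The SEEG clock is offset/drifted relative to MEG; shared triggers with
    3.0-3.5 s jittered spacing are emitted in both time bases.
    """
    rng = np.random.default_rng(scenario.seed)
    n_meg = int(round(scenario.duration * fs_meg))
    t_phys = np.arange(n_meg) / fs_meg

    # -- check montage coverage
    for spec in scenario.sources:
        if not montage.channels_for_label(spec.structure):
            raise ValueError(
                f"montage has no SEEG channel labeled {spec.structure!r}"
            )

    # -- events and per-event amplitudes
    events = _event_times(rng, scenario)
    active_sets: list[tuple[str, ...]] = []
    for _ in events:
        active_sets.append(
            tuple(scenario.co_activation[rng.integers(len(scenario.co_activation))])
            if scenario.co_activation
            else ()
        )
    wf, anchor = spike_waveform(fs_meg)

    source_tc = np.zeros((len(scenario.sources), n_meg))
    event_amps = np.zeros((len(events), len(scenario.sources)))
    for e, (t_ev, active) in enumerate(zip(events, active_sets)):
        start = int(round(t_ev * fs_meg)) - anchor
        for s, spec in enumerate(scenario.sources):
            if spec.structure not in active:
                continue
            amp = float(
                np.exp(rng.normal(0.0, scenario.amplitude_jitter))
            )
            event_amps[e, s] = amp
            lo, hi = max(start, 0), min(start + len(wf), n_meg)
            source_tc[s, lo:hi] += amp * wf[lo - start : hi - start]

    # -- MEG forward projection of the spiking sources
    meg = np.zeros((sensors.n_sensors, n_meg))
    gains = []
    for s, spec in enumerate(scenario.sources):
        ori = _source_orientation(spec, sphere)
        gain = ori @ _sarvas_matrix(np.asarray(spec.position), sensors, sphere)
        gains.append(gain * spec.amplitude)  # fT at unit (peak) time course
        meg += np.outer(gains[-1], source_tc[s])

    # -- reference deep amplitude used to scale the ongoing background
    deep_idx = [
        s
        for s, spec in enumerate(scenario.sources)
        if spec.structure in DEEP_STRUCTURES
    ]
    if deep_idx:
        ref = deep_idx[0]
        best_sensor = int(np.argmax(np.abs(gains[ref])))
        deep_peak_ft = float(np.abs(gains[ref][best_sensor]))
    else:
        best_sensor, deep_peak_ft = 0, np.nan

    # -- distributed superficial background rhythm
    if scenario.n_background_dipoles > 0:
        n_bg = scenario.n_background_dipoles
        bg_gains = np.empty((n_bg, sensors.n_sensors))
        phases = np.empty(n_bg)
        for k in range(n_bg):
            z = rng.uniform(0.1, 0.95)
            phi = rng.uniform(0, 2 * np.pi)
            sin_t = np.sqrt(1 - z**2)
            pos = 0.8 * sphere.radius * np.array(
                [sin_t * np.cos(phi), sin_t * np.sin(phi), z]
            ) + sphere.center_arr
            ori = tangential_unit(pos, sphere)
            bg_gains[k] = ori @ _sarvas_matrix(pos, sensors, sphere)
            phases[k] = rng.uniform(0, 2 * np.pi)
        bg_osc = np.sin(
            2 * np.pi * scenario.alpha_freq * t_phys[None, :] + phases[:, None]
        ) * _slow_envelopes(rng, n_bg, n_meg, fs_meg)
        bg = bg_gains.T @ bg_osc
        if scenario.background_rms_ft is not None:
            target = scenario.background_rms_ft
            current = float(np.sqrt(np.mean(bg**2)))
        else:
            target = scenario.background_factor * deep_peak_ft
            current = float(np.sqrt(np.mean(bg[best_sensor] ** 2)))
        if current > 0 and np.isfinite(target):
            bg *= target / current
        meg += bg

    # -- sensor noise
    if scenario.pink_noise_ft > 0:
        meg += scenario.pink_noise_ft * _pink_noise(rng, meg.shape)
    if scenario.sensor_noise_ft > 0:
        meg += scenario.sensor_noise_ft * rng.standard_normal(meg.shape)

    # -- clock model and shared triggers
    offset = float(rng.uniform(0.5, 1.5))
    drift = float(1.0 + rng.uniform(-2e-5, 2e-5))
    trig = [2.0]
    while trig[-1] + 3.5 < scenario.duration - 1.0:
        trig.append(trig[-1] + float(rng.uniform(3.0, 3.5)))
    meg_triggers = np.asarray(trig)
    seeg_triggers = offset + drift * meg_triggers

    # -- SEEG synthesis in its own (shifted) clock
    seeg_duration = offset + drift * scenario.duration
    n_seeg = int(round(seeg_duration * fs_seeg))
    wf_seeg, anchor_seeg = spike_waveform(fs_seeg)
    seeg = np.zeros((len(montage.bipolar_channels), n_seeg))
    label_to_rows: dict[str, list[int]] = {}
    for row, ch in enumerate(montage.bipolar_channels):
        label_to_rows.setdefault(ch.label, []).append(row)
    for s, spec in enumerate(scenario.sources):
        rows = label_to_rows.get(spec.structure, [])
        for e, t_ev in enumerate(events):
            if event_amps[e, s] == 0.0:
                continue
            t_seeg = offset + drift * t_ev
            start = int(round(t_seeg * fs_seeg)) - anchor_seeg
            lo, hi = max(start, 0), min(start + len(wf_seeg), n_seeg)
            chunk = event_amps[e, s] * scenario.seeg_spike_uv * wf_seeg[
                lo - start : hi - start
            ]
            for row in rows:
                seeg[row, lo:hi] += chunk
            if scenario.seeg_leakage > 0:
                for other, rows_o in label_to_rows.items():
                    if other == spec.structure:
                        continue
                    for row in rows_o:
                        seeg[row, lo:hi] += scenario.seeg_leakage * chunk
    if scenario.seeg_pink_uv > 0:
        seeg += scenario.seeg_pink_uv * _pink_noise(rng, seeg.shape)
    if scenario.seeg_noise_uv > 0:
        seeg += scenario.seeg_noise_uv * rng.standard_normal(seeg.shape)

    # -- markers: anchors of events where the marked structure fired (SEEG clock)
    marker_times, marker_structs, marker_chans = [], [], []
    if scenario.marked_structure is not None:
        mark_chan = montage.channels_for_label(scenario.marked_structure)[0]
        for t_ev, active in zip(events, active_sets):
            if scenario.marked_structure in active:
                marker_times.append(offset + drift * t_ev)
                marker_structs.append(scenario.marked_structure)
                marker_chans.append(mark_chan.channel_id)

    meg_rec = Recording(
        meg,
        fs_meg,
        [f"MEG{i:03d}" for i in range(sensors.n_sensors)],
        "meg_mag",
    )
    seeg_rec = Recording(
        seeg, fs_seeg, [c.channel_id for c in montage.bipolar_channels], "seeg_bipolar"
    )
    truth = GroundTruth(
        source_structures=[s.structure for s in scenario.sources],
        source_positions=np.array([s.position for s in scenario.sources], dtype=float)
        if scenario.sources
        else np.empty((0, 3)),
        source_timecourses=source_tc,
        fs=fs_meg,
        event_times=events,
        event_active_sets=active_sets,
        clock_offset=offset,
        clock_drift=drift,
    )
    return SimulatedSession(
        meg=meg_rec,
        seeg=seeg_rec,
        markers=EventMarkers(np.asarray(marker_times), marker_structs, marker_chans),
        meg_triggers=meg_triggers,
        seeg_triggers=seeg_triggers,
        ground_truth=truth,
        scenario=scenario,
        montage=montage,
    )


# ---------------------------------------------------------------------------
# Presets and default geometry
# ---------------------------------------------------------------------------

PRESET_NAMES = ("M", "L", "ML", "eL_thalamus", "null")


def scenario_presets(name: str, seed: int = 0, **overrides) -> NetworkScenario:
    """Named scenario families mirroring the observed interictal networks.

    M: a lone mesial (hippocampal) spiking source. L: a lone lateral
    neocortical source. ML: hippocampus + lateral neocortex co-activated at
    zero lag. eL_thalamus: hippocampus + thalamus co-activated. null:
    background only, no spike sources and no markers.
    """
    hip = SourceSpec("hippocampus", STRUCTURE_POSITIONS["hippocampus"], 20e-9)
    lat = SourceSpec(
        "lateral temporal neocortex",
        STRUCTURE_POSITIONS["lateral temporal neocortex"],
        30e-9,
    )
    tha = SourceSpec("thalamus", STRUCTURE_POSITIONS["thalamus"], 15e-9)
    if name == "M":
        scn = NetworkScenario(
            "M", [hip], [("hippocampus",)], "hippocampus", seed=seed
        )
    elif name == "L":
        scn = NetworkScenario(
            "L",
            [lat],
            [("lateral temporal neocortex",)],
            "lateral temporal neocortex",
            seed=seed,
        )
    elif name == "ML":
        scn = NetworkScenario(
            "ML",
            [hip, lat],
            [("hippocampus", "lateral temporal neocortex")],
            "hippocampus",
            seed=seed,
        )
    elif name == "eL_thalamus":
        scn = NetworkScenario(
            "eL_thalamus",
            [hip, tha],
            [("hippocampus", "thalamus")],
            "hippocampus",
            seed=seed,
        )
    elif name == "null":
        scn = NetworkScenario(
            "null",
            [],
            [],
            None,
            spike_rate=0.0,
            background_rms_ft=150.0,
            seed=seed,
        )
    else:
        raise ValueError(f"unknown preset {name!r}; valid presets: {PRESET_NAMES}")
    return replace(scn, **overrides) if overrides else scn


def make_default_montage(
    scenario: NetworkScenario,
    n_electrodes: int = 12,
    n_contacts: int = 10,
    contact_spacing_mm: float = 3.5,
    sphere: Sphere | None = None,
    seed: int = 12345,
) -> ContactMontage:
    """Synthetic implantation covering the scenario's structures.

    One electrode per source structure enters radially with its deepest
    contact at the source; the deepest three contacts are gray matter with
    the structure's label, middle contacts are white matter, outer contacts
    gray "other". Additional filler electrodes labelled "other" bring the
    bipolar channel count to a realistic implantation density.
    """
    sphere = sphere or Sphere()
    rng = np.random.default_rng(seed)
    contacts: list[Contact] = []
    letters = [chr(ord("A") + i) for i in range(26)]
    targets = [
        (spec.structure, np.asarray(spec.position, dtype=float))
        for spec in scenario.sources
    ]
    n_filler = max(0, n_electrodes - len(targets))
    for _ in range(n_filler):
        z = rng.uniform(-0.2, 0.9)
        phi = rng.uniform(0, 2 * np.pi)
        sin_t = np.sqrt(1 - z**2)
        pos = rng.uniform(0.3, 0.7) * sphere.radius * np.array(
            [sin_t * np.cos(phi), sin_t * np.sin(phi), z]
        ) + sphere.center_arr
        targets.append(("other", pos))
    for e, (structure, deep_pos) in enumerate(targets):
        direction = deep_pos - sphere.center_arr
        nrm = np.linalg.norm(direction)
        direction = (
            direction / nrm if nrm > 1e-9 else np.array([1.0, 0.0, 0.0])
        )
        elec = letters[e % 26] + ("" if e < 26 else str(e // 26))
        for k in range(n_contacts):
            pos_mm = (deep_pos + k * contact_spacing_mm / 1000.0 * direction) * 1000.0
            if k < 3:
                tissue, label = "gray", structure
            elif k < 6:
                tissue, label = "white", "other"
            else:
                tissue, label = "gray", "other"
            contacts.append(
                Contact(
                    contact_id=f"{elec}{k + 1}",
                    electrode=elec,
                    index=k + 1,
                    position_mm=tuple(np.round(pos_mm, 3)),
                    label=label,
                    tissue=tissue,
                )
            )
    return build_bipolar_montage(contacts)


def default_sensors(n_sensors: int = 248) -> SensorArray:
    return make_helmet(n_sensors=n_sensors)
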