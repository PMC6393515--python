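"""Depth-surface coupling statistics: the core component-selection machinery.

A surface ICA component is linked to an intracerebral (SEEG) channel through
a multi-step test battery, all at zero lag:

1. *Temporal correlation*: Pearson r between the component's single-trial
   time course and each SEEG channel, with all spike epochs concatenated
   along time. The r values are variance-stabilised by the Fisher
   transform, eta = 1/2 log((1+r)/(1-r)), and thresholded by a local false
   discovery rate (lFDR <= 0.2) with an empirical Gaussian null fitted to
   the centre of the pooled histogram.
2. *Inter-trial correlation (ITCOR)*: at each peri-spike time point, the
   correlation across trials between component and channel amplitudes —
   requiring that amplitudes co-fluctuate across events, not merely that
   average shapes agree. The Fisher-transformed series is thresholded by
   the same lFDR machinery, pooled over channels and time per component.
3. *Zero-lag check*: the peaks of the averaged absolute waveforms of the
   component and its best channel must align within a small tolerance, so
   delayed (propagated) activity is not mistaken for a direct contribution.

A component is selected only if it passes all three stages; the
significant channel set is the intersection of channels passing stages
1 and 2.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io import Epochs
from .preprocessing import IcaComponent

logger = logging.getLogger("deepmeg")


# ---------------------------------------------------------------------------
# Fisher transform
# ---------------------------------------------------------------------------


def fisher_transform(r: np.ndarray | float, strict: bool = True):
    """Variance-stabilising transform eta = 1/2 log((1+r)/(1-r)).

    Odd and strictly increasing on (-1, 1). With ``strict`` (default),
    |r| >= 1 is rejected; otherwise +-inf sentinels are returned.
    """
    arr = np.asarray(r, dtype=float)
    if strict and np.any(np.abs(arr) >= 1.0):
        raise ValueError("|r| must be < 1 for the Fisher transform")
    with np.errstate(divide="ignore"):
        eta = np.arctanh(np.clip(arr, -1.0, 1.0))
    return eta if isinstance(r, np.ndarray) else float(eta)


# ---------------------------------------------------------------------------
# Correlation stages
# ---------------------------------------------------------------------------


def temporal_correlation(
    component_timecourses: np.ndarray, seeg_epochs: Epochs
) -> np.ndarray:
    """Zero-lag Pearson r over concatenated epochs, per (component, channel).

    ``component_timecourses`` is (n_components, n_trials * n_samples) in the
    same concatenation order as ``seeg_epochs``. Zero-variance series yield
    NaN and are excluded from downstream pooling.
    """
    comp = np.atleast_2d(np.asarray(component_timecourses, dtype=float))
    seeg = seeg_epochs.concatenate()  # (n_channels, T)
    if comp.shape[1] != seeg.shape[1]:
        raise ValueError(
            f"concatenated lengths differ: components {comp.shape[1]} vs "
            f"SEEG {seeg.shape[1]}"
        )

    def _standardize(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, keepdims=True)
        ok = sd[:, 0] > 0
        xs = np.where(sd > 0, (x - mu) / np.where(sd > 0, sd, 1.0), 0.0)
        return xs, ok

    cs, c_ok = _standardize(comp)
    ss, s_ok = _standardize(seeg)
    r = cs @ ss.T / comp.shape[1]
    r[~c_ok, :] = np.nan
    r[:, ~s_ok] = np.nan
    return np.clip(r, -1.0, 1.0)


def itcor(component_epochs: np.ndarray, seeg_epochs: Epochs, min_trials: int = 10):
    """Inter-trial correlation series per SEEG channel.

    For each channel and each peri-spike time point t, the Pearson
    correlation across trials between the component amplitude at t and the
    channel amplitude at t. Returns (n_channels, n_samples).
    """
    comp = np.asarray(component_epochs, dtype=float)  # (trials, samples)
    if comp.ndim != 2:
        raise ValueError("component epochs must be (trials, samples)")
    seeg = seeg_epochs.data  # (trials, channels, samples)
    if comp.shape[0] != seeg.shape[0]:
        raise ValueError("component and SEEG trial counts differ")
    if comp.shape[1] != seeg.shape[2]:
        raise ValueError("component and SEEG epoch lengths differ")
    n_trials = comp.shape[0]
    if n_trials < min_trials:
        raise ValueError(f"ITCOR requires at least {min_trials} trials, got {n_trials}")

    def _std_trials(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mu = x.mean(axis=0, keepdims=True)
        sd = x.std(axis=0, keepdims=True)
        ok = sd > 0
        return np.where(ok, (x - mu) / np.where(ok, sd, 1.0), 0.0), ok

    cs, c_ok = _std_trials(comp)  # (trials, samples)
    ss, s_ok = _std_trials(seeg)  # (trials, channels, samples)
    r = np.einsum("ts,tcs->cs", cs, ss) / n_trials
    bad = (~c_ok[0])[None, :] | (~s_ok[0])
    r[bad] = np.nan
    return np.clip(r, -1.0, 1.0)


def exact_null_z(r: np.ndarray, n_trials: int) -> np.ndarray:
    """Map trial-dimension correlations through their exact null to z-scores.

    With only tens of trials the Fisher transform of a Pearson r has
    visibly heavier-than-Gaussian tails, which defeats a Gaussian
    empirical null. The exact null of r (via t = r sqrt((n-2)/(1-r^2)) ~
    t_{n-2}) maps to strictly standard-normal z-values, so the lFDR
    machinery stays calibrated at any trial count. NaNs pass through.
    """
    if n_trials < 3:
        raise ValueError("need at least 3 trials for the exact null")
    r = np.asarray(r, dtype=float)
    out = np.full(r.shape, np.nan)
    ok = np.isfinite(r)
    rc = np.clip(r[ok], -0.9999999, 0.9999999)
    t = rc * np.sqrt((n_trials - 2) / (1.0 - rc**2))
    p = np.clip(stats.t.cdf(t, n_trials - 2), 1e-300, 1.0 - 1e-16)
    out[ok] = stats.norm.ppf(p)
    return out


def itcor_select(
    series: np.ndarray, n_trials: int, threshold: float = 0.2
) -> tuple[np.ndarray, "LocalFdrFit"]:
    """lFDR significance of an ITCOR series pooled over channels and time."""
    return local_fdr_select(exact_null_z(series, n_trials), threshold=threshold)


def zero_lag_check(
    component_average: np.ndarray,
    channel_average: np.ndarray,
    fs: float,
    tolerance_ms: float = 10.0,
) -> tuple[bool, float]:
    """Are the peaks of the two averaged |waveforms| aligned in time?

    Returns ``(ok, latency_difference_s)``. Flat averages fail with a
    warning (no peak to align).
    """
    a = np.abs(np.asarray(component_average, dtype=float))
    b = np.abs(np.asarray(channel_average, dtype=float))
    if a.max() <= 0 or b.max() <= 0:
        warnings.warn("flat average in zero-lag check", stacklevel=2)
        return False, np.nan
    lag = (int(np.argmax(a)) - int(np.argmax(b))) / fs
    return bool(abs(lag) <= tolerance_ms / 1000.0), lag


# ---------------------------------------------------------------------------
# Local false discovery rate with empirical null
# ---------------------------------------------------------------------------


@dataclass
class LocalFdrFit:
    """Fitted empirical-null mixture for a pooled set of z-values.

    The histogram is modelled as pi0 * N(mu0, sd0) + (1 - pi0) * signal.
    The mixture density f is a Poisson-regression (log-polynomial) smooth
    of the histogram; lfdr(z) = pi0 f0(z) / f(z), capped at 1.
    """

    null_mean: float
    null_sd: float
    pi0: float
    bin_centers: np.ndarray
    f_hat: np.ndarray  # smoothed mixture density at bin centers
    n_values: int

    def lfdr(self, z: np.ndarray | float) -> np.ndarray:
        z = np.atleast_1d(np.asarray(z, dtype=float))
        log_f = np.interp(z, self.bin_centers, np.log(self.f_hat + 1e-300))
        f0 = stats.norm.pdf(z, self.null_mean, self.null_sd)
        with np.errstate(over="ignore"):
            out = self.pi0 * f0 / np.exp(log_f)
        return np.clip(out, 0.0, 1.0)


def _fit_empirical_null(
    z: np.ndarray, centers: np.ndarray, f_hat: np.ndarray, width: float
) -> tuple[float, float, float]:
    """Central-matching fit of the empirical null N(mu0, sd0) and pi0.

    The smoothed log density is quadratic near its centre if the central
    mass is Gaussian; a weighted quadratic fit over the central-50% bins
    recovers the null parameters. This is markedly more stable than
    truncated maximum likelihood on the raw central values, whose
    likelihood is nearly flat in sigma at realistic pooling sizes.
    """
    a, b = np.quantile(z, [0.25, 0.75])
    mu_fallback = float(np.median(z))
    sd_fallback = max(float((b - a) / 1.349), 1e-12)
    central = (centers >= a) & (centers <= b)
    if central.sum() < 5:
        # widen to the central 80% when the bulk sits in very few bins
        a2, b2_ = np.quantile(z, [0.10, 0.90])
        central = (centers >= a2) & (centers <= b2_)
    central &= f_hat > 0
    if central.sum() < 3:
        return mu_fallback, sd_fallback, 1.0
    # weighted quadratic match of the *smoothed* log density: the smooth
    # removes the Poisson bin noise that makes raw-count curvature
    # estimates unstable over a narrow central window
    x = centers[central]
    y = np.log(f_hat[central])
    w = np.maximum(f_hat[central] * len(z) * width, 1e-6)  # expected counts
    try:
        coefs = np.polynomial.polynomial.polyfit(x, y, 2, w=np.sqrt(w))
        b0, b1, b2 = (
            coefs[0] + np.log(len(z) * width),
            coefs[1],
            coefs[2],
        )
    except (ValueError, np.linalg.LinAlgError):
        return mu_fallback, sd_fallback, 1.0
    if not np.isfinite(b2) or b2 >= -1e-12:
        return mu_fallback, sd_fallback, 1.0
    sd = float(np.sqrt(-1.0 / (2.0 * b2)))
    mu = float(-b1 / (2.0 * b2))
    # log density intercept -> null mass: counts = n*width*pi0*phi((z-mu)/sd)/sd
    log_peak = b0 - b1**2 / (4.0 * b2) - np.log(len(z) * width)
    pi0 = float(np.exp(log_peak) * np.sqrt(2 * np.pi) * sd)
    if not np.isfinite(pi0) or pi0 <= 0:
        pi0 = 1.0
    return mu, sd, min(pi0, 1.0)


def fit_local_fdr(
    values: np.ndarray,
    n_bins: int = 120,
    poly_degree: int = 7,
    min_values: int = 50,
) -> LocalFdrFit:
    """Fit the empirical-null lFDR model to a pooled set of z-values."""
    z = np.asarray(values, dtype=float)
    z = z[np.isfinite(z)]
    if len(z) < min_values:
        raise ValueError(f"lFDR fitting needs at least {min_values} finite values")
    if np.ptp(z) <= 0:
        warnings.warn("degenerate (constant) value histogram; no discoveries")
        return LocalFdrFit(float(z[0]), 1e-12, 1.0, np.array([z[0]]), np.array([1.0]), len(z))
    lo, hi = z.min(), z.max()
    pad = 0.01 * (hi - lo)
    # small pooled sets get proportionally fewer bins: a 120-bin histogram
    # of a few hundred values is mostly empty and the log-polynomial
    # smoother oscillates through the gaps
    n_bins = int(min(n_bins, max(20, len(z) // 8)))
    edges = np.linspace(lo - pad, hi + pad, n_bins + 1)
    counts, _ = np.histogram(z, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    width = edges[1] - edges[0]
    # Poisson-regression histogram smoothing on an orthogonal poly basis.
    # The degree is chosen by BIC over 2..poly_degree: a pure-null
    # histogram keeps the quadratic (Gaussian) shape, so lone extreme
    # order statistics do not carve their own bump into f and inflate
    # the apparent signal; genuine signal mass earns the extra degrees.
    x = (centers - centers.mean()) / (centers.std() + 1e-30)
    x = x / max(1e-12, np.abs(x).max())
    f_hat, best_bic = None, np.inf
    for degree in range(2, min(poly_degree, max(2, n_bins // 6)) + 1):
        basis = np.polynomial.legendre.legvander(x, degree)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                fitted = sm.GLM(counts, basis, family=sm.families.Poisson()).fit(
                    maxiter=200
                )
        except (ValueError, np.linalg.LinAlgError):
            continue
        if not np.all(np.isfinite(fitted.mu)):
            continue
        bic = -2.0 * fitted.llf + (degree + 1) * np.log(n_bins)
        if bic < best_bic:
            best_bic = bic
            f_hat = np.asarray(fitted.mu) / (len(z) * width)
    if f_hat is None:
        f_hat = (counts + 0.5) / (len(z) * width)
    mu0, sd0, pi0 = _fit_empirical_null(z, centers, f_hat, width)
    return LocalFdrFit(mu0, sd0, pi0, centers, f_hat, len(z))


def local_fdr_select(
    values: np.ndarray,
    threshold: float = 0.2,
    n_bins: int = 120,
    min_values: int = 50,
) -> tuple[np.ndarray, LocalFdrFit]:
    """Significance mask (lfdr <= threshold) for pooled Fisher-z values.

    NaN inputs are never significant. Significance is two-sided: a value
    stands out of the null on either tail whenever its local FDR is small.
    """
    z = np.asarray(values, dtype=float)
    finite = np.isfinite(z)
    fit = fit_local_fdr(z[finite], n_bins=n_bins, min_values=min_values)
    mask = np.zeros(z.shape, dtype=bool)
    if fit.null_sd <= 1e-11:  # degenerate histogram
        return mask, fit
    mask[finite] = fit.lfdr(z[finite]) <= threshold
    return mask, fit


# ---------------------------------------------------------------------------
# Selection verdicts
# ---------------------------------------------------------------------------


@dataclass
class ComponentCoupling:
    """Per-component verdict with its supporting evidence."""

    component: IcaComponent
    significant_temporal_channels: list[str]
    significant_itcor_channels: list[str]
    significant_channels: list[str]  # intersection of the two stages
    itcor_series: np.ndarray | None  # (n_channels, n_samples)
    itcor_sig_mask: np.ndarray | None
    zero_lag_ok: bool
    zero_lag_s: float
    selected: bool
    best_channel: str | None = None
    best_r: float = np.nan


@dataclass
class CouplingResults:
    """All (component, channel) statistics of one decomposition."""

    table: pd.DataFrame  # component, channel, r, eta, lfdr, sig flags, selected
    components: list[ComponentCoupling]
    r_matrix: np.ndarray
    temporal_fit: LocalFdrFit
    channel_ids: list[str]

    @property
    def selected(self) -> list[ComponentCoupling]:
        return [c for c in self.components if c.selected]


def select_components(
    components: list[IcaComponent],
    seeg_epochs: Epochs,
    lfdr_threshold: float = 0.2,
    peri_window_ms: float = 50.0,
    zero_lag_tolerance_ms: float = 10.0,
    min_trials: int = 10,
) -> CouplingResults:
    """Run the full multi-step selection on one decomposition.

    Components must be triggered-mode (or pre-epoched continuous-mode)
    with trial structure matching ``seeg_epochs``. Selection requires a
    significant temporal correlation, a significant ITCOR time within
    +-``peri_window_ms`` of the spike anchor on a temporally significant
    channel, and peak alignment at zero lag.
    """
    if not components:
        raise ValueError("no components to select from")
    channel_ids = list(seeg_epochs.channel_ids or [])
    comp_tc = np.stack([c.timecourse for c in components])
    r = temporal_correlation(comp_tc, seeg_epochs)
    eta = fisher_transform(np.where(np.isnan(r), np.nan, np.clip(r, -0.999999, 0.999999)), strict=False)
    temporal_mask, temporal_fit = local_fdr_select(eta, threshold=lfdr_threshold)
    lfdr_vals = np.full(eta.shape, np.nan)
    finite = np.isfinite(eta)
    lfdr_vals[finite] = temporal_fit.lfdr(eta[finite])

    rel_times = seeg_epochs.rel_times()
    in_window = np.abs(rel_times) <= peri_window_ms / 1000.0

    results: list[ComponentCoupling] = []
    rows = []
    for i, comp in enumerate(components):
        temp_channels = [channel_ids[j] for j in np.nonzero(temporal_mask[i])[0]]
        itc_series = itc_mask = None
        itc_channels: list[str] = []
        zero_ok, lag = False, np.nan
        best_channel, best_r = None, np.nan
        if temp_channels:
            comp_ep = comp.epoched()
            itc_series = itcor(comp_ep, seeg_epochs, min_trials=min_trials)
            itc_mask, _ = itcor_select(
                itc_series, seeg_epochs.n_trials, threshold=lfdr_threshold
            )
            for j in np.nonzero(temporal_mask[i])[0]:
                if np.any(itc_mask[j] & in_window):
                    itc_channels.append(channel_ids[j])
            if itc_channels:
                # best channel: largest |r| among doubly significant channels
                cand = [channel_ids.index(c) for c in itc_channels]
                best_j = cand[int(np.argmax(np.abs(r[i, cand])))]
                best_channel, best_r = channel_ids[best_j], float(r[i, best_j])
                zero_ok, lag = zero_lag_check(
                    comp_ep.mean(axis=0),
                    seeg_epochs.data[:, best_j, :].mean(axis=0),
                    seeg_epochs.fs,
                    tolerance_ms=zero_lag_tolerance_ms,
                )
        sig_channels = sorted(set(temp_channels) & set(itc_channels))
        selected = bool(temp_channels) and bool(sig_channels) and zero_ok
        results.append(
            ComponentCoupling(
                component=comp,
                significant_temporal_channels=temp_channels,
                significant_itcor_channels=itc_channels,
                significant_channels=sig_channels,
                itcor_series=itc_series,
                itcor_sig_mask=itc_mask,
                zero_lag_ok=zero_ok,
                zero_lag_s=lag,
                selected=selected,
                best_channel=best_channel,
                best_r=best_r,
            )
        )
        for j, chan in enumerate(channel_ids):
            rows.append(
                {
                    "component": comp.index,
                    "channel": chan,
                    "r": r[i, j],
                    "eta": eta[i, j],
                    "lfdr": lfdr_vals[i, j],
                    "significant_temporal": bool(temporal_mask[i, j]),
                    "significant_itcor": chan in itc_channels,
                    "selected": selected and chan in sig_channels,
                }
            )
    return CouplingResults(
        table=pd.DataFrame(rows),
        components=results,
        r_matrix=r,
        temporal_fit=temporal_fit,
        channel_ids=channel_ids,
    )
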