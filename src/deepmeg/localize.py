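"""Equivalent-current-dipole grid scans on ICA topographies.

At every grid point the 3-column lead-field block (one column per
orthogonal unit moment) is regressed onto the topography; the goodness of
fit GOF = 1 - RSS/TSS measures the variance explained by a dipole at that
point. The confidence interval collects all grid points with

    GOF >= max(GOF) - (1 - max(GOF)),

i.e. the distance of the best fit from 1 is taken as the noise level of
the topography. A single-dipole map is valid when max GOF > 0.75; the
two-dipole scan (for tri/quadripolar maps) requires joint GOF > 0.8 and an
F-test showing that both dipoles of a pair contribute.

In a spherical conductor the radial moment column is silent, so every
3-column block has effective rank 2; fits use the pseudo-inverse on the
effective column space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import format_truncated
from .forward import LeadField

SINGLE_GOF_VALID = 0.75
PAIR_GOF_VALID = 0.8


@dataclass
class GofMap:
    """Single-dipole scan result over a grid."""

    gof: np.ndarray  # (n_grid,)
    moments: np.ndarray  # (n_grid, 3) fitted moments, A·m
    max_gof: float
    argmax: int  # grid index of the best fit
    ci_indices: np.ndarray  # grid indices inside the confidence interval
    valid: bool
    ci_threshold: float
    rank_flags: np.ndarray  # grid points fit on a reduced column space
    leadfield: LeadField

    @property
    def argmax_position(self) -> np.ndarray:
        return self.leadfield.grid[self.argmax]

    @property
    def ci_positions(self) -> np.ndarray:
        return self.leadfield.grid[self.ci_indices]


@dataclass
class PairScanResult:
    """Two-dipole scan: retained pairs and the per-point score map."""

    pairs: np.ndarray  # (n_pairs, 2) grid indices
    pair_gof: np.ndarray
    f_stat: np.ndarray
    retained: np.ndarray  # boolean mask over pairs
    score_map: np.ndarray  # per grid point: number of retained pairs containing it
    max_gof: float
    valid: bool
    ghost_flagged: np.ndarray  # retained pairs whose midpoint outscores both members
    single_map: GofMap
    leadfield: LeadField

    @property
    def best_point(self) -> int:
        return int(np.argmax(self.score_map))


@dataclass(frozen=True)
class LocalizationVerdict:
    component: int
    region_class: str  # "mesial" | "lateral" | "other" | "inconclusive"
    structure_in_ci: bool
    max_gof: float
    argmax_position: tuple[float, float, float] | None


@dataclass
class ContingencyStats:
    """2x2 localized-class table with the column-normalised rates.

    ``sensitivity`` = mesial-truth fraction of the localized-mesial column;
    ``specificity`` = lateral-truth fraction of the localized-lateral
    column (per-localized-class rates). Region-specific sensitivity is the
    structure-in-CI fraction among correctly localized components of each
    class. Displayed values are truncated to two decimals.
    """

    mesial_mesial: int
    mesial_lateral: int
    lateral_mesial: int
    lateral_lateral: int
    mesial_in_ci: int
    lateral_in_ci: int
    n_inconclusive: int = 0

    def _rate(self, num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    @property
    def sensitivity(self) -> float | None:
        return self._rate(self.mesial_mesial, self.mesial_mesial + self.lateral_mesial)

    @property
    def specificity(self) -> float | None:
        return self._rate(
            self.lateral_lateral, self.lateral_lateral + self.mesial_lateral
        )

    @property
    def region_sensitivity_mesial(self) -> float | None:
        return self._rate(self.mesial_in_ci, self.mesial_mesial)

    @property
    def region_sensitivity_lateral(self) -> float | None:
        return self._rate(self.lateral_in_ci, self.lateral_lateral)

    def display(self) -> dict[str, str | None]:
        out = {}
        for name in (
            "sensitivity",
            "specificity",
            "region_sensitivity_mesial",
            "region_sensitivity_lateral",
        ):
            v = getattr(self, name)
            out[name] = None if v is None else format_truncated(v, 2)
        return out


# ---------------------------------------------------------------------------
# Batched least-squares helpers
# ---------------------------------------------------------------------------


def _batched_fit(ata: np.ndarray, atb: np.ndarray, rcond: float = 1e-10):
    """Min-norm least-squares solutions for stacked normal equations.

    ``ata``: (n, k, k) symmetric blocks, ``atb``: (n, k). Returns
    (solutions (n, k), effective rank (n,)).
    """
    w, v = np.linalg.eigh(ata)
    wmax = w[:, -1:]
    keep = w > np.maximum(wmax * rcond, 1e-300)
    winv = np.where(keep, 1.0 / np.where(keep, w, 1.0), 0.0)
    sol = np.einsum("nij,nj,nkj,nk->ni", v, winv, v, atb)
    return sol, keep.sum(axis=1)


def single_dipole_scan(topography: np.ndarray, leadfield: LeadField) -> GofMap:
    """Regress the 3-column gain at every grid point onto the topography."""
    t = np.asarray(topography, dtype=float)
    if t.shape[0] != leadfield.gain.shape[2]:
        raise ValueError(
            f"topography has {t.shape[0]} sensors but the lead field has "
            f"{leadfield.gain.shape[2]}"
        )
    tss = float(t @ t)
    if tss == 0:
        raise ValueError("zero topography")
    gain = leadfield.gain  # (g, 3, s)
    ata = np.einsum("gms,gns->gmn", gain, gain)
    atb = np.einsum("gms,s->gm", gain, t)
    moments, ranks = _batched_fit(ata, atb)
    rss = np.maximum(tss - np.einsum("gm,gm->g", atb, moments), 0.0)
    gof = 1.0 - rss / tss
    argmax = int(np.argmax(gof))
    max_gof = float(gof[argmax])
    # CI: closure of the strict ">" rule at the maximum, so the point
    # estimate is always a member of its own confidence interval.
    threshold = max_gof - (1.0 - max_gof)
    ci = np.nonzero(gof >= threshold)[0]
    if argmax not in ci:
        ci = np.append(ci, argmax)
    return GofMap(
        gof=gof,
        moments=moments,
        max_gof=max_gof,
        argmax=argmax,
        ci_indices=np.sort(ci),
        valid=max_gof > SINGLE_GOF_VALID,
        ci_threshold=threshold,
        rank_flags=ranks < 2,
        leadfield=leadfield,
    )


def double_dipole_scan(
    topography: np.ndarray,
    leadfield: LeadField,
    f_percentile: float = 95.0,
    max_grid_points: int = 600,
    min_separation: float = 0.0,
    chunk: int = 20000,
) -> PairScanResult:
    """Joint 6-column fit of every admissible grid-point pair.

    Retained pairs must (a) lie in the top ``100 - f_percentile`` percent
    of the F statistic comparing the pair fit against the better of its
    two single-dipole fits, and (b) satisfy the confidence-interval
    condition on the pair GOF with validity GOF > 0.8. The score map
    counts, per grid point, the retained pairs containing it. Pairs whose
    midpoint fits better than both members are flagged as potential ghost
    sources (not auto-excluded).
    """
    t = np.asarray(topography, dtype=float)
    n_sensors = leadfield.gain.shape[2]
    if n_sensors < 7:
        raise ValueError("two-dipole F test needs at least 7 sensors")
    if leadfield.n_grid > max_grid_points:
        raise ValueError(
            f"grid of {leadfield.n_grid} points exceeds max_grid_points="
            f"{max_grid_points}; use a coarser scan grid"
        )
    single = single_dipole_scan(t, leadfield)
    tss = float(t @ t)
    g = leadfield.n_grid
    gain = leadfield.gain
    rss1 = (1.0 - single.gof) * tss

    ii, jj = np.triu_indices(g, k=1)
    if min_separation > 0:
        sep = np.linalg.norm(leadfield.grid[ii] - leadfield.grid[jj], axis=1)
        keep = sep >= min_separation
        ii, jj = ii[keep], jj[keep]
    n_pairs = len(ii)
    ata_self = np.einsum("gms,gns->gmn", gain, gain)
    atb_self = np.einsum("gms,s->gm", gain, t)
    pair_rss = np.empty(n_pairs)
    for lo in range(0, n_pairs, chunk):
        hi = min(lo + chunk, n_pairs)
        bi, bj = ii[lo:hi], jj[lo:hi]
        cross = np.einsum("pms,pns->pmn", gain[bi], gain[bj])
        ata = np.empty((hi - lo, 6, 6))
        ata[:, :3, :3] = ata_self[bi]
        ata[:, 3:, 3:] = ata_self[bj]
        ata[:, :3, 3:] = cross
        ata[:, 3:, :3] = np.swapaxes(cross, 1, 2)
        atb = np.concatenate([atb_self[bi], atb_self[bj]], axis=1)
        sol, _ = _batched_fit(ata, atb)
        pair_rss[lo:hi] = np.maximum(
            tss - np.einsum("pm,pm->p", atb, sol), 0.0
        )
    pair_gof = 1.0 - pair_rss / tss
    best_single_rss = np.minimum(rss1[ii], rss1[jj])
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = ((best_single_rss - pair_rss) / 3.0) / (
            pair_rss / (n_sensors - 6)
        )
    f_stat = np.where(np.isfinite(f_stat), f_stat, np.inf)
    max_gof = float(pair_gof.max()) if n_pairs else 0.0
    gof_threshold = max_gof - (1.0 - max_gof)
    f_cut = np.percentile(f_stat, f_percentile) if n_pairs else np.inf
    retained = (f_stat >= f_cut) & (pair_gof >= gof_threshold) & (pair_gof > PAIR_GOF_VALID)

    score = np.zeros(g, dtype=int)
    np.add.at(score, ii[retained], 1)
    np.add.at(score, jj[retained], 1)

    ghost = np.zeros(n_pairs, dtype=bool)
    ridx = np.nonzero(retained)[0]
    if ridx.size:
        mids = (leadfield.grid[ii[ridx]] + leadfield.grid[jj[ridx]]) / 2.0
        d2 = np.sum(
            (leadfield.grid[None, :, :] - mids[:, None, :]) ** 2, axis=2
        )
        mid_pts = np.argmin(d2, axis=1)
        better = single.gof[mid_pts] > np.maximum(
            single.gof[ii[ridx]], single.gof[jj[ridx]]
        )
        ghost[ridx] = better

    return PairScanResult(
        pairs=np.column_stack([ii, jj]),
        pair_gof=pair_gof,
        f_stat=f_stat,
        retained=retained,
        score_map=score,
        max_gof=max_gof,
        valid=max_gof > PAIR_GOF_VALID,
        ghost_flagged=ghost,
        single_map=single,
        leadfield=leadfield,
    )


# ---------------------------------------------------------------------------
# Verdicts and summary statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SphericalAtlas:
    """Synthetic region atlas: a deep ball is 'mesial', a superficial shell
    'lateral', everything between 'other'."""

    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    deep_radius: float = 0.045
    lateral_radius: float = 0.055

    def region(self, position: np.ndarray) -> str:
        r = float(np.linalg.norm(np.asarray(position) - np.asarray(self.center)))
        if r <= self.deep_radius:
            return "mesial"
        if r >= self.lateral_radius:
            return "lateral"
        return "other"


def evaluate_localization(
    scan: GofMap | PairScanResult,
    atlas: SphericalAtlas,
    structure_position: np.ndarray | None,
    component: int = -1,
) -> LocalizationVerdict:
    """Classify the scan's best point by region and test structure-in-CI.

    The correlated structure counts as inside the confidence interval when
    its position lies within the CI point set dilated by one grid spacing.
    """
    if isinstance(scan, PairScanResult):
        lead = scan.leadfield
        valid = scan.valid and scan.score_map.max() > 0
        best = scan.best_point
        max_gof = scan.max_gof
        ci_positions = lead.grid[scan.score_map > 0] if valid else np.empty((0, 3))
    else:
        lead = scan.leadfield
        valid = scan.valid
        best = scan.argmax
        max_gof = scan.max_gof
        ci_positions = scan.ci_positions
    if not valid:
        return LocalizationVerdict(component, "inconclusive", False, max_gof, None)
    best_pos = lead.grid[best]
    region = atlas.region(best_pos)
    spacing = lead.spacing or _grid_spacing(lead.grid)
    in_ci = False
    if structure_position is not None and len(ci_positions):
        pos = np.asarray(structure_position, dtype=float)
        hull_lo, hull_hi = lead.grid.min(axis=0), lead.grid.max(axis=0)
        if np.any(pos < hull_lo - spacing) or np.any(pos > hull_hi + spacing):
            warnings.warn("structure position outside the scan grid hull")
        else:
            dmin = float(
                np.min(np.linalg.norm(ci_positions - pos[None, :], axis=1))
            )
            in_ci = dmin <= spacing * 1.000001
    return LocalizationVerdict(
        component, region, in_ci, max_gof, tuple(np.round(best_pos, 6))
    )


def _grid_spacing(grid: np.ndarray) -> float:
    if grid.shape[0] < 2:
        return np.inf
    d2 = np.sum((grid[:1] - grid[1:]) ** 2, axis=1)
    return float(np.sqrt(d2.min()))


def contingency_stats(records: pd.DataFrame | list[dict]) -> ContingencyStats:
    """Build the 2x2 localized-class table from per-component verdicts.

    ``records`` needs columns ``truth_class`` ("mesial"/"lateral"),
    ``localized_class`` and ``structure_in_ci``; inconclusive verdicts are
    excluded from the table and counted separately.
    """
    df = pd.DataFrame(records)
    for col in ("truth_class", "localized_class", "structure_in_ci"):
        if col not in df.columns:
            raise ValueError(f"records are missing column {col!r}")
    inconclusive = df["localized_class"] == "inconclusive"
    d = df[~inconclusive]

    def count(truth, localized, in_ci=None):
        sel = (d["truth_class"] == truth) & (d["localized_class"] == localized)
        if in_ci:
            sel &= d["structure_in_ci"].astype(bool)
        return int(sel.sum())

    return ContingencyStats(
        mesial_mesial=count("mesial", "mesial"),
        mesial_lateral=count("mesial", "lateral"),
        lateral_mesial=count("lateral", "mesial"),
        lateral_lateral=count("lateral", "lateral"),
        mesial_in_ci=count("mesial", "mesial", in_ci=True),
        lateral_in_ci=count("lateral", "lateral", in_ci=True),
        n_inconclusive=int(inconclusive.sum()),
    )
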