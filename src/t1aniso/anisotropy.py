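"""Orientation-resolved statistics of quantitative maps.

Everything here operates on cohorts: lists of per-subject maps on a common
grid.  The central objects are 4.5-degree angular-bin profiles of T1 (or
S0) restricted to voxels selected by a microstructural index window, the
two-anchor straight-line baseline used to extract peak contrasts, and the
parallel-minus-perpendicular (first bin minus last bin) difference.
Averaging is per subject first, then across subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "BIN_WIDTH",
    "N_BINS",
    "SelectionRule",
    "SelectionError",
    "AngularProfile",
    "DeltaSummary",
    "bin_edges",
    "bin_centres",
    "bin_index",
    "select_voxels",
    "profile_1d",
    "baseline_anchors",
    "delta_from_profile",
    "d090_from_profile",
    "baseline_and_deltas",
    "profile_2d",
    "normalize_s0",
    "cc_roi_stats",
    "mask_snr",
    "group_table",
]

BIN_WIDTH = 4.5
N_BINS = 20
BASELINE_LOW = (0.0, 20.0)
BASELINE_HIGH = (80.0, 90.0)


class SelectionError(ValueError):
    """Raised when a voxel-selection rule matches nothing."""


@dataclass(frozen=True)
class SelectionRule:
    """Closed index window applied to exactly one index map."""

    index_name: str
    lower: float
    upper: float

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValueError(
                f"rule {self.index_name}: lower ({self.lower}) must be < upper ({self.upper})"
            )


def bin_edges() -> np.ndarray:
    return np.arange(N_BINS + 1) * BIN_WIDTH


def bin_centres() -> np.ndarray:
    return (np.arange(N_BINS) + 0.5) * BIN_WIDTH


def bin_index(theta) -> np.ndarray:
    """Bin of an angle in degrees: edges ``[k*4.5, (k+1)*4.5)``, with 90
    folded into the last bin."""
    idx = np.floor(np.asarray(theta, dtype=float) / BIN_WIDTH).astype(int)
    return np.clip(idx, 0, N_BINS - 1)


def select_voxels(index_map, rule: SelectionRule, mask):
    """Voxels inside ``mask`` whose index falls in ``[lower, upper]``.

    Returns ``(selection, median_index)``; raises :class:`SelectionError`
    on an empty selection.
    """
    index_map = np.asarray(index_map, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    with np.errstate(invalid="ignore"):
        sel = mask & (index_map >= rule.lower) & (index_map <= rule.upper)
    if not np.any(sel):
        raise SelectionError(
            f"rule {rule.index_name} in [{rule.lower}, {rule.upper}] selects no voxels"
        )
    return sel, float(np.median(index_map[sel]))


@dataclass
class AngularProfile:
    """Per-subject, per-bin statistics of a quantity over a voxel selection.

    ``per_subject`` is (n_subjects, 20) with NaN for empty bins;
    ``mean``/``sd`` are across-subject statistics per bin; ``counts`` the
    per-subject voxel counts per bin; ``subject_means`` the per-subject
    mean of the quantity over the whole selection (used for the
    percent-of-mean summary).
    """

    per_subject: np.ndarray
    counts: np.ndarray
    subject_means: np.ndarray
    quantity: str = "T1"
    rule: SelectionRule | None = None
    median_index: float = np.nan

    @property
    def n_subjects(self) -> int:
        return self.per_subject.shape[0]

    @property
    def mean(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.per_subject, axis=0)

    @property
    def sd(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanstd(self.per_subject, axis=0, ddof=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_centre_deg": bin_centres(),
                "mean": self.mean,
                "sd": self.sd,
                "n_voxels": self.counts.sum(axis=0),
            }
        )


def profile_1d(
    quantity_maps: Sequence[np.ndarray],
    theta_maps: Sequence[np.ndarray],
    selections: Sequence[np.ndarray],
    quantity: str = "T1",
    rule: SelectionRule | None = None,
    median_index: float = np.nan,
) -> AngularProfile:
    """Build the 4.5-degree-bin angular profile for a cohort.

    For each subject the mean of ``quantity_maps[s]`` over selected voxels
    falling in each angle bin is computed; empty bins are recorded as NaN
    (missing, never zero).  Voxels with NaN quantity or NaN angle are
    dropped.
    """
    if not (len(quantity_maps) == len(theta_maps) == len(selections)):
        raise ValueError("cohort lists must have equal length")
    n_subj = len(quantity_maps)
    if n_subj == 0:
        raise ValueError("empty cohort")
    per_subject = np.full((n_subj, N_BINS), np.nan)
    counts = np.zeros((n_subj, N_BINS), dtype=int)
    subject_means = np.full(n_subj, np.nan)
    for s in range(n_subj):
        q = np.asarray(quantity_maps[s], dtype=float).ravel()
        th = np.asarray(theta_maps[s], dtype=float).ravel()
        sel = np.asarray(selections[s], dtype=bool).ravel()
        valid = sel & np.isfinite(q) & np.isfinite(th)
        if not np.any(valid):
            continue
        idx = bin_index(th[valid])
        qv = q[valid]
        sums = np.bincount(idx, weights=qv, minlength=N_BINS)
        ns = np.bincount(idx, minlength=N_BINS)
        occupied = ns > 0
        per_subject[s, occupied] = sums[occupied] / ns[occupied]
        counts[s] = ns
        subject_means[s] = qv.mean()
    return AngularProfile(
        per_subject=per_subject,
        counts=counts,
        subject_means=subject_means,
        quantity=quantity,
        rule=rule,
        median_index=median_index,
    )


def _window_bins(lo: float, hi: float) -> np.ndarray:
    edges = bin_edges()
    return np.flatnonzero((edges[:-1] >= lo - 1e-9) & (edges[1:] <= hi + 1e-9))


def baseline_anchors(values: np.ndarray):
    """Two baseline anchors from one profile vector (length 20).

    Each anchor averages the occupied bins whose edges lie fully inside
    the 0-20 (respectively 80-90) degree window; its abscissa is the mean
    of the contributing bin centres, so a profile affine in the bin centre
    is reproduced exactly by the anchor line.
    """
    values = np.asarray(values, dtype=float)
    centres = bin_centres()
    anchors = []
    for lo, hi in (BASELINE_LOW, BASELINE_HIGH):
        bins = _window_bins(lo, hi)
        bins = bins[np.isfinite(values[bins])]
        if bins.size == 0:
            raise ValueError(
                f"no occupied bins in the {lo}-{hi} degree baseline window"
            )
        anchors.append((float(centres[bins].mean()), float(values[bins].mean())))
    return tuple(anchors)


def _baseline_at(values: np.ndarray, x: float) -> float:
    (x1, y1), (x2, y2) = baseline_anchors(values)
    return y1 + (y2 - y1) * (x - x1) / (x2 - x1)


def delta_from_profile(values, peak_angle: float) -> float:
    """Profile value in the bin containing ``peak_angle`` minus the
    two-anchor baseline evaluated at that bin's centre."""
    values = np.asarray(values, dtype=float)
    k = int(bin_index(peak_angle))
    if not np.isfinite(values[k]):
        raise ValueError(f"bin containing {peak_angle} degrees is empty")
    centre = float(bin_centres()[k])
    return float(values[k] - _baseline_at(values, centre))


def d090_from_profile(values) -> float:
    """First-bin minus last-bin profile value (parallel minus perpendicular)."""
    values = np.asarray(values, dtype=float)
    if not (np.isfinite(values[0]) and np.isfinite(values[-1])):
        raise ValueError("first and last angle bins must both be occupied")
    return float(values[0] - values[-1])


@dataclass
class DeltaSummary:
    """Baseline-subtracted contrasts of one angular profile."""

    peak_angle: float
    peak_bin: int
    per_subject_delta_peak: np.ndarray
    per_subject_delta_090: np.ndarray
    delta_peak: float
    delta_peak_sd: float
    delta_090: float
    delta_090_sd: float
    baseline: tuple
    percent_of_mean: float
    mean_t1: float


def baseline_and_deltas(profile: AngularProfile, peak_angle: float) -> DeltaSummary:
    """Per-subject baseline-subtracted peak and 0-90 contrasts.

    Deltas are computed on each subject's profile, then summarised as
    cohort mean +/- SD.  ``percent_of_mean`` is 100 times the cohort-mean
    peak delta over the cohort-mean of the per-subject selection means.
    """
    dp = np.array([
        delta_from_profile(profile.per_subject[s], peak_angle)
        for s in range(profile.n_subjects)
    ])
    d090 = np.array([
        d090_from_profile(profile.per_subject[s])
        for s in range(profile.n_subjects)
    ])
    mean_t1 = float(np.nanmean(profile.subject_means))
    delta_peak = float(dp.mean())
    return DeltaSummary(
        peak_angle=float(peak_angle),
        peak_bin=int(bin_index(peak_angle)),
        per_subject_delta_peak=dp,
        per_subject_delta_090=d090,
        delta_peak=delta_peak,
        delta_peak_sd=float(dp.std(ddof=1)) if dp.size > 1 else np.nan,
        delta_090=float(d090.mean()),
        delta_090_sd=float(d090.std(ddof=1)) if d090.size > 1 else np.nan,
        baseline=baseline_anchors(profile.mean),
        percent_of_mean=100.0 * delta_peak / mean_t1,
        mean_t1=mean_t1,
    )


def profile_2d(
    quantity_maps: Sequence[np.ndarray],
    theta_maps: Sequence[np.ndarray],
    index_maps: Sequence[np.ndarray],
    masks: Sequence[np.ndarray],
    index_range: tuple[float, float],
    n_index_bins: int = 10,
):
    """Mean quantity over a (theta bin x index bin) grid, cohort-averaged.

    Returns ``(surface, counts, index_edges)`` where ``surface`` is
    (20, n_index_bins), per-subject-then-across-subject averaged, NaN
    where no subject has voxels.
    """
    lo, hi = index_range
    if not lo < hi:
        raise ValueError("index_range must be increasing")
    index_edges = np.linspace(lo, hi, n_index_bins + 1)
    n_subj = len(quantity_maps)
    acc = np.full((n_subj, N_BINS, n_index_bins), np.nan)
    counts = np.zeros((N_BINS, n_index_bins), dtype=int)
    for s in range(n_subj):
        q = np.asarray(quantity_maps[s], dtype=float).ravel()
        th = np.asarray(theta_maps[s], dtype=float).ravel()
        ix = np.asarray(index_maps[s], dtype=float).ravel()
        m = np.asarray(masks[s], dtype=bool).ravel()
        valid = m & np.isfinite(q) & np.isfinite(th) & (ix >= lo) & (ix <= hi)
        if not np.any(valid):
            continue
        ti = bin_index(th[valid])
        ii = np.clip(
            np.floor((ix[valid] - lo) / (hi - lo) * n_index_bins).astype(int),
            0,
            n_index_bins - 1,
        )
        flat = ti * n_index_bins + ii
        sums = np.bincount(flat, weights=q[valid], minlength=N_BINS * n_index_bins)
        ns = np.bincount(flat, minlength=N_BINS * n_index_bins)
        sums = sums.reshape(N_BINS, n_index_bins)
        ns = ns.reshape(N_BINS, n_index_bins)
        with np.errstate(invalid="ignore"):
            acc[s] = np.where(ns > 0, sums / np.maximum(ns, 1), np.nan)
        counts += ns
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        surface = np.nanmean(acc, axis=0)
    return surface, counts, index_edges


def normalize_s0(s0_map, index_map, reference_rule: SelectionRule, mask):
    """Divide an S0 map by the mean S0 of reference voxels.

    The reference is the set of voxels whose index falls in the reference
    rule's window (e.g. FA within 0.2 +/- 0.05).
    """
    s0_map = np.asarray(s0_map, dtype=float)
    ref, _ = select_voxels(index_map, reference_rule, mask)
    ref_vals = s0_map[ref]
    ref_vals = ref_vals[np.isfinite(ref_vals)]
    if ref_vals.size == 0:
        raise SelectionError("reference selection contains no finite S0 values")
    return s0_map / ref_vals.mean()


def _roi_slices(box):
    if len(box) != 6:
        raise ValueError("ROI box must be (x0, x1, y0, y1, z0, z1), half-open")
    x0, x1, y0, y1, z0, z1 = (int(v) for v in box)
    if not (x0 < x1 and y0 < y1 and z0 < z1):
        raise ValueError(f"degenerate ROI box {box}")
    return (slice(x0, x1), slice(y0, y1), slice(z0, z1))


def cc_roi_stats(
    t1_maps: Sequence[np.ndarray],
    rois: dict,
    mask=None,
    alpha: float = 0.005,
):
    """Per-ROI mean +/- SD of T1 across subjects plus pairwise Welch tests.

    ``rois`` maps names to half-open voxel boxes (x0, x1, y0, y1, z0, z1),
    0-based.  Every ROI must contain at least 2 voxels and, if ``mask`` is
    given, lie entirely inside it.  Returns ``(summary, tests)`` DataFrames;
    ``tests.significant`` applies the (already-corrected) ``alpha``.
    """
    if len(t1_maps) == 0:
        raise ValueError("empty cohort")
    grid = np.asarray(t1_maps[0]).shape
    per_roi = {}
    for name, box in rois.items():
        sl = _roi_slices(box)
        if any(s.stop > dim for s, dim in zip(sl, grid)):
            raise ValueError(f"ROI {name} extends outside the image grid")
        n_vox = (sl[0].stop - sl[0].start) * (sl[1].stop - sl[1].start) * (sl[2].stop - sl[2].start)
        if n_vox < 2:
            raise ValueError(f"ROI {name} has a single voxel; SD undefined")
        if mask is not None and not np.all(np.asarray(mask, dtype=bool)[sl]):
            raise ValueError(f"ROI {name} extends outside the mask")
        means = []
        for t1 in t1_maps:
            vals = np.asarray(t1, dtype=float)[sl]
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                raise ValueError(f"ROI {name} contains no finite T1 values")
            means.append(vals.mean())
        per_roi[name] = np.array(means)

    summary = pd.DataFrame(
        {
            "roi": list(per_roi),
            "mean": [v.mean() for v in per_roi.values()],
            "sd": [v.std(ddof=1) if v.size > 1 else np.nan for v in per_roi.values()],
            "n_subjects": [v.size for v in per_roi.values()],
        }
    )
    rows = []
    names = list(per_roi)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if per_roi[a].size > 1 and per_roi[b].size > 1:
                t, p = sps.ttest_ind(per_roi[a], per_roi[b], equal_var=False)
            else:
                t, p = np.nan, np.nan
            rows.append({"roi_a": a, "roi_b": b, "t": t, "p": p,
                         "significant": bool(p < alpha) if np.isfinite(p) else False})
    return summary, pd.DataFrame(rows)


def mask_snr(dwi, mask, background=None, bg_fraction: float = 0.1) -> pd.DataFrame:
    """Per-direction SNR table for a DWI dataset.

    Noise sigma is estimated from pure-background voxels (Rician corrected:
    ``sigma = sqrt(mean(M^2) / 2)``); the signal is the mean over ``mask``.
    Reported for the mean b0 volume and, per shell, for the volumes whose
    gradient directions lie closest to the x, y and z axes.  Noise-free
    data reports ``inf``.
    """
    mask = np.asarray(mask, dtype=bool)
    if not np.any(mask):
        raise ValueError("signal mask is empty")
    if background is None:
        background = np.zeros(dwi.grid_shape, dtype=bool)
        nx, ny, nz = dwi.grid_shape
        cx, cy, cz = (max(1, int(round(bg_fraction * d))) for d in (nx, ny, nz))
        for sx in (slice(0, cx), slice(nx - cx, nx)):
            for sy in (slice(0, cy), slice(ny - cy, ny)):
                for sz in (slice(0, cz), slice(nz - cz, nz)):
                    background[sx, sy, sz] = True
        background &= ~mask
    else:
        background = np.asarray(background, dtype=bool)
    if not np.any(background):
        raise ValueError("no background voxels available for noise estimation")

    is_b0 = dwi.bvals <= 50.0
    bg = dwi.data[background][:, is_b0]
    sigma = float(np.sqrt(np.mean(bg ** 2) / 2.0))

    def snr(vol):
        sig = float(np.mean(vol[mask]))
        return np.inf if sigma == 0 else sig / sigma

    rows = [{"volume": "b0", "b": 0.0, "axis": "-", "snr": snr(dwi.data[..., is_b0].mean(axis=-1))}]
    axes = {"X": np.array([1.0, 0, 0]), "Y": np.array([0, 1.0, 0]), "Z": np.array([0, 0, 1.0])}
    for shell in dwi.shells():
        on_shell = np.flatnonzero(np.abs(dwi.bvals - shell) <= 50.0)
        for label, ax in axes.items():
            dots = np.abs(dwi.bvecs[:, on_shell].T @ ax)
            vol_idx = on_shell[int(np.argmax(dots))]
            rows.append({
                "volume": int(vol_idx),
                "b": float(shell),
                "axis": label,
                "snr": snr(dwi.data[..., vol_idx]),
            })
    out = pd.DataFrame(rows)
    out.attrs["sigma"] = sigma
    return out


def group_table(results_by_field: dict, alpha: float = 0.01) -> pd.DataFrame:
    """Summary table across index rules and field strengths.

    ``results_by_field`` maps field strength (e.g. 3.0, 7.0) to a dict of
    rule name -> ``(AngularProfile, DeltaSummary)``.  Emits one row per
    (field, rule) with median index, mean +/- SD T1 and both deltas, plus
    Welch t-tests between fields per rule when both cohorts have >= 2
    subjects (suppressed otherwise).  Rules absent from a field are
    omitted with a warning.
    """
    rows = []
    rules = []
    for fs, per_rule in results_by_field.items():
        for name in per_rule:
            if name not in rules:
                rules.append(name)
    for name in rules:
        fields_with = [fs for fs in results_by_field if name in results_by_field[fs]]
        if len(fields_with) < len(results_by_field):
            warnings.warn(f"index rule {name!r} missing for some fields; row(s) omitted")
        for fs in fields_with:
            profile, deltas = results_by_field[fs][name]
            n = profile.n_subjects
            row = {
                "index": name,
                "field_T": fs,
                "n_subjects": n,
                "median_index": profile.median_index,
                "t1_mean": float(np.nanmean(profile.subject_means)),
                "t1_sd": float(np.nanstd(profile.subject_means, ddof=1)) if n > 1 else np.nan,
                "delta_peak_deg": deltas.peak_angle,
                "delta_peak": deltas.delta_peak,
                "delta_peak_sd": deltas.delta_peak_sd,
                "delta_090": deltas.delta_090,
                "delta_090_sd": deltas.delta_090_sd,
                "percent_of_mean": deltas.percent_of_mean,
            }
            others = [f for f in fields_with if f != fs]
            if len(others) == 1:
                a = deltas
                b = results_by_field[others[0]][name][1]
                if a.per_subject_delta_peak.size > 1 and b.per_subject_delta_peak.size > 1:
                    for stat, xa, xb in (
                        ("peak", a.per_subject_delta_peak, b.per_subject_delta_peak),
                        ("090", a.per_subject_delta_090, b.per_subject_delta_090),
                    ):
                        t, p = sps.ttest_ind(xa, xb, equal_var=False)
                        row[f"p_{stat}_between_fields"] = p
                        row[f"sig_{stat}_between_fields"] = bool(p < alpha)
            rows.append(row)
    return pd.DataFrame(rows)
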