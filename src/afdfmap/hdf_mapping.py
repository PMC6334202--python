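"""Highest-dominant-frequency (HDF) mapping and the paired intracardiac /
body-surface difference analysis.

Per 4 s window and dataset (atrial nodes or torso electrodes), the HDF is
the maximum DF over all channels whose OI exceeds a threshold; the hosting
area is the set of channels whose DF lies within 0.25 Hz below the HDF.
Windows whose HDF peak looks like a harmonic (on either dataset) are
excluded from the paired analysis. The per-window body-surface minus
intracardiac HDF difference is binned by intracardiac HDF in 0.5 Hz bins
and the bin medians are summarized with an exponential trend fitted by
Levenberg–Marquardt nonlinear least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import FitError, ValidationError
from .spectral import HARMONIC_NONE

HDF_MARGIN_HZ = 0.25  # a node hosts the HDF if its DF >= HDF - 0.25 Hz

REASON_NONE = "none"
REASON_HARMONIC = "harmonic"
REASON_NO_NODE = "no-node-above-threshold"


@dataclass
class HDFWindowResult:
    """HDF of one window of one dataset plus the node set hosting it."""

    window: int
    dataset: str
    hdf: float  # NaN when undefined
    hosting_nodes: frozenset[str]
    oi_threshold: float
    excluded: bool = False
    exclusion_reason: str = REASON_NONE
    harmonic_flagged: bool = False

    @property
    def defined(self) -> bool:
        return np.isfinite(self.hdf)


@dataclass
class PairedWindow:
    """One window's intracardiac (vegm) and torso (bsm) HDF results."""

    window: int
    vegm: HDFWindowResult
    bsm: HDFWindowResult
    excluded: bool = False
    exclusion_reason: str = REASON_NONE

    @property
    def diff(self) -> float:
        return self.bsm.hdf - self.vegm.hdf


@dataclass
class OIThresholdSweep:
    """Effect of the OI threshold on HDF detectability and hosting areas.

    ``pct_windows_defined`` counts, per threshold, the share of windows
    with a defined HDF over two denominators: all analyzable windows
    (``incl_harmonic``) and windows surviving harmonic exclusion
    (``excl_harmonic``). The node-level arrays compare, per window, the
    hosting set at ``comparison_threshold`` against threshold 0:
    persisting = 100·|before ∩ after| / |before|,
    new = 100·|after \\ before| / |after|.
    """

    dataset: str
    thresholds: np.ndarray
    pct_windows_defined_incl_harmonic: np.ndarray
    pct_windows_defined_excl_harmonic: np.ndarray
    comparison_threshold: float
    pct_nodes_hosting: np.ndarray
    pct_persisting: np.ndarray
    pct_new: np.ndarray

    def summary(self) -> dict[str, dict[str, float]]:
        """Median and interquartile range of the per-window node statistics."""
        out = {}
        for name, arr in [
            ("pct_nodes_hosting", self.pct_nodes_hosting),
            ("pct_persisting", self.pct_persisting),
            ("pct_new", self.pct_new),
        ]:
            arr = np.asarray(arr, dtype=float)
            arr = arr[np.isfinite(arr)]
            if arr.size:
                q1, med, q3 = np.percentile(arr, [25, 50, 75])
            else:
                q1 = med = q3 = float("nan")
            out[name] = {"median": float(med), "iqr": float(q3 - q1), "n": int(arr.size)}
        return out

    def curve(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "pct_defined_incl_harmonic": self.pct_windows_defined_incl_harmonic,
                "pct_defined_excl_harmonic": self.pct_windows_defined_excl_harmonic,
            }
        )


@dataclass
class HDFDifferenceTable:
    """Paired per-window HDF records with 0.5 Hz bin summaries.

    ``records``: columns window, vegm_hdf, bsm_hdf, diff.
    ``bins``: columns bin_center, median, iqr, count — bins are half-open
    [x.0, x.5) intervals of the intracardiac HDF with centers x.25 / x.75.
    """

    records: pd.DataFrame
    bins: pd.DataFrame


@dataclass
class ExpFitParams:
    """Exponential trend d(f) = −a·exp(b·(f − f0)) + c fitted to bin medians."""

    a: float
    b: float
    c: float
    f0: float
    r_squared: float
    ci95: dict[str, tuple[float, float]]

    def predict(self, f: np.ndarray) -> np.ndarray:
        f = np.asarray(f, dtype=float)
        return -self.a * np.exp(self.b * (f - self.f0)) + self.c


@dataclass
class AreaComparison:
    """Atrial HDF-area distributions for windows where torso and atrial HDF
    agree (|diff| ≤ 0.5 Hz) versus disagree, with a rank-sum p-value."""

    same_areas: np.ndarray
    diff_areas: np.ndarray
    hist_edges: np.ndarray
    same_hist: np.ndarray | None
    diff_hist: np.ndarray | None
    p_value: float


# ---------------------------------------------------------------------------
# Window-level HDF
# ---------------------------------------------------------------------------

def hdf_for_window(
    df_results: pd.DataFrame,
    oi_threshold: float = 0.0,
    dataset: str = "vegm",
    margin: float = HDF_MARGIN_HZ,
) -> HDFWindowResult:
    """HDF of one window from its per-channel DF table.

    Channels are eligible iff their OI strictly exceeds ``oi_threshold``.
    The HDF is the maximum DF among eligible channels; hosting nodes are
    the eligible channels with DF ≥ HDF − ``margin``. The window carries a
    harmonic flag when a channel attaining the HDF has a non-``none``
    harmonic status.
    """
    if len(df_results) == 0:
        raise ValidationError("df_results is empty")
    windows = df_results["window"].unique()
    if len(windows) != 1:
        raise ValidationError(f"df_results spans several windows: {windows}")
    window = int(windows[0])
    eligible = df_results[df_results["oi"] > oi_threshold]
    if len(eligible) == 0:
        return HDFWindowResult(
            window=window,
            dataset=dataset,
            hdf=float("nan"),
            hosting_nodes=frozenset(),
            oi_threshold=oi_threshold,
            excluded=True,
            exclusion_reason=REASON_NO_NODE,
        )
    hdf = float(eligible["df"].max())
    tol = 1e-9
    hosts = eligible[eligible["df"] >= hdf - margin - tol]
    top = eligible[np.abs(eligible["df"] - hdf) <= tol]
    flagged = bool((top["harmonic_status"] != HARMONIC_NONE).any())
    return HDFWindowResult(
        window=window,
        dataset=dataset,
        hdf=hdf,
        hosting_nodes=frozenset(hosts["channel"]),
        oi_threshold=oi_threshold,
        harmonic_flagged=flagged,
    )


def hdf_per_window(
    df_table: pd.DataFrame, oi_threshold: float = 0.0, dataset: str = "vegm"
) -> list[HDFWindowResult]:
    """Apply :func:`hdf_for_window` to every window of a DF table."""
    return [
        hdf_for_window(group, oi_threshold, dataset)
        for _, group in df_table.groupby("window", sort=True)
    ]


def exclude_harmonic_windows(
    vegm: HDFWindowResult, bsm: HDFWindowResult
) -> PairedWindow:
    """Pair the two datasets' window results; the window is excluded from
    paired analysis iff either HDF peak is harmonic-flagged (or either HDF
    is undefined)."""
    if vegm.window != bsm.window:
        raise ValidationError(
            f"window indices differ: {vegm.window} vs {bsm.window}"
        )
    pair = PairedWindow(vegm.window, vegm, bsm)
    if vegm.harmonic_flagged or bsm.harmonic_flagged:
        pair.excluded = True
        pair.exclusion_reason = REASON_HARMONIC
    elif not (vegm.defined and bsm.defined):
        pair.excluded = True
        pair.exclusion_reason = REASON_NO_NODE
    return pair


def pair_windows(
    vegm_results: list[HDFWindowResult], bsm_results: list[HDFWindowResult]
) -> list[PairedWindow]:
    """Pair per-window results of the two datasets on their common windows."""
    bsm_by_window = {r.window: r for r in bsm_results}
    return [
        exclude_harmonic_windows(v, bsm_by_window[v.window])
        for v in vegm_results
        if v.window in bsm_by_window
    ]


# ---------------------------------------------------------------------------
# OI threshold sweep
# ---------------------------------------------------------------------------

def oi_threshold_sweep(
    df_table: pd.DataFrame,
    thresholds: np.ndarray | None = None,
    comparison_threshold: float = 0.5,
    dataset: str = "vegm",
) -> OIThresholdSweep:
    """Sweep the OI threshold over a grid (default 0–1, step 0.1).

    Per threshold: the percentage of windows with a defined HDF, over both
    the all-windows denominator and the harmonic-excluded denominator.
    Per window: the hosting-node percentage at ``comparison_threshold`` and
    the persisting/new percentages of the hosting set relative to
    threshold 0.
    """
    if thresholds is None:
        thresholds = np.round(np.arange(0.0, 1.0 + 1e-9, 0.1), 10)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any((thresholds < 0) | (thresholds > 1)):
        raise ValidationError("thresholds must lie in [0, 1]")

    base = hdf_per_window(df_table, 0.0, dataset)
    harmonic_ok = np.array([not r.harmonic_flagged for r in base])
    n_all = len(base)
    n_clean = int(harmonic_ok.sum())

    pct_incl, pct_excl = [], []
    for th in thresholds:
        res = hdf_per_window(df_table, th, dataset)
        defined = np.array([r.defined for r in res])
        pct_incl.append(100.0 * defined.sum() / n_all if n_all else np.nan)
        pct_excl.append(
            100.0 * defined[harmonic_ok].sum() / n_clean if n_clean else np.nan
        )

    n_channels = df_table["channel"].nunique()
    after = hdf_per_window(df_table, comparison_threshold, dataset)
    hosting, persisting, new = [], [], []
    for r0, r1 in zip(base, after):
        before_set, after_set = set(r0.hosting_nodes), set(r1.hosting_nodes)
        hosting.append(100.0 * len(after_set) / n_channels if n_channels else np.nan)
        persisting.append(
            100.0 * len(before_set & after_set) / len(before_set)
            if before_set
            else np.nan
        )
        new.append(
            100.0 * len(after_set - before_set) / len(after_set)
            if after_set
            else np.nan
        )

    return OIThresholdSweep(
        dataset=dataset,
        thresholds=thresholds,
        pct_windows_defined_incl_harmonic=np.array(pct_incl),
        pct_windows_defined_excl_harmonic=np.array(pct_excl),
        comparison_threshold=comparison_threshold,
        pct_nodes_hosting=np.array(hosting),
        pct_persisting=np.array(persisting),
        pct_new=np.array(new),
    )


# ---------------------------------------------------------------------------
# Paired difference analysis
# ---------------------------------------------------------------------------

def hdf_difference_analysis(pairs: list[PairedWindow]) -> HDFDifferenceTable:
    """Torso-minus-atrial HDF differences binned by atrial HDF.

    Only non-excluded pairs enter. Bins are half-open [x.0, x.5) Hz
    intervals of the atrial HDF; per bin the median, interquartile range
    and count of the differences are reported.
    """
    kept = [p for p in pairs if not p.excluded]
    if not kept:
        warnings.warn("no surviving paired windows for difference analysis")
        empty_r = pd.DataFrame(columns=["window", "vegm_hdf", "bsm_hdf", "diff"])
        empty_b = pd.DataFrame(columns=["bin_center", "median", "iqr", "count"])
        return HDFDifferenceTable(empty_r, empty_b)
    records = pd.DataFrame(
        {
            "window": [p.window for p in kept],
            "vegm_hdf": [p.vegm.hdf for p in kept],
            "bsm_hdf": [p.bsm.hdf for p in kept],
            "diff": [p.diff for p in kept],
        }
    )
    left_edge = np.floor(records["vegm_hdf"] / 0.5) * 0.5
    records["bin_center"] = np.round(left_edge + 0.25, 10)
    grouped = records.groupby("bin_center")["diff"]
    bins = pd.DataFrame(
        {
            "bin_center": grouped.median().index,
            "median": grouped.median().to_numpy(),
            "iqr": (grouped.quantile(0.75) - grouped.quantile(0.25)).to_numpy(),
            "count": grouped.count().to_numpy(),
        }
    ).reset_index(drop=True)
    return HDFDifferenceTable(records, bins)


def _exp_model(f, a, b, c, f0):
    return -a * np.exp(b * (f - f0)) + c


def fit_exponential(
    table: HDFDifferenceTable | pd.DataFrame,
    seed: int = 0,
    n_restarts: int = 5,
) -> ExpFitParams:
    """Fit d(f) = −a·exp(b·(f − f0)) + c to the bin medians.

    ``f0`` is fixed at the lowest bin center; a, b, c are free. Initial
    values come from a log-linearization of the residuals around the
    largest median, refined by Levenberg–Marquardt least squares with
    ``n_restarts`` seeded jittered restarts; the best (lowest-SSE)
    converged fit wins. 95% confidence intervals are asymptotic (t-based,
    from the parameter covariance). Constant medians yield the degenerate
    flat fit a = 0.
    """
    bins = table.bins if isinstance(table, HDFDifferenceTable) else table
    bins = bins.dropna(subset=["median"])
    if len(bins) < 4:
        raise ValidationError(
            f"need at least 4 bins with defined medians, got {len(bins)}"
        )
    f = bins["bin_center"].to_numpy(dtype=float)
    d = bins["median"].to_numpy(dtype=float)
    f0 = float(f.min())

    if np.ptp(d) < 1e-12:
        return ExpFitParams(
            a=0.0, b=0.0, c=float(d[0]), f0=f0, r_squared=1.0,
            ci95={"a": (0.0, 0.0), "b": (0.0, 0.0), "c": (float(d[0]), float(d[0]))},
        )

    # log-linearized start: choose c slightly above the max, regress
    # log(c - d) on (f - f0)
    spread = np.ptp(d)
    c0 = d.max() + 0.05 * spread
    y = np.log(np.maximum(c0 - d, 1e-12))
    slope, intercept = np.polyfit(f - f0, y, 1)
    p0 = np.array([np.exp(intercept), slope, c0])

    rng = np.random.default_rng(seed)
    best = None
    last_resid = None
    for trial in range(n_restarts + 1):
        start = p0 if trial == 0 else p0 * rng.uniform(0.5, 1.5, 3)
        try:
            popt, pcov = optimize.curve_fit(
                lambda x, a, b, c: _exp_model(x, a, b, c, f0),
                f, d, p0=start, method="lm", maxfev=20000,
            )
        except (RuntimeError, optimize.OptimizeWarning):
            continue
        resid = d - _exp_model(f, *popt, f0)
        last_resid = resid
        sse = float(resid @ resid)
        if np.all(np.isfinite(popt)) and (best is None or sse < best[0]):
            best = (sse, popt, pcov)
    if best is None:
        raise FitError("exponential fit failed to converge", residuals=last_resid)
    sse, popt, pcov = best
    ss_tot = float(((d - d.mean()) ** 2).sum())
    r_squared = 1.0 - sse / ss_tot if ss_tot > 0 else 1.0
    dof = max(len(f) - 3, 1)
    tcrit = stats.t.ppf(0.975, dof)
    se = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    names = ["a", "b", "c"]
    ci95 = {
        nm: (float(p - tcrit * s), float(p + tcrit * s))
        for nm, p, s in zip(names, popt, se)
    }
    return ExpFitParams(
        a=float(popt[0]), b=float(popt[1]), c=float(popt[2]),
        f0=f0, r_squared=float(r_squared), ci95=ci95,
    )


# ---------------------------------------------------------------------------
# HDF-area distributions
# ---------------------------------------------------------------------------

def area_distribution_comparison(
    pairs: list[PairedWindow],
    n_atrial_nodes: int,
    agreement_hz: float = 0.5,
    n_hist_bins: int = 20,
) -> AreaComparison:
    """Atrial HDF-area percentage distributions split by torso agreement.

    Per non-excluded window the atrial HDF area is
    ``100 · |hosting nodes| / n_atrial_nodes``; windows are partitioned by
    whether |BSM − VEGM HDF| ≤ ``agreement_hz``. Distributions are returned
    as density-normalized histograms on shared edges and compared with a
    Mann-Whitney rank-sum test.
    """
    if n_atrial_nodes <= 0:
        raise ValidationError("n_atrial_nodes must be positive")
    kept = [p for p in pairs if not p.excluded]
    areas = np.array(
        [100.0 * len(p.vegm.hosting_nodes) / n_atrial_nodes for p in kept]
    )
    agree = np.array([abs(p.diff) <= agreement_hz + 1e-9 for p in kept], dtype=bool)
    same, diff = areas[agree], areas[~agree]
    hi = float(areas.max()) if areas.size else 1.0
    edges = np.linspace(0.0, max(hi, 1e-6), n_hist_bins + 1)

    def hist(x: np.ndarray) -> np.ndarray | None:
        if x.size == 0:
            warnings.warn("empty HDF-area partition; distribution omitted")
            return None
        h, _ = np.histogram(x, bins=edges, density=True)
        return h

    if same.size and diff.size:
        p_value = float(stats.mannwhitneyu(same, diff, alternative="two-sided").pvalue)
    else:
        p_value = float("nan")
    return AreaComparison(
        same_areas=same,
        diff_areas=diff,
        hist_edges=edges,
        same_hist=hist(same),
        diff_hist=hist(diff),
        p_value=p_value,
    )
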