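"""Detection of wind-driven subterranean CO2 ventilation episodes (VE).

The detector scans a site-year in consecutive, non-overlapping 5-calendar-day
windows anchored at 1 January (73 windows in a 365-day year; day 366 of a
leap year falls in the dropped remainder).  Each window passes through:

1. *Stability screening* - the window is admitted only if the mean air
   temperature of day 1 and day 5 differ by at most 3 degC and the mean soil
   water content by at most 1 % (inclusive bounds, computed on all
   non-missing half-hours of those days, before record filtering).
2. *Record filtering* - daytime (radiation > 50), emitting (Fc > 0), dry
   (precipitation <= 1e-5 mm), turbulent (u* > 0.2 m s-1, strict), measured
   best quality (qc flag = 0), and complete for every mapped covariate
   (listwise deletion).  Each removed record is attributed to the first
   criterion it fails, in that order.
3. *Classification* - with more than 40 surviving records, the partial
   Spearman correlation of Fc against u* given the ancillary covariates
   (TA, VPD, TS, PA, SWC, PPFD_IN, SW_IN; constant or rank-collinear columns
   are pruned deterministically and recorded) decides the verdict:
   a ventilation episode requires rho > 0.2 *and* p < 0.05, both strict.

Multi-year sites follow the year policy: up to 4 years -> analyse all;
5-6 years -> the first four consecutive; more than 6 -> years 1, 3, 5, 7 of
the record.  The reported year is the analysed year with the most VE
(earliest on ties).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

from .errors import IllConditionedError, UndefinedCorrelationError
from .io_flux import FluxSeries
from .stats_core import PartialCorrResult, partial_spearman

__all__ = [
    "DetectionConfig",
    "FilterReport",
    "WindowResult",
    "SiteResult",
    "make_windows",
    "window_stability",
    "filter_records",
    "classify_window",
    "ve_verdict",
    "select_years",
    "select_reporting_year",
    "swc_percentile_at_ve",
    "emission_period",
    "summarize_coefficients",
    "detect_site",
]

# Rejection / removal reason labels
STABILITY_TA = "stability_TA"
STABILITY_SWC = "stability_SWC"
STABILITY_UNEVALUABLE = "stability_unevaluable"
TOO_FEW_RECORDS = "too_few_records"
DEGENERATE = "degenerate"

FILTER_ORDER = (
    "night",
    "nonpositive_fc",
    "rain",
    "low_ustar",
    "bad_qc",
    "missing_any_required",
)


@dataclass(frozen=True)
class DetectionConfig:
    """All thresholds of the detection algorithm, overridable per run.

    Radiation thresholds are per-variable: SW_IN is compared in W m-2 and the
    PPFD_IN fallback in umol m-2 s-1, both defaulting to 50 in their native
    units.  ``stride_days`` enables sliding windows for sensitivity studies;
    the default tiling is non-overlapping.
    """

    window_days: int = 5
    daytime_threshold_sw: float = 50.0       # W m-2, strict
    daytime_threshold_ppfd: float = 50.0     # umol m-2 s-1, strict
    fc_positive_threshold: float = 0.0       # umol m-2 s-1, strict
    ta_stability_max: float = 3.0            # degC, inclusive
    swc_stability_max: float = 1.0           # volumetric %, inclusive
    precip_zero_tol: float = 1e-5            # mm; records above are excluded
    ustar_min: float = 0.2                   # m s-1, strict
    n_min: int = 40                          # strict (N > 40)
    qc_required: int = 0
    rho_min: float = 0.2                     # strict
    alpha: float = 0.05                      # strict
    covariate_set: tuple = ("TA", "VPD", "TS", "PA", "SWC", "SW_IN", "PPFD_IN")
    consecutive_years_max: int = 4
    nonconsecutive_years_above: int = 6
    stride_days: int | None = None

    def __post_init__(self):
        if self.window_days < 2:
            raise ValueError("window_days must be >= 2 (stability needs "
                             "distinct first and last days)")


@dataclass(frozen=True)
class FilterReport:
    """Per-criterion removal counts, first-failing-criterion attribution."""

    records_total: int
    removed: dict
    records_surviving: int


@dataclass(frozen=True)
class WindowResult:
    site_id: str
    year: int
    index: int
    start: date
    admitted: bool
    rejection_reason: str | None = None
    n: int | None = None
    covariates_used: tuple = ()
    rho: float | None = None
    p_value: float | None = None
    is_ve: bool = False
    filter_report: FilterReport | None = None


@dataclass
class SiteResult:
    site_id: str
    years_analyzed: tuple
    windows: dict
    selected_year: int
    ve_count_selected_year: int
    diagnostics: dict = field(default_factory=dict)


def make_windows(series: FluxSeries, year: int, cfg: DetectionConfig):
    """Start timestamps of the year's windows (calendar-anchored tiling)."""
    days_in_year = 366 if pd.Timestamp(year=year, month=1, day=1).is_leap_year else 365
    stride = cfg.stride_days or cfg.window_days
    starts = []
    day = 0
    while day + cfg.window_days <= days_in_year:
        starts.append(pd.Timestamp(year=year, month=1, day=1) + pd.Timedelta(days=day))
        day += stride
    return starts


def _window_frame(series: FluxSeries, start: pd.Timestamp, cfg: DetectionConfig):
    end = start + pd.Timedelta(days=cfg.window_days) - pd.Timedelta(seconds=1)
    return series.data.loc[start:end]


def window_stability(window: pd.DataFrame, start: pd.Timestamp, cfg: DetectionConfig):
    """(admitted, reason) from the day-1 / day-last stability criteria.

    Daily means use every non-missing half-hour of the window's first and
    last calendar day, before record-level filtering.  A mapped variable
    entirely missing on either day makes the window unevaluable; an unmapped
    variable skips its test.
    """
    last = start + pd.Timedelta(days=cfg.window_days - 1)
    days = window.index.normalize()
    for var, bound, reason in (
        ("TA", cfg.ta_stability_max, STABILITY_TA),
        ("SWC", cfg.swc_stability_max, STABILITY_SWC),
    ):
        if var not in window.columns:
            continue
        first_vals = window.loc[days == start, var].dropna()
        last_vals = window.loc[days == last, var].dropna()
        if first_vals.empty or last_vals.empty:
            return False, STABILITY_UNEVALUABLE
        if abs(first_vals.mean() - last_vals.mean()) > bound:
            return False, reason
    return True, None


def filter_records(window: pd.DataFrame, cfg: DetectionConfig):
    """Apply the six record-level predicates; return survivors + report.

    A record with a missing value fails the first predicate that needs that
    value.  Missing precipitation is treated as zero only when the site maps
    no precipitation column at all.
    """
    n_total = len(window)
    idx = window.index
    if "SW_IN" in window.columns:
        rad_ok = window["SW_IN"] > cfg.daytime_threshold_sw
    else:
        rad_ok = window["PPFD_IN"] > cfg.daytime_threshold_ppfd
    fc_ok = window["FC"] > cfg.fc_positive_threshold
    if "P" in window.columns:
        rain_ok = window["P"] <= cfg.precip_zero_tol
    else:
        rain_ok = pd.Series(True, index=idx)
    ustar_ok = window["USTAR"] > cfg.ustar_min
    if "FC_QC" in window.columns:
        qc_ok = window["FC_QC"] == cfg.qc_required
    else:
        qc_ok = pd.Series(True, index=idx)
    required = [c for c in cfg.covariate_set if c in window.columns]
    if required:
        complete = window[required].notna().all(axis=1)
    else:
        complete = pd.Series(True, index=idx)

    passes = {
        "night": rad_ok.fillna(False),
        "nonpositive_fc": fc_ok.fillna(False),
        "rain": rain_ok.fillna(False) if "P" in window.columns else rain_ok,
        "low_ustar": ustar_ok.fillna(False),
        "bad_qc": qc_ok.fillna(False),
        "missing_any_required": complete,
    }
    removed = {}
    alive = pd.Series(True, index=idx)
    for name in FILTER_ORDER:
        fail = alive & ~passes[name]
        removed[name] = int(fail.sum())
        alive &= passes[name]
    surviving = window[alive]
    return surviving, FilterReport(
        records_total=n_total,
        removed=removed,
        records_surviving=len(surviving),
    )


def ve_verdict(rho: float, p_value: float, cfg: DetectionConfig) -> bool:
    """The episode decision rule: rho strictly above 0.2 and p strictly
    below 0.05 (defaults)."""
    return rho > cfg.rho_min and p_value < cfg.alpha


def _prune_covariates(surviving: pd.DataFrame, cfg: DetectionConfig):
    """Mapped covariates, minus constant columns, in configured order."""
    covs = []
    for name in cfg.covariate_set:
        if name in surviving.columns and surviving[name].nunique() > 1:
            covs.append(name)
    return covs


def classify_window(
    site_id: str,
    year: int,
    index: int,
    start: pd.Timestamp,
    surviving: pd.DataFrame,
    cfg: DetectionConfig,
    filter_report: FilterReport | None = None,
) -> WindowResult:
    """Partial-correlation classification of one filtered window."""
    base = dict(
        site_id=site_id, year=year, index=index, start=start.date(),
        filter_report=filter_report,
    )
    n = len(surviving)
    if n <= cfg.n_min:
        return WindowResult(
            admitted=False, rejection_reason=TOO_FEW_RECORDS, n=n, **base
        )
    covs = _prune_covariates(surviving, cfg)
    fc = surviving["FC"].to_numpy()
    ustar = surviving["USTAR"].to_numpy()
    result: PartialCorrResult | None = None
    while result is None:
        Z = surviving[covs].to_numpy() if covs else None
        try:
            result = partial_spearman(fc, ustar, Z, covariate_names=covs)
        except IllConditionedError as exc:
            covs = [c for c in covs if c not in exc.columns]
        except UndefinedCorrelationError:
            return WindowResult(
                admitted=True, rejection_reason=DEGENERATE, n=n,
                covariates_used=tuple(covs), is_ve=False, **base
            )
    return WindowResult(
        admitted=True,
        n=n,
        covariates_used=result.covariates_used,
        rho=result.rho,
        p_value=result.p_value,
        is_ve=ve_verdict(result.rho, result.p_value, cfg),
        **base,
    )


def analyze_year(series: FluxSeries, year: int, cfg: DetectionConfig):
    """All window results for one site-year."""
    results = []
    for index, start in enumerate(make_windows(series, year, cfg)):
        window = _window_frame(series, start, cfg)
        admitted, reason = window_stability(window, start, cfg)
        if not admitted:
            results.append(
                WindowResult(
                    site_id=series.site_id, year=year, index=index,
                    start=start.date(), admitted=False, rejection_reason=reason,
                )
            )
            continue
        surviving, report = filter_records(window, cfg)
        results.append(
            classify_window(
                series.site_id, year, index, start, surviving, cfg, report
            )
        )
    return results


def select_years(years, cfg: DetectionConfig):
    """The multi-year policy applied to a site's available years."""
    years = sorted(years)
    if not years:
        raise ValueError("no years with data")
    if len(years) <= cfg.consecutive_years_max:
        return list(years)
    if len(years) <= cfg.nonconsecutive_years_above:
        return years[: cfg.consecutive_years_max]
    return years[0::2][: cfg.consecutive_years_max]


def select_reporting_year(ve_counts: dict) -> int:
    """Year with the most VE; earliest year breaks ties."""
    if not ve_counts:
        raise ValueError("no analysed years")
    best = max(ve_counts.values())
    return min(y for y, c in ve_counts.items() if c == best)


def swc_percentile_at_ve(series: FluxSeries, year: int, ve_windows, cfg=None):
    """Annual percentile rank (0-100, midrank convention) of each VE
    window's mean SWC within the year's non-missing half-hourly SWC."""
    if "SWC" not in series.data.columns:
        import warnings

        warnings.warn(f"{series.site_id}: SWC unmapped, percentile diagnostic "
                      "skipped", stacklevel=2)
        return []
    cfg = cfg or DetectionConfig()
    annual = series.year_frame(year)["SWC"].dropna().to_numpy()
    if annual.size == 0:
        return []
    out = []
    for win in ve_windows:
        start = pd.Timestamp(win.start)
        frame = _window_frame(series, start, cfg)
        vals = frame["SWC"].dropna()
        if vals.empty:
            out.append(float("nan"))
            continue
        mean = float(vals.mean())
        less = int((annual < mean).sum())
        equal = int((annual == mean).sum())
        out.append(100.0 * (less + 0.5 * equal) / annual.size)
    return out


def emission_period(series: FluxSeries, year: int):
    """(first DOY, last DOY, span in days) of positive daily-mean net flux.

    Span counts the inclusive DOY range; returns None when no day has a
    positive daily mean.
    """
    frame = series.year_frame(year)
    daily = frame["FC"].groupby(frame.index.dayofyear).mean()
    positive = daily[daily > 0]
    if positive.empty:
        return None
    first = int(positive.index.min())
    last = int(positive.index.max())
    return first, last, last - first + 1


def summarize_coefficients(rho_by_group: dict) -> dict:
    """Five-number summary (min, q1, median, q3, max) of VE coefficients per
    group; groups without any VE are omitted."""
    out = {}
    for group, values in rho_by_group.items():
        arr = np.asarray([v for v in values if v is not None], dtype=float)
        if arr.size == 0:
            continue
        q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75])
        out[group] = {
            "min": float(arr.min()),
            "q1": float(q1),
            "median": float(med),
            "q3": float(q3),
            "max": float(arr.max()),
            "count": int(arr.size),
        }
    return out


def detect_site(series: FluxSeries, cfg: DetectionConfig | None = None) -> SiteResult:
    """Run the full per-site workflow and assemble diagnostics."""
    from .io_flux import data_availability

    cfg = cfg or DetectionConfig()
    years = select_years(series.years_available, cfg)
    windows = {year: analyze_year(series, year, cfg) for year in years}
    ve_counts = {
        year: sum(w.is_ve for w in wins) for year, wins in windows.items()
    }
    selected = select_reporting_year(ve_counts)
    ve_windows = [w for w in windows[selected] if w.is_ve]
    diagnostics = {
        "availability": {y: data_availability(series, y) for y in years},
        "emission_period": emission_period(series, selected),
        "swc_percentiles_at_ve": swc_percentile_at_ve(
            series, selected, ve_windows, cfg
        ) if "SWC" in series.data.columns else [],
        "rho_summary": summarize_coefficients(
            {series.site_id: [w.rho for w in ve_windows]}
        ).get(series.site_id),
    }
    return SiteResult(
        site_id=series.site_id,
        years_analyzed=tuple(years),
        windows=windows,
        selected_year=selected,
        ve_count_selected_year=ve_counts[selected],
        diagnostics=diagnostics,
    )
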