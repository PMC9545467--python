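"""Reading, validation and writing of half-hourly flux-network tables.

Input files follow the FLUXNET2015 / AmeriFlux BASE half-hourly dialect:
comma-separated, a header row, ``TIMESTAMP_START`` (and usually
``TIMESTAMP_END``) as ``YYYYMMDDHHMM`` strings, and ``-9999`` as the missing
sentinel.  Columns are mapped onto canonical variable names through a
:class:`VariableMap`; two maps for the common dialects ship with the package.

Records are indexed by TIMESTAMP_START in the file's local standard time
(flux-network files carry no timezone, and none is invented).  After reading,
the series is re-indexed onto the complete 30-minute grid of the covered
period, so gaps appear as missing fields rather than absent rows; grid
completion never invents values.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, TimestampParseError

__all__ = [
    "CANONICAL_VARIABLES",
    "MANDATORY_VARIABLES",
    "VariableMap",
    "FluxSeries",
    "FLUXNET2015_MAP",
    "AMERIFLUX_BASE_MAP",
    "read_flux_csv",
    "data_availability",
    "write_results",
]

#: Canonical variable names, in canonical column order.
CANONICAL_VARIABLES = (
    "FC",       # net CO2 flux, umol m-2 s-1, positive = emission
    "USTAR",    # friction velocity, m s-1
    "TA",       # air temperature, degC
    "TS",       # soil temperature, degC
    "SW_IN",    # incoming shortwave radiation, W m-2
    "PPFD_IN",  # incoming photosynthetic photon flux density, umol m-2 s-1
    "SWC",      # volumetric soil water content, %
    "P",        # precipitation, mm per half-hour
    "PA",       # atmospheric pressure, kPa
    "VPD",      # vapour pressure deficit, hPa
    "FC_QC",    # quality flag for FC; 0 = directly measured, best quality
)

MANDATORY_VARIABLES = ("FC", "USTAR")

#: Any mapped numeric value at or below this is treated as the missing
#: sentinel (absorbs -9999 vs -9999.0 dialects).
MISSING_SENTINEL_MAX = -9990.0


@dataclass(frozen=True)
class VariableMap:
    """Mapping canonical name -> source column name.

    FC and USTAR are mandatory, as is at least one of SW_IN / PPFD_IN; the
    mapping must be injective over the entries present.
    """

    mapping: dict

    def __post_init__(self):
        unknown = set(self.mapping) - set(CANONICAL_VARIABLES)
        if unknown:
            raise ConfigurationError(
                f"unknown canonical variables in map: {sorted(unknown)}"
            )
        for name in MANDATORY_VARIABLES:
            if name not in self.mapping:
                raise ConfigurationError(f"variable map must include {name}")
        if "SW_IN" not in self.mapping and "PPFD_IN" not in self.mapping:
            raise ConfigurationError(
                "variable map must include SW_IN or PPFD_IN"
            )
        sources = list(self.mapping.values())
        if len(sources) != len(set(sources)):
            raise ConfigurationError("variable map is not injective")

    def __contains__(self, name):
        return name in self.mapping

    def items(self):
        return self.mapping.items()


FLUXNET2015_MAP = VariableMap(
    {
        "FC": "NEE_VUT_REF",
        "FC_QC": "NEE_VUT_REF_QC",
        "USTAR": "USTAR",
        "TA": "TA_F",
        "TS": "TS_F_MDS_1",
        "SW_IN": "SW_IN_F",
        "PPFD_IN": "PPFD_IN",
        "SWC": "SWC_F_MDS_1",
        "P": "P_F",
        "PA": "PA_F",
        "VPD": "VPD_F",
    }
)

AMERIFLUX_BASE_MAP = VariableMap(
    {
        "FC": "FC",
        "FC_QC": "FC_SSITC_TEST",
        "USTAR": "USTAR",
        "TA": "TA",
        "TS": "TS",
        "SW_IN": "SW_IN",
        "PPFD_IN": "PPFD_IN",
        "SWC": "SWC",
        "P": "P",
        "PA": "PA",
        "VPD": "VPD",
    }
)

DEFAULT_MAPS = {
    "fluxnet2015": FLUXNET2015_MAP,
    "ameriflux": AMERIFLUX_BASE_MAP,
}


@dataclass
class FluxSeries:
    """A site's canonicalised half-hourly record table.

    ``data`` is indexed by TIMESTAMP_START on a complete 30-minute grid with
    canonical column names; missing values are NaN.
    """

    site_id: str
    data: pd.DataFrame
    variable_provenance: VariableMap = field(default=FLUXNET2015_MAP)

    @property
    def years_available(self) -> tuple:
        """Calendar years with at least one non-missing mapped value."""
        if self.data.empty:
            return ()
        present = self.data.notna().any(axis=1)
        years = np.unique(self.data.index.year[present.to_numpy()])
        return tuple(int(y) for y in years)

    def year_frame(self, year: int) -> pd.DataFrame:
        return self.data.loc[f"{year}-01-01": f"{year}-12-31 23:59:59"]


def _parse_timestamps(raw: pd.Series) -> pd.DatetimeIndex:
    text = raw.astype(str).str.strip()
    parsed = pd.to_datetime(text, format="%Y%m%d%H%M", errors="coerce")
    bad = parsed.isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise TimestampParseError(
            f"unparseable TIMESTAMP_START {text.iloc[row]!r} at data row {row + 1}"
        )
    idx = pd.DatetimeIndex(parsed)
    off_grid = (idx.minute % 30 != 0) | (idx.second != 0)
    if off_grid.any():
        row = int(np.flatnonzero(off_grid)[0])
        raise DataError(
            f"timestamp not on the half-hour grid at data row {row + 1}"
        )
    return idx


def read_flux_csv(
    path,
    vmap: VariableMap = FLUXNET2015_MAP,
    site_id: str | None = None,
    strict: bool = False,
) -> FluxSeries:
    """Read one half-hourly flux CSV into a :class:`FluxSeries`.

    Sentinel values (<= -9990) become NaN, rows are re-indexed onto the
    complete 30-minute grid between the first and last timestamp, and
    unmapped columns are ignored.  ``strict=True`` rejects files whose SWC
    never exceeds 1.5 (likely a fraction, not a percentage); otherwise such
    files only trigger a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype=str)
    if "TIMESTAMP_START" not in raw.columns:
        raise ConfigurationError(f"{path.name}: missing column TIMESTAMP_START")

    idx = _parse_timestamps(raw["TIMESTAMP_START"])
    if idx.has_duplicates:
        dup = idx[idx.duplicated()][0]
        raise DataError(f"{path.name}: duplicate timestamp {dup}")

    columns = {}
    for canonical, source in vmap.items():
        if source not in raw.columns:
            if canonical in MANDATORY_VARIABLES:
                raise ConfigurationError(
                    f"{path.name}: missing mandatory column {source}"
                )
            continue
        col = pd.to_numeric(raw[source], errors="coerce")
        col[col <= MISSING_SENTINEL_MAX] = np.nan
        columns[canonical] = col.to_numpy()
    if "SW_IN" not in columns and "PPFD_IN" not in columns:
        raise ConfigurationError(
            f"{path.name}: neither SW_IN nor PPFD_IN source column present"
        )

    data = pd.DataFrame(columns, index=idx).sort_index()
    grid = pd.date_range(data.index[0], data.index[-1], freq="30min")
    data = data.reindex(grid)
    data.index.name = "TIMESTAMP_START"

    if "SWC" in data.columns and data["SWC"].notna().any():
        if float(np.nanmax(data["SWC"].to_numpy())) <= 1.5:
            msg = (
                f"{path.name}: SWC never exceeds 1.5 - values look fractional, "
                "expected volumetric %"
            )
            if strict:
                raise DataError(msg)
            warnings.warn(msg, stacklevel=2)

    if site_id is None:
        site_id = path.stem.split("_")[0]
    return FluxSeries(site_id=site_id, data=data, variable_provenance=vmap)


def data_availability(series: FluxSeries, year: int) -> float:
    """Fraction of the year's half-hour slots with measured, qc-0 net flux.

    The denominator is the full calendar year (17,520 slots, or 17,568 in a
    leap year) regardless of the span actually covered by the file.
    """
    if year not in series.years_available:
        raise ValueError(f"year {year} not available for site {series.site_id}")
    frame = series.year_frame(year)
    good = frame["FC"].notna()
    if "FC_QC" in frame.columns:
        good &= frame["FC_QC"] == 0
    slots = 17568 if pd.Timestamp(year=year, month=1, day=1).is_leap_year else 17520
    return float(good.sum()) / slots


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        if np.isnan(value):
            return ""
        return format(value, ".6g")
    return str(value)


def write_results(results, out_dir, config=None, version="0.1.0") -> dict:
    """Write windows.csv, sites.csv and run.json for a collection of sites.

    windows.csv holds one row per *admitted* window; sites.csv one row per
    site; run.json the effective detection configuration and package version.
    Output is byte-stable for identical inputs and config.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "windows": out_dir / "windows.csv",
        "sites": out_dir / "sites.csv",
        "run": out_dir / "run.json",
    }

    with open(paths["windows"], "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            [
                "site_id", "year", "window_index", "window_start", "n",
                "rho", "p_value", "is_ve", "covariates_used",
            ]
        )
        for site in results:
            for year in site.years_analyzed:
                for win in site.windows[year]:
                    if not win.admitted:
                        continue
                    writer.writerow(
                        [
                            site.site_id,
                            year,
                            win.index,
                            win.start.isoformat(),
                            win.n,
                            _fmt(win.rho),
                            _fmt(win.p_value),
                            win.is_ve,
                            ";".join(win.covariates_used),
                        ]
                    )

    with open(paths["sites"], "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            [
                "site_id", "years_analyzed", "selected_year",
                "ve_count_selected_year", "no_ve", "availability_selected_year",
                "emission_first_doy", "emission_last_doy", "emission_span_days",
            ]
        )
        for site in results:
            diag = site.diagnostics
            period = diag.get("emission_period")
            writer.writerow(
                [
                    site.site_id,
                    ";".join(str(y) for y in site.years_analyzed),
                    site.selected_year,
                    site.ve_count_selected_year,
                    site.ve_count_selected_year == 0,
                    _fmt(diag.get("availability", {}).get(site.selected_year)),
                    period[0] if period else "",
                    period[1] if period else "",
                    period[2] if period else "",
                ]
            )

    manifest = {"package": "ventiscan", "version": version}
    if config is not None:
        from dataclasses import asdict

        cfg = asdict(config)
        cfg = {k: list(v) if isinstance(v, tuple) else v for k, v in cfg.items()}
        manifest["config"] = cfg
    with open(paths["run"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
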