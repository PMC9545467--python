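"""Seeded synthetic dryland flux-tower generator with ground-truth episodes.

The generator emulates the *statistical* structure of a half-hourly
eddy-covariance record at a winter-wet / summer-dry (Mediterranean-type)
dryland site, together with injected turbulence-driven CO2 efflux episodes,
so the whole detection pipeline can be exercised end to end without flux
archives.  It mimics diurnal/seasonal radiation, AR(1) weather noise,
a precipitation event process, a soil-moisture bucket with radiative
drydown, lognormal friction velocity, a light-response/Q10 biosphere, and
finally the ventilation component

    ve_flux = gain * max(0, ustar - ustar_offset)

active only inside scheduled 5-day blocks, during daytime, and while soil
water content sits below a dryness ceiling - turbulence as the trigger,
soil dryness as the enabling condition, and the gain playing the role of
the below-ground CO2 store.

Determinism: every random draw flows from one seeded generator in a fixed,
schema-versioned order (clouds, temperature noise, rain, pressure, humidity
noise, turbulence noise, flux noise, quality corruption, missingness), so a
scenario plus seed reproduces the series - and its CSV fixture - bit for
bit.  VPD is generated after the soil bucket because relative humidity is
tied to soil moisture.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .errors import ConfigurationError
from .io_flux import FLUXNET2015_MAP, FluxSeries

__all__ = ["SyntheticScenario", "GroundTruth", "generate", "write_fixture"]

SCHEMA_VERSION = 1

#: Standard approximation for the photon-flux equivalent of shortwave
#: radiation, umol J-1.
PPFD_PER_SW = 2.1


@dataclass(frozen=True)
class SyntheticScenario:
    """Full parameterisation of one simulated site-year.

    Defaults describe a semiarid site with a winter wet season, a ~5-month
    summer drydown, and six ventilation blocks scheduled in the driest part
    of the year.  ``ve_blocks`` are zero-based window indices (window ``i``
    covers DOY ``5 i + 1 .. 5 i + 5``).
    """

    seed: int = 42
    site_id: str = "SYN-DRY"
    year: int = 2013

    # Radiation / day length
    rad_peak: float = 950.0          # clear-sky summer noon, W m-2
    rad_min: float = 420.0           # clear-sky winter noon, W m-2
    daylength_amp_h: float = 3.2     # half peak-to-trough day-length swing, h
    cloud_atten_wet: float = 0.55    # max fractional attenuation, wet season
    cloud_atten_dry: float = 0.25

    # Air / soil temperature
    ta_mean: float = 16.0            # degC annual mean
    ta_seasonal_amp: float = 9.0     # degC, peak DOY ~200
    ta_diurnal_amp: float = 5.0      # degC, peak mid-afternoon
    ta_ar1: float = 0.97             # per half-hour
    ta_noise_sd: float = 1.0         # stationary sd of the AR(1) anomaly
    ts_offset: float = 0.8           # degC, soil warmer than 5-day air mean

    # Turbulence
    ustar_day: float = 0.46          # m s-1, daytime mean level
    ustar_night: float = 0.12
    ustar_ar1: float = 0.9
    ustar_lognoise_sd: float = 0.45  # stationary sd on the log scale

    # Precipitation (wet season only)
    wet_doy_ranges: tuple = ((1, 120), (300, 366))
    rain_prob_per_day: float = 0.35
    rain_mean_mm: float = 8.0

    # Soil-moisture bucket
    swc_capacity: float = 30.0       # volumetric %
    swc_residual: float = 2.0        # asymptotic dry value, %
    swc_init_frac: float = 0.75      # initial fill fraction of capacity
    drydown_efold_days: float = 15.0
    evap_rad_coef: float = 1.0       # radiative enhancement of drydown
    infil_pct_per_mm: float = 1.2    # bucket gain per mm of rain

    # Biology
    gpp_max: float = 12.0            # umol m-2 s-1 light-saturated uptake
    ppfd_half: float = 600.0         # umol m-2 s-1 half-saturation
    swc_wilt: float = 5.0            # % below which GPP shuts down
    swc_opt: float = 15.0            # % above which GPP is unconstrained
    reco_base: float = 1.6           # umol m-2 s-1 at 15 degC, moist soil
    q10: float = 2.0
    reco_swc_floor: float = 0.3      # dry-soil floor of the moisture limiter

    # Ventilation injection
    ve_blocks: tuple = (41, 43, 45, 47, 49, 51)
    ve_gain: float = 4.7             # umol m-2 s-1 per m s-1 (pilot-calibrated)
    ve_ustar_offset: float = 0.15    # m s-1
    ve_swc_ceiling: float = 8.0      # % above which ventilation is disabled

    # Observation model
    fc_noise_sd: float = 0.7         # umol m-2 s-1
    missing_rate: float = 0.01       # per variable-record
    qc_bad_rate: float = 0.03        # fraction of records flagged non-measured
    pa_mean: float = 95.0            # kPa
    pa_amp: float = 0.6              # stationary sd of synoptic pressure, kPa
    pa_ar1: float = 0.995

    schema_version: int = SCHEMA_VERSION


@dataclass
class GroundTruth:
    """Per-block injection labels plus the per-record ventilation flux."""

    blocks: list            # dicts: index, injected, gain, mean_swc
    ve_flux: np.ndarray     # clean ventilation component, one per record

    @property
    def injected_indices(self) -> tuple:
        return tuple(b["index"] for b in self.blocks if b["injected"])


def _validate(sc: SyntheticScenario, n_windows: int):
    if sc.ve_gain < 0:
        raise ConfigurationError("ve_gain must be non-negative")
    if sc.missing_rate < 0 or sc.missing_rate >= 1:
        raise ConfigurationError("missing_rate must be in [0, 1)")
    if sc.qc_bad_rate < 0 or sc.qc_bad_rate >= 1:
        raise ConfigurationError("qc_bad_rate must be in [0, 1)")
    for b in sc.ve_blocks:
        if not 0 <= b < n_windows:
            raise ConfigurationError(f"ve_blocks: window {b} outside the year")
    if not 0 < sc.swc_residual < sc.swc_capacity:
        raise ConfigurationError("need 0 < swc_residual < swc_capacity")
    if sc.schema_version != SCHEMA_VERSION:
        raise ConfigurationError(
            f"scenario schema_version must be {SCHEMA_VERSION}"
        )


def _ar1(rng, n, phi, stationary_sd):
    eps = rng.normal(0.0, stationary_sd * np.sqrt(1.0 - phi * phi), n)
    return lfilter([1.0], [1.0, -phi], eps)


def generate(sc: SyntheticScenario):
    """Build one site-year; returns ``(FluxSeries, GroundTruth)``."""
    ndays = 366 if pd.Timestamp(year=sc.year, month=1, day=1).is_leap_year else 365
    n_windows = ndays // 5
    _validate(sc, n_windows)
    n = ndays * 48
    rng = np.random.default_rng(sc.seed)

    idx = pd.date_range(f"{sc.year}-01-01", periods=n, freq="30min")
    doy = idx.dayofyear.to_numpy().astype(float)
    hour = idx.hour.to_numpy() + idx.minute.to_numpy() / 60.0
    day_of = (doy - 1).astype(int)
    doy_days = np.arange(1, ndays + 1)
    wet_daily = np.zeros(ndays, dtype=bool)
    for lo, hi in sc.wet_doy_ranges:
        wet_daily |= (doy_days >= lo) & (doy_days <= hi)

    # Clear-sky radiation: seasonal amplitude envelope x clipped cosine arch.
    phase = 2.0 * np.pi * (doy - 172.0) / 365.0
    seasonal = 0.5 * (1.0 + np.cos(phase))
    amp = sc.rad_min + (sc.rad_peak - sc.rad_min) * seasonal
    half_daylength = (12.0 + sc.daylength_amp_h * np.cos(phase)) / 2.0
    hour_angle = (hour - 12.0) / half_daylength
    sw_clear = np.where(
        np.abs(hour_angle) < 1.0, amp * np.cos(0.5 * np.pi * hour_angle), 0.0
    )
    # draw 1: daily cloud attenuation
    u_cloud = rng.uniform(size=ndays)
    atten = np.where(wet_daily, sc.cloud_atten_wet, sc.cloud_atten_dry)
    cloud_factor = 1.0 - atten * u_cloud**2
    sw_in = sw_clear * cloud_factor[day_of]
    ppfd_in = PPFD_PER_SW * sw_in

    # draw 2: air temperature AR(1) anomaly
    ta_anom = _ar1(rng, n, sc.ta_ar1, sc.ta_noise_sd)
    ta = (
        sc.ta_mean
        + sc.ta_seasonal_amp * np.cos(2.0 * np.pi * (doy - 200.0) / 365.0)
        + sc.ta_diurnal_amp * np.cos(2.0 * np.pi * (hour - 15.0) / 24.0)
        + ta_anom
    )
    ts = (
        pd.Series(ta).rolling(240, center=True, min_periods=1).mean().to_numpy()
        + sc.ts_offset
    )

    # draw 3: precipitation event process (occurrence, depth, timing)
    rain_day = wet_daily & (rng.uniform(size=ndays) < sc.rain_prob_per_day)
    depth = rng.exponential(sc.rain_mean_mm, ndays)
    slot = rng.integers(0, 48, ndays)
    p = np.zeros(n)
    rain_days = np.flatnonzero(rain_day)
    p[rain_days * 48 + slot[rain_days]] = depth[rain_days]

    # draw 4: atmospheric pressure, slow synoptic AR(1)
    pa = sc.pa_mean + _ar1(rng, n, sc.pa_ar1, sc.pa_amp)

    # Soil bucket: rain infiltration, radiation-scaled exponential drydown.
    loss_rate = (0.5 + sc.evap_rad_coef * sw_in / sc.rad_peak) / (
        sc.drydown_efold_days * 48.0
    )
    swc = np.empty(n)
    level = sc.swc_init_frac * sc.swc_capacity
    for i in range(n):
        level = min(level + sc.infil_pct_per_mm * p[i], sc.swc_capacity)
        level -= (level - sc.swc_residual) * loss_rate[i]
        swc[i] = level

    # draw 5: humidity noise -> VPD (RH tied to soil moisture)
    rh = np.clip(
        0.25 + 0.6 * swc / sc.swc_capacity + rng.normal(0.0, 0.07, n),
        0.05,
        0.98,
    )
    esat = 6.112 * np.exp(17.62 * ta / (243.12 + ta))  # hPa
    vpd = np.maximum(esat * (1.0 - rh), 0.0)

    # draw 6: friction velocity, daytime-enhanced lognormal AR(1)
    # sqrt coupling: turbulence rises faster than radiation in the morning
    diurnal_weight = np.sqrt(sw_clear / np.maximum(amp, 1e-9))
    level_u = sc.ustar_night + (sc.ustar_day - sc.ustar_night) * diurnal_weight
    if sc.ustar_lognoise_sd > 0:
        ln_noise = _ar1(rng, n, sc.ustar_ar1, sc.ustar_lognoise_sd)
        ustar = level_u * np.exp(ln_noise - 0.5 * sc.ustar_lognoise_sd**2)
    else:
        _ = rng.normal(0.0, 1.0, n)  # keep the draw order stable
        ustar = level_u.copy()

    # Biosphere
    f_swc = np.clip((swc - sc.swc_wilt) / (sc.swc_opt - sc.swc_wilt), 0.0, 1.0)
    gpp = sc.gpp_max * ppfd_in / (sc.ppfd_half + ppfd_in) * f_swc
    reco = (
        sc.reco_base
        * sc.q10 ** ((ts - 15.0) / 10.0)
        * (sc.reco_swc_floor + (1.0 - sc.reco_swc_floor) * np.clip(swc / 20.0, 0.0, 1.0))
    )

    # Ventilation component: scheduled blocks, daytime, dry soil only.
    window_index = ((doy - 1) // 5).astype(int)
    in_block = np.isin(window_index, sc.ve_blocks) & (window_index < n_windows)
    active = in_block & (sw_in > 50.0) & (swc < sc.ve_swc_ceiling)
    ve_flux = np.where(
        active, sc.ve_gain * np.maximum(0.0, ustar - sc.ve_ustar_offset), 0.0
    )

    # draw 7: observation noise on the net flux
    fc = -gpp + reco + ve_flux + rng.normal(0.0, sc.fc_noise_sd, n)

    # draw 8: quality-flag corruption (2 = gap-filled / rejected)
    fc_qc = np.where(rng.uniform(size=n) < sc.qc_bad_rate, 2.0, 0.0)

    clean = {
        "FC": fc, "USTAR": ustar, "TA": ta, "TS": ts, "SW_IN": sw_in,
        "PPFD_IN": ppfd_in, "SWC": swc, "P": p, "PA": pa, "VPD": vpd,
    }
    # draw 9: per-variable missingness
    observed = {}
    for name, values in clean.items():
        col = values.astype(float).copy()
        if sc.missing_rate > 0:
            col[rng.uniform(size=n) < sc.missing_rate] = np.nan
        else:
            _ = rng.uniform(size=n)
        observed[name] = col
    observed["FC_QC"] = fc_qc

    data = pd.DataFrame(observed, index=idx)
    data.index.name = "TIMESTAMP_START"
    series = FluxSeries(
        site_id=sc.site_id, data=data, variable_provenance=FLUXNET2015_MAP
    )

    blocks = []
    for b in range(n_windows):
        mask = window_index == b
        blocks.append(
            {
                "index": int(b),
                "injected": bool(b in sc.ve_blocks),
                "gain": float(sc.ve_gain if b in sc.ve_blocks else 0.0),
                "mean_swc": float(swc[mask].mean()),
            }
        )
    return series, GroundTruth(blocks=blocks, ve_flux=ve_flux)


def _fixture_cell(value) -> str:
    if np.isnan(value):
        return "-9999"
    return format(value, ".6g")


def write_fixture(series: FluxSeries, truth: GroundTruth, out_dir,
                  scenario: SyntheticScenario | None = None):
    """Write the series as a FLUXNET-dialect CSV plus a truth JSON.

    The CSV is readable by :func:`ventiscan.io_flux.read_flux_csv` with the
    shipped FLUXNET2015 variable map; numeric values carry 6 significant
    digits, missing cells the -9999 sentinel.  Returns the two paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    year = int(series.data.index[0].year)
    csv_path = out_dir / f"{series.site_id}_HH_{year}.csv"
    truth_path = out_dir / f"{series.site_id}_truth.json"

    vmap = series.variable_provenance
    columns = [(canonical, source) for canonical, source in vmap.items()
               if canonical in series.data.columns]
    start = series.data.index.strftime("%Y%m%d%H%M")
    end = (series.data.index + pd.Timedelta(minutes=30)).strftime("%Y%m%d%H%M")
    with open(csv_path, "w", newline="") as fh:
        fh.write(
            "TIMESTAMP_START,TIMESTAMP_END,"
            + ",".join(source for _, source in columns)
            + "\n"
        )
        matrix = series.data[[c for c, _ in columns]].to_numpy()
        qc_col = [c for c, _ in columns].index("FC_QC") if "FC_QC" in series.data.columns else None
        for i in range(len(series.data)):
            cells = []
            for j in range(matrix.shape[1]):
                v = matrix[i, j]
                if j == qc_col and not np.isnan(v):
                    cells.append(str(int(v)))
                else:
                    cells.append(_fixture_cell(v))
            fh.write(f"{start[i]},{end[i]}," + ",".join(cells) + "\n")

    payload = {
        "site_id": series.site_id,
        "year": year,
        "schema_version": SCHEMA_VERSION,
        "blocks": truth.blocks,
        "injected_blocks": list(truth.injected_indices),
    }
    if scenario is not None:
        payload["scenario"] = dataclasses.asdict(scenario)
        payload["scenario"]["ve_blocks"] = list(scenario.ve_blocks)
        payload["scenario"]["wet_doy_ranges"] = [
            list(r) for r in scenario.wet_doy_ranges
        ]
    with open(truth_path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return csv_path, truth_path
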