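"""Survey-table I/O and the end-to-end dose pipeline.

A survey record is one soil-sampling location: coordinates, sampling
date and surface activities of I-131, Cs-137 and Te-129m (kBq/m2), any
of which may be missing or censored.  The pipeline decay-corrects the
activity ratios to the deposition date, fills missing Te-129m/Cs-137
ratios by multilevel B-spline interpolation, evaluates the one-year
dose surface per location, scales it by the Cs-137 deposition density,
and optionally rasterizes the resulting doses.

Records may instead carry pre-corrected ratios (``r_i``/``r_t``
columns); such records are treated as already referred to the
deposition date, including their Cs-137 deposition density.
"""
from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dose_surface import PUBLISHED_FIT, Parameterization, apply_deposition, evaluate
from .mbspline import GridField, GridSpec, interpolate_missing_ratios, mbs_fit, normalize_coords, ScatterSet, evaluate_field
from .nuclides import (
    REFERENCE_DATE,
    NuclideSet,
    RatioSet,
    cumulative_dose,
    decay_correct_ratio,
    decay_factor,
    default_nuclides,
)

__all__ = [
    "SurveyRecord",
    "DoseTableRow",
    "PipelineResult",
    "SURVEY_COLUMNS",
    "DEFAULT_SAMPLE_DATE",
    "read_survey",
    "write_dose_table",
    "run_pipeline",
    "format_dose",
]

logger = logging.getLogger(__name__)

#: Canonical survey-table column order.
SURVEY_COLUMNS = (
    "location_id",
    "lon",
    "lat",
    "sample_date",
    "i131_kbq_m2",
    "cs137_kbq_m2",
    "te129m_kbq_m2",
)

#: Mid survey-window fallback when a record has no sampling date.
DEFAULT_SAMPLE_DATE = _dt.date(2011, 7, 1)

_NA_TOKENS = ("", "ND", "N.D.", "NA", "N/A", "nan", "NaN", "null")


@dataclass(frozen=True)
class SurveyRecord:
    """One sampling location's raw measurements."""

    location_id: str
    lon: float
    lat: float
    sample_date: _dt.date | None = None
    i131_kbq_m2: float | None = None
    cs137_kbq_m2: float | None = None
    te129m_kbq_m2: float | None = None

    def __post_init__(self) -> None:
        for name in ("i131_kbq_m2", "cs137_kbq_m2", "te129m_kbq_m2"):
            v = getattr(self, name)
            if v is not None and not np.isnan(v) and v < 0:
                raise ValueError(f"{self.location_id}: {name} must be >= 0, got {v}")


@dataclass(frozen=True)
class DoseTableRow:
    """A survey record augmented with ratios and doses."""

    record: SurveyRecord
    r_i: float | None
    r_t: float | None
    r_t_origin: str  # "measured" | "interpolated" | ""
    d_unit_msv: float | None
    d_a_msv: float | None
    excluded_reason: str = ""


@dataclass(frozen=True)
class PipelineResult:
    """Pipeline output: augmented table, optional rasters, stage counts."""

    table: pd.DataFrame
    ratio_field: GridField | None
    dose_field: GridField | None
    counts: dict = field(default_factory=dict)


def read_survey(path, schema: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a survey table (comma-delimited, UTF-8) into a typed DataFrame.

    ``schema`` optionally maps canonical column names (see
    :data:`SURVEY_COLUMNS`) to the file's header names.  Blank and
    not-detected tokens become missing values; a non-numeric activity or
    unparseable date raises with the offending row number.  Optional
    pre-corrected ``r_i``/``r_t`` columns are carried through.
    """
    schema = schema or {}
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    rename = {schema.get(k, k): k for k in SURVEY_COLUMNS + ("r_i", "r_t")}
    df = df.rename(columns={v: k for k, v in rename.items() if v in df.columns})
    missing = [c for c in ("location_id", "lon", "lat", "cs137_kbq_m2") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    unknown = [c for c in df.columns if c not in SURVEY_COLUMNS + ("r_i", "r_t")]
    if unknown:
        logger.warning("%s: ignoring unknown columns %s", path, unknown)

    def _num(col):
        if col not in df.columns:
            return np.full(len(df), np.nan)
        out = np.full(len(df), np.nan)
        for i, tok in enumerate(df[col].str.strip()):
            if tok in _NA_TOKENS:
                continue
            try:
                out[i] = float(tok)
            except ValueError:
                raise ValueError(f"{path}: row {i + 1}: non-numeric value {tok!r} in {col}")
        return out

    def _dates():
        if "sample_date" not in df.columns:
            return [None] * len(df)
        out = []
        for i, tok in enumerate(df["sample_date"].str.strip()):
            if tok in _NA_TOKENS:
                out.append(None)
                continue
            try:
                out.append(_dt.date.fromisoformat(tok))
            except ValueError:
                raise ValueError(f"{path}: row {i + 1}: unparseable date {tok!r}")
        return out

    result = pd.DataFrame(
        {
            "location_id": df["location_id"].str.strip(),
            "lon": _num("lon"),
            "lat": _num("lat"),
            "sample_date": _dates(),
            "i131_kbq_m2": _num("i131_kbq_m2"),
            "cs137_kbq_m2": _num("cs137_kbq_m2"),
            "te129m_kbq_m2": _num("te129m_kbq_m2"),
        }
    )
    for extra in ("r_i", "r_t"):
        if extra in df.columns:
            result[extra] = _num(extra)
    neg = [
        c
        for c in ("i131_kbq_m2", "cs137_kbq_m2", "te129m_kbq_m2")
        if (result[c].dropna() < 0).any()
    ]
    if neg:
        raise ValueError(f"{path}: negative activities in columns {neg}")
    logger.info(
        "%s: %d records (I-131 present %d, Cs-137 %d, Te-129m %d)",
        path,
        len(result),
        int(result["i131_kbq_m2"].notna().sum()),
        int(result["cs137_kbq_m2"].notna().sum()),
        int(result["te129m_kbq_m2"].notna().sum()),
    )
    return result


def format_dose(d_msv: float) -> str:
    """Report rounding: doses >= 100 mSv to 3 significant figures, else 1 decimal."""
    if not np.isfinite(d_msv):
        return ""
    if abs(d_msv) >= 100:
        return f"{float(f'{d_msv:.3g}'):g}"
    return f"{d_msv:.1f}"


def run_pipeline(
    records: pd.DataFrame,
    *,
    param: Parameterization = PUBLISHED_FIT,
    nuclides: NuclideSet | None = None,
    mode: str = "surface",
    grid_spec: GridSpec | None = None,
    reference_date: _dt.date = REFERENCE_DATE,
    default_sample_date: _dt.date = DEFAULT_SAMPLE_DATE,
    interpolate_r_i: bool = False,
    n_levels: int = 6,
    base_resolution: int = 4,
) -> PipelineResult:
    """Run the full per-location dose pipeline.

    Stages: (1) decay-correct per-record ratios to ``reference_date``;
    (2) fill missing Te-129m/Cs-137 ratios by multilevel B-spline
    interpolation; (3) evaluate the unit dose via the linear surface
    (``mode="surface"``) or the calibrated forward model
    (``mode="forward"``; identical by the calibration round-trip);
    (4) scale by the Cs-137 deposition density (decay-corrected to the
    reference date for raw records); (5) rasterize doses when
    ``grid_spec`` is given.

    Records without an I-131 ratio are excluded from dose output unless
    ``interpolate_r_i`` is set (the ratio map interpolation covers only
    r_t by default).  Every input record appears in the output table;
    excluded rows carry an ``excluded_reason``.
    """
    if mode not in ("surface", "forward"):
        raise ValueError(f"mode must be 'surface' or 'forward', got {mode!r}")
    if mode == "forward" and nuclides is None:
        from .nuclides import calibrate_coefficients

        nuclides = calibrate_coefficients(param)
    nset = nuclides if nuclides is not None else default_nuclides()
    i131, te129m, cs137 = nset["I-131"], nset["Te-129m"], nset["Cs-137"]

    df = records.copy().reset_index(drop=True)
    n_in = len(df)
    for col in ("r_i", "r_t"):
        if col not in df.columns:
            df[col] = np.nan
    pre_corrected = df["r_i"].notna() | df["r_t"].notna()

    # stage 1: decay-correct measured ratios; correct deposition density
    dep = df["cs137_kbq_m2"].to_numpy(dtype=float).copy()
    r_t_origin = np.where(df["r_t"].notna(), "measured", "")
    n_defaulted_dates = 0
    for i in df.index:
        if pre_corrected[i]:
            continue  # ratios and deposition already at the reference date
        date = df.at[i, "sample_date"] if "sample_date" in df.columns else None
        if not isinstance(date, _dt.date):
            date = default_sample_date
            n_defaulted_dates += 1
        cs = df.at[i, "cs137_kbq_m2"]
        if not np.isfinite(cs) or cs <= 0:
            continue
        dt_hours = (date - reference_date).days * 24.0
        dep[i] = cs / decay_factor(cs137, dt_hours)
        if np.isfinite(df.at[i, "i131_kbq_m2"]):
            df.at[i, "r_i"] = decay_correct_ratio(
                df.at[i, "i131_kbq_m2"], cs, i131, cs137, date, reference_date
            )
        if np.isfinite(df.at[i, "te129m_kbq_m2"]):
            df.at[i, "r_t"] = decay_correct_ratio(
                df.at[i, "te129m_kbq_m2"], cs, te129m, cs137, date, reference_date
            )
            r_t_origin[i] = "measured"
    if n_defaulted_dates:
        logger.info("run_pipeline: %d records without sampling date; using %s",
                    n_defaulted_dates, default_sample_date)

    # stage 2: interpolate missing r_t (and optionally r_i)
    ratio_field = None
    hierarchy = None
    missing_rt = df["r_t"].isna().to_numpy()
    if missing_rt.any() or grid_spec is not None:
        filled, measured, hierarchy, ratio_field = interpolate_missing_ratios(
            df["lon"].to_numpy(),
            df["lat"].to_numpy(),
            df["r_t"].to_numpy(dtype=float),
            grid_spec=grid_spec,
            n_levels=n_levels,
            base_resolution=base_resolution,
        )
        df["r_t"] = filled
        r_t_origin = np.where(missing_rt, "interpolated", r_t_origin)
    if interpolate_r_i and df["r_i"].isna().any():
        filled_ri, _, _, _ = interpolate_missing_ratios(
            df["lon"].to_numpy(),
            df["lat"].to_numpy(),
            df["r_i"].to_numpy(dtype=float),
            n_levels=n_levels,
            base_resolution=base_resolution,
        )
        df["r_i"] = filled_ri
    df["r_t_origin"] = r_t_origin

    # stages 3-4: per-location unit dose and absolute dose
    d_unit = np.full(n_in, np.nan)
    d_a = np.full(n_in, np.nan)
    reasons = np.full(n_in, "", dtype=object)
    for i in df.index:
        r_i, r_t = df.at[i, "r_i"], df.at[i, "r_t"]
        if not np.isfinite(r_i):
            reasons[i] = "no I-131 ratio"
            continue
        if not np.isfinite(r_t):
            reasons[i] = "no Te-129m ratio"
            continue
        if not np.isfinite(dep[i]):
            reasons[i] = "no Cs-137 deposition"
            continue
        ratios = RatioSet(float(r_i), float(r_t))
        if mode == "surface":
            d_unit[i] = evaluate(param, ratios)
        else:
            d_unit[i] = cumulative_dose(nset, ratios)
        d_a[i] = apply_deposition(d_unit[i], float(dep[i]))
    df["d_unit_msv"] = d_unit
    df["d_a_msv"] = d_a
    df["excluded_reason"] = reasons
    n_excluded = int((reasons != "").sum())
    if n_excluded:
        logger.info("run_pipeline: %d of %d records excluded from dose output (%s)",
                    n_excluded, n_in,
                    ", ".join(f"{r}: {c}" for r, c in
                              pd.Series(reasons[reasons != ""]).value_counts().items()))

    # stage 5: dose raster
    dose_field = None
    if grid_spec is not None:
        ok = np.isfinite(d_a)
        if ok.any():
            x, y, norm = normalize_coords(
                df["lon"].to_numpy()[ok],
                df["lat"].to_numpy()[ok],
                (grid_spec.west, grid_spec.south, grid_spec.east, grid_spec.north),
            )
            scatter = ScatterSet(np.clip(x, 0, 1), np.clip(y, 0, 1), d_a[ok], norm)
            dose_hier = mbs_fit(scatter, n_levels=n_levels, base_resolution=base_resolution)
            dose_field = evaluate_field(dose_hier, grid_spec)
            dose_field = GridField(
                grid_spec,
                np.clip(dose_field.values, 0.0, None),
                extrapolated=dose_field.extrapolated,
            )
    counts = {
        "input": n_in,
        "pre_corrected": int(pre_corrected.sum()),
        "r_t_interpolated": int((df["r_t_origin"] == "interpolated").sum()),
        "dosed": n_in - n_excluded,
        "excluded": n_excluded,
    }
    logger.info("run_pipeline: %s", counts)
    return PipelineResult(df, ratio_field, dose_field, counts)


def write_dose_table(table: pd.DataFrame, path, rounded: bool = False) -> None:
    """Write the pipeline table as CSV, deterministically ordered by location_id.

    With ``rounded`` the dose columns use the report precision
    (3 significant figures at >= 100 mSv, otherwise one decimal).
    """
    cols = [c for c in SURVEY_COLUMNS if c in table.columns]
    cols += [c for c in ("r_i", "r_t", "r_t_origin", "d_unit_msv", "d_a_msv", "excluded_reason")
             if c in table.columns]
    out = table[cols].sort_values("location_id", kind="mergesort").reset_index(drop=True)
    if rounded:
        for col in ("d_unit_msv", "d_a_msv"):
            if col in out.columns:
                out[col] = [format_dose(v) if np.isfinite(v) else "" for v in out[col]]
    out.to_csv(path, index=False)
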