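"""Seven-nuclide decay and surface beta dose-rate model.

The fallout mixture deposited on 15 March 2011 is modelled as seven
radionuclides (Te-129m, Te-129, I-131, Te-132, I-132, Cs-134, Cs-137)
whose surface activities relative to Cs-137 are parameterized by two
free ratios: ``r_i`` (I-131/Cs-137) and ``r_t`` (Te-129m/Cs-137).  The
short-lived daughters Te-129 and I-132 are held in equilibrium with
their parents, so their activities track the parent half-life and their
ratios to Cs-137 are fixed multiples (0.7 and 8.3) of ``r_t``.

Each nuclide carries an initial surface beta dose rate ``d0`` (uSv/h at
70 um tissue depth, per 1000 kBq/m2 of its *own* deposition).  The
total dose rate at time ``t`` after deposition is the ratio-weighted sum
of exponentially decaying components, and the cumulative dose over a
horizon is its closed-form time integral.
"""
from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Nuclide",
    "NuclideSet",
    "RatioSet",
    "DoseRateCurve",
    "HOURS_PER_YEAR",
    "REFERENCE_DATE",
    "NUCLIDE_ORDER",
    "default_nuclides",
    "deposition_ratio_vector",
    "dose_rate",
    "dose_rate_curve",
    "cumulative_dose",
    "decay_correct_ratio",
    "decay_factor",
    "calibrate_coefficients",
    "read_nuclide_config",
    "write_nuclide_config",
]

#: Hours in one year (365.25 d); the default integration horizon.
HOURS_PER_YEAR = 365.25 * 24.0

#: Date of the main deposition event; activities and ratios are referred to it.
REFERENCE_DATE = _dt.date(2011, 3, 15)

#: Fixed member order of a NuclideSet.
NUCLIDE_ORDER = ("Te-129m", "Te-129", "I-131", "Te-132", "I-132", "Cs-134", "Cs-137")

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class Nuclide:
    """One radionuclide: identity, half-life and initial surface dose rate.

    Parameters
    ----------
    name : str
        Nuclide identifier, e.g. ``"I-131"``.
    half_life : float
        Physical half-life in hours; must be positive.
    d0 : float
        Initial beta dose rate at the soil surface (70 um dose
        equivalent), uSv/h, produced when this nuclide's own deposition
        equals 1000 kBq/m2.
    decay_parent : str, optional
        If set, the nuclide is an equilibrium daughter: its time decay
        anywhere in the model is governed by the parent's half-life.
    """

    name: str
    half_life: float
    d0: float = 0.0
    decay_parent: str | None = None

    def __post_init__(self) -> None:
        if not self.half_life > 0:
            raise ValueError(f"{self.name}: half_life must be > 0, got {self.half_life}")
        if self.d0 < 0:
            raise ValueError(f"{self.name}: d0 must be >= 0, got {self.d0}")


def _default_members() -> tuple[Nuclide, ...]:
    day = 24.0
    year = 365.25 * day
    return (
        Nuclide("Te-129m", 33.6 * day),
        Nuclide("Te-129", 69.6 / 60.0, decay_parent="Te-129m"),
        Nuclide("I-131", 8.021 * day),
        Nuclide("Te-132", 3.204 * day),
        Nuclide("I-132", 2.295, decay_parent="Te-132"),
        Nuclide("Cs-134", 2.0652 * year),
        Nuclide("Cs-137", 30.07 * year),
    )


@dataclass(frozen=True)
class NuclideSet:
    """Ordered collection of the seven fallout nuclides.

    Member order is fixed (:data:`NUCLIDE_ORDER`); ``reference_date`` is
    the calendar date of deposition to which ratios are decay-corrected.
    """

    members: tuple[Nuclide, ...] = field(default_factory=_default_members)
    reference_date: _dt.date = REFERENCE_DATE

    def __post_init__(self) -> None:
        names = tuple(n.name for n in self.members)
        if names != NUCLIDE_ORDER:
            raise ValueError(
                f"NuclideSet requires exactly the members {NUCLIDE_ORDER} in order, got {names}"
            )
        by_name = {n.name: n for n in self.members}
        for n in self.members:
            if n.decay_parent is not None and n.decay_parent not in by_name:
                raise ValueError(f"{n.name}: unknown decay_parent {n.decay_parent!r}")

    def __getitem__(self, name: str) -> Nuclide:
        for n in self.members:
            if n.name == name:
                return n
        raise KeyError(name)

    def __iter__(self):
        return iter(self.members)

    def effective_half_lives(self) -> np.ndarray:
        """Half-lives (hours) governing time decay, parent-resolved."""
        by_name = {n.name: n for n in self.members}
        out = []
        for n in self.members:
            eff = by_name[n.decay_parent] if n.decay_parent else n
            out.append(eff.half_life)
        return np.array(out)

    def d0_vector(self) -> np.ndarray:
        return np.array([n.d0 for n in self.members])

    def with_d0(self, d0: Sequence[float]) -> "NuclideSet":
        """Return a copy with the seven ``d0`` coefficients replaced."""
        d0 = np.asarray(d0, dtype=float)
        if d0.shape != (7,):
            raise ValueError("d0 must have exactly seven entries")
        members = tuple(replace(n, d0=float(v)) for n, v in zip(self.members, d0))
        return NuclideSet(members, self.reference_date)


def default_nuclides(reference_date: _dt.date = REFERENCE_DATE) -> NuclideSet:
    """The default seven-nuclide set (d0 unset; see calibrate_coefficients)."""
    return NuclideSet(_default_members(), reference_date)


@dataclass(frozen=True)
class RatioSet:
    """The two free deposition-ratio parameters at deposition time.

    ``r_i`` is the I-131/Cs-137 activity ratio, ``r_t`` the
    Te-129m/Cs-137 ratio; both dimensionless and non-negative.
    """

    r_i: float
    r_t: float

    def __post_init__(self) -> None:
        if self.r_i < 0 or self.r_t < 0:
            raise ValueError(f"deposition ratios must be >= 0, got ({self.r_i}, {self.r_t})")


@dataclass(frozen=True)
class DoseRateCurve:
    """A sampled dose-rate time series (hours; uSv/h per 1000 kBq/m2 Cs-137)."""

    times: np.ndarray
    rates: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        r = np.asarray(self.rates, dtype=float)
        if t.ndim != 1 or t.shape != r.shape:
            raise ValueError("times and rates must be matching 1-d sequences")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(r < 0):
            raise ValueError("rates must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "rates", r)


def deposition_ratio_vector(ratios: RatioSet) -> np.ndarray:
    """Seven-component deposition-ratio vector f_i in NuclideSet order.

    ``(r_t, 0.7*r_t, r_i, 8.3*r_t, 8.3*r_t, 1, 1)``: Te-129 and I-132
    ride on ``r_t`` through their fixed equilibrium factors, caesium
    isotopes are taken at parity with Cs-137.
    """
    r_i, r_t = ratios.r_i, ratios.r_t
    return np.array([r_t, 0.7 * r_t, r_i, 8.3 * r_t, 8.3 * r_t, 1.0, 1.0])


def dose_rate(nuclides: NuclideSet, ratios: RatioSet, t) -> float | np.ndarray:
    """Surface beta dose rate at time ``t`` (hours) after deposition.

    Returns uSv/h per 1000 kBq/m2 of Cs-137 deposition:
    ``sum_i f_i * d0_i * 2**(-t / T_i)`` with parent-resolved half-lives.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time since deposition must be >= 0")
    f = deposition_ratio_vector(ratios)
    d0 = nuclides.d0_vector()
    half = nuclides.effective_half_lives()
    rates = (f * d0) @ np.power(2.0, -np.atleast_1d(t_arr)[:, None] / half).T
    return float(rates[0]) if t_arr.ndim == 0 else rates


def dose_rate_curve(nuclides: NuclideSet, ratios: RatioSet, times) -> DoseRateCurve:
    """Sample the dose-rate function on a time grid (hours)."""
    times = np.asarray(times, dtype=float)
    return DoseRateCurve(times, dose_rate(nuclides, ratios, times))


def cumulative_dose(
    nuclides: NuclideSet, ratios: RatioSet, horizon: float = HOURS_PER_YEAR
) -> float:
    """Cumulative surface beta dose over ``horizon`` hours after deposition.

    Closed-form integral of :func:`dose_rate`, in mSv per 1000 kBq/m2 of
    Cs-137 deposition::

        (1/1000) * sum_i f_i * d0_i * (T_i/ln 2) * (1 - 2**(-horizon/T_i))

    The 1/1000 converts the uSv-valued time integral to mSv.
    """
    if not horizon > 0:
        raise ValueError(f"horizon must be > 0, got {horizon}")
    f = deposition_ratio_vector(ratios)
    d0 = nuclides.d0_vector()
    half = nuclides.effective_half_lives()
    integral = half / _LN2 * (1.0 - np.power(2.0, -horizon / half))
    return float(np.dot(f * d0, integral) / 1000.0)


def decay_factor(nuclide: Nuclide, dt_hours: float, nuclides: NuclideSet | None = None) -> float:
    """Activity decay factor 2**(-dt/T) with the parent-resolved half-life."""
    half = nuclide.half_life
    if nuclide.decay_parent is not None:
        if nuclides is None:
            raise ValueError(
                f"{nuclide.name} decays with its parent's half-life; pass the NuclideSet"
            )
        half = nuclides[nuclide.decay_parent].half_life
    return 2.0 ** (-dt_hours / half)


def decay_correct_ratio(
    a_num: float,
    a_den: float,
    nuclide_num: Nuclide,
    nuclide_den: Nuclide,
    sample_date: _dt.date,
    reference_date: _dt.date = REFERENCE_DATE,
    nuclides: NuclideSet | None = None,
) -> float:
    """Rescale a measured activity ratio back to the reference date.

    ``(a_num/a_den) * 2**(dt/T_num) / 2**(dt/T_den)`` with ``dt`` the
    sampling delay in whole days (converted to hours) and half-lives
    parent-resolved.  The sample must not precede the reference date.
    """
    if a_den <= 0:
        raise ValueError(f"denominator activity must be > 0, got {a_den}")
    if sample_date < reference_date:
        raise ValueError(f"sample date {sample_date} precedes reference date {reference_date}")
    dt_hours = (sample_date - reference_date).days * 24.0
    fac_num = decay_factor(nuclide_num, dt_hours, nuclides)
    fac_den = decay_factor(nuclide_den, dt_hours, nuclides)
    return (a_num / a_den) / fac_num * fac_den


def _unsaturated_integral(half_life: float, horizon: float) -> float:
    """Time integral of 2**(-t/T) over [0, horizon], in hours."""
    return half_life / _LN2 * (1.0 - 2.0 ** (-horizon / half_life))


def calibrate_coefficients(
    targets,
    te_split: float = 0.5,
    cs_split: float = 0.5,
    nuclides: NuclideSet | None = None,
    horizon: float = HOURS_PER_YEAR,
) -> NuclideSet:
    """Fill the seven d0 coefficients from fitted dose-surface constants.

    The linear dose surface ``D(r_i, r_t) = a*r_i + slope_b*r_t +
    intercept_b`` (mSv per 1000 kBq/m2 over ``horizon``) identifies only
    group composites of the per-nuclide initial dose rates:

    - the iodine slope fixes ``d0(I-131)`` exactly;
    - ``slope_b`` is split between the 33.6-d tellurium group
      (Te-129m + 0.7 Te-129) and the 3.204-d group (8.3 (Te-132 + I-132))
      by ``te_split``;
    - ``intercept_b`` is split between Cs-134 and Cs-137 by ``cs_split``.

    Within each group the composite is divided equally between the two
    members; any split reproduces the same cumulative dose, so downstream
    results do not depend on it.
    """
    a, slope_b, intercept_b = targets.a, targets.slope_b, targets.intercept_b
    if not (0.0 <= te_split <= 1.0 and 0.0 <= cs_split <= 1.0):
        raise ValueError("calibration splits must lie in [0, 1]")
    base = nuclides if nuclides is not None else default_nuclides()
    half = {n.name: h for n, h in zip(base.members, base.effective_half_lives())}

    i_i131 = _unsaturated_integral(half["I-131"], horizon)
    i_te129m = _unsaturated_integral(half["Te-129m"], horizon)
    i_te132 = _unsaturated_integral(half["Te-132"], horizon)
    i_cs134 = _unsaturated_integral(half["Cs-134"], horizon)
    i_cs137 = _unsaturated_integral(half["Cs-137"], horizon)

    d0_i131 = 1000.0 * a / i_i131
    # 33.6-d group: (d0_Te129m + 0.7 d0_Te129) * I = te_split * 1000 * slope_b
    c_slow = te_split * 1000.0 * slope_b / i_te129m / 1.7
    # 3.204-d group: 8.3 (d0_Te132 + d0_I132) * I = (1-te_split) * 1000 * slope_b
    c_fast = (1.0 - te_split) * 1000.0 * slope_b / i_te132 / 8.3 / 2.0
    d0_cs134 = cs_split * 1000.0 * intercept_b / i_cs134
    d0_cs137 = (1.0 - cs_split) * 1000.0 * intercept_b / i_cs137

    return base.with_d0([c_slow, c_slow, d0_i131, c_fast, c_fast, d0_cs134, d0_cs137])


# ---------------------------------------------------------------------------
# configuration file round-trip (TOML-subset key-value dialect)

def read_nuclide_config(path) -> dict:
    """Read a nuclide configuration file.

    The dialect is TOML with one ``[nuclide.<name>]`` table per nuclide
    (keys ``half_life_days``, optional ``d0``, optional ``decay_parent``),
    an optional top-level ``reference_date``, and an optional
    ``[calibration]`` table (``a``, ``slope_b``, ``intercept_b``,
    optional ``te_split``/``cs_split``).  Returns a dict with keys
    ``nuclides`` (a :class:`NuclideSet`) and ``calibration`` (a dict or
    None).  If a calibration table is present the returned set already
    has its d0 coefficients filled.
    """
    import tomllib

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    ref = raw.get("reference_date", REFERENCE_DATE)
    if isinstance(ref, str):
        ref = _dt.date.fromisoformat(ref)
    members = []
    defaults = {n.name: n for n in _default_members()}
    for name in NUCLIDE_ORDER:
        entry = raw.get("nuclide", {}).get(name, {})
        d = defaults[name]
        members.append(
            Nuclide(
                name,
                half_life=float(entry.get("half_life_days", d.half_life / 24.0)) * 24.0,
                d0=float(entry.get("d0", d.d0)),
                decay_parent=entry.get("decay_parent", d.decay_parent),
            )
        )
    nset = NuclideSet(tuple(members), ref)
    calib = raw.get("calibration")
    if calib is not None:
        from .dose_surface import Parameterization

        targets = Parameterization(
            a=float(calib["a"]),
            slope_b=float(calib["slope_b"]),
            intercept_b=float(calib["intercept_b"]),
        )
        nset = calibrate_coefficients(
            targets,
            te_split=float(calib.get("te_split", 0.5)),
            cs_split=float(calib.get("cs_split", 0.5)),
            nuclides=nset,
        )
    return {"nuclides": nset, "calibration": calib}


def write_nuclide_config(path, nuclides: NuclideSet, calibration: dict | None = None) -> None:
    """Write a nuclide configuration readable by :func:`read_nuclide_config`."""
    lines = [f'reference_date = "{nuclides.reference_date.isoformat()}"', ""]
    for n in nuclides.members:
        lines.append(f"[nuclide.{n.name}]")
        lines.append(f"half_life_days = {n.half_life / 24.0!r}")
        lines.append(f"d0 = {n.d0!r}")
        if n.decay_parent:
            lines.append(f'decay_parent = "{n.decay_parent}"')
        lines.append("")
    if calibration:
        lines.append("[calibration]")
        for key, val in calibration.items():
            lines.append(f"{key} = {float(val)!r}")
        lines.append("")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines))
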