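"""Growth (LMS) and blood-pressure reference tables.

Two kinds of reference data drive all percentile math in the package:

* **LMS rows** — the CDC growth-chart representation of an age-varying
  reference distribution via the Box-Cox power ``L``, the median ``M`` and the
  coefficient of variation ``S``.  Rows are indexed at month midpoints
  (24.5, 25.5, ...): a patient whose exact age in months lies in ``[t, t+1)``
  maps to the row at ``t + 0.5``.  No interpolation across rows is performed.
* **BP reference rows** — the NHLBI-style pediatric blood-pressure tables,
  keyed by sex, completed age in years and height-percentile column, holding
  monotone (percentile, systolic, diastolic) knots that are inverted to turn
  an observed pressure into a percentile.

Both kinds can be read from plain CSV and synthesized with closed-form
structure so that every downstream computation can be checked against an
analytic truth (the synthetic BP tables are exact normal quantiles).
"""

from __future__ import annotations

import math
from collections.abc import Callable, Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .errors import ConfigurationError, CoverageError, DomainError, FormatError, ValidationError

__all__ = [
    "LMSRow",
    "BPReferenceRow",
    "ReferenceLibrary",
    "read_lms_table",
    "write_lms_table",
    "read_bp_table",
    "write_bp_table",
    "synth_lms_reference",
    "synth_bp_reference",
    "default_reference_library",
    "normalize_sex",
    "DEFAULT_HEIGHT_KNOTS",
    "DEFAULT_BP_KNOTS",
]

_SEX_ALIASES = {
    "1": "male", "2": "female",
    "m": "male", "f": "female",
    "male": "male", "female": "female",
}

#: Height-percentile columns of the NHLBI tables.
DEFAULT_HEIGHT_KNOTS = (5.0, 10.0, 25.0, 50.0, 75.0, 90.0, 95.0)
#: BP percentile knots carried per (sex, age, height) cell.
DEFAULT_BP_KNOTS = (5.0, 10.0, 25.0, 50.0, 75.0, 90.0, 95.0, 99.0)


def normalize_sex(value) -> str:
    """Map the CDC numeric coding (1/2) and common spellings onto {male, female}."""
    if isinstance(value, (int, np.integer)) or isinstance(value, float) and float(value).is_integer():
        value = str(int(value))
    key = str(value).strip().lower()
    try:
        return _SEX_ALIASES[key]
    except KeyError:
        raise ValidationError(f"unrecognized sex code: {value!r}") from None


@dataclass(frozen=True)
class LMSRow:
    """One (sex, age) entry of an LMS growth reference."""

    sex: str
    age_months: float
    L: float
    M: float
    S: float

    def __post_init__(self):
        object.__setattr__(self, "sex", normalize_sex(self.sex))
        if not self.M > 0:
            raise ValidationError(
                f"LMS row (sex={self.sex}, age={self.age_months}): M must be > 0, got {self.M}")
        if not self.S > 0:
            raise ValidationError(
                f"LMS row (sex={self.sex}, age={self.age_months}): S must be > 0, got {self.S}")


@dataclass(frozen=True)
class BPReferenceRow:
    """Knots of the BP reference for one (sex, age-in-years, height-percentile) cell.

    ``knots`` is an ordered tuple of ``(percentile, systolic, diastolic)``
    triples, strictly increasing in all three components — the tabulated
    percentile-to-value function must be invertible.
    """

    sex: str
    age_years: int
    height_percentile: float
    knots: tuple[tuple[float, float, float], ...]

    def __post_init__(self):
        object.__setattr__(self, "sex", normalize_sex(self.sex))
        object.__setattr__(self, "knots", tuple(tuple(map(float, k)) for k in self.knots))
        key = f"(sex={self.sex}, age={self.age_years}, height_pct={self.height_percentile})"
        if len(self.knots) < 2:
            raise ValidationError(f"BP row {key}: at least 2 knots required")
        for (p0, s0, d0), (p1, s1, d1) in zip(self.knots, self.knots[1:]):
            if not (p0 < p1 and s0 < s1 and d0 < d1):
                raise ValidationError(
                    f"BP row {key}: knots must be strictly increasing in percentile, "
                    f"systolic and diastolic (violated between p={p0} and p={p1})")
        for p, s, d in self.knots:
            if not 0 < p < 100:
                raise ValidationError(f"BP row {key}: percentile {p} outside (0, 100)")

    @property
    def key(self) -> tuple[str, int, float]:
        return (self.sex, self.age_years, self.height_percentile)


def _check_lms_series(rows: Sequence[LMSRow]) -> None:
    seen = set()
    by_sex: dict[str, float] = {}
    for row in rows:
        k = (row.sex, row.age_months)
        if k in seen:
            raise ValidationError(f"duplicate LMS key (sex={row.sex}, age={row.age_months})")
        seen.add(k)
        prev = by_sex.get(row.sex)
        if prev is not None and not row.age_months > prev:
            raise ValidationError(
                f"LMS ages not strictly increasing for sex={row.sex} at {row.age_months}")
        by_sex[row.sex] = row.age_months


@dataclass
class ReferenceLibrary:
    """Bundle of the references an assessment needs, with explicit age coverage."""

    lms_bmi: tuple[LMSRow, ...] = ()
    lms_stature: tuple[LMSRow, ...] = ()
    bp: tuple[BPReferenceRow, ...] = ()
    provenance: str = "unspecified"
    _lms_index: dict = field(default_factory=dict, repr=False)
    _bp_index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.lms_bmi = tuple(self.lms_bmi)
        self.lms_stature = tuple(self.lms_stature)
        self.bp = tuple(self.bp)
        _check_lms_series(self.lms_bmi)
        _check_lms_series(self.lms_stature)
        self._lms_index = {
            "bmi": {(r.sex, r.age_months): r for r in self.lms_bmi},
            "stature": {(r.sex, r.age_months): r for r in self.lms_stature},
        }
        self._bp_index = {}
        for row in self.bp:
            if row.key in self._bp_index:
                raise ValidationError(f"duplicate BP reference key {row.key}")
            self._bp_index[row.key] = row

    # -- coverage ---------------------------------------------------------
    def lms_coverage(self, which: str = "bmi") -> tuple[float, float] | None:
        """Half-open coverage in exact months, ``[lo, hi)``, or None if empty."""
        rows = {"bmi": self.lms_bmi, "stature": self.lms_stature}[which]
        if not rows:
            return None
        ages = [r.age_months for r in rows]
        return (math.floor(min(ages)), math.floor(max(ages)) + 1)

    def bp_age_coverage(self) -> tuple[int, int] | None:
        """Closed integer-year coverage ``(lo, hi)`` of the BP table, or None."""
        if not self.bp:
            return None
        years = [r.age_years for r in self.bp]
        return (min(years), max(years))

    # -- lookup -----------------------------------------------------------
    def lms_row_for(self, sex: str, exact_months: float, which: str = "bmi") -> LMSRow:
        """Row at the month midpoint covering ``exact_months`` (no interpolation)."""
        sex = normalize_sex(sex)
        midpoint = math.floor(exact_months) + 0.5
        row = self._lms_index[which].get((sex, midpoint))
        if row is None:
            bounds = self.lms_coverage(which)
            raise CoverageError(
                f"no {which} LMS row for sex={sex} at {exact_months:.2f} months "
                f"(coverage {bounds})", key=(sex, midpoint), bounds=bounds)
        return row

    def bp_row_for(self, sex: str, age_years: int, height_percentile: float) -> BPReferenceRow:
        sex = normalize_sex(sex)
        key = (sex, int(age_years), float(height_percentile))
        row = self._bp_index.get(key)
        if row is None:
            raise CoverageError(
                f"no BP reference row for {key} (age coverage {self.bp_age_coverage()})",
                key=key, bounds=self.bp_age_coverage())
        return row

    def height_knots(self, sex: str, age_years: int) -> tuple[float, ...]:
        sex = normalize_sex(sex)
        knots = sorted({r.height_percentile for r in self.bp
                        if r.sex == sex and r.age_years == int(age_years)})
        if not knots:
            raise CoverageError(
                f"no BP reference rows for sex={sex}, age={age_years} years",
                key=(sex, int(age_years)), bounds=self.bp_age_coverage())
        return tuple(knots)


# ---------------------------------------------------------------------------
# CSV input/output
# ---------------------------------------------------------------------------

_LMS_HEADERS = {
    "cdc": ("Sex", "Agemos", "L", "M", "S"),
    "generic": ("sex", "age_months", "L", "M", "S"),
}
_BP_HEADER = ("sex", "age_years", "height_percentile", "bp_percentile", "systolic", "diastolic")


def read_lms_table(path, dialect: str = "cdc") -> tuple[LMSRow, ...]:
    """Read an LMS growth reference from CSV.

    ``cdc`` dialect uses the published growth-chart layout (``Sex`` coded 1/2,
    ``Agemos`` at month midpoints); ``generic`` spells the columns out.  Extra
    columns are ignored.  Rows come back sorted by (sex, age) with all
    invariants enforced.
    """
    if dialect not in _LMS_HEADERS:
        raise ConfigurationError(f"unknown LMS dialect {dialect!r}")
    cols = _LMS_HEADERS[dialect]
    df = pd.read_csv(path, float_precision="round_trip")
    for c in cols:
        if c not in df.columns:
            raise FormatError(f"LMS table {path}: missing required column {c!r}")
    rows = []
    for i, rec in df.iterrows():
        try:
            rows.append(LMSRow(sex=rec[cols[0]], age_months=float(rec[cols[1]]),
                               L=float(rec[cols[2]]), M=float(rec[cols[3]]), S=float(rec[cols[4]])))
        except ValidationError as e:
            raise ValidationError(f"{path} row {i}: {e}") from e
    rows.sort(key=lambda r: (r.sex, r.age_months))
    _check_lms_series(rows)
    return tuple(rows)


def write_lms_table(rows: Iterable[LMSRow], path, dialect: str = "cdc") -> None:
    cols = _LMS_HEADERS[dialect]
    sex_out = (lambda s: {"male": 1, "female": 2}[s]) if dialect == "cdc" else (lambda s: s)
    df = pd.DataFrame(
        [{cols[0]: sex_out(r.sex), cols[1]: repr(r.age_months), cols[2]: repr(r.L),
          cols[3]: repr(r.M), cols[4]: repr(r.S)} for r in rows])
    # repr() keeps floats bit-identical on re-read (round-trip invariant)
    df.to_csv(path, index=False)


def read_bp_table(path) -> tuple[BPReferenceRow, ...]:
    """Read a long-format BP reference CSV and group it into knot rows."""
    df = pd.read_csv(path, float_precision="round_trip")
    for c in _BP_HEADER:
        if c not in df.columns:
            raise FormatError(f"BP table {path}: missing required column {c!r}")
    rows = []
    grouped = df.groupby(["sex", "age_years", "height_percentile"], sort=True)
    for (sex, age, hpct), g in grouped:
        g = g.sort_values("bp_percentile")
        knots = tuple(zip(g["bp_percentile"].astype(float),
                          g["systolic"].astype(float),
                          g["diastolic"].astype(float)))
        try:
            rows.append(BPReferenceRow(sex=sex, age_years=int(age),
                                       height_percentile=float(hpct), knots=knots))
        except ValidationError as e:
            raise ValidationError(f"{path}: {e}") from e
    rows.sort(key=lambda r: r.key)
    return tuple(rows)


def write_bp_table(rows: Iterable[BPReferenceRow], path) -> None:
    records = []
    for r in sorted(rows, key=lambda r: r.key):
        for p, s, d in r.knots:
            records.append({"sex": r.sex, "age_years": r.age_years,
                            "height_percentile": repr(r.height_percentile),
                            "bp_percentile": repr(p), "systolic": repr(s), "diastolic": repr(d)})
    pd.DataFrame(records, columns=list(_BP_HEADER)).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Synthetic references
# ---------------------------------------------------------------------------

def _as_fn(param) -> Callable[[float], float]:
    return param if callable(param) else (lambda _age, _v=float(param): _v)


def synth_lms_reference(sex_list: Sequence[str], age_range: tuple[float, float],
                        L=0.0, M=16.0, S=0.1, seed: int = 0) -> tuple[LMSRow, ...]:
    """Generate an LMS series with known closed-form parameters.

    ``L``, ``M``, ``S`` may be constants or callables of age in months; one row
    is emitted per (sex, month midpoint) over ``[lo, hi)``.  The generator is a
    pure function of its arguments — ``seed`` is accepted for interface
    uniformity with the other fixture generators and recorded nowhere.
    """
    lo, hi = age_range
    if not lo < hi:
        raise DomainError(f"empty age range {age_range}")
    Lf, Mf, Sf = _as_fn(L), _as_fn(M), _as_fn(S)
    midpoints = [m + 0.5 for m in range(math.floor(lo), math.floor(hi))]
    for t in midpoints:
        if not Mf(t) > 0 or not Sf(t) > 0:
            raise DomainError(f"M and S must stay positive over the range (violated at {t})")
    return tuple(LMSRow(sex=s, age_months=t, L=float(Lf(t)), M=float(Mf(t)), S=float(Sf(t)))
                 for s in sorted(normalize_sex(s) for s in sex_list) for t in midpoints)


@dataclass(frozen=True)
class BPNormalModel:
    """Closed-form normal model behind a synthetic BP table.

    ``mu_*`` are callables ``(age_years, height_percentile) -> mmHg`` or
    constants; ``sigma_*`` are constant standard deviations.  Knot values are
    exact normal quantiles, so an inverted percentile can be compared to
    ``100 * Phi((x - mu) / sigma)``.
    """

    mu_systolic: object = 100.0
    sigma_systolic: float = 10.0
    mu_diastolic: object = 60.0
    sigma_diastolic: float = 8.0

    def mu(self, channel: str, age_years: float, height_percentile: float) -> float:
        f = {"systolic": self.mu_systolic, "diastolic": self.mu_diastolic}[channel]
        return float(f(age_years, height_percentile)) if callable(f) else float(f)

    def sigma(self, channel: str) -> float:
        return float({"systolic": self.sigma_systolic, "diastolic": self.sigma_diastolic}[channel])


def synth_bp_reference(sex_list: Sequence[str], age_range: tuple[int, int],
                       model: BPNormalModel | None = None,
                       knot_percentiles: Sequence[float] = DEFAULT_BP_KNOTS,
                       height_knots: Sequence[float] = DEFAULT_HEIGHT_KNOTS,
                       seed: int = 0) -> tuple[BPReferenceRow, ...]:
    """Generate a BP reference whose knots are exact normal quantiles.

    For each knot percentile ``p`` the tabulated value is
    ``mu + sigma * Phi^-1(p / 100)``; rows are therefore monotone by
    construction.  ``age_range`` is inclusive in integer years.
    """
    model = model or BPNormalModel()
    knots = sorted(float(p) for p in knot_percentiles)
    if len(knots) < 2:
        raise DomainError("at least 2 knot percentiles required")
    if not all(0 < p < 100 for p in knots):
        raise DomainError("knot percentiles must lie in (0, 100)")
    for ch in ("systolic", "diastolic"):
        if not model.sigma(ch) > 0:
            raise DomainError(f"sigma for {ch} must be > 0")
    lo, hi = int(age_range[0]), int(age_range[1])
    if lo > hi:
        raise DomainError(f"empty age range {age_range}")
    quantiles = {p: float(ndtri(p / 100.0)) for p in knots}
    rows = []
    for sex in sorted(normalize_sex(s) for s in sex_list):
        for age in range(lo, hi + 1):
            for hpct in sorted(float(h) for h in height_knots):
                triples = tuple(
                    (p,
                     model.mu("systolic", age, hpct) + model.sigma("systolic") * quantiles[p],
                     model.mu("diastolic", age, hpct) + model.sigma("diastolic") * quantiles[p])
                    for p in knots)
                rows.append(BPReferenceRow(sex=sex, age_years=age,
                                           height_percentile=hpct, knots=triples))
    return tuple(rows)


def default_reference_library(seed: int = 0) -> ReferenceLibrary:
    """Synthetic but realistically shaped references covering 24-252 months.

    The BMI median dips in early childhood and rises through adolescence; the
    stature median saturates; BP means rise linearly with age and gently with
    height percentile.  All three are smooth closed forms, not fitted data.
    """
    lms_bmi = synth_lms_reference(
        ["male", "female"], (24, 252),
        L=-2.0,
        M=lambda t: 15.2 + 4.5e-5 * (t - 66.0) ** 2,
        S=0.10, seed=seed)
    lms_stature = synth_lms_reference(
        ["male", "female"], (24, 252),
        L=1.0,
        M=lambda t: 0.55 + 1.25 * (1.0 - math.exp(-t / 100.0)),
        S=0.04, seed=seed)
    model = BPNormalModel(
        mu_systolic=lambda age, h: 90.0 + 1.5 * age + 0.08 * (h - 50.0),
        sigma_systolic=10.0,
        mu_diastolic=lambda age, h: 50.0 + 1.0 * age + 0.04 * (h - 50.0),
        sigma_diastolic=8.0)
    bp = synth_bp_reference(["male", "female"], (2, 20), model=model, seed=seed)
    return ReferenceLibrary(lms_bmi=lms_bmi, lms_stature=lms_stature, bp=bp,
                            provenance=f"synthetic closed-form references (seed={seed})")
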