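"""Water quality index engine with dynamic weight renormalization.

The index summarises a multi-parameter water sample as a single
dimensionless number.  Each criteria parameter carries a fixed importance
weight and a guideline limit value; for one record the weights are
renormalized over the parameters that are actually available ("dynamic
weights"), each available parameter contributes a quality value
``(concentration / limit) * 100 * dynamic_weight`` (pH uses a banded rule),
and the WQI is the sum of the quality values.  Because the weights always
sum to one over the available set, records with missing parameters remain
comparable to complete records: a sample sitting exactly at every limit
scores 100 regardless of which parameters were measured.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "MISSING",
    "ParameterSpec",
    "CriteriaSet",
    "SampleRecord",
    "WQIResult",
    "WQIError",
    "NoUsableParametersError",
    "CLASS_LABELS",
    "default_criteria",
    "resolve_availability",
    "dynamic_weights",
    "quality_value_ph",
    "quality_value_generic",
    "compute_wqi",
    "compute_many",
    "classify_wqi",
]

#: Sentinel for an absent measurement.  ``float("nan")`` cells and absent
#: keys are treated identically.
MISSING = float("nan")

# Skip reasons recorded in WQIResult.skipped
EXCLUDED_GLOBALLY = "excluded_globally"
EXCLUDED_OVERRIDE = "excluded_override"
NO_DATA = "no_data"

#: Classification bands, half-open [low, high); the top band is [300, inf).
CLASS_BANDS: tuple[tuple[float, str], ...] = (
    (50.0, "Excellent water quality"),
    (100.0, "Good water quality"),
    (200.0, "Poor water quality"),
    (300.0, "Very poor water quality"),
    (math.inf, "Unsuitable for drinking"),
)

CLASS_LABELS: tuple[str, ...] = tuple(label for _, label in CLASS_BANDS)


class WQIError(ValueError):
    """Domain error raised by the index engine."""


class NoUsableParametersError(WQIError):
    """Raised when a record has no available, included parameter."""


def _is_missing(value: object) -> bool:
    if value is None:
        return True
    try:
        return math.isnan(float(value))  # type: ignore[arg-type]
    except (TypeError, ValueError):
        return True


@dataclass(frozen=True)
class ParameterSpec:
    """One criteria parameter: its weight, limit and global inclusion flag.

    ``limit_kind`` is ``"upper_limit"`` for ordinary parameters (quality
    value grows linearly with concentration / limit) or ``"band"`` for pH,
    whose quality value is zero inside [band_low, band_high] and penalises
    departures on either side.
    """

    name: str
    weight: float
    limit_kind: str = "upper_limit"
    limit: float | None = None
    band_low: float | None = None
    band_high: float | None = None
    included: bool = True

    def __post_init__(self) -> None:
        if not self.name:
            raise WQIError("parameter name must be non-empty")
        if self.limit_kind not in ("upper_limit", "band"):
            raise WQIError(
                f"{self.name}: limit_kind must be 'upper_limit' or 'band', "
                f"got {self.limit_kind!r}"
            )
        if self.included and not self.weight > 0:
            raise WQIError(f"{self.name}: included parameter needs weight > 0")
        if self.limit_kind == "upper_limit":
            if self.limit is None or not self.limit > 0:
                raise WQIError(f"{self.name}: upper_limit kind needs limit > 0")
        else:
            if self.band_low is None or self.band_high is None:
                raise WQIError(f"{self.name}: band kind needs band_low and band_high")
            if not self.band_low < self.band_high:
                raise WQIError(f"{self.name}: band_low must be < band_high")


@dataclass(frozen=True)
class CriteriaSet:
    """Ordered collection of criteria parameters defining one index.

    At most 40 parameters; names unique; at least one included; at most one
    band-kind parameter (pH).
    """

    parameters: tuple[ParameterSpec, ...]

    MAX_PARAMETERS = 40

    def __post_init__(self) -> None:
        params = tuple(self.parameters)
        object.__setattr__(self, "parameters", params)
        if len(params) > self.MAX_PARAMETERS:
            raise WQIError(
                f"criteria set has {len(params)} parameters; max "
                f"{self.MAX_PARAMETERS}"
            )
        names = [p.name for p in params]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise WQIError(f"duplicate parameter names: {dupes}")
        if not any(p.included for p in params):
            raise WQIError("criteria set needs at least one included parameter")
        bands = [p.name for p in params if p.limit_kind == "band"]
        if len(bands) > 1:
            raise WQIError(f"at most one band-kind parameter allowed, got {bands}")

    def __iter__(self):
        return iter(self.parameters)

    def __len__(self) -> int:
        return len(self.parameters)

    def __getitem__(self, name: str) -> ParameterSpec:
        for p in self.parameters:
            if p.name == name:
                return p
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(p.name == name for p in self.parameters)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.parameters)

    @property
    def included_names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.parameters if p.included)


@dataclass
class SampleRecord:
    """One water sample: measured values plus per-record selection codes.

    ``overrides`` maps parameter name -> selection code: +1 include (the
    default), -1 exclude this parameter for this record, 0 declare the value
    missing.  A record code can only narrow the criteria set: -1/0 beat
    global inclusion, but a globally excluded parameter cannot be re-enabled
    per record.
    """

    sample_id: str
    values: dict[str, float] = field(default_factory=dict)
    overrides: dict[str, int] = field(default_factory=dict)
    location: str | None = None

    def __post_init__(self) -> None:
        for name, code in self.overrides.items():
            if code not in (-1, 0, 1):
                raise WQIError(
                    f"{self.sample_id}: selection code for {name!r} must be "
                    f"-1, 0 or +1, got {code!r}"
                )


@dataclass
class WQIResult:
    """Audit-complete result of one index computation."""

    sample_id: str
    dynamic_weights: dict[str, float]
    quality_values: dict[str, float]
    wqi: float
    class_label: str
    used: list[str]
    skipped: dict[str, str]
    warnings: list[str] = field(default_factory=list)


def default_criteria() -> CriteriaSet:
    """The bundled default index definition: 13 drinking-water parameters.

    Concentrations in mg/L except turbidity (NTU) and pH (unitless, banded
    6.5-8.5).  Total hardness ships excluded by default: it is computable
    from calcium and magnesium and including all three would double-count.
    """
    return CriteriaSet(
        (
            ParameterSpec("pH", 4, "band", band_low=6.5, band_high=8.5),
            ParameterSpec("calcium", 2, limit=300),
            ParameterSpec("magnesium", 2, limit=30),
            ParameterSpec("chloride", 3, limit=250),
            ParameterSpec("tds", 4, limit=1000),
            ParameterSpec("fluoride", 4, limit=1.5),
            ParameterSpec("manganese", 4, limit=0.1),
            ParameterSpec("nitrate", 5, limit=50),
            ParameterSpec("iron", 4, limit=0.3),
            ParameterSpec("sulfate", 4, limit=250),
            ParameterSpec("ammonium", 3, limit=1.5),
            ParameterSpec("sodium", 3, limit=200),
            ParameterSpec("turbidity", 4, limit=5),
            ParameterSpec("total_hardness", 2, limit=500, included=False),
        )
    )


def resolve_availability(
    record: SampleRecord, criteria: CriteriaSet
) -> tuple[list[str], dict[str, str]]:
    """Split the criteria parameters into used / skipped for one record.

    A parameter is used iff it is globally included, its per-record
    selection code is not -1 or 0, and its value is present.  Everything
    else lands in ``skipped`` with a reason (``excluded_globally``,
    ``excluded_override`` for code -1, ``no_data`` for code 0 or an absent
    value).

    Raises :class:`NoUsableParametersError` when nothing survives — the WQI
    is undefined for such a record.
    """
    used: list[str] = []
    skipped: dict[str, str] = {}
    for spec in criteria:
        code = record.overrides.get(spec.name, 1)
        if not spec.included:
            skipped[spec.name] = EXCLUDED_GLOBALLY
        elif code == -1:
            skipped[spec.name] = EXCLUDED_OVERRIDE
        elif code == 0 or _is_missing(record.values.get(spec.name, MISSING)):
            skipped[spec.name] = NO_DATA
        else:
            used.append(spec.name)
    if not used:
        raise NoUsableParametersError(
            f"{record.sample_id}: no usable parameters (all excluded or missing)"
        )
    return used, skipped


def dynamic_weights(
    criteria: CriteriaSet, used: Iterable[str]
) -> dict[str, float]:
    """Renormalize the criteria weights over the available parameters.

    Returns ``w_i / sum(w_j for j in used)`` so the dynamic weights always
    sum to one, which anchors the index scale at 100 for a sample sitting
    exactly at every limit.
    """
    used = list(used)
    if not used:
        raise WQIError("dynamic_weights: empty used set")
    weights = {}
    for name in used:
        w = criteria[name].weight
        if not w > 0:
            raise WQIError(f"{name}: weight must be > 0, got {w}")
        weights[name] = float(w)
    total = sum(weights.values())
    return {name: w / total for name, w in weights.items()}


def quality_value_ph(
    ph: float,
    dyn_weight: float,
    band_low: float = 6.5,
    band_high: float = 8.5,
) -> float:
    """Banded pH quality value.

    Zero inside the acceptable band (endpoints inclusive); below it the
    penalty is ``band_low / pH * 100 * w`` and above it
    ``pH / band_high * 100 * w``, so the contribution grows as pH departs
    from the band in either direction.
    """
    if not ph > 0:
        raise WQIError(f"pH must be > 0, got {ph}")
    if ph > 14:
        raise WQIError(f"pH must be <= 14, got {ph}")
    if band_low <= ph <= band_high:
        return 0.0
    if ph < band_low:
        return band_low / ph * 100.0 * dyn_weight
    return ph / band_high * 100.0 * dyn_weight


def quality_value_generic(conc: float, limit: float, dyn_weight: float) -> float:
    """Quality value of an ordinary parameter: ``conc / limit * 100 * w``."""
    if conc < 0:
        raise WQIError(f"concentration must be >= 0, got {conc}")
    if not limit > 0:
        raise WQIError(f"limit must be > 0, got {limit}")
    return conc / limit * 100.0 * dyn_weight


def classify_wqi(wqi: float) -> str:
    """Map a WQI value onto the five-band interpretation scale.

    Bands are half-open [low, high): <50 excellent, 50-100 good, 100-200
    poor, 200-300 very poor, >=300 unsuitable for drinking.
    """
    if wqi < 0 or math.isnan(wqi):
        raise WQIError(f"WQI must be >= 0, got {wqi}")
    for upper, label in CLASS_BANDS:
        if wqi < upper:
            return label
    return CLASS_BANDS[-1][1]  # pragma: no cover


def compute_wqi(record: SampleRecord, criteria: CriteriaSet) -> WQIResult:
    """Compute the full index for one record.

    Resolves availability, renormalizes the weights over the available set,
    routes pH to the banded rule and everything else to the generic rule,
    sums the quality values and classifies the total.
    """
    used, skipped = resolve_availability(record, criteria)
    weights = dynamic_weights(criteria, used)
    quality: dict[str, float] = {}
    warnings: list[str] = []
    for name in used:
        spec = criteria[name]
        value = float(record.values[name])
        try:
            if spec.limit_kind == "band":
                quality[name] = quality_value_ph(
                    value, weights[name], spec.band_low, spec.band_high
                )
            else:
                quality[name] = quality_value_generic(
                    value, spec.limit, weights[name]
                )
        except WQIError as exc:
            raise WQIError(f"{record.sample_id}: {exc}") from exc
    wqi = sum(quality.values())
    band_only = all(criteria[name].limit_kind == "band" for name in used)
    if band_only and wqi == 0.0:
        warnings.append(
            "only pH usable and inside the acceptable band; WQI 0 reflects "
            "no evidence, not pristine water"
        )
    return WQIResult(
        sample_id=record.sample_id,
        dynamic_weights=weights,
        quality_values=quality,
        wqi=wqi,
        class_label=classify_wqi(wqi),
        used=used,
        skipped=skipped,
        warnings=warnings,
    )


def compute_many(
    records: Iterable[SampleRecord],
    criteria: CriteriaSet,
    *,
    on_error: str = "raise",
) -> list[WQIResult]:
    """Compute the index for a batch of records.

    ``on_error='skip'`` drops records with no usable parameters instead of
    raising, which is convenient for exploratory runs on sparse data.
    """
    if on_error not in ("raise", "skip"):
        raise ValueError("on_error must be 'raise' or 'skip'")
    results = []
    for record in records:
        try:
            results.append(compute_wqi(record, criteria))
        except NoUsableParametersError:
            if on_error == "raise":
                raise
    return results
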