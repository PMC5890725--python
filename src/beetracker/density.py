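"""Colony-density estimation from cavity-tree surveys, and summaries.

Two density routes are supported: the survey-buffer estimate (nests found by
beelining divided by the buffered search area, see :mod:`beetracker.beelining`)
and the cavity-occupation estimate implemented here — the density of mapped
habitat trees multiplied by the fraction of inspected cavities occupied by
honey bees.  The cavity route is a lower bound: colonies nesting outside the
mapped woodpecker cavities are invisible to it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy import stats

__all__ = [
    "CavityTreeRecord",
    "DensityEstimate",
    "OccupationRate",
    "occupation_rate",
    "occupation_rate_from_records",
    "cavity_occupation_density",
    "extrapolate_population",
    "table_summary",
    "TableSummary",
]


@dataclass(frozen=True)
class CavityTreeRecord:
    """One surveyed habitat tree bearing old woodpecker cavities.

    ``occupied`` means regular honey bee flight traffic with pollen import
    was seen at a cavity.  Trees are the counting unit even when they carry
    several cavities.
    """

    tree_id: str
    location: object  # GeoPoint; kept loose to avoid a circular import
    n_cavities: int = 1
    occupied: bool = False

    def __post_init__(self) -> None:
        if self.n_cavities < 1:
            raise ValueError("a listed habitat tree has at least one cavity")


def occupation_rate_from_records(records: list["CavityTreeRecord"]) -> "OccupationRate":
    """Occupation rate over a list of inspected cavity trees."""
    if not records:
        raise ValueError("no trees inspected")
    return occupation_rate(sum(r.occupied for r in records), len(records))


@dataclass(frozen=True)
class DensityEstimate:
    """Colonies per square kilometer with its provenance retained.

    ``value`` is exactly ``numerator / denominator_km2``; rounding to the
    conventional two decimals happens only in :meth:`rounded` / ``str()``.
    """

    value: float
    numerator: float
    denominator_km2: float
    method: str  # "survey-buffer" or "cavity-occupation"
    lower_bound: bool = False

    def __post_init__(self) -> None:
        if self.denominator_km2 <= 0:
            raise ValueError("area must be positive")
        if self.value < 0:
            raise ValueError("density cannot be negative")

    def rounded(self, ndigits: int = 2) -> float:
        return round(self.value, ndigits)

    def __str__(self) -> str:
        bound = " (lower bound)" if self.lower_bound else ""
        return f"{self.rounded():.2f} colonies/km^2 [{self.method}]{bound}"


@dataclass(frozen=True)
class OccupationRate:
    """Fraction of inspected trees occupied, with a Clopper-Pearson 95% CI.

    The interval is an artifact addition for planning purposes; the point
    estimate alone feeds the density arithmetic.
    """

    occupied: int
    inspected: int
    proportion: float
    ci_low: float
    ci_high: float


def occupation_rate(occupied: int, inspected: int) -> OccupationRate:
    """Occupied/inspected proportion with an exact binomial 95% interval."""
    if inspected <= 0:
        raise ValueError("inspected must be positive")
    if not 0 <= occupied <= inspected:
        raise ValueError("need 0 <= occupied <= inspected")
    p = occupied / inspected
    alpha = 0.05
    lo = 0.0 if occupied == 0 else stats.beta.ppf(alpha / 2, occupied, inspected - occupied + 1)
    hi = (
        1.0
        if occupied == inspected
        else stats.beta.ppf(1 - alpha / 2, occupied + 1, inspected - occupied)
    )
    return OccupationRate(occupied, inspected, p, float(lo), float(hi))


def cavity_occupation_density(
    n_trees: int, region_area_km2: float, rate: float | OccupationRate
) -> DensityEstimate:
    """Habitat-tree density times cavity occupation rate (a lower bound).

    ``n_trees`` is the full count of mapped cavity trees in the region;
    ``rate`` the occupation proportion among the inspected subset.
    """
    if region_area_km2 <= 0:
        raise ValueError("region area must be positive")
    p = rate.proportion if isinstance(rate, OccupationRate) else float(rate)
    if not 0.0 <= p <= 1.0:
        raise ValueError("rate must be a proportion in [0, 1]")
    value = (n_trees / region_area_km2) * p
    return DensityEstimate(
        value=value,
        numerator=n_trees * p,
        denominator_km2=region_area_km2,
        method="cavity-occupation",
        lower_bound=True,
    )


def extrapolate_population(
    density_low: float, density_high: float, forest_area_km2: float
) -> tuple[float, float]:
    """Colony-count range implied by a density band over a forest area.

    Returns the raw product range; round to two significant figures at
    reporting time.
    """
    if not 0 <= density_low <= density_high:
        raise ValueError("need 0 <= density_low <= density_high")
    if forest_area_km2 <= 0:
        raise ValueError("forest area must be positive")
    return density_low * forest_area_km2, density_high * forest_area_km2


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (report-time convention)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + sig - 1)


@dataclass(frozen=True)
class TableSummary:
    """Median / mean / population SD of a distance column, report-rounded."""

    n: int
    median: float
    mean: float
    sd: float  # population SD (divisor n)
    values: tuple[float, ...] = field(repr=False, default=())

    def rounded(self, nearest: float = 10.0) -> "TableSummary":
        r = lambda v: round(v / nearest) * nearest
        return TableSummary(self.n, r(self.median), r(self.mean), r(self.sd), self.values)


def table_summary(
    distances: list[float | str], censored_substitute: float | None = None
) -> TableSummary:
    """Summarize a distance column as printed in field-survey tables.

    Entries like ``"<50"`` are left-censored readings; they are replaced by
    ``censored_substitute`` when given, else by the censoring limit itself
    (the convention that reproduces published summary rows).  The SD uses
    divisor *n* (population form).
    """
    if not distances:
        raise ValueError("no distances given")
    values: list[float] = []
    for d in distances:
        if isinstance(d, str) and d.strip().startswith("<"):
            limit = float(d.strip().lstrip("<").replace(",", ""))
            values.append(censored_substitute if censored_substitute is not None else limit)
        else:
            values.append(float(str(d).replace(",", "")))
    n = len(values)
    svals = sorted(values)
    mid = n // 2
    median = svals[mid] if n % 2 else (svals[mid - 1] + svals[mid]) / 2.0
    mean = sum(values) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in values) / n)
    return TableSummary(n, median, mean, sd, tuple(values))
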