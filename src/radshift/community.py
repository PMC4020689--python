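"""Domain types, trap pooling, and activity-density standardization.

Pitfall-trap catches are recorded per trap and per collection interval. For
analysis, catches from a row of traps run over a season at one site are
pooled, and pooled counts are standardized to annual activity density (aAD):
the mean number of individuals per trap per standard period of 10 trapping
days. aAD makes assemblages comparable across sites and sampling campaigns
with different trap numbers or exposure lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Mapping

__all__ = [
    "TrapCatchRecord",
    "PooledCatch",
    "CommunitySample",
    "TraitTable",
    "PairedSamples",
    "WING_MORPHS",
    "DIETS",
    "THERMAL_PREFS",
    "MOISTURE_PREFS",
    "pool_traps",
    "compute_aad",
]

WING_MORPHS = ("macropterous", "brachypterous", "dimorphic")
DIETS = ("specialized_predator", "generalist_predator", "zoophytophagous")
THERMAL_PREFS = ("microtherm", "thermophilic", "neutral")
MOISTURE_PREFS = ("hygrophilic", "xerophilic", "neutral")


@dataclass(frozen=True)
class TrapCatchRecord:
    """One species count in one trap over one collection interval.

    The raw sampling unit: a row of pitfall traps is emptied every few weeks,
    and each emptying yields one record per species per trap.
    """

    site: str
    period: str
    trap: str
    interval_start: date
    interval_end: date
    species: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError(f"count must be non-negative, got {self.count}")
        if self.interval_end <= self.interval_start:
            raise ValueError(
                f"interval_end ({self.interval_end}) must be after "
                f"interval_start ({self.interval_start})"
            )

    @property
    def key(self) -> tuple:
        """Uniqueness key: (site, period, trap, interval, species)."""
        return (
            self.site,
            self.period,
            self.trap,
            self.interval_start,
            self.interval_end,
            self.species,
        )


@dataclass(frozen=True)
class PooledCatch:
    """Species counts pooled over all traps and intervals of one site-period."""

    site: str
    period: str
    counts: Mapping[str, int]
    n_traps: int
    exposure_days: float


@dataclass(frozen=True)
class CommunitySample:
    """A site x period assemblage as standardized annual activity density.

    ``abundance`` maps each caught species to its aAD; species with zero
    pooled count are absent from the map. ``raw_counts`` keeps the pooled
    integer counts, which likelihood-based model fitting and rarefaction
    require.
    """

    site: str
    period: str
    n_traps: int
    exposure_days: float
    abundance: Mapping[str, float]
    raw_counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sp, ad in self.abundance.items():
            if ad < 0:
                raise ValueError(f"negative aAD for {sp!r}")
            if self.raw_counts and self.raw_counts.get(sp, 0) <= 0:
                raise ValueError(f"species {sp!r} has aAD > 0 but no raw count")

    @property
    def label(self) -> str:
        return f"{self.site}_{self.period}"

    @property
    def species(self) -> frozenset[str]:
        return frozenset(self.abundance)

    @property
    def richness(self) -> int:
        return len(self.abundance)

    @property
    def total_aad(self) -> float:
        return float(sum(self.abundance.values()))

    def relative_abundance(self) -> dict[str, float]:
        """aAD proportions within the sample (summing to 1)."""
        total = self.total_aad
        if total <= 0:
            raise ValueError(f"sample {self.label} has zero total abundance")
        return {sp: ad / total for sp, ad in self.abundance.items()}


@dataclass(frozen=True)
class TraitTable:
    """Per-species trait assignments (wing morphology, diet, preferences).

    ``thermal`` and ``moisture`` are optional per species (may be missing);
    ``wing_morph`` and ``diet`` are required for every listed species.
    """

    wing_morph: Mapping[str, str]
    diet: Mapping[str, str]
    thermal: Mapping[str, str] = field(default_factory=dict)
    moisture: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, mapping, allowed in (
            ("wing_morph", self.wing_morph, WING_MORPHS),
            ("diet", self.diet, DIETS),
            ("thermal", self.thermal, THERMAL_PREFS),
            ("moisture", self.moisture, MOISTURE_PREFS),
        ):
            for sp, value in mapping.items():
                if value not in allowed:
                    raise ValueError(
                        f"unknown {name} category {value!r} for species {sp!r}; "
                        f"allowed: {allowed}"
                    )

    @property
    def species(self) -> frozenset[str]:
        return frozenset(self.wing_morph)

    def missing_from(self, species: Iterable[str]) -> list[str]:
        """Species in ``species`` that have no trait entry, sorted."""
        return sorted(set(species) - self.species)


@dataclass(frozen=True)
class PairedSamples:
    """A before/now pair of samples from the same site."""

    site: str
    before: CommunitySample
    now: CommunitySample

    def __post_init__(self) -> None:
        if self.before.site != self.site or self.now.site != self.site:
            raise ValueError("paired samples must share the site id")
        if self.before.period == self.now.period:
            raise ValueError("before and now periods must differ")


def pool_traps(
    records: Iterable[TrapCatchRecord],
    site: str | None = None,
    period: str | None = None,
) -> PooledCatch:
    """Pool trap catches over traps and intervals for one site-period.

    Parameters
    ----------
    records
        Trap-catch records, all from a single (site, period). If ``site`` /
        ``period`` are given, records are filtered to them first.
    site, period
        Optional filters; if omitted, the records must already be homogeneous.

    Returns
    -------
    PooledCatch with summed counts per species, the number of distinct traps,
    and the exposure in days (span from the earliest interval start to the
    latest interval end, traps assumed simultaneously active).
    """
    recs = [
        r
        for r in records
        if (site is None or r.site == site) and (period is None or r.period == period)
    ]
    if not recs:
        raise ValueError("no records to pool")

    sites = {r.site for r in recs}
    periods = {r.period for r in recs}
    if len(sites) > 1:
        raise ValueError(f"records span multiple sites: {sorted(sites)}")
    if len(periods) > 1:
        raise ValueError(f"records span multiple periods: {sorted(periods)}")

    seen: set[tuple] = set()
    counts: dict[str, int] = {}
    for r in recs:
        if r.key in seen:
            raise ValueError(f"duplicate record for key {r.key}")
        seen.add(r.key)
        counts[r.species] = counts.get(r.species, 0) + r.count

    start = min(r.interval_start for r in recs)
    end = max(r.interval_end for r in recs)
    exposure_days = float((end - start).days)
    n_traps = len({r.trap for r in recs})
    return PooledCatch(
        site=recs[0].site,
        period=recs[0].period,
        counts=counts,
        n_traps=n_traps,
        exposure_days=exposure_days,
    )


def compute_aad(
    counts: Mapping[str, int],
    n_traps: int,
    exposure_days: float,
    *,
    site: str = "",
    period: str = "",
    trap_days: Mapping[str, float] | None = None,
) -> CommunitySample:
    """Standardize pooled counts to annual activity density.

    aAD = (count / n_traps) / (exposure_days / 10): mean individuals per trap
    per standard 10 trapping days. Species with zero count are dropped from
    the abundance map but kept out of ``raw_counts`` as well.

    ``trap_days`` optionally gives per-trap active days (for lost traps that
    were active only part of the season); when present, the divisor becomes
    the summed trap-days / 10 instead of n_traps * exposure_days / 10.
    """
    if n_traps < 1:
        raise ValueError(f"n_traps must be >= 1, got {n_traps}")
    if exposure_days <= 0:
        raise ValueError(f"exposure_days must be positive, got {exposure_days}")
    for sp, c in counts.items():
        if c < 0:
            raise ValueError(f"negative count for species {sp!r}")
        if c != int(c):
            raise ValueError(f"non-integer count for species {sp!r}: {c}")

    if trap_days is not None:
        total_trap_days = float(sum(trap_days.values()))
        if total_trap_days <= 0:
            raise ValueError("trap_days must sum to a positive number")
    else:
        total_trap_days = n_traps * exposure_days

    abundance = {
        sp: c / (total_trap_days / 10.0) for sp, c in counts.items() if c > 0
    }
    raw = {sp: int(c) for sp, c in counts.items() if c > 0}
    return CommunitySample(
        site=site,
        period=period,
        n_traps=n_traps,
        exposure_days=exposure_days,
        abundance=abundance,
        raw_counts=raw,
    )


def pooled_to_sample(pooled: PooledCatch) -> CommunitySample:
    """Convenience: standardize a PooledCatch directly."""
    return compute_aad(
        pooled.counts,
        pooled.n_traps,
        pooled.exposure_days,
        site=pooled.site,
        period=pooled.period,
    )
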