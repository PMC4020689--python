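"""Synthetic paired before/now pitfall-trap surveys with known ground truth.

The generator emulates the sampling design the analysis assumes: several
sites, each with a row of pitfall traps emptied a few times over a summer
season, resurveyed after decades. Each site draws a species subset from a
shared regional pool, receives expected abundances from a chosen SAD model,
and the "now" assemblage is derived from the "before" one by trait-dependent
turnover: cold-adapted (microtherm) and moisture-demanding (hygrophilic)
species go locally extinct with set probabilities, warm-adapted
(thermophilic) species multiply their abundance, a few colonists appear at
low-to-mid abundance, and multiplicative log-normal jitter reorders ranks.

Catches are realized as Poisson totals per species with mean
expected_abundance * n_traps * exposure_days / 10, allocated uniformly
(multinomially) over trap x interval cells, so that annual activity density
computed from the realized records is an unbiased estimator of the expected
abundance. All randomness flows from the single scenario seed through
numpy's SeedSequence spawning; there is no hidden global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from typing import Mapping, Sequence

import numpy as np

from .community import (
    DIETS,
    MOISTURE_PREFS,
    THERMAL_PREFS,
    WING_MORPHS,
    TraitTable,
    TrapCatchRecord,
)
from .rad import expected_rad

__all__ = [
    "TurnoverConfig",
    "ScenarioConfig",
    "SiteTruth",
    "GroundTruth",
    "ScenarioResult",
    "generate_community",
    "assign_traits",
    "apply_turnover",
    "realize_trap_counts",
    "simulate_scenario",
]

#: Default SAD parameters used when a scenario names a model without params.
DEFAULT_SAD_PARAMS = {
    "brokenstick": {},
    "preemption": {"alpha": 0.4},
    "lognormal": {"mu": 1.0, "sigma": 1.0},
    "zipf": {"p1": 0.4, "gamma": -1.2},
    "mandelbrot": {"c": 0.6, "beta": 1.0, "gamma": -1.5},
}


@dataclass(frozen=True)
class TurnoverConfig:
    """Before -> now transformation of a site assemblage.

    Defaults mirror decades-scale warming turnover in an alpine resurvey:
    roughly half the cold-adapted and moisture-demanding species drop out,
    warm-adapted species triple their activity density (total abundance
    roughly doubles), one colonist arrives per site, and moderate rank
    jitter reshuffles the remaining species.
    """

    p_extinct_microtherm: float = 0.5
    p_extinct_hygrophilic: float = 0.5
    p_extinct_other: float = 0.1
    n_colonists: int = 1
    thermophilic_multiplier: float = 3.0
    rank_jitter: float = 0.3

    def __post_init__(self) -> None:
        for name in ("p_extinct_microtherm", "p_extinct_hygrophilic", "p_extinct_other"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.thermophilic_multiplier <= 0:
            raise ValueError("thermophilic_multiplier must be positive")
        if self.rank_jitter < 0:
            raise ValueError("rank_jitter must be non-negative")
        if self.n_colonists < 0:
            raise ValueError("n_colonists must be non-negative")

    @staticmethod
    def off() -> "TurnoverConfig":
        """No turnover at all: the now assemblage equals the before one."""
        return TurnoverConfig(0.0, 0.0, 0.0, 0, 1.0, 0.0)


#: Trait category probabilities for a subalpine/alpine carabid pool.
DEFAULT_TRAIT_PROBS = {
    "wing_morph": {"macropterous": 0.3, "brachypterous": 0.5, "dimorphic": 0.2},
    "diet": {
        "specialized_predator": 0.35,
        "generalist_predator": 0.45,
        "zoophytophagous": 0.2,
    },
    "thermal": {"microtherm": 0.3, "thermophilic": 0.3, "neutral": 0.4},
    "moisture": {"hygrophilic": 0.3, "xerophilic": 0.3, "neutral": 0.4},
}


@dataclass(frozen=True)
class ScenarioConfig:
    """A paired-resurvey scenario.

    Defaults follow the sampling design the analysis targets: 6 sites x 2
    periods, 6 traps per site emptied 3 times over a ~90-day June-September
    season, per-site richness drawn from 5-12, roughly 250 individuals
    expected per site-period, and a shared regional pool of 40 species so
    neighbouring sites overlap in composition.
    """

    n_sites: int = 6
    s_range: tuple[int, int] = (5, 12)
    N: float = 250.0
    sad_model: str = "mandelbrot"
    sad_params: Mapping[str, float] | None = None
    n_traps: int = 6
    n_intervals: int = 3
    exposure_days: float = 90.0
    pool_size: int = 40
    periods: tuple[str, str] = ("1980", "2009")
    turnover: TurnoverConfig = field(default_factory=TurnoverConfig)
    trait_probs: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_TRAIT_PROBS
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s_range[0] < 2 or self.s_range[1] < self.s_range[0]:
            raise ValueError(f"invalid s_range {self.s_range}; need 2 <= min <= max")
        if self.pool_size < self.s_range[1] + self.turnover.n_colonists:
            raise ValueError("pool_size too small for s_range plus colonists")
        if self.n_sites < 1 or self.n_traps < 1 or self.n_intervals < 1:
            raise ValueError("n_sites, n_traps and n_intervals must be >= 1")
        if self.N <= 0 or self.exposure_days <= 0:
            raise ValueError("N and exposure_days must be positive")


@dataclass(frozen=True)
class SiteTruth:
    """True generating state for one site."""

    site: str
    sad_model: str
    sad_params: Mapping[str, float]
    before: Mapping[str, float]
    now: Mapping[str, float]
    extinct: tuple[str, ...]
    colonists: tuple[str, ...]


@dataclass(frozen=True)
class GroundTruth:
    sites: Mapping[str, SiteTruth]
    traits: TraitTable

    def __post_init__(self) -> None:
        for st in self.sites.values():
            if set(st.extinct) & set(st.colonists):
                raise ValueError(f"site {st.site}: extinct and colonist sets overlap")


@dataclass(frozen=True)
class ScenarioResult:
    config: ScenarioConfig
    records: tuple[TrapCatchRecord, ...]
    traits: TraitTable
    truth: GroundTruth


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def species_names(n: int, width: int = 3) -> list[str]:
    """Zero-padded species names (sp001, ...) for deterministic tie-breaks."""
    width = max(width, len(str(n)))
    return [f"sp{i:0{width}d}" for i in range(1, n + 1)]


def generate_community(
    sad_model: str,
    params: Mapping[str, float] | None,
    S: int,
    N: float,
    seed: int | np.random.Generator | None = None,
    *,
    names: Sequence[str] | None = None,
) -> dict[str, float]:
    """Expected abundances for S species under a SAD model, scaled to sum N.

    Species are named sp001.. (or take ``names`` in rank order). The output
    is deterministic given the model and parameters; ``seed`` is accepted
    for interface symmetry with the stochastic generator steps.
    """
    if params is None:
        params = DEFAULT_SAD_PARAMS[sad_model]
    expected = expected_rad(sad_model, params, S, N)
    expected = expected * (N / expected.sum())
    if names is None:
        names = species_names(S)
    elif len(names) != S:
        raise ValueError(f"need {S} names, got {len(names)}")
    return {name: float(a) for name, a in zip(names, expected)}


def _draw_category(rng: np.random.Generator, probs: Mapping[str, float], n: int):
    cats = list(probs)
    p = np.array([probs[c] for c in cats], dtype=float)
    p = p / p.sum()
    return [cats[i] for i in rng.choice(len(cats), size=n, p=p)]


def assign_traits(
    species: Sequence[str],
    trait_probs: Mapping[str, Mapping[str, float]] | None = None,
    seed: int | np.random.Generator | None = None,
) -> TraitTable:
    """Draw independent trait categories for each species."""
    rng = _rng(seed)
    probs = trait_probs or DEFAULT_TRAIT_PROBS
    n = len(species)
    wing = _draw_category(rng, probs["wing_morph"], n)
    diet = _draw_category(rng, probs["diet"], n)
    thermal = _draw_category(rng, probs["thermal"], n)
    moisture = _draw_category(rng, probs["moisture"], n)
    for cat, allowed in (
        (wing, WING_MORPHS),
        (diet, DIETS),
        (thermal, THERMAL_PREFS),
        (moisture, MOISTURE_PREFS),
    ):
        assert set(cat) <= set(allowed)
    return TraitTable(
        wing_morph=dict(zip(species, wing)),
        diet=dict(zip(species, diet)),
        thermal=dict(zip(species, thermal)),
        moisture=dict(zip(species, moisture)),
    )


def apply_turnover(
    community: Mapping[str, float],
    traits: TraitTable,
    turnover: TurnoverConfig,
    seed: int | np.random.Generator | None = None,
    *,
    colonist_pool: Sequence[str] = (),
) -> tuple[dict[str, float], tuple[str, ...], tuple[str, ...]]:
    """Derive the "now" assemblage from a "before" one.

    Returns (now_community, extinct_species, colonist_species). Extinction
    probability is trait-dependent (microtherm, else hygrophilic, else
    other); thermophilic species are multiplied by the configured factor;
    colonists are drawn from ``colonist_pool`` with abundances uniform
    between the smallest and the median before-abundance; finally
    log-normal jitter of scale ``rank_jitter`` perturbs every abundance.
    """
    missing = traits.missing_from(community)
    if missing:
        raise ValueError(f"traits must cover all species; missing {missing}")
    rng = _rng(seed)
    now: dict[str, float] = {}
    extinct: list[str] = []
    for sp in sorted(community):
        ab = community[sp]
        if traits.thermal.get(sp) == "microtherm":
            p_ext = turnover.p_extinct_microtherm
        elif traits.moisture.get(sp) == "hygrophilic":
            p_ext = turnover.p_extinct_hygrophilic
        else:
            p_ext = turnover.p_extinct_other
        if rng.random() < p_ext:
            extinct.append(sp)
            continue
        if traits.thermal.get(sp) == "thermophilic":
            ab = ab * turnover.thermophilic_multiplier
        now[sp] = ab

    colonists: list[str] = []
    if turnover.n_colonists > 0:
        available = [sp for sp in colonist_pool if sp not in community]
        n_new = min(turnover.n_colonists, len(available))
        if n_new:
            chosen = rng.choice(len(available), size=n_new, replace=False)
            abund = np.asarray(sorted(community.values()))
            lo = float(abund[0])
            mid = float(np.median(abund))
            for i in sorted(int(j) for j in chosen):
                sp = available[i]
                now[sp] = float(rng.uniform(lo, max(mid, lo)))
                colonists.append(sp)

    if turnover.rank_jitter > 0:
        for sp in sorted(now):
            now[sp] = float(now[sp] * rng.lognormal(0.0, turnover.rank_jitter))
    return now, tuple(extinct), tuple(colonists)


def realize_trap_counts(
    community: Mapping[str, float],
    n_traps: int,
    n_intervals: int,
    exposure_days: float,
    seed: int | np.random.Generator | None = None,
    *,
    site: str = "site1",
    period: str = "1980",
    season_start: date | None = None,
) -> list[TrapCatchRecord]:
    """Realize trap-catch records from expected abundances.

    Each species' season total is Poisson with mean
    abundance * n_traps * exposure_days / 10, split multinomially over
    trap x interval cells with equal probabilities. Zero cells are emitted
    as count-0 records so the trap/interval layout survives pooling.
    """
    rng = _rng(seed)
    if season_start is None:
        year = int(period) if period.isdigit() else 2000
        season_start = date(year, 6, 15)
    step = exposure_days / n_intervals
    bounds = [season_start + timedelta(days=round(i * step)) for i in range(n_intervals + 1)]
    traps = [f"t{j + 1}" for j in range(n_traps)]
    n_cells = n_traps * n_intervals
    records: list[TrapCatchRecord] = []
    for sp in sorted(community):
        ab = community[sp]
        if ab < 0:
            raise ValueError(f"negative expected abundance for {sp!r}")
        total = int(rng.poisson(ab * n_traps * exposure_days / 10.0)) if ab > 0 else 0
        cells = rng.multinomial(total, np.full(n_cells, 1.0 / n_cells))
        for idx, c in enumerate(cells):
            j, i = divmod(idx, n_intervals)
            records.append(
                TrapCatchRecord(
                    site=site,
                    period=period,
                    trap=traps[j],
                    interval_start=bounds[i],
                    interval_end=bounds[i + 1],
                    species=sp,
                    count=int(c),
                )
            )
    return records


def simulate_scenario(config: ScenarioConfig) -> ScenarioResult:
    """Generate a full paired-resurvey dataset with ground truth.

    Randomness is split from ``config.seed`` with SeedSequence: one child
    stream for the trait table, then per site one stream each for community
    assembly, turnover, and each period's catch realization.
    """
    ss = np.random.SeedSequence(config.seed)
    trait_ss, *site_ss = ss.spawn(1 + config.n_sites)
    pool = species_names(config.pool_size)
    traits = assign_traits(
        pool, config.trait_probs, np.random.default_rng(trait_ss)
    )
    params = dict(
        config.sad_params
        if config.sad_params is not None
        else DEFAULT_SAD_PARAMS[config.sad_model]
    )

    records: list[TrapCatchRecord] = []
    site_truths: dict[str, SiteTruth] = {}
    for i, site_seed in enumerate(site_ss, start=1):
        site = f"site{i}"
        assembly_ss, turn_ss, before_ss, now_ss = site_seed.spawn(4)
        rng = np.random.default_rng(assembly_ss)
        S = int(rng.integers(config.s_range[0], config.s_range[1] + 1))
        members = [pool[j] for j in rng.choice(config.pool_size, size=S, replace=False)]
        # community abundances live in aAD units; scale so the expected
        # number of trapped individuals over the season equals N
        total_aad = config.N * 10.0 / (config.n_traps * config.exposure_days)
        before = generate_community(
            config.sad_model, params, S, total_aad, names=members
        )
        now, extinct, colonists = apply_turnover(
            before,
            traits,
            config.turnover,
            np.random.default_rng(turn_ss),
            colonist_pool=pool,
        )
        records.extend(
            realize_trap_counts(
                before,
                config.n_traps,
                config.n_intervals,
                config.exposure_days,
                np.random.default_rng(before_ss),
                site=site,
                period=config.periods[0],
            )
        )
        records.extend(
            realize_trap_counts(
                now,
                config.n_traps,
                config.n_intervals,
                config.exposure_days,
                np.random.default_rng(now_ss),
                site=site,
                period=config.periods[1],
            )
        )
        site_truths[site] = SiteTruth(
            site=site,
            sad_model=config.sad_model,
            sad_params=params,
            before=before,
            now=now,
            extinct=extinct,
            colonists=colonists,
        )

    truth = GroundTruth(sites=site_truths, traits=traits)
    return ScenarioResult(
        config=config, records=tuple(records), traits=traits, truth=truth
    )


def truth_to_dict(truth: GroundTruth) -> dict:
    """JSON-serializable ground truth (for the simulate CLI)."""
    return {
        "sites": {
            site: {
                "sad_model": st.sad_model,
                "sad_params": dict(st.sad_params),
                "before": dict(st.before),
                "now": dict(st.now),
                "extinct": list(st.extinct),
                "colonists": list(st.colonists),
            }
            for site, st in truth.sites.items()
        }
    }
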