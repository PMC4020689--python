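"""End-to-end orchestration: traits, richness coverage, full comparison runs.

``run_pipeline`` executes the complete analysis on a dataset (read from CSV
files or freshly simulated): pooling and aAD standardization per site-period,
bootstrap richness per period, SAD model selection per sample, before/now
comparison (Renkonen, IRC, turnover), trait summaries, and Ward clustering
of all samples, writing a JSON report plus CSV and Newick side outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import compare, diversity, io, rad, simulate
from .community import CommunitySample, TraitTable, TrapCatchRecord, pool_traps, pooled_to_sample

__all__ = [
    "TraitSummary",
    "PipelineConfig",
    "trait_summary",
    "richness_coverage",
    "samples_from_records",
    "run_pipeline",
]

logger = logging.getLogger("radshift")

REPORT_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class TraitSummary:
    """Trait composition of one assemblage.

    hd_pct: percent of total aAD from high-dispersal (macropterous or
    dimorphic) species; zp_ad_pct: percent of total aAD from zoophytophagous
    species; spc_spp_pct: percent of species that are specialized predators.
    """

    site: str
    period: str
    hd_pct: float
    zp_ad_pct: float
    spc_spp_pct: float

    def __post_init__(self) -> None:
        for name in ("hd_pct", "zp_ad_pct", "spc_spp_pct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must be a percentage in [0, 100], got {v}")


def trait_summary(sample: CommunitySample, traits: TraitTable) -> TraitSummary:
    """Percent activity density and species shares of key trait groups."""
    missing = traits.missing_from(sample.species)
    if missing:
        raise ValueError(
            f"species missing from trait table: {', '.join(missing)}"
        )
    total = sample.total_aad
    if total <= 0:
        raise ValueError(f"sample {sample.label} has zero total abundance")
    hd = sum(
        ad
        for sp, ad in sample.abundance.items()
        if traits.wing_morph[sp] in ("macropterous", "dimorphic")
    )
    zp = sum(
        ad
        for sp, ad in sample.abundance.items()
        if traits.diet[sp] == "zoophytophagous"
    )
    spc = sum(
        1 for sp in sample.abundance if traits.diet[sp] == "specialized_predator"
    )
    return TraitSummary(
        site=sample.site,
        period=sample.period,
        hd_pct=100.0 * hd / total,
        zp_ad_pct=100.0 * zp / total,
        spc_spp_pct=100.0 * spc / sample.richness,
    )


def richness_coverage(s_obs: int, s_expected: float) -> int:
    """Observed richness as a rounded percent of the expected richness."""
    if s_expected <= 0:
        raise ValueError("expected richness must be positive")
    return _round_half_away(100.0 * s_obs / s_expected)


def _round_half_away(x: float) -> int:
    import math

    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def samples_from_records(
    records: Sequence[TrapCatchRecord],
) -> dict[tuple[str, str], CommunitySample]:
    """Pool and standardize records into one sample per (site, period)."""
    keys = sorted({(r.site, r.period) for r in records})
    out = {}
    for site, period in keys:
        pooled = pool_traps(records, site=site, period=period)
        out[(site, period)] = pooled_to_sample(pooled)
    return out


@dataclass(frozen=True)
class PipelineConfig:
    """Inputs for a full pipeline run.

    Either ``catch_csv`` (with optional ``trait_csv``) or ``scenario`` must
    be given. ``periods`` orders the before and now labels; if omitted they
    are inferred as the sorted distinct period labels (requires exactly 2).
    """

    out_dir: str | Path
    catch_csv: str | Path | None = None
    trait_csv: str | Path | None = None
    scenario: simulate.ScenarioConfig | None = None
    periods: tuple[str, str] | None = None
    n_boot: int = 999
    boot_unit: str = "trap_interval"
    seed: int = 0
    strict_four: bool = False

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        scenario = None
        if "scenario" in raw:
            sc = dict(raw["scenario"])
            if "turnover" in sc:
                sc["turnover"] = simulate.TurnoverConfig(**sc["turnover"])
            if "s_range" in sc:
                sc["s_range"] = tuple(sc["s_range"])
            if "periods" in sc:
                sc["periods"] = tuple(sc["periods"])
            scenario = simulate.ScenarioConfig(**sc)
        return PipelineConfig(
            out_dir=raw.get("out_dir", "."),
            catch_csv=raw.get("catch_csv"),
            trait_csv=raw.get("trait_csv"),
            scenario=scenario,
            periods=tuple(raw["periods"]) if "periods" in raw else None,
            n_boot=raw.get("n_boot", 999),
            boot_unit=raw.get("boot_unit", "trap_interval"),
            seed=raw.get("seed", 0),
            strict_four=raw.get("strict_four", False),
        )


def _stage(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                logger.info("stage %s: done in %.2fs", name, dt)
            else:
                logger.error("stage %s: failed after %.2fs: %s", name, dt, exc)
            return False

    return _Timer()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every analysis stage and write the report; returns the report.

    Output files under ``config.out_dir``: report.json, comparison.csv,
    richness.csv, traits.csv, sad_selection.csv, dendrogram.nwk, and for a
    simulated run the generated catches.csv / traits_table.csv /
    ground_truth.json.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run_pipeline(config, out_dir, written)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def _run_pipeline(config: PipelineConfig, out_dir: Path, written: list[Path]) -> dict:
    with _stage("load"):
        if config.scenario is not None:
            result = simulate.simulate_scenario(config.scenario)
            records = list(result.records)
            traits: TraitTable | None = result.traits
            catch_path = out_dir / "catches.csv"
            io.write_long_table(records, catch_path)
            io.write_trait_table(traits, out_dir / "traits_table.csv")
            (out_dir / "ground_truth.json").write_text(
                json.dumps(simulate.truth_to_dict(result.truth), indent=1)
            )
            written += [catch_path, out_dir / "traits_table.csv", out_dir / "ground_truth.json"]
        elif config.catch_csv is not None:
            if not Path(config.catch_csv).exists():
                raise FileNotFoundError(f"catch table not found: {config.catch_csv}")
            records = io.read_long_table(config.catch_csv)
            traits = None
            if config.trait_csv is not None:
                if not Path(config.trait_csv).exists():
                    raise FileNotFoundError(
                        f"trait table not found: {config.trait_csv}"
                    )
                traits = io.read_trait_table(config.trait_csv)
        else:
            raise ValueError("config needs either catch_csv or scenario")

    with _stage("standardize"):
        samples = samples_from_records(records)
        periods = config.periods
        if periods is None:
            found = sorted({p for _, p in samples})
            if len(found) != 2:
                raise ValueError(
                    f"expected exactly 2 periods, found {found}; set periods"
                )
            periods = (found[0], found[1])
        sites = sorted({s for s, _ in samples})

    with _stage("richness"):
        richness = {}
        for idx, period in enumerate(periods):
            period_records = [r for r in records if r.period == period]
            inc = diversity.incidence_matrix(period_records, unit=config.boot_unit)
            est = diversity.bootstrap_richness(
                inc,
                n_boot=config.n_boot,
                seed=config.seed + idx,
                unit=config.boot_unit,
            )
            richness[period] = est

    with _stage("radfit"):
        selections: dict[str, rad.ModelSelection] = {}
        for (site, period), sample in samples.items():
            try:
                selections[f"{site}_{period}"] = rad.select_sad(
                    sample.raw_counts, strict_four=config.strict_four
                )
            except ValueError as e:
                logger.warning("radfit skipped for %s_%s: %s", site, period, e)

    with _stage("compare"):
        per_site = []
        for site in sites:
            before = samples.get((site, periods[0]))
            now = samples.get((site, periods[1]))
            if before is None or now is None:
                logger.warning("site %s lacks a %s/%s pair; skipped", site, *periods)
                continue
            t = compare.turnover(before, now)
            ircr = compare.irc(before, now)
            per_site.append(
                {
                    "site": site,
                    "renkonen": compare.renkonen(before, now),
                    "irc": ircr.value,
                    "n_union": ircr.n_union,
                    "shared": t.shared,
                    "only_before": t.only_before,
                    "only_now": t.only_now,
                }
            )
        dendro = compare.ward_cluster(list(samples.values()))

    trait_rows = []
    if traits is not None:
        with _stage("traits"):
            for sample in samples.values():
                ts = trait_summary(sample, traits)
                trait_rows.append(asdict(ts))

    with _stage("report"):
        report = {
            "schema_version": REPORT_SCHEMA_VERSION,
            "metadata": {
                "seed": config.seed,
                "n_boot": config.n_boot,
                "boot_unit": config.boot_unit,
                "periods": list(periods),
                "n_sites": len(sites),
            },
            "richness": {
                period: {
                    "s_obs": est.s_obs,
                    "s_expected": est.s_expected,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "coverage_pct": richness_coverage(est.s_obs, est.s_expected),
                }
                for period, est in richness.items()
            },
            "comparison": per_site,
            "sad_selection": {
                label: {
                    "best": sel.best,
                    "delta_aic": {m: round(d, 6) for m, d in sel.delta_aic.items()},
                }
                for label, sel in selections.items()
            },
            "trait_summary": trait_rows,
            "dendrogram_newick": dendro.to_newick(),
        }
        blob = json.dumps(report, sort_keys=True).encode()
        report["metadata"]["config_hash"] = hashlib.sha256(blob).hexdigest()[:16]

        report_path = out_dir / "report.json"
        report_path.write_text(json.dumps(report, indent=1, sort_keys=True))
        written.append(report_path)
        pd.DataFrame(per_site).to_csv(out_dir / "comparison.csv", index=False)
        pd.DataFrame(
            [
                {"period": p, **report["richness"][p]}
                for p in periods
                if p in report["richness"]
            ]
        ).to_csv(out_dir / "richness.csv", index=False)
        if trait_rows:
            pd.DataFrame(trait_rows).to_csv(out_dir / "traits.csv", index=False)
        sel_rows = []
        for label, sel in selections.items():
            for m, fit in sel.fits.items():
                sel_rows.append(
                    {
                        "sample": label,
                        "model": m,
                        "k": fit.k,
                        "params": ";".join(
                            f"{k}={v:.6g}" for k, v in fit.params.items()
                        ),
                        "loglik": fit.loglik,
                        "aic": fit.aic,
                        "delta_aic": sel.delta_aic[m],
                        "selected": m == sel.best,
                    }
                )
        if sel_rows:
            pd.DataFrame(sel_rows).to_csv(out_dir / "sad_selection.csv", index=False)
        (out_dir / "dendrogram.nwk").write_text(dendro.to_newick() + "\n")
    return report
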