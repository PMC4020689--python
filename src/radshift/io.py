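"""Delimited-text I/O for catch tables, trait tables, and community matrices.

Formats
-------
Long catch table
    CSV with header ``site,period,trap,interval_start,interval_end,species,count``;
    dates ISO-8601.
Trait table
    CSV with header ``species,wing_morph,diet,thermal,moisture``; the last two
    columns may be empty for a species.
Wide community matrix
    CSV, rows = species, columns = ``<site>_<period>``, cells = aAD written
    with 6 significant digits.
"""

from __future__ import annotations

from datetime import date
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .community import CommunitySample, TraitTable, TrapCatchRecord

__all__ = [
    "read_long_table",
    "write_long_table",
    "read_trait_table",
    "write_trait_table",
    "write_community_matrix",
    "read_community_matrix",
]

_CATCH_COLUMNS = (
    "site",
    "period",
    "trap",
    "interval_start",
    "interval_end",
    "species",
    "count",
)
_TRAIT_COLUMNS = ("species", "wing_morph", "diet", "thermal", "moisture")


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_long_table(path: str | Path) -> list[TrapCatchRecord]:
    """Read a long-format catch table into trap-catch records."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, _CATCH_COLUMNS, path)
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            count = int(row.count)
        except ValueError:
            raise ValueError(
                f"{path}: line {i}: non-integer count {row.count!r}"
            ) from None
        records.append(
            TrapCatchRecord(
                site=row.site,
                period=row.period,
                trap=row.trap,
                interval_start=date.fromisoformat(row.interval_start),
                interval_end=date.fromisoformat(row.interval_end),
                species=row.species,
                count=count,
            )
        )
    return records


def write_long_table(records: Iterable[TrapCatchRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "site": r.site,
                "period": r.period,
                "trap": r.trap,
                "interval_start": r.interval_start.isoformat(),
                "interval_end": r.interval_end.isoformat(),
                "species": r.species,
                "count": r.count,
            }
            for r in records
        ],
        columns=list(_CATCH_COLUMNS),
    )
    df.to_csv(path, index=False)


def read_trait_table(path: str | Path) -> TraitTable:
    """Read a species-trait table; empty thermal/moisture cells are allowed."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, _TRAIT_COLUMNS[:3], path)
    dup = df["species"][df["species"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate species: {', '.join(sorted(set(dup)))}")
    wing = dict(zip(df["species"], df["wing_morph"]))
    diet = dict(zip(df["species"], df["diet"]))
    thermal: dict[str, str] = {}
    moisture: dict[str, str] = {}
    if "thermal" in df.columns:
        thermal = {s: v for s, v in zip(df["species"], df["thermal"]) if v}
    if "moisture" in df.columns:
        moisture = {s: v for s, v in zip(df["species"], df["moisture"]) if v}
    return TraitTable(wing_morph=wing, diet=diet, thermal=thermal, moisture=moisture)


def write_trait_table(traits: TraitTable, path: str | Path) -> None:
    rows = [
        {
            "species": sp,
            "wing_morph": traits.wing_morph[sp],
            "diet": traits.diet[sp],
            "thermal": traits.thermal.get(sp, ""),
            "moisture": traits.moisture.get(sp, ""),
        }
        for sp in sorted(traits.species)
    ]
    pd.DataFrame(rows, columns=list(_TRAIT_COLUMNS)).to_csv(path, index=False)


def write_community_matrix(
    samples: Iterable[CommunitySample], path: str | Path
) -> None:
    """Write a species x sample-label matrix of aAD values (6 sig. digits)."""
    samples = list(samples)
    labels = [s.label for s in samples]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate sample labels: {labels}")
    species = sorted(set().union(*(s.species for s in samples)))
    df = pd.DataFrame(
        {s.label: [s.abundance.get(sp, 0.0) for sp in species] for s in samples},
        index=pd.Index(species, name="species"),
    )
    df.to_csv(path, float_format="%.6g")


def read_community_matrix(path: str | Path) -> list[CommunitySample]:
    """Read a wide aAD matrix back into samples (raw counts unavailable)."""
    df = pd.read_csv(path, index_col="species")
    samples = []
    for label in df.columns:
        site, _, period = label.rpartition("_")
        abundance = {sp: float(v) for sp, v in df[label].items() if v > 0}
        samples.append(
            CommunitySample(
                site=site,
                period=period,
                n_traps=1,
                exposure_days=10.0,
                abundance=abundance,
            )
        )
    return samples
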