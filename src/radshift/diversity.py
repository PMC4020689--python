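"""Species-richness estimation: rarefaction, bootstrap richness, rescaling.

Individual-based rarefaction gives the expected number of species in a random
subsample of m individuals drawn without replacement (hypergeometric closed
form). The bootstrap richness estimator of Smith & van Belle extrapolates
observed richness from species incidence across sampling units:

    S_hat = S_obs + sum_i (1 - p_i)^n

with p_i the fraction of the n units containing species i; its confidence
interval comes from resampling units with replacement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .community import TrapCatchRecord

__all__ = [
    "RichnessEstimate",
    "RarefactionCurve",
    "rarefy",
    "rarefaction_curve",
    "bootstrap_richness",
    "rescale_to_common_density",
    "incidence_matrix",
]


@dataclass(frozen=True)
class RichnessEstimate:
    """Observed and bootstrap-expected richness with a percentile CI."""

    s_obs: int
    s_expected: float
    ci_low: float
    ci_high: float
    n_boot: int
    unit: str
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.ci_low > self.ci_high:
            raise ValueError("ci_low must not exceed ci_high")
        if self.s_expected < self.s_obs - 1e-9:
            raise ValueError("expected richness cannot fall below observed")


@dataclass(frozen=True)
class RarefactionCurve:
    m: tuple[int, ...]
    expected_richness: tuple[float, ...]


def _log_choose(n: np.ndarray | float, k: np.ndarray | float) -> np.ndarray:
    return gammaln(np.asarray(n) + 1) - gammaln(np.asarray(k) + 1) - gammaln(
        np.asarray(n) - np.asarray(k) + 1
    )


def rarefy(counts: Mapping[str, int] | Sequence[int], m: int) -> float:
    """Expected species richness in a subsample of m individuals.

    E[S_m] = sum_i [1 - C(N - N_i, m) / C(N, m)], evaluated with
    log-binomial coefficients for numerical stability.
    """
    values = np.asarray(
        list(counts.values()) if isinstance(counts, Mapping) else counts,
        dtype=float,
    )
    if np.any(values < 0) or np.any(values != np.floor(values)):
        raise ValueError("counts must be non-negative integers")
    values = values[values > 0]
    N = int(values.sum())
    if not 0 <= m <= N:
        raise ValueError(f"m must be in [0, {N}], got {m}")
    if m == 0:
        return 0.0
    # species with N_i > N - m are guaranteed present (C(N-N_i, m) = 0)
    keep = values <= N - m
    certain = int(np.sum(~keep))
    if not np.any(keep):
        return float(certain)
    log_p_absent = _log_choose(N - values[keep], m) - _log_choose(N, m)
    return certain + float(np.sum(1.0 - np.exp(log_p_absent)))


def rarefaction_curve(
    counts: Mapping[str, int] | Sequence[int],
    m_values: Sequence[int] | None = None,
) -> RarefactionCurve:
    """Rarefaction curve over increasing subsample sizes (default: 20 steps)."""
    values = list(counts.values()) if isinstance(counts, Mapping) else list(counts)
    N = int(sum(values))
    if m_values is None:
        m_values = sorted(set(np.linspace(0, N, 21).astype(int).tolist()))
    return RarefactionCurve(
        m=tuple(int(m) for m in m_values),
        expected_richness=tuple(rarefy(values, int(m)) for m in m_values),
    )


def incidence_matrix(
    records: Sequence[TrapCatchRecord], unit: str = "trap_interval"
) -> pd.DataFrame:
    """Unit x species presence/absence matrix from trap-catch records.

    ``unit`` picks the resampling unit: "trap_interval" (trap x collection,
    the most granular), "trap" (pooled over intervals), or "site"
    (site x period).
    """
    keys = {
        "trap_interval": lambda r: (r.site, r.period, r.trap, r.interval_start),
        "trap": lambda r: (r.site, r.period, r.trap),
        "site": lambda r: (r.site, r.period),
    }
    if unit not in keys:
        raise ValueError(f"unknown unit {unit!r}; choose from {sorted(keys)}")
    key = keys[unit]
    cells: dict[tuple, dict[str, int]] = {}
    for r in records:
        cells.setdefault(key(r), {})
        if r.count > 0:
            cells[key(r)][r.species] = 1
    df = pd.DataFrame.from_dict(cells, orient="index").fillna(0).astype(int)
    return df.sort_index(axis=1)


def _smith_van_belle(inc: np.ndarray) -> float:
    n = inc.shape[0]
    present = inc.any(axis=0)
    p = inc[:, present].mean(axis=0)
    return float(present.sum() + np.sum((1.0 - p) ** n))


def bootstrap_richness(
    incidence: pd.DataFrame | np.ndarray,
    n_boot: int = 999,
    seed: int | None = None,
    unit: str = "trap_interval",
) -> RichnessEstimate:
    """Bootstrap expected species richness from an incidence matrix.

    The point estimate is the Smith & van Belle bootstrap estimator; the
    2.5/97.5 percentile interval comes from recomputing it on ``n_boot``
    resamples of the units (rows) with replacement.
    """
    inc = np.asarray(incidence, dtype=bool).astype(float)
    if inc.ndim != 2 or inc.shape[0] < 2:
        raise ValueError("incidence matrix needs at least 2 unit rows")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if not inc.any():
        raise ValueError("all units are empty")
    n = inc.shape[0]
    s_obs = int(inc.any(axis=0).sum())
    s_hat = _smith_van_belle(inc)
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        rows = rng.integers(0, n, size=n)
        reps[b] = _smith_van_belle(inc[rows])
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return RichnessEstimate(
        s_obs=s_obs,
        s_expected=s_hat,
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
        unit=unit,
        seed=seed,
    )


def rescale_to_common_density(
    counts_large: Mapping[str, int], counts_small: Mapping[str, int]
) -> tuple[dict[str, int], float]:
    """Rescale the denser count set to the sparser set's total.

    Each count in the denser set is multiplied by N_small / N_large and
    rounded half-to-even. Alongside the rounded counts, the exact expected
    richness of the denser set at m = N_small individuals is returned via
    closed-form rarefaction, which avoids the rounding artefact entirely.
    """
    n_large = sum(counts_large.values())
    n_small = sum(counts_small.values())
    if n_large < n_small:
        raise ValueError(
            f"first set (total {n_large}) must be at least as dense as the "
            f"second (total {n_small})"
        )
    factor = n_small / n_large
    rescaled = {
        sp: int(np.round(c * factor)) for sp, c in counts_large.items()
    }
    expected = rarefy(counts_large, n_small)
    return rescaled, expected
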