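"""The differential-regulation statistic at the core of the pipeline.

Each replicate's H/X SILAC ratios (heavy = co-cultured, X = medium or light
mono-cultured channel) are taken to log2 space; the replicate's population
mean and standard deviation of log2 ratios (equivalently, the log2 of the
geometric mean) define a z-score for every protein:

    z[b] = (log2 H/X[b] - mean(log2 ratios)) / sd(log2 ratios)

A protein is called regulated in a replicate when it passes BOTH a fold cut
(|log2 ratio| > 0.58, i.e. ratio > 1.5 or < 0.67) and a sign-consistent
z cut (z >= +1.960 for up, z <= -1.960 for down).  |z| >= 1.960 / 2.576 /
3.291 correspond to the two-sided 95% / 99% / 99.9% normal confidence tiers.
A final call requires the same direction in both biological replicates; the
reported average ratio is the geometric mean of the two replicate ratios and
the combined confidence tier is the weaker of the two.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegeneratePopulationError, InputError
from .io import QuantTable

__all__ = [
    "Direction",
    "Tier",
    "Thresholds",
    "PopulationStats",
    "log2_ratios",
    "population_stats",
    "z_scores",
    "classify_protein",
    "score_replicate",
    "combine_replicates",
    "rank_top",
]


class Direction(str, enum.Enum):
    UP = "up"
    DOWN = "down"
    UNCHANGED = "unchanged"


class Tier(str, enum.Enum):
    """Two-sided normal confidence tier of a call."""

    NONE = "none"
    CI95 = "ci95"
    CI99 = "ci99"
    CI999 = "ci999"


_TIER_RANK = {Tier.NONE: 0, Tier.CI95: 1, Tier.CI99: 2, Tier.CI999: 3}


@dataclass(frozen=True)
class Thresholds:
    """Decision-rule constants.

    ``z_cut``/``z_tier99``/``z_tier999`` are the two-sided standard-normal
    quantiles at 95/99/99.9% confidence; ``log2_cut`` = log2(1.5) rounded to
    the conventional 0.58, corresponding to fold cuts of 1.5 (up) and
    1/1.5 ≈ 0.67 (down).  The z criterion uses ``>=``, the fold criterion is
    strictly ``>`` (``<`` for down), matching how the rule is conventionally
    stated.
    """

    z_cut: float = 1.960
    z_tier99: float = 2.576
    z_tier999: float = 3.291
    log2_cut: float = 0.58
    fold_up: float = 1.5
    fold_down: float = 0.67

    def __post_init__(self) -> None:
        if not (0 < self.z_cut < self.z_tier99 < self.z_tier999):
            raise InputError("z tiers must satisfy 0 < z_cut < z_tier99 < z_tier999")
        if self.log2_cut <= 0:
            raise InputError("log2_cut must be positive")
        if not (self.fold_down < 1 < self.fold_up):
            raise InputError("fold cuts must bracket 1")


@dataclass(frozen=True)
class PopulationStats:
    """Mean and spread of one replicate's log2-ratio population."""

    mean_log2: float
    sd_log2: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InputError(f"population needs at least 2 proteins, got {self.n}")
        if self.sd_log2 < 0:
            raise InputError("sd_log2 must be non-negative")

    @property
    def geometric_mean_ratio(self) -> float:
        return float(2.0**self.mean_log2)


def log2_ratios(table: QuantTable) -> pd.Series:
    """Log2-transform a quality-filtered table's ratios.

    Returns a Series of log2 ratios indexed by accession.  Ratios must all
    be present and positive (i.e. the table passed ``filter_quality``).
    """
    for r in table.records:
        if r.ratio is None or r.ratio <= 0:
            raise InputError(
                f"non-positive or missing ratio for {r.accession}; run filter_quality first"
            )
    idx = pd.Index([r.accession for r in table.records], name="accession")
    values = np.log2(np.array([r.ratio for r in table.records], dtype=float))
    return pd.Series(values, index=idx, name="log2_ratio")


def population_stats(
    log_ratios: pd.Series | np.ndarray, ddof: int = 1, robust: bool = False
) -> PopulationStats:
    """Mean and standard deviation of a log2-ratio population.

    ``ddof=1`` (sample SD) by default; with populations of thousands of
    proteins the distinction from the population SD is negligible.  The
    robust mode substitutes median and scaled MAD (consistent for a normal
    population) and is off by default: the standard rule uses plain
    mean/SD over all quality-filtered proteins with no trimming.
    """
    values = np.asarray(log_ratios, dtype=float)
    if values.size < 2:
        raise InputError(f"need at least 2 log2 ratios, got {values.size}")
    if not np.all(np.isfinite(values)):
        raise InputError("log2 ratios must all be finite")
    if robust:
        center = float(np.median(values))
        spread = float(1.4826 * np.median(np.abs(values - center)))
    else:
        center = float(np.mean(values))
        spread = float(np.std(values, ddof=ddof))
    return PopulationStats(mean_log2=center, sd_log2=spread, n=int(values.size))


def z_scores(log_ratios: pd.Series, stats: PopulationStats) -> pd.DataFrame:
    """Standardize each protein's log2 ratio against the population.

    Returns a DataFrame indexed by accession with ``log2_ratio`` and ``z``
    columns, where z = (log2_ratio - mean) / sd in units of population σ.
    """
    if stats.sd_log2 == 0:
        raise DegeneratePopulationError(
            "population standard deviation is zero; z-scores are undefined"
        )
    z = (log_ratios.to_numpy(dtype=float) - stats.mean_log2) / stats.sd_log2
    return pd.DataFrame({"log2_ratio": log_ratios.to_numpy(dtype=float), "z": z},
                        index=log_ratios.index)


def classify_protein(
    log2_ratio: float, z: float, thresholds: Thresholds | None = None
) -> tuple[Direction, Tier]:
    """Classify one protein by the dual fold + z criterion.

    Up requires log2_ratio > +log2_cut AND z >= +z_cut; down requires
    log2_ratio < -log2_cut AND z <= -z_cut; anything else is unchanged.
    The tier grades |z| against the 95/99/99.9% quantiles and is reported
    as ``none`` for unchanged proteins.
    """
    t = thresholds or Thresholds()
    if not np.isfinite(z):
        raise InputError("z-score must be finite")
    if log2_ratio > t.log2_cut and z >= t.z_cut:
        direction = Direction.UP
    elif log2_ratio < -t.log2_cut and z <= -t.z_cut:
        direction = Direction.DOWN
    else:
        return Direction.UNCHANGED, Tier.NONE
    a = abs(z)
    if a >= t.z_tier999:
        tier = Tier.CI999
    elif a >= t.z_tier99:
        tier = Tier.CI99
    else:
        tier = Tier.CI95
    return direction, tier


def _classify_frame(scored: pd.DataFrame, t: Thresholds) -> pd.DataFrame:
    """Vectorized classify_protein over a z_scores frame."""
    lr = scored["log2_ratio"].to_numpy()
    z = scored["z"].to_numpy()
    up = (lr > t.log2_cut) & (z >= t.z_cut)
    down = (lr < -t.log2_cut) & (z <= -t.z_cut)
    direction = np.where(up, Direction.UP.value,
                         np.where(down, Direction.DOWN.value, Direction.UNCHANGED.value))
    a = np.abs(z)
    tier = np.select(
        [a >= t.z_tier999, a >= t.z_tier99, a >= t.z_cut],
        [Tier.CI999.value, Tier.CI99.value, Tier.CI95.value],
        default=Tier.NONE.value,
    )
    tier = np.where(direction == Direction.UNCHANGED.value, Tier.NONE.value, tier)
    out = scored.copy()
    out["direction"] = direction
    out["tier"] = tier
    return out


def score_replicate(
    table: QuantTable,
    thresholds: Thresholds | None = None,
    ddof: int = 1,
    robust: bool = False,
) -> pd.DataFrame:
    """Full per-replicate scoring: log2 → population stats → z → call.

    Returns a DataFrame indexed by accession with columns ``gene_name``,
    ``ratio``, ``log2_ratio``, ``z``, ``direction``, ``tier``.
    """
    t = thresholds or Thresholds()
    lr = log2_ratios(table)
    stats = population_stats(lr, ddof=ddof, robust=robust)
    scored = z_scores(lr, stats)
    scored = _classify_frame(scored, t)
    scored.insert(0, "gene_name", [r.gene_name for r in table.records])
    scored.insert(1, "ratio", [r.ratio for r in table.records])
    return scored


def combine_replicates(
    scored_by_replicate: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """Intersect two replicates' calls into final regulation calls.

    A protein is finally up (down) only if it was quantified in both
    replicates and called up (down) in both; conflicting or one-sided calls
    become unchanged.  ``average_ratio`` is the geometric mean of the two
    replicate ratios (proteins present in both replicates only) and the
    combined ``tier`` is the weaker of the two per-replicate tiers.
    """
    if len(scored_by_replicate) != 2:
        raise InputError(
            f"exactly 2 replicates required, got {len(scored_by_replicate)}"
        )
    (r1, s1), (r2, s2) = sorted(scored_by_replicate.items())
    merged = s1.join(s2, how="outer", lsuffix=f"_{r1}", rsuffix=f"_{r2}")
    g1, g2 = f"gene_name_{r1}", f"gene_name_{r2}"
    merged["gene_name"] = merged[g1].fillna(merged[g2])
    in_both = merged[f"ratio_{r1}"].notna() & merged[f"ratio_{r2}"].notna()
    d1 = merged[f"direction_{r1}"]
    d2 = merged[f"direction_{r2}"]
    agree_up = in_both & (d1 == Direction.UP.value) & (d2 == Direction.UP.value)
    agree_down = in_both & (d1 == Direction.DOWN.value) & (d2 == Direction.DOWN.value)
    merged["direction"] = np.where(
        agree_up, Direction.UP.value,
        np.where(agree_down, Direction.DOWN.value, Direction.UNCHANGED.value),
    )
    # geometric mean of the two raw ratios = 2^(mean of the log2 ratios)
    merged["average_ratio"] = np.where(
        in_both,
        2.0 ** ((merged[f"log2_ratio_{r1}"] + merged[f"log2_ratio_{r2}"]) / 2.0),
        np.nan,
    )
    rank1 = merged[f"tier_{r1}"].map(lambda v: _TIER_RANK.get(Tier(v), 0) if pd.notna(v) else 0)
    rank2 = merged[f"tier_{r2}"].map(lambda v: _TIER_RANK.get(Tier(v), 0) if pd.notna(v) else 0)
    weaker = np.minimum(rank1.to_numpy(), rank2.to_numpy())
    rank_to_tier = {v: k.value for k, v in _TIER_RANK.items()}
    merged["tier"] = [rank_to_tier[int(v)] for v in weaker]
    merged.loc[merged["direction"] == Direction.UNCHANGED.value, "tier"] = Tier.NONE.value
    cols = (
        ["gene_name"]
        + [f"{c}_{r}" for r in (r1, r2) for c in ("ratio", "log2_ratio", "z", "direction", "tier")]
        + ["direction", "tier", "average_ratio"]
    )
    out = merged[cols].copy()
    out.index.name = "accession"
    return out


def rank_top(calls: pd.DataFrame, direction: Direction | str, n: int = 10) -> pd.DataFrame:
    """Top-n regulated proteins by average ratio.

    Up: largest average ratios first; down: smallest first.  Ties are broken
    by accession lexicographic order so rankings are deterministic.
    """
    direction = Direction(direction)
    if direction is Direction.UNCHANGED:
        raise InputError("rank_top expects direction 'up' or 'down'")
    subset = calls[calls["direction"] == direction.value].copy()
    ascending = direction is Direction.DOWN
    # stable sort after an index pre-sort → ties resolved by accession order
    subset = subset.sort_index().sort_values(
        by="average_ratio", ascending=ascending, kind="mergesort"
    )
    return subset.head(n)
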