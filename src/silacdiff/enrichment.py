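"""Gene-set over-representation testing for regulated-protein lists.

Given the set of proteins called regulated (the hits) and a background
universe — by default all quality-filtered quantified proteins of the
experiment, not the whole genome — each gene set is tested for
over-representation with a one-sided Fisher's exact test (equivalently the
hypergeometric upper tail), and p-values are adjusted across sets with the
Benjamini–Hochberg step-up procedure.  Identifier matching is
case-insensitive exact string matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import InputError
from .io import GeneSetCollection
from .regulation import Direction

__all__ = [
    "EnrichmentResult",
    "fisher_enrichment",
    "bh_fdr",
    "direction_summary",
    "enrichment_table",
]


@dataclass
class EnrichmentResult:
    """Over-representation outcome for one gene set."""

    set_name: str
    overlap: int
    set_size_in_universe: int
    hits: int
    universe: int
    p_value: float
    q_value: float | None = None
    overlap_members: frozenset[str] = field(default_factory=frozenset)
    direction_label: str | None = None
    n_up: int = 0
    n_down: int = 0

    def __post_init__(self) -> None:
        if self.overlap > min(self.set_size_in_universe, self.hits):
            raise InputError("overlap exceeds its margins")
        if not 0 <= self.p_value <= 1:
            raise InputError("p-value outside [0, 1]")


def _norm(ids) -> dict[str, str]:
    """Case-folded id → original id (case-insensitive matching)."""
    return {str(i).casefold(): str(i) for i in ids}


def fisher_enrichment(
    hit_ids: set[str],
    universe_ids: set[str],
    sets: GeneSetCollection,
) -> list[EnrichmentResult]:
    """One-sided over-representation test of every gene set against the hits.

    For a universe of size N containing K members of a set, and n hits of
    which k overlap the set, the p-value is the hypergeometric upper tail
    P(X >= k) — the probability of drawing at least k set members when n
    proteins are sampled from the universe without replacement.  Sets with
    no members in the universe are skipped.
    """
    if not universe_ids:
        raise InputError("universe is empty")
    uni = _norm(universe_ids)
    hits = _norm(hit_ids)
    stray = set(hits) - set(uni)
    if stray:
        raise InputError(
            f"{len(stray)} hit identifiers are not in the universe, e.g. "
            f"{sorted(stray)[:3]}"
        )
    N, n = len(uni), len(hits)
    results = []
    for name, members in sets.sets.items():
        members_in_uni = {m.casefold() for m in members} & set(uni)
        K = len(members_in_uni)
        if K == 0:
            continue
        overlap_keys = members_in_uni & set(hits)
        k = len(overlap_keys)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        results.append(
            EnrichmentResult(
                set_name=name,
                overlap=k,
                set_size_in_universe=K,
                hits=n,
                universe=N,
                p_value=min(p, 1.0),
                overlap_members=frozenset(uni[key] for key in overlap_keys),
            )
        )
    return results


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    Input order is preserved; outputs are monotonicity-enforced and clipped
    to 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def direction_summary(
    result: EnrichmentResult, calls: pd.DataFrame
) -> EnrichmentResult:
    """Annotate a result with up/down counts among its overlapping proteins.

    A set is labelled "up" ("down") when every overlapping member is called
    up (down), otherwise "mixed" ("none" for empty overlap).  ``calls`` is a
    combined-call frame indexed by accession with a ``direction`` column;
    matching against gene names is case-insensitive.
    """
    by_acc = {str(a).casefold(): d for a, d in calls["direction"].items()}
    if "gene_name" in calls.columns:
        for acc, row in calls.iterrows():
            g = str(row["gene_name"]).casefold()
            if g and g != "nan" and g not in by_acc:
                by_acc[g] = row["direction"]
    n_up = sum(
        1 for m in result.overlap_members
        if by_acc.get(str(m).casefold()) == Direction.UP.value
    )
    n_down = sum(
        1 for m in result.overlap_members
        if by_acc.get(str(m).casefold()) == Direction.DOWN.value
    )
    if result.overlap == 0:
        label = "none"
    elif n_up == result.overlap:
        label = "up"
    elif n_down == result.overlap:
        label = "down"
    else:
        label = "mixed"
    result.n_up = n_up
    result.n_down = n_down
    result.direction_label = label
    return result


def enrichment_table(
    hit_ids: set[str],
    universe_ids: set[str],
    sets: GeneSetCollection,
    calls: pd.DataFrame | None = None,
    q_cut: float = 0.05,
) -> pd.DataFrame:
    """Full over-representation analysis as one tidy table.

    Runs :func:`fisher_enrichment`, attaches BH q-values, optionally
    annotates direction composition from a call table, and sorts by q then
    p then set name.  ``significant`` marks sets with q < ``q_cut``
    (FDR < 0.05 by default).
    """
    results = fisher_enrichment(hit_ids, universe_ids, sets)
    if not results:
        return pd.DataFrame(
            columns=["set_name", "overlap", "set_size_in_universe", "hits",
                     "universe", "p_value", "q_value", "significant",
                     "direction", "n_up", "n_down", "members"]
        )
    q = bh_fdr([r.p_value for r in results])
    for r, qv in zip(results, q):
        r.q_value = float(qv)
        if calls is not None:
            direction_summary(r, calls)
    df = pd.DataFrame(
        {
            "set_name": [r.set_name for r in results],
            "overlap": [r.overlap for r in results],
            "set_size_in_universe": [r.set_size_in_universe for r in results],
            "hits": [r.hits for r in results],
            "universe": [r.universe for r in results],
            "p_value": [r.p_value for r in results],
            "q_value": [r.q_value for r in results],
            "significant": [r.q_value < q_cut for r in results],
            "direction": [r.direction_label for r in results],
            "n_up": [r.n_up for r in results],
            "n_down": [r.n_down for r in results],
            "members": [";".join(sorted(r.overlap_members)) for r in results],
        }
    )
    return df.sort_values(["q_value", "p_value", "set_name"], kind="mergesort").reset_index(
        drop=True
    )
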