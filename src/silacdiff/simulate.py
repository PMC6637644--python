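"""Synthetic SILAC co-culture datasets with known ground truth.

The generator emulates the structure of a two-replicate SILAC co-culture
comparison at proteome scale: a few thousand protein groups whose null log2
H/X ratios scatter around zero (ratios log-normal around 1), a small
fraction of truly regulated proteins whose log2 effect is shared between
replicates, independent per-replicate noise, randomly missing ratio cells,
and appended contaminant/decoy rows.  Decoy rows draw their ratios from the
null distribution, so a pipeline that fails to filter them perturbs its
population statistics measurably.

Per protein ``i`` and replicate ``r``::

    observed log2 ratio = delta_i + N(0, null_sd_log2) + N(0, replicate_noise_sd_log2)

with ``delta_i`` = 0 for null proteins and ±|N(effect_log2_mean,
effect_log2_sd)| for up/down proteins; the exported raw ratio is
``2**observed``.  Identical configs (including the seed) yield identical
tables.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .io import ProteinRecord, QuantTable
from .regulation import Direction

__all__ = ["SimulationConfig", "simulate_experiment", "evaluate_calls"]


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings; defaults emulate one comparison of the co-culture study.

    ``n_proteins`` mirrors the ~5,500–6,000 proteins quantified per
    comparison.  Regulated fractions default to ~1% up / ~1.5% down, the
    order of magnitude the study reports after intersection.  Effects are
    log2 fold changes (mean 2 ≈ 4-fold); ``null_sd_log2`` is the spread of
    the unregulated log2-ratio population and ``replicate_noise_sd_log2``
    additional technical scatter per replicate.  ``n_extreme`` spikes that
    many extra up-proteins with |log2 effect| ≥ 7 (ratios in the hundreds,
    as the most extreme validated proteins showed) to stress-test SD
    inflation.
    """

    n_proteins: int = 5500
    frac_up: float = 0.01
    frac_down: float = 0.015
    effect_log2_mean: float = 2.0
    effect_log2_sd: float = 0.5
    null_sd_log2: float = 0.5
    replicate_noise_sd_log2: float = 0.2
    missing_rate: float = 0.05
    contaminant_rate: float = 0.02
    reverse_rate: float = 0.01
    n_replicates: int = 2
    n_extreme: int = 0
    extreme_log2_effect: float = 7.5
    comparison: str = "SIM H/M"
    seed: int = 0

    def __post_init__(self) -> None:
        problems = []
        if self.n_proteins < 10:
            problems.append("n_proteins must be >= 10")
        if not (0 <= self.frac_up < 1 and 0 <= self.frac_down < 1):
            problems.append("frac_up/frac_down must lie in [0, 1)")
        if self.frac_up + self.frac_down >= 1:
            problems.append("frac_up + frac_down must be < 1")
        if self.effect_log2_mean < 0 or self.effect_log2_sd < 0:
            problems.append("effect_log2_mean/sd must be non-negative")
        if self.null_sd_log2 <= 0:
            problems.append("null_sd_log2 must be positive")
        if self.replicate_noise_sd_log2 < 0:
            problems.append("replicate_noise_sd_log2 must be non-negative")
        for name in ("missing_rate", "contaminant_rate", "reverse_rate"):
            if not 0 <= getattr(self, name) < 1:
                problems.append(f"{name} must lie in [0, 1)")
        if self.n_replicates != 2:
            problems.append("n_replicates is fixed at 2 for this design")
        if self.n_extreme < 0 or abs(self.extreme_log2_effect) < 7:
            problems.append("n_extreme >= 0 and |extreme_log2_effect| >= 7 required")
        if problems:
            raise InputError("invalid simulation config: " + "; ".join(problems))

    def to_dict(self) -> dict:
        return asdict(self)


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[dict[str, QuantTable], pd.DataFrame]:
    """Generate per-replicate quantification tables plus a ground-truth table.

    Returns ``(tables, truth)`` where ``tables`` maps replicate id ("rep1",
    "rep2") to a :class:`QuantTable` in the same dialect ``quant_io`` reads,
    and ``truth`` is a DataFrame indexed by accession with
    ``true_direction`` ("up"/"down"/"null") and ``true_log2_effect``.
    Decoy/contaminant rows appear in the tables but not in the truth.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    n_up = int(round(n * config.frac_up))
    n_down = int(round(n * config.frac_down))

    width = max(5, len(str(n)))
    accessions = np.array([f"SIM{i:0{width}d}" for i in range(1, n + 1)])
    genes = np.array([f"G{i}" for i in range(1, n + 1)])

    delta = np.zeros(n)
    delta[:n_up] = np.abs(
        rng.normal(config.effect_log2_mean, config.effect_log2_sd, n_up)
    )
    delta[n_up : n_up + n_down] = -np.abs(
        rng.normal(config.effect_log2_mean, config.effect_log2_sd, n_down)
    )
    direction = np.array(
        [Direction.UP.value] * n_up
        + [Direction.DOWN.value] * n_down
        + ["null"] * (n - n_up - n_down)
    )
    if config.n_extreme:
        extra_acc = np.array(
            [f"SIMX{i:0{width}d}" for i in range(1, config.n_extreme + 1)]
        )
        accessions = np.concatenate([accessions, extra_acc])
        genes = np.concatenate(
            [genes, np.array([f"GX{i}" for i in range(1, config.n_extreme + 1)])]
        )
        delta = np.concatenate([delta, np.full(config.n_extreme, config.extreme_log2_effect)])
        direction = np.concatenate(
            [direction, np.array([Direction.UP.value] * config.n_extreme)]
        )
    n_total = accessions.size

    n_contam = int(round(n * config.contaminant_rate))
    n_reverse = int(round(n * config.reverse_rate))

    tables: dict[str, QuantTable] = {}
    for r in range(1, config.n_replicates + 1):
        observed = (
            delta
            + rng.normal(0.0, config.null_sd_log2, n_total)
            + rng.normal(0.0, config.replicate_noise_sd_log2, n_total)
        )
        ratios = 2.0**observed
        missing = rng.random(n_total) < config.missing_rate
        records = [
            ProteinRecord(
                accession=acc,
                gene_name=g,
                description=f"Synthetic protein {g}",
                ratio=None if miss else float(ratio),
            )
            for acc, g, ratio, miss in zip(accessions, genes, ratios, missing)
        ]
        # decoys draw from the null ratio distribution: leaving them in
        # visibly shifts population statistics downstream
        decoy_log2 = rng.normal(
            0.0,
            np.hypot(config.null_sd_log2, config.replicate_noise_sd_log2),
            n_contam + n_reverse,
        )
        for j in range(n_contam):
            records.append(
                ProteinRecord(
                    accession=f"CON{j + 1:04d}",
                    gene_name=f"CONG{j + 1}",
                    description="Synthetic contaminant",
                    ratio=float(2.0 ** decoy_log2[j]),
                    is_contaminant=True,
                )
            )
        for j in range(n_reverse):
            records.append(
                ProteinRecord(
                    accession=f"REV{j + 1:04d}",
                    gene_name=f"REVG{j + 1}",
                    description="Synthetic reversed-sequence decoy",
                    ratio=float(2.0 ** decoy_log2[n_contam + j]),
                    is_reverse=True,
                )
            )
        tables[f"rep{r}"] = QuantTable(
            records=records,
            comparison=config.comparison,
            replicate=f"rep{r}",
            channel_scheme="heavy_over_medium"
            if "H/M" in config.comparison.upper()
            else "heavy_over_light",
            provenance=f"simulated (seed={config.seed})",
        )

    truth = pd.DataFrame(
        {
            "true_direction": direction,
            "true_log2_effect": delta,
        },
        index=pd.Index(accessions, name="accession"),
    )
    return tables, truth


def evaluate_calls(calls: pd.DataFrame, truth: pd.DataFrame) -> dict[str, float]:
    """Score final regulation calls against simulation ground truth.

    ``sensitivity``: truly regulated proteins called with the correct
    direction, over all truly regulated.  ``fdp``: truly null proteins among
    all called-regulated (0 when nothing is called).  ``specificity``: nulls
    not called regulated, over all nulls.  ``direction_accuracy``: among
    truly regulated proteins that were called at all, the fraction whose
    direction is right.  Decoy rows (absent from the truth) are ignored.
    """
    common = calls.index.intersection(truth.index)
    if common.empty:
        raise InputError("no accessions shared between calls and truth")
    c = calls.loc[common, "direction"]
    t = truth.loc[common, "true_direction"]
    called = c != Direction.UNCHANGED.value
    regulated = t != "null"
    correct = called & regulated & (c == t)
    n_called = int(called.sum())
    n_reg = int(regulated.sum())
    n_null = int((~regulated).sum())
    metrics = {
        "sensitivity": float(correct.sum() / n_reg) if n_reg else 0.0,
        "fdp": float((called & ~regulated).sum() / n_called) if n_called else 0.0,
        "specificity": float((~called & ~regulated).sum() / n_null) if n_null else 1.0,
        "direction_accuracy": (
            float(correct.sum() / (called & regulated).sum())
            if int((called & regulated).sum())
            else 0.0
        ),
        "n_called": float(n_called),
        "n_regulated_true": float(n_reg),
    }
    return metrics
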