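"""End-to-end orchestration: simulate/read → filter → score → combine → enrich → report."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, InputError, PipelineError
from .io import (
    QuantTable,
    filter_quality,
    read_gmt,
    read_protein_groups,
    write_quant_table,
    write_table,
)
from .regulation import (
    Direction,
    Thresholds,
    combine_replicates,
    rank_top,
    score_replicate,
)
from .enrichment import enrichment_table
from .simulate import SimulationConfig, evaluate_calls, simulate_experiment

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One pipeline run: either two input tables or a simulation config."""

    out_dir: Path
    input_rep1: Path | None = None
    input_rep2: Path | None = None
    comparison: str = "SIM H/M"
    simulation: SimulationConfig | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    gmt: Path | None = None
    q_cut: float = 0.05
    top_n: int = 10
    universe: str = "quantified"  # background = all quality-filtered proteins
    make_plot: bool = True

    def __post_init__(self) -> None:
        have_inputs = self.input_rep1 is not None or self.input_rep2 is not None
        if have_inputs and (self.input_rep1 is None or self.input_rep2 is None):
            raise ConfigurationError(
                "exactly 2 replicate input tables are required (got 1)"
            )
        if have_inputs == (self.simulation is not None):
            raise ConfigurationError(
                "provide either two input tables or a simulation config, not both/neither"
            )
        if self.universe not in ("quantified", "custom"):
            raise ConfigurationError("universe must be 'quantified' or 'custom'")


def scatter_plot(calls: pd.DataFrame, path: str | Path, thresholds: Thresholds | None = None) -> None:
    """Replicate-1 vs replicate-2 log2 ratios, coloured by final call.

    Guide lines mark ±log2_cut (the fold criterion) on both axes; up, down
    and unchanged proteins use three distinguishable colours.
    """
    t = thresholds or Thresholds()
    lr_cols = [c for c in calls.columns if c.startswith("log2_ratio_")]
    if len(lr_cols) != 2:
        raise InputError("calls table must carry two per-replicate log2_ratio columns")
    both = calls.dropna(subset=lr_cols)
    if both.empty:
        raise InputError("no proteins quantified in both replicates to plot")
    x, y = both[lr_cols[0]], both[lr_cols[1]]
    colors = {"up": "#d62728", "down": "#1f77b4", "unchanged": "#bbbbbb"}
    fig, ax = plt.subplots(figsize=(5.5, 5.5))
    for direction in ("unchanged", "down", "up"):
        mask = both["direction"] == direction
        ax.scatter(
            x[mask], y[mask], s=6, alpha=0.6, lw=0,
            color=colors[direction],
            label=f"{direction} (n={int(mask.sum())})",
        )
    for cut in (t.log2_cut, -t.log2_cut):
        ax.axvline(cut, color="k", lw=0.6, ls="--")
        ax.axhline(cut, color="k", lw=0.6, ls="--")
    ax.set_xlabel(f"log2 H/X ratio, {lr_cols[0].removeprefix('log2_ratio_')}")
    ax.set_ylabel(f"log2 H/X ratio, {lr_cols[1].removeprefix('log2_ratio_')}")
    ax.legend(frameon=False, fontsize=8)
    ax.set_title("Normalized protein expression across replicates")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def run_analysis(config: RunConfig) -> dict:
    """Execute the full pipeline and write a result bundle into ``out_dir``.

    Writes the combined call table, top-N up/down tables, an enrichment
    table (when a GMT file is given), the replicate scatter plot and a run
    log with thresholds and per-stage counts.  Deterministic given inputs
    and config; on error, partial outputs are removed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("silacdiff")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    written.append(log_path)

    def _emit(df, name: str) -> Path:
        p = out / name
        write_table(df, p)
        written.append(p)
        return p

    try:
        logger.info("silacdiff %s", __version__)
        logger.info("thresholds: %s", config.thresholds)

        stage = "input"
        truth = None
        if config.simulation is not None:
            tables, truth = simulate_experiment(config.simulation)
            for rep, tab in tables.items():
                p = out / f"simulated_{rep}.tsv"
                write_quant_table(tab, p)
                written.append(p)
            _emit(truth.reset_index(), "truth.tsv")
            cfg_path = out / "simulation_config.yaml"
            cfg_path.write_text(yaml.safe_dump(config.simulation.to_dict()))
            written.append(cfg_path)
        else:
            tables = {
                "rep1": read_protein_groups(
                    config.input_rep1, comparison=config.comparison, replicate="rep1"
                ),
                "rep2": read_protein_groups(
                    config.input_rep2, comparison=config.comparison, replicate="rep2"
                ),
            }
        parsed_counts = {r: len(t) for r, t in tables.items()}
        logger.info("parsed: %s", parsed_counts)

        stage = "filter"
        filtered = {r: filter_quality(t) for r, t in tables.items()}
        filtered_counts = {r: len(t) for r, t in filtered.items()}
        logger.info("filtered: %s", filtered_counts)

        stage = "score"
        scored = {
            r: score_replicate(t, thresholds=config.thresholds)
            for r, t in filtered.items()
        }

        stage = "combine"
        calls = combine_replicates(scored)
        n_up = int((calls["direction"] == Direction.UP.value).sum())
        n_down = int((calls["direction"] == Direction.DOWN.value).sum())
        logger.info("called: %d up, %d down, %d total proteins", n_up, n_down, len(calls))
        _emit(calls.reset_index(), "calls.tsv")
        _emit(rank_top(calls, "up", config.top_n).reset_index(), "top_up.tsv")
        _emit(rank_top(calls, "down", config.top_n).reset_index(), "top_down.tsv")

        enrich = None
        if config.gmt is not None:
            stage = "enrich"
            sets = read_gmt(config.gmt)
            hits = set(calls.index[calls["direction"] != Direction.UNCHANGED.value])
            universe = (
                set(sets.universe)
                if config.universe == "custom" and sets.universe
                else set(calls.index)
            )
            enrich = enrichment_table(hits, universe, sets, calls=calls, q_cut=config.q_cut)
            _emit(enrich, "enrichment.tsv")
            logger.info(
                "enrichment: %d sets tested, %d significant at q<%g",
                len(enrich), int(enrich["significant"].sum()) if len(enrich) else 0,
                config.q_cut,
            )

        if config.make_plot:
            stage = "plot"
            plot_path = out / "scatter.png"
            scatter_plot(calls, plot_path, config.thresholds)
            written.append(plot_path)

        metrics = None
        if truth is not None:
            stage = "evaluate"
            metrics = evaluate_calls(calls, truth)
            logger.info("evaluation vs truth: %s", metrics)

        return {
            "calls": calls,
            "scored": scored,
            "enrichment": enrich,
            "truth": truth,
            "metrics": metrics,
            "counts": {
                "parsed": parsed_counts,
                "filtered": filtered_counts,
                "up": n_up,
                "down": n_down,
            },
            "out_dir": out,
        }
    except Exception as exc:
        root.removeHandler(handler)
        handler.close()
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        if handler in root.handlers:
            root.removeHandler(handler)
            handler.close()
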