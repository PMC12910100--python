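"""Full factorial simulation: shapes x strategies x procedures x noise x
knowledge x extremes x repetitions.

Each repetition runs the per-row pipeline
place -> draw -> select model -> predict -> score
and contributes one row to a tidy results table.  Seeding is hierarchical:
every (cell, repetition) pair gets its own child seed derived from the
master seed by counter, so any single run is re-creatable in isolation and
an interrupted grid can resume without recomputing completed cells.

A *cell* is one combination of the factor levels; repetitions within a cell
differ only in the random placement (for random/preferential strategies)
and the noise draws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import designs, fitpredict, metrics, observe
from .config import RunConfig
from .designs import PREFERENTIAL_MODES, SamplingProcedure
from .shapes import ResponseShape, default_registry

__all__ = ["ScenarioCell", "run_grid", "summarize_grid", "RESULT_COLUMNS"]

logger = logging.getLogger("gradsim")

RESULT_COLUMNS = [
    "shape",
    "strategy",
    "n_total",
    "n_locations",
    "n_replicates",
    "noise",
    "knowledge",
    "extremes",
    "rep",
    "seed",
    "selected_order",
    "r2_multiple",
    "chalcraft_ps",
    "neg_rmse",
    "failed",
]

#: factor columns identifying a cell (everything but rep/seed/outputs)
CELL_COLUMNS = RESULT_COLUMNS[:8]

_DETERMINISTIC_STRATEGIES = ("systematic", "log_systematic")


@dataclass(frozen=True)
class ScenarioCell:
    """One combination of the experimental factor levels."""

    shape_id: str
    strategy_id: str
    procedure: SamplingProcedure
    noise_level: float
    knowledge: str
    extremes: str  # "with" / "without"

    def key(self) -> tuple:
        return (
            self.shape_id,
            self.strategy_id,
            self.procedure.n_total,
            self.procedure.n_locations,
            self.procedure.n_replicates,
            self.noise_level,
            self.knowledge,
            self.extremes,
        )


def enumerate_cells(config: RunConfig) -> List[ScenarioCell]:
    """Cells in the fixed enumeration order that the seeding relies on."""
    procs = designs.enumerate_procedures(
        config.totals, config.min_locations, config.max_replicates
    )
    cells = []
    for shape_id in config.shapes:
        for strategy_id in config.strategies:
            for proc in procs:
                for noise in config.noise_levels:
                    for knowledge in config.knowledge:
                        for extremes in config.extremes:
                            cells.append(
                                ScenarioCell(shape_id, strategy_id, proc, noise, knowledge, extremes)
                            )
    return cells


def _cell_seed_sequence(master_seed: int, cell_index: int, rep: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(cell_index, rep))


def _run_cell(
    cell: ScenarioCell,
    cell_index: int,
    config: RunConfig,
    shape: ResponseShape,
    noise: observe.NoiseModel,
    known_order: Optional[int],
) -> Dict[str, np.ndarray]:
    """All repetitions of one cell; returns column arrays."""
    reps = config.reps
    proc = cell.procedure
    deterministic_place = cell.strategy_id in _DETERMINISTIC_STRATEGIES
    extremes_included = cell.extremes == "with"
    placement = None
    if deterministic_place:
        placement = designs.place_locations(
            cell.strategy_id,
            proc,
            shape=shape,
            extremes_included=extremes_included,
            candidate_grid_size=config.candidate_grid_size,
            weight_floor=config.weight_floor,
        )

    seed_col = np.empty(reps, dtype=np.int64)
    order_col = np.zeros(reps, dtype=np.int64)
    r2_col = np.full(reps, np.nan)
    ps_col = np.full(reps, np.nan)
    rmse_col = np.full(reps, np.nan)
    failed_col = np.zeros(reps, dtype=bool)

    for rep in range(reps):
        ss = _cell_seed_sequence(config.master_seed, cell_index, rep)
        seed_col[rep] = int(ss.generate_state(1)[0]) & 0x7FFFFFFF
        rng = np.random.default_rng(ss)
        try:
            pl = placement
            if pl is None:
                pl = designs.place_locations(
                    cell.strategy_id,
                    proc,
                    shape=shape,
                    extremes_included=extremes_included,
                    rng=rng,
                    candidate_grid_size=config.candidate_grid_size,
                    weight_floor=config.weight_floor,
                )
            samples = observe.draw_samples(shape, pl, proc.n_replicates, noise, rng)
            fit = fitpredict.select_model(
                samples,
                knowledge=cell.knowledge,
                shape=shape,
                max_order=config.max_order,
                known_order=known_order,
            )
            grid = fitpredict.predict_curve(fit, shape, grid_size=config.eval_grid_size)
            scores = metrics.score_grid(grid, ps_normalizer=config.ps_normalizer)
        except (ValueError, np.linalg.LinAlgError) as err:
            failed_col[rep] = True
            logger.debug("cell %d rep %d failed: %s", cell_index, rep, err)
            continue
        order_col[rep] = fit.order
        r2_col[rep] = scores.r2_multiple
        ps_col[rep] = scores.chalcraft_ps
        rmse_col[rep] = scores.neg_rmse
    return {
        "rep": np.arange(reps, dtype=np.int64),
        "seed": seed_col,
        "selected_order": order_col,
        "r2_multiple": r2_col,
        "chalcraft_ps": ps_col,
        "neg_rmse": rmse_col,
        "failed": failed_col,
    }


def _cell_frame(cell: ScenarioCell, data: Dict[str, np.ndarray]) -> pd.DataFrame:
    reps = data["rep"].size
    frame = {
        "shape": np.repeat(cell.shape_id, reps),
        "strategy": np.repeat(cell.strategy_id, reps),
        "n_total": np.repeat(cell.procedure.n_total, reps),
        "n_locations": np.repeat(cell.procedure.n_locations, reps),
        "n_replicates": np.repeat(cell.procedure.n_replicates, reps),
        "noise": np.repeat(cell.noise_level, reps),
        "knowledge": np.repeat(cell.knowledge, reps),
        "extremes": np.repeat(cell.extremes, reps),
    }
    frame.update(data)
    return pd.DataFrame(frame, columns=RESULT_COLUMNS)


def _completed_cells(out_path: Path, reps: int) -> Tuple[pd.DataFrame, set]:
    """Rows of complete cells already present in an interrupted output file."""
    existing = pd.read_csv(out_path)
    missing = [c for c in RESULT_COLUMNS if c not in existing.columns]
    if missing:
        raise ValueError(f"cannot resume from {out_path}: missing columns {missing}")
    counts = existing.groupby(CELL_COLUMNS, sort=False).size()
    done_keys = set(counts[counts >= reps].index)
    keep = existing.set_index(CELL_COLUMNS).loc[list(done_keys)].reset_index() if done_keys else existing.iloc[0:0]
    return keep[RESULT_COLUMNS], done_keys


def run_grid(
    config: RunConfig,
    out_path=None,
    resume: bool = False,
    progress_every: int = 500,
) -> pd.DataFrame:
    """Run the full factorial simulation and return the tidy results table.

    With ``out_path`` set, per-cell chunks are appended to a CSV as they
    complete; with ``resume=True`` cells already complete in that file are
    kept as-is and skipped.  Deterministic under ``config.master_seed``.
    """
    registry = default_registry()
    cells = enumerate_cells(config)
    noise_models = {
        (shape_id, lvl): observe.make_noise_model(
            registry[shape_id], lvl, config.sd_floor_fraction
        )
        for shape_id in config.shapes
        for lvl in config.noise_levels
    }
    known_orders = {
        shape_id: config.known_order_overrides.get(
            shape_id, fitpredict.nominal_order(registry[shape_id], config.max_order)
        )
        for shape_id in config.shapes
    }

    out_file = Path(out_path) if out_path is not None else None
    done_keys: set = set()
    kept: Optional[pd.DataFrame] = None
    if out_file is not None and resume and out_file.exists():
        kept, done_keys = _completed_cells(out_file, config.reps)
        logger.info("resuming: %d completed cells found", len(done_keys))
        kept.to_csv(out_file, index=False)  # drop partial chunks
    elif out_file is not None:
        out_file.parent.mkdir(parents=True, exist_ok=True)
        out_file.write_text(",".join(RESULT_COLUMNS) + "\n")

    chunks: List[pd.DataFrame] = []
    n_failed = 0
    for idx, cell in enumerate(cells):
        if cell.key() in done_keys:
            continue
        data = _run_cell(
            cell,
            idx,
            config,
            registry[cell.shape_id],
            noise_models[(cell.shape_id, cell.noise_level)],
            known_orders[cell.shape_id],
        )
        n_failed += int(data["failed"].sum())
        frame = _cell_frame(cell, data)
        if out_file is not None:
            frame.to_csv(out_file, mode="a", header=False, index=False)
        chunks.append(frame)
        if progress_every and (idx + 1) % progress_every == 0:
            logger.info("cells %d/%d done", idx + 1, len(cells))

    parts = ([kept] if kept is not None and len(kept) else []) + chunks
    result = pd.concat(parts, ignore_index=True) if parts else _cell_frame(cells[0], _empty())
    if n_failed:
        logger.info("%d repetitions flagged as failed fits", n_failed)
    return result


def _empty() -> Dict[str, np.ndarray]:  # pragma: no cover - degenerate guard
    return {
        "rep": np.empty(0, dtype=np.int64),
        "seed": np.empty(0, dtype=np.int64),
        "selected_order": np.empty(0, dtype=np.int64),
        "r2_multiple": np.empty(0),
        "chalcraft_ps": np.empty(0),
        "neg_rmse": np.empty(0),
        "failed": np.empty(0, dtype=bool),
    }


def aggregate_cells(results: pd.DataFrame) -> pd.DataFrame:
    """Monte-Carlo mean accuracy per cell, in results-table layout.

    Collapses the repetitions of each factor combination to their mean, so
    downstream explained-variance analyses describe how the *expected*
    accuracy of a design responds to the factors rather than mixing in
    repetition-level simulation scatter.
    """
    df = results[~results["failed"].astype(bool)]
    out = (
        df.groupby(CELL_COLUMNS, sort=True, observed=True)[list(metrics.METRIC_NAMES)]
        .mean()
        .reset_index()
    )
    out["rep"] = 0
    out["failed"] = False
    return out


def summarize_grid(
    results: pd.DataFrame,
    by: Optional[List[str]] = None,
    drop_failed: bool = True,
) -> pd.DataFrame:
    """Per-cell mean, standard deviation and count of each accuracy metric."""
    if results.empty:
        raise ValueError("results table is empty")
    if by is None:
        by = CELL_COLUMNS
    df = results[~results["failed"]] if drop_failed else results
    agg = df.groupby(by, sort=True, observed=True)[list(metrics.METRIC_NAMES)].agg(
        ["mean", "std", "count"]
    )
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    return agg.reset_index()
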