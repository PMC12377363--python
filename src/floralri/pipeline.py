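"""End-to-end orchestration: raw CSVs -> barrier strengths -> isolation table.

The pipeline runs whichever analysis stages have inputs (phenology,
morphology, crossing), assembles the measured directional barrier
strengths in life-cycle order, and applies the sequential contribution
calculus.  Partial runs succeed with warnings for missing stages; every
output and skipped stage is recorded in a machine-readable run summary.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from itertools import permutations
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from ._rounding import round_half_up
from .crossing import postmating_panel, summarize_crosses
from .errors import FloralRIError
from .morphology import assign_mechanical_ri, pairwise_permanova, pca_floral, permanova
from .phenology import phenology_ri_table
from .sequential import BARRIER_ORDER, build_barrier_table, category_means

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of a pipeline run (mirrors the YAML config file)."""

    phenology: str | None = None
    morphology: str | None = None
    positions: str | None = None
    crosses: str | None = None
    seeds: str | None = None
    germination: str | None = None
    barriers: str | None = None          # pre-assembled strengths, bypasses stages
    out: str = "floralri_out"
    seed: int = 0
    n_permutations: int = 999
    digits: int = 3
    barrier_order: tuple[str, ...] = BARRIER_ORDER

    def __post_init__(self):
        if self.digits < 0:
            raise ValueError("digits must be >= 0")
        if set(self.barrier_order) - set(BARRIER_ORDER):
            raise ValueError(f"unknown barriers in order override: {self.barrier_order}")

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        inputs = data.get("inputs", {})
        kwargs = {k: inputs.get(k) for k in
                  ("phenology", "morphology", "positions", "crosses",
                   "seeds", "germination", "barriers")}
        for k in ("out", "seed", "n_permutations", "digits"):
            if k in data:
                kwargs[k] = data[k]
        if "barrier_order" in data:
            kwargs["barrier_order"] = tuple(data["barrier_order"])
        return cls(**kwargs)


def _round_cols(df: pd.DataFrame, cols: list[str], digits: int) -> pd.DataFrame:
    df = df.copy()
    for c in cols:
        if c in df.columns:
            df[c] = [round_half_up(v, digits) if pd.notna(v) else np.nan for v in df[c]]
    return df


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages and write the report bundle.

    Returns the run summary (also written as ``run_summary.json``).
    """
    out_dir = Path(config.out)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "package": {"floralri": __version__, "numpy": np.__version__,
                    "pandas": pd.__version__, "python": platform.python_version()},
        "seed": config.seed,
        "stages": {},
        "outputs": {},
    }
    barrier_rows: list[pd.DataFrame] = []

    # --- phenology ---------------------------------------------------------
    if config.phenology:
        series = io.read_phenology(config.phenology)
        pheno = phenology_ri_table(series)
        path = io.write_table(_round_cols(pheno, ["H", "C", "ri"], config.digits),
                              out_dir / "phenology_ri.csv")
        summary["stages"]["phenology"] = {
            "inputs": [config.phenology], "n_series": len(series)}
        summary["outputs"]["phenology_ri"] = str(path)
        mean = pheno[pheno["season"] == "mean"]
        barrier_rows.append(pd.DataFrame({
            "recipient": mean["focal"], "donor": mean["other"],
            "barrier": "RI_F", "strength": mean["ri"],
        }))
    else:
        summary["stages"]["phenology"] = "skipped (no input)"
        logger.warning("phenology stage skipped: no census input")

    # --- morphology --------------------------------------------------------
    if config.morphology and config.positions:
        table = io.read_morphology(config.morphology)
        positions = io.read_positions(config.positions)
        glob = permanova(table, n_perm=config.n_permutations, seed=config.seed)
        pairs = pairwise_permanova(table, n_perm=config.n_permutations, seed=config.seed)
        tests = pd.DataFrame([t.__dict__ for t in [glob, *pairs]])
        path = io.write_table(tests, out_dir / "morphology_tests.csv")
        summary["outputs"]["morphology_tests"] = str(path)
        scores, loadings, explained = pca_floral(table)
        io.write_table(scores, out_dir / "pca_scores.csv")
        io.write_table(loadings.reset_index(names="trait"), out_dir / "pca_loadings.csv")
        summary["outputs"]["pca_scores"] = str(out_dir / "pca_scores.csv")
        mech = assign_mechanical_ri(table, positions,
                                    n_perm=config.n_permutations, seed=config.seed)
        path = io.write_table(mech, out_dir / "mechanical_ri.csv")
        summary["outputs"]["mechanical_ri"] = str(path)
        summary["stages"]["morphology"] = {
            "inputs": [config.morphology, config.positions],
            "global_pseudo_f": glob.pseudo_f, "global_r_squared": glob.r_squared,
            "global_p": glob.p_value, "pc1_explained": float(explained[0]),
        }
        # binary indices are symmetric: emit both directions
        directed = []
        for _, row in mech.iterrows():
            for rec, don in permutations([row["species_a"], row["species_b"]]):
                directed.append((rec, don, "RI_MS", float(row["ri_ms"])))
                directed.append((rec, don, "RI_MP", float(row["ri_mp"])))
        barrier_rows.append(pd.DataFrame(
            directed, columns=["recipient", "donor", "barrier", "strength"]))
    else:
        summary["stages"]["morphology"] = "skipped (no input)"
        logger.warning("morphology stage skipped: need both morphology and positions inputs")

    # --- crossing ----------------------------------------------------------
    if config.crosses:
        crosses = io.read_crosses(config.crosses)
        seeds = io.read_seeds(config.seeds) if config.seeds else None
        germ = io.read_germination(config.germination) if config.germination else None
        summaries = summarize_crosses(crosses, seeds, germ)
        io.write_table(_round_cols(summaries, ["fruit_rate", "mean_seeds", "sd_seeds",
                                               "germ_mean", "germ_sd"], config.digits),
                       out_dir / "cross_summaries.csv")
        panel = postmating_panel(summaries)
        path = io.write_table(_round_cols(panel, ["ri"], config.digits),
                              out_dir / "postmating_ri.csv")
        summary["outputs"]["postmating_ri"] = str(path)
        summary["stages"]["crossing"] = {
            "inputs": [p for p in (config.crosses, config.seeds, config.germination) if p],
            "n_pairs": int(panel[["recipient", "donor"]].drop_duplicates().shape[0]),
        }
        measured = panel[panel["measured"]].rename(columns={"ri": "strength"})
        barrier_rows.append(measured[["recipient", "donor", "barrier", "strength"]])
    else:
        summary["stages"]["crossing"] = "skipped (no input)"
        logger.warning("crossing stage skipped: no crossing input")

    # --- sequential --------------------------------------------------------
    if config.barriers:
        barriers = io.read_barriers(config.barriers)
        summary["stages"]["sequence_input"] = config.barriers
    elif barrier_rows:
        barriers = pd.concat(barrier_rows, ignore_index=True)
        barriers = barriers[barriers["barrier"].isin(config.barrier_order)]
        barriers = barriers.dropna(subset=["strength"])
        io.write_table(_round_cols(barriers, ["strength"], config.digits),
                       out_dir / "barriers.csv")
        summary["outputs"]["barriers"] = str(out_dir / "barriers.csv")
    else:
        raise FloralRIError("no analysis stage had inputs; nothing to do")

    table, totals = build_barrier_table(barriers)
    io.write_table(_round_cols(table, ["strength", "ac", "rc"], config.digits),
                   out_dir / "isolation_table.csv")
    io.write_table(_round_cols(totals, ["total"], config.digits),
                   out_dir / "totals.csv")
    summary["outputs"]["isolation_table"] = str(out_dir / "isolation_table.csv")
    summary["outputs"]["totals"] = str(out_dir / "totals.csv")
    try:
        means = category_means(barriers)
        io.write_table(
            pd.DataFrame(sorted(means.items()), columns=["category", "mean_strength"]),
            out_dir / "category_means.csv")
        summary["outputs"]["category_means"] = str(out_dir / "category_means.csv")
    except ValueError as exc:
        logger.warning("category means unavailable: %s", exc)

    with open(out_dir / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
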