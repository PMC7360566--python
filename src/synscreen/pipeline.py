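"""End-to-end orchestration: normalize -> assemble -> fit -> score -> report.

`run_pipeline` consumes a tidy per-well CSV (real or simulated), executes
every analysis stage and writes versioned CSV reports plus a JSON manifest
and a plain-text run log.  Re-running with identical inputs and config
reproduces identical report files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .agreement import CallSet, cv_table, overall_cv, replicate_correlation, unique_calls
from .dose_response import DEFAULT_DOSE_RANGE, auc, fit_4pl, ic_level
from .errors import DesignError, SynscreenError
from .normalize import normalize_dataset
from .screen_model import assemble_dose_matrices, read_screen_csv
from .synergy import (DEFAULT_BIN_EDGES, average_replicates, count_synergies,
                      score_matrix, summaries_frame, summarize)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "report_counts"]


@dataclass
class RunConfig:
    """Thresholds and paths for one pipeline run (defaults as screened)."""

    input_csv: str
    out_dir: str
    readouts: tuple | None = None  # None = every readout present
    synergy_threshold: float = 0.0
    effectiveness_threshold: float = 0.5
    alpha: float = 0.05
    ic_level: float = 0.2
    dose_range: tuple = DEFAULT_DOSE_RANGE
    bin_edges: tuple = DEFAULT_BIN_EDGES
    seed: int = 0


def _stage(log: list, name: str, msg: str) -> None:
    stamp = datetime.now(timezone.utc).isoformat(timespec="seconds")
    line = f"{stamp} [{name}] {msg}"
    log.append(line)
    logger.info("%s", line)


def run_pipeline(config: RunConfig) -> dict:
    """Run every analysis stage; returns the in-memory report bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    bundle: dict = {"config": config}
    try:
        _stage(log, "read", f"reading {config.input_csv}")
        dataset = read_screen_csv(config.input_csv)
        _stage(log, "read", f"{len(dataset)} records, panel {dataset.drug_panel}")

        _stage(log, "normalize", "vehicle normalization per plate/readout/timepoint")
        norm = normalize_dataset(dataset)
        norm.to_csv(out / "normalized.csv", index=False)

        readouts = (tuple(config.readouts) if config.readouts
                    else tuple(sorted(norm["readout"].unique())))
        bio_reps = sorted(norm.loc[norm["role"] == "treatment", "bio_rep"].unique())

        _stage(log, "dose_response", "fitting single-agent curves")
        bundle["dose_response"] = _fit_single_agents(norm, config)
        bundle["dose_response"].to_csv(out / "dose_response.csv", index=False)

        _stage(log, "synergy", f"scoring matrices for readouts {readouts}")
        summaries, long_rows = [], []
        for readout in readouts:
            grids_by_key: dict = {}
            for bio in bio_reps:
                for m in assemble_dose_matrices(norm, readout, int(bio)):
                    if (m.n_tech[1:, 1:] == 0).any():
                        _stage(log, "synergy",
                               f"warning: missing cell(s) in {m.cell_line}/"
                               f"{m.culture_format} {m.drug_a}+{m.drug_b} "
                               f"bio_rep={bio}")
                    key = (m.cell_line, m.culture_format, m.pair)
                    grids_by_key.setdefault(key, []).append(score_matrix(m))
            for key, grids in sorted(grids_by_key.items()):
                avg = average_replicates(grids)
                bundle.setdefault("avg_grids", []).append(avg)
                summaries.append(
                    summarize(avg, effective_viability=config.effectiveness_threshold))
                for i, da in enumerate(avg.doses_a):
                    for j, db in enumerate(avg.doses_b):
                        long_rows.append({
                            "cell_line": avg.cell_line,
                            "culture_format": avg.culture_format,
                            "drug_a": avg.drug_a, "drug_b": avg.drug_b,
                            "readout": readout, "dose_a": da, "dose_b": db,
                            "observed": avg.observed[i, j],
                            "expected": avg.expected[i, j],
                            "excess": avg.excess[i, j],
                            "sd_excess": np.nan if avg.sd is None else avg.sd[i, j],
                            "n_bio": 0 if avg.n_rep is None else int(avg.n_rep[i, j]),
                        })
        bundle["summaries"] = summaries
        summaries_frame(summaries).to_csv(out / "synergy_summary.csv", index=False)
        pd.DataFrame(long_rows).to_csv(out / "synergy_long.csv", index=False)

        _stage(log, "agreement", "callsets, CV and replicate correlations")
        bundle["callsets"] = _build_callsets(summaries)
        callset_rows = [{"readout": cs.readout, "culture_format": cs.culture_format,
                         "cell_line": c, "drug_a": p[0], "drug_b": p[1],
                         "synergistic": True}
                        for cs in bundle["callsets"] for (c, p) in sorted(cs.calls)]
        pd.DataFrame(callset_rows,
                     columns=["readout", "culture_format", "cell_line",
                              "drug_a", "drug_b", "synergistic"]
                     ).to_csv(out / "callsets.csv", index=False)
        if len(bundle["callsets"]) >= 2:
            bundle["unique_calls"] = unique_calls(bundle["callsets"])
        tbl = cv_table(norm)
        tbl.to_csv(out / "cv_conditions.csv", index=False)
        bundle["cv_overall"] = overall_cv(tbl)
        bundle["cv_overall"].to_csv(out / "cv_overall.csv", index=False)
        bundle["repro"] = {}
        for level in ("inter_screen", "intra_screen"):
            try:
                bundle["repro"][level] = replicate_correlation(norm, level)
            except DesignError as exc:
                _stage(log, "agreement", f"{level} correlation skipped: {exc}")
        repro_rows = [{"level": lvl, "key": str(k), "pearson_r": r,
                       "n_pairs": rep.n_pairs[k]}
                      for lvl, rep in bundle["repro"].items()
                      for k, r in rep.pearson_r.items()]
        pd.DataFrame(repro_rows, columns=["level", "key", "pearson_r", "n_pairs"]
                     ).to_csv(out / "replicate_correlations.csv", index=False)

        _stage(log, "report", "design and synergy counts")
        bundle["counts"] = report_counts(bundle)
        with open(out / "counts.json", "w") as fh:
            json.dump(bundle["counts"], fh, indent=2, sort_keys=True)

        manifest = {
            "package": "synscreen", "version": __version__,
            "input_csv": str(config.input_csv), "seed": config.seed,
            "readouts": list(readouts),
            "thresholds": {"synergy": config.synergy_threshold,
                           "effectiveness": config.effectiveness_threshold,
                           "alpha": config.alpha},
            "outputs": sorted(p.name for p in out.glob("*.csv")),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except SynscreenError as exc:
        _stage(log, "error", str(exc))
        (out / "run.log").write_text("\n".join(log) + "\n")
        raise
    (out / "run.log").write_text("\n".join(log) + "\n")
    return bundle


def _fit_single_agents(norm: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """One fitted curve + censored IC + AUC per (cell line, format, drug, readout)."""
    treat = norm[(norm["role"] == "treatment") & (norm["drug_b"] == "")
                 & (norm["dose_a"] > 0)]
    rows = []
    for (cell, fmt, drug, readout), grp in treat.groupby(
            ["cell_line", "culture_format", "drug_a", "readout"]):
        means = grp.groupby("dose_a")["norm_value"].mean()
        if len(means) < 4:
            continue
        fit = fit_4pl(means.index.to_numpy(), means.to_numpy())
        if fit.converged:
            ic = ic_level(fit, level=config.ic_level, dose_range=config.dose_range)
            ic_status, ic_dose = ic.status.value, ic.dose
            auc_value = auc(fit, dose_range=config.dose_range)
        else:
            ic_status, ic_dose, auc_value = "not_converged", None, np.nan
        rows.append({
            "cell_line": cell, "culture_format": fmt, "drug": drug,
            "readout": readout, "lower": fit.lower, "upper": fit.upper,
            "log10_ec50": fit.log10_ec50, "hill": fit.hill, "rss": fit.rss,
            "converged": fit.converged, "ic_level": config.ic_level,
            "ic_status": ic_status, "ic_dose": ic_dose,
            "auc": auc_value,
        })
    return pd.DataFrame(rows, columns=[
        "cell_line", "culture_format", "drug", "readout", "lower", "upper",
        "log10_ec50", "hill", "rss", "converged", "ic_level", "ic_status",
        "ic_dose", "auc"])


def _build_callsets(summaries) -> list[CallSet]:
    by_key: dict = {}
    grid = frozenset((s.cell_line, s.pair) for s in summaries)
    for s in summaries:
        by_key.setdefault((s.readout, s.culture_format), set())
        if s.synergistic:
            by_key[(s.readout, s.culture_format)].add((s.cell_line, s.pair))
    return [CallSet(readout=r, culture_format=f, calls=frozenset(calls), grid=grid)
            for (r, f), calls in sorted(by_key.items())]


def report_counts(bundle: dict, readout: str = "viability") -> dict:
    """Design totals and synergy counts per culture format.

    Reports, for the given readout, the number of combination dose points in
    the design, the number and fraction with Bliss excess < 0, the number of
    combinations synergistic in at least one cell line, and the combinations
    ranked by number of synergistically effective doses.  Denominators are
    derived from the summaries, never hard-coded.
    """
    summaries = [s for s in bundle.get("summaries", []) if s.readout == readout]
    if not summaries:
        raise DesignError(f"no synergy summaries for readout {readout!r}")
    counts: dict = {}
    for fmt in sorted({s.culture_format for s in summaries}):
        fmt_sum = [s for s in summaries if s.culture_format == fmt]
        cell_lines = sorted({s.cell_line for s in fmt_sum})
        pairs = sorted({s.pair for s in fmt_sum})
        syn = count_synergies(fmt_sum)
        # per-dose-point tally from the replicate-averaged grids
        n_points, n_neg = _dose_point_tally(bundle, fmt, readout)
        ranking = sorted(
            ({"cell_line": s.cell_line, "drug_a": s.drug_a, "drug_b": s.drug_b,
              "n_effective": s.n_effective} for s in fmt_sum),
            key=lambda r: (-r["n_effective"], r["drug_a"], r["drug_b"], r["cell_line"]))
        counts[fmt] = {
            "n_cell_lines": len(cell_lines),
            "n_combinations": len(pairs),
            "n_dose_points": n_points,
            "n_dose_points_excess_negative": n_neg,
            "fraction_excess_negative": (n_neg / n_points) if n_points else float("nan"),
            "n_synergistic_combinations":
                syn[fmt]["n_synergistic_combinations"],
            "synergistic_pairs": [list(p) for p in syn[fmt]["synergistic_pairs"]],
            "bliss_excess_bins": {"labels": syn[fmt]["bin_labels"],
                                  "counts": syn[fmt]["bin_counts"]},
            "n_effective_ranking": ranking[:10],
        }
    return counts


def _dose_point_tally(bundle: dict, fmt: str, readout: str) -> tuple[int, int]:
    grids = bundle.get("avg_grids", [])
    n_points = n_neg = 0
    for g in grids:
        if g.culture_format != fmt or g.readout != readout:
            continue
        finite = np.isfinite(g.excess)
        n_points += int(finite.sum())
        n_neg += int((g.excess[finite] < 0).sum())
    return n_points, n_neg
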