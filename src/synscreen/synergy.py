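"""Bliss-independence synergy scoring of pairwise dose matrices.

Under Bliss independence two non-interacting drugs with single-agent effects
E_A and E_B (E = 1 - V, V relative viability) combine to an expected effect

    E_AB = E_A + E_B - E_A * E_B,

equivalently an expected combined viability V_A * V_B.  The *Bliss excess*
is kept on the viability scale throughout,

    excess = V_obs - V_A * V_B,

so that negative values mean more killing than expected (synergy) and
positive values antagonism; the two formulations are algebraically identical.

Scoring is done per biological replicate using the single-agent edges of the
same 5x5 matrix (same plates, same replicate), then averaged cellwise across
replicates.  A combination is *synergistic* when its mean Bliss excess across
the 16 nonzero-dose cells is below 0, and a dose pair is *synergistically
effective* when it is synergistic (excess < 0) and strongly growth-inhibiting
(combination viability at or below 0.5).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DesignError
from .screen_model import DoseMatrix, enumerate_pairs

logger = logging.getLogger(__name__)

__all__ = ["BlissGrid", "SynergySummary", "bliss_expected_effect", "bliss_excess",
           "score_matrix", "average_replicates", "summarize", "count_synergies",
           "summaries_frame", "DEFAULT_BIN_EDGES", "EFFECTIVE_VIABILITY"]

#: Viability at or below which a dose pair counts as "effective".
EFFECTIVE_VIABILITY = 0.5

#: Default interval edges for binning per-combination mean Bliss excess.
DEFAULT_BIN_EDGES = (-0.2, -0.1, -0.05, 0.0, 0.05, 0.1, 0.2)

#: Inputs further than this outside [0, 1] trigger a suspicious-normalization
#: warning before clamping.
_CLAMP_WARN_SLACK = 0.5


def _clamp01(x: float, what: str) -> float:
    x = float(x)
    if x < -_CLAMP_WARN_SLACK or x > 1.0 + _CLAMP_WARN_SLACK:
        logger.warning("%s = %.3g far outside [0, 1]; check normalization", what, x)
    return min(max(x, 0.0), 1.0)


def bliss_expected_effect(e_a: float, e_b: float) -> float:
    """Bliss expected combined effect E_A + E_B - E_A*E_B, inputs clamped to [0, 1]."""
    e_a = _clamp01(e_a, "effect E_A")
    e_b = _clamp01(e_b, "effect E_B")
    return e_a + e_b - e_a * e_b


def bliss_excess(v_obs: float, v_a: float, v_b: float) -> float:
    """Observed minus Bliss-expected combination viability (negative = synergy).

    Single-agent viabilities are clamped to [0, 1] before forming the
    expectation; the observed combination viability is used as measured.
    """
    v_a = _clamp01(v_a, "single-agent viability V_A")
    v_b = _clamp01(v_b, "single-agent viability V_B")
    if v_obs < 0:
        raise DesignError("observed viability must be nonnegative")
    return float(v_obs) - v_a * v_b


@dataclass
class BlissGrid:
    """Per-dose Bliss scoring of one matrix (nonzero-dose cells only).

    ``excess = observed - expected`` cellwise; missing cells are NaN.  After
    :func:`average_replicates`, ``sd`` holds the cellwise standard deviation
    across biological replicates and ``n_rep`` the contributing counts.
    """

    cell_line: str
    culture_format: str
    drug_a: str
    drug_b: str
    doses_a: np.ndarray  # nonzero doses, ascending
    doses_b: np.ndarray
    readout: str
    bio_rep: int | None
    excess: np.ndarray
    observed: np.ndarray
    expected: np.ndarray
    sd: np.ndarray | None = None
    n_rep: np.ndarray | None = None

    @property
    def pair(self) -> tuple[str, str]:
        return (self.drug_a, self.drug_b)


def score_matrix(matrix: DoseMatrix) -> BlissGrid:
    """Score one dose matrix against the Bliss null using its own edges.

    Single-agent viabilities come from the matrix's dose-0 row/column
    (same plate set, same biological replicate), clamped to [0, 1].  A missing
    edge cell renders every combination cell depending on it missing.
    """
    resp = matrix.response
    if resp.shape[0] < 2 or resp.shape[1] < 2:
        raise DesignError("matrix lacks nonzero-dose cells")
    v_a = np.array([_clamp01(v, "edge viability") if np.isfinite(v) else np.nan
                    for v in resp[1:, 0]])
    v_b = np.array([_clamp01(v, "edge viability") if np.isfinite(v) else np.nan
                    for v in resp[0, 1:]])
    expected = np.outer(v_a, v_b)
    observed = resp[1:, 1:].astype(float).copy()
    excess = observed - expected
    return BlissGrid(
        cell_line=matrix.cell_line, culture_format=matrix.culture_format,
        drug_a=matrix.drug_a, drug_b=matrix.drug_b,
        doses_a=matrix.doses_a[1:].copy(), doses_b=matrix.doses_b[1:].copy(),
        readout=matrix.readout, bio_rep=matrix.bio_rep,
        excess=excess, observed=observed, expected=expected)


def average_replicates(grids: Sequence[BlissGrid]) -> BlissGrid:
    """Cellwise mean (and sd, ddof=1) of Bliss grids across biological replicates.

    Cells missing in a replicate are skipped for that replicate; the sd is NaN
    where fewer than two replicates contribute.
    """
    if not grids:
        raise DesignError("no grids to average")
    first = grids[0]
    for g in grids[1:]:
        if (g.pair != first.pair or g.readout != first.readout
                or not np.allclose(g.doses_a, first.doses_a)
                or not np.allclose(g.doses_b, first.doses_b)):
            raise DesignError(f"incompatible dose axes for pair {first.pair}")
    def stack(attr):
        return np.stack([getattr(g, attr) for g in grids])
    ex, ob, xp = stack("excess"), stack("observed"), stack("expected")
    n = np.sum(np.isfinite(ex), axis=0)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # 1-replicate cells
        mean_ex = np.nanmean(np.where(np.isfinite(ex), ex, np.nan), axis=0)
        mean_ob = np.nanmean(np.where(np.isfinite(ob), ob, np.nan), axis=0)
        mean_xp = np.nanmean(np.where(np.isfinite(xp), xp, np.nan), axis=0)
        sd = np.full(mean_ex.shape, np.nan)
        if len(grids) >= 2:
            sd = np.nanstd(np.where(np.isfinite(ex), ex, np.nan), axis=0, ddof=1)
    return BlissGrid(
        cell_line=first.cell_line, culture_format=first.culture_format,
        drug_a=first.drug_a, drug_b=first.drug_b,
        doses_a=first.doses_a.copy(), doses_b=first.doses_b.copy(),
        readout=first.readout, bio_rep=None,
        excess=mean_ex, observed=mean_ob, expected=mean_xp,
        sd=sd, n_rep=n)


@dataclass
class SynergySummary:
    """Matrix-level synergy and viability summary for one combination."""

    cell_line: str
    culture_format: str
    drug_a: str
    drug_b: str
    readout: str
    mean_excess: float
    sd_excess: float
    mean_viability: float
    synergistic: bool
    effective_doses: frozenset  # {(dose_a, dose_b)} with excess < 0 and V <= 0.5
    n_effective: int

    @property
    def pair(self) -> tuple[str, str]:
        return (self.drug_a, self.drug_b)


def summarize(grid: BlissGrid,
              effective_viability: float = EFFECTIVE_VIABILITY) -> SynergySummary:
    """Summarize a scored grid across its nonzero-dose cells.

    ``mean_excess`` and ``mean_viability`` average the combination cells only
    (missing cells skipped).  ``synergistic`` is strict: mean excess < 0.
    ``effective_doses`` collects dose pairs with excess < 0 AND observed
    viability at or below ``effective_viability``.
    """
    finite = np.isfinite(grid.excess)
    if not finite.any():
        raise DesignError(f"all cells missing for pair {grid.pair}")
    mean_excess = float(np.nanmean(grid.excess))
    obs_finite = np.isfinite(grid.observed)
    mean_viability = float(np.nanmean(grid.observed)) if obs_finite.any() else np.nan
    with np.errstate(invalid="ignore"):
        sd_excess = float(np.nanstd(grid.excess, ddof=1)) if finite.sum() > 1 else np.nan
        eff_mask = (grid.excess < 0.0) & (grid.observed <= effective_viability)
    eff_mask &= finite & obs_finite
    ii, jj = np.nonzero(eff_mask)
    effective = frozenset((float(grid.doses_a[i]), float(grid.doses_b[j]))
                          for i, j in zip(ii, jj))
    return SynergySummary(
        cell_line=grid.cell_line, culture_format=grid.culture_format,
        drug_a=grid.drug_a, drug_b=grid.drug_b, readout=grid.readout,
        mean_excess=mean_excess, sd_excess=sd_excess,
        mean_viability=mean_viability,
        synergistic=bool(mean_excess < 0.0),
        effective_doses=effective, n_effective=len(effective))


def summaries_frame(summaries: Sequence[SynergySummary]) -> pd.DataFrame:
    """Tidy one-row-per-combination frame of synergy summaries."""
    return pd.DataFrame([{
        "cell_line": s.cell_line, "culture_format": s.culture_format,
        "drug_a": s.drug_a, "drug_b": s.drug_b, "readout": s.readout,
        "mean_excess": s.mean_excess, "sd_excess": s.sd_excess,
        "mean_viability": s.mean_viability, "synergistic": s.synergistic,
        "n_effective": s.n_effective,
    } for s in summaries])


def count_synergies(summaries: Sequence[SynergySummary],
                    drug_panel: Sequence[str] | None = None,
                    cell_lines: Sequence[str] | None = None,
                    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES) -> dict:
    """Per-format synergy counts with at-least-one-cell-line semantics.

    A combination counts once per culture format if *any* cell line's summary
    flags it synergistic.  Also bins every per-(combination, cell line) mean
    excess into the given intervals.  When ``drug_panel``/``cell_lines`` are
    given, the summary set must cover the full design grid; missing keys are
    reported.
    """
    if not summaries:
        raise DesignError("no summaries provided")
    by_fmt: dict[str, dict] = {}
    seen = {}
    for s in summaries:
        seen[(s.culture_format, s.cell_line, s.pair)] = s
    if drug_panel is not None and cell_lines is not None:
        pairs = enumerate_pairs(drug_panel)
        formats = sorted({s.culture_format for s in summaries})
        missing = [(f, c, p) for f in formats for c in cell_lines for p in pairs
                   if (f, c, p) not in seen]
        if missing:
            raise DesignError(f"incomplete summary set; missing keys: {missing[:10]}"
                              f"{' ...' if len(missing) > 10 else ''}")
    edges = list(bin_edges)
    full_edges = [-np.inf] + edges + [np.inf]
    labels = ([f"< {edges[0]}"]
              + [f"[{a}, {b})" for a, b in zip(edges[:-1], edges[1:])]
              + [f">= {edges[-1]}"])
    for fmt in sorted({s.culture_format for s in summaries}):
        fmt_sum = [s for s in summaries if s.culture_format == fmt]
        syn_pairs = sorted({s.pair for s in fmt_sum if s.synergistic})
        values = np.array([s.mean_excess for s in fmt_sum])
        hist, _ = np.histogram(values, bins=full_edges)
        by_fmt[fmt] = {
            "n_synergistic_combinations": len(syn_pairs),
            "synergistic_pairs": syn_pairs,
            "bin_labels": labels,
            "bin_counts": hist.tolist(),
        }
    return by_fmt
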