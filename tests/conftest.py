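"""Shared fixtures: small simulated screens generated at test time."""

import numpy as np
import pytest

import synscreen as ss


@pytest.fixture(scope="session")
def noise_free_config():
    """Full 3 cell lines x 2 formats x 21 pairs design at zero noise,
    viability readout only, no single-drug screen (combination analysis)."""
    return ss.default_config(noise_sd={"2D": 0.0, "3D": 0.0},
                             include_single_screen=False,
                             readouts=("viability",), seed=7)


@pytest.fixture(scope="session")
def noise_free_screen(noise_free_config):
    return ss.simulate_screen(noise_free_config)


@pytest.fixture(scope="session")
def noise_free_normalized(noise_free_screen):
    return ss.normalize_dataset(noise_free_screen)


@pytest.fixture(scope="session")
def noise_free_scored(noise_free_config, noise_free_normalized):
    """Replicate-averaged Bliss grids of the noise-free screen, by key."""
    grids = {}
    for bio in range(1, noise_free_config.n_bio + 1):
        for m in ss.assemble_dose_matrices(noise_free_normalized, "viability", bio):
            grids.setdefault((m.cell_line, m.culture_format, m.pair), []).append(
                ss.score_matrix(m))
    return {key: ss.average_replicates(gs) for key, gs in grids.items()}


@pytest.fixture(scope="session")
def noise_free_summaries(noise_free_scored):
    """Replicate-averaged synergy summaries of the noise-free screen."""
    return {key: ss.summarize(g) for key, g in noise_free_scored.items()}


def small_two_drug_config(delta: float, seed: int, noise_sd: float = 0.05,
                          lower_a: float = 0.60, lower_b: float = 0.65):
    """One-pair screen used by the recovery studies: drug asymptotes keep
    the Bliss-null product above |delta| so the viability floor never clips
    and the true mean excess equals delta exactly."""
    return ss.default_config(
        cell_lines=("HCT-116",), formats=("2D",),
        drugs={"A": ss.HillParams(1.0, lower_a, 0.5, 1.2),
               "B": ss.HillParams(1.0, lower_b, 1.5, 1.0)},
        ec50_scale={}, interactions={("A", "B"): delta},
        noise_sd={"2D": noise_sd}, include_single_screen=False,
        readouts=("viability",), seed=seed)


def estimate_mean_excess(config) -> float:
    """Full-pipeline estimate of a one-pair screen's mean Bliss excess."""
    norm = ss.normalize_dataset(ss.simulate_screen(config))
    grids = [ss.score_matrix(m)
             for bio in range(1, config.n_bio + 1)
             for m in ss.assemble_dose_matrices(norm, "viability", bio)]
    return float(np.nanmean(ss.average_replicates(grids).excess))
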