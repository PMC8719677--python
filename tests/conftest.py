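"""Shared fixtures: small simulated studies and analytic noise matrices.

Everything is generated programmatically at test time; no stored fixtures.
The "direct" noise-matrix helpers skip the event/EM layer and add Gaussian
measurement scatter straight to the true noise levels — they exercise the
downstream modules at realistic signal-to-noise without paying for event
simulation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from noiseprop import cytometry, noise_floor, synth


def direct_noise_matrix(
    truth: synth.GroundTruth, residual_sd: float, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Noise matrix N = true noise + Gaussian scatter, plus the mean matrix."""
    rng = np.random.default_rng(seed)
    N = truth.true_noise() + residual_sd * rng.standard_normal(truth.base_means.shape)
    N = pd.DataFrame(N, index=truth.promoter_ids, columns=truth.condition_ids)
    M = pd.DataFrame(
        truth.base_means, index=truth.promoter_ids, columns=truth.condition_ids
    )
    return N, M


def network_frame(truth: synth.GroundTruth) -> pd.DataFrame:
    return pd.DataFrame(
        truth.network, index=truth.promoter_ids, columns=truth.regulator_ids
    )


def summarize_truth(truth: synth.GroundTruth) -> pd.DataFrame:
    """EM summaries for every promoter x condition of a simulated study."""
    frames = []
    for cond, X in synth.iter_condition_events(truth):
        fit = cytometry.fit_mixture_batch(X)
        frames.append(
            cytometry.summaries_frame(truth.promoter_ids, cond, fit, truth.n_events)
        )
    return cytometry.summarize_replicates(pd.concat(frames, ignore_index=True))


def fit_all_floors(pooled: pd.DataFrame, **kwargs) -> list[noise_floor.NoiseFloorFit]:
    return [
        noise_floor.fit_noise_floor(g, condition_id=str(c), **kwargs)
        for c, g in pooled.groupby("condition_id", sort=True)
    ]


@pytest.fixture(scope="session")
def small_study():
    """A small but complete simulated study run through events and EM."""
    truth = synth.simulate_ground_truth(
        P=400, R=12, C=4, n_condition_specific=2, n_global=2, n_events=1500, seed=11
    )
    pooled = summarize_truth(truth)
    fits = fit_all_floors(pooled)
    N, N_se = noise_floor.noise_matrix(pooled, fits)
    return {
        "truth": truth,
        "summaries": pooled,
        "floor_fits": fits,
        "N": N,
        "S": network_frame(truth),
    }


@pytest.fixture(scope="session")
def default_truth_direct():
    """Default-scale ground truth with an analytic noise matrix."""
    truth = synth.simulate_ground_truth(seed=3)
    N, M = direct_noise_matrix(truth, residual_sd=0.006, seed=30)
    return {"truth": truth, "N": N, "M": M, "S": network_frame(truth)}
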