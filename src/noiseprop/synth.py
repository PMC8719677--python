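"""Synthetic single-cell reporter data with known noise-propagation structure.

This module generates the ground truth that the rest of the pipeline is
benchmarked against: a sparse binary transcription-factor -> promoter
network, condition-dependent noise-propagating activities, a growth-rate
dependent noise floor, and per-promoter single-cell log-fluorescence events.

The statistical structure mirrors genome-wide reporter-library flow
cytometry experiments in *E. coli*:

* per promoter and condition, log-fluorescence is approximately Gaussian
  (fluorescence is log-normal), contaminated by a small uniform outlier
  component (debris, non-growing cells);
* the variance of log-fluorescence has a condition-specific lower envelope
  ``v_min(m) = a_c + b_c * exp(-m)`` in the mean ``m`` — a multiplicative
  ("extrinsic") floor ``a_c`` plus a Poissonian measurement term ``b_c``;
* the noise level of a promoter above that floor is the sum of a small
  promoter-specific baseline and additive contributions from the activities
  of the regulators that target it: ``N_pc = baseline_p + sum_r S_pr A_rc``.

Defaults reproduce the scale of the study this emulates: 1,810 promoters,
8 growth conditions, ~50,000 single-cell events per promoter in total
(5,000 per condition), 5 condition-specific and 6 globally active noise
propagators.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

__all__ = [
    "GroundTruth",
    "generate_network",
    "generate_activities",
    "generate_condition_metadata",
    "generate_events",
    "iter_condition_events",
    "generate_gene_features",
    "simulate_ground_truth",
    "condition_specific_rows",
    "globally_active_rows",
]


def _rng(seed: "int | np.random.Generator") -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_network(
    P: int, R: int, mean_in_degree: float, seed: "int | np.random.Generator"
) -> np.ndarray:
    """Sparse binary regulatory network S_pr with Poisson in-degrees.

    Each promoter draws its number of regulatory inputs from a Poisson law
    with the given mean (capped at R) and then picks that many distinct
    regulators uniformly, so a fraction exp(-mean_in_degree) of promoters is
    constitutive (no input) in expectation.

    Returns a (P, R) array with entries in {0, 1}.
    """
    if P < 1 or R < 1:
        raise ValueError("P and R must be >= 1")
    if mean_in_degree < 0:
        raise ValueError("mean_in_degree must be non-negative")
    if mean_in_degree >= R:
        raise ValueError("mean_in_degree must be smaller than R")
    rng = _rng(seed)
    k = np.minimum(rng.poisson(mean_in_degree, size=P), R)
    # rank-based sampling without replacement: no duplicate edges by construction
    ranks = np.argsort(rng.random((P, R)), axis=1).argsort(axis=1)
    return (ranks < k[:, None]).astype(np.uint8)


def generate_activities(
    R: int,
    C: int,
    n_condition_specific: int,
    n_global: int,
    scale: float,
    seed: "int | np.random.Generator",
    jitter: float = 0.2,
) -> np.ndarray:
    """True noise-propagating activities A_rc (R regulators x C conditions).

    ``n_global`` regulators are active (about ``scale``, in units of
    log-fluorescence variance) in every condition; ``n_condition_specific``
    regulators are active in exactly one randomly chosen condition each and
    silent elsewhere; the remaining regulators never propagate noise.
    Active entries are jittered multiplicatively by U(1-jitter, 1+jitter) so
    globally active regulators still vary across conditions.
    """
    if scale < 0:
        raise ValueError("scale must be non-negative")
    if n_condition_specific + n_global > R:
        raise ValueError("n_condition_specific + n_global must be <= R")
    rng = _rng(seed)
    A = np.zeros((R, C))
    rows = rng.choice(R, size=n_condition_specific + n_global, replace=False)
    global_rows = rows[:n_global]
    specific_rows = rows[n_global:]
    if n_global:
        A[global_rows, :] = scale * rng.uniform(1 - jitter, 1 + jitter, (n_global, C))
    for r in specific_rows:
        c = rng.integers(C)
        A[r, c] = scale * rng.uniform(1 - jitter, 1 + jitter)
    return A


def condition_specific_rows(A: np.ndarray) -> np.ndarray:
    """Indices of regulators truly active in exactly one condition."""
    nz = (A > 0).sum(axis=1)
    return np.flatnonzero(nz == 1)


def globally_active_rows(A: np.ndarray) -> np.ndarray:
    """Indices of regulators truly active in every condition."""
    nz = (A > 0).sum(axis=1)
    return np.flatnonzero(nz == A.shape[1])


def generate_condition_metadata(
    C: int,
    slope: float = -0.08,
    intercept: float = 0.16,
    rate_range: tuple[float, float] = (0.08, 1.65),
    jitter_sd: float = 0.0,
    seed: "int | np.random.Generator" = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Growth rates (1/h, fastest first) and the noise floor a_c per condition.

    The floor follows the linearly decreasing dependence on growth rate
    observed experimentally: ``a_c = intercept + slope * rate`` plus optional
    Gaussian jitter. Raises if any resulting floor is non-positive.
    """
    if C < 1:
        raise ValueError("need at least one condition")
    rng = _rng(seed)
    lo, hi = rate_range
    rates = np.linspace(hi, lo, C)
    a_c = intercept + slope * rates
    if jitter_sd:
        a_c = a_c + jitter_sd * rng.standard_normal(C)
    if np.any(a_c <= 0):
        raise ValueError("parameters yield a non-positive noise floor a_c")
    return rates, a_c


@dataclass
class GroundTruth:
    """Everything the generator knows and the pipeline is asked to recover."""

    network: np.ndarray          # (P, R) binary
    activities: np.ndarray       # (R, C) true A_rc, variance units
    baseline_noise: np.ndarray   # (P,) promoter-specific noise above the floor
    floor_a: np.ndarray          # (C,) extrinsic floor a_c
    floor_b: np.ndarray          # (C,) Poissonian term magnitude b_c
    growth_rates: np.ndarray     # (C,) 1/h
    base_means: np.ndarray       # (P, C) mean log-fluorescence m_pc
    outlier_fraction: float
    n_events: int
    seed: int
    promoter_ids: list[str] = field(default_factory=list)
    regulator_ids: list[str] = field(default_factory=list)
    condition_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        P, R = self.network.shape
        C = self.activities.shape[1]
        if not self.promoter_ids:
            self.promoter_ids = [f"p{i + 1:04d}" for i in range(P)]
        if not self.regulator_ids:
            self.regulator_ids = [f"tf{i + 1:02d}" for i in range(R)]
        if not self.condition_ids:
            self.condition_ids = [f"c{i + 1}" for i in range(C)]
        if np.any(self.activities < 0):
            raise ValueError("true activities must be non-negative")
        if not 0 <= self.outlier_fraction < 1:
            raise ValueError("outlier_fraction must be in [0, 1)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (*self.network.shape, self.activities.shape[1])

    def true_noise(self) -> np.ndarray:
        """True noise level above the floor, N_pc = baseline_p + sum_r S_pr A_rc."""
        return self.baseline_noise[:, None] + self.network @ self.activities

    def minimal_variance(self) -> np.ndarray:
        """v_min(m_pc) per cell of the matrix."""
        return self.floor_a[None, :] + self.floor_b[None, :] * np.exp(-self.base_means)

    def true_variance(self) -> np.ndarray:
        """Total true variance of log-fluorescence, v_min(m) + N_pc >= v_min(m)."""
        return self.minimal_variance() + self.true_noise()

    def outlier_support(self) -> tuple[float, float]:
        """Uniform outlier support: observed mean range padded by 2 log units."""
        return float(self.base_means.min() - 2.0), float(self.base_means.max() + 2.0)

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "outlier_fraction": self.outlier_fraction,
            "n_events": self.n_events,
            "promoter_ids": self.promoter_ids,
            "regulator_ids": self.regulator_ids,
            "condition_ids": self.condition_ids,
            "network": self.network.tolist(),
            "activities": self.activities.tolist(),
            "baseline_noise": self.baseline_noise.tolist(),
            "floor_a": self.floor_a.tolist(),
            "floor_b": self.floor_b.tolist(),
            "growth_rates": self.growth_rates.tolist(),
            "base_means": self.base_means.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            network=np.asarray(d["network"], dtype=np.uint8),
            activities=np.asarray(d["activities"], dtype=float),
            baseline_noise=np.asarray(d["baseline_noise"], dtype=float),
            floor_a=np.asarray(d["floor_a"], dtype=float),
            floor_b=np.asarray(d["floor_b"], dtype=float),
            growth_rates=np.asarray(d["growth_rates"], dtype=float),
            base_means=np.asarray(d["base_means"], dtype=float),
            outlier_fraction=d["outlier_fraction"],
            n_events=d["n_events"],
            seed=d["seed"],
            promoter_ids=d["promoter_ids"],
            regulator_ids=d["regulator_ids"],
            condition_ids=d["condition_ids"],
        )


def simulate_ground_truth(
    P: int = 1810,
    R: int = 40,
    C: int = 8,
    mean_in_degree: float = 0.9,
    n_condition_specific: int = 5,
    n_global: int = 6,
    activity_scale: float = 0.05,
    baseline_mean: float = 0.005,
    b_c: float = 0.8,
    outlier_fraction: float = 0.02,
    n_events: int = 5000,
    mean_range: tuple[float, float] = (3.0, 8.0),
    mean_shift_sd: float = 0.15,
    mean_shift_per_input: float = 0.15,
    floor_slope: float = -0.08,
    floor_intercept: float = 0.16,
    rate_range: tuple[float, float] = (0.08, 1.65),
    floor_jitter_sd: float = 0.004,
    seed: int = 0,
) -> GroundTruth:
    """Assemble a full ground truth at study-like defaults.

    Means m_pc are uniform over ``mean_range`` per promoter with Gaussian
    per-condition shifts whose SD grows with the number of regulatory
    inputs (``mean_shift_sd + mean_shift_per_input * min(n_inputs, 4)``), so
    regulated promoters carry more expression plasticity, as regulated genes
    do. Baseline noise is exponential with a small mean so constitutive
    promoters sit just above the floor.
    """
    ss = np.random.SeedSequence(seed)
    rng_net, rng_act, rng_meta, rng_base, rng_means = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    S = generate_network(P, R, mean_in_degree, rng_net)
    A = generate_activities(
        R, C, n_condition_specific, n_global, activity_scale, rng_act
    )
    rates, a_c = generate_condition_metadata(
        C, floor_slope, floor_intercept, rate_range, floor_jitter_sd, rng_meta
    )
    baseline = rng_base.exponential(baseline_mean, size=P) if baseline_mean > 0 else np.zeros(P)
    lo, hi = mean_range
    m0 = rng_means.uniform(lo, hi, size=P)
    n_inputs = S.sum(axis=1)
    shift_sd = mean_shift_sd + mean_shift_per_input * np.minimum(n_inputs, 4)
    m_pc = m0[:, None] + shift_sd[:, None] * rng_means.standard_normal((P, C))
    return GroundTruth(
        network=S,
        activities=A,
        baseline_noise=baseline,
        floor_a=a_c,
        floor_b=np.full(C, float(b_c)),
        growth_rates=rates,
        base_means=m_pc,
        outlier_fraction=outlier_fraction,
        n_events=n_events,
        seed=seed,
    )


def _condition_events(
    truth: GroundTruth, c: int, rng: np.random.Generator
) -> np.ndarray:
    P = truth.network.shape[0]
    m = truth.base_means[:, c]
    v = truth.minimal_variance()[:, c] + truth.true_noise()[:, c]
    x = m[:, None] + np.sqrt(v)[:, None] * rng.standard_normal((P, truth.n_events))
    if truth.outlier_fraction > 0:
        lo, hi = truth.outlier_support()
        mask = rng.random((P, truth.n_events)) < truth.outlier_fraction
        x[mask] = rng.uniform(lo, hi, size=int(mask.sum()))
    return x


def iter_condition_events(
    truth: GroundTruth, replicate: int = 0
) -> Iterator[tuple[str, np.ndarray]]:
    """Yield (condition_id, (P, n_events) array) one condition at a time.

    Each condition uses a deterministically derived child seed, so partial
    consumption or regeneration with the same truth is reproducible.
    ``replicate`` selects an independent event draw from the same ground
    truth (a technical/biological replicate of the same library).
    """
    if truth.n_events < 2:
        raise ValueError("n_events must be >= 2")
    if replicate < 0:
        raise ValueError("replicate must be >= 0")
    C = truth.activities.shape[1]
    children = np.random.SeedSequence(truth.seed).spawn(5 + C * (replicate + 1))
    children = children[5 + C * replicate:]
    for c in range(C):
        yield truth.condition_ids[c], _condition_events(
            truth, c, np.random.default_rng(children[c])
        )


def generate_events(truth: GroundTruth) -> dict[str, np.ndarray]:
    """All conditions at once; see :func:`iter_condition_events`."""
    return dict(iter_condition_events(truth))


def generate_gene_features(
    truth: GroundTruth,
    seed: "int | np.random.Generator",
    loadings: dict[str, float] | None = None,
) -> "dict[str, np.ndarray]":
    """External gene features correlated with absolute expression.

    Emulates literature-derived features (RNA and protein levels, codon
    bias, evolutionary rates dN/dS) as a one-factor model on the
    standardized condition-averaged mean expression: levels and codon bias
    load positively, evolutionary rates negatively. Values are on a
    standardized (log-like) scale.
    """
    rng = _rng(seed)
    if loadings is None:
        loadings = {
            "rna_level": 0.9,
            "protein_level": 0.85,
            "codon_bias": 0.8,
            "dN": -0.7,
            "dS": -0.6,
        }
    m = truth.base_means.mean(axis=1)
    z = (m - m.mean()) / m.std()
    P = z.size
    out = {}
    for name, lam in loadings.items():
        out[name] = lam * z + np.sqrt(1 - lam**2) * rng.standard_normal(P)
    return out
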