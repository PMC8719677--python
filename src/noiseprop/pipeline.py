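"""End-to-end orchestration: simulate/ingest -> summarize -> floor -> noise ->
propagation -> regulatory statistics -> feature PCA.

A single global seed fans out into per-stage child seeds (derived through
``numpy.random.SeedSequence``), so reruns with the same configuration are
bit-identical and stages rerun in isolation see the same streams. Every run
writes a machine-readable manifest with the seed and all parameter values.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, cytometry, feature_pca, io, noise_floor, propagation, regnet_stats, synth

logger = logging.getLogger(__name__)

DEFAULT_LAMBDA_GRID = tuple(float(x) for x in np.logspace(-2, 4, 13))

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "simulate_inputs"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Paths and parameters for one pipeline run."""

    outdir: str
    seed: int = 0
    # either simulate (kwargs for synth.simulate_ground_truth, minus seed) ...
    simulate: "dict | None" = None
    # ... or paths to pre-existing inputs
    events_path: "str | None" = None
    network_path: "str | None" = None
    growth_rates_path: "str | None" = None
    features_path: "str | None" = None
    # parameters
    background: "float | None" = None
    q: float = 0.05
    n_bins: int = 20
    lam: "float | str" = "auto"
    lambda_grid: tuple = DEFAULT_LAMBDA_GRID
    k_folds: int = 10
    n_shuffles: int = 100
    em_tol: float = 1e-8
    em_max_iter: int = 500
    write_events: bool = False
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.simulate is None:
            for name in ("events_path", "network_path", "growth_rates_path"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(f"{name} is required when not simulating")
                if not Path(p).exists():
                    raise FileNotFoundError(f"{name}: no such file {p}")
        if self.lam != "auto" and not float(self.lam) > 0:
            raise ValueError("lam must be 'auto' or a positive number")


def _child_seeds(seed: int, n: int) -> list[int]:
    # keep derived integer seeds below 2**31 for portability
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s % (2**31)) for s in state]


def simulate_inputs(config: PipelineConfig, outdir: Path):
    """Generate ground truth and write the network/growth-rate inputs."""
    params = dict(config.simulate or {})
    truth = synth.simulate_ground_truth(**params, seed=config.seed)
    S = pd.DataFrame(
        truth.network, index=truth.promoter_ids, columns=truth.regulator_ids
    )
    io.write_network_tsv(S, outdir / "network.tsv")
    io.write_growth_rates_tsv(
        truth.condition_ids, truth.growth_rates, outdir / "growth_rates.tsv"
    )
    truth.to_json(outdir / "ground_truth.json")
    return truth, S


def _summaries_from_truth(truth: synth.GroundTruth, config: PipelineConfig, outdir: Path) -> pd.DataFrame:
    frames = []
    for cond, X in synth.iter_condition_events(truth):
        fit = cytometry.fit_mixture_batch(
            X, max_iter=config.em_max_iter, tol=config.em_tol
        )
        frames.append(
            cytometry.summaries_frame(truth.promoter_ids, cond, fit, truth.n_events)
        )
        if config.write_events:
            events = pd.DataFrame(
                {
                    "promoter_id": np.repeat(truth.promoter_ids, truth.n_events),
                    "condition_id": cond,
                    "log_fluorescence": X.ravel(),
                }
            )
            io.write_events_tsv(events, outdir / f"events_{cond}.tsv")
    return pd.concat(frames, ignore_index=True)


def _summaries_from_tsv(path, config: PipelineConfig) -> pd.DataFrame:
    events = io.read_events_tsv(path)
    if "replicate_id" not in events.columns:
        events["replicate_id"] = "r1"
    rows = []
    for (p, c, r), grp in events.groupby(
        ["promoter_id", "condition_id", "replicate_id"], sort=True
    ):
        fit = cytometry.fit_gaussian_uniform_mixture(
            grp["log_fluorescence"].to_numpy(),
            max_iter=config.em_max_iter,
            tol=config.em_tol,
        )
        rows.append(
            {
                "promoter_id": p,
                "condition_id": c,
                "replicate_id": r,
                "mean": fit.mean,
                "variance": fit.variance,
                "outlier_weight": fit.outlier_weight,
                "n_used": fit.n,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages in order, writing each stage's outputs before the next.

    Returns a dict of the in-memory artifacts (summaries, floor fits, noise
    matrix, activity estimates, statistic tables, PCA results, manifest).
    """
    config.validate()
    outdir = io.ensure_dir(config.outdir)
    logging.basicConfig(level=config.log_level)
    artifacts: dict = {}
    stage = "setup"
    try:
        stage = "simulate"
        truth = None
        if config.simulate is not None:
            truth, S = simulate_inputs(config, outdir)
            growth = pd.Series(
                truth.growth_rates, index=truth.condition_ids, name="growth_rate"
            )
            artifacts["truth"] = truth

        stage = "summarize"
        if truth is not None:
            replicate_summaries = _summaries_from_truth(truth, config, outdir)
        else:
            replicate_summaries = _summaries_from_tsv(config.events_path, config)
        pooled = cytometry.summarize_replicates(replicate_summaries)
        io._write(replicate_summaries, outdir / "replicate_summaries.tsv")
        io._write(pooled, outdir / "summaries.tsv")
        if truth is None:
            S = io.read_network_tsv(
                config.network_path, promoter_ids=sorted(pooled["promoter_id"].unique())
            )
            growth = io.read_growth_rates_tsv(config.growth_rates_path)
        artifacts["summaries"] = pooled

        stage = "floor"
        if config.background is not None:
            pooled = cytometry.filter_above_background(pooled, config.background)
        fits = [
            noise_floor.fit_noise_floor(
                grp, condition_id=str(cond), q=config.q, n_bins=config.n_bins
            )
            for cond, grp in pooled.groupby("condition_id", sort=True)
        ]
        io.write_floor_fits_tsv(fits, outdir / "floor_fits.tsv")
        growth_fit = noise_floor.floor_vs_growth_rate(
            fits, [growth[f.condition_id] for f in fits]
        )
        with open(outdir / "floor_growth_fit.json", "w") as fh:
            json.dump(growth_fit, fh, indent=2)
        artifacts["floor_fits"] = fits
        artifacts["floor_growth_fit"] = growth_fit

        stage = "noise"
        N, N_se = noise_floor.noise_matrix(pooled, fits)
        means = pooled.pivot(index="promoter_id", columns="condition_id", values="mean")
        means.columns.name = None
        io.write_matrix_tsv(N, outdir / "noise_matrix.tsv")
        io.write_matrix_tsv(N_se, outdir / "noise_matrix_se.tsv")
        io.write_matrix_tsv(means, outdir / "mean_matrix.tsv")
        artifacts["noise_matrix"] = N
        artifacts["mean_matrix"] = means

        stage = "propagate"
        seeds = _child_seeds(config.seed, 3)
        if config.lam == "auto":
            lam, cv_table = propagation.select_prior_strength(
                N, S, config.lambda_grid, k_folds=config.k_folds, seed=seeds[0]
            )
            cv_table.to_csv(outdir / "lambda_cv.tsv", sep="\t")
        else:
            lam = float(config.lam)
        model = propagation.center_model_inputs(N, S)
        est = propagation.infer_activities(model, lam)
        shuffled = propagation.randomized_fov(
            N, S, n_shuffles=config.n_shuffles, lam=lam, seed=seeds[1]
        )
        cs_table, per_condition = propagation.condition_specific_propagators(est)
        avg_table = propagation.average_activities(est)
        io._write(est.A.rename_axis("regulator_id"), outdir / "activities.tsv", index=True)
        io._write(
            est.delta_A.rename_axis("regulator_id"),
            outdir / "activity_errors.tsv",
            index=True,
        )
        fov_report = pd.DataFrame(
            {
                "condition_id": est.fov.index,
                "fov": est.fov.to_numpy(),
                "shuffled_mean": shuffled["fov_mean"].to_numpy(),
                "shuffled_sd": shuffled["fov_sd"].to_numpy(),
                "shuffled_se": shuffled["fov_se"].to_numpy(),
            }
        )
        io._write(fov_report, outdir / "fov.tsv")
        io._write(cs_table, outdir / "propagators_condition_specific.tsv")
        io._write(avg_table, outdir / "propagators_average.tsv")
        artifacts.update(
            estimates=est, lam=lam, fov_report=fov_report,
            condition_specific=cs_table, average_propagators=avg_table,
            significant_per_condition=per_condition,
        )

        stage = "stats"
        table = regnet_stats.compute_plasticities(means, N, S)
        curve_inputs = regnet_stats.inputs_above_cutoff_curve(table)
        curve_frac = regnet_stats.fraction_regulated_curve(table)
        tstats = regnet_stats.cutoff_t_statistics(
            table["n_inputs"], table["mean_noise"]
        )
        _, group_tests = regnet_stats.plasticity_by_input_group(table)
        comparison = regnet_stats.constitutive_vs_regulated_comparison(
            table[table["n_inputs"] == 0], table[table["n_inputs"] >= 1]
        )
        io._write(table, outdir / "plasticity.tsv")
        io._write(curve_inputs, outdir / "inputs_above_cutoff.tsv")
        io._write(curve_frac, outdir / "fraction_regulated.tsv")
        io._write(tstats, outdir / "cutoff_t_statistics.tsv")
        io._write(group_tests, outdir / "plasticity_group_tests.tsv")
        io._write(comparison, outdir / "constitutive_vs_regulated.tsv")
        artifacts.update(
            plasticity=table, inputs_curve=curve_inputs, fraction_curve=curve_frac,
            cutoff_t=tstats, group_tests=group_tests, comparison=comparison,
        )

        stage = "pca"
        features = None
        if truth is not None:
            external = synth.generate_gene_features(truth, seeds[2])
            features = pd.DataFrame(external, index=truth.promoter_ids)
            features = features.join(
                table.set_index("promoter_id")[
                    ["n_inputs", "mean_expression", "expression_plasticity",
                     "mean_noise", "noise_plasticity"]
                ]
            )
            features = features[feature_pca.CANONICAL_FEATURES]
            features.insert(0, "gene_id", features.index)
        elif config.features_path is not None:
            features = io.read_feature_tsv(config.features_path)
        if features is not None:
            io.write_feature_tsv(features.reset_index(drop=True), outdir / "features.tsv")
            R, n_pairs = feature_pca.correlation_matrix(features)
            evals, loadings = feature_pca.pca_of_correlation(R, repair=True)
            contrib1, _ = feature_pca.component_contributions(loadings, 1)
            contrib2, _ = feature_pca.component_contributions(loadings, 2)
            io._write(R.rename_axis("feature"), outdir / "feature_correlation.tsv", index=True)
            io._write(
                pd.DataFrame(
                    {
                        "component": [f"PC{i + 1}" for i in range(len(evals))],
                        "eigenvalue": evals,
                        "variance_fraction": evals / len(evals),
                    }
                ),
                outdir / "pca_eigenvalues.tsv",
            )
            io._write(loadings.rename_axis("feature"), outdir / "pca_loadings.tsv", index=True)
            io._write(
                pd.DataFrame({"feature": contrib1.index, "pc1": contrib1.to_numpy(),
                              "pc2": contrib2.to_numpy()}),
                outdir / "pca_contributions.tsv",
            )
            artifacts.update(
                features=features, correlation=R, eigenvalues=evals, loadings=loadings
            )
        else:
            logger.info("pca: no feature table available; stage skipped")

        stage = "manifest"
        manifest = {
            "package": "noiseprop",
            "version": __version__,
            "seed": config.seed,
            "parameters": {
                k: v for k, v in dataclasses.asdict(config).items() if k != "outdir"
            },
            "stages": ["simulate", "summarize", "floor", "noise", "propagate", "stats", "pca"],
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        artifacts["manifest"] = manifest
    except (PipelineError,):
        raise
    except Exception as exc:  # noqa: BLE001 - annotate with the failing stage
        raise PipelineError(stage, str(exc)) from exc
    return artifacts
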