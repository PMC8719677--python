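"""Fit per-condition noise floors and derive the noise-level matrix.

The variance of log-expression has a condition-specific lower envelope
v_min(m) = a_c + b_c*exp(-m). This driver fits the envelope per condition
(quantile regression at q=0.05), regresses the floor a_c on growth rate,
defines noise levels N_pc = v_pc - v_min(m_pc), and compares noise-level
distributions between the fastest- and slowest-growing conditions.
"""

import importlib
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
common = importlib.import_module("00_common")

from noiseprop import io, noise_floor, synth


def main() -> None:
    args = common.study_parser(__doc__).parse_args()
    out = args.study_dir
    truth = synth.GroundTruth.from_json(out / "ground_truth.json")
    pooled = pd.read_csv(out / "summaries.tsv", sep="\t")
    growth = io.read_growth_rates_tsv(out / "growth_rates.tsv")

    fits = [noise_floor.fit_noise_floor(g, condition_id=str(c))
            for c, g in pooled.groupby("condition_id", sort=True)]
    io.write_floor_fits_tsv(fits, out / "floor_fits.tsv")
    res = noise_floor.floor_vs_growth_rate(
        fits, [growth[f.condition_id] for f in fits])
    print("noise floor vs growth rate: "
          f"slope={res['slope']:.4f}/h, intercept={res['intercept']:.4f}, "
          f"R^2={res['r2']:.3f}")
    for f, a_true in zip(fits, truth.floor_a):
        print(f"  {f.condition_id}: a_c={f.a_c:.4f} (true {a_true:.4f}), "
              f"b_c={f.b_c:.3f} (true {truth.floor_b[0]:.3f})")

    N, N_se = noise_floor.noise_matrix(pooled, fits)
    means = pooled.pivot(index="promoter_id", columns="condition_id", values="mean")
    means.columns.name = None
    io.write_matrix_tsv(N, out / "noise_matrix.tsv")
    io.write_matrix_tsv(means, out / "mean_matrix.tsv")

    fast, slow = truth.condition_ids[0], truth.condition_ids[-1]
    comp = noise_floor.noise_distribution_tests(N[fast], N[slow])
    print(f"noise levels {fast} (median {comp['median_a']:.4f}) vs {slow} "
          f"(median {comp['median_b']:.4f}): rank-sum p = {comp['p_value']:.2e}")
    print(f"wrote floor fits + noise/mean matrices -> {out}")


if __name__ == "__main__":
    main()
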