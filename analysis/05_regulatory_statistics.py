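"""Link noise and its plasticity to the number of known regulatory inputs.

Computes per-promoter expression/noise plasticities and mean noise, the
cutoff curves (mean inputs and fraction regulated above a noise cutoff),
Welch t-statistics across cutoffs, and the input-count group comparisons
of noise plasticity ({0}, {1,2}, {>=3} known regulators).
"""

import importlib
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
common = importlib.import_module("00_common")

from noiseprop import io, regnet_stats, synth


def main() -> None:
    args = common.study_parser(__doc__).parse_args()
    out = args.study_dir
    truth = synth.GroundTruth.from_json(out / "ground_truth.json")
    N = io.read_matrix_tsv(out / "noise_matrix.tsv")
    M = io.read_matrix_tsv(out / "mean_matrix.tsv")
    S = io.read_network_tsv(out / "network.tsv", promoter_ids=list(N.index),
                            regulator_ids=truth.regulator_ids)

    table = regnet_stats.compute_plasticities(M, N, S)
    io._write(table, out / "plasticity.tsv")

    curve = regnet_stats.inputs_above_cutoff_curve(table)
    io._write(curve, out / "inputs_above_cutoff.tsv")
    print(f"mean inputs, all promoters: {curve['mean_inputs'].iloc[0]:.2f}; "
          f"above the highest retained noise cutoff: {curve['mean_inputs'].iloc[-1]:.2f}")

    frac = regnet_stats.fraction_regulated_curve(table)
    io._write(frac, out / "fraction_regulated.tsv")
    print(f"fraction regulated: {frac['fraction_regulated'].iloc[0]:.1%} overall, "
          f"{frac['fraction_regulated'].iloc[-1]:.1%} among high-noise promoters")

    tstats = regnet_stats.cutoff_t_statistics(table["n_inputs"], table["mean_noise"])
    io._write(tstats, out / "cutoff_t_statistics.tsv")
    print(f"max Welch t (inputs above vs below cutoff): {tstats['t'].abs().max():.1f}")

    _, tests = regnet_stats.plasticity_by_input_group(table)
    io._write(tests, out / "plasticity_group_tests.tsv")
    for row in tests.itertuples():
        print(f"  noise plasticity {row.group_a} vs {row.group_b}: "
              f"p = {row.p_value:.2e}")

    comp = regnet_stats.constitutive_vs_regulated_comparison(
        table[table["n_inputs"] == 0], table[table["n_inputs"] >= 1])
    io._write(comp, out / "constitutive_vs_regulated.tsv")
    for row in comp.itertuples():
        print(f"  constitutive vs regulated {row.feature}: p = {row.p_value:.2e}")


if __name__ == "__main__":
    main()
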