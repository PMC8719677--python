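"""PCA of the 10-gene-feature correlation matrix.

Assembles the canonical feature table (synthetic literature features: RNA
and protein levels, codon bias, dN, dS; pipeline-measured features: number
of inputs, mean expression, expression plasticity, mean noise, noise
plasticity), computes pairwise Pearson correlations, and checks that the
top two principal axes separate absolute expression from regulation/noise.
"""

import importlib
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
common = importlib.import_module("00_common")

from noiseprop import feature_pca, io, synth


def main() -> None:
    args = common.study_parser(__doc__).parse_args()
    out = args.study_dir
    truth = synth.GroundTruth.from_json(out / "ground_truth.json")
    table = pd.read_csv(out / "plasticity.tsv", sep="\t")

    external = synth.generate_gene_features(truth, seed=args.seed + 7)
    features = pd.DataFrame(external, index=truth.promoter_ids)
    features = features.join(table.set_index("promoter_id")[
        ["n_inputs", "mean_expression", "expression_plasticity",
         "mean_noise", "noise_plasticity"]])
    features = features[feature_pca.CANONICAL_FEATURES]
    features.insert(0, "gene_id", features.index)
    io.write_feature_tsv(features.reset_index(drop=True), out / "features.tsv")

    R, _ = feature_pca.correlation_matrix(features)
    evals, loadings = feature_pca.pca_of_correlation(R, repair=True)
    io._write(R.rename_axis("feature"), out / "feature_correlation.tsv", index=True)
    io._write(loadings.rename_axis("feature"), out / "pca_loadings.tsv", index=True)

    top2 = (evals[0] + evals[1]) / len(evals)
    expr = ["rna_level", "protein_level", "codon_bias", "dN", "dS"]
    reg = ["n_inputs", "expression_plasticity", "mean_noise", "noise_plasticity"]
    _, share1 = feature_pca.component_contributions(loadings, 1, expr)
    _, share2 = feature_pca.component_contributions(loadings, 2, reg)
    print(f"top-2 components carry {top2:.1%} of the total variance")
    print(f"  PC1: expression/codon/evolution block share {share1:.1%}")
    print(f"  PC2: regulation/noise block share {share2:.1%}")


if __name__ == "__main__":
    main()
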