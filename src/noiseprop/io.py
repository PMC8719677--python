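"""Readers and writers for the pipeline's TSV interchange formats.

All interchange is tab-separated UTF-8 with a header row and '.' decimals.
Floats are written with 17 significant digits so write-read round-trips are
exact. Malformed rows are reported with their line numbers; network edges
referencing unknown promoters are dropped with a logged count.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .noise_floor import NoiseFloorFit

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.17g"

__all__ = [
    "read_events_tsv",
    "write_events_tsv",
    "read_network_tsv",
    "write_network_tsv",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_growth_rates_tsv",
    "write_growth_rates_tsv",
    "read_floor_fits_tsv",
    "write_floor_fits_tsv",
    "read_feature_tsv",
    "write_feature_tsv",
]


def _write(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def write_events_tsv(events: pd.DataFrame, path) -> None:
    """Write an event table (promoter_id, condition_id[, replicate_id], log_fluorescence)."""
    cols = ["promoter_id", "condition_id"]
    if "replicate_id" in events.columns:
        cols.append("replicate_id")
    cols.append("log_fluorescence")
    _write(events[cols], path)


def read_events_tsv(path) -> pd.DataFrame:
    """Read an event table; non-numeric fluorescence rows raise with line numbers."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if "log_fluorescence" not in df.columns:
        raise ValueError(f"{path}: missing 'log_fluorescence' column")
    vals = pd.to_numeric(df["log_fluorescence"], errors="coerce")
    bad = df.index[vals.isna()]
    if len(bad):
        lines = ", ".join(str(i + 2) for i in bad[:10])  # +2: header + 1-based
        raise ValueError(f"{path}: malformed log_fluorescence at lines {lines}")
    df["log_fluorescence"] = vals
    return df


def write_network_tsv(S: pd.DataFrame, path) -> None:
    """Write a binary network (promoters x regulators) as a two-column edge list."""
    promoters, regulators = np.nonzero(S.to_numpy())
    edges = pd.DataFrame(
        {
            "regulator_id": S.columns.to_numpy()[regulators],
            "promoter_id": S.index.to_numpy()[promoters],
        }
    )
    _write(edges, path)


def read_network_tsv(
    path, promoter_ids=None, regulator_ids=None
) -> pd.DataFrame:
    """Read an edge list into a binary promoters x regulators matrix.

    When ``promoter_ids`` is given, edges referencing unknown promoters are
    dropped with a logged count and the returned matrix covers exactly those
    promoters (all-zero rows for unannotated ones).
    """
    edges = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for col in ("regulator_id", "promoter_id"):
        if col not in edges.columns:
            raise ValueError(f"{path}: missing '{col}' column")
    if promoter_ids is not None:
        known = pd.Index(promoter_ids)
        bad = ~edges["promoter_id"].isin(known)
        if bad.any():
            logger.warning(
                "read_network_tsv: dropped %d edges with unknown promoter ids",
                int(bad.sum()),
            )
            edges = edges[~bad]
    S = (
        edges.assign(value=np.uint8(1))
        .pivot_table(
            index="promoter_id", columns="regulator_id", values="value", fill_value=0
        )
        .astype(np.uint8)
    )
    if promoter_ids is not None:
        S = S.reindex(pd.Index(promoter_ids, name="promoter_id"), fill_value=0)
    if regulator_ids is not None:
        S = S.reindex(columns=pd.Index(regulator_ids, name="regulator_id"), fill_value=0)
    S.columns.name = None
    return S


def write_matrix_tsv(M: pd.DataFrame, path) -> None:
    """Write a promoters x conditions matrix with a promoter_id index column."""
    out = M.copy()
    out.index.name = "promoter_id"
    _write(out, path, index=True)


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="promoter_id", float_precision="round_trip")


def write_growth_rates_tsv(condition_ids, growth_rates, path) -> None:
    _write(
        pd.DataFrame(
            {"condition_id": list(condition_ids), "growth_rate": np.asarray(growth_rates)}
        ),
        path,
    )


def read_growth_rates_tsv(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return df.set_index("condition_id")["growth_rate"]


def write_floor_fits_tsv(fits: "list[NoiseFloorFit]", path) -> None:
    _write(
        pd.DataFrame(
            [
                {
                    "condition_id": f.condition_id,
                    "a_c": f.a_c,
                    "b_c": f.b_c,
                    "quantile": f.quantile,
                    "n_bins": f.n_bins,
                    "n_points": f.n_points,
                }
                for f in fits
            ]
        ),
        path,
    )


def read_floor_fits_tsv(path) -> "list[NoiseFloorFit]":
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [
        NoiseFloorFit(
            condition_id=str(r.condition_id),
            a_c=float(r.a_c),
            b_c=float(r.b_c),
            quantile=float(r.quantile),
            n_bins=int(r.n_bins),
            n_points=int(r.n_points),
        )
        for r in df.itertuples()
    ]


def write_feature_tsv(features: pd.DataFrame, path) -> None:
    _write(features, path)


def read_feature_tsv(path, log_columns: "list[str] | None" = None) -> pd.DataFrame:
    """Read a gene-feature table; optionally natural-log-transform skewed columns."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for c in log_columns or []:
        vals = df[c]
        if (vals <= 0).any():
            raise ValueError(f"cannot log-transform non-positive values in '{c}'")
        df[c] = np.log(vals)
    return df


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
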