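"""Readers and writers for bin-count tables, truth tables, results and BED.

All tables are plain tab-separated text with a header. The bin-count format
carries ``site_id, bin_index, chrom, start, end, strand, x0, y0, x1, y1``;
the four genomic columns are optional (written as ``.`` when absent) and
coordinates follow the BED convention (0-based, half-open). Within a site
``bin_index`` must run 0, 1, 2, ... consecutively — the HMM chains depend
on that ordering.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

REQUIRED_COLUMNS = ("site_id", "bin_index", "x0", "y0", "x1", "y1")
COORD_COLUMNS = ("chrom", "start", "end", "strand")
COUNT_COLUMNS = ("x0", "y0", "x1", "y1")

_CANONICAL_ORDER = (
    "site_id",
    "bin_index",
    "chrom",
    "start",
    "end",
    "strand",
    "x0",
    "y0",
    "x1",
    "y1",
)


def _coerce_count(df: pd.DataFrame, col: str) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # +2: header + 1-based
        raise ValidationError(f"column {col!r}: non-numeric value at file row {row}")
    arr = vals.to_numpy(dtype=float)
    rounded = np.rint(arr)
    off = np.abs(arr - rounded) > 1e-9
    if off.any():
        row = int(np.flatnonzero(off)[0]) + 2
        raise ValidationError(f"column {col!r}: non-integer count at file row {row}")
    if (rounded < 0).any():
        row = int(np.flatnonzero(rounded < 0)[0]) + 2
        raise ValidationError(f"column {col!r}: negative count at file row {row}")
    return rounded.astype(np.int64)


def validate_bin_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalise an in-memory bin-count table."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"bin table is missing required columns {missing}")
    out = df.copy()
    for col in COUNT_COLUMNS:
        out[col] = _coerce_count(out, col)
    out["bin_index"] = _coerce_count(out, "bin_index")

    for site_id, grp in out.groupby("site_id", sort=False):
        idx = grp["bin_index"].to_numpy()
        expected = np.arange(idx.size)
        if not np.array_equal(idx, expected):
            first_bad = int(np.flatnonzero(idx != expected)[0])
            raise ValidationError(
                f"site {site_id!r}: bin_index must run 0..{idx.size - 1} "
                f"consecutively; mismatch at position {first_bad} "
                f"(found {int(idx[first_bad])}, expected {first_bad})"
            )
    for col in COORD_COLUMNS:
        if col not in out.columns:
            out[col] = "." if col in ("chrom", "strand") else np.nan
    cols = [c for c in _CANONICAL_ORDER if c in out.columns]
    extra = [c for c in out.columns if c not in cols]
    return out[cols + extra]


def read_bin_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a tab-separated bin-count table."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"site_id": str})
    except Exception as exc:  # noqa: BLE001 - surface as a validation failure
        raise ValidationError(f"cannot parse {path}: {exc}") from exc
    return validate_bin_table(df)


def _format_frame(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in ("start", "end"):
        if col in out.columns:
            out[col] = out[col].map(
                lambda v: "." if pd.isna(v) else str(int(v))
            )
    return out


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Deterministic tab-separated output with header."""
    _format_frame(df).to_csv(path, sep="\t", index=False, float_format="%.10g")


write_results = write_table
write_truth = write_table


def read_truth(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"site_id": str})
    for col in ("site_id", "bin_index", "state"):
        if col not in df.columns:
            raise ValidationError(f"truth table is missing column {col!r}")
    return df


def write_bed(dmrs: pd.DataFrame, path: str | Path) -> None:
    """BED6 export of DMR calls.

    Score is round(1000 * mean posterior) clipped to [0, 1000]. When the
    input table carried no genomic coordinates, chrom falls back to the
    site id and start/end to bin indices (half-open).
    """
    lines = []
    for _, row in dmrs.iterrows():
        if "chrom" in dmrs.columns and not pd.isna(row.get("chrom")):
            chrom = str(row["chrom"])
            start = int(row["start"])
            end = int(row["end"])
            strand = str(row.get("strand", "."))
            if strand not in ("+", "-"):
                strand = "."
        else:
            chrom = str(row["site_id"])
            start = int(row["bin_first"])
            end = int(row["bin_last"]) + 1
            strand = "."
        score = int(np.clip(round(1000 * float(row["mean_posterior"])), 0, 1000))
        lines.append(f"{chrom}\t{start}\t{end}\t{row['dmr_id']}\t{score}\t{strand}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
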