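"""Tab-separated matrix and sample-sheet readers/writers.

Matrices are probes-in-rows TSV with the probe id in the first column and a
header row of sample ids; gzip-compressed files are accepted transparently
(pandas infers compression from the filename).
"""

from __future__ import annotations

import pandas as pd


def read_matrix(path) -> pd.DataFrame:
    """Read a probes x samples TSV matrix (first column = probe id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.has_duplicates:
        raise ValueError(f"duplicate probe ids in {path}")
    if df.columns.has_duplicates:
        raise ValueError(f"duplicate sample ids in {path}")
    return df


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="probe_id")


def read_sample_sheet(path) -> pd.DataFrame:
    """Sample sheet TSV indexed by sample id (columns: family, group, sex, batch, ...)."""
    sheet = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    sheet.index = sheet.index.astype(str)
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, sep="\t", index_label="sample_id")


def read_sites(path) -> list[str]:
    """Plain-text site list, one CpG id per line."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_sites(sites: list[str], path) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(str(s) for s in sites) + "\n")
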