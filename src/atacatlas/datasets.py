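"""Bundled reference tables.

The package ships the sample-metadata / mapping-statistics sheet of a
66-library mouse tissue ATAC-seq atlas (20 tissues, male and female, two
technical replicates each) as a plain-text transcription of the published
tables. It carries, per library: tissue/sex/replicate metadata, total,
mapped, mitochondrial and usable read counts, the printed usable-read
percentage, the TSS enrichment score, and the number of
replicate-reproducible (IDR) peaks.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .io import SampleRecord, read_sample_sheet


def atlas_sheet_path() -> Path:
    """Path to the bundled mouse-tissue atlas sample sheet (TSV)."""
    return Path(resources.files("atacatlas").joinpath(
        "data/mouse_tissue_atlas_samples.tsv"))


def load_atlas_records() -> list[SampleRecord]:
    """The 66 atlas libraries as validated :class:`SampleRecord` objects."""
    return read_sample_sheet(atlas_sheet_path())


def load_atlas_frame() -> pd.DataFrame:
    """The raw sheet as a DataFrame, including the printed percentage column."""
    df = pd.read_csv(atlas_sheet_path(), sep="\t", dtype=str)
    for col in ("total_reads", "mapped_reads", "chrm_reads", "usable_reads",
                "reproducible_peaks"):
        df[col] = df[col].str.replace(",", "").astype(int)
    df["pct_usable"] = df["pct_usable"].astype(float)
    df["tss_enrichment"] = df["tss_enrichment"].astype(float)
    df["replicate"] = df["replicate"].astype(int)
    df["serial"] = df["serial"].astype(int)
    return df
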