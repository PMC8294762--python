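"""File formats: count/design TSVs, BED6 peaks, gene models, TIFF rasters.

Conventions
-----------
- Count matrices: TSV with the gene identifier in the first column and one
  column per sample; integer counts; lossless round trip.
- Designs: TSV with columns ``sample`` and ``group``.
- Peaks: BED6, 0-based half-open, kept 0-based internally.
- Gene models: TSV with columns ``gene, region, chrom, start, end, strand``
  in 1-based inclusive coordinates (the common annotation-table convention);
  converted on read to the internal 0-based half-open representation by
  ``start - 1`` / ``end`` unchanged.
- Images: multi-channel TIFF, channels as pages, pixel size recorded in the
  image description metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from ribodrop.containers import CountMatrix, ImageRaster
from ribodrop.errors import ParseError
from ribodrop.shift import REGION_LABELS

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_counts(path: str | Path, design_path: str | Path) -> CountMatrix:
    """Read a gene × sample count TSV plus a sample/group design TSV."""
    path = Path(path)
    try:
        table = pd.read_csv(path, sep="\t", header=0)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty counts file") from exc
    if table.shape[1] < 2:
        raise ParseError(f"{path}: need a gene column plus at least one sample column")
    gene_col = table.columns[0]
    genes = table[gene_col].astype(str)
    dup = genes[genes.duplicated()]
    if not dup.empty:
        row = int(dup.index[0]) + 2  # header is line 1
        raise ParseError(f"{path}: duplicate gene id {dup.iloc[0]!r} at line {row}")
    values = table.drop(columns=[gene_col])
    for col in values.columns:
        numeric = pd.to_numeric(values[col], errors="coerce")
        bad = numeric.isna() | (numeric % 1 != 0) | (numeric < 0)
        if bad.any():
            row = int(np.argmax(bad.to_numpy())) + 2
            raise ParseError(f"{path}: non-integer or negative count in column {col!r}, line {row}")
        values[col] = numeric.astype(np.int64)
    values.index = pd.Index(genes, name=gene_col)

    design = pd.read_csv(design_path, sep="\t", header=0)
    if not {"sample", "group"} <= set(design.columns):
        raise ParseError(f"{design_path}: design needs columns 'sample' and 'group'")
    design = design.set_index("sample")["group"].astype(str)
    missing = [s for s in values.columns if s not in design.index]
    if missing:
        raise ParseError(f"{design_path}: samples missing from design: {missing}")
    return CountMatrix(values, design.reindex(values.columns))


def write_counts(cm: CountMatrix, path: str | Path, design_path: str | Path) -> None:
    """Write a count matrix and its design as TSVs (inverse of read_counts)."""
    out = cm.counts.copy()
    out.index.name = out.index.name or "gene"
    out.to_csv(path, sep="\t")
    cm.design.rename_axis("sample").rename("group").reset_index().to_csv(
        design_path, sep="\t", index=False
    )


def write_table(obj: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV without the index."""
    obj.to_csv(path, sep="\t", index=False)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED6 peak file (0-based half-open) into a peak table."""
    path = Path(path)
    try:
        table = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty BED file") from exc
    if table.shape[1] < 6:
        raise ParseError(f"{path}: BED6 requires 6 columns, found {table.shape[1]}")
    table = table.iloc[:, :6]
    table.columns = BED6_COLUMNS
    table["start"] = pd.to_numeric(table["start"], errors="raise").astype(int)
    table["end"] = pd.to_numeric(table["end"], errors="raise").astype(int)
    bad = table["start"] >= table["end"]
    if bad.any():
        row = int(np.argmax(bad.to_numpy())) + 1
        raise ParseError(f"{path}: start >= end at line {row} (BED is 0-based half-open)")
    bad_strand = ~table["strand"].isin(["+", "-", "."])
    if bad_strand.any():
        row = int(np.argmax(bad_strand.to_numpy())) + 1
        raise ParseError(f"{path}: invalid strand at line {row}")
    return table


def write_bed(peaks: pd.DataFrame, path: str | Path) -> None:
    peaks[BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_gene_models(path: str | Path) -> pd.DataFrame:
    """Read a gene-model TSV (1-based inclusive) into 0-based half-open form."""
    path = Path(path)
    table = pd.read_csv(path, sep="\t", header=0)
    needed = {"gene", "region", "chrom", "start", "end", "strand"}
    if not needed <= set(table.columns):
        raise ParseError(f"{path}: gene models need columns {sorted(needed)}")
    bad = ~table["region"].isin(REGION_LABELS)
    if bad.any():
        row = int(np.argmax(bad.to_numpy())) + 2
        raise ParseError(f"{path}: unknown region label at line {row}")
    table = table.copy()
    table["start"] = table["start"].astype(int) - 1  # 1-based inclusive -> 0-based half-open
    table["end"] = table["end"].astype(int)
    bad = table["start"] >= table["end"]
    if bad.any():
        row = int(np.argmax(bad.to_numpy())) + 2
        raise ParseError(f"{path}: empty or inverted interval at line {row}")
    return table


def read_gene_list(path: str | Path) -> set[str]:
    """Read a plain one-gene-per-line target list (e.g. a published CLIP set)."""
    lines = Path(path).read_text().splitlines()
    return {line.strip() for line in lines if line.strip() and not line.startswith("#")}


def write_image(image: ImageRaster, path: str | Path) -> None:
    """Write a raster as a multi-page TIFF with channel names and pixel size."""
    names = list(image.channels)
    stack = np.stack([image.channels[ch].astype(np.float32) for ch in names])
    meta = {"channels": names, "pixel_size_um": image.pixel_size_um}
    tifffile.imwrite(path, stack, description=json.dumps(meta))


def read_image(path: str | Path) -> ImageRaster:
    """Read a multi-page TIFF written by :func:`write_image`."""
    with tifffile.TiffFile(path) as tif:
        stack = tif.asarray()
        desc = tif.pages[0].description
    try:
        meta = json.loads(desc)
        names = meta["channels"]
        pixel_size = float(meta["pixel_size_um"])
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise ParseError(f"{path}: missing channel/pixel-size metadata") from exc
    if stack.ndim == 2:
        stack = stack[None]
    channels = {name: stack[i].astype(float) for i, name in enumerate(names)}
    return ImageRaster(channels, pixel_size)
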