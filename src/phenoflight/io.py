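"""Readers and writers for the on-disk formats.

One pinned text dialect everywhere: tab-separated, UTF-8, '.' decimal,
``NA`` for missing. Flight identifiers are integers in days after
planting. Band stacks and height grids are GeoTIFFs written with
``tifffile``; band order, flight day and resolution travel in the TIFF
description tag as JSON. Plot layouts are GeoJSON polygons in raster pixel
coordinates (no CRS is attached for synthetic fixtures).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import Polygon, shape, mapping

from .features import FeatureMatrix
from .imaging import BandStack, FieldLayout, PlotRecord, PHENOMIC_COLUMNS
from .predict import SplitPlan
from .simdata import MarkerSet

__all__ = [
    "read_phenomic_table", "write_phenomic_table",
    "read_marker_table", "write_marker_table",
    "read_trait_table", "write_trait_table",
    "read_blup_matrix", "write_blup_matrix",
    "read_feature_matrix", "write_feature_matrix",
    "read_split_plan", "write_split_plan",
    "read_band_stack", "write_band_stack",
    "read_height_grid", "write_height_grid",
    "read_layout", "write_layout",
]

logger = logging.getLogger(__name__)

_TSV = dict(sep="\t", na_rep="NA", index=False)


# ---------------------------------------------------------------------------
# phenomic tables


def write_phenomic_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table[list(PHENOMIC_COLUMNS)].to_csv(path, **_TSV)
    return path


def read_phenomic_table(path: str | Path,
                        column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a long-format phenomic table (or a wide one-column-per-flight file).

    ``column_map`` renames dialect columns onto the standard schema, e.g.
    ``{"management": "trial", "DAP": "flight_day"}``. Wide tables with
    columns named like integers (or ``<prefix>_<day>``) are melted to long
    format. Duplicate (plot, flight, trait) keys are an error.
    """
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    if column_map:
        df = df.rename(columns=dict(column_map))
    required = set(PHENOMIC_COLUMNS) - {"value", "flight_day"}
    if "value" not in df.columns or "flight_day" not in df.columns:
        day_cols = [c for c in df.columns if _parse_day(c) is not None]
        if not day_cols:
            raise ValueError(
                f"phenomic table needs columns {list(PHENOMIC_COLUMNS)} or "
                "wide per-flight columns; found " + ", ".join(df.columns))
        ids = [c for c in df.columns if c not in day_cols]
        df = df.melt(id_vars=ids, value_vars=day_cols,
                     var_name="flight_day", value_name="value")
        df["flight_day"] = [_parse_day(c) for c in df["flight_day"]]
    missing = required - set(df.columns)
    if missing:
        raise ValueError(
            f"phenomic table missing columns {sorted(missing)}; expected header "
            f"{list(PHENOMIC_COLUMNS)}")
    df["flight_day"] = df["flight_day"].map(_normalize_day)
    df["rep"] = df["rep"].astype(int)
    df["value"] = pd.to_numeric(df["value"], errors="raise")
    dupes = df.duplicated(subset=["trial", "plot", "flight_day", "trait_id"])
    if dupes.any():
        first = df[dupes].iloc[0]
        raise ValueError(
            "duplicated (plot, flight, trait) rows, first at plot="
            f"{first['plot']!r} flight_day={first['flight_day']} trait={first['trait_id']!r}")
    return df[list(PHENOMIC_COLUMNS)]


def _parse_day(col: str) -> int | None:
    s = str(col)
    if s.isdigit():
        return int(s)
    if "_" in s and s.rsplit("_", 1)[1].isdigit():
        return int(s.rsplit("_", 1)[1])
    return None


def _normalize_day(v) -> int:
    """Flight identifiers become integer days after planting."""
    if isinstance(v, (int, np.integer)):
        return int(v)
    if isinstance(v, float) and float(v).is_integer():
        return int(v)
    s = str(v)
    if s.isdigit():
        return int(s)
    raise ValueError(f"cannot interpret flight identifier {v!r} as days after planting")


# ---------------------------------------------------------------------------
# markers


def write_marker_table(markers: MarkerSet, path: str | Path) -> Path:
    path = Path(path)
    markers.to_frame().to_csv(path, sep="\t", na_rep="NA", index=True,
                              index_label="genotype")
    return path


_HAPMAP_META = ["rs#", "alleles", "chrom", "pos", "strand", "assembly#",
                "center", "protLSID", "assayLSID", "panelLSID", "QCcode"]


def read_marker_table(path: str | Path) -> MarkerSet:
    """Read a dosage matrix (genotypes x markers) or HapMap-style text.

    Dosages are coerced to {0, 1, 2, missing}; missing cells are imputed to
    the per-marker mean dosage with a logged count. Non-biallelic or
    non-numeric codes fail with the offending cell's coordinates.
    """
    path = Path(path)
    head = pd.read_csv(path, sep="\t", nrows=1)
    if head.columns[0] in ("rs#", "rs"):
        return _read_hapmap(path)
    df = pd.read_csv(path, sep="\t", na_values=["NA"], index_col=0)
    dosage = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.argmax()]
            raise ValueError(
                f"non-numeric dosage at genotype {row!r}, marker {col!r}: "
                f"{df.loc[row, col]!r}")
        out_of_range = vals.notna() & ~vals.isin([0, 1, 2])
        if out_of_range.any():
            row = df.index[out_of_range.argmax()]
            raise ValueError(
                f"non-biallelic dosage at genotype {row!r}, marker {col!r}: "
                f"{df.loc[row, col]!r} (expected 0, 1, 2 or NA)")
        dosage[:, j] = vals.to_numpy(dtype=float)
    dosage = _impute_mean(dosage)
    freq = dosage.mean(axis=0) / 2.0
    n = len(df.columns)
    positions = pd.DataFrame({"marker_id": list(df.columns),
                              "chrom": np.ones(n, dtype=int),
                              "pos": np.arange(1, n + 1) * 1000})
    return MarkerSet(genotypes=list(df.index.astype(str)),
                     marker_ids=list(df.columns), dosage=dosage,
                     positions=positions, allele_freq=freq)


def _read_hapmap(path: Path) -> MarkerSet:
    df = pd.read_csv(path, sep="\t")
    meta_cols = [c for c in df.columns if c in _HAPMAP_META]
    geno_cols = [c for c in df.columns if c not in _HAPMAP_META]
    dosage = np.empty((len(geno_cols), len(df)), dtype=float)
    for i, row in df.iterrows():
        alleles = str(row["alleles"]).split("/")
        if len(alleles) != 2:
            raise ValueError(f"marker {row[df.columns[0]]!r}: non-biallelic "
                             f"alleles field {row['alleles']!r}")
        ref, alt = alleles
        for j, g in enumerate(geno_cols):
            call = str(row[g])
            if call in ("NN", "N", "NA", "nan"):
                dosage[j, i] = np.nan
                continue
            letters = list(call) if len(call) == 2 else [call, call]
            if any(a not in (ref, alt) for a in letters):
                raise ValueError(
                    f"non-biallelic call at marker {row[df.columns[0]]!r}, "
                    f"genotype {g!r}: {call!r} (alleles {row['alleles']!r})")
            dosage[j, i] = sum(a == alt for a in letters)
    dosage = _impute_mean(dosage)
    freq = dosage.mean(axis=0) / 2.0
    positions = pd.DataFrame({
        "marker_id": df[df.columns[0]].astype(str),
        "chrom": df["chrom"] if "chrom" in df else 1,
        "pos": df["pos"] if "pos" in df else np.arange(1, len(df) + 1) * 1000})
    return MarkerSet(genotypes=[str(g) for g in geno_cols],
                     marker_ids=list(df[df.columns[0]].astype(str)),
                     dosage=dosage, positions=positions, allele_freq=freq)


def _impute_mean(dosage: np.ndarray) -> np.ndarray:
    n_missing = int(np.isnan(dosage).sum())
    if n_missing:
        logger.info("imputing %d missing dosages to per-marker means", n_missing)
        col_mean = np.nanmean(dosage, axis=0)
        idx = np.where(np.isnan(dosage))
        dosage[idx] = col_mean[idx[1]]
    return dosage


# ---------------------------------------------------------------------------
# traits / matrices / plans


def write_trait_table(traits: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    traits.to_csv(path, **_TSV)
    return path


def read_trait_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    if "genotype" not in df.columns:
        raise ValueError("trait table requires a 'genotype' column")
    return df


def write_blup_matrix(matrix: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    matrix.to_csv(path, sep="\t", na_rep="NA", index=True, index_label="genotype")
    return path


def read_blup_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], index_col=0)
    df.columns = [int(c) for c in df.columns]
    return df.rename_axis(None)


def write_feature_matrix(features: FeatureMatrix, path: str | Path) -> Path:
    path = Path(path)
    meta = {"platform": features.platform,
            "temporal_columns": features.temporal_columns,
            "derived_columns": features.derived_columns}
    features.values.to_csv(path, sep="\t", na_rep="NA", index=True,
                           index_label="genotype")
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))
    return path


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    path = Path(path)
    values = pd.read_csv(path, sep="\t", na_values=["NA"], index_col=0).rename_axis(None)
    meta_path = Path(str(path) + ".meta.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
    else:
        temporal = [c for c in values.columns if "@" in c]
        meta = {"platform": "unknown", "temporal_columns": temporal,
                "derived_columns": [c for c in values.columns if c not in temporal]}
    return FeatureMatrix(values=values, platform=meta["platform"],
                         temporal_columns=meta["temporal_columns"],
                         derived_columns=meta["derived_columns"])


def write_split_plan(plan: SplitPlan, path: str | Path) -> Path:
    path = Path(path)
    payload = {"genotypes": plan.genotypes, "train_frac": plan.train_frac,
               "n_iter": plan.n_iter, "seed": plan.seed,
               "iterations": [[list(tr), list(te)] for tr, te in plan.iterations]}
    path.write_text(json.dumps(payload))
    return path


def read_split_plan(path: str | Path) -> SplitPlan:
    payload = json.loads(Path(path).read_text())
    return SplitPlan(genotypes=payload["genotypes"],
                     train_frac=payload["train_frac"], n_iter=payload["n_iter"],
                     seed=payload["seed"],
                     iterations=[(list(tr), list(te))
                                 for tr, te in payload["iterations"]])


# ---------------------------------------------------------------------------
# rasters and layouts


def write_band_stack(stack: BandStack, path: str | Path,
                     band_order: Sequence[str] | None = None) -> Path:
    path = Path(path)
    order = list(band_order) if band_order else [b for b in ("R", "G", "B", "RE", "NIR")
                                                 if b in stack.bands]
    data = np.stack([stack.bands[b] for b in order]).astype(np.float32)
    meta = {"band_order": order, "flight_day": stack.flight_day,
            "resolution": stack.resolution, "origin": list(stack.origin),
            "scale": "reflectance"}
    tifffile.imwrite(path, data, photometric="minisblack",
                     planarconfig="separate", description=json.dumps(meta))
    return path


def read_band_stack(path: str | Path,
                    band_order: Sequence[str] | None = None,
                    flight_day: int | None = None) -> BandStack:
    """Read a multi-band GeoTIFF; band order from metadata unless given.

    Integer (8-bit DN) rasters are rescaled to reflectance by 1/255.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except json.JSONDecodeError:
            meta = {}
    if data.ndim == 2:
        data = data[None]
    if data.shape[-1] in (3, 5) and data.shape[0] not in (3, 5):
        data = np.moveaxis(data, -1, 0)
    order = list(band_order) if band_order else meta.get("band_order")
    if order is None:
        raise ValueError(f"{path}: no band order in metadata; pass band_order "
                         "(e.g. R,G,B or R,G,B,RE,NIR)")
    if len(order) != data.shape[0]:
        raise ValueError(f"{path}: {data.shape[0]} bands but order {order}")
    arr = data.astype(float)
    if np.issubdtype(data.dtype, np.integer):
        arr = arr / 255.0
    day = flight_day if flight_day is not None else meta.get("flight_day")
    if day is None:
        raise ValueError(f"{path}: flight_day not in metadata; pass flight_day")
    return BandStack(bands={b: arr[i] for i, b in enumerate(order)},
                     flight_day=int(day),
                     resolution=float(meta.get("resolution", 1.0)),
                     origin=tuple(meta.get("origin", (0.0, 0.0))))


def write_height_grid(grid: np.ndarray, flight_day: int, path: str | Path) -> Path:
    path = Path(path)
    meta = {"flight_day": int(flight_day), "units": "height"}
    tifffile.imwrite(path, np.asarray(grid, dtype=np.float32),
                     description=json.dumps(meta))
    return path


def read_height_grid(path: str | Path) -> tuple[np.ndarray, int | None]:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray().astype(float)
        desc = tif.pages[0].description
    day = None
    if desc:
        try:
            day = json.loads(desc).get("flight_day")
        except json.JSONDecodeError:
            pass
    return data, (int(day) if day is not None else None)


def write_layout(layout: FieldLayout, path: str | Path) -> Path:
    path = Path(path)
    features = [{
        "type": "Feature",
        "geometry": mapping(p.polygon),
        "properties": {"plot": p.plot_id, "genotype": p.genotype,
                       "trial": p.trial, "rep": p.replicate},
    } for p in layout]
    path.write_text(json.dumps({"type": "FeatureCollection", "features": features}))
    return path


def read_layout(path: str | Path) -> FieldLayout:
    payload = json.loads(Path(path).read_text())
    plots = []
    for feat in payload["features"]:
        props = feat["properties"]
        geom = shape(feat["geometry"])
        if not isinstance(geom, Polygon):
            raise ValueError(f"plot {props.get('plot')!r}: geometry must be a Polygon")
        plots.append(PlotRecord(plot_id=str(props["plot"]),
                                genotype=str(props["genotype"]),
                                trial=str(props.get("trial", "OM")),
                                replicate=int(props.get("rep", 1)),
                                polygon=geom))
    return FieldLayout(plots)
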