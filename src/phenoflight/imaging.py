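"""Vegetation indices and plot-level extraction from band stacks.

A :class:`BandStack` holds co-registered reflectance rasters for one UAS
flight (R, G, B and optionally red-edge RE and near-infrared NIR). Plot
polygons from a :class:`FieldLayout` are applied to per-pixel vegetation
index (VI) arrays and height grids to produce a long-format phenomic table
with one row per (plot, flight, trait).

Conventions
-----------
* Reflectance is floating point in [0, 1]; 8-bit inputs are rescaled by
  1/255 on read (see :mod:`phenoflight.io`).
* Pixel (row r, col c) has its center at raster coordinates
  (x = c + 0.5, y = r + 0.5). A pixel belongs to a polygon when its center
  falls in the half-open interior: centers on a shared boundary are
  assigned to the polygon whose interior lies toward +x/+y, so adjacent
  plots partition the raster deterministically.
* Undefined pixels (division by zero in an index) become NaN and are
  excluded from plot aggregation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

__all__ = [
    "BandStack",
    "FieldLayout",
    "PlotRecord",
    "VIRegistry",
    "DEFAULT_REGISTRY",
    "compute_vi",
    "extract_plot_value",
    "extract_canopy_height",
    "build_phenomic_table",
]

RGB_BANDS = ("R", "G", "B")
ALL_BANDS = ("R", "G", "B", "RE", "NIR")

#: Column schema of the long-format phenomic table.
PHENOMIC_COLUMNS = ("trial", "flight_day", "rep", "plot", "genotype", "trait_id", "value")


# ---------------------------------------------------------------------------
# containers


@dataclass
class BandStack:
    """Co-registered reflectance bands for a single flight."""

    bands: dict[str, np.ndarray]
    flight_day: int
    resolution: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        shapes = {b: a.shape for b, a in self.bands.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"band arrays differ in shape: {shapes}")
        for name, arr in self.bands.items():
            if name not in ALL_BANDS:
                raise ValueError(f"unknown band {name!r}; expected one of {ALL_BANDS}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"band {name!r} contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.bands.values())).shape


@dataclass
class PlotRecord:
    plot_id: str
    genotype: str
    trial: str
    replicate: int
    polygon: Polygon


@dataclass
class FieldLayout:
    """Plot polygons in raster coordinates with their design metadata."""

    plots: list[PlotRecord]

    def __post_init__(self) -> None:
        ids = [p.plot_id for p in self.plots]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate plot ids: {dupes}")
        bad = [p.plot_id for p in self.plots if not p.polygon.is_valid]
        if bad:
            raise ValueError(f"non-simple polygons for plots: {bad}")

    def __iter__(self):
        return iter(self.plots)

    def __len__(self) -> int:
        return len(self.plots)

    def bounds(self) -> tuple[float, float, float, float]:
        geoms = [p.polygon for p in self.plots]
        return shapely.unary_union(geoms).bounds


# ---------------------------------------------------------------------------
# vegetation-index registry


@dataclass(frozen=True)
class VIDefinition:
    index_id: str
    required_bands: tuple[str, ...]
    formula: Callable[[Mapping[str, np.ndarray]], np.ndarray]
    valid_range: tuple[float, float] | None
    description: str = ""


class VIRegistry:
    """Registry mapping index ids to band requirements and formulas.

    Formulas are evaluated element-wise on reflectance arrays; pixels where
    a denominator vanishes are returned as NaN rather than +/-inf.
    """

    def __init__(self, entries: Iterable[VIDefinition] = ()) -> None:
        self._entries: dict[str, VIDefinition] = {}
        for e in entries:
            self.register(e)

    def register(self, entry: VIDefinition) -> None:
        self._entries[entry.index_id] = entry

    def __contains__(self, index_id: str) -> bool:
        return index_id in self._entries

    def __getitem__(self, index_id: str) -> VIDefinition:
        try:
            return self._entries[index_id]
        except KeyError:
            raise KeyError(
                f"unknown vegetation index {index_id!r}; available: "
                f"{sorted(self._entries)}"
            ) from None

    def ids(self, bands: Sequence[str] | None = None) -> list[str]:
        """Index ids computable from the given band set (all if None)."""
        if bands is None:
            return sorted(self._entries)
        avail = set(bands)
        return sorted(i for i, e in self._entries.items() if set(e.required_bands) <= avail)

    def rgb_ids(self) -> list[str]:
        return self.ids(RGB_BANDS)

    def multispectral_ids(self) -> list[str]:
        """Indices that require RE and/or NIR in addition to RGB."""
        return sorted(
            i for i, e in self._entries.items() if {"RE", "NIR"} & set(e.required_bands)
        )


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.full(np.broadcast(num, den).shape, np.nan)
    ok = np.abs(den) > 1e-12
    np.divide(num, den, out=out, where=ok)
    return out


def _build_default_registry() -> VIRegistry:
    reg = VIRegistry()

    def add(index_id, bands, formula, rng, desc=""):
        reg.register(VIDefinition(index_id, tuple(bands), formula, rng, desc))

    # --- RGB-only indices -------------------------------------------------
    add("RCC", "RGB", lambda b: _safe_div(b["R"], b["R"] + b["G"] + b["B"]), (0, 1),
        "red chromatic coordinate")
    add("GCC", "RGB", lambda b: _safe_div(b["G"], b["R"] + b["G"] + b["B"]), (0, 1),
        "green chromatic coordinate")
    add("BCC", "RGB", lambda b: _safe_div(b["B"], b["R"] + b["G"] + b["B"]), (0, 1),
        "blue chromatic coordinate")
    add("NGRDI", "RG", lambda b: _safe_div(b["G"] - b["R"], b["G"] + b["R"]), (-1, 1),
        "normalized green-red difference")
    add("NGBDI", "GB", lambda b: _safe_div(b["G"] - b["B"], b["G"] + b["B"]), (-1, 1),
        "normalized green-blue difference")
    add("IKAW", "RB", lambda b: _safe_div(b["R"] - b["B"], b["R"] + b["B"]), (-1, 1),
        "Kawashima index")
    add("MGRVI", "RG",
        lambda b: _safe_div(b["G"] ** 2 - b["R"] ** 2, b["G"] ** 2 + b["R"] ** 2),
        (-1, 1), "modified green-red vegetation index")
    add("RGBVI", "RGB",
        lambda b: _safe_div(b["G"] ** 2 - b["B"] * b["R"], b["G"] ** 2 + b["B"] * b["R"]),
        (-1, 1), "RGB vegetation index")
    add("GLI", "RGB",
        lambda b: _safe_div(2 * b["G"] - b["R"] - b["B"], 2 * b["G"] + b["R"] + b["B"]),
        (-1, 1), "green leaf index")
    add("VARI", "RGB",
        lambda b: _safe_div(b["G"] - b["R"], b["G"] + b["R"] - b["B"]), None,
        "visible atmospherically resistant index")
    add("ExG", "RGB", lambda b: 2 * b["G"] - b["R"] - b["B"], (-2, 2),
        "excess green")
    add("ExR", "RG", lambda b: 1.4 * b["R"] - b["G"], (-1, 1.4), "excess red")
    add("ExB", "GB", lambda b: 1.4 * b["B"] - b["G"], (-1, 1.4), "excess blue")
    add("ExGR", "RGB", lambda b: (2 * b["G"] - b["R"] - b["B"]) - (1.4 * b["R"] - b["G"]),
        (-3.4, 3), "excess green minus excess red")
    add("CIVE", "RGB",
        lambda b: 0.441 * b["R"] - 0.811 * b["G"] + 0.385 * b["B"] + 18.78745, None,
        "color index of vegetation extraction")
    add("VEG", "RGB",
        lambda b: _safe_div(b["G"], np.clip(b["R"], 1e-12, None) ** (2 / 3)
                            * np.clip(b["B"], 1e-12, None) ** (1 / 3)),
        None, "vegetativen index")
    add("MExG", "RGB", lambda b: 1.262 * b["G"] - 0.884 * b["R"] - 0.311 * b["B"],
        None, "modified excess green")
    add("COM", "RGB",
        lambda b: 0.25 * (2 * b["G"] - b["R"] - b["B"])
        + 0.30 * ((2 * b["G"] - b["R"] - b["B"]) - (1.4 * b["R"] - b["G"]))
        + 0.33 * (0.441 * b["R"] - 0.811 * b["G"] + 0.385 * b["B"] + 18.78745)
        + 0.12 * _safe_div(b["G"], np.clip(b["R"], 1e-12, None) ** (2 / 3)
                           * np.clip(b["B"], 1e-12, None) ** (1 / 3)),
        None, "combined greenness index")
    add("RGRI", "RG", lambda b: _safe_div(b["R"], b["G"]), None, "red-green ratio")
    add("BGI", "GB", lambda b: _safe_div(b["B"], b["G"]), None, "blue-green ratio")

    # --- indices using red-edge / NIR ------------------------------------
    add("NDVI", ("R", "NIR"),
        lambda b: _safe_div(b["NIR"] - b["R"], b["NIR"] + b["R"]), (-1, 1),
        "normalized difference vegetation index")
    add("GNDVI", ("G", "NIR"),
        lambda b: _safe_div(b["NIR"] - b["G"], b["NIR"] + b["G"]), (-1, 1),
        "green NDVI")
    add("NDRE", ("RE", "NIR"),
        lambda b: _safe_div(b["NIR"] - b["RE"], b["NIR"] + b["RE"]), (-1, 1),
        "normalized difference red edge")
    add("SAVI", ("R", "NIR"),
        lambda b: 1.5 * _safe_div(b["NIR"] - b["R"], b["NIR"] + b["R"] + 0.5),
        (-1.5, 1.5), "soil-adjusted vegetation index (L=0.5)")
    add("OSAVI", ("R", "NIR"),
        lambda b: 1.16 * _safe_div(b["NIR"] - b["R"], b["NIR"] + b["R"] + 0.16),
        (-1.16, 1.16), "optimized SAVI")
    add("NLI", ("R", "NIR"),
        lambda b: _safe_div(b["NIR"] ** 2 - b["R"], b["NIR"] ** 2 + b["R"]), (-1, 1),
        "nonlinear index")
    add("MNLI", ("R", "NIR"),
        lambda b: 1.5 * _safe_div(b["NIR"] ** 2 - b["R"], b["NIR"] ** 2 + b["R"] + 0.5),
        (-1.5, 1.5), "modified nonlinear index (L=0.5)")
    add("EVI2", ("R", "NIR"),
        lambda b: 2.5 * _safe_div(b["NIR"] - b["R"], b["NIR"] + 2.4 * b["R"] + 1),
        (-2.5, 2.5), "two-band enhanced vegetation index")
    add("MSAVI", ("R", "NIR"),
        lambda b: 0.5 * (2 * b["NIR"] + 1
                         - np.sqrt(np.clip((2 * b["NIR"] + 1) ** 2
                                           - 8 * (b["NIR"] - b["R"]), 0, None))),
        None, "modified SAVI")
    add("RDVI", ("R", "NIR"),
        lambda b: _safe_div(b["NIR"] - b["R"],
                            np.sqrt(np.clip(b["NIR"] + b["R"], 1e-12, None))),
        None, "renormalized difference vegetation index")
    add("SR", ("R", "NIR"), lambda b: _safe_div(b["NIR"], b["R"]), None,
        "simple ratio")
    add("DVI", ("R", "NIR"), lambda b: b["NIR"] - b["R"], (-1, 1),
        "difference vegetation index")
    add("CIG", ("G", "NIR"), lambda b: _safe_div(b["NIR"], b["G"]) - 1, None,
        "chlorophyll index green")
    add("CIRE", ("RE", "NIR"), lambda b: _safe_div(b["NIR"], b["RE"]) - 1, None,
        "chlorophyll index red edge")
    add("SRRE", ("RE", "NIR"), lambda b: _safe_div(b["NIR"], b["RE"]), None,
        "red-edge simple ratio")
    add("MSR", ("R", "NIR"),
        lambda b: _safe_div(_safe_div(b["NIR"], b["R"]) - 1,
                            np.sqrt(np.clip(_safe_div(b["NIR"], b["R"]) + 1, 0, None))),
        None, "modified simple ratio")
    add("WDRVI", ("R", "NIR"),
        lambda b: _safe_div(0.12 * b["NIR"] - b["R"], 0.12 * b["NIR"] + b["R"]),
        (-1, 1), "wide dynamic range vegetation index (alpha=0.12)")
    add("TVI", ("G", "R", "NIR"),
        lambda b: 0.5 * (120 * (b["NIR"] - b["G"]) - 200 * (b["R"] - b["G"])),
        None, "triangular vegetation index")
    add("MCARI", ("G", "R", "RE"),
        lambda b: ((b["RE"] - b["R"]) - 0.2 * (b["RE"] - b["G"]))
        * _safe_div(b["RE"], b["R"]),
        None, "modified chlorophyll absorption ratio index")
    add("TCARI", ("G", "R", "RE"),
        lambda b: 3 * ((b["RE"] - b["R"])
                       - 0.2 * (b["RE"] - b["G"]) * _safe_div(b["RE"], b["R"])),
        None, "transformed chlorophyll absorption ratio index")
    return reg


#: Default index panel: >=20 RGB-only and >=20 red-edge/NIR indices.
DEFAULT_REGISTRY = _build_default_registry()


# ---------------------------------------------------------------------------
# operations


def compute_vi(
    stack: BandStack, index_id: str, registry: VIRegistry = DEFAULT_REGISTRY
) -> np.ndarray:
    """Evaluate a registered vegetation index over a band stack.

    Returns a float array of the stack's shape; pixels where the formula is
    undefined (vanishing denominator) are NaN.
    """
    entry = registry[index_id]
    missing = [b for b in entry.required_bands if b not in stack.bands]
    if missing:
        raise ValueError(f"index {index_id!r} requires missing band(s) {missing}")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = entry.formula(stack.bands).astype(float)
    out[~np.isfinite(out)] = np.nan
    return out


class EmptyPlotError(ValueError):
    """No pixel centers fall inside the polygon (geometric miss)."""


class AllMissingError(ValueError):
    """Pixels fall inside the polygon but every one is NaN."""


# epsilon (in pixels) nudging sampling points toward +x/+y so that centers
# on a shared plot boundary are claimed by exactly one polygon
_EDGE_EPS = 1e-9


def _inside_mask(shape: tuple[int, int], polygon: Polygon) -> np.ndarray:
    minx, miny, maxx, maxy = polygon.bounds
    nrow, ncol = shape
    r0 = max(int(np.floor(miny - 0.5)), 0)
    r1 = min(int(np.ceil(maxy + 0.5)), nrow)
    c0 = max(int(np.floor(minx - 0.5)), 0)
    c1 = min(int(np.ceil(maxx + 0.5)), ncol)
    mask = np.zeros(shape, dtype=bool)
    if r1 <= r0 or c1 <= c0:
        return mask
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    xs = cc + 0.5 + _EDGE_EPS
    ys = rr + 0.5 + _EDGE_EPS
    mask[r0:r1, c0:c1] = shapely.contains_xy(polygon, xs, ys)
    return mask


def _in_plot_values(
    array: np.ndarray, polygon: Polygon, plot_id: str | None
) -> np.ndarray:
    label = f" (plot {plot_id})" if plot_id else ""
    mask = _inside_mask(array.shape, polygon)
    if not mask.any():
        raise EmptyPlotError(f"no pixel centers inside polygon{label}")
    vals = array[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise AllMissingError(f"all in-plot pixels missing{label}")
    return vals


def extract_plot_value(
    array: np.ndarray,
    polygon: Polygon,
    aggregator: str = "mean",
    plot_id: str | None = None,
) -> float:
    """Aggregate pixels whose centers fall inside the polygon.

    NaN pixels are excluded. Raises :class:`EmptyPlotError` when the polygon
    covers no pixel centers and :class:`AllMissingError` when it covers only
    NaN pixels.
    """
    if aggregator not in ("mean", "median"):
        raise ValueError(f"aggregator must be 'mean' or 'median', got {aggregator!r}")
    vals = _in_plot_values(array, polygon, plot_id)
    return float(np.mean(vals) if aggregator == "mean" else np.median(vals))


def extract_canopy_height(
    height_grid: np.ndarray,
    polygon: Polygon,
    percentile: float = 99.0,
    plot_id: str | None = None,
) -> float:
    """Percentile (linear interpolation between order statistics) of in-plot
    heights; the 99th percentile is the conventional canopy height measure."""
    if not 0 <= percentile <= 100:
        raise ValueError(f"percentile must be in [0, 100], got {percentile}")
    vals = _in_plot_values(height_grid, polygon, plot_id)
    return float(np.percentile(vals, percentile, method="linear"))


def exg_soil_mask(stack: BandStack, threshold: float = 0.05) -> np.ndarray:
    """Optional soil mask: True where ExG exceeds the threshold (vegetation)."""
    exg = compute_vi(stack, "ExG")
    return exg > threshold


def build_phenomic_table(
    stacks: Sequence[BandStack],
    height_grids: Mapping[int, np.ndarray] | None,
    layout: FieldLayout,
    panel: Sequence[str] | None = None,
    registry: VIRegistry = DEFAULT_REGISTRY,
    aggregator: str = "mean",
    chm_percentile: float = 99.0,
    soil_mask_threshold: float | None = None,
) -> pd.DataFrame:
    """Extract a long-format phenomic table from per-flight rasters.

    Parameters
    ----------
    stacks
        One :class:`BandStack` per flight, flight_days strictly increasing.
    height_grids
        Optional map flight_day -> height raster; adds a CHM trait.
    panel
        Vegetation index ids to extract; defaults to every registry index
        computable from the first stack's bands. May be empty (CHM only).
    soil_mask_threshold
        When given, pixels with ExG below the threshold are masked out of
        every index before aggregation.

    Returns a DataFrame with columns ``trial, flight_day, rep, plot,
    genotype, trait_id, value``; plots where an index is undefined
    everywhere are flagged missing (NaN value) rather than dropped.
    """
    days = [s.flight_day for s in stacks]
    if len(set(days)) != len(days):
        raise ValueError(f"duplicated flight_day in stacks: {days}")
    if days != sorted(days):
        raise ValueError(f"flight_days must be strictly increasing, got {days}")
    if panel is None:
        panel = registry.ids(list(stacks[0].bands)) if stacks else []

    rows = []
    for stack in stacks:
        arrays = {}
        mask = None
        if soil_mask_threshold is not None:
            mask = exg_soil_mask(stack, soil_mask_threshold)
        for index_id in panel:
            arr = compute_vi(stack, index_id, registry)
            if mask is not None:
                arr = np.where(mask, arr, np.nan)
            arrays[index_id] = arr
        hgrid = None
        if height_grids is not None and stack.flight_day in height_grids:
            hgrid = height_grids[stack.flight_day]
        for plot in layout:
            for index_id, arr in arrays.items():
                try:
                    val = extract_plot_value(arr, plot.polygon, aggregator, plot.plot_id)
                except AllMissingError:
                    val = np.nan
                rows.append((plot.trial, stack.flight_day, plot.replicate,
                             plot.plot_id, plot.genotype, index_id, val))
            if hgrid is not None:
                chm = extract_canopy_height(hgrid, plot.polygon, chm_percentile,
                                            plot.plot_id)
                rows.append((plot.trial, stack.flight_day, plot.replicate,
                             plot.plot_id, plot.genotype, "CHM", chm))
    table = pd.DataFrame(rows, columns=list(PHENOMIC_COLUMNS))
    n_missing = int(table["value"].isna().sum())
    if n_missing:
        warnings.warn(f"{n_missing} plot/flight/trait cells flagged missing",
                      stacklevel=2)
    return table
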