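"""Secondary temporal features: growth-curve fits, AUC, feature matrices.

Flight-wise genotypic values of each vegetation index are strung into a
wide predictor matrix — one column per (trait, flight) — optionally
augmented with the cumulative area under each temporal curve (AUC) and the
parameters of an asymptotic Weibull growth curve fitted to canopy height:

    H(t) = A * (1 - exp(-(t / B)^C)),

with asymptotic height ``A`` (height units), scale ``B`` (days, the time
to reach 1 - 1/e of the asymptote) and shape ``C`` (dimensionless). The
curve is non-decreasing and bounded by ``A``, matching sigmoid canopy
growth toward a terminal height.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "GrowthFit",
    "FeatureMatrix",
    "auc_trapezoid",
    "weibull_curve",
    "fit_weibull",
    "assemble_feature_matrix",
    "temporal_correlation_profile",
]

logger = logging.getLogger(__name__)


@dataclass
class GrowthFit:
    A: float       # asymptote, height units
    B: float       # scale, days
    C: float       # shape, dimensionless
    rmse: float
    n_points: int

    def __post_init__(self) -> None:
        if not (self.A > 0 and self.B > 0 and self.C > 0):
            raise ValueError(f"Weibull parameters must be positive: A={self.A}, B={self.B}, C={self.C}")
        if self.rmse < 0:
            raise ValueError("rmse must be non-negative")

    def predict(self, t) -> np.ndarray:
        return weibull_curve(np.asarray(t, dtype=float), self.A, self.B, self.C)


@dataclass
class FeatureMatrix:
    """Genotype x feature predictor table for one phenomic platform."""

    values: pd.DataFrame   # index genotypes; columns "trait@day" then derived
    platform: str          # e.g. "TPP_RGB" or "TPP_Multi"
    temporal_columns: list[str]
    derived_columns: list[str]

    @property
    def genotypes(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_temporal(self) -> int:
        return len(self.temporal_columns)


# ---------------------------------------------------------------------------
# AUC


def auc_trapezoid(times: Sequence[float], values: Sequence[float]) -> float:
    """Trapezoidal area under a temporal curve over the observed span.

    Units are value x days. Times must be strictly increasing with at
    least two points and no missing values.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise ValueError("times and values must be 1-D and of equal length")
    if t.size < 2:
        raise ValueError(f"need >= 2 points for AUC, got {t.size}")
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"times must be strictly increasing, got {t.tolist()}")
    if np.any(~np.isfinite(t)) or np.any(~np.isfinite(y)):
        raise ValueError("missing/non-finite values not allowed in AUC")
    return float(np.trapezoid(y, t))


# ---------------------------------------------------------------------------
# Weibull growth fit


def weibull_curve(t: np.ndarray, A: float, B: float, C: float) -> np.ndarray:
    t = np.clip(np.asarray(t, dtype=float), 0, None)
    return A * (1.0 - np.exp(-((t / B) ** C)))


def fit_weibull(times: Sequence[float], heights: Sequence[float],
                max_restarts: int = 4) -> GrowthFit:
    """Least-squares fit of the asymptotic Weibull growth curve.

    Self-starting: A0 = 1.05 * max height, B0 = time at half-max, C0 = 2;
    all parameters bounded positive. Restarts from perturbed starts on
    failure and raises with the best attempt's diagnostics if none
    converge.
    """
    t = np.asarray(times, dtype=float)
    h = np.asarray(heights, dtype=float)
    if t.shape != h.shape or t.ndim != 1:
        raise ValueError("times and heights must be 1-D and of equal length")
    if t.size < 4:
        raise ValueError(f"need >= 4 points to fit a 3-parameter curve, got {t.size}")
    if np.any(h < 0):
        raise ValueError("heights must be non-negative")
    hmax = h.max()
    if hmax <= 0:
        raise ValueError("all heights are zero: asymptote A > 0 is infeasible")

    half = 0.5 * hmax
    above = t[h >= half]
    b0 = float(above[0]) if above.size else float(np.median(t))
    b0 = max(b0, 1e-6)
    x0 = np.array([1.05 * hmax, b0, 2.0])

    def residuals(p):
        return weibull_curve(t, *p) - h

    lb = np.array([1e-9, 1e-9, 1e-9])
    ub = np.array([np.inf, np.inf, 50.0])
    best = None
    rng = np.random.default_rng(0)
    start = x0.copy()
    for attempt in range(max_restarts + 1):
        try:
            res = least_squares(residuals, np.clip(start, lb, ub), bounds=(lb, ub),
                                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=20_000)
        except Exception:  # pragma: no cover - scipy raises only on bad input
            res = None
        if res is not None and res.success:
            if best is None or res.cost < best.cost:
                best = res
        start = x0 * np.exp(rng.normal(0, 0.3, size=3))
    if best is None:
        raise RuntimeError(
            f"Weibull fit failed after {max_restarts + 1} starts "
            f"(initial A0={x0[0]:.3g}, B0={x0[1]:.3g}, C0={x0[2]:.3g})")
    A, B, C = best.x
    rmse = float(np.sqrt(np.mean(best.fun ** 2)))
    return GrowthFit(A=float(A), B=float(B), C=float(C), rmse=rmse, n_points=t.size)


# ---------------------------------------------------------------------------
# feature assembly


def _column_name(trait_id: str, flight_day: int | float) -> str:
    return f"{trait_id}@{int(flight_day)}"


def assemble_feature_matrix(
    blup_matrices: Mapping[str, pd.DataFrame],
    growth_fits: Mapping[str, GrowthFit] | None = None,
    traits: Sequence[str] | None = None,
    flights: Sequence[int] | None = None,
    platform: str = "TPP_RGB",
    include_auc: bool = False,
    include_weibull: bool = False,
    strict: bool = False,
) -> FeatureMatrix:
    """Assemble the genotype x (trait x flight) predictor table.

    Temporal columns are sorted by (trait_id, flight_day) — giving the
    n_traits x n_flights column convention (e.g. 35 x 15 = 525 RGB
    features, 89 x 12 = 1,068 multispectral features) — with AUC and
    Weibull A/B/C columns appended on request. Genotypes with any missing
    cell are dropped with a logged count, or rejected under ``strict``.
    """
    traits = sorted(blup_matrices) if traits is None else list(traits)
    missing_traits = [t for t in traits if t not in blup_matrices]
    if missing_traits:
        raise ValueError(f"no genotypic-value matrix for traits {missing_traits}")
    if flights is None:
        flights = sorted({int(c) for t in traits for c in blup_matrices[t].columns})
    flights = [int(f) for f in flights]

    pairs_missing = [(t, f) for t in traits for f in flights
                     if f not in {int(c) for c in blup_matrices[t].columns}]
    if pairs_missing:
        raise ValueError(f"(trait, flight) cells unavailable: {pairs_missing[:10]}"
                         + ("..." if len(pairs_missing) > 10 else ""))

    genotypes = sorted(set.intersection(*(set(blup_matrices[t].index) for t in traits)))
    blocks = []
    for t in traits:
        m = blup_matrices[t]
        m = m.loc[genotypes, [c for c in m.columns if int(c) in set(flights)]]
        m = m.rename(columns={c: _column_name(t, c) for c in m.columns})
        m = m[[_column_name(t, f) for f in flights]]
        blocks.append(m)
    wide = pd.concat(blocks, axis=1)
    temporal_columns = list(wide.columns)

    derived_columns: list[str] = []
    if include_auc:
        for t in traits:
            col = f"AUC_{t}"
            m = blup_matrices[t].loc[genotypes]
            days = sorted(int(c) for c in m.columns if int(c) in set(flights))
            vals = m[[c for c in m.columns if int(c) in set(flights)]]
            vals = vals[sorted(vals.columns, key=int)]
            wide[col] = [auc_trapezoid(days, row) for row in vals.to_numpy()]
            derived_columns.append(col)
    if include_weibull:
        if growth_fits is None:
            raise ValueError("include_weibull requires growth_fits")
        for par in ("A", "B", "C"):
            col = f"Weibull_{par}"
            wide[col] = [getattr(growth_fits[g], par) if g in growth_fits else np.nan
                         for g in genotypes]
            derived_columns.append(col)

    n_bad = int(wide.isna().any(axis=1).sum())
    if n_bad:
        if strict:
            raise ValueError(f"{n_bad} genotypes have missing feature cells (strict mode)")
        logger.info("dropping %d genotypes with missing feature cells", n_bad)
        wide = wide.dropna()
    return FeatureMatrix(values=wide, platform=platform,
                         temporal_columns=temporal_columns,
                         derived_columns=derived_columns)


def temporal_correlation_profile(
    features: FeatureMatrix, trait: pd.Series
) -> pd.DataFrame:
    """Pearson correlation of every temporal feature column with a trait.

    Returns a table (trait_id, flight_day, r) plus a per-trait ``max_abs_r``
    column repeated across flights; zero-variance columns get r = NaN.
    """
    shared = [g for g in features.genotypes if g in trait.index]
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared genotypes, got {len(shared)}")
    y = trait.loc[shared].to_numpy(dtype=float)
    rows = []
    for col in features.temporal_columns:
        trait_id, day = col.rsplit("@", 1)
        x = features.values.loc[shared, col].to_numpy(dtype=float)
        if np.std(x) < 1e-14 or np.std(y) < 1e-14:
            r = np.nan
        else:
            r = float(np.corrcoef(x, y)[0, 1])
        rows.append((trait_id, int(day), r))
    out = pd.DataFrame(rows, columns=["trait_id", "flight_day", "r"])
    out["max_abs_r"] = out.groupby("trait_id").r.transform(lambda s: s.abs().max())
    return out
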