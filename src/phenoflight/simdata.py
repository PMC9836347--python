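"""Synthetic maize-trial generator with UAS-style temporal structure.

Generates a hybrid breeding trial the way the downstream analysis assumes it
is structured: inbred parents crossed to hybrids genotyped at biallelic
markers; a randomized complete block design with ``n_rep`` replicates grown
under an optimal (OM) and a stressed (SM) management, the SM genotypes a
subset of OM; temporal plot phenotypes (vegetation indices and canopy
height) observed at every drone flight, with variance dominated by the
flight term and a small genotype-within-flight term; and terminal traits
(GY, DTA, DTS, PHT) that are partly marker-determined.

Two deliberate generator features matter downstream:

* **Variance targeting** — each random component (flight, rep-within-flight,
  genotype-within-flight, residual) is centered and rescaled after drawing
  so its realized sample variance equals its configured share exactly.
  Recovery tests therefore measure estimator error, not draw-to-draw
  sampling noise of the generator.
* **Plasticity** — a per-genotype latent factor, not expressible from the
  marker panel, loads on both the temporal genotype effects and (optionally)
  grain yield. It models the repeatable genotype-by-environment signal that
  sensors observe but markers cannot, and is what allows temporal phenomic
  predictors to beat marker-only prediction in a tested environment.

All randomness flows from one root seed through named substreams (markers /
effects / trial / raster), so each stage is independently reproducible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import box

from .imaging import BandStack, FieldLayout, PlotRecord, PHENOMIC_COLUMNS

__all__ = [
    "SimConfig",
    "TruthRecord",
    "SyntheticTrial",
    "FlightRaster",
    "simulate_marker_panel",
    "simulate_genetic_architecture",
    "simulate_temporal_trial",
    "simulate",
    "render_band_stacks",
    "MarkerSet",
]

TERMINAL_TRAITS = ("GY", "DTA", "DTS", "PHT")

_SUBSTREAMS = {"markers": 0, "effects": 1, "trial": 2, "raster": 3}


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, independent random stream derived from the root seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_SUBSTREAMS[name],)))


def _standardized(x: np.ndarray, target_var: float, rng=None) -> np.ndarray:
    """Center x and rescale so its sample variance (ddof=1) is target_var."""
    x = np.asarray(x, dtype=float)
    if target_var <= 0:
        return np.zeros_like(x)
    x = x - x.mean()
    sd = x.std(ddof=1)
    if sd < 1e-300:
        raise ValueError("cannot rescale a constant vector to nonzero variance")
    return x * (np.sqrt(target_var) / sd)


def _default_variance_shares() -> dict[str, dict[str, float]]:
    # flight-dominant decomposition; genotype-in-flight in the low-% range
    # typical of plot-level VI data
    shares = {
        "NGRDI": {"flight": 0.88, "rep_in_flight": 0.02, "genotype_in_flight": 0.04, "residual": 0.06},
        "RCC":   {"flight": 0.90, "rep_in_flight": 0.02, "genotype_in_flight": 0.03, "residual": 0.05},
        "ExG":   {"flight": 0.85, "rep_in_flight": 0.03, "genotype_in_flight": 0.05, "residual": 0.07},
        "GLI":   {"flight": 0.92, "rep_in_flight": 0.01, "genotype_in_flight": 0.02, "residual": 0.05},
        "MGRVI": {"flight": 0.86, "rep_in_flight": 0.02, "genotype_in_flight": 0.04, "residual": 0.08},
        "CHM":   {"flight": 0.93, "rep_in_flight": 0.01, "genotype_in_flight": 0.03, "residual": 0.03},
    }
    return shares


#: plausible grand mean and total plot-level variance per temporal trait
_DEFAULT_BASELINE = {
    "NGRDI": (0.15, 0.020), "RCC": (0.33, 0.008), "ExG": (0.25, 0.030),
    "GLI": (0.12, 0.015), "MGRVI": (0.20, 0.025), "CHM": (140.0, 4000.0),
}
_FALLBACK_BASELINE = (0.30, 0.02)

#: terminal-trait grand means, phenotypic variances and SM mean shifts
_TRAIT_SCALE = {  # trait: (OM mean, phenotypic variance)
    "GY": (8.5, 1.44), "DTA": (68.0, 6.25), "DTS": (70.0, 6.25), "PHT": (230.0, 225.0),
}
_DEFAULT_ENV_SHIFT = {"GY": -2.5, "DTA": 2.0, "DTS": 3.0, "PHT": -30.0}


@dataclass
class SimConfig:
    """Parameters of the synthetic trial.

    Defaults mirror the reference design this generator emulates: ~280
    hybrids from inbred crosses, 2-rep RCBD under two managements, 15 RGB
    (12 multispectral) flights between 27 and 144 days after planting,
    flight-dominant variance with a percent-scale genotype-within-flight
    term, and heritable GY/DTA/DTS/PHT.
    """

    n_parents: int = 40
    n_hybrids: int = 280
    n_hybrids_sm: int | None = None  # default ~230/280 of n_hybrids
    n_markers: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_flights_rgb: int = 15
    n_flights_multi: int = 12
    flight_days: Sequence[int] | None = None  # default: n_flights_rgb days in 27..144
    n_rep: int = 2
    variance_shares: Mapping[str, Mapping[str, float]] = field(default_factory=_default_variance_shares)
    trait_h2: Mapping[str, float] = field(
        default_factory=lambda: {"GY": 0.55, "DTA": 0.75, "DTS": 0.75, "PHT": 0.65})
    env_shift: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_ENV_SHIFT))
    gxe_corr: float = 0.6
    effect_corr: float = 0.7        # correlation of marker effects across flights
    plasticity_share: float = 0.30  # non-marker fraction of genotype-in-flight variance
    gy_plasticity_share: float = 0.15  # GY variance fraction from the plasticity factor
    vi_gy_marker_corr: float = 0.5  # correlation of temporal marker effects with GY's
    genetic_profile: Sequence[float] | None = None  # per-flight genetic-share multipliers
    trait_corr: np.ndarray | None = None  # correlation of terminal-trait marker effects
    trait_baseline: Mapping[str, tuple[float, float]] | None = None
    plot_px: int = 8                # plot side length in pixels for rendering
    plot_gap: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}")
        for name, n in [("n_parents", self.n_parents), ("n_hybrids", self.n_hybrids),
                        ("n_markers", self.n_markers), ("n_rep", self.n_rep),
                        ("n_flights_rgb", self.n_flights_rgb)]:
            if n < 1:
                raise ValueError(f"{name} must be positive, got {n}")
        for trait, shares in self.variance_shares.items():
            total = sum(shares.values())
            if abs(total - 1.0) > 1e-12:
                raise ValueError(
                    f"variance_shares[{trait!r}] sums to {total!r}, must sum to 1")
        for trait, h2 in self.trait_h2.items():
            if not 0 <= h2 <= 1:
                raise ValueError(f"trait_h2[{trait!r}]={h2} outside [0, 1]")
        if not -1 <= self.gxe_corr <= 1:
            raise ValueError(f"gxe_corr={self.gxe_corr} outside [-1, 1]")

    @property
    def resolved_flight_days(self) -> list[int]:
        if self.flight_days is not None:
            days = [int(d) for d in self.flight_days]
        else:
            days = sorted({int(round(d)) for d in np.linspace(27, 144, self.n_flights_rgb)})
        if len(days) != len(set(days)) or days != sorted(days):
            raise ValueError(f"flight_days must be strictly increasing, got {days}")
        return days

    @property
    def resolved_n_sm(self) -> int:
        if self.n_hybrids_sm is not None:
            if not 1 <= self.n_hybrids_sm <= self.n_hybrids:
                raise ValueError("n_hybrids_sm must be in [1, n_hybrids]")
            return self.n_hybrids_sm
        return max(1, int(round(self.n_hybrids * 230 / 280)))

    def baseline(self, trait_id: str) -> tuple[float, float]:
        table = self.trait_baseline or {}
        if trait_id in table:
            return table[trait_id]
        return _DEFAULT_BASELINE.get(trait_id, _FALLBACK_BASELINE)


@dataclass
class MarkerSet:
    """Genotype x marker dosage matrix with allele frequencies and map."""

    genotypes: list[str]
    marker_ids: list[str]
    dosage: np.ndarray            # n_genotypes x n_markers, values in {0,1,2}
    positions: pd.DataFrame       # marker_id, chrom, pos
    allele_freq: np.ndarray       # frequency of the counted allele
    parents: dict[str, tuple[str, str]] | None = None
    parent_dosage: pd.DataFrame | None = None

    @property
    def maf(self) -> np.ndarray:
        return np.minimum(self.allele_freq, 1 - self.allele_freq)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosage, index=self.genotypes, columns=self.marker_ids)


@dataclass
class TruthRecord:
    """Ground truth of the simulated genetic architecture."""

    marker_effects: dict[str, np.ndarray]            # trait -> markers x flights
    genetic_values: pd.DataFrame                     # genotype x terminal trait (marker part)
    temporal_genetic_values: dict[str, pd.DataFrame]  # trait -> genotype x flight_day
    plasticity: pd.Series | None = None              # latent per-genotype factor
    realized_components: dict[str, dict[str, float]] | None = None


@dataclass
class SyntheticTrial:
    phenomic: pd.DataFrame     # long table, PHENOMIC_COLUMNS, trials OM and SM
    traits: pd.DataFrame       # columns: trial, genotype, GY, DTA, DTS, PHT
    markers: MarkerSet
    truth: TruthRecord
    layout: FieldLayout
    config: SimConfig

    @property
    def genotypes_om(self) -> list[str]:
        return list(self.markers.genotypes)

    @property
    def genotypes_sm(self) -> list[str]:
        return sorted(self.traits.loc[self.traits.trial == "SM", "genotype"].unique())


@dataclass
class FlightRaster:
    flight_day: int
    stack: BandStack
    height: np.ndarray


# ---------------------------------------------------------------------------
# marker panel


def simulate_marker_panel(config: SimConfig) -> MarkerSet:
    """Inbred parents crossed to F1 hybrids at biallelic markers.

    Parents are fully homozygous (dosage 0 or 2); each hybrid's dosage is
    the mean of its parents' dosages, heterozygous exactly where the
    parents differ. Markers whose realized minor-allele frequency among
    hybrids falls outside ``maf_range`` are removed.
    """
    if config.n_parents < 2:
        raise ValueError("need at least 2 parents to make hybrids")
    rng = substream(config.seed, "markers")
    lo, hi = config.maf_range

    p = rng.uniform(lo, hi, size=config.n_markers)
    parent_names = [f"P{i:03d}" for i in range(config.n_parents)]
    parent_dos = 2 * rng.binomial(1, p, size=(config.n_parents, config.n_markers))

    all_pairs = list(itertools.combinations(range(config.n_parents), 2))
    if len(all_pairs) < config.n_hybrids:
        raise ValueError(
            f"{config.n_parents} parents give only {len(all_pairs)} crosses, "
            f"fewer than n_hybrids={config.n_hybrids}")
    pick = rng.choice(len(all_pairs), size=config.n_hybrids, replace=False)
    pairs = [all_pairs[i] for i in sorted(pick)]

    dosage = np.empty((config.n_hybrids, config.n_markers))
    names, pedigree = [], {}
    for k, (i, j) in enumerate(pairs):
        dosage[k] = (parent_dos[i] + parent_dos[j]) / 2.0
        name = f"H{k:04d}"
        names.append(name)
        pedigree[name] = (parent_names[i], parent_names[j])

    freq = dosage.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1 - freq)
    keep = (maf >= lo) & (maf <= hi)
    if not keep.any():
        raise ValueError(
            f"minor-allele-frequency filter [{lo}, {hi}] removed every marker "
            "(all markers monomorphic or out of range)")

    marker_ids = [f"M{m:05d}" for m in range(config.n_markers)]
    kept_ids = [marker_ids[m] for m in np.flatnonzero(keep)]
    n_kept = len(kept_ids)
    positions = pd.DataFrame({
        "marker_id": kept_ids,
        "chrom": 1 + (np.arange(n_kept) % 10),
        "pos": 1_000 * (1 + np.arange(n_kept)),
    })
    return MarkerSet(
        genotypes=names,
        marker_ids=kept_ids,
        dosage=dosage[:, keep],
        positions=positions,
        allele_freq=freq[keep],
        parents=pedigree,
        parent_dosage=pd.DataFrame(parent_dos[:, keep], index=parent_names, columns=kept_ids),
    )


# ---------------------------------------------------------------------------
# genetic architecture


def _psd_transform(corr: np.ndarray) -> np.ndarray:
    """Square root of a correlation matrix; rejects non-PSD input."""
    corr = np.asarray(corr, dtype=float)
    w, v = np.linalg.eigh((corr + corr.T) / 2)
    if w.min() < -1e-8:
        raise ValueError(
            f"trait correlation matrix is not positive semidefinite "
            f"(min eigenvalue {w.min():.3g})")
    return v @ np.diag(np.sqrt(np.clip(w, 0, None)))


def simulate_genetic_architecture(markers: MarkerSet, config: SimConfig) -> TruthRecord:
    """Draw time-varying marker effects and terminal-trait genetic values.

    Temporal traits get per-flight marker effects sharing a configured
    across-flight correlation, so genotype rankings drift over the season;
    a per-genotype plasticity factor (fraction ``plasticity_share`` of the
    genotype-in-flight variance) adds heritable-but-unmarked signal.
    Temporal genetic values are stored on the trait scale: their variance
    at flight f equals genotype_share * total_var * profile_f.
    """
    if len(markers.genotypes) == 0 or len(markers.marker_ids) == 0:
        raise ValueError("marker set is empty")
    rng = substream(config.seed, "effects")
    n_g, n_m = markers.dosage.shape
    days = config.resolved_flight_days
    n_f = len(days)

    profile = np.ones(n_f) if config.genetic_profile is None else np.asarray(
        config.genetic_profile, dtype=float)
    if profile.shape != (n_f,):
        raise ValueError(f"genetic_profile must have length {n_f}")
    if (profile < 0).any():
        raise ValueError("genetic_profile entries must be non-negative")

    Z = markers.dosage - markers.dosage.mean(axis=0)
    ps = config.plasticity_share
    plast = pd.Series(_standardized(rng.standard_normal(n_g), 1.0),
                      index=markers.genotypes, name="plasticity") if n_g > 1 else pd.Series(
                      np.zeros(n_g), index=markers.genotypes, name="plasticity")

    # terminal-trait marker effects drawn first so temporal effects can be
    # partially aligned with the yield architecture
    traits = list(config.trait_h2)
    base = rng.standard_normal((n_m, len(traits)))
    if config.trait_corr is not None:
        if np.shape(config.trait_corr) != (len(traits), len(traits)):
            raise ValueError("trait_corr must be square over trait_h2 traits")
        base = base @ _psd_transform(np.asarray(config.trait_corr)).T
    w_gy = base[:, traits.index("GY")] if "GY" in traits else rng.standard_normal(n_m)
    w_gy = w_gy / max(np.linalg.norm(w_gy) / np.sqrt(n_m), 1e-300)

    rho = config.effect_corr
    cvy = float(np.clip(config.vi_gy_marker_corr, -1, 1))
    marker_effects: dict[str, np.ndarray] = {}
    temporal: dict[str, pd.DataFrame] = {}
    for trait, shares in config.variance_shares.items():
        mean_, var_ = config.baseline(trait)
        sigma2_g = shares["genotype_in_flight"] * var_
        alpha0 = cvy * w_gy + np.sqrt(1 - cvy ** 2) * rng.standard_normal(n_m)
        eff = np.empty((n_m, n_f))
        vals = np.empty((n_g, n_f))
        for f in range(n_f):
            a_f = np.sqrt(max(rho, 0.0)) * alpha0 + np.sqrt(1 - max(rho, 0.0)) * rng.standard_normal(n_m)
            eff[:, f] = a_f
            target = sigma2_g * profile[f]
            if target <= 0 or n_g < 2:
                vals[:, f] = 0.0
            else:
                u_marker = _standardized(Z @ a_f, 1.0)
                # orthogonalize against the plasticity factor so the mixed
                # effect has exactly the target variance
                pv = plast.to_numpy()
                if pv.std() > 0:
                    u_marker = u_marker - (u_marker @ pv / (pv @ pv)) * pv
                    u_marker = _standardized(u_marker, 1.0)
                vals[:, f] = np.sqrt(target) * (
                    np.sqrt(1 - ps) * u_marker + np.sqrt(ps) * pv)
        marker_effects[trait] = eff
        temporal[trait] = pd.DataFrame(vals, index=markers.genotypes, columns=days)

    # terminal traits: linear in markers, optional correlation among traits
    genetic = {}
    for k, trait in enumerate(traits):
        _, pheno_var = _TRAIT_SCALE.get(trait, (0.0, 1.0))
        target = config.trait_h2[trait] * pheno_var
        raw = Z @ base[:, k]
        genetic[trait] = _standardized(raw, target) if (target > 0 and n_g > 1) else np.zeros(n_g)
    genetic_values = pd.DataFrame(genetic, index=markers.genotypes)

    return TruthRecord(marker_effects=marker_effects, genetic_values=genetic_values,
                       temporal_genetic_values=temporal, plasticity=plast)


# ---------------------------------------------------------------------------
# trial simulation


def _make_layout(config: SimConfig, genotypes_om: list[str], genotypes_sm: list[str]) -> FieldLayout:
    """Grid layout: per trial, one block of plots per replicate."""
    px, gap = config.plot_px, config.plot_gap
    pitch = px + gap
    plots: list[PlotRecord] = []
    y_off = 0
    for trial, genos in (("OM", genotypes_om), ("SM", genotypes_sm)):
        n = len(genos)
        ncol = int(np.ceil(np.sqrt(n)))
        nrow = int(np.ceil(n / ncol))
        for rep in range(1, config.n_rep + 1):
            x_off = (rep - 1) * (ncol * pitch + 2 * gap)
            for k, g in enumerate(genos):
                r, c = divmod(k, ncol)
                x0 = x_off + c * pitch + gap / 2
                y0 = y_off + r * pitch + gap / 2
                plots.append(PlotRecord(
                    plot_id=f"{trial}_r{rep}_p{k:04d}", genotype=g, trial=trial,
                    replicate=rep, polygon=box(x0, y0, x0 + px, y0 + px)))
        y_off += nrow * pitch + 2 * gap
    return FieldLayout(plots)


def simulate_temporal_trial(truth: TruthRecord, config: SimConfig,
                            markers: MarkerSet | None = None) -> SyntheticTrial:
    """Realize plot observations from the truth record.

    Plot value = grand mean + flight effect + rep-within-flight effect +
    genotype-within-flight effect + residual; every component is rescaled
    to its exact configured variance share. The SM trial mixes the OM
    genotype effects with an independent draw at weight ``gxe_corr`` and
    adds the per-trait environmental mean shift.
    """
    rng = substream(config.seed, "trial")
    days = config.resolved_flight_days
    n_f, n_rep = len(days), config.n_rep
    genotypes_om = list(truth.genetic_values.index)
    genotypes_sm = genotypes_om[: config.resolved_n_sm]

    for trait, shares in config.variance_shares.items():
        missing = {"flight", "rep_in_flight", "genotype_in_flight", "residual"} - set(shares)
        if missing:
            raise ValueError(f"variance_shares[{trait!r}] missing terms {sorted(missing)}")

    frames = []
    realized: dict[str, dict[str, float]] = {}
    gxe = config.gxe_corr
    for trait, shares in config.variance_shares.items():
        mean_, var_ = config.baseline(trait)
        sig = {k: s * var_ for k, s in shares.items()}
        geno_om = truth.temporal_genetic_values[trait]  # genotype x flight_day
        # independent genotype-effect draw for the SM mixture, same variance profile
        ind = np.empty_like(geno_om.to_numpy())
        for f in range(n_f):
            col_var = geno_om.iloc[:, f].var(ddof=1) if len(genotypes_om) > 1 else 0.0
            draw = rng.standard_normal(len(genotypes_om))
            ind[:, f] = _standardized(draw, col_var) if col_var > 0 else 0.0
        geno_sm_full = gxe * geno_om.to_numpy() + np.sqrt(max(0.0, 1 - gxe ** 2)) * ind

        for trial, genos, geno_eff in (("OM", genotypes_om, geno_om.to_numpy()),
                                       ("SM", genotypes_sm, geno_sm_full[: len(genotypes_sm)])):
            n_g = len(genos)
            shift = config.env_shift.get(trait, 0.0) if trial == "SM" else 0.0
            beta = _standardized(rng.standard_normal(n_f), sig["flight"]) if n_f > 1 else np.zeros(n_f)
            rep_eff = (_standardized(rng.standard_normal(n_f * n_rep), sig["rep_in_flight"])
                       if n_f * n_rep > 1 else np.zeros(n_f * n_rep)).reshape(n_f, n_rep)
            n_obs = n_f * n_rep * n_g
            resid = (_standardized(rng.standard_normal(n_obs), sig["residual"])
                     if sig["residual"] > 0 else np.zeros(n_obs)).reshape(n_f, n_rep, n_g)

            flight_idx = np.repeat(np.arange(n_f), n_rep * n_g)
            rep_idx = np.tile(np.repeat(np.arange(n_rep), n_g), n_f)
            geno_idx = np.tile(np.arange(n_g), n_f * n_rep)
            values = (mean_ + shift + beta[flight_idx] + rep_eff[flight_idx, rep_idx]
                      + geno_eff[geno_idx, flight_idx] + resid[flight_idx, rep_idx, geno_idx])
            frames.append(pd.DataFrame({
                "trial": trial,
                "flight_day": np.asarray(days)[flight_idx],
                "rep": rep_idx + 1,
                "plot": [f"{trial}_r{r + 1}_p{g:04d}" for r, g in zip(rep_idx, geno_idx)],
                "genotype": np.asarray(genos)[geno_idx],
                "trait_id": trait,
                "value": values,
            }))
            if trial == "OM":
                realized[trait] = {
                    "flight": float(np.var(beta, ddof=1)) / var_ if n_f > 1 else 0.0,
                    "rep_in_flight": float(np.var(rep_eff, ddof=1)) / var_,
                    "genotype_in_flight": float(np.mean(np.var(geno_eff, axis=0, ddof=1))) / var_
                    if n_g > 1 else 0.0,
                    "residual": float(np.var(resid, ddof=1)) / var_,
                }
    phenomic = pd.concat(frames, ignore_index=True)[list(PHENOMIC_COLUMNS)]

    # terminal traits at genotype level
    trait_rows = []
    plast = truth.plasticity.to_numpy() if truth.plasticity is not None else np.zeros(len(genotypes_om))
    for trial, genos in (("OM", genotypes_om), ("SM", genotypes_sm)):
        n_g = len(genos)
        rec: dict[str, np.ndarray] = {}
        for trait in truth.genetic_values.columns:
            mean_t, pheno_var = _TRAIT_SCALE.get(trait, (0.0, 1.0))
            shift = config.env_shift.get(trait, 0.0) if trial == "SM" else 0.0
            h2 = config.trait_h2.get(trait, 0.0)
            a = truth.genetic_values[trait].to_numpy()[:n_g]
            if trial == "SM" and n_g > 1:
                ind = _standardized(rng.standard_normal(n_g), np.var(a, ddof=1) if np.var(a) > 0 else 0.0)
                a = gxe * a + np.sqrt(max(0.0, 1 - gxe ** 2)) * ind
            ps = config.gy_plasticity_share if trait == "GY" else 0.0
            env_var = max(0.0, (1 - h2 - ps)) * pheno_var
            e = (_standardized(rng.standard_normal(n_g), env_var)
                 if (env_var > 0 and n_g > 1) else np.zeros(n_g))
            rec[trait] = (mean_t + shift + a
                          + np.sqrt(ps * pheno_var) * plast[:n_g] + e)
        df = pd.DataFrame(rec, index=genos)
        df.insert(0, "genotype", genos)
        df.insert(0, "trial", trial)
        trait_rows.append(df.reset_index(drop=True))
    traits = pd.concat(trait_rows, ignore_index=True)

    truth.realized_components = realized
    layout = _make_layout(config, genotypes_om, genotypes_sm)
    mk = markers if markers is not None else MarkerSet(
        genotypes=genotypes_om, marker_ids=[], dosage=np.zeros((len(genotypes_om), 0)),
        positions=pd.DataFrame(columns=["marker_id", "chrom", "pos"]),
        allele_freq=np.zeros(0))
    return SyntheticTrial(phenomic=phenomic, traits=traits, markers=mk,
                          truth=truth, layout=layout, config=config)


def simulate(config: SimConfig) -> SyntheticTrial:
    """Full generator: marker panel -> architecture -> trial."""
    markers = simulate_marker_panel(config)
    truth = simulate_genetic_architecture(markers, config)
    return simulate_temporal_trial(truth, config, markers=markers)


# ---------------------------------------------------------------------------
# raster rendering


def render_band_stacks(
    trial: SyntheticTrial,
    config: SimConfig | None = None,
    trial_name: str = "OM",
    flights: Sequence[int] | None = None,
    vi: str = "NGRDI",
    pixel_noise: float = 0.0,
) -> list[FlightRaster]:
    """Render per-flight RGB band stacks and height grids from plot values.

    Bands are chosen so each pixel's NGRDI equals the plot's simulated VI
    value plus optional Gaussian pixel noise: with G + R held constant, the
    plot-mean index is the plot value up to the noise mean. Heights are the
    plot CHM value plus noise. Background (non-plot) pixels get soil-like
    reflectance and zero height.
    """
    config = config or trial.config
    rng = substream(config.seed, "raster")
    plots = [p for p in trial.layout if p.trial == trial_name]
    if not plots:
        raise ValueError(f"layout has no plots for trial {trial_name!r}")
    for a, b in itertools.combinations(plots, 2):
        inter = a.polygon.intersection(b.polygon)
        if inter.area > 0:
            raise ValueError(f"overlapping plot polygons: {a.plot_id}, {b.plot_id}")

    minx, miny, maxx, maxy = FieldLayout(plots).bounds()
    gap = config.plot_gap
    ncol = int(np.ceil(maxx + gap / 2))
    nrow = int(np.ceil(maxy + gap / 2))

    table = trial.phenomic
    sub = table[(table.trial == trial_name) & (table.trait_id.isin([vi, "CHM"]))]
    if sub[sub.trait_id == vi].empty:
        raise ValueError(f"trait {vi!r} not present in the simulated phenomic table")
    days = flights if flights is not None else sorted(sub.flight_day.unique())

    masks = {}
    from .imaging import _inside_mask  # reuse the pixel-center containment rule
    for p in plots:
        masks[p.plot_id] = _inside_mask((nrow, ncol), p.polygon)

    rasters = []
    s_total = 0.5  # G + R held fixed so the per-pixel NGRDI is exact
    for day in days:
        flight = sub[sub.flight_day == day].set_index(["plot", "trait_id"])["value"]
        R = np.full((nrow, ncol), 0.20)
        G = np.full((nrow, ncol), 0.15)
        B = np.full((nrow, ncol), 0.10)
        H = np.zeros((nrow, ncol))
        for p in plots:
            m = masks[p.plot_id]
            n_px = int(m.sum())
            v = float(flight[(p.plot_id, vi)])
            v_pix = np.clip(v + pixel_noise * rng.standard_normal(n_px), -1, 1)
            G[m] = s_total * (1 + v_pix) / 2
            R[m] = s_total * (1 - v_pix) / 2
            B[m] = 0.10
            if (p.plot_id, "CHM") in flight.index:
                h = float(flight[(p.plot_id, "CHM")])
                H[m] = np.clip(h + pixel_noise * rng.standard_normal(n_px), 0, None)
        stack = BandStack(bands={"R": R, "G": G, "B": B}, flight_day=int(day))
        rasters.append(FlightRaster(flight_day=int(day), stack=stack, height=H))
    return rasters
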