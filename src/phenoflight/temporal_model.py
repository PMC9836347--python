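"""Flight-nested variance decomposition of temporal plot phenotypes.

Raw plot values of one vegetation index (or canopy height) across a season
of drone flights are modelled as

    y = mu + beta_i + R_j(i) + Omega_g(i) + eps,

where ``beta_i`` is the flight (time point) effect, ``R_j(i)`` the
replicate-within-flight effect, ``Omega_g(i)`` the genotype-within-flight
effect, and ``eps`` the plot residual — all random, the intercept fixed.
Treating replicate and genotype as nested within flight lets one phenotype
series absorb the (dominant) temporal plasticity of spectral reflectance
while still exposing a genetic signal at each time point.

Two estimation paths are provided:

* ``anova_mom`` — closed-form method-of-moments from the balanced nested
  ANOVA expected mean squares; refuses unbalanced tables.
* ``em_reml`` — EM iterations on Henderson's mixed-model equations; handles
  unbalanced data and never produces negative components. For a balanced
  design the two paths converge to the same estimates.

Temporal repeatability is the entry-mean repeatability of the
genotype-within-flight term: TR = s2_g / (s2_g + s2_e / n_rep). Flight-wise
genotypic values (grand mean + flight effect + shrunken genotype deviation)
are the BLUPs used downstream as phenomic predictors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "NestedModelSpec",
    "NestedFit",
    "RepeatabilityReport",
    "fit_nested_model",
    "variance_percentages",
    "temporal_repeatability",
    "genotypic_values",
    "reml_loglik",
]

TERMS = ("flight", "rep_in_flight", "genotype_in_flight", "residual")


@dataclass
class NestedModelSpec:
    estimation: str = "em_reml"        # or "anova_mom"
    max_iter: int = 10_000
    tol: float = 1e-8                  # relative change per component
    track_loglik: bool = False         # record restricted log-likelihood per iteration

    def __post_init__(self) -> None:
        if self.estimation not in ("em_reml", "anova_mom"):
            raise ValueError(f"unknown estimation {self.estimation!r}")


@dataclass
class NestedFit:
    components: dict[str, float]            # variance estimates, >= 0
    components_raw: dict[str, float]        # before truncation (ANOVA may go negative)
    blups: pd.DataFrame                     # genotype x flight_day genotypic values
    flight_effects: pd.Series               # BLUP of beta_i per flight_day
    grand_mean: float
    n_rep: float                            # replicates per genotype-flight (harmonic mean)
    converged: bool
    n_iter: int
    trait_id: str
    loglik_trace: list[float] = field(default_factory=list)

    @property
    def percentages(self) -> dict[str, float]:
        return variance_percentages(self)


@dataclass
class RepeatabilityReport:
    tr: float
    per_component_inputs: dict[str, float]


# ---------------------------------------------------------------------------
# helpers


def _validate(table: pd.DataFrame, trait_id: str) -> pd.DataFrame:
    required = {"flight_day", "rep", "genotype", "trait_id", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"phenomic table missing columns {sorted(missing)}")
    sub = table[table.trait_id == trait_id].dropna(subset=["value"]).copy()
    if sub.empty:
        avail = sorted(table.trait_id.unique())
        raise ValueError(f"trait {trait_id!r} absent from table; available: {avail}")
    if sub.flight_day.nunique() < 2:
        raise ValueError(
            "only one flight present: the flight term and the "
            "genotype-within-flight term are not identifiable")
    if sub.genotype.nunique() < 2:
        raise ValueError("need at least 2 genotypes")
    return sub


def _is_balanced(sub: pd.DataFrame) -> bool:
    counts = sub.groupby(["flight_day", "rep", "genotype"], observed=True).size()
    if (counts != 1).any():
        return False
    n_f = sub.flight_day.nunique()
    n_r = sub.rep.nunique()
    n_g = sub.genotype.nunique()
    return len(counts) == n_f * n_r * n_g


def _anova_mom(sub: pd.DataFrame) -> dict[str, float]:
    """Closed-form method of moments from balanced nested expected MS."""
    if not _is_balanced(sub):
        raise ValueError(
            "anova_mom requires a balanced design (every flight x rep x "
            "genotype cell observed exactly once); use em_reml instead")
    I = sub.flight_day.nunique()
    J = sub.rep.nunique()
    G = sub.genotype.nunique()
    y = sub.value.to_numpy()
    grand = y.mean()
    m_i = sub.groupby("flight_day", observed=True).value.mean()
    m_ij = sub.groupby(["flight_day", "rep"], observed=True).value.mean()
    m_ig = sub.groupby(["flight_day", "genotype"], observed=True).value.mean()

    ss_flight = J * G * ((m_i - grand) ** 2).sum()
    ss_rep = G * ((m_ij - m_i.reindex(m_ij.index.get_level_values(0)).to_numpy()) ** 2).sum()
    ss_geno = J * ((m_ig - m_i.reindex(m_ig.index.get_level_values(0)).to_numpy()) ** 2).sum()
    fitted = (m_ij.reindex(list(zip(sub.flight_day, sub.rep))).to_numpy()
              + m_ig.reindex(list(zip(sub.flight_day, sub.genotype))).to_numpy()
              - m_i.reindex(sub.flight_day).to_numpy())
    ss_res = ((y - fitted) ** 2).sum()

    ms_flight = ss_flight / (I - 1)
    ms_rep = ss_rep / (I * (J - 1)) if J > 1 else np.nan
    ms_geno = ss_geno / (I * (G - 1))
    df_res = I * (J - 1) * (G - 1)
    ms_res = ss_res / df_res if df_res > 0 else 0.0

    s2_e = ms_res
    s2_g = (ms_geno - ms_res) / J
    if J > 1:
        s2_r = (ms_rep - ms_res) / G
        s2_f = (ms_flight - ms_rep - ms_geno + ms_res) / (J * G)
    else:
        s2_r = 0.0
        s2_f = (ms_flight - ms_geno) / (J * G)
    return {"flight": s2_f, "rep_in_flight": s2_r, "genotype_in_flight": s2_g,
            "residual": s2_e}


def _design(sub: pd.DataFrame):
    """Sparse indicator matrices for the three random terms."""
    flights = np.sort(sub.flight_day.unique())
    reps = np.sort(sub.rep.unique())
    genos = np.sort(sub.genotype.unique())
    n = len(sub)
    fi = pd.Categorical(sub.flight_day, categories=flights).codes.astype(np.int64)
    ri = pd.Categorical(sub.rep, categories=reps).codes.astype(np.int64)
    gi = pd.Categorical(sub.genotype, categories=genos).codes.astype(np.int64)

    def indicator(codes, n_levels):
        return sparse.csr_matrix(
            (np.ones(n), (np.arange(n), codes)), shape=(n, n_levels))

    Zf = indicator(fi, len(flights))
    Zr = indicator(fi * len(reps) + ri, len(flights) * len(reps))
    Zg = indicator(fi * len(genos) + gi, len(flights) * len(genos))
    return flights, reps, genos, Zf, Zr, Zg


_FLOOR = 1e-9


def _solve_mme(y, Zs, sigma2, sigma2_e, need_cinv=True):
    """Henderson MME solve; returns (mu_hat, [u_k], C_inverse, q_offsets).

    Components at (numerical) zero are floored relative to the total
    variance so the system stays well conditioned; the corresponding
    effects shrink to ~0.
    """
    n = len(y)
    X = np.ones((n, 1))
    W = sparse.hstack([sparse.csr_matrix(X)] + list(Zs), format="csr")
    lhs = (W.T @ W).toarray()
    total = sum(sigma2) + sigma2_e
    se = max(sigma2_e, _FLOOR * max(total, 1.0))
    off = 1
    offsets = []
    for Z, s2 in zip(Zs, sigma2):
        q = Z.shape[1]
        lam = se / max(s2, _FLOOR * max(total, 1.0))
        lhs[off:off + q, off:off + q] += lam * np.eye(q)
        offsets.append((off, q))
        off += q
    rhs = W.T @ y
    if need_cinv:
        cinv = np.linalg.inv(lhs)
        sol = cinv @ rhs
    else:
        cinv = None
        sol = np.linalg.solve(lhs, rhs)
    mu = sol[0]
    us = [sol[o:o + q] for o, q in offsets]
    return mu, us, cinv, offsets


def _em_reml(sub: pd.DataFrame, spec: NestedModelSpec):
    flights, reps, genos, Zf, Zr, Zg = _design(sub)
    y = sub.value.to_numpy(dtype=float)
    n = len(y)
    Zs = [Zf, Zr, Zg]
    qs = [Z.shape[1] for Z in Zs]

    v0 = max(y.var(ddof=1), _FLOOR)
    sigma2 = [v0 / 4, v0 / 4, v0 / 4]
    sigma2_e = v0 / 4
    trace = []
    converged = False
    it = 0
    for it in range(1, spec.max_iter + 1):
        mu, us, cinv, offsets = _solve_mme(y, Zs, sigma2, sigma2_e)
        if spec.track_loglik:
            trace.append(reml_loglik(y, Zs, sigma2, sigma2_e))
        se = max(sigma2_e, _FLOOR * max(sum(sigma2) + sigma2_e, 1.0))
        new = []
        for (o, q), u in zip(offsets, us):
            tr_c = np.trace(cinv[o:o + q, o:o + q])
            new.append(float((u @ u + se * tr_c) / q))
        fitted = mu + sum(Z @ u for Z, u in zip(Zs, us))
        new_e = float(y @ (y - fitted) / (n - 1))
        old = sigma2 + [sigma2_e]
        cur = new + [new_e]
        scale = max(sum(cur), _FLOOR)
        rel = max(abs(a - b) / max(abs(b), _FLOOR * scale) for a, b in zip(cur, old))
        sigma2, sigma2_e = new, new_e
        if rel < spec.tol:
            converged = True
            break
    if spec.track_loglik:
        trace.append(reml_loglik(y, Zs, sigma2, sigma2_e))
    comps = {"flight": sigma2[0], "rep_in_flight": sigma2[1],
             "genotype_in_flight": sigma2[2], "residual": sigma2_e}
    return comps, converged, it, trace


def reml_loglik(y, Zs, sigma2, sigma2_e) -> float:
    """Restricted log-likelihood of the intercept-plus-random-terms model.

    Dense O(n^2) evaluation intended for fixture-sized problems (used to
    assert the EM iterations are monotone).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    V = sigma2_e * np.eye(n)
    for Z, s2 in zip(Zs, sigma2):
        Zd = Z.toarray() if sparse.issparse(Z) else np.asarray(Z)
        V += s2 * (Zd @ Zd.T)
    X = np.ones((n, 1))
    sign, logdet_v = np.linalg.slogdet(V)
    Vinv_y = np.linalg.solve(V, y)
    Vinv_X = np.linalg.solve(V, X)
    xvx = X.T @ Vinv_X
    _, logdet_x = np.linalg.slogdet(xvx)
    beta = np.linalg.solve(xvx, X.T @ Vinv_y)
    resid_term = y @ Vinv_y - (X.T @ Vinv_y).T @ beta
    return float(-0.5 * (logdet_v + logdet_x + resid_term + (n - 1) * np.log(2 * np.pi)))


# ---------------------------------------------------------------------------
# operations


def fit_nested_model(
    table: pd.DataFrame, trait_id: str, spec: NestedModelSpec | None = None
) -> NestedFit:
    """Fit the flight-nested variance decomposition for one trait.

    Returns variance components, flight-wise genotype BLUPs, and flight
    effects. Negative ANOVA components are truncated to zero after
    estimation; EM-REML stays in the parameter space by construction.
    """
    spec = spec or NestedModelSpec()
    sub = _validate(table, trait_id)

    trace: list[float] = []
    if spec.estimation == "anova_mom":
        comps_raw = _anova_mom(sub)
        converged, n_iter = True, 0
    else:
        comps_raw, converged, n_iter, trace = _em_reml(sub, spec)

    comps = {k: max(v, 0.0) for k, v in comps_raw.items()}

    # BLUPs from a single MME solve at the estimated components
    flights, reps, genos, Zf, Zr, Zg = _design(sub)
    y = sub.value.to_numpy(dtype=float)
    sigma2 = [comps["flight"], comps["rep_in_flight"], comps["genotype_in_flight"]]
    mu, us, _, _ = _solve_mme(y, [Zf, Zr, Zg], sigma2, comps["residual"],
                              need_cinv=False)
    beta = pd.Series(us[0], index=flights, name="flight_effect")
    omega = us[2].reshape(len(flights), len(genos))  # flight-major
    blups = pd.DataFrame(mu + beta.to_numpy()[:, None] + omega,
                         index=flights, columns=genos).T
    # flag genotype x flight cells never observed
    seen = sub.groupby(["genotype", "flight_day"], observed=True).size().unstack()
    seen = seen.reindex(index=blups.index, columns=blups.columns)
    blups = blups.where(seen.notna())

    counts = sub.groupby(["flight_day", "genotype"], observed=True).size()
    n_rep = len(counts) / float((1.0 / counts).sum())  # harmonic mean

    return NestedFit(components=comps, components_raw=comps_raw, blups=blups,
                     flight_effects=beta, grand_mean=float(mu), n_rep=float(n_rep),
                     converged=converged, n_iter=n_iter, trait_id=trait_id,
                     loglik_trace=trace)


def variance_percentages(fit: NestedFit) -> dict[str, float]:
    """Each component as a percentage of the summed components."""
    total = sum(fit.components.values())
    if total <= 0:
        raise ValueError("all variance components are zero; percentages undefined")
    return {k: 100.0 * v / total for k, v in fit.components.items()}


def temporal_repeatability(fit: NestedFit, n_rep: float | None = None) -> RepeatabilityReport:
    """Entry-mean repeatability of the genotype-within-flight term.

    TR = s2_g / (s2_g + s2_e / n_rep), clamped to [0, 1].
    """
    n_rep = fit.n_rep if n_rep is None else n_rep
    if n_rep < 1:
        raise ValueError(f"n_rep must be >= 1, got {n_rep}")
    s2_g = fit.components["genotype_in_flight"]
    s2_e = fit.components["residual"]
    denom = s2_g + s2_e / n_rep
    tr = 0.0 if denom <= 0 else s2_g / denom
    tr = float(np.clip(tr, 0.0, 1.0))
    return RepeatabilityReport(tr=tr, per_component_inputs={
        "genotype_in_flight": s2_g, "residual": s2_e, "n_rep": n_rep})


def genotypic_values(fit: NestedFit) -> pd.DataFrame:
    """Genotype x flight matrix of BLUP genotypic values.

    Value = grand mean + flight effect + shrunken genotype-within-flight
    deviation; cells for genotypes never observed at a flight are NaN.
    """
    if not fit.converged:
        raise ValueError("fit did not converge; genotypic values unreliable")
    return fit.blups.copy()
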