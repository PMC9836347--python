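"""Phenomic and genomic prediction of terminal traits under CV1-CV4.

Terminal traits (grain yield, flowering dates, plant height) are predicted
from either a temporal phenomic feature matrix (linear, ridge, lasso,
elastic net or random forest regression) or a genomic relationship matrix
(GBLUP, equivalent to per-marker ridge / RR-BLUP). Four cross-validation
schemes cross tested/untested genotypes with tested/untested environments:

* CV1 — tested genotypes, tested environment (resubstitution on the
  training genotypes in the optimal-management trial; the overfitting
  control),
* CV2 — untested genotypes, tested environment,
* CV3 — tested genotypes, untested (stressed) environment,
* CV4 — untested genotypes, untested environment.

Every method consumes the same :class:`SplitPlan` (70/30 genotype
partitions by default, 500 iterations), so per-iteration accuracies are
directly comparable across methods; :func:`compare_methods` enforces this
by hashing the plan. Accuracy is the Pearson correlation between predicted
and observed genotype-level trait values, averaged over iterations.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import ElasticNetCV, Lasso, LassoCV, Ridge, RidgeCV

from .features import FeatureMatrix
from .simdata import MarkerSet

__all__ = [
    "SplitPlan",
    "CVScheme",
    "CV_SCHEMES",
    "ModelSpec",
    "PredictionResult",
    "GenomicKernel",
    "make_split_plan",
    "fit_phenomic_model",
    "grm_vanraden",
    "gblup_predict",
    "reml_variance_ratio",
    "evaluate",
    "run_cv_scheme",
    "per_timepoint_gp",
    "compare_methods",
]

logger = logging.getLogger(__name__)

DEFAULT_PENALTY_GRID = np.logspace(-4, 4, 25)
DEFAULT_L1_RATIOS = np.arange(0.1, 1.0, 0.1)


# ---------------------------------------------------------------------------
# split plans and schemes


@dataclass
class SplitPlan:
    """Shared genotype partitions reused by every method in a comparison."""

    genotypes: list[str]
    train_frac: float
    n_iter: int
    seed: int
    iterations: list[tuple[list[str], list[str]]]

    @property
    def plan_hash(self) -> str:
        payload = json.dumps(
            {"genotypes": self.genotypes, "train_frac": self.train_frac,
             "seed": self.seed, "iterations": self.iterations},
            sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def make_split_plan(genotypes: Sequence[str], train_frac: float = 0.7,
                    n_iter: int = 500, seed: int = 0) -> SplitPlan:
    """Uniform random train/test genotype partitions, |train| = floor(frac*n)."""
    genotypes = sorted(genotypes)
    n = len(genotypes)
    if n < 3:
        raise ValueError(f"need >= 3 genotypes, got {n}")
    if not 0 < train_frac < 1:
        raise ValueError(f"train_frac must be in (0, 1), got {train_frac}")
    n_train = int(np.floor(train_frac * n))
    if n_train == 0 or n_train == n:
        raise ValueError(
            f"train_frac={train_frac} with n={n} leaves an empty train or test set")
    rng = np.random.default_rng(seed)
    iterations = []
    for _ in range(n_iter):
        perm = rng.permutation(n)
        train = sorted(genotypes[i] for i in perm[:n_train])
        test = sorted(genotypes[i] for i in perm[n_train:])
        iterations.append((train, test))
    return SplitPlan(genotypes=genotypes, train_frac=train_frac, n_iter=n_iter,
                     seed=seed, iterations=iterations)


@dataclass(frozen=True)
class CVScheme:
    id: str
    test_env: str          # "OM" or "SM"
    test_genotypes: str    # "trained" or "held_out"


CV_SCHEMES: dict[str, CVScheme] = {
    "CV1": CVScheme("CV1", "OM", "trained"),
    "CV2": CVScheme("CV2", "OM", "held_out"),
    "CV3": CVScheme("CV3", "SM", "trained"),
    "CV4": CVScheme("CV4", "SM", "held_out"),
}


@dataclass
class ModelSpec:
    family: str                      # linear | ridge | lasso | elasticnet | randomforest | gblup
    hyperparameters: dict = field(default_factory=dict)
    tuning_folds: int = 5
    tuning_seed: int = 0
    standardize: bool = True
    fit_intercept: bool = True

    def __post_init__(self) -> None:
        families = ("linear", "ridge", "lasso", "elasticnet", "randomforest", "gblup")
        if self.family not in families:
            raise ValueError(f"unknown family {self.family!r}; expected one of {families}")
        if self.family in ("ridge", "lasso", "elasticnet"):
            grid = self.hyperparameters.get("penalty_grid", DEFAULT_PENALTY_GRID)
            if len(np.atleast_1d(grid)) == 0:
                raise ValueError("penalty grid must be non-empty for penalized families")

    @property
    def label(self) -> str:
        return self.hyperparameters.get("label", self.family)


# ---------------------------------------------------------------------------
# phenomic model fitting


class FittedModel:
    """A fitted predictor: a pure function of new feature rows.

    Stores the training-set standardization statistics so test rows are
    transformed with training means/SDs only (no leakage).
    """

    def __init__(self, spec: ModelSpec, estimator, mean: np.ndarray | None,
                 scale: np.ndarray | None, columns: list[str]):
        self.spec = spec
        self.estimator = estimator
        self._mean = mean
        self._scale = scale
        self.columns = columns

    def _transform(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.columns].to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
        if self._mean is not None:
            X = (X - self._mean) / self._scale
        return X

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        return np.asarray(self.estimator.predict(self._transform(X)), dtype=float)

    @property
    def coef_(self) -> np.ndarray:
        return np.asarray(self.estimator.coef_)


class _LstsqLinear:
    """Minimum-norm least squares; interpolates exactly when p >= n."""

    def __init__(self, fit_intercept: bool = True):
        self.fit_intercept = fit_intercept

    def fit(self, X, y):
        if self.fit_intercept:
            X = np.hstack([np.ones((X.shape[0], 1)), X])
        self._beta = np.linalg.lstsq(X, y, rcond=None)[0]
        return self

    def predict(self, X):
        if self.fit_intercept:
            X = np.hstack([np.ones((X.shape[0], 1)), X])
        return X @ self._beta

    @property
    def coef_(self):
        return self._beta[1:] if self.fit_intercept else self._beta


def fit_phenomic_model(spec: ModelSpec, X: pd.DataFrame | np.ndarray,
                       y: Sequence[float]) -> FittedModel:
    """Fit one phenomic regression family on training rows only.

    Features are standardized with training means/SDs (constant columns get
    unit scale); penalized families tune their penalty by inner k-fold CV
    on the training rows. Returns a :class:`FittedModel` whose ``predict``
    is a pure function of new feature rows.
    """
    if isinstance(X, pd.DataFrame):
        columns = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        columns = [f"x{i}" for i in range(Xa.shape[1])]
    ya = np.asarray(y, dtype=float)
    if Xa.shape[0] != ya.shape[0]:
        raise ValueError("X and y row counts differ")
    if Xa.shape[0] < 2:
        raise ValueError("need >= 2 training rows")
    if np.isnan(Xa).any() or np.isnan(ya).any():
        raise ValueError("missing values in training data")
    if spec.family in ("ridge", "lasso", "elasticnet") and np.std(ya) < 1e-14:
        raise ValueError(
            f"constant response: penalty tuning for {spec.family} is undefined")

    mean = scale = None
    if spec.standardize:
        mean = Xa.mean(axis=0)
        scale = Xa.std(axis=0)
        scale[scale < 1e-14] = 1.0
        Xa = (Xa - mean) / scale

    hp = spec.hyperparameters
    grid = np.atleast_1d(hp.get("penalty_grid", DEFAULT_PENALTY_GRID)).astype(float)
    fixed = hp.get("penalty")

    if spec.family == "linear":
        est = _LstsqLinear(fit_intercept=spec.fit_intercept).fit(Xa, ya)
    elif spec.family == "ridge":
        if fixed is not None:
            est = Ridge(alpha=float(fixed), fit_intercept=spec.fit_intercept,
                        solver="svd").fit(Xa, ya)
        else:
            est = RidgeCV(alphas=grid, cv=spec.tuning_folds,
                          fit_intercept=spec.fit_intercept).fit(Xa, ya)
    elif spec.family == "lasso":
        if fixed is not None:
            est = Lasso(alpha=float(fixed), fit_intercept=spec.fit_intercept,
                        max_iter=50_000).fit(Xa, ya)
        else:
            est = LassoCV(alphas=grid, cv=spec.tuning_folds, max_iter=50_000,
                          fit_intercept=spec.fit_intercept,
                          random_state=spec.tuning_seed).fit(Xa, ya)
    elif spec.family == "elasticnet":
        l1s = np.atleast_1d(hp.get("l1_ratio_grid", DEFAULT_L1_RATIOS)).astype(float)
        est = ElasticNetCV(alphas=grid, l1_ratio=list(l1s), cv=spec.tuning_folds,
                           max_iter=50_000, fit_intercept=spec.fit_intercept,
                           random_state=spec.tuning_seed).fit(Xa, ya)
    elif spec.family == "randomforest":
        est = RandomForestRegressor(
            n_estimators=int(hp.get("n_trees", 500)),
            max_features=hp.get("max_features", 1 / 3),
            min_samples_leaf=int(hp.get("min_samples_leaf", 5)),
            random_state=spec.tuning_seed, n_jobs=1).fit(Xa, ya)
    else:
        raise ValueError(f"family {spec.family!r} is not a phenomic regression; "
                         "use gblup_predict for genomic prediction")
    return FittedModel(spec, est, mean, scale, columns)


# ---------------------------------------------------------------------------
# genomic kernel and GBLUP


@dataclass
class GenomicKernel:
    grm: pd.DataFrame          # genotype x genotype relationship matrix
    allele_freqs: np.ndarray
    n_markers: int

    @property
    def genotypes(self) -> list[str]:
        return list(self.grm.index)


def grm_vanraden(markers: MarkerSet, maf_filter: float = 0.025) -> GenomicKernel:
    """VanRaden method-1 genomic relationship matrix.

    Z = dosage - 2p per marker (observed allele frequencies), G = ZZ' /
    (2 * sum p(1-p)). Markers failing the MAF filter (monomorphic included)
    are excluded with a logged count.
    """
    dosage = np.asarray(markers.dosage, dtype=float)
    p = dosage.mean(axis=0) / 2.0
    maf = np.minimum(p, 1 - p)
    keep = maf >= maf_filter
    n_dropped = int((~keep).sum())
    if not keep.any():
        raise ValueError("all markers monomorphic or below the MAF filter; "
                         "cannot build a relationship matrix")
    if n_dropped:
        logger.info("GRM: excluded %d markers below MAF %.3g", n_dropped, maf_filter)
    Z = dosage[:, keep] - 2 * p[keep]
    denom = 2.0 * float(np.sum(p[keep] * (1 - p[keep])))
    G = (Z @ Z.T) / denom
    grm = pd.DataFrame(G, index=markers.genotypes, columns=markers.genotypes)
    return GenomicKernel(grm=grm, allele_freqs=p[keep], n_markers=int(keep.sum()))


def reml_variance_ratio(G_train: np.ndarray, y_train: np.ndarray,
                        bounds: tuple[float, float] = (1e-6, 1e6)) -> float:
    """REML estimate of lambda = sigma2_e / sigma2_g for y = mu + u + e.

    Maximizes the restricted likelihood on the eigenbasis of the training
    kernel (profiling out mu and sigma2_g), which is exact and
    deterministic for this single-kernel model.
    """
    y = np.asarray(y_train, dtype=float)
    n = len(y)
    d, U = np.linalg.eigh((G_train + G_train.T) / 2)
    d = np.clip(d, 0, None)
    yt = U.T @ y
    xt = U.T @ np.ones(n)

    def neg2_reml(log_lam: float) -> float:
        lam = np.exp(log_lam)
        w = 1.0 / (d + lam)
        sxx = float(w @ xt ** 2)
        mu = float(w @ (xt * yt)) / sxx
        sse = float(w @ (yt - mu * xt) ** 2)
        sg2 = max(sse / (n - 1), 1e-300)
        return float(np.sum(np.log(d + lam)) + np.log(sxx) + (n - 1) * np.log(sg2))

    res = minimize_scalar(neg2_reml, bounds=(np.log(bounds[0]), np.log(bounds[1])),
                          method="bounded", options={"xatol": 1e-10})
    return float(np.exp(res.x))


def gblup_predict(kernel: GenomicKernel, y_train: Mapping[str, float] | pd.Series,
                  train_ids: Sequence[str], test_ids: Sequence[str],
                  variance_ratio: float | None = None) -> pd.Series:
    """GBLUP predictions for test genotypes.

    u_test = G_test,train (G_train,train + lambda I)^-1 (y_train - ybar)
    + ybar, with lambda REML-estimated on the training data unless fixed.
    """
    y_train = pd.Series(y_train)
    missing = [g for g in list(train_ids) + list(test_ids)
               if g not in kernel.grm.index]
    if missing:
        raise ValueError(f"genotypes absent from kernel: {missing[:5]}")
    train_ids = list(train_ids)
    test_ids = list(test_ids)
    G_tt = kernel.grm.loc[train_ids, train_ids].to_numpy()
    G_st = kernel.grm.loc[test_ids, train_ids].to_numpy()
    y = y_train.loc[train_ids].to_numpy(dtype=float)
    ybar = float(y.mean())
    lam = reml_variance_ratio(G_tt, y) if variance_ratio is None else float(variance_ratio)
    A = G_tt + lam * np.eye(len(train_ids))
    try:
        alpha = np.linalg.solve(A, y - ybar)
    except np.linalg.LinAlgError:
        A = A + 1e-8 * np.eye(len(train_ids))
        try:
            alpha = np.linalg.solve(A, y - ybar)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "GBLUP system singular beyond ridge-jitter tolerance") from exc
    return pd.Series(G_st @ alpha + ybar, index=test_ids)


# ---------------------------------------------------------------------------
# evaluation


def evaluate(predicted: Sequence[float], observed: Sequence[float]) -> dict[str, float]:
    """Accuracy (Pearson r), RMSE, MAE and R2 of predictions."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape or p.ndim != 1:
        raise ValueError("predicted and observed must be 1-D of equal length")
    if p.size < 3:
        raise ValueError(f"need >= 3 pairs, got {p.size}")
    if np.std(p) < 1e-14 or np.std(o) < 1e-14:
        raise ValueError("zero variance in predicted or observed values: "
                         "correlation accuracy is undefined")
    r = float(np.corrcoef(p, o)[0, 1])
    rmse = float(np.sqrt(np.mean((p - o) ** 2)))
    mae = float(np.mean(np.abs(p - o)))
    sst = float(np.sum((o - o.mean()) ** 2))
    r2 = float(1.0 - np.sum((p - o) ** 2) / sst)
    return {"accuracy": r, "rmse": rmse, "mae": mae, "r2": r2}


@dataclass
class PredictionResult:
    records: pd.DataFrame       # iteration, scheme, model, trait, accuracy, rmse, mae, r2
    scheme: str
    model: str
    trait: str
    plan_hash: str

    @property
    def mean_accuracy(self) -> float:
        return float(self.records.accuracy.mean())

    def summary(self) -> pd.Series:
        return self.records[["accuracy", "rmse", "mae", "r2"]].mean()


# ---------------------------------------------------------------------------
# cross-validation harness


def run_cv_scheme(scheme: CVScheme | str, model: ModelSpec,
                  features_or_kernel: FeatureMatrix | GenomicKernel,
                  traits_om: pd.Series, traits_sm: pd.Series | None,
                  plan: SplitPlan, trait_name: str = "trait") -> PredictionResult:
    """Run one (scheme, model, trait) combination over a shared split plan.

    Models are always trained on the training genotypes' optimal-management
    (OM) values. Prediction targets per scheme: CV1 — the training
    genotypes in OM (resubstitution); CV2 — held-out genotypes in OM;
    CV3 — training genotypes in SM; CV4 — held-out genotypes in SM.
    """
    if isinstance(scheme, str):
        scheme = CV_SCHEMES[scheme]
    if scheme.test_env == "SM":
        if traits_sm is None:
            raise ValueError(f"{scheme.id} tests the SM environment but no SM trait "
                             "values were provided")
    is_genomic = isinstance(features_or_kernel, GenomicKernel)
    if is_genomic and model.family != "gblup":
        raise ValueError("a GenomicKernel input requires family 'gblup'")
    if not is_genomic and model.family == "gblup":
        raise ValueError("family 'gblup' requires a GenomicKernel input")

    if is_genomic:
        available = set(features_or_kernel.genotypes)
    else:
        available = set(features_or_kernel.genotypes)
    available &= set(traits_om.index)
    if scheme.test_env == "SM":
        available_test = available & set(traits_sm.index)
    else:
        available_test = available
    not_in_data = set(plan.genotypes) - available
    if not_in_data:
        raise ValueError(f"plan genotypes missing from data: {sorted(not_in_data)[:5]}")

    y_target = traits_om if scheme.test_env == "OM" else traits_sm
    rows = []
    for it, (train, test) in enumerate(plan.iterations):
        target_ids = train if scheme.test_genotypes == "trained" else test
        target_ids = [g for g in target_ids if g in available_test]
        y_train = traits_om.loc[train].to_numpy(dtype=float)
        y_obs = y_target.loc[target_ids].to_numpy(dtype=float)
        if is_genomic:
            pred = gblup_predict(features_or_kernel, traits_om.loc[train],
                                 train, target_ids).to_numpy()
        else:
            X = features_or_kernel.values
            fitted = fit_phenomic_model(model, X.loc[train], y_train)
            pred = fitted.predict(X.loc[target_ids])
        m = evaluate(pred, y_obs)
        rows.append({"iteration": it, "scheme": scheme.id, "model": model.label,
                     "trait": trait_name, **m})
    records = pd.DataFrame(rows)
    return PredictionResult(records=records, scheme=scheme.id, model=model.label,
                            trait=trait_name, plan_hash=plan.plan_hash)


def per_timepoint_gp(kernel: GenomicKernel,
                     blups: Mapping[str, pd.DataFrame],
                     plan: SplitPlan) -> pd.DataFrame:
    """Genomic prediction of every temporal (trait, flight) phenotype.

    Each genotypic-value column is predicted for held-out genotypes under
    the shared plan; returns a trait x flight table of mean accuracies
    (NaN for zero-variance columns).
    """
    out = {}
    for trait, matrix in blups.items():
        shared = [g for g in matrix.index if g in kernel.grm.index]
        accs = {}
        for col in matrix.columns:
            y = matrix.loc[shared, col].dropna()
            if y.std() < 1e-14 or len(y) < 3:
                accs[col] = np.nan
                continue
            vals = []
            for train, test in plan.iterations:
                tr = [g for g in train if g in y.index]
                te = [g for g in test if g in y.index]
                if len(te) < 3 or len(tr) < 3:
                    continue
                pred = gblup_predict(kernel, y.loc[tr], tr, te)
                try:
                    vals.append(evaluate(pred.to_numpy(), y.loc[te].to_numpy())["accuracy"])
                except ValueError:
                    continue
            accs[col] = float(np.mean(vals)) if vals else np.nan
        out[trait] = pd.Series(accs)
    return pd.DataFrame(out).T


def compare_methods(results: Sequence[PredictionResult], n_boot: int = 2000,
                    seed: int = 0, ci: float = 0.95) -> pd.DataFrame:
    """Paired comparison of methods sharing one split plan.

    For each (scheme, trait) the per-iteration accuracy differences between
    each method and the first are bootstrap-resampled over iterations.
    Refuses results produced under different plans.
    """
    if not results:
        raise ValueError("no results to compare")
    hashes = {r.plan_hash for r in results}
    if len(hashes) > 1:
        raise ValueError(
            "results come from different split plans and are not comparable; "
            "rerun every method on one shared SplitPlan")
    rng = np.random.default_rng(seed)
    lo_q, hi_q = (1 - ci) / 2, 1 - (1 - ci) / 2
    rows = []
    groups: dict[tuple[str, str], list[PredictionResult]] = {}
    for r in results:
        groups.setdefault((r.scheme, r.trait), []).append(r)
    for (scheme, trait), group in groups.items():
        ref = group[0]
        for r in group:
            diff = (r.records.accuracy.to_numpy()
                    - ref.records.accuracy.to_numpy())
            n = len(diff)
            boots = diff[rng.integers(0, n, size=(n_boot, n))].mean(axis=1)
            rows.append({
                "scheme": scheme, "trait": trait, "model": r.model,
                "mean_accuracy": r.mean_accuracy,
                "mean_diff_vs_first": float(diff.mean()),
                "diff_ci_low": float(np.quantile(boots, lo_q)),
                "diff_ci_high": float(np.quantile(boots, hi_q)),
                "reference_model": ref.model,
            })
    return pd.DataFrame(rows)
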