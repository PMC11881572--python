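"""Per-animal parameter estimation with Fisher-information uncertainty.

Free model parameters (glomerular, non-renal and tubular-secretion plasma
clearances, kidney interstitium->blood permeability) are fitted per animal
by proportional-error weighted least squares between recovery-corrected
microdialysis concentrations and model interval averages, on log-transformed
parameters with deterministic multi-start.  Uncertainty comes from the
Gauss-Newton Fisher information matrix (finite-difference sensitivities at
the optimum); it is propagated by multivariate-normal sampling on the log
scale, and derived PK metrics (AUCs, tissue:plasma AUC ratios, clearance
decomposition) are summarized as medians with percentile 95% CIs over the
parameter draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .config import DoseRegimen, DrugParameters, KidneyGeometry, SpeciesPhysiology
from .microdialysis import PROBE_TRACKER
from .model import build_whole_body_model
from .simulate import simulate

__all__ = [
    "FREE_PARAMETERS",
    "FitSpec",
    "FitResult",
    "PKMetrics",
    "fit_animal",
    "sample_parameters",
    "derive_pk_metrics",
    "summarize_cohort",
    "default_fit_spec",
]

#: Parameters that may be estimated, with broad positive default bounds.
FREE_PARAMETERS = {
    "cl_glomerular": (1e-4, 1e3),
    "cl_nonrenal": (1e-6, 1e3),
    "cl_tubular_secretion": (1e-6, 1e3),
    "p_interstitium_to_blood": (1e-8, 1e-2),
}

KIDNEY_PARAMETERS = {"cl_glomerular", "cl_tubular_secretion", "p_interstitium_to_blood"}

#: Default free-parameter sets mirroring which clearances are estimated per
#: drug (non-renal clearance only where the data support it, i.e. pig CAZ).
DEFAULT_FREE = {
    ("CAZ", "rat"): ("cl_glomerular", "p_interstitium_to_blood"),
    ("CAZ", "pig"): ("cl_glomerular", "cl_nonrenal", "p_interstitium_to_blood"),
    ("AVI", "rat"): ("cl_glomerular", "cl_tubular_secretion", "p_interstitium_to_blood"),
    ("AVI", "pig"): ("cl_glomerular", "cl_tubular_secretion", "p_interstitium_to_blood"),
}


@dataclass(frozen=True)
class FitSpec:
    """What to estimate and how.

    ``free`` names the estimated parameters; ``initial`` their starting
    values (natural scale); ``bounds`` optional per-parameter (lo, hi);
    ``fixed`` values overriding the drug defaults for non-estimated
    parameters.  The residual model is proportional with a separate
    coefficient per probe site.
    """

    free: tuple
    initial: dict
    bounds: dict = field(default_factory=dict)
    fixed: dict = field(default_factory=dict)
    n_starts: int = 5
    start_spread: float = 0.5   # SD of the log-scale start perturbations

    def __post_init__(self) -> None:
        unknown = set(self.free) - set(FREE_PARAMETERS)
        if unknown:
            raise ValueError(f"unknown free parameters: {sorted(unknown)}")
        if set(self.free) & set(self.fixed):
            raise ValueError("free and fixed parameter sets overlap")
        missing = set(self.free) - set(self.initial)
        if missing:
            raise ValueError(f"missing initial values for {sorted(missing)}")

    def bounds_for(self, name: str):
        return self.bounds.get(name, FREE_PARAMETERS[name])


def default_fit_spec(drug: DrugParameters, species: str, n_starts: int = 5) -> FitSpec:
    """Free parameters and starting values matching the drug/species design."""
    free = DEFAULT_FREE.get((drug.drug_name, species))
    if free is None:
        free = ("cl_glomerular", "p_interstitium_to_blood")
    initial = {}
    for name in free:
        value = getattr(drug, name)
        if name == "cl_glomerular" and value is None:
            value = 0.9 * 0.1  # generic positive start; caller should override
        initial[name] = value if value and value > 0 else 1e-3
    return FitSpec(free=tuple(free), initial=initial, n_starts=n_starts)


@dataclass
class FitResult:
    """Point estimates with log-scale Gauss-Newton covariance."""

    estimates: dict
    objective: float
    param_names: tuple
    covariance_log: np.ndarray
    fim_log: np.ndarray
    sigma_by_site: dict
    residuals: pd.DataFrame
    converged_starts: int
    spec: FitSpec

    def ci95(self, name: str) -> tuple:
        """Log-normal Wald 95% CI for one parameter (natural scale)."""
        j = self.param_names.index(name)
        se = float(np.sqrt(self.covariance_log[j, j]))
        est = self.estimates[name]
        return est * np.exp(-1.959963984540054 * se), est * np.exp(1.959963984540054 * se)


def _apply_parameters(drug: DrugParameters, values: dict) -> DrugParameters:
    return drug.with_updates(**values)


def _predict(
    theta_nat: dict,
    phys: SpeciesPhysiology,
    geom: KidneyGeometry,
    drug: DrugParameters,
    regimen: DoseRegimen,
    obs: pd.DataFrame,
) -> np.ndarray:
    """Interval-average predictions for every observation row."""
    net = build_whole_body_model(phys, geom, _apply_parameters(drug, theta_nat))
    bounds = np.unique(np.concatenate([obs["t_start_h"].values, obs["t_end_h"].values, [0.0]]))
    t_end = float(bounds.max())
    res = simulate(net, regimen, t_end, grid=bounds)
    preds = np.empty(len(obs))
    trackers = {site: PROBE_TRACKER[site] for site in obs["probe_site"].unique()}
    cache = {name: dict(zip(res.times, res.tracker(name))) for name in set(trackers.values())}
    for i, row in enumerate(obs.itertuples(index=False)):
        tr = cache[trackers[row.probe_site]]
        preds[i] = (tr[row.t_end_h] - tr[row.t_start_h]) / (row.t_end_h - row.t_start_h)
    return preds


def fit_animal(
    data: pd.DataFrame,
    phys: SpeciesPhysiology,
    geom: KidneyGeometry,
    drug: DrugParameters,
    regimen: DoseRegimen,
    spec: FitSpec,
    seed: int = 0,
    scale_variance_by_site: dict | None = None,
) -> FitResult:
    """Fit one animal's corrected concentration-time data.

    ``data`` needs columns probe_site, t_start_h, t_end_h and
    conc_corrected_mg_L (recovery-corrected unbound tissue concentrations).
    Proportional-error least squares on log parameters, ``spec.n_starts``
    deterministic starts seeded by ``seed``; returns the best converged fit.

    ``scale_variance_by_site`` optionally gives the log-scale variance of a
    shared multiplicative calibration error per probe site (typically the
    squared relative standard error of the mean retrodialysis recovery used
    to correct that probe's dialysates).  It is propagated into the
    parameter covariance by the delta method, since a shared scale error is
    invisible to the residual-only Fisher information.
    """
    obs = data.reset_index(drop=True)
    required = {"probe_site", "t_start_h", "t_end_h", "conc_corrected_mg_L"}
    missing = required - set(obs.columns)
    if missing:
        raise ValueError(f"data lacks columns {sorted(missing)}")
    y = obs["conc_corrected_mg_L"].to_numpy(dtype=float)
    if np.any(y <= 0):
        raise ValueError("corrected concentrations must be > 0 for proportional error")
    sites = obs["probe_site"].unique()
    if len(sites) < 2 and len(set(spec.free) & KIDNEY_PARAMETERS) >= 2:
        warnings.warn(
            "two or more kidney parameters with data from a single probe site: "
            "the fit is likely unidentifiable",
            RuntimeWarning,
        )

    names = tuple(spec.free)
    lo = np.log([spec.bounds_for(n)[0] for n in names])
    hi = np.log([spec.bounds_for(n)[1] for n in names])
    x0 = np.log([spec.initial[n] for n in names])
    base = _apply_parameters(drug, spec.fixed)

    def residuals(x_log: np.ndarray) -> np.ndarray:
        theta = {n: float(np.exp(v)) for n, v in zip(names, x_log)}
        pred = _predict(theta, phys, geom, base, regimen, obs)
        return (y - pred) / pred

    rng = np.random.default_rng(seed)
    starts = [x0]
    for _ in range(spec.n_starts - 1):
        starts.append(np.clip(x0 + rng.normal(0.0, spec.start_spread, len(names)), lo, hi))

    best = None
    converged = 0
    failures = []
    for start in starts:
        try:
            sol = least_squares(residuals, start, bounds=(lo, hi), method="trf",
                                xtol=1e-10, ftol=1e-10, gtol=1e-10)
        except Exception as exc:  # pragma: no cover - solver crash path
            failures.append(str(exc))
            continue
        if not sol.success:
            failures.append(sol.message)
            continue
        converged += 1
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError(
            "no optimizer start converged; messages: " + "; ".join(failures)
        )

    x_hat = best.x
    theta_hat = {n: float(np.exp(v)) for n, v in zip(names, x_hat)}
    pred = _predict(theta_hat, phys, geom, base, regimen, obs)
    rel = (y - pred) / pred
    sigma_by_site = {
        site: float(np.sqrt(np.mean(rel[obs["probe_site"] == site] ** 2)))
        for site in sites
    }
    sigma_vec = obs["probe_site"].map(sigma_by_site).to_numpy(dtype=float)
    # small-sample inflation for the plug-in residual variances
    dof = max(len(obs) - len(names), 1)
    sigma_vec = np.maximum(sigma_vec * np.sqrt(len(obs) / dof), 1e-6)

    # Gauss-Newton FIM on the log scale: sensitivities of predictions by
    # central differences, weighted by the proportional-error variances.
    h = 1e-4
    sens = np.empty((len(obs), len(names)))
    for j in range(len(names)):
        xp, xm = x_hat.copy(), x_hat.copy()
        xp[j] += h
        xm[j] -= h
        pp = _predict({n: float(np.exp(v)) for n, v in zip(names, xp)},
                      phys, geom, base, regimen, obs)
        pm = _predict({n: float(np.exp(v)) for n, v in zip(names, xm)},
                      phys, geom, base, regimen, obs)
        sens[:, j] = (pp - pm) / (2 * h)
    weights = 1.0 / (sigma_vec * pred) ** 2
    fim = (sens * weights[:, None]).T @ sens
    try:
        cov = np.linalg.inv(fim)
    except np.linalg.LinAlgError:
        warnings.warn("singular Fisher information matrix; using pseudo-inverse",
                      RuntimeWarning)
        cov = np.linalg.pinv(fim)

    if scale_variance_by_site:
        # Delta method for a shared multiplicative calibration error per
        # probe: d(theta_hat)/d(log scale_s) = FIM^-1 A^T b_s with the
        # weighted design A = S/(sigma*pred) and b_s = 1/sigma on site s.
        a_design = sens / (sigma_vec * pred)[:, None]
        for site, var in scale_variance_by_site.items():
            if var <= 0:
                continue
            b = np.where(obs["probe_site"] == site, 1.0 / sigma_vec, 0.0)
            g = cov @ (a_design.T @ b)
            cov = cov + var * np.outer(g, g)

    residual_frame = obs.copy()
    residual_frame["prediction_mg_L"] = pred
    residual_frame["relative_residual"] = rel
    return FitResult(
        estimates=theta_hat,
        objective=float(best.cost),
        param_names=names,
        covariance_log=cov,
        fim_log=fim,
        sigma_by_site=sigma_by_site,
        residuals=residual_frame,
        converged_starts=converged,
        spec=spec,
    )


def _nearest_psd(cov: np.ndarray) -> np.ndarray:
    sym = 0.5 * (cov + cov.T)
    vals, vecs = np.linalg.eigh(sym)
    if vals.min() >= 0:
        return sym
    warnings.warn("covariance not positive semidefinite; clipping eigenvalues",
                  RuntimeWarning)
    return (vecs * np.clip(vals, 0.0, None)) @ vecs.T


def sample_parameters(fit: FitResult, n: int, seed: int = 0) -> pd.DataFrame:
    """Multivariate-normal parameter draws on the log scale, back-transformed.

    The estimate distribution is normal in log parameters with mean at the
    point estimates and the FIM-based covariance, so the natural-scale
    draws are strictly positive and the point estimate is the median.
    """
    if n < 1:
        raise ValueError("need n >= 1")
    rng = np.random.default_rng(seed)
    mean = np.log([fit.estimates[name] for name in fit.param_names])
    cov = _nearest_psd(fit.covariance_log)
    draws = rng.multivariate_normal(mean, cov, size=n, method="cholesky" if
                                    np.all(np.linalg.eigvalsh(cov) > 0) else "svd")
    return pd.DataFrame(np.exp(draws), columns=list(fit.param_names))


#: Metrics reported per parameter draw.
METRIC_COLUMNS = (
    "auc_unbound_plasma", "auc_muscle_interstitium", "auc_cortex_interstitium",
    "auc_ratio_muscle", "auc_ratio_cortex",
    "cl_total", "cl_renal", "cl_glomerular", "cl_tubular_secretion", "cl_nonrenal",
)


@dataclass
class PKMetrics:
    """Derived PK metrics over parameter draws (medians + percentile 95% CI)."""

    per_draw: pd.DataFrame
    n_failed: int = 0

    @property
    def median(self) -> pd.Series:
        return self.per_draw.median()

    @property
    def ci95(self) -> pd.DataFrame:
        return self.per_draw.quantile([0.025, 0.975])

    def summary(self) -> pd.DataFrame:
        out = pd.DataFrame({
            "median": self.median,
            "ci_lower": self.ci95.loc[0.025],
            "ci_upper": self.ci95.loc[0.975],
        })
        return out


def derive_pk_metrics(
    draws: pd.DataFrame,
    phys: SpeciesPhysiology,
    geom: KidneyGeometry,
    drug: DrugParameters,
    regimen: DoseRegimen,
    t_end: float = 100.0,
) -> PKMetrics:
    """Simulate each parameter draw to ``t_end`` (default 100 h, by which the
    drugs are fully eliminated) and derive AUCs, AUC ratios and the
    clearance decomposition."""
    if len(draws) == 0:
        raise ValueError("need at least one parameter draw")
    rows = []
    n_failed = 0
    grid = np.array([0.0, t_end])
    for theta in draws.to_dict("records"):
        try:
            applied = _apply_parameters(drug, theta)
            net = build_whole_body_model(phys, geom, applied)
            res = simulate(net, regimen, t_end, grid=grid)
            auc_u = res.tracker("auc_unbound_plasma")[-1]
            auc_m = res.tracker("auc_muscle_interstitium")[-1]
            auc_c = res.tracker("auc_cortex_interstitium")[-1]
            cl_glom = applied.glomerular_clearance(phys.gfr)
            cl_sec = applied.cl_tubular_secretion
            cl_nr = applied.cl_nonrenal
            rows.append({
                "auc_unbound_plasma": auc_u,
                "auc_muscle_interstitium": auc_m,
                "auc_cortex_interstitium": auc_c,
                "auc_ratio_muscle": auc_m / auc_u,
                "auc_ratio_cortex": auc_c / auc_u,
                "cl_total": cl_glom + cl_sec + cl_nr,
                "cl_renal": cl_glom + cl_sec,
                "cl_glomerular": cl_glom,
                "cl_tubular_secretion": cl_sec,
                "cl_nonrenal": cl_nr,
            })
        except Exception:
            n_failed += 1
    if n_failed:
        warnings.warn(f"{n_failed} parameter draw(s) failed to simulate and were "
                      "dropped", RuntimeWarning)
    return PKMetrics(pd.DataFrame(rows, columns=list(METRIC_COLUMNS)), n_failed)


def summarize_cohort(per_animal: list) -> pd.DataFrame:
    """Across-animal medians with pooled percentile 95% CIs.

    The point summary is the median over animals of each animal's median
    metric; the CI pools all animals' parameter draws.
    """
    if not per_animal:
        raise ValueError("need at least one animal")
    medians = pd.concat([m.median for m in per_animal], axis=1).median(axis=1)
    pooled = pd.concat([m.per_draw for m in per_animal], ignore_index=True)
    return pd.DataFrame({
        "median": medians,
        "ci_lower": pooled.quantile(0.025),
        "ci_upper": pooled.quantile(0.975),
    })
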