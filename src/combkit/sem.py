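"""Covariance-structure maximum-likelihood SEM and bootstrap mediation.

The model is held in all-variable form: for the stacked vector of observed
and latent variables, ``A`` collects directed coefficients (loadings and
structural paths) and ``S`` symmetric (co)variances, so the model-implied
covariance of the observed block is

    Sigma(theta) = [ (I - A)^-1 S (I - A)^-T ]_observed

F_ML(theta) = ln|Sigma| + tr(S_sample Sigma^-1) - ln|S_sample| - p is
minimized by L-BFGS with the analytic gradient

    dF/dA = 2 B' P V,   dF/dS = B' P B   (x2 off the diagonal)

where B = (I - A)^-1, V = B S B', and P embeds
W = Sigma^-1 (Sigma - S_sample) Sigma^-1 into the observed block.

Identification follows the convention: exogenous latent variances fixed to
1 with all loadings free; endogenous latents scaled by fixing their first
loading to 1, with a free disturbance.  The standardized solution (which is
invariant to the scaling convention) is derived from the fitted covariance
of all variables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

logger = logging.getLogger(__name__)

_PENALTY = 1e12


class SemError(ValueError):
    pass


class ConvergenceError(SemError):
    def __init__(self, message: str, best_f: float, grad_norm: float):
        super().__init__(message)
        self.best_f = best_f
        self.grad_norm = grad_norm


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------

@dataclass
class SemModel:
    """Measurement + structural specification.

    ``factors`` maps a latent name to its ordered indicators (observed item
    codes or other latents, for second-order factors).  ``paths`` maps an
    endogenous variable to its ordered predictors.
    """

    factors: dict[str, list[str]]
    paths: dict[str, list[str]] = field(default_factory=dict)
    covariances: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.latents = list(self.factors)
        observed: list[str] = []
        for inds in self.factors.values():
            for v in inds:
                if v not in self.factors and v not in observed:
                    observed.append(v)
        for dv, ivs in self.paths.items():
            for v in (dv, *ivs):
                if v not in self.factors and v not in observed:
                    observed.append(v)
        self.observed = observed
        self.variables = observed + self.latents
        self._index = {v: i for i, v in enumerate(self.variables)}
        # endogenous = any variable with an incoming directed edge
        incoming = set(self.paths)
        for fac, inds in self.factors.items():
            incoming.update(inds)
        self.endogenous = incoming
        self.exogenous = [v for v in self.variables if v not in incoming]
        self._build_parameters()

    def _build_parameters(self) -> None:
        m = len(self.variables)
        self.fixed_a = np.zeros((m, m))
        self.fixed_s = np.zeros((m, m))
        names: list[str] = []
        a_idx: list[tuple[int, int]] = []
        s_idx: list[tuple[int, int]] = []
        ix = self._index
        for fac, inds in self.factors.items():
            scale_by_loading = fac in self.endogenous
            for pos, ind in enumerate(inds):
                if scale_by_loading and pos == 0:
                    self.fixed_a[ix[ind], ix[fac]] = 1.0
                else:
                    names.append(f"{fac}=~{ind}")
                    a_idx.append((ix[ind], ix[fac]))
        for dv, ivs in self.paths.items():
            for iv in ivs:
                names.append(f"{dv}~{iv}")
                a_idx.append((ix[dv], ix[iv]))
        n_a = len(a_idx)
        for v in self.variables:
            if v in self.exogenous and v in self.factors:
                self.fixed_s[ix[v], ix[v]] = 1.0  # exogenous latent variance
            else:
                names.append(f"{v}~~{v}")
                s_idx.append((ix[v], ix[v]))
        exo_struct = [v for v in self.exogenous
                      if v in self.factors or any(v in ivs for ivs in self.paths.values())]
        auto_covs = [
            (exo_struct[i], exo_struct[j])
            for i in range(len(exo_struct))
            for j in range(i + 1, len(exo_struct))
        ]
        for a, b in auto_covs + [c for c in self.covariances if c not in auto_covs]:
            names.append(f"{a}~~{b}")
            s_idx.append((ix[a], ix[b]))
        self.param_names = names
        self._a_rows = np.array([t[0] for t in a_idx], dtype=int)
        self._a_cols = np.array([t[1] for t in a_idx], dtype=int)
        self._s_rows = np.array([t[0] for t in s_idx], dtype=int)
        self._s_cols = np.array([t[1] for t in s_idx], dtype=int)
        self.n_a = n_a
        self.n_free = len(names)
        self.obs_idx = np.array([ix[v] for v in self.observed], dtype=int)

    # -- assembly ---------------------------------------------------------

    def matrices(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        a = self.fixed_a.copy()
        s = self.fixed_s.copy()
        a[self._a_rows, self._a_cols] = theta[: self.n_a]
        tv = theta[self.n_a:]
        s[self._s_rows, self._s_cols] = tv
        s[self._s_cols, self._s_rows] = tv
        return a, s

    def total_covariance(self, theta: np.ndarray) -> np.ndarray:
        """Covariance of the stacked (observed, latent) vector."""
        a, s = self.matrices(theta)
        m = a.shape[0]
        try:
            b = linalg.solve(np.eye(m) - a, np.eye(m))
        except linalg.LinAlgError as exc:
            raise SemError("(I - A) is singular; structural part not invertible") from exc
        return b @ s @ b.T

    def theta_dict(self, theta: np.ndarray) -> dict[str, float]:
        return dict(zip(self.param_names, map(float, theta)))


def parse_model(text: str) -> SemModel:
    """Parse the small model DSL.

    Lines: ``factor BR =~ BR1 BR2 BR4``, ``second Capability =~ BR DM KS``,
    ``path Motivation ~ Capability Opportunity``,
    ``cov Capability ~~ Opportunity``.  ``#`` starts a comment.
    """
    factors: dict[str, list[str]] = {}
    paths: dict[str, list[str]] = {}
    covs: list[tuple[str, str]] = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.split()
        kind = tokens[0]
        if kind in ("factor", "second"):
            if len(tokens) < 4 or tokens[2] != "=~":
                raise SemError(f"bad factor line: {raw!r}")
            factors[tokens[1]] = tokens[3:]
        elif kind == "path":
            if len(tokens) < 4 or tokens[2] != "~":
                raise SemError(f"bad path line: {raw!r}")
            paths[tokens[1]] = tokens[3:]
        elif kind == "cov":
            if len(tokens) != 4 or tokens[2] != "~~":
                raise SemError(f"bad cov line: {raw!r}")
            covs.append((tokens[1], tokens[3]))
        else:
            raise SemError(f"unknown directive {kind!r}")
    return SemModel(factors=factors, paths=paths, covariances=covs)


def implied_covariance(model: SemModel, theta: np.ndarray) -> np.ndarray:
    """Model-implied covariance of the observed variables."""
    v = model.total_covariance(np.asarray(theta, dtype=float))
    return v[np.ix_(model.obs_idx, model.obs_idx)]


# ---------------------------------------------------------------------------
# ML fitting
# ---------------------------------------------------------------------------

@dataclass
class SemFit:
    model: SemModel
    theta: np.ndarray
    params: dict[str, float]
    standardized: dict[str, float]
    fml: float
    sigma: np.ndarray
    converged: bool
    grad_norm: float
    heywood: list[str]
    n: int

    @property
    def df(self) -> int:
        p = len(self.model.observed)
        return p * (p + 1) // 2 - self.model.n_free

    def chi2(self) -> float:
        return (self.n - 1) * self.fml


def _objective(theta, model, s_samp, logdet_s, eye_m, obs):
    a = model.fixed_a.copy()
    smat = model.fixed_s.copy()
    a[model._a_rows, model._a_cols] = theta[: model.n_a]
    tv = theta[model.n_a:]
    smat[model._s_rows, model._s_cols] = tv
    smat[model._s_cols, model._s_rows] = tv
    ima = eye_m - a
    try:
        b = linalg.solve(ima, eye_m)
    except linalg.LinAlgError:
        return _PENALTY, np.zeros_like(theta)
    v = b @ smat @ b.T
    sigma = v[np.ix_(obs, obs)]
    try:
        cho = linalg.cho_factor(sigma, check_finite=False)
    except linalg.LinAlgError:
        return _PENALTY, np.zeros_like(theta)
    logdet = 2 * np.sum(np.log(np.diag(cho[0])))
    sigma_inv = linalg.cho_solve(cho, np.eye(len(obs)), check_finite=False)
    f = logdet + float(np.sum(sigma_inv * s_samp)) - logdet_s - len(obs)
    if not np.isfinite(f):
        return _PENALTY, np.zeros_like(theta)
    w = sigma_inv @ (sigma - s_samp) @ sigma_inv
    p_full = np.zeros_like(a)
    p_full[np.ix_(obs, obs)] = w
    bt_p = b.T @ p_full
    grad_a = 2 * bt_p @ v
    grad_s_full = bt_p @ b
    grad = np.empty_like(theta)
    grad[: model.n_a] = grad_a[model._a_rows, model._a_cols]
    diag = model._s_rows == model._s_cols
    gs = grad_s_full[model._s_rows, model._s_cols]
    grad[model.n_a:] = np.where(diag, gs, 2 * gs)
    return f, grad


def _start_values(model: SemModel, s_samp: np.ndarray) -> np.ndarray:
    sd = {v: float(np.sqrt(s_samp[i, i])) for i, v in enumerate(model.observed)}

    def var_of(v: str) -> float:
        if v in model.factors:
            ref = model.factors[v][0]
            return 0.49 * var_of(ref) if v in model.endogenous else 1.0
        return sd[v] ** 2

    theta = np.empty(model.n_free)
    for k, name in enumerate(model.param_names):
        if "=~" in name:
            fac, ind = name.split("=~")
            theta[k] = 0.7 * np.sqrt(var_of(ind)) / np.sqrt(var_of(fac))
        elif name.count("~") == 1:
            theta[k] = 0.1
        else:
            a, b = name.split("~~")
            theta[k] = 0.5 * var_of(a) if a == b else 0.2 * np.sqrt(var_of(a) * var_of(b))
    return theta


def fit_ml(
    model: SemModel,
    s_samp: np.ndarray | pd.DataFrame,
    n: int,
    *,
    seed: int = 0,
    n_starts: int = 5,
    theta0: np.ndarray | None = None,
    ftol: float = 1e-11,
    maxiter: int = 2000,
) -> SemFit:
    """Minimize F_ML by multi-start L-BFGS with analytic gradients.

    ``theta0`` replaces the smart start (e.g. warm starts during
    bootstrapping); random restarts perturb the start multiplicatively
    with a seeded generator.
    """
    if isinstance(s_samp, pd.DataFrame):
        s_samp = s_samp.loc[model.observed, model.observed].to_numpy()
    s_samp = np.asarray(s_samp, dtype=float)
    p = len(model.observed)
    if s_samp.shape != (p, p):
        raise SemError(f"sample covariance must be {p}x{p}")
    sign, logdet_s = np.linalg.slogdet(s_samp)
    if sign <= 0:
        raise SemError("sample covariance is not positive definite")
    eye_m = np.eye(len(model.variables))
    obs = model.obs_idx
    args = (model, s_samp, logdet_s, eye_m, obs)

    base = _start_values(model, s_samp) if theta0 is None else np.asarray(theta0, float)
    rng = np.random.default_rng(seed)
    best = None
    for trial in range(max(1, n_starts)):
        x0 = base if trial == 0 else base * rng.uniform(0.6, 1.4, base.size) + rng.normal(
            0, 0.05, base.size
        )
        res = optimize.minimize(
            _objective, x0, args=args, jac=True, method="L-BFGS-B",
            options={"ftol": ftol, "gtol": 1e-9, "maxiter": maxiter},
        )
        if best is None or res.fun < best.fun:
            best = res
        if best.fun < _PENALTY and np.linalg.norm(best.jac) < 1e-6:
            break
    grad_norm = float(np.linalg.norm(best.jac))
    converged = best.fun < _PENALTY and grad_norm < 1e-4
    if not converged:
        raise ConvergenceError(
            f"ML fit did not converge after {n_starts} starts "
            f"(best F={best.fun:.6g}, |grad|={grad_norm:.3g})",
            best_f=float(best.fun), grad_norm=grad_norm,
        )
    theta = best.x
    sigma = implied_covariance(model, theta)
    heywood = [
        name for name, val in zip(model.param_names, theta)
        if "~~" in name and name.split("~~")[0] == name.split("~~")[1] and val < 0
    ]
    if heywood:
        logger.warning("Heywood case: negative variance for %s", heywood)
    return SemFit(
        model=model,
        theta=theta,
        params=model.theta_dict(theta),
        standardized=standardize(model, theta),
        fml=float(best.fun),
        sigma=sigma,
        converged=converged,
        grad_norm=grad_norm,
        heywood=heywood,
        n=n,
    )


def standardize(model: SemModel, theta: np.ndarray) -> dict[str, float]:
    """Standardized loadings/paths/covariances from the fitted covariance."""
    v = model.total_covariance(theta)
    sdv = np.sqrt(np.clip(np.diag(v), 1e-12, None))
    ix = model._index
    a, smat = model.matrices(theta)
    out: dict[str, float] = {}
    for name in model.param_names:
        if "=~" in name:
            fac, ind = name.split("=~")
            out[name] = float(a[ix[ind], ix[fac]] * sdv[ix[fac]] / sdv[ix[ind]])
        elif "~~" in name:
            x, y = name.split("~~")
            out[name] = float(smat[ix[x], ix[y]] / (sdv[ix[x]] * sdv[ix[y]]))
        else:
            dv, iv = name.split("~")
            out[name] = float(a[ix[dv], ix[iv]] * sdv[ix[iv]] / sdv[ix[dv]])
    # standardized value of scaling loadings fixed to 1
    for fac, inds in model.factors.items():
        if fac in model.endogenous:
            ind = inds[0]
            out[f"{fac}=~{ind}"] = float(sdv[ix[fac]] / sdv[ix[ind]])
    return out


# ---------------------------------------------------------------------------
# fit indices
# ---------------------------------------------------------------------------

@dataclass
class FitIndices:
    chi2: float
    df: int
    chi2_df: float | None
    gfi: float
    agfi: float | None
    rmsea: float | None
    srmr: float
    nfi: float
    tli: float
    cfi: float
    notes: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "chi2": self.chi2, "df": self.df, "chi2_df": self.chi2_df,
            "GFI": self.gfi, "AGFI": self.agfi, "RMSEA": self.rmsea,
            "SRMR": self.srmr, "NFI": self.nfi, "TLI": self.tli,
            "CFI": self.cfi, "notes": self.notes,
        }


def baseline_fml(s_samp: np.ndarray) -> float:
    """F_ML of the independence model (Sigma = diag(S))."""
    sign, logdet = np.linalg.slogdet(s_samp)
    if sign <= 0:
        raise SemError("sample covariance is not positive definite")
    return float(np.sum(np.log(np.diag(s_samp))) - logdet)


def fit_indices(fit: SemFit, s_samp: np.ndarray | pd.DataFrame, n: int) -> FitIndices:
    """chi2/df, GFI, AGFI, RMSEA, SRMR, NFI, TLI, CFI with (n-1) scaling."""
    if isinstance(s_samp, pd.DataFrame):
        s_samp = s_samp.loc[fit.model.observed, fit.model.observed].to_numpy()
    s_samp = np.asarray(s_samp, dtype=float)
    p = s_samp.shape[0]
    sigma = fit.sigma
    df_m = fit.df
    chi2_m = (n - 1) * fit.fml
    f_b = baseline_fml(s_samp)
    chi2_b = (n - 1) * f_b
    df_b = p * (p - 1) // 2

    sigma_inv = np.linalg.inv(sigma)
    g = sigma_inv @ s_samp
    gfi = float(1 - np.trace((g - np.eye(p)) @ (g - np.eye(p))) / np.trace(g @ g))

    d = np.sqrt(np.outer(np.diag(s_samp), np.diag(s_samp)))
    resid = (s_samp - sigma) / d
    tril = np.tril_indices(p)
    srmr = float(np.sqrt(np.mean(resid[tril] ** 2)))

    notes: dict[str, str] = {}
    if df_m > 0:
        rmsea = float(np.sqrt(max(chi2_m - df_m, 0.0) / (df_m * (n - 1))))
        agfi = float(1 - (p * (p + 1) / (2 * df_m)) * (1 - gfi))
        chi2_df = chi2_m / df_m
    else:
        rmsea = agfi = chi2_df = None
        notes["rmsea"] = notes["agfi"] = notes["chi2_df"] = "undefined: df = 0"

    nfi = float((chi2_b - chi2_m) / chi2_b) if chi2_b > 0 else 1.0
    if df_m > 0 and df_b > 0 and chi2_b / df_b > 1:
        tli = float(
            (chi2_b / df_b - chi2_m / df_m) / (chi2_b / df_b - 1)
        )
    else:
        tli = 1.0
        notes.setdefault("tli", "baseline ratio <= 1 or df = 0; reported as 1")
    denom = max(chi2_b - df_b, chi2_m - df_m, 0.0)
    cfi = 1.0 if denom == 0 else float(1 - max(chi2_m - df_m, 0.0) / denom)
    return FitIndices(
        chi2=float(chi2_m), df=df_m, chi2_df=chi2_df, gfi=gfi, agfi=agfi,
        rmsea=rmsea, srmr=srmr, nfi=nfi, tli=tli, cfi=min(cfi, 1.0), notes=notes,
    )


# ---------------------------------------------------------------------------
# bootstrap mediation
# ---------------------------------------------------------------------------

@dataclass
class MediationResult:
    effects: dict[str, float]              # direct / indirect / total
    se: dict[str, float]                   # bootstrap SD
    ci_bias_corrected: dict[str, tuple[float, float]]
    ci_percentile: dict[str, tuple[float, float]]
    p_values: dict[str, float]
    classification: str                    # none / partial / full
    n_boot: int
    n_dropped: int
    path_estimates: dict[str, float]
    path_draws: dict[str, np.ndarray]

    def path_ci(self, name: str, level: float = 0.95) -> tuple[float, float]:
        lo = (1 - level) / 2
        d = self.path_draws[name]
        return (float(np.quantile(d, lo)), float(np.quantile(d, 1 - lo)))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for eff in ("direct", "indirect", "total"):
            rows.append({
                "effect": eff,
                "estimate": self.effects[eff],
                "se": self.se[eff],
                "bc_low": self.ci_bias_corrected[eff][0],
                "bc_high": self.ci_bias_corrected[eff][1],
                "pct_low": self.ci_percentile[eff][0],
                "pct_high": self.ci_percentile[eff][1],
                "p": self.p_values[eff],
            })
        return pd.DataFrame(rows)


def percentile_ci(draws: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    lo = (1 - level) / 2
    return (float(np.quantile(draws, lo)), float(np.quantile(draws, 1 - lo)))


def bias_corrected_ci(
    draws: np.ndarray, estimate: float, level: float = 0.95
) -> tuple[float, float]:
    """BC bootstrap interval: quantiles shifted by z0 = Phi^-1(P(draw < est))."""
    b = len(draws)
    prop = np.clip(np.mean(draws < estimate), 1 / (b + 1), b / (b + 1))
    z0 = stats.norm.ppf(prop)
    zc = stats.norm.ppf(1 - (1 - level) / 2)
    lo = stats.norm.cdf(2 * z0 - zc)
    hi = stats.norm.cdf(2 * z0 + zc)
    return (float(np.quantile(draws, lo)), float(np.quantile(draws, hi)))


def _boot_pvalue(draws: np.ndarray) -> float:
    b = len(draws)
    p_lo = (np.sum(draws <= 0) + 1) / (b + 1)
    p_hi = (np.sum(draws >= 0) + 1) / (b + 1)
    return float(min(1.0, 2 * min(p_lo, p_hi)))


def bootstrap_mediation(
    model: SemModel,
    data: pd.DataFrame,
    x: str,
    mediator: str,
    y: str,
    n_boot: int = 5000,
    seed: int | None = None,
    n_starts: int = 3,
    max_dropped_fraction: float = 0.10,
) -> MediationResult:
    """Case-resampling bootstrap of the standardized mediation effects.

    The indirect effect per replicate is the product of the standardized
    x -> mediator and mediator -> y paths; direct is the standardized
    x -> y path.  Replicates whose resampled covariance is not positive
    definite or whose fit fails are dropped and counted.
    """
    if n_boot < 100:
        raise SemError("need at least 100 bootstrap replicates")
    cols = list(model.observed)
    arr = data[cols].to_numpy(dtype=float)
    n = arr.shape[0]
    s_full = np.cov(arr, rowvar=False, ddof=1)
    full = fit_ml(model, s_full, n, seed=0, n_starts=n_starts)
    a_name, b_name, c_name = f"{mediator}~{x}", f"{y}~{mediator}", f"{y}~{x}"
    for name in (a_name, b_name, c_name):
        if name not in full.standardized:
            raise SemError(f"path {name!r} not present in the model")
    est = {
        "direct": full.standardized[c_name],
        "indirect": full.standardized[a_name] * full.standardized[b_name],
    }
    est["total"] = est["direct"] + est["indirect"]

    struct_names = [nm for nm in model.param_names if nm.count("~") == 1 and "=~" not in nm]
    rng = np.random.default_rng(seed)
    draws = {k: [] for k in ("direct", "indirect", "total")}
    path_draws: dict[str, list[float]] = {nm: [] for nm in struct_names}
    dropped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        s_b = np.cov(arr[idx], rowvar=False, ddof=1)
        try:
            fit_b = fit_ml(model, s_b, n, theta0=full.theta, n_starts=1)
        except SemError:
            dropped += 1
            continue
        std = fit_b.standardized
        d = std[c_name]
        ind = std[a_name] * std[b_name]
        draws["direct"].append(d)
        draws["indirect"].append(ind)
        draws["total"].append(d + ind)
        for nm in struct_names:
            path_draws[nm].append(std[nm])
    if dropped > max_dropped_fraction * n_boot:
        raise SemError(
            f"{dropped}/{n_boot} bootstrap replicates failed to converge"
        )
    arrs = {k: np.asarray(v) for k, v in draws.items()}
    ci_bc = {k: bias_corrected_ci(arrs[k], est[k]) for k in arrs}
    ci_pc = {k: percentile_ci(arrs[k]) for k in arrs}
    pvals = {k: _boot_pvalue(arrs[k]) for k in arrs}
    indirect_sig = not (ci_bc["indirect"][0] <= 0 <= ci_bc["indirect"][1])
    direct_sig = not (ci_bc["direct"][0] <= 0 <= ci_bc["direct"][1])
    if indirect_sig and not direct_sig:
        classification = "full"
    elif indirect_sig:
        classification = "partial"
    else:
        classification = "none"
    return MediationResult(
        effects=est,
        se={k: float(np.std(arrs[k], ddof=1)) for k in arrs},
        ci_bias_corrected=ci_bc,
        ci_percentile=ci_pc,
        p_values=pvals,
        classification=classification,
        n_boot=n_boot - dropped,
        n_dropped=dropped,
        path_estimates={nm: full.standardized[nm] for nm in struct_names},
        path_draws={nm: np.asarray(v) for nm, v in path_draws.items()},
    )


# ---------------------------------------------------------------------------
# the COM-B structural model over domain scores
# ---------------------------------------------------------------------------

def comb_model_text(spec) -> str:
    """DSL for the structural COM-B model with domain scores as indicators.

    Each module factor is measured by the mean scores of its domains
    (Behavior by its single-item behaviors); Motivation and Behavior are
    endogenous.
    """
    lines = [
        f"factor {module} =~ " + " ".join(spec.domains[module])
        for module in spec.domains
    ]
    lines.append("factor Behavior =~ " + " ".join(spec.behavior_items))
    lines.append("path Motivation ~ Capability Opportunity")
    lines.append("path Behavior ~ Capability Opportunity Motivation")
    return "\n".join(lines)
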