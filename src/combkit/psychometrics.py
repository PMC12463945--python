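"""Item screening, exploratory factor analysis, reliability and validity.

All variances and correlations use the sample (n-1) denominator.  The EFA
is a principal-component factoring of the correlation matrix with varimax
rotation (Kaiser normalization on, sign convention: each factor's
largest-|loading| entry is positive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


class PsychometricsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# item screening
# ---------------------------------------------------------------------------

REASON_LOW_ITEM_TOTAL = "low_item_total"
REASON_LOW_LOADING = "low_loading"
REASON_CROSS_LOADING = "cross_loading"
REASON_ORPHAN_FACTOR = "orphan_factor"


@dataclass
class ItemScreeningReport:
    """Per-item corrected item-total correlations and elimination flags."""

    item_total: dict[str, float]
    eliminated: dict[str, str] = field(default_factory=dict)  # item -> reason
    thresholds: dict[str, float] = field(default_factory=dict)

    @property
    def retained(self) -> list[str]:
        return [i for i in self.item_total if i not in self.eliminated]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "item": list(self.item_total),
                "item_total": [self.item_total[i] for i in self.item_total],
                "eliminated": [i in self.eliminated for i in self.item_total],
                "reason": [self.eliminated.get(i, "") for i in self.item_total],
            }
        )


def listwise_complete(data: pd.DataFrame, min_rows: int = 50) -> pd.DataFrame:
    """Drop respondents with any missing value, logging the count."""
    complete = data.dropna()
    dropped = len(data) - len(complete)
    if dropped:
        logger.info("listwise deletion removed %d of %d respondents", dropped, len(data))
    if len(complete) < min_rows:
        raise PsychometricsError(
            f"only {len(complete)} complete rows remain (need >= {min_rows})"
        )
    return complete


def corrected_item_total(data: pd.DataFrame, items: list[str]) -> dict[str, float]:
    """Correlation of each item with the sum of the other items in its set."""
    if len(items) < 2:
        raise PsychometricsError("need at least two items")
    sub = data[list(items)].astype(float)
    if len(sub) < 3:
        raise PsychometricsError("need at least three respondents")
    out: dict[str, float] = {}
    for item in items:
        col = sub[item].to_numpy()
        if np.var(col, ddof=1) == 0:
            raise PsychometricsError(f"item {item!r} has zero variance")
        rest = sub.drop(columns=item).sum(axis=1).to_numpy()
        if np.var(rest, ddof=1) == 0:
            # rest score degenerate: correlation undefined for this item
            logger.warning("rest score for %r has zero variance", item)
            out[item] = float("nan")
            continue
        out[item] = float(np.corrcoef(col, rest)[0, 1])
    return out


def screen_item_totals(
    data: pd.DataFrame, items: list[str], threshold: float = 0.5
) -> ItemScreeningReport:
    values = corrected_item_total(data, items)
    eliminated = {
        i: REASON_LOW_ITEM_TOTAL for i, v in values.items() if v < threshold
    }
    return ItemScreeningReport(
        item_total=values, eliminated=eliminated, thresholds={"item_total": threshold}
    )


def cronbach_alpha(data: pd.DataFrame, items: list[str]) -> float:
    """alpha = k/(k-1) * (1 - sum(var_i)/var_total), sample variances."""
    if len(items) < 2:
        raise PsychometricsError("need at least two items")
    sub = data[list(items)].astype(float).to_numpy()
    k = sub.shape[1]
    item_var = sub.var(axis=0, ddof=1)
    total_var = sub.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise PsychometricsError("zero total-score variance")
    return float(k / (k - 1) * (1 - item_var.sum() / total_var))


# ---------------------------------------------------------------------------
# sampling adequacy
# ---------------------------------------------------------------------------

@dataclass
class SamplingAdequacyReport:
    kmo: float
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float


def _corr(data: pd.DataFrame) -> np.ndarray:
    r = np.corrcoef(data.astype(float).to_numpy(), rowvar=False)
    return np.atleast_2d(r)


def kmo(data: pd.DataFrame) -> float:
    """Kaiser-Meyer-Olkin sampling adequacy.

    KMO = sum r_ij^2 / (sum r_ij^2 + sum q_ij^2) over i != j, where q are
    the anti-image partial correlations from the inverse correlation matrix.
    """
    r = _corr(data)
    p = r.shape[0]
    try:
        rinv = np.linalg.inv(r)
    except np.linalg.LinAlgError as exc:
        raise PsychometricsError("singular correlation matrix") from exc
    d = np.sqrt(np.outer(np.diag(rinv), np.diag(rinv)))
    q = -rinv / d
    off = ~np.eye(p, dtype=bool)
    num = np.sum(r[off] ** 2)
    den = num + np.sum(q[off] ** 2)
    if den < 1e-12:
        raise PsychometricsError("no common variance among items")
    return float(num / den)


def bartlett_sphericity(data: pd.DataFrame) -> tuple[float, int, float]:
    """Bartlett test that the correlation matrix is the identity.

    chi2 = -(n - 1 - (2p + 5)/6) * ln|R| on p(p-1)/2 degrees of freedom.
    """
    r = _corr(data)
    n, p = data.shape
    if n <= p:
        raise PsychometricsError("need more respondents than items")
    sign, logdet = np.linalg.slogdet(r)
    if sign <= 0:
        raise PsychometricsError("correlation matrix has non-positive determinant")
    chi2 = -(n - 1 - (2 * p + 5) / 6) * logdet
    df = p * (p - 1) // 2
    pval = float(stats.chi2.sf(chi2, df))
    return float(chi2), int(df), pval


def sampling_adequacy(data: pd.DataFrame) -> SamplingAdequacyReport:
    chi2, df, p = bartlett_sphericity(data)
    return SamplingAdequacyReport(kmo=kmo(data), bartlett_chi2=chi2,
                                  bartlett_df=df, bartlett_p=p)


# ---------------------------------------------------------------------------
# EFA: principal components + varimax
# ---------------------------------------------------------------------------

@dataclass
class FactorSolution:
    loadings: pd.DataFrame          # items x retained factors, rotated
    eigenvalues: np.ndarray         # all eigenvalues of R, descending
    pct_variance: np.ndarray        # per retained factor, post-rotation
    total_pct_variance: float
    communalities: pd.Series
    rotation_iterations: int

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]


def _varimax(loadings: np.ndarray, tol: float = 1e-8, max_iter: int = 200
             ) -> tuple[np.ndarray, int]:
    """Varimax rotation with Kaiser normalization; returns (rotated, sweeps)."""
    p, k = loadings.shape
    if k < 2:
        return loadings.copy(), 0
    h = np.sqrt((loadings**2).sum(axis=1))
    h[h == 0] = 1.0
    a = loadings / h[:, None]
    rotation = np.eye(k)
    d = 0.0
    it = 0
    for it in range(1, max_iter + 1):
        lam = a @ rotation
        u, s, vt = np.linalg.svd(
            a.T @ (lam**3 - lam @ np.diag((lam**2).sum(axis=0)) / p)
        )
        rotation = u @ vt
        d_new = s.sum()
        if d_new < d * (1 + tol):
            break
        d = d_new
    rotated = (a @ rotation) * h[:, None]
    return rotated, it


def efa_pca_varimax(
    data: pd.DataFrame,
    eigen_threshold: float = 1.0,
    rotation_tol: float = 1e-8,
    max_rotation_iter: int = 200,
) -> FactorSolution:
    """Principal-component factoring of R with varimax rotation.

    Components with eigenvalue > ``eigen_threshold`` are retained;
    unrotated loadings are eigenvector * sqrt(eigenvalue); explained
    variance is recomputed from the rotated loadings.
    """
    if len(data) <= data.shape[1]:
        raise PsychometricsError("need more respondents than items")
    r = _corr(data)
    eigvals, eigvecs = np.linalg.eigh(r)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    keep = eigvals > eigen_threshold
    if not keep.any():
        raise PsychometricsError(
            f"no eigenvalue exceeds {eigen_threshold}; nothing to retain"
        )
    k = int(keep.sum())
    loadings = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    rotated, iters = _varimax(loadings, tol=rotation_tol, max_iter=max_rotation_iter)
    # sign convention: dominant loading of each factor positive
    for j in range(k):
        if rotated[np.argmax(np.abs(rotated[:, j])), j] < 0:
            rotated[:, j] = -rotated[:, j]
    p = r.shape[0]
    ssq = (rotated**2).sum(axis=0)
    order2 = np.argsort(ssq)[::-1]
    rotated = rotated[:, order2]
    ssq = ssq[order2]
    items = list(data.columns)
    frame = pd.DataFrame(
        rotated, index=items, columns=[f"F{j + 1}" for j in range(k)]
    )
    return FactorSolution(
        loadings=frame,
        eigenvalues=eigvals,
        pct_variance=100 * ssq / p,
        total_pct_variance=float(100 * ssq.sum() / p),
        communalities=pd.Series((rotated**2).sum(axis=1), index=items),
        rotation_iterations=iters,
    )


def apply_item_retention_rules(
    solution: FactorSolution,
    screening: ItemScreeningReport,
    loading_threshold: float = 0.5,
    cross_loading_threshold: float = 0.5,
    min_items_per_factor: int = 3,
) -> ItemScreeningReport:
    """Flag items by loading rules, then dissolve under-populated factors.

    Order of application: item-total eliminations (already present in
    ``screening``) -> low primary loading -> cross-loading -> orphan-factor
    check.  Each eliminated item carries exactly one (first) reason.
    """
    if set(solution.loadings.index) != set(screening.item_total):
        raise PsychometricsError("solution and screening cover different items")
    eliminated = dict(screening.eliminated)
    load = solution.loadings.abs()
    for item in solution.loadings.index:
        if item in eliminated:
            continue
        row = load.loc[item].sort_values(ascending=False)
        if row.iloc[0] <= loading_threshold:
            eliminated[item] = REASON_LOW_LOADING
        elif len(row) > 1 and row.iloc[1] > cross_loading_threshold:
            eliminated[item] = REASON_CROSS_LOADING
    # orphan check on surviving items: a factor keeping < min_items is dissolved
    surviving = [i for i in solution.loadings.index if i not in eliminated]
    assignment = load.loc[surviving].idxmax(axis=1) if surviving else pd.Series(dtype=object)
    for factor in solution.loadings.columns:
        members = assignment[assignment == factor].index.tolist()
        if 0 < len(members) < min_items_per_factor:
            for item in members:
                eliminated[item] = REASON_ORPHAN_FACTOR
    thresholds = dict(screening.thresholds)
    thresholds.update(
        loading=loading_threshold,
        cross_loading=cross_loading_threshold,
        min_items_per_factor=min_items_per_factor,
    )
    return ItemScreeningReport(
        item_total=dict(screening.item_total),
        eliminated=eliminated,
        thresholds=thresholds,
    )


# ---------------------------------------------------------------------------
# reliability / validity from standardized loadings
# ---------------------------------------------------------------------------

def ave(loadings: list[float]) -> float:
    """Average variance extracted: mean of squared standardized loadings."""
    lam = np.asarray(loadings, dtype=float)
    if lam.size == 0:
        raise PsychometricsError("empty loading list")
    if np.any(lam <= -1) or np.any(lam > 1):
        raise PsychometricsError("standardized loadings must lie in (-1, 1]")
    return float(np.mean(lam**2))


def composite_reliability(loadings: list[float]) -> float:
    """CR = (sum lam)^2 / ((sum lam)^2 + sum(1 - lam^2))."""
    lam = np.asarray(loadings, dtype=float)
    if lam.size == 0:
        raise PsychometricsError("empty loading list")
    if np.any(lam <= -1) or np.any(lam > 1):
        raise PsychometricsError("standardized loadings must lie in (-1, 1]")
    s2 = lam.sum() ** 2
    return float(s2 / (s2 + np.sum(1 - lam**2)))


@dataclass
class ReliabilityValidityReport:
    alpha: dict[str, float]
    cr: dict[str, float]
    ave: dict[str, float]
    sqrt_ave: dict[str, float]
    factor_correlations: pd.DataFrame
    fornell_larcker_pass: dict[tuple[str, str], bool]
    variance_denominator: str = "n-1"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for dom in self.ave:
            rows.append(
                {
                    "domain": dom,
                    "alpha": self.alpha.get(dom, np.nan),
                    "CR": self.cr[dom],
                    "AVE": self.ave[dom],
                    "sqrt_AVE": self.sqrt_ave[dom],
                }
            )
        return pd.DataFrame(rows)


def fornell_larcker(
    ave_by_domain: dict[str, float], factor_correlations: pd.DataFrame
) -> tuple[dict[str, float], dict[tuple[str, str], bool]]:
    """Discriminant validity: pass iff sqrt(AVE_i) strictly exceeds |r_ij|."""
    domains = list(factor_correlations.index)
    missing = [d for d in domains if d not in ave_by_domain]
    if missing:
        raise PsychometricsError(f"AVE missing for {missing}")
    sqrt_ave = {d: float(np.sqrt(ave_by_domain[d])) for d in domains}
    result: dict[tuple[str, str], bool] = {}
    for i in domains:
        for j in domains:
            if i == j:
                continue
            result[(i, j)] = sqrt_ave[i] > abs(float(factor_correlations.loc[i, j]))
    return sqrt_ave, result


def reliability_validity_report(
    data: pd.DataFrame,
    domain_items: dict[str, list[str]],
    loadings_by_domain: dict[str, list[float]],
) -> ReliabilityValidityReport:
    """Assemble alpha/CR/AVE and the Fornell-Larcker table for a subscale."""
    alpha = {d: cronbach_alpha(data, items) for d, items in domain_items.items()}
    cr = {d: composite_reliability(l) for d, l in loadings_by_domain.items()}
    ave_ = {d: ave(l) for d, l in loadings_by_domain.items()}
    scores = pd.DataFrame(
        {d: data[list(items)].mean(axis=1) for d, items in domain_items.items()}
    )
    corr = scores.corr()
    sqrt_ave, passes = fornell_larcker(ave_, corr)
    return ReliabilityValidityReport(
        alpha=alpha,
        cr=cr,
        ave=ave_,
        sqrt_ave=sqrt_ave,
        factor_correlations=corr,
        fornell_larcker_pass=passes,
    )


def split_half(
    data: pd.DataFrame, mode: str = "first-half", seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split respondents for EFA (first part) and CFA (second part).

    ``mode='first-half'`` is an ordered split; ``mode='random'`` shuffles
    respondents with the given seed first.
    """
    if mode == "random":
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(data))
        data = data.iloc[order]
    elif mode != "first-half":
        raise PsychometricsError(f"unknown split mode {mode!r}")
    half = len(data) // 2
    return data.iloc[:half], data.iloc[half:]
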