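"""Synthetic Likert survey generator with a known latent structure.

Responses are produced by a thresholded latent-normal (graded-response
style) mechanism:

1. the exogenous module factors Capability and Opportunity are drawn from
   a bivariate standard normal with correlation ``exog_correlation``;
2. Motivation and Behavior are built from the standardized structural
   paths (C->M, O->M, C->B, O->B, M->B), each with a disturbance scaled so
   the composite stays unit-variance;
3. each first-order domain factor is ``gamma * module + sqrt(1-gamma^2) * z``
   where gamma is its second-order loading;
4. each item latent is ``lambda * domain + noise``, standardized by default
   (noise sd = sqrt(1 - lambda^2)); behavior items load directly on the
   Behavior factor;
5. item latents are cut at four ordered thresholds into the integers 1-5.

With the default symmetric thresholds the Likert categories are symmetric
around a mean near 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .instrument import InstrumentSpec, default_instrument

PATH_KEYS = ("M~C", "M~O", "B~C", "B~O", "B~M")

DEFAULT_THRESHOLDS = (-1.5, -0.5, 0.5, 1.5)

#: Standardized structural coefficients of the fitted COM-B model used as
#: simulation ground truth (C->M, O->M, C->B, O->B, M->B).
DEFAULT_STRUCTURAL_PATHS = {
    "M~C": 0.21,
    "M~O": 0.18,
    "B~C": -0.04,
    "B~O": 0.26,
    "B~M": 0.41,
}

#: Second-order loadings of each domain on its module factor.
DEFAULT_SECOND_ORDER = {
    "KS": 0.849, "DM": 0.888, "BR": 0.886,
    "OP": 0.659, "SR": 0.686, "EM": 0.710, "REI": 0.722,
    "INT": 0.680, "BCO": 0.709, "BCA": 0.691,
    "VAL": 0.765, "LS": 0.732, "PN": 0.811, "PE": 0.816, "EI": 0.740,
}

#: First-order standardized item loadings (retained capability and
#: motivation items; a common value for the opportunity and behavior items,
#: whose per-item loadings are not individually reported).
DEFAULT_ITEM_LOADINGS = {
    "BR1": 0.821, "BR2": 0.802, "BR4": 0.738,
    "DM2": 0.833, "DM4": 0.812, "DM3": 0.722,
    "KS4": 0.847, "KS2": 0.835, "KS1": 0.703,
    "SR3": 0.830, "SR1": 0.827, "SR2": 0.827,
    "OP1": 0.859, "OP2": 0.817, "OP3": 0.816,
    "BCO1": 0.823, "BCO3": 0.816, "BCO2": 0.816,
    "REI3": 0.830, "REI1": 0.815, "REI2": 0.804,
    "EM3": 0.819, "EM2": 0.819, "EM1": 0.801,
    "INT1": 0.832, "INT2": 0.824, "INT3": 0.807,
    "BCA1": 0.828, "BCA2": 0.802, "BCA3": 0.796,
}
DEFAULT_OPPORTUNITY_LOADING = 0.78
DEFAULT_BEHAVIOR_LOADING = 0.70


class SimulationError(ValueError):
    """Invalid ground-truth parameters."""


@dataclass
class GroundTruthParams:
    """Latent ground truth for the generator.

    Attributes
    ----------
    loadings
        item code -> standardized first-order loading in [0, 1].
    second_order_loadings
        domain code -> loading of the domain factor on its module factor.
    structural_paths
        standardized module-level coefficients, keys ``M~C``, ``M~O``,
        ``B~C``, ``B~O``, ``B~M``.
    exog_correlation
        correlation between the exogenous Capability and Opportunity
        factors.
    thresholds
        four strictly increasing cut points on the standardized item
        latent; category k is emitted when the latent falls in the k-th
        interval.
    noise_sd
        optional residual sd per item; by default ``sqrt(1 - loading^2)``
        so item latents are standardized.
    missing_rate
        optional MCAR missingness proportion applied after thresholding.
    """

    loadings: dict[str, float]
    second_order_loadings: dict[str, float] = field(default_factory=dict)
    structural_paths: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STRUCTURAL_PATHS)
    )
    exog_correlation: float = 0.5
    thresholds: tuple[float, float, float, float] = DEFAULT_THRESHOLDS
    noise_sd: dict[str, float] | None = None
    missing_rate: float = 0.0

    def validate(self) -> None:
        thr = np.asarray(self.thresholds, dtype=float)
        if thr.size != 4 or not np.all(np.diff(thr) > 0):
            raise SimulationError("thresholds must be 4 strictly increasing values")
        if not -1 < self.exog_correlation < 1:
            raise SimulationError("exogenous correlation matrix not positive definite")
        for key, value in self.structural_paths.items():
            if key not in PATH_KEYS:
                raise SimulationError(f"unknown structural path {key!r}")
            if abs(value) > 1:
                raise SimulationError(f"|standardized path| > 1 for {key!r}")
        for item, lam in self.loadings.items():
            if not 0 <= lam <= 1:
                raise SimulationError(f"loading for {item!r} outside [0, 1]")
        for dom, gam in self.second_order_loadings.items():
            if not 0 <= gam <= 1:
                raise SimulationError(f"second-order loading for {dom!r} outside [0, 1]")
        if not 0 <= self.missing_rate < 1:
            raise SimulationError("missing_rate must be in [0, 1)")

    def item_loading(self, item: str) -> float:
        return float(self.loadings.get(item, 0.0))

    def to_dict(self) -> dict:
        return {
            "loadings": dict(self.loadings),
            "second_order_loadings": dict(self.second_order_loadings),
            "structural_paths": dict(self.structural_paths),
            "exog_correlation": self.exog_correlation,
            "thresholds": list(self.thresholds),
            "noise_sd": dict(self.noise_sd) if self.noise_sd else None,
            "missing_rate": self.missing_rate,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "GroundTruthParams":
        return cls(
            loadings=data["loadings"],
            second_order_loadings=data.get("second_order_loadings", {}),
            structural_paths=data.get(
                "structural_paths", dict(DEFAULT_STRUCTURAL_PATHS)
            ),
            exog_correlation=data.get("exog_correlation", 0.5),
            thresholds=tuple(data.get("thresholds", DEFAULT_THRESHOLDS)),
            noise_sd=data.get("noise_sd"),
            missing_rate=data.get("missing_rate", 0.0),
        )


def default_ground_truth(spec: InstrumentSpec | None = None) -> GroundTruthParams:
    """Ground truth calibrated to the reported COM-B solution."""
    spec = spec or default_instrument()
    loadings: dict[str, float] = {}
    for dom in spec.non_behavior_domains:
        for item in spec.items[dom]:
            loadings[item] = DEFAULT_ITEM_LOADINGS.get(
                item, DEFAULT_OPPORTUNITY_LOADING
            )
    for beh in spec.behavior_items:
        loadings[beh] = DEFAULT_BEHAVIOR_LOADING
    second = {
        d: DEFAULT_SECOND_ORDER.get(d, 0.75) for d in spec.non_behavior_domains
    }
    return GroundTruthParams(loadings=loadings, second_order_loadings=second)


def _module_factors(
    spec: InstrumentSpec, params: GroundTruthParams, n: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Draw the four module factors under the structural model."""
    r = params.exog_correlation
    cov = np.array([[1.0, r], [r, 1.0]])
    co = rng.multivariate_normal(np.zeros(2), cov, size=n, method="cholesky")
    cap, opp = co[:, 0], co[:, 1]
    p = {k: params.structural_paths.get(k, 0.0) for k in PATH_KEYS}

    var_m_pred = p["M~C"] ** 2 + p["M~O"] ** 2 + 2 * p["M~C"] * p["M~O"] * r
    if var_m_pred >= 1:
        raise SimulationError("structural paths imply Motivation variance > 1")
    mot = (
        p["M~C"] * cap
        + p["M~O"] * opp
        + np.sqrt(1 - var_m_pred) * rng.standard_normal(n)
    )

    # covariance of (C, O, M) under the model, for the Behavior disturbance
    cov_cm = p["M~C"] + p["M~O"] * r
    cov_om = p["M~O"] + p["M~C"] * r
    v = np.array([
        [1.0, r, cov_cm],
        [r, 1.0, cov_om],
        [cov_cm, cov_om, 1.0],
    ])
    beta = np.array([p["B~C"], p["B~O"], p["B~M"]])
    var_b_pred = float(beta @ v @ beta)
    if var_b_pred >= 1:
        raise SimulationError("structural paths imply Behavior variance > 1")
    beh = (
        p["B~C"] * cap
        + p["B~O"] * opp
        + p["B~M"] * mot
        + np.sqrt(1 - var_b_pred) * rng.standard_normal(n)
    )
    return {"Capability": cap, "Opportunity": opp, "Motivation": mot, "Behavior": beh}


def generate_responses(
    spec: InstrumentSpec,
    params: GroundTruthParams,
    n: int,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate ``n`` respondents; returns respondents x items integers 1-5.

    Deterministic for fixed ``(spec, params, n, seed)``.  Missing values
    (if ``params.missing_rate > 0``) are emitted as pandas NA.
    """
    if n < 1:
        raise SimulationError("n must be >= 1")
    params.validate()
    rng = np.random.default_rng(seed)
    modules = _module_factors(spec, params, n, rng)

    thr = np.asarray(params.thresholds, dtype=float)
    columns: dict[str, np.ndarray] = {}
    for module, domains in spec.domains.items():
        mod_f = modules[module]
        for dom in domains:
            gam = float(params.second_order_loadings.get(dom, 1.0))
            dom_f = gam * mod_f + np.sqrt(max(1 - gam**2, 0.0)) * rng.standard_normal(n)
            for item in spec.items[dom]:
                lam = params.item_loading(item)
                sd = (
                    float(params.noise_sd[item])
                    if params.noise_sd and item in params.noise_sd
                    else float(np.sqrt(max(1 - lam**2, 0.0)))
                )
                latent = lam * dom_f + sd * rng.standard_normal(n)
                columns[item] = np.searchsorted(thr, latent, side="left") + 1
    beh_f = modules["Behavior"]
    for beh in spec.behavior_items:
        lam = params.item_loading(beh)
        sd = (
            float(params.noise_sd[beh])
            if params.noise_sd and beh in params.noise_sd
            else float(np.sqrt(max(1 - lam**2, 0.0)))
        )
        latent = lam * beh_f + sd * rng.standard_normal(n)
        columns[beh] = np.searchsorted(thr, latent, side="left") + 1

    data = pd.DataFrame(
        {item: columns[item] for item in spec.all_items},
        index=pd.RangeIndex(1, n + 1, name="respondent"),
        dtype="int64",
    )
    if params.missing_rate > 0:
        mask = rng.random(data.shape) < params.missing_rate
        data = data.astype("Int64")
        data[mask] = pd.NA
    return data


def write_responses(data: pd.DataFrame, path) -> None:
    """CSV with the respondent id as first column and item codes as header."""
    data.to_csv(path, index=True)


def read_responses(path) -> pd.DataFrame:
    data = pd.read_csv(path, index_col=0)
    bad = data.stack().pipe(lambda s: s[(s < 1) | (s > 5)])
    if len(bad):
        raise SimulationError(
            f"{len(bad)} response values outside 1..5 (first at {bad.index[0]})"
        )
    return data
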