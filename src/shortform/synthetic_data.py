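"""Synthetic multidimensional Likert data with planned missingness.

The generator emulates the data situation this toolkit is built for: a
long questionnaire measuring several correlated latent factors, items of
varying quality (loadings), some reverse-keyed, external criterion
variables correlated with the factors, and matrix-sampling missingness
where each respondent answers only a random subset of a larger survey
frame.

The measurement model is a standard one-factor-per-item ordinal model:
factors are jointly multivariate normal with a specified correlation
matrix; the latent continuum of an item with loading ``a`` on its factor
``f`` is ``a*f + sqrt(1-a^2)*e`` with independent standard-normal error;
responses are obtained by cutting that continuum at ordered thresholds
(default: equal-probability cuts).  Reverse-keyed items are stored in
their raw, reflected direction so that the keying machinery is exercised
end to end.

``simple_mi_impute`` is a plain multivariate-normal EM imputer with
conditional draws for the missing cells.  It is a deliberately simple
normal-model imputer — not a bootstrapped EM — which is sufficient here
because downstream item selection only needs plausible completed
matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from shortform.scale_model import ItemSpec, ScaleSpec

__all__ = [
    "FactorModelSpec",
    "SimulatedDataset",
    "simulate_responses",
    "apply_planned_missingness",
    "simple_mi_impute",
    "meaq_like_spec",
    "planted_structure_spec",
]


@dataclass
class FactorModelSpec:
    """Generative model for a multi-subscale Likert instrument.

    Parameters
    ----------
    scale :
        Instrument structure (items, subscales, reverse keys, range).
        Subscale order defines factor order.
    factor_corr :
        s x s symmetric positive-definite correlation matrix of the
        latent factors.
    loadings :
        item_id -> loading in [0, 1) of the item on its own factor.
    thresholds :
        Ordered cut points on the latent scale, one fewer than the
        number of response categories.  ``None`` selects
        equal-probability normal quantiles.
    criteria :
        criterion name -> length-s vector of target correlations between
        the criterion and the factors.
    """

    scale: ScaleSpec
    factor_corr: np.ndarray
    loadings: dict
    thresholds: np.ndarray | None = None
    criteria: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        s = self.scale.n_subscales
        R = np.asarray(self.factor_corr, dtype=float)
        if R.shape != (s, s):
            raise ValueError(f"factor_corr must be {s}x{s}, got {R.shape}")
        if not np.allclose(R, R.T):
            raise ValueError("factor_corr must be symmetric")
        if not np.allclose(np.diag(R), 1.0):
            raise ValueError("factor_corr must have unit diagonal")
        eigmin = float(np.linalg.eigvalsh(R).min())
        if eigmin <= 0:
            raise ValueError(
                f"factor_corr is not positive definite (smallest eigenvalue {eigmin:.3g})"
            )
        self.factor_corr = R
        for iid in self.scale.item_ids:
            if iid not in self.loadings:
                raise ValueError(f"no loading given for item {iid!r}")
            if not 0.0 <= abs(self.loadings[iid]) < 1.0:
                raise ValueError(f"|loading| of {iid!r} must be < 1")
        n_cat = self.scale.response_max - self.scale.response_min + 1
        if self.thresholds is None:
            self.thresholds = stats.norm.ppf(np.arange(1, n_cat) / n_cat)
        else:
            self.thresholds = np.asarray(self.thresholds, dtype=float)
            if len(self.thresholds) != n_cat - 1:
                raise ValueError(
                    f"need {n_cat - 1} thresholds for {n_cat} categories, "
                    f"got {len(self.thresholds)}"
                )
            if not np.all(np.diff(self.thresholds) > 0):
                raise ValueError("thresholds must be strictly increasing")
        Rinv = np.linalg.inv(R)
        for name, rho in self.criteria.items():
            rho = np.asarray(rho, dtype=float)
            if rho.shape != (s,):
                raise ValueError(f"criterion {name!r} needs {s} correlations")
            expl = float(rho @ Rinv @ rho)
            if expl >= 1.0:
                raise ValueError(
                    f"criterion {name!r} correlations are infeasible "
                    f"(implied explained variance {expl:.3f} >= 1)"
                )
            self.criteria[name] = rho


@dataclass
class SimulatedDataset:
    """One simulated sample with its ground truth."""

    responses: pd.DataFrame          # raw (reverse items stored reflected), may have NaN
    criteria: pd.DataFrame           # respondents x criterion variables
    factor_scores: pd.DataFrame      # ground-truth latent factors
    latent_items: pd.DataFrame       # pre-discretization item continua (keyed direction)
    model: FactorModelSpec
    seed: int


def simulate_responses(model: FactorModelSpec, n: int, seed: int) -> SimulatedDataset:
    """Draw ``n`` respondents from the factor model; reproducible from seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    scale = model.scale
    rng = np.random.default_rng(seed)
    s = scale.n_subscales
    chol = np.linalg.cholesky(model.factor_corr)
    F = rng.standard_normal((n, s)) @ chol.T

    sub_index = {sub: i for i, sub in enumerate(scale.subscales)}
    L = scale.n_items
    lam = np.array([model.loadings[it.item_id] for it in scale.items])
    fcol = np.array([sub_index[it.subscale_id] for it in scale.items])
    eps = rng.standard_normal((n, L))
    latent = lam * F[:, fcol] + np.sqrt(1.0 - lam**2) * eps

    lo, hi = scale.response_min, scale.response_max
    cats = lo + np.searchsorted(model.thresholds, latent)  # keyed direction
    raw = cats.copy()
    rev = scale.reverse_flags
    raw[:, rev] = lo + hi - raw[:, rev]

    idx = pd.RangeIndex(n, name="respondent")
    responses = pd.DataFrame(raw, index=idx, columns=scale.item_ids)

    crit = {}
    Rinv = np.linalg.inv(model.factor_corr)
    for name, rho in model.criteria.items():
        a = Rinv @ rho
        resid_sd = np.sqrt(1.0 - float(rho @ a))
        crit[name] = F @ a + resid_sd * rng.standard_normal(n)
    criteria = pd.DataFrame(crit, index=idx)

    return SimulatedDataset(
        responses=responses,
        criteria=criteria,
        factor_scores=pd.DataFrame(F, index=idx, columns=scale.subscales),
        latent_items=pd.DataFrame(latent, index=idx, columns=scale.item_ids),
        model=model,
        seed=seed,
    )


def apply_planned_missingness(
    data: SimulatedDataset,
    items_per_respondent: int,
    seed: int,
    frame_size: int | None = None,
) -> SimulatedDataset:
    """Matrix sampling: each respondent answers a uniform random subset.

    ``frame_size`` models a survey frame larger than this instrument
    (the instrument's items occupy the first positions of the frame): a
    respondent sees ``items_per_respondent`` of ``frame_size`` survey
    items, so each instrument item is observed with probability
    ``items_per_respondent / frame_size``.  Missingness is independent
    of all values (MCAR by construction).
    """
    L = data.responses.shape[1]
    frame = L if frame_size is None else frame_size
    if frame < L:
        raise ValueError("frame_size must be >= number of instrument items")
    if not 0 < items_per_respondent <= frame:
        raise ValueError("items_per_respondent must be in 1..frame_size")
    rng = np.random.default_rng(seed)
    masked = data.responses.to_numpy(dtype=float).copy()
    n = masked.shape[0]
    for r in range(n):
        shown = rng.choice(frame, size=items_per_respondent, replace=False)
        keep = np.zeros(frame, dtype=bool)
        keep[shown] = True
        masked[r, ~keep[:L]] = np.nan
    responses = pd.DataFrame(
        masked, index=data.responses.index, columns=data.responses.columns
    )
    return replace(data, responses=responses)


# ---------------------------------------------------------------------------
# multivariate-normal EM imputation
# ---------------------------------------------------------------------------

def _em_mvn(X: np.ndarray, max_iter: int, tol: float, ridge: float = 1e-6):
    """EM estimates (mu, Sigma) for MVN data with missing values."""
    n, p = X.shape
    obs = ~np.isnan(X)
    mu = np.nanmean(X, axis=0)
    var = np.nanvar(X, axis=0)
    var[var <= 0] = 1.0
    Sigma = np.diag(var)
    rows = [(np.flatnonzero(obs[r]), np.flatnonzero(~obs[r])) for r in range(n)]

    for it in range(max_iter):
        sum_x = np.zeros(p)
        sum_xx = np.zeros((p, p))
        for r, (O, M) in enumerate(rows):
            x = X[r]
            xhat = x.copy()
            if M.size:
                Soo = Sigma[np.ix_(O, O)]
                Smo = Sigma[np.ix_(M, O)]
                B = Smo @ np.linalg.inv(Soo + ridge * np.eye(O.size))
                xhat[M] = mu[M] + B @ (x[O] - mu[O])
                Cmm = Sigma[np.ix_(M, M)] - B @ Smo.T
            sum_x += xhat
            outer = np.outer(xhat, xhat)
            if M.size:
                outer[np.ix_(M, M)] += Cmm
            sum_xx += outer
        mu_new = sum_x / n
        Sigma_new = sum_xx / n - np.outer(mu_new, mu_new)
        Sigma_new += ridge * np.eye(p)
        delta = max(
            float(np.abs(mu_new - mu).max()), float(np.abs(Sigma_new - Sigma).max())
        )
        mu, Sigma = mu_new, Sigma_new
        if delta < tol:
            return mu, Sigma, it + 1
    raise RuntimeError(
        f"EM did not converge in {max_iter} iterations "
        f"(last max parameter change {delta:.3g}, tolerance {tol:g})"
    )


def simple_mi_impute(
    responses: pd.DataFrame,
    spec: ScaleSpec,
    m: int,
    seed: int,
    max_iter: int = 200,
    tol: float = 1e-3,
) -> list[pd.DataFrame]:
    """Multiple imputation under a multivariate-normal model.

    Fits (mu, Sigma) by EM on the incomplete matrix, then produces ``m``
    completed copies by drawing each respondent's missing cells from
    their conditional normal distribution, rounding to the nearest
    response category and clipping to the response range.  Observed
    cells are never altered.  Reproducible from ``seed``.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    X = responses.to_numpy(dtype=float)
    n, p = X.shape
    obs = ~np.isnan(X)
    if obs.all():
        return [responses.copy() for _ in range(m)]

    pair_counts = obs.astype(int).T @ obs.astype(int)
    off = pair_counts[~np.eye(p, dtype=bool)]
    if off.min() < 2:
        i, j = np.argwhere(pair_counts < 2)[0]
        raise ValueError(
            f"items {responses.columns[i]!r} and {responses.columns[j]!r} are "
            f"jointly observed for {pair_counts[i, j]} respondents (< 2); "
            "the covariance is not estimable"
        )

    mu, Sigma, _ = _em_mvn(X, max_iter=max_iter, tol=tol)
    rng = np.random.default_rng(seed)
    lo, hi = spec.response_min, spec.response_max

    rows = [(np.flatnonzero(obs[r]), np.flatnonzero(~obs[r])) for r in range(n)]
    cond = []
    for O, M in rows:
        if M.size == 0:
            cond.append(None)
            continue
        Soo = Sigma[np.ix_(O, O)]
        Smo = Sigma[np.ix_(M, O)]
        B = Smo @ np.linalg.inv(Soo + 1e-8 * np.eye(O.size))
        Cmm = Sigma[np.ix_(M, M)] - B @ Smo.T
        Cmm = (Cmm + Cmm.T) / 2 + 1e-8 * np.eye(M.size)
        cond.append((O, M, B, np.linalg.cholesky(Cmm)))

    copies = []
    for _ in range(m):
        Y = X.copy()
        for r, c in enumerate(cond):
            if c is None:
                continue
            O, M, B, chol = c
            mean = mu[M] + B @ (X[r, O] - mu[O])
            draw = mean + chol @ rng.standard_normal(M.size)
            Y[r, M] = np.clip(np.rint(draw), lo, hi)
        copies.append(
            pd.DataFrame(Y, index=responses.index, columns=responses.columns)
        )
    return copies


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

# Factor correlations typical of the six experiential-avoidance
# dimensions (behavioral avoidance, distress aversion, procrastination,
# distraction/suppression, repression/denial, distress endurance).
_MEAQ_FACTOR_CORR = np.array(
    [
        [1.00, 0.71, 0.58, 0.53, 0.49, -0.12],
        [0.71, 1.00, 0.43, 0.51, 0.53, -0.07],
        [0.58, 0.43, 1.00, 0.18, 0.62, -0.32],
        [0.53, 0.51, 0.18, 1.00, 0.20, 0.38],
        [0.49, 0.53, 0.62, 0.20, 1.00, -0.30],
        [-0.12, -0.07, -0.32, 0.38, -0.30, 1.00],
    ]
)

_MEAQ_SUBSCALES = [
    ("behavioral_avoidance", "ba", 11),
    ("distress_aversion", "da", 11),
    ("procrastination", "pr", 11),
    ("distraction_suppression", "ds", 10),
    ("repression_denial", "rd", 9),
    ("distress_endurance", "de", 10),
]

# criterion variables emulating mental-distress and life-satisfaction
# correlates of the six dimensions
_MEAQ_CRITERIA = {
    "mental_distress": np.array([0.36, 0.41, 0.44, 0.07, 0.52, -0.18]),
    "life_satisfaction": np.array([-0.05, -0.13, -0.19, 0.19, -0.07, 0.42]),
}


def meaq_like_spec(loading_seed: int = 0) -> FactorModelSpec:
    """62-item, six-subscale preset on a 1..6 response scale.

    Item loadings are drawn once, uniformly in [0.45, 0.75], from
    ``loading_seed`` (so the instrument itself is reproducible); the
    procrastination subscale contains one reverse-keyed item.
    """
    rng = np.random.default_rng(loading_seed)
    items, loadings = [], {}
    for name, prefix, count in _MEAQ_SUBSCALES:
        for j in range(count):
            iid = f"{prefix}{j + 1:02d}"
            reverse = name == "procrastination" and j == count - 1
            items.append(ItemSpec(item_id=iid, subscale_id=name, reverse_keyed=reverse))
            loadings[iid] = float(rng.uniform(0.45, 0.75))
    scale = ScaleSpec(items=items, response_min=1, response_max=6)
    return FactorModelSpec(
        scale=scale,
        factor_corr=_MEAQ_FACTOR_CORR,
        loadings=loadings,
        criteria=dict(_MEAQ_CRITERIA),
    )


def planted_structure_spec() -> FactorModelSpec:
    """3 subscales x 8 items with a planted answer.

    In each subscale the first five items load 0.8 ("good" items) and
    the last three load 0.1 ("poor" items), so a k=5 selection procedure
    has an unambiguous ground truth.  One good item is reverse-keyed to
    exercise the keying path end to end.
    """
    subscales = [("s1", 8), ("s2", 8), ("s3", 8)]
    items, loadings = [], {}
    for name, count in subscales:
        for j in range(count):
            iid = f"{name}_i{j + 1}"
            reverse = name == "s1" and j == 0
            items.append(ItemSpec(item_id=iid, subscale_id=name, reverse_keyed=reverse))
            loadings[iid] = 0.8 if j < 5 else 0.1
    scale = ScaleSpec(items=items, response_min=1, response_max=6)
    R = np.full((3, 3), 0.3)
    np.fill_diagonal(R, 1.0)
    return FactorModelSpec(scale=scale, factor_corr=R, loadings=loadings)


def planted_good_items(model: FactorModelSpec, threshold: float = 0.5) -> dict:
    """Ground-truth high-loading items per subscale (for recovery checks)."""
    return {
        sub: [i for i in model.scale.items_in_subscale(sub)
              if abs(model.loadings[i]) >= threshold]
        for sub in model.scale.subscales
    }
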