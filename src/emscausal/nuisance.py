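"""Nuisance models: candidate logistic regressions and discrete super learner.

The outcome regression Q̄, the exposure model ĝ, and the reference-exposure
model π̂_ref are each selected from candidate logistic regressions with and
without second-order interaction terms by V-fold cross-validation on the
negative Bernoulli log-likelihood (discrete super learner: the single best
candidate is refit on all data).

Fits use an unpenalized Newton–Raphson (IRLS) routine; the simulation
studies refit these models hundreds of thousands of times, so the hot path
is kept to plain linear algebra.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AnalysisConfig

logger = logging.getLogger(__name__)

_EPS = 1e-12


class DegenerateOutcomeError(ValueError):
    """The response is constant; no model can be fit."""


class NonEstimableError(RuntimeError):
    """Positivity failure or unfittable nuisance; the analysis cell is flagged."""


class UnseenCategoryError(ValueError):
    """A categorical level at prediction time was absent from the training data."""


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------


@dataclass
class CandidateSpec:
    """One candidate: a covariate list and the interaction order (1 or 2)."""

    covariates: tuple[str, ...]
    interaction_order: int = 1

    def __post_init__(self):
        if self.interaction_order not in (1, 2):
            raise ValueError("interaction_order must be 1 or 2")
        self.covariates = tuple(self.covariates)

    @property
    def label(self) -> str:
        return f"order{self.interaction_order}"


@dataclass
class DesignInfo:
    """Training-set facts needed to rebuild the design at prediction time."""

    spec: CandidateSpec
    columns: list[str]
    cat_levels: dict[str, list]
    age_mean: float
    age_sd: float


def _main_effect_columns(records: pd.DataFrame, spec: CandidateSpec, info: DesignInfo | None):
    cols: dict[str, np.ndarray] = {}
    cat_levels: dict[str, list] = {} if info is None else info.cat_levels
    for name in spec.covariates:
        if name not in records.columns:
            raise KeyError(f"covariate {name!r} not in records")
        series = records[name]
        if name == "age":
            if info is None:
                mean = float(series.mean())
                sd = float(series.std(ddof=0))
                sd = sd if sd > 0 else 1.0
            else:
                mean, sd = info.age_mean, info.age_sd
            cols["age_std"] = (series.to_numpy(float) - mean) / sd
            if info is None:
                age_stats = (mean, sd)
        elif series.dtype == object or isinstance(series.dtype, pd.CategoricalDtype):
            values = series.astype(str)
            if info is None:
                levels = sorted(values.unique())
                cat_levels[name] = levels
            else:
                levels = info.cat_levels[name]
                unseen = set(values.unique()) - set(levels)
                if unseen:
                    raise UnseenCategoryError(
                        f"unseen level(s) {sorted(unseen)} for {name!r}"
                    )
            for level in levels[1:]:
                cols[f"{name}:{level}"] = (values == level).to_numpy(float)
        else:
            cols[name] = series.to_numpy(float)
    if "age" in spec.covariates and info is None:
        return cols, cat_levels, age_stats
    return cols, cat_levels, None


def build_design(
    records: pd.DataFrame, spec: CandidateSpec, info: DesignInfo | None = None
) -> tuple[np.ndarray, DesignInfo]:
    """Numeric design matrix for a candidate.

    Categorical covariates expand to indicator contrasts (first level as
    reference), age is standardized with training-set statistics stored in
    the returned :class:`DesignInfo`, and order-2 candidates add all
    pairwise products of the main-effect columns.  Constant and duplicate
    product columns are dropped at training time; the surviving column set
    is frozen in ``info`` so prediction designs line up.
    """
    if len(records) == 0:
        raise ValueError("cannot build a design for an empty record set")
    cols, cat_levels, age_stats = _main_effect_columns(records, spec, info)

    if spec.interaction_order == 2:
        names = list(cols)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                cols[f"{names[i]}*{names[j]}"] = cols[names[i]] * cols[names[j]]

    if info is None:
        keep = ["intercept"]
        data = [np.ones(len(records))]
        seen = set()
        for name, values in cols.items():
            if values.std() == 0.0:
                continue
            key = values.tobytes()
            if key in seen:
                continue
            seen.add(key)
            keep.append(name)
            data.append(values)
        mean, sd = age_stats if age_stats is not None else (0.0, 1.0)
        info = DesignInfo(
            spec=spec, columns=keep, cat_levels=cat_levels, age_mean=mean, age_sd=sd
        )
        X = np.column_stack(data)
    else:
        data = []
        for name in info.columns:
            if name == "intercept":
                data.append(np.ones(len(records)))
            else:
                data.append(cols[name])
        X = np.column_stack(data)
    return X, info


# ---------------------------------------------------------------------------
# Newton/IRLS logistic fit
# ---------------------------------------------------------------------------


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    offset: np.ndarray | None = None,
    start: np.ndarray | None = None,
    max_iter: int = 60,
    tol: float = 1e-9,
) -> tuple[np.ndarray, bool]:
    """Maximum-likelihood logistic regression by damped Newton-Raphson.

    Returns ``(beta, converged)``; convergence means the score is below
    ``tol`` in max-norm.  Near-singular information matrices fall back to a
    pseudo-inverse step, so saturated designs converge to fitted values even
    when coefficients are not unique.
    """
    n, p = X.shape
    beta = np.zeros(p) if start is None else start.astype(float).copy()
    off = np.zeros(n) if offset is None else offset

    def loglik(eta):
        return float(y @ eta - np.logaddexp(0.0, eta).sum())

    eta = off + X @ beta
    ll = loglik(eta)
    converged = False
    for _ in range(max_iter):
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (y - mu)
        if np.abs(grad).max() < tol:
            converged = True
            break
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(p), grad)
        except np.linalg.LinAlgError:
            step = np.linalg.pinv(H) @ grad
        if not np.all(np.isfinite(step)):
            step = np.linalg.pinv(H) @ grad
        # damped update with step halving; inside the quadratic-convergence
        # zone the log-likelihood comparison is pure rounding noise, so the
        # full Newton step is accepted unconditionally there
        if np.abs(grad).max() < 1e-4:
            beta = beta + step
            eta = off + X @ beta
            ll = loglik(eta)
        else:
            scale = 1.0
            for _ in range(30):
                cand = beta + scale * step
                eta_new = off + X @ cand
                ll_new = loglik(eta_new)
                if ll_new >= ll - 1e-10 * max(1.0, abs(ll)):
                    break
                scale *= 0.5
            beta, eta, ll = cand, eta_new, ll_new
        if np.abs(eta).max() > 40.0:
            break  # heading to separation; report non-convergence
    else:
        mu = 1.0 / (1.0 + np.exp(-eta))
        if np.abs(X.T @ (y - mu)).max() < tol:
            converged = True
    return beta, converged


def _bernoulli_loss(y, p):
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _stratified_folds(y: np.ndarray, V: int, seed) -> np.ndarray:
    rng = np.random.default_rng(seed)
    assignment = np.empty(len(y), dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        assignment[idx] = np.arange(len(idx)) % V
    return assignment


# ---------------------------------------------------------------------------
# discrete super learner
# ---------------------------------------------------------------------------


@dataclass
class FittedClassifier:
    """Winner of the discrete super learner with its CV loss table."""

    info: DesignInfo
    beta: np.ndarray
    cv_table: pd.DataFrame
    fold_seed: int
    n_obs: int

    @property
    def spec(self) -> CandidateSpec:
        return self.info.spec

    @property
    def coefficients(self) -> dict[str, float]:
        return dict(zip(self.info.columns, map(float, self.beta)))

    def linear_predictor(self, records: pd.DataFrame) -> np.ndarray:
        X, _ = build_design(records, self.info.spec, self.info)
        return X @ self.beta

    def predict_proba(self, records: pd.DataFrame) -> np.ndarray:
        p = 1.0 / (1.0 + np.exp(-self.linear_predictor(records)))
        return np.clip(p, _EPS, 1.0 - _EPS)

    def to_dict(self) -> dict:
        """JSON-serializable summary: candidate, coefficients, CV table."""
        cv = [
            {
                "candidate": str(r["candidate"]),
                "n_params": int(r["n_params"]),
                "cv_loss": float(r["cv_loss"]),
                "converged": bool(r["converged"]),
            }
            for r in self.cv_table.to_dict(orient="records")
        ]
        return {
            "candidate": self.spec.label,
            "covariates": list(self.spec.covariates),
            "coefficients": self.coefficients,
            "cv_loss": cv,
            "fold_seed": int(self.fold_seed),
        }


def fit_discrete_superlearner(
    records: pd.DataFrame,
    y: np.ndarray,
    candidates: list[CandidateSpec],
    V: int = 10,
    seed: int = 0,
) -> FittedClassifier:
    """Select among candidates by V-fold CV and refit the winner on all data.

    The loss is the mean negative Bernoulli log-likelihood on held-out
    folds, stratified on the response.  Candidates whose fit fails to
    converge in any fold (e.g. perfect separation) receive infinite loss;
    ties are broken toward the candidate with fewer parameters.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if not candidates:
        raise ValueError("at least one candidate is required")
    if V < 2:
        raise ValueError("V must be at least 2")
    if V > n:
        raise ValueError(f"V={V} folds exceed n={n} observations")
    if n < 2 * V:
        raise ValueError(f"need at least 2V={2 * V} observations, got {n}")
    uniq = np.unique(y)
    if uniq.size < 2:
        raise DegenerateOutcomeError("outcome is constant")
    if not set(uniq) <= {0.0, 1.0}:
        raise ValueError("y must be binary")

    folds = _stratified_folds(y.astype(int), V, seed)
    rows = []
    fits = []
    for spec in candidates:
        X, info = build_design(records, spec)
        beta_full, conv_full = fit_logistic(X, y)
        loss = 0.0
        ok = conv_full
        for v in range(V):
            test = folds == v
            train = ~test
            if ok and y[train].min() == y[train].max():
                ok = False
            if not ok:
                break
            # fold fits only rank candidates; a looser score tolerance than
            # the final refit is ample for CV-loss differences of O(1e-3)
            beta, conv = fit_logistic(
                X[train], y[train], start=beta_full, max_iter=30, tol=1e-6
            )
            if not conv:
                ok = False
                break
            p = 1.0 / (1.0 + np.exp(-(X[test] @ beta)))
            loss += _bernoulli_loss(y[test], p) * test.sum()
        cv_loss = loss / n if ok else np.inf
        if not ok:
            logger.warning(
                "candidate %s penalized with infinite CV loss (non-convergence)",
                spec.label,
            )
        rows.append(
            {
                "candidate": spec.label,
                "n_params": len(info.columns),
                "cv_loss": cv_loss,
                "converged": ok,
            }
        )
        fits.append((info, beta_full))
    cv_table = pd.DataFrame(rows)
    if not np.isfinite(cv_table["cv_loss"]).any():
        raise NonEstimableError("no candidate could be fit")
    order = np.lexsort((cv_table["n_params"].to_numpy(), cv_table["cv_loss"].to_numpy()))
    best = int(order[0])
    info, beta = fits[best]
    return FittedClassifier(
        info=info, beta=beta, cv_table=cv_table, fold_seed=int(seed), n_obs=n
    )


# ---------------------------------------------------------------------------
# the full nuisance set of one analysis
# ---------------------------------------------------------------------------

_EXPOSURE_COLUMNS = {"ambulance": "amb", "asa": "asa"}
REFERENCE_GROUP = "chest"


@dataclass
class NuisanceSet:
    """Fitted Q̄, ĝ, π̂_ref, the group share p̂0 and truncation bounds."""

    exposure: str
    outcome: str
    target_group: str
    q_model: FittedClassifier
    g_model: FittedClassifier
    pi_ref_model: FittedClassifier
    p0: float
    trunc: tuple[float, float]
    exposure_col: str = field(init=False)

    def __post_init__(self):
        self.exposure_col = _EXPOSURE_COLUMNS[self.exposure]
        lo, hi = self.trunc
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("truncation bounds must satisfy 0 < lo < hi < 1")
        if not 0.0 < self.p0 < 1.0:
            raise ValueError("p0 must lie in (0, 1)")

    def predict_q(self, records: pd.DataFrame, a: int | None = None) -> np.ndarray:
        """Q̄(a, W); ``a=None`` evaluates at the observed exposure."""
        if a is None:
            return self.q_model.predict_proba(records)
        work = records.copy()
        work[self.exposure_col] = float(a)
        return self.q_model.predict_proba(work)

    def predict_g(self, records: pd.DataFrame) -> np.ndarray:
        return np.clip(self.g_model.predict_proba(records), *self.trunc)

    def predict_pi_ref(self, records: pd.DataFrame) -> np.ndarray:
        return np.clip(self.pi_ref_model.predict_proba(records), *self.trunc)


def candidate_specs(covariates: tuple[str, ...]) -> list[CandidateSpec]:
    """The two candidate logistic regressions of the analysis."""
    return [
        CandidateSpec(covariates, interaction_order=1),
        CandidateSpec(covariates, interaction_order=2),
    ]


def fit_nuisances(
    population: pd.DataFrame,
    exposure: str,
    outcome: str,
    config: AnalysisConfig | None = None,
    target_group: str = "nonchest",
) -> NuisanceSet:
    """Fit all nuisance models for one analysis.

    ``population`` is the analysis population (the full cohort for the
    ambulance exposure; the dispatched, non-contraindicated subset for the
    ASA exposure).  Q̄ and ĝ are fit on the target symptom group, π̂_ref on
    the chest-pain group, and p̂0 is the target group's empirical share.
    """
    if config is None:
        config = AnalysisConfig()
    if exposure not in _EXPOSURE_COLUMNS:
        raise ValueError(f"unknown exposure {exposure!r}")
    a_col = _EXPOSURE_COLUMNS[exposure]
    groups = population["symptom_group"]
    target = population[groups == target_group]
    reference = population[groups == REFERENCE_GROUP]
    if target.empty or reference.empty:
        raise NonEstimableError("both symptom groups must be present")

    a_target = target[a_col].to_numpy(float)
    if np.isnan(a_target).any():
        raise ValueError(f"{a_col} undefined for part of the analysis population")
    if a_target.min() == a_target.max():
        raise NonEstimableError(
            f"no {'unexposed' if a_target.min() == 1 else 'exposed'} records "
            f"in the {target_group} group"
        )
    y = target[outcome].to_numpy(float)
    if y.min() == y.max():
        raise DegenerateOutcomeError(f"{outcome} is constant in the target group")

    q_cands = candidate_specs(tuple(config.q_covariates) + (a_col,))
    g_cands = candidate_specs(tuple(config.g_covariates))
    work = target.copy()
    work[a_col] = a_target
    q_model = fit_discrete_superlearner(work, y, q_cands, V=config.sl_folds, seed=config.sl_seed)
    g_model = fit_discrete_superlearner(
        target, a_target, g_cands, V=config.sl_folds, seed=config.sl_seed + 1
    )
    if target_group == REFERENCE_GROUP:
        pi_ref_model = g_model
    else:
        a_ref = reference[a_col].to_numpy(float)
        pi_ref_model = fit_discrete_superlearner(
            reference, a_ref, g_cands, V=config.sl_folds, seed=config.sl_seed + 2
        )
    return NuisanceSet(
        exposure=exposure,
        outcome=outcome,
        target_group=target_group,
        q_model=q_model,
        g_model=g_model,
        pi_ref_model=pi_ref_model,
        p0=len(target) / len(population),
        trunc=config.g_trunc,
    )
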