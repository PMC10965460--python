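"""Illness-death multistate Markov model for interval-censored two-wave panel data.

The model has three states: 1 = disease-free, 2 = diseased (here T2DM),
3 = dead. Three transitions are allowed — onset (1→2), death while
disease-free (1→3) and death with disease (2→3) — and no recovery (2→1).
Transition intensities follow a Gompertz (log-linear in age) form with
proportional covariate effects:

    q_rs(age, z) = exp(alpha_rs + xi_rs * (age - reference_age) + beta_rs' z)

Living states are observed only at the two interview waves, so onset times
are interval-censored; death times are taken as exactly observed (register
linkage) with the living state immediately before death unknown, and the
likelihood sums over both possible pre-death states.

``IllnessDeathModel`` / ``IllnessDeathResults`` follow the statsmodels
model/results idiom: the model holds the data and likelihood, ``fit()``
maximises it and returns a results object carrying estimates, standard
errors from the observed information, a ``summary()`` table, and
life-expectancy methods (total and state-specific remaining years by
numerical integration of the occupancy probabilities, in the style of the
ELECT approach used with the R ``msm`` package).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize
from statsmodels.tools.numdiff import approx_hess

__all__ = [
    "TRANSITIONS",
    "GompertzIntensities",
    "StateLifeExpectancy",
    "IllnessDeathModel",
    "IllnessDeathResults",
    "build_intensity_matrix",
    "transition_probability",
    "panel_log_likelihood",
    "fit_model",
    "state_specific_life_expectancy",
    "life_expectancy_ci",
]

#: transition order used everywhere: onset, death-from-healthy, death-with-disease
TRANSITIONS = ((1, 2), (1, 3), (2, 3))

_TRANSITION_LABELS = ("1->2", "1->3", "2->3")


def _exprel(x: np.ndarray) -> np.ndarray:
    """(exp(x) - 1)/x, continuous through x = 0."""
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    nz = x != 0.0
    out[nz] = np.expm1(x[nz]) / x[nz]
    return out


@dataclass(frozen=True)
class GompertzIntensities:
    """Parameterised transition intensities of the illness-death process.

    Parameters
    ----------
    alpha : array (3,)
        Log baseline intensity of each transition at ``reference_age`` for a
        subject with all covariates zero. Transition order is
        :data:`TRANSITIONS`.
    xi : array (3,)
        Log-linear age slope per year (Gompertz shape). Zero gives an
        age-constant intensity.
    beta : array (3, k)
        Additive log-intensity covariate effects (log hazard ratios).
    reference_age : float
        Age at which ``exp(alpha)`` is the baseline intensity.
    covariate_names : tuple of str
        Names of the k covariate columns, in ``beta`` column order.
    """

    alpha: np.ndarray
    xi: np.ndarray
    beta: np.ndarray
    reference_age: float = 65.0
    covariate_names: tuple = ("sex_male",)

    def __post_init__(self):
        object.__setattr__(self, "alpha", np.asarray(self.alpha, dtype=float).reshape(3))
        object.__setattr__(self, "xi", np.asarray(self.xi, dtype=float).reshape(3))
        beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        if beta.shape[0] != 3:
            beta = beta.reshape(3, -1)
        object.__setattr__(self, "beta", beta)
        # alpha = -inf encodes an exactly-zero intensity (e.g. null process)
        if (np.any(np.isnan(self.alpha)) or np.any(self.alpha == np.inf)
                or not np.all(np.isfinite(self.xi))
                or not np.all(np.isfinite(self.beta))):
            raise ValueError("intensity parameters must be finite "
                             "(alpha may be -inf for a zero intensity)")
        if len(self.covariate_names) != self.beta.shape[1]:
            raise ValueError("covariate_names must match beta columns")

    @classmethod
    def constant(cls, q12: float, q13: float, q23: float,
                 reference_age: float = 65.0) -> "GompertzIntensities":
        """Age-constant intensities with no covariates (testing / closed forms)."""
        if min(q12, q13, q23) < 0:
            raise ValueError("intensities must be non-negative")
        with np.errstate(divide="ignore"):
            alpha = np.log([q12, q13, q23])
        return cls(alpha=alpha, xi=np.zeros(3), beta=np.zeros((3, 0)),
                   reference_age=reference_age, covariate_names=())

    @property
    def n_covariates(self) -> int:
        return self.beta.shape[1]

    @property
    def age_constant(self) -> bool:
        return bool(np.all(self.xi == 0.0))

    def rates(self, age, z=None):
        """Intensities (q12, q13, q23) at ``age`` for covariate row(s) ``z``.

        ``age`` may be a scalar or array; ``z`` a (k,) row or (n, k) matrix
        broadcastable against ``age``.
        """
        age = np.asarray(age, dtype=float)
        if z is None:
            z = np.zeros((self.n_covariates,))
        z = np.atleast_1d(np.asarray(z, dtype=float))
        if z.ndim == 1:
            lin_cov = self.beta @ z                      # (3,)
            da = age - self.reference_age
            out = [np.exp(self.alpha[j] + self.xi[j] * da + lin_cov[j]) for j in range(3)]
        else:
            lin_cov = z @ self.beta.T                    # (n, 3)
            da = age - self.reference_age
            out = [np.exp(self.alpha[j] + self.xi[j] * da + lin_cov[..., j]) for j in range(3)]
        return tuple(out)

    def intensity_matrix(self, age: float, z=None) -> np.ndarray:
        """3x3 generator Q(age, z): rows sum to zero, death row absorbing."""
        q12, q13, q23 = (float(v) for v in self.rates(age, z))
        if not all(np.isfinite(v) for v in (q12, q13, q23)):
            raise ValueError(f"non-finite intensities at age {age}")
        return np.array([
            [-(q12 + q13), q12, q13],
            [0.0, -q23, q23],
            [0.0, 0.0, 0.0],
        ])

    # -- parameter-vector mapping (optimisation scale) ------------------------

    def to_vector(self, age_constant: bool = False) -> np.ndarray:
        parts = []
        for j in range(3):
            parts.append([self.alpha[j]])
            if not age_constant:
                parts.append([self.xi[j]])
            parts.append(self.beta[j])
        return np.concatenate(parts)

    def with_vector(self, vec: np.ndarray, age_constant: bool = False) -> "GompertzIntensities":
        vec = np.asarray(vec, dtype=float)
        k = self.n_covariates
        per = 1 + (0 if age_constant else 1) + k
        if vec.size != 3 * per:
            raise ValueError(f"expected parameter vector of length {3 * per}")
        alpha, xi, beta = np.empty(3), np.zeros(3), np.empty((3, k))
        for j in range(3):
            chunk = vec[j * per:(j + 1) * per]
            alpha[j] = chunk[0]
            off = 1
            if not age_constant:
                xi[j] = chunk[1]
                off = 2
            beta[j] = chunk[off:off + k]
        return replace(self, alpha=alpha, xi=xi, beta=beta)

    def param_names(self, age_constant: bool = False) -> list[str]:
        names = []
        for j, lab in enumerate(_TRANSITION_LABELS):
            names.append(f"alpha[{lab}]")
            if not age_constant:
                names.append(f"xi[{lab}]")
            names.extend(f"beta[{lab}].{c}" for c in self.covariate_names)
        return names


def build_intensity_matrix(model: GompertzIntensities, age: float, z=None) -> np.ndarray:
    """Generator matrix Q at (age, covariates); see ``GompertzIntensities.intensity_matrix``."""
    return model.intensity_matrix(age, z)


# ---------------------------------------------------------------------------
# transition probabilities
# ---------------------------------------------------------------------------

def _step_factors(q12, q13, q23, dt):
    """Entries of exp(Q dt) for a constant upper-triangular generator.

    Returns (p11, p12, p22); the remaining entries follow from row sums.
    The off-diagonal p12 uses the exprel form

        p12 = q12 * dt * exp(-(q12+q13) dt) * exprel((q12+q13-q23) dt)

    which is algebraically identical to q12 (e^{-q23 dt} - e^{-(q12+q13) dt})
    / (q12+q13-q23) but remains exact and stable through the eigenvalue
    collision q12+q13 == q23.
    """
    a = q12 + q13
    p11 = np.exp(-a * dt)
    p22 = np.exp(-q23 * dt)
    p12 = q12 * dt * p11 * _exprel((a - q23) * dt)
    return p11, p12, p22


def _occupancy_rows(model: GompertzIntensities, a0, a1, z, grid_step: float):
    """Living-state occupancy probabilities over [a0, a1], vectorised.

    Returns (u1, u2, w2): u1 = P_11(a0,a1), u2 = P_12(a0,a1),
    w2 = P_22(a0,a1). Age-varying intensities are approximated as piecewise
    constant at subinterval midpoints on a grid of width <= grid_step; for an
    age-constant model one step is exact.
    """
    a0 = np.atleast_1d(np.asarray(a0, dtype=float))
    a1 = np.atleast_1d(np.asarray(a1, dtype=float))
    if np.any(a1 < a0):
        raise ValueError("a1 must be >= a0")
    n = max(a0.size, a1.size)
    a0, a1 = np.broadcast_to(a0, (n,)).copy(), np.broadcast_to(a1, (n,)).copy()
    if z is None:
        z = np.zeros((n, model.n_covariates))
    z = np.atleast_2d(np.asarray(z, dtype=float))
    if z.shape[0] == 1 and n > 1:
        z = np.broadcast_to(z, (n, z.shape[1]))

    span = a1 - a0
    if model.age_constant:
        m = (span > 0).astype(int)
    else:
        m = np.ceil(span / grid_step).astype(int)
    dt = np.where(m > 0, span / np.maximum(m, 1), 0.0)

    u1 = np.ones(n)
    u2 = np.zeros(n)
    w2 = np.ones(n)
    for k in range(int(m.max()) if n else 0):
        act = m > k
        if not act.any():
            break
        amid = a0[act] + (k + 0.5) * dt[act]
        q12, q13, q23 = model.rates(amid, z[act])
        p11, p12, p22 = _step_factors(q12, q13, q23, dt[act])
        u1a, u2a = u1[act], u2[act]
        u1[act] = u1a * p11
        u2[act] = u1a * p12 + u2a * p22
        w2[act] = w2[act] * p22
    return u1, u2, w2


def transition_probability(model: GompertzIntensities, a0: float, a1: float,
                           z=None, grid_step: float = 0.25) -> np.ndarray:
    """3x3 matrix of transition probabilities P(a0, a1).

    Exact matrix exponential for an age-constant model; otherwise the ordered
    product of per-subinterval matrix exponentials on a grid of width at most
    ``grid_step`` years.
    """
    if a1 < a0:
        raise ValueError("a1 must be >= a0")
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    u1, u2, w2 = _occupancy_rows(model, a0, a1, z, grid_step)
    u1, u2, w2 = float(u1[0]), float(u2[0]), float(w2[0])
    P = np.array([
        [u1, u2, 1.0 - u1 - u2],
        [0.0, w2, 1.0 - w2],
        [0.0, 0.0, 1.0],
    ])
    return np.clip(P, 0.0, 1.0)


# ---------------------------------------------------------------------------
# panel likelihood
# ---------------------------------------------------------------------------

_REQUIRED_COLS = ("entry_age", "entry_state", "exit_age", "exit_kind")


def _covariate_matrix(records: pd.DataFrame, covariates) -> np.ndarray:
    cols = []
    for c in covariates:
        if c == "sex_male":
            if "sex_male" in records.columns:
                cols.append(records["sex_male"].to_numpy(dtype=float))
            elif "sex" in records.columns:
                cols.append((records["sex"].astype(str).str.lower() == "male").to_numpy(dtype=float))
            else:
                raise ValueError("records lack a 'sex' or 'sex_male' column")
        else:
            cols.append(records[c].to_numpy(dtype=float))
    if not cols:
        return np.zeros((len(records), 0))
    return np.column_stack(cols)


def panel_log_likelihood(model: GompertzIntensities, records: pd.DataFrame,
                         grid_step: float = 0.25, per_record: bool = False):
    """Log-likelihood of two-wave panel records under the illness-death model.

    Each subject contributes one of:

    * ``alive_observed`` — log P_{s0,s1}(entry_age, exit_age); transition
      probabilities between living states are interval-censored.
    * ``death_exact`` — the death age is exact but the living state just
      before death is unknown, so the term is
      log [ P_{s0,1} q_13(exit_age) + P_{s0,2} q_23(exit_age) ].
    * ``lost`` — excluded (no information beyond baseline).

    An impossible observation (a recorded 2→1 recovery) yields ``-inf`` and a
    warning naming the offending subject(s).
    """
    for c in _REQUIRED_COLS:
        if c not in records.columns:
            raise ValueError(f"records missing column {c!r}")
    rec = records[records["exit_kind"] != "lost"]
    if rec.empty:
        return (np.zeros(0), rec.index) if per_record else 0.0

    a0 = rec["entry_age"].to_numpy(dtype=float)
    a1 = rec["exit_age"].to_numpy(dtype=float)
    s0 = rec["entry_state"].to_numpy(dtype=int)
    z = _covariate_matrix(rec, model.covariate_names)
    u1, u2, w2 = _occupancy_rows(model, a0, a1, z, grid_step)
    # occupancy of living states given the entry state
    p_in1 = np.where(s0 == 1, u1, 0.0)
    p_in2 = np.where(s0 == 1, u2, w2)

    kind = rec["exit_kind"].to_numpy()
    ll = np.full(len(rec), -np.inf)

    is_death = kind == "death_exact"
    if is_death.any():
        q12, q13, q23 = model.rates(a1[is_death], z[is_death])
        dens = p_in1[is_death] * q13 + p_in2[is_death] * q23
        with np.errstate(divide="ignore"):
            ll[is_death] = np.log(dens)

    is_alive = kind == "alive_observed"
    if is_alive.any():
        s1 = rec.loc[is_alive, "exit_state"].to_numpy(dtype=int)
        prob = np.where(s1 == 1, p_in1[is_alive], p_in2[is_alive])
        with np.errstate(divide="ignore"):
            ll[is_alive] = np.log(prob)

    if np.any(np.isneginf(ll)):
        bad = rec.index[np.isneginf(ll)]
        ids = (rec.loc[bad, "subject_id"].tolist() if "subject_id" in rec.columns
               else bad.tolist())
        warnings.warn(
            f"zero-probability observation(s) for subject(s) {ids[:5]}"
            + ("..." if len(ids) > 5 else "")
            + " (e.g. a recorded 2->1 recovery); log-likelihood is -inf",
            RuntimeWarning, stacklevel=2)
    if per_record:
        return ll, rec.index
    return float(ll.sum())


# ---------------------------------------------------------------------------
# life expectancy
# ---------------------------------------------------------------------------

@dataclass
class StateLifeExpectancy:
    """Expected remaining years by living state, from a given age and state.

    ``years_in_state[s]`` is the expected time spent in living state ``s``
    (1 = disease-free, 2 = diseased) before death; ``total`` is their sum.
    For a subject starting disease-free, ``years_in_state[1]`` is the
    health-adjusted life expectancy (HALE) and ``total`` the life expectancy.
    ``residual_mass`` is the survival probability remaining at ``max_age``,
    i.e. the truncation error of the integration window.
    """

    start_age: float
    start_state: int
    years_in_state: dict
    total: float
    residual_mass: float
    ci: pd.DataFrame | None = field(default=None, repr=False)


def state_specific_life_expectancy(model: GompertzIntensities, start_age: float,
                                   z=None, grid_step: float = 0.1,
                                   max_age: float = 110.0,
                                   start_state: int = 1) -> StateLifeExpectancy:
    """Total and state-specific remaining life expectancy by numerical integration.

    e_rs = ∫_0^{max_age - start_age} P_rs(start_age, start_age + u) du,
    evaluated by the trapezoid rule on a grid of width ``grid_step`` years.
    """
    if start_age >= max_age:
        raise ValueError("start_age must be below max_age")
    if start_state not in (1, 2):
        raise ValueError("start_state must be a living state (1 or 2)")
    n_steps = int(np.ceil((max_age - start_age) / grid_step))
    ages = start_age + (max_age - start_age) * np.arange(n_steps + 1) / n_steps
    if z is None:
        z = np.zeros(model.n_covariates)
    z = np.asarray(z, dtype=float).reshape(1, -1)

    p1 = np.empty(n_steps + 1)
    p2 = np.empty(n_steps + 1)
    p1[0] = 1.0 if start_state == 1 else 0.0
    p2[0] = 1.0 if start_state == 2 else 0.0
    v1, v2 = p1[0], p2[0]
    for k in range(n_steps):
        dt = ages[k + 1] - ages[k]
        q12, q13, q23 = model.rates(ages[k] + 0.5 * dt, z[0])
        f11, f12, f22 = _step_factors(q12, q13, q23, dt)
        v1, v2 = v1 * f11, v1 * f12 + v2 * f22
        p1[k + 1], p2[k + 1] = v1, v2

    e1 = float(np.trapezoid(p1, ages))
    e2 = float(np.trapezoid(p2, ages))
    residual = float(p1[-1] + p2[-1])
    if residual > 1e-3:
        warnings.warn(
            f"survival mass {residual:.2e} remains at max_age={max_age}; "
            "life expectancy is truncated — raise max_age",
            RuntimeWarning, stacklevel=2)
    return StateLifeExpectancy(
        start_age=start_age, start_state=start_state,
        years_in_state={1: e1, 2: e2}, total=e1 + e2, residual_mass=residual)


def life_expectancy_ci(model: GompertzIntensities, cov: np.ndarray, start_age: float,
                       z=None, grid_step: float = 0.1, max_age: float = 110.0,
                       start_state: int = 1, n_draws: int = 500, seed: int = 0,
                       alpha: float = 0.05, age_constant: bool = False) -> pd.DataFrame:
    """Percentile confidence intervals for state-specific life expectancies.

    Parametric bootstrap: parameter vectors are drawn from the asymptotic
    normal N(theta_hat, cov) on the log-intensity scale, the life expectancies
    recomputed for each draw, and percentile intervals reported. A zero
    covariance matrix degenerates to the point estimate.
    """
    theta = model.to_vector(age_constant=age_constant)
    cov = np.asarray(cov, dtype=float)
    if cov.shape != (theta.size, theta.size):
        raise ValueError("covariance shape does not match the parameter vector")
    if np.any(cov):
        # tolerate semi-definite matrices (e.g. exactly-zero rows) but not indefinite
        eigvals = np.linalg.eigvalsh((cov + cov.T) / 2)
        if eigvals.min() < -1e-8 * max(eigvals.max(), 1.0):
            raise ValueError("covariance matrix is not positive semi-definite")
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(theta, cov, size=n_draws, method="svd")
    sims = np.empty((n_draws, 3))
    for i, vec in enumerate(draws):
        m = model.with_vector(vec, age_constant=age_constant)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            le = state_specific_life_expectancy(
                m, start_age, z=z, grid_step=grid_step, max_age=max_age,
                start_state=start_state)
        sims[i] = (le.years_in_state[1], le.years_in_state[2], le.total)
    lo, hi = 100 * alpha / 2, 100 * (1 - alpha / 2)
    qs = np.percentile(sims, [lo, hi], axis=0)
    return pd.DataFrame(
        {"estimate": [np.mean(sims[:, j]) for j in range(3)],
         "ci_low": qs[0], "ci_high": qs[1]},
        index=["years_state_1", "years_state_2", "total"])


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class IllnessDeathModel:
    """Maximum-likelihood illness-death model for two-wave panel records.

    Parameters
    ----------
    data : DataFrame
        One row per subject with columns ``entry_age``, ``entry_state`` (1 or
        2), ``exit_age``, ``exit_kind`` (``alive_observed``, ``death_exact``
        or ``lost``), ``exit_state`` (1 or 2 where alive), and covariate
        columns. A ``sex`` column with values ``male``/``female`` is encoded
        as the indicator ``sex_male``.
    covariates : sequence of str
        Covariate names entering every transition intensity log-linearly.
        Default ``("sex_male",)``.
    reference_age : float
        Centring age of the Gompertz intensities.
    age_constant : bool
        Fix all age slopes at zero (exponential intensities); mainly for
        testing against closed forms.
    grid_step : float
        Grid width (years) of the piecewise-constant likelihood approximation.
    lost : {"exclude", "censor_baseline"}
        Handling of lost-to-follow-up subjects. Both drop them from the
        likelihood: censoring at the baseline (their only observation)
        contributes a likelihood factor of exactly one.
    """

    def __init__(self, data: pd.DataFrame, covariates=("sex_male",),
                 reference_age: float = 65.0, age_constant: bool = False,
                 grid_step: float = 0.25, lost: str = "exclude"):
        if lost not in ("exclude", "censor_baseline"):
            raise ValueError("lost must be 'exclude' or 'censor_baseline'")
        self.data = data.reset_index(drop=True)
        self.covariates = tuple(covariates)
        self.reference_age = float(reference_age)
        self.age_constant = bool(age_constant)
        self.grid_step = float(grid_step)
        self.lost = lost
        self._fitting = self.data[self.data["exit_kind"] != "lost"]
        self.nobs = len(self._fitting)
        self._template = GompertzIntensities(
            alpha=np.full(3, np.log(0.01)), xi=np.zeros(3),
            beta=np.zeros((3, len(self.covariates))),
            reference_age=self.reference_age, covariate_names=self.covariates)
        self._check_identifiability()

    def _check_identifiability(self):
        rec = self._fitting
        n_death = int((rec["exit_kind"] == "death_exact").sum())
        alive = rec["exit_kind"] == "alive_observed"
        n_incident = int((alive & (rec["entry_state"] == 1)
                          & (rec["exit_state"] == 2)).sum())
        if n_death == 0:
            warnings.warn("no deaths observed: mortality intensities are not "
                          "identifiable", RuntimeWarning, stacklevel=3)
        if n_incident == 0 and int((rec["entry_state"] == 2).sum()) == 0:
            warnings.warn("no diseased subjects at either wave: onset and "
                          "diseased-mortality intensities are not identifiable",
                          RuntimeWarning, stacklevel=3)

    # objective is the MEAN log-likelihood so that gradient tolerances are
    # sample-size free; total loglik = nobs * mean
    def loglike(self, params: np.ndarray) -> float:
        model = self._template.with_vector(params, age_constant=self.age_constant)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return panel_log_likelihood(model, self._fitting, grid_step=self.grid_step)

    def _neg_mean_loglike(self, params: np.ndarray) -> float:
        ll = self.loglike(params)
        if not np.isfinite(ll):
            return 1e10
        return -ll / self.nobs

    def _start_params(self) -> np.ndarray:
        """Crude occurrence/exposure rates as starting values."""
        rec = self._fitting
        py = (rec["exit_age"] - rec["entry_age"]).sum()
        py = max(py, 1.0)
        n_death = max((rec["exit_kind"] == "death_exact").sum(), 0.5)
        alive = rec["exit_kind"] == "alive_observed"
        n_inc = max(((rec["entry_state"] == 1) & alive
                     & (rec["exit_state"] == 2)).sum(), 0.5)
        base = GompertzIntensities(
            alpha=np.log([n_inc / py, 0.7 * n_death / py, 1.2 * n_death / py]),
            xi=np.zeros(3), beta=np.zeros((3, len(self.covariates))),
            reference_age=self.reference_age, covariate_names=self.covariates)
        return base.to_vector(age_constant=self.age_constant)

    def fit(self, start_params=None, gtol: float = 1e-6,
            maxiter: int = 500) -> "IllnessDeathResults":
        """Maximise the panel likelihood by quasi-Newton (BFGS) search.

        Raises ``RuntimeError`` on non-convergence. The covariance of the
        estimates is the inverse of the numerically differentiated observed
        information.
        """
        x0 = np.asarray(start_params, dtype=float) if start_params is not None \
            else self._start_params()
        res = optimize.minimize(self._neg_mean_loglike, x0, method="BFGS",
                                options={"gtol": gtol, "maxiter": maxiter})
        grad_norm = float(np.max(np.abs(res.jac)))
        # BFGS can stall on FD-gradient noise after reaching the optimum
        # (status 2, "precision loss"); accept if the gradient is small.
        converged = bool(res.success or (res.status == 2 and grad_norm < 100 * gtol))
        if not converged:
            raise RuntimeError(
                f"optimisation failed to converge: {res.message} "
                f"(iterations={res.nit}, |grad|={grad_norm:.2e})")
        hess = approx_hess(res.x, self._neg_mean_loglike) * self.nobs
        try:
            cov = np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(hess)
            warnings.warn("observed information is singular; using a "
                          "pseudo-inverse covariance", RuntimeWarning, stacklevel=2)
        intens = self._template.with_vector(res.x, age_constant=self.age_constant)
        return IllnessDeathResults(
            model=self, intensities=intens, params=res.x, cov_params_=cov,
            llf=float(-res.fun * self.nobs), converged=converged,
            n_iter=int(res.nit), grad_norm=grad_norm)


class IllnessDeathResults:
    """Fitted illness-death model: estimates, uncertainty and life expectancy."""

    def __init__(self, model: IllnessDeathModel, intensities: GompertzIntensities,
                 params: np.ndarray, cov_params_: np.ndarray, llf: float,
                 converged: bool, n_iter: int, grad_norm: float):
        self.model = model
        self.intensities = intensities
        self.params = np.asarray(params, dtype=float)
        self._cov = np.asarray(cov_params_, dtype=float)
        self.llf = llf
        self.converged = converged
        self.n_iter = n_iter
        self.grad_norm = grad_norm
        self.param_names = intensities.param_names(age_constant=model.age_constant)

    def cov_params(self) -> np.ndarray:
        return self._cov

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self._cov), 0.0, None))

    def params_frame(self) -> pd.DataFrame:
        se = self.bse
        z = np.divide(self.params, se, out=np.full_like(self.params, np.nan),
                      where=se > 0)
        return pd.DataFrame(
            {"estimate": self.params, "se": se,
             "ci_low": self.params - 1.959963984540054 * se,
             "ci_high": self.params + 1.959963984540054 * se,
             "z": z},
            index=self.param_names)

    def summary(self) -> str:
        frame = self.params_frame()
        lines = [
            "Illness-death multistate model (maximum likelihood, panel data)",
            f"  subjects fitted: {self.model.nobs}   log-likelihood: {self.llf:.2f}",
            f"  converged: {self.converged}   iterations: {self.n_iter}"
            f"   max|grad|: {self.grad_norm:.2e}",
            "",
            frame.to_string(float_format=lambda v: f"{v:10.4f}"),
        ]
        return "\n".join(lines)

    def life_expectancy(self, start_age: float, z=None, grid_step: float = 0.1,
                        max_age: float = 110.0, start_state: int = 1) -> StateLifeExpectancy:
        return state_specific_life_expectancy(
            self.intensities, start_age, z=z, grid_step=grid_step,
            max_age=max_age, start_state=start_state)

    def life_expectancy_ci(self, start_age: float, z=None, grid_step: float = 0.1,
                           max_age: float = 110.0, start_state: int = 1,
                           n_draws: int = 500, seed: int = 0,
                           alpha: float = 0.05) -> pd.DataFrame:
        return life_expectancy_ci(
            self.intensities, self._cov, start_age, z=z, grid_step=grid_step,
            max_age=max_age, start_state=start_state, n_draws=n_draws,
            seed=seed, alpha=alpha, age_constant=self.model.age_constant)


def fit_model(records: pd.DataFrame, initial: GompertzIntensities | None = None,
              covariates=("sex_male",), age_constant: bool = False,
              grid_step: float = 0.25, **fit_kwargs) -> IllnessDeathResults:
    """Functional wrapper: build an :class:`IllnessDeathModel` and fit it."""
    ref = initial.reference_age if initial is not None else 65.0
    if initial is not None:
        covariates = initial.covariate_names
    model = IllnessDeathModel(records, covariates=covariates, reference_age=ref,
                              age_constant=age_constant, grid_step=grid_step)
    start = initial.to_vector(age_constant=age_constant) if initial is not None else None
    return model.fit(start_params=start, **fit_kwargs)
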