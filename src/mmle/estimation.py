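"""Age-dependent transition probabilities via weighted multinomial logit.

One model is fitted per living origin state (and stratum): the destination is
multinomial over the permitted-and-observed states, the reference category is
remaining in the origin state, and the linear predictor is an intercept plus a
linear age term (optionally quadratic).  Survey weights enter the score and
information as a pseudo-likelihood; the default coefficient covariance is the
robust sandwich, with the model-based inverse information as an option.
Fitted models expand onto the wave-spaced age grid as row-stochastic matrices
with structural zeros exactly where the forward-only topology forbids moves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .states import (
    ALLOWED_TRANSITIONS,
    LIVING_STATES,
    N_STATES,
    STATE_LABELS,
    State,
    make_age_grid,
)

AGE_CENTER = 60.0  # covariate is (age - 60)


class EstimationError(RuntimeError):
    pass


def _design(ages: np.ndarray, has_age: bool, quadratic: bool) -> np.ndarray:
    x = np.asarray(ages, dtype=float) - AGE_CENTER
    cols = [np.ones_like(x)]
    if has_age:
        cols.append(x)
        if quadratic:
            cols.append(x * x)
    return np.column_stack(cols)


@dataclass
class TransitionModel:
    """Multinomial-logit coefficients for one origin state and stratum.

    ``coef`` has one row per non-reference destination in ``destinations``
    order and one column per design term (intercept, age, [age^2]); ``vcov``
    covers the row-major flattening of ``coef``.
    """

    origin: State
    destinations: tuple[State, ...]
    coef: np.ndarray
    vcov: np.ndarray
    delta: int
    age_grid: np.ndarray
    stratum: dict = field(default_factory=dict)
    has_age_term: bool = True
    quadratic_age: bool = False
    sandwich: bool = True
    n_obs: int = 0
    loglik: float = np.nan
    loglik_null: float = np.nan
    n_iter: int = 0

    def __post_init__(self):
        k, p = self.coef.shape if self.coef.size else (0, self.n_params_per_dest)
        if self.coef.size and self.vcov.shape != (k * p, k * p):
            raise ValueError("vcov dimensions do not match the free-coefficient count")
        if self.coef.size and not np.allclose(self.vcov, self.vcov.T, atol=1e-10):
            raise ValueError("vcov must be symmetric")
        for d in self.destinations:
            if not ALLOWED_TRANSITIONS[self.origin, d]:
                raise ValueError(f"destination {d!r} is forbidden from {self.origin!r}")

    @property
    def n_params_per_dest(self) -> int:
        return 1 + (1 if self.has_age_term else 0) + (1 if self.quadratic_age else 0)

    @property
    def n_free(self) -> int:
        return self.coef.size

    def predict_row(self, age: float) -> np.ndarray:
        """Full 5-vector of destination probabilities at one age."""
        row = np.zeros(N_STATES)
        x = _design(np.atleast_1d(age), self.has_age_term, self.quadratic_age)[0]
        if len(self.destinations) == 0:
            row[self.origin] = 1.0
            return row
        eta = self.coef @ x
        # softmax with implicit 0 for the reference (stay) category
        m = max(0.0, float(eta.max()))
        w = np.exp(eta - m)
        denom = np.exp(-m) + w.sum()
        row[self.origin] = np.exp(-m) / denom
        for j, d in enumerate(self.destinations):
            row[d] = w[j] / denom
        return row

    def to_dict(self) -> dict:
        """JSON-serializable form (coefficients, vcov, grid, stratum)."""
        return {
            "origin": STATE_LABELS[self.origin],
            "destinations": [STATE_LABELS[d] for d in self.destinations],
            "reference": STATE_LABELS[self.origin],
            "coef": self.coef.tolist(),
            "vcov": self.vcov.tolist(),
            "delta": self.delta,
            "age_grid": self.age_grid.tolist(),
            "stratum": self.stratum,
            "has_age_term": self.has_age_term,
            "quadratic_age": self.quadratic_age,
            "sandwich": self.sandwich,
            "n_obs": self.n_obs,
            "loglik": self.loglik,
            "loglik_null": self.loglik_null,
            "n_iter": self.n_iter,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "TransitionModel":
        label = {lab: State(i) for i, lab in enumerate(STATE_LABELS)}
        return cls(
            origin=label[payload["origin"]],
            destinations=tuple(label[d] for d in payload["destinations"]),
            coef=np.asarray(payload["coef"], dtype=float),
            vcov=np.asarray(payload["vcov"], dtype=float),
            delta=payload["delta"],
            age_grid=np.asarray(payload["age_grid"], dtype=float),
            stratum=dict(payload.get("stratum", {})),
            has_age_term=payload["has_age_term"],
            quadratic_age=payload.get("quadratic_age", False),
            sandwich=payload.get("sandwich", True),
            n_obs=payload.get("n_obs", 0),
            loglik=payload.get("loglik", np.nan),
            loglik_null=payload.get("loglik_null", np.nan),
            n_iter=payload.get("n_iter", 0),
        )

    def with_coef(self, coef: np.ndarray) -> "TransitionModel":
        """Copy with replaced coefficients (used by delta method / bootstrap)."""
        new = TransitionModel(
            origin=self.origin,
            destinations=self.destinations,
            coef=np.asarray(coef, dtype=float).reshape(self.coef.shape),
            vcov=self.vcov,
            delta=self.delta,
            age_grid=self.age_grid,
            stratum=self.stratum,
            has_age_term=self.has_age_term,
            quadratic_age=self.quadratic_age,
            sandwich=self.sandwich,
            n_obs=self.n_obs,
            loglik=self.loglik,
            loglik_null=self.loglik_null,
            n_iter=self.n_iter,
        )
        return new


@dataclass
class TransitionProbabilityArray:
    """Row-stochastic transition matrices P[a] over the age grid."""

    ages: np.ndarray
    probs: np.ndarray  # (n_ages, 5, 5)
    delta: int
    stratum: dict = field(default_factory=dict)

    def validate(self, atol: float = 1e-12) -> None:
        if self.probs.shape != (len(self.ages), N_STATES, N_STATES):
            raise ValueError("probability array has wrong shape")
        if (self.probs < 0).any() or (self.probs > 1).any():
            raise ValueError("probabilities must lie in [0, 1]")
        sums = self.probs.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=atol, rtol=0):
            raise ValueError("rows must sum to 1 within 1e-12")
        forbidden = ~ALLOWED_TRANSITIONS
        if self.probs[:, forbidden].any():
            raise ValueError("nonzero mass on a forbidden transition")
        dead = self.probs[:, State.DEAD, :]
        expect = np.zeros(N_STATES)
        expect[State.DEAD] = 1.0
        if not np.array_equal(dead, np.broadcast_to(expect, dead.shape)):
            raise ValueError("the death row must be a point mass on death")

    def at(self, age: float) -> np.ndarray:
        idx = np.flatnonzero(np.isclose(self.ages, age))
        if idx.size == 0:
            raise EstimationError(f"age {age} is not on the grid {self.ages[[0, -1]]}")
        return self.probs[idx[0]]

    def to_frame(self) -> pd.DataFrame:
        """Tidy (age, origin, destination, probability) table."""
        rows = []
        for i, a in enumerate(self.ages):
            for o in State:
                for d in State:
                    if ALLOWED_TRANSITIONS[o, d]:
                        rows.append(
                            (a, STATE_LABELS[o], STATE_LABELS[d], self.probs[i, o, d])
                        )
        return pd.DataFrame(rows, columns=["age", "origin", "destination", "probability"])


def _mnl_loglik_score_hess(beta, X, y, w, n_dest):
    """Weighted multinomial log-likelihood, score and Hessian.

    ``y`` codes the reference (stay) as 0 and destination j as j+1.
    ``beta`` is (n_dest, p).
    """
    n, p = X.shape
    eta = X @ beta.T  # (n, k)
    m = np.maximum(0.0, eta.max(axis=1))
    ew = np.exp(eta - m[:, None])
    denom = np.exp(-m) + ew.sum(axis=1)
    logdenom = m + np.log(denom)
    # per-obs loglik
    pick = np.zeros(n)
    for j in range(n_dest):
        pick[y == j + 1] = eta[y == j + 1, j]
    ll = float(np.sum(w * (pick - logdenom)))
    probs = ew / denom[:, None]  # (n, k) destination probs
    ind = np.zeros((n, n_dest))
    for j in range(n_dest):
        ind[y == j + 1, j] = 1.0
    resid = ind - probs
    score = (X.T @ (w[:, None] * resid)).T.ravel()  # (k*p,) row-major over dests
    # Hessian blocks H[j,l] = -X' diag(w * p_j (delta_jl - p_l)) X
    H = np.empty((n_dest * p, n_dest * p))
    for j in range(n_dest):
        for l in range(j, n_dest):
            wjl = w * probs[:, j] * ((1.0 if j == l else 0.0) - probs[:, l])
            block = -(X.T * wjl) @ X
            H[j * p : (j + 1) * p, l * p : (l + 1) * p] = block
            if l != j:
                H[l * p : (l + 1) * p, j * p : (j + 1) * p] = block.T
    return ll, score, H, probs, resid


def fit_origin_model(
    pairs: pd.DataFrame,
    origin: State,
    delta: int,
    age_grid: np.ndarray | None = None,
    stratum: dict | None = None,
    quadratic_age: bool = False,
    sandwich: bool = True,
    min_pairs: int = 30,
    max_iter: int = 200,
    tol: float = 1e-10,
) -> TransitionModel:
    """Fit the weighted multinomial logit for one origin state.

    Destinations that are permitted but never observed in this stratum are
    kept as structural zeros (no coefficients) with a warning; perfect
    separation or non-convergence raises naming the origin and stratum.
    """
    stratum = dict(stratum or {})
    age_grid = make_age_grid(delta) if age_grid is None else np.asarray(age_grid, float)
    sub = pairs[pairs["origin_state"] == int(origin)]
    for key, val in stratum.items():
        sub = sub[sub[key] == val]
    label = f"origin={STATE_LABELS[origin]}, stratum={stratum or 'pooled'}"
    if len(sub) == 0:
        raise EstimationError(f"no transition pairs for {label}")
    if len(sub) < min_pairs:
        warnings.warn(f"only {len(sub)} pairs for {label} (small cell)", stacklevel=2)

    permitted = [d for d in State if ALLOWED_TRANSITIONS[origin, d] and d != origin]
    observed = set(int(s) for s in sub["dest_state"].unique()) - {int(origin)}
    dests = tuple(d for d in permitted if int(d) in observed)
    never = [STATE_LABELS[d] for d in permitted if int(d) not in observed]
    if never:
        warnings.warn(
            f"destinations never observed for {label}: {never}; kept as structural zeros",
            stacklevel=2,
        )

    ages = sub["age"].to_numpy(dtype=float)
    has_age = np.ptp(ages) > 0
    if not has_age:
        warnings.warn(
            f"no age variation for {label}; fitting intercept-only model", stacklevel=2
        )
    X = _design(ages, has_age, quadratic_age and has_age)
    p = X.shape[1]
    w = sub["weight"].to_numpy(dtype=float)
    if w.sum() <= 0:
        raise EstimationError(f"zero total weight for {label}")

    dest_index = {int(d): j + 1 for j, d in enumerate(dests)}
    y = np.array([dest_index.get(int(d), 0) for d in sub["dest_state"]], dtype=np.int64)
    k = len(dests)

    if k == 0:  # everyone stays: degenerate, staying probability 1
        model = TransitionModel(
            origin=origin,
            destinations=(),
            coef=np.zeros((0, p)),
            vcov=np.zeros((0, 0)),
            delta=delta,
            age_grid=age_grid,
            stratum=stratum,
            has_age_term=bool(has_age),
            quadratic_age=bool(quadratic_age and has_age),
            sandwich=sandwich,
            n_obs=len(sub),
            loglik=0.0,
            loglik_null=0.0,
        )
        return model

    beta = np.zeros((k, p))
    ll_prev, score, H, _, _ = _mnl_loglik_score_hess(beta, X, y, w, k)
    ll_null = ll_prev
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(-H, score)
        except np.linalg.LinAlgError as exc:
            raise EstimationError(f"singular information matrix for {label}") from exc
        new = beta + step.reshape(k, p)
        ll_new, score_new, H_new, _, _ = _mnl_loglik_score_hess(new, X, y, w, k)
        halves = 0
        while ll_new < ll_prev and halves < 30:
            step *= 0.5
            new = beta + step.reshape(k, p)
            ll_new, score_new, H_new, _, _ = _mnl_loglik_score_hess(new, X, y, w, k)
            halves += 1
        beta, score, H = new, score_new, H_new
        if np.abs(beta).max() > 50:
            raise EstimationError(
                f"coefficients diverging for {label}: likely perfect separation"
            )
        if abs(ll_new - ll_prev) < tol * (abs(ll_prev) + 1.0):
            ll_prev = ll_new
            break
        ll_prev = ll_new
    else:
        raise EstimationError(f"multinomial logit did not converge for {label}")

    # a perfect fit (zero deviance) or a saturated linear predictor means the
    # destinations are separable in age: no finite MLE exists
    if ll_prev > -1e-6 or np.abs(X @ beta.T).max() > 30:
        raise EstimationError(
            f"saturated linear predictor for {label}: likely perfect separation"
        )
    _, _, H, probs, resid = _mnl_loglik_score_hess(beta, X, y, w, k)
    try:
        bread = np.linalg.inv(-H)
    except np.linalg.LinAlgError as exc:
        raise EstimationError(f"singular information at optimum for {label}") from exc
    if sandwich:
        # per-obs score contributions u_i = w_i * (resid_i kron x_i)
        U = (w[:, None, None] * resid[:, :, None] * X[:, None, :]).reshape(len(w), k * p)
        meat = U.T @ U
        vcov = bread @ meat @ bread
    else:
        vcov = bread
    vcov = 0.5 * (vcov + vcov.T)

    return TransitionModel(
        origin=origin,
        destinations=dests,
        coef=beta,
        vcov=vcov,
        delta=delta,
        age_grid=age_grid,
        stratum=stratum,
        has_age_term=bool(has_age),
        quadratic_age=bool(quadratic_age and has_age),
        sandwich=sandwich,
        n_obs=len(sub),
        loglik=ll_prev,
        loglik_null=ll_null,
        n_iter=n_iter,
    )


def fit_models(
    pairs: pd.DataFrame,
    delta: int,
    stratum: dict | None = None,
    age_grid: np.ndarray | None = None,
    **kwargs,
) -> dict[State, TransitionModel]:
    """One model per living origin state for a stratum."""
    return {
        o: fit_origin_model(pairs, o, delta, age_grid=age_grid, stratum=stratum, **kwargs)
        for o in LIVING_STATES
    }


def predict_matrix(models: dict[State, TransitionModel], age: float) -> np.ndarray:
    """5x5 transition matrix at one grid age; the death row is identity."""
    grid = next(iter(models.values())).age_grid
    if not np.isclose(grid, age).any():
        raise EstimationError(f"age {age} is not on the model grid")
    P = np.zeros((N_STATES, N_STATES))
    for o in LIVING_STATES:
        P[o] = models[o].predict_row(age)
    P[State.DEAD, State.DEAD] = 1.0
    return P


def build_probability_array(
    models: dict[State, TransitionModel], age_grid: np.ndarray | None = None
) -> TransitionProbabilityArray:
    """Expand fitted models onto the age grid and validate all invariants."""
    if set(models) != set(LIVING_STATES):
        raise ValueError("need exactly one model per living origin state")
    first = models[State.NONE]
    grid = first.age_grid if age_grid is None else np.asarray(age_grid, float)
    probs = np.stack([predict_matrix(models, a) for a in grid])
    arr = TransitionProbabilityArray(
        ages=grid, probs=probs, delta=first.delta, stratum=first.stratum
    )
    arr.validate()
    return arr


def matrix_from_coeffs(
    betas: dict[State, dict[State, tuple[float, float]]], age: float
) -> np.ndarray:
    """Transition matrix implied by per-origin logit coefficients at one age.

    ``betas[origin][dest] = (intercept, age_slope)`` on the (age - 60) scale;
    the stay-in-origin category is the reference with linear predictor 0.
    """
    P = np.zeros((N_STATES, N_STATES))
    x = float(age) - AGE_CENTER
    for o in LIVING_STATES:
        dests = list(betas.get(o, {}).keys())
        for d in dests:
            if not ALLOWED_TRANSITIONS[o, d] or d == o:
                raise ValueError(f"coefficients supplied for forbidden move {o}->{d}")
        eta = np.array([betas[o][d][0] + betas[o][d][1] * x for d in dests])
        m = max(0.0, eta.max()) if len(eta) else 0.0
        w = np.exp(eta - m)
        denom = np.exp(-m) + w.sum()
        P[o, o] = np.exp(-m) / denom
        for j, d in enumerate(dests):
            P[o, d] = w[j] / denom
    P[State.DEAD, State.DEAD] = 1.0
    return P


def array_from_coeffs(
    betas: dict, delta: int, age_max: int = 100, stratum: dict | None = None
) -> TransitionProbabilityArray:
    grid = make_age_grid(delta, age_max)
    probs = np.stack([matrix_from_coeffs(betas, a) for a in grid])
    arr = TransitionProbabilityArray(
        ages=grid, probs=probs, delta=delta, stratum=dict(stratum or {})
    )
    arr.validate()
    return arr
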