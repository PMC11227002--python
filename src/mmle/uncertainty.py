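"""Delta-method confidence intervals for expectancies, with bootstrap check.

The expectancy pipeline (coefficients -> matrices -> occupancies ->
expectancies -> aggregates) is smooth in the stacked multinomial-logit
coefficients, so the variance of any output quantity is g' V g with g the
numerical gradient through the full pipeline and V the stacked coefficient
covariance.  Origin models are fitted on disjoint pair subsets, so V is
block-diagonal across models; the initial distribution is held fixed.
95% intervals use the normal 1.96 quantile; a negative lower bound on a
nonnegative quantity is set to zero and flagged.  A parametric bootstrap
(coefficient draws from a multivariate normal at the estimate) provides an
independent check on the delta-method standard errors.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .estimation import TransitionModel, build_probability_array
from .expectancy import (
    ExpectancyTable,
    InitialDistribution,
    QUANTITY_NAMES,
    compute_expectancies,
)
from .states import LIVING_STATES, State

Z95 = 1.96  # fixed normal quantile for 95% intervals


class UncertaintyError(RuntimeError):
    pass


def stack_coefficients(models: dict[State, TransitionModel]) -> np.ndarray:
    """Free coefficients of all origin models, in living-state order."""
    return np.concatenate(
        [models[o].coef.ravel() for o in LIVING_STATES if models[o].n_free]
        or [np.zeros(0)]
    )


def stacked_vcov(models: dict[State, TransitionModel]) -> np.ndarray:
    """Block-diagonal covariance over the stacked coefficients.

    Independence across origin models holds because each is fitted on the
    disjoint subset of pairs leaving its origin state.
    """
    blocks = [models[o].vcov for o in LIVING_STATES if models[o].n_free]
    if not blocks:
        return np.zeros((0, 0))
    dim = sum(b.shape[0] for b in blocks)
    V = np.zeros((dim, dim))
    pos = 0
    for b in blocks:
        k = b.shape[0]
        V[pos : pos + k, pos : pos + k] = b
        pos += k
    return V


def _unstack(models: dict[State, TransitionModel], theta: np.ndarray):
    out = {}
    pos = 0
    for o in LIVING_STATES:
        m = models[o]
        if m.n_free:
            out[o] = m.with_coef(theta[pos : pos + m.n_free])
            pos += m.n_free
        else:
            out[o] = m
    return out


def pipeline_table(
    models: dict[State, TransitionModel],
    pi: InitialDistribution | np.ndarray,
    theta: np.ndarray | None = None,
) -> ExpectancyTable:
    """Expectancy table from (possibly perturbed) stacked coefficients."""
    if theta is not None:
        models = _unstack(models, theta)
    parr = build_probability_array(models)
    return compute_expectancies(parr, pi)


def delta_ci(
    models: dict[State, TransitionModel],
    pi: InitialDistribution | np.ndarray,
    quantities: tuple[str, ...] = QUANTITY_NAMES,
    clamp_at_zero: bool = True,
) -> pd.DataFrame:
    """Delta-method variance report for the selected quantities.

    One central-difference sweep over the stacked coefficients serves every
    quantity at once, so gradients of aggregates are exactly the sums of the
    gradients of their components.  When the initial distribution was
    estimated from a panel (it carries a sampling covariance), baseline
    uncertainty is propagated through an additional, independent block of
    share gradients.  Columns: quantity, estimate, se, raw and clamped 95%
    bounds, clamped flag, gradient norm.
    """
    theta0 = stack_coefficients(models)
    V = stacked_vcov(models)
    base = pipeline_table(models, pi)
    est = {q: base.quantity(q) for q in quantities}

    n = theta0.size
    grads = np.zeros((len(quantities), n))
    for j in range(n):
        h = max(1e-5, 1e-5 * abs(theta0[j]))
        up, dn = theta0.copy(), theta0.copy()
        up[j] += h
        dn[j] -= h
        t_up = pipeline_table(models, pi, up)
        t_dn = pipeline_table(models, pi, dn)
        for qi, q in enumerate(quantities):
            grads[qi, j] = (t_up.quantity(q) - t_dn.quantity(q)) / (2 * h)
    if not np.isfinite(grads).all():
        bad = np.argwhere(~np.isfinite(grads))
        raise UncertaintyError(
            f"non-finite gradient for quantity {quantities[bad[0][0]]!r} "
            f"at coefficient index {bad[0][1]}"
        )

    pi_vcov = pi.pi_vcov if isinstance(pi, InitialDistribution) else None
    pi_grads = np.zeros((len(quantities), 4))
    if pi_vcov is not None:
        shares = pi.pi
        for k in range(4):
            h = 1e-5
            up, dn = shares.copy(), shares.copy()
            up[k] += h
            dn[k] = max(dn[k] - h, 0.0)
            step = up[k] - dn[k]
            t_up = pipeline_table(models, up / up.sum())
            t_dn = pipeline_table(models, dn / dn.sum())
            for qi, q in enumerate(quantities):
                pi_grads[qi, k] = (t_up.quantity(q) - t_dn.quantity(q)) / step

    rows = []
    for qi, q in enumerate(quantities):
        g = grads[qi]
        var = float(g @ V @ g)
        if pi_vcov is not None:
            var += float(pi_grads[qi] @ pi_vcov @ pi_grads[qi])
        var = max(var, 0.0)
        se = np.sqrt(var)
        lo_raw = est[q] - Z95 * se
        hi = est[q] + Z95 * se
        clamped = bool(clamp_at_zero and lo_raw < 0)
        lo = 0.0 if clamped else lo_raw
        rows.append((q, est[q], se, var, lo_raw, lo, hi, clamped, float(np.linalg.norm(g))))
    return pd.DataFrame(
        rows,
        columns=[
            "quantity",
            "estimate",
            "se",
            "variance",
            "lower_raw",
            "lower_95",
            "upper_95",
            "clamped",
            "gradient_norm",
        ],
    )


def attach_cis(table: ExpectancyTable, report: pd.DataFrame) -> ExpectancyTable:
    """Store 95% bounds from a variance report on the expectancy table."""
    name_map = {"none": "none", "one": "one", "dfmm": "dfmm", "dmm": "dmm",
                "mmfree_le": "mmfree_le", "mmle": "mmle", "le": "le"}
    for _, row in report.iterrows():
        if row["quantity"] in name_map:
            table.ci[name_map[row["quantity"]]] = (row["lower_95"], row["upper_95"])
    return table


def _safe_cholesky(V: np.ndarray, label: str):
    if not V.size or np.abs(V).max() == 0.0:
        return np.zeros_like(V)
    try:
        return np.linalg.cholesky(V + 1e-12 * np.eye(len(V)))
    except np.linalg.LinAlgError:
        w, Q = np.linalg.eigh(0.5 * (V + V.T))
        if w.min() < -1e-6 * max(w.max(), 1.0):
            raise UncertaintyError(
                f"covariance for {label} is not positive-semidefinite "
                f"(min eigenvalue {w.min():.3g})"
            )
        warnings.warn(f"repaired near-PSD covariance for {label}", stacklevel=2)
        w = np.clip(w, 0.0, None)
        return Q * np.sqrt(w)


def parametric_bootstrap(
    models: dict[State, TransitionModel],
    pi: InitialDistribution | np.ndarray,
    n_draws: int = 500,
    seed: int = 0,
    quantities: tuple[str, ...] = QUANTITY_NAMES,
) -> pd.DataFrame:
    """Percentile intervals from coefficient draws at the fitted estimate.

    Serves as the oracle for the delta method: on smooth quantities the
    bootstrap standard deviation should match the delta-method SE closely.
    """
    rng = np.random.default_rng(seed)
    theta0 = stack_coefficients(models)
    V = stacked_vcov(models)
    if theta0.size:
        L = _safe_cholesky(V, "stacked models")
        draws = theta0[None, :] + rng.standard_normal((n_draws, theta0.size)) @ L.T
    else:
        draws = np.zeros((n_draws, 0))
    pi_vcov = pi.pi_vcov if isinstance(pi, InitialDistribution) else None
    if pi_vcov is not None:
        Lp = _safe_cholesky(pi_vcov, "initial distribution")
        pi_draws = pi.pi[None, :] + rng.standard_normal((n_draws, 4)) @ Lp.T
        pi_draws = np.clip(pi_draws, 0.0, None)
        pi_draws /= pi_draws.sum(axis=1, keepdims=True)
    else:
        base_pi = pi.pi if isinstance(pi, InitialDistribution) else np.asarray(pi, float)
        pi_draws = np.broadcast_to(base_pi, (n_draws, 4))
    samples = np.zeros((n_draws, len(quantities)))
    for i in range(n_draws):
        t = pipeline_table(models, pi_draws[i], draws[i])
        for qi, q in enumerate(quantities):
            samples[i, qi] = t.quantity(q)
    base = pipeline_table(models, pi)
    rows = []
    for qi, q in enumerate(quantities):
        col = samples[:, qi]
        rows.append(
            (
                q,
                base.quantity(q),
                float(col.mean()),
                float(col.std(ddof=1)),
                float(np.percentile(col, 2.5)),
                float(np.percentile(col, 97.5)),
            )
        )
    return pd.DataFrame(
        rows, columns=["quantity", "estimate", "boot_mean", "boot_se", "lower_95", "upper_95"]
    )
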