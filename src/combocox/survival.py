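"""Cox partial-likelihood machinery and classical survival statistics.

This module owns everything the rest of the package needs from survival
analysis proper: the log partial likelihood of the Cox proportional hazards
model (Breslow or Efron tie handling), its analytic derivatives, an
L1-penalized fitter used as the path corrector, and thin wrappers around
Kaplan-Meier, logrank and likelihood-ratio tests.

The central object is :class:`CoxPartialLikelihood`, which precomputes a
"risk term" decomposition of the partial likelihood::

    l(eta) = sum_i delta_i * eta_i - sum_t m_t * log( sum_k A[t, k] * exp(eta_k) )

where each row ``t`` of ``A`` describes one risk-set sum.  Under Breslow's
tie rule there is one row per distinct event time (risk-set indicator,
multiplicity ``m_t`` = number of tied events); under Efron's rule each tied
group contributes ``d`` rows with the tied subjects progressively
down-weighted.  Every quantity the path engine needs — gradient weights,
Hessians, and the per-sample derivative weights along the path — falls out
of this single decomposition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateDataError, FittingError, InputError

TIE_RULES = ("breslow", "efron")

#: Coefficients are clipped to this magnitude during unpenalized fits as a
#: guard against monotone-likelihood (separation) divergence; a hazard ratio
#: of exp(15) is beyond anything interpretable.
COEF_BOUND = 15.0


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------

@dataclass
class SurvivalDataset:
    """A binarized covariate matrix with right-censored survival outcomes.

    Parameters
    ----------
    items : ndarray of shape (n_samples, n_items)
        0/1 matrix; column ``j`` indicates which samples carry item ``j``
        (e.g. ``up.TP53`` = TP53 over-expressed).
    time : ndarray of shape (n_samples,)
        Non-negative observed times (event or censoring).
    event : ndarray of shape (n_samples,)
        1 for an observed event, 0 for right censoring.
    item_names : list of str
        One label per item column, conventionally ``up.<feature>`` /
        ``dn.<feature>``.
    sample_ids : list of str, optional
        Row labels; generated as ``S000..`` when absent.
    """

    items: np.ndarray
    time: np.ndarray
    event: np.ndarray
    item_names: list[str]
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.items = np.ascontiguousarray(np.asarray(self.items))
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        if self.items.ndim != 2:
            raise InputError("items must be a 2-D matrix")
        vals = np.unique(self.items)
        if not np.isin(vals, (0, 1)).all():
            raise InputError("items must contain only 0 and 1")
        self.items = self.items.astype(np.uint8)
        if self.time.ndim != 1 or self.event.ndim != 1:
            raise InputError("time and event must be 1-D vectors")
        n = self.items.shape[0]
        if len(self.time) != n or len(self.event) != n:
            raise InputError(
                f"length mismatch: items has {n} rows, time has "
                f"{len(self.time)}, event has {len(self.event)}"
            )
        if np.any(self.time < 0) or not np.all(np.isfinite(self.time)):
            raise InputError("time must be finite and non-negative")
        ev = np.unique(self.event)
        if not np.isin(ev, (0, 1)).all():
            raise InputError("event must contain only 0 and 1")
        self.event = self.event.astype(np.int8)
        if len(self.item_names) != self.items.shape[1]:
            raise InputError("item_names length must equal the number of items")
        if self.sample_ids is None:
            self.sample_ids = [f"S{i:04d}" for i in range(n)]
        elif len(self.sample_ids) != n:
            raise InputError("sample_ids length must equal the number of samples")

    @property
    def n_samples(self) -> int:
        return self.items.shape[0]

    @property
    def n_items(self) -> int:
        return self.items.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, indices: np.ndarray) -> "SurvivalDataset":
        """Row-subset (samples); item columns are preserved."""
        indices = np.asarray(indices)
        return SurvivalDataset(
            items=self.items[indices],
            time=self.time[indices],
            event=self.event[indices],
            item_names=list(self.item_names),
            sample_ids=[self.sample_ids[i] for i in indices],
        )

    def drop_rare_items(self, min_count: int = 2) -> "SurvivalDataset":
        """Drop item columns carried by fewer than ``min_count`` samples.

        A pattern matched by a single sample can only overfit; removing such
        items up front also keeps the itemset lattice small.
        """
        keep = np.flatnonzero(self.items.sum(axis=0) >= min_count)
        return SurvivalDataset(
            items=self.items[:, keep],
            time=self.time,
            event=self.event,
            item_names=[self.item_names[j] for j in keep],
            sample_ids=list(self.sample_ids),
        )


@dataclass
class CoxFitResult:
    """Outcome of a (possibly L1-penalized) Cox partial-likelihood fit."""

    beta: np.ndarray
    log_partial_likelihood: float
    n_iter: int
    converged: bool
    l1_lambda: float = 0.0
    kkt_residual: float = np.nan

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)


# ---------------------------------------------------------------------------
# Partial likelihood core
# ---------------------------------------------------------------------------

class CoxPartialLikelihood:
    """Risk-term decomposition of the Cox log partial likelihood.

    Risk sets follow the standard convention that a subject censored at an
    event time is still at risk at that time (``time >= tau``).
    """

    def __init__(self, time: np.ndarray, event: np.ndarray, ties: str = "breslow"):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event)
        if ties not in TIE_RULES:
            raise InputError(f"ties must be one of {TIE_RULES}, got {ties!r}")
        if time.ndim != 1 or event.shape != time.shape:
            raise InputError("time and event must be 1-D vectors of equal length")
        if not np.isin(np.unique(event), (0, 1)).all():
            raise InputError("event must contain only 0 and 1")
        self.n = len(time)
        self.time = time
        self.delta = event.astype(float)
        self.ties = ties
        if self.delta.sum() == 0:
            raise DegenerateDataError("no events in the data (all censored)")

        event_times = np.unique(time[event == 1])
        rows: list[np.ndarray] = []
        mult: list[float] = []
        for tau in event_times:
            at_risk = (time >= tau).astype(float)
            tied = ((time == tau) & (event == 1)).astype(float)
            d = int(tied.sum())
            if ties == "breslow":
                rows.append(at_risk)
                mult.append(float(d))
            else:  # efron
                for r in range(d):
                    rows.append(at_risk - (r / d) * tied)
                    mult.append(1.0)
        self.A = np.array(rows)           # (n_terms, n)
        self.m = np.array(mult)           # (n_terms,)

    # -- values ------------------------------------------------------------

    def loglik(self, eta: np.ndarray) -> float:
        eta = np.asarray(eta, dtype=float)
        emax = eta.max()
        e = np.exp(eta - emax)
        s = self.A @ e
        return float(self.delta @ eta - self.m @ (np.log(s) + emax))

    def _pi(self, eta: np.ndarray) -> np.ndarray:
        """Per-term risk shares: pi[t, i] = A[t, i] e^eta_i / sum_k A[t, k] e^eta_k."""
        e = np.exp(eta - eta.max())
        num = self.A * e
        return num / num.sum(axis=1, keepdims=True)

    def weights(self, eta: np.ndarray) -> np.ndarray:
        """Martingale-residual-form gradient weights.

        Returns ``w`` such that d l/d beta_j = sum_i w_i X[i, j] for any
        covariate column: each sample's event indicator minus its accumulated
        share of risk-set mass under the current linear predictor.
        """
        pi = self._pi(np.asarray(eta, dtype=float))
        return self.delta - self.m @ pi

    def gradient(self, eta: np.ndarray, X: np.ndarray) -> np.ndarray:
        return X.T @ self.weights(eta)

    def hessian(self, eta: np.ndarray, X: np.ndarray) -> np.ndarray:
        """Hessian of the log partial likelihood (negative semidefinite)."""
        pi = self._pi(np.asarray(eta, dtype=float))
        u = self.m @ pi                      # per-sample total risk share
        P = pi @ X                           # (n_terms, p) risk-set means
        H = -(X.T @ (u[:, None] * X) - P.T @ (self.m[:, None] * P))
        return H

    def direction_weights(self, eta: np.ndarray, g: np.ndarray) -> np.ndarray:
        """Per-sample weights of the Hessian contracted with a direction.

        Given a per-sample direction ``g`` (typically ``X_A @ dbeta/dlambda``),
        returns ``v`` such that for any column ``x``::

            x^T  [d^2 l / d beta^2]  (restricted to the direction)  =  sum_i v_i x_i

        i.e. ``v_i = -sum_t m_t pi[t,i] (g_i - gbar_t)`` with ``gbar_t`` the
        pi-weighted mean of ``g`` in term ``t``.  This is what makes the
        step-length candidates linear sums over samples.
        """
        pi = self._pi(np.asarray(eta, dtype=float))
        u = self.m @ pi
        gbar = pi @ g
        return -(g * u - (self.m * gbar) @ pi)


# ---------------------------------------------------------------------------
# Public functional surface
# ---------------------------------------------------------------------------

def _check_design(beta: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if X.ndim != 2:
        raise InputError("X must be a 2-D matrix")
    if beta.shape != (X.shape[1],):
        raise InputError(
            f"beta has length {beta.shape}, X has {X.shape[1]} columns"
        )
    return beta, X


def log_partial_likelihood(beta, X, time, event, ties: str = "breslow") -> float:
    """Cox log partial likelihood at ``beta`` (baseline hazard never needed)."""
    beta, X = _check_design(beta, X)
    pl = CoxPartialLikelihood(time, event, ties)
    if X.shape[0] != pl.n:
        raise InputError("X row count does not match time/event length")
    return pl.loglik(X @ beta)


def gradient_and_hessian(beta, X, time, event, ties: str = "breslow"):
    """Analytic first and second derivatives of the log partial likelihood."""
    beta, X = _check_design(beta, X)
    pl = CoxPartialLikelihood(time, event, ties)
    if X.shape[0] != pl.n:
        raise InputError("X row count does not match time/event length")
    eta = X @ beta
    return pl.gradient(eta, X), pl.hessian(eta, X)


def kkt_residual(grad_neg_loglik: np.ndarray, beta: np.ndarray, lam: float) -> float:
    """Max violation of the L1 subgradient conditions.

    For ``beta_j != 0`` the gradient of the negative log likelihood must equal
    ``-lam * sign(beta_j)``; for ``beta_j == 0`` its magnitude must not exceed
    ``lam``.
    """
    g = np.asarray(grad_neg_loglik, dtype=float)
    beta = np.asarray(beta, dtype=float)
    res = np.where(
        beta != 0,
        np.abs(g + lam * np.sign(beta)),
        np.maximum(np.abs(g) - lam, 0.0),
    )
    return float(res.max()) if res.size else 0.0


def _l1_qp_coordinate_descent(c, H, lam, z0, max_sweeps=1000, tol=1e-13):
    """Minimize c^T z + 0.5 z^T H z + lam * ||z||_1 by cyclic soft-thresholding."""
    z = np.array(z0, dtype=float)
    p = len(z)
    Hz = H @ z
    diag = np.diag(H)
    for _ in range(max_sweeps):
        max_delta = 0.0
        for j in range(p):
            rho = c[j] + Hz[j] - diag[j] * z[j]
            if diag[j] <= 0:
                znew = 0.0
            else:
                znew = -np.sign(rho) * max(abs(rho) - lam, 0.0) / diag[j]
            dz = znew - z[j]
            if dz != 0.0:
                Hz += H[:, j] * dz
                z[j] = znew
                max_delta = max(max_delta, abs(dz))
        if max_delta <= tol * max(1.0, np.abs(z).max()):
            break
    return z


def fit_cox(
    X,
    time,
    event,
    ties: str = "breslow",
    l1_lambda: float = 0.0,
    warm_start=None,
    tol: float = 1e-9,
    max_iter: int = 100,
    _pl: "CoxPartialLikelihood | None" = None,
) -> CoxFitResult:
    """Maximize the log partial likelihood minus ``l1_lambda * ||beta||_1``.

    A proximal Newton method: at each outer iteration the smooth part is
    replaced by its local quadratic model and the resulting L1-penalized
    quadratic is solved exactly by coordinate descent (producing exact zeros),
    followed by a backtracking line search on the true penalized objective.
    Convergence is declared on the subgradient (KKT) residual, not the
    objective, so the returned optimality certificate is explicit.

    Notes
    -----
    With ``l1_lambda = 0`` this is plain Newton-Raphson.  Coefficients are
    clipped at +-``COEF_BOUND`` as a monotone-likelihood guard; a fit ending
    on the bound is flagged unconverged.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise InputError("X must be a 2-D matrix")
    n, p = X.shape
    lam = float(l1_lambda)
    if lam < 0:
        raise InputError("l1_lambda must be non-negative")
    pl = _pl if _pl is not None else CoxPartialLikelihood(time, event, ties)
    if n != pl.n:
        raise InputError("X row count does not match time/event length")

    if warm_start is None:
        beta = np.zeros(p)
    else:
        beta = np.array(warm_start, dtype=float)
        if beta.shape != (p,):
            raise InputError("warm_start length must match the number of columns")

    def objective(b):
        return -pl.loglik(X @ b) + lam * np.abs(b).sum()

    f = objective(beta)
    converged = False
    kkt = np.inf
    it = 0
    for it in range(max_iter + 1):
        eta = X @ beta
        g = -(X.T @ pl.weights(eta))        # gradient of -loglik
        kkt = kkt_residual(g, beta, lam)
        if kkt <= tol:
            converged = True
            break
        if it == max_iter:
            break
        H = -pl.hessian(eta, X)
        ridge = 1e-10 * (np.trace(H) / max(p, 1) + 1.0)
        Hr = H + ridge * np.eye(p)
        if lam == 0.0:
            try:
                z = beta - np.linalg.solve(Hr, g)
            except np.linalg.LinAlgError:
                z = beta - np.linalg.lstsq(Hr, g, rcond=None)[0]
        else:
            z = _l1_qp_coordinate_descent(g - Hr @ beta, Hr, lam, beta)
        d = z - beta
        # predicted decrease of the penalized objective
        decr = g @ d + lam * (np.abs(z).sum() - np.abs(beta).sum())
        step = 1.0
        accepted = False
        for _ in range(60):
            cand = np.clip(beta + step * d, -COEF_BOUND, COEF_BOUND)
            fc = objective(cand)
            if fc <= f + 0.25 * step * min(decr, 0.0) + 1e-14 * abs(f):
                beta, f = cand, fc
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break

    if np.any(np.abs(beta) >= COEF_BOUND - 1e-9) and kkt > tol:
        converged = False
    if not converged:
        warnings.warn(
            f"fit_cox did not reach KKT tolerance {tol:g} "
            f"(residual {kkt:.3g} after {it} iterations)",
            RuntimeWarning,
            stacklevel=2,
        )
    return CoxFitResult(
        beta=beta,
        log_partial_likelihood=pl.loglik(X @ beta),
        n_iter=it,
        converged=converged,
        l1_lambda=lam,
        kkt_residual=kkt,
    )


# ---------------------------------------------------------------------------
# Classical two-sample statistics (delegated to lifelines)
# ---------------------------------------------------------------------------

@dataclass
class KaplanMeierCurve:
    """Product-limit estimate for one stratum: right-continuous step function."""

    timeline: np.ndarray
    survival: np.ndarray
    n: int = 0

    def at(self, t: float) -> float:
        idx = np.searchsorted(self.timeline, t, side="right") - 1
        return float(self.survival[idx]) if idx >= 0 else 1.0


def _km_one(time, event) -> KaplanMeierCurve:
    from lifelines import KaplanMeierFitter

    km = KaplanMeierFitter().fit(time, event_observed=event)
    tl = np.asarray(km.survival_function_.index, dtype=float)
    sv = np.asarray(km.survival_function_.iloc[:, 0], dtype=float)
    return KaplanMeierCurve(timeline=tl, survival=sv, n=len(time))


def kaplan_meier(time, event, group=None) -> dict[int, KaplanMeierCurve]:
    """Kaplan-Meier estimates, overall (``group=None``) or per binary stratum."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if group is None:
        return {0: _km_one(time, event)}
    group = np.asarray(group)
    if not np.isin(np.unique(group), (0, 1)).all():
        raise InputError("group must be a binary 0/1 vector")
    out = {}
    for gval in (0, 1):
        mask = group == gval
        if not mask.any():
            raise InputError(f"stratum {gval} is empty")
        out[gval] = _km_one(time[mask], event[mask])
    return out


def logrank_test(time, event, group) -> tuple[float, float]:
    """Two-sample logrank test (chi-square, 1 df) comparing group 0 vs 1."""
    from lifelines.statistics import logrank_test as _ll_logrank

    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    group = np.asarray(group)
    if not np.isin(np.unique(group), (0, 1)).all():
        raise InputError("group must be a binary 0/1 vector")
    m0, m1 = group == 0, group == 1
    if not m0.any() or not m1.any():
        raise InputError("both strata must be non-empty")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = _ll_logrank(time[m0], time[m1], event[m0], event[m1])
        stat = float(res.test_statistic)
        p = float(res.p_value)
    if not np.isfinite(stat):  # zero-variance degenerate case
        stat, p = 0.0, 1.0
    return stat, p


def likelihood_ratio_test(full: CoxFitResult, reduced: CoxFitResult, df: int) -> float:
    """P-value of 2*(l_full - l_reduced) against chi-square with ``df`` df."""
    from scipy import stats

    stat = 2.0 * (full.log_partial_likelihood - reduced.log_partial_likelihood)
    scale = max(1.0, abs(full.log_partial_likelihood))
    if stat < -1e-6 * scale:
        raise FittingError(
            "full model has lower likelihood than nested reduced model "
            f"(statistic {stat:.4g}); fits are unreliable"
        )
    stat = max(stat, 0.0)
    return float(stats.chi2.sf(stat, df))
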