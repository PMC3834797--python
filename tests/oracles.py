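"""Independent reference implementations used to certify the package.

Everything here is deliberately naive and shares no code with
``combocox``'s vectorized machinery: plain Python loops over event times for
the partial-likelihood quantities, exhaustive enumeration over the itemset
lattice instead of mining, scipy's L-BFGS-B (on the positive/negative split)
plus a sign-fixed Newton polish instead of the proximal-Newton corrector,
and a dense single-variable path follower on the explicitly expanded
all-itemsets design matrix instead of the combinatorial engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.optimize import minimize

# conventions shared with the engine (documented constants, not imports)
ADMISSION_SLACK = 1e-7
MIN_STEP_RATIO = 1e-10
DEN_EPS = 1e-12


# ---------------------------------------------------------------------------
# Naive Breslow partial-likelihood quantities (loops over event times)
# ---------------------------------------------------------------------------

def naive_loglik(beta, X, time, event):
    eta = X @ np.asarray(beta, float)
    ll = 0.0
    for tau in np.unique(time[event == 1]):
        risk = time >= tau
        dead = (time == tau) & (event == 1)
        d = dead.sum()
        ll += eta[dead].sum() - d * np.log(np.exp(eta[risk]).sum())
    return ll


def naive_weights(eta, time, event):
    """w_i = delta_i - sum over event times with i at risk of d * pi_i."""
    n = len(eta)
    w = np.asarray(event, float).copy()
    e = np.exp(eta)
    for tau in np.unique(time[event == 1]):
        risk = time >= tau
        d = ((time == tau) & (event == 1)).sum()
        s = e[risk].sum()
        for i in range(n):
            if risk[i]:
                w[i] -= d * e[i] / s
    return w


def naive_gradient(beta, X, time, event):
    return X.T @ naive_weights(X @ np.asarray(beta, float), time, event)


def naive_hessian(beta, X, time, event):
    eta = X @ np.asarray(beta, float)
    e = np.exp(eta)
    p = X.shape[1]
    H = np.zeros((p, p))
    for tau in np.unique(time[event == 1]):
        risk = np.flatnonzero(time >= tau)
        d = ((time == tau) & (event == 1)).sum()
        pi = e[risk] / e[risk].sum()
        xbar = pi @ X[risk]
        cov = (X[risk] * pi[:, None]).T @ X[risk] - np.outer(xbar, xbar)
        H -= d * cov
    return H


def naive_direction_weights(eta, g, time, event):
    """v_i with sum_i v_i x_i = x^T H (direction), H the loglik Hessian."""
    e = np.exp(eta)
    v = np.zeros(len(eta))
    for tau in np.unique(time[event == 1]):
        risk = np.flatnonzero(time >= tau)
        d = ((time == tau) & (event == 1)).sum()
        pi = e[risk] / e[risk].sum()
        gbar = pi @ g[risk]
        v[risk] -= d * pi * (g[risk] - gbar)
    return v


# ---------------------------------------------------------------------------
# Independent L1-penalized Cox fit (L-BFGS-B split + sign-fixed polish)
# ---------------------------------------------------------------------------

def l1_cox_fit(X, time, event, lam, x0=None, zero_tol=1e-8):
    """Minimize -loglik + lam*||beta||_1; machine-accurate via polish."""
    n, p = X.shape
    x0 = np.zeros(p) if x0 is None else np.asarray(x0, float)
    u0 = np.concatenate([np.maximum(x0, 0), np.maximum(-x0, 0)])

    def fun(uv):
        beta = uv[:p] - uv[p:]
        g = -naive_gradient(beta, X, time, event)
        f = -naive_loglik(beta, X, time, event) + lam * uv.sum()
        return f, np.concatenate([g + lam, -g + lam])

    res = minimize(fun, u0, jac=True, method="L-BFGS-B",
                   bounds=[(0, None)] * (2 * p),
                   options={"ftol": 1e-15, "gtol": 1e-10, "maxiter": 1000})
    beta = res.x[:p] - res.x[p:]
    beta[np.abs(beta) < zero_tol] = 0.0
    # sign-fixed Newton polish on the detected support
    for _ in range(8):
        supp = np.flatnonzero(beta != 0)
        if supp.size == 0:
            break
        signs = np.sign(beta[supp])
        for _ in range(60):
            r = -naive_gradient(beta, X, time, event)[supp] + lam * signs
            if np.abs(r).max() < 1e-12:
                break
            Hs = -naive_hessian(beta, X, time, event)[np.ix_(supp, supp)]
            Hs += 1e-12 * np.eye(len(supp))
            step = np.linalg.solve(Hs, r)
            for t in (1.0, 0.5, 0.25, 0.1):
                cand = beta.copy()
                cand[supp] -= t * step
                if -naive_loglik(cand, X, time, event) + lam * np.abs(cand).sum() \
                        <= -naive_loglik(beta, X, time, event) + lam * np.abs(beta).sum() + 1e-14:
                    beta = cand
                    break
        flipped = np.sign(beta[supp]) != signs
        if not flipped.any():
            break
        beta[supp[flipped]] = 0.0
    return beta


# ---------------------------------------------------------------------------
# Exhaustive lattice enumeration
# ---------------------------------------------------------------------------

def all_itemsets(matrix, max_order):
    """Every (items tuple, indicator) with support >= 1, by enumeration."""
    matrix = np.asarray(matrix).astype(bool)
    m = matrix.shape[1]
    out = []
    for k in range(1, max_order + 1):
        for combo in combinations(range(m), k):
            ind = matrix[:, combo].all(axis=1)
            if ind.any():
                out.append((combo, ind))
    return out


def canonical_dedup(itemsets):
    """Keep, per indicator, the itemset with fewest items (ties: lexicographic)."""
    best = {}
    for items, ind in itemsets:
        key = ind.tobytes()
        if key not in best or (len(items), items) < (len(best[key][0]),
                                                     best[key][0]):
            best[key] = (items, ind)
    return sorted(best.values(), key=lambda x: (len(x[0]), x[0]))


def brute_mine(matrix, w, threshold, max_order):
    """All itemsets with |weighted support| >= threshold, both signs."""
    hits = []
    for items, ind in all_itemsets(matrix, max_order):
        val = w[ind].sum()
        if val >= threshold or val <= -threshold:
            hits.append((items, float(val)))
    return sorted(hits)


def brute_fractional_min(matrix, p0, p, q0, q, max_order,
                         exclude=frozenset(), floor=0.0, curmin=np.inf):
    """Exhaustive minimum of (p0 + sum p)/(q0 + sum q) over the lattice."""
    best_val, best_items = float(curmin), None
    for items, ind in all_itemsets(matrix, max_order):
        if items in exclude:
            continue
        den = q0 + q[ind].sum()
        if den <= DEN_EPS:
            continue
        val = (p0 + p[ind].sum()) / den
        if val <= floor:
            continue
        tie = 1e-12 * (abs(best_val) + abs(val)) if np.isfinite(best_val) else 0.0
        if val < best_val - tie or (
            val <= best_val + tie
            and best_items is not None
            and (len(items), items) < (len(best_items), best_items)
        ):
            best_val, best_items = min(best_val, val), items
    return best_val, best_items


# ---------------------------------------------------------------------------
# Hand-computed classical statistics
# ---------------------------------------------------------------------------

def km_by_hand(time, event):
    """Product-limit estimate: breakpoints at event times."""
    tl = [0.0]
    sv = [1.0]
    s = 1.0
    for tau in np.unique(time[event == 1]):
        n_risk = (time >= tau).sum()
        d = ((time == tau) & (event == 1)).sum()
        s *= 1.0 - d / n_risk
        tl.append(float(tau))
        sv.append(s)
    return np.array(tl), np.array(sv)


def logrank_by_hand(time, event, group):
    """Observed-minus-expected logrank chi-square with 1 df."""
    from scipy import stats

    o_minus_e = 0.0
    var = 0.0
    for tau in np.unique(time[event == 1]):
        risk = time >= tau
        n = risk.sum()
        n1 = (risk & (group == 1)).sum()
        d = ((time == tau) & (event == 1)).sum()
        d1 = ((time == tau) & (event == 1) & (group == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    stat = o_minus_e**2 / var
    return float(stat), float(stats.chi2.sf(stat, 1))


# ---------------------------------------------------------------------------
# Expansion-path oracle: dense single-variable L1 Cox path on the
# materialized all-itemsets design matrix
# ---------------------------------------------------------------------------

@dataclass
class OracleState:
    lam: float
    active: list[tuple[int, ...]]
    beta: np.ndarray


@dataclass
class OracleTrace:
    lambda_max: float
    states: list[OracleState] = field(default_factory=list)
    events: list[tuple[float, str, tuple[int, ...]]] = field(default_factory=list)


def expansion_path(data, max_order=3, max_active=50, lambda_min_ratio=0.01,
                   max_events=200):
    """Follow the L1 Cox path over explicitly expanded itemset columns.

    Same algorithmic conventions as the engine (linearized step candidates,
    admission slack, removal-first ties, banned-at-lambda re-admission guard)
    but a completely dense implementation: no mining, no fractional-search
    pruning, naive per-event-time partial-likelihood quantities, and an
    independent corrector.
    """
    time, event = data.time, data.event
    expanded = canonical_dedup(all_itemsets(data.items, max_order))
    names = [items for items, _ in expanded]
    Z = np.column_stack([ind.astype(float) for _, ind in expanded])
    M = Z.shape[1]

    w0 = naive_weights(np.zeros(len(time)), time, event)
    c0 = Z.T @ w0
    order = sorted(range(M), key=lambda j: (-abs(c0[j]), len(names[j]), names[j]))
    j0 = order[0]
    lam_max = abs(c0[j0])
    lam_min = lambda_min_ratio * lam_max

    active = [j0]
    beta_a = np.zeros(1)
    lam = lam_max
    trace = OracleTrace(lambda_max=lam_max)
    trace.events.append((lam_max, "add", names[j0]))
    prev_set = {j0}

    def fit_active(act, warm, lam_v):
        Xa = Z[:, act]
        return l1_cox_fit(Xa, time, event, lam_v, x0=warm)

    for _ in range(20 * max_events + 200):
        Xa = Z[:, active]
        eta = Xa @ beta_a
        w = naive_weights(eta, time, event)
        c_act = Xa.T @ w
        s = np.sign(beta_a)
        s[s == 0] = np.sign(c_act[s == 0])
        H = naive_hessian(beta_a, Xa, time, event)
        try:
            dbdl = np.linalg.solve(H, s)
        except np.linalg.LinAlgError:
            scale = np.abs(np.diag(H)).max() + 1.0
            dbdl = np.linalg.solve(H - 1e-8 * scale * np.eye(len(s)), s)

        best_d, kind = np.inf, None
        for jloc in range(len(active)):
            if beta_a[jloc] != 0 and dbdl[jloc] != 0:
                d = beta_a[jloc] / dbdl[jloc]
                if 0 < d < best_d:
                    best_d, kind = d, "remove"
        g = Xa @ dbdl
        v = naive_direction_weights(eta, g, time, event)
        c_all = Z.T @ w
        cp_all = Z.T @ v
        floor = 1e-12 * lam
        act_set = set(active)
        for j in range(M):
            if j in act_set:
                continue
            for sgn in (+1.0, -1.0):
                den = 1.0 - sgn * cp_all[j]
                if den > DEN_EPS:
                    d = (lam - sgn * c_all[j]) / den
                    if floor < d < best_d:
                        best_d, kind = d, "add"
        if not np.isfinite(best_d):
            lam_next, final = lam_min, True
        else:
            lam_next = lam - max(best_d, MIN_STEP_RATIO * lam)
            lam_next = max(lam_next, lam_min)
            final = lam_next <= lam_min * (1 + 1e-12)

        warm = beta_a + (lam_next - lam) * dbdl
        beta_a = fit_active(active, warm, lam_next)

        banned: set[int] = set()
        newly: set[int] = set()
        for _ in range(20):
            changed = False
            eta = Z[:, active] @ beta_a
            w = naive_weights(eta, time, event)
            c_all = Z.T @ w
            viol = [
                j for j in order
                if j not in set(active) and j not in banned
                and abs(c_all[j]) >= lam_next - ADMISSION_SLACK
            ]
            if viol:
                active = active + viol
                newly.update(viol)
                beta_a = fit_active(active, np.concatenate(
                    [beta_a, np.zeros(len(viol))]), lam_next)
                changed = True
            # an itemset admitted at its own entry event legitimately sits at
            # exactly zero; only previously active zeros are removals
            zero = [k for k in range(len(active))
                    if beta_a[k] == 0.0 and active[k] not in newly]
            if zero:
                banned.update(active[k] for k in zero)
                keep = [k for k in range(len(active)) if k not in set(zero)]
                active = [active[k] for k in keep]
                beta_a = beta_a[keep]
                changed = True
            if not changed:
                break

        new_set = set(active)
        if new_set != prev_set:
            for j in sorted(prev_set - new_set,
                            key=lambda j: (len(names[j]), names[j])):
                trace.events.append((lam_next, "remove", names[j]))
            for j in sorted(new_set - prev_set,
                            key=lambda j: (len(names[j]), names[j])):
                trace.events.append((lam_next, "add", names[j]))
        if new_set != prev_set or not trace.states or final:
            order_loc = sorted(range(len(active)),
                               key=lambda k: (len(names[active[k]]),
                                              names[active[k]]))
            trace.states.append(OracleState(
                lam=lam_next,
                active=[names[active[k]] for k in order_loc],
                beta=beta_a[order_loc].copy(),
            ))
        prev_set = new_set
        lam = lam_next
        if len(active) >= max_active or final or len(trace.events) >= max_events:
            break
    return trace


def random_fixture(seed, n=40, m=10, density=0.25, censoring=0.25):
    """A small random dataset with mild planted structure for oracle tests."""
    from combocox import SurvivalDataset

    rng = np.random.default_rng(seed)
    items = (rng.random((n, m)) < density).astype(np.uint8)
    # keep items carried by >= 2 samples so the lattice has no trivial columns
    keep = items.sum(axis=0) >= 2
    items = items[:, keep]
    if items.shape[1] < 3:  # pad with fresh columns if the draw was too sparse
        extra = (rng.random((n, 3)) < 0.4).astype(np.uint8)
        items = np.column_stack([items, extra])
    mcols = items.shape[1]
    beta = np.zeros(mcols)
    picks = rng.choice(mcols, size=min(2, mcols), replace=False)
    beta[picks] = rng.normal(0, 0.8, size=len(picks))
    hazard = 0.5 * np.exp(items @ beta)
    T = rng.exponential(1.0 / hazard)
    C = rng.exponential(1.0 / (0.5 * censoring / (1 - censoring)), size=n) \
        if censoring > 0 else np.full(n, np.inf)
    timev = np.minimum(T, C)
    ev = (T <= C).astype(int)
    if ev.sum() < 3:  # guarantee a handful of events
        ev[:3] = 1
    return SurvivalDataset(items=items, time=timev, event=ev,
                           item_names=[f"i{j}" for j in range(mcols)])
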