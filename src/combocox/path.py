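"""Predictor-corrector regularization path over the itemset lattice.

The model is the L1-penalized Cox partial likelihood whose covariates are
*all* itemsets (conjunctions of binarized features) up to a maximum order —
an exponentially large design matrix that is never materialized.  Starting
from ``lambda_max`` (the smallest penalty at which every coefficient is
zero), the engine repeats four steps as the penalty decreases:

1. **predict** — linear extrapolation of the active coefficients using
   ``d beta / d lambda``, the solution of ``H_A d = s_A`` (active-set Hessian
   of the log partial likelihood against the coefficient sign vector);
2. **correct** — re-optimize the penalized fit restricted to the active
   itemsets (proximal Newton, warm-started at the prediction);
3. **update the active set** — the KKT conditions say an itemset ``t`` must
   be active as soon as ``|c(t)| >= lambda``, where ``c(t)`` is a weighted
   support over samples; all violators are found by pruned itemset mining
   and the correct/update pair loops until the active set is stable;
4. **step** — the next penalty at which the active set changes is the
   smallest positive candidate among active-coefficient zero crossings and
   inactive-itemset entries; each entry candidate is the root of a ratio of
   two linear functions of the itemset indicator, minimized over the lattice
   by a branch-and-bound fractional 0-1 search.

All formulas are certified against brute-force and finite-difference oracles
in the test suite; on small inputs the whole trace is reproduced exactly by
an explicit expansion of every itemset into a design-matrix column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateDataError, InputError, PathError
from .patterns import (
    ItemLattice,
    Itemset,
    MiningProblem,
    canonicalize,
    max_weighted_support,
    mine_threshold_itemsets,
)
from .survival import CoxFitResult, CoxPartialLikelihood, SurvivalDataset, fit_cox

#: absolute slack on |c(t)| - lambda for admission into the active set;
#: prevents churn from float noise while letting the step search converge
#: onto an event from below (its error shrinks quadratically).
KKT_SLACK = 1e-7

#: denominator guard in the fractional search.
_DEN_EPS = 1e-12


@dataclass
class PathConfig:
    """Knobs of the path-following loop (defaults sized for sparse models)."""

    max_order: int = 3
    ties: str = "breslow"
    max_active: int = 50
    lambda_min_ratio: float = 0.01
    max_events: int = 200
    corrector_tol: float = 1e-9
    max_inner_loops: int = 20
    tight_pruning: bool = False
    tight_depth: int = 2
    #: smallest relative decrement of lambda per outer iteration, guaranteeing
    #: progress even when the linearized step underestimates.
    min_step_ratio: float = 1e-10


@dataclass
class PathState:
    """The penalized optimum at one recorded value of lambda."""

    lam: float
    active: list[Itemset]
    beta_active: np.ndarray
    loss: float  # log partial likelihood at the fit

    def __post_init__(self) -> None:
        self.beta_active = np.asarray(self.beta_active, dtype=float)


@dataclass
class PathEvent:
    lam: float
    action: str  # "add" | "remove"
    itemset: Itemset


@dataclass
class PathTrace:
    states: list[PathState]
    events: list[PathEvent]
    lambda_max: float
    termination_reason: str
    item_names: list[str] = field(default_factory=list)

    def state_at(self, lam: float) -> PathState:
        """The recorded state with the smallest lambda >= ``lam``."""
        cands = [s for s in self.states if s.lam >= lam - 1e-12]
        return cands[-1] if cands else self.states[0]

    def all_itemsets(self, min_order: int = 1) -> list[Itemset]:
        seen: dict[tuple, Itemset] = {}
        for s in self.states:
            for t in s.active:
                if len(t.items) >= min_order:
                    seen.setdefault(t.items, t)
        return [seen[k] for k in sorted(seen)]


@dataclass
class StepSearchProblem:
    """min over itemsets t of (p0 + sum p_i x_{t,i}) / (q0 + sum q_i x_{t,i})."""

    p0: float
    p: np.ndarray
    q0: float
    q: np.ndarray
    curmin: float = np.inf

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.q = np.asarray(self.q, dtype=float)


def search_fractional_min(
    data: SurvivalDataset | np.ndarray | ItemLattice,
    problem: StepSearchProblem,
    max_order: int,
    *,
    exclude: frozenset = frozenset(),
    floor: float = 0.0,
    use_tight: bool = False,
    tight_depth: int = 2,
) -> tuple[float, tuple[int, ...] | None]:
    """Exact minimum of the linear-fractional objective over the lattice.

    Only itemsets with positive denominator and value strictly above
    ``floor`` are candidates (a zero value corresponds to an itemset already
    on the penalty boundary).  Branches are pruned when no superset can beat
    the running minimum:

    * **fast bound** — from the running positive/negative partial sums over
      the branch support: any superset has numerator >= ``p0 - P^-`` and
      denominator <= ``q0 + Q^+``, so when the former is non-negative their
      ratio is at least ``(p0 - P^-) / (q0 + Q^+)``; a branch whose maximal
      denominator is non-positive contains no candidate at all;
    * **tight bound** (optional, shallow depths) — the parametric check
      ``min over subsets of (N - curmin * D) >= 0``, separable per sample,
      which certifies no superset has ratio below ``curmin``.

    Pruning is sound, never lossy: disabled and enabled searches return the
    same optimum, which the tests verify by enumeration.
    """
    if isinstance(data, ItemLattice):
        lattice = data
    else:
        matrix = data.items if isinstance(data, SurvivalDataset) else np.asarray(data)
        lattice = ItemLattice(matrix)
    if max_order < 1:
        raise InputError("max_order must be >= 1")
    p, q = problem.p, problem.q
    if len(p) != lattice.n or len(q) != lattice.n:
        raise InputError("coefficient vectors must have one entry per sample")
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(q))):
        raise InputError("fractional-search coefficients must be finite")
    p0, q0 = float(problem.p0), float(problem.q0)
    curmin = float(problem.curmin)
    best_items: tuple[int, ...] | None = None
    p_neg = np.minimum(p, 0.0)
    q_pos = np.maximum(q, 0.0)

    def recurse(start: int, prefix: tuple[int, ...], supp: np.ndarray) -> None:
        nonlocal curmin, best_items
        if start >= lattice.m:
            return
        sub = lattice.colsf[supp, start:]
        nums = p0 + p[supp] @ sub
        dens = q0 + q[supp] @ sub
        n_mins = p0 + p_neg[supp] @ sub
        d_maxs = q0 + q_pos[supp] @ sub
        sizes = sub.sum(axis=0)
        for idx in range(sub.shape[1]):
            if sizes[idx] == 0:
                continue
            d_max = d_maxs[idx]
            if d_max <= _DEN_EPS:
                continue  # no superset can have a positive denominator
            n_min = n_mins[idx]
            # prune only on a strict margin so exact-tie candidates (which
            # the canonical tie-break must still see) are never discarded
            if n_min >= 0.0 and np.isfinite(curmin):
                thr = curmin * d_max
                if n_min > thr + 1e-12 * (abs(thr) + abs(n_min)):
                    continue  # fast bound
            pos = start + idx
            items = prefix + (pos,)
            if (
                use_tight
                and len(items) <= tight_depth
                and np.isfinite(curmin)
            ):
                new_supp = supp[sub[:, idx] > 0]
                margin = (p0 - curmin * q0) + np.minimum(
                    0.0, p[new_supp] - curmin * q[new_supp]
                ).sum()
                if margin > 1e-12 * (abs(curmin * q0) + abs(p0) + 1.0):
                    continue  # tight parametric bound
            if dens[idx] > _DEN_EPS:
                val = nums[idx] / dens[idx]
                if val > floor:
                    orig = lattice.original(items)
                    if orig not in exclude:
                        # ties within float noise (e.g. indicator-identical
                        # itemsets summed in different orders) resolve toward
                        # fewer items, then lexicographically
                        tie = 1e-12 * (abs(curmin) + abs(val)) \
                            if np.isfinite(curmin) else 0.0
                        if val < curmin - tie or (
                            val <= curmin + tie
                            and best_items is not None
                            and (len(orig), orig) < (len(best_items), best_items)
                        ):
                            curmin, best_items = min(curmin, val), orig
            if len(items) < max_order:
                recurse(pos + 1, items, supp[sub[:, idx] > 0])

    recurse(0, (), np.arange(lattice.n))
    return curmin, best_items


# ---------------------------------------------------------------------------
# Single steps of the loop
# ---------------------------------------------------------------------------

def _active_design(active: list[Itemset], n: int | None = None) -> np.ndarray:
    if not active:
        return np.zeros((n or 0, 0))
    return np.column_stack([t.indicator.astype(float) for t in active])


def _path_direction(
    pl: CoxPartialLikelihood, X: np.ndarray, beta: np.ndarray, signs: np.ndarray
) -> tuple[np.ndarray, bool]:
    """Solve H_A (dbeta/dlambda) = s_A; ridge fallback when singular."""
    H = pl.hessian(X @ beta, X)
    try:
        return np.linalg.solve(H, signs), True
    except np.linalg.LinAlgError:
        scale = np.abs(np.diag(H)).max() + 1.0
        Hr = H - 1e-8 * scale * np.eye(len(beta))
        return np.linalg.solve(Hr, signs), False


def _signs(beta: np.ndarray, c_active: np.ndarray) -> np.ndarray:
    """Coefficient signs; a just-entered zero coefficient takes the sign of
    its gradient (the side of the penalty boundary it sits on)."""
    s = np.sign(beta)
    zero = s == 0
    s[zero] = np.sign(c_active[zero])
    return s


@dataclass
class _StepPlan:
    lam_next: float
    dbeta_dlambda: np.ndarray
    kind: str  # "add" | "remove" | "floor" | "exhausted"
    trigger: tuple[int, ...] | None


def lambda_max(
    data: SurvivalDataset, max_order: int = 3, ties: str = "breslow"
) -> tuple[float, Itemset]:
    """The largest penalty with a non-null solution, and the first entrant.

    At ``beta = 0`` the activation weights reduce to the null-model
    martingale residuals; ``lambda_max`` is the maximal ``|c(t)|`` over the
    lattice, found by the same branch-and-bound search that the miner uses.
    """
    if data.n_events == 0:
        raise DegenerateDataError("no events: lambda_max undefined")
    pl = CoxPartialLikelihood(data.time, data.event, ties)
    w0 = pl.weights(np.zeros(data.n_samples))
    vpos, tpos = max_weighted_support(data.items, w0, max_order)
    vneg, tneg = max_weighted_support(data.items, -w0, max_order)
    tol = 1e-12 * (np.abs(w0).sum() + 1.0)
    if vneg > vpos + tol:
        val, items = vneg, tneg
    elif vpos > vneg + tol:
        val, items = vpos, tpos
    else:  # tie across signs: canonical tie-break
        val = max(vpos, vneg)
        items = min((len(tpos), tpos), (len(tneg), tneg))[1]
    if val <= 0:
        raise DegenerateDataError("all weighted supports vanish; no path to follow")
    return float(val), Itemset.from_items(items, data.items)


def predictor_step(
    data: SurvivalDataset, state: PathState, lam_next: float, ties: str = "breslow"
) -> np.ndarray:
    """Linear extrapolation of the active coefficients to ``lam_next``."""
    if lam_next > state.lam:
        raise InputError("lam_next must not exceed the current lambda")
    pl = CoxPartialLikelihood(data.time, data.event, ties)
    X = _active_design(state.active, data.n_samples)
    w = pl.weights(X @ state.beta_active)
    c_act = X.T @ w
    s = _signs(state.beta_active.copy(), c_act)
    dbdl, ok = _path_direction(pl, X, state.beta_active, s)
    if not ok:
        warnings.warn(
            "singular active-set Hessian; predictor falls back to warm start",
            RuntimeWarning,
            stacklevel=2,
        )
        return state.beta_active.copy()
    return state.beta_active + (lam_next - state.lam) * dbdl


def corrector_step(
    data: SurvivalDataset,
    active: list[Itemset],
    beta_predicted: np.ndarray,
    lam_next: float,
    tol: float = 1e-9,
    ties: str = "breslow",
    _pl: CoxPartialLikelihood | None = None,
) -> CoxFitResult:
    """Exact penalized re-fit restricted to the active itemsets."""
    X = _active_design(active, data.n_samples)
    return fit_cox(
        X,
        data.time,
        data.event,
        ties=ties,
        l1_lambda=lam_next,
        warm_start=beta_predicted,
        tol=tol,
        _pl=_pl,
    )


def update_active_set(
    data: SurvivalDataset,
    state: PathState,
    max_order: int = 3,
    tol: float = 1e-9,
    ties: str = "breslow",
    max_inner_loops: int = 20,
    _lattice: ItemLattice | None = None,
    _pl: CoxPartialLikelihood | None = None,
) -> tuple[PathState, bool]:
    """Enforce the KKT optimality of the state over the *whole* lattice.

    Mines every itemset with ``|c(t)| >= lambda`` (within admission slack),
    adds the missing ones, removes active itemsets whose refitted coefficient
    is exactly zero, and repeats until stable.  Two boundary rules keep this
    deterministic: an itemset removed at this lambda is not re-admitted
    within the same update (its weighted support sits exactly on the penalty
    boundary, which would otherwise oscillate), and an itemset *admitted*
    during this update is exempt from zero-removal here — at its own entry
    event its optimal coefficient is exactly zero and only becomes non-null
    as lambda decreases further.
    """
    lattice = _lattice if _lattice is not None else ItemLattice(data.items)
    pl = _pl if _pl is not None else CoxPartialLikelihood(data.time, data.event, ties)
    active = list(state.active)
    beta = np.asarray(state.beta_active, dtype=float).copy()
    lam = state.lam
    banned: set[tuple[int, ...]] = set()
    newly_added: set[tuple[int, ...]] = set()
    changed_any = False
    fit_loss = state.loss

    for _ in range(max_inner_loops):
        X = _active_design(active, data.n_samples)
        eta = X @ beta
        w = pl.weights(eta)
        threshold = max(lam - KKT_SLACK, 1e-300)
        hits = canonicalize(
            mine_threshold_itemsets(lattice,
                                    MiningProblem(weights=w, threshold=threshold,
                                                  max_order=max_order))
        )
        active_keys = {t.items for t in active}
        active_inds = {np.packbits(t.indicator).tobytes() for t in active}
        new = [
            t
            for t in hits
            if t.items not in active_keys
            and t.items not in banned
            and np.packbits(t.indicator).tobytes() not in active_inds
        ]
        if new:
            active = active + new
            beta = np.concatenate([beta, np.zeros(len(new))])
            newly_added.update(t.items for t in new)
            fit = corrector_step(data, active, beta, lam, tol=tol, ties=ties,
                                 _pl=pl)
            beta = fit.beta
            fit_loss = fit.log_partial_likelihood
            changed_any = True
        zero_idx = [
            j
            for j in range(len(active))
            if beta[j] == 0.0 and active[j].items not in newly_added
        ]
        if zero_idx:
            for j in zero_idx:
                banned.add(active[j].items)
            keep = [j for j in range(len(active)) if j not in set(zero_idx)]
            active = [active[j] for j in keep]
            beta = beta[keep]
            changed_any = True
        if not new and not zero_idx:
            break
    else:
        raise PathError(
            f"active set failed to stabilize within {max_inner_loops} "
            f"correct/update loops at lambda={lam:.6g}"
        )
    new_state = PathState(lam=lam, active=active, beta_active=beta, loss=fit_loss)
    return new_state, changed_any


def step_length(
    data: SurvivalDataset,
    state: PathState,
    max_order: int = 3,
    ties: str = "breslow",
    config: PathConfig | None = None,
    _lattice: ItemLattice | None = None,
) -> tuple[float, tuple[int, ...] | None]:
    """Next lambda at which the active set changes (linearized candidates).

    Removal candidates come from zero crossings of the active coefficients
    along ``dbeta/dlambda``; entry candidates are roots of the linearized
    boundary equations ``c(t; lambda - d) = +-(lambda - d)``, each a ratio of
    two per-sample linear sums minimized over the lattice.  Ties resolve
    toward removal first.  Returns ``(lambda_next, triggering itemset or
    None)``; exhaustion returns ``lambda_next = 0``.
    """
    plan = _plan_step(
        data, state, config or PathConfig(max_order=max_order, ties=ties),
        _lattice=_lattice,
    )
    return plan.lam_next, plan.trigger


def _plan_step(
    data: SurvivalDataset,
    state: PathState,
    config: PathConfig,
    _lattice: ItemLattice | None = None,
    _pl: CoxPartialLikelihood | None = None,
) -> _StepPlan:
    lattice = _lattice if _lattice is not None else ItemLattice(data.items)
    pl = _pl if _pl is not None else CoxPartialLikelihood(data.time, data.event,
                                                          config.ties)
    X = _active_design(state.active, data.n_samples)
    beta = state.beta_active
    lam = state.lam
    eta = X @ beta
    w = pl.weights(eta)
    c_act = X.T @ w
    s = _signs(beta.copy(), c_act)
    dbdl, _ = _path_direction(pl, X, beta, s)

    # (a) removal events: active coefficients crossing zero
    best_d = np.inf
    kind = "exhausted"
    trigger: tuple[int, ...] | None = None
    for j in range(len(beta)):
        if beta[j] != 0.0 and dbdl[j] != 0.0:
            d = beta[j] / dbdl[j]
            if d > 0 and d < best_d:
                best_d, kind, trigger = d, "remove", state.active[j].items

    # (b) entry events via the fractional search on both penalty sides
    g = X @ dbdl
    v = pl.direction_weights(eta, g)
    floor = 1e-12 * lam
    exclude = frozenset(t.items for t in state.active)
    for p_i, q_i in ((-w, -v), (w, v)):  # +lambda side, then -lambda side
        prob = StepSearchProblem(p0=lam, p=p_i, q0=1.0, q=q_i, curmin=best_d)
        val, items = search_fractional_min(
            lattice,
            prob,
            config.max_order,
            exclude=exclude,
            floor=floor,
            use_tight=config.tight_pruning,
            tight_depth=config.tight_depth,
        )
        if items is not None and val < best_d:
            best_d, kind, trigger = val, "add", items

    if not np.isfinite(best_d):
        return _StepPlan(lam_next=0.0, dbeta_dlambda=dbdl, kind="exhausted",
                         trigger=None)
    min_step = config.min_step_ratio * lam
    d = max(best_d, min_step)
    return _StepPlan(lam_next=lam - d, dbeta_dlambda=dbdl, kind=kind,
                     trigger=trigger)


# ---------------------------------------------------------------------------
# The full loop
# ---------------------------------------------------------------------------

def follow_path(data: SurvivalDataset, config: PathConfig | None = None) -> PathTrace:
    """Follow the regularization path from ``lambda_max`` downward.

    Terminates when the active set reaches ``max_active`` itemsets, the
    penalty falls to ``lambda_min_ratio * lambda_max``, or ``max_events``
    recorded changes have accumulated; the trace carries the reason.
    """
    config = config or PathConfig()
    if data.n_events == 0:
        raise DegenerateDataError("no events in the data")
    lattice = ItemLattice(data.items)
    pl = CoxPartialLikelihood(data.time, data.event, config.ties)
    lam_max, first = lambda_max(data, config.max_order, config.ties)
    lam_min = config.lambda_min_ratio * lam_max

    active: list[Itemset] = [first]
    beta = np.zeros(1)
    lam = lam_max
    events: list[PathEvent] = [PathEvent(lam=lam_max, action="add", itemset=first)]
    states: list[PathState] = []
    prev_keys = {first.items}
    prev_map = {first.items: first}
    reason = None
    loss = -np.inf
    max_outer = 20 * config.max_events + 200

    for _ in range(max_outer):
        state = PathState(lam=lam, active=active, beta_active=beta, loss=loss)
        plan = _plan_step(data, state, config, _lattice=lattice, _pl=pl)
        if plan.kind == "exhausted":
            reason = "lambda_min"
            lam_next, final = lam_min, True
        else:
            lam_next = max(plan.lam_next, lam_min)
            final = lam_next <= lam_min * (1 + 1e-12)
        beta_pred = beta + (lam_next - lam) * plan.dbeta_dlambda
        fit = corrector_step(data, active, beta_pred, lam_next,
                             tol=config.corrector_tol, ties=config.ties, _pl=pl)
        interim = PathState(lam=lam_next, active=active, beta_active=fit.beta,
                            loss=fit.log_partial_likelihood)
        new_state, _ = update_active_set(
            data, interim, config.max_order, config.corrector_tol,
            config.ties, config.max_inner_loops, _lattice=lattice, _pl=pl,
        )
        active, beta, loss = new_state.active, new_state.beta_active, new_state.loss
        new_keys = {t.items for t in active}
        if new_keys != prev_keys:
            removed = sorted(prev_keys - new_keys, key=lambda k: (len(k), k))
            added = sorted(new_keys - prev_keys, key=lambda k: (len(k), k))
            cur_map = {t.items: t for t in active}
            for k in removed:
                events.append(PathEvent(lam=lam_next, action="remove",
                                        itemset=prev_map[k]))
            for k in added:
                events.append(PathEvent(lam=lam_next, action="add",
                                        itemset=cur_map[k]))
        if new_keys != prev_keys or not states or final:
            states.append(new_state)
        prev_keys = new_keys
        prev_map = {t.items: t for t in active}
        lam = lam_next

        if len(active) >= config.max_active:
            reason = "max_active"
        elif final:
            reason = reason or "lambda_min"
        elif len(events) >= config.max_events:
            reason = "max_events"
        if reason:
            break
    else:
        warnings.warn("path loop hit the outer iteration cap; partial trace",
                      RuntimeWarning, stacklevel=2)
        reason = "failed:outer-iteration-cap"

    return PathTrace(states=states, events=events, lambda_max=lam_max,
                     termination_reason=reason, item_names=list(data.item_names))
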