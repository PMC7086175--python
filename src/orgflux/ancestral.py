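"""Maximum-likelihood ancestral character estimation for a binary trait.

The trait (presence/absence of an organellar targeting signal) evolves
along a gene tree under a two-state continuous-time Markov chain with
gain rate alpha (0 -> 1) and loss rate beta (1 -> 0), both per unit of
branch length (substitutions per site).  Two parameterisations are
supported: equal rates (ER, alpha = beta) and all rates different (ARD).

The log-likelihood is computed with Felsenstein's pruning algorithm with
per-node rescaling; marginal (empirical-Bayes) state probabilities at
internal nodes combine the downward conditional likelihoods with an
upward pass under the fitted rates.  Rates are estimated by bounded
quasi-Newton optimisation on the log-rate scale from multiple starting
points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import optimize
from scipy.stats import chi2

from .trees import OrgfluxError, PhyloNode, PhyloTree

RATE_BOUNDS = (1e-8, 1e3)
#: zero-length branches are floored here to keep transition matrices nonsingular
MIN_BRANCH_LENGTH = 1e-9


class AceError(OrgfluxError):
    pass


@dataclass(frozen=True)
class MkModel:
    """Two-state Markov model; ``constraint`` is ``"ER"`` or ``"ARD"``."""

    alpha: float
    beta: float
    constraint: str = "ARD"

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise AceError("rates must be positive")
        if self.constraint not in ("ER", "ARD"):
            raise AceError("constraint must be 'ER' or 'ARD'")
        if self.constraint == "ER" and not math.isclose(self.alpha, self.beta):
            raise AceError("ER model requires alpha == beta")

    @property
    def n_parameters(self) -> int:
        return 1 if self.constraint == "ER" else 2

    @property
    def stationary(self) -> np.ndarray:
        s = self.alpha + self.beta
        return np.array([self.beta / s, self.alpha / s])


def transition_matrix(model: MkModel, t: float) -> np.ndarray:
    """P(t) for the two-state chain, row-stochastic.

    Closed form: with s = alpha + beta and E = exp(-s t),
    P(0->1) = (alpha/s)(1-E), P(1->0) = (beta/s)(1-E).
    """
    if t < 0:
        raise AceError("branch length must be nonnegative")
    a, b = model.alpha, model.beta
    s = a + b
    e = math.exp(-s * t)
    p01 = a / s * (1.0 - e)
    p10 = b / s * (1.0 - e)
    return np.array([[1.0 - p01, p01], [p10, 1.0 - p10]])


def _root_prior(model: MkModel, root_prior: str) -> np.ndarray:
    if root_prior == "uniform":
        return np.array([0.5, 0.5])
    if root_prior == "stationary":
        return model.stationary
    raise AceError(f"unknown root prior {root_prior!r}")


@njit(cache=True)
def _downward_jit(internal, child_left, child_right, tip_state, p01, p10):
    """Felsenstein pass over a binary tree in postorder; returns per-node
    conditional likelihoods (rescaled) and the accumulated log scale."""
    n = tip_state.shape[0]
    L0 = np.zeros(n)
    L1 = np.zeros(n)
    for i in range(n):
        if tip_state[i] == 0:
            L0[i] = 1.0
        elif tip_state[i] == 1:
            L1[i] = 1.0
    logscale = 0.0
    for k in range(internal.shape[0]):
        i = internal[k]
        v0 = 1.0
        v1 = 1.0
        for c in (child_left[i], child_right[i]):
            q01 = p01[c]
            q10 = p10[c]
            v0 *= (1.0 - q01) * L0[c] + q01 * L1[c]
            v1 *= q10 * L0[c] + (1.0 - q10) * L1[c]
        m = v0 if v0 > v1 else v1
        if m <= 0.0:
            return L0, L1, np.nan
        L0[i] = v0 / m
        L1[i] = v1 / m
        logscale += np.log(m)
    return L0, L1, logscale


@njit(cache=True)
def _downward_grad_jit(
    internal, child_left, child_right, tip_state,
    p01, p10, d01a, d01b, d10a, d10b, root, pi0, pi1,
):
    """Log-likelihood and its gradient wrt (alpha, beta), propagating
    conditional likelihoods and their derivatives through the same
    per-node rescaling."""
    n = tip_state.shape[0]
    L = np.zeros((n, 2))
    G = np.zeros((n, 4))  # dL0/da, dL1/da, dL0/db, dL1/db
    for i in range(n):
        if tip_state[i] == 0:
            L[i, 0] = 1.0
        elif tip_state[i] == 1:
            L[i, 1] = 1.0
    logscale = 0.0
    dsa = 0.0  # d logscale / d alpha
    dsb = 0.0
    for k in range(internal.shape[0]):
        i = internal[k]
        cl = child_left[i]
        cr = child_right[i]
        # per-child contributions c0 = P[0,:] . L, c1 = P[1,:] . L
        a0l = (1.0 - p01[cl]) * L[cl, 0] + p01[cl] * L[cl, 1]
        a1l = p10[cl] * L[cl, 0] + (1.0 - p10[cl]) * L[cl, 1]
        a0r = (1.0 - p01[cr]) * L[cr, 0] + p01[cr] * L[cr, 1]
        a1r = p10[cr] * L[cr, 0] + (1.0 - p10[cr]) * L[cr, 1]
        # derivatives of those contributions
        da0l_a = d01a[cl] * (L[cl, 1] - L[cl, 0]) + (1.0 - p01[cl]) * G[cl, 0] + p01[cl] * G[cl, 1]
        da1l_a = d10a[cl] * (L[cl, 0] - L[cl, 1]) + p10[cl] * G[cl, 0] + (1.0 - p10[cl]) * G[cl, 1]
        da0l_b = d01b[cl] * (L[cl, 1] - L[cl, 0]) + (1.0 - p01[cl]) * G[cl, 2] + p01[cl] * G[cl, 3]
        da1l_b = d10b[cl] * (L[cl, 0] - L[cl, 1]) + p10[cl] * G[cl, 2] + (1.0 - p10[cl]) * G[cl, 3]
        da0r_a = d01a[cr] * (L[cr, 1] - L[cr, 0]) + (1.0 - p01[cr]) * G[cr, 0] + p01[cr] * G[cr, 1]
        da1r_a = d10a[cr] * (L[cr, 0] - L[cr, 1]) + p10[cr] * G[cr, 0] + (1.0 - p10[cr]) * G[cr, 1]
        da0r_b = d01b[cr] * (L[cr, 1] - L[cr, 0]) + (1.0 - p01[cr]) * G[cr, 2] + p01[cr] * G[cr, 3]
        da1r_b = d10b[cr] * (L[cr, 0] - L[cr, 1]) + p10[cr] * G[cr, 2] + (1.0 - p10[cr]) * G[cr, 3]
        v0 = a0l * a0r
        v1 = a1l * a1r
        dv0a = da0l_a * a0r + a0l * da0r_a
        dv1a = da1l_a * a1r + a1l * da1r_a
        dv0b = da0l_b * a0r + a0l * da0r_b
        dv1b = da1l_b * a1r + a1l * da1r_b
        if v0 > v1:
            m, dma, dmb = v0, dv0a, dv0b
        else:
            m, dma, dmb = v1, dv1a, dv1b
        if m <= 0.0:
            return np.nan, 0.0, 0.0
        L[i, 0] = v0 / m
        L[i, 1] = v1 / m
        G[i, 0] = (dv0a - L[i, 0] * dma) / m
        G[i, 1] = (dv1a - L[i, 1] * dma) / m
        G[i, 2] = (dv0b - L[i, 0] * dmb) / m
        G[i, 3] = (dv1b - L[i, 1] * dmb) / m
        logscale += np.log(m)
        dsa += dma / m
        dsb += dmb / m
    tot = pi0 * L[root, 0] + pi1 * L[root, 1]
    logL = np.log(tot) + logscale
    ga = (pi0 * G[root, 0] + pi1 * G[root, 1]) / tot + dsa
    gb = (pi0 * G[root, 2] + pi1 * G[root, 3]) / tot + dsb
    return logL, ga, gb


class _Pruner:
    """Cached tree structure for repeated likelihood evaluations."""

    def __init__(self, tree: PhyloTree, tip_states: dict):
        if not tree.is_binary():
            raise AceError("ancestral estimation requires a binary tree")
        if not tree.has_branch_lengths():
            raise AceError("tree has missing branch lengths")
        self.tree = tree
        self.n = len(tree.postorder)
        self.lengths = np.empty(self.n)
        self.child_left = np.full(self.n, -1, dtype=np.int64)
        self.child_right = np.full(self.n, -1, dtype=np.int64)
        self.tip_state = np.full(self.n, -1, dtype=np.int64)
        for node in tree.postorder:
            i = node.index
            self.lengths[i] = max(node.length or 0.0, MIN_BRANCH_LENGTH)
            if node.is_leaf:
                if node.label not in tip_states:
                    raise AceError(f"no observed state for tip {node.label!r}")
                state = int(tip_states[node.label])
                if state not in (0, 1):
                    raise AceError(f"tip state must be 0/1, got {state!r}")
                self.tip_state[i] = state
            else:
                self.child_left[i] = node.children[0].index
                self.child_right[i] = node.children[1].index
        self.root_index = tree.root.index
        self.internal = np.array(
            [n.index for n in tree.postorder if not n.is_leaf], dtype=np.int64
        )

    def _matrix_rows(self, model: MkModel):
        a, b = model.alpha, model.beta
        s = a + b
        frac = (1.0 - np.exp(-s * self.lengths)) / s
        return a * frac, b * frac

    def downward(self, model: MkModel):
        """Conditional likelihoods per node (rescaled) and total log scale."""
        p01, p10 = self._matrix_rows(model)
        L0, L1, logscale = _downward_jit(
            self.internal, self.child_left, self.child_right, self.tip_state, p01, p10
        )
        if math.isnan(logscale):
            raise AceError("zero likelihood encountered")
        self._p01, self._p10 = p01, p10
        return L0, L1, logscale

    def log_likelihood(self, model: MkModel, root_prior: str = "uniform") -> float:
        L0, L1, logscale = self.downward(model)
        pr = _root_prior(model, root_prior)
        r = self.root_index
        return math.log(pr[0] * L0[r] + pr[1] * L1[r]) + logscale

    def log_likelihood_grad(self, model: MkModel, root_prior: str = "uniform"):
        """(logL, dlogL/dalpha, dlogL/dbeta); exact for the uniform root
        prior (the stationary prior's own rate dependence is not chained)."""
        a, b = model.alpha, model.beta
        s = a + b
        t = self.lengths
        e = np.exp(-s * t)
        one_e = 1.0 - e
        te_s = t * e / s
        p01 = a / s * one_e
        p10 = b / s * one_e
        d01a = b * one_e / s**2 + a * te_s
        d01b = -a * one_e / s**2 + a * te_s
        d10a = -b * one_e / s**2 + b * te_s
        d10b = a * one_e / s**2 + b * te_s
        pr = _root_prior(model, root_prior)
        logL, ga, gb = _downward_grad_jit(
            self.internal, self.child_left, self.child_right, self.tip_state,
            p01, p10, d01a, d01b, d10a, d10b, self.root_index, pr[0], pr[1],
        )
        if math.isnan(logL):
            raise AceError("zero likelihood encountered")
        return logL, ga, gb

    def marginals(self, model: MkModel, root_prior: str = "uniform") -> np.ndarray:
        """Marginal P(state) per node, shape (n_nodes, 2)."""
        L0, L1, _ = self.downward(model)
        L = np.column_stack([L0, L1])
        p01 = np.asarray(self._p01)
        p10 = np.asarray(self._p10)
        P = np.empty((self.n, 2, 2))
        P[:, 0, 0] = 1.0 - p01
        P[:, 0, 1] = p01
        P[:, 1, 0] = p10
        P[:, 1, 1] = 1.0 - p10
        up = np.zeros((self.n, 2))
        up[self.root_index] = _root_prior(model, root_prior)
        for node in self.tree.preorder:
            i = node.index
            for child in node.children:
                c = child.index
                partial = up[i].copy()
                for sib in node.children:
                    if sib is child:
                        continue
                    partial = partial * (P[sib.index] @ L[sib.index])
                vec = partial @ P[c]
                tot = vec.sum()
                up[c] = vec / tot if tot > 0 else vec
        post = up * L
        norm = post.sum(axis=1, keepdims=True)
        return post / norm


@dataclass
class AceFit:
    model: MkModel
    log_likelihood: float
    marginal: dict = field(default_factory=dict)  # node index -> P(state 1)
    converged: bool = True
    at_boundary: bool = False
    root_prior: str = "uniform"

    def probability(self, node: PhyloNode) -> float:
        return self.marginal[node.index]


def tree_log_likelihood(
    tree: PhyloTree,
    tip_states: dict,
    model: MkModel,
    root_prior: str = "uniform",
) -> float:
    """Pruning-algorithm log-likelihood of the tip states under ``model``."""
    return _Pruner(tree, tip_states).log_likelihood(model, root_prior)


def marginal_probabilities(
    tree: PhyloTree,
    tip_states: dict,
    model: MkModel,
    root_prior: str = "uniform",
) -> dict:
    """Marginal probability of the targeted state (1) per node index."""
    marg = _Pruner(tree, tip_states).marginals(model, root_prior)
    return {i: float(marg[i, 1]) for i in range(marg.shape[0])}


def fit_mk(
    tree: PhyloTree,
    tip_states: dict,
    constraint: str = "ARD",
    root_prior: str = "uniform",
    compute_marginals: bool = True,
) -> AceFit:
    """Fit rates by maximum likelihood.

    Three deterministic starts (an ER-derived point, 0.1 and 1.0 per unit
    length) feed a bounded L-BFGS-B search on log rates.  Monomorphic tip
    data drive the rates to the lower bound; such boundary fits are
    flagged rather than raised.
    """
    pruner = _Pruner(tree, tip_states)
    lo, hi = math.log(RATE_BOUNDS[0]), math.log(RATE_BOUNDS[1])

    def make_model(x) -> MkModel:
        if constraint == "ER":
            r = math.exp(x[0])
            return MkModel(r, r, "ER")
        return MkModel(math.exp(x[0]), math.exp(x[1]), "ARD")

    analytic = root_prior == "uniform"

    def nll(x) -> float:
        try:
            return -pruner.log_likelihood(make_model(x), root_prior)
        except (AceError, ValueError, OverflowError):
            return 1e12

    def nll_and_grad(x):
        # gradient on the log-rate scale: d/d log r = r d/dr
        try:
            logL, ga, gb = pruner.log_likelihood_grad(make_model(x), root_prior)
        except (AceError, ValueError, OverflowError):
            return 1e12, np.zeros(len(x))
        if constraint == "ER":
            r = math.exp(x[0])
            return -logL, np.array([-(ga + gb) * r])
        return -logL, np.array([-ga * math.exp(x[0]), -gb * math.exp(x[1])])

    ndim = 1 if constraint == "ER" else 2
    starts = [[math.log(0.1)] * ndim, [0.0] * ndim]
    if constraint == "ARD":
        # seed from a quick ER profile
        er = min(
            (nll([v, v]), v) for v in (math.log(0.05), math.log(0.2), 0.0)
        )[1]
        starts.insert(0, [er, er])
    else:
        starts.insert(0, [math.log(0.5)])

    best = None
    converged = False
    for x0 in starts:
        res = optimize.minimize(
            nll_and_grad if analytic else nll,
            x0,
            jac=analytic,
            method="L-BFGS-B",
            bounds=[(lo, hi)] * ndim,
            options={"ftol": 1e-10, "gtol": 1e-8, "maxiter": 500},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
        converged = converged or bool(res.success)

    model = make_model(best.x)
    eps = 1e-3
    monomorphic = len({int(s) for s in tip_states.values()}) < 2
    at_boundary = monomorphic or bool(
        np.any(best.x <= lo + eps) or np.any(best.x >= hi - eps)
    )
    fit = AceFit(
        model=model,
        log_likelihood=-float(best.fun),
        converged=converged,
        at_boundary=at_boundary,
        root_prior=root_prior,
    )
    if compute_marginals:
        marg = pruner.marginals(model, root_prior)
        fit.marginal = {i: float(marg[i, 1]) for i in range(marg.shape[0])}
    return fit


def lrt_er_vs_ard(fit_er: AceFit, fit_ard: AceFit, tol: float = 1e-6) -> tuple[float, float]:
    """Chi-squared likelihood-ratio test of ARD against nested ER.

    Returns ``(statistic, p_value)`` with 1 degree of freedom; the
    statistic is clamped at zero within ``tol`` (optimizer noise), and a
    genuinely worse ARD fit raises, since nesting forbids it.
    """
    stat = 2.0 * (fit_ard.log_likelihood - fit_er.log_likelihood)
    if stat < -tol:
        raise AceError(
            f"ARD log-likelihood below ER by {-stat / 2:.3g}: optimizer failure"
        )
    stat = max(stat, 0.0)
    return stat, float(chi2.sf(stat, df=1))
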