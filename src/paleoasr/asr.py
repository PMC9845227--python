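"""Ancestral-state inference for one unordered k-state character.

Three methods on a rooted tree:

* Sankoff parsimony (unit cost matrix, branch lengths ignored), with
  MPR state sets — the states a node takes in at least one
  most-parsimonious reconstruction;
* Mk maximum likelihood (Felsenstein pruning with per-node log scaling)
  with exact marginal node probabilities via an up–down pass;
* Bayesian inference: Metropolis–Hastings over the log transition rate
  with an exponential prior, node posteriors Rao–Blackwellized (the
  exact marginal at each sampled rate, averaged over retained samples).

The Mk model is equal-rates (ER) by default; SYM and ARD
parameterizations are available and use a matrix exponential.  For ER
the transition probabilities have the closed form
``P_same(t) = 1/k + (k-1)/k * exp(-k q t)`` and
``P_diff(t) = 1/k - 1/k * exp(-k q t)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import brentq, minimize, minimize_scalar

from .coding import ALL_STATES, CharacterCoding
from .trees import Node, Tree


class AsrError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Mk model
# ---------------------------------------------------------------------------

def _n_free_rates(k: int, parameterization: str) -> int:
    if parameterization == "ER":
        return 1
    if parameterization == "SYM":
        return k * (k - 1) // 2
    if parameterization == "ARD":
        return k * (k - 1)
    raise AsrError(f"unknown parameterization {parameterization!r}")


@dataclass
class MkModel:
    """Continuous-time Markov model for a k-state unordered character.

    ``rates`` holds the free off-diagonal rates in events/Myr: one value
    for ER; upper-triangle row-major for SYM; row-major off-diagonals
    for ARD.  ``root_prior`` is "flat" or an explicit probability vector.
    """

    k: int = 3
    parameterization: str = "ER"
    rates: np.ndarray = field(default_factory=lambda: np.array([0.01]))
    root_prior: Union[str, np.ndarray] = "flat"

    def __post_init__(self):
        self.rates = np.atleast_1d(np.asarray(self.rates, dtype=float))
        expected = _n_free_rates(self.k, self.parameterization)
        if self.rates.size != expected:
            raise AsrError(
                f"{self.parameterization} with k={self.k} needs {expected} rates, "
                f"got {self.rates.size}"
            )
        if np.any(self.rates <= 0):
            raise AsrError("all rates must be > 0")
        if isinstance(self.root_prior, str):
            if self.root_prior not in ("flat", "stationary"):
                raise AsrError(f"unknown root prior {self.root_prior!r}")
        else:
            self.root_prior = np.asarray(self.root_prior, dtype=float)
            if self.root_prior.shape != (self.k,) or abs(self.root_prior.sum() - 1) > 1e-9:
                raise AsrError("root prior must be a length-k vector summing to 1")

    def q_matrix(self) -> np.ndarray:
        k = self.k
        Q = np.zeros((k, k))
        if self.parameterization == "ER":
            Q[:] = self.rates[0]
        elif self.parameterization == "SYM":
            it = iter(self.rates)
            for i in range(k):
                for j in range(i + 1, k):
                    Q[i, j] = Q[j, i] = next(it)
        else:  # ARD
            it = iter(self.rates)
            for i in range(k):
                for j in range(k):
                    if i != j:
                        Q[i, j] = next(it)
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); closed form for ER."""
        if t < 0:
            raise AsrError("negative branch length")
        k = self.k
        if self.parameterization == "ER":
            q = self.rates[0]
            e = math.exp(-k * q * t)
            same = 1.0 / k + (k - 1) / k * e
            diff = 1.0 / k - 1.0 / k * e
            P = np.full((k, k), diff)
            np.fill_diagonal(P, same)
            return P
        return expm(self.q_matrix() * t)

    def prior_vector(self) -> np.ndarray:
        if isinstance(self.root_prior, np.ndarray):
            return self.root_prior
        if self.root_prior == "flat":
            return np.full(self.k, 1.0 / self.k)
        # stationary distribution: left null vector of Q
        Q = self.q_matrix()
        w, v = np.linalg.eig(Q.T)
        idx = int(np.argmin(np.abs(w)))
        pi = np.real(v[:, idx])
        pi = np.abs(pi)
        return pi / pi.sum()

    def with_rates(self, rates) -> "MkModel":
        return MkModel(self.k, self.parameterization, np.asarray(rates, float), self.root_prior)


# ---------------------------------------------------------------------------
# Results container
# ---------------------------------------------------------------------------

@dataclass
class AsrResult:
    """Per-node ancestral-state estimates plus method metadata.

    ``node_states`` maps node id → probability vector (ML/MB) or MPR
    state frozenset (MP).  Node ids are the tree's stable postorder
    indices; ``tip_ids`` maps taxon label → node id.
    """

    method: str                       # "MP" | "ML" | "MB"
    tree: Tree
    node_states: dict[int, Union[np.ndarray, frozenset]]
    branch_mode: Optional[str] = None  # "timescaled" | "unit" | None (MP)
    coding_label: Optional[str] = None
    cost: Optional[int] = None        # MP: minimum number of changes
    model: Optional[MkModel] = None
    log_likelihood: Optional[float] = None
    converged: Optional[bool] = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        for nid, val in self.node_states.items():
            if isinstance(val, np.ndarray):
                if np.any(val < -1e-12) or abs(val.sum() - 1.0) > 1e-9:
                    raise AsrError(f"node {nid}: probability vector does not sum to 1")
            elif not val:
                raise AsrError(f"node {nid}: empty MPR set")

    def at_node(self, node: Node):
        return self.node_states[node.id]

    def at_mrca(self, taxa):
        return self.node_states[self.tree.mrca(taxa).id]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        labels = {n.id: n.label for n in self.tree.postorder()}
        for nid in sorted(self.node_states):
            val = self.node_states[nid]
            if isinstance(val, frozenset):
                rows.append({"node": nid, "label": labels[nid], "mpr_set": "/".join(map(str, sorted(val)))})
            else:
                row = {"node": nid, "label": labels[nid]}
                row.update({f"p_state{s}": val[s] for s in range(len(val))})
                rows.append(row)
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        payload = {
            "method": self.method,
            "branch_mode": self.branch_mode,
            "coding": self.coding_label,
            "cost": self.cost,
            "log_likelihood": self.log_likelihood,
            "diagnostics": self.diagnostics,
            "nodes": {
                str(nid): (sorted(v) if isinstance(v, frozenset) else [float(x) for x in v])
                for nid, v in self.node_states.items()
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Shared plumbing
# ---------------------------------------------------------------------------

def _tip_indicator(states: frozenset, k: int) -> np.ndarray:
    v = np.zeros(k)
    for s in states:
        v[s] = 1.0
    return v


def _check_coding(tree: Tree, coding: CharacterCoding) -> None:
    missing = [lab for lab in tree.leaf_labels() if lab not in coding]
    if missing:
        raise AsrError(f"tips missing from coding: {sorted(missing)}")


def _branch_lengths_ok(tree: Tree) -> None:
    for node in tree.postorder():
        if node.parent is not None and (node.length is None or node.length <= 0):
            raise AsrError(
                f"node {node.label or node.id}: branch length must be > 0 "
                "(timescale or use unit branch lengths first)"
            )


class _ErEngine:
    """Flattened ER pruning for repeated likelihood evaluation (MCMC).

    For the equal-rates model the child-to-parent message has the
    closed form P(t) @ L = (1-e)/k * ΣL + e * L with e = exp(-k q t),
    so the per-branch exponentials can be vectorized over the tree and
    no transition matrix is ever materialized.
    """

    def __init__(self, tree: Tree, coding: CharacterCoding, k: int, prior: np.ndarray):
        self.k = k
        self.prior = prior
        nodes = list(tree.postorder())
        index = {n.id: i for i, n in enumerate(nodes)}
        self.children = [[index[c.id] for c in n.children] for n in nodes]
        self.lengths = np.array(
            [n.length if n.parent is not None else 0.0 for n in nodes]
        )
        self.tip_partial = [
            _tip_indicator(coding[n.label], k) if n.is_leaf else None for n in nodes
        ]

    def loglik(self, q: float) -> float:
        k = self.k
        e = np.exp(-k * q * self.lengths)
        n = len(self.children)
        partial: list = [None] * n
        msg: list = [None] * n
        logscale = 0.0
        for i in range(n):
            ch = self.children[i]
            if not ch:
                L = self.tip_partial[i]
            else:
                L = msg[ch[0]].copy()
                for c in ch[1:]:
                    L *= msg[c]
                s = L.max()
                if s <= 0:
                    return -np.inf
                L = L / s
                logscale += math.log(s)
            partial[i] = L
            ei = e[i]
            msg[i] = (L.sum() * (1.0 - ei)) / k + ei * L
        lik = float(self.prior @ partial[-1])
        if lik <= 0:
            return -np.inf
        return math.log(lik) + logscale


# ---------------------------------------------------------------------------
# Sankoff parsimony
# ---------------------------------------------------------------------------

def sankoff_parsimony(tree: Tree, coding: CharacterCoding, k: int = 3) -> AsrResult:
    """Minimum-change reconstruction under a unit cost matrix.

    Returns the minimum change count and, per node, the MPR state set.
    Ambiguous tips contribute cost 0 for any state in their set; branch
    lengths are ignored entirely.
    """
    _check_coding(tree, coding)
    INF = float("inf")
    nodes = list(tree.postorder())
    down: dict[int, np.ndarray] = {}

    def min_plus(cost_vec: np.ndarray) -> np.ndarray:
        # transition under unit costs: min(c_s, 1 + min_all)
        m = cost_vec.min()
        return np.minimum(cost_vec, 1.0 + m)

    for node in nodes:
        if node.is_leaf:
            c = np.full(k, INF)
            for s in coding[node.label]:
                c[s] = 0.0
            down[node.id] = c
        else:
            down[node.id] = sum(min_plus(down[ch.id]) for ch in node.children)

    total_cost = down[tree.root.id].min()

    # up-pass: outside cost O_v(s) = min cost of the rest of the tree
    # given node v fixed to s
    up: dict[int, np.ndarray] = {tree.root.id: np.zeros(k)}
    for node in tree.preorder():
        if node.is_leaf:
            continue
        child_msgs = {ch.id: min_plus(down[ch.id]) for ch in node.children}
        total_msg = sum(child_msgs.values())
        for ch in node.children:
            sib = up[node.id] + total_msg - child_msgs[ch.id]
            # O_ch(s) = min_{s'} sib(s') + cost(s', s)
            m = sib.min()
            up[ch.id] = np.minimum(sib, 1.0 + m)

    node_states: dict[int, frozenset] = {}
    for node in nodes:
        tot = down[node.id] + up[node.id]
        best = tot.min()
        node_states[node.id] = frozenset(int(s) for s in range(k) if tot[s] <= best + 1e-9)

    return AsrResult(
        method="MP",
        tree=tree,
        node_states=node_states,
        branch_mode=None,
        cost=int(round(total_cost)),
        diagnostics={"note": "branch lengths ignored (parsimony)"},
    )


# ---------------------------------------------------------------------------
# Likelihood machinery
# ---------------------------------------------------------------------------

def _postorder_partials(tree: Tree, coding: CharacterCoding, model: MkModel):
    """Conditional likelihoods of each subtree, with per-node log scaling.

    Returns (partials, logscale, messages) where ``messages[child id]``
    is P(t_child) @ L_child — the contribution of a child to its parent
    — cached for reuse by the marginal up-pass.
    """
    k = model.k
    partials: dict[int, np.ndarray] = {}
    messages: dict[int, np.ndarray] = {}
    logscale = 0.0
    for node in tree.postorder():
        if node.is_leaf:
            L = _tip_indicator(coding[node.label], k)
        else:
            L = np.ones(k)
            for ch in node.children:
                L = L * messages[ch.id]
            scale = L.max()
            if scale <= 0:
                raise AsrError("zero likelihood: incompatible coding")
            L = L / scale
            logscale += math.log(scale)
        partials[node.id] = L
        if node.parent is not None:
            messages[node.id] = model.transition_matrix(node.length) @ L
    return partials, logscale, messages


def mk_loglik(tree: Tree, coding: CharacterCoding, model: MkModel) -> float:
    """Log-likelihood of the character by Felsenstein pruning."""
    _check_coding(tree, coding)
    _branch_lengths_ok(tree)
    partials, logscale, _ = _postorder_partials(tree, coding, model)
    lik = float(model.prior_vector() @ partials[tree.root.id])
    if lik <= 0:
        return -np.inf
    return math.log(lik) + logscale


def fit_mk(
    tree: Tree,
    coding: CharacterCoding,
    parameterization: str = "ER",
    root_prior: Union[str, np.ndarray] = "flat",
    k: int = 3,
    rate_bounds: tuple[float, float] = (1e-8, 1e3),
) -> tuple[MkModel, float, bool]:
    """Maximum-likelihood rate(s) for the Mk model.

    ER uses bounded 1-D optimization on the log rate; SYM/ARD use
    L-BFGS-B on log rates.  Returns (model, loglik, converged); a
    non-converged optimizer is flagged, never silent.
    """
    _check_coding(tree, coding)
    _branch_lengths_ok(tree)
    lo, hi = math.log(rate_bounds[0]), math.log(rate_bounds[1])
    n_free = _n_free_rates(k, parameterization)

    def make(rates_log: np.ndarray) -> MkModel:
        return MkModel(k, parameterization, np.exp(rates_log), root_prior)

    if n_free == 1:
        res = minimize_scalar(
            lambda lr: -mk_loglik(tree, coding, make(np.array([lr]))),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-8},
        )
        model = make(np.array([res.x]))
        return model, -res.fun, bool(res.success)
    res = minimize(
        lambda lrs: -mk_loglik(tree, coding, make(lrs)),
        x0=np.zeros(n_free),
        method="L-BFGS-B",
        bounds=[(lo, hi)] * n_free,
    )
    model = make(res.x)
    return model, -res.fun, bool(res.success)


def marginal_asr_ml(tree: Tree, coding: CharacterCoding, model: MkModel) -> AsrResult:
    """Exact marginal node probabilities P(state | data, rates).

    Up–down message passing: the marginal at node v is proportional to
    the product of its subtree conditional likelihood and the likelihood
    of the rest of the tree given v's state.  Equivalent to re-rooting
    at every node.  Tips with singleton codings get probability 1 on
    their state; ambiguous tips get their posterior over the state set.
    """
    _check_coding(tree, coding)
    _branch_lengths_ok(tree)
    k = model.k
    partials, _, messages = _postorder_partials(tree, coding, model)

    up: dict[int, np.ndarray] = {tree.root.id: model.prior_vector().copy()}
    for node in tree.preorder():
        if node.is_leaf:
            continue
        for ch in node.children:
            sib = up[node.id].copy()
            for other in node.children:
                if other is not ch:
                    sib = sib * messages[other.id]
            msg = model.transition_matrix(ch.length).T @ sib
            s = msg.max()
            up[ch.id] = msg / s if s > 0 else msg

    node_states: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        post = partials[node.id] * up[node.id]
        tot = post.sum()
        if tot <= 0:
            raise AsrError("zero marginal likelihood at a node")
        node_states[node.id] = post / tot

    return AsrResult(
        method="ML",
        tree=tree,
        node_states=node_states,
        branch_mode=tree.branch_mode,
        model=model,
        log_likelihood=mk_loglik(tree, coding, model),
    )


def rate_confidence_interval(
    tree: Tree,
    coding: CharacterCoding,
    model: MkModel,
    loglik_hat: float,
    level_drop: float = 1.92,
    rate_bounds: tuple[float, float] = (1e-8, 1e3),
) -> tuple[float, float]:
    """Profile likelihood-ratio interval for the single ER rate.

    Bounds where the log-likelihood drops by ``level_drop`` (1.92 for a
    95% interval); clipped at the search bounds.
    """
    if model.parameterization != "ER":
        raise AsrError("likelihood-ratio interval implemented for ER only")
    qhat = float(model.rates[0])
    target = loglik_hat - level_drop

    def f(logq):
        return mk_loglik(tree, coding, model.with_rates([math.exp(logq)])) - target

    lo_bound, hi_bound = math.log(rate_bounds[0]), math.log(rate_bounds[1])
    lq = math.log(qhat)
    lower = rate_bounds[0]
    if f(lo_bound) < 0:
        lower = math.exp(brentq(f, lo_bound, lq, xtol=1e-10))
    upper = rate_bounds[1]
    if f(hi_bound) < 0:
        upper = math.exp(brentq(f, lq, hi_bound, xtol=1e-10))
    return lower, upper


# ---------------------------------------------------------------------------
# Bayesian inference
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class McmcSettings:
    """Metropolis–Hastings settings; the seed is mandatory."""

    iterations: int = 100_000
    burn_in_fraction: float = 0.2
    thin: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.iterations < 1000:
            raise AsrError("MCMC needs at least 1000 iterations")
        if not 0 <= self.burn_in_fraction < 1:
            raise AsrError("burn_in_fraction must be in [0, 1)")
        if self.thin < 1:
            raise AsrError("thin must be >= 1")


def bayes_asr(
    tree: Tree,
    coding: CharacterCoding,
    mcmc: McmcSettings,
    parameterization: str = "ER",
    root_prior: Union[str, np.ndarray] = "flat",
    prior_mean: Optional[float] = None,
    k: int = 3,
) -> AsrResult:
    """Bayesian node posteriors under an ER Mk model.

    Metropolis–Hastings on log(q) with an exponential prior on q whose
    mean defaults to 100/tree-depth (so that q × depth/100 has prior
    mean 1).  The proposal is Gaussian on log(q) with scale adapted
    toward 20–40% acceptance during burn-in, then frozen.  Node
    posteriors are Rao–Blackwellized: the exact marginal conditional at
    each retained sampled rate, averaged.  Identical seeds give
    bit-identical output.
    """
    if parameterization != "ER":
        raise AsrError("Bayesian sampler implemented for the ER model")
    _check_coding(tree, coding)
    _branch_lengths_ok(tree)

    if prior_mean is None:
        depth = tree.depth()
        prior_mean = 100.0 / depth if depth > 0 else 1.0

    rng = np.random.default_rng(mcmc.seed)
    burn = int(mcmc.iterations * mcmc.burn_in_fraction)
    prior_vec = MkModel(k, "ER", np.array([1.0]), root_prior).prior_vector()
    engine = _ErEngine(tree, coding, k, prior_vec)

    def log_post(logq: float) -> float:
        q = math.exp(logq)
        # exponential prior density + Jacobian of the log transform
        return engine.loglik(q) - q / prior_mean + logq

    logq = math.log(prior_mean)
    lp = log_post(logq)
    scale = 0.5
    samples: list[float] = []
    accepted_post = 0
    proposed_post = 0
    window_acc = 0
    window_n = 0

    marg_sum: Optional[dict[int, np.ndarray]] = None
    n_retained = 0

    for it in range(mcmc.iterations):
        prop = logq + scale * rng.standard_normal()
        lp_prop = log_post(prop)
        accept = math.log(rng.uniform()) < lp_prop - lp if lp_prop > -np.inf else False
        if accept:
            logq, lp = prop, lp_prop
        if it < burn:
            window_acc += int(accept)
            window_n += 1
            if window_n == 100:  # adapt toward 20-40% acceptance, frozen after burn-in
                rate = window_acc / window_n
                if rate < 0.2:
                    scale *= 0.8
                elif rate > 0.4:
                    scale *= 1.25
                window_acc = window_n = 0
        else:
            proposed_post += 1
            accepted_post += int(accept)
            samples.append(logq)
            if (it - burn) % mcmc.thin == 0:
                model = MkModel(k, "ER", np.array([math.exp(logq)]), root_prior)
                marg = marginal_asr_ml(tree, coding, model).node_states
                if marg_sum is None:
                    marg_sum = {nid: v.copy() for nid, v in marg.items()}
                else:
                    for nid, v in marg.items():
                        marg_sum[nid] += v
                n_retained += 1

    assert marg_sum is not None and n_retained > 0
    node_states = {nid: v / n_retained for nid, v in marg_sum.items()}
    # renormalize away accumulated float error
    node_states = {nid: v / v.sum() for nid, v in node_states.items()}

    q_chain = np.exp(np.asarray(samples))
    import arviz  # heavy import kept local

    ess = float(arviz.ess(np.asarray(samples)[None, :]))
    acc_rate = accepted_post / max(proposed_post, 1)

    return AsrResult(
        method="MB",
        tree=tree,
        node_states=node_states,
        branch_mode=tree.branch_mode,
        model=MkModel(k, "ER", np.array([float(np.mean(q_chain))]), root_prior),
        diagnostics={
            "ess_rate": ess,
            "low_ess_warning": bool(ess < 100),
            "acceptance_rate": acc_rate,
            "proposal_scale": scale,
            "n_retained": n_retained,
            "prior_mean_rate": prior_mean,
            "posterior_mean_rate": float(np.mean(q_chain)),
            "seed": mcmc.seed,
            "iterations": mcmc.iterations,
            "burn_in_fraction": mcmc.burn_in_fraction,
            "thin": mcmc.thin,
        },
    )
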