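"""Random-walk flow, the two-level map equation, and module detection.

The decomposition model: an infinite random walk over the directed weighted
network (PageRank-style, teleport rate tau, dangling nodes teleport with
probability 1) induces node visit rates p_i and per-link flows
f(s, t) = (1 - tau) p_s W[s, t] / s_out(s).  A two-level code describes the
walk with one index codebook over modules and one codebook per module; the
map equation gives its per-step description length in bits,

    L(M) = q H(Q) + sum_m p_m H(P_m),

with q_m the flow exiting module m (cross-module link flow plus the
teleportation share landing outside m), q = sum q_m, H(Q) the entropy of
{q_m / q}, and H(P_m) the entropy of module m's codebook {q_m, p_i : i in m}
normalised by p_m = q_m + sum_{i in m} p_i.  Minimising L over partitions
(greedy node moves plus module agglomeration, repeated from shuffled orders)
yields the modular decomposition; module flow sums rank the modules.

Teleportation here is *recorded* and uniform over nodes, so with all nodes
in one module the exit flow vanishes and L reduces exactly to the entropy of
the visit rates.

A weighted Louvain modularity decomposition (on the symmetrised matrix) is
provided for comparison, along with undirected and directed modularity Q.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

from .connectome import Connectome

__all__ = [
    "FlowField",
    "Partition",
    "stationary_flow",
    "codelength",
    "optimize_partition",
    "modularity",
    "louvain_partition",
    "top_flow_links",
    "MapEquation",
    "LouvainCommunities",
]

_EPS = 1e-12


# ---------------------------------------------------------------------------
# stationary flow
# ---------------------------------------------------------------------------


@dataclass
class FlowField:
    """Stationary visit rates and per-link probability flows.

    ``node_flow`` sums to 1; ``link_flow[s, t]`` is the stationary rate of
    walk steps along the link, and for a non-dangling node the out-link
    flows sum to ``(1 - teleport) * node_flow``.
    """

    labels: list[str]
    node_flow: np.ndarray
    link_flow: np.ndarray
    teleport: float
    dangling: np.ndarray  # bool: zero out-strength
    n_iterations: int = 0

    @property
    def n_nodes(self) -> int:
        return len(self.labels)


def stationary_flow(
    c: Connectome,
    teleport: float = 0.15,
    method: str = "power",
    tol: float = 1e-12,
    max_iter: int = 200_000,
) -> FlowField:
    """Solve the stationary distribution of the teleporting random walk.

    With probability ``1 - teleport`` the walker follows out-links of its
    current node proportionally to weight; with probability ``teleport``
    (probability 1 from a dangling node) it jumps uniformly over all nodes.

    ``method="power"`` iterates to an L1 residual below ``tol``;
    ``method="direct"`` solves the linear stationarity system.  Both agree
    to ~1e-10 on well-posed inputs.
    """
    W = c.W
    n = c.n_nodes
    if not (0 < teleport < 1):
        raise ValueError("teleport rate must lie strictly between 0 and 1")
    if c.n_links == 0:
        raise ValueError("connectome has no links; stationary flow undefined")
    s_out = W.sum(axis=1)
    dangling = s_out == 0
    P = np.zeros_like(W)
    nd = ~dangling
    P[nd] = W[nd] / s_out[nd, None]

    n_iter = 0
    if method == "power":
        p = np.full(n, 1.0 / n)
        for n_iter in range(1, max_iter + 1):
            jump = teleport * p[nd].sum() + p[dangling].sum()
            p_new = (1 - teleport) * (p[nd] @ P[nd]) + jump / n
            if np.abs(p_new - p).sum() < tol:
                p = p_new
                break
            p = p_new
        else:
            raise RuntimeError(
                f"power iteration did not converge in {max_iter} steps "
                "(pathological input?)"
            )
    elif method == "direct":
        # p = M^T p with sum(p) = 1; M[i, :] = (1-tau) P[i] + tau_i / n
        tau_i = np.where(dangling, 1.0, teleport)
        M = (1 - teleport) * P + (tau_i / n)[:, None]
        M[dangling] = 1.0 / n
        A = M.T - np.eye(n)
        A[-1, :] = 1.0
        b = np.zeros(n)
        b[-1] = 1.0
        p = np.linalg.solve(A, b)
    else:
        raise ValueError(f"unknown method {method!r}")

    p = np.clip(p, 0.0, None)
    p = p / p.sum()
    F = np.zeros_like(W)
    F[nd] = (1 - teleport) * p[nd, None] * P[nd]
    return FlowField(
        labels=list(c.labels),
        node_flow=p,
        link_flow=F,
        teleport=teleport,
        dangling=dangling,
        n_iterations=n_iter,
    )


# ---------------------------------------------------------------------------
# map-equation codelength
# ---------------------------------------------------------------------------


def _plogp(x: np.ndarray | float) -> np.ndarray | float:
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = x[pos] * np.log2(x[pos])
    return out if out.ndim else float(out)


def _module_stats(
    a: np.ndarray,
    p: np.ndarray,
    tele_p: np.ndarray,
    outflow: np.ndarray,
    links: tuple[np.ndarray, np.ndarray, np.ndarray],
    n_mod: int,
):
    """Aggregate per-module size, flow, teleport mass, out-flow and exit flow."""
    n = len(p)
    ss, tt, ff = links
    n_m = np.bincount(a, minlength=n_mod).astype(float)
    p_m = np.bincount(a, weights=p, minlength=n_mod)
    tele_m = np.bincount(a, weights=tele_p, minlength=n_mod)
    out_m = np.bincount(a, weights=outflow, minlength=n_mod)
    same = a[ss] == a[tt]
    within_m = np.bincount(a[ss[same]], weights=ff[same], minlength=n_mod)
    q_m = tele_m * (n - n_m) / n + out_m - within_m
    q_m = np.clip(q_m, 0.0, None)
    return n_m, p_m, q_m


def _L_from_q(p: np.ndarray, p_m: np.ndarray, q_m: np.ndarray) -> float:
    q = q_m.sum()
    pout = p_m + q_m
    return float(
        _plogp(q)
        - 2 * np.sum(_plogp(q_m))
        + np.sum(_plogp(pout))
        - np.sum(_plogp(p))
    )


def _codelength_of(flow: FlowField, a: np.ndarray) -> float:
    p = flow.node_flow
    tele_prob = np.where(flow.dangling, 1.0, flow.teleport)
    tele_p = tele_prob * p
    outflow = flow.link_flow.sum(axis=1)
    ss, tt = np.nonzero(flow.link_flow)
    ff = flow.link_flow[ss, tt]
    a = np.asarray(a, dtype=int)
    # compress module ids
    uniq, a_c = np.unique(a, return_inverse=True)
    n_m, p_m, q_m = _module_stats(a_c, p, tele_p, outflow, (ss, tt, ff), len(uniq))
    if np.any(n_m == 0):
        raise ValueError("empty module in partition")
    return _L_from_q(p, p_m, q_m)


def codelength(flow: FlowField, partition) -> float:
    """Two-level map-equation description length, in bits.

    ``partition`` may be a :class:`Partition`, a dict label -> module id, or
    an integer array aligned with ``flow.labels``.  Every node carried by the
    flow field must be assigned.
    """
    if isinstance(partition, Partition):
        lut = {lab: m for lab, m in zip(partition.labels, partition.modules)}
        a = np.array([lut[lab] for lab in flow.labels], dtype=int)
    elif isinstance(partition, dict):
        a = np.array([partition[lab] for lab in flow.labels], dtype=int)
    else:
        a = np.asarray(partition, dtype=int)
        if a.shape != (flow.n_nodes,):
            raise ValueError("partition array length mismatch")
    if np.any(a < 0):
        raise ValueError("all flow-carrying nodes must be assigned to a module")
    return _codelength_of(flow, a)


# ---------------------------------------------------------------------------
# codelength optimisation (InfoMap-style greedy search)
# ---------------------------------------------------------------------------


class _SearchState:
    """Mutable partition with O(degree) codelength deltas for node moves."""

    def __init__(self, flow: FlowField, rng: np.random.Generator):
        self.n = flow.n_nodes
        self.p = flow.node_flow
        tele_prob = np.where(flow.dangling, 1.0, flow.teleport)
        self.tele_p = tele_prob * self.p
        self.outflow = flow.link_flow.sum(axis=1)
        ss, tt = np.nonzero(flow.link_flow)
        ff = flow.link_flow[ss, tt]
        self.links = (ss, tt, ff)
        self.out_nbr: list[tuple[np.ndarray, np.ndarray]] = [()] * self.n  # type: ignore
        self.in_nbr: list[tuple[np.ndarray, np.ndarray]] = [()] * self.n  # type: ignore
        for v in range(self.n):
            m_out = ss == v
            m_in = tt == v
            self.out_nbr[v] = (tt[m_out], ff[m_out])
            self.in_nbr[v] = (ss[m_in], ff[m_in])
        self.node_term = -float(np.sum(_plogp(self.p)))
        self.rng = rng
        self.reset_singletons()

    # -- state initialisation -------------------------------------------
    def reset_singletons(self) -> None:
        n = self.n
        self.a = np.arange(n)
        self.mod_n = np.ones(n)
        self.mod_p = self.p.copy()
        self.mod_tele = self.tele_p.copy()
        self.mod_out = self.outflow.copy()
        self.mod_within = np.zeros(n)
        self._refresh_caches()

    def set_assignment(self, a: np.ndarray) -> None:
        uniq, a_c = np.unique(a, return_inverse=True)
        k = len(uniq)
        n = self.n
        self.a = a_c.copy()
        self.mod_n = np.zeros(n)
        self.mod_p = np.zeros(n)
        self.mod_tele = np.zeros(n)
        self.mod_out = np.zeros(n)
        self.mod_within = np.zeros(n)
        self.mod_n[:k] = np.bincount(a_c, minlength=k)
        self.mod_p[:k] = np.bincount(a_c, weights=self.p, minlength=k)
        self.mod_tele[:k] = np.bincount(a_c, weights=self.tele_p, minlength=k)
        self.mod_out[:k] = np.bincount(a_c, weights=self.outflow, minlength=k)
        ss, tt, ff = self.links
        same = a_c[ss] == a_c[tt]
        w = np.bincount(a_c[ss[same]], weights=ff[same], minlength=k)
        self.mod_within[:k] = w
        self._refresh_caches()

    def _refresh_caches(self) -> None:
        self.q_m = self._q(self.mod_n, self.mod_tele, self.mod_out, self.mod_within)
        self.q_m[self.mod_n == 0] = 0.0
        self.pout_m = np.where(self.mod_n > 0, self.mod_p + self.q_m, 0.0)
        self.q_tot = float(self.q_m.sum())
        self.S1 = float(np.sum(_plogp(self.q_m)))
        self.S2 = float(np.sum(_plogp(self.pout_m)))

    def _q(self, n_m, tele_m, out_m, within_m):
        return np.clip(tele_m * (self.n - n_m) / self.n + out_m - within_m, 0.0, None)

    @property
    def L(self) -> float:
        return float(_plogp(self.q_tot)) - 2 * self.S1 + self.S2 + self.node_term

    # -- node moves ------------------------------------------------------
    def _flows_to_modules(self, v: int) -> dict[int, float]:
        acc: dict[int, float] = {}
        tt, ft = self.out_nbr[v]
        for j, f in zip(tt, ft):
            m = self.a[j]
            acc[m] = acc.get(m, 0.0) + f
        ss, fs = self.in_nbr[v]
        for j, f in zip(ss, fs):
            m = self.a[j]
            acc[m] = acc.get(m, 0.0) + f
        return acc

    def _module_delta(self, m: int, dn, dp, dtele, dout, dwithin):
        """New (q, pout) of module m after adding the deltas."""
        n_new = self.mod_n[m] + dn
        if n_new <= 0:
            return 0.0, 0.0, 0.0
        q_new = max(
            (self.mod_tele[m] + dtele) * (self.n - n_new) / self.n
            + (self.mod_out[m] + dout)
            - (self.mod_within[m] + dwithin),
            0.0,
        )
        p_new = self.mod_p[m] + dp
        return q_new, p_new + q_new, p_new

    def try_moves(self, order: np.ndarray) -> int:
        """One pass of best single-node moves; returns number of moves made."""
        moves = 0
        for v in order:
            a0 = int(self.a[v])
            fmod = self._flows_to_modules(v)
            f_a = fmod.get(a0, 0.0)
            # state of module a0 after v leaves
            qa_new, pouta_new, _ = self._module_delta(
                a0, -1, -self.p[v], -self.tele_p[v], -self.outflow[v], -f_a
            )
            base_dS1 = _plogp(qa_new) - _plogp(self.q_m[a0])
            base_dS2 = _plogp(pouta_new) - _plogp(self.pout_m[a0])
            base_dq = qa_new - self.q_m[a0]

            candidates = [m for m in fmod if m != a0]
            if self.mod_n[a0] > 1:
                candidates.append(self._free_module())
            best_dL, best_b, best_fb = -1e-10, None, 0.0
            for b in candidates:
                f_b = fmod.get(b, 0.0)
                qb_new, poutb_new, _ = self._module_delta(
                    b, +1, self.p[v], self.tele_p[v], self.outflow[v], f_b
                )
                dq = base_dq + qb_new - self.q_m[b]
                dS1 = base_dS1 + _plogp(qb_new) - _plogp(self.q_m[b])
                dS2 = base_dS2 + _plogp(poutb_new) - _plogp(self.pout_m[b])
                dL = (
                    float(_plogp(self.q_tot + dq))
                    - float(_plogp(self.q_tot))
                    - 2 * dS1
                    + dS2
                )
                if dL < best_dL:
                    best_dL, best_b, best_fb = dL, b, f_b
            if best_b is not None:
                self._apply_move(v, a0, int(best_b), f_a, best_fb)
                moves += 1
        return moves

    def _free_module(self) -> int:
        empty = np.nonzero(self.mod_n == 0)[0]
        return int(empty[0])

    def _apply_move(self, v: int, a0: int, b: int, f_a: float, f_b: float) -> None:
        for m, sgn, f in ((a0, -1.0, f_a), (b, +1.0, f_b)):
            self.q_tot -= self.q_m[m]
            self.S1 -= _plogp(self.q_m[m])
            self.S2 -= _plogp(self.pout_m[m])
            self.mod_n[m] += sgn
            self.mod_p[m] += sgn * self.p[v]
            self.mod_tele[m] += sgn * self.tele_p[v]
            self.mod_out[m] += sgn * self.outflow[v]
            self.mod_within[m] += sgn * f
            if self.mod_n[m] > 0:
                q = max(
                    self.mod_tele[m] * (self.n - self.mod_n[m]) / self.n
                    + self.mod_out[m]
                    - self.mod_within[m],
                    0.0,
                )
                self.q_m[m] = q
                self.pout_m[m] = self.mod_p[m] + q
            else:
                self.q_m[m] = 0.0
                self.pout_m[m] = 0.0
            self.q_tot += self.q_m[m]
            self.S1 += _plogp(self.q_m[m])
            self.S2 += _plogp(self.pout_m[m])
        self.a[v] = b

    # -- module merges ---------------------------------------------------
    def try_merges(self) -> int:
        """Greedy best-pair module merges; returns number of merges."""
        merges = 0
        while True:
            active = np.nonzero(self.mod_n > 0)[0]
            if len(active) < 2:
                return merges
            ss, tt, ff = self.links
            cross = {}
            a = self.a
            for s, t, f in zip(a[ss], a[tt], ff):
                if s != t:
                    key = (min(s, t), max(s, t))
                    cross[key] = cross.get(key, 0.0) + f
            best = None
            for (m1, m2), f12 in cross.items():
                n_new = self.mod_n[m1] + self.mod_n[m2]
                tele = self.mod_tele[m1] + self.mod_tele[m2]
                out = self.mod_out[m1] + self.mod_out[m2]
                within = self.mod_within[m1] + self.mod_within[m2] + f12
                q_new = max(tele * (self.n - n_new) / self.n + out - within, 0.0)
                p_new = self.mod_p[m1] + self.mod_p[m2]
                dq = q_new - self.q_m[m1] - self.q_m[m2]
                dS1 = _plogp(q_new) - _plogp(self.q_m[m1]) - _plogp(self.q_m[m2])
                dS2 = (
                    _plogp(p_new + q_new)
                    - _plogp(self.pout_m[m1])
                    - _plogp(self.pout_m[m2])
                )
                dL = (
                    float(_plogp(self.q_tot + dq))
                    - float(_plogp(self.q_tot))
                    - 2 * dS1
                    + dS2
                )
                if dL < -1e-10 and (best is None or dL < best[0]):
                    best = (dL, m1, m2)
            if best is None:
                return merges
            _, m1, m2 = best
            new_a = self.a.copy()
            new_a[new_a == m2] = m1
            self.set_assignment(new_a)
            merges += 1

    def optimise(self) -> None:
        while True:
            moved = 0
            for _ in range(200):
                m = self.try_moves(self.rng.permutation(self.n))
                moved += m
                if m == 0:
                    break
            if self.try_merges() == 0 and moved == 0:
                return


def _optimise_flow(
    flow: FlowField, n_trials: int, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    """Best assignment over ``n_trials`` shuffled restarts."""
    best_a, best_L = None, np.inf
    state = _SearchState(flow, rng)
    one_module_L = _codelength_of(flow, np.zeros(flow.n_nodes, dtype=int))
    for _ in range(max(1, n_trials)):
        state.reset_singletons()
        state.optimise()
        a = state.a.copy()
        L = _codelength_of(flow, a)  # recompute from scratch: guards drift
        if L < best_L - _EPS:
            best_L, best_a = L, a
    if best_L > one_module_L + _EPS:  # never worse than the trivial partition
        best_L = one_module_L
        best_a = np.zeros(flow.n_nodes, dtype=int)
    uniq, a_c = np.unique(best_a, return_inverse=True)
    return a_c, float(best_L)


# ---------------------------------------------------------------------------
# partitions
# ---------------------------------------------------------------------------


@dataclass
class Partition:
    """A node -> module assignment with per-module flow and codelength.

    Module ids are 0..K-1 ordered by descending module flow when flow is
    available; orphans (nodes without any measured link, hence zero walk
    flow) carry id -1 and are listed in ``orphans``.
    """

    labels: list[str]
    modules: np.ndarray
    module_flow: np.ndarray | None = None
    codelength: float | None = None
    modularity: float | None = None
    node_flow: np.ndarray | None = None
    orphans: list[str] = field(default_factory=list)
    degenerate: bool = False
    seed: int | None = None

    @property
    def n_modules(self) -> int:
        return int(self.modules.max()) + 1 if np.any(self.modules >= 0) else 0

    def as_dict(self) -> dict[str, int]:
        return {lab: int(m) for lab, m in zip(self.labels, self.modules)}

    def members(self, module: int) -> list[str]:
        return [lab for lab, m in zip(self.labels, self.modules) if m == module]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"label": self.labels, "module": self.modules})
        if self.node_flow is not None:
            df["node_flow"] = self.node_flow
        return df


class MapEquation(ClusterMixin, BaseEstimator):
    """Map-equation (InfoMap-style) module detection for directed weighted graphs.

    Parameters
    ----------
    teleport : float, default 0.15
        Random-walk teleportation rate (recorded, uniform over nodes);
        dangling nodes teleport with probability 1.
    n_trials : int, default 100
        Number of shuffled greedy restarts; the lowest-codelength partition
        is kept.
    random_state : int or None
        Seed for the shuffle order; fixed seed gives a fixed result.

    Attributes
    ----------
    labels_ : ndarray of int
        Module id per node, -1 for orphans (nodes with no links at all).
    codelength_ : float
        Map-equation description length of the best partition, bits.
    node_flow_ : ndarray
        Stationary visit rates (0 for orphans).
    module_flow_ : ndarray
        Total visit rate per module, descending.
    orphans_ : ndarray of int
        Indices of orphan nodes.
    """

    def __init__(
        self,
        teleport: float = 0.15,
        n_trials: int = 100,
        random_state: int | None = None,
    ):
        self.teleport = teleport
        self.n_trials = n_trials
        self.random_state = random_state

    def fit(self, X, y=None):
        W = np.asarray(X, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("X must be a square adjacency matrix (rows=sources)")
        if np.any(W < 0):
            raise ValueError("negative weights")
        n = W.shape[0]
        if n < 2:
            raise ValueError("need at least 2 nodes")
        deg = W.sum(axis=0) + W.sum(axis=1)
        active = np.nonzero(deg > 0)[0]
        orphans = np.nonzero(deg == 0)[0]
        labels = np.full(n, -1, dtype=int)
        node_flow = np.zeros(n)
        if len(active) == 0:
            raise ValueError("graph has no links")
        sub = Connectome(
            labels=[f"n{i}" for i in active],
            W=W[np.ix_(active, active)],
            weight_kind="LNe",
        )
        flow = stationary_flow(sub, teleport=self.teleport)
        rng = np.random.default_rng(self.random_state)
        a, L = _optimise_flow(flow, self.n_trials, rng)
        # renumber modules by descending flow
        k = int(a.max()) + 1
        mflow = np.bincount(a, weights=flow.node_flow, minlength=k)
        order = np.argsort(-mflow, kind="stable")
        rank = np.empty(k, dtype=int)
        rank[order] = np.arange(k)
        labels[active] = rank[a]
        node_flow[active] = flow.node_flow
        self.labels_ = labels
        self.codelength_ = L
        self.node_flow_ = node_flow
        self.module_flow_ = mflow[order]
        self.n_modules_ = k
        self.orphans_ = orphans
        self.flow_ = flow
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


class LouvainCommunities(ClusterMixin, BaseEstimator):
    """Weighted Louvain modularity decomposition on the symmetrised matrix.

    Delegates to :func:`networkx.algorithms.community.louvain_communities`
    with default resolution; ``degenerate_`` flags the case where the method
    fails to decompose the network (a single module), as happens on
    binarised cortical matrices.
    """

    def __init__(self, weighted: bool = True, random_state: int | None = None):
        self.weighted = weighted
        self.random_state = random_state

    def fit(self, X, y=None):
        W = np.asarray(X, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("X must be a square adjacency matrix")
        n = W.shape[0]
        if n < 2:
            raise ValueError("need at least 2 nodes")
        Ws = (W + W.T) / 2.0
        if not self.weighted:
            Ws = (Ws > 0).astype(float)
        G = nx.from_numpy_array(Ws)  # undirected, weight attribute set
        comms = nx.algorithms.community.louvain_communities(
            G, weight="weight", seed=self.random_state
        )
        comms = sorted(comms, key=lambda s: (-len(s), min(s)))
        labels = np.zeros(n, dtype=int)
        for m, members in enumerate(comms):
            for v in members:
                labels[v] = m
        self.labels_ = labels
        self.n_modules_ = len(comms)
        self.modularity_ = modularity_matrix(W, labels, variant="undirected")
        self.degenerate_ = self.n_modules_ <= 1
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def optimize_partition(
    c: Connectome,
    teleport: float = 0.15,
    n_trials: int = 100,
    seed: int | None = None,
) -> Partition:
    """Minimise the two-level map equation over partitions of the connectome.

    Greedy node-moving plus module-agglomeration passes from ``n_trials``
    shuffled starting orders; the lowest-codelength result is returned with
    modules numbered by descending probability flow.  Nodes without any
    links are reported as orphans (module -1, zero flow).
    """
    est = MapEquation(teleport=teleport, n_trials=n_trials, random_state=seed).fit(c.W)
    return Partition(
        labels=list(c.labels),
        modules=est.labels_,
        module_flow=est.module_flow_,
        codelength=est.codelength_,
        node_flow=est.node_flow_,
        orphans=[c.labels[i] for i in est.orphans_],
        seed=seed,
    )


def louvain_partition(
    c: Connectome, seed: int | None = None, weighted: bool = True
) -> Partition:
    """Weighted Louvain decomposition (undirected Q); all nodes assigned."""
    est = LouvainCommunities(weighted=weighted, random_state=seed).fit(c.W)
    return Partition(
        labels=list(c.labels),
        modules=est.labels_,
        modularity=est.modularity_,
        degenerate=est.degenerate_,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# modularity
# ---------------------------------------------------------------------------


def modularity_matrix(W: np.ndarray, labels: np.ndarray, variant: str = "undirected") -> float:
    """Newman modularity Q of a labelled adjacency matrix.

    undirected (default): W is symmetrised first, then
    Q = sum_m [ e_m / m_tot - (a_m / m_tot)^2 ] with e_m the within-module
    weight and a_m the module strength (m_tot = total weight, both counted
    in the symmetric 2m convention).  directed:
    Q = (1/m_tot) sum_ij [ W_ij - s_out_i s_in_j / m_tot ] delta(c_i, c_j).
    Orphan labels (-1) are treated as singleton modules.
    """
    W = np.asarray(W, dtype=float)
    a = np.asarray(labels, dtype=int).copy()
    next_id = a.max() + 1 if a.size else 0
    for i in np.nonzero(a < 0)[0]:
        a[i] = next_id
        next_id += 1
    if variant == "undirected":
        Ws = (W + W.T) / 2.0
        two_m = Ws.sum()
        if two_m == 0:
            return 0.0
        k = Ws.sum(axis=1)
        Q = 0.0
        for m in np.unique(a):
            mask = a == m
            e_m = Ws[np.ix_(mask, mask)].sum() / two_m
            a_m = k[mask].sum() / two_m
            Q += e_m - a_m**2
        return float(Q)
    if variant == "directed":
        m_tot = W.sum()
        if m_tot == 0:
            return 0.0
        s_out = W.sum(axis=1)
        s_in = W.sum(axis=0)
        delta = a[:, None] == a[None, :]
        return float(((W - np.outer(s_out, s_in) / m_tot) * delta).sum() / m_tot)
    raise ValueError(f"unknown variant {variant!r}")


def modularity(c: Connectome, partition: Partition, variant: str = "undirected") -> float:
    """Modularity Q of a partition of the connectome (see :func:`modularity_matrix`)."""
    lut = {lab: m for lab, m in zip(partition.labels, partition.modules)}
    labels = np.array([lut[lab] for lab in c.labels], dtype=int)
    return modularity_matrix(c.W, labels, variant=variant)


# ---------------------------------------------------------------------------
# link-flow ranking
# ---------------------------------------------------------------------------


def top_flow_links(
    flow: FlowField, fraction: float | None = None, k: int | None = None
) -> pd.DataFrame:
    """Rank links by probability flow, descending.

    Returns the top ``fraction`` of all links (e.g. 0.15 for the top 15%
    highest-traffic links) or the top ``k``; ties are broken by (source,
    target) label order.  Columns: source, target, link_flow.
    """
    if (fraction is None) == (k is None):
        raise ValueError("specify exactly one of fraction or k")
    ss, tt = np.nonzero(flow.link_flow)
    ff = flow.link_flow[ss, tt]
    df = pd.DataFrame(
        {
            "source": [flow.labels[i] for i in ss],
            "target": [flow.labels[j] for j in tt],
            "link_flow": ff,
        }
    )
    df = df.sort_values(
        ["link_flow", "source", "target"], ascending=[False, True, True], kind="stable"
    ).reset_index(drop=True)
    if fraction is not None:
        if not (0 <= fraction <= 1):
            raise ValueError("fraction must lie in [0, 1]")
        k = int(round(fraction * len(df)))
    return df.head(int(k)).reset_index(drop=True)
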