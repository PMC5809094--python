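"""Biogeographic and guild histories, Mk models, stochastic character maps,
and the piecewise interaction matrices A(t) consumed by the competition
models.

A lineage here is an edge of the tree, identified by the canonical id of the
edge's child node (see :mod:`phylocomp.tree`).  Histories are
piecewise-constant segment lists per edge, in the age convention (time
before present, My): a segment runs from ``t_start_age`` (older) down to
``t_end_age`` (younger).  Segments must tile each edge exactly.

The interaction matrix A(t) is binary and symmetric: two lineages interact
at time t when both are alive, their region sets intersect, and both belong
to the focal guild.  Lineages outside the focal guild (or with no sympatric
guild member) evolve as if in allopatry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize

from .tree import TimeTree

__all__ = [
    "RegionHistory",
    "GuildHistory",
    "MkModel",
    "InteractionTimeline",
    "fit_mk_ard",
    "mk_loglik",
    "sample_stochastic_maps",
    "build_timeline",
    "pairwise_congruence",
    "write_history",
    "read_history",
]

REGION_CODES = tuple("abcdefghij")

_AGE_TOL = 1e-9


# -- histories -------------------------------------------------------------


class _SegmentHistory:
    """Base container: per-edge list of (t_start_age, t_end_age, payload)."""

    def __init__(self, tree: TimeTree, segments: dict):
        self.tree = tree
        self.segments = {int(k): sorted(v, key=lambda s: -s[0]) for k, v in segments.items()}
        self._validate()

    def _validate(self):
        tree = self.tree
        tol = max(_AGE_TOL, 1e-9 * tree.root_age)
        n_nodes = 2 * tree.n_tips - 1
        for c in range(n_nodes):
            if c == tree.root:
                continue
            top = tree.age[tree.parent[c]]
            bot = tree.age[c]
            segs = self.segments.get(c)
            if not segs:
                raise ValueError(f"history does not cover edge above node {c}")
            if abs(segs[0][0] - top) > tol or abs(segs[-1][1] - bot) > tol:
                raise ValueError(
                    f"history segments do not tile edge above node {c}: "
                    f"span [{segs[0][0]:.6g}, {segs[-1][1]:.6g}] vs edge "
                    f"[{top:.6g}, {bot:.6g}]"
                )
            for (s0, s1, _), (u0, u1, _) in zip(segs, segs[1:]):
                if s1 < u1 - tol or abs(s1 - u0) > tol:
                    raise ValueError(f"gap/overlap in history on edge above node {c}")

    def state_at(self, lineage: int, age: float):
        """Payload on ``lineage`` at ``age`` (inclusive of segment start)."""
        for s0, s1, payload in self.segments[lineage]:
            if s0 + _AGE_TOL >= age >= s1 - _AGE_TOL:
                return payload
        raise KeyError(f"age {age} outside edge above node {lineage}")

    def change_ages(self) -> np.ndarray:
        """All interior segment boundaries (history change-points)."""
        out = []
        for c, segs in self.segments.items():
            for s in segs[:-1]:
                out.append(s[1])
        return np.array(sorted(set(out), reverse=True))


class RegionHistory(_SegmentHistory):
    """Piecewise-constant region occupancy; payloads are frozensets of codes."""

    def __init__(self, tree, segments, map_id: int = 0):
        segments = {
            k: [(a, b, frozenset(p)) for a, b, p in v] for k, v in segments.items()
        }
        super().__init__(tree, segments)
        self.map_id = map_id
        for c, segs in self.segments.items():
            for _, _, p in segs:
                if not p:
                    raise ValueError(f"empty region set on edge above node {c}")


class GuildHistory(_SegmentHistory):
    """Piecewise-constant guild membership; payloads are state strings."""

    def __init__(self, tree, segments, scheme: str = "custom", map_id: int = 0):
        super().__init__(tree, segments)
        self.scheme = scheme
        self.map_id = map_id


# -- Mk model --------------------------------------------------------------


@dataclass
class MkModel:
    """Continuous-time Markov model of a discrete character (ARD)."""

    states: tuple
    Q: np.ndarray
    log_likelihood: float | None = None
    converged: bool = True

    def __post_init__(self):
        self.Q = np.asarray(self.Q, dtype=float)
        k = len(self.states)
        if self.Q.shape != (k, k):
            raise ValueError("Q shape does not match state count")
        if np.any(self.Q[~np.eye(k, dtype=bool)] < 0):
            raise ValueError("negative off-diagonal rate in Q")
        if np.max(np.abs(self.Q.sum(axis=1))) > 1e-10:
            raise ValueError("Q rows must sum to zero")


def _tip_state_idx(tree, tip_states, states):
    idx = np.empty(tree.n_tips, dtype=int)
    lookup = {s: i for i, s in enumerate(states)}
    for lab in tree.labels:
        if lab not in tip_states:
            raise ValueError(f"tip {lab!r} has no observed state")
        idx[tree.tip_index(lab)] = lookup[tip_states[lab]]
    return idx


def _partials(tree, Q, state_idx, k):
    """Postorder conditional likelihoods, scaled; returns (L, log-scale)."""
    n_nodes = 2 * tree.n_tips - 1
    L = np.zeros((n_nodes, k))
    L[np.arange(tree.n_tips), state_idx] = 1.0
    logscale = 0.0
    P = {}
    for v in tree.postorder():
        if v < tree.n_tips:
            continue
        L[v] = 1.0
        for c in tree.children[v]:
            Pc = expm(Q * tree.length[c])
            P[c] = Pc
            L[v] *= Pc @ L[c]
        s = L[v].sum()
        if s <= 0:
            return L, -np.inf, P
        L[v] /= s
        logscale += np.log(s)
    return L, logscale, P


def mk_loglik(tree: TimeTree, Q: np.ndarray, tip_states: dict, states) -> float:
    """Pruning-algorithm log-likelihood of tip states under ``Q``.

    Root state prior is flat over the alphabet.
    """
    k = len(states)
    idx = _tip_state_idx(tree, tip_states, states)
    L, logscale, _ = _partials(tree, np.asarray(Q, float), idx, k)
    root_lik = L[tree.root].mean()  # flat prior
    if root_lik <= 0 or not np.isfinite(logscale):
        return -np.inf
    return float(np.log(root_lik) + logscale)


def fit_mk_ard(tree: TimeTree, tip_states: dict, n_restarts: int = 3) -> MkModel:
    """MLE of an all-rates-different Mk model by pruning-likelihood search.

    Raises on a single observed state (nothing to fit); a non-converged
    optimizer is flagged on the returned model, never silent.
    """
    states = tuple(sorted(set(tip_states[lab] for lab in tree.labels)))
    k = len(states)
    if k < 2:
        raise ValueError("need at least 2 observed states to fit an Mk model")
    idx = _tip_state_idx(tree, tip_states, states)
    off = ~np.eye(k, dtype=bool)

    def unpack(logr):
        Q = np.zeros((k, k))
        Q[off] = np.exp(logr)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    def nll(logr):
        if np.any(logr > 12):
            return 1e10
        Q = unpack(logr)
        L, logscale, _ = _partials(tree, Q, idx, k)
        root_lik = L[tree.root].mean()
        if root_lik <= 0 or not np.isfinite(logscale):
            return 1e10
        return -(np.log(root_lik) + logscale)

    base = np.log(max(k - 1, 1) / tree.root_age)
    best = None
    rng = np.random.default_rng(0)
    for r in range(n_restarts):
        x0 = np.full(k * (k - 1), base + (r - 1) * 1.5)
        if r > 0:
            x0 = x0 + rng.normal(0, 0.25, size=x0.shape)
        res = minimize(nll, x0, method="L-BFGS-B",
                       bounds=[(-20, 12)] * len(x0),
                       options={"maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    Q = unpack(best.x)
    return MkModel(states=states, Q=Q, log_likelihood=-float(best.fun),
                   converged=bool(best.success))


# -- stochastic maps -------------------------------------------------------


def node_state_posteriors(tree: TimeTree, model: MkModel, tip_states: dict) -> np.ndarray:
    """Exact marginal conditional state distribution at every node.

    Computed by belief propagation (up + down pass) under a flat root prior;
    used both for map sampling and as the enumeration-checkable oracle
    surface in tests.
    """
    k = len(model.states)
    idx = _tip_state_idx(tree, tip_states, model.states)
    L, logscale, P = _partials(tree, model.Q, idx, k)
    n_nodes = 2 * tree.n_tips - 1
    up = np.zeros((n_nodes, k))  # messages from above, incl. prior
    up[tree.root] = 1.0 / k
    post = np.zeros((n_nodes, k))
    for v in tree.preorder():
        post[v] = up[v] * L[v]
        post[v] /= post[v].sum()
        for c in tree.children[v]:
            sibs = np.ones(k)
            for c2 in tree.children[v]:
                if c2 != c:
                    sibs *= P[c2] @ L[c2]
            msg = (up[v] * sibs) @ P[c]
            up[c] = msg / msg.sum()
    return post


def _sample_ctmc_path(rng, Q, states_k, s0, t):
    """Forward-simulate a CTMC path; returns (end state, [(time, state), ...])."""
    path = []
    s, clock = s0, 0.0
    rates = -np.diag(Q)
    while True:
        if rates[s] <= 0:
            break
        w = rng.exponential(1.0 / rates[s])
        if clock + w >= t:
            break
        clock += w
        probs = Q[s].copy()
        probs[s] = 0.0
        probs = probs / probs.sum()
        s = rng.choice(states_k, p=probs)
        path.append((clock, s))
    return s, path


def _uniformization_bridge(rng, Q, a, b, t):
    """Sample a CTMC path conditioned on endpoints via uniformization."""
    k = Q.shape[0]
    omega = max(np.max(-np.diag(Q)), 1e-12) * 1.05
    P = np.eye(k) + Q / omega
    Pt = expm(Q * t)
    if Pt[a, b] <= 0:
        raise RuntimeError("endpoint-conditioned path has zero probability")
    # sample number of (virtual) jumps
    mats = [np.eye(k)]
    logw = -omega * t
    target = rng.random()
    cum, n = 0.0, -1
    term = np.exp(logw)
    while cum < target and n < 10000:
        n += 1
        if n >= len(mats):
            mats.append(mats[-1] @ P)
        pn = term * mats[n][a, b] / Pt[a, b]
        cum += pn
        term *= omega * t / (n + 1)
    times = np.sort(rng.random(n) * t)
    seq = [a]
    for i in range(n):
        rem = n - i - 1
        probs = P[seq[-1]] * mats[rem][:, b]
        probs = probs / probs.sum()
        seq.append(rng.choice(k, p=probs))
    path = [(times[i], seq[i + 1]) for i in range(n) if seq[i + 1] != seq[i]]
    return path


def sample_stochastic_maps(tree: TimeTree, model: MkModel, tip_states: dict,
                           n_maps: int, seed: int, scheme: str = "custom",
                           max_reject: int = 1000) -> list[GuildHistory]:
    """Draw stochastic character maps consistent with the tip data.

    Node states come from exact conditional distributions; branch histories
    by Nielsen-style rejection sampling from the Markov process, falling
    back to uniformization after ``max_reject`` failed attempts on a branch.
    """
    if n_maps < 1:
        raise ValueError("n_maps must be >= 1")
    rng = np.random.default_rng(seed)
    k = len(model.states)
    idx = _tip_state_idx(tree, tip_states, model.states)
    L, _, P = _partials(tree, model.Q, idx, k)
    maps = []
    for m in range(n_maps):
        node_state = {}
        # root
        probs = L[tree.root] / L[tree.root].sum()
        node_state[tree.root] = rng.choice(k, p=probs)
        for v in tree.preorder():
            for c in tree.children[v]:
                pr = P[c][node_state[v]] * L[c]
                pr = pr / pr.sum()
                node_state[c] = rng.choice(k, p=pr)
        segments = {}
        for v in tree.preorder():
            for c in tree.children[v]:
                t = tree.length[c]
                a, b = node_state[v], node_state[c]
                path = None
                for _ in range(max_reject):
                    end, cand = _sample_ctmc_path(rng, model.Q, k, a, t)
                    if end == b:
                        path = cand
                        break
                if path is None:
                    path = _uniformization_bridge(rng, model.Q, a, b, t)
                top = tree.age[v]
                segs, cur, t_prev = [], a, 0.0
                for (tt, s) in path:
                    segs.append((top - t_prev, top - tt, model.states[cur]))
                    cur, t_prev = s, tt
                segs.append((top - t_prev, tree.age[c], model.states[cur]))
                segments[c] = segs
        maps.append(GuildHistory(tree, segments, scheme=scheme, map_id=m))
    return maps


# -- interaction timeline --------------------------------------------------


@dataclass
class InteractionTimeline:
    """Piecewise-constant lineage interaction structure over [0, T].

    ``breakpoints`` are ages, descending from the root age to 0 (length
    m+1 for m intervals).  Per interval: ``alive`` (canonical child-node
    ids, ascending), symmetric 0/1 ``A`` with zero diagonal, sympatric
    counts ``n`` (including self; 1 for non-focal or isolated lineages) and
    ``focal`` membership flags.
    """

    tree: TimeTree
    breakpoints: np.ndarray
    alive: list = field(default_factory=list)
    A: list = field(default_factory=list)
    n: list = field(default_factory=list)
    focal: list = field(default_factory=list)

    @property
    def n_intervals(self):
        return len(self.alive)

    def durations(self) -> np.ndarray:
        return -np.diff(self.breakpoints)

    def interval_at(self, age: float) -> int:
        """Index of the interval containing ``age`` (root-side inclusive)."""
        bp = self.breakpoints
        if age > bp[0] + _AGE_TOL or age < bp[-1] - _AGE_TOL:
            raise ValueError("age outside timeline span")
        i = int(np.searchsorted(-bp, -age, side="right")) - 1
        return min(max(i, 0), self.n_intervals - 1)

    def validate(self):
        for i, (a, A, n, f) in enumerate(zip(self.alive, self.A, self.n, self.focal)):
            if not np.allclose(A, A.T) or np.any(np.diag(A) != 0):
                raise ValueError(f"interval {i}: A not symmetric zero-diagonal")
            nf = 1 + A.sum(axis=1)
            nf[~f] = 1
            if not np.array_equal(nf.astype(int), np.asarray(n, int)):
                raise ValueError(f"interval {i}: n inconsistent with A")
        return self

    # convenience constructors used throughout tests and simulations -------

    @classmethod
    def _from_states(cls, tree, extra_ages, region_at, guild_at, focal_guild):
        ages = set(np.round(tree.age[tree.n_tips:], 12)) | {0.0}
        ages |= set(np.round(np.asarray(extra_ages, float), 12))
        bp = np.array(sorted(a for a in ages if 0.0 <= a <= tree.root_age + _AGE_TOL),
                      dtype=float)[::-1]
        if abs(bp[0] - tree.root_age) > _AGE_TOL:
            bp = np.concatenate([[tree.root_age], bp])
        tl = cls(tree=tree, breakpoints=bp)
        parent = tree.parent
        age = tree.age
        nonroot = [v for v in range(2 * tree.n_tips - 1) if v != tree.root]
        for i in range(len(bp) - 1):
            hi, lo = bp[i], bp[i + 1]
            mid = 0.5 * (hi + lo)
            alive = np.array(sorted(v for v in nonroot
                                    if age[parent[v]] > mid >= age[v]), dtype=int)
            d = len(alive)
            focal = np.array([guild_at(v, mid) == focal_guild for v in alive])
            regions = [region_at(v, mid) for v in alive]
            A = np.zeros((d, d), dtype=int)
            for a_i in range(d):
                if not focal[a_i]:
                    continue
                for b_i in range(a_i + 1, d):
                    if focal[b_i] and regions[a_i] & regions[b_i]:
                        A[a_i, b_i] = A[b_i, a_i] = 1
            n = 1 + A.sum(axis=1)
            n[~focal] = 1
            tl.alive.append(alive)
            tl.A.append(A)
            tl.n.append(n.astype(int))
            tl.focal.append(focal)
        return tl

    @classmethod
    def full_sympatry(cls, tree: TimeTree):
        """Everyone shares one region and one guild (maximal interaction)."""
        one = frozenset({"a"})
        return cls._from_states(tree, [], lambda v, t: one, lambda v, t: "g",
                                focal_guild="g")

    @classmethod
    def full_allopatry(cls, tree: TimeTree):
        """Every lineage in a private region: A == 0 everywhere."""
        return cls._from_states(tree, [], lambda v, t: frozenset({f"r{v}"}),
                                lambda v, t: "g", focal_guild="g")


def build_timeline(tree: TimeTree, regions: RegionHistory, guilds: GuildHistory,
                   focal_guild) -> InteractionTimeline:
    """Combine a region history and a guild history into A(t) intervals.

    Breakpoints are the union of branching events and history change-points;
    within each interval two lineages interact iff their region sets
    intersect and both carry the focal guild state.
    """
    if regions.tree is not tree and regions.tree.labels != tree.labels:
        raise ValueError("region history not defined on this tree")
    if guilds.tree is not tree and guilds.tree.labels != tree.labels:
        raise ValueError("guild history not defined on this tree")
    extra = np.concatenate([regions.change_ages(), guilds.change_ages()]) \
        if (len(regions.change_ages()) or len(guilds.change_ages())) else []
    return InteractionTimeline._from_states(
        tree, extra, regions.state_at, guilds.state_at, focal_guild
    ).validate()


def pairwise_congruence(timelines: list[InteractionTimeline], grid) -> pd.DataFrame:
    """Mean pairwise agreement of sympatry designations through time.

    For each grid age, averages over all timeline pairs the fraction of live
    lineage pairs with identical A_ij.  Returns a frame with the raw profile
    and a smoothed (5-point moving average) curve.
    """
    if len(timelines) < 2:
        raise ValueError("need at least 2 timelines")
    grid = np.asarray(grid, dtype=float)
    vals = np.empty(len(grid))
    for g, age in enumerate(grid):
        agrees = []
        mats = []
        for tl in timelines:
            i = tl.interval_at(age)
            mats.append((tl.alive[i], tl.A[i]))
        for x in range(len(mats)):
            ax, Ax = mats[x]
            for y in range(x + 1, len(mats)):
                ay, Ay = mats[y]
                if not np.array_equal(ax, ay):
                    raise ValueError("timelines not on the same tree/intervals")
                d = len(ax)
                if d < 2:
                    continue
                iu = np.triu_indices(d, 1)
                agrees.append(np.mean(Ax[iu] == Ay[iu]))
        vals[g] = np.mean(agrees) if agrees else np.nan
    out = pd.DataFrame({"age": grid, "congruence": vals})
    out["smoothed"] = out["congruence"].rolling(5, center=True, min_periods=1).mean()
    return out


# -- event-table exchange format ------------------------------------------

_EVENT_COLS = ["lineage_id", "parent_id", "t_start_age", "t_end_age", "payload", "map_id"]


def write_history(histories, path):
    """Write a bank of histories to the event-table TSV format."""
    rows = []
    for h in histories if isinstance(histories, (list, tuple)) else [histories]:
        for c, segs in sorted(h.segments.items()):
            for s0, s1, payload in segs:
                pay = ",".join(sorted(payload)) if isinstance(payload, frozenset) else str(payload)
                rows.append((c, int(h.tree.parent[c]), s0, s1, pay, h.map_id))
    pd.DataFrame(rows, columns=_EVENT_COLS).to_csv(path, sep="\t", index=False)


def read_history(path, tree: TimeTree, kind: str = "region", scheme: str = "custom"):
    """Read an event-table TSV into a bank of Region/Guild histories."""
    df = pd.read_csv(path, sep="\t")
    missing = set(_EVENT_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"event table missing columns {sorted(missing)}")
    out = []
    for map_id, sub in df.groupby("map_id"):
        segments = {}
        for _, row in sub.iterrows():
            payload = (frozenset(str(row.payload).split(","))
                       if kind == "region" else str(row.payload))
            segments.setdefault(int(row.lineage_id), []).append(
                (float(row.t_start_age), float(row.t_end_age), payload))
        if kind == "region":
            out.append(RegionHistory(tree, segments, map_id=int(map_id)))
        else:
            out.append(GuildHistory(tree, segments, scheme=scheme, map_id=int(map_id)))
    return out
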