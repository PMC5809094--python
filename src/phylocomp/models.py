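"""Likelihood core: tip means and covariances under BM, OU, matching
competition (MC) and diversity-dependent (DD) trait evolution, maximum
likelihood fitting, and AICc-based model comparison.

Model contracts
---------------
All five families share a Brownian noise floor sigma dW.  Focal lineages
with at least one sympatric competitor additionally experience, under MC,
a deterministic repulsion ``S * (mu_i - z_i)`` where ``mu_i`` is the mean
trait of the lineages ``j`` with ``A_ij = 1`` (self excluded by default) and
``S <= 0``; under DD the instantaneous rate is ``sigma0^2 + b * n_i(t)``
(linear) or ``sigma0^2 * exp(r * n_i(t))`` (exponential), where ``n_i``
counts the focal lineage itself plus its sympatric guild members.
Non-focal and fully allopatric lineages evolve by plain BM.

Because the drift matrix has zero row sums, the tip expectation is the root
state ``z0`` under every family (OU is fitted with the optimum at the root
state, the convention of standard single-optimum fitters on ultrametric
trees), and the covariance is linear in the overall rate.  Both ``z0`` and
the rate are therefore profiled analytically, reducing each fit to a
bounded one-dimensional search over the structural parameter (S, alpha, b
or r).  Interval propagation of the MC moment ODEs is exact: within each
interaction interval the generator is constant, ``G = S * G0``, and the
parameter-free eigendecomposition of ``G0`` is cached per interval.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

from .interactions import InteractionTimeline
from .tree import TimeTree, phylo_vcv

__all__ = [
    "ModelParams",
    "FitResult",
    "FitComparison",
    "mc_moments",
    "dd_vcv",
    "ou_vcv",
    "subgroup_loglik",
    "model_loglik",
    "fit_model",
    "compare_models",
    "fit_over_maps",
    "FAMILIES",
]

FAMILIES = ("BM", "OU", "MC", "DDlin", "DDexp")
_COMPETITION = ("MC", "DDlin", "DDexp")
_NEUTRAL = ("BM", "OU")

#: AICc parameter counts (z0 included), the geiger/RPANDA convention
K_PARAMS = {"BM": 2, "OU": 3, "MC": 3, "DDlin": 3, "DDexp": 3}

_EXP_CLIP = 600.0


@dataclass
class ModelParams:
    """Parameters of one trait-evolution model family."""

    family: str
    z0: float = 0.0
    sigma2: float | None = None      # BM, OU, MC: diffusion rate
    alpha: float | None = None       # OU: attraction strength (1/My)
    theta: float | None = None       # OU: optimum (defaults to z0)
    S: float | None = None           # MC: competition strength (<= 0)
    sigma0_2: float | None = None    # DD: baseline rate
    b: float | None = None           # DDlin: rate slope per lineage
    r: float | None = None           # DDexp: rate exponent per lineage

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.family in ("BM", "OU", "MC") and self.sigma2 is not None:
            if self.sigma2 < 0:
                raise ValueError("sigma2 must be >= 0")
        if self.family == "OU":
            if self.alpha is None:
                self.alpha = 0.0
            if self.alpha < 0:
                raise ValueError("alpha must be >= 0")
            if self.theta is None:
                self.theta = self.z0
        if self.family == "MC":
            if self.S is None:
                self.S = 0.0
            if self.S > 0:
                raise ValueError("MC strength S must be <= 0")
        if self.family in ("DDlin", "DDexp") and self.sigma0_2 is not None:
            if self.sigma0_2 < 0:
                raise ValueError("sigma0_2 must be >= 0")


@dataclass
class FitResult:
    """One maximum-likelihood fit."""

    params: ModelParams
    loglik: float
    k: int
    n: int
    aicc: float
    converged: bool = True
    restarts: list = field(default_factory=list)

    @property
    def family(self):
        return self.params.family


@dataclass
class FitComparison:
    """Five fits for one trait x subgroup x map, with Akaike weights."""

    fits: dict
    weights: dict
    relative_support: float
    best: str


# -- interval caches -------------------------------------------------------


def _interval_maps(tl: InteractionTimeline):
    """Per-interval source indices for carrying moments across breakpoints."""
    maps = [None]
    for i in range(1, tl.n_intervals):
        prev = {v: j for j, v in enumerate(tl.alive[i - 1])}
        src = np.empty(len(tl.alive[i]), dtype=int)
        for j, v in enumerate(tl.alive[i]):
            if v in prev:
                src[j] = prev[v]
            else:
                p = tl.tree.parent[v]
                if p not in prev:
                    raise ValueError(f"lineage {v} appears without parent in timeline")
                src[j] = prev[p]
        maps.append(src)
    return maps


def _mc_cache(tl: InteractionTimeline, include_self: bool):
    key = ("_mc_cache", include_self)
    cache = getattr(tl, "_caches", None)
    if cache is None:
        cache = {}
        object.__setattr__(tl, "_caches", cache)
    if key in cache:
        return cache[key]
    entries = []
    for i in range(tl.n_intervals):
        A = tl.A[i]
        n = np.asarray(tl.n[i], float)
        d = len(n)
        if A.sum() == 0:
            entries.append(("zero", d))
            continue
        G0 = np.zeros((d, d))
        interacting = n > 1
        if include_self:
            # mu_i averages the clique including self
            G0[interacting, :] = 0.0
            for a in np.nonzero(interacting)[0]:
                G0[a, a] = 1.0 / n[a] - 1.0
                G0[a, A[a] > 0] = 1.0 / n[a]
        else:
            for a in np.nonzero(interacting)[0]:
                G0[a, a] = -1.0
                G0[a, A[a] > 0] = 1.0 / (n[a] - 1.0)
        if np.allclose(G0, G0.T, atol=1e-12):
            w, U = np.linalg.eigh(G0)
            entries.append(("sym", w, U))
        else:
            w, U = np.linalg.eig(G0)
            Uinv = np.linalg.inv(U)
            C = Uinv @ Uinv.T
            entries.append(("gen", w, U, Uinv, C))
    out = (entries, _interval_maps(tl))
    cache[key] = out
    return out


def _dd_cache(tl: InteractionTimeline):
    cache = getattr(tl, "_caches", None)
    if cache is None:
        cache = {}
        object.__setattr__(tl, "_caches", cache)
    if "_dd_cache" in cache:
        return cache["_dd_cache"]
    tree = tl.tree
    n_tips = tree.n_tips
    D = tree.descendant_tips()
    durs = tl.durations()
    acc: dict[int, np.ndarray] = {}
    for i in range(tl.n_intervals):
        dt = durs[i]
        if dt <= 0:
            continue
        for j, v in enumerate(tl.alive[i]):
            cnt = int(tl.n[i][j])
            M = acc.setdefault(cnt, np.zeros((n_tips, n_tips)))
            mask = D[v]
            M[np.ix_(mask, mask)] += dt
    counts = np.array(sorted(acc))
    stack = np.stack([acc[c] for c in counts])
    cache["_dd_cache"] = (counts, stack)
    return counts, stack


def _propagate_mc(entries, maps, S, durations, d0):
    """Unit-noise covariance at the final interval's lineages under MC."""
    V = np.zeros((d0, d0))
    for i, entry in enumerate(entries):
        if i > 0:
            src = maps[i]
            V = V[np.ix_(src, src)]
        dt = durations[i]
        if dt <= 0:
            continue
        kind = entry[0]
        d = V.shape[0]
        if kind == "zero" or S == 0.0:
            V = V + dt * np.eye(d)
            continue
        if kind == "sym":
            _, w, U = entry
            lam = S * w
            ex = np.exp(np.clip(lam * dt, -_EXP_CLIP, _EXP_CLIP))
            B = U.T @ V @ U
            B *= np.multiply.outer(ex, ex)
            Psum = np.add.outer(lam, lam)
            with np.errstate(over="ignore", invalid="ignore"):
                phi = np.where(
                    np.abs(Psum) > 1e-12,
                    (np.exp(np.clip(Psum * dt, -_EXP_CLIP, _EXP_CLIP)) - 1.0) / Psum,
                    dt,
                )
            # C = I for orthogonal U, so the noise term is diagonal in eigenspace
            V = U @ (B + np.diag(np.diag(phi))) @ U.T
            V = 0.5 * (V + V.T)
        else:
            _, w, U, Uinv, C = entry
            lam = S * w
            ex = np.exp(np.clip(lam * dt, -_EXP_CLIP, _EXP_CLIP))
            B = Uinv @ V @ Uinv.T
            B = B * np.multiply.outer(ex, ex)
            Psum = np.add.outer(lam, lam)
            with np.errstate(over="ignore", invalid="ignore"):
                phi = np.where(
                    np.abs(Psum) > 1e-12,
                    (np.exp(np.clip(Psum * dt, -_EXP_CLIP, _EXP_CLIP)) - 1.0) / Psum,
                    dt,
                )
            W = C * phi
            V = (U @ (B + W) @ U.T).real
            V = 0.5 * (V + V.T)
    return V


# -- moments / covariances -------------------------------------------------


def mc_unit_cov(tree: TimeTree, timeline: InteractionTimeline, S: float,
                include_self: bool = False) -> np.ndarray:
    """Tip covariance under MC with unit diffusion rate (sigma^2 = 1)."""
    if S > 0:
        raise ValueError("MC strength S must be <= 0")
    if timeline.tree is not tree:
        if timeline.tree.labels != tree.labels:
            raise ValueError("timeline not defined on this tree")
    entries, maps = _mc_cache(timeline, include_self)
    durations = timeline.durations()
    V = _propagate_mc(entries, maps, float(S), durations, len(timeline.alive[0]))
    # final interval lineages are the pendant edges == canonical tip order
    order = np.argsort(timeline.alive[-1])
    return V[np.ix_(order, order)]


def mc_moments(tree: TimeTree, timeline: InteractionTimeline, S: float,
               sigma2: float, z0: float, include_self: bool = False):
    """Tip mean vector and covariance under the matching-competition model.

    The drift matrix has zero row sums, so the mean stays at ``z0`` for
    every lineage; the covariance solves the piecewise-constant Lyapunov
    system exactly (matrix-exponential propagation per interval).
    """
    V = sigma2 * mc_unit_cov(tree, timeline, S, include_self)
    m = np.full(tree.n_tips, float(z0))
    return m, V


def dd_unit_cov(tree: TimeTree, timeline: InteractionTimeline, slope: float,
                form: str) -> np.ndarray:
    """Tip covariance under DD with baseline rate 1.

    ``slope`` is ``b / sigma0^2`` for the linear form and ``r`` for the
    exponential form.
    """
    counts, stack = _dd_cache(timeline)
    if form == "lin":
        rates = 1.0 + slope * counts
        if np.any(rates <= 0):
            raise ValueError(
                f"negative DDlin rate at lineage count {counts[rates <= 0][0]}"
            )
    elif form == "exp":
        rates = np.exp(np.clip(slope * counts, -_EXP_CLIP, _EXP_CLIP))
    else:
        raise ValueError(f"unknown DD form {form!r}")
    return np.tensordot(rates, stack, axes=1)


def dd_vcv(tree: TimeTree, timeline: InteractionTimeline, sigma0_2: float,
           slope: float, form: str) -> np.ndarray:
    """Tip covariance under diversity-dependent rates (mean is ``z0``).

    Linear form: instantaneous rate ``sigma0^2 + slope * n_i(t)``;
    exponential form: ``sigma0^2 * exp(slope * n_i(t))``.  Each pair's
    covariance integrates the ancestral lineage's rate along the shared
    root-to-MRCA path (root-to-tip for the variances).
    """
    if sigma0_2 <= 0:
        raise ValueError("sigma0_2 must be positive")
    if form == "lin":
        return sigma0_2 * dd_unit_cov(tree, timeline, slope / sigma0_2, form)
    return sigma0_2 * dd_unit_cov(tree, timeline, slope, form)


def ou_unit_cov(tree: TimeTree, alpha: float, C: np.ndarray | None = None) -> np.ndarray:
    """OU tip covariance with sigma^2 = 1 (single optimum, ultrametric)."""
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if C is None:
        C = phylo_vcv(tree)
    if alpha < 1e-9:
        # BM limit; first-order series keeps the fit surface smooth
        T = tree.root_age
        return C * (1.0 - alpha * (2.0 * T - C))
    T = tree.root_age
    return (1.0 / (2.0 * alpha)) * np.exp(-2.0 * alpha * (T - C)) * (
        1.0 - np.exp(-2.0 * alpha * C)
    )


def ou_vcv(tree: TimeTree, sigma2: float, alpha: float, theta: float, z0: float):
    """Mean and covariance of a single-optimum OU process at the tips.

    ``m_i = theta + (z0 - theta) * exp(-alpha T)``; covariance per the
    standard ultrametric formula, with the alpha -> 0 limit equal to BM.
    """
    V = sigma2 * ou_unit_cov(tree, alpha)
    m = np.full(tree.n_tips, theta + (z0 - theta) * np.exp(-alpha * tree.root_age))
    return m, V


# -- likelihood ------------------------------------------------------------


def subgroup_loglik(x: np.ndarray, m: np.ndarray, V: np.ndarray, focal_idx) -> float:
    """Multivariate-normal log density of trait values on the focal tips.

    ``V`` is computed on the full tree; tips outside the focal subgroup and
    tips with missing data are dropped from ``x``, ``m`` and ``V`` before
    evaluating the density (restriction equals marginalization for a MVN).
    """
    x = np.asarray(x, float)
    focal_idx = np.asarray(focal_idx)
    if focal_idx.dtype == bool:
        focal_idx = np.nonzero(focal_idx)[0]
    keep = focal_idx[np.isfinite(x[focal_idx])]
    if keep.size < 1:
        raise ValueError("no focal tips with data")
    xr = x[keep]
    mr = np.asarray(m, float)[keep]
    Vr = V[np.ix_(keep, keep)]
    try:
        cho = cho_factor(Vr, lower=True)
    except np.linalg.LinAlgError:
        ev = np.linalg.eigvalsh(Vr)
        raise ValueError(
            f"restricted covariance not positive-definite "
            f"(smallest eigenvalue {ev[0]:.3e})"
        )
    res = xr - mr
    quad = res @ cho_solve(cho, res)
    logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
    nn = keep.size
    return float(-0.5 * (nn * np.log(2.0 * np.pi) + logdet + quad))


def model_loglik(tree: TimeTree, timeline, x, family: str, params: ModelParams,
                 focal_idx=None, include_self: bool = False) -> float:
    """Log-likelihood of tip data at fully specified parameters."""
    x = _align(tree, x)
    if focal_idx is None:
        focal_idx = np.arange(tree.n_tips)
    if family == "BM":
        m = np.full(tree.n_tips, params.z0)
        V = params.sigma2 * phylo_vcv(tree)
    elif family == "OU":
        m, V = ou_vcv(tree, params.sigma2, params.alpha, params.theta, params.z0)
    elif family == "MC":
        m, V = mc_moments(tree, timeline, params.S, params.sigma2, params.z0,
                          include_self=include_self)
    elif family == "DDlin":
        m = np.full(tree.n_tips, params.z0)
        V = dd_vcv(tree, timeline, params.sigma0_2, params.b, "lin")
    elif family == "DDexp":
        m = np.full(tree.n_tips, params.z0)
        V = dd_vcv(tree, timeline, params.sigma0_2, params.r, "exp")
    else:
        raise ValueError(f"unknown family {family!r}")
    return subgroup_loglik(x, m, V, focal_idx)


def _align(tree, x):
    """Trait input (dict / Series / array in tip order) -> array with NaN."""
    import pandas as pd

    if isinstance(x, dict):
        return np.array([x.get(lab, np.nan) for lab in tree.labels], float)
    if isinstance(x, pd.Series):
        return np.array([x.get(lab, np.nan) for lab in tree.labels], float)
    arr = np.asarray(x, float)
    if arr.shape != (tree.n_tips,):
        raise ValueError("trait vector length does not match tip count")
    return arr


def _profiled(x, V1):
    """(lnL, z0_hat, rate_hat) for V = rate * V1, mean = z0 * 1."""
    n = x.size
    try:
        cho = cho_factor(V1, lower=True)
    except np.linalg.LinAlgError:
        return -np.inf, np.nan, np.nan
    ones = np.ones(n)
    Vi1 = cho_solve(cho, ones)
    Vix = cho_solve(cho, x)
    denom = ones @ Vi1
    z0 = (ones @ Vix) / denom
    res = x - z0
    q = res @ cho_solve(cho, res)
    if q <= 0:
        return -np.inf, z0, 0.0
    rate = q / n
    logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
    lnL = -0.5 * (n * np.log(2.0 * np.pi) + n * np.log(rate) + logdet + n)
    return float(lnL), float(z0), float(rate)


def _aicc(lnL, k, n):
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined: n={n} <= k+1={k + 1}")
    return -2.0 * lnL + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def focal_tip_indices(timeline: InteractionTimeline) -> np.ndarray:
    """Tips in the focal subgroup at the present (last interval's flags)."""
    alive = timeline.alive[-1]
    focal = timeline.focal[-1]
    return np.sort(alive[focal])


def fit_model(tree: TimeTree, timeline, x, family: str,
              focal_idx=None, include_self: bool = False,
              bounds=None, restarts=None) -> FitResult:
    """Maximum-likelihood fit of one family to one trait.

    ``z0`` and the overall rate are profiled analytically (the tip mean is
    constant under every family as parameterized here), leaving a bounded
    1-D search over the structural parameter started from several points.
    OU is fitted with the optimum at the root state (theta = z0).
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    xfull = _align(tree, x)
    if focal_idx is None:
        # every family is fit to the same focal-subgroup data so that the
        # AICc comparison is coherent
        if timeline is not None:
            focal_idx = focal_tip_indices(timeline)
        else:
            focal_idx = np.arange(tree.n_tips)
    focal_idx = np.asarray(focal_idx)
    if focal_idx.dtype == bool:
        focal_idx = np.nonzero(focal_idx)[0]
    keep = focal_idx[np.isfinite(xfull[focal_idx])]
    n = keep.size
    k = K_PARAMS[family]
    if n < k + 2:
        raise ValueError(f"need at least {k + 2} focal tips with data, have {n}")
    xr = xfull[keep]
    sub = np.ix_(keep, keep)
    C = phylo_vcv(tree)
    T = tree.root_age

    def pack(theta_struct):
        """Profiled lnL at structural parameter value."""
        if family == "BM":
            V1 = C[sub]
        elif family == "OU":
            V1 = ou_unit_cov(tree, theta_struct, C)[sub]
        elif family == "MC":
            V1 = mc_unit_cov(tree, timeline, theta_struct, include_self)[sub]
        elif family == "DDlin":
            try:
                V1 = dd_unit_cov(tree, timeline, theta_struct, "lin")[sub]
            except ValueError:
                return -np.inf, np.nan, np.nan
        else:
            V1 = dd_unit_cov(tree, timeline, theta_struct, "exp")[sub]
        return _profiled(xr, V1)

    diag = []
    if family == "BM":
        lnL, z0, rate = pack(None)
        params = ModelParams("BM", z0=z0, sigma2=rate)
        return FitResult(params, lnL, k, n, _aicc(lnL, k, n), converged=np.isfinite(lnL))

    # structural-parameter transform, bounds and restart points per family
    if family == "OU":
        lo, hi = bounds or (1e-9, 50.0 / T)
        to_nat = lambda u: np.exp(u)
        to_u = lambda a: np.log(a)
        starts = restarts or [0.1 / T, 1.0 / T, 10.0 / T]
    elif family == "MC":
        lo, hi = bounds or (1e-8 / T, 30.0 / T)  # bounds on |S|
        to_nat = lambda u: -np.exp(u)
        to_u = lambda s: np.log(-s)
        starts = restarts or [-0.01, -0.1, -1.0]
        starts = [max(min(-s, hi), lo) * -1.0 for s in starts]
    elif family == "DDexp":
        nmax = int(max(np.max(nv) for nv in timeline.n))
        lim = bounds or (-min(20.0 / max(nmax, 1), 5.0), min(20.0 / max(nmax, 1), 5.0))
        lo, hi = lim
        to_nat = lambda u: u
        to_u = lambda r: r
        starts = restarts or [-0.1, -0.01, 0.0, 0.01, 0.1]
        starts = [min(max(s, lo), hi) for s in starts]
    else:  # DDlin: slope ratio b/sigma0^2
        nmax = int(max(np.max(nv) for nv in timeline.n))
        lo = -1.0 / nmax + 1e-6 if bounds is None else bounds[0]
        hi = 100.0 if bounds is None else bounds[1]
        to_nat = lambda u: u
        to_u = lambda bb: bb
        starts = restarts or [lo / 2.0, -0.1 / nmax, 0.0, 0.1 / nmax, 1.0 / nmax]
        starts = [min(max(s, lo), hi) for s in starts]

    best = None
    for s0 in starts:
        if family in ("OU", "MC"):
            u0 = to_u(s0 if family == "OU" else s0)
            ulo, uhi = np.log(lo), np.log(hi)
        else:
            u0, ulo, uhi = s0, lo, hi

        def nll(uv):
            u = float(np.clip(uv[0], ulo, uhi))
            lnL, _, _ = pack(to_nat(u))
            return -lnL if np.isfinite(lnL) else 1e10

        res = minimize(nll, [np.clip(u0, ulo, uhi)], method="L-BFGS-B",
                       bounds=[(ulo, uhi)], options={"maxiter": 200})
        diag.append({"start": s0, "fun": float(res.fun), "success": bool(res.success)})
        if best is None or res.fun < best[0]:
            best = (float(res.fun), float(np.clip(res.x[0], ulo, uhi)),
                    bool(res.success))
    fun, u, ok = best
    struct = to_nat(u)
    lnL, z0, rate = pack(struct)
    if family == "OU":
        params = ModelParams("OU", z0=z0, sigma2=rate, alpha=struct, theta=z0)
    elif family == "MC":
        params = ModelParams("MC", z0=z0, sigma2=rate, S=struct)
    elif family == "DDexp":
        params = ModelParams("DDexp", z0=z0, sigma0_2=rate, r=struct)
    else:
        params = ModelParams("DDlin", z0=z0, sigma0_2=rate, b=struct * rate)
    converged = ok and np.isfinite(lnL)
    return FitResult(params, lnL, k, n, _aicc(lnL, k, n),
                     converged=converged, restarts=diag)


def compare_models(fits) -> FitComparison:
    """Akaike weights and the relative-support index over the five fits.

    RS = max(w_MC, w_DDlin, w_DDexp) /
         (max(w_BM, w_OU) + max(w_MC, w_DDlin, w_DDexp)).
    Best model = lowest AICc among converged fits; ties break toward the
    simpler family.
    """
    if isinstance(fits, (list, tuple)):
        fits = {f.family: f for f in fits}
    for group in (_NEUTRAL, _COMPETITION):
        if not any(fam in fits and fits[fam].converged for fam in group):
            raise ValueError(f"no converged fit in family group {group}")
    usable = {fam: f for fam, f in fits.items() if f.converged}
    aicc = np.array([usable[f].aicc for f in usable])
    fams = list(usable)
    d = aicc - aicc.min()
    w = np.exp(-0.5 * d)
    w = w / w.sum()
    weights = dict(zip(fams, w))
    w_comp = max(weights.get(f, 0.0) for f in _COMPETITION)
    w_neut = max(weights.get(f, 0.0) for f in _NEUTRAL)
    rs = w_comp / (w_neut + w_comp)
    order = {f: (usable[f].k, FAMILIES.index(f)) for f in fams}
    best = min(fams, key=lambda f: (round(usable[f].aicc, 10), order[f]))
    return FitComparison(fits=fits, weights=weights, relative_support=float(rs),
                         best=best)


def fit_over_maps(tree: TimeTree, timelines, x, families=FAMILIES,
                  include_self: bool = False):
    """Fit the model set once per stochastic map and summarize.

    Returns (list of per-map FitComparison or None on failure, summary dict
    with mean/SD relative support over converged maps and the modal best
    family).
    """
    if not timelines:
        raise ValueError("empty timeline bank")
    comps = []
    for tl in timelines:
        try:
            fits = {}
            for fam in families:
                fits[fam] = fit_model(tree, tl, x, fam, include_self=include_self)
            comps.append(compare_models(fits))
        except (ValueError, np.linalg.LinAlgError) as exc:  # propagate per-map
            comps.append(None)
    ok = [c for c in comps if c is not None]
    if not ok:
        raise ValueError("all per-map fits failed")
    rs = np.array([c.relative_support for c in ok])
    modal = Counter(c.best for c in ok).most_common(1)[0][0]
    summary = {
        "mean_rs": float(rs.mean()),
        "sd_rs": float(rs.std(ddof=1)) if len(rs) > 1 else 0.0,
        "best_family": modal,
        "n_maps": len(comps),
        "n_converged_maps": len(ok),
    }
    return comps, summary
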