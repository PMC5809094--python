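"""Synthetic studies: trees, biogeographic and guild histories, traits,
measurement replicates and range overlaps with known generating parameters.

The generator emulates the structure of a continental songbird radiation:
a time-calibrated birth-death phylogeny (crown age 25 My by default),
piecewise-constant occupancy of up to 10 discrete regions (anagenetic
gain/loss with occasional budding speciation), guild membership evolving
under Mk, 27 continuous traits in four classes generated under the five
trait models, per-individual measurement replicates, and pairwise range
overlaps from toy circular ranges on a plane.  Every component is
reproducible from (config, master seed); per-component seeds derive from
the master seed through a documented counter scheme
(``default_rng([master_seed, component_counter])``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .interactions import (GuildHistory, InteractionTimeline, RegionHistory,
                           build_timeline)
from .models import ModelParams
from .simulate import simulate_traits
from .tree import TimeTree, TreeSet, _from_dendropy, write_tree, read_tree
from .traits import TraitMatrix

__all__ = [
    "SyntheticStudy",
    "sim_tree",
    "sim_tree_exp",
    "sim_region_history",
    "sim_guild_history",
    "sim_traits",
    "sim_overlaps",
    "make_fixture_bank",
    "PROFILES",
]

REGION_CODES = tuple("abcdefghij")

#: study-condition profiles (tips, regions, map-bank size)
PROFILES = {
    "tiny": {"n_tips": 16, "n_regions": 2, "n_maps": 3, "n_trees": 1},
    "standard": {"n_tips": 64, "n_regions": 4, "n_maps": 5, "n_trees": 3},
    "paper-scale": {"n_tips": 323, "n_regions": 10, "n_maps": 50, "n_trees": 10},
}

#: per-class replicate-count targets (mean, sd), echoing typical museum /
#: recording sampling depth per species
REPLICATE_COUNTS = {
    "resource-use": (5.35, 7.69),
    "male plumage": (4.27, 1.17),
    "female plumage": (3.84, 1.32),
    "song": (8.53, 7.24),
}

GUILD_SCHEMES = {
    "diet4": ("invertivore", "frugivore", "granivore", "omnivore"),
    "habitat3": ("dense", "semi-open", "open"),
    "territorial2": ("territorial", "non-territorial"),
}


def _rng(master_seed: int, counter: int) -> np.random.Generator:
    return np.random.default_rng([int(master_seed) % (2 ** 31), counter])


# -- trees -----------------------------------------------------------------


def sim_tree(lam: float, mu: float, n_tips: int, seed: int,
             root_age: float | None = 25.0, return_log: bool = False):
    """Constant-rate birth-death tree conditioned on the number of extant
    tips, rescaled to a fixed crown age (default 25 My).

    Forward simulation stops at the moment the extant count reaches
    ``n_tips``; fully extinct runs are retried (bounded).  With
    ``return_log`` the recorded speciation ages of surviving lineages are
    returned alongside (the independent record of branching times).
    """
    if not (lam > mu >= 0):
        raise ValueError("need lam > mu >= 0")
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    for attempt in range(200):
        out = _sim_bd_once(lam, mu, n_tips, rng)
        if out is not None:
            break
    else:
        raise RuntimeError("birth-death simulation went extinct in 200 attempts")
    tree, spec_times = out
    if root_age is not None:
        scale = root_age / tree.root_age
        tree = TimeTree(tree.labels, tree.parent, tree.length * scale)
        spec_times = [t * scale for t in spec_times]
    if return_log:
        return tree, np.sort(np.asarray(spec_times))[::-1]
    return tree


def _sim_bd_once(lam, mu, n_tips, rng):
    t = 0.0
    next_id = [0]

    def new_leaf(tx):
        nd = dendropy.Node()
        nd.birth = t
        nd.alive = True
        next_id[0] += 1
        nd.tag = next_id[0]
        return nd

    dtree = dendropy.Tree()
    root = dtree.seed_node
    root.birth = 0.0
    a, b = new_leaf(0), new_leaf(1)
    root.add_child(a)
    root.add_child(b)
    extant = [a, b]
    spec_forward = [0.0]
    while len(extant) < n_tips:
        k = len(extant)
        if k == 0:
            return None
        rate = k * (lam + mu)
        t += rng.exponential(1.0 / rate)
        nd = extant[rng.integers(k)]
        if rng.random() < lam / (lam + mu):
            nd.alive = False
            nd.edge.length = t - nd.birth
            c1, c2 = new_leaf(0), new_leaf(0)
            c1.birth = c2.birth = t
            nd.add_child(c1)
            nd.add_child(c2)
            extant.remove(nd)
            extant.extend([c1, c2])
            spec_forward.append(t)
        else:
            nd.alive = False
            nd.dead = True
            nd.edge.length = t - nd.birth
            extant.remove(nd)
    # the present falls inside the waiting interval during which exactly
    # n_tips lineages exist (uniform draw within it)
    w = rng.exponential(1.0 / (len(extant) * (lam + mu)))
    t += rng.random() * w
    tns = dtree.taxon_namespace
    drop = []
    for i, nd in enumerate(extant):
        nd.edge.length = t - nd.birth
        nd.taxon = tns.new_taxon(f"t{i + 1:04d}")
    for leaf in dtree.leaf_node_iter():
        if getattr(leaf, "dead", False):
            drop.append(leaf)
    for leaf in drop:
        _prune_leaf(dtree, leaf)
    dtree.suppress_unifurcations()
    tree = _from_dendropy(dtree)
    # surviving speciation ages (forward time -> age), pruned tree only
    ages = [t - ft for ft in spec_forward]
    # with extinction some recorded splits vanish from the reconstructed
    # tree; recompute from the tree itself in that case
    if len(ages) != tree.n_tips - 1:
        ages = list(tree.age[tree.n_tips:])
    return tree, ages


def sim_tree_exp(lam_init: float, g: float, n_tips: int, seed: int) -> TimeTree:
    """Pure-birth tree whose speciation rate varies exponentially in time.

    Forward-time rate ``lam(s) = lam_init * exp(g * s)`` from the crown
    origin; ``g < 0`` produces a diversification slowdown toward the
    present.  The waiting times are drawn exactly by inverting the
    cumulative hazard.  Growth saturates at ``2*exp(lam_init/|g|)`` for
    ``g < 0``; ``n_tips`` must stay safely below that asymptote.
    """
    if lam_init <= 0 or n_tips < 2:
        raise ValueError("need lam_init > 0 and n_tips >= 2")
    if g < 0 and n_tips >= 2 * np.exp(lam_init / -g):
        raise ValueError("n_tips unreachable under this slowdown")
    rng = np.random.default_rng(seed)
    s = 0.0
    split_times = [0.0]
    k = 2
    while k < n_tips:
        E = rng.exponential()
        if abs(g) < 1e-12:
            w = E / (k * lam_init)
        else:
            arg = np.exp(g * s) + g * E / (k * lam_init)
            if arg <= 0:
                # hazard exhausted: restart (astronomically rare given the
                # reachability check above)
                return sim_tree_exp(lam_init, g, n_tips,
                                    int(rng.integers(2 ** 31)))
            w = np.log(arg) / g - s
        s += w
        split_times.append(s)
        k += 1
    # present inside the n-lineage waiting interval
    E = rng.exponential()
    if abs(g) < 1e-12:
        w = E / (k * lam_init)
    else:
        arg = np.exp(g * s) + g * E / (k * lam_init)
        w = (np.log(arg) / g - s) if arg > 0 else 5.0 / lam_init
    present = s + rng.random() * w
    # assemble topology: each split attaches to a uniformly chosen extant
    # lineage (exchangeable, as in the constant-rate case)
    dtree = dendropy.Tree()
    root = dtree.seed_node
    nodes = []
    birth = {}

    def leaf(t0):
        nd = dendropy.Node()
        birth[id(nd)] = t0
        return nd

    a, b = leaf(0.0), leaf(0.0)
    root.add_child(a)
    root.add_child(b)
    extant = [a, b]
    for st in split_times[1:]:
        nd = extant[rng.integers(len(extant))]
        nd.edge.length = st - birth[id(nd)]
        c1, c2 = leaf(st), leaf(st)
        nd.add_child(c1)
        nd.add_child(c2)
        extant.remove(nd)
        extant.extend([c1, c2])
    tns = dtree.taxon_namespace
    for i, nd in enumerate(extant):
        nd.edge.length = present - birth[id(nd)]
        nd.taxon = tns.new_taxon(f"t{i + 1:04d}")
    return _from_dendropy(dtree)


def _prune_leaf(dtree, leaf):
    p = leaf.parent_node
    if p is None:
        return
    p.remove_child(leaf)
    while p is not None and p.num_child_nodes() == 0 and p.parent_node is not None:
        gp = p.parent_node
        gp.remove_child(p)
        p = gp


# -- histories -------------------------------------------------------------


def sim_region_history(tree: TimeTree, n_regions: int = 10, d: float = 0.12,
                       e: float = 0.04, seed: int = 0,
                       p_budding: float = 0.25, map_id: int = 0,
                       root_range=None) -> RegionHistory:
    """Continuous-time gain/loss of regions along the tree.

    Each absent region is gained at rate ``d``, each present region lost at
    rate ``e`` (loss of the last region is suppressed).  At speciation,
    with probability ``p_budding`` one daughter buds off with a single
    random region; otherwise both daughters inherit the full range.  The
    default rates give mostly-overlapping present-day ranges, so that
    independently drawn maps agree on roughly three quarters of sympatry
    designations near the present.
    """
    if d < 0 or e < 0:
        raise ValueError("rates must be >= 0")
    regions = REGION_CODES[:n_regions]
    rng = np.random.default_rng(seed)
    if root_range is None:
        k0 = max(1, n_regions // 2)
        root_range = frozenset(rng.choice(regions, size=k0, replace=False))
    else:
        root_range = frozenset(root_range)
    segments = {}
    range_at_node = {tree.root: root_range}
    for v in tree.preorder():
        if not tree.children[v]:
            continue
        R = range_at_node[v]
        kids = tree.children[v]
        if len(R) > 1 and rng.random() < p_budding:
            bud = frozenset([rng.choice(sorted(R))])
            daughters = [R, bud] if rng.random() < 0.5 else [bud, R]
        else:
            daughters = [R, R]
        for c, R0 in zip(kids, daughters):
            segs, R_end = _evolve_range(
                rng, R0, regions, d, e, tree.age[v], tree.age[c])
            segments[c] = segs
            range_at_node[c] = R_end
    return RegionHistory(tree, segments, map_id=map_id)


def _evolve_range(rng, R, regions, d, e, age_top, age_bot):
    segs = []
    t = age_top
    R = frozenset(R)
    while True:
        n_gain = len(regions) - len(R)
        n_loss = len(R) if len(R) > 1 else 0
        rate = d * n_gain + e * n_loss
        if rate <= 0:
            segs.append((t, age_bot, R))
            return segs, R
        w = rng.exponential(1.0 / rate)
        if t - w <= age_bot:
            segs.append((t, age_bot, R))
            return segs, R
        t_new = t - w
        segs.append((t, t_new, R))
        if rng.random() < d * n_gain / rate:
            gained = rng.choice(sorted(set(regions) - R))
            R = R | {gained}
        else:
            lost = rng.choice(sorted(R))
            R = R - {lost}
        t = t_new


def sim_guild_history(tree: TimeTree, states, Q: np.ndarray, seed: int = 0,
                      scheme: str = "custom", map_id: int = 0,
                      root_state=None) -> tuple[GuildHistory, dict]:
    """Simulate a discrete guild character under an Mk process.

    Returns the full history and the induced tip-state dict.  The root
    state is drawn from a flat prior unless given.
    """
    states = tuple(states)
    Q = np.asarray(Q, float)
    rng = np.random.default_rng(seed)
    k = len(states)
    idx = {s: i for i, s in enumerate(states)}
    s_root = idx[root_state] if root_state is not None else rng.integers(k)
    state_at_node = {tree.root: s_root}
    segments = {}
    for v in tree.preorder():
        for c in tree.children[v]:
            s = state_at_node[v]
            t = tree.age[v]
            segs = []
            while True:
                rate = -Q[s, s]
                if rate <= 0:
                    segs.append((t, tree.age[c], states[s]))
                    break
                w = rng.exponential(1.0 / rate)
                if t - w <= tree.age[c]:
                    segs.append((t, tree.age[c], states[s]))
                    break
                segs.append((t, t - w, states[s]))
                probs = Q[s].copy()
                probs[s] = 0.0
                s = rng.choice(k, p=probs / probs.sum())
                t = t - w
            segments[c] = segs
            state_at_node[c] = s
    hist = GuildHistory(tree, segments, scheme=scheme, map_id=map_id)
    tips = {lab: hist.state_at(tree.tip_index(lab), 0.0) for lab in tree.labels}
    return hist, tips


def sim_traits(tree: TimeTree, timeline, family: str, params: dict,
               seed: int = 0, n_rep: int = 1, dt_max=None) -> np.ndarray:
    """Tip trait values under one family (delegates to the forward
    simulator); returns an (n_rep, n_tips) array."""
    mp = ModelParams(family=family, **params)
    sims = simulate_traits(tree, timeline, mp, n_rep=n_rep, seed=seed,
                           dt_max=dt_max)
    return sims.tips


# -- overlaps --------------------------------------------------------------


def sim_overlaps(species, seed: int = 0, extent: float = 10.0,
                 r_min: float = 1.0, r_max: float = 4.0) -> pd.DataFrame:
    """Pairwise Szymkiewicz-Simpson coefficients from toy circular ranges.

    Each species gets a circle (center uniform on a square, radius uniform)
    and overlap areas come from the circle-lens closed form.  Toy geometry:
    a documented stand-in for polygon-based range overlap.
    """
    rng = np.random.default_rng(seed)
    species = list(species)
    n = len(species)
    cx, cy = rng.uniform(0, extent, n), rng.uniform(0, extent, n)
    r = rng.uniform(r_min, r_max, n)
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            dist = float(np.hypot(cx[i] - cx[j], cy[i] - cy[j]))
            inter = _lens_area(r[i], r[j], dist)
            a_i, a_j = np.pi * r[i] ** 2, np.pi * r[j] ** 2
            rows.append({
                "sp1": species[i], "sp2": species[j],
                "area1": a_i, "area2": a_j, "intersection": inter,
                "overlap": inter / min(a_i, a_j),
            })
    return pd.DataFrame(rows)


def _lens_area(r1, r2, d):
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        return float(np.pi * min(r1, r2) ** 2)
    a1 = r1 ** 2 * np.arccos((d ** 2 + r1 ** 2 - r2 ** 2) / (2 * d * r1))
    a2 = r2 ** 2 * np.arccos((d ** 2 + r2 ** 2 - r1 ** 2) / (2 * d * r2))
    tri = 0.5 * np.sqrt(max((-d + r1 + r2) * (d + r1 - r2)
                            * (d - r1 + r2) * (d + r1 + r2), 0.0))
    return float(a1 + a2 - tri)


# -- full study ------------------------------------------------------------


#: generating parameters per trait class: (family, structural params).
#: Competition-generated traits evolve among sympatric members of the
#: focal (modal) diet guild; rates echo the empirical ordering (song
#: fastest, resource-use slowest).  Effect sizes are set so a ~25-tip
#: subgroup on a 25-My tree carries a detectable signal (|S| * T of order
#: 4-8; |r| * n of order 3-6, mostly negative DD -- positive DD is
#: structurally confounded with OU at this subgroup size).
TRAIT_PLAN = [
    # resource-use traits 1-9: competition-shaped
    ("resource-use", "MC", {"S": -0.2, "sigma2": 1.0}),
    ("resource-use", "DDexp", {"r": -0.2, "sigma0_2": 1.0}),
    ("resource-use", "DDexp", {"r": 0.12, "sigma0_2": 0.3}),
    ("resource-use", "MC", {"S": -0.3, "sigma2": 1.0}),
    ("resource-use", "DDlin", {"b": 0.05, "sigma0_2": 0.5}),
    ("resource-use", "MC", {"S": -0.15, "sigma2": 0.8}),
    ("resource-use", "DDexp", {"r": -0.22, "sigma0_2": 1.2}),
    ("resource-use", "BM", {"sigma2": 0.8}),
    ("resource-use", "DDexp", {"r": -0.2, "sigma0_2": 0.6}),
    # male plumage 10-14: mixed
    ("male plumage", "MC", {"S": -0.15, "sigma2": 1.5}),
    ("male plumage", "BM", {"sigma2": 1.5}),
    ("male plumage", "DDexp", {"r": -0.18, "sigma0_2": 1.0}),
    ("male plumage", "OU", {"alpha": 0.12, "sigma2": 2.0}),
    ("male plumage", "BM", {"sigma2": 1.8}),
    # female plumage 15-19: mixed
    ("female plumage", "MC", {"S": -0.18, "sigma2": 1.4}),
    ("female plumage", "DDexp", {"r": -0.2, "sigma0_2": 1.0}),
    ("female plumage", "BM", {"sigma2": 1.6}),
    ("female plumage", "OU", {"alpha": 0.1, "sigma2": 1.8}),
    ("female plumage", "BM", {"sigma2": 1.5}),
    # song 20-27: fast, competition-neutral
    ("song", "OU", {"alpha": 0.2, "sigma2": 6.0}),
    ("song", "BM", {"sigma2": 4.0}),
    ("song", "OU", {"alpha": 0.15, "sigma2": 5.0}),
    ("song", "BM", {"sigma2": 4.5}),
    ("song", "OU", {"alpha": 0.25, "sigma2": 6.0}),
    ("song", "BM", {"sigma2": 3.5}),
    ("song", "OU", {"alpha": 0.2, "sigma2": 5.5}),
    ("song", "BM", {"sigma2": 4.0}),
]


@dataclass
class SyntheticStudy:
    """A complete synthetic study with its generating-parameter ledger."""

    profile: str
    seed: int
    tree_set: TreeSet
    region_bank: list
    guild_banks: dict          # scheme -> list of GuildHistory
    guild_tips: dict           # scheme -> tip-state dict (true, map 0)
    traits: TraitMatrix
    individuals: pd.DataFrame
    overlaps: pd.DataFrame
    ledger: dict = field(default_factory=dict)

    @property
    def tree(self) -> TimeTree:
        return self.tree_set.trees[0]

    def modal_guild(self, scheme: str) -> str:
        """Most common present-day guild state (the largest subgroup)."""
        from collections import Counter

        return Counter(self.guild_tips[scheme].values()).most_common(1)[0][0]

    def timeline(self, scheme: str, focal_guild: str, map_index: int = 0
                 ) -> InteractionTimeline:
        nb_r = len(self.region_bank)
        nb_g = len(self.guild_banks[scheme])
        return build_timeline(self.tree, self.region_bank[map_index % nb_r],
                              self.guild_banks[scheme][map_index % nb_g],
                              focal_guild)

    def write(self, outdir):
        from .interactions import write_history

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for i, t in enumerate(self.tree_set.trees):
            write_tree(t, outdir / f"tree_{i:02d}.nwk")
        write_history(self.region_bank, outdir / "regions.tsv")
        for scheme, bank in self.guild_banks.items():
            write_history(bank, outdir / f"guild_{scheme}.tsv")
        self.traits.values.to_csv(outdir / "traits.csv",
                                  index_label="species")
        self.individuals.to_csv(outdir / "individuals.csv", index=False)
        self.overlaps.to_csv(outdir / "overlaps.tsv", sep="\t", index=False)
        ledger = {
            "profile": self.profile, "seed": self.seed,
            "trait_classes": self.traits.classes,
            "guild_tips": self.guild_tips,
            "generating": self.ledger,
        }
        (outdir / "ledger.json").write_text(json.dumps(ledger, indent=1))

    @classmethod
    def load(cls, outdir):
        from .interactions import read_history

        outdir = Path(outdir)
        ledger = json.loads((outdir / "ledger.json").read_text())
        trees = sorted(outdir.glob("tree_*.nwk"))
        tree_set = TreeSet([read_tree(p) for p in trees], source="synthetic")
        tree = tree_set.trees[0]
        region_bank = read_history(outdir / "regions.tsv", tree, kind="region")
        guild_banks, guild_tips = {}, ledger["guild_tips"]
        for p in sorted(outdir.glob("guild_*.tsv")):
            scheme = p.stem.replace("guild_", "")
            guild_banks[scheme] = read_history(p, tree, kind="guild",
                                               scheme=scheme)
        values = pd.read_csv(outdir / "traits.csv", index_col="species")
        traits = TraitMatrix(values=values, classes=ledger["trait_classes"])
        individuals = pd.read_csv(outdir / "individuals.csv")
        overlaps = pd.read_csv(outdir / "overlaps.tsv", sep="\t")
        return cls(profile=ledger["profile"], seed=ledger["seed"],
                   tree_set=tree_set, region_bank=region_bank,
                   guild_banks=guild_banks, guild_tips=guild_tips,
                   traits=traits, individuals=individuals, overlaps=overlaps,
                   ledger=ledger["generating"])


def make_fixture_bank(profile: str = "standard", seed: int = 0,
                      n_traits: int | None = None) -> SyntheticStudy:
    """Build a complete synthetic study for one profile.

    tiny = 16 tips / 2 regions (smoke tests); standard = 64 tips / 4
    regions (default tests); paper-scale = 323 tips / 10 regions / 50 maps.
    Competition-generated traits evolve among sympatric members of the
    focal diet guild; song traits are fast and competition-neutral.
    """
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}; choose from {list(PROFILES)}")
    cfg = PROFILES[profile]
    n_tips, n_regions = cfg["n_tips"], cfg["n_regions"]
    n_maps, n_trees = cfg["n_maps"], cfg["n_trees"]
    trees = [sim_tree(0.25, 0.05, n_tips, seed=_rng(seed, 100 + i).integers(2 ** 31))
             for i in range(n_trees)]
    tree_set = TreeSet(trees, source="synthetic")
    tree = trees[0]
    region_bank = [
        sim_region_history(tree, n_regions=n_regions, seed=int(_rng(seed, 200 + m).integers(2 ** 31)),
                           map_id=m)
        for m in range(n_maps)
    ]
    schemes = {"diet4": GUILD_SCHEMES["diet4"],
               "habitat3": GUILD_SCHEMES["habitat3"],
               "territorial2": GUILD_SCHEMES["territorial2"]}
    if profile == "tiny":
        schemes = {"diet2": ("invertivore", "frugivore")}
    guild_banks, guild_tips = {}, {}
    for s_i, (scheme, states) in enumerate(schemes.items()):
        k = len(states)
        Q = np.full((k, k), 0.05)
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        # map 0 is the true history; the rest are stochastic maps
        # conditioned on its present-day states (as in an empirical bank,
        # where tip guilds are observed data)
        h0, tips = sim_guild_history(
            tree, states, Q,
            seed=int(_rng(seed, 300 + 10 * s_i).integers(2 ** 31)),
            scheme=scheme, map_id=0)
        guild_tips[scheme] = tips
        bank = [h0]
        if n_maps > 1:
            from .interactions import MkModel, sample_stochastic_maps

            model = MkModel(states=states, Q=Q)
            bank.extend(sample_stochastic_maps(
                tree, model, tips, n_maps - 1,
                seed=int(_rng(seed, 310 + 10 * s_i).integers(2 ** 31)),
                scheme=scheme))
            for m, h in enumerate(bank[1:], start=1):
                h.map_id = m
        guild_banks[scheme] = bank
    # traits: generated on the true (map 0) timeline of the diet scheme,
    # with the largest (modal) present-day class as the focal guild
    from collections import Counter

    diet_scheme = next(iter(schemes))
    focal = Counter(guild_tips[diet_scheme].values()).most_common(1)[0][0]
    tl_comp = build_timeline(tree, region_bank[0], guild_banks[diet_scheme][0], focal)
    tl_allo = InteractionTimeline.full_allopatry(tree)
    plan = TRAIT_PLAN if n_traits is None else TRAIT_PLAN[:n_traits]
    values = {}
    classes, ledger = {}, {}
    for t_i, (cls_name, family, params) in enumerate(plan):
        name = f"trait_{t_i + 1:02d}"
        pr = dict(params, z0=0.0)
        tl = tl_comp if family in ("MC", "DDlin", "DDexp") else tl_allo
        tips_arr = sim_traits(tree, tl, family, pr,
                              seed=int(_rng(seed, 400 + t_i).integers(2 ** 31)),
                              dt_max=tree.root_age / 400)
        values[name] = tips_arr[0]
        classes[name] = cls_name
        ledger[name] = {"family": family, "params": pr,
                        "focal_guild": focal if family in ("MC", "DDlin", "DDexp")
                        else None}
    values_df = pd.DataFrame(values, index=list(tree.labels))
    traits = TraitMatrix(values=values_df, classes=classes)
    # measurement replicates on a shifted positive scale (toy measurement
    # units so relative ME stays defined)
    rows = []
    rng_me = _rng(seed, 500)
    for name, cls_name in classes.items():
        mean_n, sd_n = REPLICATE_COUNTS[cls_name]
        base = values_df[name].to_numpy()
        offset = 10.0 + 3.0 * float(np.std(base))
        for s_i2, sp in enumerate(tree.labels):
            k = max(1, int(round(rng_me.normal(mean_n, sd_n))))
            mu_sp = offset + base[s_i2]
            draws = rng_me.normal(mu_sp, 0.05 * offset, size=k)
            for j, v in enumerate(draws):
                rows.append((sp, name, j, float(v)))
    individuals = pd.DataFrame(rows, columns=["species", "trait",
                                              "replicate_id", "value"])
    overlaps = sim_overlaps(tree.labels, seed=int(_rng(seed, 600).integers(2 ** 31)))
    return SyntheticStudy(
        profile=profile, seed=seed, tree_set=tree_set,
        region_bank=region_bank, guild_banks=guild_banks,
        guild_tips=guild_tips, traits=traits, individuals=individuals,
        overlaps=overlaps, ledger=ledger,
    )
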