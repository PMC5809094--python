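"""Trait preparation: phylogenetic PCA, standardization, and measurement
error from individual replicates.

The phylogenetic PCA works in the Brownian metric of the tree: variables
are centered on their GLS (phylogenetic) mean and the evolutionary
covariance ``(X - 1a)' C^-1 (X - 1a) / (n - 1)`` is eigen-decomposed.
pPCA uses the covariance (not correlation) of the, typically
ln-transformed, input variables; eigenvector signs are fixed so the
largest-magnitude loading on each axis is positive.

Relative measurement error (ME) per individual is
``|(x_individual - x_species_mean) / x_species_mean|``, averaged per
species x trait; species with a single replicate are excluded downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tree import TimeTree, phylo_vcv

__all__ = [
    "TraitMatrix",
    "PPCAxes",
    "MEEstimates",
    "phylogenetic_pca",
    "z_transform",
    "me_from_replicates",
    "simulate_resource_replicates",
    "mass_me_from_summaries",
]

TRAIT_CLASSES = ("resource-use", "male plumage", "female plumage", "song")


@dataclass
class TraitMatrix:
    """Species x trait table with optional metadata and standard errors."""

    values: pd.DataFrame                   # index = species, columns = traits
    classes: dict = field(default_factory=dict)    # trait -> class
    transforms: dict = field(default_factory=dict)  # trait -> "ln" | "none"
    se: pd.DataFrame | None = None

    def __post_init__(self):
        if self.values.index.has_duplicates:
            raise ValueError("duplicate species rows")
        bad = set(self.classes.values()) - set(TRAIT_CLASSES)
        if bad:
            raise ValueError(f"unknown trait classes {sorted(bad)}")


@dataclass
class PPCAxes:
    loadings: pd.DataFrame      # variable x axis
    means: pd.Series            # phylogenetic (GLS) mean per variable
    evol_cov: pd.DataFrame      # evolutionary covariance of the variables
    scores: pd.DataFrame        # species x axis
    eigenvalues: np.ndarray


@dataclass
class MEEstimates:
    per_species: pd.DataFrame   # species x trait mean relative ME
    replicate_counts: pd.DataFrame
    excluded_single: pd.DataFrame  # species x trait flags (single replicate)

    def median_me(self, species=None, traits=None) -> pd.Series:
        """Per-trait median ME over an analysis subset."""
        sub = self.per_species
        if species is not None:
            sub = sub.loc[sub.index.intersection(species)]
        if traits is not None:
            sub = sub[[t for t in traits if t in sub.columns]]
        return sub.median(axis=0, skipna=True)


def phylogenetic_pca(tree: TimeTree, X: pd.DataFrame) -> PPCAxes:
    """Phylogenetic principal components of species-by-variable data.

    Requires complete cases for the included species (rows are aligned to
    tip labels; species absent from the tree are ignored).  On a star
    phylogeny this reduces to ordinary PCA of the centered data.
    """
    if X.shape[1] < 1:
        raise ValueError("need at least 1 variable")
    common = [lab for lab in tree.labels if lab in X.index]
    if len(common) < len(tree.labels):
        missing = set(tree.labels) - set(common)
        raise ValueError(f"tips missing trait rows: {sorted(missing)[:5]}")
    Xm = X.loc[list(tree.labels)].to_numpy(float)
    if np.any(~np.isfinite(Xm)):
        raise ValueError("phylogenetic PCA requires complete cases")
    C = phylo_vcv(tree)
    Ci = np.linalg.inv(C)
    ones = np.ones(tree.n_tips)
    denom = ones @ Ci @ ones
    a = (ones @ Ci @ Xm) / denom           # GLS mean per variable
    R = (Xm - a).T @ Ci @ (Xm - a) / (tree.n_tips - 1)
    cond = np.linalg.cond(R)
    if cond > 1e12:
        raise ValueError(
            f"evolutionary covariance is singular (cond={cond:.2e}); "
            "remove collinear variables"
        )
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # sign convention: largest-magnitude loading positive on each axis
    for j in range(evecs.shape[1]):
        i = np.argmax(np.abs(evecs[:, j]))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]
    scores = (Xm - a) @ evecs
    axes = [f"pPC{j + 1}" for j in range(evecs.shape[1])]
    return PPCAxes(
        loadings=pd.DataFrame(evecs, index=X.columns, columns=axes),
        means=pd.Series(a, index=X.columns),
        evol_cov=pd.DataFrame(R, index=X.columns, columns=X.columns),
        scores=pd.DataFrame(scores, index=list(tree.labels), columns=axes),
        eigenvalues=evals,
    )


def z_transform(X: pd.DataFrame) -> pd.DataFrame:
    """Scale each trait column to sample mean 0, sample SD 1 (ddof=1),
    ignoring missing values.  Zero-variance traits are an error."""
    X = X.copy()
    for col in X.columns:
        v = X[col].astype(float)
        ok = v.notna()
        if ok.sum() < 2:
            raise ValueError(f"trait {col!r}: fewer than 2 non-missing values")
        sd = v[ok].std(ddof=1)
        if sd == 0:
            raise ValueError(f"trait {col!r} has zero variance")
        X[col] = (v - v[ok].mean()) / sd
    return X


def me_from_replicates(individuals: pd.DataFrame) -> MEEstimates:
    """Mean relative measurement error per species x trait.

    ``individuals`` is long format with columns ``species``, ``trait``,
    ``value`` (and optionally ``replicate_id``).  ME per replicate is
    |(x - mean) / mean|; averaged within species x trait.  Species-trait
    cells with a single replicate are flagged for exclusion; cells whose
    species mean is exactly 0 are recorded as missing (ME undefined).
    """
    need = {"species", "trait", "value"}
    if not need <= set(individuals.columns):
        raise ValueError(f"individuals table needs columns {sorted(need)}")
    g = individuals.groupby(["species", "trait"])["value"]
    counts = g.count().unstack("trait")
    means = g.mean()

    def cell_me(vals):
        mu = vals.mean()
        if len(vals) < 2:
            return np.nan
        if mu == 0:
            return np.nan
        return float(np.mean(np.abs((vals - mu) / mu)))

    zero_mean = (means == 0) & (g.count() >= 2)
    if zero_mean.any():
        import warnings

        warnings.warn(
            f"{int(zero_mean.sum())} species x trait cells have mean 0; "
            "relative ME undefined, recorded as missing"
        )
    me = g.apply(lambda v: cell_me(v.to_numpy())).unstack("trait")
    excluded = counts == 1
    return MEEstimates(per_species=me, replicate_counts=counts,
                       excluded_single=excluded)


def simulate_resource_replicates(means, sds, counts, seed,
                                 trait: str = "trait") -> pd.DataFrame:
    """Draw per-species measurement replicates from Normal(mean, sd).

    ``means``/``sds``/``counts`` are aligned per-species (Series or dict).
    Species with a single replicate get ``excluded=True`` so downstream ME
    analyses can drop them; sd=0 reproduces the mean exactly.
    """
    means = pd.Series(means, dtype=float)
    sds = pd.Series(sds, dtype=float).reindex(means.index)
    counts = pd.Series(counts, dtype=int).reindex(means.index)
    if (counts < 1).any():
        raise ValueError("replicate counts must be >= 1")
    if (sds < 0).any():
        raise ValueError("standard deviations must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for sp in means.index:
        k = int(counts[sp])
        draws = means[sp] + sds[sp] * rng.standard_normal(k)
        for j, v in enumerate(draws):
            rows.append((sp, trait, j, float(v), k == 1))
    return pd.DataFrame(rows, columns=["species", "trait", "replicate_id",
                                       "value", "excluded"])


def mass_me_from_summaries(means, sds=None, ranges=None, counts=None) -> pd.Series:
    """Squared standard error of the species mean as a mass-ME stand-in.

    When only a range is available the SD is imputed as range/4; when only
    a sample size and mean exist the across-species average SD is used.
    This is an approximation (clearly labeled in outputs); it is not the
    formulation used for trait ME from replicates.
    """
    means = pd.Series(means, dtype=float)
    sds = pd.Series(sds, dtype=float).reindex(means.index) if sds is not None \
        else pd.Series(np.nan, index=means.index)
    if ranges is not None:
        ranges = pd.Series(ranges, dtype=float).reindex(means.index)
        sds = sds.fillna(ranges / 4.0)
    counts = pd.Series(counts, dtype=float).reindex(means.index) if counts is not None \
        else pd.Series(1.0, index=means.index)
    sds = sds.fillna(sds.mean())
    out = sds ** 2 / counts.clip(lower=1)
    out.name = "mass_me_se2_approx"
    return out
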