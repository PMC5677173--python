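"""Expression correlation structure controls.

Checks whether inversion-affected loci (IAL) merely ride an underlying
co-expression structure: (a) mean pairwise adjusted r^2 within IAL vs
IAL-to-other vs genome-wide, and (b) the number of distinct expression
modules occupied by the IAL against a module-label permutation null.

Pairwise correlations are computed on line means by default (lines are
the units that receive a karyotype); adjusted r^2 for a simple regression
on n points is 1 - (1 - r^2)(n - 1)/(n - 2), symmetric in the pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import InputError


def adjusted_r2(x, y) -> float:
    """Adjusted r^2 of the simple regression of y on x (symmetric)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise InputError("adjusted r^2 needs n >= 3 observations")
    if x.std() == 0 or y.std() == 0:
        raise InputError("adjusted r^2 undefined for a constant vector")
    r = np.corrcoef(x, y)[0, 1]
    return float(1.0 - (1.0 - r * r) * (n - 1) / (n - 2))


@dataclass
class CorrelationSummary:
    mean_ial_ial: float
    mean_ial_other: float
    mean_genome: float
    n_pairs_ial_ial: int
    n_pairs_ial_other: int
    n_pairs_genome: int
    mode: str  # "exhaustive" | "subsampled"
    seed: int | None = None
    ci_genome: tuple[float, float] | None = None


def _adjusted_from_corr(c: np.ndarray, n: int) -> np.ndarray:
    return 1.0 - (1.0 - c * c) * (n - 1) / (n - 2)


def correlation_summary(
    values: pd.DataFrame,
    ial: set[str],
    max_exhaustive_probes: int = 3000,
    max_pairs: int = 5_000_000,
    n_boot: int = 200,
    seed: int = 0,
) -> CorrelationSummary:
    """Mean pairwise adjusted r^2 for IAL x IAL, IAL x other and genome-wide.

    ``values`` is an observations-by-probes frame (typically line means).
    All pairs are enumerated when the probe count is at most
    ``max_exhaustive_probes``; beyond that the genome-wide mean is
    estimated from ``max_pairs`` uniformly subsampled pairs with a
    bootstrap CI (the IAL-involving classes are still exhaustive, their
    pair counts being quadratic only in the IAL count).
    """
    probes = list(values.columns)
    n_obs, P = values.shape
    if n_obs < 3:
        raise InputError("need >= 3 observations per probe")
    if P < 2:
        raise InputError("need >= 2 probes for any pairwise summary")
    ial_idx = np.array([i for i, p in enumerate(probes) if p in ial], dtype=int)
    other_idx = np.array(
        [i for i, p in enumerate(probes) if p not in ial], dtype=int
    )
    if ial_idx.size < 2:
        warnings.warn("fewer than 2 IAL: IAL x IAL mean undefined", stacklevel=2)
    if ial_idx.size < 1 or other_idx.size < 1:
        warnings.warn("a class is empty: IAL x other mean undefined",
                      stacklevel=2)

    X = values.to_numpy(dtype=float)
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"{int((~keep).sum())} constant probes excluded", stacklevel=2)
        X = X[:, keep]
        idx_map = np.cumsum(keep) - 1
        ial_idx = idx_map[ial_idx[keep[ial_idx]]]
        other_idx = idx_map[other_idx[keep[other_idx]]]
        P = X.shape[1]

    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 31]))
    if P <= max_exhaustive_probes:
        corr = np.corrcoef(X, rowvar=False)
        adj = _adjusted_from_corr(corr, n_obs)
        iu = np.triu_indices(P, k=1)
        genome_vals = adj[iu]
        a = adj[np.ix_(ial_idx, ial_idx)]
        ial_vals = a[np.triu_indices(ial_idx.size, k=1)]
        cross = adj[np.ix_(ial_idx, other_idx)].ravel()
        return CorrelationSummary(
            mean_ial_ial=float(ial_vals.mean()) if ial_vals.size else np.nan,
            mean_ial_other=float(cross.mean()) if cross.size else np.nan,
            mean_genome=float(genome_vals.mean()),
            n_pairs_ial_ial=ial_vals.size,
            n_pairs_ial_other=cross.size,
            n_pairs_genome=genome_vals.size,
            mode="exhaustive",
        )

    # large-P path: exhaustive for IAL classes, subsampled genome-wide
    Xs = (X - X.mean(axis=0)) / (X.std(axis=0) * np.sqrt(n_obs))
    sub_a = Xs[:, ial_idx]
    corr_aa = sub_a.T @ sub_a
    ial_vals = _adjusted_from_corr(
        corr_aa[np.triu_indices(ial_idx.size, k=1)], n_obs
    )
    corr_ao = (sub_a.T @ Xs[:, other_idx]).ravel()
    cross_vals = _adjusted_from_corr(corr_ao, n_obs)

    i = rng.integers(0, P, size=max_pairs)
    j = rng.integers(0, P, size=max_pairs)
    ok = i != j
    i, j = i[ok], j[ok]
    r = np.sum(Xs[:, i] * Xs[:, j], axis=0)
    g = _adjusted_from_corr(r, n_obs)
    boots = np.array(
        [g[rng.integers(0, g.size, size=g.size)].mean() for _ in range(n_boot)]
    )
    return CorrelationSummary(
        mean_ial_ial=float(ial_vals.mean()) if ial_vals.size else np.nan,
        mean_ial_other=float(cross_vals.mean()) if cross_vals.size else np.nan,
        mean_genome=float(g.mean()),
        n_pairs_ial_ial=ial_vals.size,
        n_pairs_ial_other=cross_vals.size,
        n_pairs_genome=g.size,
        mode="subsampled",
        seed=seed,
        ci_genome=(
            float(np.quantile(boots, 0.025)),
            float(np.quantile(boots, 0.975)),
        ),
    )


def module_occupancy(ial: set[str], assignment: pd.Series) -> int:
    """Number of distinct modules containing at least one IAL."""
    missing = set(ial) - set(assignment.index)
    if missing:
        raise InputError(
            f"IAL without module assignment: {sorted(missing)[:5]}"
        )
    if not ial:
        return 0
    return int(assignment.loc[sorted(ial)].nunique())


@dataclass
class OccupancyNull:
    observed: int
    ci_low: float
    ci_high: float
    n_perm: int
    verdict: str  # "more modules", "fewer modules", "within CI"
    samples: np.ndarray | None = None


def occupancy_null(
    assignment: pd.Series,
    ial: set[str],
    n_perm: int = 100_000,
    seed: int = 0,
    keep_samples: bool = False,
) -> OccupancyNull:
    """Permutation null for the module-occupancy count.

    Each permutation shuffles the module labels across genes (preserving
    the module-size multiset exactly) while the IAL id set stays fixed,
    then counts the distinct modules hit. Equivalent to drawing |IAL|
    labels without replacement from the label multiset. The CI is the
    empirical 2.5-97.5% band.
    """
    observed = module_occupancy(ial, assignment)
    k = len(ial)
    labels = assignment.to_numpy()
    if k > labels.size:
        raise InputError("IAL set larger than the assigned gene set")
    n_modules = len(np.unique(labels))
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 32]))
    if n_modules == 1:
        samples = np.ones(n_perm, dtype=int)
        warnings.warn("single module: occupancy null is degenerate", stacklevel=2)
    elif k == 0:
        samples = np.zeros(n_perm, dtype=int)
    else:
        samples = np.empty(n_perm, dtype=int)
        for b in range(n_perm):
            drawn = rng.choice(labels, size=k, replace=False)
            samples[b] = np.unique(drawn).size
    ci_low, ci_high = np.quantile(samples, [0.025, 0.975])
    if observed > ci_high:
        verdict = "more modules"
    elif observed < ci_low:
        verdict = "fewer modules"
    else:
        verdict = "within CI"
    return OccupancyNull(
        observed=observed,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_perm=n_perm,
        verdict=verdict,
        samples=samples if keep_samples else None,
    )
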