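"""Cross-species sharing of caste-biased genes, against chance expectations.

Three questions, three tools:

* *How many orthogroups are caste-biased in exactly k species?* —
  :func:`count_shared_degs`, with an optional same-direction requirement
  (a gene counts at level k when k species agree on queen- or worker-bias).
* *Is that more than chance?* — :func:`permutation_overlap_null` draws random
  gene sets of the observed per-species sizes, rebuilds the k-histogram each
  time, and compares observed vs expected with a two-sided Fisher test.
* *Do two gene sets overlap more or less than chance?* —
  :func:`hypergeom_overlap`, a one-tailed hypergeometric test with the tail
  picked by the sign of (observed - expected) and the fold change reported as
  enrichment or depletion accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, hypergeom

__all__ = [
    "OverlapCounts",
    "GeneSetOverlapResult",
    "count_shared_degs",
    "permutation_overlap_null",
    "overlap_summary",
    "hypergeom_overlap",
    "hypergeom_overlap_counts",
]


@dataclass
class OverlapCounts:
    """k-sharing histogram of caste-biased orthogroups.

    ``per_gene`` maps each biased orthogroup to its sharing level k;
    ``exact_k``/``at_least_k`` are histograms indexed k = 1..n_species;
    ``members`` lists the orthogroups at each exact level.
    """

    per_gene: pd.Series
    exact_k: pd.Series
    at_least_k: pd.Series
    members: dict[int, list[str]]


def _sharing_level(directions: list[str], same_direction: bool) -> int:
    if not same_direction:
        return len(directions)
    n_queen = sum(d == "queen" for d in directions)
    return max(n_queen, len(directions) - n_queen)


def count_shared_degs(
    deg_sets: Mapping[str, Mapping[str, str]],
    universe: Iterable[str],
    same_direction: bool = True,
) -> OverlapCounts:
    """Histogram of how many species share each caste-biased orthogroup.

    ``deg_sets`` maps species -> {orthogroup: 'queen'|'worker'}.  With
    ``same_direction`` a gene biased queenward in some species and workerward
    in others contributes at the size of its larger direction-consistent
    subset.
    """
    universe = set(universe)
    n_species = len(deg_sets)
    per_gene_dirs: dict[str, list[str]] = {}
    for sp, mapping in deg_sets.items():
        for og, direction in mapping.items():
            if og not in universe:
                raise ValueError(f"orthogroup {og!r} (species {sp}) not in the universe")
            per_gene_dirs.setdefault(og, []).append(direction)
    levels = {
        og: _sharing_level(dirs, same_direction) for og, dirs in per_gene_dirs.items()
    }
    ks = pd.Index(range(1, n_species + 1), name="k")
    exact = pd.Series(0, index=ks, name="observed")
    members: dict[int, list[str]] = {k: [] for k in ks}
    for og in sorted(levels):
        k = levels[og]
        exact[k] += 1
        members[k].append(og)
    at_least = exact[::-1].cumsum()[::-1].rename("observed_at_least")
    per_gene = pd.Series(levels, dtype=int).sort_index()
    per_gene.index.name = "orthogroup"
    return OverlapCounts(per_gene=per_gene, exact_k=exact, at_least_k=at_least, members=members)


def permutation_overlap_null(
    set_sizes: Mapping[str, int],
    universe: Iterable[str],
    n_perm: int = 1000,
    seed: int = 0,
    same_direction: bool = True,
    observed: pd.Series | None = None,
) -> pd.DataFrame:
    """Expected k-sharing under random gene sets of the observed sizes.

    Each permutation draws, per species, a uniform subset (without
    replacement) of the species' observed caste-biased set size, assigns
    directions uniformly at random when ``same_direction``, and recomputes the
    exact-k histogram.  Returns per k the permutation mean and SD and — when
    ``observed`` exact-k counts are supplied — a two-sided Fisher exact p on
    the 2x2 table [observed_k, N - observed_k; round(expected_k),
    N - round(expected_k)].
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    universe = sorted(set(universe))
    n_universe = len(universe)
    species = sorted(set_sizes)
    for sp in species:
        if set_sizes[sp] > n_universe:
            raise ValueError(f"set size for {sp} exceeds the universe")
    n_species = len(species)
    rng = np.random.default_rng(seed)
    ks = np.arange(1, n_species + 1)
    hists = np.zeros((n_perm, n_species))
    for it in range(n_perm):
        queen_hits = np.zeros(n_universe, dtype=np.int64)
        worker_hits = np.zeros(n_universe, dtype=np.int64)
        for sp in species:
            idx = rng.choice(n_universe, size=set_sizes[sp], replace=False)
            if same_direction:
                is_queen = rng.random(set_sizes[sp]) < 0.5
                np.add.at(queen_hits, idx[is_queen], 1)
                np.add.at(worker_hits, idx[~is_queen], 1)
            else:
                np.add.at(queen_hits, idx, 1)
        level = np.maximum(queen_hits, worker_hits) if same_direction else queen_hits
        counts = np.bincount(level, minlength=n_species + 1)[1:]
        hists[it] = counts
    out = pd.DataFrame(
        {
            "expected_mean": hists.mean(axis=0),
            "expected_sd": hists.std(axis=0, ddof=1) if n_perm > 1 else 0.0,
        },
        index=pd.Index(ks, name="k"),
    )
    if observed is not None:
        fisher_p = []
        for k in ks:
            obs_k = int(observed.get(k, 0))
            exp_k = int(round(out.at[k, "expected_mean"]))
            table = [[obs_k, n_universe - obs_k], [exp_k, n_universe - exp_k]]
            fisher_p.append(fisher_exact(table, alternative="two-sided")[1])
        out["observed"] = [int(observed.get(k, 0)) for k in ks]
        out["fisher_p"] = fisher_p
    return out


def overlap_summary(
    deg_sets: Mapping[str, Mapping[str, str]],
    universe: Iterable[str],
    n_perm: int = 1000,
    seed: int = 0,
    same_direction: bool = True,
) -> pd.DataFrame:
    """Observed k-sharing with its permutation null and Fisher tests, one table."""
    universe = sorted(set(universe))
    counts = count_shared_degs(deg_sets, universe, same_direction=same_direction)
    sizes = {sp: len(m) for sp, m in deg_sets.items()}
    null = permutation_overlap_null(
        sizes, universe, n_perm=n_perm, seed=seed,
        same_direction=same_direction, observed=counts.exact_k,
    )
    null["observed_at_least"] = counts.at_least_k
    return null


@dataclass
class GeneSetOverlapResult:
    """One-tailed hypergeometric comparison of two gene sets in a universe."""

    universe_n: int
    set_a_n: int
    set_b_n: int
    observed_overlap: int
    expected_overlap: float
    fold: float
    direction: str  # 'enriched' | 'depleted' | 'as_expected'
    hypergeom_p: float


def hypergeom_overlap_counts(
    universe_n: int, set_a_n: int, set_b_n: int, observed: int
) -> GeneSetOverlapResult:
    """Hypergeometric overlap test from set sizes alone.

    Expected overlap is ``a * b / N``.  If the observed overlap falls below
    it, the lower tail P(X <= observed) is reported with the depletion fold
    expected/observed; otherwise the upper tail P(X >= observed) with the
    enrichment fold observed/expected.
    """
    if universe_n <= 0:
        raise ValueError("universe must be non-empty")
    if not (0 <= set_a_n <= universe_n and 0 <= set_b_n <= universe_n):
        raise ValueError("set sizes must lie within the universe")
    if not 0 <= observed <= min(set_a_n, set_b_n):
        raise ValueError("observed overlap must lie in [0, min(a, b)]")
    expected = set_a_n * set_b_n / universe_n
    dist = hypergeom(universe_n, set_a_n, set_b_n)
    if observed < expected:
        p = float(dist.cdf(observed))
        fold = np.inf if observed == 0 else expected / observed
        direction = "depleted"
    elif observed > expected:
        p = float(dist.sf(observed - 1))
        fold = np.inf if expected == 0 else observed / expected
        direction = "enriched"
    else:
        p = float(min(dist.cdf(observed), dist.sf(observed - 1)))
        fold = 1.0
        direction = "as_expected"
    return GeneSetOverlapResult(
        universe_n=universe_n,
        set_a_n=set_a_n,
        set_b_n=set_b_n,
        observed_overlap=observed,
        expected_overlap=expected,
        fold=float(fold),
        direction=direction,
        hypergeom_p=min(p, 1.0),
    )


def hypergeom_overlap(
    set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str]
) -> GeneSetOverlapResult:
    """Hypergeometric overlap test between two explicit gene sets."""
    universe = set(universe)
    a, b = set(set_a), set(set_b)
    if not a <= universe or not b <= universe:
        raise ValueError("both sets must be subsets of the universe")
    return hypergeom_overlap_counts(len(universe), len(a), len(b), len(a & b))
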