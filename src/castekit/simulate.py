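"""Synthetic multi-species two-caste transcriptome generator with known ground truth.

Emulates the study design this package analyses: a handful of social-wasp-like
species, each contributing one pooled queen and one pooled worker brain RNA-seq
sample, with a conserved "toolkit" of caste genes shared by all species on top
of species-private caste genes, strong per-species expression offsets, and
negative-binomial count noise at a fixed dispersion.  Every planted effect is
returned as a :class:`SimulationTruth` so downstream stages (harmonisation,
normalisation, differential expression, overlap statistics, the SVM transfer
framework) can be tested for recovery of a known signal.

Generative model, per orthogroup ``g`` and species ``s``:

* baseline transcript abundance ``a_g`` ~ LogNormal(meanlog 3, sdlog 1.2)
  on the TPM scale — spans a realistic bulk dynamic range (~1–1000 TPM);
* a per-gene per-species offset ``o_gs`` ~ Normal(0, species_sd) on the log2
  scale, which makes species identity the dominant axis of raw expression
  variation, as in real cross-species data;
* a signed caste effect ``e_gs`` (log2 queen/worker fold change): queens
  express ``a_g * 2**(o_gs + e_gs/2)``, workers ``a_g * 2**(o_gs - e_gs/2)``;
* read counts NB(mean = lib_size * relative read share, dispersion), where a
  gene's read share is proportional to abundance x effective length.

All randomness flows from one ``numpy`` Generator seeded by the config; the
draw order is fixed and documented in :func:`_realize`, so an identical config
reproduces the dataset exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .orthology import CountTable, OrthogroupMap

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "generate_dataset",
    "generate_group_asymmetry",
    "sample_nb",
    "write_dataset",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the design being emulated: nine species, a couple of
    thousand orthogroups, a ~150-gene direction-consistent toolkit, 2-fold
    mean caste effects, strong species offsets and NB dispersion 0.1 (the
    value used for single pooled samples per caste throughout the package).
    """

    n_species: int = 9
    n_orthogroups: int = 3000
    toolkit_size: int = 150
    private_caste_frac: float = 0.05
    effect_log2fc: float = 1.0
    species_sd: float = 0.5
    dispersion: float = 0.1
    lib_size: int = 1_000_000
    length_range: tuple[int, int] = (500, 3000)
    dup_rate: float = 0.05
    missing_rate: float = 0.02
    group_labels: tuple[tuple[str, ...], tuple[str, ...]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if not 0 <= self.toolkit_size <= self.n_orthogroups:
            raise ValueError("toolkit_size must lie in [0, n_orthogroups]")
        for name in ("private_caste_frac", "dup_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.effect_log2fc < 0 or self.species_sd < 0 or self.dispersion < 0:
            raise ValueError("effect_log2fc, species_sd and dispersion must be >= 0")
        if self.lib_size <= 0:
            raise ValueError("lib_size must be positive")
        lo, hi = self.length_range
        if lo <= 0 or hi < lo:
            raise ValueError("length_range must be a positive (lo, hi) pair with lo <= hi")
        if self.group_labels is not None:
            g1, g2 = self.group_labels
            if set(g1) & set(g2):
                raise ValueError("group_labels must be disjoint")
            if set(g1) | set(g2) != set(self.species_names):
                raise ValueError("group_labels must partition the species")

    @property
    def species_names(self) -> list[str]:
        return [f"sp{i + 1}" for i in range(self.n_species)]

    @property
    def orthogroup_ids(self) -> list[str]:
        return [f"OG{i:07d}" for i in range(self.n_orthogroups)]


@dataclass
class SimulationTruth:
    """Ground truth of the planted effects.

    ``table`` is indexed by orthogroup with columns ``toolkit_member`` (bool:
    biased with one direction in every species), ``direction`` ('queen',
    'worker' or 'none') and ``biased_species`` (tuple).  ``log2fc`` holds the
    signed true queen/worker log2 fold change per (orthogroup, species).
    """

    table: pd.DataFrame
    log2fc: pd.DataFrame

    @property
    def toolkit_genes(self) -> frozenset[str]:
        return frozenset(self.table.index[self.table["toolkit_member"]])

    def to_json(self, path: str | Path) -> None:
        payload = {
            og: {
                "toolkit_member": bool(row["toolkit_member"]),
                "direction": row["direction"],
                "biased_species": list(row["biased_species"]),
                "true_log2fc": {
                    sp: float(self.log2fc.at[og, sp]) for sp in self.log2fc.columns
                },
            }
            for og, row in self.table.iterrows()
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def sample_nb(mean: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    """Draw NB counts with the mean/dispersion parameterisation var = mu + phi*mu^2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0.0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _plant_symmetric(config: SimulationConfig, rng: np.random.Generator):
    """Effects for generate_dataset: shared toolkit + species-private caste genes."""
    n_og, n_sp = config.n_orthogroups, config.n_species
    effects = np.zeros((n_og, n_sp))
    toolkit = np.zeros(n_og, dtype=bool)
    toolkit[: config.toolkit_size] = True
    if config.toolkit_size:
        dirs = rng.choice([1.0, -1.0], size=config.toolkit_size)
        effects[: config.toolkit_size, :] = dirs[:, None] * config.effect_log2fc
    remaining = np.arange(config.toolkit_size, n_og)
    n_private = int(round(config.private_caste_frac * remaining.size))
    if n_private:
        priv_ogs = rng.choice(remaining, size=n_private, replace=False)
        priv_sp = rng.integers(0, n_sp, size=n_private)
        priv_dirs = rng.choice([1.0, -1.0], size=n_private)
        effects[priv_ogs, priv_sp] = priv_dirs * config.effect_log2fc
    return effects, toolkit


def generate_dataset(
    config: SimulationConfig,
) -> tuple[CountTable, OrthogroupMap, SimulationTruth]:
    """Generate counts, orthogroup map and ground truth for a symmetric design."""
    rng = np.random.default_rng(config.seed)
    effects, toolkit = _plant_symmetric(config, rng)
    return _realize(config, rng, effects, toolkit)


def generate_group_asymmetry(
    config: SimulationConfig, shared_size: int, extra_group2_size: int
) -> tuple[CountTable, OrthogroupMap, SimulationTruth]:
    """Generate a two-group design where group 2 carries extra caste genes.

    Group 1 species use only a shared toolkit (``shared_size`` genes biased in
    every species); group 2 species additionally share ``extra_group2_size``
    caste genes of their own.  A classifier trained on group 1 should therefore
    transfer to group 2 better than the reverse: group-2 training dilutes its
    feature ranking with genes that carry no signal in group 1.
    """
    if config.group_labels is None:
        half = config.n_species // 2
        names = config.species_names
        config = dataclasses.replace(
            config, group_labels=(tuple(names[:half]), tuple(names[half:]))
        )
    g1, g2 = config.group_labels
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 species")
    if shared_size + extra_group2_size > config.n_orthogroups:
        raise ValueError("shared_size + extra_group2_size exceeds n_orthogroups")
    n_og, n_sp = config.n_orthogroups, config.n_species
    sp_index = {sp: i for i, sp in enumerate(config.species_names)}
    effects = np.zeros((n_og, n_sp))
    toolkit = np.zeros(n_og, dtype=bool)
    toolkit[:shared_size] = True
    rng = np.random.default_rng(config.seed)
    if shared_size:
        dirs = rng.choice([1.0, -1.0], size=shared_size)
        effects[:shared_size, :] = dirs[:, None] * config.effect_log2fc
    if extra_group2_size:
        extra_dirs = rng.choice([1.0, -1.0], size=extra_group2_size)
        cols = [sp_index[sp] for sp in g2]
        sl = slice(shared_size, shared_size + extra_group2_size)
        for c in cols:
            effects[sl, c] = extra_dirs * config.effect_log2fc
    return _realize(config, rng, effects, toolkit)


def _realize(
    config: SimulationConfig,
    rng: np.random.Generator,
    effects: np.ndarray,
    toolkit: np.ndarray,
) -> tuple[CountTable, OrthogroupMap, SimulationTruth]:
    """Sample a dataset given the signed log2 caste-effect matrix.

    Fixed draw order (after effect planting): baseline abundances; species
    offsets; per-cell gene lengths; missing mask; duplication mask, isoform
    numbers, Dirichlet shares and isoform lengths; then NB counts species by
    species, queen sample before worker sample.
    """
    n_og, n_sp = config.n_orthogroups, config.n_species
    species = config.species_names
    og_ids = config.orthogroup_ids

    base = rng.lognormal(mean=3.0, sigma=1.2, size=n_og)
    offsets = rng.normal(0.0, config.species_sd, size=(n_og, n_sp))
    lo, hi = config.length_range
    lengths = rng.integers(lo, hi + 1, size=(n_og, n_sp))
    missing = rng.random((n_og, n_sp)) < config.missing_rate
    dup = (rng.random((n_og, n_sp)) < config.dup_rate) & ~missing
    n_iso = np.ones((n_og, n_sp), dtype=int)
    n_iso[dup] = rng.integers(2, 4, size=int(dup.sum()))

    # Dirichlet(1,..) expression shares and lengths for duplicated cells,
    # drawn in row-major cell order.
    shares: dict[tuple[int, int], np.ndarray] = {}
    iso_lengths: dict[tuple[int, int], np.ndarray] = {}
    for gi, si in zip(*np.nonzero(dup)):
        k = n_iso[gi, si]
        shares[(gi, si)] = rng.dirichlet(np.ones(k))
        iso_lengths[(gi, si)] = rng.integers(lo, hi + 1, size=k)

    abundance = base[:, None] * np.exp2(offsets)  # caste-free abundance per cell
    tables: dict[str, pd.DataFrame] = {}
    groups: dict[str, dict[str, list[str]]] = {og: {} for og in og_ids}

    for si, sp in enumerate(species):
        gene_ids: list[str] = []
        gene_len: list[int] = []
        rel_q: list[float] = []
        rel_w: list[float] = []
        for gi in range(n_og):
            if missing[gi, si]:
                continue
            a = abundance[gi, si]
            q = a * 2.0 ** (effects[gi, si] / 2.0)
            w = a * 2.0 ** (-effects[gi, si] / 2.0)
            if n_iso[gi, si] == 1:
                gid = f"{sp}_g{gi:05d}"
                groups[og_ids[gi]][sp] = [gid]
                gene_ids.append(gid)
                gene_len.append(int(lengths[gi, si]))
                rel_q.append(q)
                rel_w.append(w)
            else:
                sh = shares[(gi, si)]
                ln = iso_lengths[(gi, si)]
                ids = [f"{sp}_g{gi:05d}_i{j + 1}" for j in range(len(sh))]
                groups[og_ids[gi]][sp] = ids
                for j, gid in enumerate(ids):
                    gene_ids.append(gid)
                    gene_len.append(int(ln[j]))
                    rel_q.append(q * sh[j])
                    rel_w.append(w * sh[j])
        gene_len_arr = np.asarray(gene_len, dtype=float)
        counts = {}
        for caste, rel in (("queen", rel_q), ("worker", rel_w)):
            rel_arr = np.asarray(rel)
            read_share = rel_arr * gene_len_arr
            mu = config.lib_size * read_share / read_share.sum()
            counts[caste] = sample_nb(mu, config.dispersion, rng)
        tables[sp] = pd.DataFrame(
            {
                "length": np.asarray(gene_len, dtype=np.int64),
                "queen": counts["queen"].astype(np.int64),
                "worker": counts["worker"].astype(np.int64),
            },
            index=pd.Index(gene_ids, name="gene_id"),
        )

    # drop orthogroups absent everywhere (possible at high missing_rate)
    groups = {og: row for og, row in groups.items() if row}
    ogmap = OrthogroupMap(species=species, groups=groups)

    biased = effects != 0.0
    direction = np.where(
        biased.any(axis=1),
        np.where(effects.sum(axis=1) > 0, "queen", "worker"),
        "none",
    )
    truth_table = pd.DataFrame(
        {
            "toolkit_member": toolkit,
            "direction": direction,
            "biased_species": [
                tuple(np.asarray(species)[biased[gi]]) for gi in range(n_og)
            ],
        },
        index=pd.Index(og_ids, name="orthogroup"),
    )
    log2fc = pd.DataFrame(effects, index=truth_table.index, columns=species)
    return CountTable(tables), ogmap, SimulationTruth(table=truth_table, log2fc=log2fc)


def write_dataset(
    counts: CountTable,
    ogmap: OrthogroupMap,
    truth: SimulationTruth,
    directory: str | Path,
) -> None:
    """Write per-species count TSVs, Orthogroups.tsv and the truth JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    counts.to_dir(directory)
    ogmap.to_tsv(directory / "Orthogroups.tsv")
    truth.to_json(directory / "truth.json")
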