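"""Orthogroup harmonisation: from per-species gene counts to a cross-species matrix.

Cross-species expression comparison needs one row per orthogroup and one value
per (species, caste) sample.  Real orthology tables are messier than that:
within-species duplications put several gene isoforms into one orthogroup cell,
and assembly gaps leave some cells empty.  This module implements the three
harmonisation regimes used throughout the package:

``strict_single_copy``
    keep only orthogroups with exactly one member gene in every species;
``isoforms3``
    allow up to three isoforms per (orthogroup, species) cell and represent the
    cell by its most highly expressed member;
``isoforms3_na2``
    as above, but additionally tolerate up to two species with no member gene,
    imputing a neutral pseudo-gene with a raw count of 10 in each caste.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CASTES = ("queen", "worker")

MODES = ("strict_single_copy", "isoforms3", "isoforms3_na2")
_MODE_ALIASES = {
    "strict": "strict_single_copy",
    "iso3": "isoforms3",
    "iso3na2": "isoforms3_na2",
}


@dataclass
class CountTable:
    """Raw gene-level counts for one pooled sample per caste in each species.

    ``tables`` maps species name to a DataFrame indexed by gene ID with columns
    ``length`` (effective length, bp), ``queen`` and ``worker`` (raw counts).
    """

    tables: dict[str, pd.DataFrame]

    def __post_init__(self) -> None:
        for sp, df in self.tables.items():
            missing = {"length", "queen", "worker"} - set(df.columns)
            if missing:
                raise ValueError(f"count table for {sp!r} lacks columns {sorted(missing)}")
            if not df.index.is_unique:
                raise ValueError(f"duplicate gene IDs in species {sp!r}")
            if (df["length"] <= 0).any():
                raise ValueError(f"non-positive gene length in species {sp!r}")

    @property
    def species(self) -> list[str]:
        return list(self.tables)

    def library_sizes(self) -> pd.Series:
        """Total raw counts per (species, caste) sample."""
        idx = pd.MultiIndex.from_product([self.species, CASTES], names=["species", "caste"])
        vals = [int(self.tables[sp][caste].sum()) for sp, caste in idx]
        return pd.Series(vals, index=idx, name="library_size")

    def to_dir(self, directory: str | Path) -> None:
        """Write one TSV per species (gene_id, length, queen_count, worker_count)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for sp, df in self.tables.items():
            out = df.rename(columns={"queen": "queen_count", "worker": "worker_count"})
            out.to_csv(directory / f"{sp}.counts.tsv", sep="\t", index_label="gene_id")

    @classmethod
    def from_dir(cls, directory: str | Path) -> "CountTable":
        directory = Path(directory)
        tables = {}
        for path in sorted(directory.glob("*.counts.tsv")):
            sp = path.name[: -len(".counts.tsv")]
            df = pd.read_csv(path, sep="\t", index_col="gene_id")
            tables[sp] = df.rename(columns={"queen_count": "queen", "worker_count": "worker"})
        if not tables:
            raise FileNotFoundError(f"no *.counts.tsv files under {directory}")
        return cls(tables)


@dataclass
class OrthogroupMap:
    """orthogroup -> species -> member gene IDs; species absent from a cell are missing.

    ``audit`` records orthogroups dropped by harmonisation steps with the reason,
    so dataset-dependent row counts stay traceable.  ``collapsed_from`` records,
    after :func:`collapse_isoforms`, how many isoforms each retained cell had.
    """

    species: list[str]
    groups: dict[str, dict[str, list[str]]]
    audit: dict[str, str] = field(default_factory=dict)
    collapsed_from: dict[str, dict[str, int]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.groups)

    def to_tsv(self, path: str | Path) -> None:
        """Write in the Orthofinder Orthogroups.tsv dialect (comma-space gene lists)."""
        with open(path, "w") as fh:
            fh.write("Orthogroup\t" + "\t".join(self.species) + "\n")
            for og in sorted(self.groups):
                cells = [", ".join(self.groups[og].get(sp, [])) for sp in self.species]
                fh.write(og + "\t" + "\t".join(cells) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "OrthogroupMap":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            species = header[1:]
            groups: dict[str, dict[str, list[str]]] = {}
            for line in fh:
                cells = line.rstrip("\n").split("\t")
                og = cells[0]
                row = {}
                for sp, cell in zip(species, cells[1:]):
                    cell = cell.strip()
                    if cell:
                        row[sp] = [g.strip() for g in cell.split(",")]
                groups[og] = row
        return cls(species=species, groups=groups)


@dataclass
class HarmonizedMatrix:
    """One expression value per (orthogroup, species, caste), with provenance flags.

    ``counts`` is orthogroups x (species, caste); ``lengths`` holds the effective
    length of the representative gene per cell; ``filled`` flags imputed cells;
    ``collapsed_from`` gives the pre-collapse isoform count (1 = untouched).
    ``library_sizes`` are the totals of the *source* count tables, so CPM and
    library-size adjustments refer to the full sequenced library rather than the
    harmonised subset.
    """

    counts: pd.DataFrame
    lengths: pd.DataFrame
    filled: pd.DataFrame
    collapsed_from: pd.DataFrame
    genes: pd.DataFrame
    library_sizes: pd.Series
    mode: str

    @property
    def species(self) -> list[str]:
        return list(self.lengths.columns)

    def to_tsv(self, path: str | Path) -> None:
        flat = self.counts.copy()
        flat.columns = [f"{sp}.{caste}" for sp, caste in flat.columns]
        for sp in self.species:
            flat[f"{sp}.filled"] = self.filled[sp].astype(int)
            flat[f"{sp}.n_isoforms"] = self.collapsed_from[sp]
        flat.to_csv(path, sep="\t", index_label="orthogroup")


def _check_genes_exist(counts: CountTable, ogmap: OrthogroupMap) -> None:
    for og, row in ogmap.groups.items():
        for sp, genes in row.items():
            table = counts.tables.get(sp)
            if table is None:
                raise ValueError(f"species {sp!r} in orthogroup map has no count table")
            for g in genes:
                if g not in table.index:
                    raise ValueError(
                        f"gene {g!r} (orthogroup {og}, species {sp}) absent from count table"
                    )


def collapse_isoforms(
    counts: CountTable, ogmap: OrthogroupMap, max_isoforms: int = 3
) -> OrthogroupMap:
    """Reduce every (orthogroup, species) cell to its most highly expressed gene.

    "Most highly expressed" means the largest queen+worker summed raw count;
    ties break by lexicographic gene ID for determinism.  Orthogroups where any
    species contributes more than ``max_isoforms`` members are dropped and the
    reason recorded in the returned map's ``audit``.
    """
    if max_isoforms < 1:
        raise ValueError("max_isoforms must be >= 1")
    _check_genes_exist(counts, ogmap)
    groups: dict[str, dict[str, list[str]]] = {}
    audit = dict(ogmap.audit)
    collapsed_from: dict[str, dict[str, int]] = {}
    for og, row in ogmap.groups.items():
        over = [sp for sp, genes in row.items() if len(genes) > max_isoforms]
        if over:
            audit[og] = f"dropped: >{max_isoforms} isoforms in {','.join(sorted(over))}"
            logger.info("orthogroup %s %s", og, audit[og])
            continue
        new_row: dict[str, list[str]] = {}
        sizes: dict[str, int] = {}
        for sp, genes in row.items():
            if not genes:
                continue
            table = counts.tables[sp]
            # max by summed expression, lexicographic gene ID as tie-break
            best = min(genes, key=lambda g: (-(table.at[g, "queen"] + table.at[g, "worker"]), g))
            new_row[sp] = [best]
            sizes[sp] = len(genes)
        groups[og] = new_row
        collapsed_from[og] = sizes
    return OrthogroupMap(
        species=list(ogmap.species), groups=groups, audit=audit, collapsed_from=collapsed_from
    )


def strict_single_copy(ogmap: OrthogroupMap) -> OrthogroupMap:
    """Retain only orthogroups with exactly one member gene in every species."""
    groups = {}
    audit = dict(ogmap.audit)
    for og, row in ogmap.groups.items():
        if all(len(row.get(sp, [])) == 1 for sp in ogmap.species):
            groups[og] = {sp: list(genes) for sp, genes in row.items()}
        else:
            audit[og] = "dropped: not single-copy in all species"
    return OrthogroupMap(species=list(ogmap.species), groups=groups, audit=audit)


def fill_missing(
    ogmap: OrthogroupMap,
    counts: CountTable,
    max_missing_species: int = 2,
    fill_count: int = 10,
    mode: str = "isoforms3_na2",
) -> HarmonizedMatrix:
    """Build the harmonised matrix, imputing orthogroups missing in few species.

    Must run after :func:`collapse_isoforms` (every cell at most one gene).  An
    orthogroup missing in at most ``max_missing_species`` species gets a neutral
    pseudo-gene there: ``fill_count`` raw counts in each caste and the median
    effective length of its present members.  Orthogroups missing in more
    species are dropped.
    """
    n_species = len(ogmap.species)
    if max_missing_species >= n_species:
        raise ValueError("max_missing_species must be smaller than the number of species")
    _check_genes_exist(counts, ogmap)

    rows = []
    audit = dict(ogmap.audit)
    for og in sorted(ogmap.groups):
        row = ogmap.groups[og]
        for sp, genes in row.items():
            if len(genes) > 1:
                raise ValueError(
                    f"orthogroup {og} has {len(genes)} genes in {sp}; collapse isoforms first"
                )
        present = [sp for sp in ogmap.species if row.get(sp)]
        n_missing = n_species - len(present)
        if n_missing > max_missing_species:
            audit[og] = f"dropped: missing in {n_missing} species"
            continue
        med_len = int(statistics.median(
            counts.tables[sp].at[row[sp][0], "length"] for sp in present
        ))
        rec: dict = {"orthogroup": og}
        for sp in ogmap.species:
            if row.get(sp):
                g = row[sp][0]
                t = counts.tables[sp]
                rec[(sp, "queen")] = int(t.at[g, "queen"])
                rec[(sp, "worker")] = int(t.at[g, "worker"])
                rec[(sp, "length")] = int(t.at[g, "length"])
                rec[(sp, "gene")] = g
                rec[(sp, "filled")] = False
                rec[(sp, "n_iso")] = ogmap.collapsed_from.get(og, {}).get(sp, 1)
            else:
                rec[(sp, "queen")] = fill_count
                rec[(sp, "worker")] = fill_count
                rec[(sp, "length")] = med_len
                rec[(sp, "gene")] = None
                rec[(sp, "filled")] = True
                rec[(sp, "n_iso")] = 0
        rows.append(rec)

    index = pd.Index([r["orthogroup"] for r in rows], name="orthogroup")
    species = list(ogmap.species)
    sample_cols = pd.MultiIndex.from_product([species, list(CASTES)], names=["species", "caste"])
    count_mat = pd.DataFrame(
        [[r[(sp, caste)] for sp, caste in sample_cols] for r in rows],
        index=index, columns=sample_cols, dtype=np.int64,
    )
    lengths = pd.DataFrame(
        [[r[(sp, "length")] for sp in species] for r in rows],
        index=index, columns=species, dtype=np.int64,
    )
    filled = pd.DataFrame(
        [[r[(sp, "filled")] for sp in species] for r in rows],
        index=index, columns=species, dtype=bool,
    )
    n_iso = pd.DataFrame(
        [[r[(sp, "n_iso")] for sp in species] for r in rows],
        index=index, columns=species, dtype=np.int64,
    )
    genes = pd.DataFrame(
        [[r[(sp, "gene")] for sp in species] for r in rows],
        index=index, columns=species, dtype=object,
    )
    return HarmonizedMatrix(
        counts=count_mat,
        lengths=lengths,
        filled=filled,
        collapsed_from=n_iso,
        genes=genes,
        library_sizes=counts.library_sizes(),
        mode=mode,
    )


def harmonize(
    counts: CountTable,
    ogmap: OrthogroupMap,
    mode: str = "isoforms3_na2",
    max_isoforms: int = 3,
    max_missing_species: int = 2,
    fill_count: int = 10,
) -> HarmonizedMatrix:
    """Run the full harmonisation for one of the three regimes.

    Modes (aliases in parentheses): ``strict_single_copy`` (``strict``),
    ``isoforms3`` (``iso3``), ``isoforms3_na2`` (``iso3na2``).
    """
    mode = _MODE_ALIASES.get(mode, mode)
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    if mode == "strict_single_copy":
        reduced = strict_single_copy(ogmap)
        hm = fill_missing(reduced, counts, max_missing_species=0, fill_count=fill_count, mode=mode)
        assert not hm.filled.values.any() and (hm.collapsed_from.values == 1).all()
        return hm
    collapsed = collapse_isoforms(counts, ogmap, max_isoforms=max_isoforms)
    if mode == "isoforms3":
        return fill_missing(collapsed, counts, max_missing_species=0,
                            fill_count=fill_count, mode=mode)
    return fill_missing(collapsed, counts, max_missing_species=max_missing_species,
                        fill_count=fill_count, mode=mode)
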