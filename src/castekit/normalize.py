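"""Expression normalisation chain producing the species-free [-1, 1] matrix.

The steps, in pipeline order: TPM per sample -> log2(TPM + 1) -> quantile
normalisation across all samples -> low-expression filtering on CPM ->
per-gene per-species mean scaling ``(x - m) / m``.

With exactly two samples (queen, worker) per species, the mean scaling reduces
to ``(Q - W) / (Q + W)`` for the queen sample and its negation for the worker,
so every retained value lies in [-1, 1] and the per-species pair sums to zero.
This removes species-level expression location entirely: multiplying one
species' expression by any positive constant leaves the output unchanged,
which is what makes samples comparable across species in the principal
component analysis and the caste classifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .orthology import HarmonizedMatrix

logger = logging.getLogger(__name__)


@dataclass
class NormalizedMatrix:
    """Orthogroups x (species, caste) values on the species-free [-1, 1] scale."""

    values: pd.DataFrame
    steps: list[str] = field(default_factory=list)

    @property
    def species(self) -> list[str]:
        return list(self.values.columns.get_level_values("species").unique())


def compute_tpm(counts: pd.DataFrame, lengths: pd.DataFrame) -> pd.DataFrame:
    """Transcripts per million per sample column.

    ``counts`` has (species, caste) columns, ``lengths`` one column per species
    (the representative gene's effective length applies to both castes).
    """
    if (lengths <= 0).any().any():
        raise ValueError("effective lengths must be positive")
    len_by_sample = lengths.loc[counts.index, counts.columns.get_level_values("species")]
    rate = counts.to_numpy(dtype=float) / len_by_sample.to_numpy(dtype=float)
    totals = rate.sum(axis=0)
    if np.any(totals == 0):
        raise ValueError("a sample has zero total length-normalised count")
    tpm = 1e6 * rate / totals
    return pd.DataFrame(tpm, index=counts.index, columns=counts.columns)


def log_quantile(matrix: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(x + pseudocount), then quantile normalisation over all samples.

    Each column's sorted values are replaced by the across-column mean of the
    sorted columns; ties get the average of the reference values they span.
    Afterwards every column holds the same multiset of values (up to tie
    averaging), so only rank information survives within a sample.
    """
    if (matrix < 0).any().any():
        raise ValueError("expression values must be non-negative")
    logged = np.log2(matrix.to_numpy(dtype=float) + pseudocount)
    n = logged.shape[0]
    reference = np.sort(logged, axis=0).mean(axis=1)
    positions = np.arange(1, n + 1, dtype=float)
    out = np.empty_like(logged)
    for j in range(logged.shape[1]):
        ranks = pd.Series(logged[:, j]).rank(method="average").to_numpy()
        out[:, j] = np.interp(ranks, positions, reference)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def filter_low_expression(
    counts: pd.DataFrame,
    library_sizes: pd.Series,
    threshold_cpm: float = 10.0,
    exempt: pd.DataFrame | None = None,
) -> pd.Series:
    """Mask of orthogroups expressed above ``threshold_cpm`` counts per million.

    An orthogroup is dropped when, in at least one species, its CPM falls below
    the threshold in *both* the queen and the worker sample — a single
    well-expressed caste rescues the gene.  ``exempt`` (orthogroup x species
    bool) marks cells that may not trigger the drop; the pipeline passes the
    imputed-cell flags here, since an imputed pseudo-count carries no evidence
    of low expression.
    """
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    libs = library_sizes.loc[counts.columns].to_numpy(dtype=float)
    cpm = 1e6 * counts.to_numpy(dtype=float) / libs
    low = cpm < threshold_cpm
    species = counts.columns.get_level_values("species")
    keep = pd.Series(True, index=counts.index)
    for sp in species.unique():
        cols = np.flatnonzero(species == sp)
        both_low = low[:, cols].all(axis=1)
        if exempt is not None:
            both_low &= ~exempt[sp].to_numpy()
        keep &= ~both_low
    return keep


def species_scale(matrix: pd.DataFrame) -> NormalizedMatrix:
    """Per-gene per-species mean scaling ``(x - m) / m``.

    ``m`` is the mean over that species' samples.  Rows with ``m == 0`` for
    some species are set to 0 there and the event logged; upstream filtering
    should preclude this.
    """
    species = matrix.columns.get_level_values("species")
    out = np.empty(matrix.shape)
    vals = matrix.to_numpy(dtype=float)
    for sp in species.unique():
        cols = np.flatnonzero(species == sp)
        m = vals[:, cols].mean(axis=1)
        zero = m == 0
        if zero.any():
            logger.warning(
                "species %s: %d orthogroups with zero mean expression scaled to 0",
                sp, int(zero.sum()),
            )
        safe_m = np.where(zero, 1.0, m)
        scaled = (vals[:, cols] - m[:, None]) / safe_m[:, None]
        scaled[zero, :] = 0.0
        out[:, cols] = scaled
    values = pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return NormalizedMatrix(values=values, steps=["species_scale"])


def pca(matrix: pd.DataFrame, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Centred PCA on samples (columns become observations).

    Returns per-sample component scores and the explained variance fractions.
    """
    X = matrix.to_numpy(dtype=float).T
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    n_components = min(n_components, X.shape[0], X.shape[1])
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return (
        pd.DataFrame(scores, index=matrix.columns, columns=cols),
        model.explained_variance_ratio_,
    )


def normalize_pipeline(
    hm: HarmonizedMatrix,
    threshold_cpm: float = 10.0,
    pseudocount: float = 1.0,
) -> NormalizedMatrix:
    """Full chain: TPM -> log2(+1) -> quantile -> CPM filter -> species scaling.

    The CPM filter runs before the species scaling so that retained rows can
    never have a zero species mean; imputed cells are exempt from triggering
    the filter.
    """
    tpm = compute_tpm(hm.counts, hm.lengths)
    lq = log_quantile(tpm, pseudocount=pseudocount)
    keep = filter_low_expression(
        hm.counts, hm.library_sizes, threshold_cpm=threshold_cpm, exempt=hm.filled
    )
    nm = species_scale(lq.loc[keep])
    nm.steps = [
        "tpm",
        f"log2(+{pseudocount:g})",
        "quantile",
        f"cpm_filter(<{threshold_cpm:g})",
        "species_scale",
    ]
    return nm
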