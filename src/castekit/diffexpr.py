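"""Caste-biased gene calls from one pooled sample per caste.

With a single pooled queen and worker sample per species there is no replication
to estimate dispersion from, so differential expression uses a negative-binomial
*conditional* exact test with a fixed dispersion (default 0.1, a typical value
for pooled bulk libraries).  Under the null of equal relative abundance, both
counts are NB(mu, phi) with a common mean; conditioning on the observed total
``n = q + w`` makes the distribution of the queen count free of ``mu``:

    P(Q = a | Q + W = n)  ~  C(a + r - 1, a) * C(n - a + r - 1, n - a),
    r = 1 / phi,

a Polya (Dirichlet-multinomial with two cells) weight.  The two-sided p-value
sums the conditional probabilities of all outcomes no more probable than the
observed one — the "small-p sum" convention, which guarantees p <= 1.  Unequal
library sizes are handled by rescaling both counts to the geometric-mean
library before conditioning.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .orthology import HarmonizedMatrix

__all__ = [
    "nb_exact_test",
    "log2_fold_change",
    "bh_fdr",
    "de_table",
    "call_degs",
]

DE_RULES = ("fdr_0.05", "raw_p_0.05")

# relative tolerance when deciding which outcomes are "no more probable than
# observed": protects the tie at the observed outcome from round-off
_TIE_REL = 1e-12


def _conditional_log_weights(total: int, r: float) -> np.ndarray:
    a = np.arange(total + 1, dtype=float)
    lw = (
        gammaln(a + r) - gammaln(a + 1.0)
        + gammaln(total - a + r) - gammaln(total - a + 1.0)
    )
    return lw - logsumexp(lw)


def _equalize(count_q: int, count_w: int, lib_q: int, lib_w: int) -> tuple[int, int]:
    """Rescale both counts to the geometric-mean library size (nearest integer)."""
    common = float(np.sqrt(float(lib_q) * float(lib_w)))
    return int(round(count_q * common / lib_q)), int(round(count_w * common / lib_w))


def nb_exact_test(
    count_q: int, count_w: int, lib_q: int, lib_w: int, dispersion: float = 0.1
) -> float:
    """Two-sided conditional NB exact test of equal queen/worker abundance."""
    if count_q < 0 or count_w < 0:
        raise ValueError("counts must be non-negative")
    if lib_q <= 0 or lib_w <= 0:
        raise ValueError("library sizes must be positive")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    q, w = _equalize(count_q, count_w, lib_q, lib_w)
    total = q + w
    if total == 0:
        return 1.0
    lw = _conditional_log_weights(total, 1.0 / dispersion)
    observed = lw[q]
    p = float(np.exp(logsumexp(lw[lw <= observed + _TIE_REL])))
    return min(max(p, np.nextafter(0.0, 1.0)), 1.0)


def log2_fold_change(
    count_q: int, count_w: int, lib_q: int, lib_w: int, prior_count: float = 0.5
) -> float:
    """Moderated log2 queen/worker fold change on library-equalised counts.

    A prior count shrinks extreme ratios at low counts; the statistic is
    antisymmetric under a caste swap.
    """
    if lib_q <= 0 or lib_w <= 0:
        raise ValueError("library sizes must be positive")
    common = float(np.sqrt(float(lib_q) * float(lib_w)))
    q = count_q * common / lib_q
    w = count_w * common / lib_w
    return float(np.log2((q + prior_count) / (w + prior_count)))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p))):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def de_table(hm: HarmonizedMatrix, dispersion: float = 0.1) -> pd.DataFrame:
    """Per-(orthogroup, species) exact-test results.

    Columns: ``log2fc`` (queen vs worker), ``p``, ``fdr`` (BH within species)
    and ``direction`` under the default FDR < 0.05 rule.  Both counts zero
    yields p = 1 and log2fc = 0.
    """
    frames = []
    for sp in hm.species:
        lib_q = int(hm.library_sizes[(sp, "queen")])
        lib_w = int(hm.library_sizes[(sp, "worker")])
        qs = hm.counts[(sp, "queen")].to_numpy()
        ws = hm.counts[(sp, "worker")].to_numpy()
        pvals = np.array(
            [nb_exact_test(int(q), int(w), lib_q, lib_w, dispersion) for q, w in zip(qs, ws)]
        )
        lfcs = np.array(
            [
                0.0 if (q == 0 and w == 0) else log2_fold_change(int(q), int(w), lib_q, lib_w)
                for q, w in zip(qs, ws)
            ]
        )
        frames.append(
            pd.DataFrame(
                {
                    "orthogroup": hm.counts.index,
                    "species": sp,
                    "log2fc": lfcs,
                    "p": pvals,
                    "fdr": bh_fdr(pvals),
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    sig = table["fdr"] < 0.05
    table["direction"] = np.where(
        sig & (table["log2fc"] > 0), "queen", np.where(sig & (table["log2fc"] < 0), "worker", "none")
    )
    return table


def call_degs(table: pd.DataFrame, rule: str = "fdr_0.05") -> dict[str, pd.Series]:
    """Directed caste-biased gene sets per species under the chosen rule.

    ``fdr_0.05`` uses BH-adjusted values (the within-species analysis rule);
    ``raw_p_0.05`` uses unadjusted p-values (the cross-species overlap rule).
    Returns, per species, a Series mapping orthogroup -> 'queen' / 'worker'.
    """
    if rule == "fdr_0.05":
        sig = table["fdr"] < 0.05
    elif rule == "raw_p_0.05":
        sig = table["p"] < 0.05
    else:
        raise ValueError(f"unknown rule {rule!r}; expected one of {DE_RULES}")
    sig = sig & (table["log2fc"] != 0)
    out: dict[str, pd.Series] = {}
    for sp, sub in table[sig].groupby("species"):
        direction = np.where(sub["log2fc"] > 0, "queen", "worker")
        out[sp] = pd.Series(direction, index=pd.Index(sub["orthogroup"], name="orthogroup"))
    for sp in table["species"].unique():
        out.setdefault(sp, pd.Series(dtype=object))
    return out
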