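"""Post-processing statistics for the selection and convergence scans.

Covers the likelihood-ratio test p-value for the branch-site contrast under
the boundary null (a 50:50 mixture of a point mass at zero and chi-square
with one degree of freedom), Benjamini–Hochberg FDR control, and classical
hypergeometric term enrichment against a custom background (here, the
single-copy gene universe).  The branch-site ML fits themselves are external
inputs: this module only consumes (gene, lnL_null, lnL_alt) tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, hypergeom
from statsmodels.stats.multitest import multipletests

from .seqio import ValidationError


@dataclass
class LrtResult:
    gene_id: str
    delta_lnl: float          # lnL(alt) - lnL(null); the LRT statistic is 2x this
    p_value: float
    q_value: float
    significant: bool


def lrt_pvalue_mixture(two_delta_lnl: float) -> float:
    """P-value of the branch-site LRT statistic under the boundary null.

    The null distribution is an equal mixture of a point mass at zero and
    chi-square(1): p = 1 for a statistic of 0, else half the chi-square(1)
    upper tail.  Negative statistics (numerical noise from the optimiser)
    are clamped to 0 with a warning.
    """
    x = float(two_delta_lnl)
    if not np.isfinite(x):
        raise ValidationError(f"non-finite LRT statistic: {x}")
    if x < 0:
        warnings.warn(f"negative LRT statistic {x} clamped to 0")
        x = 0.0
    if x == 0.0:
        return 1.0
    return 0.5 * float(chi2.sf(x, df=1))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def lrt_table(
    fits: pd.DataFrame,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Apply the mixture LRT and BH correction to a table of ML fits.

    ``fits`` needs columns ``gene``, ``lnL_null``, ``lnL_alt``; the returned
    frame adds ``two_delta_lnl``, ``p``, ``q`` and ``significant`` (q <= fdr).
    """
    for col in ("gene", "lnL_null", "lnL_alt"):
        if col not in fits.columns:
            raise ValidationError(f"fits table lacks column {col!r}")
    out = fits.copy()
    stat = 2.0 * (out["lnL_alt"].astype(float) - out["lnL_null"].astype(float))
    out["two_delta_lnl"] = stat.clip(lower=0.0)
    out["p"] = [lrt_pvalue_mixture(x) for x in out["two_delta_lnl"]]
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["significant"] = out["q"] <= fdr
    return out


def enrich_hypergeom(
    study: Iterable[str],
    background: Iterable[str],
    term_map: Mapping[str, Iterable[str]],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Classical (hypergeometric upper-tail) term enrichment.

    ``background`` is the custom gene universe — for this pipeline, all
    single-copy genes.  Term gene sets are intersected with the background;
    per term the p-value is P(X >= k) for X ~ Hypergeom(N, K, n) with N the
    background size, K the term size, n the study size and k the observed
    overlap.  BH q-values are computed across terms.  This is the
    "classical" algorithm only: no graph decorrelation is attempted.
    """
    study_set = set(study)
    bg = set(background)
    if not study_set <= bg:
        raise ValidationError(
            f"study genes outside background: {sorted(study_set - bg)[:5]}")
    N, n = len(bg), len(study_set)
    rows = []
    for term in sorted(term_map):
        genes = set(term_map[term]) & bg
        K = len(genes)
        k = len(genes & study_set)
        p = float(hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({
            "term": term, "count": k, "term_size": K,
            "expected": n * K / N if N else 0.0, "p": min(p, 1.0),
        })
    df = pd.DataFrame(rows, columns=["term", "count", "term_size",
                                     "expected", "p"])
    if len(df):
        df["q"] = bh_fdr(df["p"].to_numpy())
        df["significant"] = df["q"] <= fdr
    else:
        df["q"] = []
        df["significant"] = []
    return df
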