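"""Differential methylation statistics and cross-assay validation.

Beta-values are tested on their raw [0, 1] scale, locus by locus, with
one BH-FDR adjustment across all loci; an optional M-value (logit)
transform is available for variance stabilization.  Cross-assay
validation (array vs pyrosequencing at the same CpG) is a plain Pearson
correlation of paired measurements.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_fdr
from .synthetic import MethylationMatrix

__all__ = ["differential_loci", "assay_crossval", "m_values"]


def m_values(beta: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Logit transform of beta-values, clipped away from {0, 1}."""
    b = np.clip(np.asarray(beta, dtype=float), eps, 1 - eps)
    return np.log2(b / (1 - b))


def differential_loci(
    beta: MethylationMatrix,
    group: np.ndarray,
    variant: str = "welch",
    use_m_values: bool = False,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Locus-wise two-sample t-tests with BH-FDR across all loci.

    Returns a DataFrame (locus, t, p, q, mean_patient, mean_control)
    sorted by q then descending |t|.
    """
    X = beta.beta
    if X.min() < 0 or X.max() > 1:
        raise ValueError("beta-values out of [0, 1]")
    g = np.asarray(group, dtype=int)
    if (g == 0).sum() < 2 or (g == 1).sum() < 2:
        raise ValueError("need at least 2 subjects per class")
    Y = m_values(X) if use_m_values else X
    t, p = sps.ttest_ind(Y[g == 1], Y[g == 0], axis=0, equal_var=(variant == "pooled"))
    _, q = bh_fdr(np.asarray(p), alpha=alpha)
    df = pd.DataFrame(
        {
            "locus": beta.locus_ids,
            "t": t,
            "p": p,
            "q": q,
            "mean_patient": X[g == 1].mean(axis=0),
            "mean_control": X[g == 0].mean(axis=0),
        }
    )
    df["abs_t"] = df["t"].abs()
    df = df.sort_values(["q", "abs_t"], ascending=[True, False]).drop(columns="abs_t")
    return df.reset_index(drop=True)


def assay_crossval(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and two-sided p between paired assay measurements."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("measurements must be paired")
    if x.size < 4:
        raise ValueError("need at least 4 pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant measurement vector")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
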