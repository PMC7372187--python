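"""Component selection and post-hoc statistics.

All tests operate on subject loadings of the final joint components.
The family for FDR correction is components x modalities, i.e. every
(component, modality) pair enters one Benjamini–Hochberg adjustment for
the group contrast and one for the reference correlation.  A component
is *selected* in a modality when both adjusted q-values fall below
alpha.  Loading/map signs are aligned so that the control group mean
exceeds the patient group mean ("control > patient" convention): a
positive map value then marks features reduced in patients.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ThresholdedMap",
    "align_component_sign",
    "group_ttest_loadings",
    "summary_ttest",
    "correlate_with_reference",
    "correlate_with_clinical",
    "partial_correlation",
    "bh_fdr",
    "zscore_threshold_map",
    "spatial_similarity",
    "match_components",
    "component_statistics",
]


@dataclass
class ThresholdedMap:
    z_map: np.ndarray  # zero mean, unit SD
    threshold: float
    mask: np.ndarray  # boolean, |z| > threshold


def align_component_sign(
    loadings: Sequence[np.ndarray],
    maps: Sequence[np.ndarray],
    group: np.ndarray,
) -> tuple[list, list]:
    """Flip (loading column, map row) pairs so mean(control) >= mean(patient).

    Applying the alignment twice is the identity.  ``group`` is 1 for
    patients, 0 for controls.
    """
    group = np.asarray(group)
    if len(np.unique(group)) < 2:
        raise ValueError("both classes required for sign alignment")
    out_load, out_maps = [], []
    for A, C in zip(loadings, maps):
        A = np.array(A, dtype=float, copy=True)
        C = np.array(C, dtype=float, copy=True)
        for c in range(A.shape[1]):
            if A[group == 0, c].mean() < A[group == 1, c].mean():
                A[:, c] *= -1.0
                C[c, :] *= -1.0
        out_load.append(A)
        out_maps.append(C)
    return out_load, out_maps


def group_ttest_loadings(
    loadings: Sequence[np.ndarray],
    group: np.ndarray,
    variant: str = "welch",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sample t-test per (component, modality) with BH-FDR over all.

    The FDR family is all M x K tests pooled together.
    """
    group = np.asarray(group)
    if (group == 0).sum() < 2 or (group == 1).sum() < 2:
        raise ValueError("need at least 2 subjects per class")
    rows = []
    for k, A in enumerate(loadings):
        A = np.asarray(A, dtype=float)
        x0, x1 = A[group == 0], A[group == 1]
        for c in range(A.shape[1]):
            if x0[:, c].std() == 0 and x1[:, c].std() == 0:
                raise ValueError(f"zero within-class variance for modality {k}, component {c}")
            t, p = sps.ttest_ind(x0[:, c], x1[:, c], equal_var=(variant == "pooled"))
            rows.append({"modality": k, "component": c, "t": float(t), "p": float(p)})
    df = pd.DataFrame(rows)
    reject, q = bh_fdr(df["p"].to_numpy(), alpha=alpha)
    df["q"] = q
    df["reject"] = reject
    return df


def summary_ttest(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
    variant: str = "pooled",
) -> tuple[float, float, float]:
    """Two-sample t-test from summary statistics; returns (t, df, p)."""
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    res = sps.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=(variant == "pooled")
    )
    if variant == "pooled":
        df = n1 + n2 - 2
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def correlate_with_reference(
    loadings: Sequence[np.ndarray],
    reference: np.ndarray,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlation of every loading column with the reference.

    Two-sided p-values, BH-FDR adjusted over the M x K family.
    """
    ref = np.asarray(reference, dtype=float).ravel()
    if ref.std() == 0:
        raise ValueError("reference is constant")
    rows = []
    for k, A in enumerate(loadings):
        A = np.asarray(A, dtype=float)
        for c in range(A.shape[1]):
            if A[:, c].std() == 0:
                raise ValueError(f"constant loading column (modality {k}, component {c})")
            r, p = sps.pearsonr(A[:, c], ref)
            rows.append({"modality": k, "component": c, "r_ref": float(r), "p_ref": float(p)})
    df = pd.DataFrame(rows)
    reject, q = bh_fdr(df["p_ref"].to_numpy(), alpha=alpha)
    df["q_ref"] = q
    df["reject_ref"] = reject
    return df


def correlate_with_clinical(
    loadings: Sequence[np.ndarray],
    clinical: pd.DataFrame,
    subset: np.ndarray | None = None,
) -> pd.DataFrame:
    """Pearson r/p of each loading column with each clinical score.

    Missing clinical entries are dropped pairwise; ``subset`` restricts
    the rows considered (e.g. patients only for age of onset).
    """
    rows = []
    for k, A in enumerate(loadings):
        A = np.asarray(A, dtype=float)
        for c in range(A.shape[1]):
            x = A[:, c]
            for score in clinical.columns:
                y = clinical[score].to_numpy(dtype=float)
                keep = np.isfinite(y)
                if subset is not None:
                    keep &= np.asarray(subset, dtype=bool)
                if keep.sum() < 4:
                    r, p = np.nan, np.nan
                else:
                    r, p = sps.pearsonr(x[keep], y[keep])
                rows.append(
                    {"modality": k, "component": c, "score": score, "r": float(r), "p": float(p), "n": int(keep.sum())}
                )
    return pd.DataFrame(rows)


def partial_correlation(x: np.ndarray, y: np.ndarray, group: np.ndarray) -> tuple[float, float]:
    """Correlation of x and y after regressing out the group effect.

    Both vectors are residualized on [intercept, group]; the p-value uses
    the t-transform with n - 3 degrees of freedom.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    g = np.asarray(group, dtype=float).ravel()
    if len(np.unique(g)) < 2:
        raise ValueError("both classes required for partial correlation")
    n = x.size
    Z = np.column_stack([np.ones(n), g])
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("degenerate residuals in partial correlation")
    r = float(np.dot(rx, ry) / (np.linalg.norm(rx) * np.linalg.norm(ry)))
    df = n - 3
    r_cl = min(max(r, -1 + 1e-15), 1 - 1e-15)
    t = r_cl * np.sqrt(df / (1 - r_cl**2))
    p = 2 * sps.t.sf(abs(t), df)
    return r, float(p)


def bh_fdr(pvalues: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up; returns (reject flags, adjusted q)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject, q


def zscore_threshold_map(component_map: np.ndarray, threshold: float) -> ThresholdedMap:
    """Z-score a component map over features and mask |z| > threshold."""
    m = np.asarray(component_map, dtype=float).ravel()
    sd = m.std()
    if sd == 0:
        raise ValueError("constant map cannot be z-scored")
    z = (m - m.mean()) / sd
    return ThresholdedMap(z_map=z, threshold=float(threshold), mask=np.abs(z) > threshold)


def spatial_similarity(map_a: np.ndarray, map_b: np.ndarray) -> float:
    """Pearson correlation of two component maps over features."""
    a = np.asarray(map_a, dtype=float).ravel()
    b = np.asarray(map_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("maps must share the feature space")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant map has undefined similarity")
    return float(sps.pearsonr(a, b)[0])


def match_components(reference_maps: np.ndarray, maps: np.ndarray) -> np.ndarray:
    """Greedy |spatial r| assignment of ``maps`` rows to ``reference_maps`` rows.

    Returns ``perm`` with ``maps[perm[c]]`` matched to ``reference_maps[c]``;
    absorbs the arbitrary ordering and sign of ICA output.
    """
    R = np.asarray(reference_maps, float)
    Mp = np.asarray(maps, float)
    sim = np.abs(np.corrcoef(R, Mp)[: R.shape[0], R.shape[0]:])
    perm = -np.ones(R.shape[0], dtype=int)
    used: set[int] = set()
    for _ in range(R.shape[0]):
        masked = sim.copy()
        masked[perm >= 0, :] = -1
        masked[:, list(used)] = -1
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        perm[i] = j
        used.add(int(j))
    return perm


def component_statistics(
    loadings: Sequence[np.ndarray],
    group: np.ndarray,
    reference: np.ndarray,
    modality_names: Sequence[str] | None = None,
    alpha: float = 0.05,
    variant: str = "welch",
) -> pd.DataFrame:
    """Full per-(component, modality) statistics table with selection flags.

    Columns: component, modality, t, p, q, r_ref, p_ref, q_ref,
    r_partial, p_partial, selected.  ``selected`` requires both the
    group-difference q and the reference-correlation q below alpha.
    """
    tt = group_ttest_loadings(loadings, group, variant=variant, alpha=alpha)
    rc = correlate_with_reference(loadings, reference, alpha=alpha)
    df = tt.merge(rc, on=["modality", "component"])
    r_part, p_part = [], []
    for _, row in df.iterrows():
        A = np.asarray(loadings[int(row["modality"])], dtype=float)
        r, p = partial_correlation(A[:, int(row["component"])], reference, group)
        r_part.append(r)
        p_part.append(p)
    df["r_partial"] = r_part
    df["p_partial"] = p_part
    df["selected"] = (df["q"] < alpha) & (df["q_ref"] < alpha)
    if modality_names is not None:
        df["modality"] = [modality_names[k] for k in df["modality"]]
    cols = [
        "component", "modality", "t", "p", "q",
        "r_ref", "p_ref", "q_ref", "r_partial", "p_partial", "selected",
    ]
    return df[cols].sort_values(["component", "modality"]).reset_index(drop=True)
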