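"""Per-modality feature matrices and their conditioning.

A *modality* is one kind of imaging-derived feature vector per subject:
functional connectivity (FC) edge strengths, fractional anisotropy (FA)
voxel values, gray matter volume (GMV) voxel values, or anything else
that can be stacked into a subjects x features matrix.  Before fusion
each modality is residualized against nuisance covariates and normalized
so that every modality contributes comparable total variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ModalityFeatures",
    "CohortDesign",
    "compute_fc",
    "vectorize_symmetric",
    "devectorize_symmetric",
    "regress_covariates",
    "normalize_modality",
]

#: Correlations are clipped to +/- (1 - FISHER_CLIP) before atanh so a
#: perfect correlation maps to a large finite z rather than infinity.
FISHER_CLIP = 1e-7


@dataclass
class ModalityFeatures:
    """One modality's subjects x features data with provenance flags."""

    modality: str
    data: np.ndarray
    feature_ids: list[str] = field(default_factory=list)
    subject_ids: list[str] = field(default_factory=list)
    normalized: bool = False
    residualized: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D subjects x features matrix")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"modality {self.modality!r} contains non-finite entries")
        n, p = self.data.shape
        if not self.feature_ids:
            self.feature_ids = [f"{self.modality}_f{i}" for i in range(p)]
        if not self.subject_ids:
            self.subject_ids = [f"sub{i:04d}" for i in range(n)]
        if len(self.feature_ids) != p:
            raise ValueError("feature_ids length does not match data columns")
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length does not match data rows")
        if len(set(self.subject_ids)) != n:
            raise ValueError("subject_ids must be unique")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def subset(self, idx: np.ndarray) -> "ModalityFeatures":
        """Row-subset (subjects) by integer or boolean index."""
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(
            self,
            data=self.data[idx].copy(),
            subject_ids=[self.subject_ids[i] for i in idx],
        )


@dataclass
class CohortDesign:
    """Group labels, nuisance covariates and clinical scores for a cohort.

    ``group`` is coded 1 for patients and 0 for controls.  ``covariates``
    and ``clinical`` are pandas DataFrames indexed like ``subject_ids``;
    clinical columns may contain missing values (dropped pairwise by the
    statistics layer), covariates may not.
    """

    subject_ids: list[str]
    group: np.ndarray
    covariates: "object" = None  # pandas.DataFrame or None
    clinical: "object" = None  # pandas.DataFrame or None

    def __post_init__(self) -> None:
        self.group = np.asarray(self.group, dtype=int)
        if self.group.shape != (len(self.subject_ids),):
            raise ValueError("group length must match subject_ids")
        if not set(np.unique(self.group)) <= {0, 1}:
            raise ValueError("group must be coded 0 (control) / 1 (patient)")
        for name in ("covariates", "clinical"):
            tab = getattr(self, name)
            if tab is not None and len(tab) != len(self.subject_ids):
                raise ValueError(f"{name} rows must align with subject_ids")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def subset(self, idx: np.ndarray) -> "CohortDesign":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CohortDesign(
            subject_ids=[self.subject_ids[i] for i in idx],
            group=self.group[idx].copy(),
            covariates=None if self.covariates is None else self.covariates.iloc[idx].reset_index(drop=True),
            clinical=None if self.clinical is None else self.clinical.iloc[idx].reset_index(drop=True),
        )


def compute_fc(
    timeseries: Sequence[np.ndarray],
    subject_ids: Sequence[str] | None = None,
    fisher_z: bool = True,
) -> ModalityFeatures:
    """Build an FC modality from per-subject region time series.

    Each element of ``timeseries`` is a timepoints x regions array.  The
    region-by-region Pearson correlation matrix is (optionally) Fisher
    z-transformed with ``|r|`` clipped to ``1 - 1e-7`` and vectorized as
    the strict upper triangle in row-major order, giving R(R-1)/2
    features per subject.

    Raises
    ------
    ValueError
        If any region series is constant (correlation undefined); the
        message names the subject and region.
    """
    mats = [np.asarray(ts, dtype=float) for ts in timeseries]
    if not mats:
        raise ValueError("need at least one subject")
    R = mats[0].shape[1]
    if R < 2:
        raise ValueError("need at least 2 regions")
    rows = []
    for s, ts in enumerate(mats):
        if ts.ndim != 2 or ts.shape[1] != R:
            raise ValueError(f"subject {s}: expected timepoints x {R} array")
        if ts.shape[0] < 3:
            raise ValueError(f"subject {s}: need at least 3 timepoints")
        sd = ts.std(axis=0)
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            sid = subject_ids[s] if subject_ids else f"sub{s:04d}"
            raise ValueError(
                f"constant time series for subject {sid}, region(s) {bad.tolist()}: "
                "correlation undefined"
            )
        r = np.corrcoef(ts, rowvar=False)
        v = vectorize_symmetric(r, _check_symmetry=False)
        if fisher_z:
            v = np.arctanh(np.clip(v, -1 + FISHER_CLIP, 1 - FISHER_CLIP))
        rows.append(v)
    iu = np.triu_indices(R, k=1)
    feature_ids = [f"fc_{i}_{j}" for i, j in zip(*iu)]
    return ModalityFeatures(
        modality="FC",
        data=np.vstack(rows),
        feature_ids=feature_ids,
        subject_ids=list(subject_ids) if subject_ids else [],
    )


def vectorize_symmetric(matrix: np.ndarray, atol: float = 1e-8, _check_symmetry: bool = True) -> np.ndarray:
    """Strict upper triangle of a symmetric matrix, row-major: (0,1),(0,2),...,(R-2,R-1)."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("expected a square matrix")
    if _check_symmetry and not np.allclose(m, m.T, atol=atol):
        raise ValueError("matrix is not symmetric within tolerance")
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu].copy()


def devectorize_symmetric(vector: np.ndarray) -> np.ndarray:
    """Inverse of :func:`vectorize_symmetric`; the diagonal is set to zero."""
    v = np.asarray(vector, dtype=float).ravel()
    # solve R(R-1)/2 = len(v) for integer R
    R = int(round((1 + np.sqrt(1 + 8 * v.size)) / 2))
    if R * (R - 1) // 2 != v.size:
        raise ValueError(f"length {v.size} is not R(R-1)/2 for any integer R")
    m = np.zeros((R, R))
    iu = np.triu_indices(R, k=1)
    m[iu] = v
    m += m.T
    return m


def regress_covariates(
    features: ModalityFeatures,
    design: CohortDesign,
    covariate_names: Sequence[str],
) -> ModalityFeatures:
    """Residualize every feature on [intercept, covariates] by OLS.

    The returned residual columns are orthogonal to every covariate
    column; the ``residualized`` flag is set.  Covariates must be
    complete; a rank-deficient design raises with the offending columns.
    """
    covariate_names = list(covariate_names)
    if not covariate_names:
        return features
    if design.covariates is None:
        raise ValueError("design has no covariates table")
    C = design.covariates[covariate_names].to_numpy(dtype=float)
    if np.isnan(C).any():
        raise ValueError("covariates contain missing values")
    n = features.n_subjects
    if C.shape[0] != n:
        raise ValueError("covariate rows do not match feature rows")
    if n <= C.shape[1] + 1:
        raise ValueError("need n_subjects > n_covariates + 1")
    X = np.column_stack([np.ones(n), C])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify which covariates are collinear with the rest
        bad = []
        for j, name in enumerate(covariate_names):
            others = np.delete(X, j + 1, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(name)
        raise ValueError(f"rank-deficient covariate design; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(X, features.data, rcond=None)
    resid = features.data - X @ beta
    return replace(features, data=resid, residualized=True)


def normalize_modality(features: ModalityFeatures) -> ModalityFeatures:
    """Center each feature and scale the whole matrix by one pooled SD.

    Every column is mean-centered, then the entire matrix is divided by a
    single scalar — the standard deviation pooled over all entries — so
    the modality as a whole has unit variance and contributes on the same
    scale as every other modality in the fusion.  Per-feature variance
    structure is preserved.
    """
    centered = features.data - features.data.mean(axis=0)
    pooled_sd = float(np.sqrt(np.mean(centered**2)))
    if pooled_sd == 0:
        raise ValueError(f"modality {features.modality!r} has zero pooled variance")
    return replace(features, data=centered / pooled_sd, normalized=True)
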