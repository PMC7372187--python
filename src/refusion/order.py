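"""Model-order selection by the minimum description length criterion.

The number of components retained per modality is chosen by the
Wax–Kailath MDL criterion on the eigenvalues of the sample covariance:
an m-component model is scored by how far the trailing eigenvalues
depart from sphericity (geometric vs arithmetic mean) plus a complexity
penalty of m(2p - m)/2 free parameters times log N.

Volumetric imaging data are spatially smooth, so the nominal sample
count overstates the information available; ``n_effective`` lets the
caller substitute a corrected effective sample size.  The pipeline also
supports bypassing MDL entirely with a fixed order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import ModalityFeatures

__all__ = ["OrderEstimate", "estimate_order_mdl"]


@dataclass
class OrderEstimate:
    modality: str
    mdl_curve: np.ndarray  # indexed by candidate order m = 0..p-1
    selected_order: int

    def __post_init__(self) -> None:
        if int(np.argmin(self.mdl_curve)) != self.selected_order:
            raise ValueError("selected_order must be the argmin of mdl_curve")


def estimate_order_mdl(
    features: ModalityFeatures,
    n_effective: int | None = None,
) -> OrderEstimate:
    """Estimate the number of signal components in one modality.

    With eigenvalues l_1 >= ... >= l_p of the sample covariance
    (p = min(n - 1, n_features)),

        MDL(m) = -N (p - m) log( GM(l_{m+1..p}) / AM(l_{m+1..p}) )
                 + 0.5 m (2p - m) log N,    m = 0 .. p-1,

    where GM/AM are geometric/arithmetic means and N is the (effective)
    number of samples.  Returns the argmin.

    When there are more features than subjects (the usual voxel-wise
    regime) the subjects cannot serve as the sample index: the trailing
    eigenvalues then follow a wide Marchenko-Pastur spread and the
    sphericity term never flattens.  The criterion is therefore applied
    in the orientation where the larger dimension provides the samples
    (features/voxels as i.i.d. draws of a subject-space vector, the
    convention of multivariate fusion toolkits); the GM/AM ratio is
    scale-invariant, so only N changes.  ``n_effective`` overrides this
    default, e.g. to discount spatially smooth voxels.
    """
    X = features.data
    n, p_feat = X.shape
    if n < 4:
        raise ValueError("need at least 4 subjects for order estimation")
    N = int(n_effective) if n_effective is not None else max(n, p_feat)
    if N < 2:
        raise ValueError("effective sample size must be >= 2")
    Xc = X - X.mean(axis=0)
    s = np.linalg.svd(Xc, compute_uv=False)
    lam = (s**2) / (n - 1)
    if not np.all(np.isfinite(lam)):
        raise ValueError("non-finite covariance eigenvalues")
    # restrict to the effective rank: dimensions removed by centering or
    # covariate residualization carry numerically-zero eigenvalues that
    # would otherwise dominate the geometric mean
    rank = int(np.sum(lam > lam[0] * 1e-10))
    p = min(n - 1, p_feat, rank)
    lam = np.maximum(lam[:p], np.finfo(float).tiny)
    log_lam = np.log(lam)

    mdl = np.empty(p)
    for m in range(p):
        rest = p - m
        log_gm = log_lam[m:].mean()
        log_am = np.log(lam[m:].mean())
        mdl[m] = -N * rest * (log_gm - log_am) + 0.5 * m * (2 * p - m) * np.log(N)
    selected = int(np.argmin(mdl))
    return OrderEstimate(modality=features.modality, mdl_curve=mdl, selected_order=selected)
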