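"""End-to-end fusion pipeline.

Order of operations mirrors the analysis workflow: subset to subjects
with complete reference data, residualize nuisance covariates (age and
sex everywhere, mean framewise displacement for FC only), normalize each
modality to equal pooled variance, choose the model order (fixed or MDL)
and the reference weight lambda (fixed or cross-validated), whiten, fit
the reference-guided multi-set CCA, refine with joint ICA, re-estimate
subject loadings on the final maps, align signs to the control > patient
convention, and compute the full statistics table plus thresholded
z-maps (|Z| > 3 for FC edge maps, |Z| > 2 for voxel maps).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .features import CohortDesign, ModalityFeatures, normalize_modality, regress_covariates
from .fusion import (
    FusionConfig,
    JointDecomposition,
    LambdaSelection,
    compute_subject_loadings,
    fit_mcca_with_reference,
    joint_ica,
    whiten,
)
from .order import estimate_order_mdl
from .stats import (
    ThresholdedMap,
    align_component_sign,
    component_statistics,
    match_components,
    zscore_threshold_map,
)

__all__ = ["FusionResult", "run_fusion", "DEFAULT_THRESHOLDS"]

#: |Z| display thresholds per modality; FC edge maps use 3, voxel maps 2.
DEFAULT_THRESHOLDS = {"FC": 3.0, "default": 2.0}


@dataclass
class FusionResult:
    decomposition: JointDecomposition
    statistics: pd.DataFrame
    thresholded: dict  # modality -> list[ThresholdedMap] per component
    joint_selected: list[int]  # components selected in every modality
    selected_component: int | None
    modality_names: list[str]
    orders: dict | None  # modality -> OrderEstimate when MDL was used
    lambda_selection: LambdaSelection | None
    config: FusionConfig  # resolved (n_components and lam concrete)
    design: CohortDesign  # after reference-completeness subsetting
    reference: np.ndarray
    prepared: list  # ModalityFeatures actually fused

    @property
    def loadings(self) -> list:
        return self.decomposition.loadings

    @property
    def maps(self) -> list:
        return self.decomposition.maps


def run_fusion(
    modalities: Sequence[ModalityFeatures],
    design: CohortDesign,
    reference: np.ndarray,
    config: FusionConfig | None = None,
    covariate_names: Sequence[str] = ("age", "sex"),
    fc_extra_covariates: Sequence[str] = ("meanFD",),
    regress: bool = True,
    alpha: float = 0.05,
    thresholds: dict | None = None,
) -> FusionResult:
    """Run the full fusion analysis on one cohort.

    Subjects with a missing reference value are dropped (the analysis
    requires complete reference data).  ``config.n_components=None``
    triggers per-modality MDL estimation (the joint order is the minimum
    across modalities); ``config.lam=None`` triggers cross-validated
    lambda selection.
    """
    config = config or FusionConfig()
    thresholds = thresholds or DEFAULT_THRESHOLDS
    reference = np.asarray(reference, dtype=float).ravel()
    n_all = design.n_subjects
    if any(m.n_subjects != n_all for m in modalities) or reference.size != n_all:
        raise ValueError("modalities, design and reference disagree on subject count")
    for m in modalities:
        if m.subject_ids != design.subject_ids:
            mismatched = [
                a for a, b in zip(m.subject_ids, design.subject_ids) if a != b
            ][:5]
            raise ValueError(
                f"subject order mismatch between modality {m.modality!r} and design "
                f"(first offenders: {mismatched})"
            )

    keep = np.isfinite(reference)
    if not keep.all():
        modalities = [m.subset(keep) for m in modalities]
        design = design.subset(keep)
        reference = reference[keep]
    if len(np.unique(design.group)) < 2:
        raise ValueError("both classes required after reference subsetting")

    prepared = []
    for m in modalities:
        feat = m
        if regress and design.covariates is not None:
            names = [c for c in covariate_names if c in design.covariates.columns]
            if m.modality == "FC":
                names += [c for c in fc_extra_covariates if c in design.covariates.columns]
            if names:
                feat = regress_covariates(feat, design, names)
        prepared.append(normalize_modality(feat))

    orders = None
    if config.n_components is None:
        orders = {f.modality: estimate_order_mdl(f) for f in prepared}
        M = max(2, min(est.selected_order for est in orders.values()))
    else:
        M = config.n_components
    max_rank = min(f.n_subjects - 1 for f in prepared)
    M = min(M, max_rank, min(f.n_features for f in prepared))
    resolved = replace(config, n_components=M)

    whitened, whiteners = [], []
    for f in prepared:
        Y, wh = whiten(f, M)
        whitened.append(Y)
        whiteners.append(wh)

    lam_sel = None
    if resolved.lam is None:
        from .fusion import select_lambda_cv

        lam_sel = select_lambda_cv(whitened, reference, resolved)
        resolved = replace(resolved, lam=lam_sel.lam)

    dec = fit_mcca_with_reference(whitened, reference, resolved)
    dec.whiteners = whiteners
    dec.canonical_maps = [
        np.linalg.pinv(dec.weights[k]) @ whiteners[k].dewhiten_ for k in range(len(prepared))
    ]

    splits = np.cumsum([f.n_features for f in prepared])[:-1]
    concat = np.hstack(dec.canonical_maps)
    if M >= 2:
        unmix, sources, ica_conv = joint_ica(concat, resolved)
        # keep the canonical ordering: match ICA rows back to the
        # canonical maps so "component 0" stays the strongest joint one
        perm = match_components(concat, sources)
        sources = sources[perm]
        unmix = unmix[perm]
    else:
        unmix = np.eye(1)
        sources = concat - concat.mean(axis=1, keepdims=True)
        ica_conv = True
    final_maps = [np.ascontiguousarray(part) for part in np.hsplit(sources, splits)]

    loadings = [
        compute_subject_loadings(prepared[k].data, final_maps[k]) for k in range(len(prepared))
    ]
    loadings, final_maps = align_component_sign(loadings, final_maps, design.group)

    dec.maps = final_maps
    dec.loadings = loadings
    dec.unmixing = unmix
    dec.ica_converged = ica_conv

    names = [f.modality for f in prepared]
    stats_table = component_statistics(
        loadings, design.group, reference, modality_names=names, alpha=alpha
    )

    thresholded = {}
    for k, f in enumerate(prepared):
        thr = thresholds.get(f.modality, thresholds.get("default", 2.0))
        thresholded[f.modality] = [
            zscore_threshold_map(final_maps[k][c], thr) for c in range(M)
        ]

    sel = stats_table.groupby("component")["selected"].all()
    joint_selected = [int(c) for c in sel.index[sel]]
    selected_component = None
    if joint_selected:
        qsum = stats_table.groupby("component")["q_ref"].sum()
        selected_component = int(min(joint_selected, key=lambda c: qsum.loc[c]))

    return FusionResult(
        decomposition=dec,
        statistics=stats_table,
        thresholded=thresholded,
        joint_selected=joint_selected,
        selected_component=selected_component,
        modality_names=names,
        orders=orders,
        lambda_selection=lam_sel,
        config=resolved,
        design=design,
        reference=reference,
        prepared=prepared,
    )
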