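"""Subset replication: rerun the fusion on subsets and quantify agreement.

Two schemes are supported: ``two_thirds`` draws R random subsamples of
floor(2n/3) subjects (patients and controls subsampled independently to
preserve the class ratio), and ``by_label`` takes explicit user-supplied
subsets (e.g. left-focus patients with their matched controls).  Every
subset gets the identical pipeline; the selected component's map in each
run is compared to every other run by absolute spatial correlation, and
an overlap mask marks features surviving the z-threshold in at least two
runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import CohortDesign, ModalityFeatures
from .fusion import FusionConfig
from .pipeline import DEFAULT_THRESHOLDS, FusionResult, run_fusion
from .stats import spatial_similarity, zscore_threshold_map

__all__ = ["SimilarityReport", "run_subset_replication"]


@dataclass
class SimilarityReport:
    runs: list[str]  # e.g. ["all", "subset_1", "subset_2"]
    similarity: dict  # modality -> DataFrame (runs x runs) of |spatial r|
    overlap: dict  # modality -> bool array, surviving threshold in >= 2 runs
    selected_components: dict  # run -> component index used for comparison
    results: dict  # run -> FusionResult

    def min_pairwise(self, modality: str) -> float:
        m = self.similarity[modality].to_numpy()
        iu = np.triu_indices(m.shape[0], k=1)
        return float(m[iu].min())


def _chosen_map(result: FusionResult, k: int, fallback: np.ndarray | None) -> tuple[int, np.ndarray]:
    """Map used for cross-run comparison in modality k.

    Prefer the run's own selected joint component; if the run selected
    nothing, fall back to the component whose map best matches the full
    run's selected map (|r|), so stability can still be quantified.
    """
    comp = result.selected_component
    maps = result.decomposition.maps[k]
    if comp is None:
        if fallback is None:
            comp = 0
        else:
            sims = [abs(spatial_similarity(maps[c], fallback)) for c in range(maps.shape[0])]
            comp = int(np.argmax(sims))
    return comp, maps[comp]


def run_subset_replication(
    modalities: Sequence[ModalityFeatures],
    design: CohortDesign,
    reference: np.ndarray,
    config: FusionConfig | None = None,
    scheme: str = "two_thirds",
    n_repeats: int = 10,
    seed: int = 0,
    subset_labels: Mapping[str, np.ndarray] | None = None,
    thresholds: dict | None = None,
    **fusion_kwargs,
) -> SimilarityReport:
    """Full-cohort run plus subset reruns with a cross-run similarity report.

    ``scheme='two_thirds'`` draws ``n_repeats`` seeded subsamples without
    replacement (floor(2/3) per class); ``scheme='by_label'`` uses
    ``subset_labels`` (name -> boolean mask or integer indices over the
    cohort).  Subsets must retain both classes and at least
    n_components + 2 subjects.
    """
    config = config or FusionConfig()
    thresholds = thresholds or DEFAULT_THRESHOLDS
    reference = np.asarray(reference, dtype=float).ravel()

    full = run_fusion(modalities, design, reference, config, thresholds=thresholds, **fusion_kwargs)
    M = full.config.n_components

    subsets: dict[str, np.ndarray] = {}
    if scheme == "two_thirds":
        rng = np.random.default_rng(seed)
        pat = np.flatnonzero(design.group == 1)
        ctl = np.flatnonzero(design.group == 0)
        for r in range(n_repeats):
            take_p = rng.choice(pat, size=len(pat) * 2 // 3, replace=False)
            take_c = rng.choice(ctl, size=len(ctl) * 2 // 3, replace=False)
            subsets[f"subset_{r + 1}"] = np.sort(np.concatenate([take_p, take_c]))
    elif scheme == "by_label":
        if not subset_labels:
            raise ValueError("scheme='by_label' requires subset_labels")
        for name, sel in subset_labels.items():
            sel = np.asarray(sel)
            idx = np.flatnonzero(sel) if sel.dtype == bool else sel.astype(int)
            subsets[name] = np.sort(idx)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    results: dict[str, FusionResult] = {"all": full}
    for name, idx in subsets.items():
        g = design.group[idx]
        if len(np.unique(g)) < 2:
            raise ValueError(f"subset {name!r} lost a class")
        if idx.size < M + 2:
            raise ValueError(f"subset {name!r} smaller than n_components + 2")
        sub_mod = [m.subset(idx) for m in modalities]
        sub_design = design.subset(idx)
        results[name] = run_fusion(
            sub_mod, sub_design, reference[idx], config, thresholds=thresholds, **fusion_kwargs
        )

    run_names = list(results)
    similarity: dict[str, pd.DataFrame] = {}
    overlap: dict[str, np.ndarray] = {}
    selected: dict[str, int] = {}
    for k, name_k in enumerate(full.modality_names):
        chosen = {}
        for rn in run_names:
            fallback = None
            if rn != "all":
                _, fallback = _chosen_map(full, k, None)
            comp, cmap = _chosen_map(results[rn], k, fallback)
            chosen[rn] = cmap
            selected.setdefault(rn, comp)
        mat = np.eye(len(run_names))
        for i in range(len(run_names)):
            for j in range(i + 1, len(run_names)):
                r = abs(spatial_similarity(chosen[run_names[i]], chosen[run_names[j]]))
                mat[i, j] = mat[j, i] = r
        similarity[name_k] = pd.DataFrame(mat, index=run_names, columns=run_names)
        thr = thresholds.get(name_k, thresholds.get("default", 2.0))
        masks = np.vstack(
            [zscore_threshold_map(chosen[rn], thr).mask for rn in run_names]
        )
        overlap[name_k] = masks.sum(axis=0) >= 2
    return SimilarityReport(
        runs=run_names,
        similarity=similarity,
        overlap=overlap,
        selected_components=selected,
        results=results,
    )
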