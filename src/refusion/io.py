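"""Reading and writing the pipeline's file formats.

A *cohort directory* holds one delimited matrix per modality
(``<MOD>.csv``: header row of feature ids, first column ``subject_id``),
a phenotype table (``phenotype.csv``), the reference (``reference.csv``:
``subject_id,beta``) and, for synthetic cohorts, a ground-truth bundle
(``truth.json`` plus loading/source matrices).  A *results directory*
holds per-modality maps and loadings, the statistics table, and a JSON
run manifest with config snapshot, input checksums, seed, timings and
convergence flags.  See FORMATS.md for the full layout.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .features import CohortDesign, ModalityFeatures
from .pipeline import FusionResult
from .synthetic import MethylationMatrix, SimulationConfig, SyntheticGroundTruth

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_results",
    "write_manifest",
    "write_methylation",
    "read_methylation",
    "nifti_to_features",
    "features_to_nifti",
]

PHENO_COLS = ["subject_id", "group", "age", "sex", "meanFD", "onset_age", "MMSE", "HSCT"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _matrix_df(data: np.ndarray, subject_ids, feature_ids) -> pd.DataFrame:
    df = pd.DataFrame(data, columns=feature_ids)
    df.insert(0, "subject_id", subject_ids)
    return df


def write_cohort(
    out_dir: str | Path,
    modalities: list[ModalityFeatures],
    reference: np.ndarray,
    design: CohortDesign,
    truth: SyntheticGroundTruth | None = None,
) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for m in modalities:
        _matrix_df(m.data, m.subject_ids, m.feature_ids).to_csv(out / f"{m.modality}.csv", index=False)
    pheno = pd.DataFrame({"subject_id": design.subject_ids, "group": design.group})
    if design.covariates is not None:
        pheno = pd.concat([pheno, design.covariates.reset_index(drop=True)], axis=1)
    if design.clinical is not None:
        pheno = pd.concat([pheno, design.clinical.reset_index(drop=True)], axis=1)
    pheno.to_csv(out / "phenotype.csv", index=False)
    pd.DataFrame({"subject_id": design.subject_ids, "beta": np.asarray(reference, float)}).to_csv(
        out / "reference.csv", index=False
    )
    if truth is not None:
        meta = {
            "config": dataclasses.asdict(truth.config),
            "target_component_index": truth.target_index,
            "modalities": [m.modality for m in modalities],
        }
        (out / "truth.json").write_text(json.dumps(meta, indent=2, default=list))
        for k, m in enumerate(modalities):
            np.savetxt(out / f"truth_sources_{m.modality}.csv", truth.sources[k], delimiter=",")
            np.savetxt(out / f"truth_loadings_{m.modality}.csv", truth.loadings[k], delimiter=",")
    return out


def read_cohort(cohort_dir: str | Path) -> tuple[list[ModalityFeatures], np.ndarray, CohortDesign]:
    d = Path(cohort_dir)
    pheno = pd.read_csv(d / "phenotype.csv")
    subject_ids = pheno["subject_id"].astype(str).tolist()
    cov_cols = [c for c in ("age", "sex", "meanFD") if c in pheno.columns]
    clin_cols = [c for c in pheno.columns if c not in cov_cols + ["subject_id", "group"]]
    design = CohortDesign(
        subject_ids=subject_ids,
        group=pheno["group"].to_numpy(int),
        covariates=pheno[cov_cols] if cov_cols else None,
        clinical=pheno[clin_cols] if clin_cols else None,
    )
    ref_df = pd.read_csv(d / "reference.csv")
    ref_df = ref_df.set_index("subject_id").loc[subject_ids]
    reference = ref_df["beta"].to_numpy(float)
    modalities = []
    skip = {"phenotype.csv", "reference.csv", "methylation.csv"}
    for f in sorted(d.glob("*.csv")):
        if f.name in skip or f.name.startswith("truth"):
            continue
        df = pd.read_csv(f)
        if "subject_id" not in df.columns:
            continue
        df = df.set_index("subject_id").loc[subject_ids]
        modalities.append(
            ModalityFeatures(
                modality=f.stem,
                data=df.to_numpy(float),
                feature_ids=df.columns.tolist(),
                subject_ids=subject_ids,
            )
        )
    if not modalities:
        raise FileNotFoundError(f"no modality matrices found in {d}")
    return modalities, reference, design


def write_methylation(out_dir: str | Path, meth: MethylationMatrix, group: np.ndarray) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(meth.beta, columns=meth.locus_ids)
    df.insert(0, "subject_id", meth.subject_ids)
    df.insert(1, "group", np.asarray(group, int))
    df.to_csv(out / "methylation.csv", index=False)
    return out / "methylation.csv"


def read_methylation(path: str | Path) -> tuple[MethylationMatrix, np.ndarray]:
    df = pd.read_csv(path)
    group = df.pop("group").to_numpy(int)
    sids = df.pop("subject_id").astype(str).tolist()
    return MethylationMatrix(beta=df.to_numpy(float), locus_ids=df.columns.tolist(), subject_ids=sids), group


def write_results(out_dir: str | Path, result: FusionResult) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.statistics.to_csv(out / "component_statistics.csv", index=False)
    dec = result.decomposition
    for k, name in enumerate(result.modality_names):
        np.savetxt(out / f"maps_{name}.csv", dec.maps[k], delimiter=",")
        _matrix_df(
            dec.loadings[k],
            result.design.subject_ids,
            [f"comp{c}" for c in range(dec.n_components)],
        ).to_csv(out / f"loadings_{name}.csv", index=False)
        zs = np.vstack([tm.z_map for tm in result.thresholded[name]])
        np.savetxt(out / f"zmaps_{name}.csv", zs, delimiter=",")
    D = dec.variates
    pair_corr = [
        float(np.corrcoef(D[i][:, 0], D[j][:, 0])[0, 1])
        for i in range(len(D))
        for j in range(i + 1, len(D))
    ]
    meta = {
        "selected_component": result.selected_component,
        "joint_selected": result.joint_selected,
        "top_component_interset_corr": pair_corr,
        "n_components": int(result.config.n_components),
        "lambda": float(result.config.lam),
        "converged": bool(dec.converged),
        "ica_converged": bool(dec.ica_converged),
        "objective_final": float(dec.objective_trace[-1]) if len(dec.objective_trace) else None,
        "achieved_top_canonical_correlation": float(np.max(np.abs(dec.ref_correlations[:, 0]))),
    }
    (out / "fusion_summary.json").write_text(json.dumps(meta, indent=2))
    return out


def write_manifest(
    out_dir: str | Path,
    config: dict,
    seed: int,
    input_files: list[str | Path] = (),
    timings: dict | None = None,
    convergence: dict | None = None,
) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "software": {"name": "refusion", "version": __version__, "python": platform.python_version()},
        "seed": int(seed),
        "config": config,
        "inputs": {str(p): _sha256(Path(p)) for p in input_files},
        "timings_s": timings or {},
        "convergence": convergence or {},
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def nifti_to_features(volume_paths, mask_path, modality: str) -> ModalityFeatures:
    """Stack 3-D NIfTI volumes into a subjects x voxels matrix.

    The binary mask defines feature order: ascending linear index with x
    fastest (Fortran order over the [x, y, z] array).
    """
    import nibabel as nib

    mask = np.asanyarray(nib.load(str(mask_path)).dataobj) > 0
    idx = np.flatnonzero(mask.ravel(order="F"))
    rows = []
    for p in volume_paths:
        vol = np.asanyarray(nib.load(str(p)).dataobj, dtype=float)
        if vol.shape != mask.shape:
            raise ValueError(f"volume {p} shape {vol.shape} != mask shape {mask.shape}")
        rows.append(vol.ravel(order="F")[idx])
    return ModalityFeatures(
        modality=modality,
        data=np.vstack(rows),
        feature_ids=[f"vox{i}" for i in idx],
    )


def features_to_nifti(values: np.ndarray, mask_path, out_path) -> None:
    """Write a feature vector back into the mask's voxel grid."""
    import nibabel as nib

    img = nib.load(str(mask_path))
    mask = np.asanyarray(img.dataobj) > 0
    idx = np.flatnonzero(mask.ravel(order="F"))
    values = np.asarray(values, float).ravel()
    if values.size != idx.size:
        raise ValueError(f"{values.size} values for {idx.size} mask voxels")
    flat = np.zeros(mask.size)
    flat[idx] = values
    vol = flat.reshape(mask.shape, order="F")
    nib.save(nib.Nifti1Image(vol.astype(np.float32), img.affine), str(out_path))
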