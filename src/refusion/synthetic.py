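"""Synthetic multimodal cohorts with planted ground truth.

No imaging or methylation data accompany the analysis this package
reproduces, so every downstream stage is exercised on simulated cohorts
that carry the statistical structure the fusion model assumes:

* each modality k is ``loadings_k @ sources_k + noise`` with sparse,
  heavy-tailed (Laplacian) source rows so the ICA stage is identifiable;
* exactly one *target* component shares its subject loading across all
  modalities (one common latent plus small modality-specific noise);
* the reference (methylation beta at the target CpG) is the same latent
  mixed with independent noise so that corr(reference, target loading)
  is approximately ``rho_ref``;
* patients' target loadings are shifted down by ``group_effect_d``
  standard deviations (control > patient convention);
* clinical scores are noisy linear functions of the target loading with
  configured correlations;
* non-target loadings are independent standard normals per modality, so
  only the target component carries cross-modality and reference
  structure.

Methylation matrices are simulated separately as Beta-distributed
beta-values in [0, 1], with a configurable mean shift at target loci
(defaults 0.34 patient vs 0.28 control, SD 0.06 — the scale of a
strongly differentially methylated promoter CpG in blood).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import CohortDesign, ModalityFeatures

__all__ = [
    "SimulationConfig",
    "SyntheticGroundTruth",
    "MethylationMatrix",
    "generate_multimodal",
    "generate_methylation",
]

#: SD of the modality-specific noise added to the shared target latent.
TARGET_LOADING_JITTER = 0.2

MODALITY_NAMES = ("FC", "FA", "GMV")


@dataclass
class SimulationConfig:
    """Parameters of the multimodal cohort generator.

    Defaults mirror the study conditions the analysis is designed for: a
    33-patient / 40-control cohort, three modalities, five latent
    sources per modality, a reference correlating -0.4 with the target
    loading (higher methylation, lower loading) and a 0.8-SD group
    shift (control > patient).
    """

    n_patients: int = 33
    n_controls: int = 40
    n_modalities: int = 3
    features_per_modality: tuple[int, ...] = (300, 250, 200)
    n_sources: int = 5
    target_component_index: int = 0
    rho_ref: float = -0.4
    group_effect_d: float = 0.8
    clinical_effects: Mapping[str, float] = field(
        default_factory=lambda: {"onset_age": 0.6, "MMSE": 0.4, "HSCT": 0.3}
    )
    noise_sd: float = 0.5
    source_sparsity: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        self.features_per_modality = tuple(int(p) for p in self.features_per_modality)
        if min(self.n_patients, self.n_controls, self.n_modalities, self.n_sources) < 1:
            raise ValueError("all counts must be >= 1")
        if len(self.features_per_modality) != self.n_modalities:
            raise ValueError("features_per_modality length must equal n_modalities")
        if not np.isfinite([self.rho_ref, self.group_effect_d, self.noise_sd]).all():
            raise ValueError("non-finite generator parameters")
        if abs(self.rho_ref) >= 1:
            raise ValueError("|rho_ref| must be < 1")
        if not (0 < self.source_sparsity <= 1):
            raise ValueError("source_sparsity must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not (0 <= self.target_component_index < self.n_sources):
            raise ValueError("target_component_index out of range")
        if any(p < self.n_sources for p in self.features_per_modality):
            raise ValueError("each modality needs at least as many features as sources")
        for name, rho in self.clinical_effects.items():
            if abs(rho) >= 1:
                raise ValueError(f"clinical effect {name!r} must have |rho| < 1")


@dataclass
class SyntheticGroundTruth:
    sources: list  # per modality: n_sources x features
    loadings: list  # per modality: subjects x n_sources
    reference: np.ndarray
    group: np.ndarray
    clinical: pd.DataFrame
    config: SimulationConfig

    @property
    def target_index(self) -> int:
        return self.config.target_component_index


@dataclass
class MethylationMatrix:
    beta: np.ndarray  # subjects x loci, values in [0, 1]
    locus_ids: list[str]
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.min() < 0 or self.beta.max() > 1:
            raise ValueError("beta-values must lie in [0, 1]")
        if len(self.locus_ids) != len(set(self.locus_ids)):
            raise ValueError("duplicated locus_ids")
        if self.beta.shape != (len(self.subject_ids), len(self.locus_ids)):
            raise ValueError("beta shape does not match ids")


def _sparse_laplacian_sources(rng: np.random.Generator, n_sources: int, p: int, sparsity: float) -> np.ndarray:
    """Heavy-tailed sparse source rows (super-Gaussian, ICA-identifiable)."""
    S = np.zeros((n_sources, p))
    n_active = max(2, int(round(sparsity * p)))
    for m in range(n_sources):
        idx = rng.choice(p, size=n_active, replace=False)
        S[m, idx] = rng.laplace(0.0, 1.0, size=n_active)
    return S


def generate_multimodal(
    config: SimulationConfig,
) -> tuple[list[ModalityFeatures], np.ndarray, CohortDesign, SyntheticGroundTruth]:
    """Generate one multimodal cohort.

    Returns ``(modalities, reference, design, truth)``.  With
    ``noise_sd=0`` every modality's data equals ``loadings @ sources``
    exactly; two calls with the same config are byte-identical.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients + config.n_controls
    K = config.n_modalities
    Mx = config.n_sources
    tgt = config.target_component_index

    group = np.concatenate([np.ones(config.n_patients, int), np.zeros(config.n_controls, int)])
    subject_ids = [f"{'tle' if g else 'hc'}{i:04d}" for i, g in enumerate(group)]

    # shared latent for the target component, plus the group shift on
    # the loadings (patients lower by group_effect_d SD)
    z = rng.standard_normal(n)
    shift = -config.group_effect_d * group
    common = z + shift

    loadings, sources, modalities = [], [], []
    for k in range(K):
        p = config.features_per_modality[k]
        A = rng.standard_normal((n, Mx))
        A[:, tgt] = z + TARGET_LOADING_JITTER * rng.standard_normal(n) + shift
        S = _sparse_laplacian_sources(rng, Mx, p, config.source_sparsity)
        X = A @ S
        if config.noise_sd > 0:
            X = X + config.noise_sd * rng.standard_normal((n, p))
        name = MODALITY_NAMES[k] if k < len(MODALITY_NAMES) else f"MOD{k}"
        modalities.append(
            ModalityFeatures(modality=name, data=X, subject_ids=list(subject_ids))
        )
        loadings.append(A)
        sources.append(S)

    # reference shares the latent z: corr(reference, target loading) ~ rho_ref
    rho = config.rho_ref
    z_std = (z - z.mean()) / z.std()
    reference = rho * z_std + np.sqrt(1 - rho**2) * rng.standard_normal(n)

    # clinical scores driven by the (standardized) common target loading
    common_std = (common - common.mean()) / common.std()
    clinical = {}
    score_scale = {"onset_age": (18.0, 8.0), "MMSE": (27.0, 2.0), "HSCT": (70.0, 10.0)}
    for score, rho_c in config.clinical_effects.items():
        s = rho_c * common_std + np.sqrt(1 - rho_c**2) * rng.standard_normal(n)
        loc, scale = score_scale.get(score, (0.0, 1.0))
        clinical[score] = loc + scale * s
    clinical = pd.DataFrame(clinical)
    if "onset_age" in clinical:
        # disease onset is undefined for controls
        clinical.loc[group == 0, "onset_age"] = np.nan

    covariates = pd.DataFrame(
        {
            "age": np.clip(rng.normal(28.0, 8.0, n), 16, 70),
            "sex": rng.integers(0, 2, n).astype(float),
            "meanFD": np.abs(rng.normal(0.12, 0.04, n)),
        }
    )
    design = CohortDesign(
        subject_ids=list(subject_ids), group=group, covariates=covariates, clinical=clinical
    )
    truth = SyntheticGroundTruth(
        sources=sources,
        loadings=loadings,
        reference=reference.copy(),
        group=group.copy(),
        clinical=clinical.copy(),
        config=config,
    )
    return modalities, reference, design, truth


def generate_methylation(
    n_patients: int,
    n_controls: int,
    n_loci: int,
    target_loci: Sequence[int] = (0,),
    delta: float = 0.06,
    mean_control: float = 0.28,
    sd: float = 0.06,
    seed: int = 0,
) -> tuple[MethylationMatrix, np.ndarray]:
    """Simulate a beta-value matrix with differentially methylated target loci.

    Beta-values are drawn from Beta(a, b) distributions parameterized by
    mean/SD via method of moments.  At target loci the patient mean is
    ``mean_control + delta``; elsewhere both groups share a per-locus
    baseline mean drawn uniformly in [0.1, 0.9].  Group labels returned
    as 1 = patient, 0 = control (patients first).
    """
    rng = np.random.default_rng(seed)
    target_loci = np.asarray(target_loci, dtype=int)
    if target_loci.size and (target_loci.min() < 0 or target_loci.max() >= n_loci):
        raise ValueError("target_loci out of range")
    m_pat = mean_control + delta
    for m in (mean_control, m_pat):
        if not (0 < m < 1):
            raise ValueError(f"group mean {m} outside (0, 1); delta incompatible with support")
        if sd**2 >= m * (1 - m):
            raise ValueError("sd too large for a Beta distribution with this mean")

    n = n_patients + n_controls
    group = np.concatenate([np.ones(n_patients, int), np.zeros(n_controls, int)])

    base_means = rng.uniform(0.1, 0.9, size=n_loci)
    means = np.tile(base_means, (n, 1))
    for locus in target_loci:
        means[group == 0, locus] = mean_control
        means[group == 1, locus] = m_pat

    # method-of-moments Beta(a, b); cap sd below the support limit per locus
    sd_l = np.minimum(sd, 0.9 * np.sqrt(means * (1 - means)))
    nu = means * (1 - means) / sd_l**2 - 1.0
    a = means * nu
    b = (1.0 - means) * nu
    beta = rng.beta(a, b)

    locus_ids = [f"cg{j:08d}" for j in range(n_loci)]
    subject_ids = [f"{'tle' if g else 'hc'}{i:04d}" for i, g in enumerate(group)]
    return MethylationMatrix(beta=beta, locus_ids=locus_ids, subject_ids=subject_ids), group
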