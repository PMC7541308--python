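"""Synthetic two-batch TMT proteome generator with planted ground truth.

The generator emulates the study design the analysis assumes: 16 samples
(2 genotypes x 2 ages x 4 replicates, one TMT batch per age group), a set of
co-expressed modules driven by latent eigenprofiles with genotype and/or age
effects, background proteins that are pure noise, a tranche of proteins
quantified in exactly one batch (50% missing), and cell-type marker sets with
known overlap into planted modules.

The generative model is a spiked latent factor per module m:

    e_m  = standardize( beta_geno[m] * I(KO) + beta_age[m] * I(old)
                        + eigen_noise_sd * N(0, 1) )
    x_pj = baseline_p + loading_p * e_m[j] + N(0, noise_sd^2)

Effects enter at the eigenprofile level (matching module-level trait
correlation), and eigenprofiles are standardized across samples so the
within-module correlation is controlled by ``loading`` and ``noise_sd``
alone: mean pairwise r ~= 1 / (1 + noise_sd^2) at unit loadings (~0.6 at the
default noise_sd 0.8).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import AbundanceMatrix, GeneSetCollection, SampleMeta


@dataclass
class SimConfig:
    n_modules: int = 5
    proteins_per_module: int = 40
    n_background: int = 200
    n_half_missing: int = 40
    n_per_group: int = 4
    effect_size_genotype: tuple[float, ...] = (1.0, 0.0, 0.8, 0.0, 0.0)
    effect_size_age: tuple[float, ...] = (0.0, 1.0, 0.8, 0.0, 0.0)
    loading_mean: float = 1.0
    loading_sd: float = 0.2
    noise_sd: float = 0.8
    eigen_noise_sd: float = 0.25
    baseline_mean: float = 12.0
    baseline_sd: float = 1.0
    marker_size: int = 40
    marker_overlap: dict[str, tuple[int, float]] = field(
        default_factory=lambda: {
            "Microglia": (1, 0.8),
            "Astrocyte": (2, 0.5),
            "Oligodendrocyte": (3, 0.4),
            "Neuron": (4, 0.5),
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_modules, self.proteins_per_module, self.n_per_group) < 1:
            raise ValueError("module counts and group size must be positive")
        if self.n_background < 0 or self.n_half_missing < 0:
            raise ValueError("counts must be non-negative")
        if len(self.effect_size_genotype) != self.n_modules:
            raise ValueError("effect_size_genotype must have one entry per module")
        if len(self.effect_size_age) != self.n_modules:
            raise ValueError("effect_size_age must have one entry per module")
        if self.noise_sd < 0 or self.eigen_noise_sd < 0:
            raise ValueError("noise scales must be non-negative")
        for name, (mod, frac) in self.marker_overlap.items():
            if not 1 <= mod <= self.n_modules:
                raise ValueError(f"marker {name!r}: module index {mod} out of range")
            if not 0 <= frac <= 1:
                raise ValueError(f"marker {name!r}: overlap fraction must be in [0, 1]")


@dataclass
class SyntheticTruth:
    """Ground truth for recovery testing (0 = background)."""

    true_module: dict[str, int]
    effect_genotype: dict[int, float]
    effect_age: dict[int, float]
    marker_members: dict[str, list[str]]
    half_missing: dict[str, bool]

    def labels_for(self, proteins: list[str]) -> np.ndarray:
        return np.array([self.true_module[p] for p in proteins], dtype=int)


def _design(n_per_group: int) -> list[SampleMeta]:
    samples = []
    for age in ("young", "old"):
        for geno in ("WT", "KO"):
            for r in range(1, n_per_group + 1):
                samples.append(
                    SampleMeta(
                        sample_id=f"{geno}_{age}_{r}",
                        genotype=geno,
                        age_group=age,
                        batch=age,  # one TMT batch per age group
                        replicate=r,
                    )
                )
    return samples


def simulate(config: SimConfig) -> tuple[AbundanceMatrix, SyntheticTruth, GeneSetCollection]:
    """Generate the abundance matrix, its ground truth, and marker gene sets."""
    rng = np.random.default_rng(config.seed)
    samples = _design(config.n_per_group)
    n_s = len(samples)
    ko = np.array([1.0 if s.genotype == "KO" else 0.0 for s in samples])
    old = np.array([1.0 if s.age_group == "old" else 0.0 for s in samples])

    eigenprofiles = np.empty((config.n_modules, n_s))
    for m in range(config.n_modules):
        e = (
            config.effect_size_genotype[m] * ko
            + config.effect_size_age[m] * old
            + config.eigen_noise_sd * rng.standard_normal(n_s)
        )
        sd = e.std()
        eigenprofiles[m] = (e - e.mean()) / (sd if sd > 0 else 1.0)

    proteins: list[str] = []
    true_module: dict[str, int] = {}
    half_missing: dict[str, bool] = {}
    rows: list[np.ndarray] = []

    def add_protein(pid: str, module: int, half: bool) -> None:
        baseline = rng.normal(config.baseline_mean, config.baseline_sd)
        noise = rng.normal(0.0, config.noise_sd, size=n_s)
        if module > 0:
            loading = rng.normal(config.loading_mean, config.loading_sd)
            profile = baseline + loading * eigenprofiles[module - 1] + noise
        else:
            profile = baseline + noise
        proteins.append(pid)
        true_module[pid] = module
        half_missing[pid] = half
        rows.append(profile)

    idx = 0
    for m in range(1, config.n_modules + 1):
        for _ in range(config.proteins_per_module):
            idx += 1
            add_protein(f"P{idx:05d}", m, half=False)
    for _ in range(config.n_background):
        idx += 1
        add_protein(f"P{idx:05d}", 0, half=False)
    # half-missing proteins are planted module members (cycled over modules)
    half_ids: list[str] = []
    for i in range(config.n_half_missing):
        idx += 1
        pid = f"P{idx:05d}"
        add_protein(pid, (i % config.n_modules) + 1, half=True)
        half_ids.append(pid)

    matrix = AbundanceMatrix(
        proteins=proteins,
        samples=samples,
        values=np.vstack(rows) if rows else np.zeros((0, n_s)),
        mask=np.ones((len(proteins), n_s), dtype=bool),
    )
    # alternate which batch retains each half-missing protein
    for j, pid in enumerate(half_ids):
        matrix = inject_half_missing(matrix, [pid], batch="young" if j % 2 == 0 else "old")

    marker_members: dict[str, list[str]] = {}
    complete_by_module = {
        m: [p for p in proteins if true_module[p] == m and not half_missing[p]]
        for m in range(config.n_modules + 1)
    }
    for name, (mod, frac) in config.marker_overlap.items():
        n_in = int(round(frac * config.marker_size))
        pool_in = complete_by_module[mod]
        n_in = min(n_in, len(pool_in))
        members = list(rng.choice(pool_in, size=n_in, replace=False))
        pool_out = [p for p in proteins
                    if true_module[p] != mod and not half_missing[p]]
        n_out = min(config.marker_size - n_in, len(pool_out))
        members += list(rng.choice(pool_out, size=n_out, replace=False))
        marker_members[name] = [str(p) for p in members]

    truth = SyntheticTruth(
        true_module=true_module,
        effect_genotype={m + 1: config.effect_size_genotype[m] for m in range(config.n_modules)},
        effect_age={m + 1: config.effect_size_age[m] for m in range(config.n_modules)},
        marker_members=marker_members,
        half_missing=half_missing,
    )
    markers = GeneSetCollection(sets=dict(marker_members))
    return matrix, truth, markers


def inject_half_missing(
    matrix: AbundanceMatrix, protein_ids: list[str], batch: str
) -> AbundanceMatrix:
    """Mask the listed proteins in every sample *outside* the given batch.

    In the two-equal-batch design this leaves exactly 50% of each listed
    protein's cells missing.  Idempotent; unknown protein ids are fatal.
    """
    row_of = {p: i for i, p in enumerate(matrix.proteins)}
    unknown = [p for p in protein_ids if p not in row_of]
    if unknown:
        raise KeyError(f"unknown protein id(s): {unknown}")
    keep_cols = matrix.batch_columns(batch)
    mask = matrix.mask.copy()
    other = np.setdiff1d(np.arange(matrix.n_samples), keep_cols)
    for p in protein_ids:
        mask[row_of[p], other] = False
    return AbundanceMatrix(
        proteins=list(matrix.proteins),
        samples=list(matrix.samples),
        values=matrix.values.copy(),
        mask=mask,
    )
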