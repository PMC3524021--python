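"""Case-control simulation under four epistatic disease models.

Disease-locus genotypes are drawn under Hardy-Weinberg equilibrium at a
common minor-allele frequency (MAF); disease status is assigned by a
penetrance function and the cohort is filled by retrospective rejection
sampling to exactly the requested numbers of cases and controls. With
baseline risk alpha, genotype g_i the minor-allele count at disease locus i:

model 1 (multiplicative)                  f(g1, g2) = alpha * (1 + lambda)^(g1 + g2)
model 2 (interaction multiplicative)      f(g1, g2) = alpha * (1 + lambda)^(g1 * g2)
model 3 (interaction threshold)           f(g1, g2) = alpha * (1 + lambda * 1[g1 >= 1 and g2 >= 1])
model 4 (three-locus genotypic)           f(g1, g2, g3) = alpha * theta^1[(g1, g2, g3) in risk set]

The default model-4 risk set is every genotype combination carrying at least
one minor allele at all three loci.

Each disease locus is observed only through a genotyped tag marker in
linkage disequilibrium r^2 with it: marker alleles are drawn from the
two-locus haplotype distribution with equal MAFs and D = sqrt(r^2) * p(1-p),
so r^2 = 1 makes the marker identical to the (then discarded) locus. The
remaining markers are null SNPs under HWE with MAFs uniform on a background
range. Disease-marker positions are placed uniformly at random among the M
columns and recorded only in the returned :class:`SimTruth`.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np

from .dataset import GenotypeDataset

__all__ = [
    "DiseaseModelSpec",
    "SimConfig",
    "SimTruth",
    "penetrance",
    "penetrance_table",
    "prevalence",
    "simulate_dataset",
    "replicate_batch",
    "replicate_seed",
]

MODEL_ALIASES = {
    1: "model1_multiplicative",
    2: "model2_interaction_multiplicative",
    3: "model3_threshold",
    4: "model4_three_locus",
}
MODEL_NAMES = tuple(MODEL_ALIASES.values())


@dataclasses.dataclass
class DiseaseModelSpec:
    """Penetrance-model parameters.

    ``marginal_effect`` is lambda (models 1-3), ``genotypic_effect`` is
    theta (model 4). ``risk_set`` (model 4 only) overrides the default set
    of high-risk genotype tuples.
    """

    model: str | int
    marginal_effect: float | None = None
    genotypic_effect: float | None = None
    baseline_risk: float = 0.01
    disease_maf: float = 0.5
    ld_r2: float = 1.0
    risk_set: frozenset[tuple[int, int, int]] | None = None

    def __post_init__(self) -> None:
        if isinstance(self.model, int):
            if self.model not in MODEL_ALIASES:
                raise ValueError(f"unknown model {self.model}")
            self.model = MODEL_ALIASES[self.model]
        if self.model not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.model!r}")
        if self.model == "model4_three_locus":
            if self.genotypic_effect is None:
                raise ValueError("model 4 requires genotypic_effect (theta)")
            if self.genotypic_effect < 1:
                raise ValueError("genotypic_effect (theta) must be >= 1")
        else:
            if self.marginal_effect is None:
                raise ValueError(f"{self.model} requires marginal_effect (lambda)")
            if self.marginal_effect < 0:
                raise ValueError("marginal_effect (lambda) must be >= 0")
        if not (0.0 < self.baseline_risk <= 1.0):
            raise ValueError("baseline_risk must be in (0, 1]")
        if not (0.0 < self.disease_maf <= 0.5):
            raise ValueError("disease_maf must be in (0, 0.5]")
        if not (0.0 < self.ld_r2 <= 1.0):
            raise ValueError("ld_r2 must be in (0, 1]")
        if self.risk_set is not None:
            if self.model != "model4_three_locus":
                raise ValueError("risk_set only applies to model 4")
            self.risk_set = frozenset(tuple(t) for t in self.risk_set)
        max_pen = float(penetrance_table(self).max())
        if max_pen > 1.0:
            raise ValueError(
                f"maximum penetrance {max_pen:.4g} exceeds 1; "
                "reduce baseline_risk or the effect size"
            )

    @property
    def n_loci(self) -> int:
        return 3 if self.model == "model4_three_locus" else 2


@dataclasses.dataclass
class SimConfig:
    n_cases: int
    n_controls: int
    n_markers: int
    background_maf_range: tuple[float, float] = (0.05, 0.5)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("cohort sizes must be >= 1")
        lo, hi = self.background_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("background_maf_range must lie within (0, 0.5]")


@dataclasses.dataclass
class SimTruth:
    """Ground truth of one simulated replicate (for evaluation only)."""

    disease_marker_indices: tuple[int, ...]
    model_spec: DiseaseModelSpec
    sim_config: SimConfig
    achieved_r2: tuple[float, ...]

    @property
    def disease_snp_ids(self) -> list[str]:
        return [f"snp{i + 1}" for i in self.disease_marker_indices]

    def to_dict(self) -> dict:
        return {
            "disease_marker_indices": list(self.disease_marker_indices),
            "disease_snp_ids": self.disease_snp_ids,
            "achieved_r2": list(self.achieved_r2),
            "model_spec": {
                k: (sorted(map(list, v)) if isinstance(v, frozenset) else v)
                for k, v in dataclasses.asdict(self.model_spec).items()
            },
            "sim_config": dataclasses.asdict(self.sim_config),
        }


def _default_risk_set() -> frozenset[tuple[int, int, int]]:
    return frozenset(
        t
        for t in itertools.product((0, 1, 2), repeat=3)
        if all(g >= 1 for g in t)
    )


def penetrance(spec: DiseaseModelSpec, genotypes: tuple[int, ...]) -> float:
    """Disease probability for a disease-locus genotype combination."""
    expected = spec.n_loci
    if len(genotypes) != expected:
        raise ValueError(f"{spec.model} takes {expected}-locus genotype tuples")
    if any(g not in (0, 1, 2) for g in genotypes):
        raise ValueError(f"genotypes must be in {{0,1,2}}: {genotypes}")
    a = spec.baseline_risk
    if spec.model == "model1_multiplicative":
        return a * (1.0 + spec.marginal_effect) ** (genotypes[0] + genotypes[1])
    if spec.model == "model2_interaction_multiplicative":
        return a * (1.0 + spec.marginal_effect) ** (genotypes[0] * genotypes[1])
    if spec.model == "model3_threshold":
        hit = genotypes[0] >= 1 and genotypes[1] >= 1
        return a * (1.0 + spec.marginal_effect) if hit else a
    risk = spec.risk_set if spec.risk_set is not None else _default_risk_set()
    return a * (spec.genotypic_effect if tuple(genotypes) in risk else 1.0)


def penetrance_table(spec: DiseaseModelSpec) -> np.ndarray:
    """Penetrance over all genotype combinations, shape (3,) * n_loci."""
    shape = (3,) * spec.n_loci
    table = np.empty(shape)
    for t in itertools.product((0, 1, 2), repeat=spec.n_loci):
        table[t] = penetrance(spec, t)
    return table


def _hwe_probs(maf: float) -> np.ndarray:
    p = maf
    return np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])


def prevalence(spec: DiseaseModelSpec) -> float:
    """Population disease probability sum_g P(g) * penetrance(g) under HWE."""
    probs = _hwe_probs(spec.disease_maf)
    joint = probs
    for _ in range(spec.n_loci - 1):
        joint = np.multiply.outer(joint, probs)
    return float((joint * penetrance_table(spec)).sum())


def _tag_marker(
    locus_genotypes: np.ndarray,
    maf: float,
    r2: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Marker genotypes in LD r^2 with the given disease-locus genotypes.

    Equal marker/locus MAFs; per haplotype, the marker allele is Bernoulli
    with P(m=1 | l=1) = p + r(1-p) and P(m=1 | l=0) = p(1-r), r = sqrt(r^2),
    which realizes D = r * p * (1 - p). r = 1 copies the locus exactly.
    """
    r = float(np.sqrt(r2))
    p = maf
    p_m_given_1 = p + r * (1 - p)
    p_m_given_0 = p * (1 - r)
    if r2 >= 1.0:
        return locus_genotypes.copy()
    g = locus_genotypes
    allele1 = (g >= 1).astype(np.int8)  # first haplotype carries a minor allele
    allele2 = (g == 2).astype(np.int8)
    out = np.zeros_like(g)
    for allele in (allele1, allele2):
        probs = np.where(allele == 1, p_m_given_1, p_m_given_0)
        out = out + (rng.random(g.shape[0]) < probs).astype(np.int8)
    return out.astype(np.int8)


def _sample_cohort(
    spec: DiseaseModelSpec, cfg: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample disease-locus genotypes for cases and controls."""
    table = penetrance_table(spec)
    need_cases, need_controls = cfg.n_cases, cfg.n_controls
    case_rows: list[np.ndarray] = []
    control_rows: list[np.ndarray] = []
    prev = max(prevalence(spec), 1e-6)
    while need_cases > 0 or need_controls > 0:
        chunk = int(
            min(
                5_000_000,
                max(
                    need_cases / prev * 1.3,
                    need_controls / max(1 - prev, 1e-6) * 1.3,
                    1000,
                ),
            )
        )
        loci = rng.binomial(2, spec.disease_maf, size=(chunk, spec.n_loci)).astype(
            np.int8
        )
        pen = table[tuple(loci[:, i] for i in range(spec.n_loci))]
        affected = rng.random(chunk) < pen
        if need_cases > 0:
            take = loci[affected][:need_cases]
            case_rows.append(take)
            need_cases -= take.shape[0]
        if need_controls > 0:
            take = loci[~affected][:need_controls]
            control_rows.append(take)
            need_controls -= take.shape[0]
    cases = np.concatenate(case_rows) if case_rows else np.empty((0, spec.n_loci), np.int8)
    controls = (
        np.concatenate(control_rows) if control_rows else np.empty((0, spec.n_loci), np.int8)
    )
    return cases, controls


def simulate_dataset(
    spec: DiseaseModelSpec, cfg: SimConfig
) -> tuple[GenotypeDataset, SimTruth]:
    """Simulate one case-control dataset and its ground truth."""
    if cfg.n_markers < spec.n_loci:
        raise ValueError(
            f"n_markers={cfg.n_markers} is smaller than the {spec.n_loci} "
            "disease markers"
        )
    rng = np.random.default_rng(np.random.SeedSequence([cfg.rng_seed]))
    cases, controls = _sample_cohort(spec, cfg, rng)
    loci = np.concatenate([cases, controls])
    phenotype = np.concatenate(
        [np.ones(cfg.n_cases, np.int8), np.zeros(cfg.n_controls, np.int8)]
    )
    n = loci.shape[0]

    markers = np.empty((n, spec.n_loci), dtype=np.int8)
    achieved = []
    for i in range(spec.n_loci):
        markers[:, i] = _tag_marker(loci[:, i], spec.disease_maf, spec.ld_r2, rng)
        if spec.ld_r2 >= 1.0:
            achieved.append(1.0)
        else:
            c = np.corrcoef(markers[:, i].astype(float), loci[:, i].astype(float))
            achieved.append(float(c[0, 1] ** 2))

    n_null = cfg.n_markers - spec.n_loci
    lo, hi = cfg.background_maf_range
    null_mafs = rng.uniform(lo, hi, size=n_null)
    null = rng.binomial(2, null_mafs[None, :], size=(n, n_null)).astype(np.int8)

    positions = np.sort(rng.choice(cfg.n_markers, size=spec.n_loci, replace=False))
    genotypes = np.empty((n, cfg.n_markers), dtype=np.int8)
    null_cols = [j for j in range(cfg.n_markers) if j not in set(positions)]
    genotypes[:, list(positions)] = markers
    genotypes[:, null_cols] = null

    order = rng.permutation(n)  # shuffle so case/control blocks are not contiguous
    ds = GenotypeDataset(
        genotypes[order],
        phenotype[order],
        [f"snp{j + 1}" for j in range(cfg.n_markers)],
    )
    truth = SimTruth(
        disease_marker_indices=tuple(int(j) for j in positions),
        model_spec=spec,
        sim_config=cfg,
        achieved_r2=tuple(achieved),
    )
    return ds, truth


def replicate_seed(base_seed: int, index: int) -> int:
    """Deterministic per-replicate seed, reproducible in isolation."""
    ss = np.random.SeedSequence([int(base_seed), int(index)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def replicate_batch(
    spec: DiseaseModelSpec,
    cfg: SimConfig,
    n_replicates: int,
    base_seed: int,
) -> list[tuple[GenotypeDataset, SimTruth]]:
    """Independent replicate datasets with seeds derived from ``base_seed``."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    out = []
    for i in range(n_replicates):
        rep_cfg = dataclasses.replace(cfg, rng_seed=replicate_seed(base_seed, i))
        out.append(simulate_dataset(spec, rep_cfg))
    return out
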