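"""Synthetic cohorts with planted intragenic variant modules.

The restricted study cohort cannot ship with the package, so every pipeline
stage is exercised on generated cohorts that emulate its structure: binary
carrier calls for variants grouped into genes, a rare binary phenotype
(default 10% cases), and planted variant subsets whose co-occurrence is
enriched in cases.

Generative model (latent activation). Phenotype is drawn first: exactly
round(n_patients * case_fraction) patients are cases. For each patient and
each planted module, a latent module activation is drawn Bernoulli with
probability p_active_case or p_active_control according to the phenotype.
Given activation, each of the module's variants is carried with probability
q_carrier_active, otherwise with the background probability; variants outside
any planted module are carried with the background probability independently.
Latent activation produces both of the signals the level-of-association
statistic is built to detect: the module's variants co-occur (they switch on
together), and the co-occurrence is phenotype-conditional (activation is more
frequent in cases).

Randomness is a hierarchical stream: one global seed spawns one child stream
for the phenotype and one per gene, so adding genes to a configuration never
perturbs the draws of earlier genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort, ValidationError


def _check_prob(name: str, p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"{name}={p} outside [0, 1]")


@dataclass
class PlantedModuleSpec:
    """One planted module: a latent activation shared by a set of variants.

    p_active_case / p_active_control: probability the latent module is active
    in a case / control patient (case >= control for a positive-association
    module). q_carrier_active: per-variant carrier probability given the
    module is active. q_background: carrier probability otherwise; ``None``
    falls back to the configuration's background rate.
    """

    gene_id: str
    variant_ids: list[str]
    p_active_case: float
    p_active_control: float
    q_carrier_active: float
    q_background: float | None = None

    def __post_init__(self) -> None:
        if len(self.variant_ids) < 2:
            raise ValidationError("a planted module needs at least 2 variants")
        _check_prob("p_active_case", self.p_active_case)
        _check_prob("p_active_control", self.p_active_control)
        _check_prob("q_carrier_active", self.q_carrier_active)
        if self.q_background is not None:
            _check_prob("q_background", self.q_background)
            if self.q_carrier_active <= self.q_background:
                raise ValidationError("q_carrier_active must exceed q_background")


@dataclass
class SimulationConfig:
    """Cohort layout: genes with variant counts, planted modules, rates, seed."""

    n_patients: int
    case_fraction: float
    genes: list[tuple[str, int]]
    planted: list[PlantedModuleSpec] = field(default_factory=list)
    q_background: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 4:
            raise ValidationError("need at least 4 patients")
        if not 0.0 < self.case_fraction < 1.0:
            raise ValidationError("case_fraction must lie in (0, 1)")
        _check_prob("q_background", self.q_background)
        declared = {g: default_variant_names(g, n) for g, n in self.genes}
        for spec in self.planted:
            if spec.gene_id not in declared:
                raise ValidationError(f"planted module in undeclared gene {spec.gene_id!r}")
            extra = set(spec.variant_ids) - set(declared[spec.gene_id])
            if extra:
                raise ValidationError(
                    f"planted variants {sorted(extra)} not declared in {spec.gene_id!r}"
                )
            if spec.q_background is None and spec.q_carrier_active <= self.q_background:
                raise ValidationError("q_carrier_active must exceed q_background")


def default_variant_names(gene_id: str, n_variants: int) -> list[str]:
    """Deterministic per-gene variant ids ("GENE:v000", "GENE:v001", ...)."""
    return [f"{gene_id}:v{i:03d}" for i in range(n_variants)]


@dataclass
class GroundTruth:
    """Per gene: the planted partition (modules + one background remainder)."""

    modules: dict[str, list[set]]
    background: dict[str, set]

    def partition_labels(self, gene_id: str, variant_order: list[str]) -> np.ndarray:
        """Integer labels over `variant_order`: background 0, modules 1, 2, ..."""
        labels = np.zeros(len(variant_order), dtype=int)
        for m, members in enumerate(self.modules.get(gene_id, []), start=1):
            for i, v in enumerate(variant_order):
                if v in members:
                    labels[i] = m
        return labels


def simulate_cohort(config: SimulationConfig) -> tuple[Cohort, GroundTruth]:
    """Draw a cohort under the latent-activation model; bitwise seed-determined."""
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(1 + len(config.genes))
    rng_phen = np.random.default_rng(streams[0])

    n = config.n_patients
    n_cases = round(n * config.case_fraction)
    phenotype = np.zeros(n, dtype=np.uint8)
    phenotype[rng_phen.permutation(n)[:n_cases]] = 1

    planted_by_gene: dict[str, list[PlantedModuleSpec]] = {}
    for spec in config.planted:
        planted_by_gene.setdefault(spec.gene_id, []).append(spec)

    columns: list[str] = []
    blocks: list[np.ndarray] = []
    truth_modules: dict[str, list[set]] = {}
    truth_background: dict[str, set] = {}

    for g, (gene_id, n_variants) in enumerate(config.genes):
        rng = np.random.default_rng(streams[1 + g])
        names = default_variant_names(gene_id, n_variants)
        carriers = np.empty((n, n_variants), dtype=np.uint8)
        in_module = set()
        truth_modules[gene_id] = []
        for spec in planted_by_gene.get(gene_id, []):
            q_bg = config.q_background if spec.q_background is None else spec.q_background
            p_active = np.where(phenotype == 1, spec.p_active_case, spec.p_active_control)
            active = rng.random(n) < p_active
            q = np.where(active, spec.q_carrier_active, q_bg)
            for v in spec.variant_ids:
                j = names.index(v)
                carriers[:, j] = rng.random(n) < q
                in_module.add(v)
            truth_modules[gene_id].append(set(spec.variant_ids))
        for j, v in enumerate(names):
            if v not in in_module:
                carriers[:, j] = rng.random(n) < config.q_background
        truth_background[gene_id] = set(names) - in_module
        columns.extend(names)
        blocks.append(carriers)

    patients = [f"P{i:06d}" for i in range(n)]
    cohort = Cohort(patients, columns, np.hstack(blocks), phenotype)
    return cohort, GroundTruth(truth_modules, truth_background)


def gene_map_of(config: SimulationConfig):
    """The GeneMap implied by a simulation configuration."""
    from .cohort import GeneMap

    return GeneMap({g: default_variant_names(g, k) for g, k in config.genes})


def describe_truth(truth: GroundTruth) -> pd.DataFrame:
    """Tabulate planted modules: one row per module with sizes for harnesses."""
    rows = []
    for gene_id, mods in truth.modules.items():
        n_background = len(truth.background.get(gene_id, set()))
        for i, members in enumerate(mods):
            rows.append(
                {
                    "gene_id": gene_id,
                    "module_index": i,
                    "module_size": len(members),
                    "n_background": n_background,
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "module_index", "module_size", "n_background"])
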