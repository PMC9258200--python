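"""Patient-by-variant carrier cohorts, gene maps, and stratified splitting.

A cohort is a binary matrix of carrier calls (1 = the patient carries the
variant) over an ordered list of patients and variants, optionally paired
with a binary phenotype vector (1 = case, e.g. early-onset disease).
Variant identifiers use the canonical "chrom:pos:ref:alt" form (1-based
position, as in VCF), but any unique non-empty string is accepted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    """Input violates a structural invariant (duplicates, non-binary values...)."""


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending row/column."""


@dataclass
class Cohort:
    """Binary carrier matrix with optional binary phenotype.

    Parameters
    ----------
    patients : ordered unique patient identifiers (length n).
    variants : ordered unique variant identifiers (length m).
    carriers : (n, m) array with entries in {0, 1}.
    phenotype : optional (n,) array with entries in {0, 1}; 1 marks a case.
    """

    patients: list[str]
    variants: list[str]
    carriers: np.ndarray
    phenotype: np.ndarray | None = None
    _vindex: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.patients = [str(p) for p in self.patients]
        self.variants = [str(v) for v in self.variants]
        self.carriers = np.asarray(self.carriers, dtype=np.uint8)
        if self.carriers.shape != (len(self.patients), len(self.variants)):
            raise ValidationError(
                f"carrier matrix shape {self.carriers.shape} does not match "
                f"{len(self.patients)} patients x {len(self.variants)} variants"
            )
        if len(set(self.patients)) != len(self.patients):
            raise ValidationError("duplicate patient identifiers")
        if len(set(self.variants)) != len(self.variants):
            raise ValidationError("duplicate variant identifiers")
        if any(not v for v in self.variants):
            raise ValidationError("empty variant identifier")
        if not np.isin(self.carriers, (0, 1)).all():
            raise ValidationError("carrier matrix entries must be 0 or 1")
        if self.phenotype is not None:
            self.phenotype = np.asarray(self.phenotype, dtype=np.uint8)
            if self.phenotype.shape != (len(self.patients),):
                raise ValidationError("phenotype length does not match patients")
            if not np.isin(self.phenotype, (0, 1)).all():
                raise ValidationError("phenotype entries must be 0 or 1")
        self._vindex = {v: i for i, v in enumerate(self.variants)}

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self, variant: str) -> int:
        try:
            return self._vindex[variant]
        except KeyError:
            raise KeyError(f"unknown variant {variant!r}") from None

    def carriers_of(self, variant: str) -> np.ndarray:
        """Boolean vector over patients: does each patient carry `variant`?"""
        return self.carriers[:, self.variant_index(variant)].astype(bool)

    def class_mask(self, k: int) -> np.ndarray:
        """Boolean patient mask for phenotype class k (0 or 1)."""
        if self.phenotype is None:
            raise ValidationError("cohort has no phenotype")
        return self.phenotype == k

    def subset_patients(self, index: np.ndarray) -> "Cohort":
        """New cohort restricted to the given patient indices (order kept)."""
        index = np.asarray(index, dtype=int)
        return Cohort(
            patients=[self.patients[i] for i in index],
            variants=list(self.variants),
            carriers=self.carriers[index],
            phenotype=None if self.phenotype is None else self.phenotype[index],
        )

    def with_phenotype(self, phenotype: np.ndarray) -> "Cohort":
        return Cohort(self.patients, self.variants, self.carriers, phenotype)


@dataclass
class GeneMap:
    """Mapping gene id -> ordered list of variant ids.

    Each variant belongs to exactly one gene (variants are intragenic by
    construction; a variant is assigned to the gene it lies in).
    """

    genes: dict[str, list[str]]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for gene, vs in self.genes.items():
            if not vs:
                raise ValidationError(f"gene {gene!r} has an empty variant list")
            for v in vs:
                if v in seen:
                    raise ValidationError(
                        f"variant {v!r} mapped to both {seen[v]!r} and {gene!r}"
                    )
                seen[v] = gene

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes.items())

    @property
    def n_variants(self) -> int:
        return sum(len(vs) for vs in self.genes.values())

    def all_variants(self) -> list[str]:
        return [v for vs in self.genes.values() for v in vs]


def attach_phenotype(cohort: Cohort, table: dict[str, int]) -> Cohort:
    """Attach a phenotype mapping (patient id -> 0/1), aligned to patient order.

    Raises if any cohort patient is missing from the table or a value falls
    outside {0, 1}. See :func:`varmodnet.io.read_phenotype` for the TSV reader.
    """
    missing = [p for p in cohort.patients if p not in table]
    if missing:
        raise ValidationError(f"phenotype table missing patients: {missing}")
    values = []
    for p in cohort.patients:
        v = table[p]
        if v not in (0, 1):
            raise ValidationError(f"phenotype for patient {p!r} is {v!r}, not 0/1")
        values.append(v)
    return cohort.with_phenotype(np.array(values, dtype=np.uint8))


def split_cohort(cohort: Cohort, fraction: float, seed: int) -> tuple[Cohort, Cohort]:
    """Stratified random train/test split.

    Within each phenotype class, floor(fraction * n_class) patients go to the
    training split and the remainder to the test split, so the test split gets
    the odd patient (e.g. 3,181 cases at fraction 0.5 -> 1,590 train / 1,591
    test). Deterministic given `seed`. Patient order inside each split follows
    the original cohort order.
    """
    if cohort.phenotype is None:
        raise ValidationError("split requires a phenotype")
    if not 0.0 < fraction < 1.0:
        raise ValidationError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for k in (1, 0):
        members = np.flatnonzero(cohort.phenotype == k)
        if members.size < 2:
            raise ValidationError(f"phenotype class {k} has fewer than 2 patients")
        n_train = math.floor(fraction * members.size)
        perm = rng.permutation(members.size)
        train_idx.extend(members[perm[:n_train]])
        test_idx.extend(members[perm[n_train:]])
    train_idx.sort()
    test_idx.sort()
    return cohort.subset_patients(np.array(train_idx)), cohort.subset_patients(
        np.array(test_idx)
    )


def restrict_to_observed(cohort: Cohort, gene_map: GeneMap) -> GeneMap:
    """Drop variants carried by no patient in `cohort`; drop genes left empty.

    Variants in the map that are absent from the cohort's columns are treated
    as unobserved. Idempotent. Logs the number of dropped variants and genes.
    """
    observed = set()
    counts = cohort.carriers.sum(axis=0)
    for v, c in zip(cohort.variants, counts):
        if c > 0:
            observed.add(v)
    genes: dict[str, list[str]] = {}
    n_dropped_variants = 0
    n_dropped_genes = 0
    for gene, vs in gene_map.genes.items():
        kept = [v for v in vs if v in observed]
        n_dropped_variants += len(vs) - len(kept)
        if kept:
            genes[gene] = kept
        else:
            n_dropped_genes += 1
    if n_dropped_variants or n_dropped_genes:
        logger.info(
            "restrict_to_observed: dropped %d unobserved variants and %d empty genes",
            n_dropped_variants,
            n_dropped_genes,
        )
    return GeneMap(genes)
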