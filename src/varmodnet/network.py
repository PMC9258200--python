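"""Phenotype-conditional co-occurrence networks over intragenic variants.

The level of association (LOA) between two variants A and B for a binary
phenotype X is the log-ratio of their phenotype-conditional Jaccard
similarities::

    LOA(A, B | X) = log( JCS(A, B | X=1) / JCS(A, B | X=0) )

where JCS(A, B | X=k) is the Jaccard similarity of the two variants' carrier
sets restricted to patients of phenotype class k. A positive LOA means the
pair co-occurs preferentially in cases, negative the opposite, 0 means no
differential co-occurrence. Per gene, the symmetric matrix of pairwise LOA
values is the adjacency matrix of the gene's association network; its
elementwise exponential (all entries positive) is used wherever nonnegative
weights are required (NMF, random-walk transition weights).

Because a Jaccard similarity of zero would make the log-ratio undefined,
both numerator and denominator receive an additive smoothing constant
epsilon. This keeps LOA finite, preserves its sign and symmetry, gives
exactly 0 when the two similarities are equal, and keeps the antisymmetry
of LOA under swapping the phenotype labels. The default (0.2) is set by the
sampling resolution of the Jaccard estimate in the smaller phenotype class:
for rare variants in a cohort with a few hundred cases, a single chance
co-carrier yields a Jaccard similarity of roughly 1/(union count) ~ 0.1,
and epsilon must exceed that scale or such flukes dominate the network as
spurious edges of magnitude |log(JCS/epsilon)| >> 1. Analyses of large
cohorts with rarer variants should lower epsilon accordingly; it is a
parameter everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import Cohort, ValidationError

DEFAULT_EPSILON = 0.2


@dataclass
class AssociationMatrix:
    """Per-gene symmetric matrix of pairwise LOA values (diagonal = 0)."""

    gene_id: str
    variant_order: list[str]
    loa: np.ndarray
    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self) -> None:
        self.loa = np.asarray(self.loa, dtype=float)
        n = len(self.variant_order)
        if self.loa.shape != (n, n):
            raise ValidationError("LOA matrix shape does not match variant order")
        if not np.isfinite(self.loa).all():
            raise ValidationError("LOA matrix contains non-finite entries")

    @property
    def n_variants(self) -> int:
        return len(self.variant_order)


def _class_matrix(cohort: Cohort, k: int) -> np.ndarray:
    mask = cohort.class_mask(k)
    if not mask.any():
        raise ValidationError(f"phenotype class {k} is empty")
    return cohort.carriers[mask].astype(np.int64)


def jcs(a: str, b: str, cohort: Cohort, k: int) -> float:
    """Jaccard similarity of the carrier sets of `a` and `b` in class k.

    |carriers(a) ∩ carriers(b)| / |carriers(a) ∪ carriers(b)| over patients
    with phenotype == k. An empty union (neither variant seen in the class)
    carries no co-occurrence evidence and returns 0.
    """
    C = _class_matrix(cohort, k)
    ca = C[:, cohort.variant_index(a)]
    cb = C[:, cohort.variant_index(b)]
    inter = int(np.sum(ca & cb))
    union = int(np.sum(ca | cb))
    return inter / union if union else 0.0


def loa(a: str, b: str, cohort: Cohort, epsilon: float = DEFAULT_EPSILON) -> float:
    """Smoothed level of association: log((JCS_1 + eps) / (JCS_0 + eps))."""
    if epsilon <= 0:
        raise ValidationError("epsilon must be positive")
    return float(
        np.log((jcs(a, b, cohort, 1) + epsilon) / (jcs(a, b, cohort, 0) + epsilon))
    )


def _pairwise_jcs(C: np.ndarray) -> np.ndarray:
    """All-pairs Jaccard over the columns of a binary patients x variants block."""
    inter = C.T @ C
    counts = C.sum(axis=0)
    union = counts[:, None] + counts[None, :] - inter
    out = np.zeros_like(inter, dtype=float)
    np.divide(inter, union, out=out, where=union > 0)
    return out


def build_ajm(
    gene_id: str,
    variants: list[str],
    cohort: Cohort,
    epsilon: float = DEFAULT_EPSILON,
) -> AssociationMatrix:
    """Assemble the gene's association matrix of pairwise LOA values.

    The upper triangle is computed and mirrored; the diagonal is fixed at 0
    (self-association is uninformative). Requires at least two variants —
    single-variant genes have no intragenic network.
    """
    if len(variants) < 2:
        raise ValidationError(f"gene {gene_id!r} has fewer than 2 variants")
    if epsilon <= 0:
        raise ValidationError("epsilon must be positive")
    cols = [cohort.variant_index(v) for v in variants]
    j1 = _pairwise_jcs(_class_matrix(cohort, 1)[:, cols])
    j0 = _pairwise_jcs(_class_matrix(cohort, 0)[:, cols])
    mat = np.log((j1 + epsilon) / (j0 + epsilon))
    upper = np.triu(mat, k=1)
    mat = upper + upper.T
    return AssociationMatrix(gene_id, list(variants), mat, epsilon)


def to_ajnm(ajm: AssociationMatrix) -> np.ndarray:
    """Elementwise exponential of the LOA matrix: strictly positive, diag = 1."""
    return np.exp(ajm.loa)
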