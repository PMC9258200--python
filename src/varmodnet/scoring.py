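"""Module-phenotype association scoring via activation and Fisher's exact test.

For a module m (a set of variants R_m) and a patient p with carried-variant
set F_p, the module activation level is the carried fraction

    MAL(p, m) = |R_m ∩ F_p| / |R_m|,

binarised against the cohort-mean level thr(m) = mean_p MAL(p, m) with a
strict inequality: MAS(p, m) = 1 iff MAL(p, m) > thr(m). Tallying activation
status against the binary phenotype gives a 2x2 table

    a = activated cases,   b = activated controls,
    c = inactivated cases, d = inactivated controls,

from which FEP is the positive one-sided Fisher exact p-value (upper tail on
a: does activation enrich in cases?) and FER the (prior) odds ratio
(a*d)/(b*c).

Candidates from the individual-variant control (``ctrl_inv``) are scored on
carrier status directly — for a singleton module MAL is the 0/1 carrier call
and the activation rule reduces to "carries the variant".

The threshold is recomputed within whatever cohort is being scored, so the
training and test splits are each scored against their own mean level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .cohort import Cohort, ValidationError
from .discovery import ModuleCandidate


@dataclass(frozen=True)
class ModuleContingency:
    """Activation x phenotype counts: (a, b, c, d) as defined above."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("negative contingency count")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class ModuleScore:
    """Scored candidate: threshold, contingency counts, FEP p-value, FER odds."""

    module: ModuleCandidate
    thr: float
    contingency: ModuleContingency
    fep: float
    fer: float


def mal_vector(module: ModuleCandidate, cohort: Cohort) -> np.ndarray:
    """MAL for every patient: fraction of the module's variants carried."""
    if not module.variants:
        raise ValidationError("empty module")
    cols = [cohort.variant_index(v) for v in module.sorted_variants()]
    return cohort.carriers[:, cols].mean(axis=1)


def mal(patient: str, module: ModuleCandidate, cohort: Cohort) -> float:
    """Module activation level of one patient."""
    idx = cohort.patients.index(patient)
    return float(mal_vector(module, cohort)[idx])


def activation_threshold(module: ModuleCandidate, cohort: Cohort) -> float:
    """thr(m): mean MAL over all patients of the cohort being scored."""
    if cohort.n_patients == 0:
        raise ValidationError("empty cohort")
    return float(mal_vector(module, cohort).mean())


def mas(mal_value: float, thr_value: float) -> int:
    """Activation status: 1 iff the level strictly exceeds the threshold."""
    return int(mal_value > thr_value)


def _activation(module: ModuleCandidate, cohort: Cohort) -> np.ndarray:
    """Boolean activation vector; ctrl_inv modules use carrier status directly."""
    levels = mal_vector(module, cohort)
    if module.approach == "ctrl_inv":
        return levels > 0
    return levels > levels.mean()


def contingency(module: ModuleCandidate, cohort: Cohort) -> ModuleContingency:
    """Tally activation status against phenotype over all patients."""
    if cohort.phenotype is None:
        raise ValidationError("cohort has no phenotype")
    act = _activation(module, cohort)
    case = cohort.phenotype.astype(bool)
    return ModuleContingency(
        a=int(np.sum(act & case)),
        b=int(np.sum(act & ~case)),
        c=int(np.sum(~act & case)),
        d=int(np.sum(~act & ~case)),
    )


def fep(ct: ModuleContingency) -> float:
    """Positive one-sided Fisher exact p-value: P(X >= a) with margins fixed.

    X follows the hypergeometric law with population ct.n, ct.a + ct.c cases
    and ct.a + ct.b activated draws.
    """
    p = float(hypergeom.sf(ct.a - 1, ct.n, ct.a + ct.c, ct.a + ct.b))
    return min(1.0, max(0.0, p))


def fer(ct: ModuleContingency, haldane: bool = False) -> float:
    """Odds ratio (a/b)/(c/d) = (a*d)/(b*c).

    Zero cells: +inf when b*c == 0 with a*d > 0; NaN ("undefined") when both
    products vanish. `haldane` applies the +0.5 Haldane–Anscombe correction
    to every cell instead (off by default).
    """
    if haldane:
        return ((ct.a + 0.5) * (ct.d + 0.5)) / ((ct.b + 0.5) * (ct.c + 0.5))
    ad, bc = ct.a * ct.d, ct.b * ct.c
    if bc == 0:
        return math.inf if ad > 0 else math.nan
    return ad / bc


def score_module(module: ModuleCandidate, cohort: Cohort) -> ModuleScore:
    """Full score: threshold, activation tally, FEP and FER for one candidate."""
    if module.approach == "ctrl_inv":
        thr_value = 0.0  # carrier status: MAL > 0 is exactly "carries the variant"
    else:
        thr_value = activation_threshold(module, cohort)
    ct = contingency(module, cohort)
    return ModuleScore(module, thr_value, ct, fep(ct), fer(ct))
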