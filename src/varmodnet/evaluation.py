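"""Train/test reproducibility benchmark for all five module approaches.

Protocol: (1) split the cohort once, stratified by phenotype; (2) discover
module candidates on the training split only (per gene: association matrix
-> embedding -> silhouette-selected clustering; the controls use the
train-observed gene map directly); (3) score every candidate on the training
split and accept those with FEP < alpha; (4) re-score the accepted modules
on the held-out test split; (5) report

    acceptance rate   = accepted / candidates        (training split)
    reproduction rate = still significant / accepted (test split).

Because the test split plays no part in discovery, the reproduction rate
estimates how reproducible each approach's modules are on an independent
dataset. Rates are kept as raw count ratios; rounding happens only at
presentation (4 decimals in the tabular report).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .cohort import Cohort, GeneMap, ValidationError, restrict_to_observed, split_cohort
from .discovery import (
    APPROACHES,
    ModuleCandidate,
    _make_candidates,
    cluster_embeddings,
    modules_gla,
    modules_inv,
)
from .embedding import embed
from .network import DEFAULT_EPSILON, build_ajm
from .scoring import score_module


@dataclass
class EvalConfig:
    """Benchmark parameters: split, significance level, backend settings."""

    seed: int = 0
    fraction: float = 0.5
    alpha: float = 0.05
    epsilon: float = DEFAULT_EPSILON
    walks_per_node: int = 10
    walk_length: int = 10
    sg_dim: int = 8
    sg_window: int = 5
    sg_epochs: int = 5
    gmf_dim: int = 2
    nmf_max_iter: int = 500
    k_min: int = 2
    k_max: int = 20
    linkage: str = "ward"

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class ApproachResult:
    """Candidate/acceptance/reproduction counts and rates for one approach."""

    approach: str
    n_candidates: int
    n_accepted_train: int
    n_reproduced_test: int
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.n_reproduced_test <= self.n_accepted_train <= self.n_candidates:
            raise ValidationError(
                f"inconsistent counts for {self.approach}: "
                f"{self.n_reproduced_test} <= {self.n_accepted_train} <= {self.n_candidates}"
            )

    @property
    def acceptance_rate(self) -> float | None:
        """Accepted / candidates; None (undefined) when there are no candidates."""
        if self.n_candidates == 0:
            return None
        return self.n_accepted_train / self.n_candidates

    @property
    def reproduction_rate(self) -> float | None:
        """Reproduced / accepted; None (undefined) when nothing was accepted."""
        if self.n_accepted_train == 0:
            return None
        return self.n_reproduced_test / self.n_accepted_train


@dataclass
class EvalReport:
    """Per-approach results plus a provenance block (config + version)."""

    results: list[ApproachResult]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [r.approach for r in self.results]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate approaches in report")

    def to_tsv(self) -> str:
        def fmt(rate: float | None) -> str:
            return "NA" if rate is None else f"{rate:.4f}"

        lines = ["approach\tn_candidates\tn_accepted\tacceptance_rate\tn_reproduced\treproduction_rate"]
        for r in self.results:
            lines.append(
                f"{r.approach}\t{r.n_candidates}\t{r.n_accepted_train}\t"
                f"{fmt(r.acceptance_rate)}\t{r.n_reproduced_test}\t{fmt(r.reproduction_rate)}"
            )
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        payload = {
            "results": [
                {
                    "approach": r.approach,
                    "n_candidates": r.n_candidates,
                    "n_accepted_train": r.n_accepted_train,
                    "acceptance_rate": r.acceptance_rate,
                    "n_reproduced_test": r.n_reproduced_test,
                    "reproduction_rate": r.reproduction_rate,
                    "alpha": r.alpha,
                }
                for r in self.results
            ],
            "provenance": self.provenance,
        }
        return json.dumps(payload, sort_keys=True, indent=2) + "\n"


def _backend_seed(seed: int, approach: str, gene_index: int) -> int:
    code = APPROACHES.index(approach)
    ss = np.random.SeedSequence(entropy=(seed, code, gene_index))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def run_approach(
    approach: str, train: Cohort, gene_map: GeneMap, config: EvalConfig
) -> list[ModuleCandidate]:
    """Discover module candidates on the training split only.

    Embedding approaches: per gene, association matrix -> embedding ->
    silhouette clustering; single-variant genes yield one whole-gene
    candidate. Controls come straight from the gene map.
    """
    if approach == "ctrl_gla":
        return modules_gla(gene_map)
    if approach == "ctrl_inv":
        return modules_inv(gene_map)
    if approach not in APPROACHES:
        raise ValidationError(f"unknown approach {approach!r}")
    candidates: list[ModuleCandidate] = []
    for gi, (gene, vs) in enumerate(gene_map):
        if len(vs) < 2:
            candidates.extend(_make_candidates(gene, approach, [list(vs)]))
            continue
        ajm = build_ajm(gene, vs, train, config.epsilon)
        table = embed(
            ajm,
            approach,
            seed=_backend_seed(config.seed, approach, gi),
            walks_per_node=config.walks_per_node,
            walk_length=config.walk_length,
            sg_dim=config.sg_dim,
            sg_window=config.sg_window,
            sg_epochs=config.sg_epochs,
            gmf_dim=config.gmf_dim,
            nmf_max_iter=config.nmf_max_iter,
        )
        candidates.extend(
            cluster_embeddings(table, config.k_min, config.k_max, config.linkage)
        )
    return candidates


def acceptance_and_reproduction(
    candidates: list[ModuleCandidate],
    train: Cohort,
    test: Cohort,
    alpha: float = 0.05,
) -> ApproachResult:
    """Score on train, keep FEP < alpha, re-score survivors on test."""
    approach = candidates[0].approach if candidates else "none"
    accepted = [c for c in candidates if score_module(c, train).fep < alpha]
    reproduced = [c for c in accepted if score_module(c, test).fep < alpha]
    return ApproachResult(
        approach=approach,
        n_candidates=len(candidates),
        n_accepted_train=len(accepted),
        n_reproduced_test=len(reproduced),
        alpha=alpha,
    )


def evaluate_all(cohort: Cohort, gene_map: GeneMap, config: EvalConfig) -> EvalReport:
    """Run the full benchmark: one split, all five approaches, one report.

    Module discovery uses the training split's observed gene map (variants
    never carried in the training data are dropped, and genes left empty are
    skipped), so every approach sees exactly the same inputs.
    """
    train, test = split_cohort(cohort, config.fraction, config.seed)
    observed = restrict_to_observed(train, gene_map)
    results = []
    for approach in APPROACHES:
        candidates = run_approach(approach, train, observed, config)
        result = acceptance_and_reproduction(candidates, train, test, config.alpha)
        result.approach = approach
        results.append(result)
    provenance = {
        "config": config.to_dict(),
        "version": __version__,
        "n_patients": cohort.n_patients,
        "n_cases": int(cohort.phenotype.sum()) if cohort.phenotype is not None else None,
        "n_genes_observed": len(observed),
        "n_variants_observed": observed.n_variants,
    }
    return EvalReport(results, provenance)


def rate_ratio(r1: ApproachResult, r2: ApproachResult) -> float:
    """Ratio of two reproduction rates, computed from raw (unrounded) counts."""
    a, b = r1.reproduction_rate, r2.reproduction_rate
    if a is None or b is None or b == 0:
        raise ValidationError("reproduction rate undefined; ratio unavailable")
    return a / b
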