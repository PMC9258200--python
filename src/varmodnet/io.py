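"""Readers and writers for cohorts, gene maps and pipeline artifacts.

All tabular formats are UTF-8 tab-delimited text:

- carrier matrix: header row of variant ids, first column the patient id,
  cells 0/1;
- phenotype: two columns (patient id, 0/1), optional header;
- gene map: two columns (variant id, gene id), optional header;
- association network: edge list (gene, variant_i, variant_j, loa) over the
  upper triangle, or a per-gene square matrix with the variant order as
  header;
- embeddings: gene, variant, v1..vd;
- module candidates: JSON lines {module_id, gene, approach, variants};
- module scores: one row per candidate with threshold, contingency counts,
  FEP and FER.

VCF ingestion is zygosity-blind: any genotype containing at least one
alternate allele marks the sample as a carrier (1); missing genotypes count
as non-carriers (0). Multi-allelic records collapse to a single carrier
column.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort, GeneMap, ParseError, ValidationError
from .cohort import attach_phenotype as _attach_phenotype_table
from .discovery import ModuleCandidate
from .embedding import EmbeddingTable
from .network import AssociationMatrix
from .scoring import ModuleScore


def _read_two_columns(path) -> list[tuple[str, str]]:
    rows = []
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}: line {ln}: expected 2 columns, got {len(parts)}")
            rows.append((parts[0], parts[1]))
    return rows


def read_carrier_matrix(path, format: str = "tsv") -> Cohort:
    """Read a carrier matrix (phenotype left unset). `format`: "tsv" or "vcf"."""
    if format == "tsv":
        return _read_carrier_tsv(path)
    if format == "vcf":
        return _read_carrier_vcf(path)
    raise ValidationError(f"unknown carrier-matrix format {format!r}")


def _read_carrier_tsv(path) -> Cohort:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    variants = [str(c) for c in df.columns]
    patients = [str(p) for p in df.index]
    if len(set(patients)) != len(patients):
        raise ValidationError(f"{path}: duplicate patient ids")
    if len(set(variants)) != len(variants):
        raise ValidationError(f"{path}: duplicate variant ids")
    carriers = np.empty(df.shape, dtype=np.uint8)
    for j, col in enumerate(df.columns):
        for i, cell in enumerate(df[col]):
            if cell not in ("0", "1"):
                raise ParseError(
                    f"{path}: row {patients[i]!r}, column {variants[j]!r}: "
                    f"expected 0/1, got {cell!r}"
                )
            carriers[i, j] = int(cell)
    return Cohort(patients, variants, carriers)


def _read_carrier_vcf(path) -> Cohort:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    patients = list(vcf.samples)
    variants: list[str] = []
    rows: list[np.ndarray] = []
    for record in vcf:
        vid = f"{record.CHROM}:{record.POS}:{record.REF}:{','.join(record.ALT)}"
        if vid in variants:
            raise ValidationError(f"{path}: duplicate variant {vid!r}")
        variants.append(vid)
        # gt_types: 0 hom-ref, 1 het, 2 unknown/missing, 3 hom-alt
        gt = np.asarray(record.gt_types)
        rows.append(((gt == 1) | (gt == 3)).astype(np.uint8))
    vcf.close()
    if not variants:
        raise ParseError(f"{path}: no variant records")
    return Cohort(patients, variants, np.column_stack(rows))


def write_carrier_matrix(cohort: Cohort, path) -> None:
    df = pd.DataFrame(cohort.carriers, index=cohort.patients, columns=cohort.variants)
    df.to_csv(path, sep="\t", index_label="patient")


def read_phenotype(path) -> dict[str, int]:
    """Two-column TSV -> {patient: 0/1}; a non-numeric first row is a header."""
    rows = _read_two_columns(path)
    if rows and rows[0][1] not in ("0", "1"):
        rows = rows[1:]
    table: dict[str, int] = {}
    for ln, (patient, value) in enumerate(rows, start=1):
        if value not in ("0", "1"):
            raise ValidationError(
                f"{path}: phenotype for {patient!r} is {value!r}, not 0/1"
            )
        if patient in table:
            raise ValidationError(f"{path}: duplicate patient {patient!r}")
        table[patient] = int(value)
    return table


def attach_phenotype(cohort: Cohort, path) -> Cohort:
    """Read a phenotype TSV and align it to the cohort's patient order."""
    return _attach_phenotype_table(cohort, read_phenotype(path))


def write_phenotype(cohort: Cohort, path) -> None:
    if cohort.phenotype is None:
        raise ValidationError("cohort has no phenotype")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("patient\tphenotype\n")
        for p, x in zip(cohort.patients, cohort.phenotype):
            fh.write(f"{p}\t{int(x)}\n")


def read_gene_map(path) -> GeneMap:
    """Two-column TSV (variant id, gene id); gene order = first appearance."""
    rows = _read_two_columns(path)
    if rows and rows[0][0].lower() in ("variant", "variant_id"):
        rows = rows[1:]
    genes: dict[str, list[str]] = {}
    for variant, gene in rows:
        genes.setdefault(gene, []).append(variant)
    return GeneMap(genes)


def write_gene_map(gene_map: GeneMap, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("variant_id\tgene_id\n")
        for gene, vs in gene_map:
            for v in vs:
                fh.write(f"{v}\t{gene}\n")


def write_edge_list(ajms: list[AssociationMatrix], path) -> None:
    """Upper-triangle edge list: gene, variant_i, variant_j, loa."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tvariant_i\tvariant_j\tloa\n")
        for ajm in ajms:
            vs = ajm.variant_order
            for i in range(len(vs)):
                for j in range(i + 1, len(vs)):
                    fh.write(f"{ajm.gene_id}\t{vs[i]}\t{vs[j]}\t{ajm.loa[i, j]:.10g}\n")


def write_ajm_matrix(ajm: AssociationMatrix, path) -> None:
    df = pd.DataFrame(ajm.loa, index=ajm.variant_order, columns=ajm.variant_order)
    df.to_csv(path, sep="\t", index_label="variant", float_format="%.10g")


def write_embeddings(tables: list[EmbeddingTable], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        dim = tables[0].dim if tables else 0
        header = "\t".join(["gene_id", "variant_id"] + [f"v{i+1}" for i in range(dim)])
        fh.write(header + "\n")
        for t in tables:
            for v, x in t.vectors.items():
                coords = "\t".join(f"{c:.10g}" for c in x)
                fh.write(f"{t.gene_id}\t{v}\t{coords}\n")


def write_candidates(candidates: list[ModuleCandidate], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for c in candidates:
            fh.write(
                json.dumps(
                    {
                        "module_id": c.module_id,
                        "gene": c.gene_id,
                        "approach": c.approach,
                        "variants": c.sorted_variants(),
                    },
                    sort_keys=True,
                )
                + "\n"
            )


def read_candidates(path) -> list[ModuleCandidate]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            out.append(
                ModuleCandidate(
                    rec["gene"], frozenset(rec["variants"]), rec["approach"], rec["module_id"]
                )
            )
    return out


def _format_fer(x: float) -> str:
    if math.isnan(x):
        return "undefined"
    if math.isinf(x):
        return "inf"
    return f"{x:.6g}"


def write_scores(scores: list[ModuleScore], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "module_id\tgene_id\tapproach\tn_variants\tthr\ta\tb\tc\td\tfep\tfer\n"
        )
        for s in scores:
            ct = s.contingency
            fh.write(
                f"{s.module.module_id}\t{s.module.gene_id}\t{s.module.approach}\t"
                f"{len(s.module.variants)}\t{s.thr:.6g}\t{ct.a}\t{ct.b}\t{ct.c}\t{ct.d}\t"
                f"{s.fep:.6g}\t{_format_fer(s.fer)}\n"
            )


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
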