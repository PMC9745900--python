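"""Somatic-variant triage for tumour cell lines without matched normals.

Variant calling on cell lines mixes germline and somatic variants, so a
filtering cascade is applied to an annotated variant table:

1. drop likely germline variants: 1000 Genomes phase-3 MAF > 1% in any
   population, or NHLBI ESP MAF > 0.1% in any population (strict >);
2. drop dbSNP build-138 variants without ClinVar clinical associations;
3. keep only coding-consequence variants (missense, stop-gain/loss,
   frameshift/non-frameshift, splice donor/acceptor) in COSMIC
   cancer-gene-census genes;
4. annotate (not drop) PolyPhen-2 damaging predictions as priority.

The three drop-filters are row-wise predicates, hence commute.  Missing
MAFs mean "not observed in the population database" and never exclude.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CODING_CONSEQUENCES = frozenset(
    {
        "missense",
        "stop-gain",
        "stop-loss",
        "frameshift",
        "non-frameshift",
        "splice-donor",
        "splice-acceptor",
    }
)
CONSEQUENCE_VOCABULARY = CODING_CONSEQUENCES | {"other"}

KG_MAF_THRESHOLD = 0.01
ESP_MAF_THRESHOLD = 0.001

DAMAGING_CALLS = frozenset({"possibly_damaging", "probably_damaging"})


class VariantTableError(ValueError):
    pass


def _check_maf(values: pd.Series, name: str) -> pd.Series:
    v = pd.to_numeric(values, errors="coerce")
    bad = v.notna() & ((v < 0) | (v > 0.5))
    if bad.any():
        raise VariantTableError(
            f"{name} outside [0, 0.5] at rows {list(values.index[bad])}"
        )
    return v.fillna(0.0)  # missing = not observed in the population


def filter_germline(variants: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop population-frequent variants; returns (survivors, exclusion log)."""
    kg = _check_maf(variants["kg_max_maf"], "kg_max_maf")
    esp = _check_maf(variants["esp_max_maf"], "esp_max_maf")
    drop_kg = kg > KG_MAF_THRESHOLD
    drop_esp = esp > ESP_MAF_THRESHOLD
    dropped = variants[drop_kg | drop_esp].copy()
    dropped["excluded_by"] = np.where(
        drop_kg[drop_kg | drop_esp], "1000g_maf", "esp_maf"
    )
    return variants[~(drop_kg | drop_esp)].copy(), dropped


def filter_dbsnp(variants: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop dbSNP-138 variants lacking ClinVar clinical associations."""
    drop = variants["in_dbsnp138"].astype(bool) & ~variants["has_clinvar"].astype(bool)
    dropped = variants[drop].copy()
    dropped["excluded_by"] = "dbsnp_no_clinvar"
    return variants[~drop].copy(), dropped


def restrict_coding_census(
    variants: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep coding-consequence variants in cancer-census genes."""
    unknown = set(variants["consequence"]) - CONSEQUENCE_VOCABULARY
    if unknown:
        raise VariantTableError(
            f"unknown consequence classes {sorted(unknown)}; "
            f"valid: {sorted(CONSEQUENCE_VOCABULARY)}"
        )
    keep = variants["consequence"].isin(CODING_CONSEQUENCES) & variants[
        "in_census"
    ].astype(bool)
    dropped = variants[~keep].copy()
    dropped["excluded_by"] = np.where(
        ~variants.loc[~keep, "consequence"].isin(CODING_CONSEQUENCES),
        "non_coding_class",
        "not_census",
    )
    return variants[keep].copy(), dropped


def triage(variants: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Full cascade; returns survivors (with priority flag) and exclusion log."""
    after_germline, log_g = filter_germline(variants)
    after_dbsnp, log_d = filter_dbsnp(after_germline)
    survivors, log_c = restrict_coding_census(after_dbsnp)
    survivors = flag_damaging(survivors)
    log = {
        "germline": log_g.to_dict("records"),
        "dbsnp": log_d.to_dict("records"),
        "coding_census": log_c.to_dict("records"),
    }
    return survivors, log


def flag_damaging(variants: pd.DataFrame) -> pd.DataFrame:
    """Annotate PolyPhen-2 damaging predictions; never drops rows.

    ``priority`` is True for possibly/probably damaging calls;
    ``needs_review`` marks rows with an unknown prediction.
    """
    out = variants.copy()
    out["priority"] = out["polyphen"].isin(DAMAGING_CALLS)
    out["needs_review"] = out["polyphen"] == "unknown"
    return out


def build_mutation_matrix(
    variants: pd.DataFrame,
    genes=None,
    cell_lines=None,
) -> tuple[pd.DataFrame, dict]:
    """Binary genes × cell lines matrix from surviving variants.

    An entry is 1 iff at least one surviving variant hits that gene in that
    cell line; a provenance map records the contributing protein changes.
    """
    genes = sorted(set(variants["gene"])) if genes is None else list(genes)
    if cell_lines is None:
        cell_lines = sorted(set(variants["cell_line"]))
    else:
        cell_lines = list(cell_lines)
        extra = set(variants["cell_line"]) - set(cell_lines)
        if extra:
            raise VariantTableError(
                f"variants reference undeclared cell lines: {sorted(extra)}"
            )
    mat = pd.DataFrame(0, index=genes, columns=cell_lines, dtype=int)
    provenance: dict[tuple[str, str], list[str]] = {}
    for row in variants.itertuples(index=False):
        if row.gene not in mat.index:
            continue
        mat.loc[row.gene, row.cell_line] = 1
        provenance.setdefault((row.gene, row.cell_line), []).append(
            row.protein_change
        )
    mat.index.name = "gene"
    mat.columns.name = "cell_line"
    return mat, provenance


def aggregate_pathway(
    matrix: pd.DataFrame, gene_sets: dict[str, list[str]]
) -> pd.DataFrame:
    """Pathway-level indicators: OR over member genes per cell line."""
    rows = {}
    for name, members in gene_sets.items():
        if not members:
            raise ValueError(f"gene set {name!r} is empty")
        present = [g for g in members if g in matrix.index]
        if present:
            rows[name] = matrix.loc[present].max(axis=0)
        else:
            rows[name] = pd.Series(0, index=matrix.columns)
    out = pd.DataFrame(rows).T.astype(int)
    out.index.name = "pathway"
    out.columns.name = matrix.columns.name
    return out
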