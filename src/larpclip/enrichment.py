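"""GO-term enrichment of bound genes and the TE-change cross-tabulation.

Classic per-term one-sided Fisher exact tests against a background of
expressed genes, Bonferroni-corrected over the terms tested, with a
significance cutoff of adjusted p < 0.001. Significant terms are grouped
into manually curated super-categories (a packaged default covers the
translation super-category); a gene is translation-related iff annotated
to at least one translation-super-category term. Optional parent links in
the annotation propagate gene annotations up the term graph.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

ALPHA = 0.001


@dataclass(slots=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    study_hits: int
    study_size: int
    background_hits: int
    background_size: int
    p: float
    p_adj: float
    significant: bool
    super_category: str = ""


def fisher_enrichment(
    study: Iterable[str],
    background: Iterable[str],
    annotation: Mapping[str, set[str]],
    term_names: Mapping[str, str] | None = None,
    alpha: float = ALPHA,
) -> list[EnrichmentResult]:
    """Per-term Fisher exact enrichment of the study set in the background.

    The 2x2 table per term is (study hit, study miss, background-only hit,
    background-only miss); p is the one-sided (greater) Fisher exact
    probability; Bonferroni multiplies by the number of terms tested
    (terms annotating >= 1 background gene). Sorted by adjusted p.
    """
    study = set(study)
    background = set(background)
    missing = study - background
    if missing:
        raise ValueError(f"study genes absent from background: {sorted(missing)}")
    term_names = term_names or {}
    genes_per_term: dict[str, set[str]] = {}
    for gene in background:
        for term in annotation.get(gene, ()):
            genes_per_term.setdefault(term, set()).add(gene)
    n_terms = len(genes_per_term)
    results = []
    for term, genes in sorted(genes_per_term.items()):
        sh = len(genes & study)
        bh = len(genes)
        table = [
            [sh, len(study) - sh],
            [bh - sh, len(background) - len(study) - (bh - sh)],
        ]
        _, p = stats.fisher_exact(table, alternative="greater")
        p_adj = min(1.0, float(p) * n_terms)
        results.append(
            EnrichmentResult(
                term_id=term,
                term_name=term_names.get(term, ""),
                study_hits=sh,
                study_size=len(study),
                background_hits=bh,
                background_size=len(background),
                p=float(p),
                p_adj=p_adj,
                significant=p_adj < alpha,
            )
        )
    results.sort(key=lambda r: (r.p_adj, r.p, r.term_id))
    return results


def read_annotation(path: str | Path) -> dict[str, set[str]]:
    """Gene -> term-set TSV (gene_id, term_id[, parent_terms]).

    A third column of comma-separated parent terms propagates annotations
    up the term graph (a gene annotated to a term is annotated to its
    ancestors); without it, annotation is flat.
    """
    parents: dict[str, set[str]] = {}
    direct: dict[str, set[str]] = {}
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        for row in reader:
            if not row or not row[0]:
                continue
            gene, term = row[0], row[1]
            direct.setdefault(gene, set()).add(term)
            if len(row) > 2 and row[2]:
                parents.setdefault(term, set()).update(
                    p for p in row[2].split(",") if p
                )
    if not parents:
        return direct
    def ancestors(term: str, seen: set[str]) -> set[str]:
        out = set()
        for p in parents.get(term, ()):
            if p not in seen:
                seen.add(p)
                out.add(p)
                out |= ancestors(p, seen)
        return out
    return {
        gene: terms | set().union(*(ancestors(t, {t}) for t in terms))
        for gene, terms in direct.items()
    }


def default_supercategory_path() -> Path:
    return Path(resources.files("larpclip").joinpath("data/supercategories.tsv"))


def read_supercategories(path: str | Path | None = None) -> dict[str, str]:
    """term_id -> super-category mapping TSV."""
    path = path or default_supercategory_path()
    out: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise ValueError(f"malformed super-category mapping at line {ln}")
            out[fields[0]] = fields[1]
    return out


def group_supercategories(
    results: Sequence[EnrichmentResult],
    mapping: Mapping[str, str] | str | Path | None = None,
) -> list[EnrichmentResult]:
    """Attach super-category labels; unmapped significant terms get 'other'."""
    if mapping is None or isinstance(mapping, (str, Path)):
        mapping = read_supercategories(mapping)
    for r in results:
        r.super_category = mapping.get(r.term_id, "other" if r.significant else "")
    return list(results)


def translation_related_genes(
    annotation: Mapping[str, set[str]],
    mapping: Mapping[str, str] | None = None,
) -> set[str]:
    """Genes annotated to >= 1 term of the translation super-category."""
    if mapping is None:
        mapping = read_supercategories()
    translation_terms = {t for t, c in mapping.items() if c == "translation"}
    return {
        gene for gene, terms in annotation.items() if terms & translation_terms
    }


# --- TE cross-tabulation ----------------------------------------------------

TE_CLASSES = ("down", "unchanged", "up")


def te_cross_tab(
    te_table: Mapping[str, float], bound_genes: Iterable[str]
) -> pd.DataFrame:
    """Bound-gene fraction per translation-efficiency change class.

    down: fold change < 1/1.5; up: > 1.5; unchanged otherwise. Classes
    partition the gene set of the TE table.
    """
    bound = set(bound_genes)
    rows = {c: [0, 0] for c in TE_CLASSES}
    for gene, fc in te_table.items():
        if fc <= 0:
            raise ValueError(f"non-positive fold change for {gene}: {fc}")
        if fc < 1.0 / 1.5:
            cls = "down"
        elif fc > 1.5:
            cls = "up"
        else:
            cls = "unchanged"
        rows[cls][0] += 1
        rows[cls][1] += gene in bound
    df = pd.DataFrame(
        [
            (cls, total, hit, hit / total if total else float("nan"))
            for cls, (total, hit) in rows.items()
        ],
        columns=["te_class", "total_genes", "bound_genes", "bound_fraction"],
    )
    return df


def write_enrichment_tsv(path: str | Path, results: Sequence[EnrichmentResult]) -> None:
    with open(path, "w") as fh:
        fh.write(
            "term_id\tterm_name\tstudy_hits\tstudy_size\tbackground_hits"
            "\tbackground_size\tp\tp_adj\tsignificant\tsuper_category\n"
        )
        for r in results:
            fh.write(
                f"{r.term_id}\t{r.term_name}\t{r.study_hits}\t{r.study_size}"
                f"\t{r.background_hits}\t{r.background_size}\t{r.p:.6g}"
                f"\t{r.p_adj:.6g}\t{r.significant}\t{r.super_category}\n"
            )


def read_te_table(path: str | Path) -> dict[str, float]:
    out = {}
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out[row["gene_id"]] = float(row["fold_change"])
    return out
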