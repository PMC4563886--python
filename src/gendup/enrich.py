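"""Term enrichment and class-wise feature comparisons.

Enrichment is the classic one-sided Fisher / hypergeometric test per
term against a background set, BH-FDR corrected across tested terms
(graph-aware decorrelation as in topGO's "elim" is deliberately not
applied, so p-values are per-term exact tail probabilities). Feature
comparisons mirror a structural/expression feature table: Mann–Whitney
for numeric features, 2x2 chi-squared (no continuity correction by
default) for binary ones.
"""
from __future__ import annotations

import logging
import warnings
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, hypergeom, mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .models import EnrichmentRow

logger = logging.getLogger(__name__)


def enrich(
    study: set[str],
    background: set[str],
    annotation: pd.DataFrame,
) -> list[EnrichmentRow]:
    """Hypergeometric (one-sided, upper tail) term enrichment.

    ``annotation`` has columns gene_id, term_id, term_name; genes without
    annotation stay in the totals. One row per term with >= 1 study
    gene, BH-adjusted across tested terms, sorted by p then term id.
    """
    if not study:
        raise ValueError("empty study set")
    if not study <= background:
        raise ValueError("study set is not a subset of the background")
    ann = annotation[annotation["gene_id"].isin(background)]
    M = len(background)
    N = len(study)
    rows = []
    for (term_id, term_name), sub in ann.groupby(["term_id", "term_name"], sort=True):
        genes = set(sub["gene_id"])
        annotated = len(genes)
        significant = len(genes & study)
        if significant == 0:
            continue
        expected = annotated * N / M
        p = float(hypergeom.sf(significant - 1, M, annotated, N))
        rows.append(
            EnrichmentRow(
                term_id=term_id,
                term_name=term_name,
                annotated=annotated,
                significant=significant,
                expected=expected,
                p_value=min(p, 1.0),
                adj_p=float("nan"),
            )
        )
    if not rows:
        warnings.warn("no study gene carries any annotation term")
        return []
    pvals = [r.p_value for r in rows]
    _, adj, _, _ = multipletests(pvals, method="fdr_bh")
    for r, a in zip(rows, adj):
        r.adj_p = float(a)
    rows.sort(key=lambda r: (r.p_value, r.term_id))
    return rows


def compare_features(
    classes: dict[str, str],
    features: pd.DataFrame,
    binary_continuity_correction: bool = False,
) -> pd.DataFrame:
    """Per-feature comparison between two gene classes.

    ``features`` is indexed by gene_id with one column per feature
    (genomic size, CDS size, exon count, expression breadth/level, ...).
    Numeric features get per-class mean/median and a two-sided
    Mann–Whitney test; binary (0/1) features a 2x2 chi-squared test.
    Features where a class has < 2 observations are skipped (logged).
    """
    labels = sorted(set(classes.values()))
    if len(labels) < 2:
        raise ValueError("need two gene classes to compare")
    if len(labels) > 2:
        raise ValueError(f"expected two classes, got {labels}")
    rows = []
    cls = pd.Series(classes, name="_class")
    df = features.join(cls, how="inner")
    for feat in features.columns:
        sub = df[[feat, "_class"]].dropna()
        groups = [sub.loc[sub["_class"] == lab, feat].to_numpy() for lab in labels]
        if any(len(g) < 2 for g in groups):
            logger.info("feature %s skipped: a class has < 2 observations", feat)
            continue
        values = sub[feat]
        if values.nunique() < 2:
            logger.info("feature %s skipped: no variation", feat)
            continue
        is_binary = set(np.unique(values)) <= {0, 1, True, False}
        if is_binary:
            table = [
                [int(g.sum()), int(len(g) - g.sum())] for g in groups
            ]
            if min(min(r) for r in table) < 0:
                continue
            stat, p, _, _ = chi2_contingency(
                table, correction=binary_continuity_correction
            )
            test = "chi-squared"
        else:
            stat, p = mannwhitneyu(groups[0], groups[1], alternative="two-sided")
            test = "mann-whitney"
        row = {"feature": feat, "test": test, "statistic": float(stat),
               "p_value": float(p)}
        for lab, g in zip(labels, groups):
            row[f"mean_{lab}"] = float(np.mean(g))
            row[f"median_{lab}"] = float(np.median(g))
            row[f"n_{lab}"] = int(len(g))
        rows.append(row)
    return pd.DataFrame(rows)


def expression_features(expression: pd.DataFrame) -> pd.DataFrame:
    """Summarize a long (gene_id, condition, fpkm) table into per-gene
    features: expressed (any condition > 0), breadth (conditions with
    signal), and mean level over expressed conditions."""
    def _per_gene(g: pd.DataFrame) -> pd.Series:
        on = g["fpkm"] > 0
        return pd.Series(
            {
                "expressed": int(on.any()),
                "n_conditions_expressed": int(on.sum()),
                "mean_fpkm_expressed": float(g.loc[on, "fpkm"].mean()) if on.any() else np.nan,
            }
        )
    return expression.groupby("gene_id").apply(_per_gene, include_groups=False)


def structural_features(genes: Iterable) -> pd.DataFrame:
    """Genomic size, CDS size and exon count per gene (collapsed models)."""
    rows = {}
    for g in genes:
        tr = g.primary_transcript()
        rows[g.gene_id] = {
            "genomic_size": g.span,
            "cds_size": tr.cds_length,
            "n_exons": len(tr.exons),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
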