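"""Annotation joins: GO-Slim category counts and characterized-gene lookup.

Both operations consume static file snapshots (no live database calls);
they report classification counts, not enrichment statistics.
"""

from __future__ import annotations

import pandas as pd

from heatmir.errors import FormatError

ASPECTS = ("BP", "CC", "MF")


def goslim_counts(
    genes,
    annotation: pd.DataFrame,
) -> tuple[dict[str, pd.DataFrame], list[str]]:
    """Per-aspect GO-Slim term counts over a gene list.

    Returns ``(tables, unannotated)``: for each aspect a DataFrame with
    columns term, count, percentage -- where ``count`` is the number of
    input genes carrying the term and ``percentage`` is count over the
    number of input genes annotated in that aspect (a gene may carry several
    terms, so percentages within an aspect may sum past 100) -- plus the
    genes absent from the annotation entirely.
    """
    bad = set(annotation["aspect"]) - set(ASPECTS)
    if bad:
        raise FormatError(f"unknown GO aspect {sorted(bad)[0]!r}")
    genes = list(dict.fromkeys(genes))
    ann = annotation[annotation["gene_id"].isin(genes)].drop_duplicates()
    tables: dict[str, pd.DataFrame] = {}
    for aspect in ASPECTS:
        sub = ann[ann["aspect"] == aspect]
        n_genes = sub["gene_id"].nunique()
        counts = (
            sub.groupby("term")["gene_id"].nunique().sort_values(ascending=False)
        )
        table = counts.rename("count").reset_index()
        table["percentage"] = (
            100.0 * table["count"] / n_genes if n_genes else 0.0
        )
        table = table.sort_values(["count", "term"], ascending=[False, True])
        tables[aspect] = table.reset_index(drop=True)
    annotated = set(ann["gene_id"])
    unannotated = [g for g in genes if g not in annotated]
    return tables, unannotated


def ogro_lookup(
    genes,
    ogro: pd.DataFrame,
) -> tuple[pd.DataFrame, int]:
    """Inner-join a gene list against characterized-gene records.

    Returns the joined record table (one row per (locus, character) record,
    sorted by locus then character) and the number of distinct characterized
    loci found.
    """
    genes = set(genes)
    hits = ogro[ogro["locus_id"].isin(genes)].copy()
    hits = hits.sort_values(["locus_id", "character_major", "character_minor"])
    return hits.reset_index(drop=True), hits["locus_id"].nunique()
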