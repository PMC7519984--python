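"""High-confidence miRNA-family -> target pairing by direction opposition.

A predicted (family, gene) pair is *high confidence* when the family and the
gene change in opposite directions during the heat time course.  Two
readings of "opposite direction within any time period" are implemented:

* ``same_timepoint`` (default, stricter): there is at least one timepoint at
  which both sides are significant and their directions oppose;
* ``overall``: the family's and the gene's overall direction labels oppose
  (an ``up_down`` label on either side is compatible with any label on the
  other, matching how mixed families carry targets of both signs in the
  curated pair table).
"""

from __future__ import annotations

import pandas as pd

from heatmir.containers import FamilyProfile
from heatmir.diffexpr import timepoints_of
from heatmir.errors import ConfigError


def candidate_pairs(
    family_targets: pd.DataFrame,
    family_profiles: dict[str, FamilyProfile],
    gene_calls: pd.DataFrame,
) -> pd.DataFrame:
    """(family, gene) pairs where both sides are DE and the gene is predicted.

    ``family_targets`` is the family-level prediction table (columns
    ``family`` and ``transcript_id``); ``family_profiles`` holds the DE
    families; ``gene_calls`` is a call_de table over genes with a ``de``
    column.
    """
    de_genes = set(gene_calls.index[gene_calls["de"]])
    keep = family_targets["family"].isin(family_profiles) & family_targets[
        "transcript_id"
    ].isin(de_genes)
    out = family_targets[keep].copy()
    out = out.rename(columns={"transcript_id": "gene_id"})
    return out.sort_values(["family", "gene_id"]).reset_index(drop=True)


def _opposite(a: str, b: str) -> bool:
    return {a, b} == {"up", "down"}


def high_confidence_pairs(
    pairs: pd.DataFrame,
    family_profiles: dict[str, FamilyProfile],
    gene_calls: pd.DataFrame,
    mode: str = "same_timepoint",
) -> pd.DataFrame:
    """Filter candidate pairs to those with opposing expression changes.

    Adds ``family_overall``, ``gene_overall`` and (in ``same_timepoint``
    mode) the comma-joined ``supporting_timepoints`` at which the opposition
    holds.  A family timepoint in ``conflict`` supports no pair at that
    timepoint, while ``up_down`` families support pairs wherever their
    per-timepoint direction is defined.
    """
    if mode not in ("same_timepoint", "overall"):
        raise ConfigError(f"unknown pairing mode {mode!r}")
    tps = timepoints_of(gene_calls)
    rows = []
    for _, row in pairs.iterrows():
        fam = family_profiles[row["family"]]
        gene = gene_calls.loc[row["gene_id"]]
        gene_overall = gene["overall_direction"]
        if mode == "same_timepoint":
            support = [
                tp for tp in tps
                if _opposite(fam.direction_by_timepoint.get(tp, "none"),
                             gene[f"direction_{tp}"])
            ]
            if not support:
                continue
        else:
            f, g = fam.overall_direction, gene_overall
            if not (_opposite(f, g) or "up_down" in (f, g)):
                continue
            support = []
        out = dict(row)
        out["family_overall"] = fam.overall_direction
        out["gene_overall"] = gene_overall
        out["supporting_timepoints"] = ",".join(support)
        rows.append(out)
    columns = list(pairs.columns) + [
        "family_overall", "gene_overall", "supporting_timepoints"
    ]
    return pd.DataFrame(rows, columns=columns)


def timecourse_counts(
    mirna_calls: pd.DataFrame,
    gene_calls: pd.DataFrame,
) -> pd.DataFrame:
    """Per-timepoint counts of significantly up/down miRNAs and target genes.

    Rows: (side, direction) for side in {mirna, target_gene}, direction in
    {up, down}; one column per treatment timepoint.  This is the plotting
    input for the time-lag bar chart.
    """
    tables = {"mirna": mirna_calls, "target_gene": gene_calls}
    tps = timepoints_of(gene_calls if not gene_calls.empty else mirna_calls)
    rows = []
    for side, calls in tables.items():
        for direction in ("up", "down"):
            counts = {
                tp: 0 if calls.empty else int(
                    (calls[f"direction_{tp}"] == direction).sum()
                )
                for tp in tps
            }
            rows.append({"side": side, "direction": direction, **counts})
    return pd.DataFrame(rows, columns=["side", "direction", *tps])
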