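"""Per-timepoint differential expression and miRNA-family aggregation.

Each treatment timepoint is contrasted against the control timepoint with a
two-sample test on normalized log2 intensities.  Two tests are offered:

* ``student_t`` -- pooled-variance two-sample t (the pooled form rather than
  Welch, because Welch's df estimate degenerates at n = 2 per group);
* ``moderated_t`` (default) -- empirical-Bayes variance shrinkage: each
  probe's pooled variance is shrunk toward a prior variance whose scale and
  degrees of freedom are fitted by method of moments across all probes
  (the sample variances are modeled as s^2 ~ s0^2 * F(d, d0)); the t
  statistic then uses the posterior variance with d + d0 degrees of freedom.
  With only two replicates per group, raw per-probe variances are too noisy
  for a stable plain t, which is why moderation is the default.

An entity is differentially expressed (DE) when |log2FC| >= 1.0 (inclusive)
and p < 0.05 (strict) at one or more treatment timepoints.  No
multiple-testing correction enters the DE call; a BH-FDR column is emitted
for reference only.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd
from scipy import stats

from heatmir.containers import ExpressionMatrix, FamilyProfile
from heatmir.errors import ConfigError, FormatError

MIRNA_ID_RE = re.compile(
    r"^(?P<prefix>[a-zA-Z]{2,4})-miR(?P<number>\d+)"
    r"(?P<variant>[a-z]*)(?P<suffix>([.-]\S+)?)$"
)


# ---------------------------------------------------------------------------
# two-sample tests
# ---------------------------------------------------------------------------

def _group_stats(arr: np.ndarray):
    n = arr.shape[1]
    mean = arr.mean(axis=1)
    ss = ((arr - mean[:, None]) ** 2).sum(axis=1)
    return n, mean, ss


def _fit_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F model s^2 ~ s0^2 * F(df, d0).

    Matches the observed mean and variance of the per-entity sample
    variances.  Returns (prior_df d0, prior variance s0^2); d0 = inf when the
    observed dispersion is no larger than sampling noise alone predicts
    (complete shrinkage).
    """
    s2 = s2[np.isfinite(s2)]
    m1 = float(s2.mean())
    if m1 <= 0 or len(s2) < 2:
        return np.inf, max(m1, 1e-12)
    r = float(s2.var(ddof=1)) / m1**2
    # Var[F]/E[F]^2 = 2 (d + d0 - 2) / (d (d0 - 4)) for F(d, d0)
    denom = r * df - 2.0
    if denom <= 0:
        return np.inf, m1
    d0 = (4.0 * r * df + 2.0 * df - 4.0) / denom
    if d0 <= 4.0:  # moment formula valid only for d0 > 4; heavy-tail fallback
        d0 = 4.0 + 1e-6
    s0_2 = m1 * (d0 - 2.0) / d0
    return d0, s0_2


def compute_de(
    m: ExpressionMatrix,
    control: str,
    treatment: str,
    method: str = "moderated_t",
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Contrast one treatment timepoint against the control.

    Returns a DataFrame indexed by entity with columns ``log2fc`` (mean
    treatment minus mean control) and ``pvalue`` (two-sided).

    ``prior_df`` overrides the fitted prior degrees of freedom of the
    moderated test (0 disables shrinkage, reproducing the plain t).
    """
    if control == treatment:
        raise ConfigError("control and treatment timepoints must differ")
    if method not in ("student_t", "moderated_t"):
        raise ConfigError(f"unknown DE method {method!r}")
    ctrl_ids = m.samples_at(control)
    trt_ids = m.samples_at(treatment)
    min_rep = 2 if method == "student_t" else 1
    for name, ids in (("control", ctrl_ids), ("treatment", trt_ids)):
        if len(ids) < min_rep:
            raise ConfigError(
                f"group {name!r} ({control if name == 'control' else treatment}) "
                f"has {len(ids)} replicates; {method} needs >= {min_rep}"
            )
    a = m.values[trt_ids].to_numpy(dtype=float)
    b = m.values[ctrl_ids].to_numpy(dtype=float)
    n1, mean1, ss1 = _group_stats(a)
    n2, mean2, ss2 = _group_stats(b)
    lfc = mean1 - mean2
    df = n1 + n2 - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        s2 = (ss1 + ss2) / df if df > 0 else np.full_like(lfc, np.nan)
    se_factor = 1.0 / n1 + 1.0 / n2

    if method == "student_t":
        pvalue = _t_pvalues(lfc, s2, df, se_factor)
    else:
        if prior_df is None:
            d0, s0_2 = _fit_variance_prior(s2, df)
        elif prior_df == 0:
            d0, s0_2 = 0.0, 0.0
        else:
            d0 = float(prior_df)
            s0_2 = float(np.nanmean(s2)) if np.isfinite(d0) else float(np.nanmean(s2))
        if np.isinf(d0):
            post = np.full_like(lfc, s0_2)
            total_df = np.inf
        else:
            post = (d0 * s0_2 + df * s2) / (d0 + df) if (d0 + df) > 0 else s2
            total_df = d0 + df
        pvalue = _t_pvalues(lfc, post, total_df, se_factor)

    return pd.DataFrame({"log2fc": lfc, "pvalue": pvalue}, index=m.values.index)


def _t_pvalues(lfc, s2, df, se_factor):
    se = np.sqrt(s2 * se_factor)
    pvalue = np.ones_like(lfc)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / se
    zero_se = ~np.isfinite(t)
    # degenerate variance: identical values -> p = 1 when means agree,
    # perfectly separated groups -> p = 0
    pvalue[zero_se & (lfc != 0)] = 0.0
    ok = ~zero_se
    if np.any(ok):
        dff = df if np.ndim(df) == 0 else np.asarray(df)[ok]
        pvalue[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), dff)
    return np.clip(pvalue, 0.0, 1.0)


# ---------------------------------------------------------------------------
# multi-timepoint profiles and DE calling
# ---------------------------------------------------------------------------

def de_profile(
    m: ExpressionMatrix,
    control: str | None = None,
    method: str = "moderated_t",
) -> pd.DataFrame:
    """Contrast every treatment timepoint against the control.

    Returns one row per entity with columns ``log2fc_<t>`` and
    ``pvalue_<t>`` for each treatment timepoint t.
    """
    timepoints = m.timepoints
    if control is None:
        control = timepoints[0]
    if control not in timepoints:
        raise ConfigError(f"control timepoint {control!r} not in {timepoints}")
    pieces = {}
    for tp in timepoints:
        if tp == control:
            continue
        res = compute_de(m, control, tp, method=method)
        pieces[f"log2fc_{tp}"] = res["log2fc"]
        pieces[f"pvalue_{tp}"] = res["pvalue"]
    return pd.DataFrame(pieces)


def timepoints_of(profiles: pd.DataFrame) -> list[str]:
    """Treatment timepoints covered by a DE profile table."""
    return [c[len("log2fc_"):] for c in profiles.columns if c.startswith("log2fc_")]


def call_de(
    profiles: pd.DataFrame,
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Apply the DE rule: |log2FC| >= threshold (inclusive) and p < alpha
    (strict) at >= 1 timepoint.

    Adds per-timepoint ``significant_<t>`` and ``direction_<t>`` columns
    (direction in {up, down, none}; a direction is assigned only where the
    timepoint is significant), a ``de`` flag, a BH-FDR reference column per
    timepoint, and an ``overall_direction`` for DE entities.
    """
    out = profiles.copy()
    sig_cols = []
    for tp in timepoints_of(profiles):
        lfc = profiles[f"log2fc_{tp}"]
        p = profiles[f"pvalue_{tp}"]
        sig = (lfc.abs() >= lfc_threshold) & (p < alpha)
        out[f"significant_{tp}"] = sig
        out[f"direction_{tp}"] = np.where(
            sig & (lfc > 0), "up", np.where(sig & (lfc < 0), "down", "none")
        )
        out[f"fdr_{tp}"] = stats.false_discovery_control(np.clip(p, 0, 1))
        sig_cols.append(f"significant_{tp}")
    out["de"] = out[sig_cols].any(axis=1)
    out["overall_direction"] = [
        overall_direction_of(row, timepoints_of(profiles)) for _, row in out.iterrows()
    ]
    return out


def overall_direction_of(row, timepoints) -> str:
    """Summarize one entity's significant calls: up, down, up_down, or none."""
    dirs = {row[f"direction_{tp}"] for tp in timepoints} - {"none"}
    if not dirs:
        return "none"
    if dirs == {"up"}:
        return "up"
    if dirs == {"down"}:
        return "down"
    return "up_down"


# ---------------------------------------------------------------------------
# family mapping and aggregation
# ---------------------------------------------------------------------------

def map_to_family(mirna_id: str, lenient: bool = False) -> str:
    """Collapse a mature miRNA id to its family name.

    Strips trailing variant letters and arm/isoform suffixes:
    osa-miR169g -> osa-miR169; osa-miR397b.2 -> osa-miR397;
    osa-miR156a-5p -> osa-miR156.  Idempotent.  Under ``lenient`` an id
    that does not match the naming convention is passed through unchanged.
    """
    match = MIRNA_ID_RE.match(mirna_id)
    if match is None:
        if lenient:
            return mirna_id
        raise FormatError(f"id {mirna_id!r} does not follow miRNA naming convention")
    return f"{match.group('prefix')}-miR{match.group('number')}"


def aggregate_family(
    family: str,
    member_profiles: pd.DataFrame,
) -> FamilyProfile:
    """Aggregate DE member profiles (rows of a call_de table) into a family call.

    Per timepoint: ``up`` if at least one member is significantly up and none
    significantly down, ``down`` symmetrically, ``conflict`` if both occur,
    ``none`` if neither.  The overall direction is the common direction when
    every significant member call agrees, else ``up_down``.
    """
    if len(member_profiles) == 0:
        raise ConfigError(f"family {family!r} has no DE members to aggregate")
    tps = timepoints_of(member_profiles)
    direction_by_tp: dict[str, str] = {}
    all_calls: set[str] = set()
    for tp in tps:
        dirs = set(member_profiles[f"direction_{tp}"]) - {"none"}
        all_calls |= dirs
        if dirs == {"up"}:
            direction_by_tp[tp] = "up"
        elif dirs == {"down"}:
            direction_by_tp[tp] = "down"
        elif dirs == {"up", "down"}:
            direction_by_tp[tp] = "conflict"
        else:
            direction_by_tp[tp] = "none"
    if all_calls == {"up"}:
        overall = "up"
    elif all_calls == {"down"}:
        overall = "down"
    else:
        overall = "up_down"
    return FamilyProfile(
        family=family,
        members=list(member_profiles.index),
        direction_by_timepoint=direction_by_tp,
        overall_direction=overall,
    )


def aggregate_families(
    de_calls: pd.DataFrame,
    lenient_ids: bool = False,
) -> dict[str, FamilyProfile]:
    """Group DE miRNAs by family and aggregate each (non-DE members excluded)."""
    de_only = de_calls[de_calls["de"]]
    families: dict[str, list[str]] = {}
    for mirna_id in de_only.index:
        fam = map_to_family(str(mirna_id), lenient=lenient_ids)
        families.setdefault(fam, []).append(mirna_id)
    return {
        fam: aggregate_family(fam, de_only.loc[members])
        for fam, members in sorted(families.items())
    }


def family_profile_table(profiles: dict[str, FamilyProfile]) -> pd.DataFrame:
    """Tabular view of family profiles (one row per family)."""
    rows = []
    for fam, prof in sorted(profiles.items()):
        row = {
            "family": fam,
            "members": ",".join(prof.members),
            "n_members": len(prof.members),
            "overall_direction": prof.overall_direction,
        }
        for tp, d in prof.direction_by_timepoint.items():
            row[f"direction_{tp}"] = d
        rows.append(row)
    return pd.DataFrame(rows)
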