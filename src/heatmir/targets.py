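"""Plant miRNA target-site prediction by complementarity expectation scoring.

A miRNA is aligned antiparallel against every transcript window and each
duplex column is penalized:

===========================  ========
column                       penalty
===========================  ========
Watson-Crick match           0.0
G:U wobble                   0.5
mismatch                     1.0
gapped position (bulge)      2.0
===========================  ========

Penalties are doubled in the seed region, miRNA positions 2-13 counted from
the miRNA 5' end.  The sum over columns is the site's *expectation*; lower
is better and sites with expectation <= cutoff (default 3.0) are reported.
At most ``max_gaps`` (default 1) bulged positions are allowed, on either
strand; a bulged target base is never placed at a duplex terminus.  A gap
column takes the miRNA position of the next miRNA base (clipped to the
miRNA length) for seed weighting and mode classification.

Regulation mode: a site is classified ``translation_inhibition`` when a
mismatch or gap disrupts the central cleavage positions (miRNA positions
10-11), otherwise ``cleavage`` -- the canonical plant rule, where AGO-
mediated cleavage occurs between target bases opposite miRNA positions
10 and 11.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from heatmir.containers import TargetSite
from heatmir.errors import ConfigError, FormatError

MATCH, GU, MISMATCH, GAP = 0.0, 0.5, 1.0, 2.0
SEED_START, SEED_END = 2, 13  # miRNA positions, 1-based inclusive
CENTRAL_POSITIONS = (10, 11)

_ENC = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}
_DEC = "ACGUN"

# penalty lookup for (miRNA base, target base); N never pairs
_PAIR_PENALTY = np.full((5, 5), MISMATCH)
for _m, _t in ((0, 3), (3, 0), (1, 2), (2, 1)):  # A:U, U:A, C:G, G:C
    _PAIR_PENALTY[_m, _t] = MATCH
for _m, _t in ((2, 3), (3, 2)):  # G:U, U:G
    _PAIR_PENALTY[_m, _t] = GU

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G", "N": "N"}


def encode(seq: str) -> np.ndarray:
    try:
        return np.array([_ENC[c] for c in seq], dtype=np.int8)
    except KeyError as exc:
        raise FormatError(f"illegal RNA character {exc.args[0]!r}") from None


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


def position_weight(pos: int) -> float:
    """Seed doubling: weight 2 for miRNA positions 2-13, else 1."""
    return 2.0 if SEED_START <= pos <= SEED_END else 1.0


def classify_column(mirna_base: str, target_base: str) -> str:
    """Classify one duplex column: '|' match, 'o' G:U wobble, 'x' mismatch."""
    pen = _PAIR_PENALTY[_ENC[mirna_base], _ENC[target_base]]
    return "|" if pen == MATCH else ("o" if pen == GU else "x")


# ---------------------------------------------------------------------------
# explicit-alignment scoring
# ---------------------------------------------------------------------------

def score_duplex(mirna: str, site: str, alignment: str) -> float:
    """Score an explicit duplex alignment and return its expectation.

    ``mirna`` is 5'->3'; ``site`` is the transcript subsequence 5'->3';
    ``alignment`` has one character per column, ordered from the miRNA 5'
    end: ``|`` match, ``o`` G:U, ``x`` mismatch, ``-`` bulged miRNA base,
    ``^`` bulged target base.  The declared pair classes are recomputed from
    the bases; any inconsistency raises.
    """
    mirna = mirna.upper().replace("T", "U")
    site_rev = site.upper().replace("T", "U")[::-1]  # pair antiparallel
    mi = ti = 0
    total = 0.0
    for col in alignment:
        if col == "-":  # miRNA base bulged, no target base consumed
            mi += 1
            total += GAP * position_weight(mi)
        elif col == "^":  # target base bulged; weight by next miRNA position
            ti += 1
            total += GAP * position_weight(min(mi + 1, len(mirna)))
        elif col in "|ox":
            if mi >= len(mirna) or ti >= len(site_rev):
                raise FormatError("alignment longer than its sequences")
            observed = classify_column(mirna[mi], site_rev[ti])
            if observed != col:
                raise FormatError(
                    f"alignment column {mi + 1}: declared {col!r} but bases "
                    f"{mirna[mi]}/{site_rev[ti]} give {observed!r}"
                )
            mi += 1
            ti += 1
            pen = {"|": MATCH, "o": GU, "x": MISMATCH}[col]
            total += pen * position_weight(mi)
        else:
            raise FormatError(f"unknown alignment symbol {col!r}")
    if mi != len(mirna) or ti != len(site_rev):
        raise FormatError("alignment does not cover both sequences")
    return total


def classify_mode(site: TargetSite) -> str:
    """Cleavage unless central pairing (miRNA positions 10-11) is disrupted."""
    return _mode_from_alignment(site.alignment)


def _mode_from_alignment(alignment: str) -> str:
    mi = 0
    for col in alignment:
        if col == "-":
            mi += 1
            pos = mi
        elif col == "^":
            pos = mi + 1
        else:
            mi += 1
            pos = mi
        if col in "x-^" and pos in CENTRAL_POSITIONS:
            return "translation_inhibition"
    return "cleavage"


# ---------------------------------------------------------------------------
# transcript scanning
# ---------------------------------------------------------------------------

def _window_matrix(rev_enc: np.ndarray, width: int) -> np.ndarray:
    """All sliding windows of the reversed transcript, one row per window."""
    n = len(rev_enc) - width + 1
    if n <= 0:
        return np.empty((0, width), dtype=np.int8)
    return np.lib.stride_tricks.sliding_window_view(rev_enc, width)


def _alignment_string(mirna_enc, window_enc, target_idx, gap_cols):
    """Rebuild the column string for one scored configuration.

    ``target_idx[i]`` is the window index paired with miRNA index i (or -1
    for a bulged miRNA base); ``gap_cols`` maps column insertion points for
    bulged target bases.
    """
    cols = []
    for i, t in enumerate(target_idx):
        if i in gap_cols:
            cols.append("^")
        if t < 0:
            cols.append("-")
        else:
            pen = _PAIR_PENALTY[mirna_enc[i], window_enc[t]]
            cols.append("|" if pen == MATCH else ("o" if pen == GU else "x"))
    if len(mirna_enc) in gap_cols:
        cols.append("^")
    return "".join(cols)


def scan_transcript(
    mirna: str,
    transcript: str,
    cutoff: float = 3.0,
    max_gaps: int = 1,
    mirna_id: str = "miRNA",
    transcript_id: str = "transcript",
) -> list[TargetSite]:
    """Score the miRNA against every transcript window; report passing sites.

    Evaluates the antiparallel duplex at every start for the gapless
    configuration and, when ``max_gaps`` >= 1, every single-bulge
    configuration (one unpaired miRNA base, or one unpaired internal target
    base).  Sites with expectation <= ``cutoff`` are kept, overlapping sites
    are collapsed to the best-scoring one (ties broken by smallest start),
    and the result is sorted by (expectation, start).  Start/end are 1-based
    closed transcript coordinates of the site, 5'-most base first.
    """
    mirna = mirna.upper().replace("T", "U")
    transcript = transcript.upper().replace("T", "U")
    if not mirna or not transcript:
        raise ConfigError("empty sequence")
    if len(transcript) < len(mirna):
        raise ConfigError("transcript shorter than miRNA")
    if max_gaps not in (0, 1):
        raise ConfigError("max_gaps must be 0 or 1")
    L = len(mirna)
    m_enc = encode(mirna)
    rev = encode(transcript)[::-1]
    n = len(transcript)
    weights = np.array([position_weight(i + 1) for i in range(L)])

    candidates: list[tuple[float, int, int, str]] = []  # (exp, start, width, aln)

    def harvest(scores, width, describe):
        hit = np.nonzero(scores <= cutoff)[0]
        for k in hit:
            start = n - int(k) - width + 1  # 1-based transcript coordinate
            exp, aln = describe(int(k))
            candidates.append((exp, start, width, aln))

    # gapless
    win = _window_matrix(rev, L)
    if win.shape[0]:
        pen = _PAIR_PENALTY[m_enc[None, :], win] * weights[None, :]
        scores = pen.sum(axis=1)

        def describe_plain(k, scores=scores, win=win):
            return float(scores[k]), _alignment_string(
                m_enc, win[k], list(range(L)), set()
            )

        harvest(scores, L, describe_plain)

    if max_gaps >= 1:
        # One bulged miRNA base at 0-based index g0: prefix columns pair
        # unshifted, suffix columns pair shifted by one.  Prefix/suffix
        # cumulative sums give every g0 from two penalty matrices.
        win = _window_matrix(rev, L - 1)
        if win.shape[0]:
            pref = _PAIR_PENALTY[m_enc[:L - 1][None, :], win] * weights[:L - 1][None, :]
            suff = _PAIR_PENALTY[m_enc[1:][None, :], win] * weights[1:][None, :]
            pref_cum = np.concatenate(
                [np.zeros((win.shape[0], 1)), pref.cumsum(axis=1)], axis=1
            )
            suff_cum = np.concatenate(
                [suff[:, ::-1].cumsum(axis=1)[:, ::-1], np.zeros((win.shape[0], 1))],
                axis=1,
            )
            for g0 in range(L):
                scores = pref_cum[:, g0] + suff_cum[:, g0] + GAP * weights[g0]
                t_idx = [-1 if i == g0 else (i if i < g0 else i - 1)
                         for i in range(L)]

                def describe_mgap(k, scores=scores, win=win, t_idx=t_idx):
                    return float(scores[k]), _alignment_string(
                        m_enc, win[k], t_idx, set()
                    )

                harvest(scores, L - 1, describe_mgap)

        # One bulged internal target base at window index b (1 <= b <= L-1):
        # miRNA index i pairs window i below b, window i+1 from b on.
        win = _window_matrix(rev, L + 1)
        if win.shape[0]:
            pref = _PAIR_PENALTY[m_enc[None, :], win[:, :L]] * weights[None, :]
            suff = _PAIR_PENALTY[m_enc[None, :], win[:, 1:]] * weights[None, :]
            pref_cum = np.concatenate(
                [np.zeros((win.shape[0], 1)), pref.cumsum(axis=1)], axis=1
            )
            suff_cum = np.concatenate(
                [suff[:, ::-1].cumsum(axis=1)[:, ::-1], np.zeros((win.shape[0], 1))],
                axis=1,
            )
            for b in range(1, L):
                scores = pref_cum[:, b] + suff_cum[:, b] + GAP * weights[b]
                t_idx = [i if i < b else i + 1 for i in range(L)]

                def describe_tgap(k, scores=scores, win=win, t_idx=t_idx, b=b):
                    return float(scores[k]), _alignment_string(
                        m_enc, win[k], t_idx, {b}
                    )

                harvest(scores, L + 1, describe_tgap)

    # collapse overlaps: best expectation wins, ties to smallest start
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    kept: list[tuple[float, int, int, str]] = []
    occupied: list[tuple[int, int]] = []
    for exp, start, width, aln in candidates:
        end = start + width - 1
        if any(start <= e and end >= s for s, e in occupied):
            continue
        occupied.append((start, end))
        kept.append((exp, start, width, aln))

    sites = [
        TargetSite(
            mirna_id=mirna_id,
            transcript_id=transcript_id,
            start=start,
            end=start + width - 1,
            alignment=aln,
            expectation=exp,
            mode=_mode_from_alignment(aln),
        )
        for exp, start, width, aln in kept
    ]
    sites.sort(key=lambda s: (s.expectation, s.start))
    return sites


# ---------------------------------------------------------------------------
# batch prediction
# ---------------------------------------------------------------------------

def predict_targets(
    mirnas: dict[str, str],
    transcripts: dict[str, str],
    cutoff: float = 3.0,
    max_gaps: int = 1,
) -> pd.DataFrame:
    """Best passing site for every (miRNA, transcript) pair that has one.

    Columns: mirna_id, transcript_id, start, end, expectation, mode,
    alignment.  Rows are sorted by (mirna_id, transcript_id).
    """
    if not mirnas or not transcripts:
        raise ConfigError("empty sequence set")
    rows = []
    for mid in sorted(mirnas):
        for tid in sorted(transcripts):
            if len(transcripts[tid]) < len(mirnas[mid]):
                continue
            sites = scan_transcript(
                mirnas[mid], transcripts[tid], cutoff=cutoff, max_gaps=max_gaps,
                mirna_id=mid, transcript_id=tid,
            )
            if sites:
                best = sites[0]
                rows.append({
                    "mirna_id": mid,
                    "transcript_id": tid,
                    "start": best.start,
                    "end": best.end,
                    "expectation": best.expectation,
                    "mode": best.mode,
                    "alignment": best.alignment,
                })
    return pd.DataFrame(
        rows,
        columns=["mirna_id", "transcript_id", "start", "end",
                 "expectation", "mode", "alignment"],
    )


def family_level_targets(predictions: pd.DataFrame, family_of) -> pd.DataFrame:
    """Collapse member-level predictions to one row per (family, gene).

    ``family_of`` maps a miRNA id to its family.  Within a family the best
    (lowest-expectation, then earliest-start) member site represents the
    pair; each gene appears once per family ("removing repeated genes").
    """
    if predictions.empty:
        return predictions.assign(family=pd.Series(dtype=str)).iloc[0:0][
            ["family", "transcript_id", "start", "end",
             "expectation", "mode", "alignment", "mirna_id"]
        ]
    pred = predictions.copy()
    pred["family"] = [family_of(m) for m in pred["mirna_id"]]
    pred = pred.sort_values(
        ["family", "transcript_id", "expectation", "start", "mirna_id"]
    )
    best = pred.groupby(["family", "transcript_id"], as_index=False).first()
    return best[["family", "transcript_id", "start", "end",
                 "expectation", "mode", "alignment", "mirna_id"]]
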