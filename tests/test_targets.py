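import numpy as np
import pytest

from heatmir import targets
from heatmir.containers import TargetSite
from heatmir.errors import FormatError
from heatmir.targets import (
    predict_targets,
    reverse_complement,
    scan_transcript,
    score_duplex,
)

MIR = "ACGUACGUACGUACGUACGUA"  # 21 nt
COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


def perfect_site(mirna=MIR):
    return reverse_complement(mirna)


def mutate(site, mirna, mirna_pos, new_base):
    """Replace the site base facing the given miRNA position (1-based)."""
    idx = len(site) - mirna_pos  # antiparallel: miRNA pos 1 faces site 3' end
    return site[:idx] + new_base + site[idx + 1:]


# ---------------------------------------------------------------------------
# independent brute-force oracle (plain Python, no shared scoring code)
# ---------------------------------------------------------------------------

def _pair_penalty(m, t):
    if COMP[m] == t:
        return 0.0
    if (m, t) in (("G", "U"), ("U", "G")):
        return 0.5
    return 1.0


def _w(pos):
    return 2.0 if 2 <= pos <= 13 else 1.0


def brute_force_sites(mirna, transcript, cutoff, max_gaps=1):
    """Enumerate every window and single-bulge placement by hand."""
    L, n = len(mirna), len(transcript)
    rev = transcript[::-1]
    cands = []  # (expectation, start, width)

    def window(k, width):  # window k of reversed transcript -> 1-based start
        return rev[k:k + width], n - k - width + 1

    for k in range(n - L + 1):  # gapless
        w, start = window(k, L)
        exp = sum(_pair_penalty(mirna[i], w[i]) * _w(i + 1) for i in range(L))
        cands.append((exp, start, L))
    if max_gaps >= 1:
        for k in range(n - (L - 1) + 1):  # one bulged miRNA base
            w, start = window(k, L - 1)
            for g in range(1, L + 1):
                exp = 2.0 * _w(g)
                for i in range(L):
                    if i == g - 1:
                        continue
                    t = w[i] if i < g - 1 else w[i - 1]
                    exp += _pair_penalty(mirna[i], t) * _w(i + 1)
                cands.append((exp, start, L - 1))
        for k in range(n - (L + 1) + 1):  # one bulged internal target base
            w, start = window(k, L + 1)
            for b in range(1, L):
                exp = 2.0 * _w(b + 1)
                for i in range(L):
                    t = w[i] if i < b else w[i + 1]
                    exp += _pair_penalty(mirna[i], t) * _w(i + 1)
                cands.append((exp, start, L + 1))

    passing = sorted((c for c in cands if c[0] <= cutoff),
                     key=lambda c: (c[0], c[1], c[2]))
    kept, occupied = [], []
    for exp, start, width in passing:
        end = start + width - 1
        if any(start <= e and end >= s for s, e in occupied):
            continue
        occupied.append((start, end))
        kept.append((exp, start, end))
    return sorted(kept, key=lambda c: (c[0], c[1]))


# ---------------------------------------------------------------------------
# score_duplex
# ---------------------------------------------------------------------------

class TestScoreDuplex:
    def test_perfect_complement_scores_zero(self):
        assert score_duplex(MIR, perfect_site(), "|" * 21) == 0.0

    def test_single_gu_in_seed_costs_one(self):
        # miRNA position 4 is U; facing base A -> G gives a U:G wobble
        site = mutate(perfect_site(), MIR, 4, "G")
        aln = "|" * 3 + "o" + "|" * 17
        assert score_duplex(MIR, site, aln) == 1.0  # 0.5 doubled in seed

    def test_mismatches_at_positions_1_and_10(self):
        site = mutate(perfect_site(), MIR, 1, "C")   # A faced by C: mismatch
        site = mutate(site, MIR, 10, "A")            # G faced by A: mismatch
        aln = "x" + "|" * 8 + "x" + "|" * 11
        assert score_duplex(MIR, site, aln) == 3.0   # 1.0 + 1.0 * 2

    def test_seed_defect_costs_exactly_double(self):
        in_seed = mutate(perfect_site(), MIR, 7, "A")    # G:A mismatch, seed
        out_seed = mutate(perfect_site(), MIR, 17, "C")  # A:C mismatch, non-seed
        aln_in = "|" * 6 + "x" + "|" * 14
        aln_out = "|" * 16 + "x" + "|" * 4
        assert score_duplex(MIR, in_seed, aln_in) == \
            2 * score_duplex(MIR, out_seed, aln_out)

    def test_inconsistent_alignment_rejected(self):
        with pytest.raises(FormatError, match="declared"):
            score_duplex(MIR, perfect_site(), "x" + "|" * 20)

    def test_gapped_alignment_scoring(self):
        # bulged miRNA base at position 1 (non-seed): gap penalty 2.0
        site = perfect_site()[:-1]  # site lacks the base facing miRNA pos 1
        aln = "-" + "|" * 20
        assert score_duplex(MIR, site, aln) == 2.0


class TestClassifyMode:
    def test_perfect_complement_is_cleavage(self):
        sites = scan_transcript(MIR, "AA" + perfect_site() + "GG")
        assert sites[0].mode == "cleavage"

    @pytest.mark.parametrize("pos,mode", [
        (10, "translation_inhibition"),
        (11, "translation_inhibition"),
        (3, "cleavage"),
        (17, "cleavage"),
    ])
    def test_central_mismatch_switches_mode(self, pos, mode):
        base = {"A": "C", "C": "A", "G": "A", "U": "C"}[MIR[pos - 1]]
        site = mutate(perfect_site(), MIR, pos, base)
        found = scan_transcript(MIR, "AA" + site + "GG", cutoff=5.0)
        assert found[0].mode == mode

    def test_classify_mode_reads_alignment_only(self):
        site = TargetSite("m", "t", 1, 21, "|" * 9 + "x" + "|" * 11,
                          2.0, "cleavage")
        assert targets.classify_mode(site) == "translation_inhibition"


class TestScanTranscript:
    def test_planted_perfect_site_found_with_coordinates(self):
        tx = "AGGA" * 10 + perfect_site() + "GGCC" * 5
        sites = scan_transcript(MIR, tx)
        assert len(sites) == 1
        s = sites[0]
        assert (s.start, s.end, s.expectation) == (41, 61, 0.0)
        assert tx[s.start - 1:s.end] == perfect_site()
        # reported site substring re-scores to the reported expectation
        assert score_duplex(MIR, tx[s.start - 1:s.end], s.alignment) == 0.0

    def test_random_transcript_has_no_passing_window(self):
        rng = np.random.default_rng(9)
        tx = "".join(rng.choice(list("ACGU"), size=1000))
        mir = "".join(rng.choice(list("ACGU"), size=21))
        assert scan_transcript(mir, tx, cutoff=3.0) == []
        assert brute_force_sites(mir, tx, cutoff=3.0) == []

    def test_equals_brute_force_enumeration_on_random_instances(self):
        """Banded scan must match exhaustive window/gap enumeration exactly."""
        rng = np.random.default_rng(17)
        for trial in range(50):
            mir = "".join(rng.choice(list("ACGU"), size=21))
            tx = "".join(rng.choice(list("ACGU"), size=80))
            if trial % 2 == 0:  # embed a degraded near-site half the time
                site = list(reverse_complement(mir))
                for pos in rng.choice(21, size=rng.integers(0, 4), replace=False):
                    site[pos] = str(rng.choice(list("ACGU")))
                k = int(rng.integers(0, len(tx) - 21))
                tx = tx[:k] + "".join(site) + tx[k + 21:]
            cutoff = float(rng.choice([3.0, 8.0, 14.0]))
            got = [(s.expectation, s.start, s.end)
                   for s in scan_transcript(mir, tx, cutoff=cutoff)]
            assert got == brute_force_sites(mir, tx, cutoff), (trial, cutoff)

    def test_overlapping_sites_collapse_to_best(self):
        tx = "AAAA" + perfect_site() + "AAAA"
        sites = scan_transcript(MIR, tx, cutoff=10.0)
        starts = [s.start for s in sites]
        assert len(starts) == len(set(starts))
        spans = sorted((s.start, s.end) for s in sites)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 < s2  # no overlap survives

    def test_expectation_nonnegative_zero_iff_perfect(self):
        sites = scan_transcript(MIR, perfect_site(), cutoff=30.0, max_gaps=0)
        assert sites[0].expectation == 0.0
        worse = scan_transcript(MIR, mutate(perfect_site(), MIR, 5, "C"),
                                cutoff=30.0, max_gaps=0)
        assert worse[0].expectation > 0.0


class TestPredictTargets:
    def test_single_planted_site_gives_single_row(self):
        mirnas = {"osa-miR1001": MIR, "osa-miR1002": "GGGGGGGGGGGGGGGGGGGGG"}
        transcripts = {
            "LOC_Os01g10001": "AAAA" + perfect_site() + "CCCC",
            "LOC_Os01g10002": "AAGG" * 20,
            "LOC_Os01g10003": "AGGA" * 20,
        }
        table = predict_targets(mirnas, transcripts, cutoff=3.0)
        assert len(table) == 1
        assert table.loc[0, "mirna_id"] == "osa-miR1001"
        assert table.loc[0, "transcript_id"] == "LOC_Os01g10001"

    def test_family_level_deduplication(self):
        # two members of one family both hit the same gene -> one family row
        mirnas = {"osa-miR1001a": MIR, "osa-miR1001b": MIR}
        transcripts = {"LOC_Os01g10001": "AAAA" + perfect_site() + "CCCC"}
        member_level = predict_targets(mirnas, transcripts)
        assert len(member_level) == 2
        fam = targets.family_level_targets(member_level, lambda m: m[:-1])
        assert len(fam) == 1
        assert fam.loc[0, "family"] == "osa-miR1001"

    def test_planted_sites_and_decoys_separate_cleanly(self, small_study):
        truth = small_study.truth.sites
        pred = predict_targets(
            {m: small_study.mirnas[m] for m in truth["mirna_id"].unique()},
            small_study.transcripts, cutoff=3.0,
        )
        predicted = set(zip(pred["mirna_id"], pred["transcript_id"]))
        real = truth[truth["kind"] != "decoy"]
        decoys = truth[truth["kind"] == "decoy"]
        for pair in zip(real["mirna_id"], real["transcript_id"]):
            assert pair in predicted  # recall 1.0 by construction
        for pair in zip(decoys["mirna_id"], decoys["transcript_id"]):
            assert pair not in predicted  # decoy margin guarantees exclusion
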