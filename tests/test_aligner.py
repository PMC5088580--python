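"""Probabilistic aligner: threshold arithmetic, the in-trie worked example,
oracle equivalence, score validity, and liftover."""

import math

import numpy as np
import pytest

from paraclip import aligner as al
from paraclip.error_model import ErrorProfile
from paraclip.fmindex import FmIndex
from paraclip.formats_io import ReadRecord, SamRecord, TranscriptMap, revcomp
from paraclip.simulator import (SimulatorConfig, parclip_error_profile,
                                simulate_dataset, synthetic_transcripts)

from oracles import exhaustive_hits

A, C, G, T = 0, 1, 2, 3


def _uniform_profile(diag: float, I: float = 0.0, D: float = 0.0) -> ErrorProfile:
    off = (1.0 - diag) / 3.0
    M = np.full((4, 4), off)
    np.fill_diagonal(M, diag)
    return ErrorProfile(M, I, D)


IDENTITY = ErrorProfile(np.eye(4), 0.0, 0.0)


# ---------------------------------------------------------------------------
# avg rates / X / threshold
# ---------------------------------------------------------------------------

def test_avg_rates_error_free_limit():
    assert al.avg_rates(IDENTITY) == (1.0, 0.0)


def test_avg_rates_arithmetic():
    prof = _uniform_profile(0.98, I=0.005, D=0.005)
    am, _ = al.avg_rates(prof)
    assert am == pytest.approx((4 * 0.98 + (1 - 0.01)) / 5)         # 0.982
    # off-diagonal sum 0.24, I = D = 0.005 -> avg_mismatch = 0.25/14
    prof2 = _uniform_profile(0.94, I=0.005, D=0.005)
    _, amm = al.avg_rates(prof2)
    assert amm == pytest.approx((0.24 + 0.01) / 14)                  # ~0.017857


def test_estimate_x_floor_and_scaling():
    # mbar = 0.02 -> X(25) = max(1, 0.5) = 1
    prof = _uniform_profile(1 - 3 * (0.02 / 3))     # off-diagonal sum = 0.08
    assert al.estimate_X(prof, 25) == 1.0
    # mbar = 0.03 -> X(100) = 3
    prof2 = _uniform_profile(1 - 3 * (0.02 / 3), I=0.005, D=0.005)
    assert al.estimate_X(prof2, 100) == pytest.approx(3.0)
    assert al.estimate_X(IDENTITY, 50) == 1.0       # floor dominates


def test_threshold_closed_form():
    assert al.threshold(IDENTITY, 30, 0) == 1.0
    prof = parclip_error_profile()
    am, amm = al.avg_rates(prof)
    for L, X in [(10, 1), (25, 2), (30, 3.5)]:
        expect = math.exp((L - X) * math.log(am) + X * math.log(amm))
        assert al.threshold(prof, L, X) == pytest.approx(expect, rel=1e-12)


def test_threshold_strictly_decreasing_in_x():
    prof = parclip_error_profile()
    ts = [al.threshold(prof, 25, x) for x in (0, 0.5, 1, 2, 3, 5)]
    assert all(a > b for a, b in zip(ts, ts[1:]))


# ---------------------------------------------------------------------------
# the in-trie worked example
# ---------------------------------------------------------------------------

def test_worked_example_probabilistic_search():
    """Read GCCATG vs reference GTTATG: the probability-threshold search
    finds the placement with two T->C substitutions in 14 comparisons."""
    idx = FmIndex([("ref", "GTTATG")])
    params = al.SearchParams(profile=parclip_error_profile(), X=2.0,
                             allow_indels=False, both_strands=False,
                             count_comparisons=True)
    hits, comparisons = al.align_read(idx, "GCCATG", params)
    assert comparisons == 14
    assert len(hits) == 1
    h = hits[0]
    assert (h.ref_name, h.start, h.strand) == ("ref", 1, "+")
    assert [(off, kind) for off, kind, *_ in h.edits] == [(1, "sub"), (2, "sub")]


def test_worked_example_two_mismatch_baseline():
    """The counted-mismatch search (<=2) finds the same placement in 16
    comparisons."""
    idx = FmIndex([("ref", "GTTATG")])
    hits, comparisons = al.align_baseline(idx, "GCCATG", 2)
    assert comparisons == 16
    assert [(h.ref_name, h.start, h.n_mismatches) for h in hits] == [("ref", 1, 2)]


def test_baseline_zero_mismatches():
    idx = FmIndex([("ref", "GTTATGACGT")])
    hits, n = al.align_baseline(idx, "TATGA", 0)
    assert [(h.ref_name, h.start) for h in hits] == [("ref", 3)]
    assert n >= 5                      # true path plus failed branches
    hits2, _ = al.align_baseline(idx, "TACGA", 0)
    assert hits2 == []


def test_exact_read_identity_profile():
    idx = FmIndex([("ref", "GTTATGACGTTTACG")])
    params = al.SearchParams(profile=IDENTITY, X=0.0, allow_indels=False,
                             both_strands=False)
    hits, _ = al.align_read(idx, "ATGACGT", params)
    assert len(hits) == 1
    assert hits[0].p == pytest.approx(1.0)
    assert hits[0].edits == []


def test_short_read_rejected():
    idx = FmIndex([("ref", "GTTATG")])
    with pytest.raises(al.ReadTooShortError):
        al.align_read(idx, "ATG", al.SearchParams(profile=IDENTITY))


# ---------------------------------------------------------------------------
# scoring properties
# ---------------------------------------------------------------------------

def test_tc_conversion_outscores_other_substitution():
    """Under a PAR-CLIP profile a read differing by one T->C aligns with
    strictly higher p than the same read differing by T->G."""
    ref = "ACGGATTCAGGTACCATTGGACT"
    idx = FmIndex([("ref", ref)])
    params = al.SearchParams(profile=parclip_error_profile(), X=2.0,
                             both_strands=False)
    base = ref[2:20]
    t_off = base.index("T")
    read_tc = base[:t_off] + "C" + base[t_off + 1:]
    read_tg = base[:t_off] + "G" + base[t_off + 1:]
    hit_tc = al.align_read(idx, read_tc, params)[0][0]
    hit_tg = al.align_read(idx, read_tg, params)[0][0]
    assert hit_tc.start == hit_tg.start == 3
    assert hit_tc.p > hit_tg.p


def test_reported_p_at_least_threshold_and_recomputable(transcripts_small,
                                                        parclip_profile):
    res = simulate_dataset(SimulatorConfig(lam=0.65, n_reads=120, seed=8),
                           transcripts_small)
    idx = FmIndex(transcripts_small)
    params = al.SearchParams(profile=parclip_profile, X=2.0)
    with np.errstate(divide="ignore"):
        log_M = np.log(parclip_profile.M)
    log_Mc = np.log(parclip_profile.complemented().M)
    log_I = math.log(parclip_profile.I)
    log_D = math.log(parclip_profile.D)
    for read in res.reads:
        T_val = params.threshold_for(len(read.sequence))
        hits, _ = al.align_read(idx, read, params)
        for h in hits:
            assert h.p >= T_val * (1 - 1e-9)
            lm = log_M if h.strand == "+" else log_Mc
            recomputed = al.path_log_probability(h.ops, lm, log_I, log_D,
                                                 float(lm.min()))
            assert h.log_p == pytest.approx(recomputed, rel=1e-12)


def test_hits_match_exhaustive_oracle_small(transcripts_small, parclip_profile):
    """Hit sets and p values equal the window-scoring oracle on a small
    reference (the deep 50 kb check runs in the acceptance suite)."""
    res = simulate_dataset(SimulatorConfig(lam=0.65, n_reads=60, seed=5),
                           transcripts_small)
    idx = FmIndex(transcripts_small)
    params = al.SearchParams(profile=parclip_profile, X=2.0)
    for read in res.reads:
        T_val = params.threshold_for(len(read.sequence))
        hits, _ = al.align_read(idx, read, params)
        impl = {(h.ref_name, h.start, h.strand): h.log_p for h in hits}
        oracle = exhaustive_hits(transcripts_small, read.sequence,
                                 parclip_profile, T_val)
        assert set(impl) == set(oracle)
        for key, log_p in impl.items():
            assert log_p == pytest.approx(oracle[key], abs=1e-9)


def test_reverse_strand_placement():
    """A reverse-complemented fragment maps to the minus strand at the same
    leftmost position, scored against its own (complemented) template."""
    rng = np.random.default_rng(3)
    seq = "".join("ACGT"[b] for b in rng.integers(0, 4, size=400))
    idx = FmIndex([("ref", seq)])
    frag = seq[100:125]
    prof = parclip_error_profile()
    params = al.SearchParams(profile=prof, X=2.0)
    hits, _ = al.align_read(idx, revcomp(frag), params)
    assert (hits[0].ref_name, hits[0].start, hits[0].strand) == ("ref", 101, "-")
    assert hits[0].edits == []
    # exact match against the minus-strand template: product of diagonal
    # entries over the template's bases
    expected = sum(math.log(prof.M["ACGT".index(b), "ACGT".index(b)])
                   for b in revcomp(frag))
    assert hits[0].log_p == pytest.approx(expected, rel=1e-12)


# ---------------------------------------------------------------------------
# dataset alignment
# ---------------------------------------------------------------------------

def test_noise_free_dataset_maps_perfectly(transcripts_small, parclip_profile):
    rng = np.random.default_rng(9)
    reads = []
    tdb = dict(transcripts_small)
    names = list(tdb)
    truth = {}
    for i in range(60):
        t = names[int(rng.integers(len(names)))]
        s = int(rng.integers(0, len(tdb[t]) - 25))
        reads.append(ReadRecord(f"r{i}", tdb[t][s:s + 25], [35] * 25))
        truth[f"r{i}"] = (t, s + 1)
    idx = FmIndex(transcripts_small)
    recs = al.align_dataset(idx, reads, al.SearchParams(profile=parclip_profile, X=2.0))
    for rec in recs:
        assert not rec.is_unmapped
        t, pos = truth[rec.read_name]
        assert (rec.ref_name, rec.pos) == (t, pos)


def test_empty_dataset_gives_header_only_sam(tmp_path, transcripts_small,
                                             parclip_profile):
    from paraclip.formats_io import write_sam
    idx = FmIndex(transcripts_small)
    recs = al.align_dataset(idx, [], al.SearchParams(profile=parclip_profile))
    p = tmp_path / "empty.sam"
    write_sam(recs, [(n, idx.ref_lengths[n]) for n in idx.ref_names], p)
    lines = p.read_text().splitlines()
    assert all(l.startswith("@") for l in lines)
    assert len(lines) == 1 + len(transcripts_small)


def test_probabilistic_recall_exceeds_baseline(transcripts_small, parclip_profile):
    """On PAR-CLIP-like simulated data the probability-threshold search maps
    multi-conversion reads the 2-mismatch baseline loses."""
    from paraclip import benchmark as bm
    res = simulate_dataset(SimulatorConfig(lam=0.65, n_reads=1200, seed=31),
                           transcripts_small)
    idx = FmIndex(transcripts_small)
    params = al.SearchParams(profile=parclip_profile, X=2.0)
    truths = {t.read_name: t for t in res.truths}
    para = bm.benchmark(al.align_dataset(idx, res.reads, params), truths)
    base = bm.benchmark(al.align_dataset(idx, res.reads, params, baseline_mm=2), truths)
    assert para.recall > base.recall


# ---------------------------------------------------------------------------
# multi-reference combination
# ---------------------------------------------------------------------------

def _tx_record(name, pos1, ref_sub, read_seq, cigar=None):
    from conftest import make_sam
    return make_sam(name, "tx1", pos1, ref_sub, read_seq, cigar=cigar)


def test_liftover_single_exon_offset():
    # transcript offset 10 of a single-exon transcript at genome 1,000 (0-based)
    tmap = {"tx1": TranscriptMap("tx1", "chr1", "+", ((1000, 1100),))}
    rec = _tx_record("q", 11, "A" * 20, "A" * 20)
    unmapped = SamRecord("q", 0x4, "*", 0, 0, "*", "A" * 20, [30] * 20, {})
    merged = al.combine_references([unmapped], [rec], tmap)
    assert merged[0].ref_name == "chr1"
    assert merged[0].pos == 1011
    assert merged[0].cigar == "20M"


def test_liftover_junction_spanning_read():
    # exon1 = transcript offsets [0,20) at genome [1000,1020),
    # exon2 = offsets [20,50) at genome [1070,1100); read covers 15..34
    tmap = {"tx1": TranscriptMap("tx1", "chr1", "+", ((1000, 1020), (1070, 1100)))}
    rec = _tx_record("q", 16, "C" * 20, "C" * 20)
    unmapped = SamRecord("q", 0x4, "*", 0, 0, "*", "C" * 20, [30] * 20, {})
    merged = al.combine_references([unmapped], [rec], tmap)
    assert merged[0].pos == 1016
    assert merged[0].cigar == "5M50N15M"


def test_liftover_minus_strand_transcript():
    # minus-strand transcript: offset 0 is the *last* genome base of the block
    tmap = {"tx1": TranscriptMap("tx1", "chr1", "-", ((1000, 1050),))}
    read = "ACGTACGTAC"
    rec = _tx_record("q", 5, read, read)
    unmapped = SamRecord("q", 0x4, "*", 0, 0, "*", read, [30] * 10, {})
    merged = al.combine_references([unmapped], [rec], tmap)
    m = merged[0]
    # transcript offsets 4..13 -> genome 1049-4-9 .. 1049-4 = 1036..1045
    assert m.pos == 1037
    assert m.cigar == "10M"
    assert m.sequence == revcomp(read)
    assert m.is_reverse


def test_genome_mapping_takes_precedence():
    tmap = {"tx1": TranscriptMap("tx1", "chr1", "+", ((1000, 1100),))}
    gmapped = SamRecord("q", 0, "chr2", 500, 60, "10M", "A" * 10, [30] * 10,
                        {"MD": "10", "NM": 0})
    trec = _tx_record("q", 1, "A" * 10, "A" * 10)
    merged = al.combine_references([gmapped], [trec], tmap)
    assert merged[0] is gmapped


def test_liftover_unknown_transcript_raises():
    rec = _tx_record("q", 1, "A" * 10, "A" * 10)
    unmapped = SamRecord("q", 0x4, "*", 0, 0, "*", "A" * 10, [30] * 10, {})
    with pytest.raises(ValueError, match="tx1"):
        al.combine_references([unmapped], [rec], {})
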