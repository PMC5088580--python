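"""Estimator behaviour: substitution matrices, background exclusion,
conversion model and position models."""

import numpy as np
import pytest

from paraclip import error_model as em
from paraclip.clustering import Cluster
from paraclip.formats_io import SamRecord

from conftest import make_sam

A, C, G, T = 0, 1, 2, 3


def _records_with_rates(rates: dict[tuple[int, int], float], per_row: int = 1000):
    """Hand-made alignments realising exact empirical substitution rates:
    one long record per reference base, mismatching a known count of bases."""
    bases = "ACGT"
    recs = []
    for r in range(4):
        ref = bases[r] * per_row
        read = list(ref)
        pos = 0
        for b in range(4):
            if b == r:
                continue
            k = int(round(rates.get((r, b), 0.0) * per_row))
            for _ in range(k):
                read[pos] = bases[b]
                pos += 1
        recs.append(make_sam(f"row{r}", "chr", 1, ref, "".join(read)))
    return recs


def test_error_free_alignment_gives_floored_identity():
    ref = "ACGT" * 25
    recs = [make_sam("r0", "chr", 1, ref, ref)]
    prof = em.estimate_error_profile(recs)
    floor_entry = em.PROB_FLOOR / (1.0 + 3 * em.PROB_FLOOR)
    assert np.allclose(np.diag(prof.M), 1.0 / (1.0 + 3 * em.PROB_FLOOR))
    off = prof.M[~np.eye(4, dtype=bool)]
    assert np.allclose(off, floor_entry)
    assert prof.I == pytest.approx(em.PROB_FLOOR)
    assert prof.D == pytest.approx(em.PROB_FLOOR)


def test_tc_rate_hand_count():
    # 1,000 aligned ref-T positions of which 60 read C
    ref = "T" * 1000
    read = "C" * 60 + "T" * 940
    recs = [make_sam("r0", "chr", 1, ref, read),
            make_sam("r1", "chr2", 1, "ACG" * 100, "ACG" * 100)]
    prof = em.estimate_error_profile(recs)
    assert prof.M[T, C] == pytest.approx(0.06, abs=1e-3)
    assert prof.M[T, T] == pytest.approx(0.94, abs=1e-3)


def test_background_mean_of_constant_rates():
    rates = {(i, j): 0.004 for i in range(4) for j in range(4) if i != j}
    rates.pop((T, C))
    recs = _records_with_rates(rates)
    bg = em.estimate_background_profile(recs)
    assert bg.epsilon[T, C] == pytest.approx(0.004, abs=2e-4)


def test_background_mean_arithmetic():
    # ten rates at 0.002, one at 0.013 -> mean (10*0.002 + 0.013)/11 = 0.003
    pairs = [(i, j) for i in range(4) for j in range(4)
             if i != j and (i, j) != (T, C)]
    rates = {p: 0.002 for p in pairs}
    rates[pairs[0]] = 0.013
    recs = _records_with_rates(rates)
    bg = em.estimate_background_profile(recs)
    assert bg.epsilon[T, C] == pytest.approx(0.003, abs=2e-4)


def test_background_excludes_observed_tc():
    # 30% observed T->C must not leak into epsilon
    pairs = [(i, j) for i in range(4) for j in range(4)
             if i != j and (i, j) != (T, C)]
    rates = {p: 0.002 for p in pairs}
    rates[(T, C)] = 0.30
    recs = _records_with_rates(rates)
    bg = em.estimate_background_profile(recs)
    assert bg.epsilon[T, C] == pytest.approx(0.002, abs=2e-4)
    err = em.estimate_error_profile(recs)
    assert err.M[T, C] == pytest.approx(0.30, abs=5e-3)


def test_error_and_background_agree_off_tc_row():
    pairs = [(i, j) for i in range(4) for j in range(4)
             if i != j and (i, j) != (T, C)]
    rates = {p: 0.003 for p in pairs}
    rates[(T, C)] = 0.25
    recs = _records_with_rates(rates)
    M = em.estimate_error_profile(recs).M
    eps = em.estimate_background_profile(recs).epsilon
    for i in range(4):
        for j in range(4):
            if i == T and j in (T, C):
                continue
            assert M[i, j] == pytest.approx(eps[i, j], abs=1e-3)


def test_estimation_order_invariance():
    rates = {(A, G): 0.01, (T, C): 0.05}
    recs = _records_with_rates(rates)
    M1 = em.estimate_error_profile(recs).M
    M2 = em.estimate_error_profile(list(reversed(recs))).M
    assert np.array_equal(M1, M2)


def test_reverse_strand_counts_in_sense_orientation():
    # genomic A read as G on a reverse-strand record is a sense T->C event
    ref = "A" * 100
    read = "G" * 10 + "A" * 90
    recs = [make_sam("r0", "chr", 1, ref, read, reverse=True)]
    prof = em.estimate_error_profile(recs)
    assert prof.M[T, C] == pytest.approx(0.10, abs=2e-3)
    assert prof.M[A, G] < 0.01


def test_empty_input_raises():
    with pytest.raises(em.EstimationError):
        em.estimate_error_profile([])


def test_rows_are_stochastic_after_flooring():
    rng = np.random.default_rng(5)
    rates = {(i, j): float(rng.uniform(0, 0.05)) for i in range(4)
             for j in range(4) if i != j}
    prof = em.estimate_error_profile(_records_with_rates(rates))
    assert np.allclose(prof.M.sum(axis=1), 1.0, atol=1e-9)
    assert np.all(prof.M >= em.PROB_FLOOR / 2)


# ---------------------------------------------------------------------------
# conversion model
# ---------------------------------------------------------------------------

def _cluster(site_table, start=101, end=130, n_reads=100, tc_reads=70):
    cl = Cluster("tx", "+", start, end)
    cl.read_names = [f"r{i}" for i in range(n_reads)]
    cl.tc_read_count = tc_reads
    cl.site_table = site_table
    return cl


def test_alpha_single_site_hand_count():
    # one T site converted in 70 of 100 covering reads -> alpha[0] = 0.70
    cl = _cluster({115: [100, 70]})
    model = em.estimate_conversion_model([cl])
    assert model.alpha[0] == pytest.approx(0.70)
    assert model.n_sites_dist.tolist() == [1.0]


def test_beta_indicator_on_central_bin():
    clusters = []
    for s in (101, 501, 901):
        span = 30
        centre = s + span // 2
        clusters.append(_cluster({centre: [50, 40]}, start=s, end=s + span - 1))
    model = em.estimate_conversion_model(clusters)
    assert np.count_nonzero(model.beta) == 1
    assert model.beta[10] == pytest.approx(1.0)


def test_alpha_ranking_across_sites():
    cl = _cluster({110: [100, 80], 120: [100, 30], 125: [100, 10]})
    model = em.estimate_conversion_model([cl])
    assert model.alpha.tolist() == pytest.approx([0.8, 0.3, 0.1])
    assert model.n_sites_dist.tolist() == [0.0, 0.0, 1.0]


def test_conversion_sites_require_coverage_and_frequency():
    # 4 covering reads (below 5) and a 2% site are both ignored
    cl = _cluster({110: [4, 4], 120: [100, 2]})
    with pytest.raises(em.EstimationError):
        em.estimate_conversion_model([cl])


def test_alpha_recovery_from_simulated_clusters(no_indel_position_models):
    """Simulate ~500 well-separated binding clusters from known alpha,
    rebuild a perfect alignment from truth, and re-estimate alpha within
    +-0.05."""
    from paraclip.simulator import (SimulatorConfig, default_background_profile,
                                    default_conversion_model, simulate_dataset,
                                    synthetic_transcripts)
    from paraclip.clustering import stack_reads, filter_high_confidence
    transcripts = synthetic_transcripts(300, (700, 1100), seed=29)
    cfg = SimulatorConfig(lam=1.0, n_reads=8000, seed=23)
    res = simulate_dataset(cfg, transcripts,
                           default_background_profile(),
                           default_conversion_model(),
                           no_indel_position_models)
    tdb = dict(transcripts)
    recs = []
    for sr in res.sim_reads:
        ref_sub = tdb[sr.transcript][sr.start:sr.start + len(sr.sequence)]
        recs.append(make_sam(sr.name, sr.transcript, sr.start + 1, ref_sub, sr.sequence))
    kept, _ = filter_high_confidence(stack_reads(recs))
    model = em.estimate_conversion_model(kept)
    assert model.alpha[0] == pytest.approx(0.70, abs=0.05)


# ---------------------------------------------------------------------------
# position models
# ---------------------------------------------------------------------------

def test_error_free_input_gives_zero_mu():
    ref = "ACGT" * 10
    recs = [make_sam(f"r{i}", "chr", 1, ref, ref) for i in range(5)]
    posm = em.estimate_position_models(recs)
    assert np.all(posm.mu == 0)


def test_constant_quality_gives_point_mass_delta():
    ref = "ACGT" * 5
    recs = [make_sam(f"r{i}", "chr", 1, ref, ref, qual=30) for i in range(4)]
    posm = em.estimate_position_models(recs)
    assert np.all(posm.delta[:, 30] == 1.0)


def test_mu_hand_count_for_planted_insertions():
    # insertions only at read offset 5 in 2% of reads
    ref_plain = "ACGTT" + "ACGTACGTACGTACGTACGT"
    ref_ins = "ACGTT" + "ACGTACGTACGTACGTACG"   # 24 ref bases for 25-base read
    recs = []
    for i in range(100):
        if i < 2:
            read = ref_ins[:5] + "A" + ref_ins[5:]
            recs.append(make_sam(f"r{i}", "chr", 1, ref_ins, read, cigar="5M1I19M"))
        else:
            recs.append(make_sam(f"r{i}", "chr", 1, ref_plain, ref_plain))
    posm = em.estimate_position_models(recs)
    assert posm.mu[5] == pytest.approx(0.02)
    mask = np.ones_like(posm.mu, dtype=bool)
    mask[5] = False
    assert np.all(posm.mu[mask] == 0)


# ---------------------------------------------------------------------------
# profile document
# ---------------------------------------------------------------------------

def test_profile_json_roundtrip(tmp_path, default_profiles):
    from paraclip.simulator import parclip_error_profile
    bg, conv, posm = default_profiles
    p = tmp_path / "profile.json"
    em.save_profiles(p, error=parclip_error_profile(), background=bg,
                     conversion=conv, position=posm)
    doc = em.load_profiles(p)
    assert np.allclose(doc["error"].M, parclip_error_profile().M)
    assert np.allclose(doc["background"].epsilon, bg.epsilon)
    assert np.allclose(doc["conversion"].alpha, conv.alpha)
    assert np.allclose(doc["position"].mu, posm.mu)
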