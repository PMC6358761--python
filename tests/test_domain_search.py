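"""Profile construction, local alignment (against a brute-force oracle),
Gumbel calibration, and the two-pass search logic."""

import itertools
import math

import numpy as np
import pytest

from trihelix import domain_search as ds
from trihelix import synthetic_data as sd
from trihelix.errors import PipelineError, ValidationError

AA = ds.AMINO_ACIDS


# ---------------------------------------------------------------------------
# build_profile
# ---------------------------------------------------------------------------


def test_identical_sequences_argmax_is_the_residue():
    profile = ds.build_profile(["ACD", "ACD"], pseudocount_weight=1e-9)
    assert profile.consensus == "ACD"


def test_background_frequency_column_has_zero_log_odds():
    # a column holding each residue exactly once matches the uniform background
    seqs = [AA[i] for i in range(20)]
    profile = ds.build_profile(seqs, pseudocount_weight=1.0)
    assert np.allclose(profile.match_emissions, 0.0, atol=1e-12)


def test_three_sequence_toy_matches_hand_computed_log_odds():
    # alignment columns: [A,A,A] and [C,C,T]; uniform bg 0.05, pseudocount 1
    profile = ds.build_profile(["AC", "AC", "AT"], pseudocount_weight=1.0)
    a = ds.AA_INDEX["A"]
    c = ds.AA_INDEX["C"]
    t = ds.AA_INDEX["T"]
    g = ds.AA_INDEX["G"]
    assert profile.match_emissions[0, a] == pytest.approx(math.log2(15.25), abs=1e-9)
    assert profile.match_emissions[1, c] == pytest.approx(math.log2(10.25), abs=1e-9)
    assert profile.match_emissions[1, t] == pytest.approx(math.log2(5.25), abs=1e-9)
    assert profile.match_emissions[1, g] == pytest.approx(-2.0, abs=1e-9)


def test_gappy_columns_are_dropped():
    profile = ds.build_profile(["A-C", "A-C", "AGC", "A-C"])
    assert profile.length == 2


@pytest.mark.parametrize("bad", [[], ["A"], ["AC", "A"]])
def test_invalid_alignments_rejected(bad):
    with pytest.raises(ValidationError):
        ds.build_profile(bad)


# ---------------------------------------------------------------------------
# score_local vs exhaustive enumeration
# ---------------------------------------------------------------------------


def _oracle_best_local(profile: ds.ProfileModel, seq: str) -> float:
    """Enumerate every local alignment (starting and ending on a match state)
    and return the best affine-gap score; 0 if none is positive."""
    m = profile.length
    L = len(seq)
    em = profile.match_emissions
    go, ge = profile.gap_open, profile.gap_extend

    def extend(i, j, prev_op, score, best):
        # i: next model index (0-based), j: next seq index
        best = max(best, score) if prev_op == "M" else best
        if i < m and j < L:
            s = em[i, ds.AA_INDEX[seq[j]]]
            best = extend(i + 1, j + 1, "M", score + s, best)
        if prev_op is not None:  # gaps only inside an alignment
            if i < m:
                pen = ge if prev_op == "D" else go
                best = extend(i + 1, j, "D", score - pen, best)
            if j < L:
                pen = ge if prev_op == "I" else go
                best = extend(i, j + 1, "I", score - pen, best)
        return best

    best = 0.0
    for i0 in range(m):
        for j0 in range(L):
            best = extend(i0, j0, None, 0.0, best)
    return best


def test_score_local_matches_bruteforce_enumeration(rng):
    letters = "ACDE"
    for trial in range(30):
        m = int(rng.integers(1, 5))
        L = int(rng.integers(1, 7))
        aligned = ["".join(rng.choice(list(letters), size=m)) for _ in range(3)]
        profile = ds.build_profile(aligned, pseudocount_weight=0.5)
        seq = "".join(rng.choice(list(letters), size=L))
        expected = _oracle_best_local(profile, seq)
        hit = ds.score_local(profile, seq)
        got = 0.0 if hit is None else hit.score
        assert got == pytest.approx(expected, abs=1e-9), (aligned, seq)


def test_consensus_sequence_scores_sum_of_max_and_full_coverage(seed_profile):
    hit = ds.score_local(seed_profile, seed_profile.consensus)
    assert hit.score == pytest.approx(seed_profile.match_emissions.max(axis=1).sum())
    assert hit.model_coverage == 1.0
    assert (hit.seq_start, hit.seq_end) == (1, seed_profile.length)


def test_no_positive_scoring_residue_gives_no_hit():
    # profile strongly prefers W; a sequence of A scores negative everywhere
    profile = ds.build_profile(["WWW", "WWW"], pseudocount_weight=0.1)
    assert ds.score_local(profile, "AAAA") is None


def test_batch_scores_equal_single_scores(seed_profile, rng):
    seqs = ["".join(rng.choice(list(AA), size=int(rng.integers(30, 80)))) for _ in range(10)]
    batch = ds.batch_local_scores(seed_profile, seqs)
    for seq, expected in zip(seqs, batch):
        hit = ds.score_local(seed_profile, seq)
        got = 0.0 if hit is None else hit.score
        assert got == pytest.approx(float(expected), abs=1e-6)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


def test_evalue_at_mu_is_gumbel_location_value(calibrated_profile):
    mu, _ = calibrated_profile.calibration
    assert ds.evalue(calibrated_profile, mu, db_size=1) == pytest.approx(
        1 - math.exp(-1), abs=1e-9
    )


def test_gumbel_fit_location_equivariance(rng):
    scores = rng.gumbel(10.0, 2.0, size=2000)
    mu1, lam1 = ds.fit_gumbel(scores)
    mu2, lam2 = ds.fit_gumbel(scores + 7.0)
    assert mu2 - mu1 == pytest.approx(7.0, abs=1e-6)
    assert lam2 == pytest.approx(lam1, rel=1e-6)


def test_evalue_monotone_decreasing_in_score(calibrated_profile):
    scores = np.linspace(0, 60, 50)
    evals = [ds.evalue(calibrated_profile, s, db_size=100) for s in scores]
    assert all(a >= b for a, b in zip(evals, evals[1:]))


def test_empirical_tail_within_factor_two_of_fit(seed_profile):
    rng = np.random.default_rng(1)
    letters = np.array(list(AA))
    decoys = ["".join(rng.choice(letters, size=300, p=seed_profile.background))
              for _ in range(1000)]
    scores = ds.batch_local_scores(seed_profile, decoys)
    mu, lam = ds.fit_gumbel(scores)
    q95 = np.quantile(scores, 0.95)
    fitted_tail = -np.expm1(-np.exp(-lam * (q95 - mu)))
    empirical_tail = float((scores >= q95).mean())
    assert fitted_tail / 2 <= empirical_tail <= fitted_tail * 2


def test_degenerate_scores_raise():
    with pytest.raises(ValidationError, match="decoy"):
        ds.fit_gumbel(np.full(500, 3.0))


# ---------------------------------------------------------------------------
# two-pass identification
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def two_pass_result(seed_profile):
    spec = sd.FamilyGenomeSpec(n_family=20, n_decoy=80, rng_seed=7)
    proteome, truth = sd.generate_proteome(spec, seed_profile=seed_profile)
    config = ds.SearchConfig(n_calibration_shuffles=300, rng_seed=3)
    hits, species_profile = ds.two_pass_identify(seed_profile, proteome, config)
    return proteome, truth, config, hits, species_profile


def test_two_pass_recovers_family_without_decoys(two_pass_result):
    _, truth, _, hits, _ = two_pass_result
    found = {h.sequence_id for h in hits}
    family = set(truth[truth.is_family].index)
    assert len(found & family) >= 19
    assert not found - family


def test_final_hits_respect_threshold_and_coverage(two_pass_result):
    proteome, _, config, hits, species_profile = two_pass_result
    assert hits, "expected some hits"
    for h in hits:
        assert h.e_value < config.e_threshold
        assert h.model_coverage >= config.min_model_coverage
    # sequences with e-value at/above threshold are excluded: recompute from
    # the species profile and compare the kept set
    scores = ds.batch_local_scores(species_profile, list(proteome.values()))
    expected_pass = {
        name
        for name, score in zip(proteome, scores)
        if score > 0 and ds.evalue(species_profile, score, len(proteome)) < config.e_threshold
    }
    assert {h.sequence_id for h in hits} <= expected_pass


def test_threshold_monotonicity(two_pass_result):
    proteome, _, _, _, species_profile = two_pass_result
    loose = ds._scan(species_profile, proteome, 0.01, len(proteome))
    tight = ds._scan(species_profile, proteome, 0.001, len(proteome))
    assert {h.sequence_id for h in tight} <= {h.sequence_id for h in loose}


def test_pass_two_rescan_is_idempotent(two_pass_result):
    proteome, _, config, hits, species_profile = two_pass_result
    rescan = ds._scan(species_profile, proteome, config.e_threshold, len(proteome))
    rescan_ids = {
        h.sequence_id for h in rescan if h.model_coverage >= config.min_model_coverage
    }
    assert {h.sequence_id for h in hits} == rescan_ids


def test_seed_domain_sequences_fully_retained(seed_alignment, seed_profile):
    config = ds.SearchConfig(n_calibration_shuffles=200, rng_seed=0)
    hits, _ = ds.two_pass_identify(seed_profile, dict(seed_alignment), config)
    assert {h.sequence_id for h in hits} == set(seed_alignment)
    assert all(h.model_coverage == 1.0 for h in hits)


def test_zero_candidates_is_a_pipeline_error():
    # every proteome residue scores negatively against a W-only profile, so
    # pass one cannot produce a single local alignment above the floor
    profile = ds.build_profile(["WWWWW", "WWWWW"], pseudocount_weight=0.1)
    proteome = {"x": "AAAA", "y": "CCCC"}
    with pytest.raises(PipelineError, match="no candidates"):
        ds.two_pass_identify(
            profile, proteome, ds.SearchConfig(n_calibration_shuffles=200)
        )


def test_profile_roundtrip_through_text_format(tmp_path, calibrated_profile):
    path = tmp_path / "profile.txt"
    ds.save_profile(calibrated_profile, path)
    loaded = ds.load_profile(path)
    assert np.allclose(loaded.match_emissions, calibrated_profile.match_emissions)
    assert np.allclose(loaded.background, calibrated_profile.background)
    assert loaded.calibration == pytest.approx(calibrated_profile.calibration)
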