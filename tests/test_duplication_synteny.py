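"""Tandem clustering (vs all-pairs brute force), collinear chaining (vs
exhaustive longest-chain search), anchor discovery, and NG86 Ka/Ks (vs an
independent enumeration oracle and a frozen hand tally)."""

import itertools
import math

import numpy as np
import pytest
from Bio.Seq import Seq

from trihelix import duplication_synteny as dup
from trihelix import synthetic_data as sd
from trihelix.errors import ValidationError


# ---------------------------------------------------------------------------
# tandem events
# ---------------------------------------------------------------------------


def _bruteforce_tandem(loci, window):
    """All-pairs O(n^2): connected components of the within-window graph per
    chromosome, then adjacent pairs within each component sorted by start."""
    events = set()
    by_chrom = {}
    for locus in loci:
        by_chrom.setdefault(locus.chromosome, []).append(locus)
    for genes in by_chrom.values():
        parent = {g.gene_id: g.gene_id for g in genes}

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        for a, b in itertools.combinations(genes, 2):
            if abs(a.start - b.start) <= window:
                parent[find(a.gene_id)] = find(b.gene_id)
        comps = {}
        for g in genes:
            comps.setdefault(find(g.gene_id), []).append(g)
        for comp in comps.values():
            comp.sort(key=lambda g: (g.start, g.gene_id))
            for a, b in zip(comp, comp[1:]):
                events.add((a.gene_id, b.gene_id))
    return events


def test_two_genes_within_window_are_tandem():
    loci = [dup.GeneLocus("a", "Chr1", 100_000), dup.GeneLocus("b", "Chr1", 250_000)]
    events = dup.find_tandem_events(loci, window=200_000)
    assert [(e.gene_a, e.gene_b, e.kind) for e in events] == [("a", "b", "tandem")]


def test_genes_beyond_window_are_not_tandem():
    loci = [dup.GeneLocus("a", "Chr1", 100_000), dup.GeneLocus("b", "Chr1", 350_001)]
    assert dup.find_tandem_events(loci, window=200_000) == []


def test_tandem_matches_bruteforce_over_random_layouts():
    rng = np.random.default_rng(42)
    for _ in range(100):
        n = int(rng.integers(2, 15))
        loci = [
            dup.GeneLocus(
                f"g{k}", f"Chr{int(rng.integers(1, 4))}", int(rng.integers(0, 2_000_000))
            )
            for k in range(n)
        ]
        window = int(rng.integers(50_000, 400_000))
        got = {(e.gene_a, e.gene_b) for e in dup.find_tandem_events(loci, window)}
        assert got == _bruteforce_tandem(loci, window)


# ---------------------------------------------------------------------------
# anchors
# ---------------------------------------------------------------------------


def _toy_loci(ids, chrom="Chr1"):
    return {g: dup.GeneLocus(g, chrom, 1000 * (i + 1)) for i, g in enumerate(ids)}


def test_identical_proteome_anchors_on_duplicates(rng):
    letters = list("ACDEFGHIKLMNPQRSTVWY")
    base = {f"g{k}": "".join(rng.choice(letters, size=150)) for k in range(4)}
    dup_prot = {**base, **{f"g{k}_d": base[f"g{k}"] for k in range(4)}}
    loci = _toy_loci(sorted(dup_prot))
    anchors = dup.find_anchor_pairs(dup_prot, dup_prot, loci, top_k=1)
    pairs = {frozenset((a.gene_a, a.gene_b)) for a in anchors}
    assert pairs == {frozenset((f"g{k}", f"g{k}_d")) for k in range(4)}


def test_unrelated_random_proteins_score_below_threshold(rng):
    letters = list("ACDEFGHIKLMNPQRSTVWY")
    aligner = dup._blastp_like_aligner()
    scores = []
    for _ in range(50):
        a = "".join(rng.choice(letters, size=100))
        b = "".join(rng.choice(letters, size=100))
        scores.append(aligner.score(a, b))
    assert np.median(scores) < 60.0


def test_handworked_alignment_score():
    # identical 8-mer, no gaps: score is the sum of BLOSUM62 diagonal entries
    # for MKWVTFIS = 5+5+11+4+5+6+4+4 = 44
    prot = {"a": "MKWVTFIS", "b": "MKWVTFIS"}
    anchors = dup.find_anchor_pairs(prot, prot, _toy_loci(["a", "b"]), score_threshold=1.0)
    assert len(anchors) == 1
    assert anchors[0].score == pytest.approx(44.0)


# ---------------------------------------------------------------------------
# collinear chaining
# ---------------------------------------------------------------------------


def _anchor(a, b, ra, rb, ca="Chr1", cb="Chr2", score=10.0):
    return dup.AnchorPair(a, b, score, ca, cb, ra, rb)


def _exhaustive_best_chain(anchors, max_gap):
    """Longest (count, then score) strictly-monotone chain over all subsets."""
    best = (0, 0.0)
    n = len(anchors)
    for mask in range(1, 1 << n):
        subset = [anchors[i] for i in range(n) if mask >> i & 1]
        subset.sort(key=lambda x: (x.rank_a, x.rank_b))
        for sign in (1, -1):
            ok = True
            for x, y in zip(subset, subset[1:]):
                da = y.rank_a - x.rank_a
                db = sign * (y.rank_b - x.rank_b)
                if da <= 0 or db <= 0 or da > max_gap or db > max_gap:
                    ok = False
                    break
            if ok:
                key = (len(subset), sum(a.score for a in subset))
                best = max(best, key)
    return best


def test_preserved_block_of_six_is_one_block():
    anchors = [_anchor(f"a{i}", f"b{i}", i, i) for i in range(6)]
    blocks = dup.chain_collinear_blocks(anchors, min_anchors=5, max_gap=25)
    assert len(blocks) == 1
    assert len(blocks[0].anchors) == 6
    assert blocks[0].orientation == "same"


def test_scrambled_anchors_make_no_block():
    ranks_b = [3, 0, 5, 1, 4, 2]  # longest monotone run < 5
    anchors = [_anchor(f"a{i}", f"b{i}", i, rb) for i, rb in enumerate(ranks_b)]
    assert dup.chain_collinear_blocks(anchors, min_anchors=5, max_gap=25) == []


def test_inverted_block_is_flagged():
    anchors = [_anchor(f"a{i}", f"b{i}", i, 9 - i) for i in range(6)]
    blocks = dup.chain_collinear_blocks(anchors, min_anchors=5, max_gap=25)
    assert len(blocks) == 1
    assert blocks[0].orientation == "inverted"


def test_chaining_matches_exhaustive_search():
    rng = np.random.default_rng(9)
    for _ in range(30):
        n = int(rng.integers(3, 12))
        anchors = [
            _anchor(
                f"a{i}", f"b{i}", int(rng.integers(0, 15)) , int(rng.integers(0, 15)),
                score=float(rng.integers(1, 20)),
            )
            for i in range(n)
        ]
        # deduplicate equal rank_a (strict monotonicity needs distinct ranks)
        seen = set()
        anchors = [
            a for a in anchors
            if (a.rank_a, a.rank_b) not in seen and not seen.add((a.rank_a, a.rank_b))
        ]
        max_gap = int(rng.integers(1, 6))
        blocks = dup.chain_collinear_blocks(anchors, min_anchors=1, max_gap=max_gap)
        got = max(
            ((len(b.anchors), sum(a.score for a in b.anchors)) for b in blocks),
            default=(0, 0.0),
        )
        assert got == _exhaustive_best_chain(anchors, max_gap)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def test_tandem_takes_precedence_over_block_membership():
    anchors = [_anchor(f"a{i}", f"b{i}", i, i, ca="Chr1", cb="Chr1") for i in range(5)]
    blocks = dup.chain_collinear_blocks(anchors, min_anchors=5, max_gap=25)
    tandem = [dup.DuplicationEvent("a0", "b0", "tandem", "span=1000bp")]
    events = dup.classify_family_duplications(blocks, tandem, {"a0", "b0"})
    assert len(events) == 1
    assert events[0].kind == "tandem"


def test_unrelated_family_pair_stays_unclassified():
    events = dup.classify_family_duplications([], [], {"x", "y"})
    assert events == []


def test_synthetic_genome_duplications_recovered_exactly():
    spec = sd.FamilyGenomeSpec(
        n_family=14,
        n_decoy=100,
        n_chromosomes=4,
        tandem_clusters=((0, 2, 150_000), (1, 2, 150_000)),
        segmental_blocks=((8, 0.05),),
        rng_seed=0,
    )
    genome = sd.generate_duplicated_genome(spec)
    proteins = {g.gene_id: str(Seq(g.cds).translate()).rstrip("*") for g in genome.genes}
    loci = {
        g.gene_id: dup.GeneLocus(g.gene_id, g.chromosome, g.exons[0][0], g.exons[-1][1])
        for g in genome.genes
    }
    family_ids = set(genome.truth[genome.truth.is_family].index)
    anchors = dup.find_anchor_pairs(proteins, proteins, loci)
    blocks = dup.chain_collinear_blocks(anchors, min_anchors=5, max_gap=3)
    tandem = dup.find_tandem_events([loci[i] for i in sorted(family_ids)])
    events = dup.classify_family_duplications(blocks, tandem, family_ids)
    got = {frozenset((e.gene_a, e.gene_b)): e.kind for e in events}

    truth = genome.truth
    expected_tandem = set()
    for cid in truth.tandem_cluster_id.dropna().unique():
        members = truth[truth.tandem_cluster_id == cid].sort_values("start").index
        expected_tandem |= {frozenset(p) for p in zip(members, members[1:])}
    expected_segmental = {
        frozenset((gid, row.segmental_source))
        for gid, row in truth[truth.segmental_source.notna()].iterrows()
        if row.is_family
    }
    assert set(got) == expected_tandem | expected_segmental
    assert all(got[p] == "tandem" for p in expected_tandem)
    assert all(got[p] == "segmental" for p in expected_segmental)


# ---------------------------------------------------------------------------
# NG86 Ka/Ks
# ---------------------------------------------------------------------------


def test_identical_cds_has_undefined_ratio():
    result = dup.kaks_ng86("ATGGCT", "ATGGCT")
    assert result.ka == 0 and result.ks == 0
    assert result.ratio is None


def test_synonymous_third_position_change():
    result = dup.kaks_ng86("TTT", "TTC")
    assert result.syn_diffs == pytest.approx(1.0)
    assert result.nonsyn_diffs == pytest.approx(0.0)


def test_handtallied_toy_pair():
    # codons TTT TTT GGG GGG AAA vs TTC TTT GGG GGG AGA:
    # one synonymous third-position change (TTT->TTC) and one nonsynonymous
    # (AAA Lys -> AGA Arg); site counts tallied by hand give S = 19/6
    a = "TTTTTTGGGGGGAAA"
    b = "TTCTTTGGGGGGAGA"
    result = dup.kaks_ng86(a, b)
    assert result.syn_sites == pytest.approx(19 / 6, abs=1e-9)
    assert result.nonsyn_sites == pytest.approx(15 - 19 / 6, abs=1e-9)
    assert result.syn_diffs == pytest.approx(1.0)
    assert result.nonsyn_diffs == pytest.approx(1.0)
    assert result.ks == pytest.approx(0.40990, abs=1e-4)
    assert result.ka == pytest.approx(0.08967, abs=1e-4)
    assert result.ratio == pytest.approx(0.08967 / 0.40990, abs=1e-3)


def test_kaks_is_symmetric(rng):
    a = sd.random_cds(40, rng)
    b = sd._mutate_cds(a, 0.1, rng)
    r1 = dup.kaks_ng86(a, b)
    r2 = dup.kaks_ng86(b, a)
    assert r1.ka == pytest.approx(r2.ka)
    assert r1.ks == pytest.approx(r2.ks)


def test_kaks_input_validation():
    with pytest.raises(ValidationError):
        dup.kaks_ng86("ATG", "ATGGCT")
    with pytest.raises(ValidationError, match="stop"):
        dup.kaks_ng86("TAAGCT", "TAAGCT")


def test_purifying_selection_recovered_from_simulations():
    below = defined = 0
    for seed in range(200):
        a, b, _ = sd.evolve_codon_pair(300, omega=0.2, branch_length=0.3, rng_seed=seed)
        result = dup.kaks_ng86(a, b)
        if result.ratio is not None:
            defined += 1
            below += result.ratio < 1
    assert defined >= 190
    assert below / defined >= 0.95


def test_codon_alignment_backthreads_frames(rng):
    a = sd.random_cds(50, rng) + "TAA"
    b = sd._mutate_cds(a, 0.05, rng)
    aligned_a, aligned_b = dup.align_codon_pair(a, b)
    assert len(aligned_a) == len(aligned_b)
    assert len(aligned_a) % 3 == 0
    result = dup.kaks_ng86(aligned_a, aligned_b)
    assert result.ka >= 0 and result.ks >= 0
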