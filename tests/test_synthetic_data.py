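"""Generator ground-truth consistency: every truth label must be verifiable
by direct inspection of the generated artifact."""

import numpy as np
import pandas as pd
import pytest
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from trihelix import domain_search as ds
from trihelix import motifs_elements as me
from trihelix import synthetic_data as sd
from trihelix.errors import ValidationError


# ---------------------------------------------------------------------------
# spec validation and serialization
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "kwargs,field",
    [
        ({"n_family": -1}, "n_family"),
        ({"tandem_clusters": ((0, 2, 0),)}, "max-span"),
        ({"tandem_clusters": ((0, 1, 5000),)}, "gene-count"),
        ({"segmental_blocks": ((3, 1.5),)}, "divergence"),
        ({"promoter_implants": {"GATABOX": 1.5}}, "fraction"),
    ],
)
def test_invalid_spec_names_the_field(kwargs, field):
    with pytest.raises(ValidationError, match=field):
        sd.FamilyGenomeSpec(**kwargs)


def test_spec_yaml_roundtrip():
    spec = sd.FamilyGenomeSpec(
        n_family=5,
        tandem_clusters=((0, 2, 100_000),),
        segmental_blocks=((4, 0.1),),
        promoter_implants={"GATABOX": 0.5},
        rng_seed=9,
    )
    assert sd.spec_from_yaml(sd.spec_to_yaml(spec)) == spec


def test_unknown_spec_keys_rejected():
    with pytest.raises(ValidationError, match="unknown"):
        sd.spec_from_yaml("n_family: 3\nbogus_knob: 1\n")


# ---------------------------------------------------------------------------
# proteome
# ---------------------------------------------------------------------------


def test_empty_family_yields_only_decoys():
    proteome, truth = sd.generate_proteome(sd.FamilyGenomeSpec(n_family=0, n_decoy=5))
    assert len(proteome) == 5
    assert not truth.is_family.any()


def test_same_seed_is_byte_identical():
    spec = sd.FamilyGenomeSpec(n_family=6, n_decoy=6, rng_seed=12)
    p1, t1 = sd.generate_proteome(spec)
    p2, t2 = sd.generate_proteome(spec)
    assert p1 == p2
    pd.testing.assert_frame_equal(t1, t2)


def test_consensus_mode_embeds_profile_consensus(seed_profile):
    spec = sd.FamilyGenomeSpec(n_family=20, n_decoy=0, rng_seed=2)
    proteome, truth = sd.generate_proteome(
        spec, seed_profile=seed_profile, domain_mode="consensus"
    )
    for gene, row in truth.iterrows():
        assert seed_profile.consensus in proteome[gene]
        start = int(row.domain_start)
        assert proteome[gene][start - 1: start - 1 + seed_profile.length] == seed_profile.consensus


def test_truth_domain_span_matches_sampled_domain(seed_profile):
    spec = sd.FamilyGenomeSpec(n_family=5, n_decoy=0, rng_seed=4)
    proteome, truth = sd.generate_proteome(spec, seed_profile=seed_profile)
    for gene, row in truth.iterrows():
        domain = proteome[gene][int(row.domain_start) - 1: int(row.domain_end)]
        hit = ds.score_local(seed_profile, domain)
        assert hit is not None and hit.model_coverage > 0.9


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def genome_bundle():
    spec = sd.FamilyGenomeSpec(
        n_family=8,
        n_decoy=20,
        n_chromosomes=3,
        tandem_clusters=((0, 2, 150_000),),
        segmental_blocks=((5, 0.05),),
        promoter_implants={"GATABOX": 1.0},
        rng_seed=21,
    )
    return spec, sd.generate_duplicated_genome(spec)


def test_every_gene_appears_once_in_truth(genome_bundle):
    _, genome = genome_bundle
    assert genome.truth.index.is_unique
    assert set(genome.truth.index) == {g.gene_id for g in genome.genes}


def test_cds_splices_back_from_genome(genome_bundle):
    _, genome = genome_bundle
    for gene in genome.genes:
        assert sd.extract_cds_from_genome(genome.chromosomes, gene) == gene.cds


def test_tandem_cluster_genes_lie_within_span(genome_bundle):
    _, genome = genome_bundle
    truth = genome.truth
    cluster = truth[truth.tandem_cluster_id == 0].sort_values("start")
    assert len(cluster) == 2
    assert cluster.chromosome.nunique() == 1
    assert cluster.start.iloc[1] - cluster.start.iloc[0] < 150_000


def test_segmental_block_preserves_rank_order(genome_bundle):
    _, genome = genome_bundle
    truth = genome.truth
    copies = truth[truth.segmental_source.notna()]
    assert len(copies) == 5
    sources = truth.loc[copies.segmental_source]
    # identical relative order on source and duplicate chromosomes
    assert (
        copies.sort_values("start").segmental_source.tolist()
        == sources.sort_values("start").index.tolist()
    )


def test_zero_divergence_copies_are_identical():
    spec = sd.FamilyGenomeSpec(
        n_family=4, n_decoy=10, n_chromosomes=2,
        segmental_blocks=((4, 0.0),), rng_seed=3,
    )
    genome = sd.generate_duplicated_genome(spec)
    cds = {g.gene_id: g.cds for g in genome.genes}
    for gene_id, row in genome.truth[genome.truth.segmental_source.notna()].iterrows():
        assert cds[gene_id] == cds[row.segmental_source]


def test_span_below_gene_footprint_is_an_error():
    spec = sd.FamilyGenomeSpec(
        n_family=2, n_decoy=0, tandem_clusters=((0, 2, 500),), rng_seed=0
    )
    with pytest.raises(ValidationError, match="footprint"):
        sd.generate_duplicated_genome(spec)


def test_implanted_elements_present_in_upstream_window(genome_bundle):
    _, genome = genome_bundle
    element = [e for e in me.load_element_library() if e.element_id == "GATABOX"][0]
    genes = {g.gene_id: g for g in genome.genes}
    for gene_id, row in genome.truth[genome.truth.is_family].iterrows():
        if "GATABOX" not in (row.implanted_elements or ""):
            continue
        [prom] = me.extract_promoters(genome.chromosomes, [genes[gene_id]], length=1500)
        assert me.iupac_scan(prom.sequence, element), gene_id


# ---------------------------------------------------------------------------
# codon pair evolution
# ---------------------------------------------------------------------------


def test_zero_branch_length_gives_identical_sequences():
    a, b, _ = sd.evolve_codon_pair(40, omega=0.5, branch_length=0.0, rng_seed=1)
    assert a == b


def test_near_zero_omega_fixes_only_synonymous_changes():
    a, b, _ = sd.evolve_codon_pair(100, omega=1e-9, branch_length=0.3, rng_seed=5)
    prot_a = Seq(a).translate()
    prot_b = Seq(b).translate()
    assert a != b
    assert str(prot_a) == str(prot_b)


def test_invalid_omega_rejected():
    with pytest.raises(ValidationError):
        sd.evolve_codon_pair(40, omega=0.0, branch_length=0.1)
    with pytest.raises(ValidationError):
        sd.evolve_codon_pair(10, omega=0.5, branch_length=0.1)


def test_no_internal_stops_generated():
    for seed in range(5):
        a, b, _ = sd.evolve_codon_pair(60, omega=0.8, branch_length=0.5, rng_seed=seed)
        for seq in (a, b):
            codons = [seq[i: i + 3] for i in range(0, len(seq), 3)]
            assert not set(codons) & set(standard_dna_table.stop_codons)


# ---------------------------------------------------------------------------
# promoters
# ---------------------------------------------------------------------------


def test_promoter_truth_positions_verified_by_scan():
    proms, truth = sd.generate_promoters(10, {"GT1CONSENSUS": 1.0}, rng_seed=6)
    element = [e for e in me.load_element_library() if e.element_id == "GT1CONSENSUS"][0]
    for row in truth.itertuples():
        hits = me.iupac_scan(proms[row.promoter_id], element)
        assert (row.position, row.strand) in {(m.start, m.strand) for m in hits}


def test_promoter_lengths_and_empty_case():
    proms, truth = sd.generate_promoters(3, {}, length=120, rng_seed=0)
    assert all(len(p) == 120 for p in proms.values())
    assert truth.empty
    proms0, truth0 = sd.generate_promoters(0, {"GATABOX": 1.0})
    assert proms0 == {} and truth0.empty


def test_element_longer_than_promoter_rejected():
    with pytest.raises(ValidationError, match="longer"):
        sd.generate_promoters(2, {"GATABOX": 1.0}, length=3)


# ---------------------------------------------------------------------------
# Ct tables
# ---------------------------------------------------------------------------


def test_ct_table_shape_and_validation():
    ct, truth = sd.generate_ct_table(
        ["a"], ["t1", "t2"], {("a", "t1"): 1.0}, replicates=3, rng_seed=0
    )
    assert len(ct) == 3 * 3  # baseline + two timepoints, 3 replicates
    assert set(truth.columns) == {"gene", "condition", "true_log2_fc"}
    with pytest.raises(ValidationError):
        sd.generate_ct_table(["a"], ["t1"], {}, replicates=1)
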