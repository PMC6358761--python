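"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the statistical structure the analysis assumes: a
proteome of domain-bearing family members (optionally split into diverged
subfamilies) among random decoys; a genome with tandem gene clusters and
segmentally duplicated blocks; codon-sequence pairs diverged under a known
dN/dS; promoters with implanted IUPAC elements; expression matrices with
group structure; and qPCR Ct tables with known fold changes.

Every operation is deterministic given its seed, and every truth label is
verifiable by direct inspection of the generated artifact (substring
presence, coordinates, spans).  Truth tables are pandas DataFrames indexed
by gene id.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio.Data.CodonTable import standard_dna_table

from trihelix import domain_search as _ds
from trihelix.errors import ValidationError
from trihelix.motifs_elements import (
    IUPAC_DNA,
    CisElement,
    load_element_library,
    reverse_complement,
)
from trihelix.phylogeny import SUBFAMILIES

DNA = "ACGT"
_STOPS = tuple(standard_dna_table.stop_codons)
_NON_STOP_CODONS = tuple(
    a + b + c
    for a in DNA
    for b in DNA
    for c in DNA
    if a + b + c not in _STOPS
)
_SYNONYMOUS: dict[str, tuple[str, ...]] = {}
for _codon in _NON_STOP_CODONS:
    _SYNONYMOUS.setdefault(standard_dna_table.forward_table[_codon], ())
    _SYNONYMOUS[standard_dna_table.forward_table[_codon]] += (_codon,)

_TRANSITIONS = {"A": "G", "G": "A", "C": "T", "T": "C"}


# ---------------------------------------------------------------------------
# specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FamilyGenomeSpec:
    """Parameters of one synthetic family/genome realization.

    ``tandem_clusters`` entries are ``(chromosome_index, gene_count,
    max_span_bp)``; ``segmental_blocks`` entries are ``(anchor_count,
    divergence)`` with divergence the per-nucleotide substitution
    probability of the duplicated copy.  ``promoter_implants`` maps element
    id (or raw IUPAC string) to the fraction of promoters carrying it.
    """

    n_family: int = 20
    n_decoy: int = 80
    n_chromosomes: int = 5
    tandem_clusters: tuple[tuple[int, int, int], ...] = ()
    segmental_blocks: tuple[tuple[int, float], ...] = ()
    promoter_implants: Mapping[str, float] = field(default_factory=dict)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_family", "n_decoy", "n_chromosomes"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for chrom, count, span in self.tandem_clusters:
            if span <= 0:
                raise ValidationError("tandem_clusters: max-span must be > 0")
            if count < 2:
                raise ValidationError("tandem_clusters: gene-count must be >= 2")
            if not (0 <= chrom < max(self.n_chromosomes, 1)):
                raise ValidationError("tandem_clusters: chromosome index out of range")
        for anchors, divergence in self.segmental_blocks:
            if anchors < 1:
                raise ValidationError("segmental_blocks: anchor-count must be >= 1")
            if not (0 <= divergence < 1):
                raise ValidationError("segmental_blocks: divergence must be in [0, 1)")
        for element, fraction in self.promoter_implants.items():
            if not (0 <= fraction <= 1):
                raise ValidationError(
                    f"promoter_implants[{element}]: fraction must be in [0, 1]"
                )


def spec_to_yaml(spec: FamilyGenomeSpec) -> str:
    data = asdict(spec)
    data["tandem_clusters"] = [list(t) for t in spec.tandem_clusters]
    data["segmental_blocks"] = [list(t) for t in spec.segmental_blocks]
    data["promoter_implants"] = dict(spec.promoter_implants)
    return yaml.safe_dump(data, sort_keys=True)


def spec_from_yaml(text: str) -> FamilyGenomeSpec:
    data = yaml.safe_load(_io.StringIO(text))
    known = set(FamilyGenomeSpec.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown spec keys: {sorted(unknown)}")
    data["tandem_clusters"] = tuple(tuple(t) for t in data.get("tandem_clusters", ()))
    data["segmental_blocks"] = tuple(tuple(t) for t in data.get("segmental_blocks", ()))
    return FamilyGenomeSpec(**data)


# ---------------------------------------------------------------------------
# seed domain alignment and proteome
# ---------------------------------------------------------------------------


def make_seed_alignment(
    n_seqs: int = 8, length: int = 48, rng_seed: int = 13, mutation_rate: float = 0.15
) -> dict[str, str]:
    """A small gapless alignment of diverged copies of a random consensus,
    standing in for a curated seed-domain alignment."""
    rng = np.random.default_rng(rng_seed)
    letters = np.array(list(_ds.AMINO_ACIDS))
    consensus = rng.choice(letters, size=length)
    seqs = {}
    for k in range(n_seqs):
        seq = consensus.copy()
        mask = rng.random(length) < mutation_rate
        seq[mask] = rng.choice(letters, size=int(mask.sum()))
        seqs[f"seed{k:02d}"] = "".join(seq)
    return seqs


def _mutate_protein(seq: str, fraction: float, rng: np.random.Generator) -> str:
    arr = np.array(list(seq))
    n_mut = int(round(fraction * len(arr)))
    if n_mut == 0:
        return seq
    pos = rng.choice(len(arr), size=n_mut, replace=False)
    arr[pos] = rng.choice(list(_ds.AMINO_ACIDS), size=n_mut)
    return "".join(arr)


def generate_proteome(
    spec: FamilyGenomeSpec,
    seed_profile: _ds.ProfileModel | None = None,
    domain_mode: str = "sample",
    n_subfamilies: int = 1,
    subfamily_divergence: float = 0.3,
    member_noise: float = 0.05,
    flank_length: tuple[int, int] = (60, 200),
) -> tuple[dict[str, str], pd.DataFrame]:
    """Proteome of family proteins (one embedded domain each) plus decoys.

    Family domains are the profile consensus (``domain_mode="consensus"``) or
    drawn from the profile's emission frequencies (``"sample"``), optionally
    diverged into ``n_subfamilies`` subfamily consensi first.  Decoys are
    i.i.d. background residues.  Deterministic given ``spec.rng_seed``.
    """
    if domain_mode not in ("sample", "consensus"):
        raise ValidationError("domain_mode must be 'sample' or 'consensus'")
    if not (1 <= n_subfamilies <= len(SUBFAMILIES)):
        raise ValidationError(f"n_subfamilies must be in [1, {len(SUBFAMILIES)}]")
    rng = np.random.default_rng(spec.rng_seed)
    if seed_profile is None:
        seed_profile = _ds.build_profile(make_seed_alignment())
    letters = np.array(list(_ds.AMINO_ACIDS))
    consensus = seed_profile.consensus
    emission_p = seed_profile.emission_probabilities()

    sub_consensi = [consensus]
    for _ in range(1, n_subfamilies):
        sub_consensi.append(_mutate_protein(consensus, subfamily_divergence, rng))

    proteome: dict[str, str] = {}
    rows = []
    for k in range(spec.n_family):
        sub = k % n_subfamilies
        if domain_mode == "consensus":
            domain = sub_consensi[sub]
        else:
            if sub == 0:
                domain = "".join(
                    letters[rng.choice(len(letters), p=emission_p[i])]
                    for i in range(seed_profile.length)
                )
            else:
                domain = _mutate_protein(sub_consensi[sub], member_noise, rng)
        left = int(rng.integers(flank_length[0], flank_length[1] + 1))
        right = int(rng.integers(flank_length[0], flank_length[1] + 1))
        protein = (
            "".join(rng.choice(letters, size=left))
            + domain
            + "".join(rng.choice(letters, size=right))
        )
        name = f"fam{k + 1:03d}"
        proteome[name] = protein
        rows.append(
            {
                "gene_id": name,
                "is_family": True,
                "subfamily": SUBFAMILIES[sub],
                "domain_start": left + 1,
                "domain_end": left + len(domain),
            }
        )
    for k in range(spec.n_decoy):
        length = int(rng.integers(150, 450))
        name = f"dec{k + 1:03d}"
        proteome[name] = "".join(rng.choice(letters, size=length))
        rows.append(
            {
                "gene_id": name,
                "is_family": False,
                "subfamily": None,
                "domain_start": None,
                "domain_end": None,
            }
        )
    truth = pd.DataFrame(rows).set_index("gene_id")
    return proteome, truth


def generate_subfamily_alignment(
    n_per_subfamily: int = 6,
    n_subfamilies: int = 5,
    length: int = 60,
    member_noise: float = 0.05,
    markers_per_subfamily: int = 2,
    rng_seed: int = 0,
) -> tuple[dict[str, str], dict[str, str], pd.Series]:
    """Gapless protein alignment drawn from divergent subfamily consensi.

    Each subfamily has an independent random consensus; members carry
    i.i.d. substitutions at rate ``member_noise``.  The first
    ``markers_per_subfamily`` members of each subfamily are designated
    markers.  Returns (alignment, marker map, true labels).
    """
    if n_subfamilies > len(SUBFAMILIES):
        raise ValidationError(f"n_subfamilies must be <= {len(SUBFAMILIES)}")
    if markers_per_subfamily >= n_per_subfamily:
        raise ValidationError("need at least one non-marker member per subfamily")
    rng = np.random.default_rng(rng_seed)
    letters = np.array(list(_ds.AMINO_ACIDS))
    alignment: dict[str, str] = {}
    markers: dict[str, str] = {}
    labels = {}
    for s in range(n_subfamilies):
        consensus = rng.choice(letters, size=length)
        for k in range(n_per_subfamily):
            seq = consensus.copy()
            mask = rng.random(length) < member_noise
            seq[mask] = rng.choice(letters, size=int(mask.sum()))
            name = f"{SUBFAMILIES[s]}_m{k:02d}" if k < markers_per_subfamily else f"sub{s}_g{k:02d}"
            alignment[name] = "".join(seq)
            labels[name] = SUBFAMILIES[s]
            if k < markers_per_subfamily:
                markers[name] = SUBFAMILIES[s]
    return alignment, markers, pd.Series(labels, name="true_subfamily")


# ---------------------------------------------------------------------------
# codon sequences
# ---------------------------------------------------------------------------


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """CDS for a protein with codons drawn uniformly among synonymous
    codons, terminated by a random stop codon."""
    codons = []
    for aa in protein:
        if aa not in _SYNONYMOUS:
            raise ValidationError(f"cannot reverse-translate residue {aa!r}")
        options = _SYNONYMOUS[aa]
        codons.append(options[rng.integers(len(options))])
    codons.append(_STOPS[rng.integers(len(_STOPS))])
    return "".join(codons)


def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """Random in-frame CDS of ``n_codons`` sense codons (no stop appended)."""
    return "".join(
        _NON_STOP_CODONS[rng.integers(len(_NON_STOP_CODONS))] for _ in range(n_codons)
    )


def _mutate_cds(
    cds: str, divergence: float, rng: np.random.Generator, omega: float = 1.0
) -> str:
    """Per-nucleotide substitution with probability ``divergence``; changes
    creating stop codons are skipped and nonsynonymous changes are accepted
    with relative probability ``omega`` (1 = neutral).  A terminal stop
    codon is preserved."""
    arr = list(cds)
    limit = len(arr)
    if len(cds) % 3 == 0 and cds[-3:] in _STOPS:
        limit -= 3
    for i in range(limit):
        if rng.random() >= divergence:
            continue
        old = arr[i]
        new = DNA[rng.integers(4)]
        while new == old:
            new = DNA[rng.integers(4)]
        codon_start = 3 * (i // 3)
        codon_old = "".join(arr[codon_start: codon_start + 3])
        arr[i] = new
        codon_new = "".join(arr[codon_start: codon_start + 3])
        if codon_new in _STOPS:
            arr[i] = old
            continue
        if omega < 1.0 and codon_old not in _STOPS:
            synonymous = (
                standard_dna_table.forward_table[codon_old]
                == standard_dna_table.forward_table[codon_new]
            )
            if not synonymous and rng.random() >= omega:
                arr[i] = old
    return "".join(arr)


def evolve_codon_pair(
    n_codons: int,
    omega: float,
    kappa: float = 2.0,
    branch_length: float = 0.2,
    rng_seed: int = 0,
) -> tuple[str, str, float]:
    """Two CDS descended from a random ancestor under a codon model in which
    nonsynonymous changes fix with relative probability ``omega``.

    ``branch_length`` is the expected number of accepted substitutions per
    codon separating the two sequences (split evenly between lineages);
    ``kappa`` biases proposals toward transitions.  Stop codons are never
    created.  Returns ``(cds_a, cds_b, omega)``.
    """
    if n_codons < 30:
        raise ValidationError("n_codons must be >= 30")
    if omega <= 0:
        raise ValidationError("omega must be > 0")
    if branch_length < 0:
        raise ValidationError("branch_length must be >= 0")
    rng = np.random.default_rng(rng_seed)
    ancestor = random_cds(n_codons, rng)

    def evolve(seq: str, n_target: int) -> str:
        arr = list(seq)
        accepted = 0
        attempts = 0
        max_attempts = 1000 * max(n_target, 1) + 10000
        while accepted < n_target and attempts < max_attempts:
            attempts += 1
            i = int(rng.integers(len(arr)))
            old = arr[i]
            others = [b for b in DNA if b != old]
            weights = np.array([kappa if b == _TRANSITIONS[old] else 1.0 for b in others])
            new = others[rng.choice(3, p=weights / weights.sum())]
            codon_start = 3 * (i // 3)
            codon_old = "".join(arr[codon_start: codon_start + 3])
            codon_new = codon_old[: i - codon_start] + new + codon_old[i - codon_start + 1:]
            if codon_new in _STOPS:
                continue
            synonymous = (
                standard_dna_table.forward_table[codon_old]
                == standard_dna_table.forward_table[codon_new]
            )
            if synonymous or rng.random() < omega:
                arr[i] = new
                accepted += 1
        return "".join(arr)

    per_lineage = branch_length / 2.0 * n_codons
    n_a = int(rng.poisson(per_lineage)) if per_lineage > 0 else 0
    n_b = int(rng.poisson(per_lineage)) if per_lineage > 0 else 0
    return evolve(ancestor, n_a), evolve(ancestor, n_b), omega


# ---------------------------------------------------------------------------
# genome with tandem and segmental duplications
# ---------------------------------------------------------------------------

_MIN_GENE_FOOTPRINT = 2000  # upper bound on a generated gene's genomic span


@dataclass(frozen=True)
class SyntheticGenome:
    """Generated genome bundle: chromosome sequences, gene models (with
    genomic coordinates), GFF3 feature tuples, and the truth table."""

    chromosomes: dict[str, str]
    genes: list
    gff_features: list[tuple]
    truth: pd.DataFrame


def generate_duplicated_genome(
    spec: FamilyGenomeSpec,
    seed_profile: _ds.ProfileModel | None = None,
    duplicate_omega: float = 0.2,
    promoter_length: int = 1500,
) -> SyntheticGenome:
    """Genome with family genes arranged in tandem clusters and segmental
    blocks, plus decoy genes, with 1-based strand-aware GFF3 annotation.

    Tandem clusters place their genes consecutively with start-coordinate
    gaps below the stated span.  Each segmental block copies an ordered run
    of genes (family anchors interleaved with decoys) onto the last
    chromosome with the stated per-nucleotide divergence.  Duplicate copies
    diverge under purifying selection (nonsynonymous changes accepted with
    probability ``duplicate_omega``), and ``spec.promoter_implants``
    elements are written into the upstream ``promoter_length`` window of
    family genes.
    """
    rng = np.random.default_rng(spec.rng_seed)
    if seed_profile is None:
        seed_profile = _ds.build_profile(make_seed_alignment())
    consensus = seed_profile.consensus
    letters = np.array(list(_ds.AMINO_ACIDS))
    n_chrom = max(spec.n_chromosomes, 1)

    n_tandem = sum(count for _, count, _ in spec.tandem_clusters)
    if spec.n_family < n_tandem:
        raise ValidationError("n_family smaller than total tandem cluster genes")
    for _, count, span in spec.tandem_clusters:
        if span < _MIN_GENE_FOOTPRINT:
            raise ValidationError(
                f"tandem span {span} smaller than minimal gene footprint"
            )

    def family_protein() -> str:
        # each family gene carries its own anciently-diverged domain copy, so
        # only recent (tandem/segmental) duplicates are near-identical
        domain = _mutate_protein(consensus, 0.3, rng)
        left = int(rng.integers(20, 60))
        right = int(rng.integers(20, 60))
        flanks = rng.choice(letters, size=left + right)
        return "".join(flanks[:left]) + domain + "".join(flanks[left:])

    def decoy_protein() -> str:
        return "".join(rng.choice(letters, size=int(rng.integers(80, 200))))

    # assemble the gene roster: tandem cluster members first, then free
    # family genes, then decoys, distributed over chromosomes
    roster: dict[int, list[dict]] = {c: [] for c in range(n_chrom)}
    truth_rows: dict[str, dict] = {}
    fam_idx = 0
    dec_idx = 0

    def new_gene(is_family: bool, cds: str | None = None) -> dict:
        nonlocal fam_idx, dec_idx
        if is_family:
            fam_idx += 1
            gene_id = f"g_fam{fam_idx:03d}"
            protein = family_protein()
        else:
            dec_idx += 1
            gene_id = f"g_dec{dec_idx:03d}"
            protein = decoy_protein()
        if cds is None:
            cds = reverse_translate(protein, rng)
        return {"gene_id": gene_id, "cds": cds, "is_family": is_family}

    # assemble per-chromosome gene order as shuffled "units" so family genes
    # are interspersed among decoys in gene-order rank; a tandem cluster is
    # one unit and stays contiguous
    units: dict[int, list[list[dict]]] = {c: [] for c in range(n_chrom)}
    for cluster_id, (chrom, count, span) in enumerate(spec.tandem_clusters):
        source = new_gene(True)
        members = [source]
        for _ in range(count - 1):
            members.append(
                new_gene(
                    True,
                    cds=_mutate_cds(source["cds"], 0.03, rng, omega=duplicate_omega),
                )
            )
        for member in members:
            member["tandem_cluster_id"] = cluster_id
            member["tandem_span"] = span
        units[chrom].append(members)
    n_free_family = spec.n_family - n_tandem
    for _ in range(n_free_family):
        units[int(rng.integers(n_chrom))].append([new_gene(True)])
    for _ in range(spec.n_decoy):
        units[int(rng.integers(n_chrom))].append([new_gene(False)])
    for c in range(n_chrom):
        order = rng.permutation(len(units[c]))
        roster[c] = [gene for u in order for gene in units[c][u]]

    # segmental blocks: copy a contiguous run of genes (in final gene order)
    # from the fullest chromosome onto the last chromosome, preserving order
    dup_chrom = n_chrom - 1
    for block_id, (anchor_count, divergence) in enumerate(spec.segmental_blocks):
        candidates = [
            c
            for c in range(n_chrom)
            if c != dup_chrom and len(roster[c]) >= anchor_count
        ]
        if not candidates:
            raise ValidationError(
                f"segmental block {block_id}: no chromosome with {anchor_count} genes"
            )
        source_chrom = max(candidates, key=lambda c: len(roster[c]))
        n_windows = len(roster[source_chrom]) - anchor_count + 1
        # prefer runs that carry at least one family gene, so blocks anchor
        # family duplicate pairs as in real surveys
        windows_with_family = [
            s
            for s in range(n_windows)
            if any(g["is_family"] for g in roster[source_chrom][s: s + anchor_count])
        ]
        pool = windows_with_family or list(range(n_windows))
        start = int(pool[rng.integers(len(pool))])
        run = roster[source_chrom][start: start + anchor_count]
        copies = []
        for gene in run:
            gene.setdefault("segmental_block_id", block_id)
            copy = {
                "gene_id": gene["gene_id"] + "_d",
                "cds": _mutate_cds(gene["cds"], divergence, rng, omega=duplicate_omega),
                "is_family": gene["is_family"],
                "segmental_block_id": block_id,
                "segmental_source": gene["gene_id"],
            }
            copies.append(copy)
        roster[dup_chrom].extend(copies)

    # place genes on chromosomes and build sequences; intergenic gaps exceed
    # the tandem window so only intended clusters sit within it
    from trihelix.catalog import GeneModel

    chromosomes: dict[str, str] = {}
    genes: list[GeneModel] = []
    gff: list[tuple] = []
    bases = np.frombuffer(b"ACGT", dtype="S1")
    for c in range(n_chrom):
        chrom_name = f"Chr{c + 1}"
        cursor = 5000
        placements = []
        chrom_roster = roster[c]
        for gi, gene in enumerate(chrom_roster):
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(1, 4))
            cds = gene["cds"]
            pieces = _split_cds(cds, n_exons, rng)
            introns = ["".join(rng.choice(list(DNA), size=int(rng.integers(80, 300))))
                       for _ in range(n_exons - 1)]
            pre_mrna = pieces[0]
            for intron, piece in zip(introns, pieces[1:]):
                pre_mrna += intron + piece
            genomic = pre_mrna if strand == "+" else reverse_complement(pre_mrna)
            start = cursor
            end = start + len(genomic) - 1
            exon_coords = _exon_coordinates(start, pieces, introns, strand, len(genomic))
            placements.append((gene, strand, start, end, genomic, exon_coords))
            nxt = chrom_roster[gi + 1] if gi + 1 < len(chrom_roster) else None
            same_cluster = (
                nxt is not None
                and "tandem_cluster_id" in gene
                and nxt.get("tandem_cluster_id") == gene["tandem_cluster_id"]
            )
            if same_cluster:
                span = gene["tandem_span"]
                step = min(max(span // 4, _MIN_GENE_FOOTPRINT), span - 1)
                cursor = start + max(len(genomic) + 200, step)
            else:
                cursor = end + int(rng.integers(250_000, 500_000))
        chrom_len = cursor + 5000
        seq = bases[rng.integers(0, 4, size=chrom_len)]
        for gene, strand, start, end, genomic, exon_coords in placements:
            seq[start - 1: end] = np.frombuffer(genomic.encode(), dtype="S1")
        # implant cis-elements into family upstream windows, clamped so no
        # neighbouring gene body is overwritten
        implant_lib = _resolve_implants(spec.promoter_implants) if spec.promoter_implants else {}
        for gi, (gene, strand, start, end, genomic, exon_coords) in enumerate(placements):
            if not gene["is_family"] or not implant_lib:
                continue
            prev_end = placements[gi - 1][3] if gi > 0 else 0
            next_start = placements[gi + 1][2] if gi + 1 < len(placements) else chrom_len + 1
            if strand == "+":
                lo, hi = max(prev_end + 1, start - promoter_length), start - 1
            else:
                lo, hi = end + 1, min(next_start - 1, end + promoter_length, chrom_len)
            implanted = []
            for key, fraction in spec.promoter_implants.items():
                if rng.random() >= fraction:
                    continue
                word = _concrete_word(implant_lib[key], rng)
                if rng.random() < 0.5:
                    word = reverse_complement(word)
                if hi - lo + 1 < len(word):
                    continue
                pos = int(rng.integers(lo, hi - len(word) + 2))
                seq[pos - 1: pos - 1 + len(word)] = np.frombuffer(word.encode(), dtype="S1")
                implanted.append(key)
            gene["implanted_elements"] = ";".join(sorted(implanted))
        chromosomes[chrom_name] = seq.tobytes().decode()
        for gene, strand, start, end, genomic, exon_coords in placements:
            gene_id = gene["gene_id"]
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    chromosome=chrom_name,
                    strand=strand,
                    exons=tuple(exon_coords),
                    cds=gene["cds"],
                    transcript_ids=(gene_id + ".1",),
                )
            )
            gff.append((chrom_name, "synthetic", "gene", start, end, ".", strand, ".",
                        {"ID": gene_id}))
            gff.append((chrom_name, "synthetic", "mRNA", start, end, ".", strand, ".",
                        {"ID": gene_id + ".1", "Parent": gene_id}))
            for k, (es, ee) in enumerate(exon_coords):
                gff.append((chrom_name, "synthetic", "exon", es, ee, ".", strand, ".",
                            {"ID": f"{gene_id}.1.exon{k + 1}", "Parent": gene_id + ".1"}))
                gff.append((chrom_name, "synthetic", "CDS", es, ee, ".", strand, "0",
                            {"ID": f"{gene_id}.1.cds{k + 1}", "Parent": gene_id + ".1"}))
            truth_rows[gene_id] = {
                "gene_id": gene_id,
                "is_family": gene["is_family"],
                "chromosome": chrom_name,
                "strand": strand,
                "start": start,
                "end": end,
                "tandem_cluster_id": gene.get("tandem_cluster_id"),
                "segmental_block_id": gene.get("segmental_block_id"),
                "segmental_source": gene.get("segmental_source"),
                "implanted_elements": gene.get("implanted_elements", ""),
                "true_omega": duplicate_omega if gene.get("segmental_source") or gene.get("tandem_cluster_id") is not None else None,
            }
    truth = pd.DataFrame(truth_rows.values()).set_index("gene_id")
    return SyntheticGenome(chromosomes=chromosomes, genes=genes, gff_features=gff, truth=truth)


def _split_cds(cds: str, n_exons: int, rng: np.random.Generator) -> list[str]:
    if n_exons == 1 or len(cds) < 2 * n_exons:
        return [cds]
    cuts = sorted(rng.choice(np.arange(1, len(cds)), size=n_exons - 1, replace=False))
    pieces = []
    prev = 0
    for cut in cuts:
        pieces.append(cds[prev:cut])
        prev = cut
    pieces.append(cds[prev:])
    return pieces


def _exon_coordinates(
    start: int, pieces: list[str], introns: list[str], strand: str, total: int
) -> list[tuple[int, int]]:
    """Genomic exon intervals (ascending) for a gene whose plus-strand
    genomic sequence is the (possibly reverse-complemented) spliced layout."""
    offsets = []
    pos = 0
    for k, piece in enumerate(pieces):
        offsets.append((pos, pos + len(piece) - 1))
        pos += len(piece)
        if k < len(introns):
            pos += len(introns[k])
    if strand == "+":
        coords = [(start + a, start + b) for a, b in offsets]
    else:
        coords = [(start + total - 1 - b, start + total - 1 - a) for a, b in offsets]
        coords.reverse()
    return coords


def extract_cds_from_genome(
    genome: Mapping[str, str], gene
) -> str:
    """Splice a gene's CDS back out of the genome (verification helper)."""
    parts = [genome[gene.chromosome][s - 1: e] for s, e in gene.exons]
    seq = "".join(parts)
    return seq if gene.strand == "+" else reverse_complement(seq)


# ---------------------------------------------------------------------------
# promoters
# ---------------------------------------------------------------------------


def _concrete_word(consensus: str, rng: np.random.Generator) -> str:
    return "".join(
        sorted(IUPAC_DNA[c])[rng.integers(len(IUPAC_DNA[c]))] for c in consensus.upper()
    )


def _resolve_implants(
    implant_map: Mapping[str, float], library: Sequence[CisElement] | None = None
) -> dict[str, str]:
    """Map implant keys (library element ids or raw IUPAC words) to their
    IUPAC consensus strings."""
    if library is None:
        library = load_element_library()
    by_id = {e.element_id: e for e in library}
    resolved = {}
    for key in implant_map:
        consensus = by_id[key].consensus if key in by_id else key
        bad = [c for c in consensus.upper() if c not in IUPAC_DNA]
        if bad:
            raise ValidationError(f"implant {key}: invalid IUPAC {''.join(bad)}")
        resolved[key] = consensus.upper()
    return resolved


def generate_promoters(
    n: int,
    implant_map: Mapping[str, float],
    length: int = 1500,
    rng_seed: int = 0,
    library: Sequence[CisElement] | None = None,
    allow_reverse: bool = True,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Random promoters with elements implanted at recorded positions.

    ``implant_map`` keys are element ids from ``library`` (defaulting to the
    shipped PLACE-keyed library) or raw IUPAC strings; values are the
    fraction of promoters carrying the element.  Implants may be placed on
    the reverse strand.  Truth columns: promoter id, element, 1-based
    position, strand.
    """
    resolved = _resolve_implants(implant_map, library)
    for key, consensus in resolved.items():
        if len(consensus) > length:
            raise ValidationError(f"implant {key} longer than promoter")

    rng = np.random.default_rng(rng_seed)
    promoters: dict[str, str] = {}
    rows = []
    for k in range(n):
        name = f"prom{k + 1:03d}"
        seq = list("".join(rng.choice(list(DNA), size=length)))
        for key, fraction in implant_map.items():
            if rng.random() >= fraction:
                continue
            consensus = resolved[key]
            word = _concrete_word(consensus, rng)
            strand = "-" if (allow_reverse and rng.random() < 0.5) else "+"
            placed = reverse_complement(word) if strand == "-" else word
            pos = int(rng.integers(0, length - len(word) + 1))
            seq[pos: pos + len(word)] = list(placed)
            rows.append(
                {
                    "promoter_id": name,
                    "element": key,
                    "position": pos + 1,
                    "strand": strand,
                    "word": placed,
                }
            )
        promoters[name] = "".join(seq)
    truth = pd.DataFrame(rows, columns=["promoter_id", "element", "position", "strand", "word"])
    return promoters, truth


# ---------------------------------------------------------------------------
# expression matrix and Ct tables
# ---------------------------------------------------------------------------


def generate_expression_matrix(
    n_genes: int,
    conditions: Sequence[str] = ("root", "stem", "leaf", "sheath"),
    n_groups: int = 5,
    noise_sd: float = 0.5,
    rng_seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Genes x conditions expression values with group structure: each group
    shares a random archetype profile on the 0-8 scale plus Gaussian noise.
    Returns (matrix, true group labels)."""
    if n_groups > n_genes:
        raise ValidationError("n_groups must be <= n_genes")
    rng = np.random.default_rng(rng_seed)
    archetypes = rng.uniform(0.0, 8.0, size=(n_groups, len(conditions)))
    labels = np.sort(rng.integers(0, n_groups, size=n_genes))
    labels[:n_groups] = np.arange(n_groups)  # every group non-empty
    values = archetypes[labels] + rng.normal(0.0, noise_sd, size=(n_genes, len(conditions)))
    idx = [f"gene{k + 1:03d}" for k in range(n_genes)]
    matrix = pd.DataFrame(values, index=idx, columns=list(conditions))
    return matrix, pd.Series(labels, index=idx, name="true_group")


def generate_ct_table(
    genes: Sequence[str],
    timepoints: Sequence[str],
    true_log2_fc: Mapping[tuple[str, str], float],
    replicates: int = 3,
    noise_sd: float = 0.2,
    rng_seed: int = 0,
    baseline: str = "t0",
    reference_ct: float = 18.0,
    baseline_dct: float = 5.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """qPCR Ct table with known fold changes.

    The noiseless ΔΔCT at (gene, timepoint) equals ``-true_log2_fc``;
    Gaussian noise of sd ``noise_sd`` is added per well (target and
    reference independently).  Returns (Ct table, truth table).
    """
    if replicates < 2:
        raise ValidationError("replicates must be >= 2")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    rng = np.random.default_rng(rng_seed)
    rows = []
    truth_rows = []
    for gene in genes:
        for tp in [baseline, *timepoints]:
            log2_fc = 0.0 if tp == baseline else float(true_log2_fc.get((gene, tp), 0.0))
            dct = baseline_dct - log2_fc
            for rep in range(1, replicates + 1):
                ct_ref = reference_ct + rng.normal(0.0, noise_sd)
                ct_tgt = reference_ct + dct + rng.normal(0.0, noise_sd)
                rows.append(
                    {
                        "gene": gene,
                        "condition": tp,
                        "replicate": rep,
                        "ct_target": ct_tgt,
                        "ct_reference": ct_ref,
                    }
                )
            if tp != baseline:
                truth_rows.append(
                    {"gene": gene, "condition": tp, "true_log2_fc": log2_fc}
                )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)
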