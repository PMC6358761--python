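"""Duplication and synteny analysis of a gene family.

Tandem duplications are clusters of family genes within a chromosomal window
(200 kb by default).  Segmental duplications are family gene pairs anchored in
collinear blocks: chains of homologous gene pairs whose gene-order ranks are
monotone on both chromosomes (MCScanX-style, min 5 anchors, rank gap <= 25).
Substitution pressure on duplicated pairs is estimated with the Nei-Gojobori
(NG86) method: pathway-averaged synonymous/nonsynonymous counting with
Jukes-Cantor multiple-hit correction, Ka/Ks < 1 indicating purifying
selection.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from trihelix.errors import ValidationError

DEFAULT_TANDEM_WINDOW = 200_000
DEFAULT_MIN_ANCHORS = 5
DEFAULT_MAX_GAP = 25


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneLocus:
    gene_id: str
    chromosome: str
    start: int
    end: int = 0


@dataclass(frozen=True)
class AnchorPair:
    """Homologous gene pair with gene-order ranks on its two chromosomes."""

    gene_a: str
    gene_b: str
    score: float
    chrom_a: str
    chrom_b: str
    rank_a: int
    rank_b: int

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValidationError("anchor pair must join distinct genes")
        if self.score <= 0:
            raise ValidationError("anchor score must be > 0")


@dataclass(frozen=True)
class CollinearBlock:
    anchors: tuple[AnchorPair, ...]
    chromosomes: tuple[str, str]
    orientation: str  # "same" | "inverted"
    score: float

    def __post_init__(self) -> None:
        ra = [a.rank_a for a in self.anchors]
        rb = [a.rank_b for a in self.anchors]
        if sorted(ra) != ra:
            raise ValidationError("anchor ranks must increase on chromosome A")
        inc = all(x < y for x, y in zip(rb, rb[1:]))
        dec = all(x > y for x, y in zip(rb, rb[1:]))
        if not (inc or dec):
            raise ValidationError("anchor ranks must be monotone on chromosome B")


@dataclass(frozen=True)
class DuplicationEvent:
    gene_a: str
    gene_b: str
    kind: str  # "tandem" | "segmental"
    evidence: str  # span in bp (tandem) or block id (segmental)


@dataclass(frozen=True)
class KaKsResult:
    ka: float
    ks: float
    ratio: float | None  # None when undefined (Ks == 0)
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    saturated: bool = False

    def __post_init__(self) -> None:
        if self.ka < 0 or self.ks < 0:
            raise ValidationError("Ka and Ks must be >= 0")


# ---------------------------------------------------------------------------
# tandem duplication
# ---------------------------------------------------------------------------


def find_tandem_events(
    loci: Sequence[GeneLocus], window: int = DEFAULT_TANDEM_WINDOW
) -> list[DuplicationEvent]:
    """Maximal same-chromosome clusters in which consecutive family genes
    start within ``window`` bp; each cluster of >= 2 genes emits one tandem
    event per adjacent pair."""
    events = []
    by_chrom: dict[str, list[GeneLocus]] = {}
    for locus in loci:
        by_chrom.setdefault(locus.chromosome, []).append(locus)
    for chrom in sorted(by_chrom):
        genes = sorted(by_chrom[chrom], key=lambda g: (g.start, g.gene_id))
        cluster = [genes[0]]
        for gene in genes[1:]:
            if gene.start - cluster[-1].start <= window:
                cluster.append(gene)
            else:
                events.extend(_cluster_events(cluster))
                cluster = [gene]
        events.extend(_cluster_events(cluster))
    return events


def _cluster_events(cluster: list[GeneLocus]) -> Iterable[DuplicationEvent]:
    if len(cluster) < 2:
        return []
    span = cluster[-1].start - cluster[0].start
    return [
        DuplicationEvent(a.gene_id, b.gene_id, "tandem", f"span={span}bp")
        for a, b in zip(cluster, cluster[1:])
    ]


# ---------------------------------------------------------------------------
# anchor pairs (all-vs-all protein similarity)
# ---------------------------------------------------------------------------


def _blastp_like_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def find_anchor_pairs(
    proteome_a: Mapping[str, str],
    proteome_b: Mapping[str, str],
    loci: Mapping[str, GeneLocus],
    top_k: int = 5,
    score_threshold: float = 60.0,
) -> list[AnchorPair]:
    """All-vs-all local protein alignment (BLOSUM62, affine gaps); for each
    query the ``top_k`` best non-self matches above ``score_threshold`` are
    kept, symmetric duplicates removed, and gene-order ranks attached."""
    if not proteome_a or not proteome_b:
        raise ValidationError("proteomes must be non-empty")
    aligner = _blastp_like_aligner()
    ranks = gene_order_ranks(loci.values())
    seen: set[frozenset[str]] = set()
    pairs = []
    for qid, qseq in proteome_a.items():
        scored = []
        for tid, tseq in proteome_b.items():
            if tid == qid:
                continue
            score = aligner.score(qseq, tseq)
            if score >= score_threshold:
                scored.append((score, tid))
        scored.sort(key=lambda t: (-t[0], t[1]))
        for score, tid in scored[:top_k]:
            key = frozenset((qid, tid))
            if key in seen:
                continue
            seen.add(key)
            a, b = sorted((qid, tid), key=lambda g: (loci[g].chromosome, ranks[g]))
            pairs.append(
                AnchorPair(
                    gene_a=a,
                    gene_b=b,
                    score=float(score),
                    chrom_a=loci[a].chromosome,
                    chrom_b=loci[b].chromosome,
                    rank_a=ranks[a],
                    rank_b=ranks[b],
                )
            )
    pairs.sort(key=lambda p: (p.chrom_a, p.chrom_b, p.rank_a, p.rank_b))
    return pairs


def gene_order_ranks(loci: Iterable[GeneLocus]) -> dict[str, int]:
    """0-based gene-order index along each chromosome."""
    ranks = {}
    by_chrom: dict[str, list[GeneLocus]] = {}
    for locus in loci:
        by_chrom.setdefault(locus.chromosome, []).append(locus)
    for chrom, genes in by_chrom.items():
        for rank, gene in enumerate(sorted(genes, key=lambda g: (g.start, g.gene_id))):
            ranks[gene.gene_id] = rank
    return ranks


# ---------------------------------------------------------------------------
# collinear block chaining
# ---------------------------------------------------------------------------


def chain_collinear_blocks(
    anchors: Sequence[AnchorPair],
    min_anchors: int = DEFAULT_MIN_ANCHORS,
    max_gap: int = DEFAULT_MAX_GAP,
) -> list[CollinearBlock]:
    """Chain anchors into collinear blocks by dynamic programming.

    Within each chromosome pair, the longest chain with strictly monotone
    ranks on both axes (same or inverted orientation) and rank gaps
    <= ``max_gap`` is extracted; its anchors are removed and the search
    repeats, so each anchor belongs to at most one block per chromosome pair.
    Chains shorter than ``min_anchors`` are discarded.
    """
    groups: dict[tuple[str, str], list[AnchorPair]] = {}
    for anchor in anchors:
        groups.setdefault((anchor.chrom_a, anchor.chrom_b), []).append(anchor)

    blocks = []
    for chrom_pair in sorted(groups):
        remaining = list(groups[chrom_pair])
        while True:
            best_chain, best_orient = None, None
            for orient in ("same", "inverted"):
                chain = _longest_chain(remaining, orient, max_gap)
                if best_chain is None or _chain_key(chain) > _chain_key(best_chain):
                    best_chain, best_orient = chain, orient
            if best_chain is None or len(best_chain) < min_anchors:
                break
            blocks.append(
                CollinearBlock(
                    anchors=tuple(best_chain),
                    chromosomes=chrom_pair,
                    orientation=best_orient,
                    score=sum(a.score for a in best_chain),
                )
            )
            used = set(map(id, best_chain))
            remaining = [a for a in remaining if id(a) not in used]
    return blocks


def _chain_key(chain: list[AnchorPair] | None) -> tuple:
    if not chain:
        return (0, 0.0)
    return (len(chain), sum(a.score for a in chain))


def _longest_chain(
    anchors: list[AnchorPair], orientation: str, max_gap: int
) -> list[AnchorPair]:
    """Longest (by count, then score) chain with strictly increasing rank_a
    and strictly increasing (same) / decreasing (inverted) rank_b, with rank
    gaps <= max_gap on both axes."""
    if not anchors:
        return []
    order = sorted(anchors, key=lambda a: (a.rank_a, a.rank_b))
    n = len(order)
    length = [1] * n
    score = [a.score for a in order]
    back = [-1] * n
    for i in range(n):
        for j in range(i):
            da = order[i].rank_a - order[j].rank_a
            if orientation == "same":
                db = order[i].rank_b - order[j].rank_b
            else:
                db = order[j].rank_b - order[i].rank_b
            if da <= 0 or db <= 0 or da > max_gap or db > max_gap:
                continue
            cand_len = length[j] + 1
            cand_score = score[j] + order[i].score
            if (cand_len, cand_score) > (length[i], score[i]):
                length[i], score[i], back[i] = cand_len, cand_score, j
    best = max(range(n), key=lambda i: (length[i], score[i]))
    chain = []
    while best != -1:
        chain.append(order[best])
        best = back[best]
    chain.reverse()
    return chain


# ---------------------------------------------------------------------------
# duplication classification
# ---------------------------------------------------------------------------


def classify_family_duplications(
    blocks: Sequence[CollinearBlock],
    tandem_events: Sequence[DuplicationEvent],
    family_ids: Iterable[str],
) -> list[DuplicationEvent]:
    """Label family gene pairs: anchored in a collinear block -> segmental,
    in a tandem cluster -> tandem; tandem takes precedence when both apply."""
    family = set(family_ids)
    tandem_pairs = {
        frozenset((e.gene_a, e.gene_b)): e
        for e in tandem_events
        if e.gene_a in family and e.gene_b in family
    }
    events = list(tandem_pairs.values())
    seen = set(tandem_pairs)
    for idx, block in enumerate(blocks):
        for anchor in block.anchors:
            if anchor.gene_a in family and anchor.gene_b in family:
                key = frozenset((anchor.gene_a, anchor.gene_b))
                if key in seen:
                    continue
                seen.add(key)
                events.append(
                    DuplicationEvent(
                        anchor.gene_a, anchor.gene_b, "segmental", f"block={idx}"
                    )
                )
    return events


# ---------------------------------------------------------------------------
# NG86 Ka/Ks
# ---------------------------------------------------------------------------

_STOPS = set(standard_dna_table.stop_codons)
_BASES = "ACGT"


def _translate_codon(codon: str) -> str:
    return "*" if codon in _STOPS else standard_dna_table.forward_table[codon]


def _codon_site_counts(codon: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous site counts for one codon.

    Each position contributes the fraction of its three possible changes
    that are synonymous; changes producing stop codons count as
    nonsynonymous.
    """
    aa = _translate_codon(codon)
    syn = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1:]
            if mutant not in _STOPS and _translate_codon(mutant) == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def _pathway_diffs(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous differences between two codons, averaged over
    all mutational pathways; pathways crossing a stop codon are excluded
    unless every pathway does."""
    positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not positions:
        return 0.0, 0.0
    pathways = []
    for order in itertools.permutations(positions):
        current = codon_a
        syn = nonsyn = 0.0
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
            if nxt in _STOPS:
                blocked = True
            if _translate_codon(current) == _translate_codon(nxt):
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        pathways.append((blocked, syn, nonsyn))
    usable = [p for p in pathways if not p[0]] or pathways
    sd = sum(p[1] for p in usable) / len(usable)
    nd = sum(p[2] for p in usable) / len(usable)
    return sd, nd


def _jukes_cantor(p: float) -> tuple[float, bool]:
    """JC69 correction d = -(3/4) ln(1 - 4p/3); p >= 3/4 is saturated and
    capped at the value for p just below the pole."""
    if p >= 0.75:
        return _jukes_cantor(0.7499)[0], True
    return -0.75 * math.log1p(-4.0 * p / 3.0), False


def kaks_ng86(cds_a: str, cds_b: str) -> KaKsResult:
    """Nei-Gojobori (1986) Ka/Ks for an in-frame, gap-free aligned CDS pair.

    Sites S and N are averaged over both sequences; differences Sd/Nd use
    pathway averaging; proportions are Jukes-Cantor corrected.  The ratio is
    flagged undefined (None) when Ks = 0.
    """
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    if len(cds_a) != len(cds_b):
        raise ValidationError("CDS pair must be equal length")
    if len(cds_a) % 3 != 0:
        raise ValidationError("CDS length must be a multiple of 3")
    if "-" in cds_a or "-" in cds_b:
        raise ValidationError("CDS pair must be gap-free (pre-align and strip)")

    s_sites = n_sites = sd = nd = 0.0
    n_codons = len(cds_a) // 3
    for k in range(n_codons):
        ca, cb = cds_a[3 * k: 3 * k + 3], cds_b[3 * k: 3 * k + 3]
        terminal = k == n_codons - 1
        if ca in _STOPS or cb in _STOPS:
            if terminal:
                continue  # terminal stop codon excluded from counting
            raise ValidationError(f"internal stop codon at codon {k + 1}")
        sa, na = _codon_site_counts(ca)
        sb, nb = _codon_site_counts(cb)
        s_sites += (sa + sb) / 2.0
        n_sites += (na + nb) / 2.0
        d_s, d_n = _pathway_diffs(ca, cb)
        sd += d_s
        nd += d_n

    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ks, sat_s = _jukes_cantor(ps)
    ka, sat_n = _jukes_cantor(pn)
    ratio = None if ks == 0 else ka / ks
    return KaKsResult(
        ka=ka,
        ks=ks,
        ratio=ratio,
        syn_sites=s_sites,
        nonsyn_sites=n_sites,
        syn_diffs=sd,
        nonsyn_diffs=nd,
        saturated=sat_s or sat_n,
    )


def align_codon_pair(cds_a: str, cds_b: str) -> tuple[str, str]:
    """Align two CDS by their protein translations (global, BLOSUM62, affine
    gaps), back-thread the codons, and drop gapped codon columns, yielding an
    equal-length gap-free pair suitable for NG86."""
    prot_a = str(Seq(cds_a).translate()).rstrip("*")
    prot_b = str(Seq(cds_b).translate()).rstrip("*")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -0.5
    alignment = aligner.align(prot_a, prot_b)[0]
    out_a, out_b = [], []
    ia = ib = 0
    for col_a, col_b in zip(alignment[0], alignment[1]):
        codon_a = cds_a[3 * ia: 3 * ia + 3] if col_a != "-" else None
        codon_b = cds_b[3 * ib: 3 * ib + 3] if col_b != "-" else None
        if col_a != "-":
            ia += 1
        if col_b != "-":
            ib += 1
        if codon_a is not None and codon_b is not None:
            out_a.append(codon_a)
            out_b.append(codon_b)
    return "".join(out_a), "".join(out_b)
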