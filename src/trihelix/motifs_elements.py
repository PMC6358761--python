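"""Promoter extraction, IUPAC cis-element scanning, shared-element
intersection, and a ZOOPS EM motif discoverer.

Promoters are the 1500 bp upstream of the gene start (strand-aware,
truncated at chromosome edges).  Cis-elements are degenerate IUPAC words
(e.g. GT1CONSENSUS ``GRWAAW``) scanned on both strands; the family-level
readout is the set of elements present in every promoter.  The motif
discoverer fits a zero-or-one-occurrence-per-sequence (ZOOPS) mixture by
expectation-maximization, masking each converged motif before fitting the
next.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from trihelix.errors import ValidationError

IUPAC_DNA: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

DNA = "ACGT"
DNA_INDEX = {b: i for i, b in enumerate(DNA)}


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CisElement:
    element_id: str
    consensus: str  # IUPAC DNA
    annotation: str = ""

    def __post_init__(self) -> None:
        bad = [c for c in self.consensus.upper() if c not in IUPAC_DNA]
        if bad:
            raise ValidationError(
                f"{self.element_id}: invalid IUPAC characters {''.join(bad)}"
            )


@dataclass(frozen=True)
class ElementMatch:
    promoter_id: str
    element_id: str
    start: int  # 1-based in promoter forward coordinates
    strand: str  # "+" | "-"
    matched: str  # substring of the forward sequence


@dataclass(frozen=True)
class Promoter:
    gene_id: str
    sequence: str
    truncated: bool = False


@dataclass(frozen=True)
class MotifModel:
    width: int
    pwm: np.ndarray  # (width, 4), columns sum to 1
    site_posteriors: dict[str, tuple[int, float]]  # seq id -> (best site 0-based, posterior)
    log_likelihood: float

    def __post_init__(self) -> None:
        if not np.allclose(self.pwm.sum(axis=1), 1.0, atol=1e-6):
            raise ValidationError("PWM rows must sum to 1")

    @property
    def consensus(self) -> str:
        return "".join(DNA[i] for i in self.pwm.argmax(axis=1))

    def information_content(self) -> float:
        """Total IC in bits relative to a uniform background."""
        p = np.clip(self.pwm, 1e-9, 1.0)
        return float((p * (np.log2(p) + 2.0)).sum())


def load_element_library(path=None) -> list[CisElement]:
    """Read the element library TSV (id, IUPAC consensus, annotation);
    defaults to the PLACE-keyed library shipped with the package."""
    if path is None:
        with resources.files("trihelix.data").joinpath("cis_elements.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    return [
        CisElement(r.element_id, r.iupac_consensus, r.annotation)
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# promoter extraction
# ---------------------------------------------------------------------------


def extract_promoters(
    genome: Mapping[str, str],
    genes: Iterable,  # objects with gene_id, chromosome, strand, and exons or start/end
    length: int = 1500,
) -> list[Promoter]:
    """Strand-aware upstream sequences.

    Plus strand: ``[start - length, start - 1]``; minus strand: reverse
    complement of ``[end + 1, end + length]`` (1-based inclusive).  Windows
    are truncated at chromosome edges and flagged.
    """
    promoters = []
    for gene in genes:
        if gene.chromosome not in genome:
            raise ValidationError(f"{gene.gene_id}: chromosome {gene.chromosome} absent")
        chrom = genome[gene.chromosome]
        if hasattr(gene, "exons") and gene.exons:
            start, end = gene.exons[0][0], gene.exons[-1][1]
        else:
            start, end = gene.start, gene.end
        if gene.strand == "+":
            lo = max(1, start - length)
            seq = chrom[lo - 1: start - 1]
            truncated = lo > start - length
        else:
            hi = min(len(chrom), end + length)
            seq = reverse_complement(chrom[end: hi])
            truncated = hi < end + length
        promoters.append(Promoter(gene.gene_id, seq, truncated))
    return promoters


# ---------------------------------------------------------------------------
# IUPAC scanning
# ---------------------------------------------------------------------------


def _matches_at(seq: str, pattern: str, pos: int) -> bool:
    return all(seq[pos + k] in IUPAC_DNA[pattern[k]] for k in range(len(pattern)))


def iupac_scan(
    sequence: str,
    element: CisElement,
    both_strands: bool = True,
    promoter_id: str = "",
) -> list[ElementMatch]:
    """All (overlapping) positions matching the element's IUPAC consensus.

    Reverse-strand hits are reported in forward coordinates (1-based start of
    the matched forward-strand substring) with strand ``-``.
    """
    seq = sequence.upper()
    pattern = element.consensus.upper()
    w, L = len(pattern), len(seq)
    matches = []
    for pos in range(L - w + 1):
        if _matches_at(seq, pattern, pos):
            matches.append(
                ElementMatch(promoter_id, element.element_id, pos + 1, "+", seq[pos: pos + w])
            )
    if both_strands:
        rc_pattern = reverse_complement(pattern)
        for pos in range(L - w + 1):
            if _matches_at(seq, rc_pattern, pos):
                matches.append(
                    ElementMatch(promoter_id, element.element_id, pos + 1, "-", seq[pos: pos + w])
                )
    matches.sort(key=lambda m: (m.start, m.strand))
    return matches


def shared_elements(
    promoters: Sequence[Promoter],
    library: Sequence[CisElement],
    both_strands: bool = True,
) -> set[str]:
    """Element ids with at least one match in EVERY promoter."""
    if not promoters:
        raise ValidationError("need at least one promoter")
    shared = set()
    for element in library:
        if all(
            iupac_scan(p.sequence, element, both_strands, p.gene_id) for p in promoters
        ):
            shared.add(element.element_id)
    return shared


def scan_promoters(
    promoters: Sequence[Promoter],
    library: Sequence[CisElement],
    both_strands: bool = True,
) -> pd.DataFrame:
    """BED-like table of all element matches: promoter id, 0-based half-open
    interval in promoter coordinates, strand, element id."""
    rows = []
    for promoter in promoters:
        for element in library:
            for m in iupac_scan(promoter.sequence, element, both_strands, promoter.gene_id):
                rows.append(
                    {
                        "promoter_id": m.promoter_id,
                        "start": m.start - 1,
                        "end": m.start - 1 + len(element.consensus),
                        "strand": m.strand,
                        "element_id": m.element_id,
                        "matched": m.matched,
                    }
                )
    return pd.DataFrame(
        rows, columns=["promoter_id", "start", "end", "strand", "element_id", "matched"]
    )


# ---------------------------------------------------------------------------
# ZOOPS EM motif discovery
# ---------------------------------------------------------------------------


def _seq_onehot_windows(seq: str, width: int) -> np.ndarray:
    """(n_windows, width) base-index array for all windows of ``width``."""
    idx = np.array([DNA_INDEX.get(c, 0) for c in seq.upper()])
    n = len(seq) - width + 1
    return np.stack([idx[i: i + width] for i in range(n)])


def _em_single_motif(
    windows: dict[str, np.ndarray],
    width: int,
    rng: np.random.Generator,
    max_iter: int = 200,
    tol: float = 1e-6,
    init_window: np.ndarray | None = None,
):
    """One ZOOPS EM fit; returns (pwm, gamma, loglik, per-sequence site
    posteriors).  When ``init_window`` is given the PWM starts biased toward
    that observed subsequence (site-driven seeding); otherwise it starts from
    a Dirichlet draw."""
    if init_window is not None:
        pwm = np.full((width, 4), 0.1)
        pwm[np.arange(width), init_window] = 0.7
    else:
        pwm = rng.dirichlet(np.full(4, 2.0), size=width)
    gamma = 0.5  # prior probability a sequence carries a site
    background = np.full(4, 0.25)
    prev_ll = -np.inf
    for _ in range(max_iter):
        counts = np.zeros((width, 4))
        gamma_num = 0.0
        ll = 0.0
        posteriors = {}
        for name, win in windows.items():
            n_win = win.shape[0]
            log_odds = np.log(np.clip(pwm, 1e-12, 1.0)) - np.log(background)
            site_ll = log_odds[np.arange(width)[None, :], win].sum(axis=1)
            # mixture: no-site component vs each window (uniform site prior)
            w_site = (gamma / n_win) * np.exp(site_ll - site_ll.max())
            w_none = (1.0 - gamma) * np.exp(-site_ll.max())
            total = w_none + w_site.sum()
            post_site = w_site / total
            posteriors[name] = post_site
            gamma_num += post_site.sum()
            ll += np.log(total) + site_ll.max()
            counts += np.einsum("n,nwb->wb", post_site, np.eye(4)[win])
        gamma = min(max(gamma_num / len(windows), 1e-3), 1 - 1e-3)
        pwm = (counts + 0.25) / (counts.sum(axis=1, keepdims=True) + 1.0)
        if abs(ll - prev_ll) < tol:
            break
        prev_ll = ll
    site_calls = {
        name: (int(p.argmax()), float(p.max())) for name, p in posteriors.items()
    }
    return pwm, gamma, ll, site_calls


def _rank_seed_windows(
    windows: dict[str, np.ndarray],
    width: int,
    n_seeds: int,
    rng: np.random.Generator,
    max_candidates: int = 1500,
) -> list[np.ndarray]:
    """Rank observed windows as EM starting points (subsequence seeding).

    Each candidate window defines a sharply peaked PWM whose one-step ZOOPS
    log-likelihood reduces to a function of Hamming matches to every other
    window; the ``n_seeds`` best candidates are returned.
    """
    names = sorted(windows)
    all_win = np.vstack([windows[n] for n in names])
    seq_sizes = [windows[n].shape[0] for n in names]
    bounds = np.cumsum([0, *seq_sizes])
    n_total = all_win.shape[0]
    if n_total <= max_candidates:
        cand_idx = np.arange(n_total)
    else:
        cand_idx = rng.choice(n_total, size=max_candidates, replace=False)
    a = np.log(0.7 / 0.25)
    b = np.log(0.1 / 0.25)
    scores = np.empty(len(cand_idx))
    cand = all_win[cand_idx]
    for c in range(len(cand_idx)):
        matches = (all_win == cand[c]).sum(axis=1)
        sll = a * matches + b * (width - matches)
        ll = 0.0
        for s in range(len(names)):
            seg = sll[bounds[s]: bounds[s + 1]]
            m = seg.max()
            # gamma = 0.5 prior, uniform site position
            ll += m + np.log(
                0.5 * np.exp(-m) + (0.5 / len(seg)) * np.exp(seg - m).sum()
            )
        scores[c] = ll
    top = np.argsort(-scores, kind="stable")[:n_seeds]
    return [cand[t] for t in top]


def discover_motifs_em(
    sequences: Mapping[str, str],
    width: int,
    n_motifs: int = 1,
    n_restarts: int = 5,
    rng_seed: int = 0,
) -> list[MotifModel]:
    """Discover up to ``n_motifs`` ungapped motifs of ``width`` by ZOOPS EM.

    For each motif, several random restarts are run and the best
    log-likelihood kept; the best sites are then masked (replaced by
    independent uniform bases from the seeded generator) before the next
    motif is fitted.  Deterministic given ``rng_seed``.
    """
    if len(sequences) < 2:
        raise ValidationError("need at least 2 sequences")
    if width > min(len(s) for s in sequences.values()):
        raise ValidationError("motif width exceeds shortest sequence")
    if n_motifs > 10:
        raise ValidationError("n_motifs must be <= 10")
    rng = np.random.default_rng(rng_seed)
    working = {k: v.upper() for k, v in sequences.items()}
    models = []
    for _ in range(n_motifs):
        windows = {name: _seq_onehot_windows(seq, width) for name, seq in working.items()}
        seeds = _rank_seed_windows(windows, width, n_restarts, rng)
        best = None
        for init in [*seeds, None]:  # best data-driven seeds + one random start
            fit = _em_single_motif(windows, width, rng, init_window=init)
            if best is None or fit[2] > best[2]:
                best = fit
        pwm, gamma, ll, site_calls = best
        models.append(
            MotifModel(width=width, pwm=pwm, site_posteriors=site_calls, log_likelihood=float(ll))
        )
        # mask the called sites so the next motif must explain something else
        masked = {}
        for name, seq in working.items():
            pos, post = site_calls[name]
            if post > 0.5:
                fill = "".join(rng.choice(list(DNA), size=width))
                seq = seq[:pos] + fill + seq[pos + width:]
            masked[name] = seq
        working = masked
    return models
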