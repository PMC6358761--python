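"""Per-gene catalog of a gene family: ORF/protein lengths, molecular weight,
isoelectric point, exon counts, chromosomal distribution, and transcript
accounting, summarized the way gene-family surveys tabulate them.

Molecular weight uses average residue masses plus one water per chain
(ExPASy convention); the isoelectric point solves the Henderson-Hasselbalch
net-charge equation by bisection with the Bjellqvist pKa set.  Both data
tables ship as editable TSV files under ``trihelix/data``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Mapping

import pandas as pd

from trihelix.errors import ValidationError

WATER_AVG_MASS = 18.0153  # Da


def _load_data_table(name: str) -> pd.DataFrame:
    with resources.files("trihelix.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


@lru_cache(maxsize=None)
def load_average_masses() -> dict[str, float]:
    df = _load_data_table("aa_average_masses.tsv")
    return dict(zip(df["residue"], df["mass"]))


@lru_cache(maxsize=None)
def load_pka_table() -> dict[str, tuple[float, int]]:
    """``{group: (pKa, charge)}`` with charge +1 for basic, -1 for acidic."""
    df = _load_data_table("pka_bjellqvist.tsv")
    return {r.group: (float(r.pka), int(r.charge)) for r in df.itertuples()}


@dataclass(frozen=True)
class GeneModel:
    """Annotated gene: exon structure and coding sequence."""

    gene_id: str
    chromosome: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # 1-based inclusive, sorted
    cds: str
    transcript_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        prev_end = 0
        for start, end in self.exons:
            if start <= prev_end:
                raise ValidationError(
                    f"{self.gene_id}: exons must be sorted and non-overlapping"
                )
            prev_end = end
        if len(self.cds) % 3 != 0:
            raise ValidationError(f"{self.gene_id}: CDS length not divisible by 3")

    @property
    def orf_length_nt(self) -> int:
        return len(self.cds)

    @property
    def exon_count(self) -> int:
        return len(self.exons)


@dataclass(frozen=True)
class ProteinRecord:
    """Derived protein properties plus the pass-through localization label."""

    gene_id: str
    length_aa: int
    mw_kda: float
    pi: float
    localization: str = ""

    def __post_init__(self) -> None:
        if self.length_aa <= 0:
            raise ValidationError("protein length must be > 0")
        if not (0 < self.pi < 14):
            raise ValidationError("pI must be in (0, 14)")


def protein_length_from_orf(orf_nt: int) -> int:
    """Protein length in residues for an ORF of ``orf_nt`` bp including the
    stop codon: ``orf_nt/3 - 1``."""
    if orf_nt % 3 != 0:
        raise ValidationError(
            f"ORF length {orf_nt} not divisible by 3 (annotation problem)"
        )
    if orf_nt < 6:
        raise ValidationError("ORF must be at least 6 nt (start + stop)")
    return orf_nt // 3 - 1


def molecular_weight(sequence: str, masses: Mapping[str, float] | None = None) -> float:
    """Average molecular weight of a protein in kDa."""
    if masses is None:
        masses = load_average_masses()
    if not sequence:
        raise ValidationError("empty protein sequence")
    bad = sorted({c for c in sequence.upper() if c not in masses})
    if bad:
        raise ValidationError(f"nonstandard residues: {''.join(bad)}")
    dalton = sum(masses[c] for c in sequence.upper()) + WATER_AVG_MASS
    return dalton / 1000.0


def net_charge(sequence: str, ph: float, pka_table: Mapping[str, tuple[float, int]]) -> float:
    """Net charge at ``ph``: sum over ionizable groups of the
    Henderson-Hasselbalch fractional charges (termini always included)."""
    seq = sequence.upper()
    groups = [pka_table["nterm"], pka_table["cterm"]]
    groups += [pka_table[c] for c in seq if c in pka_table and len(c) == 1]
    q = 0.0
    for pka, charge in groups:
        if charge > 0:
            q += 1.0 / (1.0 + 10 ** (ph - pka))
        else:
            q -= 1.0 / (1.0 + 10 ** (pka - ph))
    return q


def isoelectric_point(
    sequence: str,
    pka_table: Mapping[str, tuple[float, int]] | None = None,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> float:
    """pH at which the protein's net charge crosses zero, by bisection.

    The charge is strictly decreasing in pH, so bisection on [0, 14] converges;
    iteration stops when |Q| < ``tol``.
    """
    if pka_table is None:
        pka_table = load_pka_table()
    if not sequence:
        raise ValidationError("empty protein sequence")
    lo, hi = 0.0, 14.0
    for _ in range(max_iter):
        mid = (lo + hi) / 2.0
        q = net_charge(sequence, mid, pka_table)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    raise ValidationError("isoelectric point bisection did not converge")


def build_protein_record(
    gene: GeneModel, localization: str = "", translate_check: bool = True
) -> ProteinRecord:
    """Derive protein properties from a gene model's CDS."""
    from Bio.Seq import Seq

    protein = str(Seq(gene.cds).translate())
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        raise ValidationError(f"{gene.gene_id}: internal stop codon in CDS")
    if translate_check and len(protein) != protein_length_from_orf(gene.orf_length_nt):
        raise ValidationError(f"{gene.gene_id}: translation length mismatch")
    return ProteinRecord(
        gene_id=gene.gene_id,
        length_aa=len(protein),
        mw_kda=round(molecular_weight(protein), 2),
        pi=round(isoelectric_point(protein), 2),
        localization=localization,
    )


# ---------------------------------------------------------------------------
# catalog table
# ---------------------------------------------------------------------------

CATALOG_COLUMNS = [
    "gene_name",
    "gene_locus",
    "chromosome",
    "orf_bp",
    "exon_count",
    "length_aa",
    "mw_kda",
    "pi",
    "localization",
]


def read_catalog(path) -> pd.DataFrame:
    """Read a catalog TSV (one row per gene)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"catalog missing columns: {missing}")
    return df


def summarize_catalog(
    catalog: pd.DataFrame, isoforms: Mapping[str, int] | None = None
) -> dict:
    """Summary statistics of a gene-family catalog.

    ``isoforms`` maps gene name -> number of transcripts (default 1 each);
    the transcript count is the sum over genes.
    """
    if catalog.empty:
        return {
            "n_genes": 0,
            "n_transcripts": 0,
            "per_chromosome": {},
            "per_localization": {},
            "ranges": {},
        }
    isoforms = dict(isoforms or {})
    n_transcripts = int(
        sum(isoforms.get(g, 1) for g in catalog["gene_name"])
    )

    def _rng(col):
        return (float(catalog[col].min()), float(catalog[col].max()))

    return {
        "n_genes": int(len(catalog)),
        "n_transcripts": n_transcripts,
        "per_chromosome": catalog["chromosome"].value_counts().to_dict(),
        "per_localization": catalog["localization"].value_counts().to_dict(),
        "ranges": {
            "length_aa": _rng("length_aa"),
            "mw_kda": _rng("mw_kda"),
            "pi": _rng("pi"),
            "exon_count": _rng("exon_count"),
        },
    }


def catalog_from_genes(
    genes: list[GeneModel], localizations: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Build the catalog table from gene models (Table-1 analog)."""
    localizations = dict(localizations or {})
    rows = []
    for gene in genes:
        rec = build_protein_record(gene, localizations.get(gene.gene_id, ""))
        rows.append(
            {
                "gene_name": gene.gene_id,
                "gene_locus": gene.gene_id,
                "chromosome": gene.chromosome,
                "orf_bp": gene.orf_length_nt,
                "exon_count": gene.exon_count,
                "length_aa": rec.length_aa,
                "mw_kda": rec.mw_kda,
                "pi": rec.pi,
                "localization": rec.localization,
            }
        )
    return pd.DataFrame(rows, columns=CATALOG_COLUMNS)
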