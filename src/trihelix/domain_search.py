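"""Two-pass profile-based identification of domain-bearing family members.

A protein family is identified from a proteome by (1) searching with a seed
profile built from an aligned set of known domain sequences, (2) rebuilding a
species-specific profile from the aligned hit segments, and (3) re-searching
the whole proteome with the refined profile, keeping hits below an E-value
threshold that also cover most of the model ("complete domain" check).

The profile is a position-specific log-odds model scored against sequences by
Smith-Waterman local alignment with affine gaps.  E-values come from a Gumbel
(EVD) fit to the scores of random background sequences, following the standard
Karlin-Altschul picture for local alignment score tails.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import gumbel_r

from trihelix.errors import PipelineError, ValidationError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

_NEG = -1e9  # effective -infinity that stays finite under arithmetic


# ---------------------------------------------------------------------------
# model types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProfileModel:
    """Position-specific scoring model of a protein domain.

    ``match_emissions[i, a]`` is the log2-odds (bits) of residue ``a`` at
    model position ``i`` relative to ``background``.  ``calibration`` holds
    the ``(mu, lam)`` parameters of a Gumbel fit to local-alignment scores of
    random background sequences; ``lam = 1/beta`` in scipy's location/scale
    parameterization.
    """

    match_emissions: np.ndarray  # (length, 20) bits
    background: np.ndarray  # (20,) frequencies, sums to 1
    gap_open: float = 4.0
    gap_extend: float = 1.0
    calibration: tuple[float, float] | None = None  # (mu, lambda)

    def __post_init__(self) -> None:
        em = np.asarray(self.match_emissions, dtype=float)
        if em.ndim != 2 or em.shape[1] != len(AMINO_ACIDS) or em.shape[0] < 1:
            raise ValidationError("match_emissions must be a (length, 20) array")
        if not np.all(np.isfinite(em)):
            raise ValidationError("match_emissions must be finite")
        if self.calibration is not None and self.calibration[1] <= 0:
            raise ValidationError("calibrated lambda must be > 0")

    @property
    def length(self) -> int:
        return self.match_emissions.shape[0]

    @property
    def consensus(self) -> str:
        """Residue of maximal log-odds at each model position."""
        return "".join(AMINO_ACIDS[a] for a in self.match_emissions.argmax(axis=1))

    def emission_probabilities(self) -> np.ndarray:
        """Per-position emission frequencies implied by the log-odds."""
        p = self.background[None, :] * np.exp2(self.match_emissions)
        return p / p.sum(axis=1, keepdims=True)


@dataclass(frozen=True)
class DomainHit:
    """Best local alignment of a sequence to a profile.

    Coordinates are 1-based inclusive.  ``model_aligned`` is the hit segment
    re-threaded onto model coordinates (one character per model position,
    ``-`` for unaligned/deleted positions); it is what pass two realigns.
    """

    sequence_id: str
    score: float  # bits
    e_value: float | None
    seq_start: int
    seq_end: int
    model_start: int
    model_end: int
    model_coverage: float
    model_aligned: str = field(repr=False, default="")

    def __post_init__(self) -> None:
        if self.seq_start > self.seq_end:
            raise ValidationError("seq_start must be <= seq_end")
        if not (0 < self.model_coverage <= 1):
            raise ValidationError("model_coverage must be in (0, 1]")
        if self.e_value is not None and self.e_value < 0:
            raise ValidationError("e_value must be >= 0")


@dataclass(frozen=True)
class SearchConfig:
    """Thresholds of the two-pass search.

    ``e_threshold`` is the final inclusion cutoff; ``pass1_e_threshold`` is
    the permissive first-pass cutoff used only to gather segments for the
    species-specific profile.  ``min_model_coverage`` operationalizes the
    "complete domain" verification.
    """

    e_threshold: float = 0.01
    min_model_coverage: float = 0.8
    n_calibration_shuffles: int = 1000
    pass1_e_threshold: float = 5.0
    calibration_length: int = 300
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("e_threshold", "min_model_coverage", "pass1_e_threshold"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# profile construction
# ---------------------------------------------------------------------------

uniform_background = np.full(len(AMINO_ACIDS), 1.0 / len(AMINO_ACIDS))


def build_profile(
    aligned_domains: Mapping[str, str] | Sequence[str],
    pseudocount_weight: float = 1.0,
    background: np.ndarray | None = None,
    max_gap_fraction: float = 0.5,
    gap_open: float = 4.0,
    gap_extend: float = 1.0,
) -> ProfileModel:
    """Build a log-odds profile from a gapped protein alignment.

    Columns with more than ``max_gap_fraction`` gaps are excluded from match
    states.  Per-position emission odds use Laplace-style pseudocounts scaled
    by the background: ``(counts + w*bg) / (total + w)`` over ``bg``.
    """
    seqs = list(aligned_domains.values()) if isinstance(aligned_domains, Mapping) else list(aligned_domains)
    if len(seqs) < 2:
        raise ValidationError("need at least 2 aligned sequences")
    if len({len(s) for s in seqs}) != 1:
        raise ValidationError("aligned sequences must have equal gapped length")
    if background is None:
        background = uniform_background
    background = np.asarray(background, dtype=float)

    n = len(seqs)
    width = len(seqs[0])
    columns = []
    for j in range(width):
        col = [s[j].upper() for s in seqs]
        gaps = sum(c in "-." for c in col)
        if gaps / n > max_gap_fraction:
            continue
        counts = np.zeros(len(AMINO_ACIDS))
        for c in col:
            if c in AA_INDEX:
                counts[AA_INDEX[c]] += 1
        total = counts.sum()
        probs = (counts + pseudocount_weight * background) / (total + pseudocount_weight)
        columns.append(np.log2(probs / background))
    if not columns:
        raise ValidationError("no usable alignment columns (all exceed gap fraction)")
    return ProfileModel(
        match_emissions=np.array(columns),
        background=background,
        gap_open=gap_open,
        gap_extend=gap_extend,
    )


# ---------------------------------------------------------------------------
# local alignment
# ---------------------------------------------------------------------------


def _emission_row(profile: ProfileModel, sequence: str) -> np.ndarray:
    """(length, L) matrix of match scores; unknown residues score 0 bits."""
    idx = np.array([AA_INDEX.get(c, -1) for c in sequence.upper()])
    em = np.hstack([profile.match_emissions, np.zeros((profile.length, 1))])
    return em[:, idx]


def score_local(profile: ProfileModel, sequence: str, sequence_id: str = "") -> DomainHit | None:
    """Best-scoring Smith-Waterman local alignment of ``sequence`` against the
    profile, with affine gap penalties.  Returns ``None`` when no alignment
    scores above zero (the local-alignment floor).

    Ties are broken deterministically: the maximal cell with the smallest
    sequence position, then smallest model position, wins, and the traceback
    prefers match over deletion over insertion.
    """
    if not sequence:
        raise ValidationError("sequence must be non-empty")
    m, L = profile.length, len(sequence)
    S = _emission_row(profile, sequence)
    go, ge = profile.gap_open, profile.gap_extend

    M = np.full((m + 1, L + 1), _NEG)
    Ix = np.full((m + 1, L + 1), _NEG)  # deletion: consumes model position
    Iy = np.full((m + 1, L + 1), _NEG)  # insertion: consumes sequence residue
    for i in range(1, m + 1):
        Ix[i] = np.maximum(M[i - 1] - go, Ix[i - 1] - ge)
        row_s = S[i - 1]
        for j in range(1, L + 1):
            diag = max(0.0, M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            M[i][j] = row_s[j - 1] + diag
            Iy[i][j] = max(M[i][j - 1] - go, Iy[i][j - 1] - ge)

    best = M[1:, 1:].max()
    if best <= 0:
        return None
    # smallest j (sequence end), then smallest i, among maximal cells
    js, iis = np.where(M[1:, 1:].T >= best - 1e-9)
    j, i = js[0] + 1, iis[0] + 1
    seq_end, model_end = j, i

    aligned = ["-"] * m
    state = "M"
    tol = 1e-9
    while True:
        if state == "M":
            aligned[i - 1] = sequence[j - 1].upper()
            prev = M[i][j] - S[i - 1][j - 1]
            i, j = i - 1, j - 1
            if prev <= tol:
                break
            if abs(M[i][j] - prev) <= tol:
                state = "M"
            elif abs(Ix[i][j] - prev) <= tol:
                state = "Ix"
            else:
                state = "Iy"
        elif state == "Ix":
            val = Ix[i][j]
            i -= 1
            state = "M" if abs(M[i][j] - go - val) <= tol else "Ix"
        else:  # Iy
            val = Iy[i][j]
            j -= 1
            state = "M" if abs(M[i][j] - go - val) <= tol else "Iy"
    seq_start, model_start = j + 1, i + 1

    coverage = (model_end - model_start + 1) / m
    e_value = None
    if profile.calibration is not None:
        e_value = evalue(profile, best, db_size=1)
    return DomainHit(
        sequence_id=sequence_id,
        score=float(best),
        e_value=e_value,
        seq_start=seq_start,
        seq_end=seq_end,
        model_start=model_start,
        model_end=model_end,
        model_coverage=coverage,
        model_aligned="".join(aligned),
    )


def batch_local_scores(profile: ProfileModel, sequences: Sequence[str]) -> np.ndarray:
    """Local-alignment scores (no traceback) for many sequences at once.

    Sequences are padded to a common length with a sentinel residue of very
    negative score, which cannot participate in an optimal local alignment, so
    padded scores equal unpadded ones.
    """
    if len(sequences) == 0:
        return np.zeros(0)
    m = profile.length
    go, ge = profile.gap_open, profile.gap_extend
    Lmax = max(len(s) for s in sequences)
    B = len(sequences)
    em = np.hstack(
        [profile.match_emissions, np.zeros((m, 1)), np.full((m, 1), _NEG)]
    )
    idx = np.full((B, Lmax), em.shape[1] - 1, dtype=int)  # pad sentinel
    for b, s in enumerate(sequences):
        idx[b, : len(s)] = [AA_INDEX.get(c, len(AMINO_ACIDS)) for c in s.upper()]

    M_prev = np.full((B, Lmax + 1), _NEG)
    Ix_prev = np.full((B, Lmax + 1), _NEG)
    Iy_prev = np.full((B, Lmax + 1), _NEG)
    best = np.zeros(B)
    for i in range(1, m + 1):
        S_row = em[i - 1][idx]  # (B, Lmax)
        Ix_cur = np.maximum(M_prev - go, Ix_prev - ge)
        M_cur = np.full((B, Lmax + 1), _NEG)
        Iy_cur = np.full((B, Lmax + 1), _NEG)
        for j in range(1, Lmax + 1):
            diag = np.maximum.reduce(
                [M_prev[:, j - 1], Ix_prev[:, j - 1], Iy_prev[:, j - 1]]
            )
            np.maximum(diag, 0.0, out=diag)
            M_cur[:, j] = S_row[:, j - 1] + diag
            Iy_cur[:, j] = np.maximum(M_cur[:, j - 1] - go, Iy_cur[:, j - 1] - ge)
        np.maximum(best, M_cur.max(axis=1), out=best)
        M_prev, Ix_prev, Iy_prev = M_cur, Ix_cur, Iy_cur
    return best


# ---------------------------------------------------------------------------
# E-value calibration
# ---------------------------------------------------------------------------


def fit_gumbel(scores: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood Gumbel fit; returns ``(mu, lambda)``."""
    scores = np.asarray(scores, dtype=float)
    if scores.std() < 1e-9:
        raise ValidationError(
            "degenerate score variance; increase the number of decoy sequences"
        )
    mu, beta = gumbel_r.fit(scores)
    return float(mu), float(1.0 / beta)


def evalue(profile: ProfileModel, score: float, db_size: int) -> float:
    """Expected number of hits at >= ``score`` in ``db_size`` sequences under
    the profile's Gumbel calibration."""
    if profile.calibration is None:
        raise ValidationError("profile is not calibrated")
    mu, lam = profile.calibration
    # P(S >= s) = 1 - exp(-exp(-lam (s - mu)))
    tail = -np.expm1(-np.exp(-lam * (score - mu)))
    return float(db_size * tail)


def calibrate_evalue(
    profile: ProfileModel,
    decoy_count: int = 1000,
    rng_seed: int = 0,
    decoy_length: int = 300,
) -> ProfileModel:
    """Fit the Gumbel null score distribution on random background sequences
    and return a calibrated copy of the profile."""
    if decoy_count < 100:
        raise ValidationError("decoy_count must be >= 100 for a stable fit")
    rng = np.random.default_rng(rng_seed)
    letters = np.array(list(AMINO_ACIDS))
    decoys = [
        "".join(rng.choice(letters, size=decoy_length, p=profile.background))
        for _ in range(decoy_count)
    ]
    scores = batch_local_scores(profile, decoys)
    mu, lam = fit_gumbel(scores)
    return replace(profile, calibration=(mu, lam))


# ---------------------------------------------------------------------------
# two-pass identification
# ---------------------------------------------------------------------------


def _scan(
    profile: ProfileModel,
    proteome: Mapping[str, str],
    e_cut: float,
    db_size: int,
) -> list[DomainHit]:
    """Score every sequence, keep those under ``e_cut``, traceback survivors."""
    ids = list(proteome)
    scores = batch_local_scores(profile, [proteome[i] for i in ids])
    hits = []
    for name, sc in zip(ids, scores):
        if sc <= 0:
            continue
        e = evalue(profile, sc, db_size)
        if e >= e_cut:
            continue
        hit = score_local(profile, proteome[name], sequence_id=name)
        if hit is not None:
            hits.append(replace(hit, e_value=e))
    hits.sort(key=lambda h: (h.e_value, h.sequence_id))
    return hits


def two_pass_identify(
    seed_profile: ProfileModel,
    proteome: Mapping[str, str],
    config: SearchConfig = SearchConfig(),
) -> tuple[list[DomainHit], ProfileModel]:
    """Identify family members with a seed profile, rebuild a species-specific
    profile from the pass-one hit segments, and re-search the proteome.

    Final hits must satisfy ``e_value < e_threshold`` and
    ``model_coverage >= min_model_coverage`` under the species-specific
    profile; pass-one-only candidates that fail pass two are dropped.
    """
    if not proteome:
        raise ValidationError("proteome must be non-empty")
    db_size = len(proteome)

    pass1_profile = seed_profile
    if pass1_profile.calibration is None:
        pass1_profile = calibrate_evalue(
            pass1_profile,
            decoy_count=config.n_calibration_shuffles,
            rng_seed=config.rng_seed,
            decoy_length=config.calibration_length,
        )
    pass1_hits = _scan(pass1_profile, proteome, config.pass1_e_threshold, db_size)
    if not pass1_hits:
        raise PipelineError("no candidates: pass-one search found zero hits")

    segments = [h.model_aligned for h in pass1_hits]
    species_profile = build_profile(
        segments,
        background=pass1_profile.background,
        gap_open=pass1_profile.gap_open,
        gap_extend=pass1_profile.gap_extend,
    )
    species_profile = calibrate_evalue(
        species_profile,
        decoy_count=config.n_calibration_shuffles,
        rng_seed=config.rng_seed + 1,
        decoy_length=config.calibration_length,
    )

    pass2_hits = _scan(species_profile, proteome, config.e_threshold, db_size)
    final = [h for h in pass2_hits if h.model_coverage >= config.min_model_coverage]
    return final, species_profile


# ---------------------------------------------------------------------------
# profile text serialization (versioned)
# ---------------------------------------------------------------------------

_PROFILE_FORMAT_VERSION = 1


def save_profile(profile: ProfileModel, path) -> None:
    """Write the profile in a small versioned text format."""
    with open(path, "w") as fh:
        fh.write(f"#trihelix-profile v{_PROFILE_FORMAT_VERSION}\n")
        fh.write(f"length\t{profile.length}\n")
        fh.write(f"gap_open\t{profile.gap_open}\n")
        fh.write(f"gap_extend\t{profile.gap_extend}\n")
        if profile.calibration is not None:
            fh.write(f"calibration\t{float(profile.calibration[0]):.17g}\t{float(profile.calibration[1]):.17g}\n")
        fh.write("background\t" + "\t".join(f"{float(x):.17g}" for x in profile.background) + "\n")
        fh.write("alphabet\t" + AMINO_ACIDS + "\n")
        for row in profile.match_emissions:
            fh.write("emit\t" + "\t".join(f"{float(x):.17g}" for x in row) + "\n")


def load_profile(path) -> ProfileModel:
    meta: dict[str, str] = {}
    rows = []
    background = None
    calibration = None
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#trihelix-profile"):
            raise ValidationError("not a trihelix profile file")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "emit":
                rows.append([float(x) for x in parts[1:]])
            elif parts[0] == "background":
                background = np.array([float(x) for x in parts[1:]])
            elif parts[0] == "calibration":
                calibration = (float(parts[1]), float(parts[2]))
            else:
                meta[parts[0]] = parts[1]
    return ProfileModel(
        match_emissions=np.array(rows),
        background=background,
        gap_open=float(meta["gap_open"]),
        gap_extend=float(meta["gap_extend"]),
        calibration=calibration,
    )
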