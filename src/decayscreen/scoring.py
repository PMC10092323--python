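"""Pairwise similarity scoring of orthogroup members against the focal sequence.

Replicates the within-orthogroup all-vs-focal search design with affine-gap
Smith-Waterman local alignment and Karlin-Altschul bit-score conversion
S' = (lambda*S - ln K) / ln 2. BLAST's seeding/extension heuristics and
composition-based statistics are deliberately not reproduced: downstream
detectability depends only on (L, R, threshold).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

GAP_CHAR = "-"
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

# published gapped Karlin-Altschul constants for BLOSUM62, gap open 11 / extend 1
BLOSUM62_GAPPED_LAMBDA = 0.267
BLOSUM62_GAPPED_K = 0.041


class SequenceFormatError(ValueError):
    pass


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix, affine gap penalties, and Karlin-Altschul constants.

    Gap penalties follow the BLAST convention: a gap of length k costs
    gap_open + gap_extend * k.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    ka_lambda: float = BLOSUM62_GAPPED_LAMBDA
    ka_k: float = BLOSUM62_GAPPED_K
    matrix: substitution_matrices.Array = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.ka_lambda <= 0 or self.ka_k <= 0:
            raise ValueError("Karlin-Altschul lambda and K must be > 0")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be nonnegative")
        object.__setattr__(
            self, "matrix", substitution_matrices.load(self.matrix_name)
        )

    def bitscore(self, raw_score: float) -> float:
        """Convert a raw alignment score to bits."""
        return (self.ka_lambda * raw_score - np.log(self.ka_k)) / np.log(2.0)

    def aligner(self) -> Align.PairwiseAligner:
        a = Align.PairwiseAligner()
        a.mode = "local"
        a.substitution_matrix = self.matrix
        # Biopython charges open_gap_score for the first gap position and
        # extend_gap_score thereafter; BLAST charges open + extend*k.
        a.open_gap_score = -(self.gap_open + self.gap_extend)
        a.extend_gap_score = -self.gap_extend
        return a


def strip_gaps(aligned_seq: str) -> str:
    """Remove gap characters, validating the amino-acid alphabet."""
    for ch in aligned_seq:
        if ch != GAP_CHAR and ch.upper() not in VALID_RESIDUES:
            raise SequenceFormatError(f"invalid residue {ch!r} in aligned sequence")
    return aligned_seq.replace(GAP_CHAR, "").upper()


def local_align_bitscore(
    query: str, target: str, scheme: ScoringScheme | None = None
) -> tuple[float, float]:
    """Optimal local-alignment raw score and bit-score for a sequence pair."""
    if not query or not target:
        raise ValueError("cannot align an empty sequence")
    scheme = scheme or ScoringScheme()
    raw = float(scheme.aligner().score(query, target))
    return raw, scheme.bitscore(raw)


def evalue(bitscore: float, query_len: int, db_len: int) -> float:
    """Expected chance hits at or above a bit-score: E = m * n * 2^(-S')."""
    if query_len < 1 or db_len < 1:
        raise ValueError("query and database lengths must be >= 1")
    return float(query_len) * float(db_len) * float(2.0 ** (-bitscore))


def score_orthogroup(
    og_alignment: dict[str, str],
    focal_id: str,
    scheme: ScoringScheme | None = None,
    og_id: str = "",
) -> pd.DataFrame:
    """Bit-scores of every orthogroup member against the focal sequence.

    Sequences are gap-stripped first. The focal row carries the focal
    self-score (the empirical L). Rows are (og_id, species_id, bitscore).
    """
    scheme = scheme or ScoringScheme()
    if focal_id not in og_alignment:
        raise KeyError(f"orthogroup {og_id or '<unnamed>'}: focal sequence {focal_id!r} missing")
    focal_seq = strip_gaps(og_alignment[focal_id])
    if not focal_seq:
        raise SequenceFormatError(
            f"orthogroup {og_id or '<unnamed>'}: focal sequence is all gaps"
        )
    rows = []
    for sp in sorted(og_alignment):
        seq = strip_gaps(og_alignment[sp])
        if not seq:
            rows.append((og_id, sp, np.nan))
            continue
        _, bits = local_align_bitscore(seq, focal_seq, scheme)
        rows.append((og_id, sp, bits))
    df = pd.DataFrame(rows, columns=["og_id", "species_id", "bitscore"])
    df["og_id"] = df["og_id"].astype("string")
    df["species_id"] = df["species_id"].astype("string")
    return df


def score_orthogroups(
    alignments: dict[str, dict[str, str]],
    focal_id: str,
    scheme: ScoringScheme | None = None,
) -> pd.DataFrame:
    parts = [
        score_orthogroup(aln, focal_id, scheme, og_id=og)
        for og, aln in sorted(alignments.items())
    ]
    return pd.concat(parts, ignore_index=True)
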