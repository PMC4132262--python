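"""T20-style humanness scoring of antibody V regions.

The humanness of a V-region sequence is summarized as the mean percent
identity of its top 20 global-alignment matches in a database of human
antibody V sequences — computed full-length and framework-only (CDR
positions masked from the query).  At desk scale the candidate-retrieval
step of the original tool is replaced by an exhaustive pairwise scan over
the database, which gives the identical top-k result.

Identity is ``100 · matches / alignment_length`` with the alignment length
counting gap columns; alignment is global with match +1, mismatch 0 and
affine gaps (open −10 for the first gap position, −1 for each further one).
Absolute scores are database-dependent: scores computed against a synthetic
database are comparable to each other, not to scores from any other
database.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align

from .antibody_model import VRegionSequence


class HumannessError(ValueError):
    pass


@dataclass(frozen=True)
class HumannessResult:
    t20_full: float | None
    t20_framework: float | None
    top_matches: tuple[tuple[str, float], ...]   # (db_id, identity) desc

    def __post_init__(self) -> None:
        for score in (self.t20_full, self.t20_framework):
            if score is not None and not (0.0 <= score <= 100.0):
                raise HumannessError(f"score {score} outside [0, 100]")
        if len(self.top_matches) > 20:
            raise HumannessError("top_matches longer than 20")


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    return aligner


def pairwise_identity(a: str, b: str) -> float:
    """Percent identity of the optimal global alignment of two sequences."""
    if not a or not b:
        raise HumannessError("empty sequence")
    aln = _aligner().align(a, b)[0]
    counts = aln.counts()
    return 100.0 * counts.identities / aln.length


def t20_score(query: VRegionSequence | str, db, framework_only: bool = False,
              top_k: int = 20) -> HumannessResult:
    """Mean percent identity of the query's top-k database matches.

    ``db`` is a sequence of :class:`VRegionSequence` (or plain strings);
    with fewer than k entries the mean runs over all of them.
    ``framework_only`` masks CDR positions from the query (requires region
    annotations) before aligning.
    """
    entries = list(db)
    if not entries:
        raise HumannessError("empty database")
    if framework_only:
        if isinstance(query, str):
            raise HumannessError("framework_only needs region annotations")
        qseq = query.framework_only()
    else:
        qseq = query if isinstance(query, str) else query.residues
    idents = []
    for i, entry in enumerate(entries):
        seq = entry if isinstance(entry, str) else entry.residues
        name = f"db{i}" if isinstance(entry, str) else (entry.name or f"db{i}")
        idents.append((name, pairwise_identity(qseq, seq)))
    idents.sort(key=lambda t: -t[1])
    top = idents[:min(top_k, len(idents))]
    score = float(np.mean([v for _, v in top]))
    return HumannessResult(
        t20_full=None if framework_only else score,
        t20_framework=score if framework_only else None,
        top_matches=tuple(top),
    )
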