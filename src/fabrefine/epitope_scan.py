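"""Matrix-based MHC class II T-cell epitope scanning.

MHC-II ligands are ~15-mer peptides whose affinity is dominated by a 9-mer
binding core.  Each 15-residue window of the query is scored by its best
9-mer core under a position-specific scoring matrix (9 positions × 20 amino
acids); windows at or above the "moderate" threshold are reported as
potential epitopes.  This transparent PSSM scanner stands in for trained
neural predictors: the downstream decision only needs a binary
"moderate-affinity epitope present" flag, and real matrices can be supplied
via CSV (9 rows × 20 amino-acid columns).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .antibody_model import AA1, PointMutation

CORE_LEN = 9
WINDOW_LEN = 15


class EpitopeError(ValueError):
    pass


@dataclass(frozen=True)
class EpitopeHit:
    start: int          # 1-based window start
    core_start: int     # 1-based core start (inclusive; core end exclusive)
    peptide: str
    score: float
    affinity_class: str  # "high" | "moderate"

    @property
    def core_end(self) -> int:
        """Exclusive 1-based end of the 9-mer core."""
        return self.core_start + CORE_LEN


def load_matrix(path_or_buffer) -> pd.DataFrame:
    """Read a 9 × 20 scoring matrix CSV (columns = amino acids)."""
    df = pd.read_csv(path_or_buffer)
    df = df[[c for c in df.columns if c in set(AA1)]]
    return _validate_matrix(df)


def _validate_matrix(matrix) -> pd.DataFrame:
    if isinstance(matrix, np.ndarray):
        if matrix.shape != (CORE_LEN, len(AA1)):
            raise EpitopeError(f"matrix must be 9x20, got {matrix.shape}")
        matrix = pd.DataFrame(matrix, columns=list(AA1))
    if sorted(matrix.columns) != sorted(AA1):
        raise EpitopeError("matrix columns must be the 20 amino acids")
    if len(matrix) != CORE_LEN:
        raise EpitopeError(f"matrix must have 9 rows, got {len(matrix)}")
    if not np.all(np.isfinite(matrix.to_numpy())):
        raise EpitopeError("matrix contains non-finite scores")
    return matrix


def _core_score(core: str, mat: np.ndarray, col: dict[str, int]) -> float:
    return float(sum(mat[i, col[aa]] for i, aa in enumerate(core)))


def scan_epitopes(seq: str, matrix, thresholds: tuple[float, float]
                  ) -> list[EpitopeHit]:
    """Score every 15-mer window by its best 9-mer core (leftmost tie).

    ``thresholds`` is (high, moderate); hits are windows scoring at or above
    the moderate threshold, in sequence order.  Sequences of length 9–14
    are scored as a single window.
    """
    seq = str(seq).upper()
    if len(seq) < CORE_LEN:
        raise EpitopeError(f"sequence shorter than {CORE_LEN}")
    bad = set(seq) - set(AA1)
    if bad:
        raise EpitopeError(f"non-standard amino acids: {sorted(bad)}")
    df = _validate_matrix(matrix)
    mat = df.to_numpy(dtype=float)
    col = {aa: i for i, aa in enumerate(df.columns)}
    high, moderate = thresholds
    window = WINDOW_LEN if len(seq) >= WINDOW_LEN else len(seq)
    hits: list[EpitopeHit] = []
    for start in range(len(seq) - window + 1):
        pep = seq[start:start + window]
        best_score, best_off = -np.inf, 0
        for off in range(window - CORE_LEN + 1):
            score = _core_score(pep[off:off + CORE_LEN], mat, col)
            if score > best_score:           # strict: leftmost tie wins
                best_score, best_off = score, off
        if best_score >= moderate:
            hits.append(EpitopeHit(
                start=start + 1,
                core_start=start + best_off + 1,
                peptide=pep,
                score=best_score,
                affinity_class="high" if best_score >= high else "moderate",
            ))
    return hits


def epitope_overlap(hits: list[EpitopeHit], muts: list[PointMutation]
                    ) -> list[tuple[PointMutation, EpitopeHit]]:
    """(mutation, hit) pairs where the mutated position falls inside the
    hit's 9-mer core ([core_start, core_start+9), 1-based, half-open).
    Positions must share the hit's coordinate system."""
    return [(m, h) for m in muts for h in hits
            if h.core_start <= m.position < h.core_end]
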