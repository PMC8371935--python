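"""Protein scoring scheme shared by the search and alignment stages.

BLOSUM62 with affine gaps (open 11, extend 1 — the canonical translated-
search defaults) scores all local search work; the codon-alignment stage
uses the slightly milder open 10 / extend 1 scheme conventional for global
protein alignment.  Karlin-Altschul statistics use the standard gapped
BLOSUM62(11,1) parameters.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

# Gapped Karlin-Altschul parameters for BLOSUM62, gap open 11 / extend 1.
GAPPED_LAMBDA = 0.267
GAPPED_K = 0.041

# Gap costs expressed as: a gap of length L costs OPEN + L * EXT.
GAP_OPEN = 11
GAP_EXT = 1
GLOBAL_GAP_OPEN = 10
GLOBAL_GAP_EXT = 1

_B62 = substitution_matrices.load("BLOSUM62")
AA_ALPHABET: str = str(_B62.alphabet)  # 'ARNDCQEGHILKMFPSTWYVBZX*'
AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}
_X = AA_INDEX["X"]

BLOSUM62 = np.array(_B62, dtype=np.int16)


def encode_protein(seq: str) -> np.ndarray:
    """Encode a protein string as BLOSUM62 row indices (unknowns -> X)."""
    return np.fromiter(
        (AA_INDEX.get(c, _X) for c in seq.upper()), dtype=np.int8, count=len(seq)
    )


def bit_score(raw_score: float) -> float:
    return (GAPPED_LAMBDA * raw_score - np.log(GAPPED_K)) / np.log(2.0)
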