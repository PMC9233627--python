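"""Codon state space under the universal genetic code, stop codons excluded.

The substitution process walks over sequences of *sense* codons: the three
stop codons (TAA, TAG, TGA) are prohibited, leaving 61 states per site.
Codons are indexed lexicographically in the DNA alphabet A < C < G < T, so
index 0 is AAA and index 60 is TTT-minus-stops; this ordering is fixed and
documented so that rate matrices and substitution histories are comparable
across runs.

Besides the index maps, this module provides the two predicates the rate law
needs (transition vs transversion, synonymous vs nonsynonymous) and the
enumeration of single-nucleotide neighbours of a codon. Multi-nucleotide
events have rate zero, so the neighbours are the only accessible states:
at most 9 per codon, fewer when a stop codon would be produced.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

NUCLEOTIDES = "ACGT"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def is_transition(x: str, y: str) -> bool:
    """True iff the point mutation x -> y is a transition (A<->G or C<->T)."""
    if x not in _PURINES | _PYRIMIDINES or y not in _PURINES | _PYRIMIDINES:
        raise ValueError(f"invalid nucleotide in pair ({x!r}, {y!r})")
    if x == y:
        raise ValueError(f"transition/transversion undefined for identical nucleotides {x!r}")
    return {x, y} <= _PURINES or {x, y} <= _PYRIMIDINES


@dataclass(frozen=True)
class GeneticCode:
    """The universal genetic code restricted to its 61 sense codons."""

    codon_to_index: dict[str, int] = field(repr=False)
    index_to_codon: tuple[str, ...] = field(repr=False)
    amino_acid_of: dict[str, str] = field(repr=False)
    stop_set: frozenset[str] = STOP_CODONS

    @classmethod
    def standard(cls) -> "GeneticCode":
        codons = ["".join(c) for c in itertools.product(NUCLEOTIDES, repeat=3)]
        sense = [c for c in codons if c not in STOP_CODONS]
        return cls(
            codon_to_index={c: i for i, c in enumerate(sense)},
            index_to_codon=tuple(sense),
            amino_acid_of={c: str(Seq(c).translate()) for c in sense},
        )

    @property
    def n_states(self) -> int:
        return len(self.index_to_codon)

    def _require_sense(self, codon: str) -> None:
        if codon in self.stop_set:
            raise ValueError(f"stop codon {codon} is outside the state space")
        if codon not in self.codon_to_index:
            raise ValueError(f"invalid codon {codon!r}")

    def is_synonymous(self, i: str, j: str) -> bool:
        """True iff sense codons i != j encode the same amino acid."""
        self._require_sense(i)
        self._require_sense(j)
        if i == j:
            raise ValueError(f"synonymy undefined for identical codons {i}")
        return self.amino_acid_of[i] == self.amino_acid_of[j]

    def neighbors(self, codon: str) -> list[tuple[str, int, str, str]]:
        """Sense codons one point mutation away from `codon`.

        Returns (neighbour codon, position 1-3, from-nucleotide,
        to-nucleotide) tuples, enumerated position-major then by target
        nucleotide in A < C < G < T order. This enumeration order is the
        event order used when drawing the next state of the jump chain.
        """
        self._require_sense(codon)
        out = []
        for pos in range(3):
            x = codon[pos]
            for y in NUCLEOTIDES:
                if y == x:
                    continue
                j = codon[:pos] + y + codon[pos + 1:]
                if j in self.stop_set:
                    continue
                out.append((j, pos + 1, x, y))
        return out


STANDARD_CODE = GeneticCode.standard()

#: Number of sense codons (the per-site state-space size).
N_CODONS = STANDARD_CODE.n_states

# ---------------------------------------------------------------------------
# Integer lookup tables used by the vectorized rate machinery and the
# jit-compiled jump-chain kernel. All are derived from STANDARD_CODE.
# ---------------------------------------------------------------------------

NUC_INDEX = {n: i for i, n in enumerate(NUCLEOTIDES)}

#: (61, 3) nucleotide index of each codon position.
CODON_NUCS = np.array(
    [[NUC_INDEX[n] for n in codon] for codon in STANDARD_CODE.index_to_codon],
    dtype=np.int64,
)

_MAX_NEIGHBORS = 9


def _build_neighbor_tables():
    code = STANDARD_CODE
    n = code.n_states
    counts = np.zeros(n, dtype=np.int64)
    to_state = np.full((n, _MAX_NEIGHBORS), -1, dtype=np.int64)
    position = np.zeros((n, _MAX_NEIGHBORS), dtype=np.int64)   # 0-based 0..2
    from_nuc = np.zeros((n, _MAX_NEIGHBORS), dtype=np.int64)
    to_nuc = np.zeros((n, _MAX_NEIGHBORS), dtype=np.int64)
    syn = np.zeros((n, _MAX_NEIGHBORS), dtype=np.bool_)
    ts = np.zeros((n, _MAX_NEIGHBORS), dtype=np.bool_)
    for i, codon in enumerate(code.index_to_codon):
        for k, (j, pos, x, y) in enumerate(code.neighbors(codon)):
            to_state[i, k] = code.codon_to_index[j]
            position[i, k] = pos - 1
            from_nuc[i, k] = NUC_INDEX[x]
            to_nuc[i, k] = NUC_INDEX[y]
            syn[i, k] = code.is_synonymous(codon, j)
            ts[i, k] = is_transition(x, y)
            counts[i] = k + 1
    return counts, to_state, position, from_nuc, to_nuc, syn, ts


(
    NEIGHBOR_COUNTS,
    NEIGHBOR_STATE,
    NEIGHBOR_POS,
    NEIGHBOR_FROM,
    NEIGHBOR_TO,
    NEIGHBOR_SYN,
    NEIGHBOR_TS,
) = _build_neighbor_tables()
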