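"""Genetic code tables and in-frame codon alignments.

The unit of data throughout the package is the *sense-codon state*: an
integer index into the ordered list of non-stop codons of a genetic code
(61 states under the universal code).  State indices are assigned by
alphabetical codon order (``AAA`` = 0, ``AAC`` = 1, ...) and are stable
across runs and platforms.  Missing data (gaps, ambiguity codes, stop
triplets masked at read time) is encoded as :data:`MISSING`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
NUC_INDEX = {n: i for i, n in enumerate(NUCLEOTIDES)}

#: sentinel state for missing / masked codons
MISSING: int = -1


@dataclass(frozen=True)
class GeneticCode:
    """A genetic code as an ordered sense-codon state space.

    Sense codons and stop codons partition the 64 triplets.  Alongside the
    translation table the object precomputes everything codon substitution
    models need: the nucleotide composition of each sense codon and the set
    of single-nucleotide neighbour pairs with their synonymous /
    non-synonymous status.
    """

    name: str
    sense_codons: tuple[str, ...]
    stop_codons: frozenset[str]
    codon_to_aa: dict[str, str]
    #: (n_sense, 3) nucleotide index of each codon position
    codon_nucs: np.ndarray = field(repr=False)
    state_of: dict[str, int] = field(repr=False)

    @classmethod
    def from_ncbi_id(cls, table_id: int = 1) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[table_id]
        stops = frozenset(table.stop_codons)
        all_codons = ["".join(c) for c in itertools.product(NUCLEOTIDES, repeat=3)]
        sense = tuple(c for c in all_codons if c not in stops)
        if len(sense) + len(stops) != 64:
            raise ValueError("sense and stop codons must partition the 64 triplets")
        nucs = np.array([[NUC_INDEX[n] for n in c] for c in sense], dtype=np.int64)
        return cls(
            name=table.names[0],
            sense_codons=sense,
            stop_codons=stops,
            codon_to_aa={c: table.forward_table[c] for c in sense},
            codon_nucs=nucs,
            state_of={c: i for i, c in enumerate(sense)},
        )

    @property
    def n_states(self) -> int:
        return len(self.sense_codons)

    def translate_state(self, state: int) -> str:
        return self.codon_to_aa[self.sense_codons[state]]

    def single_step_pairs(self):
        """Arrays describing all ordered sense-codon pairs one nucleotide apart.

        Returns ``(i, j, pos, from_nuc, to_nuc, is_syn)`` where ``pos`` is the
        codon position (0..2) that differs and ``is_syn`` flags synonymous
        exchanges.  Cached after first call.
        """
        return _single_step_pairs(self)


def _single_step_pairs(code: GeneticCode):
    if not hasattr(code, "_pairs"):
        n = code.n_states
        nucs = code.codon_nucs
        ii, jj, pp, fa, ta, syn = [], [], [], [], [], []
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                diff = np.nonzero(nucs[i] != nucs[j])[0]
                if len(diff) != 1:
                    continue
                k = int(diff[0])
                ii.append(i)
                jj.append(j)
                pp.append(k)
                fa.append(int(nucs[i, k]))
                ta.append(int(nucs[j, k]))
                syn.append(code.translate_state(i) == code.translate_state(j))
        pairs = (
            np.array(ii),
            np.array(jj),
            np.array(pp),
            np.array(fa),
            np.array(ta),
            np.array(syn, dtype=bool),
        )
        object.__setattr__(code, "_pairs", pairs)
    return code._pairs


_UNIVERSAL: GeneticCode | None = None


def universal_code() -> GeneticCode:
    """The standard (universal) genetic code with 61 sense codons."""
    global _UNIVERSAL
    if _UNIVERSAL is None:
        _UNIVERSAL = GeneticCode.from_ncbi_id(1)
    return _UNIVERSAL


class CodonAlignment:
    """An in-frame codon alignment indexed by sense-codon state.

    Parameters
    ----------
    labels :
        Unique taxon labels, one per row.
    states :
        Integer array of shape ``(n_taxa, L)`` with sense-codon states or
        :data:`MISSING`.
    code :
        The genetic code defining the state space.
    """

    def __init__(self, labels, states, code: GeneticCode | None = None):
        self.code = code or universal_code()
        self.labels = list(labels)
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("taxon labels must be unique")
        self.states = np.asarray(states, dtype=np.int16)
        if self.states.ndim != 2:
            raise ValueError("states must be a 2-D (taxa x codons) array")
        if len(self.labels) != self.states.shape[0]:
            raise ValueError("one label per sequence required")
        bad = (self.states >= self.code.n_states) | (
            (self.states < 0) & (self.states != MISSING)
        )
        if np.any(bad):
            raise ValueError("states must be sense-codon indices or MISSING")

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_sequences(cls, seqs: dict[str, str], code: GeneticCode | None = None,
                       on_stop: str = "mask"):
        """Build from label -> nucleotide string mapping.

        Triplets with gaps or ambiguity codes become missing; stop codons are
        masked (``on_stop='mask'``) or rejected (``on_stop='error'``).
        Returns ``(alignment, n_masked)``.
        """
        code = code or universal_code()
        labels = list(seqs)
        lens = {len(s) for s in seqs.values()}
        if len(lens) != 1:
            raise ValueError("all sequences must have equal length")
        (nt_len,) = lens
        if nt_len % 3 != 0:
            raise ValueError("sequence length must be divisible by 3")
        L = nt_len // 3
        states = np.full((len(labels), L), MISSING, dtype=np.int16)
        n_masked = 0
        for r, lab in enumerate(labels):
            s = seqs[lab].upper().replace("U", "T")
            for c in range(L):
                triplet = s[3 * c: 3 * c + 3]
                if triplet in code.state_of:
                    states[r, c] = code.state_of[triplet]
                elif triplet in code.stop_codons:
                    if on_stop == "error":
                        raise ValueError(
                            f"stop codon {triplet} in record {lab!r} at codon {c + 1}"
                        )
                    n_masked += 1
                else:
                    n_masked += 1
        return cls(labels, states, code), n_masked

    # -- basic protocol ----------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return self.states.shape[0]

    @property
    def n_codons(self) -> int:
        return self.states.shape[1]

    def row(self, label: str) -> np.ndarray:
        return self.states[self.labels.index(label)]

    def column(self, site: int) -> np.ndarray:
        """Codon states of 1-based codon position ``site``."""
        if not 1 <= site <= self.n_codons:
            raise IndexError(f"site {site} outside 1..{self.n_codons}")
        return self.states[:, site - 1]

    def subset(self, labels) -> "CodonAlignment":
        idx = [self.labels.index(l) for l in labels]
        return CodonAlignment(labels, self.states[idx], self.code)

    def to_sequences(self) -> dict[str, str]:
        """Inverse of :meth:`from_sequences`; missing codons become ``---``."""
        out = {}
        for r, lab in enumerate(self.labels):
            parts = [
                self.code.sense_codons[s] if s != MISSING else "---"
                for s in self.states[r]
            ]
            out[lab] = "".join(parts)
        return out

    def __eq__(self, other):
        return (
            isinstance(other, CodonAlignment)
            and self.labels == other.labels
            and np.array_equal(self.states, other.states)
        )

    def __repr__(self):
        return f"CodonAlignment({self.n_taxa} taxa x {self.n_codons} codons)"
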