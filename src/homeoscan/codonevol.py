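"""Codon-aware divergence estimation and subgenome attribution.

Implements the Nei–Gojobori (1986) counting method with Jukes–Cantor
correction for synonymous (dS) and nonsynonymous (dN) divergence between
in-frame coding sequences, translation-guided codon alignment, the
lower-dS rule that attributes the member of a homeolog pair closer to the
extant progenitor to subgenome 1, and the coalescent conversion of dS to a
divergence time in generations (T = dS / 2mu).

Conventions for NG86 here:

* per-codon synonymous site fractions come from single-step mutation
  enumeration; mutations that create a stop codon are excluded from the
  site denominator, so S + N = 3 x (compared codons) exactly;
* codons differing at several positions are scored by averaging synonymous
  and nonsynonymous difference counts over all shortest mutational paths;
  paths that pass through a stop codon are excluded (if every path is
  blocked, all paths are used as a deterministic fallback);
* pS = Sd / S-bar with sites averaged over the two sequences, and
  dS = -(3/4) ln(1 - (4/3) pS); pS >= 3/4 leaves dS undefined.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))
BASES = "ACGT"

JC_MAX_P = 0.75


def translate_codon(codon: str) -> str:
    """Amino acid for a sense codon, ``*`` for a stop."""
    return CODON_TO_AA.get(codon, "*")


@lru_cache(maxsize=None)
def synonymous_sites(codon: str) -> float:
    """NG86 synonymous site count of one codon (0..3).

    Each position contributes the fraction of its non-stop single-base
    changes that preserve the amino acid.
    """
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r} has no site counts")
    aa = CODON_TO_AA[codon]
    total = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            valid += 1
            if CODON_TO_AA[alt] == aa:
                syn += 1
        if valid:
            total += syn / valid
    return total


@lru_cache(maxsize=None)
def codon_differences(c1: str, c2: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) difference counts between two codons.

    Averages over all shortest mutational paths; paths through stop codons
    are excluded.  Falls back to all paths if every one is blocked.
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order: tuple[int, ...], allow_stops: bool) -> Optional[tuple[float, float]]:
        sd = nd = 0.0
        cur = c1
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and not allow_stops:
                return None
            if translate_codon(nxt) == translate_codon(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        return sd, nd

    paths = [walk(order, False) for order in itertools.permutations(diff_pos)]
    valid = [p for p in paths if p is not None]
    if not valid:
        valid = [walk(order, True) for order in itertools.permutations(diff_pos)]
    sd = float(np.mean([p[0] for p in valid]))
    nd = float(np.mean([p[1] for p in valid]))
    return sd, nd


def jukes_cantor(p: float) -> Optional[float]:
    """JC69 multiple-hit correction; None when p >= 3/4."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= JC_MAX_P:
        return None
    if p == 0.0:
        return 0.0
    return -0.75 * float(np.log(1.0 - 4.0 * p / 3.0))


@dataclass
class Ng86Result:
    """Site and difference counts plus corrected rates for one sequence pair."""

    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: Optional[float]
    dN: Optional[float]

    @property
    def defined(self) -> bool:
        return self.dS is not None and self.dN is not None


def ng86(columns: Sequence[tuple[str, str]]) -> Ng86Result:
    """NG86 estimate from paired, ungapped codon columns.

    Parameters
    ----------
    columns
        Sequence of ``(codon_a, codon_b)`` pairs; both must be sense codons.
    """
    if not columns:
        raise ValueError("ng86 requires at least one ungapped codon column")
    s_a = s_b = sd = nd = 0.0
    for ca, cb in columns:
        s_a += synonymous_sites(ca)
        s_b += synonymous_sites(cb)
        d = codon_differences(ca, cb)
        sd += d[0]
        nd += d[1]
    s_bar = (s_a + s_b) / 2.0
    n_bar = 3.0 * len(columns) - s_bar
    p_s = sd / s_bar if s_bar > 0 else 0.0
    p_n = nd / n_bar if n_bar > 0 else 0.0
    return Ng86Result(
        S=s_bar,
        N=n_bar,
        Sd=sd,
        Nd=nd,
        pS=p_s,
        pN=p_n,
        dS=jukes_cantor(p_s),
        dN=jukes_cantor(p_n),
    )


def ng86_sequences(a: str, b: str) -> Ng86Result:
    """NG86 on two equal-length, in-frame coding sequences (no gaps)."""
    if len(a) != len(b) or len(a) % 3:
        raise ValueError("sequences must be equal length and in frame")
    cols = [(a[i : i + 3], b[i : i + 3]) for i in range(0, len(a), 3)]
    return ng86(cols)


# ---------------------------------------------------------------------------
# ORF handling and translation-guided codon alignment


class FrameshiftError(ValueError):
    """Raised when no ORF of the required length can be found."""


def longest_orf(seq: str, min_codons: int = 50) -> tuple[int, int]:
    """Locate the longest stop-free stretch of codons across forward frames.

    Returns ``(start, n_codons)`` in nucleotide coordinates.  Raises
    :class:`FrameshiftError` if the longest stretch is shorter than
    ``min_codons``.
    """
    seq = seq.upper()
    best = (0, 0)
    for frame in range(3):
        start = frame
        i = frame
        while i + 3 <= len(seq):
            codon = seq[i : i + 3]
            if codon in STOP_CODONS or any(c not in BASES for c in codon):
                n = (i - start) // 3
                if n > best[1]:
                    best = (start, n)
                start = i + 3
            i += 3
        n = (i - start) // 3
        if n > best[1]:
            best = (start, n)
    if best[1] < min_codons:
        raise FrameshiftError(
            f"longest ORF has {best[1]} codons (< {min_codons})"
        )
    return best


_protein_aligner: Optional[PairwiseAligner] = None


def _get_protein_aligner() -> PairwiseAligner:
    global _protein_aligner
    if _protein_aligner is None:
        aligner = PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -10.0
        aligner.extend_gap_score = -0.5
        _protein_aligner = aligner
    return _protein_aligner


def align_codons(a: str, b: str, min_codons: int = 50) -> list[tuple[str, str]]:
    """Translation-guided codon alignment of the longest ORFs of two sequences.

    The ORFs are translated, globally aligned at the protein level, and the
    alignment is mapped back to codons.  Columns with a gap in either
    sequence are excluded.  Raises :class:`FrameshiftError` when either
    sequence lacks an ORF of ``min_codons``.
    """
    sa, na = longest_orf(a, min_codons)
    sb, nb = longest_orf(b, min_codons)
    codons_a = [a[sa + 3 * i : sa + 3 * i + 3].upper() for i in range(na)]
    codons_b = [b[sb + 3 * i : sb + 3 * i + 3].upper() for i in range(nb)]
    prot_a = "".join(translate_codon(c) for c in codons_a)
    prot_b = "".join(translate_codon(c) for c in codons_b)
    if prot_a == prot_b:
        return list(zip(codons_a, codons_b))
    aln = _get_protein_aligner().align(prot_a, prot_b)[0]
    cols: list[tuple[str, str]] = []
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        for i, j in zip(range(a0, a1), range(b0, b1)):
            cols.append((codons_a[i], codons_b[j]))
    return cols


# ---------------------------------------------------------------------------
# Homeolog pair bookkeeping


@dataclass
class HomeologPair:
    """A candidate homeolog pair anchored to a progenitor ortholog.

    ``member_a``/``member_b`` are transcripts of the polyploid,
    ``progenitor`` the shared best-hit ortholog.  dS fields are filled by
    :func:`ng86` runs; subgenome labels by :func:`assign_subgenome`.
    """

    member_a: str
    member_b: str
    progenitor: str
    ds_a_prog: Optional[float] = None
    ds_b_prog: Optional[float] = None
    ds_a_b: Optional[float] = None
    subgenome_of_a: str = "unassigned"  # {sub1, sub2, unassigned}
    topology_class: str = "unresolved"  # {expected, homeolog_sister, sub2_prog_sister, unresolved}
    extras: dict = field(default_factory=dict)

    @property
    def sub1_member(self) -> Optional[str]:
        if self.subgenome_of_a == "sub1":
            return self.member_a
        if self.subgenome_of_a == "sub2":
            return self.member_b
        return None

    @property
    def sub2_member(self) -> Optional[str]:
        if self.subgenome_of_a == "sub1":
            return self.member_b
        if self.subgenome_of_a == "sub2":
            return self.member_a
        return None


def assign_subgenome(pair: HomeologPair) -> HomeologPair:
    """Attribute pair members to subgenomes by the lower-dS rule.

    The member with the lower silent-site divergence from the progenitor is
    attributed to subgenome 1 (derived from the same lineage as the extant
    progenitor); the other member to subgenome 2.  Equal or undefined dS
    leaves the pair unassigned.
    """
    a, b = pair.ds_a_prog, pair.ds_b_prog
    if a is None or b is None or a == b:
        pair.subgenome_of_a = "unassigned"
    elif a < b:
        pair.subgenome_of_a = "sub1"
    else:
        pair.subgenome_of_a = "sub2"
    return pair


def estimate_tmrca(ds: float, mu: float = 7.5e-9) -> float:
    """Time to most recent common ancestor in generations: T = dS / (2 mu)."""
    if mu <= 0:
        raise ValueError("mutation rate must be positive")
    if ds < 0:
        raise ValueError("dS must be non-negative")
    return ds / (2.0 * mu)
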