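"""Transcriptome reduction and homeolog pair identification.

An isoform-redundant transcriptome is reduced to one representative per
gene: transcripts are connected when a local alignment gives a
blat-style match score above 50 and divergence (mismatches per aligned
column) below 1%, connected components are clusters, and the longest
member represents each cluster.  Candidate homeolog pairs are transcripts
of the reduced polyploid set whose best non-self hits are reciprocal
(the best hit in an all-vs-all search being the transcript itself) and
that share the same best hit in the reduced progenitor transcriptome —
the shared hit is recorded as the progenitor ortholog anchoring the pair.

Local alignment uses unit match/mismatch scoring with affine gaps
(match +1, mismatch -1, open -2, extend -1); an exact shared 15-mer is
required before aligning a pair, which prunes the all-vs-all search
without affecting hits at the divergences of interest (well under 10%).
Only the forward strand is compared.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import networkx as nx
from Bio import SeqIO
from Bio.Align import PairwiseAligner

MIN_SCORE = 50
MAX_DIVERGENCE = 0.01
KMER = 15


@dataclass(frozen=True)
class Transcript:
    """A transcript with its nucleotide sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.id}")
        bad = set(self.sequence.upper()) - set("ACGTN")
        if bad:
            raise ValueError(f"non-nucleotide characters in {self.id}: {bad}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SimilarityHit:
    """Best-local-alignment summary between two transcripts."""

    query: str
    target: str
    match_score: int  # aligned matches minus mismatches
    divergence: float  # mismatches / aligned columns


def read_fasta(path: str) -> list[Transcript]:
    return [Transcript(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fasta")]


def write_fasta(transcripts: Iterable[Transcript], path: str) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            fh.write(f">{t.id}\n")
            for i in range(0, len(t.sequence), 70):
                fh.write(t.sequence[i : i + 70] + "\n")


_aligner: Optional[PairwiseAligner] = None


def _get_aligner() -> PairwiseAligner:
    global _aligner
    if _aligner is None:
        a = PairwiseAligner()
        a.mode = "local"
        a.match_score = 1.0
        a.mismatch_score = -1.0
        a.open_gap_score = -2.0
        a.extend_gap_score = -1.0
        _aligner = a
    return _aligner


def pairwise_similarity(a: Transcript, b: Transcript) -> SimilarityHit:
    """Best local alignment of two transcripts under unit scoring.

    The match score is (matches - mismatches) over the aligned columns of
    the best local alignment; divergence is mismatches / aligned columns.
    Sequences with no alignable content yield a zero-score hit.
    """
    sa, sb = a.sequence.upper(), b.sequence.upper()
    if set(sa) <= {"N"} or set(sb) <= {"N"}:
        return SimilarityHit(a.id, b.id, 0, 1.0)
    aln = _get_aligner().align(sa, sb)
    if len(aln) == 0:
        return SimilarityHit(a.id, b.id, 0, 1.0)
    best = aln[0]
    matches = mismatches = 0
    for (a0, a1), (b0, b1) in zip(*best.aligned):
        for i, j in zip(range(a0, a1), range(b0, b1)):
            if sa[i] == sb[j]:
                matches += 1
            else:
                mismatches += 1
    cols = matches + mismatches
    return SimilarityHit(
        a.id,
        b.id,
        matches - mismatches,
        mismatches / cols if cols else 1.0,
    )


def _kmer_index(transcripts: list[Transcript], k: int = KMER) -> dict[str, set[int]]:
    index: dict[str, set[int]] = {}
    for i, t in enumerate(transcripts):
        seq = t.sequence.upper()
        for j in range(0, len(seq) - k + 1):
            index.setdefault(seq[j : j + k], set()).add(i)
    return index


def candidate_pairs(transcripts: list[Transcript], k: int = KMER) -> set[tuple[int, int]]:
    """Index pairs sharing at least one exact k-mer (i < j)."""
    index = _kmer_index(transcripts, k)
    pairs: set[tuple[int, int]] = set()
    for members in index.values():
        if len(members) < 2:
            continue
        ms = sorted(members)
        for x in range(len(ms)):
            for y in range(x + 1, len(ms)):
                pairs.add((ms[x], ms[y]))
    return pairs


def all_vs_all(transcripts: list[Transcript], k: int = KMER) -> list[SimilarityHit]:
    """All-vs-all similarity within a set, k-mer prefiltered."""
    hits = []
    for i, j in sorted(candidate_pairs(transcripts, k)):
        hits.append(pairwise_similarity(transcripts[i], transcripts[j]))
    return hits


def cross_hits(queries: list[Transcript], targets: list[Transcript], k: int = KMER) -> list[SimilarityHit]:
    """Similarity hits of each query against a target set, k-mer prefiltered."""
    index = _kmer_index(targets, k)
    hits = []
    for q in queries:
        seq = q.sequence.upper()
        cands: set[int] = set()
        for j in range(0, len(seq) - k + 1):
            cands |= index.get(seq[j : j + k], set())
        for c in sorted(cands):
            hits.append(pairwise_similarity(q, targets[c]))
    return hits


def cluster_and_select(
    transcripts: Iterable[Transcript],
    min_score: int = MIN_SCORE,
    max_divergence: float = MAX_DIVERGENCE,
    hits: Optional[list[SimilarityHit]] = None,
) -> tuple[list[Transcript], list[set[str]]]:
    """Reduce a transcriptome to the longest representative per cluster.

    Clusters are connected components of the graph whose edges join
    transcripts with match score > ``min_score`` and divergence <
    ``max_divergence`` (single linkage, so near-identical isoform chains
    collapse).  Ties in length break lexicographically by id.  Returns
    the representatives and the clusters.
    """
    tlist = list(transcripts)
    if not tlist:
        return [], []
    if hits is None:
        hits = all_vs_all(tlist)
    g = nx.Graph()
    g.add_nodes_from(t.id for t in tlist)
    for h in hits:
        if h.match_score > min_score and h.divergence < max_divergence:
            g.add_edge(h.query, h.target)
    by_id = {t.id: t for t in tlist}
    reps = []
    clusters = []
    for comp in nx.connected_components(g):
        clusters.append(set(comp))
        rep = max(comp, key=lambda tid: (by_id[tid].length, [-ord(c) for c in tid]))
        reps.append(by_id[rep])
    reps.sort(key=lambda t: t.id)
    return reps, clusters


def _rank_key(h: SimilarityHit) -> tuple:
    # higher score, then lower divergence, then id
    return (-h.match_score, h.divergence, h.target)


def best_hits(hits: list[SimilarityHit]) -> dict[str, SimilarityHit]:
    """Best hit per query under (score desc, divergence asc, id) ranking."""
    best: dict[str, SimilarityHit] = {}
    for h in hits:
        cur = best.get(h.query)
        if cur is None or _rank_key(h) < _rank_key(cur):
            best[h.query] = h
    return best


def find_homeolog_pairs(
    reduced_poly: list[Transcript],
    reduced_prog: list[Transcript],
    min_score: int = MIN_SCORE,
    poly_hits: Optional[list[SimilarityHit]] = None,
    prog_hits: Optional[list[SimilarityHit]] = None,
) -> list[tuple[str, str, str]]:
    """Identify homeolog pairs anchored to a shared progenitor ortholog.

    Within the reduced polyploid set, each transcript's best non-self hit
    (its second-best hit counting the self-hit) must be reciprocal; the
    pair is kept only when both members also share the same best hit in
    the reduced progenitor set.  Returns ``(member_a, member_b,
    progenitor)`` triples with member ids sorted; each transcript appears
    in at most one pair.
    """
    if poly_hits is None:
        poly_hits = all_vs_all(reduced_poly)
    sym = poly_hits + [SimilarityHit(h.target, h.query, h.match_score, h.divergence) for h in poly_hits]
    sym = [h for h in sym if h.match_score > min_score]
    partner = {q: h.target for q, h in best_hits(sym).items()}

    if prog_hits is None:
        prog_hits = cross_hits(reduced_poly, reduced_prog)
    prog_best = {q: h.target for q, h in best_hits([h for h in prog_hits if h.match_score > min_score]).items()}

    pairs = []
    seen = set()
    for x, y in partner.items():
        if x in seen or y in seen:
            continue
        if partner.get(y) != x:
            continue
        tx, ty = prog_best.get(x), prog_best.get(y)
        if tx is None or tx != ty:
            continue
        a, b = sorted((x, y))
        pairs.append((a, b, tx))
        seen.update((x, y))
    pairs.sort()
    return pairs
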