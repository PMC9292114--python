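"""Quartet gene-tree topology classification for homeolog pairs.

For each homeolog pair the four-taxon tree of (member a, member b,
progenitor ortholog, outgroup) is inferred from Jukes-Cantor pairwise
distances by ordinary least squares: each of the three unrooted quartet
topologies gets OLS branch lengths (non-negative, via NNLS) and the
topology with the smallest residual sum of squares wins, rooted on the
outgroup.  The topology consistent with allopolyploid origin — the
lower-dS member sister to the progenitor, the other member outside, the
outgroup most distal — is the "expected" class; pairs whose residual
margin is below tolerance (including the all-equal-distance three-way
tie) are unresolved, as are pairs with saturated distances (p >= 3/4).

This distance/least-squares decision replaces a likelihood tree search:
with four taxa the topology call is the only quantity consumed
downstream, and the OLS fit is deterministic and directly checkable on
additive distances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import nnls

from .codonevol import jukes_cantor

RESIDUAL_TOL = 1e-9

#: pair index order for the 6 distances between taxa (a, b, p, o)
PAIR_ORDER = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]

# branch order: [ea, eb, ep, eo, internal]
_TOPOLOGY_DESIGNS = {
    # ((a,p),(b,o)): cherries (a,p) and (b,o)
    "a_prog": [
        [1, 1, 0, 0, 1],  # d(a,b)
        [1, 0, 1, 0, 0],  # d(a,p)
        [1, 0, 0, 1, 1],  # d(a,o)
        [0, 1, 1, 0, 1],  # d(b,p)
        [0, 1, 0, 1, 0],  # d(b,o)
        [0, 0, 1, 1, 1],  # d(p,o)
    ],
    # ((a,b),(p,o)): cherries (a,b) and (p,o)
    "ab": [
        [1, 1, 0, 0, 0],
        [1, 0, 1, 0, 1],
        [1, 0, 0, 1, 1],
        [0, 1, 1, 0, 1],
        [0, 1, 0, 1, 1],
        [0, 0, 1, 1, 0],
    ],
    # ((b,p),(a,o)): cherries (b,p) and (a,o)
    "b_prog": [
        [1, 1, 0, 0, 1],
        [1, 0, 1, 0, 1],
        [1, 0, 0, 1, 0],
        [0, 1, 1, 0, 0],
        [0, 1, 0, 1, 1],
        [0, 0, 1, 1, 1],
    ],
}


@dataclass
class QuartetResult:
    """Distances, per-topology OLS fits and the winning topology."""

    distances: np.ndarray  # 6 JC distances in PAIR_ORDER for (a, b, p, o)
    residuals: dict[str, float]
    topology: str  # {a_prog, ab, b_prog, unresolved}

    def newick(self, names: Sequence[str] = ("a", "b", "prog", "out")) -> Optional[str]:
        a, b, p, o = names
        return {
            "a_prog": f"((({a},{p}),{b}),{o});",
            "ab": f"((({a},{b}),{p}),{o});",
            "b_prog": f"((({b},{p}),{a}),{o});",
        }.get(self.topology)


def jc_pairwise_distances(aligned: Sequence[str]) -> Optional[np.ndarray]:
    """JC69 distances for all pairs of equal-length aligned sequences.

    Columns with a gap or N in either member of a pair are excluded for
    that pair.  Returns None when any distance is undefined (p >= 3/4 or
    no comparable columns).
    """
    seqs = [s.upper() for s in aligned]
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("aligned sequences must have equal length")
    arrs = [np.frombuffer(s.encode(), dtype="S1") for s in seqs]
    acgt = np.array([b"A", b"C", b"G", b"T"])
    valid = [np.isin(a, acgt) for a in arrs]
    out = np.empty(len(PAIR_ORDER))
    for k, (i, j) in enumerate(PAIR_ORDER):
        ok = valid[i] & valid[j]
        n = int(ok.sum())
        if n == 0:
            return None
        p = float(np.mean(arrs[i][ok] != arrs[j][ok]))
        d = jukes_cantor(p)
        if d is None:
            return None
        out[k] = d
    return out


def quartet_topology(
    aligned: Sequence[str],
    min_columns: int = 100,
    tol: float = RESIDUAL_TOL,
) -> QuartetResult:
    """Classify the quartet topology of four aligned sequences (a, b, prog, out).

    Fits OLS branch lengths (clamped non-negative) for the three unrooted
    topologies and selects the minimal-residual one; a relative residual
    margin below ``tol`` — or undefined distances — yields ``unresolved``.
    """
    seqs = [s.upper() for s in aligned]
    if len(seqs) != 4:
        raise ValueError("a quartet needs exactly four sequences")
    ungapped = sum(
        1
        for col in zip(*seqs)
        if all(c in "ACGT" for c in col)
    )
    if ungapped < min_columns:
        raise ValueError(f"only {ungapped} ungapped columns (< {min_columns})")
    d = jc_pairwise_distances(seqs)
    if d is None:
        return QuartetResult(distances=np.full(6, np.nan), residuals={}, topology="unresolved")
    residuals = {}
    for name, design in _TOPOLOGY_DESIGNS.items():
        A = np.asarray(design, dtype=float)
        x, rnorm = nnls(A, d)
        residuals[name] = float(rnorm**2)
    ranked = sorted(residuals.items(), key=lambda kv: kv[1])
    best, second = ranked[0], ranked[1]
    scale = max(second[1], 1e-30)
    if (second[1] - best[1]) / scale < tol:
        topo = "unresolved"
    else:
        topo = best[0]
    return QuartetResult(distances=d, residuals=residuals, topology=topo)


def concordance_summary(classes: Sequence[str]) -> dict:
    """Counts and proportions per topology class.

    The concordance percentage (share of pairs in the expected class,
    rounded to the nearest integer) is reported alongside raw counts.
    """
    classes = list(classes)
    if not classes:
        raise ValueError("no quartet results to summarize")
    labels = ["expected", "homeolog_sister", "sub2_prog_sister", "unresolved"]
    counts = {lab: classes.count(lab) for lab in labels}
    for c in set(classes) - set(labels):
        counts[c] = classes.count(c)
    n = len(classes)
    props = {k: v / n for k, v in counts.items()}
    return {
        "n": n,
        "counts": counts,
        "proportions": props,
        "concordance_percent": round(100.0 * counts.get("expected", 0) / n),
    }
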