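"""Independent brute-force oracles used by the test-suite.

These deliberately share no code path with the implementation they check:
correlations use numpy.corrcoef, alignment enumerations are plain loops,
and the Smith-Waterman oracle is a standalone affine-gap dynamic program.
"""

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def pcc(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _pwm(motif, pseudocount=0.01):
    bg = np.full(4, 0.25)
    rows = motif.counts.sum(axis=1, keepdims=True)
    return (motif.counts + pseudocount * bg) / (rows + pseudocount)


def _revcomp_counts(counts):
    return counts[::-1, [3, 2, 1, 0]]


def brute_force_align(a, b, min_overlap=5, both_strands=True):
    """Exhaustive (sum, ncols, offset, orientation) enumeration.

    Selection maximises the summed column correlation with ties broken by
    more columns, smaller |offset|, forward orientation.
    """
    from cisbind.motif_model import NucleotideMotif
    pq = _pwm(a)
    orientations = [("forward", _pwm(b))]
    if both_strands:
        rc = NucleotideMotif(id=b.id, counts=_revcomp_counts(b.counts),
                             nsites=b.nsites)
        orientations.append(("revcomp", _pwm(rc)))
    best = None
    for orient, pt in orientations:
        wq, wt = len(pq), len(pt)
        for off in range(-wt + 1, wq):
            qs, qe = max(0, off), min(wq, off + wt)
            k = qe - qs
            if k < min_overlap:
                continue
            s = sum(pcc(pq[i], pt[i - off]) for i in range(qs, qe))
            key = (round(s, 9), k, -abs(off), orient == "forward")
            if best is None or key > best[0]:
                best = (key, (s, k, off, orient))
    return best[1]


def brute_force_interface(structure, cutoff=4.5):
    """All-pairs distance check between protein heavy atoms and base atoms."""
    base_names = {"N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9",
                  "N2", "N4", "N6", "O2", "O4", "O6"}
    base_atoms = []
    for res in structure.dna_residues:
        for atom in res.atoms:
            if atom.name in base_names:
                base_atoms.append((atom.x, atom.y, atom.z))
    hits = []
    for i, res in enumerate(structure.protein_residues):
        found = False
        for atom in res.atoms:
            if atom.element in ("H", "D"):
                continue
            for bx, by, bz in base_atoms:
                d = ((atom.x - bx) ** 2 + (atom.y - by) ** 2
                     + (atom.z - bz) ** 2) ** 0.5
                if d <= cutoff:
                    found = True
                    break
            if found:
                break
        if found:
            hits.append(i)
    return tuple(hits)


def smith_waterman_score(a, b, gap_open=11, gap_extend=1):
    """Affine-gap local alignment score (first gap residue costs
    open + extend), independent dynamic program."""
    m, n = len(a), len(b)
    NEG = -1e9
    M = [[0.0] * (n + 1) for _ in range(m + 1)]
    Ix = [[NEG] * (n + 1) for _ in range(m + 1)]
    Iy = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            sub = _BLOSUM62[a[i - 1], b[j - 1]]
            M[i][j] = max(0.0,
                          max(M[i - 1][j - 1], Ix[i - 1][j - 1],
                              Iy[i - 1][j - 1]) + sub)
            Ix[i][j] = max(M[i - 1][j] - gap_open - gap_extend,
                           Ix[i - 1][j] - gap_extend)
            Iy[i][j] = max(M[i][j - 1] - gap_open - gap_extend,
                           Iy[i][j - 1] - gap_extend)
            best = max(best, M[i][j])
    return best
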