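"""Nucleotide motif data model, motif file I/O and sequence scanning.

A motif is a W x 4 matrix of per-position base counts (or weights) in fixed
A, C, G, T column order.  Motifs are exchanged in three common text dialects
(TRANSFAC-style matrix stanzas, MEME minimal, JASPAR PFM) and can be built
directly from aligned binding-site sequences.  Degenerate-site scanning uses
the 15-letter IUPAC nucleotide code.

All coordinates in this package are 0-based, half-open; rendered reports are
the only place 1-based positions appear.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .errors import MotifParseError, ValidationError

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: IUPAC nucleotide codes mapped to the base sets they denote.
IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_SET_TO_IUPAC = {frozenset(v): k for k, v in IUPAC_CODES.items()}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass
class NucleotideMotif:
    """A position count matrix over A, C, G, T.

    Parameters
    ----------
    id : str
        Motif identifier.
    counts : (W, 4) array of non-negative reals
        Per-position base counts; every row must have a positive sum.
    nsites : int
        Number of contributing site sequences.
    source_seqs : list of str, optional
        The aligned sites the matrix was built from; when present they must
        all have length W and tally exactly to ``counts``.
    description : str, optional
    """

    id: str
    counts: np.ndarray
    nsites: int = 1
    source_seqs: list[str] | None = None
    description: str | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValidationError(
                f"motif {self.id!r}: counts must be W x 4, got {self.counts.shape}")
        if self.counts.shape[0] < 1:
            raise ValidationError(f"motif {self.id!r}: width must be >= 1")
        if np.any(self.counts < 0):
            raise ValidationError(f"motif {self.id!r}: negative counts")
        if np.any(self.counts.sum(axis=1) <= 0):
            raise ValidationError(f"motif {self.id!r}: zero-sum row")
        if self.nsites < 1:
            raise ValidationError(f"motif {self.id!r}: nsites must be positive")
        if self.source_seqs is not None:
            tallied = _tally(self.source_seqs)
            if tallied.shape != self.counts.shape or not np.allclose(
                    tallied, self.counts, atol=1e-6):
                raise ValidationError(
                    f"motif {self.id!r}: source_seqs do not tally to counts")

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    def pwm(self, pseudocount: float = 0.01,
            background: np.ndarray | None = None) -> np.ndarray:
        return normalize_to_pwm(self, pseudocount, background)

    def consensus(self) -> str:
        return consensus_string(self)

    def __eq__(self, other):
        if not isinstance(other, NucleotideMotif):
            return NotImplemented
        return (self.id == other.id and self.nsites == other.nsites
                and self.counts.shape == other.counts.shape
                and np.allclose(self.counts, other.counts, atol=1e-6))


@dataclass
class CisSequence:
    """A single selected cis-element with its genomic provenance."""

    seq_nr: str
    element: str
    motif_group: str
    query_id: str = ""
    gene: str = ""
    position: int = 0

    _GROUPS = ("I", "II", "III", "IV", "V", "VI", "VII")

    def __post_init__(self):
        self.element = self.element.upper()
        if not (5 <= len(self.element) <= 11):
            raise ValidationError(
                f"cis-sequence {self.seq_nr}: element length {len(self.element)} "
                "outside [5, 11]")
        if set(self.element) - set(BASES):
            raise ValidationError(
                f"cis-sequence {self.seq_nr}: non-ACGT characters")
        if self.motif_group not in self._GROUPS:
            raise ValidationError(
                f"cis-sequence {self.seq_nr}: unknown motif group "
                f"{self.motif_group!r}")


@dataclass
class IUPACPattern:
    """A degenerate nucleotide pattern such as the E-box CANNTG."""

    pattern: str

    def __post_init__(self):
        self.pattern = self.pattern.upper()
        if not self.pattern:
            raise ValidationError("empty IUPAC pattern")
        bad = set(self.pattern) - set(IUPAC_CODES)
        if bad:
            raise ValidationError(f"invalid IUPAC symbols: {sorted(bad)}")

    def __len__(self):
        return len(self.pattern)

    def reverse_complement(self) -> "IUPACPattern":
        return IUPACPattern(self.pattern.translate(_COMPLEMENT)[::-1])

    def to_regex(self) -> str:
        return "".join(
            c if len(IUPAC_CODES[c]) == 1 else f"[{IUPAC_CODES[c]}]"
            for c in self.pattern)


def _tally(seqs: list[str]) -> np.ndarray:
    width = len(seqs[0])
    counts = np.zeros((width, 4))
    for s in seqs:
        for i, b in enumerate(s):
            counts[i, _BASE_INDEX[b]] += 1
    return counts


def motif_from_sequences(seqs: list[str], id: str) -> NucleotideMotif:
    """Build a count motif from equal-length aligned ACGT sequences."""
    if not seqs:
        raise ValidationError("need at least one sequence")
    seqs = [s.upper() for s in seqs]
    width = len(seqs[0])
    if any(len(s) != width for s in seqs):
        raise ValidationError("ragged sequence lengths")
    for s in seqs:
        bad = set(s) - set(BASES)
        if bad:
            raise ValidationError(f"non-ACGT characters: {sorted(bad)}")
    return NucleotideMotif(id=id, counts=_tally(seqs), nsites=len(seqs),
                           source_seqs=list(seqs))


def normalize_to_pwm(m: NucleotideMotif, pseudocount: float = 0.01,
                     background: np.ndarray | None = None) -> np.ndarray:
    """Convert counts to per-position frequencies.

    Each row becomes ``(count + pseudocount * bg) / (rowsum + pseudocount)``,
    so rows sum to 1.  The default pseudocount (0.01, spread over a uniform
    background) keeps sharp columns essentially intact while avoiding exact
    zeros downstream.
    """
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    if background is None:
        background = np.full(4, 0.25)
    background = np.asarray(background, dtype=float)
    if background.shape != (4,) or not np.isclose(background.sum(), 1.0):
        raise ValidationError("background must be a 4-vector summing to 1")
    if pseudocount > 0 and np.any(background <= 0):
        raise ValidationError("background must be strictly positive "
                              "when pseudocount > 0")
    rowsums = m.counts.sum(axis=1, keepdims=True)
    return (m.counts + pseudocount * background) / (rowsums + pseudocount)


def reverse_complement(m: NucleotideMotif) -> NucleotideMotif:
    """Motif on the opposite strand: positions reversed, A<->T, C<->G."""
    rc_counts = m.counts[::-1, [3, 2, 1, 0]]
    rc_seqs = None
    if m.source_seqs is not None:
        rc_seqs = [s.translate(_COMPLEMENT)[::-1] for s in m.source_seqs]
    return NucleotideMotif(id=m.id, counts=rc_counts, nsites=m.nsites,
                           source_seqs=rc_seqs, description=m.description)


def consensus_string(m: NucleotideMotif) -> str:
    """IUPAC consensus: a single base when it holds > 50% of a column,
    otherwise the smallest top-frequency base set jointly >= 50% with every
    member >= 25%; N when no such set exists."""
    pwm = normalize_to_pwm(m, pseudocount=0.0)
    out = []
    for row in pwm:
        order = np.argsort(-row, kind="stable")
        if row[order[0]] > 0.5:
            out.append(BASES[order[0]])
            continue
        code = "N"
        for k in range(2, 4):
            top, rest = order[:k], order[k:]
            if (row[top].sum() >= 0.5 and np.all(row[top] >= 0.25)
                    and row[top].min() > row[rest].max() + 1e-9):
                code = _SET_TO_IUPAC[frozenset(BASES[i] for i in top)]
                break
        out.append(code)
    return "".join(out)


def iupac_scan(pattern: IUPACPattern | str, seq: str,
               both_strands: bool = True) -> list[tuple[int, str]]:
    """All (start, strand) windows of ``seq`` matching a degenerate pattern.

    Starts are 0-based on the forward sequence for both strands; overlapping
    matches are reported.
    """
    if isinstance(pattern, str):
        pattern = IUPACPattern(pattern)
    seq = seq.upper()
    hits = [(m.start(), "+")
            for m in re.finditer(f"(?=({pattern.to_regex()}))", seq)]
    if both_strands:
        rc = pattern.reverse_complement()
        rc_hits = [(m.start(), "-")
                   for m in re.finditer(f"(?=({rc.to_regex()}))", seq)]
        # a palindromic pattern matches both strands at the same start
        hits.extend(rc_hits)
    return sorted(set(hits))


def concatemer(seq: str, n: int) -> str:
    """Tandem repeat of ``seq`` (n=6 mimics hexamer bait construction)."""
    if n < 1:
        raise ValidationError("repeat count must be >= 1")
    return seq * n


# ---------------------------------------------------------------------------
# Motif file formats
# ---------------------------------------------------------------------------

FORMATS = ("transfac", "meme", "jaspar")


def read_motifs(path, format: str) -> list[NucleotideMotif]:
    """Read motifs from a file in one of the supported dialects."""
    if format not in FORMATS:
        raise ValidationError(
            f"unknown format {format!r}; expected one of {FORMATS}")
    with open(path) as fh:
        lines = fh.read().splitlines()
    reader = {"transfac": _read_transfac, "meme": _read_meme,
              "jaspar": _read_jaspar}[format]
    return reader(lines)


def write_motifs(motifs: list[NucleotideMotif], path, format: str) -> None:
    if format not in FORMATS:
        raise ValidationError(
            f"unknown format {format!r}; expected one of {FORMATS}")
    writer = {"transfac": _write_transfac, "meme": _write_meme,
              "jaspar": _write_jaspar}[format]
    with open(path, "w") as fh:
        fh.write(writer(motifs))


def _fmt(x: float) -> str:
    s = f"{x:.6f}"
    return s


def _read_transfac(lines) -> list[NucleotideMotif]:
    motifs = []
    cur_id = None
    cur_desc = None
    rows = []
    nsites = 0
    for ln, raw in enumerate(lines, start=1):
        line = raw.rstrip()
        if not line or line == "XX":
            continue
        tag = line.split(None, 1)[0]
        if tag == "ID" or tag == "AC":
            if cur_id is None:
                cur_id = line.split(None, 1)[1].strip() if " " in line else ""
        elif tag == "DE":
            cur_desc = line.split(None, 1)[1].strip() if " " in line else ""
        elif tag in ("P0", "PO"):
            header = line.split()[1:5]
            if [h.upper() for h in header] != list(BASES):
                raise MotifParseError(
                    f"matrix header must be 'A C G T', got {header}", ln)
        elif tag == "//":
            if cur_id is not None or rows:
                if not rows:
                    raise MotifParseError("matrix stanza with no rows", ln)
                motifs.append(NucleotideMotif(
                    id=cur_id or f"motif{len(motifs) + 1}",
                    counts=np.array(rows), nsites=max(1, nsites),
                    description=cur_desc))
            cur_id, cur_desc, rows, nsites = None, None, [], 0
        elif re.fullmatch(r"\d+", tag):
            fields = line.split()
            try:
                vals = [float(v) for v in fields[1:5]]
            except ValueError:
                raise MotifParseError(f"malformed count row {line!r}", ln)
            if len(vals) != 4:
                raise MotifParseError(f"expected 4 counts, got {len(vals)}", ln)
            rows.append(vals)
            nsites = max(nsites, int(round(sum(vals))))
        elif tag in ("BF", "CC", "NA"):
            continue
        else:
            raise MotifParseError(f"unrecognised record tag {tag!r}", ln)
    if cur_id is not None or rows:
        raise MotifParseError("unterminated matrix stanza (missing '//')",
                              len(lines))
    return motifs


def _write_transfac(motifs) -> str:
    out = []
    for m in motifs:
        out.append(f"ID  {m.id}")
        if m.description:
            out.append(f"DE  {m.description}")
        out.append("P0" + "".join(f"{b:>13s}" for b in BASES))
        for i, row in enumerate(m.counts, start=1):
            out.append(f"{i:02d}" + "".join(f"{_fmt(v):>13s}" for v in row))
        out.append("XX")
        out.append("//")
    return "\n".join(out) + "\n"


def _read_meme(lines) -> list[NucleotideMotif]:
    motifs = []
    i = 0
    n = len(lines)
    saw_version = any(l.startswith("MEME version") for l in lines)
    if not saw_version:
        raise MotifParseError("missing 'MEME version' header", 1)
    while i < n:
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            parts = line.split()
            if len(parts) < 2:
                raise MotifParseError("MOTIF line without identifier", i + 1)
            mid = parts[1]
            desc = " ".join(parts[2:]) or None
            i += 1
            while i < n and not lines[i].strip().startswith(
                    "letter-probability matrix"):
                if lines[i].strip().startswith("MOTIF"):
                    raise MotifParseError(
                        f"motif {mid!r} lacks a letter-probability matrix", i)
                i += 1
            if i >= n:
                raise MotifParseError(
                    f"motif {mid!r} lacks a letter-probability matrix", n)
            header = lines[i].strip()
            kv = dict(re.findall(r"(\w+)=\s*(\S+)", header))
            try:
                width = int(kv["w"])
            except (KeyError, ValueError):
                raise MotifParseError("matrix header lacks 'w='", i + 1)
            nsites = int(float(kv.get("nsites", 20)))
            rows = []
            for j in range(width):
                i += 1
                if i >= n:
                    raise MotifParseError("truncated probability matrix", n)
                try:
                    vals = [float(v) for v in lines[i].split()]
                except ValueError:
                    raise MotifParseError(
                        f"malformed probability row {lines[i]!r}", i + 1)
                if len(vals) != 4:
                    raise MotifParseError(
                        f"expected 4 probabilities, got {len(vals)}", i + 1)
                rows.append(vals)
            counts = np.array(rows) * max(1, nsites)
            motifs.append(NucleotideMotif(id=mid, counts=counts,
                                          nsites=max(1, nsites),
                                          description=desc))
        i += 1
    return motifs


def _write_meme(motifs) -> str:
    out = ["MEME version 4", "", "ALPHABET= ACGT", "", "strands: + -", "",
           "Background letter frequencies",
           "A 0.25 C 0.25 G 0.25 T 0.25", ""]
    for m in motifs:
        name = f"MOTIF {m.id}"
        if m.description:
            name += f" {m.description}"
        out.append(name)
        pwm = m.counts / m.counts.sum(axis=1, keepdims=True)
        out.append(f"letter-probability matrix: alength= 4 w= {m.width} "
                   f"nsites= {m.nsites} E= 0")
        for row in pwm:
            q = np.round(row, 6)
            q[int(np.argmax(q))] += 1.0 - q.sum()  # keep the row stochastic
            out.append(" " + "  ".join(f"{v:.6f}" for v in q))
        out.append("")
    return "\n".join(out) + "\n"


def _read_jaspar(lines) -> list[NucleotideMotif]:
    motifs = []
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.startswith(">"):
            raise MotifParseError(f"expected '>' header, got {line!r}", i + 1)
        head = line[1:].split(None, 1)
        mid = head[0] if head else f"motif{len(motifs) + 1}"
        desc = head[1] if len(head) > 1 else None
        rows = {}
        for k in range(4):
            i += 1
            if i >= n:
                raise MotifParseError(f"motif {mid!r}: truncated PFM", n)
            mrow = re.match(r"\s*([ACGT])\s*\[?\s*([^\]]*)\]?\s*$", lines[i])
            if not mrow:
                raise MotifParseError(f"malformed PFM row {lines[i]!r}", i + 1)
            base = mrow.group(1)
            try:
                vals = [float(v) for v in mrow.group(2).split()]
            except ValueError:
                raise MotifParseError(f"malformed PFM row {lines[i]!r}", i + 1)
            rows[base] = vals
        if set(rows) != set(BASES):
            raise MotifParseError(f"motif {mid!r}: missing base rows", i + 1)
        widths = {len(v) for v in rows.values()}
        if len(widths) != 1:
            raise MotifParseError(f"motif {mid!r}: ragged PFM rows", i + 1)
        counts = np.array([rows[b] for b in BASES]).T  # 4 x W -> W x 4
        nsites = max(1, int(round(counts.sum(axis=1).max())))
        motifs.append(NucleotideMotif(id=mid, counts=counts, nsites=nsites,
                                      description=desc))
        i += 1
    return motifs


def _write_jaspar(motifs) -> str:
    out = []
    for m in motifs:
        head = f">{m.id}"
        if m.description:
            head += f" {m.description}"
        out.append(head)
        for bi, b in enumerate(BASES):
            vals = "  ".join(_fmt(v) for v in m.counts[:, bi])
            out.append(f"{b}  [ {vals} ]")
    return "\n".join(out) + "\n"
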