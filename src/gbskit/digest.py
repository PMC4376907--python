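"""In silico restriction digestion for reduced-representation library design.

GBS libraries sample a genome at restriction-fragment ends. Choosing the
enzyme system (a single frequent cutter such as ApeKI versus a rare/common
pair such as PstI + MspI) determines how many fragments enter the library
and therefore the per-site depth at fixed sequencing effort. This module
predicts those fragment sets from a genome assembly: it scans sequences for
IUPAC-degenerate recognition sites, cuts at the enzyme's top-strand offset,
tiles each sequence into fragments classified by the cut types flanking
them, and compares the complexity reduction of one- versus two-enzyme
protocols.

Conventions: sequences are A/C/G/T/N, case-insensitive; coordinates are
0-based, half-open; `N` in a genome never matches a non-N pattern letter, so
assembly gaps cannot create phantom sites. Overlapping recognition matches
are all reported (degenerate 4-6mers can self-overlap).
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

__all__ = [
    "Enzyme",
    "CutType",
    "Fragment",
    "DigestSummary",
    "DigestError",
    "APEKI",
    "PSTI",
    "MSPI",
    "BUILTIN_ENZYMES",
    "find_sites",
    "digest_single",
    "digest_double",
    "compare_protocols",
    "write_fragments_tsv",
]

# IUPAC nucleotide codes -> the set of concrete bases each matches.
# Pattern letter N additionally matches sequence N (everything); any other
# pattern letter rejects sequence N.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGTN",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class DigestError(ValueError):
    """Raised for invalid sequences, enzymes, or degenerate digest setups."""


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme: IUPAC recognition site plus top-strand cut offset.

    ``cut_offset`` is the index within the recognition site where the top
    strand is cleaved (0 <= cut_offset <= len(recognition)). The built-in
    enzymes are palindromic under IUPAC complement, so a single-strand scan
    finds every site.
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not self.recognition:
            raise DigestError(f"enzyme {self.name!r}: empty recognition site")
        bad = [c for c in self.recognition.upper() if c not in IUPAC]
        if bad:
            raise DigestError(
                f"enzyme {self.name!r}: non-IUPAC letters {bad} in recognition site"
            )
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise DigestError(
                f"enzyme {self.name!r}: cut offset {self.cut_offset} outside "
                f"recognition site of length {len(self.recognition)}"
            )
        object.__setattr__(self, "recognition", self.recognition.upper())

    @property
    def is_palindromic(self) -> bool:
        """True if the recognition site equals its IUPAC reverse complement."""
        rc = self.recognition.translate(_COMPLEMENT)[::-1]
        return rc == self.recognition

    def _regex(self) -> re.Pattern:
        # Lookahead so overlapping matches are all reported.
        body = "".join(f"[{IUPAC[c]}]" for c in self.recognition)
        return re.compile(f"(?={body})")


# ApeKI G^CWGC; PstI CTGCA^G; MspI C^CGG (top-strand chemistry).
APEKI = Enzyme("ApeKI", "GCWGC", 1)
PSTI = Enzyme("PstI", "CTGCAG", 5)
MSPI = Enzyme("MspI", "CCGG", 1)

BUILTIN_ENZYMES = {e.name: e for e in (APEKI, PSTI, MSPI)}


class CutType(str, Enum):
    """Origin of the cut flanking a fragment end."""

    RARE = "RARE"
    COMMON = "COMMON"
    SINGLE = "SINGLE"
    TERMINUS = "TERMINUS"


@dataclass(frozen=True)
class Fragment:
    """A digest interval, 0-based half-open, classified by its flanking cuts."""

    seq_id: str
    start: int
    end: int
    left_cut: CutType
    right_cut: CutType

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise DigestError(
                f"fragment {self.seq_id}:{self.start}-{self.end}: empty or negative"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def cut_class(self) -> str:
        """Unordered flanking-cut class, e.g. 'RARE-COMMON' (orientation-free)."""
        order = {ct: i for i, ct in enumerate(
            (CutType.RARE, CutType.COMMON, CutType.SINGLE, CutType.TERMINUS))}
        pair = sorted((self.left_cut, self.right_cut), key=order.__getitem__)
        return "-".join(ct.value for ct in pair)


def _validate_sequence(sequence: str) -> str:
    seq = sequence.upper()
    m = re.search("[^ACGTN]", seq)
    if m:
        raise DigestError(
            f"invalid character {m.group()!r} in sequence at position {m.start()}"
        )
    return seq


def find_sites(sequence: str, enzyme: Enzyme) -> list[int]:
    """Return 0-based start positions of every recognition-site match.

    Overlapping matches are included; positions are strictly increasing.
    `N` in the sequence matches only a pattern `N`.
    """
    seq = _validate_sequence(sequence)
    return [m.start() for m in enzyme._regex().finditer(seq)]


def _cuts(sequence: str, enzyme: Enzyme) -> list[int]:
    """Internal cut coordinates (excluding sequence ends)."""
    n = len(sequence)
    return [
        s + enzyme.cut_offset
        for s in find_sites(sequence, enzyme)
        if 0 < s + enzyme.cut_offset < n
    ]


def _tile(seq_id: str, n: int, cuts: dict[int, CutType]) -> list[Fragment]:
    """Tile [0, n) into fragments given cut position -> cut type."""
    bounds = [0, *sorted(cuts), n]
    frags = []
    for a, b in zip(bounds, bounds[1:]):
        left = cuts.get(a, CutType.TERMINUS) if a else CutType.TERMINUS
        right = cuts.get(b, CutType.TERMINUS) if b != n else CutType.TERMINUS
        frags.append(Fragment(seq_id, a, b, left, right))
    return frags


def digest_single(sequence: str, enzyme: Enzyme, seq_id: str = "seq") -> list[Fragment]:
    """Digest with one enzyme. Internal fragments are SINGLE/SINGLE flanked."""
    seq = _validate_sequence(sequence)
    cuts = {c: CutType.SINGLE for c in _cuts(seq, enzyme)}
    return _tile(seq_id, len(seq), cuts)


def digest_double(
    sequence: str, rare: Enzyme, common: Enzyme, seq_id: str = "seq"
) -> list[Fragment]:
    """Digest with a rare/common enzyme pair; each cut is labelled by origin.

    A coordinate cut by both enzymes is ambiguous to classify and is
    reported as an error rather than silently resolved.
    """
    if rare.recognition == common.recognition:
        raise DigestError(
            f"rare and common enzymes share recognition site {rare.recognition!r}"
        )
    seq = _validate_sequence(sequence)
    rare_cuts = set(_cuts(seq, rare))
    common_cuts = set(_cuts(seq, common))
    clash = rare_cuts & common_cuts
    if clash:
        raise DigestError(
            f"{seq_id}: coincident {rare.name}/{common.name} cuts at "
            f"{sorted(clash)}; cut-origin classification is ambiguous"
        )
    cuts = {c: CutType.RARE for c in rare_cuts}
    cuts.update({c: CutType.COMMON for c in common_cuts})
    return _tile(seq_id, len(seq), cuts)


@dataclass
class DigestSummary:
    """Per-class fragment counts and length tallies for one digest."""

    class_counts: Counter = field(default_factory=Counter)
    class_lengths: dict[str, list[int]] = field(default_factory=dict)
    total_length: int = 0
    n_fragments: int = 0

    def add(self, frag: Fragment) -> None:
        cls = frag.cut_class
        self.class_counts[cls] += 1
        self.class_lengths.setdefault(cls, []).append(frag.length)
        self.total_length += frag.length
        self.n_fragments += 1

    def count(self, cut_class: str) -> int:
        return self.class_counts.get(cut_class, 0)

    def to_dict(self) -> dict:
        return {
            "n_fragments": self.n_fragments,
            "total_length": self.total_length,
            "class_counts": dict(self.class_counts),
            "class_mean_length": {
                k: sum(v) / len(v) for k, v in self.class_lengths.items()
            },
        }


def summarize(fragments: Iterable[Fragment]) -> DigestSummary:
    s = DigestSummary()
    for f in fragments:
        s.add(f)
    return s


@dataclass
class ProtocolComparison:
    """One-enzyme vs two-enzyme fragment counts and the relative reduction."""

    one_enzyme: DigestSummary
    two_enzyme: DigestSummary
    one_count: int
    two_count: int
    reduction: float

    def to_dict(self) -> dict:
        return {
            "one_enzyme": self.one_enzyme.to_dict(),
            "two_enzyme": self.two_enzyme.to_dict(),
            "one_enzyme_count": self.one_count,
            "two_enzyme_count": self.two_count,
            "reduction": self.reduction,
        }


def compare_protocols(
    genome: Iterable[tuple[str, str]],
    one_enzyme: Enzyme,
    rare: Enzyme,
    common: Enzyme,
    count_class: str = "sequenced",
    min_length: int | None = None,
    max_length: int | None = None,
) -> ProtocolComparison:
    """Compare one-enzyme vs rare/common two-enzyme complexity reduction.

    ``genome`` yields (seq_id, sequence) records. By default the one-enzyme
    protocol is scored on internal SINGLE-SINGLE fragments and the
    two-enzyme protocol on RARE-COMMON fragments (the sequenced class in a
    rare/common library, where only fragments with one end of each kind
    amplify); ``count_class='all'`` counts every fragment instead. Reports
    ``reduction = 1 - two/one``. An optional fragment-length window
    (off by default) restricts both counts.
    """
    if count_class not in ("sequenced", "all"):
        raise DigestError(f"unknown count_class {count_class!r}")

    def keep(f: Fragment) -> bool:
        if min_length is not None and f.length < min_length:
            return False
        if max_length is not None and f.length > max_length:
            return False
        return True

    one = DigestSummary()
    two = DigestSummary()
    n_records = 0
    for seq_id, seq in genome:
        n_records += 1
        for f in digest_single(seq, one_enzyme, seq_id):
            if keep(f):
                one.add(f)
        for f in digest_double(seq, rare, common, seq_id):
            if keep(f):
                two.add(f)
    if n_records == 0:
        raise DigestError("empty genome: no sequences to digest")

    if count_class == "sequenced":
        one_count = one.count("SINGLE-SINGLE")
        two_count = two.count("RARE-COMMON")
    else:
        one_count = one.n_fragments
        two_count = two.n_fragments
    if one_count == 0:
        raise DigestError(
            "one-enzyme protocol produced zero countable fragments; "
            "relative reduction is undefined"
        )
    reduction = 1.0 - two_count / one_count
    return ProtocolComparison(one, two, one_count, two_count, reduction)


def write_fragments_tsv(fragments: Sequence[Fragment], path: str) -> None:
    """TSV of fragments: seq_id, start, end, length, left_cut, right_cut."""
    with open(path, "w") as fh:
        fh.write("seq_id\tstart\tend\tlength\tleft_cut\tright_cut\n")
        for f in fragments:
            fh.write(
                f"{f.seq_id}\t{f.start}\t{f.end}\t{f.length}\t"
                f"{f.left_cut.value}\t{f.right_cut.value}\n"
            )


def write_summary_json(summary: DigestSummary | ProtocolComparison, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(summary.to_dict(), fh, indent=2)
        fh.write("\n")
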