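"""Barcode demultiplexing with restriction-remnant validation.

In a two-enzyme GBS library each read-1 begins with a sample-specific inline
barcode followed by the rare cutter's remnant (TGCAG for PstI), and each
read-2 begins with the common cutter's remnant (CGG for MspI). A read pair
is assigned to a sample only when both signatures check out; pairs without
a recognizable barcode, with a corrupted remnant on either mate, or
matching two barcodes equally well are rejected with a reason code. The
barcode is trimmed from read 1; the rare remnant is genome-adjacent and is
retained for alignment. Read 2 is left untrimmed.

Technical replicates of a sample (separate barcodes, often separate
libraries) are merged downstream with :func:`merge_replicates` because read
depth is typically uneven between reactions.
"""

from __future__ import annotations

import gzip
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

logger = logging.getLogger(__name__)

__all__ = [
    "BarcodeSpec",
    "ReadPair",
    "DemuxReport",
    "DemuxError",
    "load_barcodes",
    "validate_barcodes",
    "demultiplex",
    "merge_replicates",
    "read_fastq_pairs",
    "write_fastq_pairs",
]

REJECT_REASONS = ("no_barcode", "bad_rare_remnant", "bad_common_remnant", "ambiguous")


class DemuxError(ValueError):
    """Raised for invalid barcode tables or malformed read input."""


@dataclass(frozen=True)
class BarcodeSpec:
    """One barcode -> sample assignment, with replicate/run bookkeeping."""

    sample_id: str
    barcode: str
    replicate_id: str = ""
    run_id: str = ""

    def __post_init__(self) -> None:
        if not self.barcode or set(self.barcode.upper()) - set("ACGT"):
            raise DemuxError(
                f"barcode {self.barcode!r} for sample {self.sample_id!r} "
                "must be a non-empty A/C/G/T string"
            )
        object.__setattr__(self, "barcode", self.barcode.upper())


@dataclass
class ReadPair:
    """A paired-end read: sequences plus Phred qualities, same pair id."""

    pair_id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise DemuxError(f"pair {self.pair_id!r}: quality/sequence length mismatch")


@dataclass
class DemuxReport:
    """Per-sample assignment counts and per-reason reject counts."""

    assigned: Counter = field(default_factory=Counter)
    rejected: Counter = field(default_factory=Counter)
    total: int = 0

    @property
    def n_assigned(self) -> int:
        return sum(self.assigned.values())

    @property
    def n_rejected(self) -> int:
        return sum(self.rejected.values())

    def check_conservation(self) -> None:
        if self.n_assigned + self.n_rejected != self.total:
            raise AssertionError(
                f"demux accounting broken: {self.n_assigned} assigned + "
                f"{self.n_rejected} rejected != {self.total} input pairs"
            )

    def to_dict(self) -> dict:
        return {
            "total_pairs": self.total,
            "assigned": dict(sorted(self.assigned.items())),
            "rejected": {r: self.rejected.get(r, 0) for r in REJECT_REASONS},
        }

    def write_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    def write_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("category\tkey\tcount\n")
            for sample, n in sorted(self.assigned.items()):
                fh.write(f"assigned\t{sample}\t{n}\n")
            for reason in REJECT_REASONS:
                fh.write(f"rejected\t{reason}\t{self.rejected.get(reason, 0)}\n")


def validate_barcodes(barcodes: list[BarcodeSpec], rare_remnant: str = "TGCAG") -> None:
    """Check barcode uniqueness and prefix-safety against the rare remnant.

    A barcode that is a proper prefix of another barcode whose next base
    equals the remnant's first base is ambiguous even under longest-first
    matching (the short barcode + remnant start is indistinguishable from
    the long barcode's start); such tables are rejected at load time.
    """
    if not barcodes:
        raise DemuxError("empty barcode table")
    seen: dict[str, str] = {}
    for spec in barcodes:
        if spec.barcode in seen:
            raise DemuxError(
                f"duplicate barcode {spec.barcode!r} "
                f"(samples {seen[spec.barcode]!r} and {spec.sample_id!r})"
            )
        seen[spec.barcode] = spec.sample_id
    for short in barcodes:
        for long in barcodes:
            b1, b2 = short.barcode, long.barcode
            if len(b1) < len(b2) and b2.startswith(b1) and b2[len(b1)] == rare_remnant[0]:
                raise DemuxError(
                    f"barcode {b1!r} ({short.sample_id}) is a prefix of "
                    f"{b2!r} ({long.sample_id}) continued by the rare-remnant "
                    f"base {rare_remnant[0]!r}; assignments would be ambiguous"
                )


def load_barcodes(path: str, rare_remnant: str = "TGCAG") -> list[BarcodeSpec]:
    """Load a barcode table TSV: sample_id, barcode[, replicate_id[, run_id]]."""
    specs = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if i == 1 and fields[0].lower() in ("sample", "sample_id"):
                continue
            if len(fields) < 2:
                raise DemuxError(f"{path}:{i}: expected >= 2 tab-separated fields")
            specs.append(BarcodeSpec(*fields[:4]))
    validate_barcodes(specs, rare_remnant)
    return specs


def _hamming_within(a: str, b: str, limit: int) -> bool:
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > limit:
                return False
    return True


def demultiplex(
    pairs: Iterable[ReadPair],
    barcodes: list[BarcodeSpec],
    rare_remnant: str = "TGCAG",
    common_remnant: str = "CGG",
    max_mismatch: int = 0,
) -> tuple[dict[str, list[ReadPair]], DemuxReport]:
    """Assign read pairs to samples by barcode + dual remnant check.

    A pair is assigned to sample S iff read 1 starts with S's barcode
    (allowing ``max_mismatch`` mismatches within the barcode only)
    immediately followed by an exact ``rare_remnant``, and read 2 starts
    with an exact ``common_remnant``. Matching is longest-barcode-first;
    two equally long candidate barcodes reject the pair as ambiguous.
    Returns per-sample lists of barcode-trimmed pairs plus a report.
    """
    if set(rare_remnant) - set("ACGT") or set(common_remnant) - set("ACGT"):
        raise DemuxError("remnants must be A/C/G/T strings")
    validate_barcodes(barcodes, rare_remnant)

    by_length: dict[int, list[BarcodeSpec]] = {}
    for spec in barcodes:
        by_length.setdefault(len(spec.barcode), []).append(spec)
    lengths = sorted(by_length, reverse=True)

    assigned: dict[str, list[ReadPair]] = {s.sample_id: [] for s in barcodes}
    report = DemuxReport()

    for pair in pairs:
        report.total += 1
        hit: BarcodeSpec | None = None
        ambiguous = False
        barcode_seen = False
        for L in lengths:
            prefix = pair.seq1[:L]
            if len(prefix) < L:
                continue
            cands = [
                s for s in by_length[L]
                if _hamming_within(prefix, s.barcode, max_mismatch)
            ]
            if not cands:
                continue
            barcode_seen = True
            # remnant must follow the barcode exactly
            valid = [
                s for s in cands
                if pair.seq1[L:L + len(rare_remnant)] == rare_remnant
            ]
            if len(valid) > 1:
                ambiguous = True
                break
            if valid:
                hit = valid[0]
                break
            # barcode matched but remnant corrupted: keep looking at shorter
            # barcodes only if none matched; record the failure otherwise
            break
        if ambiguous:
            report.rejected["ambiguous"] += 1
            continue
        if hit is None:
            report.rejected["bad_rare_remnant" if barcode_seen else "no_barcode"] += 1
            continue
        if not pair.seq2.startswith(common_remnant):
            report.rejected["bad_common_remnant"] += 1
            continue
        L = len(hit.barcode)
        assigned[hit.sample_id].append(
            ReadPair(pair.pair_id, pair.seq1[L:], pair.qual1[L:], pair.seq2, pair.qual2)
        )
        report.assigned[hit.sample_id] += 1

    report.check_conservation()
    return assigned, report


def merge_replicates(
    assigned: Mapping[str, list[ReadPair]],
    replicate_to_sample: Mapping[str, str],
) -> dict[str, list[ReadPair]]:
    """Pool technical-replicate read streams into per-sample streams.

    ``replicate_to_sample`` maps each replicate stream id to its sample.
    Merged counts are the sums of replicate counts; read ids are preserved.
    """
    targets: dict[str, str] = {}
    for rep, sample in replicate_to_sample.items():
        if rep in targets and targets[rep] != sample:
            raise DemuxError(f"replicate {rep!r} mapped to two samples")
        targets[rep] = sample
    merged: dict[str, list[ReadPair]] = {}
    for rep, reads in assigned.items():
        if rep not in targets:
            raise DemuxError(f"replicate stream {rep!r} missing from metadata")
        if not reads:
            logger.warning("replicate %s contributed zero read pairs", rep)
        merged.setdefault(targets[rep], []).extend(reads)
    return merged


def _open_text(path: str, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq_pairs(r1_path: str, r2_path: str) -> Iterator[ReadPair]:
    """Stream mate-synchronized pairs from two FASTQ files (plain or gzip)."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with _open_text(r1_path) as fh1, _open_text(r2_path) as fh2:
        it1 = FastqGeneralIterator(fh1)
        it2 = FastqGeneralIterator(fh2)
        for (t1, s1, q1), (t2, s2, q2) in zip(it1, it2, strict=True):
            id1, id2 = t1.split()[0], t2.split()[0]
            if id1 != id2:
                raise DemuxError(f"mate id mismatch: {id1!r} vs {id2!r}")
            yield ReadPair(id1, s1, q1, s2, q2)


def write_fastq_pairs(reads: Iterable[ReadPair], r1_path: str, r2_path: str) -> None:
    with _open_text(r1_path, "wt") as f1, _open_text(r2_path, "wt") as f2:
        for p in reads:
            f1.write(f"@{p.pair_id}\n{p.seq1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.pair_id}\n{p.seq2}\n+\n{p.qual2}\n")
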