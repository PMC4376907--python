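"""Genotype-matrix construction and the GBS SNP filter cascade.

Per-sample variant calls are merged into one samples x sites dosage matrix
(0/1/2 alternate-allele copies, -1 for missing), then filtered the way
reduced-representation SNP sets are prepared for phylogenetics:

1. repeat masking — drop SNPs inside repeat intervals (mismapping risk);
2. missingness — drop sites, then samples, with too much missing data;
3. minor allele frequency — drop rare/monomorphic sites;
4. LD pruning — drop SNPs redundant (r^2 above cutoff) with a retained
   neighbour, leaving a quasi-independent marker set.

Every stage returns an accounting record and the identity
sites_in - sites_removed = sites_out is enforced throughout, so the full
cascade can be audited after the fact.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MISSING",
    "SiteKey",
    "GenotypeMatrix",
    "FilterConfig",
    "FilterAccounting",
    "MatrixError",
    "merge_vcfs",
    "mask_repeats",
    "filter_missing",
    "filter_maf",
    "ld_prune",
    "filter_quality",
    "het_rate",
    "apply_filter_cascade",
    "read_bed",
]

MISSING: int = -1


class MatrixError(ValueError):
    """Raised for malformed variant input or degenerate filter outcomes."""


class SiteKey(NamedTuple):
    """Identity of one biallelic SNP column."""

    seq_id: str
    pos: int  # 1-based, as printed in VCF
    ref: str
    alt: str


@dataclass
class GenotypeMatrix:
    """Samples x sites dosage matrix with a missing-data sentinel.

    ``dosages[i, j]`` is the alternate-allele count (0, 1, 2) of sample i at
    site j, or ``MISSING`` (-1). Sites are unique and sorted by
    (seq_id, pos, ref, alt).
    """

    samples: list[str]
    sites: list[SiteKey]
    dosages: np.ndarray
    quality: np.ndarray | None = None  # optional per-site QUAL, parallel to sites

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.samples), len(self.sites)):
            raise MatrixError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        if len(set(self.samples)) != len(self.samples):
            raise MatrixError("duplicate sample ids")
        if len(set(self.sites)) != len(self.sites):
            raise MatrixError("duplicate site keys")
        if list(self.sites) != sorted(self.sites):
            raise MatrixError("sites must be sorted by (seq_id, pos, ref, alt)")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise MatrixError(f"invalid dosage values at {np.argwhere(bad)[:5]}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def called(self) -> np.ndarray:
        """Boolean mask of non-missing cells."""
        return self.dosages != MISSING

    def take_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.samples,
            [self.sites[j] for j in idx],
            self.dosages[:, idx],
            None if self.quality is None else self.quality[idx],
        )

    def take_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            [self.samples[i] for i in idx], self.sites, self.dosages[idx, :],
            self.quality,
        )

    def to_dosage_frame(self) -> pd.DataFrame:
        """TSV-friendly table: rows = sites, columns = samples."""
        index = pd.Index(
            [f"{s.seq_id}:{s.pos}:{s.ref}:{s.alt}" for s in self.sites], name="site"
        )
        return pd.DataFrame(self.dosages.T, index=index, columns=self.samples)

    def write_tsv(self, path: str) -> None:
        self.to_dosage_frame().to_csv(path, sep="\t")

    def write_vcf(self, path: str) -> None:
        """Write the matrix as a minimal multi-sample VCF 4.2 file."""
        gt = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            for seq in sorted({s.seq_id for s in self.sites}):
                fh.write(f"##contig=<ID={seq}>\n")
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(self.samples) + "\n"
            )
            for j, site in enumerate(self.sites):
                qual = "." if self.quality is None else f"{self.quality[j]:g}"
                cells = "\t".join(gt[int(d)] for d in self.dosages[:, j])
                fh.write(
                    f"{site.seq_id}\t{site.pos}\t.\t{site.ref}\t{site.alt}\t"
                    f"{qual}\t.\t.\tGT\t{cells}\n"
                )


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the SNP filter cascade.

    Defaults follow standard GBS-phylogenetics practice: drop sites and
    samples with more than 20% missing data (strictly greater), keep sites
    with minor allele frequency >= 10%, and prune SNPs whose r^2 with a
    retained neighbour within a 50-site window exceeds 0.8.
    """

    max_site_missing: float = 0.20
    max_sample_missing: float = 0.20
    min_maf: float = 0.10
    ld_r2_cutoff: float = 0.80
    ld_window_sites: int = 50
    min_qual: float | None = None  # optional site-quality predicate, off by default

    def __post_init__(self) -> None:
        for name in ("max_site_missing", "max_sample_missing", "min_maf", "ld_r2_cutoff"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise MatrixError(f"{name}={v} outside [0, 1]")
        if self.ld_window_sites < 1:
            raise MatrixError("ld_window_sites must be >= 1")


@dataclass
class FilterAccounting:
    """Per-stage bookkeeping; stages must compose exactly."""

    stages: list[dict] = field(default_factory=list)

    def add(self, stage: str, sites_in: int, sites_removed: int, sites_out: int,
            samples_in: int, samples_out: int) -> None:
        if sites_in - sites_removed != sites_out:
            raise AssertionError(
                f"stage {stage}: {sites_in} - {sites_removed} != {sites_out}"
            )
        if self.stages and self.stages[-1]["sites_out"] != sites_in:
            raise AssertionError(
                f"stage {stage}: sites_in {sites_in} does not continue from "
                f"previous stage output {self.stages[-1]['sites_out']}"
            )
        self.stages.append(dict(
            stage=stage, sites_in=sites_in, sites_removed=sites_removed,
            sites_out=sites_out, samples_in=samples_in, samples_out=samples_out,
        ))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages)

    def write_tsv(self, path: str) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def write_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.stages, fh, indent=2)
            fh.write("\n")


def _dosage_from_gt(gt: Sequence[int]) -> int:
    # cyvcf2 genotype: [allele0, allele1, phased]
    a = [x for x in gt[:2] if x is not None and x >= 0]
    if len(a) < 2:
        return MISSING
    return int(a[0] > 0) + int(a[1] > 0)


def merge_vcfs(paths: Sequence[str]) -> GenotypeMatrix:
    """Merge per-sample (or multi-sample) VCFs into one genotype matrix.

    Sites are unioned across files; a sample lacking a record at a site is
    MISSING there. Multi-allelic and non-SNP records are dropped (counted in
    the log). The same (seq_id, pos) with conflicting REF alleles across
    files is an error; differing ALT alleles form distinct matrix columns.
    """
    from cyvcf2 import VCF

    if not paths:
        raise MatrixError("no VCF files given")
    calls: dict[SiteKey, dict[str, int]] = {}
    quals: dict[SiteKey, float] = {}
    ref_at: dict[tuple[str, int], str] = {}
    samples: list[str] = []
    n_multiallelic = 0
    n_nonsnp = 0
    for path in paths:
        try:
            vcf = VCF(str(path))
        except Exception as exc:
            raise MatrixError(f"cannot read VCF {path}: {exc}") from exc
        file_samples = list(vcf.samples)
        for s in file_samples:
            if s in samples:
                raise MatrixError(f"sample {s!r} appears in more than one VCF")
            samples.append(s)
        for var in vcf:
            if len(var.ALT) != 1:
                n_multiallelic += 1
                continue
            ref, alt = var.REF, var.ALT[0]
            if len(ref) != 1 or len(alt) != 1 or alt not in "ACGT":
                n_nonsnp += 1
                continue
            locus = (var.CHROM, var.POS)
            if locus in ref_at and ref_at[locus] != ref:
                raise MatrixError(
                    f"{path}: conflicting REF at {var.CHROM}:{var.POS} "
                    f"({ref_at[locus]!r} vs {ref!r})"
                )
            ref_at[locus] = ref
            key = SiteKey(var.CHROM, var.POS, ref, alt)
            cell = calls.setdefault(key, {})
            if var.QUAL is not None:
                quals[key] = max(quals.get(key, float("-inf")), var.QUAL)
            for s, gt in zip(file_samples, var.genotypes):
                cell[s] = _dosage_from_gt(gt)
    if n_multiallelic or n_nonsnp:
        logger.info(
            "merge_vcfs: dropped %d multi-allelic and %d non-SNP records",
            n_multiallelic, n_nonsnp,
        )
    sites = sorted(calls)
    dosages = np.full((len(samples), len(sites)), MISSING, dtype=np.int8)
    for j, key in enumerate(sites):
        for s, d in calls[key].items():
            dosages[samples.index(s), j] = d
    quality = np.array([quals.get(k, np.nan) for k in sites])
    return GenotypeMatrix(samples, sites, dosages, quality)


def read_bed(path: str) -> list[tuple[str, int, int]]:
    """Read a BED3 file of 0-based half-open intervals."""
    intervals = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise MatrixError(f"{path}:{i}: BED needs >= 3 columns")
            intervals.append((f[0], int(f[1]), int(f[2])))
    return intervals


def mask_repeats(
    matrix: GenotypeMatrix,
    mask: Sequence[tuple[str, int, int]],
    accounting: FilterAccounting | None = None,
) -> tuple[GenotypeMatrix, FilterAccounting]:
    """Drop sites inside repeat intervals (BED, 0-based half-open).

    A VCF site at 1-based ``pos`` is removed when ``pos - 1`` lies in an
    interval on the same sequence. Unsorted input is tolerated.
    """
    acc = accounting if accounting is not None else FilterAccounting()
    by_seq: dict[str, list[tuple[int, int]]] = {}
    for seq_id, start, end in mask:
        if start < 0 or end < 0:
            raise MatrixError(f"negative BED coordinate on {seq_id}: [{start},{end})")
        if end > start:
            by_seq.setdefault(seq_id, []).append((start, end))
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for seq_id, ivals in by_seq.items():
        ivals.sort()
        out: list[list[int]] = []
        for s, e in ivals:
            if out and s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        arr = np.array(out)
        merged[seq_id] = (arr[:, 0], arr[:, 1])

    keep = np.ones(matrix.n_sites, dtype=bool)
    for j, site in enumerate(matrix.sites):
        if site.seq_id not in merged:
            continue
        starts, ends = merged[site.seq_id]
        p = site.pos - 1
        i = np.searchsorted(starts, p, side="right") - 1
        if i >= 0 and p < ends[i]:
            keep[j] = False
    out_m = matrix.take_sites(np.flatnonzero(keep))
    acc.add("mask_repeats", matrix.n_sites, int((~keep).sum()), out_m.n_sites,
            matrix.n_samples, out_m.n_samples)
    return out_m, acc


def filter_quality(
    matrix: GenotypeMatrix,
    cfg: FilterConfig,
    accounting: FilterAccounting | None = None,
) -> tuple[GenotypeMatrix, FilterAccounting]:
    """Optional low-quality site removal (min QUAL predicate); off by default."""
    acc = accounting if accounting is not None else FilterAccounting()
    if cfg.min_qual is None or matrix.quality is None:
        acc.add("quality", matrix.n_sites, 0, matrix.n_sites,
                matrix.n_samples, matrix.n_samples)
        return matrix, acc
    with np.errstate(invalid="ignore"):
        keep = ~(matrix.quality < cfg.min_qual)  # NaN QUAL is retained
    out = matrix.take_sites(np.flatnonzero(keep))
    acc.add("quality", matrix.n_sites, int((~keep).sum()), out.n_sites,
            matrix.n_samples, out.n_samples)
    return out, acc


def filter_missing(
    matrix: GenotypeMatrix,
    cfg: FilterConfig,
    accounting: FilterAccounting | None = None,
) -> tuple[GenotypeMatrix, FilterAccounting]:
    """Drop sites, then samples, whose missing fraction exceeds the limits.

    Site missingness is evaluated first; sample missingness is then
    recomputed on the surviving sites (removing bad sites can rescue
    borderline samples). Because removing a sample can in turn push a
    boundary site over the limit, the site/sample passes are iterated to a
    fixed point, so the output satisfies both constraints simultaneously
    and the filter is idempotent. Both comparisons are strictly
    greater-than.
    """
    acc = accounting if accounting is not None else FilterAccounting()
    out = matrix
    while True:
        site_missing = 1.0 - out.called.mean(axis=0)
        keep_sites = site_missing <= cfg.max_site_missing
        if not keep_sites.any():
            raise MatrixError(
                "missingness filter removed every site; raise max_site_missing"
            )
        m2 = out.take_sites(np.flatnonzero(keep_sites))
        sample_missing = 1.0 - m2.called.mean(axis=1)
        keep_samples = sample_missing <= cfg.max_sample_missing
        nxt = m2.take_samples(np.flatnonzero(keep_samples))
        if nxt.n_sites == out.n_sites and nxt.n_samples == out.n_samples:
            out = nxt
            break
        out = nxt
    acc.add("missing", matrix.n_sites, matrix.n_sites - out.n_sites, out.n_sites,
            matrix.n_samples, out.n_samples)
    return out, acc


def site_maf(matrix: GenotypeMatrix) -> np.ndarray:
    """Per-site minor allele frequency among called genotypes (NaN if none)."""
    called = matrix.called
    n_called = called.sum(axis=0)
    alt = np.where(called, matrix.dosages, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / (2.0 * n_called)
    return np.where(n_called > 0, np.minimum(p, 1.0 - p), np.nan)


def filter_maf(
    matrix: GenotypeMatrix,
    cfg: FilterConfig,
    accounting: FilterAccounting | None = None,
) -> tuple[GenotypeMatrix, FilterAccounting]:
    """Drop sites with minor allele frequency below ``min_maf``.

    maf = min(p, 1-p) with p the alternate-allele frequency over called
    genotypes. Sites at exactly the threshold are kept; sites with zero
    called genotypes are removed.
    """
    acc = accounting if accounting is not None else FilterAccounting()
    maf = site_maf(matrix)
    keep = maf >= cfg.min_maf  # NaN compares False -> uncalled sites removed
    out = matrix.take_sites(np.flatnonzero(keep))
    acc.add("maf", matrix.n_sites, int((~keep).sum()), out.n_sites,
            matrix.n_samples, out.n_samples)
    return out, acc


def pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage columns, pairwise-complete.

    Pairs with fewer than 3 shared called samples, or zero variance in
    either column over the shared samples, score 0 (treated as unlinked).
    """
    shared = (x != MISSING) & (y != MISSING)
    if shared.sum() < 3:
        return 0.0
    xs = x[shared].astype(float)
    ys = y[shared].astype(float)
    if xs.std() == 0.0 or ys.std() == 0.0:
        return 0.0
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


def ld_prune(
    matrix: GenotypeMatrix,
    cfg: FilterConfig,
    accounting: FilterAccounting | None = None,
) -> tuple[GenotypeMatrix, FilterAccounting]:
    """Greedy left-to-right LD pruning within each sequence.

    Scanning sites in position order, a site is kept unless its genotype
    r^2 with any of the last ``ld_window_sites`` kept sites on the same
    sequence exceeds ``ld_r2_cutoff``.
    """
    acc = accounting if accounting is not None else FilterAccounting()
    keep_idx: list[int] = []
    kept_in_seq: list[int] = []
    current_seq: str | None = None
    for j, site in enumerate(matrix.sites):
        if site.seq_id != current_seq:
            current_seq = site.seq_id
            kept_in_seq = []
        col = matrix.dosages[:, j]
        redundant = any(
            pairwise_r2(col, matrix.dosages[:, k]) > cfg.ld_r2_cutoff
            for k in kept_in_seq[-cfg.ld_window_sites:]
        )
        if not redundant:
            keep_idx.append(j)
            kept_in_seq.append(j)
    out = matrix.take_sites(np.array(keep_idx, dtype=int))
    acc.add("ld_prune", matrix.n_sites, matrix.n_sites - out.n_sites, out.n_sites,
            matrix.n_samples, out.n_samples)
    return out, acc


def het_rate(matrix: GenotypeMatrix) -> tuple[float, pd.Series]:
    """Fraction of called genotypes that are heterozygous, overall + per sample."""
    called = matrix.called
    if matrix.n_sites == 0 or matrix.n_samples == 0 or not called.any():
        raise MatrixError("empty matrix: heterozygosity undefined")
    het = matrix.dosages == 1
    overall = float(het.sum() / called.sum())
    with np.errstate(invalid="ignore"):
        per_sample = het.sum(axis=1) / called.sum(axis=1)
    return overall, pd.Series(per_sample, index=matrix.samples, name="het_rate")


def apply_filter_cascade(
    matrix: GenotypeMatrix,
    cfg: FilterConfig | None = None,
    mask: Sequence[tuple[str, int, int]] | None = None,
) -> tuple[GenotypeMatrix, FilterAccounting]:
    """Run the full pipeline: mask -> (quality) -> missing -> maf -> ld."""
    cfg = cfg or FilterConfig()
    acc = FilterAccounting()
    m = matrix
    if mask is not None:
        m, acc = mask_repeats(m, mask, acc)
    if cfg.min_qual is not None:
        m, acc = filter_quality(m, cfg, acc)
    m, acc = filter_missing(m, cfg, acc)
    m, acc = filter_maf(m, cfg, acc)
    m, acc = ld_prune(m, cfg, acc)
    return m, acc
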