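"""Synthetic GBS data with machine-readable ground truth.

Everything downstream of the sequencer can be exercised without any real
data: genomes with restriction sites implanted at known coordinates,
barcoded paired reads drawn from the sequenced fragment class, and
structured genotype matrices drawn from a Balding-Nichols population
model. Every generator is seed-deterministic and returns a truth table
sufficient to score the module that consumes its output.

The population model emulates a selfing germplasm panel: K diverged gene
pools (per-pool allele frequencies drawn Balding-Nichols around a shared
ancestral frequency with divergence F), near-complete homozygosity, and
two missingness processes — a per-sample random-call dropout and a per-run
shared site dropout that reproduces the run-to-run effect where low
coverage makes different sequencing runs observe different loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .demux import BarcodeSpec, ReadPair
from .digest import MSPI, PSTI, CutType, Enzyme, digest_double, find_sites
from .snpmatrix import MISSING, GenotypeMatrix, SiteKey

__all__ = [
    "SynthError",
    "PopulationModel",
    "ReadSimConfig",
    "make_genome",
    "make_reads",
    "make_population",
    "make_barcodes",
    "write_fasta",
]

_BASES = np.array(list("ACGT"))


class SynthError(ValueError):
    """Raised when a requested synthetic dataset is infeasible."""


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def write_fasta(records: list[tuple[str, str]], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def _clean_background(length: int, gc: float, enzymes: list[Enzyme],
                      rng: np.random.Generator, max_rounds: int = 200) -> np.ndarray:
    """Random sequence at the requested GC content with no recognition site
    of any listed enzyme (sites destroyed by point mutation, iteratively)."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = rng.choice(4, size=length, p=p)
    for _ in range(max_rounds):
        s = "".join(_BASES[seq])
        hits = [pos for e in enzymes for pos in find_sites(s, e)]
        if not hits:
            return seq
        for pos in hits:
            i = pos + int(rng.integers(0, min(4, length - pos)))
            seq[i] = (seq[i] + 1 + rng.integers(0, 3)) % 4
    raise SynthError("could not purge recognition sites from background sequence")


def make_genome(
    length: int,
    gc: float = 0.40,
    n_rare_sites: int = 5,
    n_common_sites: int = 40,
    seed: int | None = None,
    rare: Enzyme = PSTI,
    common: Enzyme = MSPI,
    seq_id: str = "synth1",
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """A genome with known restriction-site content.

    The background is free of both recognition patterns; concrete site
    sequences are implanted at recorded, non-overlapping positions, so the
    digest truth is exact. Returns ([(seq_id, sequence)], truth) where
    truth lists (seq_id, position, enzyme) per implanted site. Degenerate
    recognition letters are resolved to a concrete base at implant time.
    """
    rng = np.random.default_rng(seed)
    pat_r, pat_c = rare.recognition, common.recognition
    n_sites = n_rare_sites + n_common_sites
    slot = max(len(pat_r), len(pat_c)) + 2  # 1-base buffer each side
    if n_sites * slot * 2 > length:
        raise SynthError(
            f"{n_sites} sites of slot {slot} do not fit comfortably in {length} bp"
        )

    for attempt in range(20):
        seq = _clean_background(length, gc, [rare, common], rng)
        # stars-and-bars: sorted draws plus a fixed stride guarantee >= slot gaps
        free = length - 1 - slot - n_sites * slot
        base = np.sort(rng.choice(free, size=n_sites, replace=False))
        positions = base + slot * np.arange(n_sites) + 1
        labels = np.array([rare.name] * n_rare_sites + [common.name] * n_common_sites)
        rng.shuffle(labels)
        iupac_pick = {  # concrete base per degenerate letter, chosen at random
            "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
            "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
        }
        for pos, lab in zip(positions, labels):
            pat = pat_r if lab == rare.name else pat_c
            concrete = "".join(
                c if c in "ACGT" else iupac_pick[c][rng.integers(0, len(iupac_pick[c]))]
                for c in pat
            )
            seq[pos:pos + len(pat)] = [("ACGT").index(b) for b in concrete]
        s = "".join(_BASES[seq])
        # implanting may create extra matches at slot borders; verify exactly
        found_r = find_sites(s, rare)
        found_c = find_sites(s, common)
        want_r = sorted(int(p) for p, l in zip(positions, labels) if l == rare.name)
        want_c = sorted(int(p) for p, l in zip(positions, labels) if l == common.name)
        if found_r == want_r and found_c == want_c:
            truth = pd.DataFrame({
                "seq_id": seq_id,
                "position": positions.astype(int),
                "enzyme": labels,
            })
            return [(seq_id, s)], truth
    raise SynthError("failed to implant sites without collateral matches")


def make_barcodes(
    n: int, length: int = 6, seed: int | None = None,
    rare_remnant: str = "TGCAG", runs: int = 1,
) -> list[BarcodeSpec]:
    """Random unique A/C/G/T barcodes, prefix-safe by equal length.

    Samples are named S01, S02, ...; with ``runs`` > 1 each sample gets one
    barcode per run (technical replicates r1, r2, ...).
    """
    rng = np.random.default_rng(seed)
    need = n * runs
    if need > 4 ** length:
        raise SynthError("barcode space too small")
    codes: set[str] = set()
    while len(codes) < need:
        codes.add("".join(_BASES[rng.integers(0, 4, size=length)]))
    ordered = sorted(codes)
    rng.shuffle(ordered)
    specs = []
    width = len(str(n))
    for i in range(n):
        for r in range(runs):
            specs.append(BarcodeSpec(
                sample_id=f"S{i + 1:0{width}d}" + (f"_r{r + 1}" if runs > 1 else ""),
                barcode=ordered[i * runs + r],
                replicate_id=f"r{r + 1}",
                run_id=f"run{r + 1}",
            ))
    return specs


@dataclass(frozen=True)
class ReadSimConfig:
    """How synthetic read pairs are drawn from the sequenced fragments.

    ``depth_multipliers`` models sample-dependent DNA-quality bias: each
    sample's expected read share is proportional to its multiplier (uneven
    template quality, not run-to-run variation, drives uneven read counts).
    """

    barcodes: list[BarcodeSpec] = field(default_factory=list)
    rare: Enzyme = PSTI
    common: Enzyme = MSPI
    rare_remnant: str = "TGCAG"
    common_remnant: str = "CGG"
    read_length: int = 100
    error_rate: float = 0.0
    depth_multipliers: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.depth_multipliers is not None:
            if any(v <= 0 for v in self.depth_multipliers.values()):
                raise SynthError("depth multipliers must be positive")


def make_reads(
    genome: list[tuple[str, str]],
    cfg: ReadSimConfig,
    n_pairs: int,
    seed: int | None = None,
) -> tuple[list[ReadPair], pd.DataFrame, int]:
    """Paired reads from rare-common fragments, with assignment truth.

    read1 = barcode + rare remnant + fragment interior prefix;
    read2 = common remnant + reverse complement of the fragment's common
    end. Sequencing errors (if enabled) touch only the genomic interior so
    barcode and remnants stay intact. Returns (pairs, truth, n_skipped)
    where truth maps pair_id -> sample_id and n_skipped counts fragments
    too short to carry both remnants.
    """
    if not cfg.barcodes:
        raise SynthError("no barcodes configured")
    rng = np.random.default_rng(seed)
    frags: list[str] = []
    n_skipped = 0
    min_len = len(cfg.rare_remnant) + len(cfg.common_remnant)
    for seq_id, seq in genome:
        for f in digest_double(seq.upper(), cfg.rare, cfg.common, seq_id):
            if {f.left_cut, f.right_cut} != {CutType.RARE, CutType.COMMON}:
                continue
            sub = seq[f.start:f.end].upper()
            if f.left_cut is CutType.COMMON:  # orient rare end leftwards
                sub = _revcomp(sub)
            if len(sub) < min_len:
                n_skipped += 1
                continue
            frags.append(sub)
    if not frags:
        raise SynthError("genome yields no usable rare-common fragments")

    samples = sorted({b.sample_id for b in cfg.barcodes})
    bc_of = {b.sample_id: b.barcode for b in cfg.barcodes}
    mult = cfg.depth_multipliers or {s: 1.0 for s in samples}
    weights = np.array([mult.get(s, 1.0) for s in samples], dtype=float)
    weights /= weights.sum()

    pairs: list[ReadPair] = []
    rows = []
    for i in range(n_pairs):
        s = samples[rng.choice(len(samples), p=weights)]
        frag = frags[rng.integers(0, len(frags))]
        bc = bc_of[s]
        interior = frag  # fragment interior carries the remnant context itself
        fwd = cfg.rare_remnant + interior
        rev = cfg.common_remnant + _revcomp(interior)
        if cfg.error_rate > 0:
            fwd = fwd[:len(cfg.rare_remnant)] + _mutate(
                fwd[len(cfg.rare_remnant):], cfg.error_rate, rng)
            rev = rev[:len(cfg.common_remnant)] + _mutate(
                rev[len(cfg.common_remnant):], cfg.error_rate, rng)
        seq1 = (bc + fwd)[:cfg.read_length]
        seq2 = rev[:cfg.read_length]
        pid = f"pair{i:06d}"
        pairs.append(ReadPair(pid, seq1, "I" * len(seq1), seq2, "I" * len(seq2)))
        rows.append((pid, s))
    truth = pd.DataFrame(rows, columns=["pair_id", "sample_id"])
    return pairs, truth, n_skipped


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        out[i] = "ACGT"[(("ACGT").index(out[i]) + 1 + rng.integers(0, 3)) % 4]
    return "".join(out)


@dataclass(frozen=True)
class PopulationModel:
    """A K-pool Balding-Nichols germplasm panel.

    Per site s an ancestral frequency p_s ~ U(0.05, 0.95) is drawn; each
    pool k draws its own frequency from Beta with mean p_s and divergence
    F (larger F, more drift between pools). Genotypes follow
    Hardy-Weinberg deflated by the inbreeding coefficient (selfing crops
    are nearly fully homozygous, so ``inbreeding`` defaults to 0.99,
    leaving heterozygote rates well under 1%). Missing data combine a
    per-sample random dropout with a per-run shared site dropout.
    """

    n_pools: int = 4
    samples_per_pool: int = 10
    n_sites: int = 2000
    divergence_f: float = 0.3
    inbreeding: float = 0.99
    sample_missing_rate: float = 0.05
    n_runs: int = 1
    run_site_dropout: float = 0.0
    freq_low: float = 0.05
    freq_high: float = 0.95

    def __post_init__(self) -> None:
        for name in ("divergence_f",):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise SynthError(f"{name}={v} must be in (0, 1)")
        for name in ("inbreeding", "sample_missing_rate", "run_site_dropout"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SynthError(f"{name}={v} must be in [0, 1]")


def make_population(
    model: PopulationModel, seed: int | None = None
) -> tuple[GenotypeMatrix, dict]:
    """Draw a structured genotype matrix plus its ground truth.

    Returns (matrix, truth); truth holds ``pool_of`` (sample -> pool
    label), ``pool_freqs`` (pools x sites), ``ancestral_freqs`` and a
    ``metadata`` frame (sample_id, accession, taxon, replicate, run)
    suitable for the authenticity audit, with taxon = pool label.
    """
    rng = np.random.default_rng(seed)
    K, n_per, S = model.n_pools, model.samples_per_pool, model.n_sites
    p = rng.uniform(model.freq_low, model.freq_high, size=S)
    F = model.divergence_f
    a, b = p * (1 - F) / F, (1 - p) * (1 - F) / F
    pool_freqs = rng.beta(a, b, size=(K, S))

    samples, pools, rows = [], [], []
    dosages = np.empty((K * n_per, S), dtype=np.int8)
    f_is = model.inbreeding
    for k in range(K):
        pool = f"pool{k + 1}"
        q = pool_freqs[k]
        p_hom_alt = q * q + f_is * q * (1 - q)
        p_het = 2 * q * (1 - q) * (1 - f_is)
        for i in range(n_per):
            sid = f"{pool}_s{i + 1:02d}"
            u = rng.random(S)
            g = np.where(u < p_hom_alt, 2, np.where(u < p_hom_alt + p_het, 1, 0))
            dosages[len(samples)] = g
            run = f"run{(i % model.n_runs) + 1}"
            samples.append(sid)
            pools.append(pool)
            rows.append((sid, f"acc_{pool}_{i + 1:02d}", pool, "r1", run))

    # per-run shared site dropout, then per-sample random dropout
    meta = pd.DataFrame(
        rows, columns=["sample_id", "accession", "taxon", "replicate", "run"])
    for run in meta["run"].unique():
        if model.run_site_dropout > 0:
            drop = rng.random(S) < model.run_site_dropout
            dosages[np.ix_(meta.index[meta["run"] == run], np.flatnonzero(drop))] = MISSING
    if model.sample_missing_rate > 0:
        miss = rng.random(dosages.shape) < model.sample_missing_rate
        dosages[miss] = MISSING

    sites = [SiteKey("chr1", 10 * (j + 1), "A", "C") for j in range(S)]
    matrix = GenotypeMatrix(samples, sites, dosages)
    truth = {
        "pool_of": dict(zip(samples, pools)),
        "pool_freqs": pool_freqs,
        "ancestral_freqs": p,
        "metadata": meta,
    }
    return matrix, truth
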