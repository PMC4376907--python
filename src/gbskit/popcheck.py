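"""Downstream population checks: Evanno ΔK and germplasm authenticity.

``delta_k`` post-processes replicate log-likelihoods from any model-based
clustering tool (e.g. STRUCTURE runs at K = 1..10, five replicates each)
into the Evanno table: L'(K) = mean L(K) - mean L(K-1),
|L''(K)| = |L'(K+1) - L'(K)|, and ΔK = |L''(K)| / sd(L(K)). The K with the
largest ΔK is the supported number of clusters. ΔK depends only on
differences of L, so it is invariant to adding a constant to every value.

``check_replicates`` operationalizes the authenticity audit of a germplasm
panel: in a trustworthy collection, a sample's nearest neighbours in
genetic distance share its recorded taxon, and biological replicates of an
accession sit closer to each other than to anything else of that taxon.
Samples violating the first rule are flagged MISCLASSIFIED (label/seed-lot
errors); violations of the second are flagged REPLICATE_DISCORDANT.
"""

from __future__ import annotations

import json
import logging
import warnings

import numpy as np
import pandas as pd

from .phylo import DistanceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PopcheckError",
    "delta_k",
    "load_logl_table",
    "check_replicates",
]


class PopcheckError(ValueError):
    """Raised for malformed likelihood tables or metadata mismatches."""


def load_logl_table(path: str) -> pd.DataFrame:
    """Read a (K, replicate, logL) TSV as produced by clustering wrappers."""
    df = pd.read_csv(path, sep="\t")
    needed = {"K", "logL"}
    if not needed <= set(df.columns):
        raise PopcheckError(f"{path}: need columns {sorted(needed)}")
    return df


def delta_k(table: pd.DataFrame) -> tuple[int, pd.DataFrame]:
    """Evanno ΔK over replicate clustering log-likelihoods.

    ``table`` has columns K and logL (one row per replicate run). Returns
    (best K, full table) where the table carries mean_L, sd_L, L', |L''|
    and ΔK per K; ΔK is defined only for interior K values. A zero
    standard deviation yields an infinite ΔK with a warning.
    """
    if not {"K", "logL"} <= set(table.columns):
        raise PopcheckError("table needs columns 'K' and 'logL'")
    grouped = table.groupby("K")["logL"]
    ks = np.array(sorted(grouped.groups))
    if len(ks) < 4:
        raise PopcheckError("Evanno ΔK needs >= 4 consecutive K values")
    if not np.all(np.diff(ks) == 1):
        raise PopcheckError(f"K values must be contiguous; got {ks.tolist()}")
    counts = grouped.count().reindex(ks)
    if (counts < 2).any():
        raise PopcheckError("need >= 2 replicates per K for sd(L(K))")
    mean_l = grouped.mean().reindex(ks).to_numpy()
    sd_l = grouped.std(ddof=1).reindex(ks).to_numpy()

    lp = np.full(len(ks), np.nan)  # L'(K), defined for K >= second
    lp[1:] = np.diff(mean_l)
    lpp = np.full(len(ks), np.nan)  # |L''(K)|, interior K only
    lpp[1:-1] = np.abs(lp[2:] - lp[1:-1])
    dk = np.full(len(ks), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        dk[1:-1] = lpp[1:-1] / sd_l[1:-1]
    if np.any(sd_l[1:-1] == 0):
        warnings.warn("sd(L(K)) is zero for some K; ΔK reported as infinite")
        dk[1:-1] = np.where(sd_l[1:-1] == 0, np.inf, dk[1:-1])

    out = pd.DataFrame({
        "K": ks, "n_replicates": counts.to_numpy(), "mean_L": mean_l,
        "sd_L": sd_l, "L_prime": lp, "abs_L_doubleprime": lpp, "delta_K": dk,
    })
    interior = out["delta_K"].dropna()
    best_k = int(out.loc[interior.idxmax(), "K"])
    return best_k, out


def _validate_metadata(meta: pd.DataFrame, ids: list[str]) -> pd.DataFrame:
    needed = {"sample_id", "accession", "taxon"}
    if not needed <= set(meta.columns):
        raise PopcheckError(f"metadata needs columns {sorted(needed)}")
    if meta["sample_id"].duplicated().any():
        raise PopcheckError("duplicate sample_id in metadata")
    meta = meta.set_index("sample_id")
    missing = set(ids) - set(meta.index)
    extra = set(meta.index) - set(ids)
    if missing or extra:
        raise PopcheckError(
            f"metadata/distance sample sets differ: missing {sorted(missing)}, "
            f"extra {sorted(extra)}"
        )
    return meta.loc[ids]


def check_replicates(
    dist: DistanceMatrix,
    meta: pd.DataFrame,
    k_neighbors: int = 1,
) -> tuple[pd.DataFrame, dict]:
    """Audit taxon labels and replicate concordance from genetic distances.

    For each sample, its ``k_neighbors`` nearest neighbours (self excluded,
    distance ties broken by sample-id order) vote a taxon by majority, ties
    resolved in favour of the nearest neighbour; a sample whose voted taxon
    differs from its recorded taxon is flagged MISCLASSIFIED. Because a
    mislabeled sample also casts a wrong vote for whoever sits next to it,
    the vote is iterated to a fixed point with currently-flagged samples
    excluded as voters — so one bad label cannot drag its genuine
    neighbours into the flag set. A sample with at least one other
    replicate of its accession present is additionally flagged
    REPLICATE_DISCORDANT unless its nearest same-taxon neighbour is one of
    those replicates. Returns the per-sample audit table and a summary with
    the flagged fractions.
    """
    ids = dist.ids
    n = len(ids)
    if k_neighbors >= n:
        raise PopcheckError(f"k_neighbors={k_neighbors} must be < {n} samples")
    meta = _validate_metadata(meta.reset_index() if meta.index.name == "sample_id" else meta, ids)
    taxa = meta["taxon"].to_numpy()
    accessions = meta["accession"].to_numpy()

    # stable order: distance first, then sample id for ties
    id_rank = {s: k for k, s in enumerate(sorted(ids))}
    order_of = {
        i: sorted(
            (j for j in range(n) if j != i),
            key=lambda j: (dist.values[i, j], id_rank[ids[j]]),
        )
        for i in range(n)
    }

    def vote(i: int, excluded: frozenset[int]) -> str:
        voters = [j for j in order_of[i] if j not in excluded][:k_neighbors]
        if not voters:  # everything excluded: fall back to all neighbours
            voters = order_of[i][:k_neighbors]
        top = pd.Series([taxa[j] for j in voters]).value_counts()
        winners = set(top[top == top.max()].index)
        return next(taxa[j] for j in voters if taxa[j] in winners)

    flagged: frozenset[int] = frozenset()
    voted_now = {}
    for _ in range(10):  # fixed point is reached in 2-3 rounds in practice
        voted_now = {i: vote(i, flagged) for i in range(n)}
        new = frozenset(i for i in range(n) if voted_now[i] != taxa[i])
        if new == flagged:
            break
        flagged = new

    rows = []
    for i, sid in enumerate(ids):
        order = order_of[i]
        same_acc = [j for j in range(n) if j != i and accessions[j] == accessions[i]]
        discordant = False
        if same_acc:
            same_taxon = [j for j in order if taxa[j] == taxa[i]]
            discordant = bool(same_taxon) and same_taxon[0] not in same_acc
        rows.append(dict(
            sample_id=sid, taxon=taxa[i], voted_taxon=voted_now[i],
            nearest=ids[order[0]], misclassified=i in flagged,
            replicate_discordant=discordant,
        ))
    audit = pd.DataFrame(rows)
    summary = {
        "n_samples": n,
        "n_misclassified": int(audit["misclassified"].sum()),
        "fraction_misclassified": float(audit["misclassified"].mean()),
        "n_replicate_discordant": int(audit["replicate_discordant"].sum()),
        "fraction_flagged": float(
            (audit["misclassified"] | audit["replicate_discordant"]).mean()
        ),
    }
    return audit, summary


def write_audit(audit: pd.DataFrame, summary: dict, tsv_path: str, json_path: str) -> None:
    audit.to_csv(tsv_path, sep="\t", index=False)
    with open(json_path, "w") as fh:
        json.dump(summary, fh, indent=2)
        fh.write("\n")
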