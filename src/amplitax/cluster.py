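"""Dereplication, OTU clustering, and read-to-OTU abundance mapping.

The built-in clusterer is a greedy centroid algorithm over dereplicated
sequences in decreasing abundance order — a transparent stand-in that
lets the pipeline run end-to-end with no external dependency.  Serious
denoising clusterers (UPARSE-style) plug in through
``load_external_clusters``, which parses a seeds FASTA plus a two-column
membership table.

Abundance is estimated by mapping every high- and mid-quality read onto
the OTU seeds: best identity above the threshold wins, ties go to the
lexicographically smallest OTU id, so the matrix is order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from ._align import identity
from .seqio import SequenceRead, read_sequences

DEFAULT_IDENTITY = 0.97


@dataclass
class OtuCluster:
    otu_id: str
    seed: SequenceRead
    member_read_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.seed.bases:
            raise ValueError(f"{self.otu_id}: empty seed sequence")


@dataclass
class AbundanceMatrix:
    """Integer OTU x sample count matrix."""

    otu_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # shape (n_otus, n_samples), dtype int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("negative abundance count")
        if self.counts.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise ValueError("count matrix shape mismatch")

    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.otu_ids,
                            columns=self.sample_ids)

    def write_tsv(self, path) -> None:
        self.to_frame().rename_axis("#OTU").to_csv(path, sep="\t")


def dereplicate(
    reads: Iterable[SequenceRead],
) -> list[tuple[str, int, list[str]]]:
    """Exact-string dereplication.

    Returns ``(sequence, size, member read ids)`` sorted by size
    descending, size ties broken lexicographically by sequence.
    """
    groups: dict[str, list[str]] = {}
    for read in reads:
        groups.setdefault(read.bases, []).append(read.read_id)
    return sorted(
        ((seq, len(ids), ids) for seq, ids in groups.items()),
        key=lambda t: (-t[1], t[0]),
    )


def cluster_otus(
    dereplicated: Sequence[tuple[str, int, list[str]]],
    identity_threshold: float = DEFAULT_IDENTITY,
    otu_prefix: str = "OTU_",
) -> list[OtuCluster]:
    """Greedy centroid clustering in abundance order.

    Each dereplicated sequence joins the first existing centroid it
    matches at >= the identity threshold, else founds a new OTU.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0, 1]")
    clusters: list[OtuCluster] = []
    for seq, _size, member_ids in dereplicated:
        placed = False
        for cluster in clusters:
            if identity(seq, cluster.seed.bases) >= identity_threshold:
                cluster.member_read_ids.update(member_ids)
                placed = True
                break
        if not placed:
            clusters.append(OtuCluster(
                otu_id=f"{otu_prefix}{len(clusters) + 1}",
                seed=SequenceRead(read_id=member_ids[0], bases=seq),
                member_read_ids=set(member_ids),
            ))
    return clusters


def load_external_clusters(seed_fasta, membership_tsv) -> list[OtuCluster]:
    """Adapter for an external clusterer's output: a FASTA of seed
    sequences (headers = OTU ids) and a (read_id, otu_id) TSV."""
    members = pd.read_csv(membership_tsv, sep="\t", header=None,
                          names=["read_id", "otu_id"], dtype=str)
    by_otu = members.groupby("otu_id")["read_id"].apply(set).to_dict()
    clusters = []
    for rec in read_sequences(seed_fasta):
        clusters.append(OtuCluster(
            otu_id=rec.read_id,
            seed=rec,
            member_read_ids=by_otu.get(rec.read_id, set()),
        ))
    return clusters


def map_reads_to_otus(
    reads: Iterable[SequenceRead],
    clusters: Sequence[OtuCluster],
    identity_threshold: float = DEFAULT_IDENTITY,
) -> tuple[AbundanceMatrix, list[str]]:
    """Assign each read to its best-identity seed and count per sample.

    Returns the abundance matrix and the ids of unmapped reads (below
    threshold to every seed); each read is counted at most once.
    """
    seeds = sorted(clusters, key=lambda c: c.otu_id)
    otu_ids = [c.otu_id for c in seeds]
    otu_index = {oid: i for i, oid in enumerate(otu_ids)}
    sample_ids: list[str] = []
    sample_index: dict[str, int] = {}
    assignments: list[tuple[int, int]] = []
    unmapped: list[str] = []
    for read in reads:
        best_id = None
        best_otu = None
        for cluster in seeds:  # seeds sorted, so ties keep the smaller otu_id
            ident = identity(read.bases, cluster.seed.bases)
            if ident >= identity_threshold and (best_id is None or ident > best_id):
                best_id, best_otu = ident, cluster.otu_id
        if best_otu is None:
            unmapped.append(read.read_id)
            continue
        sample = read.sample or "unknown"
        if sample not in sample_index:
            sample_index[sample] = len(sample_ids)
            sample_ids.append(sample)
        assignments.append((otu_index[best_otu], sample_index[sample]))
    counts = np.zeros((len(otu_ids), len(sample_ids)), dtype=np.int64)
    for i, j in assignments:
        counts[i, j] += 1
    order = np.argsort(sample_ids)
    return (
        AbundanceMatrix(otu_ids, [sample_ids[k] for k in order],
                        counts[:, order] if len(sample_ids) else counts),
        unmapped,
    )


def check_otu_overlap(
    clusters: Sequence[OtuCluster],
    identity_threshold: float = DEFAULT_IDENTITY,
) -> list[tuple[str, str, float]]:
    """Report seed pairs whose mutual identity reaches the OTU radius."""
    pairs = []
    ordered = sorted(clusters, key=lambda c: c.otu_id)
    for i, a in enumerate(ordered):
        for b in ordered[i + 1:]:
            ident = identity(a.seed.bases, b.seed.bases)
            if ident >= identity_threshold:
                pairs.append((a.otu_id, b.otu_id, ident))
    return pairs


def merge_overlapping(
    clusters: list[OtuCluster],
    identity_threshold: float = DEFAULT_IDENTITY,
) -> list[OtuCluster]:
    """Collapse each overlapping seed pair: the smaller OTU (by member
    count, ties by otu_id) merges into the larger.  Idempotent: a second
    pass reports no overlaps."""
    clusters = [replace(c, member_read_ids=set(c.member_read_ids))
                for c in clusters]
    merged = True
    while merged:
        merged = False
        pairs = check_otu_overlap(clusters, identity_threshold)
        if not pairs:
            break
        a_id, b_id, _ = pairs[0]
        by_id = {c.otu_id: c for c in clusters}
        a, b = by_id[a_id], by_id[b_id]
        keep, drop = (a, b) if len(a.member_read_ids) >= len(b.member_read_ids) else (b, a)
        keep.member_read_ids |= drop.member_read_ids
        clusters.remove(drop)
        merged = True
    return clusters
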