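"""OTU seed extension: swap each cluster's truncated representative for
the best full-length member read.

Clustering runs on reads pruned to a common short length (the
high-quality 5' region), so the clustering representative is a poor
sequence to annotate or build trees from.  Seed extension searches the
full-length high-quality reads belonging to the cluster for one that is
(1) close to the centre of the OTU, (2) low in expected sequencing
error, and (3) as long as possible — ranked lexicographically in that
order, with the read id as a final determinism tie-break.

For paired-end data the mates of the winning pair are overlap-merged
here rather than calling out to an external merger.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from ._align import identity
from .demux import FilterSpec, expected_error, trim_low_quality_tail
from .cluster import OtuCluster
from .seqio import SequenceRead

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(read: SequenceRead) -> SequenceRead:
    return SequenceRead(
        read_id=read.read_id,
        bases=read.bases.translate(COMPLEMENT)[::-1],
        quals=read.quals[::-1] if read.quals is not None else None,
        pair_role=read.pair_role,
        sample=read.sample,
    )


@dataclass(frozen=True)
class SeedCandidate:
    read: SequenceRead
    identity_to_consensus: float  # vs the clustering representative
    mean_error: float  # expected error per base
    length: int


def collect_candidates(
    cluster: OtuCluster,
    full_length_high: Mapping[str, SequenceRead],
    identity_threshold: float = 0.97,
    filter_spec: Optional[FilterSpec] = None,
) -> list[SeedCandidate]:
    """Full-length high-quality member reads aligning to the cluster
    representative at or above the threshold, quality-tail-trimmed.

    Mid-quality reads never become seeds: only ids present in
    ``full_length_high`` are considered.
    """
    spec = filter_spec or FilterSpec()
    candidates = []
    for read_id in sorted(cluster.member_read_ids):
        read = full_length_high.get(read_id)
        if read is None:
            continue
        if read.quals is not None:
            read = trim_low_quality_tail(
                read, spec.window_width, spec.window_min_qual, spec.trim_from)
        if not read.bases:
            continue
        ident = identity(read.bases, cluster.seed.bases)
        if ident < identity_threshold:
            continue
        mean_err = (expected_error(read.quals) / len(read)
                    if read.quals is not None else 0.0)
        candidates.append(SeedCandidate(read, ident, mean_err, len(read)))
    return candidates


def select_seed(candidates: Sequence[SeedCandidate]) -> SequenceRead:
    """Pick the seed by lexicographic ranking: closest to the candidates'
    median identity (OTU centre), then least per-base expected error,
    then longest, then smallest read id."""
    if not candidates:
        raise ValueError("select_seed requires at least one candidate")
    median_ident = statistics.median(c.identity_to_consensus for c in candidates)
    best = min(
        candidates,
        key=lambda c: (abs(c.identity_to_consensus - median_ident),
                       c.mean_error, -c.length, c.read.read_id),
    )
    return best.read


def extend_seeds(
    clusters: Iterable[OtuCluster],
    full_length_high: Mapping[str, SequenceRead],
    identity_threshold: float = 0.97,
    filter_spec: Optional[FilterSpec] = None,
) -> tuple[list[OtuCluster], list[str]]:
    """Replace every cluster seed that has viable full-length candidates;
    clusters with none keep their representative and are reported."""
    extended = []
    kept_representative = []
    for cluster in clusters:
        cands = collect_candidates(cluster, full_length_high,
                                   identity_threshold, filter_spec)
        if cands:
            seed = select_seed(cands)
            extended.append(OtuCluster(cluster.otu_id, seed,
                                       set(cluster.member_read_ids)))
        else:
            kept_representative.append(cluster.otu_id)
            extended.append(cluster)
    return extended, kept_representative


def merge_pair(
    fwd: SequenceRead,
    rev: SequenceRead,
    min_overlap: int = 10,
    max_mismatch_fraction: float = 0.25,
) -> Optional[SequenceRead]:
    """Overlap-merge a read pair into one fragment-spanning read.

    The reverse mate is reverse-complemented, then overlap lengths are
    scanned from longest to shortest; the first overlap whose mismatch
    fraction is acceptable wins.  At overlap columns the higher-quality
    base is kept; merged quality is max(Qf, Qr) on agreement and
    max - min (floor 2) on disagreement.  Returns None when no
    acceptable overlap exists (callers fall back to the forward read).
    """
    rc = reverse_complement(rev)
    max_olap = min(len(fwd), len(rc))
    for olap in range(max_olap, min_overlap - 1, -1):
        f_tail = fwd.bases[len(fwd) - olap:]
        r_head = rc.bases[:olap]
        mism = sum(a != b for a, b in zip(f_tail, r_head))
        if mism / olap > max_mismatch_fraction:
            continue
        f_quals = fwd.quals if fwd.quals is not None else (0,) * len(fwd)
        r_quals = rc.quals if rc.quals is not None else (0,) * len(rc)
        bases = list(fwd.bases[:len(fwd) - olap])
        quals = list(f_quals[:len(fwd) - olap])
        for k in range(olap):
            fb, rb = f_tail[k], r_head[k]
            fq, rq = f_quals[len(fwd) - olap + k], r_quals[k]
            if fb == rb:
                bases.append(fb)
                quals.append(max(fq, rq))
            else:
                bases.append(fb if fq >= rq else rb)
                quals.append(max(max(fq, rq) - min(fq, rq), 2))
        bases.extend(rc.bases[olap:])
        quals.extend(r_quals[olap:])
        has_quals = fwd.quals is not None and rev.quals is not None
        return SequenceRead(
            read_id=fwd.read_id,
            bases="".join(bases),
            quals=tuple(quals) if has_quals else None,
            pair_role="single",
            sample=fwd.sample,
        )
    return None
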