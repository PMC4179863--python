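"""Read simulation and classifier validation.

Reads are simulated from a labelled reference set by truncating each
sampled reference to a fixed length from its 5' end (amplicons share
the primer-proximal region) and applying i.i.d. random substitutions.
The simulated reads are then classified with the windowed-LCA algorithm
against the same reference set — optionally with the source sequence
excluded (``exclude_self``) or every close relative removed
(``exclude_relatives_identity``), emulating a taxon absent from the
database — and the predictions are scored per rank against the truth
lineages: precision TP/(TP+FP), specificity TN/(TN+FP) and the
unassigned fraction.

A hierarchical synthetic reference generator (`make_reference_set`)
provides labelled 16S-like databases for tests and validation runs
without any download: lineages are a balanced tree, and sequence
divergence between taxa decreases with rank depth so that identity
roughly tracks taxonomic relatedness, as in real 16S data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._align import percent_identity
from .seqio import MappingRow, MappingTable, SequenceRead
from .taxonomy import (
    RANKS, UNASSIGNED, AlignmentHit, LcaSpec, TaxonomyPath, lca_assign,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_ALPHABET = "ACGT"


@dataclass
class SimSpec:
    """Conditions for one simulation: read count and length, per-base
    substitution rate, RNG seed, and which database entries the
    classifier may see."""

    n_reads: int = 1000
    read_length: int = 250
    per_base_mutation_rate: float = 0.02
    rng_seed: int = 0
    exclude_self: bool = True
    exclude_relatives_identity: Optional[float] = None  # percent

    def __post_init__(self) -> None:
        if not 0 <= self.per_base_mutation_rate < 1:
            raise ValueError("mutation rate must be in [0, 1)")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")


@dataclass(frozen=True)
class SimRead:
    read: SequenceRead
    source_id: str
    truth: TaxonomyPath


def mutate(bases: str, rate: float, rng: np.random.Generator) -> str:
    """Apply i.i.d. substitutions; each hit base becomes one of the
    three alternatives uniformly."""
    if rate == 0:
        return bases
    arr = np.frombuffer(bases.encode(), dtype="S1").copy()
    hit = rng.random(len(arr)) < rate
    idx = np.nonzero(hit)[0]
    for i in idx:
        choices = [b for b in _BASES if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return arr.tobytes().decode()


def simulate_reads(
    references: Mapping[str, str],
    taxonomy: Mapping[str, TaxonomyPath],
    spec: SimSpec,
) -> list[SimRead]:
    """Sample references (uniformly, with replacement), truncate each to
    the 5' ``read_length`` prefix and mutate.  References shorter than
    the read length are skipped.  Deterministic under ``rng_seed``."""
    eligible = sorted(rid for rid, seq in references.items()
                      if len(seq) >= spec.read_length)
    if not eligible:
        raise ValueError("no reference is at least read_length long")
    rng = np.random.default_rng(spec.rng_seed)
    picks = rng.integers(len(eligible), size=spec.n_reads)
    reads = []
    for i, pick in enumerate(picks):
        source = eligible[pick]
        bases = mutate(references[source][:spec.read_length],
                       spec.per_base_mutation_rate, rng)
        reads.append(SimRead(
            read=SequenceRead(read_id=f"sim_{i}", bases=bases),
            source_id=source,
            truth=taxonomy[source],
        ))
    return reads


def alignment_hits(
    query: SimRead,
    references: Mapping[str, str],
    spec: SimSpec,
    min_identity_percent: float = 60.0,
) -> list[AlignmentHit]:
    """Build the query's hit table by pairwise alignment against every
    searchable reference (the in-package stand-in for an external
    aligner at test scale; precomputed tabular hits plug in the same
    records)."""
    hits = []
    for ref_id, ref_seq in references.items():
        if spec.exclude_self and ref_id == query.source_id:
            continue
        pident = percent_identity(query.read.bases,
                                  ref_seq[:max(spec.read_length, 1)])
        if spec.exclude_relatives_identity is not None \
                and pident >= spec.exclude_relatives_identity:
            continue
        if pident < min_identity_percent:
            continue
        hits.append(AlignmentHit(
            query_id=query.read.read_id,
            subject_id=ref_id,
            percent_identity=pident,
            alignment_length=len(query.read),
            bitscore=pident * len(query.read) / 100.0,
        ))
    return hits


def classify_simulated(
    reads: Sequence[SimRead],
    references: Mapping[str, str],
    taxonomy: Mapping[str, TaxonomyPath],
    spec: SimSpec,
    lca_spec: Optional[LcaSpec] = None,
) -> dict[str, TaxonomyPath]:
    lca_spec = lca_spec or LcaSpec()
    return {
        q.read.read_id: lca_assign(
            alignment_hits(q, references, spec), taxonomy, lca_spec)
        for q in reads
    }


@dataclass
class RankScore:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    unassigned: int = 0
    n: int = 0

    @property
    def precision(self) -> Optional[float]:
        d = self.tp + self.fp
        return self.tp / d if d else None

    @property
    def specificity(self) -> Optional[float]:
        d = self.tn + self.fp
        return self.tn / d if d else None

    @property
    def unassigned_fraction(self) -> float:
        return self.unassigned / self.n if self.n else 0.0


def evaluate_assignments(
    predicted: Mapping[str, TaxonomyPath],
    truth: Mapping[str, TaxonomyPath],
) -> dict[str, RankScore]:
    """Score predictions per rank.

    TP: assigned and equal to truth; FP: assigned and different;
    unassigned predictions count as TN when the truth itself lacks the
    rank, else FN; the unassigned fraction counts every prediction
    lacking the rank.
    """
    if set(predicted) != set(truth):
        raise ValueError("predicted and truth read ids differ")
    scores = {rank: RankScore() for rank in RANKS}
    for read_id, pred in predicted.items():
        true_path = truth[read_id]
        for i, rank in enumerate(RANKS):
            s = scores[rank]
            s.n += 1
            p, t = pred[i], true_path[i]
            if p == UNASSIGNED:
                s.unassigned += 1
                if t == UNASSIGNED:
                    s.tn += 1
                else:
                    s.fn += 1
            elif p == t:
                s.tp += 1
            else:
                s.fp += 1
    return scores


def _score_rows(scores: Mapping[str, RankScore], **extra) -> list[dict]:
    rows = []
    for rank in RANKS:
        s = scores[rank]
        rows.append({
            "rank": rank, **extra,
            "precision": s.precision, "specificity": s.specificity,
            "unassigned_fraction": s.unassigned_fraction,
            "TP": s.tp, "FP": s.fp, "TN": s.tn, "FN": s.fn,
        })
    return rows


def scores_to_frame(scores: Mapping[str, RankScore], **extra) -> pd.DataFrame:
    return pd.DataFrame(_score_rows(scores, **extra))


def length_sweep(
    references: Mapping[str, str],
    taxonomy: Mapping[str, TaxonomyPath],
    lengths: Sequence[int],
    spec: SimSpec,
    lca_spec: Optional[LcaSpec] = None,
) -> pd.DataFrame:
    """Simulate, classify and evaluate at each read length; returns the
    long-form rank x length score table."""
    if len(lengths) < 2:
        raise ValueError("length_sweep needs at least 2 lengths")
    rows: list[dict] = []
    for length in lengths:
        run_spec = SimSpec(
            n_reads=spec.n_reads, read_length=length,
            per_base_mutation_rate=spec.per_base_mutation_rate,
            rng_seed=spec.rng_seed, exclude_self=spec.exclude_self,
            exclude_relatives_identity=spec.exclude_relatives_identity,
        )
        reads = simulate_reads(references, taxonomy, run_spec)
        predicted = classify_simulated(reads, references, taxonomy,
                                       run_spec, lca_spec)
        truth = {q.read.read_id: q.truth for q in reads}
        scores = evaluate_assignments(predicted, truth)
        rows.extend(_score_rows(scores, length=length))
    return pd.DataFrame(rows)


# divergence injected at each split of the lineage tree, expressed as a
# substitution rate over *variable* sites (conserved sites evolve at
# _CONSERVED_LEAK times these rates): identity between two references
# falls with the highest rank at which their lineages part ways
_LEVEL_DIVERGENCE = {
    "phylum": 0.50, "class": 0.36, "order": 0.26, "family": 0.18,
    "genus": 0.12, "species": 0.08,
}
_CONSERVED_LEAK = 0.08


def _substitute(arr: np.ndarray, positions: np.ndarray,
                rng: np.random.Generator) -> None:
    for i in positions:
        choices = [b for b in _BASES if b != arr[i]]
        arr[i] = choices[rng.integers(3)]


def _mutate_masked(bases: str, rate: float, mask: np.ndarray,
                   rng: np.random.Generator) -> str:
    """i.i.d. substitutions at ``rate`` on masked (variable) sites and
    at ``rate * _CONSERVED_LEAK`` elsewhere."""
    arr = np.frombuffer(bases.encode(), dtype="S1").copy()
    site_rate = np.where(mask, rate, rate * _CONSERVED_LEAK)
    _substitute(arr, np.nonzero(rng.random(len(arr)) < site_rate)[0], rng)
    return arr.tobytes().decode()


def _split_mutate(bases: str, rate: float, blocks: Sequence[tuple[int, int]],
                  mask: np.ndarray, rng: np.random.Generator) -> str:
    """Divergence applied at a lineage split: a *fixed* number of
    substitutions, ``max(1, round(rate * block length))``, in every
    variable block, plus i.i.d. leakage on conserved sites.

    The fixed per-block count guarantees that any read window covering
    a variable block sees divergence between sister taxa, instead of
    leaving it to binomial luck."""
    arr = np.frombuffer(bases.encode(), dtype="S1").copy()
    for start, stop in blocks:
        k = max(1, round(rate * (stop - start)))
        _substitute(arr, start + rng.choice(stop - start, size=k,
                                            replace=False), rng)
    leak = (~mask) & (rng.random(len(arr)) < rate * _CONSERVED_LEAK)
    _substitute(arr, np.nonzero(leak)[0], rng)
    return arr.tobytes().decode()


def _variability_mask(
    seq_length: int,
    conserved_block: int = 120,
    variable_block: int = 50,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Alternating conserved/variable blocks, conserved first.

    Mimics the 16S architecture of conserved stretches (where universal
    primers sit) interleaved with hypervariable regions: a short 5'
    read covers mostly conserved sequence and carries little taxonomic
    signal, a longer read picks up variable regions.  Returns the
    boolean variable-site mask and the variable block intervals.
    """
    mask = np.zeros(seq_length, dtype=bool)
    blocks = []
    pos = conserved_block
    while pos < seq_length:
        stop = min(pos + variable_block, seq_length)
        mask[pos:stop] = True
        blocks.append((pos, stop))
        pos += variable_block + conserved_block
    return mask, blocks


def make_reference_set(
    n_refs: int = 200,
    seq_length: int = 600,
    seed: int = 0,
    branching: Sequence[int] = (4, 2, 2, 2, 2, 2),
    per_ref_divergence: float = 0.02,
) -> tuple[dict[str, str], dict[str, TaxonomyPath]]:
    """Generate a labelled 16S-like reference database.

    Lineages form a balanced tree under one domain with the given
    branching factors (phylum .. species); each split mutates the
    parent sequence by a rank-specific divergence concentrated in
    hypervariable blocks (see `_variability_mask`), so sequence
    identity decays with taxonomic distance and short 5' reads are less
    discriminative than long ones.  References within one species
    differ by ``per_ref_divergence`` over variable sites.  Returns
    ``(id -> sequence, id -> TaxonomyPath)`` with deterministic ids.
    """
    rng = np.random.default_rng(seed)
    mask, blocks = _variability_mask(seq_length)
    root = "".join(rng.choice(list(_ALPHABET), size=seq_length))
    leaves: list[tuple[list[str], str]] = [(["Bacteria"], root)]
    for rank, k in zip(RANKS[1:], branching):
        nxt = []
        for names, seq in leaves:
            for j in range(k):
                child = _split_mutate(seq, _LEVEL_DIVERGENCE[rank], blocks,
                                      mask, rng)
                label = f"{rank[0]}{'_'.join(n[-2:] for n in names[1:])}{j}"
                nxt.append((names + [f"{rank.capitalize()}{label}"], child))
        leaves = nxt
    references: dict[str, str] = {}
    taxonomy: dict[str, TaxonomyPath] = {}
    for i in itertools.count():
        if len(references) >= n_refs:
            break
        names, seq = leaves[i % len(leaves)]
        ref_id = f"ref_{i:04d}"
        references[ref_id] = _mutate_masked(seq, per_ref_divergence, mask, rng)
        taxonomy[ref_id] = TaxonomyPath(names)
    return references, taxonomy


def make_multiplexed_run(
    n_reads: int = 1000,
    n_samples: int = 4,
    n_templates: int = 3,
    read_length: int = 300,
    mutation_rate: float = 0.01,
    max_mutations_per_read: int = 2,
    barcode_length: int = 8,
    seed: int = 0,
) -> tuple[list[SequenceRead], MappingTable, dict[str, int]]:
    """Generate a multiplexed quality-bearing run for end-to-end tests.

    Reads are drawn from ``n_templates`` unrelated template sequences
    with ``mutation_rate`` per-base substitutions capped at
    ``max_mutations_per_read`` (so any two reads of one template stay
    within the OTU radius by construction: at most 2*cap differences),
    prefixed with one of ``n_samples`` sample barcodes (pairwise
    Hamming distance >= 4), and given a mildly declining high-quality
    profile.  Returns the reads, the matching MappingTable, and each
    read's true template index.
    """
    rng = np.random.default_rng(seed)
    templates = ["".join(rng.choice(list(_ALPHABET), size=read_length))
                 for _ in range(n_templates)]
    barcodes: list[str] = []
    while len(barcodes) < n_samples:
        cand = "".join(rng.choice(list(_ALPHABET), size=barcode_length))
        if all(sum(a != b for a, b in zip(cand, bc)) >= 4 for bc in barcodes):
            barcodes.append(cand)
    mapping = MappingTable([
        MappingRow(sample_id=f"S{k + 1}", barcode=bc)
        for k, bc in enumerate(barcodes)
    ])
    base_profile = np.linspace(38, 31, read_length)
    reads: list[SequenceRead] = []
    truth: dict[str, int] = {}
    for i in range(n_reads):
        t = int(rng.integers(n_templates))
        sample = int(rng.integers(n_samples))
        n_mut = min(int(rng.binomial(read_length, mutation_rate)),
                    max_mutations_per_read)
        positions = rng.choice(read_length, size=n_mut, replace=False)
        insert_arr = list(templates[t])
        for p in positions:
            insert_arr[p] = _ALPHABET[
                (_ALPHABET.index(insert_arr[p]) + 1 + rng.integers(3)) % 4]
        insert = "".join(insert_arr)
        quals = np.clip(
            np.round(base_profile + rng.integers(-2, 3, size=read_length)),
            2, 41).astype(int)
        read_id = f"read_{i:05d}"
        reads.append(SequenceRead(
            read_id=read_id,
            bases=barcodes[sample] + insert,
            quals=tuple([40] * barcode_length) + tuple(int(q) for q in quals),
        ))
        truth[read_id] = t
    return reads, mapping, truth
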