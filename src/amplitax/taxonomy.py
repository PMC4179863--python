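"""Identity-windowed lowest-common-ancestor taxonomy for OTU seeds.

Each OTU seed is assigned a seven-rank lineage (domain .. species) from
its tabular alignment hits against a reference 16S database:

1. **Hit window** — only hits within ``identity_window`` percentage
   points (default 1.5) of the query's best percent identity are
   considered, capped at ``max_hits`` (default 200).  The window admits
   hits lost to sequencing error while excluding distant references.
2. **Rank consensus** — ranks are walked from domain towards species; a
   name is accepted at a rank iff its share among the voting references
   is strictly greater than ``consensus_fraction`` (default 0.9).
   References with no annotation at the rank abstain, so a single
   species-annotated reference among otherwise unannotated ones can
   carry a species assignment.
3. **Identity depth cap** — the best hit's identity bounds how deep the
   assignment may go: a 96% best hit, for example, is trusted at most to
   genus, because no reference species may represent the OTU.  Default
   caps: species 97, genus 95, family 93, order 91, class 88, phylum 78
   (percent identity); domain is always assignable.

The first rank that fails the vote, or lies beyond the cap, truncates
the lineage: all deeper ranks stay unassigned (marker ``"?"``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
UNASSIGNED = "?"

# greengenes-style rank prefixes, stripped on input
_GG_PREFIXES = ("k__", "d__", "p__", "c__", "o__", "f__", "g__", "s__")

BLAST6_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)


@dataclass(frozen=True)
class AlignmentHit:
    """One tabular alignment hit (one HSP) of a query against a reference."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int = 0
    bitscore: float = 0.0
    evalue: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(
                f"percent identity {self.percent_identity} outside [0, 100]")


class TaxonomyPath(tuple):
    """A seven-rank lineage; unassigned ranks hold the ``"?"`` marker.

    Truncation invariant: once a rank is unassigned, every deeper rank
    is unassigned too (enforced on construction by truncating).
    """

    def __new__(cls, ranks: Sequence[str]):
        names = list(ranks)[:len(RANKS)]
        names += [UNASSIGNED] * (len(RANKS) - len(names))
        cleaned = []
        truncated = False
        for name in names:
            name = (name or UNASSIGNED).strip()
            if truncated or name in ("", UNASSIGNED):
                cleaned.append(UNASSIGNED)
                truncated = True
            else:
                cleaned.append(name)
        return super().__new__(cls, cleaned)

    @property
    def depth(self) -> int:
        """Number of assigned ranks (0 = fully unassigned)."""
        return sum(1 for name in self if name != UNASSIGNED)

    def name_at(self, rank: str) -> str:
        return self[RANKS.index(rank)]

    @classmethod
    def unassigned(cls) -> "TaxonomyPath":
        return cls([])

    @classmethod
    def from_lineage_string(cls, lineage: str, sep: str = ";") -> "TaxonomyPath":
        names = []
        for token in lineage.split(sep):
            token = token.strip()
            for prefix in _GG_PREFIXES:
                if token.lower().startswith(prefix):
                    token = token[len(prefix):]
                    break
            names.append(token)
        return cls(names)

    def to_lineage_string(self, sep: str = ";") -> str:
        return sep.join(self)


@dataclass
class LcaSpec:
    """Tuning of the windowed LCA: hit window width (percentage points),
    hit cap, strict consensus fraction, and per-rank identity depth caps
    (percent identity required to assign at that rank)."""

    identity_window: float = 1.5
    max_hits: int = 200
    consensus_fraction: float = 0.9
    depth_caps: dict = field(default_factory=lambda: {
        "species": 97.0, "genus": 95.0, "family": 93.0,
        "order": 91.0, "class": 88.0, "phylum": 78.0,
    })

    def __post_init__(self) -> None:
        if self.identity_window < 0:
            raise ValueError("identity_window must be >= 0")
        if not 0 < self.consensus_fraction <= 1:
            raise ValueError("consensus_fraction must be in (0, 1]")

    @classmethod
    def printed_caps(cls, **kwargs) -> "LcaSpec":
        """Alternative cap set keeping the published literal rank:number
        mapping (class 91, order 88), which is not monotone in depth."""
        caps = {"species": 97.0, "genus": 95.0, "family": 93.0,
                "class": 91.0, "order": 88.0, "phylum": 78.0}
        return cls(depth_caps=caps, **kwargs)


def read_reference_taxonomy(path) -> dict[str, TaxonomyPath]:
    """Two-column TSV: subject id, semicolon-separated lineage
    (greengenes ``k__``-style prefixes accepted and stripped)."""
    table = pd.read_csv(path, sep="\t", header=None,
                        names=["subject_id", "lineage"], dtype=str,
                        comment="#", keep_default_na=False)
    taxonomy = {}
    for subject_id, lineage in zip(table["subject_id"], table["lineage"]):
        if subject_id in taxonomy:
            raise ValueError(f"duplicate reference id {subject_id!r}")
        taxonomy[subject_id] = TaxonomyPath.from_lineage_string(lineage)
    return taxonomy


def read_blast_table(path) -> dict[str, list[AlignmentHit]]:
    """Parse a BLAST tabular (outfmt 6) file, grouped by query."""
    table = pd.read_csv(path, sep="\t", header=None,
                        names=list(BLAST6_COLUMNS), comment="#")
    hits: dict[str, list[AlignmentHit]] = {}
    for row in table.itertuples(index=False):
        hits.setdefault(str(row.qseqid), []).append(AlignmentHit(
            query_id=str(row.qseqid),
            subject_id=str(row.sseqid),
            percent_identity=float(row.pident),
            alignment_length=int(row.length),
            bitscore=float(row.bitscore),
            evalue=float(row.evalue),
        ))
    return hits


def filter_hits(hits: Sequence[AlignmentHit], spec: LcaSpec) -> list[AlignmentHit]:
    """Apply HSP dedup, the best-hit identity window, and the hit cap.

    Multiple HSPs to one subject collapse to the best one first (one
    reference, one vote); the window then retains hits within
    ``identity_window`` points of the best identity; if more than
    ``max_hits`` remain, the top ones by (identity desc, bitscore desc,
    subject id asc) are kept.
    """
    if not hits:
        return []
    queries = {h.query_id for h in hits}
    if len(queries) > 1:
        raise ValueError(f"hits span multiple queries: {sorted(queries)}")
    best_per_subject: dict[str, AlignmentHit] = {}
    for h in hits:
        cur = best_per_subject.get(h.subject_id)
        if cur is None or (h.percent_identity, h.bitscore) > (
                cur.percent_identity, cur.bitscore):
            best_per_subject[h.subject_id] = h
    deduped = list(best_per_subject.values())
    best = max(h.percent_identity for h in deduped)
    windowed = [h for h in deduped
                if h.percent_identity >= best - spec.identity_window]
    windowed.sort(key=lambda h: (-h.percent_identity, -h.bitscore, h.subject_id))
    return windowed[:spec.max_hits]


def depth_cap(best_identity_percent: float, caps: Mapping[str, float]) -> str:
    """Deepest rank the best hit's identity permits; identities below
    the phylum cap leave only the domain assignable."""
    for rank in reversed(RANKS):
        cap = caps.get(rank)
        if cap is None or cap <= best_identity_percent:
            return rank
    return RANKS[0]


def rank_vote(
    hits: Sequence[AlignmentHit],
    reference_taxonomy: Mapping[str, TaxonomyPath],
    rank: str,
    consensus_fraction: float,
) -> tuple[Optional[str], dict[str, int]]:
    """Consensus vote at one rank over the retained references.

    References unannotated at the rank abstain; the majority name is
    accepted iff its share among the remaining voters is strictly
    greater than the consensus fraction.  Returns the winning name (or
    None) and the tally of non-abstaining votes.
    """
    tally: dict[str, int] = {}
    for h in hits:
        path = reference_taxonomy.get(h.subject_id)
        if path is None:
            raise KeyError(f"subject {h.subject_id!r} missing from reference taxonomy")
        name = path.name_at(rank)
        if name != UNASSIGNED:
            tally[name] = tally.get(name, 0) + 1
    voters = sum(tally.values())
    if voters == 0:
        return None, tally
    # deterministic: ties broken by name, though a tie can never pass a
    # strict majority fraction >= 0.5
    name, count = max(tally.items(), key=lambda kv: (kv[1], kv[0]))
    if count / voters > consensus_fraction:
        return name, tally
    return None, tally


def lca_assign(
    hits: Sequence[AlignmentHit],
    reference_taxonomy: Mapping[str, TaxonomyPath],
    spec: Optional[LcaSpec] = None,
) -> TaxonomyPath:
    """Assign one query's lineage from its alignment hits."""
    spec = spec or LcaSpec()
    retained = filter_hits(hits, spec)
    if not retained:
        return TaxonomyPath.unassigned()
    best = max(h.percent_identity for h in retained)
    deepest = depth_cap(best, spec.depth_caps)
    deepest_index = RANKS.index(deepest)
    names = []
    for i, rank in enumerate(RANKS):
        if i > deepest_index:
            break
        name, _ = rank_vote(retained, reference_taxonomy, rank,
                            spec.consensus_fraction)
        if name is None:
            break
        names.append(name)
    return TaxonomyPath(names)


def classify_all(
    seed_ids: Iterable[str],
    hit_table: Mapping[str, Sequence[AlignmentHit]],
    reference_taxonomy: Mapping[str, TaxonomyPath],
    spec: Optional[LcaSpec] = None,
) -> dict[str, TaxonomyPath]:
    """Assign every seed a path; seeds without hits stay unassigned, and
    hits for unknown seeds are skipped with a warning."""
    seed_ids = list(seed_ids)
    known = set(seed_ids)
    for query in hit_table:
        if query not in known:
            warnings.warn(f"hits for unknown OTU id {query!r} skipped")
    return {
        seed_id: lca_assign(hit_table.get(seed_id, ()), reference_taxonomy, spec)
        for seed_id in seed_ids
    }


def aggregate_taxa(matrix, assignments: Mapping[str, TaxonomyPath],
                   rank: str) -> pd.DataFrame:
    """Sum OTU counts by taxon name at one rank; OTUs unassigned at that
    rank pool into an ``"unassigned"`` row.  Totals are preserved."""
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    frame = matrix.to_frame()
    names = []
    for otu_id in frame.index:
        path = assignments.get(otu_id, TaxonomyPath.unassigned())
        name = path.name_at(rank)
        names.append("unassigned" if name == UNASSIGNED else name)
    out = frame.groupby(pd.Index(names, name=rank)).sum()
    return out.sort_index()


def write_taxonomy_tsv(assignments: Mapping[str, TaxonomyPath], path) -> None:
    rows = [{"otu_id": otu, **dict(zip(RANKS, path))}
            for otu, path in sorted(assignments.items())]
    pd.DataFrame(rows, columns=["otu_id", *RANKS]).to_csv(
        path, sep="\t", index=False)
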