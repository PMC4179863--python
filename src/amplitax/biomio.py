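"""BIOM 1.0 (JSON) writer/reader for OTU abundance tables.

The 1.0 JSON dialect is used (rather than 2.x HDF5) so tables stay
plain text and diffable.  Taxonomy is stored per observation as the
conventional ``taxonomy`` metadata list of seven rank names.
"""

from __future__ import annotations

import json
from datetime import datetime, timezone
from typing import Mapping, Optional

import numpy as np

from .cluster import AbundanceMatrix
from .taxonomy import RANKS, TaxonomyPath

FORMAT = "Biological Observation Matrix 1.0.0"
FORMAT_URL = "http://biom-format.org"


def write_biom(
    matrix: AbundanceMatrix,
    assignments: Optional[Mapping[str, TaxonomyPath]],
    path,
    table_id: str = "amplitax OTU table",
) -> None:
    """Write a sparse BIOM 1.0 JSON table; taxonomy becomes per-row
    metadata.  Assignments, when given, must cover every OTU id."""
    rows = []
    for otu_id in matrix.otu_ids:
        metadata = None
        if assignments is not None:
            if otu_id not in assignments:
                raise KeyError(f"no taxonomy assignment for {otu_id!r}")
            metadata = {"taxonomy": list(assignments[otu_id])}
        rows.append({"id": otu_id, "metadata": metadata})
    nz = np.nonzero(matrix.counts)
    data = [[int(r), int(c), int(matrix.counts[r, c])]
            for r, c in zip(*nz)]
    doc = {
        "id": table_id,
        "format": FORMAT,
        "format_url": FORMAT_URL,
        "type": "OTU table",
        "generated_by": "amplitax",
        "date": datetime.now(timezone.utc).isoformat(),
        "rows": rows,
        "columns": [{"id": s, "metadata": None} for s in matrix.sample_ids],
        "matrix_type": "sparse",
        "matrix_element_type": "int",
        "shape": [len(matrix.otu_ids), len(matrix.sample_ids)],
        "data": data,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_biom(path) -> tuple[AbundanceMatrix, dict[str, TaxonomyPath]]:
    """Read a BIOM 1.0 JSON table back into an AbundanceMatrix plus any
    per-observation taxonomy metadata."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != FORMAT:
        raise ValueError(f"not a BIOM 1.0 table: format={doc.get('format')!r}")
    shape = tuple(doc["shape"])
    counts = np.zeros(shape, dtype=np.int64)
    if doc["matrix_type"] == "sparse":
        for r, c, v in doc["data"]:
            counts[r, c] = v
    else:
        counts[:] = np.asarray(doc["data"], dtype=np.int64)
    otu_ids = [row["id"] for row in doc["rows"]]
    assignments = {}
    for row in doc["rows"]:
        meta = row.get("metadata") or {}
        if "taxonomy" in meta:
            assignments[row["id"]] = TaxonomyPath(meta["taxonomy"])
    matrix = AbundanceMatrix(
        otu_ids=otu_ids,
        sample_ids=[col["id"] for col in doc["columns"]],
        counts=counts,
    )
    return matrix, assignments
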