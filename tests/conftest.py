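"""Shared fixtures: synthetic sequencing runs and reference databases."""

from __future__ import annotations

from pathlib import Path

import pytest

from amplitax import seqio
from amplitax.sim import make_multiplexed_run, make_reference_set


def write_run_files(tmp_path: Path, reads, mapping) -> tuple[Path, Path]:
    """Write a FASTQ + mapping TSV pair for pipeline-level tests."""
    fq = tmp_path / "reads.fastq"
    seqio.write_fastq(reads, fq)
    mp = tmp_path / "mapping.tsv"
    with open(mp, "w") as fh:
        fh.write("#SampleID\tBarcodeSequence\n")
        for row in mapping:
            fh.write(f"{row.sample_id}\t{row.barcode}\n")
    return fq, mp


@pytest.fixture(scope="session")
def reference_db():
    """Small labelled 16S-like reference database (40 refs)."""
    return make_reference_set(n_refs=40, seq_length=600, seed=5)


@pytest.fixture(scope="session")
def multiplexed_run():
    """400 barcoded quality-bearing reads from 3 templates, 4 samples."""
    return make_multiplexed_run(n_reads=400, seed=7)
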