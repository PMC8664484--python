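"""Shared synthetic fixtures. Everything is generated at test time from
fixed seeds; session scope keeps the heavier genomes to one build."""

from pathlib import Path

import pytest

from asmrevise import fixtures as fx

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def small_truth():
    """2 x 200 kb truth genome: fast enough for per-module tests."""
    return fx.generate_genome(seed=101, n_chrom=2, chrom_length=200_000,
                              tandem_block_rate=10, repeat_fraction=0.2)


@pytest.fixture(scope="session")
def small_draft(small_truth):
    draft, truth = fx.fragment_assembly(
        small_truth, {10: 0.6, 100: 0.2, 1000: 0.2}, sized_gap_rate=5,
        seed=102)
    return draft, truth


@pytest.fixture(scope="session")
def small_contigs(small_draft):
    _, truth = small_draft
    return fx.simulate_contigs(truth, n50_target=50_000, seed=103)


@pytest.fixture(scope="session")
def grade_truth_rows():
    rows = []
    for line in (DATA / "grade_truth_table.tsv").read_text().splitlines()[1:]:
        complete, u, p, t, label = line.split("\t")
        rows.append((bool(int(complete)), u, p, t, label))
    return rows
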