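import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from cleavage_entropy import AbundanceTable, CleavageRecord, load_abundance
from cleavage_entropy.alphabet import CANONICAL_RESIDUES


@pytest.fixture(scope="session")
def uniform_bg():
    return AbundanceTable.uniform()


@pytest.fixture(scope="session")
def mccaldon_bg():
    return load_abundance("mccaldon")


@pytest.fixture(scope="session")
def skewed_bg():
    """A deliberately non-uniform, non-packaged background."""
    rng = np.random.default_rng(1234)
    freqs = rng.uniform(0.2, 3.0, size=20)
    return AbundanceTable(dict(zip(CANONICAL_RESIDUES, freqs)), name="skewed")


def make_random_records(
    n, rng, protease_id="px", gap_frac=0.0, unknown_frac=0.0
):
    """Random windows over canonical residues, optionally with gaps/unknowns."""
    symbols = list(CANONICAL_RESIDUES)
    records = []
    for _ in range(n):
        while True:
            window = []
            for _pos in range(8):
                u = rng.random()
                if u < gap_frac:
                    window.append("-")
                elif u < gap_frac + unknown_frac:
                    window.append("X")
                else:
                    window.append(symbols[rng.integers(20)])
            if any(c in CANONICAL_RESIDUES for c in window):
                break
        records.append(CleavageRecord(protease_id, tuple(window)))
    return records


@pytest.fixture
def random_records_factory():
    return make_random_records


@pytest.fixture
def write_table(tmp_path):
    """Write (protease_id, window-string) rows to a temp TSV and return its path."""

    def _write(rows, name="table.tsv", header="protease_id\twindow", extra_lines=()):
        path = tmp_path / name
        lines = [header]
        lines += [f"{pid}\t{window}" for pid, window in rows]
        lines += list(extra_lines)
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        return path

    return _write
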