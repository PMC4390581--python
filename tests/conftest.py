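import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from uprshift.sequence_io import extract_promoter
from uprshift.synthetic_data import generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Planted 11-gene cohort (7 up / 4 unchanged, sites per the 6-1-1-3
    design), shared across tests; treat as read-only."""
    genome, tss_records, truth = generate_cohort(seed=11)
    return genome, tss_records, truth


@pytest.fixture(scope="session")
def default_windows(default_cohort):
    genome, tss_records, truth = default_cohort
    return [
        extract_promoter(genome, rec, truth.upstream_bp, truth.downstream_bp)
        for rec in tss_records
    ]


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """A materialized fixture set written once per session."""
    from uprshift.synthetic_data import write_fixtures

    outdir = tmp_path_factory.mktemp("fixtures")
    paths = write_fixtures(outdir, seed=11)
    return outdir, paths
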