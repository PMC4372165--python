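from __future__ import annotations

import pytest

from dgrscope import pipeline, synthetic_data


@pytest.fixture(scope="session")
def default_sim():
    """A default-parameter synthetic genome whose planted cassette meets the
    detection thresholds (verified in-test via the truth record)."""
    record, truth = synthetic_data.generate_genome(synthetic_data.SimConfig(seed=3))
    assert truth.cassettes[0].realized_adenine_mismatches >= 10
    return record, truth


@pytest.fixture(scope="session")
def default_detection(default_sim):
    record, _truth = default_sim
    return pipeline.detect_record(record, pipeline.PipelineConfig())


@pytest.fixture
def fasta_file(tmp_path):
    def _write(content: str, name: str = "test.fasta"):
        p = tmp_path / name
        p.write_text(content)
        return p

    return _write
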