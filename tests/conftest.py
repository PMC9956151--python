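"""Shared fixtures: FASTA writers and a small synthetic cohort run once."""

from __future__ import annotations

from pathlib import Path

import pytest

from gclandscape.pipeline import PipelineConfig, run_pipeline
from gclandscape.synthetic import demo_cohort_specs, generate_cohort


@pytest.fixture
def write_fasta(tmp_path):
    """Write FASTA text to a temp file; returns the path."""

    def _write(text: str, name: str = "test.fa") -> Path:
        p = tmp_path / name
        p.write_text(text)
        return p

    return _write


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A 10-species two-group cohort on disk (5 wide + 5 narrow, 30 genes)."""
    root = tmp_path_factory.mktemp("cohort")
    specs = demo_cohort_specs(seed=7, n_wide=5, n_narrow=5, n_genes=30)
    manifest = generate_cohort(specs, root)
    return root, manifest


@pytest.fixture(scope="session")
def cohort_run(small_cohort, tmp_path_factory):
    """Full pipeline run over the small cohort; returns (out_dir, report)."""
    root, _ = small_cohort
    out = tmp_path_factory.mktemp("run")
    config = PipelineConfig(manifest=root / "manifest.tsv", out_dir=out)
    report = run_pipeline(config)
    return out, report
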