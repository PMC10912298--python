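"""Shared fixtures: synthetic datasets and one full pipeline run.

The full study-condition run (8 clades x 8 members, 40 decoys, 3% codon
divergence, 1000 bootstrap replicates) is expensive, so it is computed once
per session and shared between the end-to-end invariant tests and the
acceptance tests.
"""

from __future__ import annotations

from pathlib import Path

import pytest

from gpcrclade import RunConfig, generate_dataset, run_pipeline

STUDY_SEED = 1


@pytest.fixture(scope="session")
def study_dataset(tmp_path_factory):
    """Default-condition synthetic dataset, written to disk."""
    out = tmp_path_factory.mktemp("study")
    records, truths, seeds = generate_dataset(seed=STUDY_SEED, out_dir=out)
    return {"records": records, "truths": truths, "seeds": seeds, "dir": Path(out)}


@pytest.fixture(scope="session")
def study_result(study_dataset):
    """Full pipeline on the study dataset, topologies from the generator's
    annotation file (the external-predictor route), 1000-replicate bootstrap."""
    cfg = RunConfig(
        seed=STUDY_SEED,
        topology_mode="annotate",
        topology_file=str(study_dataset["dir"] / "topology.3line"),
        bootstrap_replicates=1000,
    )
    return run_pipeline(study_dataset["records"], study_dataset["seeds"], cfg)


@pytest.fixture(scope="session")
def truth_by_id(study_dataset):
    return {t.record_id: t for t in study_dataset["truths"]}
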