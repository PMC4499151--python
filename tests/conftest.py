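"""Shared fixtures: small simulated campaigns generated at test time."""

from __future__ import annotations

import pytest

from aptrace.pipeline import RunConfig, run_pipeline
from aptrace.simulate import SimConfig, simulate_campaign, write_campaign


@pytest.fixture(scope="session")
def screen_campaign():
    """A compact 2-round campaign whose final round is split across target,
    ortholog, control and pH-adjusted control pools; shared by pipeline tests.
    The screen sits early, while background mass still dominates the library —
    the regime in which reference-pool prevalence ratios are informative."""
    config = SimConfig(seed=11, n_rounds=2, parallel_targets=True,
                       planted_variant=True)
    return simulate_campaign(config)


@pytest.fixture(scope="session")
def campaign_dir(screen_campaign, tmp_path_factory):
    """The same campaign written to disk as FASTQ + pool sheet + truth."""
    outdir = tmp_path_factory.mktemp("simdata")
    write_campaign(screen_campaign, outdir, reads_per_pool=20000)
    return outdir


@pytest.fixture(scope="session")
def pipeline_run(screen_campaign, campaign_dir, tmp_path_factory):
    """Full pipeline output on the shared campaign."""
    out = tmp_path_factory.mktemp("pipeline")
    config = RunConfig(
        pool_sheet=str(campaign_dir / "pools.tsv"),
        reads=sorted(str(p) for p in campaign_dir.glob("*.fastq.gz")),
        out_dir=str(out),
        target_label="target",
        control_label="control",
        adjusted_label="control_pH",
        ortholog_label="ortholog",
    )
    shortlist = run_pipeline(config)
    return config, out, shortlist
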