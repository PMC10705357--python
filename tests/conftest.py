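"""Shared simulated datasets (session-scoped: each is generated once)."""

from __future__ import annotations

import pytest

from isoscope import io as iio
from isoscope import isoforms as iso_mod
from isoscope.sim import SimConfig, simulate


@pytest.fixture(scope="session")
def default_sim(tmp_path_factory):
    """Default study conditions: error-free reads, all read categories."""
    return simulate(SimConfig(seed=11), tmp_path_factory.mktemp("sim_default"))


@pytest.fixture(scope="session")
def clean_sim(tmp_path_factory):
    """Coding genes only, deep per-site read support: unambiguous gene
    assignment for APA recovery and denser fusion sampling."""
    cfg = SimConfig(
        seed=5,
        frac_noncoding_genes=0.0,
        reads_per_isoform=(6, 8),
        isoforms_per_gene=(2, 3),
        frac_fusion_reads=0.05,
    )
    return simulate(cfg, tmp_path_factory.mktemp("sim_clean"))


@pytest.fixture(scope="session")
def degraded_sim(tmp_path_factory):
    """High degradation rate for the 5'-degradation filter checks."""
    cfg = SimConfig(seed=23, frac_degraded_reads=0.3, frac_noncoding_genes=0.0)
    return simulate(cfg, tmp_path_factory.mktemp("sim_degraded"))


@pytest.fixture(scope="session")
def default_alignments(default_sim):
    return iio.read_alignments(default_sim.alignments_sam)


@pytest.fixture(scope="session")
def default_kept_isoforms(default_sim, default_alignments):
    """Isoforms surviving degradation + retention filters, loci assigned."""
    simple, _ = iso_mod.partition_split_reads(default_alignments)
    collapsed = iso_mod.collapse(simple)
    kept, _ = iso_mod.filter_degraded(collapsed)
    iso_mod.annotate_junction_support(kept, default_sim.annotation.junction_set())
    kept, _ = iso_mod.apply_retention_filter(kept)
    loci = iso_mod.assign_loci(kept)
    iso_mod.call_novelty(loci, kept, default_sim.annotation)
    return kept, loci
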