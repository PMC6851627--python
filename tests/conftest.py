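import copy

import pytest

from coiaudit import distances, clustering, library_audit, metabarcoding
from coiaudit.synthetic_data import (
    LibrarySimConfig,
    MetaSimConfig,
    simulate_library,
    simulate_metabarcoding_run,
)


@pytest.fixture(scope="session")
def sim_library():
    """Default synthetic reference library (100 species, 8 families)."""
    return simulate_library(LibrarySimConfig(seed=7))


@pytest.fixture(scope="session")
def audited(sim_library):
    records, _ = sim_library
    return library_audit.audit_report(records)


@pytest.fixture(scope="session")
def meta_run(sim_library, tmp_path_factory):
    """A small metabarcoding run plus its pipeline result.

    Six samples of 1,200 read pairs keep the full suite fast while leaving
    every species comfortably above the relative-abundance filter.
    """
    records, truth = copy.deepcopy(sim_library)
    matrix = distances.pairwise_matrix(records)
    clusters = clustering.single_linkage_clusters(matrix)
    member_cluster = clusters.member_to_cluster
    for rec in records:
        rec.cluster_id = member_cluster.get(rec.record_id)
    config = MetaSimConfig(seed=7, n_samples=6, reads_per_sample=1200)
    outdir = tmp_path_factory.mktemp("meta_run")
    manifest, truth = simulate_metabarcoding_run(records, truth, config, outdir)
    result = metabarcoding.run_pipeline(manifest, records)
    return {
        "records": records,
        "truth": truth,
        "clusters": clusters,
        "manifest": manifest,
        "config": config,
        "result": result,
    }
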