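"""Shared fixtures: tiny synthetic datasets and tree-generation helpers."""

from __future__ import annotations

import numpy as np
import pytest

from cablediv import pipeline
from cablediv.seqio import SequenceRecord
from cablediv import synthetic_data as sd


def make_record(rid: str, seq: str, **kw) -> SequenceRecord:
    return SequenceRecord(rid, seq, **kw)


def small_spec(seed: int = 11, **overrides) -> sd.RadiationSpec:
    """A 2-genera x 2-species x 2-sequences radiation on a 1,300 bp gene
    (long enough for every clade to carry a nearly complete member)."""
    defaults = dict(
        seed=seed,
        root_length=1300,
        n_genera=2,
        species_per_genus=(2, 2),
        singletons_per_genus=(0, 0),
        seqs_per_species_default=2,
    )
    defaults.update(overrides)
    return sd.RadiationSpec(**defaults)


@pytest.fixture(scope="session")
def small_dataset():
    """Clean 8-record radiation with ground truth (no artifacts)."""
    spec = small_spec()
    records, truth = sd.simulate_radiation(spec)
    return records, truth, spec


@pytest.fixture(scope="session")
def survey_run():
    """One full survey-scale pipeline run, shared by read-only assertions."""
    records, sites, truth, spec = sd.survey_dataset(seed=7)
    by_id = {r.id: r for r in records}
    result = pipeline.run_pipeline(
        records, sites, pipeline.PipelineConfig(),
        queries=[by_id[q] for q in truth.query_ids],
        outgroup=by_id[truth.outgroup_id],
    )
    return records, sites, truth, result


# ---------------------------------------------------------------------------
# random tree helpers (used by the NJ and monophyly oracles)
# ---------------------------------------------------------------------------

def random_additive_tree(n_leaves: int, rng: np.random.Generator):
    """Random binary topology with strictly positive branch lengths, returned
    as (newick string, leaf labels)."""
    labels = [f"t{i}" for i in range(n_leaves)]
    nodes = [(lab, None) for lab in labels]  # (newick, None) pendant subtrees
    # random sequential joins; lengths uniform in [0.1, 1.1] so no degeneracy
    subtrees = [f"{lab}:{rng.uniform(0.1, 1.1):.6f}" for lab in labels]
    while len(subtrees) > 3:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        merged = (
            f"({subtrees[i]},{subtrees[j]}):{rng.uniform(0.1, 1.1):.6f}"
        )
        rest = [s for k, s in enumerate(subtrees) if k not in (i, j)]
        subtrees = rest + [merged]
    newick = f"({subtrees[0]},{subtrees[1]},{subtrees[2]});"
    return newick, labels
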