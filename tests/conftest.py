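import pandas as pd
import pytest

from foramotu import curation, delimitation, synth


@pytest.fixture(scope="session")
def study_dataset():
    return synth.study_barcode_dataset(seed=1)


@pytest.fixture(scope="session")
def study_curation(study_dataset):
    """Curated basetypes/basegroups of the study-structured dataset."""
    records, stations, truth = study_dataset
    recs = curation.records_from_frame(records)
    curated, queue = curation.filter_replicated(recs)
    basetypes = curation.extract_basetypes(curated)
    basegroups, rejected = curation.assemble_basegroups(basetypes, curated)
    return {
        "records": recs,
        "curated": curated,
        "queue": queue,
        "basetypes": basetypes,
        "basegroups": basegroups,
        "rejected": rejected,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def study_hierarchy(study_curation):
    basetypes = study_curation["basetypes"]
    curated = study_curation["curated"]
    alignment = {bt.basetype_id: bt.motif for bt in basetypes}
    dm = delimitation.k80_distance(alignment)
    _, initial, recursive = delimitation.abgd_partition(dm)
    by_id = {r.sequence_id: r for r in curated}
    morpho = {
        bt.basetype_id: pd.Series(
            [by_id[s].morphospecies for s in bt.members]
        ).mode().iloc[0]
        for bt in basetypes
    }
    hierarchy = delimitation.build_hierarchy(
        [initial, recursive], study_curation["basegroups"], morpho
    )
    return {
        "alignment": alignment,
        "distance": dm,
        "initial": initial,
        "recursive": recursive,
        "hierarchy": hierarchy,
        "morphospecies": morpho,
    }
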