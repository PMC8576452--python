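"""Shared fixtures: toy volumes and one full-scale planted-atrophy cohort."""

from __future__ import annotations

import numpy as np
import pytest

from brainmorph import (
    CohortSpec,
    TissueMaps,
    VORExtractor,
    default_parcellation,
    generate_subject_table,
    records_to_frame,
)
from brainmorph.cohort import build_atrophy_model, generate_tissue_maps


def toy_maps(gm: np.ndarray) -> TissueMaps:
    """Wrap a GM array into TissueMaps with empty WM/CSF."""
    gm = np.asarray(gm, dtype=np.float64)
    return TissueMaps(gm=gm, wm=np.zeros_like(gm), csf=np.zeros_like(gm))


@pytest.fixture(scope="session")
def default_parc():
    """Brain mask + 116-region synthetic parcellation of the default phantom."""
    parc, mask = default_parcellation(seed=0)
    return parc, mask


@pytest.fixture(scope="session")
def one_subject_maps(default_parc):
    """Tissue maps of one default-spec subject on the full grid."""
    parc, _ = default_parc
    spec = CohortSpec()
    record = generate_subject_table(spec)[0]
    atrophy = build_atrophy_model(spec, parc)
    return generate_tissue_maps(record, parc, spec, atrophy)


@pytest.fixture(scope="session")
def planted_cohort(default_parc):
    """Full 123-subject cohort with d=1.5 atrophy in 10 regions (CI contrast).

    Volumes are generated streaming and reduced on the fly to VOR features
    and raw GM volumes over the atrophy region set; only those summaries are
    kept in memory.
    """
    parc, _ = default_parc
    spec = CohortSpec(atrophy_effect={"CI": 1.5})
    records = generate_subject_table(spec)
    atrophy = build_atrophy_model(spec, parc)
    extractor = None
    rows, set_volumes = [], []
    for rec in records:
        maps = generate_tissue_maps(rec, parc, spec, atrophy)
        if extractor is None:
            extractor = VORExtractor(parc).fit([maps])
        rows.append(extractor.transform_one(maps))
        set_volumes.append(float((maps.gm * atrophy.region_mask).sum()))
    return {
        "spec": spec,
        "records": records,
        "table": records_to_frame(records),
        "X_vor": np.vstack(rows),
        "y_ci": np.array([1 if r.cognition == "CI" else 0 for r in records]),
        "set_volumes": np.array(set_volumes),
        "atrophy": atrophy,
    }
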