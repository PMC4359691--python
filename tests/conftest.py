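import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import bopscan.annotation as ann
import bopscan.deconvolution as dec
import bopscan.dmr as dmr
from bopscan.simulate import CohortSpec, generate_cohort, generate_manifest, generate_reference_profiles

settings.register_profile("ci", deadline=None, max_examples=50, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def toy_manifest() -> pd.DataFrame:
    """Five-row manifest touching every class and a multi-gene cell."""
    return pd.DataFrame(
        {
            "IlmnID": ["cg001", "cg002", "cg003", "cg004", "cg005"],
            "CHR": ["chr21", "21", "21", "1", "2"],
            "MAPINFO": [100, 150, 200, 500, 900],
            "RELATION_TO_UCSC_CPG_ISLAND": ["N_Shore", "Island", "Island", "", ""],
            "UCSC_REFGENE_NAME": ["RUNX1;RUNX1", "RUNX1", "", "NCAM1", ""],
            "UCSC_CPG_ISLANDS_NAME": ["CGI1", "CGI1", "CGI1", "", ""],
        }
    )


def two_group_design(n_a: int, n_b: int, sample_ids=None) -> dmr.DesignMatrix:
    """Intercept + group design with no covariates (group_a first)."""
    n = n_a + n_b
    ids = sample_ids if sample_ids is not None else [f"s{i}" for i in range(n)]
    X = pd.DataFrame(
        {"intercept": np.ones(n), "group": np.array([1.0] * n_a + [0.0] * n_b)},
        index=pd.Index(ids),
    )
    return dmr.DesignMatrix(X=X, group_col="group", group_a="DSP", group_b="DSS")


@pytest.fixture(scope="session")
def planted_run():
    """Full pipeline on a planted cohort: 20 affected genic-island blocks
    (delta 0.2 on 3-probe blocks) among 480 nulls, 29 families.

    Session-scoped because several recovery/specificity tests share it.
    """
    spec = CohortSpec.planted(
        n_planted=20,
        delta=0.2,
        seed=11,
        n_bops_a=500,
        n_bops_b=0,
        n_sites_c=60,
        n_sites_d=40,
        probes_per_bop=(3,),
        shore_prob=0.0,
    )
    ref, cell_types = generate_reference_profiles(seed=11)
    manifest = generate_manifest(spec, reference_ids=list(ref.index))
    beta, detp, sheet, truth = generate_cohort(spec, manifest, (ref, cell_types))
    annot = ann.classify_probes(ann.parse_manifest(manifest))
    sites = dec.select_informative_cpgs(ref, cell_types, n=500)
    _, props, _ = dec.estimate_cell_proportions(beta, ref, cell_types, sites)
    design = dmr.build_design(sheet, cell_props=props)
    bops = ann.build_bops(annot)
    results, excluded = dmr.scan_bops(bops, beta, design)
    return {
        "spec": spec,
        "beta": beta,
        "sheet": sheet,
        "truth": truth,
        "annot": annot,
        "props": props,
        "design": design,
        "bops": bops,
        "results": results,
        "excluded": excluded,
    }
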