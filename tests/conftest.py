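import pandas as pd
import pytest

import methexpress as mx


def make_annotation(rows):
    """Build a validated annotation frame from (probe, chr, pos, genes,
    groups, regfeat) tuples."""
    df = pd.DataFrame(
        rows,
        columns=["IlmnID", "CHR", "MAPINFO", "UCSC_RefGene_Name",
                 "UCSC_RefGene_Group", "Regulatory_Feature_Group"],
    )
    from methexpress.io_formats import validate_annotation
    return validate_annotation(df)


def make_design(n_fetal=3, n_adult=3):
    from methexpress.io_formats import validate_design
    samples = [f"F{i+1}" for i in range(n_fetal)] + \
              [f"A{i+1}" for i in range(n_adult)]
    return validate_design(pd.DataFrame({
        "sample_id": samples,
        "group": ["fetal"] * n_fetal + ["adult"] * n_adult,
    }))


@pytest.fixture(scope="session")
def coupled_dataset():
    """Mid-sized coupled dataset shared across integration tests."""
    cfg = mx.SimulationConfig(n_cpgs=6000, n_genes=500, seed=101)
    return mx.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def coupled_analysis(coupled_dataset):
    ds = coupled_dataset
    beta, _ = mx.filter_detection(ds.beta, ds.detection_p)
    beta, _ = mx.filter_sex_chromosomes(beta, ds.annotation)
    dm = mx.differential_methylation(beta, ds.design)
    de = mx.differential_expression(ds.expression, ds.design)
    links = mx.build_links(ds.annotation)
    records = mx.build_integration_records(dm, links, de)
    return {"ds": ds, "beta": beta, "dm": dm, "de": de, "links": links,
            "records": records}
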