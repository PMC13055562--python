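import pytest
from hypothesis import settings

from faerspv.ingest import ReportCase, parse_tables, split_cohort
from faerspv.synthetic import GeneratorConfig, generate_extract

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_case(
    caseid=1,
    primaryid=None,
    sex="F",
    drugs=((1, "INFLIXIMAB", "PS"),),
    pts=("Headache",),
    indications=((1, "Crohn's disease"),),
    **kw,
):
    """Small hand-built ReportCase for unit tests."""
    return ReportCase(
        caseid=caseid,
        primaryid=primaryid if primaryid is not None else caseid * 10 + 2,
        sex=sex,
        drugs=list(drugs),
        pts=list(pts),
        indications=list(indications),
        **kw,
    )


@pytest.fixture(scope="session")
def small_extract(tmp_path_factory):
    """One synthetic extract with injected duplicates, shared across tests."""
    cfg = GeneratorConfig(n_reports=8000, p_duplicate=0.1, seed=11)
    d = tmp_path_factory.mktemp("extract")
    paths, truth = generate_extract(cfg, d)
    return d, cfg, truth


@pytest.fixture(scope="session")
def ingested(small_extract):
    d, cfg, truth = small_extract
    result = parse_tables(d)
    cohort, background = split_cohort(result.cases)
    return result, cohort, background, cfg, truth
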