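"""Shared fixtures: session-scoped synthetic studies used by several suites."""

import warnings

import pandas as pd
import pytest

from cogload import pipeline, synthetic


@pytest.fixture(scope="session")
def monotone_study(tmp_path_factory) -> tuple:
    """12-participant, 3-condition study with the default (strong) effect map.

    Recordings are 120 s (a scaled-down counterpart of the 4-min level-flight
    segment) to keep the suite fast; the study structure and effect map are
    the generator defaults.
    """
    cfg = synthetic.StudyConfig(participants=12, duration_s=120.0, seed=11)
    out = tmp_path_factory.mktemp("study") / "monotone"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        synthetic.gen_study(cfg, out)
    return cfg, out


@pytest.fixture(scope="session")
def monotone_metrics(monotone_study) -> pd.DataFrame:
    _, study_dir = monotone_study
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pipeline.extract_metrics(study_dir)


@pytest.fixture(scope="session")
def monotone_report(monotone_metrics) -> pipeline.AnalysisReport:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pipeline.analyze_study(monotone_metrics)
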