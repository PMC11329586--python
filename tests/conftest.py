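from __future__ import annotations

import pytest

from mraudit.fixtures import (DeviationSpec, FixtureConfig, ModalityConfig,
                              default_base_protocol, default_config, generate)
from mraudit.model import DatasetHierarchy, ParameterValue, Run


def make_run(run_id, subject="sub-01", session="ses-01", modality="T1W",
             vendor="SIEMENS", echo=None, **params) -> Run:
    pvs = {name: ParameterValue.from_vocab(name, value)
           for name, value in params.items()}
    return Run(run_id=run_id, subject_id=subject, session_id=session,
               modality_label=modality, vendor=vendor, echo_number=echo,
               parameters=pvs)


def make_hierarchy(runs) -> DatasetHierarchy:
    h = DatasetHierarchy(dataset_name="test")
    for r in runs:
        h.add_run(r)
    return h


@pytest.fixture
def base_protocol():
    return default_base_protocol()


@pytest.fixture
def small_dicom_tree(tmp_path):
    """3 subjects x 2 modalities, one run each, no deviations."""
    cfg = FixtureConfig(
        name="small", n_subjects=3, seed=7, formats=("dicom",),
        modalities=[
            ModalityConfig(name="T1w", datatype="anat", suffix="T1w",
                           base=default_base_protocol()),
            ModalityConfig(name="T2w", datatype="anat", suffix="T2w",
                           base={**default_base_protocol(),
                                 "RepetitionTime": 3200.0,
                                 "EchoTime": 60.0}),
        ])
    manifest = generate(cfg, tmp_path / "small")
    return tmp_path / "small" / "dicom", manifest


@pytest.fixture
def deviant_dicom_tree(tmp_path):
    """8 subjects, TR shift on a quarter of them plus a PED flip."""
    cfg = default_config(
        n_subjects=8, seed=3, formats=("dicom",),
        deviations=[
            DeviationSpec("RepetitionTime", "numeric-shift", 0.25,
                          delta=150.0),
            DeviationSpec("PhaseEncodingDirection", "categorical-flip",
                          0.25, alternate="COL"),
        ])
    manifest = generate(cfg, tmp_path / "deviant")
    return tmp_path / "deviant" / "dicom", manifest
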