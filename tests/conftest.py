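import textwrap

import pytest

from precombi import default_design, read_design


@pytest.fixture
def four_group_design():
    return default_design()


@pytest.fixture
def design_yaml(tmp_path):
    """A small 4-group design config on disk."""
    text = textwrap.dedent(
        """
        study_id: demo
        tgd_threshold_mm3: 1000
        evaluation_days: [21]
        groups:
          - name: control
            role: control
          - name: A
            role: single_agent
            arms:
              - {agent: A, dose: 100 mg/kg, route: i.v., days: [8, 15, 22, 29, 38]}
          - name: B
            role: single_agent
            arms:
              - {agent: B, dose: 1 ug/kg, route: s.c., days: [9, 11, 13, 16, 18, 20, 23, 25, 27, 30, 32, 34, 37, 39, 41, 44]}
          - name: A+B
            role: combination
            paired_singles: [A, B]
            arms:
              - {agent: A, dose: 100 mg/kg, route: i.v., days: [8, 15, 22, 29, 38]}
              - {agent: B, dose: 1 ug/kg, route: s.c., days: [9, 11, 13, 16, 18, 20, 23, 25, 27, 30, 32, 34, 37, 39, 41, 44]}
        """
    )
    path = tmp_path / "design.yaml"
    path.write_text(text)
    return path


@pytest.fixture
def design_from_yaml(design_yaml):
    return read_design(design_yaml)


def measurements_csv(tmp_path, rows, name="measurements.csv"):
    header = "animal_id,group,day,diam_short_mm,diam_long_mm,body_weight_g,status"
    path = tmp_path / name
    path.write_text("\n".join([header] + rows) + "\n")
    return path


@pytest.fixture
def make_measurements(tmp_path):
    return lambda rows, name="measurements.csv": measurements_csv(tmp_path, rows, name)
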