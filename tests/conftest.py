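import pytest

from dicscore.cohort import PatientRecord, Subgroup


@pytest.fixture
def make_record():
    """Factory for patient records with sensible normal-lab defaults."""

    def _make(**overrides):
        base = dict(
            patient_id="P1",
            subgroup=Subgroup.M3,
            pt_seconds=12.0,
            d_dimer_ng_ml=100.0,
            fibrinogen_mg_dl=300.0,
            platelet_1e9_l=250.0,
            ldh=200.0,
            hemoglobin_g_dl=10.0,
            inr=1.0,
            genetic_positive=False,
            bleeding=False,
        )
        base.update(overrides)
        return PatientRecord(**base)

    return _make
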