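import pytest

from aefi_signal.records import Recovered, ReportRecord, Sex, VaccineClass
from aefi_signal.synth import SimConfig, generate_reports
from aefi_signal.vocab import toy_vocab


def make_report(
    report_id: str,
    vaccine_class: VaccineClass = VaccineClass.PENTA,
    pts: set[str] | None = None,
    **kwargs,
) -> ReportRecord:
    defaults = dict(
        age_years=0.25,
        sex=Sex.MALE,
        recovered=Recovered.UNKNOWN,
        pts=frozenset(pts or {"Pyrexia"}),
    )
    defaults.update(kwargs)
    return ReportRecord(report_id=report_id, vaccine_class=vaccine_class, **defaults)


@pytest.fixture(scope="session")
def vocab() -> dict[str, str]:
    return toy_vocab()


@pytest.fixture(scope="session")
def small_cohort():
    """A 400+400 null cohort shared by read-only tests."""
    cfg = SimConfig(n_penta=400, n_hexa=400, seed=11)
    records, truth = generate_reports(cfg)
    return records, truth
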