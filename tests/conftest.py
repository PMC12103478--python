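import pytest

from vasoloop import ControllerConfig, NIBPReading


@pytest.fixture
def config() -> ControllerConfig:
    return ControllerConfig()


def reading(t: float, mbp: float, sbp: float | None = None,
            valid: bool = True) -> NIBPReading:
    """Build a reading from MBP alone (SBP/DBP filled in consistently)."""
    if not valid:
        return NIBPReading(t=t, sbp=float("nan"), mbp=float("nan"),
                           dbp=float("nan"), valid=False)
    if sbp is None:
        sbp = mbp + 30.0
    dbp = (3.0 * mbp - sbp) / 2.0
    return NIBPReading(t=t, sbp=sbp, mbp=mbp, dbp=dbp, valid=True)
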