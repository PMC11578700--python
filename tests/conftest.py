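import numpy as np
import pytest

from bptox.io_faers import DemoRecord, parse_date


def write_lines(path, header, rows):
    lines = [header] + rows
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def demo_record(primaryid="100", caseid="1", fda_dt="20200101", **kw):
    defaults = dict(
        event_dt=None, sex="F", age_years=70.0, reporter_code="MD", country="US"
    )
    defaults.update(kw)
    return DemoRecord(
        primaryid=primaryid,
        caseid=caseid,
        fda_dt=parse_date(fda_dt) if isinstance(fda_dt, str) else fda_dt,
        **defaults,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240)
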