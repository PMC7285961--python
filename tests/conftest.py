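import pytest

from normaudit.dataset_model import AuditDataset, PublicationRecord
from normaudit.synthetic_data import fixture_dataset


def make_record(rid="R1", **kwargs) -> PublicationRecord:
    defaults = dict(id=rid, year=2015, journal="J1")
    defaults.update(kwargs)
    return PublicationRecord(**defaults)


def make_dataset(*records) -> AuditDataset:
    return AuditDataset(tuple(records))


@pytest.fixture(scope="session")
def fixture_ds():
    """The canonical deterministic 225-record dataset."""
    return fixture_dataset()
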