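import sys
from pathlib import Path

import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

from chempfam import DomainHit, TargetRecord, ActivityRecord  # noqa: E402


@pytest.fixture
def akt3_target() -> TargetRecord:
    """Protein kinase Akt-3: PH + Pkinase + Pkinase_C architecture."""
    return TargetRecord("Q9Y243", [
        DomainHit("Q9Y243", "PH", 5, 108),
        DomainHit("Q9Y243", "Pkinase", 148, 405),
        DomainHit("Q9Y243", "Pkinase_C", 406, 479),
    ], sequence_length=479)


@pytest.fixture
def trypsin_target() -> TargetRecord:
    return TargetRecord("P00760", [DomainHit("P00760", "Trypsin", 24, 244)],
                        sequence_length=246)


def make_activity(activity_id=1, compound_id=1, target="P00760",
                  assay_type="B", multi=False, complex_=False,
                  activity_type="Ki", value=10.0, unit="nM") -> ActivityRecord:
    return ActivityRecord(activity_id, compound_id, target, assay_type,
                          multi, complex_, activity_type, value, unit)


@pytest.fixture
def toy_activities() -> list[ActivityRecord]:
    """Eight records probing every filter dimension; exactly 3 qualify.

    Keepers: the 10 nM Ki, the exactly-50 µM IC50 (inclusive boundary)
    and pKd 6.0 (above -log10(5e-5) = 4.301).  Removed: 60 µM (too
    weak), pKd 4.0 (below the log threshold), functional assay, flagged
    record, disallowed activity type.
    """
    return [
        make_activity(1, 1, value=10.0, unit="nM"),
        make_activity(2, 2, activity_type="IC50", value=50.0, unit="uM"),
        make_activity(3, 3, value=60.0, unit="uM"),
        make_activity(4, 4, activity_type="pKd", value=6.0, unit=""),
        make_activity(5, 5, activity_type="pKd", value=4.0, unit=""),
        make_activity(6, 6, assay_type="F"),
        make_activity(7, 7, multi=True),
        make_activity(8, 8, activity_type="GI50"),
    ]
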