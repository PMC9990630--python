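import pytest

from pvsignals.io import DemoRow, DrugRow, QuarterBundle, ReacRow
from pvsignals.normalize import SynonymDictionary


def demo(pid, caseid="", fda_dt="", **kw):
    return DemoRow(primaryid=pid, caseid=caseid or pid, fda_dt=fda_dt, **kw)


@pytest.fixture
def tiny_dictionary():
    d = SynonymDictionary()
    d.add("AVASTIN", ["bevacizumab"])
    d.add("BEVACIZUMAB", ["bevacizumab"])
    d.add("MEKINIST", ["trametinib"])
    d.add("TRAMETINIB", ["trametinib"])
    d.add("DABRAFENIB", ["dabrafenib"])
    d.add("SUTENT", ["sunitinib"])
    d.add("SUNITINIB", ["sunitinib"])
    d.add("PACLITAXEL", ["paclitaxel"])
    return d


@pytest.fixture
def tiny_bundle():
    """Three-report quarter: one (drugX, PT1), one (drugX, none),
    one (no drug, PT1)."""
    return QuarterBundle(
        quarter="2019Q2",
        demo=[demo("1001", "901", "20190401"),
              demo("1002", "902", "20190402"),
              demo("1003", "903", "20190403")],
        drug=[DrugRow("1001", "1", "PS", "AVASTIN", ""),
              DrugRow("1002", "1", "PS", "BEVACIZUMAB", "BEVACIZUMAB"),
              DrugRow("1003", "1", "C", "PACLITAXEL", "PACLITAXEL")],
        reac=[ReacRow("1001", "Gastrointestinal perforation"),
              ReacRow("1002", "Nausea"),
              ReacRow("1003", "Gastrointestinal perforation")],
    )
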