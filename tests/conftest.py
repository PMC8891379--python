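import numpy as np
import pytest

import pahrisk as pr


@pytest.fixture(scope="session")
def panel():
    return pr.load_panel()


@pytest.fixture(scope="session")
def targets(panel):
    return pr.load_group_targets(panel)


@pytest.fixture(scope="session")
def printed(panel):
    """The published per-group summary as a GroupSummaryTable (half-LOD imputed means)."""
    return pr.printed_group_summary(panel)


@pytest.fixture(scope="session")
def overall_means(panel):
    """Study-level mean concentration per congener, ug/kg, non-detects at LOD/2."""
    ov = pr.load_overall_summary()
    half = {ab: panel.get(ab).lod / 2.0 for ab in panel.abbrevs}
    return {
        ab: (half[ab] if np.isnan(ov.loc[ab, "mean"]) else float(ov.loc[ab, "mean"]))
        for ab in panel.abbrevs
    }


@pytest.fixture(scope="session")
def study_ds(panel, targets):
    """A study-scale synthetic dataset: 9 product types x 4 samples, censored."""
    return pr.generate(targets, panel, pr.GeneratorConfig())


@pytest.fixture
def make_dataset(panel):
    """Factory for small hand-built datasets.

    Takes ``{sample_id: (product_type, brand, {abbrev: value})}``; congeners
    not mentioned are censored, a value of None is censored explicitly.
    """

    def _make(rows, imputed=False):
        records = []
        for sid, (ptype, brand, values) in rows.items():
            ms = []
            for ab in panel.abbrevs:
                v = values.get(ab)
                if v is None:
                    ms.append(pr.Measurement(ab, None, True))
                else:
                    ms.append(pr.Measurement(ab, float(v), False))
            records.append(
                pr.SampleRecord(
                    sample_id=sid, product_type=ptype, brand=brand,
                    measurements=tuple(ms),
                )
            )
        ds = pr.SampleDataset(panel=panel, records=tuple(records))
        return pr.impute_nondetects(ds) if imputed else ds

    return _make
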