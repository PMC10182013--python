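import numpy as np
import pytest

from mrlifespan.harmonization import Action, HarmonizedInstrument
from mrlifespan.summary_stats_io import SummaryTable, VariantAssociation


def make_instruments(bx, by, se_y, se_x=None, eaf=None):
    """Build harmonized instruments from plain arrays for estimator tests."""
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    se_y = np.asarray(se_y, dtype=float)
    se_x = (
        np.full_like(bx, 0.005) if se_x is None else np.asarray(se_x, dtype=float)
    )
    eaf = np.full_like(bx, 0.3) if eaf is None else np.asarray(eaf, dtype=float)
    return [
        HarmonizedInstrument(
            variant_id=f"rs{i}",
            effect_allele="A",
            action=Action.UNCHANGED,
            bx=float(bx[i]),
            se_x=float(se_x[i]),
            by=float(by[i]),
            se_y=float(se_y[i]),
            eaf_exposure=float(eaf[i]),
        )
        for i in range(len(bx))
    ]


def make_table(rows, trait="trait", sex="overall", scale="sd"):
    """rows: iterable of dicts with VariantAssociation fields."""
    return SummaryTable(
        trait_label=trait,
        sex_stratum=sex,
        scale=scale,
        records=[VariantAssociation(**r) for r in rows],
    )


@pytest.fixture
def simple_table():
    return make_table(
        [
            dict(variant_id="rs1", effect_allele="A", other_allele="G",
                 eaf=0.3, beta=0.05, se=0.01, pvalue=1e-9),
            dict(variant_id="rs2", effect_allele="T", other_allele="C",
                 eaf=0.2, beta=-0.04, se=0.012, pvalue=1e-10),
            dict(variant_id="rs3", effect_allele="G", other_allele="C",
                 eaf=0.4, beta=0.06, se=0.009, pvalue=2e-8, n=1000.0),
        ]
    )
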