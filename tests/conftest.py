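import pytest

from ogmcll.curation import CurationConfig
from ogmcll.records import (
    CnvCall,
    CnvType,
    GenomicInterval,
    SvCall,
    SvType,
)
from ogmcll.simulate import SimConfig, simulate_cohort


def make_sv(call_id="sv1", sv_type=SvType.deletion, chrom="13",
            pos1=50_000_000, pos2=50_200_000, chrom2=None, confidence=0.9,
            labels=(30, 30), rawconf=(30.0, 30.0), molecules=20,
            patient_id="P1", size=None):
    sv_type = SvType(sv_type)
    if size is None:
        size = pos2 - pos1 if sv_type in (
            SvType.deletion, SvType.duplication, SvType.inversion) else 0
    return SvCall(
        call_id=call_id, sv_type=sv_type,
        bp1=(chrom, pos1), bp2=(chrom2 or chrom, pos2), size_bp=size,
        confidence=confidence, raw_conf_left=rawconf[0],
        raw_conf_right=rawconf[1], labels_bp1=labels[0], labels_bp2=labels[1],
        self_molecules=molecules, patient_id=patient_id)


def make_cnv(call_id="cnv1", chrom="13", start=50_000_000, end=50_900_000,
             cnv_type=CnvType.loss, confidence=0.995, cell_fraction=0.8,
             patient_id="P1"):
    return CnvCall(call_id=call_id,
                   interval=GenomicInterval(chrom, start, end),
                   cnv_type=CnvType(cnv_type), confidence=confidence,
                   cell_fraction=cell_fraction, patient_id=patient_id)


@pytest.fixture(scope="session")
def default_cfg():
    return CurationConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-patient simulated cohort shared by integration-style tests."""
    return simulate_cohort(SimConfig(n_patients=12, seed=20240917))
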