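import warnings

import pandas as pd
import pytest

import mutopt as m
from mutopt.synthetic_data import (
    ExposureSimConfig,
    MDSSimConfig,
    TumorSimConfig,
    simulate_exposures,
    simulate_mds,
    simulate_tumors,
)


def mds_observations(table: pd.DataFrame) -> list[m.MDSSiteObservation]:
    """MDS table rows as typed observations."""
    return [
        m.MDSSiteObservation(
            r.animal_id, r.arm, r.amplicon, int(r.position),
            r.ref, r.alt, r.context3, float(r.frequency),
        )
        for r in table.itertuples(index=False)
    ]


def snv_records(table: pd.DataFrame) -> list[m.SNVRecord]:
    """SNV catalog rows as typed records."""
    return [
        m.SNVRecord(
            r.sample, r.chrom, int(r.pos), r.ref, r.alt, r.context3,
            r.gene, r.effect, r.aa_change, float(r.vaf), r.group,
        )
        for r in table.itertuples(index=False)
    ]


@pytest.fixture(scope="session")
def mds_bundle():
    return simulate_mds(MDSSimConfig(seed=11))


@pytest.fixture(scope="session")
def tumor_bundle():
    return simulate_tumors(TumorSimConfig(seed=7))


@pytest.fixture(scope="session")
def exposure_bundle():
    return simulate_exposures(ExposureSimConfig(seed=5, minor_fraction=0.5))


@pytest.fixture()
def arm_spectra(mds_bundle):
    """(PBS, urethane) mean-frequency spectra from the filtered synthetic MDS table."""
    table, _ = mds_bundle
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        obs = m.filter_mds_artifacts(mds_observations(table))
        pbs = m.build_mds_spectrum([o for o in obs if o.arm == "PBS"], "PBS")
        ure = m.build_mds_spectrum(
            [o for o in obs if o.arm == "urethane"], "urethane"
        )
    return pbs, ure
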