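import hypothesis
import pytest

import gpcrprofile as gp
from gpcrprofile import simulate as sim

hypothesis.settings.register_profile(
    "default", deadline=None, derandomize=True, max_examples=50
)
hypothesis.settings.load_profile("default")


@pytest.fixture(scope="session")
def proteomics_profile() -> gp.ExpressionProfile:
    """Expression profile built from the published transcript-unit matrix."""
    return gp.profile_from_units(gp.transcript_units_matrix())


@pytest.fixture(scope="session")
def study_like() -> tuple[gp.CtDataset, sim.GroundTruth]:
    return sim.generate_study_like_dataset(seed=1)


@pytest.fixture(scope="session")
def study_like_gpcr_profile(study_like) -> gp.ExpressionProfile:
    """Normalized GPCR-only profile of the study-design synthetic dataset."""
    dataset, _truth = study_like
    matrix = gp.merge_replicates(dataset)
    ref = gp.build_reference(matrix, grand_mean_ct=gp.REFERENCE_CT)
    profiles = gp.normalize(matrix, ref)
    gpcr = set(matrix.genes("GPCR"))
    data = profiles.data[profiles.data["gene"].isin(gpcr)].reset_index(drop=True)
    return gp.ExpressionProfile(
        data=data, reference=profiles.reference, ct_cutoff=profiles.ct_cutoff
    )


def gpcr_only(profiles: gp.ExpressionProfile, matrix: gp.MeanCtMatrix) -> gp.ExpressionProfile:
    genes = set(matrix.genes("GPCR"))
    data = profiles.data[profiles.data["gene"].isin(genes)].reset_index(drop=True)
    return gp.ExpressionProfile(
        data=data, reference=profiles.reference, ct_cutoff=profiles.ct_cutoff
    )
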