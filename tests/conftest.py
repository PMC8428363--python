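import pytest

import ihc_autoscore as ia
from ihc_autoscore.pipeline import SlideRecord
from ihc_autoscore.training import fit_reference_backends


@pytest.fixture(scope="session")
def training_records():
    """Four small synthetic slides with ground truth for backend training."""
    recs = []
    for s in range(4):
        spec = ia.SlideSpec(width_px=2400, height_px=2400, seed=s,
                            positive_fraction=0.7, n_tumor_regions=1)
        image, gt = ia.generate_slide(spec)
        recs.append(SlideRecord(slide_id=f"T{s}", patient_id=f"PT{s}",
                                image=image, ground_truth=gt))
    # bare-glass material: real slides are mostly empty background
    spec = ia.SlideSpec(width_px=1600, height_px=1600, seed=4,
                        n_tumor_regions=0, nontumor_cell_density=0.0)
    image, gt = ia.generate_slide(spec)
    recs.append(SlideRecord(slide_id="T4", patient_id="PT4", image=image,
                            ground_truth=gt))
    return recs


@pytest.fixture(scope="session")
def reference_backends(training_records):
    """Fitted reference tumor-tile classifier and cell detector."""
    return fit_reference_backends(training_records, seed=0)


@pytest.fixture(scope="session")
def heldout_slide():
    """A slide never seen in training, with a planted positive fraction."""
    spec = ia.SlideSpec(width_px=2400, height_px=1600, seed=97,
                        positive_fraction=0.3, n_tumor_regions=1)
    image, gt = ia.generate_slide(spec)
    return SlideRecord(slide_id="H0", patient_id="PH0", image=image,
                       ground_truth=gt)


@pytest.fixture(scope="session")
def small_cohort():
    return ia.generate_cohort(ia.CohortParams(n_patients=400, seed=11))
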