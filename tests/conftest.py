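import numpy as np
import pytest

import skintone as st


@pytest.fixture(scope="session")
def monk():
    return st.monk_scale()


@pytest.fixture(scope="session")
def fitzpatrick():
    return st.fitzpatrick_scale()


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Small noiseless synthetic cohort: predictions must be exact."""
    spec = st.SyntheticSpec(n_images=30, seed=11, sigma=0.0)
    records, gold = st.make_cohort(spec)
    return spec, records, gold


@pytest.fixture(scope="session")
def noiseless_results(noiseless_cohort):
    _, records, gold = noiseless_cohort
    manifest = [
        {"image_id": r.image_id, "image": r.image, "parts": r.parts, "landmarks": r.landmarks}
        for r in records
    ]
    return st.run_batch(manifest, st.RunConfig()), gold


def run_cohort(records, config=None):
    manifest = [
        {"image_id": r.image_id, "image": r.image, "parts": r.parts, "landmarks": r.landmarks}
        for r in records
    ]
    return st.run_batch(manifest, config or st.RunConfig())


def monk_eval(results, gold, region=None, margin_cfg=None):
    """Join results with gold and score the Monk predictions."""
    merged = results.merge(gold[gold["scale"] == "monk"], on=["image_id", "region"])
    if region:
        merged = merged[merged["region"] == region]
    merged = merged.dropna(subset=["monk"])
    return st.evaluate(
        merged["class"].astype(int).to_numpy(),
        merged["monk"].astype(int).to_numpy(),
        10,
        scale_name="monk",
        config=margin_cfg or st.EvalConfig(),
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
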