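import numpy as np
import pytest

from sugartrait.annotations import FeatureRecord, GenomeAnnotation


def make_annotation(products, genome_id="g1", genus=""):
    feats = [
        FeatureRecord(
            genome_id=genome_id,
            feature_id=f"f{i}",
            product=p,
            protein_id=f"p{i}",
        )
        for i, p in enumerate(products)
    ]
    return GenomeAnnotation(genome_id=genome_id, features=feats, genus=genus)


@pytest.fixture
def six_product_annotation():
    """Mixed products exercising gate and family-token rules."""
    return make_annotation(
        [
            "sugar ABC transporter",
            "PTS sugar transporter subunit IIA",
            "MFS sugar transporter",
            "sugar transporter",
            "sugar porter",
            "ABC transporter",
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
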