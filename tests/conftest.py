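"""Shared fixtures: one simulated default screen per session plus guide factories."""

import pytest

from crekit import synthetic_screens as ss
from crekit.screen_io import GuideRecord


@pytest.fixture(scope="session")
def default_screen():
    """The standard study-condition sorting screen at seed 1."""
    cfg = ss.default_config(seed=1)
    guides, design, truth = ss.simulate_sorting_screen(cfg)
    return cfg, guides, design, truth


def make_guide(
    guide_id="g0",
    chrom="chr1",
    pam_start=1000,
    strand="+",
    category="targeting",
    specificity=0.9,
    protospacer="ACGTACGTACGTACGTACGT",
    counts=None,
):
    has_coords = category != "nontargeting"
    return GuideRecord(
        guide_id=guide_id,
        chrom=chrom if has_coords else None,
        pam_start=pam_start if has_coords else None,
        pam_end=pam_start + 3 if has_coords else None,
        strand=strand if has_coords else None,
        protospacer=protospacer,
        category=category,
        specificity=specificity,
        counts=counts or {},
    )
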