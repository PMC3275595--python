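"""Shared fixtures: bundled scales, synthetic datasets, constructed toy scales."""

import numpy as np
import pytest

import gfsmlp as g
from gfsmlp.scales import STANDARD_RESIDUES, NormalizedScale, PropensityScale


@pytest.fixture(scope="session")
def norm_scales():
    return g.builtin_normalized_scales()


@pytest.fixture(scope="session")
def raw_scales():
    return g.builtin_scales()


@pytest.fixture(scope="session")
def default_dataset(norm_scales):
    """The generator's default study conditions: 300/class, group 8, effect 1.5."""
    return g.generate(g.SyntheticSpec(), norm_scales)


@pytest.fixture(scope="session")
def default_model(default_dataset, norm_scales):
    return g.GFSMLP.from_dataset(default_dataset, norm_scales)


@pytest.fixture(scope="session")
def small_dataset(norm_scales):
    """A small, strongly separable dataset for fast training tests."""
    spec = g.SyntheticSpec(n_per_class=30, effect=3.0, noise=0.0, seed=7)
    return g.generate(spec, norm_scales)


@pytest.fixture(scope="session")
def small_model(small_dataset, norm_scales):
    return g.GFSMLP.from_dataset(small_dataset, norm_scales)


def make_orthogonal_scales(n: int = 4) -> list[NormalizedScale]:
    """Constructed scales with (near-)orthogonal residue patterns.

    Scale k assigns +1/-1 by the k-th bit pattern over the residue index
    (Walsh-like), so under the uniform residue distribution the scales are
    exactly uncorrelated — unlike the real bundled scales.
    """
    scales = []
    for k in range(n):
        vals = {}
        for i, res in enumerate(STANDARD_RESIDUES):
            block = 2 ** (k + 1)
            vals[res] = 1.0 if (i % block) < block // 2 else -1.0
        # break exact ties so the scale is not two-valued-degenerate for encode
        scales.append(NormalizedScale(name=f"walsh_{k + 1}", values=vals))
    return scales


@pytest.fixture(scope="session")
def orthogonal_scales():
    return make_orthogonal_scales(4)


@pytest.fixture()
def toy_records():
    seqs = [
        "ACDEFGHIKLMNPQRSTVWY",
        "AAAAAAAAAAAAAAAAAAAA",
        "YWVTSRQPNMLKIHGFEDCA",
        "CCCCCCCCCCCCCCCCCCCC",
    ]
    return [g.PeptideRecord(s, lab) for s, lab in zip(seqs, [1, 1, 0, 0])]
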