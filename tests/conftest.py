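from __future__ import annotations

import pytest

from mirvar import fixtures as fx
from mirvar.hairpin_align import locate_matures


@pytest.fixture(scope="session")
def reference():
    """Three synthetic stem-loop hairpins with their 5p/3p matures and loci."""
    hairpins, matures = fx.make_reference(seed=3, n_hairpins=3)
    loci = locate_matures(matures, hairpins)
    return hairpins, matures, loci


@pytest.fixture(scope="session")
def mixed_library(reference):
    """A 400-read library with a broad planted isomiR composition."""
    hairpins, _, _ = reference
    profile = fx.VariantProfile(
        canonical=0.40, super3=0.15, sub3=0.05, super5=0.05, sub5=0.05,
        mismatch=0.10, insertion=0.03, deletion=0.03, nta_polyA=0.06,
        nta_polyU=0.04, nta_other=0.02, mixture=0.02,
        a_to_g_fraction=0.5, n_reads=400, seed=11,
    )
    reads, manifest = fx.make_library(hairpins, profile)
    return reads, manifest


@pytest.fixture(scope="session")
def quantified(reference, mixed_library):
    """The mixed library pushed through collapse, mapping and quantification."""
    from mirvar.preprocess import collapse
    from mirvar.hairpin_align import map_all
    from mirvar.quantify import assign_counts

    hairpins, _, loci = reference
    reads, manifest = mixed_library
    collapsed = collapse(reads)
    mappings, _ = map_all(collapsed, hairpins)
    hairpin_seqs = {h.hairpin_id: h.sequence for h in hairpins}
    quant = assign_counts(collapsed, mappings, loci, hairpin_seqs)
    return collapsed, mappings, quant, manifest
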