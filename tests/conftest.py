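import pytest

from knockin import design as dz
from knockin.simulate import simulate_locus


@pytest.fixture(scope="session")
def toy_locus():
    """2-kb random window with a centred ORF; insertion after the ATG."""
    loc = simulate_locus(2000, gc=0.4, seed=11)
    return dz.TargetLocus(
        contig_id="chr1", window_seq=loc.seq, window_start=0,
        insertion_point=loc.orf_start + 3, frame_anchor=loc.orf_start,
        terminus=dz.Terminus.N), loc


@pytest.fixture(scope="session")
def tag_cassette():
    """714-nt cassette from a random 720-nt ORF (ATG and stop stripped)."""
    tagloc = simulate_locus(1440, gc=0.45, seed=12)
    orf = tagloc.seq[tagloc.orf_start:tagloc.orf_end]
    assert len(orf) == 720
    return dz.build_tag_cassette(orf, "N")


@pytest.fixture(scope="session")
def donor_780(toy_locus, tag_cassette):
    locus, _ = toy_locus
    arms = dz.extract_homology_arms(locus, 33)
    return dz.assemble_donor(locus, arms, tag_cassette)
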