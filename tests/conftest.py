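import warnings

import pytest

from famevol import family_id, seqalign, syndata

warnings.filterwarnings("ignore", message="gene .* skipped")


@pytest.fixture(scope="session")
def pssms():
    return {dom: seqalign.build_pssm([s for _, s in rows], domain_name=dom)
            for dom, rows in syndata.seed_alignments().items()}


@pytest.fixture(scope="session")
def references():
    return [family_id.Reference(h.split()[0], h.split("subfamily=")[1], s)
            for h, s in syndata.reference_proteins()]


@pytest.fixture(scope="session")
def small_genome(tmp_path_factory):
    """One small species genome with every planted structure."""
    spec = syndata.default_genome_spec("spT", seed=101, n_members=8,
                                       n_background=30)
    return syndata.make_genome(spec, tmp_path_factory.mktemp("genome"))
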