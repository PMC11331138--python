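import pytest

from lrrpockets.simulate import (
    PEPTIDE_CHAIN,
    RECEPTOR_CHAIN,
    SimConfig,
    generate_complex_ensemble,
    generate_gene_tables,
    generate_precursor_set,
    generate_receptor_family,
    generate_toy_complex,
)

ROLES = {RECEPTOR_CHAIN: "receptor", PEPTIDE_CHAIN: "peptide"}


@pytest.fixture(scope="session")
def cfg():
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def receptor_family(cfg):
    return generate_receptor_family(cfg)


@pytest.fixture(scope="session")
def precursor_set(cfg):
    return generate_precursor_set(cfg)


@pytest.fixture(scope="session")
def gene_tables(cfg):
    return generate_gene_tables(cfg)


@pytest.fixture(scope="session")
def toy_complex(cfg):
    return generate_toy_complex(cfg)


@pytest.fixture(scope="session")
def ensemble(cfg):
    return generate_complex_ensemble(cfg)


@pytest.fixture(scope="session")
def parsed_ensemble(ensemble):
    from lrrpockets.structures import parse_structure

    return [
        parse_structure(pdb, ROLES, sidecar=ensemble.sidecar, model_id=mid)
        for mid, pdb, _ in ensemble.models
    ]


@pytest.fixture(scope="session")
def family_rcm(receptor_family):
    """Grid and RCM map of the default receptor family."""
    from lrrpockets.rcm import build_lrr_grid, rcm_map
    from lrrpockets.receptors import detect_lrr_repeats

    rid, rseq = receptor_family.records[0]
    ann = detect_lrr_repeats(rseq, rid)
    grid = build_lrr_grid(receptor_family.records, ann, rid)
    return grid, rcm_map(receptor_family.records, grid)
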