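import pytest

from phosmet import (Proteome, ProteinRecord, SiteRecord, SyntheticConfig,
                     generate_proteome, plant_phosphosites)


@pytest.fixture
def tiny_proteome():
    """Hand-written five-protein proteome covering terminal edge cases."""
    return Proteome(records=[
        ProteinRecord(id="p1", sequence="MKSTMA"),
        ProteinRecord(id="p2", sequence="SAAAA"),
        ProteinRecord(id="p3", sequence="AAMASAA"),
        ProteinRecord(id="p4", sequence="MKSAAA"),
        ProteinRecord(id="p5", sequence="ACDEFGHIKLMNPQRSTVWY"),
    ], taxon_label="toy")


@pytest.fixture
def tiny_sites(tiny_proteome):
    sites = [
        SiteRecord("p1", 3, "S"),
        SiteRecord("p2", 1, "S"),
        SiteRecord("p3", 5, "S"),
        SiteRecord("p4", 3, "S"),
        SiteRecord("p5", 17, "T"),
    ]
    for s in sites:
        s.validate(tiny_proteome)
    return sites


@pytest.fixture(scope="session")
def small_synthetic():
    """A small planted dataset shared by tests that only need realism."""
    cfg = SyntheticConfig(seed=42, n_proteins=60, length_mean=300.0,
                          n_phosphosites=150)
    proteome = generate_proteome(cfg)
    proteome, sites = plant_phosphosites(proteome, cfg)
    return cfg, proteome, sites
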