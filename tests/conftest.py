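import pytest

from bgcforge.fixtures import generate_annotation_table, generate_bundle
from bgcforge.refdata import MonomerLibrary


@pytest.fixture(scope="session")
def bundle():
    """The seed-0 synthetic reference bundle shared across the suite."""
    return generate_bundle(seed=0)


@pytest.fixture(scope="session")
def fixture_dir(bundle, tmp_path_factory):
    """Fixture genomes + annotation tables written to disk."""
    d = tmp_path_factory.mktemp("fixtures")
    for name, genome in bundle.genomes.items():
        (d / f"{name}.fasta").write_text(genome.fasta())
        generate_annotation_table(genome, str(d / f"{name}.annotation.tsv"))
    with open(d / "compounds.tsv", "w") as fh:
        for c in bundle.compound_db:
            fh.write(f"{c.id}\t{c.name}\t{c.smiles}\n")
    return d


@pytest.fixture(scope="session")
def monomers():
    return MonomerLibrary()
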