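import pytest

from dcsminer.synthetic_proteomes import SyntheticSpec, generate_proteome


@pytest.fixture(scope="session")
def seed42_proteome():
    """The canonical 50-protein synthetic screen (5 intact + 2 aberrant
    fusions, 10 TS-only, 10 DTC-only, 3 SHC decoys, 20 background)."""
    spec = SyntheticSpec(seed=42)
    records, truth = generate_proteome(spec)
    return records, truth


@pytest.fixture(scope="session")
def seed42_fasta(seed42_proteome, tmp_path_factory):
    from dcsminer.seqio import write_fasta
    records, _ = seed42_proteome
    path = tmp_path_factory.mktemp("proteome") / "proteome.fasta"
    write_fasta(records, path)
    return path
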