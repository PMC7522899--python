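import pytest


@pytest.fixture
def write_fasta_file(tmp_path):
    """Write a FASTA file from (id, seq) pairs; returns the path."""

    def _write(pairs, name="seqs.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rec_id, seq in pairs:
                fh.write(f">{rec_id}\n{seq}\n")
        return path

    return _write
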