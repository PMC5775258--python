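"""Packaged plain-text fixtures.

Currently a single FASTA of the six mouse TRPA1 decapeptide substrates
used in the in vitro Cdk5 kinase assay (each carries one consensus site
with the acceptor at window position 4 and the obligate proline at 5).
"""

from importlib.resources import files
from pathlib import Path


def trpa1_peptides_path() -> Path:
    """Path to the six-decapeptide substrate FASTA."""
    return Path(str(files(__package__) / "trpa1_assay_peptides.fasta"))
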