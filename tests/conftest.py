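import numpy as np
import pytest

from nociscreen import seqscreen
from nociscreen.data import trpa1_peptides_path

#: The six decapeptide substrates from the in vitro kinase assay, with
#: the acceptor residue at window position 4 in each.
ASSAY_PEPTIDES = [
    "YGNTPLHCAA",
    "NMMSPLHIAV",
    "KKASPLHLAV",
    "DGCTPLHYAC",
    "DKKSPLHFAA",
    "HGMTPLHLAA",
]


@pytest.fixture(scope="session")
def peptide_records():
    return seqscreen.read_fasta(trpa1_peptides_path())


@pytest.fixture
def rng():
    return np.random.default_rng(20180119)


def random_protein(rng, length, pid="p"):
    seq = "".join(rng.choice(list(seqscreen.AMINO_ACIDS), size=length))
    return seqscreen.ProteinRecord(pid, seq)


def brute_force_scan(sequence, kind):
    """Independent all-windows oracle: test every 4-mer on its own.

    ``kind`` is 'consensus' for (S/T)PX(K/H/R) or 'txxh' for T/SxxH.
    Returns 1-based acceptor positions.
    """
    hits = []
    for i in range(len(sequence) - 3):
        w = sequence[i : i + 4]
        if w[0] not in "ST":
            continue
        if kind == "consensus" and w[1] == "P" and w[3] in "KHR":
            hits.append(i + 1)
        elif kind == "txxh" and w[3] == "H":
            hits.append(i + 1)
    return hits
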