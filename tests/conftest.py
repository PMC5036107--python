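import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=60)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(20160920)


@pytest.fixture()
def toy_genome(tmp_path):
    """A 100 bp genome with exon [10,20), TE [15,40), SSR [0,5) on one contig.

    With SSR > EX > TE precedence this yields EX 10 bp, TE 20 bp, NTE 65 bp.
    """
    rng = np.random.default_rng(7)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 100)])
    fasta = tmp_path / "g.fa"
    fasta.write_text(">chr1\n" + seq + "\n")
    beds = {}
    for name, iv in (("ssr", (0, 5)), ("te", (15, 40)), ("exon", (10, 20))):
        p = tmp_path / f"{name}.bed"
        p.write_text(f"chr1\t{iv[0]}\t{iv[1]}\n")
        beds[name] = str(p)
    return {"fasta": str(fasta), "seq": seq, **beds}


def write_fasta(path, sequences):
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n{seq}\n")
    return str(path)
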