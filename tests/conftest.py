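import numpy as np
import pyfaidx
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# chr1: CpG at pos 6 (C) / 7 (G), clear flanks; chr2 has a CpG at pos 2
# (insufficient flank) and a non-CpG C at pos 4
TINY_REFERENCE = {
    "chr1": "TTAAACGTTTGGACGTACGTAGCTAGCTAACGTTACG",
    "chr2": "TCGACATTTTTTTTTTTTTT",
}


@pytest.fixture()
def tiny_fasta(tmp_path):
    path = tmp_path / "tiny.fa"
    with open(path, "w") as handle:
        for name, seq in TINY_REFERENCE.items():
            handle.write(f">{name}\n{seq}\n")
    return pyfaidx.Fasta(str(path))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240730)


def write_lines(path, lines):
    with open(path, "w") as handle:
        handle.write("\n".join(lines) + ("\n" if lines else ""))
    return path
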