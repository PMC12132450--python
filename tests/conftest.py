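import numpy as np
import pytest

from crossworm.meiosis import ChromosomeModel, CrossDesign


@pytest.fixture
def autosome():
    return ChromosomeModel("I", 17.0e6)


@pytest.fixture
def x_chrom():
    return ChromosomeModel("X", 24.0e6, kind="X")


@pytest.fixture
def design():
    return CrossDesign()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def marker_tsv(tmp_path):
    """Writer for small marker tables: rows of (chrom, bp, cM)."""
    def write(rows, name="markers.tsv", header="chrom\tbp\tcM"):
        path = tmp_path / name
        lines = [header] + ["\t".join(str(v) for v in r) for r in rows]
        path.write_text("\n".join(lines) + "\n")
        return path
    return write
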