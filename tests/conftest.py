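import numpy as np
import pytest

from csikit.seqdata import Alignment, GroupAssignment, SequenceRecord
from csikit.structure import read_structure
from csikit.synthetic import ToyDimerConfig, make_preset, make_toy_dimer

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_alignment(rng, n_records=10, ncols=30, gap_prob=0.0, prefix="r"):
    recs = []
    for i in range(n_records):
        chars = [AA[k] for k in rng.integers(0, 20, size=ncols)]
        if gap_prob:
            for c in range(ncols):
                if rng.random() < gap_prob:
                    chars[c] = "-"
        recs.append(SequenceRecord(f"{prefix}{i}", "".join(chars)))
    # guard against an all-gap column
    for c in range(ncols):
        if all(r.residues[c] == "-" for r in recs):
            r0 = recs[0]
            recs[0] = SequenceRecord(
                r0.id, r0.residues[:c] + "A" + r0.residues[c + 1:]
            )
    return Alignment(recs)


@pytest.fixture(scope="session")
def fig1_dataset():
    return make_preset("fig1_like", 42)


@pytest.fixture(scope="session")
def fig2_dataset():
    return make_preset("fig2_like", 42)


@pytest.fixture(scope="session")
def hgt_dataset():
    return make_preset("hgt_like", 42)


@pytest.fixture(scope="session")
def toy_dimer(tmp_path_factory):
    cfg = ToyDimerConfig(seed=1)
    pdb_text, truth = make_toy_dimer(cfg)
    path = tmp_path_factory.mktemp("dimer") / "toy.pdb"
    path.write_text(pdb_text)
    return read_structure(path), truth, cfg


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
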