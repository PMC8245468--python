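import numpy as np
import pytest

import savpred as sp
from savpred import synthetic


@pytest.fixture(scope="session")
def toy_structure():
    """30-residue two-chain toy protein with 4 ligand atoms + DSSP records."""
    return sp.make_toy_structure(30, n_chains=2, het_atoms=4, seed=3)


@pytest.fixture(scope="session")
def toy_profile():
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("ARNDCQEGHILKMFPSTWYV"), 31))
    conservation = rng.uniform(0, 1, 31)
    return seq, sp.make_toy_pssm(seq, conservation, seed=1)


@pytest.fixture()
def toy_sav(toy_structure):
    model, dssp = toy_structure
    wt = dssp[14].aa_code.upper()
    mut = "V" if wt != "V" else "L"
    return sp.SAVRecord("TOY", "A", 15, 15, wt, mut, "cancer")


@pytest.fixture(scope="session")
def toy_files(tmp_path_factory, toy_structure, toy_profile):
    """Toy structure/DSSP/PSSM/FASTA written to disk for parser round trips."""
    d = tmp_path_factory.mktemp("toyfiles")
    model, dssp = toy_structure
    seq, profile = toy_profile
    synthetic.write_pdb(model, d / "TOY.pdb")
    synthetic.write_dssp(dssp, d / "TOY.dssp")
    synthetic.write_pssm(profile, d / "TOY.pssm")
    (d / "TOY.fasta").write_text(f">TOY synthetic\n{seq}\n")
    return d
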