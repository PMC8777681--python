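import gemmi
import pytest
from hypothesis import HealthCheck, settings

from mitoproteoscope import core_io, differential, synthetic

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def complex_defs():
    return core_io.default_complex_definitions()


@pytest.fixture(scope="session")
def seed42_dataset(complex_defs):
    """The reference disease fixture: 2000 proteins, 3v5 design, seed 42."""
    matrix, truth = synthetic.generate_quant_matrix(
        2000,
        synthetic.default_design(),
        synthetic.DiseaseProfile(),
        seed=42,
        complex_defs=complex_defs,
    )
    return matrix, truth


@pytest.fixture(scope="session")
def seed42_diff(seed42_dataset):
    matrix, _ = seed42_dataset
    result = differential.differential_test(
        core_io.log2_transform(matrix), synthetic.default_design()
    )
    return differential.classify_volcano(result)


@pytest.fixture()
def toy_structure(tmp_path):
    """A 2-chain, few-residue PDB file (chain A: 3 residues, chain B: 2)."""
    structure = gemmi.Structure()
    model = gemmi.Model("1")
    for chain_name, n_res in [("A", 3), ("B", 2)]:
        chain = gemmi.Chain(chain_name)
        for i in range(n_res):
            residue = gemmi.Residue()
            residue.name = "GLY"
            residue.seqid = gemmi.SeqId(i + 1, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(float(i), 0.0, 0.0)
            atom.occ = 1.0
            residue.add_atom(atom)
            chain.add_residue(residue)
        model.add_chain(chain)
    structure.add_model(model)
    structure.setup_entities()
    path = tmp_path / "toy.pdb"
    structure.write_pdb(str(path))
    return path
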