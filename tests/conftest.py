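import numpy as np
import pytest
from hypothesis import settings

from fgfhs import fit_calibration, make_toy_complex
from fgfhs.reference import PUBLISHED_ELUTION

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def elution_pairs():
    """Published (conductivity mS/cm, [NaCl] M) calibration pairs."""
    return list(PUBLISHED_ELUTION.values())


@pytest.fixture(scope="session")
def calibration(elution_pairs):
    return fit_calibration(elution_pairs)


@pytest.fixture()
def toy_complex():
    """10-residue poly-Ala chain, ligand 5 A above residues 3-7."""
    return make_toy_complex(n_residues=10, ligand_offset=5.0, seed=1)


def brute_force_min_ligand_distance(structure, position):
    """Plain-loop oracle for the vectorized ligand-distance computation."""
    best = np.inf
    for a in structure.residue_atoms(position):
        if not a.is_heavy:
            continue
        for b in structure.ligand_atoms:
            if not b.is_heavy:
                continue
            d = float(np.linalg.norm(a.pos - b.pos))
            best = min(best, d)
    return best


def brute_force_clash(structure, position, cutoff):
    """Plain-loop oracle for the clash detector, same exclusion rules."""
    from fgfhs.structure import BACKBONE_ATOMS
    res_atoms = structure.residue_atoms(position)
    chain = res_atoms[0].chain
    side = [a for a in res_atoms if a.name not in BACKBONE_ATOMS and a.is_heavy]
    for a in side:
        for b in structure.atoms:
            if not b.is_heavy:
                continue
            if not b.is_ligand:
                if b.chain == chain and b.res_seq == position:
                    continue
                if (b.chain == chain and abs(b.res_seq - position) == 1
                        and b.name in BACKBONE_ATOMS):
                    continue
            if float(np.linalg.norm(a.pos - b.pos)) < cutoff:
                return True
    return False
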