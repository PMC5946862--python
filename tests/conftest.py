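import numpy as np
import pytest

import groovemap as gm


def random_duplex(length: int, seed: int) -> gm.DuplexSequence:
    rng = np.random.default_rng(seed)
    return gm.DuplexSequence("".join(rng.choice(list("ACGT"), size=length)))


@pytest.fixture(scope="session")
def small_seq() -> gm.DuplexSequence:
    """60-bp random duplex used by the quick fitting tests."""
    return random_duplex(60, seed=101)


@pytest.fixture(scope="session")
def seq300() -> gm.DuplexSequence:
    """300-bp random duplex matching the study-scale smoothing window."""
    return random_duplex(300, seed=202)


def noiseless_spec(seq: gm.DuplexSequence, seed: int = 1,
                   strand: str = "forward", **over) -> gm.SimSpec:
    over.setdefault("additive_noise", 0.0)
    over.setdefault("amp_jitter", 0.0)
    return gm.make_sim_spec(seq, seed=seed, strand=strand, **over)


def pdb_atom_line(serial: int, name: str, chain: str, resseq: int,
                  x: float, y: float, z: float) -> str:
    return (f"ATOM  {serial:5d} {name:<4s} {'DA':>3s} {chain}{resseq:4d}"
            f"    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00\n")


def write_toy_duplex_pdb(path, n: int = 12, distance: float = 11.0,
                         spacing: float = 7.0, transform=None) -> None:
    """Two straight antiparallel phosphate strands.

    Paired phosphates sit exactly ``distance`` apart; all other cross-strand
    distances are larger, so the minimum is unique and known by construction.
    ``transform`` optionally maps each (3,) coordinate (rigid-body tests).
    """
    lines = []
    serial = 1
    for k in range(n):
        xyz = np.array([0.0, k * spacing, 0.0])
        if transform is not None:
            xyz = transform(xyz)
        lines.append(pdb_atom_line(serial, "P", "A", k + 1, *xyz))
        serial += 1
    for j in range(n):
        # strand B listed 5'->3'; residue j pairs with A residue n-1-j
        xyz = np.array([distance, (n - 1 - j) * spacing, 0.0])
        if transform is not None:
            xyz = transform(xyz)
        lines.append(pdb_atom_line(serial, "P", "B", j + 1, *xyz))
        serial += 1
    with open(path, "w") as fh:
        fh.writelines(lines)
        fh.write("END\n")
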